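import numpy as np
import pandas as pd
import pytest

from tmeniche.simulate import Region, TissueSpec, generate_tissue
from tmeniche.spatial import (
    classify_microenvironment,
    classify_proximity,
    classify_top_fraction,
    distance_binned_expression,
    grouped_expression,
    nearest_type_distance,
    neighborhood_composition,
    score_panel_signature,
)
from tmeniche.types import ContractError, SpatialCellTable


def _table(rows, panel=None, counts=None):
    df = pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "cell_type"])
    df["sample_id"] = "S1"
    return SpatialCellTable(
        cells=df, panel_genes=panel or [], gene_counts=counts
    )


class TestTopFraction:
    def test_distinct_scores_exact_count(self):
        scores = pd.Series(np.arange(100.0), index=[f"c{i}" for i in range(100)])
        flags = classify_top_fraction(scores, {c: "S1" for c in scores.index}, 0.10)
        assert flags.sum() == 10
        assert set(flags.index[flags]) == {f"c{i}" for i in range(90, 100)}

    def test_all_ties_all_flagged(self):
        scores = pd.Series(1.0, index=[f"c{i}" for i in range(20)])
        flags = classify_top_fraction(scores, {c: "S1" for c in scores.index})
        assert flags.all()

    def test_joint_run_equals_union_of_per_sample_runs(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=60), index=[f"c{i}" for i in range(60)])
        sample_of = {c: ("S1" if i < 30 else "S2") for i, c in enumerate(scores.index)}
        joint = classify_top_fraction(scores, sample_of, 0.2)
        for samp in ("S1", "S2"):
            ids = [c for c in scores.index if sample_of[c] == samp]
            solo = classify_top_fraction(
                scores[ids], {c: samp for c in ids}, 0.2
            )
            assert joint[ids].equals(solo)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ContractError):
            classify_top_fraction(pd.Series([1.0], index=["c"]), {"c": "S"}, 1.5)


class TestNearestDistance:
    def test_hand_example(self):
        tbl = _table(
            [("t", 0, 0, "Tfh"), ("b1", 0, 30, "B"), ("b2", 40, 0, "B")]
        )
        d = nearest_type_distance(tbl, ["t"], "B")
        assert d["t"] == pytest.approx(30.0)

    def test_no_target_gives_infinity(self):
        tbl = _table([("t", 0, 0, "Tfh"), ("x", 5, 5, "T")])
        assert np.isinf(nearest_type_distance(tbl, ["t"], "B")["t"])

    def test_self_excluded_for_target_type_index(self):
        tbl = _table([("b1", 0, 0, "B"), ("b2", 3, 4, "B")])
        assert nearest_type_distance(tbl, ["b1"], "B")["b1"] == pytest.approx(5.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 500, size=(500, 2))
        types = rng.choice(["B", "T", "Cancer"], size=500)
        tbl = _table(
            [(f"c{i}", *xy[i], types[i]) for i in range(500)]
        )
        ids = [f"c{i}" for i in range(500)]
        d = nearest_type_distance(tbl, ids, "B")
        b_pts = xy[types == "B"]
        for i in range(500):
            dists = np.linalg.norm(b_pts - xy[i], axis=1)
            if types[i] == "B":
                dists = dists[dists > 0]
            assert d[f"c{i}"] == pytest.approx(dists.min(), abs=1e-9)


class TestProximity:
    @pytest.mark.parametrize(
        "dist,expected",
        [(49.9, "close_to_B"), (50.0, "close_to_B"), (50.1, "far_from_B")],
    )
    def test_boundary_inclusive(self, dist, expected):
        tbl = _table([("t", 0, 0, "Tfh"), ("b", dist, 0, "B")])
        [lab] = classify_proximity(tbl, ["t"], threshold_um=50.0)
        assert lab.proximity_class == expected

    def test_no_b_cells_far(self):
        tbl = _table([("t", 0, 0, "Tfh")])
        [lab] = classify_proximity(tbl, ["t"])
        assert lab.proximity_class == "far_from_B"

    def test_surrounded_by_b(self):
        rows = [("t", 0, 0, "Tfh")] + [(f"b{i}", 5 + i, 0, "B") for i in range(5)]
        [lab] = classify_proximity(_table(rows), ["t"])
        assert lab.proximity_class == "close_to_B"


class TestMicroenvironment:
    def test_majority_cancer(self):
        rows = [("t", 0, 0, "Tfh")] + [
            (f"ca{i}", 10 * (i + 1), 0, "Cancer") for i in range(3)
        ] + [("b", 0, 50, "B")]
        [lab] = classify_microenvironment(_table(rows), ["t"])
        assert lab.microenv_class == "cancer_adjacent"

    def test_empty_radius_ambiguous(self):
        [lab] = classify_microenvironment(_table([("t", 0, 0, "Tfh")]), ["t"])
        assert lab.microenv_class == "ambiguous"

    def test_radius_inclusive_at_200(self):
        rows = [
            ("t", 0, 0, "Tfh"),
            ("ca1", 201, 0, "Cancer"),
            ("ca2", 0, 201, "Cancer"),
            ("b", 150, 0, "B"),
        ]
        [lab] = classify_microenvironment(_table(rows), ["t"])
        assert lab.microenv_class == "lymph_rich"

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 400, size=(200, 2))
        types = rng.choice(["Cancer", "B", "Tfh", "T"], size=200)
        tfh = [f"c{i}" for i in np.flatnonzero(types == "Tfh")]
        tbl = _table([(f"c{i}", *xy[i], types[i]) for i in range(200)])
        base = [l.microenv_class for l in classify_microenvironment(tbl, tfh)]
        theta = 0.73
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        xy2 = xy @ rot.T + np.array([1000.0, -300.0])
        tbl2 = _table([(f"c{i}", *xy2[i], types[i]) for i in range(200)])
        moved = [l.microenv_class for l in classify_microenvironment(tbl2, tfh)]
        assert base == moved

    def test_recovers_truth_regions_on_generated_tissue(self):
        """Tfh deep inside a cancer nest classify cancer_adjacent, deep
        inside a lymphoid aggregate lymph_rich (>=95% for unambiguous
        placements far from the opposite region)."""
        spec = TissueSpec(
            field_width_um=1400,
            field_height_um=500,
            nests=[Region(250, 250, 150)],
            aggregates=[Region(1150, 250, 150)],
            seed=6,
        )
        tbl = generate_tissue(spec)
        cells = tbl.cells
        tfh = cells[cells["cell_type"] == "Tfh"]
        in_region = tfh[tfh["truth_region"] != "background"]
        labels = classify_microenvironment(tbl, in_region["cell_id"].tolist())
        truth = dict(zip(in_region["cell_id"], in_region["truth_region"]))
        expect = {"nest": "cancer_adjacent", "aggregate": "lymph_rich"}
        hits = sum(
            l.microenv_class == expect[truth[l.cell_id]] for l in labels
        )
        assert len(labels) >= 10
        assert hits / len(labels) >= 0.95


class TestNeighborhood:
    def test_hand_geometry(self):
        rows = [
            ("t", 0, 0, "Tfh"),
            ("b1", 10, 0, "B"),
            ("b2", 29, 0, "B"),
            ("m1", 20, 20, "Macro"),   # ~28.28
            ("ca", 31, 0, "Cancer"),
        ]
        profiles, _ = neighborhood_composition(_table(rows), ["t"], radius_um=30)
        [p] = profiles
        assert p.counts == {"B": 2, "Macro": 1}
        assert p.fractions == pytest.approx({"B": 2 / 3, "Macro": 1 / 3})

    def test_isolated_cell_flagged_empty(self):
        profiles, mean_comp = neighborhood_composition(
            _table([("t", 0, 0, "Tfh")]), ["t"], radius_um=30
        )
        assert profiles[0].counts == {} and profiles[0].fractions == {}
        assert mean_comp.empty

    def test_brute_force_oracle_and_fraction_sum(self):
        rng = np.random.default_rng(3)
        n = 1000
        xy = rng.uniform(0, 600, size=(n, 2))
        types = rng.choice(["B", "T", "Cancer", "Macro"], size=n)
        tbl = _table([(f"c{i}", *xy[i], types[i]) for i in range(n)])
        idx = [f"c{i}" for i in range(0, n, 37)]
        profiles, _ = neighborhood_composition(tbl, idx, radius_um=30)
        for p in profiles:
            i = int(p.cell_id[1:])
            d = np.linalg.norm(xy - xy[i], axis=1)
            mask = (d <= 30) & (np.arange(n) != i)
            expect = pd.Series(types[mask]).value_counts().to_dict()
            assert p.counts == expect
            if p.fractions:
                assert sum(p.fractions.values()) == pytest.approx(1.0)


class TestGroupedExpression:
    @staticmethod
    def _panel_table(n=60, seed=0):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 100, size=(n, 2))
        counts = rng.poisson(5, size=(3, n))
        return _table(
            [(f"c{i}", *xy[i], "Tfh") for i in range(n)],
            panel=["gA", "gB", "gC"],
            counts=counts,
        ), counts

    def test_zscore_algebra(self):
        tbl, _ = self._panel_table()
        ids = tbl.cells["cell_id"].tolist()
        groups = {c: ("G1" if i < 20 else "G2") for i, c in enumerate(ids)}
        means = grouped_expression(tbl, groups)
        sizes = pd.Series(groups).value_counts()
        weighted = (means.T * sizes[means.index]).T.sum(axis=0) / sizes.sum()
        np.testing.assert_allclose(weighted.to_numpy(), 0.0, atol=1e-9)

    def test_identical_groups_identical_means(self):
        tbl, _ = self._panel_table()
        ids = tbl.cells["cell_id"].tolist()
        g1 = grouped_expression(tbl, {c: "A" for c in ids})
        g2 = grouped_expression(tbl, {c: "B" for c in ids})
        np.testing.assert_allclose(g1.to_numpy(), g2.to_numpy(), atol=1e-12)

    def test_planted_group_difference(self):
        rng = np.random.default_rng(5)
        n = 80
        xy = rng.uniform(0, 100, size=(n, 2))
        counts = rng.poisson(5, size=(2, n))
        counts[0, :40] = rng.poisson(25, size=40)  # gA 5x higher in group A
        tbl = _table(
            [(f"c{i}", *xy[i], "Tfh") for i in range(n)],
            panel=["gA", "gB"],
            counts=counts,
        )
        groups = {f"c{i}": ("A" if i < 40 else "B") for i in range(n)}
        means = grouped_expression(tbl, groups)
        assert means.loc["A", "gA"] > means.loc["B", "gA"]


class TestDistanceBins:
    def test_single_bin_when_all_close(self):
        rows = [("m", 10, 0, "Macro"), ("ca", 0, 0, "Cancer")]
        tbl = _table(rows, panel=["CXCL10"], counts=np.array([[3, 0]]))
        out = distance_binned_expression(tbl, ["m"], "Cancer", "CXCL10")
        assert len(out) == 1
        assert out.loc[0, "bin_low_um"] == 0 and out.loc[0, "n"] == 1

    def test_constant_gene_constant_means(self):
        rng = np.random.default_rng(7)
        rows = [("ca", 0, 0, "Cancer")] + [
            (f"m{i}", 10 + 20 * i, 0, "Macro") for i in range(10)
        ]
        counts = np.vstack([np.full(11, 4), np.full(11, 7)])
        tbl = _table(rows, panel=["gX", "total_pad"], counts=counts)
        out = distance_binned_expression(tbl, [f"m{i}" for i in range(10)], "Cancer", "gX")
        nonempty = out.dropna(subset=["mean_expression"])
        assert nonempty["mean_expression"].nunique() == 1

    def test_planted_decay_recovered(self):
        """Expression decaying with distance from cancer cells yields
        decreasing bin means (negative Spearman) in >=19/20 seeds."""
        from scipy.stats import spearmanr

        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 150
            x = rng.uniform(0, 300, size=n)
            rows = [("ca", 0.0, 0.0, "Cancer")] + [
                (f"m{i}", x[i], 0.0, "Macro") for i in range(n)
            ]
            lam = 20 * np.exp(-x / 100)
            counts = np.concatenate([[5], rng.poisson(lam)])[None, :]
            pad = np.full((1, n + 1), 10)
            tbl = _table(rows, panel=["gX", "pad"], counts=np.vstack([counts, pad]))
            out = distance_binned_expression(
                tbl, [f"m{i}" for i in range(n)], "Cancer", "gX"
            )
            ok = out.dropna(subset=["mean_expression"])
            rho = spearmanr(ok["bin_low_um"], ok["mean_expression"]).statistic
            wins += rho < 0
        assert wins >= 19


def test_panel_scoring_prefers_tfh(tissue):
    scores = score_panel_signature(tissue)
    meta = tissue.cells.set_index("cell_id")
    tfh_scores = scores[meta.loc[scores.index, "cell_type"] == "Tfh"]
    t_scores = scores[meta.loc[scores.index, "cell_type"] == "T"]
    assert tfh_scores.mean() > t_scores.mean()
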