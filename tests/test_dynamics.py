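import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmeniche.dynamics import (
    baseline_proportion_test,
    classify_response_genes,
    de_wilcoxon,
    expansion_bias,
    paired_log2fc,
    rank_sum_test,
    subset_frequencies,
    tfh_ratio_delta,
)
from tmeniche.simulate import CohortSpec, generate_repertoire_cohort
from tmeniche.types import CellRecord, CohortDesign, MultimodalDataset


def _meta(counts):
    """counts: {(patient, timepoint, subset): n} -> one-row-per-cell frame."""
    rows = []
    i = 0
    for (pid, tp, sub), n in counts.items():
        for _ in range(n):
            rows.append({"cell_id": f"c{i}", "patient_id": pid,
                         "timepoint": tp, "subset_label": sub})
            i += 1
    return pd.DataFrame(rows)


def _design(groups):
    return CohortDesign(
        response_group=groups, timepoints={p: {"pre", "on"} for p in groups}
    )


class TestFrequencies:
    def test_no_pseudocount(self):
        meta = _meta({("P1", "pre", "A"): 5, ("P1", "pre", "B"): 15})
        f = subset_frequencies(meta, pseudocount=0.0)
        assert f.set_index("subset_label")["frequency"].to_dict() == pytest.approx(
            {"A": 0.25, "B": 0.75}
        )

    def test_pseudocount_on_absent_subset(self):
        meta = _meta({("P1", "pre", "B"): 10})
        f = subset_frequencies(meta, pseudocount=0.5, subsets=["A", "B"])
        vals = f.set_index("subset_label")["frequency"]
        assert vals["A"] == pytest.approx(0.5 / 11)
        assert vals["B"] == pytest.approx(10.5 / 11)

    def test_frequencies_sum_to_one(self, cohort):
        _, _, ds = cohort
        meta = ds.cell_table().rename(columns={"cluster_label": "subset_label"})
        f = subset_frequencies(meta)
        sums = f.groupby(["patient_id", "timepoint"])["frequency"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestPairedFC:
    def test_doubling_gives_one(self):
        meta = _meta(
            {("P1", "pre", "A"): 5, ("P1", "pre", "B"): 95,
             ("P1", "on", "A"): 10, ("P1", "on", "B"): 90}
        )
        f = subset_frequencies(meta, pseudocount=0.0)
        fc = paired_log2fc(f, _design({"P1": "expander"}))
        a = fc[fc["subset_label"] == "A"]["log2fc"].iloc[0]
        assert a == pytest.approx(1.0)

    def test_identical_timepoints_zero(self):
        meta = _meta(
            {("P1", "pre", "A"): 7, ("P1", "pre", "B"): 3,
             ("P1", "on", "A"): 7, ("P1", "on", "B"): 3}
        )
        f = subset_frequencies(meta)
        fc = paired_log2fc(f, _design({"P1": "non_expander"}))
        np.testing.assert_allclose(fc["log2fc"], 0.0, atol=1e-12)

    def test_zero_count_finite_with_pseudocount(self):
        meta = _meta(
            {("P1", "pre", "B"): 100,
             ("P1", "on", "A"): 8, ("P1", "on", "B"): 92}
        )
        f = subset_frequencies(meta, pseudocount=0.5, subsets=["A", "B"])
        fc = paired_log2fc(f, _design({"P1": "expander"}))
        assert np.isfinite(fc["log2fc"]).all()

    def test_incomplete_patients_excluded(self):
        meta = _meta({("P1", "pre", "A"): 5, ("P2", "pre", "A"): 5,
                      ("P2", "on", "A"): 5})
        design = CohortDesign(
            response_group={"P1": "expander", "P2": "expander"},
            timepoints={"P1": {"pre"}, "P2": {"pre", "on"}},
        )
        fc = paired_log2fc(subset_frequencies(meta), design)
        assert set(fc["patient_id"]) == {"P2"}


class TestExpansionBias:
    def test_arithmetic(self):
        fcs = pd.DataFrame(
            {
                "patient_id": ["P1", "P2", "P3", "P4"],
                "subset_label": "S",
                "log2fc": [1.0, 0.5, -0.5, 0.0],
                "response_group": ["expander", "expander", "non_expander", "non_expander"],
            }
        )
        out = expansion_bias(fcs, _design({}))
        assert out.loc[0, "delta"] == pytest.approx(1.0)

    def test_identical_groups_delta_zero_p_one(self):
        fcs = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(4)],
                "subset_label": "S",
                "log2fc": [0.3, 0.7, 0.3, 0.7],
                "response_group": ["expander", "expander", "non_expander", "non_expander"],
            }
        )
        out = expansion_bias(fcs, _design({}))
        assert out.loc[0, "delta"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_exact_rank_sum_fully_separated(self):
        """3-vs-3 fully separated ranks: exact two-sided p = 2/20 = 0.1."""
        assert rank_sum_test([3, 4, 5], [0, 1, 2]) == pytest.approx(0.1)


class TestDE:
    @staticmethod
    def _dataset(rna, subset="S", group="expander", split=None):
        n = rna.shape[1]
        split = split if split is not None else n // 2
        cells = [
            CellRecord(
                cell_id=f"c{i}",
                patient_id="P1",
                timepoint="pre" if i < split else "on",
                response_group=group,
                cluster_label=subset,
            )
            for i in range(n)
        ]
        return MultimodalDataset(
            rna, np.ones((1, n), dtype=int),
            [f"g{i}" for i in range(rna.shape[0])], ["a0"], cells,
        )

    def test_identical_sides_nothing_significant(self):
        rng = np.random.default_rng(0)
        half = rng.poisson(5, size=(50, 40))
        rna = np.concatenate([half, half], axis=1)
        de = de_wilcoxon(self._dataset(rna), "S", "expander")
        assert not de["significant"].any()

    def test_alpha_zero_nothing_significant(self):
        rng = np.random.default_rng(1)
        rna = rng.poisson(5, size=(30, 60))
        de = de_wilcoxon(self._dataset(rna), "S", "expander", alpha=0.0)
        assert not de["significant"].any()

    def test_small_side_skipped(self):
        rna = np.ones((5, 4), dtype=int)
        de = de_wilcoxon(self._dataset(rna, split=2), "S", "expander")
        assert de.empty

    def test_null_pvalues_uniform(self):
        """Rank-sum p-values on exchangeable data pass a KS test against
        U(0,1) (200 null genes)."""
        rng = np.random.default_rng(3)
        rna = rng.poisson(20, size=(200, 100))
        de = de_wilcoxon(self._dataset(rna), "S", "expander")
        ks = stats.kstest(de["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_four_fold_recovered(self):
        """20 genes with a planted 4-fold on-treatment shift out of 200,
        100 cells per side: sensitivity >= 0.9, false positives within
        the BH-controlled level (aggregated over 20 seeds)."""
        sens = []
        fps = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            mu = np.exp(rng.normal(0.0, 0.5, size=200))
            # planted genes kept low-abundance so the library-size shift
            # from the 4-fold effect stays negligible
            mu[:20] = 0.15
            pre = rng.poisson(np.tile(mu[:, None], (1, 100)))
            mu_on = mu.copy()
            mu_on[:20] *= 4.0
            on = rng.poisson(np.tile(mu_on[:, None], (1, 100)))
            rna = np.concatenate([pre, on], axis=1)
            de = de_wilcoxon(self._dataset(rna), "S", "expander")
            called = set(de.loc[de["significant"], "gene"])
            truth = {f"g{i}" for i in range(20)}
            sens.append(len(called & truth) / 20)
            fps += len(called - truth)
        assert np.mean(sens) >= 0.9
        # 20 seeds x 180 null genes at FDR 0.05 with |lfc| gate
        assert fps <= 0.05 * 20 * 200


class TestClassifyResponseGenes:
    @staticmethod
    def _run(rows):
        return pd.DataFrame(
            rows, columns=["gene", "lfc", "p_value", "p_adj", "significant"]
        )

    def test_rule_application(self):
        e = self._run(
            [("g1", 0.5, 0.001, 0.01, True), ("g2", 0.5, 0.001, 0.01, True),
             ("g3", 0.5, 0.001, 0.01, True), ("g4", 0.1, 0.5, 0.9, False)]
        )
        n = self._run(
            [("g1", 0.2, 0.4, 0.5, False), ("g2", 0.4, 0.001, 0.01, True),
             ("g3", -0.5, 0.001, 0.01, True), ("g4", 0.9, 0.001, 0.01, True)]
        )
        rec, _ = classify_response_genes(e, n)
        cats = rec.set_index("gene")["category"].to_dict()
        assert cats == {
            "g1": "Expander_Specific",
            "g2": "Shared",
            "g3": "Discordant",
            "g4": "NonExpander_Specific",
        }

    def test_categories_partition_universe(self, cohort):
        _, _, ds = cohort
        e = de_wilcoxon(ds, "Tfh_LAG3", "expander")
        n = de_wilcoxon(ds, "Tfh_LAG3", "non_expander")
        rec, _ = classify_response_genes(e, n)
        assert len(rec) == len(e)
        assert rec["category"].notna().all()

    def test_deg_ratio(self):
        e = self._run([(f"g{i}", 0.5, 0.001, 0.01, i < 60) for i in range(100)])
        n = self._run([(f"g{i}", 0.5, 0.001, 0.01, i < 10) for i in range(100)])
        _, st_out = classify_response_genes(e, n)
        assert st_out["deg_ratio"] == pytest.approx(6.0)


class TestRatioDelta:
    def test_hand_arithmetic(self):
        meta = _meta(
            {("P1", "pre", "NUM"): 10, ("P1", "pre", "DEN"): 20,
             ("P1", "on", "NUM"): 30, ("P1", "on", "DEN"): 15}
        )
        per, _ = tfh_ratio_delta(meta, _design({"P1": "expander"}), "NUM", "DEN")
        row = per.iloc[0]
        assert row["ratio_pre"] == pytest.approx(10.5 / 20.5)
        assert row["ratio_on"] == pytest.approx(30.5 / 15.5)
        assert row["delta"] == pytest.approx(30.5 / 15.5 - 10.5 / 20.5)

    def test_identical_counts_zero_delta(self):
        meta = _meta(
            {("P1", "pre", "NUM"): 5, ("P1", "pre", "DEN"): 7,
             ("P1", "on", "NUM"): 5, ("P1", "on", "DEN"): 7}
        )
        per, _ = tfh_ratio_delta(meta, _design({"P1": "expander"}), "NUM", "DEN")
        assert per.iloc[0]["delta"] == pytest.approx(0.0)


class TestBaseline:
    def test_equal_means_fc_one(self):
        meta = _meta(
            {("P1", "pre", "A"): 10, ("P1", "pre", "B"): 10,
             ("P2", "pre", "A"): 10, ("P2", "pre", "B"): 10,
             ("P3", "pre", "A"): 10, ("P3", "pre", "B"): 10,
             ("P4", "pre", "A"): 10, ("P4", "pre", "B"): 10}
        )
        design = _design({"P1": "expander", "P2": "expander",
                          "P3": "non_expander", "P4": "non_expander"})
        out = baseline_proportion_test(subset_frequencies(meta), design)
        np.testing.assert_allclose(out["fc_of_means"], 1.0)
        np.testing.assert_allclose(out["p_value"], 1.0)

    def test_fc_arithmetic(self):
        freqs = pd.DataFrame(
            {
                "patient_id": ["P1", "P2", "P3", "P4"],
                "timepoint": "pre",
                "subset_label": "S",
                "n_cells": 1,
                "frequency": [0.2, 0.3, 0.1, 0.1],
            }
        )
        design = _design({"P1": "expander", "P2": "expander",
                          "P3": "non_expander", "P4": "non_expander"})
        out = baseline_proportion_test(freqs, design)
        assert out.loc[0, "fc_of_means"] == pytest.approx(2.5)


class TestEndToEndRecovery:
    def test_planted_expander_doubling_recovered(self):
        """Planted on-treatment doubling of Tfh_LAG3 in expanders only:
        expansion-bias delta positive and tfh-ratio deltas ordered
        expander > non-expander in >=19/20 seeds; null subsets show
        small mean |delta|."""
        bias_wins = ratio_wins = 0
        null_deltas = []
        for seed in range(20):
            clono, design, ds = generate_repertoire_cohort(
                CohortSpec(seed=300 + seed, n_genes=30)
            )
            meta = ds.cell_table().rename(columns={"cluster_label": "subset_label"})
            freqs = subset_frequencies(meta)
            fcs = paired_log2fc(freqs, design)
            bias = expansion_bias(fcs, design).set_index("subset_label")
            bias_wins += bias.loc["Tfh_LAG3", "delta"] > 0
            null_deltas.append(abs(bias.loc["CD8_GZMK", "delta"]))
            per, comp = tfh_ratio_delta(meta, design, "Tfh_LAG3", "Tfh_IGFL2")
            med = per.groupby("response_group")["delta"].median()
            ratio_wins += med["expander"] > med["non_expander"]
        assert bias_wins >= 19
        assert ratio_wins >= 19
        assert np.mean(null_deltas) < 0.25

    def test_statistics_invariant_to_patient_order(self, cohort):
        _, design, ds = cohort
        meta = ds.cell_table().rename(columns={"cluster_label": "subset_label"})
        f1 = subset_frequencies(meta)
        shuffled = meta.sample(frac=1.0, random_state=0)
        f2 = subset_frequencies(shuffled)
        b1 = expansion_bias(paired_log2fc(f1, design), design)
        b2 = expansion_bias(paired_log2fc(f2, design), design)
        pd.testing.assert_frame_equal(b1, b2)
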