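"""Synthetic data with planted structure for every pipeline stage.

Three generators emulate the study's data shapes without any download:

* :func:`generate_multimodal` — clustered negative-binomial RNA plus
  background-and-signal ADT counts, with a spiked-in fraction of mouse
  control cells (the study spiked ~3% 3T3 mouse cells per sample) and a
  configurable tail of high-mitochondrial cells.
* :func:`generate_tissue` — a tissue point pattern with cancer nests,
  B-cell-rich lymphoid aggregates and scattered immune cells, sampled as
  thinned homogeneous Poisson processes per region.
* :func:`generate_repertoire_cohort` — a paired pre/on-treatment cohort
  with expander/non-expander patients, planted subset-frequency shifts,
  clonal expansion, inter-subset clonotype sharing, and
  treatment-response genes.

Truth labels are always emitted next to the data so downstream recovery
can be asserted.  Same spec + same seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    CellRecord,
    ClonotypeTable,
    CohortDesign,
    MultimodalDataset,
    SpatialCellTable,
    TmenicheError,
)

__all__ = [
    "SimSpec",
    "TissueSpec",
    "Region",
    "CohortSpec",
    "generate_multimodal",
    "generate_tissue",
    "generate_repertoire_cohort",
]


class SpecError(TmenicheError):
    pass


# ---------------------------------------------------------------------------
# multimodal CITE-seq-like data


@dataclass
class SimSpec:
    """Parameters for the clustered RNA+ADT generator.

    RNA counts are negative binomial with gene-level means and a single
    dispersion; ADT counts are Poisson background plus lognormal-scaled
    Poisson signal for the planted cluster markers.
    """

    n_cells: int = 2000
    n_genes: int = 200
    n_adts: int = 30
    n_clusters: int = 4
    n_samples: int = 1
    marker_genes_per_cluster: int = 5
    gene_marker_fold: float = 4.0
    marker_adts_per_cluster: int = 2
    adt_marker_fold: float = 10.0
    nb_dispersion: float = 2.0        # NB theta; var = mu + mu^2/theta
    adt_background_rate: float = 20.0
    adt_signal_sigma: float = 0.25    # lognormal sd of the marker signal scale
    mouse_spike_fraction: float = 0.03
    ambiguous_fraction: float = 0.02  # planted mouse_fraction in (0.10, 0.95)
    mito_tail_fraction: float = 0.05  # planted mito_fraction above 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters > self.n_cells:
            raise SpecError("n_clusters > n_cells")
        for name in ("mouse_spike_fraction", "ambiguous_fraction", "mito_tail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name}={v} outside [0, 1]")
        if self.marker_genes_per_cluster and self.gene_marker_fold <= 1:
            raise SpecError("gene_marker_fold must be > 1 for planted markers")
        if self.marker_adts_per_cluster and self.adt_marker_fold <= 1:
            raise SpecError("adt_marker_fold must be > 1 for planted markers")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    # numpy parametrizes NB by (n, p); mean mu, shape theta -> p = theta/(theta+mu)
    mean = np.maximum(mean, 1e-12)
    return rng.negative_binomial(theta, theta / (theta + mean))


def generate_multimodal(spec: SimSpec) -> Tuple[MultimodalDataset, pd.DataFrame]:
    """Generate a clustered multimodal dataset plus its truth table.

    Returns ``(dataset, truth)`` where ``truth`` has one row per cell with
    the planted cluster and QC-category labels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    clusters = rng.integers(0, spec.n_clusters, size=spec.n_cells)
    samples = rng.integers(0, spec.n_samples, size=spec.n_cells)

    base_mu = np.exp(rng.normal(0.0, 1.0, size=spec.n_genes))  # gene means
    marker_genes: Dict[int, np.ndarray] = {}
    gene_pool = rng.permutation(spec.n_genes)
    for k in range(spec.n_clusters):
        lo = k * spec.marker_genes_per_cluster
        marker_genes[k] = gene_pool[lo : lo + spec.marker_genes_per_cluster]
    mu = np.tile(base_mu[:, None], (1, spec.n_cells))
    for k, genes in marker_genes.items():
        mu[np.ix_(genes, np.flatnonzero(clusters == k))] *= spec.gene_marker_fold
    rna = _nb_sample(rng, mu, spec.nb_dispersion)

    marker_adts: Dict[int, np.ndarray] = {}
    adt_pool = rng.permutation(spec.n_adts)
    for k in range(spec.n_clusters):
        lo = k * spec.marker_adts_per_cluster
        marker_adts[k] = adt_pool[lo : lo + spec.marker_adts_per_cluster]
    adt = rng.poisson(spec.adt_background_rate, size=(spec.n_adts, spec.n_cells))
    for k, adts in marker_adts.items():
        idx = np.flatnonzero(clusters == k)
        if idx.size == 0 or adts.size == 0:
            continue
        scale = np.exp(rng.normal(0.0, spec.adt_signal_sigma, size=(adts.size, idx.size)))
        rate = spec.adt_background_rate * (spec.adt_marker_fold - 1.0) * scale
        adt[np.ix_(adts, idx)] += rng.poisson(rate)

    # planted QC categories: mouse spikes, ambiguous-species band, high mito
    category = np.array(["clean"] * spec.n_cells, dtype=object)
    u = rng.random(spec.n_cells)
    is_mouse = u < spec.mouse_spike_fraction
    is_ambig = (~is_mouse) & (u < spec.mouse_spike_fraction + spec.ambiguous_fraction)
    category[is_mouse] = "mouse"
    category[is_ambig] = "ambiguous"
    mouse_frac = rng.uniform(0.0, 0.05, size=spec.n_cells)
    mouse_frac[is_mouse] = rng.uniform(0.95, 1.0, size=int(is_mouse.sum()))
    mouse_frac[is_ambig] = rng.uniform(0.15, 0.90, size=int(is_ambig.sum()))

    v = rng.random(spec.n_cells)
    hi_mito = (~is_mouse) & (~is_ambig) & (v < spec.mito_tail_fraction)
    category[hi_mito] = "high_mito"
    mito = rng.beta(2.0, 28.0, size=spec.n_cells)  # bulk well below 0.25
    mito = np.minimum(mito, 0.24)
    mito[hi_mito] = rng.uniform(0.26, 0.60, size=int(hi_mito.sum()))

    cells = [
        CellRecord(
            cell_id=f"cell{i:05d}",
            sample_id=f"S{samples[i] + 1}",
            cluster_label=f"C{clusters[i]}",
            mito_fraction=float(mito[i]),
            mouse_fraction=float(mouse_frac[i]),
        )
        for i in range(spec.n_cells)
    ]
    ds = MultimodalDataset(
        rna_counts=rna,
        adt_counts=adt,
        gene_ids=[f"G{j:04d}" for j in range(spec.n_genes)],
        adt_ids=[f"ADT{j:03d}" for j in range(spec.n_adts)],
        cells=cells,
    )
    truth = pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "true_cluster": [f"C{k}" for k in clusters],
            "qc_category": category,
            "marker_genes": [
                ";".join(f"G{g:04d}" for g in marker_genes[k]) for k in clusters
            ],
            "marker_adts": [
                ";".join(f"ADT{a:03d}" for a in marker_adts[k]) for k in clusters
            ],
        }
    )
    return ds, truth


# ---------------------------------------------------------------------------
# tissue point patterns


@dataclass
class Region:
    """A disc-shaped tissue region (cancer nest or lymphoid aggregate)."""

    x_um: float
    y_um: float
    radius_um: float


DEFAULT_MIXTURES = {
    "nest": {"Cancer": 0.70, "T": 0.10, "Tfh": 0.05, "Macrophage": 0.12, "B": 0.0, "Other": 0.03},
    "aggregate": {"Cancer": 0.02, "T": 0.25, "Tfh": 0.08, "Macrophage": 0.05, "B": 0.55, "Other": 0.05},
    "background": {"Cancer": 0.05, "T": 0.30, "Tfh": 0.02, "Macrophage": 0.18, "B": 0.05, "Other": 0.40},
}

# per-type Poisson rates for a small marker panel; "default" is the
# off-target ambient rate
DEFAULT_PANEL_RATES = {
    "CD4": {"T": 2.0, "Tfh": 3.0, "default": 0.05},
    "CXCL13": {"Tfh": 4.0, "default": 0.05},
    "BCL6": {"Tfh": 2.5, "B": 0.5, "default": 0.05},
    "CD19": {"B": 4.0, "default": 0.05},
    "EPCAM": {"Cancer": 5.0, "default": 0.05},
    "CD68": {"Macrophage": 4.0, "default": 0.05},
    "CXCL10": {"Macrophage": 2.0, "default": 0.05},
    "TCF7": {"T": 1.0, "Tfh": 1.0, "default": 0.05},
}


@dataclass
class TissueSpec:
    """Parameters for the tissue point-pattern generator (coordinates in μm)."""

    field_width_um: float = 1000.0
    field_height_um: float = 1000.0
    nests: List[Region] = field(default_factory=lambda: [Region(250.0, 250.0, 150.0)])
    aggregates: List[Region] = field(default_factory=lambda: [Region(750.0, 750.0, 120.0)])
    background_density: float = 5e-4      # cells / μm^2 outside regions
    region_density: float = 3e-3          # cells / μm^2 inside nests/aggregates
    mixtures: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MIXTURES.items()}
    )
    panel_rates: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in DEFAULT_PANEL_RATES.items()}
    )
    sample_id: str = "X1"
    seed: int = 0

    def validate(self) -> None:
        for reg in self.nests + self.aggregates:
            if not (
                reg.radius_um <= reg.x_um <= self.field_width_um - reg.radius_um
                and reg.radius_um <= reg.y_um <= self.field_height_um - reg.radius_um
            ):
                raise SpecError(f"region at ({reg.x_um}, {reg.y_um}) leaves the field")
        for kind, mix in self.mixtures.items():
            total = sum(mix.values())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise SpecError(f"{kind} mixture weights sum to {total}, not 1")
        if self.background_density < 0 or self.region_density < 0:
            raise SpecError("densities must be nonnegative")


def _region_of(x: np.ndarray, y: np.ndarray, spec: TissueSpec) -> np.ndarray:
    """Region kind at each location; nests shadow aggregates shadow background."""
    kind = np.array(["background"] * len(x), dtype=object)
    for reg in spec.aggregates:
        inside = (x - reg.x_um) ** 2 + (y - reg.y_um) ** 2 <= reg.radius_um**2
        kind[inside] = "aggregate"
    for reg in spec.nests:
        inside = (x - reg.x_um) ** 2 + (y - reg.y_um) ** 2 <= reg.radius_um**2
        kind[inside] = "nest"
    return kind


def generate_tissue(spec: TissueSpec) -> SpatialCellTable:
    """Sample a tissue point pattern with typed cells and panel counts.

    Cells arise from a homogeneous Poisson process per region (uniform in
    a disc for nests/aggregates, uniform over the field thinned to the
    background elsewhere); each cell's type is drawn from the mixture of
    the region containing its location.  The truth region is stored in a
    ``truth_region`` column.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    xs, ys = [], []

    # background process over the whole field, thinned out of dense regions
    area = spec.field_width_um * spec.field_height_um
    n_bg = rng.poisson(spec.background_density * area)
    bx = rng.uniform(0, spec.field_width_um, n_bg)
    by = rng.uniform(0, spec.field_height_um, n_bg)
    keep = _region_of(bx, by, spec) == "background"
    xs.append(bx[keep])
    ys.append(by[keep])

    for reg in spec.nests + spec.aggregates:
        n = rng.poisson(spec.region_density * math.pi * reg.radius_um**2)
        r = reg.radius_um * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * math.pi, n)
        xs.append(reg.x_um + r * np.cos(th))
        ys.append(reg.y_um + r * np.sin(th))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size == 0:
        import warnings

        warnings.warn("zero density produced an empty tissue table")
    kinds = _region_of(x, y, spec)

    type_names = sorted({t for mix in spec.mixtures.values() for t in mix})
    cell_types = np.empty(x.size, dtype=object)
    for kind in ("nest", "aggregate", "background"):
        idx = np.flatnonzero(kinds == kind)
        if idx.size == 0:
            continue
        mix = spec.mixtures[kind]
        probs = np.array([mix.get(t, 0.0) for t in type_names])
        cell_types[idx] = np.array(type_names, dtype=object)[
            rng.choice(len(type_names), size=idx.size, p=probs / probs.sum())
        ]

    panel = sorted(spec.panel_rates)
    counts = np.zeros((len(panel), x.size), dtype=int)
    for gi, gene in enumerate(panel):
        rates = spec.panel_rates[gene]
        lam = np.array([rates.get(t, rates.get("default", 0.0)) for t in cell_types])
        counts[gi] = rng.poisson(lam)

    cells = pd.DataFrame(
        {
            "cell_id": [f"{spec.sample_id}_c{i:05d}" for i in range(x.size)],
            "sample_id": spec.sample_id,
            "x_um": x,
            "y_um": y,
            "cell_type": cell_types,
            "truth_region": kinds,
        }
    )
    return SpatialCellTable(cells=cells, panel_genes=panel, gene_counts=counts)


# ---------------------------------------------------------------------------
# paired treatment cohort with TCR structure


@dataclass
class CohortSpec:
    """Parameters for the paired pre/on-treatment repertoire cohort.

    ``on_multiplier`` maps (subset, response_group) to the multiplicative
    shift applied to the subset's baseline frequency on treatment;
    ``response_genes`` plants per-gene log2 expression shifts on
    treatment for cells of a (subset, response_group); ``sharing`` is the
    symmetric probability matrix that a clonotype seeds cells in a second
    subset.
    """

    n_patients: int = 12
    expander_fraction: float = 1 / 3
    cells_per_sample: int = 300
    subsets: Tuple[str, ...] = ("Tfh_LAG3", "Tfh_IGFL2", "CD8_Tex", "CD8_GZMK", "Treg")
    baseline_freqs: Tuple[float, ...] = (0.15, 0.15, 0.20, 0.30, 0.20)
    on_multiplier: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Tfh_LAG3", "expander"): 2.0,
            ("Tfh_IGFL2", "non_expander"): 1.5,
        }
    )
    # geometric clone-size parameter per subset; the expected expanded cell
    # fraction is 1 - p^2, so these defaults put the cytotoxic Tfh and
    # exhausted CD8 compartments near ~62% / ~73% expanded cells and the
    # helper IGFL2-like Tfh near ~36%
    clone_geom_p: Dict[str, float] = field(
        default_factory=lambda: {
            "Tfh_LAG3": 0.613,
            "CD8_Tex": 0.520,
            "Tfh_IGFL2": 0.803,
            "default": 0.85,
        }
    )
    sharing: Optional[np.ndarray] = None  # subsets x subsets, symmetric, unit diag
    n_genes: int = 120
    n_adts: int = 5
    nb_dispersion: float = 2.0
    # (subset, response_group) -> (number of planted genes, log2 shift on treatment)
    response_genes: Dict[Tuple[str, str], Tuple[int, float]] = field(
        default_factory=lambda: {
            ("Tfh_LAG3", "expander"): (12, 2.0),
            ("Tfh_LAG3", "non_expander"): (2, 2.0),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.baseline_freqs) - 1.0) > 1e-9:
            raise SpecError("baseline_freqs must sum to 1")
        if len(self.baseline_freqs) != len(self.subsets):
            raise SpecError("one baseline frequency per subset")
        if self.sharing is not None:
            s = np.asarray(self.sharing, dtype=float)
            k = len(self.subsets)
            if s.shape != (k, k):
                raise SpecError("sharing matrix shape mismatch")
            if not np.allclose(s, s.T):
                raise SpecError("sharing matrix must be symmetric")
            if not np.allclose(np.diag(s), 1.0):
                raise SpecError("sharing matrix diagonal must be 1")


def _draw_clonotypes(
    rng: np.random.Generator, n_cells: int, p: float, prefix: str
) -> List[str]:
    """Partition ``n_cells`` cells into clones with geometric sizes."""
    ids: List[str] = []
    k = 0
    while len(ids) < n_cells:
        size = int(rng.geometric(p))
        ids.extend([f"{prefix}_cl{k:04d}"] * size)
        k += 1
    return ids[:n_cells]


def generate_repertoire_cohort(
    spec: CohortSpec,
) -> Tuple[ClonotypeTable, CohortDesign, MultimodalDataset]:
    """Generate a paired cohort: clonotypes, design, and expression data.

    Per patient and timepoint, cells are assigned to subsets at baseline
    frequencies (shifted on treatment per ``on_multiplier`` for the
    patient's response group); clonotype ids follow per-subset geometric
    size laws; with the probability given by ``sharing`` a clonotype from
    one subset replaces a clonotype of another subset within the same
    patient.  RNA counts carry planted treatment-response genes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_exp = int(round(spec.n_patients * spec.expander_fraction))
    groups = {}
    for i in range(spec.n_patients):
        groups[f"P{i + 1:02d}"] = "expander" if i < n_exp else "non_expander"
    design = CohortDesign(
        response_group=groups, timepoints={p: {"pre", "on"} for p in groups}
    )

    share = (
        np.eye(len(spec.subsets))
        if spec.sharing is None
        else np.asarray(spec.sharing, dtype=float)
    )
    base_mu = np.exp(rng.normal(0.0, 1.0, size=spec.n_genes))
    # disjoint planted gene sets per (subset, group) effect; planted genes
    # get a modest fixed base abundance so the treatment shift stays
    # gene-specific rather than moving whole library sizes
    total_planted = sum(n for n, _ in spec.response_genes.values())
    pool = rng.choice(spec.n_genes, size=total_planted, replace=False)
    base_mu[pool] = 0.3
    resp_genes: Dict[Tuple[str, str], np.ndarray] = {}
    offset = 0
    for key in sorted(spec.response_genes):
        n, _ = spec.response_genes[key]
        resp_genes[key] = pool[offset : offset + n]
        offset += n

    rows = []
    cells: List[CellRecord] = []
    mu_cols = []
    for pid in sorted(groups):
        grp = groups[pid]
        # clonotype pools are per (patient, subset) so 0 sharing => disjoint ids
        for tp in ("pre", "on"):
            freqs = np.array(spec.baseline_freqs, dtype=float)
            if tp == "on":
                for si, s in enumerate(spec.subsets):
                    freqs[si] *= spec.on_multiplier.get((s, grp), 1.0)
            freqs /= freqs.sum()
            counts = rng.multinomial(spec.cells_per_sample, freqs)
            clono_by_subset = {}
            for si, s in enumerate(spec.subsets):
                p = spec.clone_geom_p.get(s, spec.clone_geom_p.get("default", 0.5))
                clono_by_subset[s] = _draw_clonotypes(
                    rng, int(counts[si]), p, f"{pid}_{s}"
                )
            # planted sharing: overwrite clones of subset B with ids from A
            for ai in range(len(spec.subsets)):
                for bi in range(ai + 1, len(spec.subsets)):
                    pshare = share[ai, bi]
                    if pshare <= 0:
                        continue
                    a, b = spec.subsets[ai], spec.subsets[bi]
                    a_ids = sorted(set(clono_by_subset[a]))
                    b_list = clono_by_subset[b]
                    for b_id in sorted(set(b_list)):
                        if a_ids and rng.random() < pshare:
                            new = a_ids[rng.integers(len(a_ids))]
                            clono_by_subset[b] = [
                                new if c == b_id else c for c in clono_by_subset[b]
                            ]
            ci = 0
            for si, s in enumerate(spec.subsets):
                for clono in clono_by_subset[s]:
                    cell_id = f"{pid}_{tp}_c{ci:04d}"
                    ci += 1
                    rows.append(
                        {
                            "cell_id": cell_id,
                            "patient_id": pid,
                            "timepoint": tp,
                            "subset_label": s,
                            "clonotype_id": clono,
                        }
                    )
                    cells.append(
                        CellRecord(
                            cell_id=cell_id,
                            sample_id=f"{pid}_{tp}",
                            patient_id=pid,
                            timepoint=tp,
                            response_group=grp,
                            cluster_label=s,
                        )
                    )
                    mu = base_mu.copy()
                    if tp == "on" and (s, grp) in resp_genes:
                        _, lfc = spec.response_genes[(s, grp)]
                        mu[resp_genes[(s, grp)]] *= 2.0**lfc
                    mu_cols.append(mu)

    mu_mat = np.array(mu_cols).T  # genes x cells
    rna = _nb_sample(rng, mu_mat, spec.nb_dispersion)
    adt = rng.poisson(10.0, size=(spec.n_adts, len(cells)))
    ds = MultimodalDataset(
        rna_counts=rna,
        adt_counts=adt,
        gene_ids=[f"G{j:04d}" for j in range(spec.n_genes)],
        adt_ids=[f"ADT{j:03d}" for j in range(spec.n_adts)],
        cells=cells,
    )
    ds.truth_response_genes = {  # type: ignore[attr-defined]
        key: [f"G{j:04d}" for j in sorted(genes)] for key, genes in resp_genes.items()
    }
    return ClonotypeTable(pd.DataFrame(rows)), design, ds
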