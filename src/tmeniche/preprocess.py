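"""CITE-seq preprocessing: cell QC, ADT normalization and enrichment,
gene-module scoring, HVG selection and deconvolution-prep subsampling.

The QC rules follow the study design: cells above 25% mitochondrial
content are discarded, cells with 10–95% mouse-aligned UMIs are treated
as ambiguous-species doublets, and cells at >=95% mouse UMIs are the
spiked-in mouse controls.  ADT counts are normalized with a per-cell
centered log-ratio transform; enrichment calls use a rank-sum test with
Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CellRecord, ContractError, GeneSignature, MultimodalDataset

log = logging.getLogger("tmeniche")

__all__ = [
    "qc_filter_cells",
    "clr_normalize",
    "filter_adt_outliers",
    "adt_enrichment",
    "EnrichmentResult",
    "lognormalize_rna",
    "score_gene_module",
    "ModuleScoreResult",
    "select_hvgs",
    "subsample_by_type",
]


def qc_filter_cells(
    ds: MultimodalDataset,
    mito_max: float = 0.25,
    mouse_low: float = 0.10,
    mouse_high: float = 0.95,
) -> Tuple[MultimodalDataset, pd.DataFrame]:
    """Flag and remove QC-failing cells.

    Flags (mutually exclusive, mito rule first):

    * ``discard_mito`` — mito_fraction strictly above ``mito_max``;
    * ``discard_ambiguous_species`` — mouse_fraction strictly inside
      (``mouse_low``, ``mouse_high``);
    * ``mouse_control`` — mouse_fraction >= ``mouse_high`` (spiked control);
    * ``keep`` — everything else.

    Returns the dataset restricted to kept cells plus an audit table with
    one row per input cell recording its flag.
    """
    flags = []
    for c in ds.cells:
        if c.mito_fraction is None or c.mouse_fraction is None:
            raise ContractError(f"cell {c.cell_id} missing QC fractions")
        if c.mito_fraction > mito_max:
            flags.append("discard_mito")
        elif mouse_low < c.mouse_fraction < mouse_high:
            flags.append("discard_ambiguous_species")
        elif c.mouse_fraction >= mouse_high:
            flags.append("mouse_control")
        else:
            flags.append("keep")
    audit = pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "mito_fraction": [c.mito_fraction for c in ds.cells],
            "mouse_fraction": [c.mouse_fraction for c in ds.cells],
            "qc_flag": flags,
        }
    )
    keep_idx = np.flatnonzero(np.array(flags) == "keep")
    out = ds.subset_cells(keep_idx)
    for c in out.cells:
        c.qc_flag = "keep"
    counts = audit["qc_flag"].value_counts().to_dict()
    log.info("qc_filter_cells: %d -> %d cells (%s)", ds.n_cells, out.n_cells, counts)
    return out, audit


def clr_values(x: np.ndarray) -> np.ndarray:
    """Per-cell centered log-ratio of one ADT vector ``x``.

    The geometric mean runs over the full antibody count ``n`` but zeros
    contribute nothing to the log sum: g = exp((1/n) * sum_{x>0} ln x);
    the transformed value is ln(1 + x/g).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        raise ContractError("CLR undefined for an empty ADT vector")
    pos = x > 0
    g = np.exp(np.log(x[pos]).sum() / n)
    return np.log1p(x / g)


def clr_normalize(ds: MultimodalDataset) -> MultimodalDataset:
    """Apply the within-cell CLR transform to the ADT counts."""
    if ds.adt_counts.shape[0] == 0:
        raise ContractError("no antibodies to normalize")
    norm = np.column_stack([clr_values(ds.adt_counts[:, j]) for j in range(ds.n_cells)]) \
        if ds.n_cells else np.zeros_like(ds.adt_counts, dtype=float)
    out = replace(ds, normalized_adt=norm)
    return out


def filter_adt_outliers(
    ds: MultimodalDataset, fold: float = 10.0
) -> Tuple[MultimodalDataset, pd.DataFrame]:
    """Discard cells whose total ADT counts exceed ``fold`` x their
    cluster's median total.

    The per-cluster median absolute deviation of the totals is computed
    and reported alongside (it is logged, not used for the cut).
    Returns the filtered dataset and a per-cluster report.
    """
    labels = np.array(
        [c.cluster_label if c.cluster_label is not None else "" for c in ds.cells]
    )
    if (labels == "").all() and ds.n_cells:
        raise ContractError("cluster_label must be populated for ADT outlier filtering")
    totals = ds.adt_counts.sum(axis=0).astype(float)
    keep = np.ones(ds.n_cells, dtype=bool)
    report = []
    for lab in sorted(set(labels)):
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:
            log.warning("filter_adt_outliers: empty cluster %r skipped", lab)
            continue
        med = float(np.median(totals[idx]))
        mad = float(np.median(np.abs(totals[idx] - med)))
        out = idx[totals[idx] > fold * med]
        keep[out] = False
        report.append(
            {
                "cluster_label": lab,
                "n_cells": int(idx.size),
                "median_total_adt": med,
                "mad_total_adt": mad,
                "n_discarded": int(out.size),
            }
        )
    filtered = ds.subset_cells(np.flatnonzero(keep))
    rep = pd.DataFrame(report)
    log.info(
        "filter_adt_outliers: fold=%g, discarded %d of %d cells",
        fold,
        int((~keep).sum()),
        ds.n_cells,
    )
    return filtered, rep


@dataclass
class EnrichmentResult:
    """One ADT-versus-rest enrichment call within a (sample, cluster)."""

    sample_id: str
    cluster_label: str
    adt_id: str
    effect: float  # location shift of CLR values (cluster minus rest)
    p_value: Optional[float]
    p_adj: Optional[float]
    enriched: bool


def adt_enrichment(
    ds: MultimodalDataset, alpha: float = 0.01, min_cells: int = 3
) -> List[EnrichmentResult]:
    """One-vs-rest ADT enrichment per (sample, cluster) on CLR values.

    For each sample separately, each cluster's cells are compared with the
    rest of the sample per ADT using a two-sided Wilcoxon rank-sum test;
    p-values are BH-adjusted across ADTs within each (sample, cluster);
    an ADT is enriched when p_adj < ``alpha`` with a positive shift.
    Clusters smaller than ``min_cells`` yield rows with absent p-values.
    """
    if ds.normalized_adt is None:
        raise ContractError("run clr_normalize before adt_enrichment")
    labels = np.array([c.cluster_label or "" for c in ds.cells])
    samples = np.array([c.sample_id for c in ds.cells])
    results: List[EnrichmentResult] = []
    for samp in sorted(set(samples)):
        sidx = np.flatnonzero(samples == samp)
        for lab in sorted(set(labels[sidx])):
            in_idx = sidx[labels[sidx] == lab]
            out_idx = sidx[labels[sidx] != lab]
            rows: List[EnrichmentResult] = []
            testable = in_idx.size >= min_cells and out_idx.size >= min_cells
            for ai, adt in enumerate(ds.adt_ids):
                a = ds.normalized_adt[ai, in_idx]
                b = ds.normalized_adt[ai, out_idx]
                effect = float(np.mean(a) - np.mean(b)) if out_idx.size else 0.0
                p = None
                if testable:
                    if np.all(a[0] == a) and np.all(b[0] == b) and (a.size == 0 or b.size == 0 or a[0] == b[0]):
                        p = 1.0
                    else:
                        p = float(
                            stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                        )
                rows.append(
                    EnrichmentResult(samp, lab, adt, effect, p, None, False)
                )
            if testable:
                padj = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
                for r, q in zip(rows, padj):
                    r.p_adj = float(q)
                    r.enriched = bool(q < alpha and r.effect > 0)
            results.extend(rows)
    n_enr = sum(r.enriched for r in results)
    log.info("adt_enrichment: alpha=%g, %d enriched calls", alpha, n_enr)
    return results


def lognormalize_rna(
    ds: MultimodalDataset, target_sum: float = 1e4
) -> MultimodalDataset:
    """Scale each cell to ``target_sum`` total RNA counts and apply log1p."""
    totals = ds.rna_counts.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    norm = np.log1p(ds.rna_counts / totals * target_sum)
    return replace(ds, normalized_rna=norm)


@dataclass
class ModuleScoreResult:
    cell_id: str
    signature: str
    score: float


def score_gene_module(
    ds: MultimodalDataset,
    sig: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> List[ModuleScoreResult]:
    """Control-matched signature score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins by dataset-mean
    expression; for each signature gene, ``n_ctrl`` control genes are
    sampled from its bin (with replacement when the bin is smaller); the
    score is mean(signature expression) - mean(pooled control expression)
    per cell.  Scores are 0 everywhere when expression is identical
    across genes.
    """
    if ds.normalized_rna is None:
        raise ContractError("run lognormalize_rna before score_gene_module")
    gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
    present = [g for g in sig.genes if g in gene_index]
    missing = [g for g in sig.genes if g not in gene_index]
    if missing:
        log.warning(
            "score_gene_module[%s]: %d signature genes absent (%s...)",
            sig.name,
            len(missing),
            missing[:3],
        )
    if not present:
        raise ContractError(f"no genes of signature {sig.name!r} in the dataset")

    expr = ds.normalized_rna
    gene_means = expr.mean(axis=1)
    order = np.argsort(gene_means, kind="stable")
    n_bins_eff = min(n_bins, len(order))
    # equal-frequency bins over the mean-expression ranks
    bin_of = np.empty(len(order), dtype=int)
    bin_of[order] = np.floor(
        np.arange(len(order)) * n_bins_eff / len(order)
    ).astype(int)

    rng = np.random.default_rng(seed)
    ctrl_idx: List[np.ndarray] = []
    for g in present:
        gi = gene_index[g]
        pool = np.flatnonzero(bin_of == bin_of[gi])
        take = rng.choice(pool, size=n_ctrl, replace=len(pool) < n_ctrl)
        ctrl_idx.append(take)
    ctrl = np.concatenate(ctrl_idx)
    sig_rows = np.array([gene_index[g] for g in present])
    scores = expr[sig_rows].mean(axis=0) - expr[ctrl].mean(axis=0)
    return [
        ModuleScoreResult(cid, sig.name, float(s))
        for cid, s in zip(ds.cell_ids, scores)
    ]


def select_hvgs(
    ds: MultimodalDataset,
    n_top: int = 5000,
    n_bins: int = 20,
    target_sum: float = 1e4,
) -> List[str]:
    """Highly variable genes by normalized dispersion.

    Cells are scaled to ``target_sum`` totals and log1p-transformed; each
    gene's dispersion (variance/mean) is z-scored within ``n_bins``
    equal-frequency mean-expression bins; the ``n_top`` genes by
    normalized dispersion are returned (all expressed genes if fewer).
    """
    if n_top <= 0:
        raise ContractError("n_top must be positive")
    norm = lognormalize_rna(ds, target_sum=target_sum).normalized_rna
    means = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1) if ds.n_cells > 1 else np.zeros_like(means)
    expressed = means > 0
    disp = np.zeros_like(means)
    disp[expressed] = var[expressed] / means[expressed]

    idx = np.flatnonzero(expressed)
    if idx.size == 0:
        return []
    order = idx[np.argsort(means[idx], kind="stable")]
    n_bins_eff = min(n_bins, idx.size)
    bin_of = np.full(len(means), -1, dtype=int)
    bin_of[order] = np.floor(
        np.arange(idx.size) * n_bins_eff / idx.size
    ).astype(int)

    z = np.full(len(means), -np.inf)
    for b in range(n_bins_eff):
        members = np.flatnonzero(bin_of == b)
        d = disp[members]
        sd = d.std(ddof=1) if members.size > 1 else 0.0
        z[members] = (d - d.mean()) / sd if sd > 0 else 0.0

    ranked = sorted(
        idx, key=lambda i: (-z[i], ds.gene_ids[i])
    )
    return [ds.gene_ids[i] for i in ranked[:n_top]]


def subsample_by_type(
    cells: Sequence[CellRecord],
    lower: int = 25,
    upper: int = 250,
    seed: int = 0,
) -> List[CellRecord]:
    """Bounded per-type subsampling used to prepare deconvolution input.

    Types with fewer than ``lower`` members are removed entirely; types
    with between ``lower`` and ``upper`` members (inclusive) are kept
    whole; larger types are downsampled to exactly ``upper`` without
    replacement.
    """
    if lower > upper:
        raise ContractError(f"lower ({lower}) > upper ({upper})")
    rng = np.random.default_rng(seed)
    by_type: Dict[str, List[int]] = {}
    for i, c in enumerate(cells):
        if c.cluster_label is None:
            raise ContractError(f"cell {c.cell_id} lacks a cluster_label")
        by_type.setdefault(c.cluster_label, []).append(i)
    chosen: List[int] = []
    for lab in sorted(by_type):
        idx = by_type[lab]
        if len(idx) < lower:
            log.info("subsample_by_type: dropping type %r (n=%d < %d)", lab, len(idx), lower)
            continue
        if len(idx) <= upper:
            chosen.extend(idx)
        else:
            chosen.extend(rng.choice(idx, size=upper, replace=False).tolist())
    chosen.sort()
    return [cells[i] for i in chosen]
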