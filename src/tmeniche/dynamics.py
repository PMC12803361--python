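"""Response-stratified paired pre/on-treatment dynamics.

Per-patient T-cell subset frequencies (with a Haldane–Anscombe 0.5
pseudocount) feed log2(On/Pre) fold changes; expansion bias is the
expander-minus-non-expander difference of mean fold changes, tested with
a Wilcoxon rank-sum.  Differential expression between timepoints within
a response group uses a rank-sum test with BH adjustment; genes are then
classified as Shared / Expander-Specific / Non-Expander-Specific
(plus Discordant for opposite-sign significance).  The numerator/
denominator subset abundance ratio (e.g. Tfh-LAG3 over Tfh-IGFL2) is
summarized as its On-minus-Pre delta per patient and compared between
response groups.  Patients with incomplete timepoints are excluded from
all paired statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import lognormalize_rna
from .types import CohortDesign, ContractError, MultimodalDataset

log = logging.getLogger("tmeniche")

__all__ = [
    "subset_frequencies",
    "paired_log2fc",
    "expansion_bias",
    "rank_sum_test",
    "de_wilcoxon",
    "classify_response_genes",
    "tfh_ratio_delta",
    "baseline_proportion_test",
]

EXACT_N_MAX = 25  # exact rank-sum null up to this per-group size


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact for group sizes up to 25 without ties, normal approximation
    with continuity correction otherwise (scipy picks the same rule
    under method="auto" but we pin the size cutoff here).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("both groups must be non-empty")
    if np.all(x[0] == x) and np.all(y[0] == y) and x[0] == y[0]:
        return 1.0
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= EXACT_N_MAX and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def subset_frequencies(
    cell_meta: pd.DataFrame,
    pseudocount: float = 0.5,
    subsets: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-(patient, timepoint) subset frequencies with pseudocounts.

    ``cell_meta`` needs columns patient_id, timepoint, subset_label (one
    row per cell).  frequency = (n_subset + pc) / sum_subsets (n + pc)
    over the full subset vocabulary, so frequencies sum to 1 and absent
    subsets keep a defined (small) frequency.
    """
    for col in ("patient_id", "timepoint", "subset_label"):
        if col not in cell_meta.columns:
            raise ContractError(f"cell metadata missing column {col!r}")
    vocab = sorted(subsets) if subsets is not None else sorted(
        cell_meta["subset_label"].unique()
    )
    rows = []
    for (pid, tp), grp in cell_meta.groupby(["patient_id", "timepoint"], sort=True):
        if grp.empty:
            continue
        counts = grp["subset_label"].value_counts()
        denom = counts.reindex(vocab).fillna(0).sum() + pseudocount * len(vocab)
        for s in vocab:
            n = int(counts.get(s, 0))
            rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "subset_label": s,
                    "n_cells": n,
                    "frequency": (n + pseudocount) / denom,
                }
            )
    return pd.DataFrame(rows)


def paired_log2fc(freqs: pd.DataFrame, design: CohortDesign) -> pd.DataFrame:
    """log2(On/Pre) of subset frequency per (patient, subset).

    Only patients with both timepoints in the design contribute; others
    are excluded and logged.
    """
    paired = design.paired_patients()
    dropped = sorted(set(design.response_group) - set(paired))
    if dropped:
        log.info("paired_log2fc: excluding incomplete patients %s", dropped)
    wide = freqs.pivot_table(
        index=["patient_id", "subset_label"], columns="timepoint", values="frequency"
    )
    rows = []
    for (pid, sub), row in wide.iterrows():
        if pid not in paired or pd.isna(row.get("pre")) or pd.isna(row.get("on")):
            continue
        rows.append(
            {
                "patient_id": pid,
                "subset_label": sub,
                "log2fc": float(np.log2(row["on"] / row["pre"])),
                "response_group": design.group(pid),
            }
        )
    return pd.DataFrame(rows)


def expansion_bias(fcs: pd.DataFrame, design: CohortDesign) -> pd.DataFrame:
    """Per-subset expander-vs-non-expander bias of the paired fold change.

    delta = mean(log2fc | expanders) - mean(log2fc | non-expanders);
    significance from the two-sided rank-sum test.  Subsets with an empty
    group get an absent delta.
    """
    rows = []
    for sub, grp in fcs.groupby("subset_label", sort=True):
        e = grp.loc[grp["response_group"] == "expander", "log2fc"].to_numpy()
        ne = grp.loc[grp["response_group"] == "non_expander", "log2fc"].to_numpy()
        if e.size == 0 or ne.size == 0:
            rows.append(
                {"subset_label": sub, "delta": np.nan, "p_value": np.nan,
                 "n_expander": e.size, "n_non_expander": ne.size}
            )
            continue
        rows.append(
            {
                "subset_label": sub,
                "delta": float(e.mean() - ne.mean()),
                "p_value": rank_sum_test(e, ne),
                "n_expander": int(e.size),
                "n_non_expander": int(ne.size),
            }
        )
    return pd.DataFrame(rows)


def de_wilcoxon(
    ds: MultimodalDataset,
    subset: str,
    response_group: str,
    lfc_min: float = 0.25,
    alpha: float = 0.05,
    min_cells: int = 3,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """On-vs-pre differential expression within one subset and response
    group.

    Per gene on log-normalized expression: two-sided rank-sum p, BH
    adjustment across all tested genes, and
    lfc = log2((mean expm1 on + 1) / (mean expm1 pre + 1)); a gene is
    significant iff padj < ``alpha`` and \\|lfc\\| > ``lfc_min``.
    """
    if ds.normalized_rna is None:
        ds = lognormalize_rna(ds, target_sum=target_sum)
    meta = ds.cell_table()
    mask = (meta["cluster_label"] == subset) & (
        meta["response_group"] == response_group
    )
    on_idx = np.flatnonzero(mask & (meta["timepoint"] == "on"))
    pre_idx = np.flatnonzero(mask & (meta["timepoint"] == "pre"))
    if on_idx.size < min_cells or pre_idx.size < min_cells:
        log.warning(
            "de_wilcoxon: %s/%s skipped (on=%d, pre=%d cells)",
            subset, response_group, on_idx.size, pre_idx.size,
        )
        return pd.DataFrame(
            columns=["gene", "lfc", "p_value", "p_adj", "significant"]
        )
    expr = ds.normalized_rna
    on = expr[:, on_idx]
    pre = expr[:, pre_idx]
    # vectorized rank-sum via tie-corrected normal approximation
    p = _ranksum_rows(on, pre)
    lfc = np.log2(
        (np.expm1(on).mean(axis=1) + 1.0) / (np.expm1(pre).mean(axis=1) + 1.0)
    )
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": ds.gene_ids,
            "lfc": lfc,
            "p_value": p,
            "p_adj": padj,
            "significant": (padj < alpha) & (np.abs(lfc) > lfc_min),
        }
    )


def _ranksum_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p (normal approx., tie-corrected,
    continuity-corrected), matching scipy's asymptotic method."""
    res = stats.mannwhitneyu(
        a, b, axis=1, alternative="two-sided", method="asymptotic"
    )
    p = np.asarray(res.pvalue, dtype=float)
    # constant-and-equal rows are untestable; report p = 1
    const = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0) & (a[:, 0] == b[:, 0])
    p[const] = 1.0
    return p


def classify_response_genes(
    expander: pd.DataFrame, nonexpander: pd.DataFrame
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Combine the two response-group DE runs into gene categories.

    Shared — significant in both with the same fold-change sign;
    Expander_Specific / NonExpander_Specific — significant in one group
    only; Discordant — significant in both with opposite signs;
    NotSignificant otherwise.  Also returns the per-run DEG counts and
    their expander/non-expander ratio.
    """
    e = expander.set_index("gene")
    n = nonexpander.set_index("gene")
    common = e.index.intersection(n.index)
    if len(common) < len(e.index.union(n.index)):
        log.warning(
            "classify_response_genes: gene universes differ; using %d common genes",
            len(common),
        )
    rows = []
    for g in common:
        se, sn = bool(e.at[g, "significant"]), bool(n.at[g, "significant"])
        le, ln = float(e.at[g, "lfc"]), float(n.at[g, "lfc"])
        if se and sn:
            cat = "Shared" if np.sign(le) == np.sign(ln) else "Discordant"
        elif se:
            cat = "Expander_Specific"
        elif sn:
            cat = "NonExpander_Specific"
        else:
            cat = "NotSignificant"
        rows.append(
            {
                "gene": g,
                "lfc_expander": le,
                "padj_expander": float(e.at[g, "p_adj"]),
                "lfc_nonexpander": ln,
                "padj_nonexpander": float(n.at[g, "p_adj"]),
                "category": cat,
            }
        )
    records = pd.DataFrame(rows)
    n_e = int(e.loc[common, "significant"].sum())
    n_n = int(n.loc[common, "significant"].sum())
    stats_out = {
        "n_deg_expander": n_e,
        "n_deg_nonexpander": n_n,
        "deg_ratio": (n_e / n_n) if n_n else np.inf if n_e else np.nan,
    }
    return records, stats_out


def tfh_ratio_delta(
    cell_meta: pd.DataFrame,
    design: CohortDesign,
    numerator_subset: str,
    denominator_subset: str,
    pseudocount: float = 0.5,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-patient abundance ratio of two subsets and its on-treatment
    change, compared between response groups.

    ratio_t = (n_numerator + pc) / (n_denominator + pc) at each
    timepoint; delta = ratio_on - ratio_pre.  Patients missing a
    timepoint are excluded.  The group comparison is a two-sided
    rank-sum test of delta between expanders and non-expanders.
    """
    counts = (
        cell_meta.groupby(["patient_id", "timepoint", "subset_label"])
        .size()
        .rename("n")
        .reset_index()
    )
    rows = []
    for pid in design.paired_patients():
        vals = {}
        for tp in ("pre", "on"):
            sub = counts[(counts["patient_id"] == pid) & (counts["timepoint"] == tp)]
            n_num = int(
                sub.loc[sub["subset_label"] == numerator_subset, "n"].sum()
            )
            n_den = int(
                sub.loc[sub["subset_label"] == denominator_subset, "n"].sum()
            )
            vals[tp] = (n_num + pseudocount) / (n_den + pseudocount)
        rows.append(
            {
                "patient_id": pid,
                "response_group": design.group(pid),
                "ratio_pre": vals["pre"],
                "ratio_on": vals["on"],
                "delta": vals["on"] - vals["pre"],
            }
        )
    per_patient = pd.DataFrame(rows)
    e = per_patient.loc[per_patient["response_group"] == "expander", "delta"]
    ne = per_patient.loc[per_patient["response_group"] == "non_expander", "delta"]
    comparison = {
        "mean_delta_expander": float(e.mean()) if len(e) else np.nan,
        "mean_delta_nonexpander": float(ne.mean()) if len(ne) else np.nan,
        "p_value": rank_sum_test(e, ne) if len(e) and len(ne) else np.nan,
    }
    return per_patient, comparison


def baseline_proportion_test(
    freqs: pd.DataFrame, design: CohortDesign
) -> pd.DataFrame:
    """Pre-treatment per-subset comparison of expander vs non-expander
    frequencies: fold change of group means and rank-sum p across
    patients."""
    pre = freqs[freqs["timepoint"] == "pre"]
    rows = []
    for sub, grp in pre.groupby("subset_label", sort=True):
        e = grp.loc[
            grp["patient_id"].map(design.response_group.get) == "expander",
            "frequency",
        ].to_numpy()
        ne = grp.loc[
            grp["patient_id"].map(design.response_group.get) == "non_expander",
            "frequency",
        ].to_numpy()
        if e.size < 2 or ne.size < 2:
            log.warning("baseline_proportion_test: subset %r skipped", sub)
            continue
        rows.append(
            {
                "subset_label": sub,
                "fc_of_means": float(e.mean() / ne.mean()),
                "p_value": rank_sum_test(e, ne),
                "n_expander": int(e.size),
                "n_non_expander": int(ne.size),
            }
        )
    return pd.DataFrame(rows)
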