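"""TCR clonotype expansion stratification and inter-subset repertoire
sharing.

Clone sizes fall into four categories — Single (1), Small (2–5),
Medium (6–20), Large (>20) — and the expanded percentage of a subset is
the share of its cells belonging to clones of size >= 2.  Repertoire
sharing between subsets is the Jaccard index of their clonotype sets
within a patient, averaged across patients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import ClonotypeTable, CohortDesign, ContractError

__all__ = [
    "CATEGORIES",
    "stratify_clonotypes",
    "ExpansionSummary",
    "expansion_summary",
    "jaccard_sharing",
    "mean_sharing_matrix",
    "SharingMatrix",
]

CATEGORIES = ("Single", "Small", "Medium", "Large")


def _categorize(size: int, small_max: int = 5, medium_max: int = 20) -> str:
    if size <= 0:
        raise ContractError("clone size must be positive")
    if size == 1:
        return "Single"
    if size <= small_max:
        return "Small"
    if size <= medium_max:
        return "Medium"
    return "Large"


def stratify_clonotypes(
    tbl: ClonotypeTable,
    small_max: int = 5,
    medium_max: int = 20,
    per_subset_scope: bool = False,
) -> pd.DataFrame:
    """Assign each cell its clone's size category.

    Clone size counts the cells sharing a clonotype_id within
    (patient, timepoint) — across subsets by default, so a clone spanning
    subsets contributes its full size to every member cell; set
    ``per_subset_scope`` to count within (patient, timepoint, subset)
    instead.  Returns the cell table with ``clone_size`` and
    ``clone_category`` columns added.
    """
    df = tbl.rows.copy()
    scope = ["patient_id", "timepoint"] + (
        ["subset_label"] if per_subset_scope else []
    )
    sizes = df.groupby(scope + ["clonotype_id"])["cell_id"].transform("size")
    df["clone_size"] = sizes.astype(int)
    df["clone_category"] = [
        _categorize(s, small_max, medium_max) for s in df["clone_size"]
    ]
    return df


@dataclass
class ExpansionSummary:
    patient_id: str
    subset_label: str
    timepoint: str
    cells_per_category: Dict[str, int]
    fraction_per_category: Dict[str, float]
    pct_expanded: float  # 100 * cells in clones of size >= 2 / subset cells


def expansion_summary(
    tbl: ClonotypeTable,
    design: Optional[CohortDesign] = None,
    small_max: int = 5,
    medium_max: int = 20,
    per_subset_scope: bool = False,
) -> Tuple[List[ExpansionSummary], pd.DataFrame]:
    """Per-(patient, subset, timepoint) expansion summaries plus
    unweighted means across patients per (subset, timepoint).

    Category fractions are cell-weighted within the subset; the
    cross-patient means average each patient's fractions and expanded
    percentage equally (patients lacking a subset are excluded from its
    mean, with n reported).
    """
    df = stratify_clonotypes(tbl, small_max, medium_max, per_subset_scope)
    summaries: List[ExpansionSummary] = []
    for (pid, sub, tp), grp in df.groupby(
        ["patient_id", "subset_label", "timepoint"], sort=True
    ):
        n = len(grp)
        counts = {c: int((grp["clone_category"] == c).sum()) for c in CATEGORIES}
        fractions = {c: counts[c] / n for c in CATEGORIES}
        pct = 100.0 * int((grp["clone_size"] >= 2).sum()) / n
        summaries.append(
            ExpansionSummary(pid, sub, tp, counts, fractions, pct)
        )
    rows = []
    for s in summaries:
        grp = (
            design.response_group.get(s.patient_id, "unknown") if design else "unknown"
        )
        rows.append(
            {
                "patient_id": s.patient_id,
                "subset_label": s.subset_label,
                "timepoint": s.timepoint,
                "response_group": grp,
                "pct_expanded": s.pct_expanded,
                **{f"frac_{c}": s.fraction_per_category[c] for c in CATEGORIES},
            }
        )
    per_patient = pd.DataFrame(rows)
    means = (
        per_patient.groupby(["subset_label", "timepoint"])
        .agg(
            n_patients=("patient_id", "nunique"),
            mean_pct_expanded=("pct_expanded", "mean"),
            **{
                f"mean_frac_{c}": (f"frac_{c}", "mean") for c in CATEGORIES
            },
        )
        .reset_index()
    )
    return summaries, means


def jaccard_sharing(
    tbl: ClonotypeTable, patient_id: str, timepoint: Optional[str] = None
) -> pd.DataFrame:
    """Pairwise Jaccard index of clonotype sets between subsets of one
    patient (timepoints pooled by default; pass ``timepoint`` for a
    single-timepoint matrix).

    J(A, B) = |A ∩ B| / |A ∪ B| over unique clonotype ids; an entry is
    NaN (absent) when both subsets have empty clonotype sets.
    """
    df = tbl.rows[tbl.rows["patient_id"] == patient_id]
    if df.empty:
        raise ContractError(f"patient {patient_id!r} not in clonotype table")
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint]
    subsets = sorted(df["subset_label"].unique())
    sets = {s: set(df.loc[df["subset_label"] == s, "clonotype_id"]) for s in subsets}
    mat = pd.DataFrame(np.nan, index=subsets, columns=subsets, dtype=float)
    for a, b in itertools.combinations_with_replacement(subsets, 2):
        union = sets[a] | sets[b]
        if union:
            j = len(sets[a] & sets[b]) / len(union)
            mat.loc[a, b] = mat.loc[b, a] = j
    return mat


@dataclass
class SharingMatrix:
    subset_labels: List[str]
    per_patient: Dict[str, pd.DataFrame]
    mean: pd.DataFrame  # entrywise mean where defined
    n: pd.DataFrame  # patients contributing to each entry


def mean_sharing_matrix(per_patient: Dict[str, pd.DataFrame]) -> SharingMatrix:
    """Entrywise mean of per-patient Jaccard matrices where defined."""
    if not per_patient:
        raise ContractError("need at least one patient matrix")
    labels = sorted({lab for m in per_patient.values() for lab in m.index})
    aligned = [
        m.reindex(index=labels, columns=labels) for m in per_patient.values()
    ]
    stack = np.array([m.to_numpy(float) for m in aligned])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    n = (~np.isnan(stack)).sum(axis=0)
    mean[n == 0] = np.nan
    return SharingMatrix(
        subset_labels=labels,
        per_patient=dict(per_patient),
        mean=pd.DataFrame(mean, index=labels, columns=labels),
        n=pd.DataFrame(n, index=labels, columns=labels),
    )
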