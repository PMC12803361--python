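"""Shared data model for the tumor-microenvironment analytics pipeline.

All downstream stages operate on these containers; no stage reads files
directly (see :mod:`tmeniche.io` for the readers/writers).

Matrix orientation follows common single-cell tooling output: features
(genes or antibodies) are rows, cells are columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TmenicheError",
    "SchemaError",
    "AlignmentError",
    "ContractError",
    "CellRecord",
    "MultimodalDataset",
    "SpatialCellTable",
    "ClonotypeTable",
    "CohortDesign",
    "GeneSignature",
    "TIMEPOINTS",
    "RESPONSE_GROUPS",
    "QC_FLAGS",
]

TIMEPOINTS = ("pre", "on", "none")
RESPONSE_GROUPS = ("expander", "non_expander", "unknown")
QC_FLAGS = ("keep", "discard_mito", "discard_ambiguous_species", "mouse_control")


class TmenicheError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(TmenicheError):
    """A file or table is missing a required column or has a bad value."""


class AlignmentError(TmenicheError):
    """Barcodes/identifiers do not line up across inputs."""


class ContractError(TmenicheError):
    """An operation's precondition was violated."""


@dataclass
class CellRecord:
    """Per-cell metadata attached to a multimodal dataset.

    ``mito_fraction`` and ``mouse_fraction`` are fractions of the cell's
    UMIs assigned to mitochondrial genes and to the mouse genome
    respectively; both drive the QC flagging rules.
    """

    cell_id: str
    sample_id: str = ""
    patient_id: str = ""
    timepoint: str = "none"
    response_group: str = "unknown"
    cluster_label: Optional[str] = None
    mito_fraction: float = 0.0
    mouse_fraction: float = 0.0
    qc_flag: str = "keep"

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise SchemaError(f"unknown timepoint {self.timepoint!r}")
        if self.response_group not in RESPONSE_GROUPS:
            raise SchemaError(f"unknown response_group {self.response_group!r}")
        if self.qc_flag not in QC_FLAGS:
            raise SchemaError(f"unknown qc_flag {self.qc_flag!r}")
        for name in ("mito_fraction", "mouse_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SchemaError(f"{name}={v} outside [0, 1] for cell {self.cell_id}")


def _check_unique(ids, what: str) -> None:
    seen = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise AlignmentError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class MultimodalDataset:
    """Paired RNA and ADT count matrices over the same cells.

    ``rna_counts`` is genes x cells, ``adt_counts`` is antibodies x cells.
    The normalized matrices stay ``None`` until the corresponding
    normalization step has been applied.
    """

    rna_counts: np.ndarray
    adt_counts: np.ndarray
    gene_ids: list
    adt_ids: list
    cells: list  # list[CellRecord]
    normalized_adt: Optional[np.ndarray] = None
    normalized_rna: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rna_counts = np.asarray(self.rna_counts)
        self.adt_counts = np.asarray(self.adt_counts)
        n = len(self.cells)
        if self.rna_counts.shape != (len(self.gene_ids), n):
            raise AlignmentError(
                f"rna_counts shape {self.rna_counts.shape} != "
                f"({len(self.gene_ids)}, {n})"
            )
        if self.adt_counts.shape != (len(self.adt_ids), n):
            raise AlignmentError(
                f"adt_counts shape {self.adt_counts.shape} != "
                f"({len(self.adt_ids)}, {n})"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.adt_ids, "adt ids")
        _check_unique([c.cell_id for c in self.cells], "cell ids")
        if (self.rna_counts < 0).any() or (self.adt_counts < 0).any():
            raise SchemaError("negative counts")
        for mat, counts in (
            (self.normalized_adt, self.adt_counts),
            (self.normalized_rna, self.rna_counts),
        ):
            if mat is not None and mat.shape != counts.shape:
                raise AlignmentError("normalized matrix shape mismatch")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list:
        return [c.cell_id for c in self.cells]

    def cell_table(self) -> pd.DataFrame:
        """Cell metadata as a DataFrame indexed by cell_id."""
        df = pd.DataFrame([vars(c) for c in self.cells])
        return df.set_index("cell_id", drop=False)

    def subset_cells(self, keep_idx) -> "MultimodalDataset":
        """New dataset restricted to the given cell column indices (order kept)."""
        keep_idx = np.asarray(keep_idx, dtype=int)
        return MultimodalDataset(
            rna_counts=self.rna_counts[:, keep_idx],
            adt_counts=self.adt_counts[:, keep_idx],
            gene_ids=list(self.gene_ids),
            adt_ids=list(self.adt_ids),
            cells=[replace(self.cells[i]) for i in keep_idx],
            normalized_adt=None
            if self.normalized_adt is None
            else self.normalized_adt[:, keep_idx],
            normalized_rna=None
            if self.normalized_rna is None
            else self.normalized_rna[:, keep_idx],
        )


@dataclass
class SpatialCellTable:
    """Per-cell 2-D coordinates (micrometres) with cell-type labels.

    ``gene_counts`` optionally holds a panel-gene count matrix
    (genes x cells, same column order as ``cells``).
    """

    cells: pd.DataFrame  # columns: cell_id, sample_id, x_um, y_um, cell_type
    panel_genes: list = field(default_factory=list)
    gene_counts: Optional[np.ndarray] = None

    REQUIRED = ("cell_id", "sample_id", "x_um", "y_um", "cell_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.cells.columns]
        if missing:
            raise SchemaError(f"spatial table missing columns {missing}")
        for col in ("x_um", "y_um"):
            vals = pd.to_numeric(self.cells[col], errors="coerce")
            if vals.isna().any() or not np.isfinite(vals).all():
                bad = self.cells.loc[vals.isna() | ~np.isfinite(vals), "cell_id"]
                raise SchemaError(f"non-finite {col} for cells {list(bad[:5])}")
            self.cells[col] = vals.astype(float)
        _check_unique(self.cells["cell_id"].tolist(), "spatial cell ids")
        self.cells = self.cells.reset_index(drop=True)
        if self.gene_counts is not None:
            self.gene_counts = np.asarray(self.gene_counts)
            if self.gene_counts.shape != (len(self.panel_genes), len(self.cells)):
                raise AlignmentError("gene_counts shape mismatch with panel/cells")
            if (self.gene_counts < 0).any():
                raise SchemaError("negative panel counts")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def coords(self) -> np.ndarray:
        return self.cells[["x_um", "y_um"]].to_numpy(float)

    def types(self) -> np.ndarray:
        return self.cells["cell_type"].to_numpy()


@dataclass
class ClonotypeTable:
    """One row per T cell with patient, timepoint, subset and clonotype id."""

    rows: pd.DataFrame

    REQUIRED = ("cell_id", "patient_id", "timepoint", "subset_label", "clonotype_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise SchemaError(f"clonotype table missing columns {missing}")
        if (self.rows["clonotype_id"].astype(str).str.len() == 0).any():
            raise SchemaError("empty clonotype_id")
        dup = self.rows.duplicated(subset=["cell_id", "timepoint"])
        if dup.any():
            bad = self.rows.loc[dup, "cell_id"].unique()
            raise SchemaError(
                f"cell_id repeated within a timepoint: {list(bad[:5])}"
            )
        self.rows = self.rows.reset_index(drop=True)


@dataclass
class CohortDesign:
    """Patient response-group labels and available timepoints.

    Paired analyses only use patients with both pre- and on-treatment
    samples; patients with incomplete timepoints are excluded.
    """

    response_group: dict  # patient_id -> "expander" | "non_expander"
    timepoints: dict  # patient_id -> set of timepoints

    def __post_init__(self) -> None:
        for pid, grp in self.response_group.items():
            if grp not in ("expander", "non_expander"):
                raise SchemaError(f"patient {pid}: bad response group {grp!r}")
        self.timepoints = {p: set(t) for p, t in self.timepoints.items()}

    def paired_patients(self) -> list:
        """Patients with both pre and on samples, sorted for determinism."""
        return sorted(
            p
            for p, tps in self.timepoints.items()
            if {"pre", "on"} <= tps and p in self.response_group
        )

    def group(self, patient_id: str) -> str:
        return self.response_group[patient_id]


@dataclass
class GeneSignature:
    """Named gene set, e.g. loaded from a GMT file."""

    name: str
    genes: list

    def __post_init__(self) -> None:
        if not self.genes:
            raise SchemaError(f"signature {self.name!r} has no genes")
        _check_unique(self.genes, f"genes in signature {self.name!r}")
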