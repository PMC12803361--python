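"""File readers and writers for the pipeline's standard formats.

RNA/ADT counts travel as Matrix Market (1-based coordinate format,
features as rows, cells as columns) with sidecar features/barcodes TSVs;
everything else is CSV, plus GMT for gene signatures.  Every reader/writer
pair is a lossless round trip (bit-exact for integer counts).
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    AlignmentError,
    CellRecord,
    ClonotypeTable,
    CohortDesign,
    GeneSignature,
    MultimodalDataset,
    SchemaError,
    SpatialCellTable,
)

log = logging.getLogger("tmeniche")

__all__ = [
    "read_multimodal",
    "write_multimodal",
    "read_spatial",
    "write_spatial",
    "read_clonotypes",
    "write_clonotypes",
    "read_design",
    "write_design",
    "read_signatures",
    "write_signatures",
]

_META_COLS = [
    "cell_id",
    "sample_id",
    "patient_id",
    "timepoint",
    "response_group",
    "cluster_label",
    "mito_fraction",
    "mouse_fraction",
    "qc_flag",
]


def _read_mtx(path: str) -> np.ndarray:
    try:
        mat = scipy.io.mmread(path)
    except ValueError as exc:
        raise SchemaError(f"malformed Matrix Market file {path}: {exc}") from exc
    arr = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat
    )
    if (arr < 0).any():
        raise SchemaError(f"negative entries in {path}")
    return arr


def _read_ids(path: str, what: str) -> List[str]:
    ids = (
        pd.read_csv(path, sep="\t", header=None, dtype=str)[0].tolist()
        if os.path.getsize(path)
        else []
    )
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"duplicate ids in {what} file {path}: {dups[:10]}")
    return ids


def read_multimodal(
    rna_mtx_path: str,
    adt_mtx_path: str,
    features_paths: Tuple[str, str],
    barcodes_path: str,
    metadata_csv_path: Optional[str] = None,
) -> MultimodalDataset:
    """Load paired RNA + ADT counts and cell metadata into one dataset.

    ``features_paths`` is ``(gene_features_tsv, adt_features_tsv)``.  Cells
    present in the counts but absent from the metadata CSV get default
    :class:`CellRecord` fields (qc_flag=keep, fractions 0).
    """
    rna = _read_mtx(rna_mtx_path)
    adt = _read_mtx(adt_mtx_path)
    gene_ids = _read_ids(features_paths[0], "gene features")
    adt_ids = _read_ids(features_paths[1], "adt features")
    barcodes = _read_ids(barcodes_path, "barcodes")
    if rna.shape[1] != len(barcodes) or adt.shape[1] != len(barcodes):
        raise AlignmentError(
            f"column counts (rna {rna.shape[1]}, adt {adt.shape[1]}) "
            f"do not match {len(barcodes)} barcodes"
        )

    meta = {}
    if metadata_csv_path is not None:
        df = pd.read_csv(metadata_csv_path, dtype={"cell_id": str})
        if "cell_id" not in df.columns:
            raise SchemaError("metadata CSV missing column 'cell_id'")
        extra = set(df["cell_id"]) - set(barcodes)
        if extra:
            raise AlignmentError(
                f"metadata cells absent from barcodes: {sorted(extra)[:10]}"
            )
        for rec in df.to_dict("records"):
            meta[rec["cell_id"]] = rec

    def _get(rec, key, default):
        val = rec.get(key, default)
        return default if val is None or (isinstance(val, float) and pd.isna(val)) or val == "" else val

    cells = []
    for bc in barcodes:
        rec = meta.get(bc, {})
        cl = _get(rec, "cluster_label", None)
        cells.append(
            CellRecord(
                cell_id=bc,
                sample_id=str(_get(rec, "sample_id", "")),
                patient_id=str(_get(rec, "patient_id", "")),
                timepoint=str(_get(rec, "timepoint", "none")),
                response_group=str(_get(rec, "response_group", "unknown")),
                cluster_label=None if cl is None else str(cl),
                mito_fraction=float(_get(rec, "mito_fraction", 0.0)),
                mouse_fraction=float(_get(rec, "mouse_fraction", 0.0)),
                qc_flag=str(_get(rec, "qc_flag", "keep")),
            )
        )
    ds = MultimodalDataset(rna, adt, gene_ids, adt_ids, cells)
    log.info(
        "read_multimodal: %d genes, %d adts, %d cells", len(gene_ids), len(adt_ids), len(cells)
    )
    return ds


def write_multimodal(ds: MultimodalDataset, out_dir: str, prefix: str = "") -> None:
    """Write a dataset as MTX + features/barcodes TSVs + metadata CSV."""
    os.makedirs(out_dir, exist_ok=True)
    p = os.path.join(out_dir, prefix)
    scipy.io.mmwrite(p + "rna.mtx", scipy.sparse.coo_matrix(ds.rna_counts))
    scipy.io.mmwrite(p + "adt.mtx", scipy.sparse.coo_matrix(ds.adt_counts))
    for name, ids in (("genes.tsv", ds.gene_ids), ("adts.tsv", ds.adt_ids)):
        pd.Series(ids, dtype=str).to_csv(
            p + name, sep="\t", header=False, index=False
        )
    pd.Series(ds.cell_ids, dtype=str).to_csv(
        p + "barcodes.tsv", sep="\t", header=False, index=False
    )
    meta = ds.cell_table().reset_index(drop=True)[_META_COLS]
    meta.to_csv(p + "metadata.csv", index=False)


def read_spatial(csv_path: str) -> SpatialCellTable:
    """Load a spatial cell table CSV; panel-gene columns are ``gene:<name>``."""
    df = pd.read_csv(csv_path, dtype={"cell_id": str})
    gene_cols = [c for c in df.columns if c.startswith("gene:")]
    panel = [c.split(":", 1)[1] for c in gene_cols]
    counts = None
    if gene_cols:
        counts = df[gene_cols].to_numpy(float).T
        if not np.allclose(counts, np.round(counts)) or (counts < 0).any():
            raise SchemaError("panel gene counts must be nonnegative integers")
        counts = counts.astype(int)
    return SpatialCellTable(
        cells=df.drop(columns=gene_cols), panel_genes=panel, gene_counts=counts
    )


def write_spatial(tbl: SpatialCellTable, csv_path: str) -> None:
    df = tbl.cells.copy()
    for i, g in enumerate(tbl.panel_genes):
        df[f"gene:{g}"] = tbl.gene_counts[i]
    df.to_csv(csv_path, index=False)


def read_clonotypes(csv_path: str) -> ClonotypeTable:
    df = pd.read_csv(csv_path, dtype=str)
    return ClonotypeTable(df)


def write_clonotypes(tbl: ClonotypeTable, csv_path: str) -> None:
    tbl.rows.to_csv(csv_path, index=False)


def read_design(csv_path: str) -> CohortDesign:
    """Load a cohort design CSV with columns patient_id, response_group, timepoints.

    ``timepoints`` holds ';'-separated timepoint names.
    """
    df = pd.read_csv(csv_path, dtype=str)
    for col in ("patient_id", "response_group", "timepoints"):
        if col not in df.columns:
            raise SchemaError(f"design CSV missing column {col!r}")
    return CohortDesign(
        response_group=dict(zip(df["patient_id"], df["response_group"])),
        timepoints={
            p: set(t.split(";")) for p, t in zip(df["patient_id"], df["timepoints"])
        },
    )


def write_design(design: CohortDesign, csv_path: str) -> None:
    rows = [
        {
            "patient_id": p,
            "response_group": design.response_group[p],
            "timepoints": ";".join(sorted(design.timepoints.get(p, []))),
        }
        for p in sorted(design.response_group)
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_signatures(gmt_path: str) -> List[GeneSignature]:
    """Parse a GMT file: tab-separated name, description, genes...."""
    sigs = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description, >=1 gene"
                )
            genes = [g for g in parts[2:] if g]
            sigs.append(GeneSignature(name=parts[0], genes=genes))
    return sigs


def write_signatures(sigs: Iterable[GeneSignature], gmt_path: str) -> None:
    with open(gmt_path, "w") as fh:
        for s in sigs:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")
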