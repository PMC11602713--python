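"""Readers and writers for the tabular formats the pipeline touches.

Wide layout: first column is the protein id, one column per sample, plus a
sidecar metadata TSV keyed by ``sample_id``. Long layout: one row per
(protein, sample, intensity) triple. Interaction tables are two-column TSVs
of directed source -> target gene pairs. All files are RFC-4180-style
TSV/CSV handled through pandas; a ``#`` prefix marks provenance comment
lines written by the pipeline.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SAMPLE_COLUMNS, SCALE_LOG2, SCALE_RAW, IntensityMatrix
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: string codes normalized to missing on read
MISSING_CODES = ("", "NA", "NaN", "nan")

_FLOAT_FMT = "%.12g"  # 12 significant digits -> round-trip identity


def _read_table(path, sep="\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    try:
        df = pd.read_csv(path, sep=sep, comment="#", na_values=list(MISSING_CODES),
                         keep_default_na=False, dtype=None)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty table") from exc
    if df.empty:
        raise ParseError(f"{path}: empty table")
    return df


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sidecar sample-metadata TSV (keyed by sample_id)."""
    meta = _read_table(path)
    if "sample_id" not in meta.columns:
        raise ParseError(f"{path}: metadata lacks a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    missing = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: metadata lacks columns {missing}")
    return meta.set_index("sample_id")


def read_intensity_matrix(path, layout: str, metadata_path=None, *,
                          scale: str = SCALE_LOG2,
                          zero_is_missing: bool | None = None,
                          cohorts=None) -> IntensityMatrix:
    """Read an intensity matrix in ``wide`` or ``long`` layout.

    Numeric 0 is treated as missing only on raw-scale data (DIA exports code
    absent proteins as 0); override with ``zero_is_missing``.
    """
    if layout not in ("wide", "long"):
        raise ParseError(f"unknown layout {layout!r}; expected 'wide' or 'long'")
    if metadata_path is None:
        raise ParseError("metadata_path is required (sidecar sample metadata TSV)")
    if zero_is_missing is None:
        zero_is_missing = scale == SCALE_RAW

    df = _read_table(path)
    if layout == "wide":
        protein_col = df.columns[0]
        if df[protein_col].duplicated().any():
            dup = df.loc[df[protein_col].duplicated(), protein_col].iloc[0]
            raise ParseError(f"{path}: duplicate protein id {dup!r}")
        values = df.set_index(protein_col)
        values.index.name = "protein"
        values = values.apply(pd.to_numeric, errors="coerce")
    else:
        required = {"protein", "sample", "intensity"}
        if not required.issubset(df.columns):
            raise ParseError(
                f"{path}: long layout needs columns {sorted(required)}, "
                f"got {list(df.columns)}")
        if df.duplicated(subset=["protein", "sample"]).any():
            row = df[df.duplicated(subset=["protein", "sample"])].iloc[0]
            raise ParseError(
                f"{path}: duplicate (protein, sample) pair "
                f"({row['protein']!r}, {row['sample']!r})")
        values = df.pivot(index="protein", columns="sample", values="intensity")
        values = values.apply(pd.to_numeric, errors="coerce")

    if zero_is_missing:
        values = values.mask(values == 0)

    samples = read_sample_metadata(metadata_path)
    known = [s for s in values.columns if s in samples.index]
    unknown = [s for s in values.columns if s not in samples.index]
    if unknown:
        raise ParseError(
            f"{path}: samples without metadata: {unknown[:5]}")
    samples = samples.loc[known]
    if cohorts is not None:
        bad = sorted(set(samples["cohort"]) - set(cohorts))
        if bad:
            raise ParseError(f"{metadata_path}: unknown cohort labels {bad}")

    matrix = IntensityMatrix(values=values, samples=samples, scale=scale)
    matrix.record_step("read_intensity_matrix", path=str(path), layout=layout,
                       zero_is_missing=zero_is_missing)
    return matrix


def write_intensity_matrix(matrix: IntensityMatrix, path, metadata_path=None,
                           header_lines=()) -> None:
    """Write wide-layout values (and optionally the sample metadata sidecar).

    Floats use 12 significant digits so write . read is an identity.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.values.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)
    if metadata_path is not None:
        matrix.samples.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_interaction_table(path, *, uppercase: bool = False) -> pd.DataFrame:
    """Read a directed source->target gene interaction TSV.

    Duplicate directed pairs are dropped with a logged warning; gene symbols
    are matched case-sensitively unless ``uppercase`` normalization is on.
    """
    df = _read_table(path)
    cols = list(df.columns[:2])
    table = df.rename(columns={cols[0]: "source", cols[1]: "target"})
    for col in ("source", "target"):
        table[col] = table[col].astype(str).str.strip()
        if uppercase:
            table[col] = table[col].str.upper()
        if (table[col] == "").any():
            n = int((table[col] == "").sum())
            raise ParseError(f"{path}: {n} empty gene symbols in column {col!r}")
    n_in = len(table)
    table = table.drop_duplicates(subset=["source", "target"], ignore_index=True)
    n_dropped = n_in - len(table)
    if n_dropped:
        logger.warning("%s: dropped %d duplicate directed pairs", path, n_dropped)
    return table


def write_interaction_table(table: pd.DataFrame, path) -> None:
    table[["source", "target"]].to_csv(path, sep="\t", index=False)


def read_contours(path) -> list:
    """Read contours from CSV of (contour_id, vertex_index, x_um, y_um[, cell_type])."""
    from .imaging import Contour  # local import: avoid cycle

    df = _read_table(path, sep=",")
    required = {"contour_id", "vertex_index", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: contour CSV needs columns {sorted(required)}")
    contours = []
    for cid, grp in df.groupby("contour_id", sort=False):
        grp = grp.sort_values("vertex_index")
        verts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        label = grp["cell_type"].iloc[0] if "cell_type" in grp.columns else None
        contours.append(Contour(vertices=verts, cell_type=label, contour_id=cid))
    return contours


def write_contours(contours, path) -> None:
    rows = []
    for contour in contours:
        for i, (x, y) in enumerate(np.asarray(contour.vertices, dtype=float)):
            rows.append({"contour_id": contour.contour_id, "vertex_index": i,
                         "x_um": x, "y_um": y, "cell_type": contour.cell_type})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cell_features(path) -> pd.DataFrame:
    """Read a per-cell feature CSV (cell_id, individual, cohort, channel means)."""
    df = _read_table(path, sep=",")
    required = {"individual", "cohort"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: cell feature CSV needs columns {sorted(required)}")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = genes
    if not sets:
        raise ParseError(f"{path}: empty GMT file")
    return sets
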