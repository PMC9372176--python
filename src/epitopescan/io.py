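"""File I/O: intensity tables (TSV), metadata and serology tables (CSV).

The intensity table is a plain TSV whose header is
``peptide_id, protein_id, start, sequence`` followed by one column per
sample.  The tiling step is not stored explicitly; on read it is inferred
per protein as the most common difference between consecutive starts
(irrelevant for proteins contributing a single peptide).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import METADATA_COLUMNS, IntensityMatrix, SampleMetadata
from .library import LIBRARY_COLUMNS, PeptideLibrary

_ANNOT = ["peptide_id", "protein_id", "start", "sequence"]


def write_intensity_table(path, library: PeptideLibrary, matrix: IntensityMatrix) -> None:
    if library.peptide_ids != matrix.peptide_ids:
        raise ValueError("library and matrix are not aligned")
    out = library.df[_ANNOT].copy()
    for j, sid in enumerate(matrix.sample_ids):
        out[sid] = matrix.values[:, j]
    out.to_csv(path, sep="\t", index=False)


def _infer_steps(df: pd.DataFrame) -> np.ndarray:
    steps = np.ones(len(df), dtype=int)
    for _, idx in df.groupby("protein_id", sort=False).indices.items():
        starts = df["start"].to_numpy()[idx]
        diffs = np.diff(starts)
        diffs = diffs[diffs > 0]
        if diffs.size:
            vals, counts = np.unique(diffs, return_counts=True)
            steps[idx] = int(vals[np.argmax(counts)])
    return steps


def read_intensity_table(path) -> tuple[PeptideLibrary, IntensityMatrix]:
    """Read a TSV intensity table; returns the aligned library and matrix.

    Errors name the offending 1-based data row where possible.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "protein_id": str})
    missing = [c for c in _ANNOT if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table missing columns: {missing}")
    dup = df["peptide_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"duplicate peptide_id {df['peptide_id'].iloc[row]!r} at data row {row + 1}"
        )
    sample_cols = [c for c in df.columns if c not in _ANNOT]
    values = df[sample_cols].to_numpy(dtype=float) if sample_cols else np.zeros((len(df), 0))
    if np.isnan(values).any():
        row = int(np.argwhere(np.isnan(values))[0, 0])
        raise ValueError(f"missing/ragged intensity value at data row {row + 1}")
    if (values < 0).any():
        row = int(np.argwhere(values < 0)[0, 0])
        raise ValueError(
            f"negative intensity at data row {row + 1} "
            f"(peptide {df['peptide_id'].iloc[row]!r})"
        )
    lib_df = df[_ANNOT].copy()
    lib_df["step"] = _infer_steps(lib_df) if len(lib_df) else np.zeros(0, dtype=int)
    library = PeptideLibrary(lib_df[list(LIBRARY_COLUMNS)])
    matrix = IntensityMatrix(values, library.peptide_ids, sample_cols, library=library)
    return library, matrix


def write_library(path, library: PeptideLibrary) -> None:
    library.df.to_csv(path, sep="\t", index=False)


def read_library(path) -> PeptideLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "protein_id": str})
    return PeptideLibrary(df)


def write_metadata(path, metadata: SampleMetadata) -> None:
    metadata.df.to_csv(path, index=False)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"metadata file missing column {col!r}")
    df["outcome"] = df["outcome"].fillna("NA")
    df["anti_pla2r1"] = df["anti_pla2r1"].fillna("NA")
    return SampleMetadata(df)


def read_serology(path) -> pd.DataFrame:
    """Serology titer table: subject, group, titer (RU/ml), optional outcome."""
    df = pd.read_csv(path, dtype={"subject": str})
    for col in ("subject", "group", "titer"):
        if col not in df.columns:
            raise ValueError(f"serology table missing column {col!r}")
    if (df["titer"] < 0).any():
        raise ValueError("titers must be nonnegative")
    return df
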