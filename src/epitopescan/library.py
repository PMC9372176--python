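"""Tiled peptide libraries.

A high-density peptide array covers each protein with fixed-length peptides
(*k*-mers, default 16) placed at a fixed stride (default 3 residues; 1 for
high-resolution regions).  The :class:`PeptideLibrary` is the positional
backbone of every downstream computation: "adjacency" between two peptides —
the notion the scan statistic is built on — means consecutive tiling starts
within the same protein.

Coordinates are 1-based and inclusive: a peptide starting at ``start`` covers
protein residues ``[start, start + k - 1]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard amino acids
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

LIBRARY_COLUMNS = ("peptide_id", "protein_id", "start", "sequence", "step")


@dataclass
class PeptideLibrary:
    """An ordered collection of tiled peptides with protein coordinates.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``peptide_id, protein_id, start, sequence, step``.  Entries
        are ordered by protein (input order) and then by start; all sequences
        share one length *k*.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LIBRARY_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"library table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        ids = self.df["peptide_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate peptide_id: {dup!r}")
        if len(self.df):
            lengths = self.df["sequence"].str.len()
            if lengths.nunique() != 1:
                raise ValueError("all peptide sequences must share one length k")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def k(self) -> int:
        """Peptide length (0 for an empty library)."""
        return int(len(self.df["sequence"].iloc[0])) if len(self.df) else 0

    @property
    def peptide_ids(self) -> list[str]:
        return self.df["peptide_id"].tolist()

    # -- tiling topology -------------------------------------------------
    def adjacency(self) -> np.ndarray:
        """Boolean vector of length ``n - 1``: entry *i* is True when
        peptides *i* and *i + 1* are tiling-adjacent (same protein, start
        difference equal to the tiling step)."""
        if len(self.df) < 2:
            return np.zeros(max(len(self.df) - 1, 0), dtype=bool)
        prot = self.df["protein_id"].to_numpy()
        start = self.df["start"].to_numpy()
        step = self.df["step"].to_numpy()
        same = prot[1:] == prot[:-1]
        return same & (start[1:] - start[:-1] == step[:-1])

    def block_lengths(self) -> np.ndarray:
        """Lengths of maximal chains of tiling-adjacent peptides.

        Every peptide belongs to exactly one chain; an isolated peptide forms
        a chain of length 1.  Chains never span protein boundaries.
        """
        n = len(self.df)
        if n == 0:
            return np.zeros(0, dtype=int)
        adj = self.adjacency()
        breaks = np.flatnonzero(~adj)
        edges = np.r_[-1, breaks, n - 1]
        return np.diff(edges)


def _clean_protein(record: SeqRecord) -> str | None:
    seq = str(record.seq).upper()
    if not set(seq) <= _AA_SET:
        bad = sorted(set(seq) - _AA_SET)
        logger.warning(
            "rejecting record %s: non-amino-acid characters %s", record.id, bad
        )
        return None
    return seq


def tile_proteome(
    records: Iterable[SeqRecord], k: int = 16, step: int = 3
) -> PeptideLibrary:
    """Tile every protein of a proteome into overlapping *k*-mers.

    A protein of length ``L >= k`` yields ``floor((L - k) / step) + 1``
    peptides at starts ``1, 1 + step, ...``; shorter proteins yield none.
    Trailing residues not reached by the last full window are not rescued
    with an extra terminal window.  Records containing characters outside
    the 20 standard amino acids are rejected with a logged warning.

    Returns a :class:`PeptideLibrary` ordered by input record, then start.
    """
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    records = list(records)
    if not records:
        raise ValueError("empty FASTA: no records to tile")
    rows: list[tuple[str, str, int, str, int]] = []
    for rec in records:
        seq = _clean_protein(rec)
        if seq is None:
            continue
        L = len(seq)
        if L < k:
            continue
        for j, start0 in enumerate(range(0, L - k + 1, step)):
            rows.append(
                (f"{rec.id}|{start0 + 1}", rec.id, start0 + 1, seq[start0 : start0 + k], step)
            )
    df = pd.DataFrame(rows, columns=list(LIBRARY_COLUMNS))
    return PeptideLibrary(df)


def design_validation_library(
    hits: Sequence[tuple[str, int, int]],
    records: Iterable[SeqRecord],
    flank: int = 15,
    k: int = 16,
) -> PeptideLibrary:
    """Design a validation array from discovery hit cores.

    Each hit is a ``(protein_id, core_start, core_length)`` triple (1-based).
    The core window is extended by ``flank`` residues on each side, clipped at
    the protein termini (an array cannot display residues that do not exist),
    and the extended window is re-tiled at single-residue stride into
    *k*-mers.  Exact duplicate sequences arising from overlapping hit windows
    are removed; output is canonically ordered by (protein, start), so the
    result is invariant to hit input order.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    proteins = {rec.id: str(rec.seq).upper() for rec in records}
    seen: set[tuple[str, int]] = set()
    rows: list[tuple[str, str, int, str, int]] = []
    for protein_id, core_start, core_len in hits:
        if protein_id not in proteins:
            raise ValueError(f"hit refers to unknown protein {protein_id!r}")
        seq = proteins[protein_id]
        L = len(seq)
        if core_start < 1 or core_start + core_len - 1 > L:
            raise ValueError(
                f"hit core [{core_start}, {core_start + core_len - 1}] does not "
                f"fit protein {protein_id!r} of length {L}"
            )
        lo0 = max(core_start - 1 - flank, 0)  # 0-based window bounds
        hi0 = min(core_start - 1 + core_len + flank, L)
        for start0 in range(lo0, hi0 - k + 1):
            key = (protein_id, start0)
            if key not in seen:
                seen.add(key)
                rows.append(
                    (f"{protein_id}|{start0 + 1}", protein_id, start0 + 1,
                     seq[start0 : start0 + k], 1)
                )
    rows.sort(key=lambda r: (r[1], r[2]))
    # drop exact duplicate sequences across hits/proteins, keeping the first
    df = pd.DataFrame(rows, columns=list(LIBRARY_COLUMNS))
    df = df.drop_duplicates(subset="sequence", keep="first").reset_index(drop=True)
    return PeptideLibrary(df)
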