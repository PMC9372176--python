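"""S-PIE: sliding-window probabilistic identification of epitopes.

A true epitope on a tiled array lights up a *run* of adjacent peptides,
because consecutive probes share the recognised residues.  Isolated bright
peptides are far more likely to be noise.  S-PIE quantifies this: for a
fluorescence cut-off ``I0``, let ``P`` be the empirical probability that a
peptide of the sample exceeds ``I0``.  If exceedances were independent, a
window of ``N`` consecutive peptides would all exceed ``I0`` with
probability ``P**N``.  The statistic is the ratio

    R = P(N consecutive intensities > I0) / P(I > I0)**N ,

with both probabilities estimated empirically from all measured intensities
of the sample: the joint term is the fraction of length-``N`` windows of
tiling-adjacent peptides that are entirely above ``I0``, the marginal term
the fraction of peptides above ``I0``.  R >> 1 flags co-exceedance far in
excess of chance.

The scan walks an increasing grid of cut-offs (intensity quantiles).  At
each cut-off, every maximal run of >= 2 adjacent above-threshold peptides
is scored and R is written to all its peptides, overwriting earlier
assignments — so each peptide ends up with the R of the last (highest)
cut-off at which it still sat in a qualifying run.  Peptides never in a
qualifying run keep R = 0.

Hits are peptides whose R exceeds a cut-off (default 1e6) in at least one
case sample and in no control sample, then stripped of low-complexity
sequences (Shannon entropy below 3.17 bits, or long single-residue
repeats), which bind antibodies promiscuously.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, SampleMetadata
from .library import PeptideLibrary

logger = logging.getLogger(__name__)

#: per-sample intensity quantiles used as the increasing cut-off grid
DEFAULT_QUANTILES = (0.90, 0.95, 0.99, 0.995, 0.999, 0.9995, 0.9999)


@dataclass
class SpieConfig:
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    r_cutoff: float = 1e6
    min_run: int = 2
    min_info_bits: float = 3.17
    max_residue_run: int = 5
    min_case_hits: int = 1
    #: if set, a control peptide also suppresses a hit when its R is within
    #: this factor of the cut-off ("similar ratio"); None = strict R > cutoff
    control_slack: float | None = None

    def __post_init__(self) -> None:
        if list(self.quantiles) != sorted(set(self.quantiles)):
            raise ValueError("quantile grid must be strictly increasing")
        if not self.r_cutoff > 1:
            raise ValueError("r_cutoff must exceed 1")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")


@dataclass
class SpieResult:
    """Per-peptide, per-sample R ratios with assignment provenance.

    ``R[i, j]`` is the last-kept ratio of peptide *i* in sample *j*;
    ``I0[i, j]`` the cut-off and ``N[i, j]`` the run length at which it was
    assigned (NaN / 0 where the peptide was never in a qualifying run).
    """

    R: np.ndarray
    I0: np.ndarray
    N: np.ndarray
    peptide_ids: list[str]
    sample_ids: list[str]


def marginal_exceedance(intensities: np.ndarray, i0: float) -> float:
    """Empirical P(I > I0) over all measured intensities of a sample."""
    v = np.asarray(intensities, dtype=float)
    if v.size == 0:
        raise ValueError("empty intensity vector")
    return float(np.mean(v > i0))


def joint_run_exceedance(intensities: np.ndarray, i0: float, n: int) -> float:
    """Empirical P(N consecutive intensities > I0) within one protein.

    ``intensities`` must be ordered by tiling position; the probability is
    the fraction of the ``len - N + 1`` windows of ``n`` consecutive
    peptides that are entirely above ``i0``.
    """
    v = np.asarray(intensities, dtype=float)
    if n < 2:
        raise ValueError("run length N must be >= 2")
    if v.size < n:
        raise ValueError(f"run length {n} exceeds vector length {v.size}")
    above = (v > i0).astype(int)
    window_sums = np.convolve(above, np.ones(n, dtype=int), mode="valid")
    return float(np.mean(window_sums == n))


def _maximal_runs(above: np.ndarray, adjacent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and lengths of maximal runs of above-threshold peptides that
    are pairwise tiling-adjacent.  Includes length-1 runs."""
    n = above.size
    if n == 0:
        return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    is_start = above & np.r_[True, (~above[:-1]) | (~adjacent)]
    is_end = above & np.r_[(~above[1:]) | (~adjacent), True]
    starts = np.flatnonzero(is_start)
    ends = np.flatnonzero(is_end)
    return starts, ends - starts + 1


def _window_totals(block_lengths: np.ndarray, n: int) -> int:
    """Number of windows of ``n`` consecutive tiling-adjacent peptides."""
    return int(np.maximum(block_lengths - n + 1, 0).sum())


def compute_R_profile(
    matrix: IntensityMatrix,
    library: PeptideLibrary,
    config: SpieConfig,
    sample_id: str,
) -> SpieResult:
    """Run the S-PIE scan for one sample; see the module docstring.

    The cut-off grid is the sample's own intensity quantiles.  The scan
    stops early (with a log message) at any grid point where no intensity
    exceeds the cut-off, since the marginal probability would be zero.
    """
    v = matrix.column(sample_id)
    adjacent = library.adjacency()
    blocks = library.block_lengths()
    R = np.zeros(v.size)
    I0_assigned = np.full(v.size, np.nan)
    N_assigned = np.zeros(v.size, dtype=int)

    grid = np.quantile(v, config.quantiles) if v.size else np.zeros(0)
    for q, i0 in zip(config.quantiles, grid):
        above = v > i0
        p = above.mean()
        if p == 0.0:
            logger.info(
                "sample %s: no exceedance at quantile %g; stopping the grid",
                sample_id, q,
            )
            break
        starts, lengths = _maximal_runs(above, adjacent)
        keep = lengths >= config.min_run
        starts, lengths = starts[keep], lengths[keep]
        if starts.size == 0:
            continue
        # joint probability per distinct run length, pooled over the sample:
        # all-above windows of length N live inside maximal above-runs
        for n in np.unique(lengths):
            total = _window_totals(blocks, n)
            hit_windows = int(np.maximum(lengths - n + 1, 0).sum())
            joint = hit_windows / total if total else 0.0
            r = joint / p**int(n)
            for s in starts[lengths == n]:
                sl = slice(int(s), int(s + n))
                R[sl] = r
                I0_assigned[sl] = i0
                N_assigned[sl] = int(n)
    return SpieResult(
        R=R[:, None], I0=I0_assigned[:, None], N=N_assigned[:, None],
        peptide_ids=matrix.peptide_ids, sample_ids=[sample_id],
    )


def compute_spie(
    matrix: IntensityMatrix, library: PeptideLibrary, config: SpieConfig | None = None
) -> SpieResult:
    """Run the scan for every sample of the matrix."""
    config = config or SpieConfig()
    slices = [
        compute_R_profile(matrix, library, config, sid) for sid in matrix.sample_ids
    ]
    return SpieResult(
        R=np.hstack([s.R for s in slices]),
        I0=np.hstack([s.I0 for s in slices]),
        N=np.hstack([s.N for s in slices]),
        peptide_ids=matrix.peptide_ids,
        sample_ids=list(matrix.sample_ids),
    )


def select_spie_hits(
    result: SpieResult,
    metadata: SampleMetadata,
    config: SpieConfig | None = None,
) -> pd.DataFrame:
    """Call hit peptides with control subtraction.

    A peptide is a hit when R exceeds the cut-off in at least
    ``min_case_hits`` case samples and a similarly high ratio is seen in no
    control ("similar" defaults to the same strict cut-off; a slack factor
    can relax it).  Returns one row per peptide with per-group evidence and
    the boolean ``hit`` flag.
    """
    config = config or SpieConfig()
    case_ids = [s for s in metadata.case_ids if s in result.sample_ids]
    control_ids = [s for s in metadata.control_ids if s in result.sample_ids]
    if not case_ids:
        raise ValueError("no case samples present in the S-PIE result")
    col = {s: j for j, s in enumerate(result.sample_ids)}
    case_R = result.R[:, [col[s] for s in case_ids]]
    n_case = (case_R > config.r_cutoff).sum(axis=1)
    control_flagged = True
    if control_ids:
        control_R = result.R[:, [col[s] for s in control_ids]]
        ctrl_cut = config.r_cutoff
        if config.control_slack is not None:
            ctrl_cut = config.r_cutoff / config.control_slack
        n_control = (control_R > ctrl_cut).sum(axis=1)
    else:
        logger.warning("no control samples: control subtraction skipped")
        n_control = np.zeros(len(result.peptide_ids), dtype=int)
        control_flagged = False
    hit = (n_case >= config.min_case_hits) & (n_control == 0)
    return pd.DataFrame(
        {
            "peptide_id": result.peptide_ids,
            "best_R": result.R.max(axis=1),
            "n_case_hits": n_case,
            "n_control_hits": n_control,
            "control_subtracted": control_flagged,
            "hit": hit,
        }
    )


def shannon_information(sequence: str) -> float:
    """Shannon entropy of a peptide's residue composition, in bits.

    ``H = -sum_a f_a log2 f_a`` over the residue frequencies of the
    sequence; ranges from 0 (homopolymer) to ``log2(min(20, len))``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence)
    n = len(sequence)
    return -sum((c / n) * math.log2(c / n) for c in counts.values()) + 0.0


def longest_residue_run(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if sequence else 0


def filter_low_complexity(
    peptides: pd.DataFrame,
    min_info: float = 3.17,
    max_run: int = 5,
) -> pd.DataFrame:
    """Drop low-complexity sequences from a peptide table.

    Keeps rows whose sequence has Shannon entropy >= ``min_info`` bits and
    no single-residue run longer than ``max_run``.  Adds a ``shannon_bits``
    column; input must carry a ``sequence`` column.
    """
    bits = peptides["sequence"].map(shannon_information)
    runs = peptides["sequence"].map(longest_residue_run)
    out = peptides.copy()
    out["shannon_bits"] = bits
    return out[(bits >= min_info) & (runs <= max_run)].reset_index(drop=True)
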