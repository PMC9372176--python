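"""Weighted co-expression analysis of peptide reactivity profiles.

The stage mirrors the classical weighted gene co-expression workflow,
re-implemented from its published formulas on peptide intensity profiles:

1. keep peptides whose reactivity is elevated in cases over controls;
2. choose a soft-threshold power ``beta`` by the scale-free topology fit;
3. adjacency ``a_ij = |cor(x_i, x_j)|**beta`` (unsigned network);
4. topological overlap ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
   with ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
5. average-linkage hierarchical clustering of ``1 - TOM`` with a static
   height cut and a minimum module size (default 30 peptides);
6. module eigengenes (first principal component of the standardized module
   submatrix) and their rank correlation with clinical traits, with
   Benjamini-Hochberg correction across the module x trait table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .containers import IntensityMatrix, SampleMetadata

logger = logging.getLogger(__name__)

UNASSIGNED = 0  # sentinel module label


@dataclass
class CoexpressionModel:
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    labels: np.ndarray            # per peptide; 0 = unassigned
    eigengenes: pd.DataFrame      # samples x modules ("ME1", "ME2", ...)
    peptide_ids: list[str]
    sample_ids: list[str]


def filter_case_elevated(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    stat: str = "median",
    case_group: str = "MN",
    control_group: str = "healthy",
) -> np.ndarray:
    """Boolean mask of peptides whose case-group location exceeds controls.

    ``stat`` is ``"median"`` or ``"mean"``; the two can disagree on skewed
    peptides (a single extreme case sample moves the mean, not the median).
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    case_cols = [col[s] for s in metadata.ids_in_group(case_group) if s in col]
    ctrl_cols = [col[s] for s in metadata.ids_in_group(control_group) if s in col]
    if not case_cols or not ctrl_cols:
        raise ValueError("both case and control groups must be present")
    fn = np.median if stat == "median" else np.mean
    case = fn(matrix.values[:, case_cols], axis=1)
    ctrl = fn(matrix.values[:, ctrl_cols], axis=1)
    return case > ctrl


def _correlation(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between peptide profiles (rows of ``values``)."""
    sd = values.std(axis=1)
    if (sd == 0).any():
        offenders = list(np.flatnonzero(sd == 0)[:10])
        raise ValueError(f"zero-variance peptides at rows {offenders}")
    c = np.corrcoef(values)
    return np.clip(c, -1.0, 1.0)


def adjacency_matrix(values: np.ndarray, beta: int) -> np.ndarray:
    """Unsigned weighted adjacency ``|cor|**beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.abs(_correlation(values)) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(values: np.ndarray, beta: int, n_bins: int = 10) -> float:
    """R-squared of the scale-free topology fit at power ``beta``.

    Connectivities ``k_i`` are binned; the fit regresses log10 bin frequency
    on log10 mean connectivity per bin.
    """
    a = adjacency_matrix(values, beta)
    k = a.sum(axis=0) - 1.0
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    freq, _ = np.histogram(k, bins=edges)
    centers = np.array(
        [k[(k >= lo) & (k < hi)].mean() if f else np.nan
         for lo, hi, f in zip(edges[:-1], edges[1:], freq)]
    )
    ok = (freq > 0) & np.isfinite(centers) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(freq[ok] / freq.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def pick_soft_threshold(
    values: np.ndarray,
    target_fit: float = 0.9,
    powers: range = range(1, 21),
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches ``target_fit``.

    If no candidate reaches the target, the power with the maximal fit is
    returned with a warning.  Constant peptide rows are dropped first.
    Returns ``(beta, table)`` where the table lists the fit per power.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sd = values.std(axis=1)
    if (sd == 0).any():
        logger.warning("dropping %d constant peptides", int((sd == 0).sum()))
        values = values[sd > 0]
    if values.shape[0] < 3:
        raise ValueError("too few variable peptides for a degree distribution")
    fits = [(b, scale_free_fit(values, b)) for b in powers]
    table = pd.DataFrame(fits, columns=["power", "fit_r2"])
    reaching = table[table["fit_r2"] >= target_fit]
    if len(reaching):
        beta = int(reaching["power"].iloc[0])
    else:
        beta = int(table.loc[table["fit_r2"].idxmax(), "power"])
        logger.warning(
            "no power reaches scale-free fit %.2f; using power %d (fit %.3f)",
            target_fit, beta, table["fit_r2"].max(),
        )
    return beta, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where ``l_ij``
    counts shared-neighbour adjacency and ``k_i`` is the connectivity.
    The diagonal is set to 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    k = a.sum(axis=0) - np.diag(a)
    # l_ij excluding u in {i, j}; with unit diagonal (A @ A)_ij counts both
    l = a @ a - a * (np.diag(a)[:, None] + np.diag(a)[None, :])
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray, min_size: int = 30, cut_fraction: float = 0.99
) -> np.ndarray:
    """Assign module labels by average-linkage clustering of ``1 - TOM``.

    The tree is cut at ``cut_fraction`` of the merge-height range (a static
    cut, fully deterministic); clusters smaller than ``min_size`` become
    unassigned (label 0).  Surviving modules are relabelled 1, 2, ... by
    decreasing size (ties broken by first member) so labels are stable.
    """
    n = tom.shape[0]
    if n < min_size:
        logger.warning("fewer peptides (%d) than min module size %d", n, min_size)
        return np.full(n, UNASSIGNED, dtype=int)
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    lo, hi = float(heights.min()), float(heights.max())
    threshold = lo + cut_fraction * (hi - lo)
    raw = fcluster(z, t=threshold, criterion="distance")
    labels = np.full(n, UNASSIGNED, dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_size]
    # order: larger modules first, then first occurrence
    first_pos = {c: int(np.flatnonzero(raw == c)[0]) for c in kept}
    kept.sort(key=lambda c: (-sizes[c], first_pos[c]))
    for new, c in enumerate(kept, start=1):
        labels[raw == c] = new
    return labels


def module_eigengene(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """First-principal-component summary profile of each module.

    Each module's submatrix is z-scored per peptide; the eigengene is the
    leading left-singular vector over samples, sign-oriented to correlate
    positively with the module's mean z-scored profile.  A one-peptide
    module's eigengene is that peptide's z-scored profile (unit norm).
    """
    values = np.asarray(values, dtype=float)
    modules = sorted(set(labels) - {UNASSIGNED})
    mes = {}
    for m in modules:
        sub = values[labels == m]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)
        me = u[:, 0]
        mean_profile = z.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        mes[f"ME{m}"] = me
    return pd.DataFrame(mes)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of each eigengene with each clinical trait.

    Missing trait values are dropped pairwise; BH adjustment runs across the
    whole module x trait table.  Constant traits yield NA with a reason.
    """
    rows = []
    for me in eigengenes.columns:
        for trait in traits.columns:
            x = eigengenes[me].to_numpy()
            y = pd.to_numeric(traits[trait], errors="coerce").to_numpy()
            ok = np.isfinite(y)
            if ok.sum() < 3:
                rows.append((me, trait, np.nan, np.nan, "fewer than 3 pairs"))
                continue
            if np.ptp(y[ok]) == 0:
                rows.append((me, trait, np.nan, np.nan, "constant trait"))
                continue
            rho, p = spearmanr(x[ok], y[ok])
            rows.append((me, trait, float(rho), float(p), ""))
    table = pd.DataFrame(rows, columns=["module", "trait", "rho", "p", "note"])
    ok = table["p"].notna()
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    return table


def fit_coexpression(
    matrix: IntensityMatrix,
    metadata: SampleMetadata | None = None,
    traits: pd.DataFrame | None = None,
    beta: int | None = None,
    min_size: int = 30,
    prefilter_stat: str | None = "median",
    log_transform: bool = True,
) -> tuple[CoexpressionModel, pd.DataFrame | None]:
    """End-to-end co-expression pipeline on an intensity matrix.

    Optionally prefilters case-elevated peptides (requires metadata), picks
    ``beta`` by the scale-free criterion when not given, and correlates
    eigengenes with ``traits`` (a DataFrame indexed like the samples).
    Correlation is computed on log2(I + 1) profiles by default.
    """
    values = matrix.values
    peptide_ids = list(matrix.peptide_ids)
    if prefilter_stat is not None and metadata is not None:
        mask = filter_case_elevated(matrix, metadata, stat=prefilter_stat)
        values = values[mask]
        peptide_ids = [p for p, m in zip(peptide_ids, mask) if m]
    if log_transform:
        values = np.log2(values + 1.0)
    if beta is None:
        beta, _ = pick_soft_threshold(values)
    adj = adjacency_matrix(values, beta)
    tom = tom_similarity(adj)
    labels = detect_modules(tom, min_size=min_size)
    mes = module_eigengene(values, labels)
    model = CoexpressionModel(
        beta=beta, adjacency=adj, tom=tom, labels=labels,
        eigengenes=mes, peptide_ids=peptide_ids, sample_ids=list(matrix.sample_ids),
    )
    table = None
    if traits is not None and len(mes.columns):
        trait_cols = traits.drop(columns=["sample_id"], errors="ignore")
        table = module_trait_correlation(mes, trait_cols)
    return model, table
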