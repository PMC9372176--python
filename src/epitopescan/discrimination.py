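"""Validation-array discrimination statistics.

After the discovery stage nominates candidate epitopes, a denser validation
array is probed on a larger cohort and several complementary statistics are
run per peptide: classical MDS for cohort-level separation, Welch t-tests
with Benjamini-Hochberg adjustment and a fold-change threshold (volcano),
ANOVA-ranked linear SVM with repeated learning/holdout splits, and PLS-DA
variable-importance (VIP) scores.  Hit sets from the different methods are
combined and rolled up from peptides to proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr, ttest_ind
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .containers import IntensityMatrix
from .library import PeptideLibrary

logger = logging.getLogger(__name__)


def mds_embed(matrix: IntensityMatrix, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of samples on Spearman dissimilarity.

    The distance between two samples is ``1 - rho`` of their peptide
    profiles.  Coordinates are deterministic up to axis sign; the sign is
    canonicalised so each axis' largest-magnitude loading is positive.
    """
    n = matrix.n_samples
    if n < n_dims + 1:
        raise ValueError(f"need at least {n_dims + 1} samples for {n_dims} dimensions")
    rho = spearmanr(matrix.values).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_dims]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    for axis in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, axis]))
        if coords[i, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return coords


@dataclass
class VolcanoCurve:
    """Significance boundary ``y = c / (x - x0)`` in (|log2FC|, -log10 p)
    coordinates; cosmetic — hit calling uses the thresholds directly."""

    c: float
    x0: float = 1.0

    def y(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(x > self.x0, self.c / (x - self.x0), np.inf)


def differential_peptides(
    matrix: IntensityMatrix,
    groups: np.ndarray,
    alpha: float = 0.05,
    min_fc: float = 2.0,
) -> tuple[pd.DataFrame, VolcanoCurve]:
    """Per-peptide Welch t-tests on log2 intensities with BH adjustment.

    ``groups`` is a boolean/int vector over samples (True = case).  A
    peptide is a hit when adjusted p <= ``alpha`` and |log2 fold change| >=
    log2(``min_fc``).  Peptides constant in both groups get p = 1.
    """
    groups = np.asarray(groups).astype(bool)
    if groups.sum() < 2 or (~groups).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    logx = np.log2(matrix.values + 1.0)
    a, b = logx[:, groups], logx[:, ~groups]
    t, p = ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d zero-variance peptides set to p = 1", int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
        t = np.where(degenerate, 0.0, t)
    p_adj = multipletests(p, method="fdr_bh")[1]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    hit = (p_adj <= alpha) & (np.abs(log2fc) >= np.log2(min_fc))
    table = pd.DataFrame(
        {
            "peptide_id": matrix.peptide_ids,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "log2fc": log2fc,
            "hit_ttest": hit,
        }
    )
    x0 = 1.0
    # curve anchored so it passes through (2, -log10 alpha)
    curve = VolcanoCurve(c=(2.0 - x0) * (-np.log10(alpha)), x0=x0)
    return table, curve


def svm_rank(
    matrix: IntensityMatrix,
    labels: np.ndarray,
    folds: int = 4,
    learn_frac: float = 0.65,
    n_repeats: int = 200,
    seed: int = 0,
    top_k: int = 50,
) -> tuple[np.ndarray, dict[str, float]]:
    """ANOVA-ranked linear-SVM peptide ranking with repeated splits.

    For each of ``n_repeats`` stratified learning/holdout splits (default
    65/35), peptides are ranked by their ANOVA F statistic on the learning
    part; a linear SVM on the ``top_k`` peptides is scored by ``folds``-fold
    CV within the learning split and on the holdout.  Mean rank positions
    are converted to final integer ranks 0 (best) .. n-1.

    Returns ``(ranks, accuracy)`` where accuracy holds the mean CV and
    holdout accuracies.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("svm_rank requires exactly two classes")
    if matrix.n_samples < 8:
        raise ValueError("need at least 8 samples")
    X = np.log2(matrix.values + 1.0).T  # samples x peptides
    n_pep = X.shape[1]
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=learn_frac, random_state=seed
    )
    rank_sum = np.zeros(n_pep)
    cv_accs, hold_accs = [], []
    for learn_idx, hold_idx in splitter.split(X, y):
        f, _ = f_classif(X[learn_idx], y[learn_idx])
        f = np.nan_to_num(f, nan=0.0)
        order = np.argsort(-f, kind="stable")
        pos = np.empty(n_pep)
        pos[order] = np.arange(n_pep)
        rank_sum += pos
        top = order[: min(top_k, n_pep)]
        clf = SVC(kernel="linear", C=1.0)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in cv.split(X[learn_idx][:, top], y[learn_idx]):
            clf.fit(X[learn_idx][tr][:, top], y[learn_idx][tr])
            accs.append(clf.score(X[learn_idx][te][:, top], y[learn_idx][te]))
        cv_accs.append(float(np.mean(accs)))
        clf.fit(X[learn_idx][:, top], y[learn_idx])
        hold_accs.append(float(clf.score(X[hold_idx][:, top], y[hold_idx])))
    mean_rank = rank_sum / n_repeats
    final = np.empty(n_pep, dtype=int)
    final[np.argsort(mean_rank, kind="stable")] = np.arange(n_pep)
    return final, {
        "cv_accuracy": float(np.mean(cv_accs)),
        "holdout_accuracy": float(np.mean(hold_accs)),
    }


def plsda_vip(
    matrix: IntensityMatrix, labels: np.ndarray, n_components: int = 2
) -> np.ndarray:
    """VIP scores from a PLS-DA fit.

    ``VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a)`` over the fitted
    components, so the mean squared VIP equals 1.  ``n_components`` is
    reduced with a warning if it exceeds what the data support.
    """
    y = np.asarray(labels).astype(float)
    X = np.log2(matrix.values + 1.0).T
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        logger.warning("reducing n_components from %d to %d", n_components, max_comp)
        n_components = max_comp
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, y)
    w = pls.x_weights_            # p x a
    t = pls.x_scores_             # n x a
    q = pls.y_loadings_.ravel()   # a
    ssy = np.sum(t**2, axis=0) * q**2
    p = X.shape[1]
    wnorm2 = (w / np.linalg.norm(w, axis=0, keepdims=True)) ** 2
    vip = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())
    return vip


def combine_hit_sets(sets: dict[str, set]) -> tuple[set, pd.DataFrame]:
    """Union of named hit sets with inclusion-exclusion accounting.

    Returns the union and a table of per-set sizes plus pairwise
    intersections; the identity ``|A u B| = |A| + |B| - |A n B|`` is
    asserted for every pair.
    """
    names = list(sets)
    union: set = set().union(*sets.values()) if sets else set()
    rows = [("union", "", len(union))]
    for name in names:
        rows.append((name, "", len(sets[name])))
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = len(sets[a] & sets[b])
            assert len(sets[a] | sets[b]) == len(sets[a]) + len(sets[b]) - inter
            rows.append((a, b, inter))
    return union, pd.DataFrame(rows, columns=["set_a", "set_b", "size"])


def rollup_proteins(
    hit_peptides: list[str],
    matrix: IntensityMatrix,
    library: PeptideLibrary,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, list[int]]]:
    """Protein-level mean intensity profiles of hit peptides.

    Each protein's profile is the mean over its hit peptides' intensity
    profiles; rows are z-scored for heatmap display, and unsupervised
    average-linkage clustering orders for rows and columns are returned.
    """
    idx = {p: i for i, p in enumerate(matrix.peptide_ids)}
    missing = [p for p in hit_peptides if p not in idx]
    if missing:
        raise ValueError(f"hit peptides absent from the matrix: {missing[:5]}")
    lib = library.df.set_index("peptide_id")
    unknown = [p for p in hit_peptides if p not in lib.index]
    if unknown:
        raise ValueError(f"hit peptides absent from the library: {unknown[:5]}")
    by_protein: dict[str, list[int]] = {}
    for p in hit_peptides:
        by_protein.setdefault(str(lib.loc[p, "protein_id"]), []).append(idx[p])
    proteins = sorted(by_protein)
    profiles = np.vstack([matrix.values[by_protein[pr]].mean(axis=0) for pr in proteins])
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (profiles - mu) / sd
    table = pd.DataFrame(z, index=proteins, columns=matrix.sample_ids)
    row_order = (
        leaves_list(linkage(pdist(z), method="average")) if len(proteins) > 1
        else np.array([0])
    )
    col_order = (
        leaves_list(linkage(pdist(z.T), method="average")) if z.shape[1] > 1
        else np.array([0])
    )
    orders = {"rows": row_order.tolist(), "cols": col_order.tolist()}
    return table, z, orders
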