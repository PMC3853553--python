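"""Between-group diet comparison: Pearson chi-square on pooled tables,
abundance-based Chao dissimilarity, nonmetric multidimensional scaling,
and ANOSIM permutation tests.

The Chao abundance-based Jaccard index estimates the similarity two
samples would show if rare shared species had been fully observed: the
raw shared-read fractions U and V are inflated by a term driven by shared
species that are singletons or doubletons in the other sample.  Sample
configurations are ordinated by NMDS (Kruskal stress-1 minimised by
alternating isotonic regression and Guttman updates), and group structure
is tested by ANOSIM, a rank-based permutation test whose statistic R
contrasts mean between-group and within-group dissimilarity ranks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix


class CommunityStatsError(ValueError):
    pass


# ----------------------------------------------------------------------
# Pearson chi-square
# ----------------------------------------------------------------------

def pearson_chisq(table: pd.DataFrame) -> tuple[float, int, float]:
    """Classic Pearson chi-square test of independence on a count table.

    Rows or columns with a zero margin carry no information about
    association and are dropped with a warning before testing.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise CommunityStatsError("table must be two-dimensional")
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns from chi-square table")
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise CommunityStatsError("chi-square needs at least a 2x2 table")
    x2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(x2), int(df), float(p)


# ----------------------------------------------------------------------
# Chao abundance-based dissimilarity
# ----------------------------------------------------------------------

def _chao_u(x: np.ndarray, y: np.ndarray, shared: np.ndarray) -> float:
    """Estimated total relative abundance in x of species shared with y."""
    n = x.sum()
    m = y.sum()
    u_obs = x[shared].sum() / n
    f1 = int((y[shared] == 1).sum())  # shared species that are singletons in y
    f2 = int((y[shared] == 2).sum())  # ... doubletons in y
    f2_eff = f2 if f2 > 0 else 1
    rare = x[shared & (y == 1)].sum() / n
    u = u_obs + (m - 1) / m * f1 / (2 * f2_eff) * rare
    return min(float(u), 1.0)


def chao_dissimilarity(x, y) -> float:
    """Chao abundance-based Jaccard dissimilarity between two count vectors.

    With U and V the (unseen-species-corrected) shared relative abundances
    of each sample, similarity = UV / (U + V - UV) and the dissimilarity is
    its complement, lying in [0, 1]: 0 for identical samples, 1 for samples
    sharing no species.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CommunityStatsError("count vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise CommunityStatsError("counts must be non-negative")
    if x.sum() == 0 or y.sum() == 0:
        raise CommunityStatsError("empty sample")
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return 1.0
    u = _chao_u(x, y, shared)
    v = _chao_u(y, x, shared)
    if u == 0 or v == 0:
        return 1.0
    sim = u * v / (u + v - u * v)
    return float(1.0 - sim)


def jaccard_dissimilarity(x, y) -> float:
    """Classic Jaccard dissimilarity on presence/absence of two vectors."""
    x = np.asarray(x, dtype=float) > 0
    y = np.asarray(y, dtype=float) > 0
    union = (x | y).sum()
    if union == 0:
        raise CommunityStatsError("empty sample")
    return float(1.0 - (x & y).sum() / union)


def dissimilarity_matrix(m: pd.DataFrame, metric: str = "chao") -> DistanceMatrix:
    """Pairwise sample dissimilarities of a diet matrix.

    ``metric="chao"`` uses read counts; ``metric="jaccard"`` reduces the
    matrix to presence/absence first (the standard binary counterpart).
    """
    if metric == "chao":
        fn = chao_dissimilarity
    elif metric == "jaccard":
        fn = jaccard_dissimilarity
    else:
        raise CommunityStatsError(f"unknown metric: {metric}")
    ids = list(m.index)
    data = m.to_numpy(dtype=float)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(data[i], data[j])
    return DistanceMatrix(out, ids)


# ----------------------------------------------------------------------
# NMDS
# ----------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centred at the origin
    stress: float  # Kruskal stress-1 of the best start
    n_starts: int
    converged: bool
    seed: int | None
    stress_trace: list[float] = field(default_factory=list)


def _tie_blocks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted order of the input dissimilarities and tie-block ids."""
    order = np.argsort(d, kind="stable")
    sorted_d = d[order]
    block = np.zeros(len(d), dtype=int)
    block[1:] = np.cumsum(sorted_d[1:] != sorted_d[:-1])
    return order, block


def _disparities(dhat: np.ndarray, order: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Monotone disparities: isotonic regression of configuration distances
    on the rank order of the input dissimilarities, ties averaged."""
    y = dhat[order]
    n_blocks = block[-1] + 1
    sums = np.bincount(block, weights=y, minlength=n_blocks)
    sizes = np.bincount(block, minlength=n_blocks).astype(float)
    means = sums / sizes
    fitted = isotonic_regression(means, weights=sizes, increasing=True).x
    disp_sorted = fitted[block]
    disp = np.empty_like(y)
    disp[order] = disp_sorted
    return disp


def _stress1(dhat: np.ndarray, disp: np.ndarray) -> float:
    denom = (dhat**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - disp) ** 2).sum() / denom))


def _nmds_single(
    d: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    """One NMDS start: alternate isotonic fit and Guttman transform.

    An update that would increase stress is rejected and terminates the
    start, so the recorded stress trace is non-increasing by construction.
    """
    n = x0.shape[0]
    order, block = _tie_blocks(d)
    x = x0.copy()
    dhat = pdist(x)
    dhat[dhat == 0] = 1e-12
    disp = _disparities(dhat, order, block)
    stress = _stress1(dhat, disp)
    trace = [stress]
    converged = False
    for _ in range(max_iter):
        ratio = squareform(disp / dhat)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x_new = b @ x / n
        dhat_new = pdist(x_new)
        dhat_new[dhat_new == 0] = 1e-12
        disp_new = _disparities(dhat_new, order, block)
        stress_new = _stress1(dhat_new, disp_new)
        if stress_new > stress:
            converged = True
            break
        x, dhat, disp = x_new, dhat_new, disp_new
        improvement = stress - stress_new
        stress = stress_new
        trace.append(stress)
        if improvement < tol:
            converged = True
            break
    return x, stress, trace, converged


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling minimising Kruskal stress-1.

    Runs ``n_starts`` random initialisations and returns the lowest-stress
    configuration, centred at the origin.  Deterministic given ``seed``.
    """
    d = D.condensed_form()
    n = D.shape[0]
    if n < 3:
        raise CommunityStatsError("NMDS needs at least three samples")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        x0 = rng.normal(size=(n, k))
        x, stress, trace, converged = _nmds_single(d, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, trace, converged)
    x, stress, trace, converged = best
    x = x - x.mean(axis=0)
    coords = pd.DataFrame(x, index=list(D.ids), columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(
        coordinates=coords,
        stress=stress,
        n_starts=n_starts,
        converged=converged,
        seed=seed,
        stress_trace=trace,
    )


# ----------------------------------------------------------------------
# ANOSIM
# ----------------------------------------------------------------------

@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int | None


def _anosim_r(rank_d: np.ndarray, within: np.ndarray) -> float:
    n_pairs = len(rank_d)
    # n(n-1)/4 with n samples; n_pairs = n(n-1)/2
    denom = n_pairs / 2.0
    return float((rank_d[~within].mean() - rank_d[within].mean()) / denom)


def _within_mask(labels: np.ndarray) -> np.ndarray:
    n = len(labels)
    idx = np.triu_indices(n, k=1)
    return labels[idx[0]] == labels[idx[1]]


def anosim_r(D: DistanceMatrix, grouping) -> float:
    """Observed ANOSIM R statistic (no permutation test)."""
    labels = np.asarray([grouping[i] for i in D.ids])
    if len(set(labels.tolist())) < 2:
        raise CommunityStatsError("ANOSIM needs at least two groups")
    rank_d = stats.rankdata(D.condensed_form())
    return _anosim_r(rank_d, _within_mask(labels))


def anosim(
    D: DistanceMatrix, grouping, n_perm: int = 999, seed: int | None = None
) -> AnosimResult:
    """ANOSIM permutation test of group separation on a dissimilarity matrix.

    Dissimilarities are rank-transformed (mean ranks for ties);
    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).
    The p-value uses the add-one permutation estimator
    ``(1 + #{R_perm >= R_obs}) / (1 + n_perm)``.
    """
    labels = np.asarray([grouping[i] for i in D.ids])
    if len(set(labels.tolist())) < 2:
        raise CommunityStatsError("ANOSIM needs at least two groups")
    rank_d = stats.rankdata(D.condensed_form())
    r_obs = _anosim_r(rank_d, _within_mask(labels))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(rank_d, _within_mask(perm)) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AnosimResult(R=r_obs, p=float(p), n_permutations=n_perm, seed=seed)


def anosim_exact(D: DistanceMatrix, grouping) -> tuple[float, float]:
    """Exact ANOSIM p-value by enumerating all distinct label assignments.

    Only feasible for small n; used as an independent check of the
    permutation estimator.
    """
    labels = np.asarray([grouping[i] for i in D.ids])
    rank_d = stats.rankdata(D.condensed_form())
    r_obs = _anosim_r(rank_d, _within_mask(labels))
    values, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    positions = set(range(n))
    assignments = []

    def _enumerate(remaining: set, group_idx: int, current: dict):
        if group_idx == len(values) - 1:
            assignment = dict(current)
            for pos in remaining:
                assignment[pos] = values[-1]
            assignments.append(assignment)
            return
        for combo in itertools.combinations(sorted(remaining), counts[group_idx]):
            nxt = dict(current)
            for pos in combo:
                nxt[pos] = values[group_idx]
            _enumerate(remaining - set(combo), group_idx + 1, nxt)

    _enumerate(positions, 0, {})
    hits = 0
    for assignment in assignments:
        perm = np.asarray([assignment[i] for i in range(n)])
        if _anosim_r(rank_d, _within_mask(perm)) >= r_obs:
            hits += 1
    return r_obs, hits / len(assignments)
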