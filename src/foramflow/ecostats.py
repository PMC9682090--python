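"""Distance-based community statistics: Bray-Curtis, ANOSIM, PermANOVA
(one-way and sequential multifactor with nested terms) and nonmetric MDS.

Permutation tests use 999 permutations and the add-one convention
p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations), so the
smallest attainable p with 999 permutations is 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .community import CommunityMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with sample ids."""

    values: np.ndarray
    ids: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids must match matrix size")
        self.values = v
        self.ids = tuple(self.ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class PermutationResult:
    """A permutation test outcome: the statistic(s), p-value and provenance."""

    statistic: float                 # ANOSIM R, or pseudo-F
    p_value: float
    n_permutations: int
    seed: Optional[int] = None
    r_squared: Optional[float] = None
    extras: dict = field(default_factory=dict)


def bray_curtis(matrix: CommunityMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarities d(x,y) = 1 - 2 sum(min) / sum(x + y)."""
    counts = matrix.counts
    totals = counts.sum(axis=1)
    empty = list(totals.index[totals == 0])
    if empty:
        raise ValueError(
            f"samples with zero total counts have undefined Bray-Curtis "
            f"distances: {empty}")
    vals = squareform(pdist(counts.to_numpy(float), metric="braycurtis"))
    return DistanceMatrix(vals, tuple(counts.index))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim_r(d: DistanceMatrix, groups: Sequence) -> float:
    """The ANOSIM R statistic on average-ranked dissimilarities."""
    groups = np.asarray(groups)
    ranks = rankdata(d.condensed())       # average ranks on ties
    return _anosim_r_from_ranks(ranks, _within_mask(groups), d.n)


def _within_mask(groups: np.ndarray) -> np.ndarray:
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    return groups[iu[0]] == groups[iu[1]]


def _anosim_r_from_ranks(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    m = n * (n - 1) / 2
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return (r_b - r_w) / (m / 2.0)


def anosim(d: DistanceMatrix, groups: Sequence, n_perm: int = 999,
           seed: int | np.random.Generator = 0) -> PermutationResult:
    """Analysis of similarities with free label permutation.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; p by the add-one convention.
    """
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")
    rng = np.random.default_rng(seed)
    ranks = rankdata(d.condensed())
    observed = _anosim_r_from_ranks(ranks, _within_mask(groups), d.n)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        r = _anosim_r_from_ranks(ranks, _within_mask(perm), d.n)
        if r >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermutationResult(observed, p, n_perm,
                             seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# PermANOVA
# ---------------------------------------------------------------------------

def _oneway_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += np.triu(sub, k=1).sum() / len(idx)
    return ss_total, ss_within


def permanova_oneway(d: DistanceMatrix, groups: Sequence, n_perm: int = 999,
                     seed: int | np.random.Generator = 0) -> PermutationResult:
    """One-way permutational MANOVA (pseudo-F on a distance matrix).

    SS_total = sum_{i<j} d_ij^2 / n; SS_within = sum_g sum_{i<j in g}
    d_ij^2 / n_g; F = (SS_between/(a-1)) / (SS_within/(n-a)); free
    permutation of sample identities.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("PermANOVA needs at least two groups")
    n = d.n
    a = len(labels)
    d2 = d.values ** 2
    rng = np.random.default_rng(seed)

    def f_and_r2(g: np.ndarray) -> tuple[float, float]:
        ss_total, ss_within = _oneway_ss(d2, g)
        ss_between = ss_total - ss_within
        r2 = ss_between / ss_total if ss_total > 0 else 0.0
        if n - a == 0 or ss_within == 0:
            return np.inf, r2
        return (ss_between / (a - 1)) / (ss_within / (n - a)), r2

    f_obs, r2 = f_and_r2(groups)
    hits = 0
    for _ in range(n_perm):
        f_p, _ = f_and_r2(rng.permutation(groups))
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    if not np.isfinite(f_obs):
        p = 1.0 / (1 + n_perm)
    return PermutationResult(f_obs, p, n_perm,
                             seed if isinstance(seed, int) else None, r2)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _dummy(levels: Sequence) -> np.ndarray:
    levels = np.asarray(levels)
    cats = np.unique(levels)
    return (levels[:, None] == cats[None, :]).astype(float)


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max()))
    q = q[:, :int(rank)]
    return q @ q.T


def permanova(d: DistanceMatrix, design: pd.DataFrame | Sequence,
              terms: Optional[Sequence[str]] = None,
              nested_in: Optional[Mapping[str, str]] = None,
              n_perm: int = 999, seed: int | np.random.Generator = 0
              ) -> dict[str, PermutationResult]:
    """Sequential (Type-I) PermANOVA over an ordered factor list.

    ``design`` is a DataFrame aligned with the distance matrix's samples (or
    a bare factor, making this the one-way case).  Terms are fitted in the
    given order through the distance-based linear-model projection
    (Gower-centred inner products, hat-matrix traces); each term's pseudo-F
    uses the residual after all terms.  Sample identities are permuted
    freely, except for a term listed in ``nested_in``, whose permutations
    shuffle whole samples only within each level of its parent factor.
    """
    if not isinstance(design, pd.DataFrame):
        return {"factor": permanova_oneway(d, np.asarray(design), n_perm, seed)}
    terms = list(terms) if terms is not None else list(design.columns)
    nested_in = dict(nested_in or {})
    for t in terms:
        if design[t].nunique() < 2:
            raise ValueError(f"term {t!r} has fewer than two levels")
    n = d.n
    d2 = d.values ** 2
    g = _gower_center(d2)
    ss_total = np.trace(g)

    ones = np.ones((n, 1))
    hats = [_hat(ones)]
    dfs = []
    for i, t in enumerate(terms):
        x = np.hstack([ones] + [_dummy(design[tt]) for tt in terms[: i + 1]])
        hats.append(_hat(x))
        dfs.append(int(round(np.trace(hats[-1] - hats[-2]))))
    h_full = hats[-1]
    df_res = n - int(round(np.trace(h_full)))

    def term_stats(gmat: np.ndarray) -> list[tuple[float, float]]:
        ss_res = np.trace((np.eye(n) - h_full) @ gmat)
        out = []
        for i, t in enumerate(terms):
            ss_t = np.trace((hats[i + 1] - hats[i]) @ gmat)
            r2 = ss_t / ss_total if ss_total > 0 else 0.0
            if dfs[i] == 0:
                # term adds no rank (fully confounded with earlier terms)
                out.append((np.nan, r2))
            elif df_res <= 0 or ss_res <= 1e-12:
                out.append((np.inf, r2))
            else:
                out.append(((ss_t / dfs[i]) / (ss_res / df_res), r2))
        return out

    obs = term_stats(g)
    rng = np.random.default_rng(seed)
    hits = [0] * len(terms)
    for i, t in enumerate(terms):
        parent = nested_in.get(t)
        strata = design[parent].to_numpy() if parent is not None else None
        for _ in range(n_perm):
            perm = _permute(n, rng, strata)
            gp = g[np.ix_(perm, perm)]
            f_p = term_stats(gp)[i][0]
            if f_p >= obs[i][0] - 1e-12:
                hits[i] += 1
    results = {}
    for i, t in enumerate(terms):
        f_obs, r2 = obs[i]
        p = (1 + hits[i]) / (1 + n_perm)
        if np.isnan(f_obs):
            p = 1.0
        elif not np.isfinite(f_obs):
            p = 1.0 / (1 + n_perm)
        results[t] = PermutationResult(
            f_obs, p, n_perm, seed if isinstance(seed, int) else None, r2,
            extras={"df": dfs[i], "df_residual": df_res})
    return results


def _permute(n: int, rng: np.random.Generator,
             strata: Optional[np.ndarray]) -> np.ndarray:
    if strata is None:
        return rng.permutation(n)
    perm = np.arange(n)
    for level in np.unique(strata):
        idx = np.nonzero(strata == level)[0]
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float                     # Kruskal stress-1 of the best start
    ids: tuple
    stress_trajectories: list = field(default_factory=list)


def nmds(d: DistanceMatrix, k: int = 2, seed: int | np.random.Generator = 0,
         n_starts: int = 4, max_iter: int = 300, tol: float = 1e-7
         ) -> NmdsResult:
    """Nonmetric MDS by SMACOF with isotonic disparities (Kruskal stress-1).

    Runs ``n_starts`` random starts plus one classical-scaling start and
    returns the configuration with the lowest stress.  Deterministic for a
    fixed seed.
    """
    if d.n <= k:
        raise ValueError("need more samples than embedding dimensions")
    if not np.isfinite(d.values).all():
        raise ValueError("non-finite distances")
    rng = np.random.default_rng(seed)
    diss = d.condensed()
    order = np.argsort(diss, kind="stable")

    inits = [_classical_mds(d.values, k)]
    for _ in range(n_starts):
        inits.append(rng.normal(size=(d.n, k)))

    best: Optional[tuple[float, np.ndarray, list]] = None
    for x0 in inits:
        x, stress, traj = _smacof_nonmetric(diss, x0.copy(), max_iter, tol)
        if best is None or stress < best[0]:
            best = (stress, x, traj)
    stress, x, traj = best[0], best[1], best[2]
    x = x - x.mean(axis=0)
    return NmdsResult(x, stress, d.ids, [traj])


def _classical_mds(dmat: np.ndarray, k: int) -> np.ndarray:
    g = _gower_center(dmat ** 2)
    w, v = np.linalg.eigh(g)
    idx = np.argsort(w)[::-1][:k]
    vals = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(vals)[None, :]


def _smacof_nonmetric(diss: np.ndarray, x: np.ndarray, max_iter: int,
                      tol: float) -> tuple[np.ndarray, float, list]:
    n = x.shape[0]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    prev = np.inf
    traj: list[float] = []
    stress = np.inf
    for _ in range(max_iter):
        delta = pdist(x)
        if np.allclose(delta, 0):
            break
        disp = iso.fit_transform(diss, delta)
        # scale disparities to the embedded distances' sum of squares
        scale = np.sqrt((delta ** 2).sum() / max((disp ** 2).sum(), 1e-300))
        disp = disp * scale
        stress = np.sqrt(((disp - delta) ** 2).sum() / (delta ** 2).sum())
        traj.append(float(stress))
        if prev - stress < tol:
            break
        prev = stress
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 0, disp / delta, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    return x, float(stress), traj
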