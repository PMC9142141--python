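"""Bray-Curtis dissimilarity, ANOSIM permutation tests, and non-metric MDS.

ANOSIM (analysis of similarities) contrasts the ranks of between-group and
within-group dissimilarities: R = (rbar_between - rbar_within) / (M / 2)
with M = n (n - 1) / 2 the number of sample pairs; R = 1 means complete
separation, R near 0 none, negative R more similarity between than within
groups.  Significance comes from permuting group labels (add-one
convention), exhaustively when the number of distinct labelings is small.

The two-way crossed design (PAST-style) tests each factor by computing the
one-way R within every level (stratum) of the other factor — ranking the
sub-matrix of each stratum separately — and averaging; labels permute only
within strata.

Non-metric MDS embeds a dissimilarity matrix in the plane by minimizing
Kruskal stress-1 with monotone regression; the best of several restarts
(one warm-started from classical metric scaling) is reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import smacof

__all__ = [
    "AnosimResult",
    "TwoWayAnosimResult",
    "OrdinationResult",
    "bray_curtis",
    "anosim_oneway",
    "anosim_twoway",
    "nmds",
]


@dataclass(frozen=True)
class AnosimResult:
    R: float
    pvalue: float
    n_perm: int
    method: str  # "exact" or "sampled"
    seed: int | None = None


@dataclass(frozen=True)
class TwoWayAnosimResult:
    factor_a: AnosimResult
    factor_b: AnosimResult
    strata_a: int  # strata of B contributing to R_A
    strata_b: int


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    restarts: int
    seed: int | None


def bray_curtis(table) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities of a nonnegative sample x feature table.

    d(i, j) = sum |x_i - x_j| / sum (x_i + x_j), in [0, 1].  A single
    all-zero row is tolerated (its distance to any non-zero row is 1); two
    all-zero rows make the pair undefined and raise.
    """
    if isinstance(table, pd.DataFrame):
        values = table.to_numpy(dtype=float)
        index = table.index
    else:
        values = np.asarray(table, dtype=float)
        index = pd.RangeIndex(len(values))
    if np.any(values < 0):
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    zero_rows = np.where(values.sum(axis=1) == 0)[0]
    if len(zero_rows) > 1:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples {list(zero_rows)}"
        )
    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=index, columns=index)


def _as_matrix(dist) -> np.ndarray:
    m = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(m)) > 1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    return m


def _anosim_r_from_ranks(rank_mat: np.ndarray, labels: np.ndarray) -> float:
    """R from a square matrix of condensed-distance ranks and group labels."""
    n = rank_mat.shape[0]
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within = same[iu]
    r = rank_mat[iu]
    if within.all() or not within.any():
        raise ValueError("need both within- and between-group pairs")
    m = n * (n - 1) / 2
    return float((r[~within].mean() - r[within].mean()) / (m / 2.0))


def _rank_matrix(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dist[iu])
    out = np.zeros_like(dist)
    out[iu] = ranks
    return out + out.T


def _distinct_assignments(labels: np.ndarray) -> int:
    n = len(labels)
    total = math.factorial(n)
    for _, cnt in zip(*np.unique(labels, return_counts=True)):
        total //= math.factorial(int(cnt))
    return total


def _enumerate_labelings(labels: np.ndarray):
    """All distinct arrangements of a label multiset, as index arrays."""
    uniq = sorted(set(labels.tolist()))
    counts = {u: int((labels == u).sum()) for u in uniq}
    n = len(labels)

    def rec(positions, remaining):
        if not remaining:
            out = np.empty(n, dtype=object)
            for lab, pos in positions.items():
                for p in pos:
                    out[p] = lab
            yield out
            return
        lab = remaining[0]
        free = [i for i in range(n) if all(i not in pos for pos in positions.values())]
        for combo in itertools.combinations(free, counts[lab]):
            positions[lab] = combo
            yield from rec(positions, remaining[1:])
            del positions[lab]

    yield from rec({}, uniq)


def anosim_oneway(
    dist,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "auto",
) -> AnosimResult:
    """One-way ANOSIM with permutation inference.

    ``method``: "exact" enumerates all distinct label arrangements (p =
    #{R_perm >= R_obs} / n_arrangements, the identity included); "sampled"
    draws ``n_perm`` label permutations (p = (1 + #{R_perm >= R_obs}) /
    (1 + n_perm)); "auto" picks exact when the number of distinct
    arrangements is at most ``n_perm``.  Singleton groups are allowed and
    simply contribute no within pairs.
    """
    m = _as_matrix(dist)
    labels = np.asarray(groups)
    if len(labels) != m.shape[0]:
        raise ValueError("labels must match matrix size")
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 groups")
    rank_mat = _rank_matrix(m)
    observed = _anosim_r_from_ranks(rank_mat, labels)

    if method == "auto":
        method = "exact" if _distinct_assignments(labels) <= n_perm else "sampled"

    if method == "exact":
        count = total = 0
        for arrangement in _enumerate_labelings(labels):
            total += 1
            if _anosim_r_from_ranks(rank_mat, arrangement) >= observed - 1e-12:
                count += 1
        return AnosimResult(observed, count / total, total, "exact", seed)

    if method != "sampled":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r_from_ranks(rank_mat, perm) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(observed, p, n_perm, "sampled", seed)


def _twoway_averaged_r(
    rank_mats: list[np.ndarray], stratum_labels: list[np.ndarray]
) -> float:
    rs = [
        _anosim_r_from_ranks(rm, lab) for rm, lab in zip(rank_mats, stratum_labels)
    ]
    return float(np.mean(rs))


def _crossed_factor_test(
    m: np.ndarray,
    test_labels: np.ndarray,
    strata: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[AnosimResult, int]:
    """Averaged within-stratum one-way R for ``test_labels``, permuting within strata."""
    rank_mats, stratum_lab, stratum_idx = [], [], []
    for level in pd.unique(strata):
        idx = np.where(strata == level)[0]
        lab = test_labels[idx]
        uniq, counts = np.unique(lab, return_counts=True)
        # a stratum contributes only if it has >= 2 test groups and at least
        # one within pair (some group of size >= 2)
        if len(uniq) < 2 or counts.max() < 2:
            continue
        sub = m[np.ix_(idx, idx)]
        rank_mats.append(_rank_matrix(sub))
        stratum_lab.append(lab)
        stratum_idx.append(idx)
    if not rank_mats:
        # e.g. the other factor has a single level everywhere: this factor is
        # untestable in the crossed design
        return AnosimResult(float("nan"), float("nan"), n_perm, "sampled", None), 0
    observed = _twoway_averaged_r(rank_mats, stratum_lab)
    count = 0
    for _ in range(n_perm):
        permuted = [rng.permutation(lab) for lab in stratum_lab]
        if _twoway_averaged_r(rank_mats, permuted) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(observed, p, n_perm, "sampled", None), len(rank_mats)


def anosim_twoway(
    dist,
    factor_a,
    factor_b,
    n_perm: int = 9999,
    seed: int | None = None,
) -> TwoWayAnosimResult:
    """Two-way crossed ANOSIM (PAST-style) for two factor labelings.

    R for factor A is the unweighted mean of one-way R values computed within
    each level of factor B (each stratum's sub-matrix re-ranked on its own);
    its p-value permutes A labels within levels of B.  Symmetrically for B.
    Strata lacking two groups or any within pair are excluded from the
    average (their count is reported).
    """
    m = _as_matrix(dist)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if len(a) != m.shape[0] or len(b) != m.shape[0]:
        raise ValueError("factor labels must match matrix size")
    rng = np.random.default_rng(seed)
    res_a, strata_a = _crossed_factor_test(m, a, b, n_perm, rng)
    res_b, strata_b = _crossed_factor_test(m, b, a, n_perm, rng)
    res_a = AnosimResult(res_a.R, res_a.pvalue, n_perm, "sampled", seed)
    res_b = AnosimResult(res_b.R, res_b.pvalue, n_perm, "sampled", seed)
    return TwoWayAnosimResult(res_a, res_b, strata_a, strata_b)


def _classical_mds_init(m: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson classical scaling of the (squared) distances, as a warm start."""
    n = m.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ (m**2) @ j
    vals, vecs = np.linalg.eigh(bmat)
    order = np.argsort(vals)[::-1][:dims]
    comp = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    return comp


def nmds(
    dist,
    dims: int = 2,
    restarts: int = 50,
    seed: int | None = None,
    max_iter: int = 500,
    eps: float = 1e-9,
) -> OrdinationResult:
    """Kruskal non-metric MDS; best configuration over restarts.

    One run is warm-started from classical (metric) scaling, the remaining
    ``restarts`` runs from random configurations.  The reported stress is
    Kruskal stress-1.
    """
    m = _as_matrix(dist)
    best_coords, best_stress = None, np.inf
    inits: list[np.ndarray | None] = [_classical_mds_init(m, dims)]
    inits += [None] * restarts
    rng = np.random.default_rng(seed)
    for init in inits:
        state = int(rng.integers(0, 2**31 - 1))
        coords, stress = smacof(
            m,
            metric=False,
            n_components=dims,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            random_state=state,
            normalized_stress=True,
        )
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    if best_coords is None:
        raise RuntimeError("NMDS failed to produce a configuration")
    return OrdinationResult(
        coordinates=best_coords,
        stress=float(best_stress),
        restarts=len(inits),
        seed=seed,
    )
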