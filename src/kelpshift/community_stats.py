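"""Dissimilarity and permutation statistics for community restructuring.

Bray-Curtis, one-way PERMANOVA, homogeneity of multivariate dispersion,
and SIMPER are implemented from first principles (the test suite checks
them against independent oracles); they are deliberately not delegated to
a community-ecology library.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DistanceMatrix",
    "PermTestResult",
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova",
    "dispersion_homogeneity",
    "simper",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample labels."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", d)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} ids")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(d, d.T):
            raise ValueError("matrix must be symmetric")
        if (d < 0).any():
            raise ValueError("dissimilarities must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of a permutation (or classical) test."""

    statistic: float
    p_value: float
    n_perm: int
    seed: int | None = None
    method: str = "monte_carlo"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two cover vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("cover vectors must be nonnegative")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValueError("both vectors are all-zero; dissimilarity undefined")
    return float(np.sum(np.abs(x - y)) / denom)


def bray_curtis_matrix(
    covers: np.ndarray, ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise Bray-Curtis matrix of a samples x species cover matrix."""
    X = np.asarray(covers, dtype=float)
    if X.ndim != 2:
        raise ValueError("covers must be 2-D (samples x species)")
    n = X.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(X[i], X[j])
    return DistanceMatrix(ids=tuple(ids), values=d)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _group_codes(groups: Sequence) -> tuple[np.ndarray, list]:
    labels = list(groups)
    uniq = sorted(set(labels), key=str)
    codes = np.array([uniq.index(g) for g in labels], dtype=np.intp)
    return codes, uniq


def _pseudo_f_batch(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for each row of label codes (P x N) against squared
    distances d2 (N x N)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = np.zeros(codes.shape[0])
    for g in range(n_groups):
        m = (codes == g).astype(float)  # P x N
        n_g = m.sum(axis=1)
        # sum_{i<j in g} d2_ij = m D m^T / 2
        ss_within += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * n_g)
    ss_between = ss_total - ss_within
    a = n_groups
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ss_between / (a - 1)) / (ss_within / (n - a))


def _count_distinct_assignments(sizes: Sequence[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def _enumerate_assignments(codes: np.ndarray) -> np.ndarray:
    """All distinct arrangements of the multiset of group codes."""
    n = codes.size
    rows = []

    def rec(prefix: list[int], remaining: dict[int, int]) -> None:
        if len(prefix) == n:
            rows.append(prefix.copy())
            return
        for g in sorted(remaining):
            if remaining[g]:
                remaining[g] -= 1
                prefix.append(g)
                rec(prefix, remaining)
                prefix.pop()
                remaining[g] += 1

    counts: dict[int, int] = {}
    for c in codes:
        counts[int(c)] = counts.get(int(c), 0) + 1
    rec([], counts)
    return np.array(rows, dtype=np.intp)


def permanova(
    dm: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    permutations: str = "auto",
) -> PermTestResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Pseudo-F is computed from squared dissimilarities:
    ``SS_total = N^-1 sum_{i<j} d_ij^2``,
    ``SS_within = sum_g n_g^-1 sum_{i<j in g} d_ij^2``,
    ``F = (SS_between/(a-1)) / (SS_within/(N-a))``.

    The p-value comes from free permutation of the group labels.  When the
    number of distinct label arrangements is at most ``n_perm`` (and
    *permutations* is not ``"monte_carlo"``) the null distribution is
    enumerated exhaustively and ``p = #{F_perm >= F_obs} / n_distinct``
    (the identity arrangement counts itself); otherwise Monte-Carlo
    sampling with the +1 correction ``p = (#{>=} + 1) / (n_perm + 1)``.
    """
    if permutations not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown permutations mode {permutations!r}")
    codes, uniq = _group_codes(groups)
    n = len(dm)
    if codes.size != n:
        raise ValueError("groups length does not match matrix size")
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = dm.values**2
    f_obs = float(_pseudo_f_batch(d2, codes[None, :], a)[0])
    if not np.isfinite(f_obs):
        raise ValueError("pseudo-F undefined (zero within-group variation)")

    n_distinct = _count_distinct_assignments(sizes.tolist())
    exhaustive = permutations == "exact" or (
        permutations == "auto" and n_distinct <= n_perm
    )
    if exhaustive:
        perms = _enumerate_assignments(codes)
        f_perm = _pseudo_f_batch(d2, perms, a)
        p = float(np.count_nonzero(f_perm >= f_obs - 1e-12) / n_distinct)
        return PermTestResult(
            statistic=f_obs,
            p_value=p,
            n_perm=n_distinct,
            seed=seed,
            method="exhaustive",
        )
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.intp)
    for k in range(n_perm):
        perms[k] = rng.permutation(codes)
    f_perm = _pseudo_f_batch(d2, perms, a)
    p = float((np.count_nonzero(f_perm >= f_obs - 1e-12) + 1) / (n_perm + 1))
    return PermTestResult(
        statistic=f_obs, p_value=p, n_perm=n_perm, seed=seed, method="monte_carlo"
    )


# ---------------------------------------------------------------------------
# Homogeneity of dispersion
# ---------------------------------------------------------------------------

def _pcoa_embedding(dm: DistanceMatrix) -> np.ndarray:
    """Principal-coordinate embedding; axes with negative eigenvalues are
    dropped (no Lingoes/Cailliez correction)."""
    d2 = dm.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(g)
    if not np.isfinite(eigval).all():
        raise ValueError("principal-coordinate embedding failed")
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max()))
    keep = eigval > tol
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def dispersion_homogeneity(
    dm: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """Test equality of group dispersions (distance to group centroid in
    principal-coordinate space) with a classical one-way ANOVA F."""
    codes, uniq = _group_codes(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (np.bincount(codes) < 2).any():
        raise ValueError("every group needs at least two samples")
    coords = _pcoa_embedding(dm)
    dists = np.empty(len(dm))
    for g in range(len(uniq)):
        m = codes == g
        centroid = coords[m].mean(axis=0)
        dists[m] = np.linalg.norm(coords[m] - centroid, axis=1)
    f, p = stats.f_oneway(*(dists[codes == g] for g in range(len(uniq))))
    if not np.isfinite(f):  # identical dispersions in every group
        f, p = 0.0, 1.0
    return PermTestResult(
        statistic=float(f),
        p_value=float(min(max(p, np.finfo(float).tiny), 1.0)),
        n_perm=0,
        seed=seed,
        method="anova_f",
        extra={"distances_to_centroid": dists.tolist()},
    )


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

def simper(
    covers: np.ndarray,
    groups: Sequence,
    species: Sequence[str] | None = None,
) -> "pd.DataFrame":
    """Per-species contributions to mean between-group Bray-Curtis
    dissimilarity.

    For each between-group pair (i, j), species k contributes
    ``|x_ik - x_jk| / sum_m (x_im + x_jm)``; the species contribution is
    the mean over all between-group pairs, and percentages are relative to
    the summed contributions (= the mean between-group dissimilarity).
    """
    import pandas as pd

    X = np.asarray(covers, dtype=float)
    if X.ndim != 2:
        raise ValueError("covers must be 2-D (samples x species)")
    codes, uniq = _group_codes(groups)
    if len(uniq) != 2:
        raise ValueError(f"SIMPER needs exactly two groups, got {len(uniq)}")
    ia = np.flatnonzero(codes == 0)
    ib = np.flatnonzero(codes == 1)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty group")
    if species is None:
        species = [f"sp{k}" for k in range(X.shape[1])]
    contrib = np.zeros(X.shape[1])
    n_pairs = 0
    for i, j in itertools.product(ia, ib):
        denom = float(np.sum(X[i] + X[j]))
        if denom == 0:
            raise ValueError(
                f"samples {i} and {j} are both all-zero; dissimilarity undefined"
            )
        contrib += np.abs(X[i] - X[j]) / denom
        n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    mean_delta = (
        X[ib].mean(axis=0) - X[ia].mean(axis=0)
    )  # group-1 minus group-0 mean cover
    df = pd.DataFrame(
        {
            "species": list(species),
            "contribution": contrib,
            "percent": 100.0 * contrib / total if total > 0 else 0.0,
            "mean_cover_change": mean_delta,
        }
    )
    df.attrs["mean_dissimilarity"] = float(total)
    return df
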