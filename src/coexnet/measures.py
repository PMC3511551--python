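"""Bivariate association measures for gene-expression profiles.

Eight measures share one calling convention: each takes two equal-length
expression vectors (log2-normalized intensities across samples) and returns an
:class:`AssociationResult` with the statistic and a p-value for the
independence null.

Four are rank-based correlation coefficients (Spearman, Kendall tau-b,
weighted rank, Hoeffding's D), two are regression slopes (Theil-Sen and its
rank variant), and two are moment-based dependence measures (Pearson, squared
distance covariance).  The rank-based measures and the rank Theil-Sen slope
are invariant under strictly increasing transforms of either input, which is
what makes them robust to outliers and to monotone-nonlinear coupling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DegenerateInputError, InvalidInputError

__all__ = [
    "AssociationResult",
    "MEASURES",
    "compute",
    "rank_transform",
    "pearson",
    "spearman",
    "kendall",
    "weighted_rank",
    "weighted_rank_null_variance",
    "hoeffding_d",
    "hoeffding_null_variance",
    "distance_covariance",
    "theil_sen",
    "rank_theil_sen",
    "theil_sen_breakdown",
    "pair_seed",
]


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one pairwise association test.

    Attributes
    ----------
    method : str
        One of ``pearson, spearman, kendall, weighted_rank, hoeffding, dcov,
        theil_sen, rank_theil_sen``.
    statistic : float
        The measure on its documented scale (correlations in [-1, 1],
        Hoeffding D in [-0.5, 1] for untied data, dCov**2 >= 0, slopes
        unbounded).
    p_value : float
        Two-sided p-value for the independence null (one-sided bound for
        Hoeffding, permutation for dCov).
    n_obs : int
        Number of paired observations.
    extras : dict
        Method-specific extras (regression intercept, permutation count, ...).
    """

    method: str
    statistic: float
    p_value: float
    n_obs: int
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation helpers

def _as_vector(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def _as_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray, int]:
    xa = _as_vector(x, "x")
    ya = _as_vector(y, "y")
    if xa.shape != ya.shape:
        raise InvalidInputError(
            f"length mismatch: len(x)={xa.size}, len(y)={ya.size}"
        )
    if xa.size < min_n:
        raise InvalidInputError(f"need at least {min_n} observations, got {xa.size}")
    return xa, ya, xa.size


def _require_varying(arr: np.ndarray, name: str) -> None:
    if np.all(arr == arr[0]):
        raise DegenerateInputError(f"{name} is constant; statistic undefined")


# ---------------------------------------------------------------------------
# rank transform

def rank_transform(x) -> np.ndarray:
    """Average ranks of ``x``; tied values get the mean of their positions.

    The rank sum is always n(n+1)/2.
    """
    arr = _as_vector(x)
    if arr.size < 1:
        raise InvalidInputError("empty vector")
    return stats.rankdata(arr, method="average")


# ---------------------------------------------------------------------------
# Pearson / Spearman

def _pearson_core(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    # two-sided t test, t = r sqrt((n-2)/(1-r^2)), n-2 df
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def pearson(x, y) -> AssociationResult:
    """Product-moment correlation; p from Student's t with n-2 df."""
    xa, ya, n = _as_pair(x, y, 4)
    _require_varying(xa, "x")
    _require_varying(ya, "y")
    r, p = _pearson_core(xa, ya)
    return AssociationResult("pearson", r, p, n)


def spearman(x, y) -> AssociationResult:
    """Pearson correlation of the average ranks; p from t with n-2 df."""
    xa, ya, n = _as_pair(x, y, 4)
    _require_varying(xa, "x")
    _require_varying(ya, "y")
    rho, p = _pearson_core(rank_transform(xa), rank_transform(ya))
    return AssociationResult("spearman", rho, p, n)


# ---------------------------------------------------------------------------
# Kendall

def _tie_sizes(arr: np.ndarray) -> np.ndarray:
    _, counts = np.unique(arr, return_counts=True)
    return counts[counts > 1]


def kendall(x, y) -> AssociationResult:
    """Kendall's tau (tau-b under ties); p from the normal approximation.

    For untied data the null variance of tau is 2(2n+5)/(9n(n-1)); with ties
    the tie-corrected variance of S = C - D (Kendall 1970) is used.
    """
    xa, ya, n = _as_pair(x, y, 4)
    dx = np.sign(xa[:, None] - xa[None, :])
    dy = np.sign(ya[:, None] - ya[None, :])
    iu = np.triu_indices(n, 1)
    prod = dx[iu] * dy[iu]
    s = float(np.sum(prod))  # C - D
    n0 = n * (n - 1) / 2.0
    tx = _tie_sizes(xa)
    ty = _tie_sizes(ya)
    t1 = float(np.sum(tx * (tx - 1) / 2.0))
    u1 = float(np.sum(ty * (ty - 1) / 2.0))
    denom = np.sqrt((n0 - t1) * (n0 - u1))
    if denom == 0:
        raise DegenerateInputError("all pairs tied in one variable")
    tau = float(np.clip(s / denom, -1.0, 1.0))

    # variance of S under the null, tie-corrected (Kendall 1970)
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    v0 = n * (n - 1) * (2 * n + 5)
    var_s = (v0 - vt - vu) / 18.0
    if t1 and u1:
        var_s += (2.0 * t1 * u1) / (n * (n - 1))
        t2 = float(np.sum(tx * (tx - 1) * (tx - 2)))
        u2 = float(np.sum(ty * (ty - 1) * (ty - 2)))
        var_s += (t2 * u2) / (9.0 * n * (n - 1) * (n - 2))
    if var_s <= 0:
        raise DegenerateInputError("null variance vanishes")
    z = s / np.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(
        "kendall", tau, p, n, extras={"concordant_minus_discordant": s}
    )


# ---------------------------------------------------------------------------
# weighted rank correlation (Pinto da Costa & Soares)

def _weighted_rank_stat(R: np.ndarray, S: np.ndarray) -> float:
    n = R.size
    w = (R - S) ** 2 * (2 * n + 2 - R - S)
    return float(1.0 - 6.0 * w.sum() / (n**4 + n**3 - n**2 - n))


def weighted_rank_null_variance(n: int) -> float:
    """Exact permutation-null variance of the weighted rank coefficient.

    Under the null the second rank vector is a uniform random permutation;
    the variance of the weighted sum follows from the first two joint moments
    of sampling without replacement, computed exactly in O(n^2).
    """
    i = np.arange(1, n + 1, dtype=float)
    F = (i[:, None] - i[None, :]) ** 2 * (2 * n + 2 - i[:, None] - i[None, :])
    c = 6.0 / (n**4 + n**3 - n**2 - n)
    A = F.sum(axis=1)
    B = F @ F.T
    e_t = A.sum() / n
    sq = (F**2).sum()
    cross = ((A.sum() ** 2 - (A**2).sum()) - (B.sum() - np.trace(B))) / (n * (n - 1))
    var_t = sq / n + cross - e_t**2
    return float(c * c * var_t)


def weighted_rank(x, y) -> AssociationResult:
    """Top-weighted rank correlation; agreement among high ranks counts more.

    The statistic is rW = 1 - 6 sum d_i^2 (2n+2-R_i-S_i) / (n^4+n^3-n^2-n);
    its null expectation is exactly 0 and the p-value uses the exact
    permutation-null variance with a normal reference.
    """
    xa, ya, n = _as_pair(x, y, 4)
    _require_varying(xa, "x")
    _require_varying(ya, "y")
    R = rank_transform(xa)
    S = rank_transform(ya)
    rw = _weighted_rank_stat(R, S)
    z = rw / np.sqrt(weighted_rank_null_variance(n))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult("weighted_rank", rw, p, n)


# ---------------------------------------------------------------------------
# Hoeffding's D

def hoeffding_null_variance(n: int) -> float:
    """Exact permutation-null variance of the (30-scaled) Hoeffding D.

    ``2(n^2+5n-32) / (9n(n-1)(n-3)(n-4))`` — matches exhaustive permutation
    enumeration at n = 5, 6, 7 to machine precision.
    """
    return 2.0 * (n * n + 5 * n - 32) / (9.0 * n * (n - 1) * (n - 3) * (n - 4))


def _hoeffding_stat(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    R = stats.rankdata(x)
    S = stats.rankdata(y)
    lx = x[None, :] < x[:, None]
    ly = y[None, :] < y[:, None]
    ex = x[None, :] == x[:, None]
    ey = y[None, :] == y[:, None]
    np.fill_diagonal(ex, False)
    np.fill_diagonal(ey, False)
    # bivariate rank: the point itself plus tie-weighted counts of points
    # below-left of it (1 both strict, 1/2 one tied, 1/4 both tied)
    Q = (
        1.0
        + (lx & ly).sum(axis=1)
        + 0.5 * ((ex & ly).sum(axis=1) + (lx & ey).sum(axis=1))
        + 0.25 * (ex & ey).sum(axis=1)
    )
    d1 = float(np.sum((Q - 1) * (Q - 2)))
    d2 = float(np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2)))
    d3 = float(np.sum((R - 2) * (S - 2) * (Q - 1)))
    num = (n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3
    return 30.0 * num / (n * (n - 1) * (n - 2) * (n - 3) * (n - 4))


def hoeffding_d(
    x,
    y,
    p_method: str = "bound",
    n_perm: int = 999,
    seed: int | None = None,
) -> AssociationResult:
    """Hoeffding's D, a rank measure of general bivariate dependence.

    D is built from univariate ranks R_i, S_i and bivariate ranks Q_i; it is
    1 on perfectly monotone data in either direction and has permutation-null
    expectation 0 (range [-0.5, 1] for untied data).

    ``p_method="bound"`` (default) gives the conservative one-sided Cantelli
    bound p = v_n / (v_n + D^2) for D > 0, where v_n is the exact null
    variance.  This is the bound-style independence test of the original
    construction; it compresses p-values into a narrow range, so
    ``p_method="permutation"`` is available for calibrated comparisons.
    """
    xa, ya, n = _as_pair(x, y, 5)
    d = _hoeffding_stat(xa, ya)
    if p_method == "bound":
        vn = hoeffding_null_variance(n)
        p = float(vn / (vn + d * d)) if d > 0 else 1.0
        extras = {}
    elif p_method == "permutation":
        if seed is None:
            raise ConfigurationError("permutation p-value requires a seed")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if _hoeffding_stat(xa, rng.permutation(ya)) >= d - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        extras = {"n_perm": n_perm}
    else:
        raise ConfigurationError(f"unknown p_method {p_method!r}")
    return AssociationResult("hoeffding", d, p, n, extras=extras)


# ---------------------------------------------------------------------------
# distance covariance

def _centered_distances(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_covariance(x, y, n_perm: int = 999, seed: int | None = None) -> AssociationResult:
    """Squared distance covariance with a permutation independence test.

    dCov^2 is the average elementwise product of the two double-centered
    Euclidean distance matrices; it is >= 0 and equals 0 when either vector is
    constant.  The permutation p-value uses the +1 correction, so p > 0.
    """
    xa, ya, n = _as_pair(x, y, 4)
    if n_perm < 99:
        raise ConfigurationError("n_perm < 99 gives too coarse a p resolution")
    if seed is None:
        raise ConfigurationError("distance covariance requires an explicit seed")
    A = _centered_distances(xa)
    B = _centered_distances(ya)
    dcov2 = max(float((A * B).mean()), 0.0)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, 20_000_000 // (n * n)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)  # m independent permutations
        Bp = B[idx[:, :, None], idx[:, None, :]]
        stats_perm = np.einsum("ij,kij->k", A, Bp) / (n * n)
        count += int(np.sum(stats_perm >= dcov2 - 1e-15))
        done += m
    p = (count + 1) / (n_perm + 1)
    dvar = float((A * A).mean() * (B * B).mean())
    extras = {"n_perm": n_perm, "dcor2": dcov2 / np.sqrt(dvar) if dvar > 0 else 0.0}
    return AssociationResult("dcov", dcov2, p, n, extras=extras)


# ---------------------------------------------------------------------------
# Theil-Sen

def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(x.size, 1)
    dx = x[iu[1]] - x[iu[0]]
    dy = y[iu[1]] - y[iu[0]]
    keep = dx != 0  # ties in x carry no slope information
    if not np.any(keep):
        raise DegenerateInputError("all x values equal; no pairwise slopes")
    return dy[keep] / dx[keep]


def _slope_p_value(slopes: np.ndarray) -> float:
    # one-sample Wilcoxon signed-rank test that the slope multiset has
    # median zero (the mblm convention)
    if np.all(slopes == 0):
        return 1.0
    try:
        return float(stats.wilcoxon(slopes, method="approx").pvalue)
    except ValueError:
        return 1.0


def theil_sen(x, y) -> AssociationResult:
    """Median of pairwise slopes; robust regression of y on x.

    The statistic is the median of (y_j-y_i)/(x_j-x_i) over pairs with
    x_i != x_j; the intercept is median(y_i - slope*x_i).  Note this is a
    regression, not a correlation: theil_sen(x, y) is not 1/theil_sen(y, x)
    in general.
    """
    xa, ya, n = _as_pair(x, y, 4)
    slopes = _pairwise_slopes(xa, ya)
    slope = float(np.median(slopes))
    intercept = float(np.median(ya - slope * xa))
    p = _slope_p_value(slopes)
    return AssociationResult(
        "theil_sen", slope, p, n,
        extras={"intercept": intercept, "n_slopes": int(slopes.size)},
    )


def rank_theil_sen(x, y) -> AssociationResult:
    """Theil-Sen applied to the rank-transformed observations."""
    xa, ya, n = _as_pair(x, y, 4)
    res = theil_sen(rank_transform(xa), rank_transform(ya))
    return AssociationResult("rank_theil_sen", res.statistic, res.p_value, n,
                             extras=res.extras)


def theil_sen_breakdown(n: int | None = None) -> float:
    """Breakdown fraction of the Theil-Sen estimator from pair counting.

    Contaminating m of n points corrupts every pair touching a contaminated
    point; the median slope can be driven arbitrarily far once corrupted
    pairs reach half of all pairs, i.e. when C(n-m, 2) <= C(n, 2)/2.  For
    finite n this returns the largest tolerated m/n; with ``n=None`` it
    solves the asymptotic condition (1-f)^2 = 1/2.
    """
    from scipy.optimize import brentq

    if n is None:
        return float(brentq(lambda f: (1.0 - f) ** 2 - 0.5, 0.0, 1.0))
    total = n * (n - 1) / 2.0
    m = 0
    while (n - (m + 1)) * (n - (m + 1) - 1) / 2.0 > total / 2.0:
        m += 1
    return m / n


# ---------------------------------------------------------------------------
# registry

MEASURES: Mapping[str, Callable[..., AssociationResult]] = {
    "pearson": pearson,
    "spearman": spearman,
    "kendall": kendall,
    "weighted_rank": weighted_rank,
    "hoeffding": hoeffding_d,
    "dcov": distance_covariance,
    "theil_sen": theil_sen,
    "rank_theil_sen": rank_theil_sen,
}


def compute(method: str, x, y, **params) -> AssociationResult:
    """Dispatch by method id; unknown ids raise ConfigurationError."""
    try:
        fn = MEASURES[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown method {method!r}; valid ids: {', '.join(sorted(MEASURES))}"
        ) from None
    return fn(x, y, **params)


def pair_seed(master_seed: int, gene_a: str, gene_b: str) -> int:
    """Deterministic per-pair seed, independent of argument order.

    Hashing the sorted gene-id pair keeps permutation p-values reproducible
    regardless of worker scheduling.
    """
    a, b = sorted((gene_a, gene_b))
    digest = hashlib.blake2b(
        f"{master_seed}:{a}|{b}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)
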