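"""Normality profiling of expression vectors and the 10-category
classification of gene pairs by Pearson-vs-Spearman behavior.

Most expression vectors in microarray compendia are not normal; the category
profile (is rho much larger than r, about equal, or much smaller?) separates
regimes where rank methods and Pearson behave differently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, InvalidInputError
from .ranking import associate_all, top_n

__all__ = [
    "NormalityResult",
    "shapiro_wilk",
    "PairCategory",
    "classify_pair",
    "normal_fraction_topk",
]


@dataclass(frozen=True)
class NormalityResult:
    w_statistic: float
    p_value: float
    is_normal: bool
    alpha: float


def shapiro_wilk(x, alpha: float = 0.01) -> NormalityResult:
    """Shapiro-Wilk W and p; ``is_normal`` means p >= alpha.

    p < alpha is treated as evidence of non-normality, the convention used
    throughout the category tables.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or not np.all(np.isfinite(arr)):
        raise InvalidInputError("expression vector must be 1-D and finite")
    if not 5 <= arr.size <= 5000:
        raise InvalidInputError(f"Shapiro-Wilk needs 5 <= n <= 5000, got {arr.size}")
    if np.all(arr == arr[0]):
        raise DegenerateInputError("constant vector has zero variance")
    w, p = stats.shapiro(arr)
    return NormalityResult(float(w), float(p), bool(p >= alpha), alpha)


@dataclass(frozen=True)
class PairCategory:
    category: int  # 1..10
    group: str  # I, II, III


def classify_pair(r: float, rho: float, delta: float = 0.1) -> PairCategory:
    """Assign a (Pearson r, Spearman rho) pair to one of 10 categories.

    Group I: rho - r > delta; group III: r - rho > delta; group II otherwise
    (|r - rho| <= delta; boundary equality goes to II).  Subcategories follow
    the sign pattern of r and rho, with r = 0 or rho = 0 treated as the
    non-negative branch.
    """
    if not (-1 <= r <= 1 and -1 <= rho <= 1):
        raise InvalidInputError("r and rho must lie in [-1, 1]")
    rneg = r < 0
    rhoneg = rho < 0
    if rho - r > delta:
        group = "I"
        cat = 1 if (rneg and rhoneg) else (2 if rneg else 3)
    elif r - rho > delta:
        group = "III"
        cat = 8 if (rneg and rhoneg) else (9 if rhoneg else 10)
    else:
        group = "II"
        if rneg and rhoneg:
            cat = 4
        elif rneg:
            cat = 5
        elif rhoneg:
            cat = 6
        else:
            cat = 7
    return PairCategory(cat, group)


def normal_fraction_topk(
    matrix: pd.DataFrame,
    query: str,
    method: str,
    k: int = 500,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of the query's top-k partners whose profile tests normal."""
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    ranked = associate_all(matrix, query, method, seed=seed)
    partners = top_n(ranked, k)
    if len(partners) < k:
        warnings.warn(
            f"only {len(partners)} partners available for top-{k}", stacklevel=2
        )
    if not partners:
        raise InvalidInputError("no partners to classify")
    flags = [
        shapiro_wilk(matrix.loc[g].to_numpy(dtype=float), alpha=alpha).is_normal
        for g in partners
    ]
    return sum(flags) / len(flags)
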