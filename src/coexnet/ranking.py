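"""Genome-wide pairwise ranking: one query gene against every other gene.

The output of :func:`associate_all` is sorted by p-value ascending with a
total-order tie-break (|statistic| descending, then partner id ascending) so
that downstream overlap counting is deterministic.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, GeneLookupError, InvalidInputError
from .measures import compute, pair_seed

log = logging.getLogger(__name__)

__all__ = ["validate_matrix", "associate_all", "top_n"]


def validate_matrix(matrix: pd.DataFrame, min_samples: int = 5) -> pd.DataFrame:
    """Check an expression matrix (genes x samples) and return it as float."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"duplicate gene ids: {dups[:5]}")
    if matrix.shape[1] < min_samples:
        raise InvalidInputError(
            f"need at least {min_samples} samples, got {matrix.shape[1]}"
        )
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise InvalidInputError(
            f"non-finite value at gene {matrix.index[bad[0]]!r}, "
            f"sample {matrix.columns[bad[1]]!r}"
        )
    return matrix.astype(float)


def associate_all(
    matrix: pd.DataFrame,
    query: str,
    method: str,
    *,
    seed: int = 0,
    n_perm: int = 999,
) -> pd.DataFrame:
    """Pair ``query`` with every other gene under one association measure.

    Returns a DataFrame with columns ``partner, statistic, p_value`` sorted
    by (p ascending, |statistic| descending, partner ascending).  Degenerate
    partners (constant vectors) are logged and skipped.  For permutation-based
    measures a per-pair seed is derived from ``seed`` and the gene-id pair so
    results do not depend on evaluation order.
    """
    if query not in matrix.index:
        raise GeneLookupError(f"query gene {query!r} not in matrix")
    x = matrix.loc[query].to_numpy(dtype=float)
    rows = []
    for partner in matrix.index:
        if partner == query:
            continue
        y = matrix.loc[partner].to_numpy(dtype=float)
        params = {}
        if method == "dcov":
            params = {"seed": pair_seed(seed, query, partner), "n_perm": n_perm}
        try:
            res = compute(method, x, y, **params)
        except DegenerateInputError as exc:
            log.info("skipping degenerate partner %s: %s", partner, exc)
            continue
        rows.append((partner, res.statistic, res.p_value))
    out = pd.DataFrame(rows, columns=["partner", "statistic", "p_value"])
    if not out.empty:
        out["_abs"] = out["statistic"].abs()
        out = out.sort_values(
            ["p_value", "_abs", "partner"], ascending=[True, False, True]
        ).drop(columns="_abs")
        out = out.reset_index(drop=True)
    out.attrs["query"] = query
    out.attrs["method"] = method
    return out


def top_n(ranked: pd.DataFrame, n_top: int) -> list[str]:
    """First ``min(n_top, len)`` partner ids of a ranked pair list."""
    if n_top < 1:
        raise InvalidInputError("n_top must be >= 1")
    if ranked.empty:
        return []
    return ranked["partner"].head(n_top).tolist()
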