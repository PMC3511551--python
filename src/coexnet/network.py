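"""TF coordination network: shared-gene counts between top-N coexpression lists.

Two TFs are connected when their top-N most coexpressed genes have strictly
more than ``k_min`` members in common; the overlap count is stored in a
symmetric TF x TF matrix whose diagonal is fixed at zero (a TF never appears
in its own list, so self-overlap is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["CoordinationMatrix", "build_coordination_matrix"]


@dataclass(frozen=True)
class CoordinationMatrix:
    tf_ids: tuple[str, ...]
    overlaps: np.ndarray  # symmetric int array, diagonal 0
    n_top: int
    k_min: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.overlaps, index=self.tf_ids, columns=self.tf_ids)

    def edge_list(self) -> pd.DataFrame:
        """Nonzero upper-triangle entries as (tf_a, tf_b, overlap) rows."""
        rows = []
        n = len(self.tf_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.overlaps[i, j] > 0:
                    rows.append((self.tf_ids[i], self.tf_ids[j], int(self.overlaps[i, j])))
        return pd.DataFrame(rows, columns=["tf_a", "tf_b", "overlap"])


def build_coordination_matrix(
    top_lists: Mapping[str, Sequence[str]],
    k_min: int = 30,
    n_top: int = 100,
) -> CoordinationMatrix:
    """Count shared genes between every pair of top-N lists.

    An overlap is stored only when strictly greater than ``k_min`` ("more
    than k genes in common"); ties at exactly ``k_min`` stay disconnected.
    """
    if k_min >= n_top:
        raise ConfigurationError(f"k_min={k_min} must be < n_top={n_top}")
    too_long = [tf for tf, lst in top_lists.items() if len(lst) > n_top]
    if too_long:
        raise ConfigurationError(
            f"lists longer than n_top={n_top} (mismatched n_top?): {too_long[:5]}"
        )
    tf_ids = tuple(sorted(top_lists))
    sets = {tf: set(top_lists[tf]) for tf in tf_ids}
    n = len(tf_ids)
    overlaps = np.zeros((n, n), dtype=int)
    for i in range(n):
        si = sets[tf_ids[i]]
        for j in range(i + 1, n):
            c = len(si & sets[tf_ids[j]])
            if c > k_min:
                overlaps[i, j] = overlaps[j, i] = c
    return CoordinationMatrix(tf_ids, overlaps, n_top=n_top, k_min=k_min)
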