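"""Triple-Link: greedy decomposition of a coordination matrix into TF clusters.

Each round seeds a cluster with the heaviest remaining edge, admits a third
TF if it has a significant link to both seeds, and admits later TFs with at
least three significant links into the cluster ("triple link").  Significance
means the overlap exceeds the matrix mean plus one standard deviation
(computed once over the nonzero upper-triangle entries).  Extracted TFs do
not participate in later rounds, so tighter clusters are emitted earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyNetworkError
from .network import CoordinationMatrix

__all__ = [
    "TFCluster",
    "DecompositionResult",
    "significance_threshold",
    "decompose",
]


@dataclass(frozen=True)
class TFCluster:
    index: int  # 1-based extraction order
    members: tuple[str, ...]  # seed pair first, then join order
    seed_overlap: int


@dataclass(frozen=True)
class DecompositionResult:
    clusters: tuple[TFCluster, ...]
    singletons: tuple[str, ...]
    threshold: float
    multiplier: float = 1.0

    def labels(self) -> dict[str, int]:
        """Cluster index per TF; singletons get unique negative labels."""
        out: dict[str, int] = {}
        for cl in self.clusters:
            for tf in cl.members:
                out[tf] = cl.index
        for k, tf in enumerate(self.singletons):
            out[tf] = -(k + 1)
        return out


def _nonzero_upper(matrix: CoordinationMatrix) -> np.ndarray:
    iu = np.triu_indices(len(matrix.tf_ids), 1)
    vals = matrix.overlaps[iu]
    return vals[vals > 0]


def significance_threshold(matrix: CoordinationMatrix, multiplier: float = 1.0) -> float:
    """Mean plus ``multiplier`` sample standard deviations of the nonzero
    upper-triangle overlaps; a single nonzero entry has SD defined as 0."""
    vals = _nonzero_upper(matrix).astype(float)
    if vals.size == 0:
        raise EmptyNetworkError("coordination matrix has no nonzero entry")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()) + multiplier * sd


def decompose(matrix: CoordinationMatrix, multiplier: float = 1.0) -> DecompositionResult:
    """Run Triple-Link until no connected pair remains.

    The threshold is computed once on the full matrix.  Ties are broken
    deterministically: seed pairs lexicographically by (tf_a, tf_b); growth
    candidates by most significant links into the cluster, then largest
    summed overlap, then id.  TFs never joined to any cluster are reported
    as singletons.
    """
    tf_ids = matrix.tf_ids
    n = len(tf_ids)
    O = matrix.overlaps
    try:
        thr = significance_threshold(matrix, multiplier)
    except EmptyNetworkError:
        return DecompositionResult((), tuple(sorted(tf_ids)), float("nan"), multiplier)
    sig = O > thr

    active = np.ones(n, dtype=bool)
    clusters: list[TFCluster] = []
    while True:
        # heaviest remaining edge
        masked = np.where(active[:, None] & active[None, :], O, 0)
        iu = np.triu_indices(n, 1)
        best = masked[iu].max() if iu[0].size else 0
        if best <= 0:
            break
        cand_pairs = [
            (tf_ids[i], tf_ids[j], i, j)
            for i, j in zip(*iu)
            if masked[i, j] == best
        ]
        _, _, a, b = min(cand_pairs)
        members = [a, b]
        in_cluster = np.zeros(n, dtype=bool)
        in_cluster[[a, b]] = True
        while True:
            pool = np.flatnonzero(active & ~in_cluster)
            best_cand = None
            for c in pool:
                n_sig = int(sig[c, in_cluster].sum())
                if len(members) == 2:
                    ok = n_sig == 2  # third member: significant to both seeds
                else:
                    ok = n_sig >= 3
                if not ok:
                    continue
                key = (-n_sig, -int(O[c, in_cluster].sum()), tf_ids[c])
                if best_cand is None or key < best_cand[0]:
                    best_cand = (key, c)
            if best_cand is None:
                break
            c = best_cand[1]
            members.append(c)
            in_cluster[c] = True
        members_ids = [tf_ids[m] if isinstance(m, (int, np.integer)) else m for m in members]
        clusters.append(
            TFCluster(len(clusters) + 1, tuple(members_ids), int(best))
        )
        active &= ~in_cluster
    singletons = tuple(sorted(tf_ids[i] for i in np.flatnonzero(active)))
    return DecompositionResult(tuple(clusters), singletons, thr, multiplier)
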