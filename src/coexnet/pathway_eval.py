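"""Scoring ranked gene pairs against pathway membership, and clusters
against positive-gene sets.

A gene pair is labeled S (same pathway: at least one shared pathway id),
D (different pathways: both assigned, none shared) or N (at least one gene
outside every known pathway).  The labels are exhaustive and mutually
exclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .exceptions import InvalidInputError, SliceError
from .triple_link import DecompositionResult

__all__ = [
    "label_pair",
    "top_counts",
    "ConfusionCounts",
    "slice_confusion",
    "pvalue_cutoff_fraction",
    "cluster_positive_stats",
    "dedupe_pairs",
]

PathwayMap = Mapping[str, frozenset]


def label_pair(g1: str, g2: str, pathway_map: PathwayMap) -> str:
    """S / D / N label for an unordered gene pair."""
    if g1 == g2:
        raise InvalidInputError(f"pair of identical genes {g1!r}")
    p1 = pathway_map.get(g1)
    p2 = pathway_map.get(g2)
    if not p1 or not p2:
        return "N"
    return "S" if p1 & p2 else "D"


def top_counts(labels: Sequence[str], cutoff: int) -> dict[str, int]:
    """S/D/N counts over the first ``cutoff`` labeled pairs.

    Counts sum to ``cutoff`` (or the list length, with a warning, when the
    list is shorter).
    """
    if len(labels) < cutoff:
        warnings.warn(
            f"list has only {len(labels)} pairs; counting over all of them",
            stacklevel=2,
        )
    head = labels[:cutoff]
    return {lab: sum(1 for x in head if x == lab) for lab in ("S", "D", "N")}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d > 0 else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d > 0 else None

    @property
    def accuracy(self) -> float | None:
        d = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / d if d > 0 else None


_SLICE_SIZE = {100: 900, 500: 500}


def _slice_bounds(length: int, top_cutoff: int, slice_name: str, size: int) -> tuple[int, int]:
    if slice_name == "next":
        start = top_cutoff
    elif slice_name == "middle":
        start = (length - size) // 2  # centered on the list midpoint
    elif slice_name == "bottom":
        start = length - size
    else:
        raise InvalidInputError(f"unknown slice {slice_name!r}")
    if start < 0 or start + size > length or (slice_name == "next" and top_cutoff + size > length):
        raise SliceError(
            f"list of {length} pairs too short for {slice_name} slice of {size} "
            f"after top {top_cutoff}"
        )
    return start, start + size


def slice_confusion(
    labels: Sequence[str],
    top_cutoff: int,
    slice_name: str,
    target: str = "S",
) -> ConfusionCounts:
    """Confusion counts of the top pairs against one comparison slice.

    Top pairs with the target label are TP, the rest FP.  The slice supplies
    FN (target pairs) and TN (non-target pairs).  With ``top_cutoff=100`` the
    slices hold 900 pairs and the slice counts are divided by 9 to put both
    windows on the same footing; with ``top_cutoff=500`` the slices hold 500
    pairs and are used directly.
    """
    if top_cutoff not in _SLICE_SIZE:
        raise InvalidInputError("top_cutoff must be 100 or 500")
    if target not in ("S", "D"):
        raise InvalidInputError("target must be 'S' or 'D'")
    size = _SLICE_SIZE[top_cutoff]
    rescale = size / top_cutoff
    if len(labels) < top_cutoff:
        raise SliceError(f"list of {len(labels)} pairs shorter than top {top_cutoff}")
    lo, hi = _slice_bounds(len(labels), top_cutoff, slice_name, size)
    head = labels[:top_cutoff]
    window = labels[lo:hi]
    tp = float(sum(1 for x in head if x == target))
    fp = float(top_cutoff) - tp
    n_target = float(sum(1 for x in window if x == target))
    fn = n_target / rescale
    tn = (size - n_target) / rescale
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def pvalue_cutoff_fraction(
    labels: Sequence[str], p_values: Sequence[float], threshold: float
) -> tuple[float, int]:
    """Fraction of same-pathway pairs among pairs with p below ``threshold``.

    Returns ``(fraction_S, n_retained)``; the empty-set convention is (0, 0).
    """
    if not 0 < threshold <= 1:
        raise InvalidInputError("threshold must be in (0, 1]")
    kept = [lab for lab, p in zip(labels, p_values) if p < threshold]
    if not kept:
        return 0.0, 0
    return sum(1 for x in kept if x == "S") / len(kept), len(kept)


def dedupe_pairs(pairs: Sequence[tuple[str, str, float]]) -> list[tuple[str, str, float]]:
    """Deduplicate (g1, g2, p) records by sorted gene-id key, keeping the
    smallest p for each unordered pair."""
    best: dict[tuple[str, str], float] = {}
    for g1, g2, p in pairs:
        key = tuple(sorted((g1, g2)))
        if key not in best or p < best[key]:
            best[key] = p
    return [(a, b, p) for (a, b), p in sorted(best.items(), key=lambda kv: (kv[1], kv[0]))]


def cluster_positive_stats(
    result: DecompositionResult, positives: Mapping[str, set]
) -> list[dict]:
    """Per-cluster counts of members found in each named positive set.

    ``n_positive`` counts members in the union of all sets;
    ``positive_set_hits`` reports each set independently (overlapping sets
    may both claim a gene).
    """
    union = set().union(*positives.values()) if positives else set()
    out = []
    for cl in result.clusters:
        members = set(cl.members)
        n_pos = len(members & union)
        out.append(
            {
                "cluster_index": cl.index,
                "size": len(cl.members),
                "n_positive": n_pos,
                "percent_positive": 100.0 * n_pos / len(cl.members),
                "positive_set_hits": {
                    name: len(members & genes) for name, genes in positives.items()
                },
            }
        )
    return out
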