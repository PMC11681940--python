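"""Linear-time representative selection by farthest-first (maximin) traversal.

Used both to pick representative sequences during orthogroup splitting and
to subsample representative genomes by ANI distance.  The min-distance
array is updated incrementally, so the distance oracle is evaluated at most
k*n times; the novelty (distance to the nearest previously selected item)
of successive picks is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np

#: novelty reported for the first selected item (no prior items to compare to)
FIRST_NOVELTY = 1.0


@dataclass
class SampleTrace:
    """Ordered selection with per-item novelty.

    ``novelty[i]`` is the distance of item i to the nearest item selected
    before it; the first item carries the sentinel 1.0.
    """

    item_ids: list
    novelty: list[float]

    def __post_init__(self) -> None:
        if len(self.item_ids) != len(self.novelty):
            raise ValueError("item_ids and novelty length mismatch")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate items in trace")

    def __len__(self) -> int:
        return len(self.item_ids)


def ficlin_select(
    items: Sequence[Hashable],
    dist: Callable[[Hashable, Hashable], float],
    k: int | None = None,
    stop_novelty: float | None = None,
    rng_seed: int = 0,
) -> SampleTrace:
    """Select representatives by maximin farthest-first traversal.

    The first pick is the item farthest from a seeded-random pivot; each
    subsequent pick maximizes the minimum distance to the already-selected
    set.  Stops after ``k`` items, or before a pick whose novelty would
    fall below ``stop_novelty``.  Ties break on the lexicographically
    smallest item id.  O(k*n) distance evaluations.
    """
    items = list(items)
    if not items:
        raise ValueError("ficlin_select requires at least one item")
    if k is None and stop_novelty is None:
        k = len(items)
    if k is not None and k <= 0:
        raise ValueError("k must be positive")
    if k is None:
        k = len(items)
    k = min(k, len(items))

    rng = np.random.default_rng(rng_seed)
    pivot = items[int(rng.integers(len(items)))]
    piv_d = [dist(pivot, it) for it in items]
    first_i = max(range(len(items)), key=lambda i: (piv_d[i], _neg_key(items[i])))

    selected = [items[first_i]]
    novelty = [FIRST_NOVELTY]
    remaining = [it for i, it in enumerate(items) if i != first_i]
    if k == 1:
        return SampleTrace(selected, novelty)
    mind = [dist(selected[0], it) for it in remaining]

    while remaining and len(selected) < k:
        best_i = max(range(len(remaining)), key=lambda i: (mind[i], _neg_key(remaining[i])))
        nov = mind[best_i]
        if stop_novelty is not None and nov < stop_novelty:
            break
        pick = remaining.pop(best_i)
        mind.pop(best_i)
        selected.append(pick)
        novelty.append(nov)
        if len(selected) < k:  # last pick needs no update round
            for i, it in enumerate(remaining):
                d = dist(pick, it)
                if d < mind[i]:
                    mind[i] = d
    return SampleTrace(selected, novelty)


class _neg_key:
    """Reverse-order wrapper so max() prefers the lexicographically smallest id."""

    __slots__ = ("v",)

    def __init__(self, v):
        self.v = v

    def __lt__(self, other):
        return self.v > other.v

    def __gt__(self, other):
        return self.v < other.v

    def __eq__(self, other):
        return self.v == other.v
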