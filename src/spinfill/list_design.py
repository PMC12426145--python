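"""Construction and validation of same, spun, and scrambled list sets.

A *list set* is an ordered collection of lists built from one base set of
items.  Three designs are supported, corresponding to the three repetition
schedules of the spin-list serial learning procedure:

``same``
    every list repeats the base order, so each item keeps both its serial
    position and its neighbours across repetitions;
``spun``
    each list is the previous one rotated right by one step (the last item
    moves to the front), so items keep their neighbours — including the
    cyclic wrap from the final item to the first — but visit every serial
    position;
``scrambled``
    a Williams balanced Latin square, so each item appears exactly once in
    each serial position and each ordered pair of distinct items is adjacent
    exactly once — neither positional nor neighbour information repeats.

Spun and scrambled sets are position-balanced; only scrambled sets are also
adjacency-balanced.  :func:`check_balance` verifies both properties by
exhaustive counting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "ListSet",
    "BalanceReport",
    "make_same_set",
    "make_spun_set",
    "make_scrambled_set",
    "check_balance",
    "listset_to_frame",
    "frame_to_listsets",
    "write_listsets",
    "read_listsets",
]

LIST_TYPES = ("same", "spun", "scrambled")


@dataclass(frozen=True)
class ListSet:
    """An ordered collection of lists over one base item set.

    Serial positions are 1-based everywhere in this package.
    """

    set_id: str
    list_type: str
    base_items: tuple[str, ...]
    lists: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if self.list_type not in LIST_TYPES:
            raise ValueError(f"unknown list_type {self.list_type!r}")
        base = set(self.base_items)
        if len(base) != len(self.base_items):
            raise ValueError("base_items contains duplicates")
        for i, lst in enumerate(self.lists, start=1):
            if sorted(lst) != sorted(self.base_items):
                raise ValueError(
                    f"list {i} of set {self.set_id!r} is not a permutation "
                    f"of base_items: {lst!r}"
                )

    @property
    def n_items(self) -> int:
        return len(self.base_items)

    def __len__(self) -> int:
        return len(self.lists)


@dataclass(frozen=True)
class BalanceReport:
    """Exhaustive position/adjacency occupancy counts for a list set.

    ``position_balanced`` is true when every item occupies every serial
    position exactly once across the set; ``adjacency_balanced`` when every
    ordered pair of distinct items is adjacent (immediately consecutive)
    exactly once across the set.
    """

    position_balanced: bool
    adjacency_balanced: bool
    position_counts: dict[tuple[str, int], int]
    adjacency_counts: dict[tuple[str, str], int]


def _validate_items(items: Sequence[str]) -> tuple[str, ...]:
    items = tuple(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    if len(set(items)) != len(items):
        raise ValueError(f"items must be distinct, got {items!r}")
    return items


def make_same_set(
    items: Sequence[str], n_lists: int = 6, set_id: str = "same"
) -> ListSet:
    """Repeat ``items`` unchanged ``n_lists`` times."""
    items = _validate_items(items)
    if n_lists < 1:
        raise ValueError("n_lists must be positive")
    return ListSet(set_id, "same", items, tuple(items for _ in range(n_lists)))


def make_spun_set(items: Sequence[str], set_id: str = "spun") -> ListSet:
    """Rotate ``items`` right by one step per list (last item to the front).

    For n items the set contains the n distinct rotations, starting from the
    base order itself (e.g. ABCDEF, FABCDE, EFABCD, ...).
    """
    items = _validate_items(items)
    n = len(items)
    lists = tuple(items[n - k:] + items[: n - k] for k in range(n))
    return ListSet(set_id, "spun", items, lists)


def make_scrambled_set(items: Sequence[str], set_id: str = "scrambled") -> ListSet:
    """Build a Williams balanced Latin square over ``items``.

    Requires an even number of items (the single-square Williams
    construction: first row 1, 2, n, 3, n-1, 4, ...; subsequent rows add 1
    modulo n).  The result is both position- and adjacency-balanced for any
    input ordering; permuting the input relabels the square.
    """
    items = _validate_items(items)
    n = len(items)
    if n % 2:
        raise ValueError("Williams single-square construction requires even n")
    first = [0, 1]
    lo, hi = 2, n - 1
    while len(first) < n:
        first.append(hi)
        hi -= 1
        if len(first) < n:
            first.append(lo)
            lo += 1
    lists = tuple(
        tuple(items[(x + i) % n] for x in first) for i in range(n)
    )
    return ListSet(set_id, "scrambled", items, lists)


def check_balance(listset: ListSet) -> BalanceReport:
    """Count item-by-position occupancy and ordered adjacencies exhaustively."""
    n = listset.n_items
    pos_counts: Counter = Counter()
    adj_counts: Counter = Counter()
    for lst in listset.lists:
        if len(set(lst)) != len(lst):
            raise ValueError(f"malformed list with duplicates: {lst!r}")
        for pos, item in enumerate(lst, start=1):
            pos_counts[(item, pos)] += 1
        for a, b in zip(lst, lst[1:]):
            adj_counts[(a, b)] += 1
    position_balanced = all(
        pos_counts.get((item, pos), 0) == 1
        for item in listset.base_items
        for pos in range(1, n + 1)
    )
    adjacency_balanced = all(
        adj_counts.get((a, b), 0) == 1
        for a in listset.base_items
        for b in listset.base_items
        if a != b
    )
    return BalanceReport(
        position_balanced=position_balanced,
        adjacency_balanced=adjacency_balanced,
        position_counts=dict(pos_counts),
        adjacency_counts=dict(adj_counts),
    )


# ---------------------------------------------------------------------------
# CSV serialization: long format, one row per (list, position).

def listset_to_frame(listset: ListSet) -> pd.DataFrame:
    rows = [
        {
            "set_id": listset.set_id,
            "list_type": listset.list_type,
            "list_index": li,
            "position": pos,
            "symbol": sym,
        }
        for li, lst in enumerate(listset.lists, start=1)
        for pos, sym in enumerate(lst, start=1)
    ]
    return pd.DataFrame(rows)


def frame_to_listsets(frame: pd.DataFrame) -> list[ListSet]:
    sets = []
    for set_id, grp in frame.groupby("set_id", sort=False):
        (list_type,) = grp["list_type"].unique()
        lists = []
        for _, sub in sorted(grp.groupby("list_index")):
            sub = sub.sort_values("position")
            lists.append(tuple(sub["symbol"].astype(str)))
        sets.append(ListSet(str(set_id), str(list_type), lists[0], tuple(lists)))
    return sets


def write_listsets(listsets: Sequence[ListSet], path) -> None:
    pd.concat([listset_to_frame(s) for s in listsets]).to_csv(path, index=False)


def read_listsets(path) -> list[ListSet]:
    return frame_to_listsets(pd.read_csv(path))
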