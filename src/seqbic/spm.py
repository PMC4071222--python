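"""Sequential pattern mining over itemset-sequence databases.

A sequence is an ordered tuple of itemsets; an itemset is a sorted tuple of
integer items (for the biclustering task, items are column indices).  The
subsequence relation is the standard one: ``a`` is contained in ``b`` when
there are strictly increasing positions i1 < .. < ik with each itemset of
``a`` a subset of the corresponding itemset of ``b``.

Three miners are provided:

``mine``            prefix-projection (pattern-growth) search with early
                    pruning on the minimum item count; dispatches to a
                    compiled kernel for large item-indexable databases.
``mine_bruteforce`` exhaustive enumeration oracle for tiny instances.
``support``         direct support/coverage computation for one pattern.

Pattern representations: *simple* (all frequent patterns), *closed* (no
proper superpattern with equal support) and *maximal* (all superpatterns
infrequent).  Closed patterns are the ones that yield maximal biclusters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TSequence

import numpy as np

Itemset = tuple[int, ...]
Seq = tuple[Itemset, ...]

REPRESENTATIONS = ("simple", "closed", "maximal")


class SearchBudgetExceeded(RuntimeError):
    """The pattern search exhausted its node budget before completing."""


@dataclass(frozen=True)
class SequentialPattern:
    """A frequent itemset sequence with its support and coverage."""

    itemsets: Seq
    support: int
    coverage: frozenset[int]

    def __post_init__(self):
        if self.support != len(self.coverage):
            raise ValueError("support must equal coverage size")

    @property
    def n_items(self) -> int:
        return sum(len(s) for s in self.itemsets)

    @property
    def distinct_items(self) -> frozenset[int]:
        return frozenset(i for s in self.itemsets for i in s)

    def __str__(self) -> str:
        return format_sequence(self.itemsets)


@dataclass
class SequenceDatabase:
    """A list of itemset sequences, one per origin row of a matrix."""

    sequences: list[Seq]
    origins: list[int] = None  # origin row index per sequence
    item_universe: frozenset[int] = None
    wildcards: list[frozenset[int]] = None  # per-sequence items matching anywhere

    def __post_init__(self):
        self.sequences = [canonical_sequence(s) for s in self.sequences]
        if self.origins is None:
            self.origins = list(range(len(self.sequences)))
        if self.item_universe is None:
            self.item_universe = frozenset(
                i for s in self.sequences for itemset in s for i in itemset
            ) | frozenset(i for w in (self.wildcards or []) for i in w)
        if self.wildcards is None:
            self.wildcards = [frozenset()] * len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def has_wildcards(self) -> bool:
        return any(self.wildcards)


def canonical_sequence(s: Iterable[Iterable[int]]) -> Seq:
    """Sorted-tuple canonical form; drops empty itemsets."""
    return tuple(tuple(sorted(set(it))) for it in s if len(tuple(it)) > 0)


# ---------------------------------------------------------------------------
# Text round-trip for worked examples: "(bc)a(abc)d" style
# ---------------------------------------------------------------------------


def parse_sequence(text: str, alphabet: dict | None = None) -> Seq:
    """Parse ``(bc)a(abc)d`` notation.

    Single-character tokens are items; parentheses group co-occurring items.
    Letters map to 0-based integers (a=0, b=1, ...) unless ``alphabet``
    provides an explicit mapping.
    """

    def enc(ch: str) -> int:
        if alphabet is not None:
            return alphabet[ch]
        if ch.isalpha():
            return ord(ch.lower()) - ord("a")
        return int(ch)

    itemsets: list[tuple[int, ...]] = []
    i = 0
    text = text.strip()
    while i < len(text):
        ch = text[i]
        if ch == "(":
            j = text.index(")", i)
            itemsets.append(tuple(sorted(enc(c) for c in text[i + 1 : j])))
            i = j + 1
        elif ch.isspace():
            i += 1
        else:
            itemsets.append((enc(ch),))
            i += 1
    return canonical_sequence(itemsets)


def format_sequence(s: Seq, names: dict | None = None) -> str:
    def dec(i: int) -> str:
        if names is not None:
            return str(names[i])
        if 0 <= i < 26:
            return chr(ord("a") + i)
        return f"<{i}>"

    parts = []
    for itemset in s:
        body = "".join(dec(i) for i in itemset)
        parts.append(body if len(itemset) == 1 else f"({body})")
    return "".join(parts)


def parse_database(lines: Iterable[str]) -> SequenceDatabase:
    """One sequence per line in ``(bc)a(abc)d`` notation."""
    seqs = [parse_sequence(ln) for ln in lines if ln.strip()]
    return SequenceDatabase(seqs)


# ---------------------------------------------------------------------------
# Subsequence relation and direct support
# ---------------------------------------------------------------------------


def collapse_ties(db: SequenceDatabase) -> SequenceDatabase:
    """Collapse consecutive duplicate itemsets (inverse of or expansion)."""
    seqs = []
    for s in db.sequences:
        out = []
        for itemset in s:
            if not out or out[-1] != itemset:
                out.append(itemset)
        seqs.append(tuple(out))
    return SequenceDatabase(seqs, list(db.origins), db.item_universe, list(db.wildcards))


def or_expand(db: SequenceDatabase) -> SequenceDatabase:
    """Repeat each co-occurrence itemset once per member (or behavior)."""
    seqs = []
    for s in db.sequences:
        out = []
        for itemset in s:
            if len(itemset) > 1 and (not out or out[-1] != itemset):
                out.extend([itemset] * len(itemset))
            elif len(itemset) == 1:
                out.append(itemset)
        seqs.append(tuple(out))
    return SequenceDatabase(seqs, list(db.origins), db.item_universe, list(db.wildcards))


def is_subsequence(a: Seq, b: Seq) -> bool:
    """True when ``a`` embeds into ``b`` at strictly increasing positions.

    Greedy earliest-match is complete for the itemset-subsequence relation:
    matching each itemset of ``a`` at the earliest possible position of ``b``
    leaves the maximal suffix for the remainder.
    """
    pos = 0
    for itemset in a:
        sa = set(itemset)
        while pos < len(b) and not sa.issubset(b[pos]):
            pos += 1
        if pos == len(b):
            return False
        pos += 1
    return True


def support(pattern: TSequence[TSequence[int]], db: SequenceDatabase) -> tuple[int, frozenset[int]]:
    """Support count and coverage (ids of containing sequences) of a pattern."""
    pat = canonical_sequence(pattern)
    if not pat:
        raise ValueError("pattern must be non-empty")
    cov = frozenset(
        sid
        for sid, s in zip(db.origins, db.sequences)
        if is_subsequence(pat, s)
    )
    return len(cov), cov


# ---------------------------------------------------------------------------
# Representation filters
# ---------------------------------------------------------------------------


def _proper_superpattern(a: SequentialPattern, b: SequentialPattern) -> bool:
    return b.n_items > a.n_items and is_subsequence(a.itemsets, b.itemsets)


def filter_representation(
    patterns: list[SequentialPattern], representation: str
) -> list[SequentialPattern]:
    """Reduce a complete frequent set to closed or maximal members.

    Valid whenever ``patterns`` is closed under frequent superpatterns of its
    members (true for any min-item-count filtered frequent set, because a
    superpattern never has fewer items).
    """
    if representation == "simple":
        return list(patterns)
    if representation not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    # closed: a proper superpattern with equal support necessarily has the
    # same coverage, so grouping by coverage reduces the quadratic sweep to
    # within-group checks
    groups: dict[frozenset[int], list[SequentialPattern]] = {}
    for p in patterns:
        groups.setdefault(p.coverage, []).append(p)
    closed = []
    for grp in groups.values():
        # longest-first: a pattern can only be dominated by a longer one
        # already kept, which keeps the sweep linear in practice
        grp = sorted(grp, key=lambda p: (-p.n_items, p.itemsets))
        kept: list[SequentialPattern] = []
        for p in grp:
            if not any(_proper_superpattern(p, q) for q in kept):
                kept.append(p)
        closed.extend(kept)
    if representation == "closed":
        return closed
    # maximal: no frequent proper superpattern at all; every frequent
    # superpattern is itself dominated by a closed one, so checking against
    # the closed set suffices
    return [
        p for p in closed if not any(_proper_superpattern(p, q) for q in closed)
    ]


def sort_patterns(patterns: list[SequentialPattern]) -> list[SequentialPattern]:
    """Deterministic order: support desc, item count desc, lexicographic."""
    return sorted(patterns, key=lambda p: (-p.support, -p.n_items, p.itemsets))


def _resolve_theta(theta: float | int, n: int) -> int:
    """Relative thresholds convert via ceiling; absolute pass through."""
    if isinstance(theta, float) and 0 < theta <= 1:
        return max(1, math.ceil(theta * n))
    t = int(theta)
    if t < 1:
        raise ValueError("theta must be >= 1 after conversion")
    return t


# ---------------------------------------------------------------------------
# Prefix-projection miner (general, pure python)
# ---------------------------------------------------------------------------


def _mine_general(
    db: SequenceDatabase, theta_abs: int, delta: int
) -> list[SequentialPattern]:
    """Pattern-growth search with pseudo-projection.

    The projected database stores, per active sequence, the earliest itemset
    index at which the current prefix's last itemset embeds; sequence
    extensions scan later itemsets, itemset extensions scan itemsets from
    that index on that contain the whole last prefix itemset.  A sequence is
    dropped from a projection when the prefix plus its remaining items cannot
    reach ``delta`` items.
    """
    seqs = db.sequences
    out: list[SequentialPattern] = []

    def remaining_items(s: Seq, start: int) -> int:
        return sum(len(s[t]) for t in range(start, len(s)))

    def grow(prefix: list[Itemset], active: list[tuple[int, int]], n_items: int):
        # active: (sequence position in db, itemset index where prefix's last
        # itemset matched earliest)
        last = prefix[-1]
        last_set = set(last)
        seq_candidates: dict[int, list[tuple[int, int]]] = {}
        set_candidates: dict[int, list[tuple[int, int]]] = {}
        for spos, e in active:
            s = seqs[spos]
            seen_seq: dict[int, int] = {}
            for t in range(e + 1, len(s)):
                for x in s[t]:
                    if x not in seen_seq:
                        seen_seq[x] = t
            for x, t in seen_seq.items():
                seq_candidates.setdefault(x, []).append((spos, t))
            seen_set: dict[int, int] = {}
            for t in range(e, len(s)):
                st = set(s[t])
                if last_set <= st:
                    for x in st:
                        if x > last[-1] and x not in seen_set:
                            seen_set[x] = t
            for x, t in seen_set.items():
                set_candidates.setdefault(x, []).append((spos, t))

        for x in sorted(set_candidates):
            entries = set_candidates[x]
            if len(entries) < theta_abs:
                continue
            child = prefix[:-1] + [tuple(sorted(last + (x,)))]
            _emit(child, entries, n_items + 1)
            grow(child, entries, n_items + 1)
        for x in sorted(seq_candidates):
            entries = seq_candidates[x]
            if len(entries) < theta_abs:
                continue
            child = prefix + [(x,)]
            # a sequence whose suffix cannot reach delta items never supports
            # an emitted descendant, so dropping it keeps supports exact
            kept = [
                (spos, t)
                for spos, t in entries
                if n_items + remaining_items(seqs[spos], t) >= delta
            ]
            _emit(child, entries, n_items + 1)
            if len(kept) >= theta_abs:
                grow(child, kept, n_items + 1)

    def _emit(prefix: list[Itemset], entries: list[tuple[int, int]], n_items: int):
        if n_items >= delta:
            cov = frozenset(db.origins[spos] for spos, _ in entries)
            out.append(SequentialPattern(tuple(prefix), len(cov), cov))

    # depth-1 seeds
    seeds: dict[int, list[tuple[int, int]]] = {}
    for spos, s in enumerate(seqs):
        first: dict[int, int] = {}
        for t, itemset in enumerate(s):
            for x in itemset:
                if x not in first:
                    first[x] = t
        for x, t in first.items():
            seeds.setdefault(x, []).append((spos, t))
    for x in sorted(seeds):
        entries = seeds[x]
        if len(entries) < theta_abs:
            continue
        prefix = [(x,)]
        _emit(prefix, entries, 1)
        grow(prefix, entries, 1)
    return out


# ---------------------------------------------------------------------------
# Compiled fast path for (near-)item-indexable databases
# ---------------------------------------------------------------------------

def _mine_fast(db: SequenceDatabase, theta_abs: int, delta: int, ties: bool = False,
               node_budget: int | None = None):
    from . import _kernel2

    items = sorted(db.item_universe)
    item_pos = {x: k for k, x in enumerate(items)}
    seqs = [
        tuple(tuple(item_pos[x] for x in itemset) for itemset in s)
        for s in db.sequences
    ]
    wilds = [frozenset(item_pos[x] for x in w) for w in db.wildcards]
    res = _kernel2.run(seqs, wilds, len(items), theta_abs, delta, ties, node_budget)
    if res is None:
        return None
    pat_items, pat_isnew, covers, truncated = res
    if truncated:
        raise SearchBudgetExceeded(
            f"pattern search truncated after {node_budget} nodes"
        )
    out = []
    origins = db.origins
    for flat, isnew, cov in zip(pat_items, pat_isnew, covers):
        itemsets: list[tuple[int, ...]] = []
        cur: list[int] = []
        for x, nw in zip(flat, isnew):
            if nw and cur:
                itemsets.append(tuple(sorted(cur)))
                cur = []
            cur.append(items[x])
        itemsets.append(tuple(sorted(cur)))
        coverage = frozenset(origins[int(i)] for i in cov)
        out.append(SequentialPattern(tuple(itemsets), len(coverage), coverage))
    return out


# ---------------------------------------------------------------------------
# Public miners
# ---------------------------------------------------------------------------


def mine(
    db: SequenceDatabase,
    theta: float | int,
    delta: int = 1,
    representation: str = "simple",
    engine: str = "auto",
    ties: bool = False,
    node_budget: int | None = None,
) -> list[SequentialPattern]:
    """Mine frequent sequential patterns with at least ``delta`` items.

    ``theta`` may be an absolute count (int) or a relative fraction (float in
    (0, 1]), converted by ceiling.  ``engine`` selects the search backend:
    ``general`` (pure python, any database), ``fast`` (compiled kernel, needs
    item occurrence counts <= 4 per sequence) or ``auto``.

    With ``ties=True`` the or behavior is mined: patterns are monotone
    chains of distinct items whose ranks need only be non-decreasing along
    the pattern.  Co-occurrence itemsets are not enumerated separately —
    under the or reading a tie satisfies the chain, so the flat chain over
    the same columns always has at least the co-occurrence pattern's
    support and yields the same bicluster.  Consecutive duplicate itemsets
    in the input (an already or-expanded database) are treated as one tie
    group.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if representation not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    if len(db) == 0:
        return []
    theta_abs = _resolve_theta(theta, len(db))
    if ties:
        db = collapse_ties(db)

    patterns = None
    size = sum(sum(len(it) for it in s) for s in db.sequences)
    if engine == "fast" or (engine == "auto" and size >= 4000):
        patterns = _mine_fast(db, theta_abs, delta, ties, node_budget)
        if patterns is None and engine == "fast":
            raise ValueError("database not encodable for the fast engine")
    if patterns is None:
        if db.has_wildcards:
            raise ValueError(
                "wildcard (relaxed-missing) databases require the fast engine"
            )
        if ties:
            expanded = or_expand(db)
            patterns = [
                p
                for p in _mine_general(expanded, theta_abs, delta)
                if p.n_items == len(p.distinct_items)
                and all(len(it) == 1 for it in p.itemsets)
            ]
        else:
            patterns = _mine_general(db, theta_abs, delta)
    return sort_patterns(filter_representation(patterns, representation))


def mine_bruteforce(
    db: SequenceDatabase,
    theta: float | int,
    delta: int = 1,
    representation: str = "simple",
    max_sequences: int = 10,
    max_alphabet: int = 8,
) -> list[SequentialPattern]:
    """Exhaustive oracle: enumerate every candidate itemset sequence.

    Only for tiny instances; refuses anything above the size guard.  Support
    is tested by an independent backtracking embedding check, not the greedy
    matcher used elsewhere.
    """
    if len(db) > max_sequences:
        raise ValueError("database too large for the brute-force oracle")
    universe = sorted(db.item_universe)
    if len(universe) > max_alphabet:
        raise ValueError("alphabet too large for the brute-force oracle")
    if db.has_wildcards:
        raise ValueError("oracle does not support wildcard databases")
    max_len = max((len(s) for s in db.sequences), default=0)
    max_items = max((sum(len(it) for it in s) for s in db.sequences), default=0)
    itemsets = []
    for r in range(1, len(universe) + 1):
        itemsets.extend(tuple(c) for c in itertools.combinations(universe, r))

    def embeds(pat: Seq, s: Seq, pi: int, si: int) -> bool:
        # backtracking embedding check (independent of greedy matcher)
        if pi == len(pat):
            return True
        for t in range(si, len(s)):
            if set(pat[pi]) <= set(s[t]) and embeds(pat, s, pi + 1, t + 1):
                return True
        return False

    theta_abs = _resolve_theta(theta, len(db))
    frequent: list[SequentialPattern] = []
    for length in range(1, max_len + 1):
        for combo in itertools.product(itemsets, repeat=length):
            if sum(len(it) for it in combo) > max_items:
                continue
            cov = frozenset(
                sid
                for sid, s in zip(db.origins, db.sequences)
                if embeds(combo, s, 0, 0)
            )
            if len(cov) >= theta_abs:
                frequent.append(SequentialPattern(combo, len(cov), cov))
    kept = [p for p in frequent if p.n_items >= delta]
    if representation == "closed":
        kept = [
            p
            for p in kept
            if not any(
                q.support == p.support and _proper_superpattern(p, q) for q in frequent
            )
        ]
    elif representation == "maximal":
        kept = [
            p for p in kept if not any(_proper_superpattern(p, q) for q in frequent)
        ]
    return sort_patterns(kept)
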