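import numpy as np
import pytest

from seqbic import (
    Bicluster,
    BiclusterSet,
    ExpressionMatrix,
    discretize,
    extend,
    filter_contained,
    filter_rows_cols,
    itemize,
    merge,
    mine,
    normalize,
    rank_items,
)
from seqbic.biclustering import patterns_to_biclusters
from seqbic.closing import select_representatives


def _bic(rows, cols, order=None):
    order = order if order is not None else sorted(cols)
    return Bicluster(frozenset(rows), frozenset(cols), tuple((c,) for c in order))


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def test_merge_overlapping_pair():
    a = _bic({0, 1, 2}, {0, 1})
    b = _bic({1, 2}, {0, 1, 2})
    out = merge(BiclusterSet([a, b]), 2 / 3)
    assert len(out) == 1
    assert out[0].rows == frozenset({0, 1, 2})
    assert out[0].cols == frozenset({0, 1, 2})


def test_merge_at_full_overlap_is_identity_on_closed_output(worked_db):
    """100% required overlap leaves closed-pattern biclusters untouched
    (after the containment filter has removed nested duplicates)."""
    patterns = mine(worked_db, 3, 2, "closed")
    bset = filter_contained(patterns_to_biclusters(patterns, worked_db))
    out = merge(bset, 1.0)
    assert [(b.rows, b.cols) for b in out] == [(b.rows, b.cols) for b in bset]


def test_merge_disjoint_unchanged():
    a = _bic({0, 1}, {0, 1})
    b = _bic({2, 3}, {2, 3})
    out = merge(BiclusterSet([a, b]), 0.1)
    assert len(out) == 2


def test_merge_idempotent_at_fixpoint(rng):
    bics = []
    for _ in range(8):
        rows = frozenset(int(i) for i in rng.choice(12, 5, replace=False))
        cols = frozenset(int(j) for j in rng.choice(6, 3, replace=False))
        bics.append(_bic(rows, cols))
    once = merge(BiclusterSet(bics), 0.5)
    twice = merge(once, 0.5)
    assert [(b.rows, b.cols) for b in twice] == [(b.rows, b.cols) for b in once]


def test_merge_rows_mode():
    a = _bic({0, 1, 2, 3}, {0, 1, 2})
    b = _bic({0, 1, 2}, {3, 4, 5})
    # zero area overlap, full row overlap of the smaller
    assert len(merge(BiclusterSet([a, b]), 0.8, mode="area")) == 2
    assert len(merge(BiclusterSet([a, b]), 0.8, mode="rows")) == 1


def test_merge_homogeneity_guard_blocks_incoherent_union(rng):
    # two modules with opposite orderings over the same columns
    values = np.zeros((10, 4))
    values[:5] = np.sort(rng.uniform(-1, 1, (5, 4)), axis=1)          # increasing
    values[5:] = -np.sort(rng.uniform(-1, 1, (5, 4)), axis=1)         # decreasing
    m = ExpressionMatrix(values, [f"x{i}" for i in range(10)], list("abcd"))
    sym = rank_items(m)
    a = _bic(set(range(5)), {0, 1, 2, 3})
    b = _bic(set(range(4, 9)), {0, 1, 2, 3}, order=[3, 2, 1, 0])
    merged = merge(BiclusterSet([a, b]), 0.1, sym, "xor", max_violation=0.2)
    assert len(merged) == 2  # guard refuses the chained union


# ---------------------------------------------------------------------------
# containment filtering
# ---------------------------------------------------------------------------


def test_filter_contained_removes_duplicates():
    a = _bic({0, 1}, {0, 1})
    out = filter_contained(BiclusterSet([a, a]))
    assert len(out) == 1


def test_filter_contained_is_antichain(rng):
    bics = []
    for _ in range(15):
        rows = frozenset(int(i) for i in rng.choice(10, int(rng.integers(2, 6)), replace=False))
        cols = frozenset(int(j) for j in rng.choice(6, int(rng.integers(2, 5)), replace=False))
        bics.append(_bic(rows, cols))
    out = filter_contained(BiclusterSet(bics))
    for i, a in enumerate(out):
        for j, b in enumerate(out):
            if i != j:
                assert not (a.rows <= b.rows and a.cols <= b.cols)


def test_filter_contained_keeps_antichain_unchanged():
    a = _bic({0, 1}, {0, 1})
    b = _bic({1, 2}, {1, 2})
    out = filter_contained(BiclusterSet([a, b]))
    assert len(out) == 2


def test_simple_collapses_to_closed_after_containment(worked_db):
    simple = patterns_to_biclusters(mine(worked_db, 3, 2, "simple"), worked_db)
    closed = patterns_to_biclusters(mine(worked_db, 3, 2, "closed"), worked_db)
    got = {(b.rows, b.cols) for b in filter_contained(simple)}
    want = {(b.rows, b.cols) for b in filter_contained(closed)}
    assert got == want


# ---------------------------------------------------------------------------
# row/column filtering
# ---------------------------------------------------------------------------


def _ordered_matrix_with_scrambled_row(rng):
    values = np.sort(rng.uniform(-1, 1, (6, 5)), axis=1)
    values[3] = rng.permutation(values[3])  # scrambled
    return ExpressionMatrix(values, [f"x{i}" for i in range(6)], list("abcde"))


def test_filter_rows_cols_drops_scrambled_row(rng):
    m = _ordered_matrix_with_scrambled_row(rng)
    sym = rank_items(m)
    b = _bic(set(range(6)), set(range(5)))
    out = filter_rows_cols(b, sym, 0.75, "xor")
    assert out is not None
    assert 3 not in out.rows
    assert out.rows == frozenset({0, 1, 2, 4, 5})


def test_filter_rows_cols_zero_threshold_is_identity(rng):
    m = _ordered_matrix_with_scrambled_row(rng)
    sym = rank_items(m)
    b = _bic(set(range(6)), set(range(5)))
    assert filter_rows_cols(b, sym, 0.0, "xor") is b


def test_filter_rows_cols_perfect_bicluster_unchanged(rng):
    values = np.sort(rng.uniform(-1, 1, (5, 4)), axis=1)
    m = ExpressionMatrix(values, [f"x{i}" for i in range(5)], list("abcd"))
    sym = rank_items(m)
    b = _bic(set(range(5)), set(range(4)))
    out = filter_rows_cols(b, sym, 0.99, "xor")
    assert out.rows == b.rows and out.cols == b.cols


def test_filter_rows_cols_monotone(rng):
    m = _ordered_matrix_with_scrambled_row(rng)
    sym = rank_items(m)
    b = _bic(set(range(6)), set(range(5)))
    out = filter_rows_cols(b, sym, 0.9, "xor")
    if out is not None:
        assert out.rows <= b.rows and out.cols <= b.cols


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------


def _planted_for_extension(rng, n_extra=30, cols=6):
    # 10 rows follow one ordering over `cols` columns; extras are random
    n = 10 + n_extra
    values = rng.uniform(-1, 1, (n, cols + 4))
    order = rng.permutation(cols)
    for i in range(10):
        vals = np.sort(rng.uniform(-1, 1, cols))
        values[i, order.argsort()] = vals[order.argsort()]  # identity placement
        values[i, :cols] = np.sort(rng.uniform(-1, 1, cols))
    m = ExpressionMatrix(values, [f"x{i}" for i in range(n)], [f"c{j}" for j in range(cols + 4)])
    return m


def test_extend_adds_perfectly_matching_row(rng):
    m = _planted_for_extension(rng)
    sym = rank_items(m)
    b = _bic(set(range(9)), set(range(6)))  # row 9 matches perfectly but is left out
    out = extend(BiclusterSet([b]), sym, alpha=0.01, correction="none", behavior="xor",
                 rng=rng)
    assert 9 in out[0].rows


def test_extend_rejects_random_rows(rng):
    m = _planted_for_extension(rng)
    sym = rank_items(m)
    b = _bic(set(range(10)), set(range(6)))
    out = extend(BiclusterSet([b]), sym, alpha=0.01, correction="bonferroni",
                 behavior="xor", rng=rng)
    added = out[0].rows - b.rows
    assert len(added) <= 2  # random rows essentially never pass


def test_extend_is_monotone(rng):
    m = _planted_for_extension(rng)
    sym = rank_items(m)
    b = _bic(set(range(10)), set(range(6)))
    out = extend(BiclusterSet([b]), sym, alpha=0.05, correction="none",
                 behavior="xor", rng=rng)
    assert b.rows <= out[0].rows
    assert b.cols <= out[0].cols


def test_extend_relaxed_support_zero_factor_idempotent(worked_db):
    patterns = mine(worked_db, 3, 2, "closed")
    bset = patterns_to_biclusters(patterns, worked_db)
    out = extend(bset, None, db=worked_db, strategy="relaxed_support",
                 relax_factor=0.0, merge_overlap=1.0)
    assert {(b.rows, b.cols) for b in out} == {(b.rows, b.cols) for b in bset}


def test_extend_relaxed_support_monotone(worked_db):
    patterns = mine(worked_db, 3, 2, "closed")
    bset = patterns_to_biclusters(patterns, worked_db)
    out = extend(bset, None, db=worked_db, strategy="relaxed_support",
                 theta=3 / len(worked_db), delta=2, relax_factor=0.4,
                 merge_overlap=0.8)
    for b in bset:
        assert any(b.rows <= o.rows and b.cols <= o.cols for o in out)


def test_extend_invalid_alpha(worked_db):
    bset = patterns_to_biclusters(mine(worked_db, 3, 2, "closed"), worked_db)
    with pytest.raises(ValueError):
        extend(bset, None, alpha=1.5)


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------


def test_select_representatives_prefers_long_patterns():
    small = _bic({0, 1, 2, 3}, {0, 1})
    big = _bic({0, 1, 2}, {0, 1, 2, 3})
    out = select_representatives(BiclusterSet([small, big]), 10, 0.5)
    assert out[0] is big
    assert len(out) == 1  # row-similar family collapses to its representative


def test_select_representatives_caps_count():
    bics = [_bic({i, i + 20}, {0, 1, 2}) for i in range(15)]
    out = select_representatives(BiclusterSet(bics), 5, 0.5)
    assert len(out) == 5
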