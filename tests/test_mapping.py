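import numpy as np
import pytest
from scipy import stats

from seqbic import (
    ExpressionMatrix,
    discretize,
    handle_missing,
    itemize,
    mask_outliers,
    normalize,
    rank_items,
    relax_items,
    relax_items_centroid,
)
from seqbic.mapping import SymbolicMatrix, materialize_wildcards
from seqbic.spm import format_sequence


def _labels(n, m):
    return [f"x{i+1}" for i in range(n)], [f"y{j+1}" for j in range(m)]


# ---------------------------------------------------------------------------
# normalization / outliers
# ---------------------------------------------------------------------------


def test_normalize_row_zero_mean():
    m = ExpressionMatrix(np.array([[1.0, 2.0, 3.0]]), *_labels(1, 3))
    out = normalize(m, "row")
    assert abs(out.values.mean()) < 1e-9


def test_normalize_idempotent_on_standardized_row(rng):
    v = rng.normal(size=(1, 50))
    v = (v - v.mean()) / v.std()
    m = ExpressionMatrix(v, *_labels(1, 50))
    out = normalize(m, "row")
    np.testing.assert_allclose(out.values, v, atol=1e-9)


def test_normalize_overall_recomputation(rng):
    m = ExpressionMatrix(rng.normal(2, 3, size=(50, 10)), *_labels(50, 10))
    out = normalize(m, "overall")
    assert abs(out.values.mean()) < 1e-9
    assert out.values.std() == pytest.approx(1.0, abs=1e-9)


def test_normalize_constant_row_centered_only():
    m = ExpressionMatrix(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]), *_labels(2, 3))
    out = normalize(m, "row")
    np.testing.assert_allclose(out.values[0], 0.0)


def test_mask_outliers():
    m = ExpressionMatrix(np.array([[0.0, 0.0, 0.0, 100.0]]), *_labels(1, 4))
    out = mask_outliers(m, 3.0)
    assert out.outlier_mask.sum() == 1
    assert out.outlier_mask[0, 3]
    out2 = mask_outliers(m, np.inf)
    assert out2.outlier_mask.sum() == 0
    with pytest.raises(ValueError):
        mask_outliers(m, 0.0)


def test_mask_outliers_normal_tail_rate(rng):
    v = rng.standard_normal((100, 10))
    v = (v - v.mean()) / v.std()
    m = ExpressionMatrix(v, *_labels(100, 10))
    out = mask_outliers(m, 3.0)
    frac = out.outlier_mask.mean()
    expect = 2 * stats.norm.sf(3)
    assert frac == pytest.approx(expect, abs=3 * np.sqrt(expect / 1000))


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def test_discretize_range_midpoint_split():
    m = ExpressionMatrix(np.array([[0.0, 1.0, 2.0, 3.0]]), *_labels(1, 4))
    sym = discretize(m, 2, "range", "row")
    assert [sym.items[0, j, 0] for j in range(4)] == [0, 0, 1, 1]


def test_discretize_depth_equal_counts():
    vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]])
    sym = discretize(ExpressionMatrix(vals, *_labels(1, 8)), 4, "depth", "row")
    counts = np.bincount(sym.items[0, :, 0], minlength=4)
    assert list(counts) == [2, 2, 2, 2]


def test_discretize_gaussian_bin_occupancy(rng):
    v = rng.standard_normal((100, 100))
    m = ExpressionMatrix(v, *_labels(100, 100))
    sym = discretize(m, 4, "gaussian", "overall")
    occ = np.bincount(sym.items[..., 0].ravel(), minlength=4) / v.size
    assert np.all(np.abs(occ - 0.25) < 0.02)


def test_discretize_rejects_too_many_items():
    m = ExpressionMatrix(np.array([[1.0, 1.0, 2.0]]), *_labels(1, 3))
    with pytest.raises(ValueError, match="smaller alphabet"):
        discretize(m, 3, "depth", "row")


def test_poisson_falls_back_below_lambda_3(rng, caplog):
    v = rng.uniform(0, 1, size=(5, 30))  # lambda well under 3
    m = ExpressionMatrix(v, *_labels(5, 30))
    sym = discretize(m, 3, "poisson", "overall")
    assert sym.n_items == 3  # produced via the gaussian fallback


def test_poisson_quantile_bins(rng):
    v = rng.poisson(6.0, size=(20, 50)).astype(float) + rng.normal(0, 1e-6, (20, 50))
    m = ExpressionMatrix(v, *_labels(20, 50))
    sym = discretize(m, 3, "poisson", "overall")
    assert sorted(np.unique(sym.items[..., 0])) == [0, 1, 2]


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------


def test_relax_zero_ratio_is_identity(rng):
    m = ExpressionMatrix(rng.normal(size=(10, 8)), *_labels(10, 8))
    sym = discretize(m, 4, "gaussian", "overall")
    out = relax_items(sym, 0.0)
    np.testing.assert_array_equal(out.items, sym.items)


def test_relax_multi_item_cells_sit_near_boundaries(rng):
    m = ExpressionMatrix(rng.normal(size=(30, 20)), *_labels(30, 20))
    sym = discretize(m, 5, "gaussian", "overall")
    ratio = 0.1
    out = relax_items(sym, ratio)
    multi = np.argwhere(out.items[:, :, 1] >= 0)
    assert len(multi) > 0
    K = sym.n_items
    for i, j in multi:
        c = m.values[i, j]
        k = sym.items[i, j, 0]
        a = sym.lo[0] if k == 0 else sym.boundaries[0, k - 1]
        b = sym.hi[0] if k == K - 1 else sym.boundaries[0, k]
        assert min(c - a, b - c) / (b - a) < ratio
        ks = sorted(out.items_of(i, j))
        assert ks[1] - ks[0] == 1  # adjacent symbols only


def test_relax_centroid_distance_example():
    # value 0.5 with symbol centroids 0.2 and 1.1 and threshold 0.7 receives
    # both symbols (1.1 - 0.7 < 0.5 < 0.2 + 0.7)
    m = ExpressionMatrix(np.array([[0.5, 0.0]]), *_labels(1, 2))
    sym = SymbolicMatrix(
        items=np.array([[[0, -1, -1, -1], [0, -1, -1, -1]]], dtype=np.int16),
        wildcard=np.zeros((1, 2), dtype=bool),
        n_items=2,
        scope="overall",
        matrix=m,
        boundaries=np.array([[0.65]]),
        centroids=np.array([[0.2, 1.1]]),
        lo=np.array([0.0]),
        hi=np.array([1.2]),
    )
    out = relax_items_centroid(sym, 0.7)
    assert out.items_of(0, 0) == (0, 1)
    assert out.items_of(0, 1) == (0,)


# ---------------------------------------------------------------------------
# missing values
# ---------------------------------------------------------------------------


def _missing_row_matrix():
    # x1: y1 missing, y3 < y2 among the observed cells
    values = np.array([[np.nan, 2.0, 1.0]])
    return ExpressionMatrix(values, *_labels(1, 3))


def _sym_for_missing():
    m = _missing_row_matrix()
    items = np.full((1, 3, 4), -1, dtype=np.int16)
    items[0, 1, 0] = 2  # y2 -> symbol 2
    items[0, 2, 0] = 1  # y3 -> symbol 1
    return SymbolicMatrix(
        items, np.zeros((1, 3), dtype=bool), 3, "overall", m,
        boundaries=np.array([[0.5, 1.5]]),
        centroids=np.array([[0.0, 1.0, 2.0]]),
        lo=np.array([0.0]), hi=np.array([2.5]),
    )


def test_relaxed_missing_cooccurs_everywhere():
    sym = handle_missing(_sym_for_missing(), "relaxed")
    db = itemize(sym, "xor")
    mat = materialize_wildcards(db)
    # y1 (index 0) joins every position: y1 (y1 y3) (y1 y2) y1
    names = {0: "y1", 1: "y2", 2: "y3"}
    assert format_sequence(mat.sequences[0], names) == "y1(y1y3)(y1y2)y1"


def test_delta_replace_assigns_nearby_symbols():
    # estimate is the row median of observed values = 1.5; delta 0.5 reaches
    # the symbols with centroids 1.0 and 2.0, so s1 = (y1 y3)(y1 y2)
    sym = handle_missing(_sym_for_missing(), "delta_replace", delta=0.5)
    db = itemize(sym, "xor")
    names = {0: "y1", 1: "y2", 2: "y3"}
    assert format_sequence(db.sequences[0], names) == "(y1y3)(y1y2)"


def test_restrictive_drops_all_missing_row():
    values = np.array([[np.nan, np.nan], [1.0, 2.0]])
    m = ExpressionMatrix(values, *_labels(2, 2))
    sym = discretize(m, 2, "range", "overall")
    db = itemize(handle_missing(sym, "restrictive"), "xor")
    assert len(db) == 1
    assert db.origins == [1]


# ---------------------------------------------------------------------------
# itemization
# ---------------------------------------------------------------------------


def test_itemize_xor_toy_row(toy_matrix):
    sym = rank_items(toy_matrix)
    db = itemize(sym, "xor")
    names = {j: f"y{j+1}" for j in range(3)}
    assert format_sequence(db.sequences[1], names) == "(y1y3)y2"


def test_itemize_or_duplicates_cooccurrences(toy_matrix):
    sym = rank_items(toy_matrix)
    db = itemize(sym, "or")
    names = {j: f"y{j+1}" for j in range(3)}
    assert format_sequence(db.sequences[1], names) == "(y1y3)(y1y3)y2"


def test_itemize_all_distinct_identical_across_behaviors(toy_matrix):
    sym = rank_items(toy_matrix)
    xor_db = itemize(sym, "xor")
    or_db = itemize(sym, "or")
    assert xor_db.sequences[0] == or_db.sequences[0]
    assert len(xor_db.sequences[0]) == 3
    assert all(len(it) == 1 for it in xor_db.sequences[0])


def test_item_indexable_property(rng):
    """xor, no relaxation, no missing: each column occurs exactly once."""
    m = ExpressionMatrix(rng.normal(size=(20, 12)), *_labels(20, 12))
    sym = discretize(normalize(m, "row"), 4, "gaussian", "overall")
    db = itemize(sym, "xor")
    for s in db.sequences:
        flat = [c for it in s for c in it]
        assert sorted(flat) == list(range(12))


def test_sorting_soundness(rng):
    """Across itemsets, the earlier column's symbol is strictly smaller."""
    m = ExpressionMatrix(rng.normal(size=(10, 10)), *_labels(10, 10))
    sym = discretize(m, 5, "gaussian", "overall")
    db = itemize(sym, "xor")
    for origin, s in zip(db.origins, db.sequences):
        for t in range(len(s) - 1):
            for a in s[t]:
                for b in s[t + 1]:
                    assert sym.items[origin, a, 0] < sym.items[origin, b, 0]


def test_strictly_increasing_row_yields_singletons():
    vals = np.array([[0.0, 1.0, 2.0, 3.0]])
    m = ExpressionMatrix(vals, *_labels(1, 4))
    sym = discretize(m, 4, "range", "row")
    db = itemize(sym, "xor")
    assert db.sequences[0] == ((0,), (1,), (2,), (3,))


def test_mirrored_items_middle_symbol_self_symmetric():
    m = ExpressionMatrix(np.array([[-1.0, 0.0, 1.0]]), *_labels(1, 3))
    sym = discretize(m, 3, "range", "row")
    mirrored = sym.mirrored_items()
    # symbols 0,1,2 map to 2,1,0: the middle symbol maps to itself
    assert mirrored.items[0, 1, 0] == sym.items[0, 1, 0] == 1
    assert mirrored.items[0, 0, 0] == 2
    assert mirrored.items[0, 2, 0] == 0
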