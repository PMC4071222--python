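import numpy as np
import pytest

from seqbic import (
    Bicluster,
    ExpressionMatrix,
    RunParameters,
    check_order_preserving,
    generate,
    mine,
    mine_biclusters,
    mine_with_symmetries,
    normalize,
    patterns_to_biclusters,
    preset,
    rank_items,
)
from seqbic.biclustering import _apply_dynamic, build_symbolic, order_violations
from seqbic.mapping import itemize
from seqbic.spm import SequentialPattern


# ---------------------------------------------------------------------------
# pattern -> bicluster derivation
# ---------------------------------------------------------------------------


def test_derivation_from_toy_pattern(toy_matrix):
    """Pattern (y1 y3) y2 covering rows x2 and x4 derives the bicluster
    I = {x2, x4}, J = {y1, y2, y3} with y1, y3 tied before y2."""
    sym = rank_items(toy_matrix)
    db = itemize(sym, "xor")
    patterns = mine(db, 2, 3, "simple", engine="general")
    target = next(p for p in patterns if p.itemsets == ((0, 2), (1,)))
    bset = patterns_to_biclusters([target], db)
    b = bset[0]
    assert b.rows == frozenset({1, 3})
    assert b.cols == frozenset({0, 1, 2})
    assert b.permutation == ((0, 2), (1,))


def test_derivation_covering_everything():
    values = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
    m = ExpressionMatrix(values, [f"x{i}" for i in range(4)], list("abc"))
    db = itemize(rank_items(m), "xor")
    patterns = mine(db, 4, 3, "simple", engine="general")
    full = patterns_to_biclusters([patterns[0]], db)[0]
    assert full.rows == frozenset(range(4))
    assert full.cols == frozenset(range(3))


def test_repeated_columns_collapse():
    p = SequentialPattern(((0,), (0,), (1,)), 2, frozenset({0, 1}))
    b = patterns_to_biclusters([p], None)[0]
    assert b.cols == frozenset({0, 1})
    assert b.permutation == ((0,), (1,))


# ---------------------------------------------------------------------------
# order checking
# ---------------------------------------------------------------------------


def test_emitted_biclusters_have_zero_violations(rng):
    m = ExpressionMatrix(rng.normal(size=(12, 8)),
                         [f"x{i}" for i in range(12)], [f"y{j}" for j in range(8)])
    sym = rank_items(m)
    db = itemize(sym, "xor")
    patterns = mine(db, 2, 3, "simple", engine="general")
    for b in patterns_to_biclusters(patterns[:20], db):
        assert check_order_preserving(b, sym, "xor").sum() == 0


def test_or_permutation_supported_by_all_rows():
    """Monotone (non-strict) reading: an ordering with within-row ties is
    supported by rows that tie where others increase."""
    values = np.array(
        [
            [3.0, 0.0, 0.0, 2.0],   # y2=y3 < y4 < y1
            [4.0, 1.0, 0.0, 2.0],   # y3 < y2 < y4 < y1
            [4.0, 1.0, 1.0, 1.0],   # y2=y3=y4 < y1
        ]
    )
    m = ExpressionMatrix(values, ["x1", "x2", "x3"], ["y1", "y2", "y3", "y4"])
    sym = rank_items(m)
    perm = ((2,), (1,), (3,), (0,))  # y3, y2, y4, y1
    b = Bicluster(frozenset({0, 1, 2}), frozenset({0, 1, 2, 3}), perm)
    assert check_order_preserving(b, sym, "or").sum() == 0
    assert check_order_preserving(b, sym, "xor").sum() > 0


def test_single_flipped_pair_counts_one_violation():
    values = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 4.0, 3.0]])
    m = ExpressionMatrix(values, ["x1", "x2"], list("abcd"))
    sym = rank_items(m)
    perm = ((0,), (1,), (2,), (3,))
    v0, _ = order_violations(sym, 0, perm, "xor")
    v1, _ = order_violations(sym, 1, perm, "xor")
    assert v0 == 0
    assert v1 == 1


# ---------------------------------------------------------------------------
# the pipeline on small matrices
# ---------------------------------------------------------------------------


def test_globally_coherent_matrix_yields_single_bicluster(rng):
    base = np.sort(rng.uniform(-1, 1, size=(30, 8)), axis=1)
    m = ExpressionMatrix(base, [f"x{i}" for i in range(30)], [f"y{j}" for j in range(8)])
    params = RunParameters(theta_start=0.5, delta=4, raw_order=True,
                           extension=None, homogeneity=None)
    found = mine_biclusters(m, params)
    assert len(found) == 1
    assert found[0].rows == frozenset(range(30))
    assert found[0].cols == frozenset(range(8))


def test_pure_noise_matrix_yields_no_biclusters(rng):
    m = ExpressionMatrix(rng.uniform(-1, 1, size=(50, 20)),
                         [f"x{i}" for i in range(50)], [f"y{j}" for j in range(20)])
    params = RunParameters(theta_start=0.5, theta_floor=0.25, delta=8,
                           raw_order=True, extension=None, homogeneity=None)
    found = mine_biclusters(m, params)
    # two random rows share an 8-column order with probability 1/8!
    assert len(found) == 0


def test_matrix_narrower_than_delta_rejected(rng):
    m = ExpressionMatrix(rng.normal(size=(5, 3)), [f"x{i}" for i in range(5)], list("abc"))
    with pytest.raises(ValueError, match="delta"):
        mine_biclusters(m, RunParameters(delta=4))


def test_zero_noise_planted_recovery_small():
    """At zero noise and raw-value ordering, the planted biclusters are
    recovered with perfect row sets (support mined below the planted size)."""
    matrix, hidden = generate(preset("s100x30", seed=21, noise_factor=0.0))
    params = RunParameters(
        raw_order=True, delta=5, theta_start=0.2, theta_floor=0.1,
        extension=None, homogeneity=None, seed=0,
    )
    found = mine_biclusters(matrix, params)
    assert len(found) == len(hidden)
    for h in hidden:
        assert max(len(b.rows & h.rows) / len(b.rows | h.rows) for b in found) == 1.0


# ---------------------------------------------------------------------------
# symmetries
# ---------------------------------------------------------------------------


def test_sign_alignment_on_toy():
    """Aligning on the first column flips exactly the rows negative there."""
    values = np.array(
        [
            [1.0, -2.0, 0.5],
            [-1.0, 2.0, -0.5],
            [-2.0, 1.0, 0.5],
        ]
    )
    m = ExpressionMatrix(values, ["x1", "x2", "x3"], ["y1", "y2", "y3"])
    norm = normalize(m, "row")
    signs = np.where(np.nan_to_num(norm.values[:, 0]) < 0, -1.0, 1.0)
    assert list(signs) == [1.0, -1.0, -1.0]


def test_all_positive_matrix_symmetries_match_plain(rng):
    base = np.sort(rng.uniform(0.1, 1, size=(20, 6)), axis=1)
    m = ExpressionMatrix(base, [f"x{i}" for i in range(20)], [f"y{j}" for j in range(6)])
    params = RunParameters(raw_order=True, delta=4, theta_start=0.5,
                           extension=None, homogeneity=None)
    plain = mine_biclusters(m, params)
    symm = mine_with_symmetries(m, params)
    plain_keys = {(b.rows, b.cols) for b in plain}
    symm_keys = {(b.rows, b.cols) for b in symm}
    assert plain_keys <= symm_keys
    for b in symm:
        if b.signs is not None:
            assert set(b.signs) == {1}


def test_symmetry_recovery_small(rng):
    """A module with half its rows negated is invisible to the plain search
    but found, with the planted signs up to a global flip, by the
    sign-corrected search."""
    n, m_cols = 40, 10
    values = rng.uniform(-1, 1, size=(n, m_cols))
    rows = np.arange(12)
    cols = np.arange(6)
    for i in rows:
        values[i, cols] = np.sort(rng.uniform(-1, 1, 6))
    signs = np.ones(n)
    signs[rows[: 6]] = -1
    values[:12] *= signs[:12, None]
    m = ExpressionMatrix(values, [f"x{i}" for i in range(n)],
                         [f"y{j}" for j in range(m_cols)])
    params = RunParameters(raw_order=True, delta=5, theta_start=0.3,
                           theta_floor=0.25, extension=None, homogeneity=None,
                           merge_overlap=None, stop_coverage=1.0)
    symm = mine_with_symmetries(m, params)
    target = frozenset(int(i) for i in rows)
    best = max(symm, key=lambda b: len(b.rows & target) / len(b.rows | target))
    assert len(best.rows & target) / len(best.rows | target) >= 0.9
    got = {i: s for i, s in zip(best.row_list, best.signs)}
    planted = {int(i): int(signs[i]) for i in rows}
    shared = sorted(set(got) & set(planted))
    agree = np.mean([got[i] == planted[i] for i in shared])
    assert agree >= 0.95 or agree <= 0.05
    plain = mine_biclusters(m, params)
    if len(plain):
        worst = max(
            (len(b.rows & target) / len(b.rows | target) for b in plain), default=0
        )
        assert worst < 0.5


# ---------------------------------------------------------------------------
# dynamic parameterization
# ---------------------------------------------------------------------------


def test_dynamic_missing_thresholds(rng):
    vals = rng.normal(size=(40, 10))
    base = RunParameters()

    def with_missing(frac):
        v = vals.copy()
        mask = rng.random(v.shape) < frac
        v[mask] = np.nan
        return ExpressionMatrix(v, [f"x{i}" for i in range(40)],
                                [f"y{j}" for j in range(10)], mask)

    p0 = _apply_dynamic(with_missing(0.0), base)
    assert p0.missing == "restrictive"
    p1 = _apply_dynamic(with_missing(0.035), base)
    assert p1.missing == "delta_replace"
    p2 = _apply_dynamic(with_missing(0.10), base)
    assert p2.missing == "relaxed"


def test_dynamic_skewed_data_selects_poisson(rng):
    v = rng.exponential(1.0, size=(40, 10)) ** 2
    m = ExpressionMatrix(v, [f"x{i}" for i in range(40)], [f"y{j}" for j in range(10)])
    p = _apply_dynamic(m, RunParameters())
    assert p.discretization == "poisson"
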