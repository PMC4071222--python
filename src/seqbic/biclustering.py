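"""From sequential patterns to order-preserving biclusters.

A frequent pattern over column indexes maps directly to a bicluster: its
supporting sequences are the rows, its distinct items the columns, and the
order of first occurrence of each column the permutation (with co-occurring
columns forming tie groups).  The orchestration here runs the mapping
pipeline, a support-decrease scheduler around the miner, the closing
operators, and the iterative sign-correction search for biclusters with
symmetric (anti-correlated) rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import closing as _closing
from . import mapping as _mapping
from . import spm as _spm
from .matrix import Bicluster, BiclusterSet, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class RunParameters:
    """Everything a mining run depends on.

    Support starts at ``theta_start`` (relative) and decays multiplicatively
    by ``theta_decay`` until the solution holds ``stop_biclusters``
    non-similar biclusters, the raw (pre-closing) solution exceeds
    ``stop_raw_patterns`` biclusters, ``stop_coverage`` of the matrix cells
    are covered, the absolute support would drop below
    ``min_support_rows``, the relative support falls below ``theta_floor``
    (when set), or the search-space budget is exhausted.
    """

    theta_start: float = 0.5
    theta_decay: float = 0.9
    theta_floor: float | None = None
    stop_biclusters: int = 50
    stop_raw_patterns: int = 50
    stop_coverage: float = 0.10
    min_support_rows: int = 4
    delta: int = 4
    items: int | None = None            # None: floor(m/4) clamped to [2, 20]
    raw_order: bool = False             # order raw values, no discretization
    behavior: str = "or"
    normalization: str = "row"
    discretization: str = "gaussian"
    disc_scope: str = "overall"
    outlier_z: float | None = None
    relaxation_ratio: float = 0.10
    missing: str = "restrictive"
    missing_delta: float | None = None
    estimator: str = "row_median"
    representation: str = "closed"
    merge_overlap: float | None = 0.8   # None disables merging
    merge_max_violation: float | None = 0.25
    filter_containment: bool = True
    homogeneity: float | None = 0.75    # row/column filtering threshold
    significance_max_expected: float | None = 0.5
    extension: str | None = "statistical"
    alpha: float = 0.01
    correction: str = "none"
    relax_factor: float = 0.10
    node_budget: int = 4_000_000        # per-mine search-space cap
    symmetries: bool = False
    dynamic: bool = False
    engine: str = "auto"
    seed: int = 0

    def validate(self, n_cols: int) -> None:
        if not 0 < self.theta_decay < 1:
            raise ValueError("theta_decay must be in (0, 1)")
        if not 0 < self.stop_coverage <= 1:
            raise ValueError("stop_coverage must be in (0, 1]")
        if self.delta < 2:
            raise ValueError("delta must be >= 2")
        if n_cols < self.delta:
            raise ValueError("matrix has fewer columns than delta")

    def resolved_items(self, n_cols: int) -> int:
        if self.items is not None:
            return self.items
        return int(np.clip(n_cols // 4, 2, 20))


# ---------------------------------------------------------------------------
# Pattern -> bicluster
# ---------------------------------------------------------------------------


def patterns_to_biclusters(
    patterns: list[_spm.SequentialPattern],
    db: _spm.SequenceDatabase,
    provenance: dict | None = None,
) -> BiclusterSet:
    """Derive one bicluster per pattern (row orientation).

    Repeated column indexes inside a pattern (possible under relaxation or
    ``or`` behavior) are collapsed: only the first occurrence of a column
    contributes to the permutation.
    """
    out = []
    for p in patterns:
        if not p.coverage:
            raise ValueError("pattern with empty coverage")
        seen: set[int] = set()
        groups: list[tuple[int, ...]] = []
        for itemset in p.itemsets:
            grp = tuple(sorted(c for c in itemset if c not in seen))
            seen.update(grp)
            if grp:
                groups.append(grp)
        out.append(
            Bicluster(frozenset(p.coverage), frozenset(seen), tuple(groups))
        )
    return BiclusterSet(out, dict(provenance or {}))


# ---------------------------------------------------------------------------
# Order checking
# ---------------------------------------------------------------------------


def _row_symbols(sym: _mapping.SymbolicMatrix, i: int, sign: int):
    """Per-column symbol tuples of row i, mirrored when sign is -1."""
    row = sym.items[i]
    if sign == 1:
        return [tuple(int(x) for x in cell[cell >= 0]) for cell in row]
    if sym.boundaries is None:  # raw ranks: mirror within the row's own range
        top = int(row.max())
        return [
            tuple(sorted(top - int(x) for x in cell[cell >= 0])) for cell in row
        ]
    K = sym.n_items
    return [tuple(sorted(K - 1 - int(x) for x in cell[cell >= 0])) for cell in row]


def order_violations(
    sym: _mapping.SymbolicMatrix,
    row: int,
    permutation: tuple[tuple[int, ...], ...],
    behavior: str = "xor",
    sign: int = 1,
) -> tuple[int, int]:
    """Count column pairs of ``permutation`` that row ``row`` violates.

    xor demands the exact relation of every pair: strict increase between
    tie groups, equality inside a group.  or demands non-decreasing symbols
    between groups and leaves within-group pairs unconstrained.  Pairs
    touching a symbol-less cell are skipped.  Returns (violations, pairs
    evaluated).
    """
    symbols = _row_symbols(sym, row, sign)
    viol = pairs = 0
    flat = [(g, c) for g, grp in enumerate(permutation) for c in grp]
    for a in range(len(flat)):
        ga, ca = flat[a]
        sa = symbols[ca]
        if not sa:
            continue
        for b in range(a + 1, len(flat)):
            gb, cb = flat[b]
            sb = symbols[cb]
            if not sb:
                continue
            if ga == gb:
                if behavior == "xor":
                    pairs += 1
                    if not set(sa) & set(sb):
                        viol += 1
            else:
                pairs += 1
                if behavior == "xor":
                    ok = min(sa) < max(sb)
                else:
                    ok = min(sa) <= max(sb)
                if not ok:
                    viol += 1
    return viol, pairs


def check_order_preserving(
    bicluster: Bicluster,
    sym: _mapping.SymbolicMatrix,
    behavior: str = "xor",
) -> np.ndarray:
    """Violation count per bicluster row (0 everywhere iff order-preserving)."""
    rows = bicluster.row_list
    out = np.zeros(len(rows), dtype=int)
    for k, i in enumerate(rows):
        sign = bicluster.signs[k] if bicluster.signs is not None else 1
        out[k], _ = order_violations(
            sym, i, bicluster.permutation, behavior, sign
        )
    return out


# ---------------------------------------------------------------------------
# Mapping pipeline
# ---------------------------------------------------------------------------


def build_symbolic(
    matrix: ExpressionMatrix, params: RunParameters, normalized: bool = False
) -> _mapping.SymbolicMatrix:
    """Run the pre-processing chain up to the symbolic matrix."""
    mat = matrix if normalized else _mapping.normalize(matrix, params.normalization)
    if params.outlier_z is not None:
        mat = _mapping.mask_outliers(mat, params.outlier_z)
    if params.raw_order:
        sym = _mapping.rank_items(mat)
    else:
        n_items = params.resolved_items(mat.n_cols)
        sym = _mapping.discretize(
            mat, n_items, params.discretization, params.disc_scope
        )
        if params.relaxation_ratio > 0:
            sym = _mapping.relax_items(sym, params.relaxation_ratio)
    if params.missing != "restrictive" and not params.raw_order:
        delta = params.missing_delta
        if params.missing == "delta_replace" and delta is None:
            # default: reach the 2-3 symbols nearest the estimate
            step = float(np.median(np.diff(sym.centroids, axis=1)))
            delta = 1.1 * step
        sym = _mapping.handle_missing(
            sym, params.missing, delta, params.estimator
        )
    elif params.missing == "relaxed" and params.raw_order:
        sym = _mapping.handle_missing(sym, "relaxed")
    return sym


def _area_jaccard(a: Bicluster, b: Bicluster) -> float:
    ri = len(a.rows & b.rows) * len(a.cols & b.cols)
    ru = a.area + b.area - ri
    return ri / ru if ru else 0.0


def _count_non_similar(bics: list[Bicluster], threshold: float = 0.8) -> int:
    kept: list[Bicluster] = []
    for b in bics:
        if all(_area_jaccard(b, k) < threshold for k in kept):
            kept.append(b)
    return len(kept)


def _significant(out, sym, params):
    if params.significance_max_expected is None:
        return out
    return _closing.filter_significant(
        out, sym.shape,
        None if sym.boundaries is None else sym.n_items,
        params.behavior, params.significance_max_expected,
    )


def _close(
    bset: BiclusterSet,
    sym: _mapping.SymbolicMatrix,
    params: RunParameters,
) -> BiclusterSet:
    """In-loop closing: representative selection and containment filtering.

    Pattern populations grow combinatorially near the support floor, so the
    per-iteration solution is reduced to at most ``stop_biclusters``
    representatives (longest, best-supported patterns, one per family of
    row-similar biclusters) before the stopping metrics are evaluated.
    """
    out = _significant(bset, sym, params)
    out = _closing.select_representatives(out, params.stop_biclusters, 0.4)
    if params.filter_containment:
        out = _closing.filter_contained(out)
    return out


def _finalize(
    bset: BiclusterSet,
    sym: _mapping.SymbolicMatrix,
    db: _spm.SequenceDatabase,
    params: RunParameters,
    theta: float,
) -> BiclusterSet:
    """Post-search closing: merging, extension, homogeneity filtering."""
    out = bset
    if params.merge_overlap is not None and params.merge_overlap < 1 and len(out) > 1:
        out = _closing.merge(
            out, params.merge_overlap, sym, params.behavior,
            max_violation=params.merge_max_violation,
        )
    if params.extension is not None and len(out):
        out = _closing.extend(
            out, sym, db,
            strategy=params.extension,
            alpha=params.alpha,
            relax_factor=params.relax_factor,
            behavior=params.behavior,
            theta=theta,
            delta=params.delta,
            representation=params.representation,
            correction=params.correction,
            merge_overlap=params.merge_overlap or 0.8,
            rng=np.random.default_rng(params.seed),
            engine=params.engine,
            node_budget=params.node_budget,
            max_violation=params.merge_max_violation,
        )
    if params.homogeneity is not None:
        kept = []
        for b in out:
            fb = _closing.filter_rows_cols(
                b, sym, params.homogeneity, params.behavior,
                min_cols=params.delta,
            )
            if fb is not None:
                kept.append(fb)
        out = BiclusterSet(kept, out.provenance)
    out = _significant(out, sym, params)
    out = _closing.select_representatives(out, params.stop_biclusters, 0.4)
    if params.filter_containment:
        out = _closing.filter_contained(out)
    return out


def _schedule(
    mat: ExpressionMatrix, params: RunParameters
) -> tuple[BiclusterSet, _mapping.SymbolicMatrix, _spm.SequenceDatabase, float]:
    """Support-decrease scheduler over a pre-normalized matrix.

    Returns the representative solution of the last productive support
    level, before the final closing stage."""
    sym = build_symbolic(mat, params, normalized=True)
    db = _mapping.itemize(sym, params.behavior)
    n, m = mat.shape
    theta = params.theta_start
    best = BiclusterSet([], {})
    final_theta = theta
    last_step = 1
    prev_theta = theta
    while True:
        theta_abs = max(1, math.ceil(theta * len(db)))
        if theta_abs < params.min_support_rows:
            log.info("stopping: absolute support %d below floor", theta_abs)
            break
        try:
            patterns = _spm.mine(
                db, theta_abs, params.delta, params.representation,
                params.engine, ties=(params.behavior == "or"),
                node_budget=params.node_budget,
            )
        except _spm.SearchBudgetExceeded:
            if last_step > 1 and len(best) == 0:
                # the accelerated descent overshot a narrow productive
                # window into the explosion; back off to single steps
                theta = prev_theta * params.theta_decay
                last_step = 1
                log.info(
                    "search budget exhausted after an accelerated step; "
                    "retrying at theta=%.4f", theta,
                )
                continue
            log.info(
                "stopping: search space exhausted the node budget at "
                "theta=%.4f; keeping the previous solution", theta,
            )
            break
        bset = patterns_to_biclusters(patterns, db)
        bset = _close(bset, sym, params)
        best = bset
        final_theta = theta
        cov = bset.coverage((n, m)) if len(bset) else 0.0
        nsim = _count_non_similar(list(bset))
        log.info(
            "theta=%.4f (abs %d): %d patterns, %d biclusters "
            "(%d non-similar), coverage %.3f",
            theta, theta_abs, len(patterns), len(bset), nsim, cov,
        )
        if nsim >= params.stop_biclusters:
            break
        if len(patterns) > params.stop_raw_patterns:
            log.info("stopping: raw solution exceeds %d biclusters",
                     params.stop_raw_patterns)
            break
        if cov >= params.stop_coverage:
            break
        # nothing emitted: the stopping rules cannot trigger anywhere above
        # the first productive support level, so descend in larger steps
        prev_theta = theta
        last_step = 3 if len(patterns) == 0 else 1
        theta *= params.theta_decay**last_step
        if params.theta_floor is not None and theta < params.theta_floor:
            log.info("stopping: theta below floor %.4f", params.theta_floor)
            break
        if math.ceil(theta * len(db)) < params.min_support_rows:
            break
    return best, sym, db, final_theta


def _mine_normalized(
    mat: ExpressionMatrix, params: RunParameters
) -> tuple[BiclusterSet, _mapping.SymbolicMatrix, _spm.SequenceDatabase]:
    """Scheduler plus final closing over a pre-normalized matrix."""
    best, sym, db, final_theta = _schedule(mat, params)
    best = _finalize(best, sym, db, params, final_theta)
    best.provenance = _provenance(params, final_theta)
    return best, sym, db


def _provenance(params: RunParameters, theta: float) -> dict:
    d = {k: v for k, v in params.__dict__.items()}
    d["theta_final"] = theta
    return d


def _apply_dynamic(matrix: ExpressionMatrix, params: RunParameters) -> RunParameters:
    """Data-dependent parameterization.

    Missing handlers escalate with the missing rate (>2%: delta replacement,
    >5%: relaxed); skewed value distributions switch the discretization to
    poisson; very wide matrices would call for a vertical (column-oriented)
    search, which this implementation does not provide (logged).
    """
    n, m = matrix.shape
    p = replace(params, dynamic=False)
    frac_missing = matrix.unusable_mask.mean()
    if frac_missing > 0.05:
        p = replace(p, missing="relaxed")
    elif frac_missing > 0.02:
        p = replace(p, missing="delta_replace")
    vals = matrix.values[~matrix.unusable_mask]
    if vals.size > 2 and abs(float(_skew(vals))) > 1:
        p = replace(p, discretization="poisson")
    if m > 10 * n:
        log.warning(
            "matrix is much wider than tall; a vertical-format search would "
            "be preferable but is not implemented"
        )
    if not ((n < 20000 and m < 100) or (n < 4000 and m < 200)):
        log.info("large matrix: consider row sampling for tractability")
    return p


def _skew(v: np.ndarray) -> float:
    mu, sd = v.mean(), v.std()
    return 0.0 if sd == 0 else float(((v - mu) ** 3).mean() / sd**3)


def mine_biclusters(
    matrix: ExpressionMatrix, params: RunParameters | None = None
) -> BiclusterSet:
    """Full pipeline: mapping, support-scheduled mining, closing."""
    params = params or RunParameters()
    params.validate(matrix.n_cols)
    if params.dynamic:
        params = _apply_dynamic(matrix, params)
    mat = _mapping.normalize(matrix, params.normalization)
    bset, _, _ = _mine_normalized(mat, params)
    return bset


def mine_with_symmetries(
    matrix: ExpressionMatrix, params: RunParameters | None = None
) -> BiclusterSet:
    """Order-preserving biclusters allowing per-row sign flips.

    One iteration per alignment column: every row is multiplied by +-1 so
    the alignment column becomes non-negative, the plain pipeline runs on
    the corrected matrix, and discovered biclusters carry the sign vector
    restricted to their rows.  An identity iteration (no flips) runs first,
    so the result is always a superset of the plain search after
    deduplication.  Iterations whose canonical sign vector was already
    processed are skipped.
    """
    params = params or RunParameters()
    params.validate(matrix.n_cols)
    if params.normalization not in _mapping.SCOPES:
        raise ValueError("symmetries require zero-mean normalization")
    if params.dynamic:
        params = _apply_dynamic(matrix, params)
    mat = _mapping.normalize(matrix, params.normalization)
    n, m = mat.shape
    vals = np.where(mat.unusable_mask, np.nan, mat.values)

    seen_signs: set[tuple[int, ...]] = set()
    found: dict[tuple, Bicluster] = {}

    def canonical(signs: np.ndarray) -> tuple[int, ...]:
        return tuple((-signs if signs[0] < 0 else signs).astype(int).tolist())

    sign_vectors = [np.ones(n)]
    for j in range(m):
        col = vals[:, j]
        s = np.where(np.nan_to_num(col) < 0, -1.0, 1.0)
        sign_vectors.append(s)

    for s in sign_vectors:
        key = canonical(s)
        if key in seen_signs:
            continue
        seen_signs.add(key)
        flipped = ExpressionMatrix(
            vals * s[:, None], mat.row_labels, mat.col_labels,
            mat.missing_mask.copy(), mat.outlier_mask.copy(),
        )
        bset, _, _ = _mine_normalized(flipped, params)
        for b in bset:
            rows = b.row_list
            signs = tuple(int(s[i]) for i in rows)
            bb = Bicluster(b.rows, b.cols, b.permutation, signs)
            fkey = (b.rows, b.cols, b.permutation, bb.canonical_signs())
            found.setdefault(fkey, bb)

    out = BiclusterSet(list(found.values()), _provenance(params, params.theta_start))
    if params.filter_containment:
        out = _closing.filter_contained(out)
    return out
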