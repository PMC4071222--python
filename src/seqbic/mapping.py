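"""Pre-processing: normalization, discretization, noise relaxation, missing
values, and itemization of matrix rows into itemset sequences.

Each matrix row becomes a sequence of itemsets over its column indexes: the
columns are sorted by their (discretized) value, equal symbols co-occur in
one itemset, and increasing symbols form precedences.  Cells may carry more
than one symbol (noise relaxation near bin boundaries, delta-replacement of
missing values), in which case their column index appears at every assigned
symbol's position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix
from .spm import SequenceDatabase

log = logging.getLogger(__name__)

SCOPES = ("row", "column", "overall")
METHODS = ("range", "depth", "gaussian", "poisson")
MISSING_STRATEGIES = ("restrictive", "relaxed", "delta_replace")

#: maximum symbols stored per cell (single symbol + boundary relaxation or
#: the nearest symbols around a missing-value estimate)
ITEMS_PER_CELL = 4


def normalize(matrix: ExpressionMatrix, scope: str = "row") -> ExpressionMatrix:
    """Z-score each unit (row, column or the whole matrix).

    Zero-mean scaling is what makes symmetric discretization (and the
    symmetric sign search) meaningful.  Constant units cannot be scaled and
    are mean-centered only, with a log notice.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    out = matrix.copy()
    vals = np.where(out.unusable_mask, np.nan, out.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if scope == "overall":
            mu, sd = np.nanmean(vals), np.nanstd(vals)
            if not np.isfinite(mu):
                raise ValueError("matrix has no usable values")
            if sd == 0:
                log.info("constant matrix: mean-centered only")
                sd = 1.0
            out.values = (vals - mu) / sd
        else:
            axis = 1 if scope == "row" else 0
            mu = np.nanmean(vals, axis=axis, keepdims=True)
            sd = np.nanstd(vals, axis=axis, keepdims=True)
            if np.isnan(mu).any():
                raise ValueError(f"some {scope} has no usable values")
            nconst = int((sd == 0).sum())
            if nconst:
                log.info("%d constant %s unit(s): mean-centered only", nconst, scope)
            sd = np.where(sd == 0, 1.0, sd)
            out.values = (vals - mu) / sd
    out.values = np.where(out.unusable_mask, np.nan, out.values)
    return out


def mask_outliers(matrix: ExpressionMatrix, z_threshold: float = 3.0) -> ExpressionMatrix:
    """Flag |z| > threshold cells as outliers; they behave as missing downstream."""
    if not z_threshold > 0:
        raise ValueError("z_threshold must be positive")
    out = matrix.copy()
    vals = np.where(out.unusable_mask, np.nan, out.values)
    with np.errstate(invalid="ignore"):
        out.outlier_mask = out.outlier_mask | (
            np.abs(vals) > z_threshold
        ) & ~out.missing_mask
    return out


@dataclass
class SymbolicMatrix:
    """Per-cell symbol sets over an ordered alphabet.

    ``items[i, j]`` holds the symbols of cell (i, j), -1 padded; cells with
    no symbols and no wildcard flag contribute nothing to their row's
    sequence.  ``wildcard[i, j]`` marks cells allowed to co-occur at every
    position of the row's sequence (the relaxed missing-value strategy).

    ``boundaries``/``centroids``/``lo``/``hi`` are per scope unit (a single
    unit for ``overall`` scope); they are None for raw-value ordering, where
    symbols are per-row dense value ranks and carry no shared geometry.
    """

    items: np.ndarray           # (n, m, ITEMS_PER_CELL) int16
    wildcard: np.ndarray        # (n, m) bool
    n_items: int
    scope: str
    matrix: ExpressionMatrix
    boundaries: np.ndarray | None = None   # (U, n_items - 1)
    centroids: np.ndarray | None = None    # (U, n_items)
    lo: np.ndarray | None = None           # (U,) unit minima
    hi: np.ndarray | None = None           # (U,) unit maxima

    @property
    def shape(self) -> tuple[int, int]:
        return self.items.shape[:2]

    def unit_of(self, i: int, j: int) -> int:
        if self.scope == "overall":
            return 0
        return i if self.scope == "row" else j

    def items_of(self, i: int, j: int) -> tuple[int, ...]:
        row = self.items[i, j]
        return tuple(int(x) for x in row[row >= 0])

    def copy(self) -> "SymbolicMatrix":
        return SymbolicMatrix(
            self.items.copy(), self.wildcard.copy(), self.n_items, self.scope,
            self.matrix,
            None if self.boundaries is None else self.boundaries.copy(),
            None if self.centroids is None else self.centroids.copy(),
            None if self.lo is None else self.lo.copy(),
            None if self.hi is None else self.hi.copy(),
        )

    def mirrored_items(self) -> "SymbolicMatrix":
        """Symbol indexes after value negation (symmetric alphabet).

        With zero-mean normalization and symmetric cut-offs, negating a row
        maps symbol k to |alphabet|-1-k; an odd alphabet's middle symbol is
        its own mirror image.
        """
        out = self.copy()
        mirrored = np.where(out.items >= 0, self.n_items - 1 - out.items, np.int16(32000))
        mirrored = np.sort(mirrored, axis=2)
        mirrored[mirrored == 32000] = -1
        out.items = mirrored.astype(np.int16)
        return out


def _unit_views(vals: np.ndarray, scope: str):
    """Iterate (unit index, flat value view selector) per scope."""
    n, m = vals.shape
    if scope == "overall":
        yield 0, (slice(None), slice(None))
    elif scope == "row":
        for i in range(n):
            yield i, (i, slice(None))
    else:
        for j in range(m):
            yield j, (slice(None), j)


def discretize(
    matrix: ExpressionMatrix,
    n_items: int,
    method: str = "gaussian",
    scope: str = "overall",
) -> SymbolicMatrix:
    """Map each usable cell to exactly one of ``n_items`` ordered symbols.

    range    equal-width bins over [min, max] of the unit
    depth    equal-count quantile bins
    gaussian cut-offs at equal-probability quantiles of a fitted normal
    poisson  equal-probability quantiles of a Poisson fitted to the values
             shifted to be non-negative; requires lambda >= 3, otherwise a
             warning is issued and the gaussian method is used

    Centroids are bin mid-points for ``range`` and the median of assigned
    values otherwise.
    """
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    n, m = matrix.shape
    vals = np.where(matrix.unusable_mask, np.nan, matrix.values)
    U = 1 if scope == "overall" else (n if scope == "row" else m)
    boundaries = np.empty((U, n_items - 1))
    centroids = np.empty((U, n_items))
    lo = np.empty(U)
    hi = np.empty(U)
    items = np.full((n, m, ITEMS_PER_CELL), -1, dtype=np.int16)

    for u, sel in _unit_views(vals, scope):
        v = vals[sel]
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(f"{scope} unit {u} has no usable values")
        if np.unique(v).size < n_items:
            raise ValueError(
                f"{scope} unit {u} has fewer than {n_items} distinct values; "
                "use a smaller alphabet"
            )
        lo[u], hi[u] = v.min(), v.max()
        meth = method
        if meth == "poisson":
            lam = float(np.mean(v - v.min()))
            if lam < 3:
                log.warning(
                    "poisson discretization needs lambda >= 3 (got %.2f); "
                    "falling back to gaussian", lam,
                )
                meth = "gaussian"
        qs = np.arange(1, n_items) / n_items
        if meth == "range":
            edges = np.linspace(lo[u], hi[u], n_items + 1)
            boundaries[u] = edges[1:-1]
            centroids[u] = (edges[:-1] + edges[1:]) / 2
        elif meth == "depth":
            boundaries[u] = np.quantile(v, qs)
        elif meth == "gaussian":
            boundaries[u] = stats.norm.ppf(qs, loc=v.mean(), scale=v.std() or 1.0)
        else:  # poisson
            shift = v.min()
            lam = float(np.mean(v - shift))
            b = stats.poisson.ppf(qs, lam) + shift
            # integer quantiles may tie; nudge to keep the bin order strict
            boundaries[u] = b + np.arange(n_items - 1) * 1e-9
        cell = np.searchsorted(boundaries[u], v, side="right")
        if meth != "range":
            for k in range(n_items):
                sel_k = v[cell == k]
                centroids[u, k] = (
                    np.median(sel_k)
                    if sel_k.size
                    else _bin_mid(boundaries[u], k, lo[u], hi[u])
                )

    # vectorized assignment
    if scope == "overall":
        idx = np.searchsorted(boundaries[0], vals.ravel(), side="right").reshape(n, m)
    elif scope == "row":
        idx = np.empty((n, m), dtype=int)
        for i in range(n):
            idx[i] = np.searchsorted(boundaries[i], vals[i], side="right")
    else:
        idx = np.empty((n, m), dtype=int)
        for j in range(m):
            idx[:, j] = np.searchsorted(boundaries[j], vals[:, j], side="right")
    usable = np.isfinite(vals)
    items[..., 0] = np.where(usable, idx, -1)
    return SymbolicMatrix(
        items, np.zeros((n, m), dtype=bool), n_items, scope, matrix,
        boundaries, centroids, lo, hi,
    )


def _bin_mid(bounds: np.ndarray, k: int, lo: float, hi: float) -> float:
    a = lo if k == 0 else bounds[k - 1]
    b = hi if k == len(bounds) else bounds[k]
    return (a + b) / 2


def rank_items(matrix: ExpressionMatrix) -> SymbolicMatrix:
    """Raw-value ordering: symbols are per-row dense ranks of the values.

    No discretization — ties are exact value equality, so the derived
    biclusters are perfect orderings.
    """
    n, m = matrix.shape
    vals = np.where(matrix.unusable_mask, np.nan, matrix.values)
    items = np.full((n, m, ITEMS_PER_CELL), -1, dtype=np.int16)
    kmax = 0
    for i in range(n):
        fin = np.isfinite(vals[i])
        if not fin.any():
            continue
        uniq, inv = np.unique(vals[i][fin], return_inverse=True)
        items[i, fin, 0] = inv.astype(np.int16)
        kmax = max(kmax, len(uniq))
    return SymbolicMatrix(items, np.zeros((n, m), dtype=bool), kmax, "row", matrix)


def relax_items(sym: SymbolicMatrix, ratio: float = 0.10) -> SymbolicMatrix:
    """Boundary relaxation against the items-boundary problem.

    A cell whose value sits within ``ratio`` of its bin's width from a bin
    boundary also receives the adjacent bin's symbol; edge bins only extend
    inward.  With ratio 0 the matrix is returned unchanged.
    """
    if not 0 <= ratio < 0.5:
        raise ValueError("ratio must be in [0, 0.5)")
    if sym.boundaries is None:
        raise ValueError("raw-value ordering has no bin geometry to relax")
    out = sym.copy()
    if ratio == 0:
        return out
    n, m = sym.shape
    vals = np.where(sym.matrix.unusable_mask, np.nan, sym.matrix.values)
    K = sym.n_items
    for i in range(n):
        for j in range(m):
            k = sym.items[i, j, 0]
            if k < 0 or sym.items[i, j, 1] >= 0:
                continue
            u = sym.unit_of(i, j)
            c = vals[i, j]
            a = sym.lo[u] if k == 0 else sym.boundaries[u, k - 1]
            b = sym.hi[u] if k == K - 1 else sym.boundaries[u, k]
            width = b - a
            if width <= 0:
                continue
            d_lo, d_hi = (c - a) / width, (b - c) / width
            if min(d_lo, d_hi) >= ratio:
                continue
            if d_lo < d_hi:
                if k > 0:
                    out.items[i, j, 1] = k - 1
                    out.items[i, j, :2] = sorted((k, k - 1))
            else:
                if k < K - 1:
                    out.items[i, j, 1] = k + 1
                    out.items[i, j, :2] = sorted((k, k + 1))
    return out


def relax_items_centroid(sym: SymbolicMatrix, threshold: float) -> SymbolicMatrix:
    """Centroid-distance relaxation: a cell receives every symbol whose
    centroid lies within ``threshold`` of its value (capped at the nearest
    :data:`ITEMS_PER_CELL`)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if sym.centroids is None:
        raise ValueError("raw-value ordering has no centroids")
    out = sym.copy()
    n, m = sym.shape
    vals = np.where(sym.matrix.unusable_mask, np.nan, sym.matrix.values)
    for i in range(n):
        for j in range(m):
            if sym.items[i, j, 0] < 0:
                continue
            u = sym.unit_of(i, j)
            d = np.abs(sym.centroids[u] - vals[i, j])
            ks = np.where(d <= threshold)[0]
            if ks.size == 0:
                continue
            ks = ks[np.argsort(d[ks], kind="stable")][:ITEMS_PER_CELL]
            ks = np.sort(np.union1d(ks, [sym.items[i, j, 0]]))[:ITEMS_PER_CELL]
            out.items[i, j, :] = -1
            out.items[i, j, : len(ks)] = ks.astype(np.int16)
    return out


def handle_missing(
    sym: SymbolicMatrix,
    strategy: str = "restrictive",
    delta: float | None = None,
    estimator: str = "row_median",
) -> SymbolicMatrix:
    """Decide how unusable cells participate in their row's sequence.

    restrictive    the cell contributes nothing (its column is simply absent
                   from the row's sequence)
    relaxed        the cell's column co-occurs at every position of the
                   sequence (wildcard)
    delta_replace  the cell receives every symbol whose centroid lies within
                   ``delta`` of a row-statistic estimate of the value
                   (nearest :data:`ITEMS_PER_CELL` kept)
    """
    if strategy not in MISSING_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if estimator not in ("row_median", "row_mean"):
        raise ValueError(f"unknown estimator {estimator!r}")
    out = sym.copy()
    bad = sym.matrix.unusable_mask
    if strategy == "restrictive":
        return out
    if strategy == "relaxed":
        out.wildcard = out.wildcard | bad
        return out
    if delta is None or delta < 0:
        raise ValueError("delta_replace requires delta >= 0")
    if sym.centroids is None:
        raise ValueError("delta_replace needs discretization centroids")
    vals = np.where(bad, np.nan, sym.matrix.values)
    stat = np.nanmedian if estimator == "row_median" else np.nanmean
    n, m = sym.shape
    for i in range(n):
        cols = np.where(bad[i])[0]
        if cols.size == 0:
            continue
        fin = np.isfinite(vals[i])
        if not fin.any():
            log.info("row %d is fully missing; dropped from the sequence db", i)
            continue
        est = float(stat(vals[i]))
        for j in cols:
            u = sym.unit_of(i, j)
            d = np.abs(sym.centroids[u] - est)
            ks = np.where(d <= delta)[0]
            if ks.size == 0:
                continue
            ks = np.sort(ks[np.argsort(d[ks], kind="stable")][:ITEMS_PER_CELL])
            out.items[i, j, : len(ks)] = ks.astype(np.int16)
    return out


def itemize(sym: SymbolicMatrix, behavior: str = "xor") -> SequenceDatabase:
    """Order each row's columns by symbol into an itemset sequence.

    Columns sharing a symbol co-occur in one itemset (index order inside).
    Under ``or`` behavior a co-occurrence itemset of size g is repeated g
    times, so equal values may also be read as an ordered run.  Rows left
    with no symbols are excluded (logged).
    """
    if behavior not in ("xor", "or"):
        raise ValueError(f"unknown behavior {behavior!r}")
    n, m = sym.shape
    sequences: list[tuple] = []
    origins: list[int] = []
    wilds: list[frozenset[int]] = []
    for i in range(n):
        groups: dict[int, list[int]] = {}
        for j in range(m):
            for k in sym.items[i, j]:
                if k < 0:
                    continue
                groups.setdefault(int(k), []).append(j)
        w = frozenset(np.where(sym.wildcard[i])[0].tolist())
        if not groups and not w:
            log.debug("row %d has no symbols after mapping; excluded", i)
            continue
        seq: list[tuple[int, ...]] = []
        for k in sorted(groups):
            itemset = tuple(sorted(groups[k]))
            if behavior == "or" and len(itemset) > 1:
                seq.extend([itemset] * len(itemset))
            else:
                seq.append(itemset)
        sequences.append(tuple(seq))
        origins.append(i)
        wilds.append(w)
    universe = frozenset(
        j for s in sequences for itemset in s for j in itemset
    ) | frozenset(j for w in wilds for j in w)
    return SequenceDatabase(sequences, origins, universe, wilds)


def materialize_wildcards(db: SequenceDatabase) -> SequenceDatabase:
    """Expand wildcard columns into explicit itemsets (small databases).

    A wildcard column joins every itemset as a co-occurrence and adds one
    itemset at each end of the sequence, so it may precede, follow, or tie
    with anything — but never sit strictly between two consecutive itemsets.
    """
    seqs = []
    for s, w in zip(db.sequences, db.wildcards):
        if not w:
            seqs.append(s)
            continue
        ws = tuple(sorted(w))
        body = tuple(tuple(sorted(set(it) | w)) for it in s)
        seqs.append((ws,) + body + (ws,))
    return SequenceDatabase(seqs, list(db.origins), db.item_universe, None)
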