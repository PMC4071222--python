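"""Post-processing of bicluster sets: merging, filtering and extension.

These operators shape the structure and noise tolerance of a solution
without touching the core search: merging recovers rows and columns split
by noise or the items-boundary problem, filtering removes redundant
biclusters or offending rows/columns, and extension grows biclusters with
rows/columns that are statistically consistent with the pattern or that
appear when the support threshold is relaxed.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import warnings
from functools import lru_cache

import numpy as np

from .matrix import Bicluster, BiclusterSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def _overlap(a: Bicluster, b: Bicluster, mode: str = "area") -> float:
    """Shared fraction of the smaller bicluster (cell area or row sets)."""
    if mode == "rows":
        inter = len(a.rows & b.rows)
        return inter / min(len(a.rows), len(b.rows))
    inter = len(a.rows & b.rows) * len(a.cols & b.cols)
    return inter / min(a.area, b.area)


def _consensus_permutation(
    rows: frozenset[int], cols: frozenset[int], sym, behavior: str,
    signs: dict[int, int] | None = None,
) -> tuple[tuple[int, ...], ...]:
    """Order the columns by their mean symbol over the rows (Borda-style
    consensus); columns with equal means tie into one group."""
    col_list = sorted(cols)
    row_list = sorted(rows)
    S = sym.items[np.ix_(row_list, col_list)][:, :, 0].astype(float)  # primary
    S[S < 0] = np.nan
    if signs is not None:
        svec = np.array([signs.get(i, 1) for i in row_list], dtype=float)
        if sym.boundaries is None:
            top = np.nanmax(
                np.where(sym.items[row_list] < 0, np.nan, sym.items[row_list]),
                axis=(1, 2),
            )
            mirrored = top[:, None] - S
        else:
            mirrored = sym.n_items - 1 - S
        S = np.where(svec[:, None] < 0, mirrored, S)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(S, axis=0)
    means = [float(x) if np.isfinite(x) else np.inf for x in means]
    order = sorted(range(len(col_list)), key=lambda k: (means[k], col_list[k]))
    groups: list[list[int]] = []
    prev = None
    for k in order:
        if prev is not None and abs(means[k] - prev) < 1e-12:
            groups[-1].append(col_list[k])
        else:
            groups.append([col_list[k]])
        prev = means[k]
    return tuple(tuple(sorted(g)) for g in groups)


def _merge_pair(a: Bicluster, b: Bicluster, sym, behavior: str) -> Bicluster:
    rows = a.rows | b.rows
    cols = a.cols | b.cols
    signs_map: dict[int, int] | None = None
    if a.signs is not None or b.signs is not None:
        signs_map = {}
        for src in (b, a):  # a takes precedence on conflict
            if src.signs is None:
                signs_map.update({i: 1 for i in src.rows})
            else:
                rl = src.row_list
                signs_map.update({i: src.signs[k] for k, i in enumerate(rl)})
    if sym is not None:
        perm = _consensus_permutation(rows, cols, sym, behavior, signs_map)
    else:
        # fall back to average group position across the two permutations
        pos: dict[int, list[float]] = {}
        for src in (a, b):
            for g, grp in enumerate(src.permutation):
                for c in grp:
                    pos.setdefault(c, []).append(g / max(1, len(src.permutation) - 1))
        order = sorted(cols, key=lambda c: (float(np.mean(pos.get(c, [0.5]))), c))
        perm = tuple((c,) for c in order)
    signs = None
    if signs_map is not None:
        signs = tuple(signs_map[i] for i in sorted(rows))
    return Bicluster(rows, cols, perm, signs)


def _mean_violation_fraction(b: Bicluster, sym, behavior: str) -> float:
    """Mean per-row violation fraction against the bicluster permutation,
    using each cell's primary symbol (vectorized)."""
    rows = np.array(b.row_list, dtype=int)
    flat = [(g, c) for g, grp in enumerate(b.permutation) for c in grp]
    gvec = np.array([g for g, _ in flat])
    cvec = np.array([c for _, c in flat])
    sign_arr = None
    if b.signs is not None:
        sign_arr = np.ones(sym.shape[0])
        sign_arr[rows] = np.array(b.signs, dtype=float)
    S = _primary_symbols(sym, sign_arr)[rows][:, cvec]
    present = S >= 0
    viol = np.zeros(len(rows), dtype=np.int64)
    pairs = np.zeros(len(rows), dtype=np.int64)
    L = len(flat)
    for a in range(L):
        for bb in range(a + 1, L):
            both = present[:, a] & present[:, bb]
            if gvec[a] == gvec[bb]:
                if behavior != "xor":
                    continue
                bad = S[:, a] != S[:, bb]
            elif behavior == "xor":
                bad = ~(S[:, a] < S[:, bb])
            else:
                bad = ~(S[:, a] <= S[:, bb])
            pairs += both
            viol += both & bad
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(pairs > 0, viol / np.maximum(pairs, 1), 0.0)
    return float(frac.mean()) if len(frac) else 0.0


def merge(
    bset: BiclusterSet,
    min_overlap: float = 0.8,
    sym=None,
    behavior: str = "xor",
    max_violation: float | None = None,
    mode: str = "area",
) -> BiclusterSet:
    """Greedy best-pair-first merging until no pair overlaps enough.

    Overlap is the shared fraction of the smaller bicluster — of its cell
    area by default, or of its row set with ``mode="rows"`` (suited to
    consolidating sub-patterns of one module that differ in columns).  The
    merged bicluster spans the row and column unions with a consensus
    permutation recomputed over the merged rows.  When ``max_violation`` is
    set, a merge is also required to keep the merged bicluster homogeneous
    (mean row violation fraction against the consensus permutation at most
    ``max_violation``), which stops unrelated modules from chaining into
    one block.
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    bics = list(bset.biclusters)
    if len(bics) < 2:
        return BiclusterSet(list(bics), dict(bset.provenance))
    heap: list[tuple[float, int, int]] = []
    alive = set(range(len(bics)))
    for i, j in itertools.combinations(range(len(bics)), 2):
        o = _overlap(bics[i], bics[j], mode)
        if o >= min_overlap:
            heapq.heappush(heap, (-o, i, j))
    rejected: set[tuple[int, int]] = set()
    while heap:
        negov, bi, bj = heapq.heappop(heap)
        if bi not in alive or bj not in alive or (bi, bj) in rejected:
            continue
        merged = _merge_pair(bics[bi], bics[bj], sym, behavior)
        if max_violation is not None and sym is not None:
            if _mean_violation_fraction(merged, sym, behavior) > max_violation:
                rejected.add((bi, bj))
                continue
        alive.discard(bi)
        alive.discard(bj)
        idx = len(bics)
        bics.append(merged)
        for k in alive:
            o = _overlap(bics[k], merged, mode)
            if o >= min_overlap:
                heapq.heappush(heap, (-o, k, idx))
        alive.add(idx)
    return BiclusterSet([bics[i] for i in sorted(alive)], dict(bset.provenance))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_contained(bset: BiclusterSet) -> BiclusterSet:
    """Drop duplicates and biclusters contained in a larger retained one.

    Processes by descending area with a hash fast path for exact
    duplicates; the result is an antichain under (row set, column set)
    inclusion.
    """
    order = sorted(
        bset.biclusters,
        key=lambda b: (-b.area, sorted(b.rows), sorted(b.cols)),
    )
    kept: list[Bicluster] = []
    seen: set[tuple] = set()
    for b in order:
        key = (b.rows, b.cols)
        if key in seen:
            continue
        if any(b.rows <= k.rows and b.cols <= k.cols for k in kept):
            continue
        seen.add(key)
        kept.append(b)
    return BiclusterSet(kept, dict(bset.provenance))


def filter_rows_cols(
    b: Bicluster,
    sym,
    min_homogeneity: float = 0.75,
    behavior: str = "xor",
    min_rows: int = 2,
    min_cols: int = 2,
) -> Bicluster | None:
    """Remove the worst-offending rows/columns until every row and column
    agrees with the permutation at least ``min_homogeneity``.

    Returns None when the bicluster would shrink below ``min_rows`` rows or
    ``min_cols`` columns.
    """
    from .biclustering import order_violations

    if not 0 <= min_homogeneity <= 1:
        raise ValueError("min_homogeneity must be in [0, 1]")
    if min_homogeneity == 0:
        return b
    rows = b.row_list
    signs = list(b.signs) if b.signs is not None else [1] * len(rows)
    perm = [list(g) for g in b.permutation]

    while True:
        flat = [(g, c) for g, grp in enumerate(perm) for c in grp]
        if len(rows) < min_rows or len(flat) < min_cols:
            return None
        ptuple = tuple(tuple(sorted(g)) for g in perm if g)
        row_viol = np.zeros(len(rows))
        row_pairs = np.zeros(len(rows))
        col_viol = {c: 0.0 for _, c in flat}
        col_pairs = {c: 0.0 for _, c in flat}
        for k, i in enumerate(rows):
            from .biclustering import _row_symbols

            symbols = _row_symbols(sym, i, signs[k])
            for a in range(len(flat)):
                ga, ca = flat[a]
                sa = symbols[ca]
                if not sa:
                    continue
                for bidx in range(a + 1, len(flat)):
                    gb, cb = flat[bidx]
                    sb = symbols[cb]
                    if not sb:
                        continue
                    if ga == gb and behavior != "xor":
                        continue
                    if ga == gb:
                        bad = not (set(sa) & set(sb))
                    elif behavior == "xor":
                        bad = not (min(sa) < max(sb))
                    else:
                        bad = not (min(sa) <= max(sb))
                    row_pairs[k] += 1
                    col_pairs[ca] += 1
                    col_pairs[cb] += 1
                    if bad:
                        row_viol[k] += 1
                        col_viol[ca] += 1
                        col_viol[cb] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            row_frac = np.where(row_pairs > 0, row_viol / np.maximum(row_pairs, 1), 0)
        col_frac = {
            c: (col_viol[c] / col_pairs[c] if col_pairs[c] else 0.0)
            for c in col_viol
        }
        worst_row = int(np.argmax(row_frac)) if len(rows) else 0
        worst_col = max(col_frac, key=lambda c: col_frac[c]) if col_frac else None
        wr = row_frac[worst_row] if len(rows) else 0.0
        wc = col_frac[worst_col] if worst_col is not None else 0.0
        threshold = 1 - min_homogeneity
        if wr <= threshold and wc <= threshold:
            break
        if wr >= wc:
            del rows[worst_row]
            del signs[worst_row]
        else:
            for g in perm:
                if worst_col in g:
                    g.remove(worst_col)
            perm = [g for g in perm if g]
    if len(rows) < min_rows or sum(len(g) for g in perm) < min_cols:
        return None
    cols = frozenset(c for g in perm for c in g)
    ptuple = tuple(tuple(sorted(g)) for g in perm)
    sg = tuple(signs) if b.signs is not None else None
    return Bicluster(frozenset(rows), cols, ptuple, sg)


# ---------------------------------------------------------------------------
# Extension
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _null_cdf_exact(symbols: tuple[int, ...], groups: tuple[int, ...],
                    behavior: str) -> np.ndarray:
    """Exact CDF of the violation count when the candidate's symbol multiset
    is laid out in every distinct order over the permutation slots.

    ``groups[a]`` is the tie-group index of slot a.  Feasible up to 8 slots.
    """
    garr = np.array(groups)
    perms = np.array(sorted(set(itertools.permutations(symbols))))
    L = len(symbols)
    viol = np.zeros(len(perms), dtype=np.int64)
    for a in range(L):
        for b in range(a + 1, L):
            if garr[a] == garr[b]:
                if behavior == "xor":
                    viol += perms[:, a] != perms[:, b]
            elif behavior == "xor":
                viol += ~(perms[:, a] < perms[:, b])
            else:
                viol += ~(perms[:, a] <= perms[:, b])
    counts = np.bincount(viol, minlength=L * (L - 1) // 2 + 1)
    cdf = np.cumsum(counts) / counts.sum()
    return cdf


def _null_cdf_mc(symbols: np.ndarray, groups: np.ndarray, behavior: str,
                 rng: np.random.Generator, n_mc: int = 10000) -> np.ndarray:
    """Monte-Carlo CDF of the violation count for longer candidate rows."""
    L = len(symbols)
    draws = np.tile(symbols, (n_mc, 1))
    draws = rng.permuted(draws, axis=1)
    viol = np.zeros(n_mc, dtype=np.int64)
    for a in range(L):
        for b in range(a + 1, L):
            if groups[a] == groups[b]:
                if behavior == "xor":
                    viol += draws[:, a] != draws[:, b]
            elif behavior == "xor":
                viol += ~(draws[:, a] < draws[:, b])
            else:
                viol += ~(draws[:, a] <= draws[:, b])
    counts = np.bincount(viol, minlength=L * (L - 1) // 2 + 1)
    return np.cumsum(counts) / counts.sum()


def _primary_symbols(sym, sign_vec: np.ndarray | None = None) -> np.ndarray:
    """First symbol per cell as an (n, m) int matrix, -1 where absent.

    Statistical tests use the primary symbol of each cell; the extra symbols
    from boundary relaxation matter for mining but not for significance
    screening.
    """
    S = sym.items[:, :, 0].astype(np.int64)
    if sign_vec is not None:
        if sym.boundaries is None:
            top = sym.items.max(axis=(1, 2)).astype(np.int64)
            mirrored = top[:, None] - S
        else:
            mirrored = sym.n_items - 1 - S
        S = np.where((sign_vec[:, None] < 0) & (S >= 0), mirrored, S)
    return S


def _extend_statistical(
    bset: BiclusterSet, sym, alpha: float, behavior: str,
    correction: str, rng: np.random.Generator,
) -> BiclusterSet:
    """Statistical inclusion of columns, then rows.

    Columns first: a longer permutation sharpens the row test.  Column
    candidates are screened by inserting them at their best slot and
    comparing the violation count against a Monte-Carlo null that shuffles
    the candidate column across rows (same best-slot search).  Row
    candidates are compared against the permutation null of their own
    symbol multiset — exact enumeration up to 8 present columns,
    Monte-Carlo beyond.
    """
    from scipy import stats as sps

    n, m = sym.shape
    out = []
    for b in bset:
        row_ids = np.array(b.row_list, dtype=int)
        signs = b.signs
        sign_arr = None
        if signs is not None:
            sign_arr = np.ones(n)
            sign_arr[row_ids] = np.array(signs, dtype=float)
        Sfull = _primary_symbols(sym, sign_arr)

        # --- column inclusion -------------------------------------------
        perm = [list(g) for g in b.permutation]
        flat = [(g, c) for g, grp in enumerate(perm) for c in grp]
        gvec = np.array([g for g, _ in flat])
        cvec = np.array([c for _, c in flat])
        SI = Sfull[row_ids][:, cvec]
        pres_I = SI >= 0
        n_groups = len(perm)
        cand_cols = [c for c in range(m) if c not in b.cols]
        # column inclusion is always multiplicity-corrected: a false column
        # poisons the permutation and costs genuine rows downstream
        thr_c = alpha / max(1, len(cand_cols))
        slot_masks = [gvec < slot for slot in range(n_groups + 1)]
        n_mc_cols = min(20000, max(2000, int(np.ceil(2.0 / thr_c))))

        def _best_slot_viol(v):
            pv = v >= 0
            both = pres_I & pv[:, None]
            if behavior == "xor":
                before_bad = (SI >= v[:, None]) & both   # q before c: need Sq < v
                after_bad = (v[:, None] >= SI) & both    # q after c: need v < Sq
            else:
                before_bad = (SI > v[:, None]) & both
                after_bad = (v[:, None] > SI) & both
            bb_col = before_bad.sum(axis=0)
            ab_col = after_bad.sum(axis=0)
            tot = int(both.sum())
            best_k, best_slot = None, 0
            for slot, before in enumerate(slot_masks):
                k = int(bb_col[before].sum() + ab_col[~before].sum())
                if best_k is None or k < best_k:
                    best_k, best_slot = k, slot
            return best_k, best_slot, tot

        accepted: list[tuple[int, int]] = []
        for c in cand_cols:
            v = Sfull[row_ids, c]
            if (v >= 0).sum() < 2:
                continue
            best_k, best_slot, tot = _best_slot_viol(v)
            if tot == 0:
                continue
            # the binomial tail underestimates the shuffle-null p-value
            # (best-slot selection shifts the null left), so it is a valid
            # cheap rejection screen before the Monte-Carlo
            if float(sps.binom.cdf(best_k, tot, 0.5)) >= thr_c:
                continue
            # batch Monte-Carlo of the same best-slot statistic
            V = rng.permuted(np.tile(v, (n_mc_cols, 1)), axis=1)   # (B, r)
            PV = V >= 0
            nulls = np.full(n_mc_cols, np.iinfo(np.int64).max, dtype=np.int64)
            bb_all = np.empty((n_mc_cols, len(cvec)), dtype=np.int64)
            ab_all = np.empty((n_mc_cols, len(cvec)), dtype=np.int64)
            for q in range(len(cvec)):
                sq = SI[:, q]
                pres_q = pres_I[:, q]
                both = PV & pres_q[None, :]
                if behavior == "xor":
                    bb_all[:, q] = ((sq[None, :] >= V) & both).sum(axis=1)
                    ab_all[:, q] = ((V >= sq[None, :]) & both).sum(axis=1)
                else:
                    bb_all[:, q] = ((sq[None, :] > V) & both).sum(axis=1)
                    ab_all[:, q] = ((V > sq[None, :]) & both).sum(axis=1)
            for slot, before in enumerate(slot_masks):
                tot_slot = bb_all[:, before].sum(axis=1) + ab_all[:, ~before].sum(axis=1)
                nulls = np.minimum(nulls, tot_slot)
            p = (float((nulls <= best_k).sum()) + 1) / (n_mc_cols + 1)
            if p < thr_c:
                accepted.append((best_slot, c))
        for slot, c in sorted(accepted, reverse=True):
            perm.insert(slot, [c])
        ptuple = tuple(tuple(sorted(g)) for g in perm if g)
        cols = frozenset(c for g in ptuple for c in g)

        # --- row inclusion ----------------------------------------------
        flat = [(g, c) for g, grp in enumerate(ptuple) for c in grp]
        gvec = np.array([g for g, _ in flat])
        cvec = np.array([c for _, c in flat])
        L = len(flat)
        S = _primary_symbols(sym)[:, cvec]
        present = S >= 0
        viol = np.zeros(n, dtype=np.int64)
        pairs = np.zeros(n, dtype=np.int64)
        for a in range(L):
            for bb in range(a + 1, L):
                both = present[:, a] & present[:, bb]
                if gvec[a] == gvec[bb]:
                    if behavior != "xor":
                        continue
                    bad = S[:, a] != S[:, bb]
                elif behavior == "xor":
                    bad = ~(S[:, a] < S[:, bb])
                else:
                    bad = ~(S[:, a] <= S[:, bb])
                pairs += both
                viol += both & bad

        rows = set(b.rows)
        cand_rows = np.array([i for i in range(n) if i not in rows], dtype=int)
        thr = alpha / max(1, len(cand_rows)) if correction == "bonferroni" else alpha
        added: set[int] = set()
        if len(cand_rows):
            frac = np.where(
                pairs[cand_rows] > 0,
                viol[cand_rows] / np.maximum(pairs[cand_rows], 1),
                1.0,
            )
            # a row cannot be significant unless it violates clearly less
            # than the ~1/2 rate of a random ordering
            survivors = cand_rows[frac <= 0.4]
            for i in survivors:
                keep = present[i]
                symbols = tuple(sorted(int(x) for x in S[i][keep]))
                groups = tuple(int(g) for g in gvec[keep])
                if len(symbols) < 2:
                    continue
                if len(symbols) <= 8:
                    cdf = _null_cdf_exact(symbols, groups, behavior)
                else:
                    cdf = _null_cdf_mc(
                        np.array(symbols), np.array(groups), behavior, rng
                    )
                k = min(int(viol[i]), len(cdf) - 1)
                if cdf[k] < thr:
                    added.add(int(i))
        new_rows = frozenset(rows | added)
        new_signs = None
        if signs is not None:
            smap = {i: s for i, s in zip(b.row_list, signs)}
            new_signs = tuple(smap.get(i, 1) for i in sorted(new_rows))
        out.append(Bicluster(new_rows, cols, ptuple, new_signs))
    return BiclusterSet(out, dict(bset.provenance))


def extend(
    bset: BiclusterSet,
    sym,
    db=None,
    strategy: str = "statistical",
    alpha: float = 0.01,
    relax_factor: float = 0.10,
    behavior: str = "xor",
    theta: float | None = None,
    delta: int = 2,
    representation: str = "closed",
    correction: str = "bonferroni",
    merge_overlap: float = 0.8,
    rng: np.random.Generator | None = None,
    engine: str = "auto",
    node_budget: int | None = None,
    max_violation: float | None = None,
) -> BiclusterSet:
    """Grow biclusters; never removes existing rows or columns.

    statistical      add rows whose order violations are improbably few
                     under a random-order null, and columns whose best
                     insertion point is improbably consistent
    relaxed_support  re-mine at theta*(1-relax_factor) and merge the
                     resulting biclusters into the existing ones
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = rng or np.random.default_rng(0)
    if strategy == "statistical":
        return _extend_statistical(bset, sym, alpha, behavior, correction, rng)
    if strategy != "relaxed_support":
        raise ValueError(f"unknown strategy {strategy!r}")
    if relax_factor == 0 or db is None or theta is None:
        # nothing re-mined: no new patterns to merge in
        return BiclusterSet(list(bset.biclusters), dict(bset.provenance))
    from . import spm as _spm
    from .biclustering import patterns_to_biclusters

    try:
        patterns = _spm.mine(
            db, theta * (1 - relax_factor), delta, representation, engine,
            ties=(behavior == "or"), node_budget=node_budget,
        )
    except _spm.SearchBudgetExceeded:
        log.info("relaxed-support re-mining exceeded the node budget; "
                 "falling back to merging alone")
        return merge(bset, merge_overlap, sym, behavior, max_violation)
    extra = patterns_to_biclusters(patterns, db)
    combined = BiclusterSet(
        list(bset.biclusters) + list(extra.biclusters), dict(bset.provenance)
    )
    merged = merge(combined, merge_overlap, sym, behavior, max_violation)
    # monotonicity: every original bicluster maps into some output bicluster
    out = list(merged.biclusters)
    for b in bset:
        if not any(b.rows <= o.rows and b.cols <= o.cols for o in out):
            out.append(b)
    return BiclusterSet(out, dict(bset.provenance))


def select_representatives(
    bset: BiclusterSet,
    max_n: int = 50,
    sim_threshold: float = 0.4,
) -> BiclusterSet:
    """Keep one representative per family of similar biclusters.

    Candidates are ranked by column count, then support: long patterns are
    preferred because a spurious long order-preserving pattern is
    combinatorially implausible, so they carry the least row pollution.
    A candidate is kept when the overlap of its row set with every kept
    bicluster stays below ``sim_threshold`` of the smaller of the two row
    sets; at most ``max_n`` are kept.  Measuring overlap against the
    smaller set also suppresses side patterns whose rows are largely
    contained in an already-kept module.
    """
    order = sorted(
        bset.biclusters,
        key=lambda b: (-len(b.cols), -len(b.rows), sorted(b.cols), sorted(b.rows)),
    )
    kept: list[Bicluster] = []
    covered: set[int] = set()
    for b in order:
        if len(kept) >= max_n:
            break
        similar = False
        for k in kept:
            inter = len(b.rows & k.rows)
            smaller = min(len(b.rows), len(k.rows))
            if smaller and inter / smaller >= sim_threshold:
                similar = True
                break
        # side patterns that straddle several kept modules evade the
        # pairwise test; suppress anything mostly explained by the union
        # of the rows already selected
        if not similar and len(b.rows & covered) / len(b.rows) >= 0.5:
            similar = True
        # a pattern whose rows substantially overlap a module already
        # described by a longer pattern is a side view of that module
        if not similar:
            for k in kept:
                if len(k.cols) > len(b.cols) and (
                    len(b.rows & k.rows) / len(b.rows) >= 0.3
                ):
                    similar = True
                    break
        if not similar:
            kept.append(b)
            covered |= b.rows
    return BiclusterSet(kept, dict(bset.provenance))


def filter_significant(
    bset: BiclusterSet,
    shape: tuple[int, int],
    n_symbols: int | None,
    behavior: str = "or",
    max_expected: float = 0.5,
) -> BiclusterSet:
    """Keep only biclusters beyond what random data would produce.

    For a bicluster with L columns and support sigma in an n x m matrix over
    a K-symbol alphabet, the expected number of column chains of length L
    that reach support sigma in an i.i.d. random matrix is

        E = perm(m, L) * P(Binomial(n, p_L) >= sigma)

    where p_L is the probability that one random row matches a fixed chain:
    C(K+L-1, L)/K^L under the or behavior (non-decreasing symbols),
    C(K, L)/K^L under xor (strictly increasing), and 1/L! for raw-value
    ordering (``n_symbols`` None).  Biclusters with E above ``max_expected``
    are chance-plausible and dropped.
    """
    from math import comb, lgamma

    from scipy import stats as sps

    n, m = shape

    def log_perm(mm: int, L: int) -> float:
        return lgamma(mm + 1) - lgamma(mm - L + 1)

    def keep(b: Bicluster) -> bool:
        L = len(b.cols)
        sigma = len(b.rows)
        if L > m:
            return True
        if n_symbols is None:
            p = np.exp(-lgamma(L + 1))
        elif behavior == "xor":
            p = comb(n_symbols, L) / n_symbols**L if L <= n_symbols else 0.0
        else:
            p = comb(n_symbols + L - 1, L) / n_symbols**L
        if p <= 0:
            return True
        tail = sps.binom.sf(sigma - 1, n, p)
        if tail <= 0:
            return True
        log_e = log_perm(m, L) + np.log(tail)
        return log_e < np.log(max_expected)

    kept = [b for b in bset if keep(b)]
    return BiclusterSet(kept, dict(bset.provenance))
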