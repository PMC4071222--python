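"""Bitmask prefix-projection search for item-indexable sequence databases.

Each row of the matrix is a sequence of at most ~60 itemsets (one per
distinct symbol), so the set of itemset indexes (ranks) at which an item may
sit fits one 64-bit mask.  The projected database then needs exactly one
integer per active row: the mask of ranks at which the current pattern
itemset can still be placed.  Growing the pattern is pure bit arithmetic:

  sequence extension   ranks strictly above the smallest feasible rank
                       (non-strict under the ``ties``/or behavior)
  itemset extension    intersection with the current itemset's mask

Wildcard items (relaxed missing values) carry a full mask over the row's
ranks plus one virtual position at each end of the sequence, which encodes
"may precede, follow, or co-occur with anything" without special cases.

A node budget caps the exhaustive search; exceeding it aborts the run and
is reported to the caller, which treats the support level as unminable.
"""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import List


@njit(cache=False, inline="always")
def _lowbit_index(mask):
    b = 0
    while (mask >> b) & 1 == 0:
        b += 1
    return b


@njit(cache=False)
def _dfs(
    rankmask,   # (n, m) int64: ranks at which item x occurs in row i
    nits,       # (n,) int16: rank count per row
    cnt_after,  # (n, T+1) int32: item occurrences at rank >= r
    theta,
    delta,
    ties,       # 1: non-decreasing ranks (or behavior), distinct items only
    budget,     # (1,) int64: remaining node visits; aborts when < 0
    used,       # (m,) bool: items already in the prefix (ties mode)
    cand,       # (c,) int32: candidate extensions (anti-monotone bound)
    rows,       # (k,) int32: active row ids
    cur,        # (k,) int64: feasible rank mask of the current itemset
    rows_stack, # (D, n) int32 scratch, one level per depth
    cur_stack,  # (D, n) int64 scratch
    above,      # (D, n) int64 scratch
    cseq_stack, # (D, m) int32 scratch
    cset_stack, # (D, m) int32 scratch
    pat_items,
    pat_isnew,
    depth,
    last_item,
    out_items,
    out_isnew,
    out_cov,
):
    k = rows.shape[0]
    nc = cand.shape[0]
    budget[0] -= 1
    if budget[0] < 0:
        return
    if depth >= delta:
        out_items.append(pat_items[:depth].copy())
        out_isnew.append(pat_isnew[:depth].copy())
        out_cov.append(rows.copy())

    cseq = cseq_stack[depth]
    cset = cset_stack[depth]
    ab = above[depth]
    for idx in range(k):
        base = _lowbit_index(cur[idx])
        # or behavior (ties): monotone chains, bits >= base; strict: > base.
        # A co-occurrence itemset never adds bicluster columns beyond the
        # equally-supported flat chain, so ties mode skips itemset growth.
        ab[idx] = np.int64(-1) << (base + 1 - ties)
    # candidate-outer counting with early abandon: stop scanning a candidate
    # once the remaining rows cannot lift it to theta
    for ci in range(nc):
        x = cand[ci]
        cnt = 0
        for idx in range(k):
            if cnt + (k - idx) < theta:
                break
            if rankmask[rows[idx], x] & ab[idx]:
                cnt += 1
        cseq[ci] = cnt
    if ties == 0:
        for ci in range(nc):
            x = cand[ci]
            cnt = 0
            if x > last_item:
                for idx in range(k):
                    if cnt + (k - idx) < theta:
                        break
                    if rankmask[rows[idx], x] & cur[idx]:
                        cnt += 1
            cset[ci] = cnt

    nnew = 0
    for ci in range(nc):
        if cseq[ci] >= theta:
            nnew += 1
    new_cand = np.empty(nnew, np.int32)
    j = 0
    for ci in range(nc):
        if cseq[ci] >= theta:
            new_cand[j] = cand[ci]
            j += 1

    nrows = rows_stack[depth]
    ncur = cur_stack[depth]

    # --- itemset extensions (strict mode only) -----------------------------
    for ci in range(nc):
        if ties == 1:
            break
        x = cand[ci]
        if x <= last_item or cset[ci] < theta:
            continue
        cnt = 0
        for idx in range(k):
            i = rows[idx]
            nm = rankmask[i, x] & cur[idx]
            if nm:
                nrows[cnt] = i
                ncur[cnt] = nm
                cnt += 1
        if cnt < theta:
            continue
        pat_items[depth] = x
        pat_isnew[depth] = 0
        used[x] = True
        _dfs(
            rankmask, nits, cnt_after, theta, delta, ties, budget, used, cand,
            nrows[:cnt], ncur[:cnt],
            rows_stack, cur_stack, above, cseq_stack, cset_stack,
            pat_items, pat_isnew, depth + 1, x,
            out_items, out_isnew, out_cov,
        )
        used[x] = False
        if budget[0] < 0:
            return

    # --- sequence extensions -----------------------------------------------
    for ci in range(nc):
        x = cand[ci]
        if cseq[ci] < theta or (ties == 1 and used[x]):
            continue
        cnt = 0
        for idx in range(k):
            i = rows[idx]
            nm = rankmask[i, x] & ab[idx]
            if nm == 0:
                continue
            # min-items pruning: a row whose suffix cannot reach delta items
            # never supports an emitted pattern; supports stay exact because
            # rows are only dropped while depth+1 < delta
            ridx = _lowbit_index(nm)
            if depth + 1 + cnt_after[i, ridx] - 1 < delta:
                continue
            nrows[cnt] = i
            ncur[cnt] = nm
            cnt += 1
        if cnt < theta:
            continue
        pat_items[depth] = x
        pat_isnew[depth] = 1
        used[x] = True
        _dfs(
            rankmask, nits, cnt_after, theta, delta, ties, budget, used, new_cand,
            nrows[:cnt], ncur[:cnt],
            rows_stack, cur_stack, above, cseq_stack, cset_stack,
            pat_items, pat_isnew, depth + 1, x,
            out_items, out_isnew, out_cov,
        )
        used[x] = False
        if budget[0] < 0:
            return


@njit(cache=False)
def _root(
    rankmask, nits, cnt_after, theta, delta, ties, budget,
    out_items, out_isnew, out_cov,
):
    n, m = rankmask.shape
    D = m * 8 + 2
    pat_items = np.zeros(D, np.int32)
    pat_isnew = np.zeros(D, np.uint8)
    used = np.zeros(m, np.bool_)
    rows_stack = np.empty((D, n), np.int32)
    cur_stack = np.empty((D, n), np.int64)
    above = np.empty((D, n), np.int64)
    cseq_stack = np.empty((D, m), np.int32)
    cset_stack = np.empty((D, m), np.int32)

    sup1 = np.zeros(m, np.int64)
    for i in range(n):
        for x in range(m):
            if rankmask[i, x]:
                sup1[x] += 1
    cand = np.empty(m, np.int32)
    nc = 0
    for x in range(m):
        if sup1[x] >= theta:
            cand[nc] = x
            nc += 1
    cand = cand[:nc]

    nrows = np.empty(n, np.int32)
    ncur = np.empty(n, np.int64)
    for ci in range(nc):
        x = cand[ci]
        cnt = 0
        for i in range(n):
            nm = rankmask[i, x]
            if nm == 0:
                continue
            if cnt_after[i, 0] < delta:
                continue
            nrows[cnt] = i
            ncur[cnt] = nm
            cnt += 1
        if cnt < theta:
            continue
        pat_items[0] = x
        pat_isnew[0] = 1
        used[x] = True
        _dfs(
            rankmask, nits, cnt_after, theta, delta, ties, budget, used, cand,
            nrows[:cnt].copy(), ncur[:cnt].copy(),
            rows_stack, cur_stack, above, cseq_stack, cset_stack,
            pat_items, pat_isnew, 1, x,
            out_items, out_isnew, out_cov,
        )
        used[x] = False
        if budget[0] < 0:
            return


MAX_RANKS = 62


def encode(sequences, wildcards, m):
    """Rank-mask encoding of an itemset-sequence database.

    Returns None when some row needs more than :data:`MAX_RANKS` ranks.
    Wildcard rows get one virtual rank at each end of their sequence.
    """
    n = len(sequences)
    rankmask = np.zeros((n, m), dtype=np.int64)
    nits = np.zeros(n, dtype=np.int16)
    maxit = 0
    for i, s in enumerate(sequences):
        shift = 1 if wildcards[i] else 0
        T = len(s) + 2 * shift
        if T > MAX_RANKS:
            return None
        nits[i] = T
        for t, itemset in enumerate(s):
            for x in itemset:
                rankmask[i, x] |= np.int64(1) << (t + shift)
        if wildcards[i]:
            full = (np.int64(1) << T) - np.int64(1)
            for x in wildcards[i]:
                rankmask[i, x] = full
        maxit = max(maxit, sum(len(it) for it in s) + len(wildcards[i]))
    return rankmask, nits


def run(db_sequences, db_wildcards, m: int, theta: int, delta: int,
        ties: bool = False, node_budget: int | None = None):
    """Mine all frequent patterns with >= delta items from encoded rows."""
    enc = encode(db_sequences, db_wildcards, m)
    if enc is None:
        return None
    rankmask, nits = enc
    n = rankmask.shape[0]
    T = int(nits.max()) if n else 0
    # per-row item occurrences at rank >= r (upper bound for the delta prune;
    # wildcards count once at every rank, which is a valid upper bound)
    occ = np.zeros((n, T + 2), dtype=np.int32)
    for b in range(T + 1):
        occ[:, b] = ((rankmask >> np.int64(b)) & np.int64(1)).sum(axis=1)
    cnt_after = occ[:, ::-1].cumsum(axis=1)[:, ::-1].copy()

    out_items = List.empty_list(types.int32[:])
    out_isnew = List.empty_list(types.uint8[:])
    out_cov = List.empty_list(types.int32[:])
    budget = np.array([node_budget if node_budget is not None else 2**62], np.int64)
    _root(
        rankmask, nits, cnt_after,
        np.int64(theta), np.int64(delta), np.int64(1 if ties else 0), budget,
        out_items, out_isnew, out_cov,
    )
    truncated = bool(budget[0] < 0)
    return list(out_items), list(out_isnew), list(out_cov), truncated
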