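"""Numba-compiled tree growing and prediction for the causal survival forest.

Nodes are stored in flat per-tree arrays. A node is a leaf iff feat == -1.
Every array index below refers to positions within a tree's preallocated
node block; partitioning of sample indices is done in place on per-tree
index buffers, grf-style.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_RETRIES = 50


@njit(cache=True)
def _node_sums(arm, y, w, idx, lo, hi):
    """Weighted per-arm sums and patient counts on idx[lo:hi]."""
    w1 = 0.0
    wy1 = 0.0
    w0 = 0.0
    wy0 = 0.0
    c1 = 0
    c0 = 0
    for k in range(lo, hi):
        i = idx[k]
        if arm[i] == 1:
            w1 += w[i]
            wy1 += w[i] * y[i]
            c1 += 1
        else:
            w0 += w[i]
            wy0 += w[i] * y[i]
            c0 += 1
    return w1, wy1, w0, wy0, c1, c0


@njit(cache=True)
def _grow_tree(X, arm, y, w, sidx, s_n, hidx, h_n, mtry, min_leaf, max_depth,
               feat, thr, left, right, value):
    """Grow one honest tree; returns the number of nodes used."""
    n_s = s_n
    p = X.shape[1]
    max_nodes = feat.shape[0]

    # stack entries: node id, s_lo, s_hi, h_lo, h_hi, depth
    stack = np.empty((2 * n_s + 2, 6), dtype=np.int64)
    top = 0
    stack[top, 0] = 0
    stack[top, 1] = 0
    stack[top, 2] = s_n
    stack[top, 3] = 0
    stack[top, 4] = h_n
    stack[top, 5] = 0
    top = 1
    n_nodes = 1

    var_pool = np.arange(p)
    vals = np.empty(n_s)
    hvals = np.empty(h_n)

    while top > 0:
        top -= 1
        node = stack[top, 0]
        s_lo = stack[top, 1]
        s_hi = stack[top, 2]
        h_lo = stack[top, 3]
        h_hi = stack[top, 4]
        depth = stack[top, 5]

        hw1, hwy1, hw0, hwy0, hc1, hc0 = _node_sums(arm, y, w, hidx, h_lo, h_hi)
        hp1 = 0
        hp0 = 0
        for k in range(h_lo, h_hi):
            i = hidx[k]
            if w[i] > 0.0:
                if arm[i] == 1:
                    hp1 += 1
                else:
                    hp0 += 1
        sp1 = 0
        sp0 = 0
        for k in range(s_lo, s_hi):
            i = sidx[k]
            if w[i] > 0.0:
                if arm[i] == 1:
                    sp1 += 1
                else:
                    sp0 += 1
        # honesty estimate is valid by construction: every created node has
        # at least one positive-weight patient per arm (checked at split
        # time; at the root by the subsample redraw loop)
        value[node] = hwy1 / hw1 - hwy0 / hw0
        feat[node] = -1

        sw1, swy1, sw0, swy0, sc1, sc0 = _node_sums(arm, y, w, sidx, s_lo, s_hi)
        if depth >= max_depth or n_nodes + 2 > max_nodes:
            continue
        if sc1 < 2 * min_leaf or sc0 < 2 * min_leaf:
            continue
        if sw1 <= 0.0 or sw0 <= 0.0:
            continue
        delta_p = swy1 / sw1 - swy0 / sw0

        m = s_hi - s_lo
        hm = h_hi - h_lo

        # choose mtry variables by partial Fisher-Yates
        for t in range(mtry):
            j = t + np.random.randint(0, p - t)
            tmp = var_pool[t]
            var_pool[t] = var_pool[j]
            var_pool[j] = tmp

        best_crit = -1.0
        best_var = -1
        best_thr = 0.0

        for vi in range(mtry):
            v = var_pool[vi]
            for k in range(m):
                vals[k] = X[sidx[s_lo + k], v]
            order = np.argsort(vals[:m], kind="mergesort")

            for k in range(hm):
                hvals[k] = X[hidx[h_lo + k], v]
            horder = np.argsort(hvals[:hm], kind="mergesort")
            # honesty prefix stats along sorted order; hpre_p* count
            # positive-weight patients (those contributing to leaf means)
            hpre_c1 = np.empty(hm + 1, dtype=np.int64)
            hpre_c0 = np.empty(hm + 1, dtype=np.int64)
            hpre_p1 = np.empty(hm + 1, dtype=np.int64)
            hpre_p0 = np.empty(hm + 1, dtype=np.int64)
            hpre_c1[0] = 0
            hpre_c0[0] = 0
            hpre_p1[0] = 0
            hpre_p0[0] = 0
            for k in range(hm):
                i = hidx[h_lo + horder[k]]
                pos = 1 if w[i] > 0.0 else 0
                hpre_c1[k + 1] = hpre_c1[k] + (1 if arm[i] == 1 else 0)
                hpre_c0[k + 1] = hpre_c0[k] + (1 if arm[i] == 0 else 0)
                hpre_p1[k + 1] = hpre_p1[k] + (pos if arm[i] == 1 else 0)
                hpre_p0[k + 1] = hpre_p0[k] + (pos if arm[i] == 0 else 0)
            hsorted = np.empty(hm)
            for k in range(hm):
                hsorted[k] = hvals[horder[k]]

            cw1 = 0.0
            cwy1 = 0.0
            cw0 = 0.0
            cwy0 = 0.0
            cc1 = 0
            cc0 = 0
            cp1 = 0
            cp0 = 0
            for k in range(m - 1):
                i = sidx[s_lo + order[k]]
                if arm[i] == 1:
                    cw1 += w[i]
                    cwy1 += w[i] * y[i]
                    cc1 += 1
                    if w[i] > 0.0:
                        cp1 += 1
                else:
                    cw0 += w[i]
                    cwy0 += w[i] * y[i]
                    cc0 += 1
                    if w[i] > 0.0:
                        cp0 += 1
                xk = vals[order[k]]
                xk1 = vals[order[k + 1]]
                if xk == xk1:
                    continue
                # structure-half per-arm count and weight constraints
                if cc1 < min_leaf or cc0 < min_leaf:
                    continue
                if sc1 - cc1 < min_leaf or sc0 - cc0 < min_leaf:
                    continue
                if cp1 < 1 or cp0 < 1 or sp1 - cp1 < 1 or sp0 - cp0 < 1:
                    continue
                t_c = 0.5 * (xk + xk1)
                # honesty-half constraints at this threshold
                kk = np.searchsorted(hsorted, t_c)
                if (hpre_c1[kk] < min_leaf or hpre_c0[kk] < min_leaf or
                        hc1 - hpre_c1[kk] < min_leaf or hc0 - hpre_c0[kk] < min_leaf):
                    continue
                if (hpre_p1[kk] < 1 or hpre_p0[kk] < 1 or
                        hp1 - hpre_p1[kk] < 1 or hp0 - hpre_p0[kk] < 1):
                    continue
                d_l = cwy1 / cw1 - cwy0 / cw0
                d_r = (swy1 - cwy1) / (sw1 - cw1) - (swy0 - cwy0) / (sw0 - cw0)
                n_l = k + 1
                n_r = m - n_l
                crit = n_l * (d_l - delta_p) ** 2 + n_r * (d_r - delta_p) ** 2
                if crit > best_crit:
                    best_crit = crit
                    best_var = v
                    best_thr = t_c

        if best_var < 0:
            continue

        # partition structure indices in place
        s_mid = s_lo
        for k in range(s_lo, s_hi):
            if X[sidx[k], best_var] < best_thr:
                tmp = sidx[s_mid]
                sidx[s_mid] = sidx[k]
                sidx[k] = tmp
                s_mid += 1
        h_mid = h_lo
        for k in range(h_lo, h_hi):
            if X[hidx[k], best_var] < best_thr:
                tmp = hidx[h_mid]
                hidx[h_mid] = hidx[k]
                hidx[k] = tmp
                h_mid += 1

        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feat[node] = best_var
        thr[node] = best_thr
        left[node] = lid
        right[node] = rid

        stack[top, 0] = lid
        stack[top, 1] = s_lo
        stack[top, 2] = s_mid
        stack[top, 3] = h_lo
        stack[top, 4] = h_mid
        stack[top, 5] = depth + 1
        top += 1
        stack[top, 0] = rid
        stack[top, 1] = s_mid
        stack[top, 2] = s_hi
        stack[top, 3] = h_mid
        stack[top, 4] = h_hi
        stack[top, 5] = depth + 1
        top += 1

    return n_nodes


@njit(cache=True)
def grow_forest(X, arm, y, w, num_trees, n_sub, n_struct, mtry, min_leaf,
                max_depth, seed, swap_halves):
    """Grow the whole forest; deterministic given seed.

    Returns flat node arrays, the in-bag membership matrix, the
    structure-half membership matrix, and the count of trees whose root
    subsample never satisfied the per-arm constraints (0 on success).
    """
    n = X.shape[0]
    max_nodes = 2 * n_struct + 1
    feat = np.full((num_trees, max_nodes), -2, dtype=np.int64)
    thr = np.zeros((num_trees, max_nodes))
    left = np.full((num_trees, max_nodes), -1, dtype=np.int64)
    right = np.full((num_trees, max_nodes), -1, dtype=np.int64)
    value = np.zeros((num_trees, max_nodes))
    inbag = np.zeros((num_trees, n), dtype=np.bool_)
    structure = np.zeros((num_trees, n), dtype=np.bool_)
    n_failed = 0
    n_hon = n_sub - n_struct

    for t in range(num_trees):
        np.random.seed(seed + t)
        ok = False
        sidx = np.empty(n_struct, dtype=np.int64)
        hidx = np.empty(n_hon, dtype=np.int64)
        for _attempt in range(MAX_RETRIES):
            perm = np.random.permutation(n)
            for k in range(n_struct):
                sidx[k] = perm[k]
            for k in range(n_hon):
                hidx[k] = perm[n_struct + k]
            if swap_halves == 1 and n_struct == n_hon:
                tmp2 = sidx.copy()
                sidx = hidx.copy()
                hidx = tmp2
            sw1, swy1, sw0, swy0, sc1, sc0 = _node_sums(arm, y, w, sidx, 0, n_struct)
            hw1, hwy1, hw0, hwy0, hc1, hc0 = _node_sums(arm, y, w, hidx, 0, n_hon)
            if (sc1 >= min_leaf and sc0 >= min_leaf and
                    hc1 >= min_leaf and hc0 >= min_leaf and
                    sw1 > 0.0 and sw0 > 0.0 and hw1 > 0.0 and hw0 > 0.0):
                ok = True
                break
        if not ok:
            n_failed += 1
            feat[t, 0] = -1
            value[t, 0] = 0.0
            continue
        for k in range(n_struct):
            inbag[t, sidx[k]] = True
            structure[t, sidx[k]] = True
        for k in range(n_hon):
            inbag[t, hidx[k]] = True
        _grow_tree(X, arm, y, w, sidx, n_struct, hidx, n_hon, mtry, min_leaf,
                   max_depth, feat[t], thr[t], left[t], right[t], value[t])
    return feat, thr, left, right, value, inbag, structure, n_failed


@njit(cache=True)
def predict_forest(feat, thr, left, right, value, X, skip):
    """Average leaf value over trees; skip[t, i] True drops tree t for row i
    (used for out-of-bag prediction). Rows with no eligible tree get NaN."""
    num_trees = feat.shape[0]
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        s = 0.0
        c = 0
        for t in range(num_trees):
            if skip[t, i]:
                continue
            node = 0
            while feat[t, node] >= 0:
                if X[i, feat[t, node]] < thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            s += value[t, node]
            c += 1
        out[i] = s / c if c > 0 else np.nan
    return out
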