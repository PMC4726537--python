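"""Numba kernels for growing and evaluating regression trees.

The split criterion is classical CART variance reduction: at each node the
candidate split minimising the summed child sum-of-squared-errors (SSE) is
chosen among the midpoints of consecutive distinct sorted values of each
candidate feature.  Ties are broken towards the lowest feature index, then
the lowest threshold, which makes tree growth fully deterministic given the
per-node feature sample.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Sentinel used in the flat node arrays: feature == _LEAF marks a leaf node.
_LEAF = -1


@njit(cache=False)
def _scan_feature(xs, ys, min_leaf, sum_y, sum_y2):
    """Best split position for one (sorted) feature.

    Returns (threshold, total_child_sse, found). Cut points are midpoints of
    consecutive distinct xs values with >= min_leaf records on each side;
    scanning in ascending threshold order with strict '<' keeps the lowest
    threshold among exact SSE ties.
    """
    n = xs.shape[0]
    best_sse = np.inf
    best_thr = 0.0
    found = False
    left_sum = 0.0
    left_sum2 = 0.0
    for i in range(n - 1):
        v = ys[i]
        left_sum += v
        left_sum2 += v * v
        nl = i + 1
        nr = n - nl
        if nl < min_leaf:
            continue
        if nr < min_leaf:
            break
        if xs[i + 1] <= xs[i]:  # not a boundary between distinct values
            continue
        right_sum = sum_y - left_sum
        right_sum2 = sum_y2 - left_sum2
        sse = (left_sum2 - left_sum * left_sum / nl) + (
            right_sum2 - right_sum * right_sum / nr
        )
        if sse < best_sse:
            best_sse = sse
            best_thr = 0.5 * (xs[i] + xs[i + 1])
            found = True
    return best_thr, best_sse, found


@njit(cache=False)
def _best_split(X, y, idx, start, end, feats, min_leaf):
    """Best (feature, threshold, sse_reduction) over candidate features.

    Operates on the records idx[start:end].  Returns feature == -1 when no
    admissible split exists (constant y, or no cut leaves min_leaf on both
    sides).  feats must be sorted ascending so that strict improvement
    comparisons break SSE ties towards the lowest feature index.
    """
    n = end - start
    sum_y = 0.0
    sum_y2 = 0.0
    for i in range(start, end):
        v = y[idx[i]]
        sum_y += v
        sum_y2 += v * v
    parent_sse = sum_y2 - sum_y * sum_y / n
    if parent_sse <= 0.0:
        return -1, 0.0, 0.0

    best_feat = -1
    best_thr = 0.0
    best_sse = np.inf
    xs = np.empty(n, dtype=np.float64)
    ys = np.empty(n, dtype=np.float64)
    for k in range(feats.shape[0]):
        j = feats[k]
        for i in range(n):
            xs[i] = X[idx[start + i], j]
        order = np.argsort(xs)
        xs_s = np.empty(n, dtype=np.float64)
        for i in range(n):
            xs_s[i] = xs[order[i]]
            ys[i] = y[idx[start + order[i]]]
        thr, sse, found = _scan_feature(xs_s, ys, min_leaf, sum_y, sum_y2)
        if found and sse < best_sse:
            best_sse = sse
            best_thr = thr
            best_feat = j
    if best_feat < 0:
        return -1, 0.0, 0.0
    reduction = parent_sse - best_sse
    return best_feat, best_thr, reduction


@njit(cache=False)
def _grow(X, y, sample_idx, mtry, min_leaf, max_depth, seed):
    """Grow one regression tree depth-first; returns flat node arrays.

    sample_idx indexes the (possibly bootstrapped) training records.  At each
    node mtry distinct features are drawn without replacement using numba's
    np.random stream seeded once per tree, so growth is reproducible from
    (data, seed).
    """
    np.random.seed(seed)
    n = sample_idx.shape[0]
    n_features = X.shape[1]
    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, _LEAF, dtype=np.int64)
    threshold = np.zeros(max_nodes, dtype=np.float64)
    left = np.full(max_nodes, -1, dtype=np.int64)
    right = np.full(max_nodes, -1, dtype=np.int64)
    value = np.zeros(max_nodes, dtype=np.float64)
    n_node = np.zeros(max_nodes, dtype=np.int64)

    idx = sample_idx.copy()
    buf = np.empty(n, dtype=np.int64)
    pool = np.empty(n_features, dtype=np.int64)
    feats = np.empty(mtry, dtype=np.int64)

    stack = np.empty((max_nodes, 4), dtype=np.int64)  # node, start, end, depth
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    stack[0, 3] = 0
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        depth = stack[top, 3]
        m = end - start

        s = 0.0
        for i in range(start, end):
            s += y[idx[i]]
        value[node] = s / m
        n_node[node] = m

        if m < 2 * min_leaf or depth >= max_depth:
            continue

        # mtry features without replacement (partial Fisher-Yates), sorted
        for j in range(n_features):
            pool[j] = j
        for k in range(mtry):
            r = k + int(np.random.random() * (n_features - k))
            if r >= n_features:
                r = n_features - 1
            tmp = pool[k]
            pool[k] = pool[r]
            pool[r] = tmp
            feats[k] = pool[k]
        feats[:mtry].sort()

        feat, thr, _red = _best_split(X, y, idx, start, end, feats[:mtry], min_leaf)
        if feat < 0:
            continue

        # stable partition of idx[start:end] on the chosen split
        nl = 0
        nr = 0
        for i in range(start, end):
            if X[idx[i], feat] <= thr:
                buf[nl] = idx[i]
                nl += 1
            else:
                buf[m - 1 - nr] = idx[i]
                nr += 1
        for i in range(nl):
            idx[start + i] = buf[i]
        for i in range(nr):
            idx[start + nl + i] = buf[m - 1 - i]

        feature[node] = feat
        threshold[node] = thr
        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        left[node] = lchild
        right[node] = rchild
        stack[top, 0] = lchild
        stack[top, 1] = start
        stack[top, 2] = start + nl
        stack[top, 3] = depth + 1
        top += 1
        stack[top, 0] = rchild
        stack[top, 1] = start + nl
        stack[top, 2] = end
        stack[top, 3] = depth + 1
        top += 1

    return (
        feature[:n_nodes],
        threshold[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        value[:n_nodes],
        n_node[:n_nodes],
    )


@njit(cache=False)
def _predict_tree(feature, threshold, left, right, value, X, out):
    """Accumulate one tree's predictions into out."""
    for i in range(X.shape[0]):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] += value[node]
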