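"""Exact interventional Shapley values for axis-aligned regression trees.

For one explained record x and one background record z, the coalition game is
v(S) = f(h) with hybrid h taking features in S from x and the rest from z.
Because f is a decision tree, v depends only on which path conditions x and z
each satisfy: along the path to a leaf, each feature is either satisfied by
both (irrelevant to attribution), only by x, or only by z. A leaf reached
with ``a`` x-only features and ``b`` z-only features contributes its value

    +value / (a · C(a+b, b))   to each x-only feature,
    −value / (b · C(a+b, a))   to each z-only feature,

the closed-form Shapley weight of the induced unanimity-style game (features
off the path are dummies and carry zero weight). Summing over leaves gives
the exact Shapley vector for the pair; averaging over background records
gives the interventional Shapley value, with Σφ = f(x) − mean f(background)
holding identically.

The walk visits only leaves reachable by some hybrid: at a node whose feature
is still undecided, both children are explored when x and z diverge; once a
feature is committed to x (or z), the path follows that record alone. An
explicit stack replaces recursion; the per-feature commitment state and the
(a, b) counts are updated and restored in place.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import comb


def shapley_weight_table(max_features: int = 64) -> np.ndarray:
    """wa[a, b] = 1 / (a · C(a+b, b)); row a=0 unused."""
    wa = np.zeros((max_features + 1, max_features + 1))
    for a in range(1, max_features + 1):
        for b in range(0, max_features + 1 - a):
            wa[a, b] = 1.0 / (a * comb(a + b, b, exact=True))
    return wa


@njit(cache=True, fastmath=False)
def _tree_shap_pairs(cl, cr, feat, thr, val, X, Z, wa, phi):
    """Accumulate exact per-pair Shapley vectors of one tree into phi (n × p).

    Stack entries are (node, feature, action): action 1/2 commits ``feature``
    to the x/z record before descending into ``node``; action 0 is a restore
    sentinel clearing the commitment; action -1 is the bare root entry.
    """
    n, p = X.shape
    m = Z.shape[0]
    state = np.zeros(p, dtype=np.int8)
    stack_node = np.empty(256, dtype=np.int64)
    stack_feat = np.empty(256, dtype=np.int64)
    stack_act = np.empty(256, dtype=np.int8)
    for i in range(n):
        x = X[i]
        phi_i = phi[i]
        for j in range(m):
            z = Z[j]
            top = 1
            stack_node[0] = 0
            stack_feat[0] = -1
            stack_act[0] = -1
            a = 0
            b = 0
            while top > 0:
                top -= 1
                act = stack_act[top]
                fe = stack_feat[top]
                if act == 0:  # restore: both branches of this divergence done
                    if state[fe] == 1:
                        a -= 1
                    else:
                        b -= 1
                    state[fe] = 0
                    continue
                if act == 2:  # switch commitment from x to z
                    a -= 1
                    state[fe] = 2
                    b += 1
                node = stack_node[top]
                while True:
                    f = feat[node]
                    if f < 0:  # leaf
                        if a > 0 or b > 0:
                            v = val[node]
                            for k in range(p):
                                sk = state[k]
                                if sk == 1:
                                    phi_i[k] += v * wa[a, b]
                                elif sk == 2:
                                    phi_i[k] -= v * wa[b, a]
                        break
                    t = thr[node]
                    s = state[f]
                    if s == 1:
                        node = cl[node] if x[f] <= t else cr[node]
                    elif s == 2:
                        node = cl[node] if z[f] <= t else cr[node]
                    else:
                        x_left = x[f] <= t
                        z_left = z[f] <= t
                        if x_left == z_left:
                            node = cl[node] if x_left else cr[node]
                        else:
                            stack_node[top] = node  # ignored by restore
                            stack_feat[top] = f
                            stack_act[top] = 0
                            top += 1
                            stack_node[top] = cl[node] if z_left else cr[node]
                            stack_feat[top] = f
                            stack_act[top] = 2
                            top += 1
                            state[f] = 1
                            a += 1
                            node = cl[node] if x_left else cr[node]


def forest_shap_interventional(
    estimator, X: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Interventional Shapley values of a sklearn forest, (n × p), exact.

    Inputs are cast through float32 first so threshold comparisons agree
    bit-for-bit with sklearn's own prediction path.
    """
    X64 = np.ascontiguousarray(np.asarray(X, np.float32), dtype=np.float64)
    Z64 = np.ascontiguousarray(np.asarray(background, np.float32), dtype=np.float64)
    n, p = X64.shape
    wa = shapley_weight_table(max(p, 2))
    phi = np.zeros((n, p))
    for tree in estimator.estimators_:
        t = tree.tree_
        _tree_shap_pairs(
            np.ascontiguousarray(t.children_left, np.int64),
            np.ascontiguousarray(t.children_right, np.int64),
            np.ascontiguousarray(t.feature, np.int64),
            np.ascontiguousarray(t.threshold, np.float64),
            np.ascontiguousarray(t.value[:, 0, 0], np.float64),
            X64,
            Z64,
            wa,
            phi,
        )
    return phi / (len(estimator.estimators_) * len(Z64))
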