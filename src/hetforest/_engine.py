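"""Numba kernels for honest tree growth and forest prediction.

One engine serves three estimators:

* ``mode=0`` -- honest regression tree: splits minimize split-half weighted
  SSE, leaves predict the estimation-half weighted mean.
* ``mode=1`` -- honest causal/instrumental tree on locally centered data:
  splits maximize the expected-MSE heterogeneity criterion

      sum_L (n_L/Ntr) tau_L^2  -  (1/Ntr + 1/Nest) sum_L (S2_t/p + S2_c/(1-p))

  evaluated on split-half residuals, where tau_L is the within-leaf weighted
  residual-on-residual ratio sum(w*yc*zc)/sum(w*zc*dc), S2 are the weighted
  variances of the centered outcome by assignment arm and p the child-level
  share of assigned units. The causal forest is the dc == zc special case;
  the instrumental forest passes dc = D - dhat.

Trees are stored as flat arrays (feature < 0 marks a leaf); leaves carry
estimation-half aggregates so prediction can average per-leaf ratio
components across trees (the alpha-weight construction) without touching
training rows again.

Honesty contract: split search reads covariates and *split-half* responses
only; estimation-half responses enter solely through leaf aggregates, and
estimation-half covariates only through the per-child minimum-size counts.
"""

import numpy as np
from numba import njit

_EPS_DEN = 1e-12


@njit(cache=True)
def _select_features(p, mtry):
    arr = np.arange(p)
    for i in range(mtry):
        j = i + np.random.randint(0, p - i)
        t = arr[i]
        arr[i] = arr[j]
        arr[j] = t
    return np.sort(arr[:mtry])


@njit(cache=True)
def grow_tree(mode, X, y, zc, dc, w, treat, sidx_in, eidx_in,
              mtry, min_node, alpha, penalty, max_depth, seed):
    """Grow one honest tree; returns flat node arrays.

    sidx_in / eidx_in: row indices of the split and estimation halves.
    Returns (feature, thresh, left, right, value, num_mean, den_mean, cnt,
    inherited, eidx, leaf_of_est, n_nodes).
    """
    np.random.seed(seed)
    sidx = sidx_in.copy()
    eidx = eidx_in.copy()
    n_s = sidx.shape[0]
    n_e = eidx.shape[0]
    p = X.shape[1]
    max_nodes = 2 * n_s + 1

    feature = np.full(max_nodes, -1, np.int64)
    thresh = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    parent = np.full(max_nodes, -1, np.int64)
    value = np.zeros(max_nodes)
    num_mean = np.zeros(max_nodes)
    den_mean = np.zeros(max_nodes)
    cnt = np.zeros(max_nodes, np.int64)
    inherited = np.zeros(max_nodes, np.uint8)
    leaf_of_est = np.full(n_e, -1, np.int64)

    Ntr = float(n_s)
    Nest = float(n_e) if n_e > 0 else 1.0
    coef = 1.0 / Ntr + 1.0 / Nest

    stack = np.empty((max_nodes, 6), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n_s
    stack[0, 3] = 0
    stack[0, 4] = n_e
    stack[0, 5] = 0
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        node = stack[top, 0]
        s_lo = stack[top, 1]
        s_hi = stack[top, 2]
        e_lo = stack[top, 3]
        e_hi = stack[top, 4]
        depth = stack[top, 5]
        nn = s_hi - s_lo
        ne = e_hi - e_lo

        # estimation-half aggregates of this node
        en = 0.0
        ed = 0.0
        for k in range(e_lo, e_hi):
            r = eidx[k]
            if mode == 0:
                en += w[r] * y[r]
                ed += w[r]
            else:
                en += w[r] * y[r] * zc[r]
                ed += w[r] * zc[r] * dc[r]
        if abs(ed) > _EPS_DEN:
            value[node] = en / ed
        else:
            if parent[node] >= 0:
                value[node] = value[parent[node]]
            else:
                value[node] = 0.0
            inherited[node] = 1
        if ne > 0:
            num_mean[node] = en / ne
            den_mean[node] = ed / ne
        cnt[node] = ne

        # parent (unsplit) contribution to the criterion
        parent_ok = True
        parent_crit = -1e18
        if mode == 0:
            sw = 0.0
            swy = 0.0
            swy2 = 0.0
            for k in range(s_lo, s_hi):
                r = sidx[k]
                sw += w[r]
                swy += w[r] * y[r]
                swy2 += w[r] * y[r] * y[r]
            if sw > 0.0:
                parent_crit = -(swy2 - swy * swy / sw)
        else:
            sn = 0.0
            sd = 0.0
            tw = 0.0
            twy = 0.0
            twy2 = 0.0
            cw = 0.0
            cwy = 0.0
            cwy2 = 0.0
            tn = 0
            for k in range(s_lo, s_hi):
                r = sidx[k]
                sn += w[r] * y[r] * zc[r]
                sd += w[r] * zc[r] * dc[r]
                if treat[r] == 1:
                    tn += 1
                    tw += w[r]
                    twy += w[r] * y[r]
                    twy2 += w[r] * y[r] * y[r]
                else:
                    cw += w[r]
                    cwy += w[r] * y[r]
                    cwy2 += w[r] * y[r] * y[r]
            if tn == 0 or tn == nn or abs(sd) <= _EPS_DEN or tw <= 0.0 or cw <= 0.0:
                parent_ok = False
            else:
                tau = sn / sd
                pnode = tn / nn
                s2t = twy2 / tw - (twy / tw) ** 2
                s2c = cwy2 / cw - (cwy / cw) ** 2
                parent_crit = (nn / Ntr) * tau * tau - coef * (s2t / pnode + s2c / (1.0 - pnode))
        if not parent_ok:
            parent_crit = -1e18

        # Regression nodes split only on strict SSE improvement (CART rule);
        # causal/IV nodes take the criterion argmax among valid candidates —
        # with few covariates tried per node, requiring an immediate
        # improvement over the unsplit node stops too many trees at the root
        # and attenuates the ensemble toward the pooled effect.
        best_crit = parent_crit if mode == 0 else -1e30
        best_f = -1
        best_thr = 0.0

        can_split = nn >= 2 and (max_depth <= 0 or depth < max_depth)
        if mode == 0 and ne < 2 * min_node:
            can_split = False
        if mode == 1 and ne < 2 * 2 * min_node:
            can_split = False

        if can_split:
            feats = _select_features(p, mtry)
            alpha_n = int(np.ceil(alpha * nn))
            if alpha_n < 1:
                alpha_n = 1

            xs = np.empty(nn)
            for fi in range(feats.shape[0]):
                f = feats[fi]
                for k in range(nn):
                    xs[k] = X[sidx[s_lo + k], f]
                order = np.argsort(xs)

                # estimation-half feature values, sorted, by arm
                if mode == 0:
                    ea = np.empty(ne)
                    for k in range(ne):
                        ea[k] = X[eidx[e_lo + k], f]
                    ea = np.sort(ea)
                else:
                    net = 0
                    for k in range(ne):
                        if treat[eidx[e_lo + k]] == 1:
                            net += 1
                    et = np.empty(net)
                    ec = np.empty(ne - net)
                    it = 0
                    ic = 0
                    for k in range(ne):
                        r = eidx[e_lo + k]
                        if treat[r] == 1:
                            et[it] = X[r, f]
                            it += 1
                        else:
                            ec[ic] = X[r, f]
                            ic += 1
                    et = np.sort(et)
                    ec = np.sort(ec)

                # left-side accumulators over the sorted split-half rows
                l_sn = 0.0
                l_sd = 0.0
                l_tw = 0.0
                l_twy = 0.0
                l_twy2 = 0.0
                l_cw = 0.0
                l_cwy = 0.0
                l_cwy2 = 0.0
                l_tn = 0
                l_w = 0.0
                l_wy = 0.0
                l_wy2 = 0.0
                # node totals for the right side (recompute per feature)
                t_sn = 0.0
                t_sd = 0.0
                t_tw = 0.0
                t_twy = 0.0
                t_twy2 = 0.0
                t_cw = 0.0
                t_cwy = 0.0
                t_cwy2 = 0.0
                t_tn = 0
                t_w = 0.0
                t_wy = 0.0
                t_wy2 = 0.0
                for k in range(nn):
                    r = sidx[s_lo + k]
                    if mode == 0:
                        t_w += w[r]
                        t_wy += w[r] * y[r]
                        t_wy2 += w[r] * y[r] * y[r]
                    else:
                        t_sn += w[r] * y[r] * zc[r]
                        t_sd += w[r] * zc[r] * dc[r]
                        if treat[r] == 1:
                            t_tn += 1
                            t_tw += w[r]
                            t_twy += w[r] * y[r]
                            t_twy2 += w[r] * y[r] * y[r]
                        else:
                            t_cw += w[r]
                            t_cwy += w[r] * y[r]
                            t_cwy2 += w[r] * y[r] * y[r]

                for k in range(nn - 1):
                    r = sidx[s_lo + order[k]]
                    if mode == 0:
                        l_w += w[r]
                        l_wy += w[r] * y[r]
                        l_wy2 += w[r] * y[r] * y[r]
                    else:
                        l_sn += w[r] * y[r] * zc[r]
                        l_sd += w[r] * zc[r] * dc[r]
                        if treat[r] == 1:
                            l_tn += 1
                            l_tw += w[r]
                            l_twy += w[r] * y[r]
                            l_twy2 += w[r] * y[r] * y[r]
                        else:
                            l_cw += w[r]
                            l_cwy += w[r] * y[r]
                            l_cwy2 += w[r] * y[r] * y[r]
                    xk = xs[order[k]]
                    xk1 = xs[order[k + 1]]
                    if xk == xk1:
                        continue
                    nL = k + 1
                    nR = nn - nL
                    if nL < alpha_n or nR < alpha_n:
                        continue
                    thr = 0.5 * (xk + xk1)

                    if mode == 0:
                        neL = np.searchsorted(ea, thr, side='right')
                        neR = ne - neL
                        if neL < min_node or neR < min_node:
                            continue
                        r_w = t_w - l_w
                        r_wy = t_wy - l_wy
                        r_wy2 = t_wy2 - l_wy2
                        if l_w <= 0.0 or r_w <= 0.0:
                            continue
                        crit = -(l_wy2 - l_wy * l_wy / l_w) - (r_wy2 - r_wy * r_wy / r_w)
                    else:
                        netL = np.searchsorted(et, thr, side='right')
                        necL = np.searchsorted(ec, thr, side='right')
                        if netL < min_node or necL < min_node:
                            continue
                        if (et.shape[0] - netL) < min_node or (ec.shape[0] - necL) < min_node:
                            continue
                        if l_tn == 0 or l_tn == nL:
                            continue
                        r_tn = t_tn - l_tn
                        if r_tn == 0 or r_tn == nR:
                            continue
                        r_sn = t_sn - l_sn
                        r_sd = t_sd - l_sd
                        if abs(l_sd) <= _EPS_DEN or abs(r_sd) <= _EPS_DEN:
                            continue
                        r_tw = t_tw - l_tw
                        r_cw = t_cw - l_cw
                        if l_tw <= 0.0 or l_cw <= 0.0 or r_tw <= 0.0 or r_cw <= 0.0:
                            continue
                        tauL = l_sn / l_sd
                        tauR = r_sn / r_sd
                        pL = l_tn / nL
                        pR = r_tn / nR
                        s2tL = l_twy2 / l_tw - (l_twy / l_tw) ** 2
                        s2cL = l_cwy2 / l_cw - (l_cwy / l_cw) ** 2
                        s2tR = (t_twy2 - l_twy2) / r_tw - ((t_twy - l_twy) / r_tw) ** 2
                        s2cR = (t_cwy2 - l_cwy2) / r_cw - ((t_cwy - l_cwy) / r_cw) ** 2
                        crit = ((nL / Ntr) * tauL * tauL
                                - coef * (s2tL / pL + s2cL / (1.0 - pL))
                                + (nR / Ntr) * tauR * tauR
                                - coef * (s2tR / pR + s2cR / (1.0 - pR)))
                    crit -= penalty * (1.0 / nL + 1.0 / nR)
                    if crit > best_crit:
                        best_crit = crit
                        best_f = f
                        best_thr = thr

        if best_f < 0:
            for k in range(e_lo, e_hi):
                leaf_of_est[k] = node
            continue

        # materialize the split: partition both halves in place
        feature[node] = best_f
        thresh[node] = best_thr
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        left[node] = lid
        right[node] = rid
        parent[lid] = node
        parent[rid] = node

        tmp = np.empty(nn, np.int64)
        nl = 0
        nr = 0
        for k in range(s_lo, s_hi):
            r = sidx[k]
            if X[r, best_f] <= best_thr:
                sidx[s_lo + nl] = r
                nl += 1
            else:
                tmp[nr] = r
                nr += 1
        for k in range(nr):
            sidx[s_lo + nl + k] = tmp[k]
        s_mid = s_lo + nl

        tmpe = np.empty(ne, np.int64)
        nl_e = 0
        nr_e = 0
        for k in range(e_lo, e_hi):
            r = eidx[k]
            if X[r, best_f] <= best_thr:
                eidx[e_lo + nl_e] = r
                nl_e += 1
            else:
                tmpe[nr_e] = r
                nr_e += 1
        for k in range(nr_e):
            eidx[e_lo + nl_e + k] = tmpe[k]
        e_mid = e_lo + nl_e

        stack[top, 0] = rid
        stack[top, 1] = s_mid
        stack[top, 2] = s_hi
        stack[top, 3] = e_mid
        stack[top, 4] = e_hi
        stack[top, 5] = depth + 1
        top += 1
        stack[top, 0] = lid
        stack[top, 1] = s_lo
        stack[top, 2] = s_mid
        stack[top, 3] = e_lo
        stack[top, 4] = e_mid
        stack[top, 5] = depth + 1
        top += 1

    return (feature[:n_nodes], thresh[:n_nodes], left[:n_nodes], right[:n_nodes],
            value[:n_nodes], num_mean[:n_nodes], den_mean[:n_nodes], cnt[:n_nodes],
            inherited[:n_nodes], eidx, leaf_of_est, n_nodes)


@njit(cache=True)
def predict_forest(feature, thresh, left, right, num_mean, den_mean,
                   offsets, Xq, hh_q, inbag, oob):
    """Aggregate per-leaf ratio components across usable trees.

    Returns (num_acc, den_acc, trees_used). With ``oob`` nonzero, a tree is
    usable for query q only when q's household was outside that tree's
    subsample. tau(x) = num_acc/den_acc downstream (NaN when unusable).
    """
    nq = Xq.shape[0]
    n_trees = offsets.shape[0] - 1
    num_acc = np.zeros(nq)
    den_acc = np.zeros(nq)
    used = np.zeros(nq, np.int64)
    for t in range(n_trees):
        base = offsets[t]
        for q in range(nq):
            if oob != 0 and inbag[t, hh_q[q]] == 1:
                continue
            node = 0
            while feature[base + node] >= 0:
                if Xq[q, feature[base + node]] <= thresh[base + node]:
                    node = left[base + node]
                else:
                    node = right[base + node]
            num_acc[q] += num_mean[base + node]
            den_acc[q] += den_mean[base + node]
            used[q] += 1
    return num_acc, den_acc, used


@njit(cache=True)
def assign_leaves(feature, thresh, left, right, base, Xq):
    """Tree-local leaf ids for each query row in one tree."""
    nq = Xq.shape[0]
    out = np.empty(nq, np.int64)
    for q in range(nq):
        node = 0
        while feature[base + node] >= 0:
            if Xq[q, feature[base + node]] <= thresh[base + node]:
                node = left[base + node]
            else:
                node = right[base + node]
        out[q] = node
    return out
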