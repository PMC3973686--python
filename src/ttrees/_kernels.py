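"""Numba kernels for tree induction on integer-coded genotype matrices.

Trees are represented as flat parallel arrays (one slot per node):
``feat`` (-1 marks a leaf), ``thr``, ``left``/``right`` child ids,
``n_node``/``n_case`` in-bag sample counts and ``delta``, the per-sample
impurity decrease of the node's split.  The same layout is used for the
inner (per-block) trees of a T-Tree, stored in one pooled set of arrays
with per-outer-node offsets; inner-node ``feat`` holds the *global* SNP
column index.

All kernels consume an explicit integer seed through ``np.random.seed``
and are deterministic given it.  Genotype matrices must be C-contiguous
``int8`` with values in ``0..vmax`` (no missing values).
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _gini(n_case, n_total):
    q = n_case / n_total
    return 2.0 * q * (1.0 - q)


@njit(cache=True)
def _partial_shuffle(pool, m):
    """First m entries of a seeded partial Fisher-Yates shuffle of pool."""
    n = pool.size
    for i in range(m):
        j = i + int(np.random.random() * (n - i))
        if j >= n:
            j = n - 1
        tmp = pool[i]
        pool[i] = pool[j]
        pool[j] = tmp
    return pool[:m]


@njit(cache=True)
def grow_snp_tree(X, y, samp, m_try, n_min, random_cut, vmax, seed):
    """Grow one RF- or ET-style tree on raw SNP columns.

    random_cut=0: exhaustive cut-point search over value midpoints (RF);
    random_cut=1: one uniform random cut per candidate variable (ET).
    Returns flat node arrays trimmed to the number of nodes.
    """
    np.random.seed(seed)
    n = samp.size
    p = X.shape[1]
    max_nodes = 2 * n + 1
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    nn = np.zeros(max_nodes, np.int64)
    nc = np.zeros(max_nodes, np.int64)
    delta = np.zeros(max_nodes, np.float64)

    samples = samp.copy()
    nv = vmax + 1
    cnt = np.zeros(nv, np.int64)
    cas = np.zeros(nv, np.int64)
    varpool = np.arange(p)

    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        k = hi - lo
        cases = 0
        for i in range(lo, hi):
            cases += y[samples[i]]
        nn[node] = k
        nc[node] = cases
        if cases == 0 or cases == k or k < n_min or k < 2:
            continue

        i0 = _gini(cases, k)
        # reset pool order before the partial shuffle
        for i in range(p):
            varpool[i] = i
        cand = _partial_shuffle(varpool, m_try)

        best_delta = -1.0
        best_var = -1
        best_cut = 0.0
        found = False
        for ci in range(m_try):
            v = cand[ci]
            for u in range(nv):
                cnt[u] = 0
                cas[u] = 0
            for i in range(lo, hi):
                g = X[samples[i], v]
                cnt[g] += 1
                cas[g] += y[samples[i]]
            vmin = -1
            vmax_p = -1
            for u in range(nv):
                if cnt[u] > 0:
                    if vmin < 0:
                        vmin = u
                    vmax_p = u
            if vmin == vmax_p:
                continue  # constant variable at this node
            if random_cut == 1:
                r = np.random.random()
                while r <= 0.0:
                    r = np.random.random()
                cut = vmin + r * (vmax_p - vmin)
                t = int(np.floor(cut))
                if t >= vmax_p:
                    t = vmax_p - 1
                nl = 0
                cl = 0
                for u in range(t + 1):
                    nl += cnt[u]
                    cl += cas[u]
                d = (
                    i0
                    - (nl / k) * _gini(cl, nl)
                    - ((k - nl) / k) * _gini(cases - cl, k - nl)
                )
                if (not found) or d > best_delta or (
                    d == best_delta
                    and (cut < best_cut or (cut == best_cut and v < best_var))
                ):
                    best_delta = d
                    best_var = v
                    best_cut = cut
                    found = True
            else:
                nl = 0
                cl = 0
                for u in range(nv - 1):
                    nl += cnt[u]
                    cl += cas[u]
                    if nl == 0 or nl == k:
                        continue
                    if cnt[u] == 0:
                        continue
                    # next present value above u
                    w = -1
                    for u2 in range(u + 1, nv):
                        if cnt[u2] > 0:
                            w = u2
                            break
                    cut = (u + w) / 2.0
                    d = (
                        i0
                        - (nl / k) * _gini(cl, nl)
                        - ((k - nl) / k) * _gini(cases - cl, k - nl)
                    )
                    if (not found) or d > best_delta or (
                        d == best_delta
                        and (cut < best_cut or (cut == best_cut and v < best_var))
                    ):
                        best_delta = d
                        best_var = v
                        best_cut = cut
                        found = True

        # any valid split of an impure node is accepted (gain may be 0,
        # e.g. at the root of an XOR-like interaction)
        if not found:
            continue

        # in-place partition of samples[lo:hi]
        i = lo
        j = hi - 1
        while i <= j:
            if X[samples[i], best_var] <= best_cut:
                i += 1
            else:
                tmp = samples[i]
                samples[i] = samples[j]
                samples[j] = tmp
                j -= 1
        mid = i
        if mid == lo or mid == hi:
            continue  # degenerate (should not happen with valid cuts)

        feat[node] = best_var
        thr[node] = best_cut
        delta[node] = best_delta
        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        left[node] = lchild
        right[node] = rchild
        stack_node[top] = lchild
        stack_lo[top] = lo
        stack_hi[top] = mid
        top += 1
        stack_node[top] = rchild
        stack_lo[top] = mid
        stack_hi[top] = hi
        top += 1

    return (
        feat[:n_nodes],
        thr[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        nn[:n_nodes],
        nc[:n_nodes],
        delta[:n_nodes],
    )


@njit(cache=True)
def predict_tree(feat, thr, left, right, leaf_p, X):
    out = np.empty(X.shape[0], np.float64)
    for i in range(X.shape[0]):
        node = 0
        while feat[node] >= 0:
            if X[i, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = leaf_p[node]
    return out


@njit(cache=True)
def grow_inner_tree(
    X, y, samples, lo, hi, bcols, ic, k_int,
    ivar, icut, ileft, iright, inn, inc, idelta, node_of,
):
    """Grow a node-count-limited Extra-Tree on one block's SNPs.

    Operates on samples[lo:hi]; expansion order is uniform-random over
    the frontier of expandable leaves, stopping at ``ic`` test nodes.
    Inner-node ``ivar`` stores the global SNP column index.  ``node_of``
    (length hi-lo) receives the final leaf id of each sample position.
    Uses the kernel-global RNG (seed set by the caller).
    Returns (n_nodes, n_test_nodes).
    """
    k = hi - lo
    B = bcols.size
    cap = 2 * ic + 1
    for t in range(cap):
        ivar[t] = -1
        icut[t] = 0.0
        ileft[t] = -1
        iright[t] = -1
        inn[t] = 0
        inc[t] = 0
        idelta[t] = 0.0
    cases = 0
    for i in range(k):
        node_of[i] = 0
        cases += y[samples[lo + i]]
    inn[0] = k
    inc[0] = cases
    expandable = np.zeros(cap, np.uint8)
    expandable[0] = 1 if (0 < cases < k and k >= 2) else 0

    pos = np.empty(k, np.int64)
    mn = np.empty(B, np.int64)
    mx = np.empty(B, np.int64)
    nccols = np.empty(B, np.int64)

    n_nodes = 1
    n_test = 0
    while n_test < ic:
        # pick an expandable leaf uniformly at random
        n_exp = 0
        for t in range(n_nodes):
            if expandable[t] == 1:
                n_exp += 1
        if n_exp == 0:
            break
        r = int(np.random.random() * n_exp)
        if r >= n_exp:
            r = n_exp - 1
        L = -1
        c = 0
        for t in range(n_nodes):
            if expandable[t] == 1:
                if c == r:
                    L = t
                    break
                c += 1

        kl = 0
        for i in range(k):
            if node_of[i] == L:
                pos[kl] = i
                kl += 1
        # non-constant block columns at this leaf
        n_nc = 0
        for b in range(B):
            v0 = X[samples[lo + pos[0]], bcols[b]]
            lo_v = v0
            hi_v = v0
            for q in range(1, kl):
                g = X[samples[lo + pos[q]], bcols[b]]
                if g < lo_v:
                    lo_v = g
                if g > hi_v:
                    hi_v = g
            if lo_v < hi_v:
                mn[n_nc] = lo_v
                mx[n_nc] = hi_v
                nccols[n_nc] = b
                n_nc += 1
        if n_nc == 0:
            expandable[L] = 0
            continue

        k_eff = k_int if k_int < n_nc else n_nc
        # partial shuffle of the non-constant column slots
        for i in range(k_eff):
            j = i + int(np.random.random() * (n_nc - i))
            if j >= n_nc:
                j = n_nc - 1
            tmp = nccols[i]
            nccols[i] = nccols[j]
            nccols[j] = tmp
            tmp = mn[i]
            mn[i] = mn[j]
            mn[j] = tmp
            tmp = mx[i]
            mx[i] = mx[j]
            mx[j] = tmp

        lcase = inc[L]
        i0 = _gini(lcase, kl)
        best_d = -1.0
        best_b = -1
        best_cut = 0.0
        for ci in range(k_eff):
            b = nccols[ci]
            r2 = np.random.random()
            while r2 <= 0.0:
                r2 = np.random.random()
            cut = mn[ci] + r2 * (mx[ci] - mn[ci])
            nl = 0
            cl = 0
            col = bcols[b]
            for q in range(kl):
                s = samples[lo + pos[q]]
                if X[s, col] <= cut:
                    nl += 1
                    cl += y[s]
            d = (
                i0
                - (nl / kl) * _gini(cl, nl)
                - ((kl - nl) / kl) * _gini(lcase - cl, kl - nl)
            )
            if best_b < 0 or d > best_d:
                best_d = d
                best_b = b
                best_cut = cut

        # split leaf L
        lch = n_nodes
        rch = n_nodes + 1
        n_nodes += 2
        col = bcols[best_b]
        nl = 0
        cl = 0
        for q in range(kl):
            s = samples[lo + pos[q]]
            if X[s, col] <= best_cut:
                node_of[pos[q]] = lch
                nl += 1
                cl += y[s]
            else:
                node_of[pos[q]] = rch
        ivar[L] = col
        icut[L] = best_cut
        ileft[L] = lch
        iright[L] = rch
        idelta[L] = best_d
        expandable[L] = 0
        inn[lch] = nl
        inc[lch] = cl
        inn[rch] = kl - nl
        inc[rch] = lcase - cl
        expandable[lch] = 1 if (0 < cl < nl and nl >= 2) else 0
        expandable[rch] = 1 if (0 < lcase - cl < kl - nl and kl - nl >= 2) else 0
        n_test += 1

    return n_nodes, n_test


@njit(cache=True)
def grow_inner_tree_seeded(X, y, bcols, ic, k_int, seed):
    """Standalone entry point: seed the RNG and grow one inner tree on
    all rows of X restricted to the block columns ``bcols``."""
    np.random.seed(seed)
    n = X.shape[0]
    cap = 2 * ic + 1
    ivar = np.empty(cap, np.int64)
    icut = np.empty(cap, np.float64)
    ileft = np.empty(cap, np.int64)
    iright = np.empty(cap, np.int64)
    inn = np.empty(cap, np.int64)
    inc = np.empty(cap, np.int64)
    idelta = np.empty(cap, np.float64)
    node_of = np.empty(n, np.int64)
    samples = np.arange(n)
    n_nodes, n_test = grow_inner_tree(
        X, y, samples, 0, n, bcols, ic, k_int,
        ivar, icut, ileft, iright, inn, inc, idelta, node_of,
    )
    return (
        ivar[:n_nodes], icut[:n_nodes], ileft[:n_nodes], iright[:n_nodes],
        inn[:n_nodes], inc[:n_nodes], idelta[:n_nodes], node_of, n_test,
    )


@njit(cache=True)
def _best_cut_on_scores(probs, counts, cases, n_leaves, k, n_case):
    """Exhaustive midpoint cut over <= n_leaves distinct score levels.

    probs/counts/cases describe the leaves of an inner tree; returns
    (delta, cut) of the best threshold on the leaf scores (lowest cut on
    ties), or delta = -1 if the scores are constant.
    """
    order = np.argsort(probs[:n_leaves], kind="mergesort")
    i0 = _gini(n_case, k)
    best_d = -1.0
    best_cut = 0.0
    nl = 0
    cl = 0
    for ii in range(n_leaves - 1):
        a = order[ii]
        nl += counts[a]
        cl += cases[a]
        nxt = order[ii + 1]
        if probs[nxt] - probs[a] <= 1e-12:
            continue
        cut = 0.5 * (probs[a] + probs[nxt])
        d = (
            i0
            - (nl / k) * _gini(cl, nl)
            - ((k - nl) / k) * _gini(n_case - cl, k - nl)
        )
        if d > best_d or (d == best_d and cut < best_cut):
            best_d = d
            best_cut = cut
    return best_d, best_cut


@njit(cache=True)
def grow_ttree(
    X, y, samp, bsnps, boff, m_try, n_min, ic, k_int, laplace, seed
):
    """Grow one T-Tree: outer nodes test inner Extra-Trees on SNP blocks.

    bsnps/boff: concatenated per-block SNP indices with offsets
    (block b owns bsnps[boff[b]:boff[b+1]]).
    Returns outer node arrays plus the pooled inner-tree arrays.
    """
    np.random.seed(seed)
    n = samp.size
    nb = boff.size - 1
    cap = 2 * ic + 1
    max_outer = 2 * n + 1

    oblk = np.full(max_outer, -1, np.int64)
    ocut = np.zeros(max_outer, np.float64)
    oleft = np.full(max_outer, -1, np.int64)
    oright = np.full(max_outer, -1, np.int64)
    onn = np.zeros(max_outer, np.int64)
    onc = np.zeros(max_outer, np.int64)
    odelta = np.zeros(max_outer, np.float64)
    oioff = np.full(max_outer, -1, np.int64)
    oin = np.zeros(max_outer, np.int64)

    pool_cap = (n + 2) * cap
    pvar = np.full(pool_cap, -1, np.int64)
    pcut = np.zeros(pool_cap, np.float64)
    pleft = np.full(pool_cap, -1, np.int64)
    pright = np.full(pool_cap, -1, np.int64)
    pnn = np.zeros(pool_cap, np.int64)
    pnc = np.zeros(pool_cap, np.int64)
    pdelta = np.zeros(pool_cap, np.float64)
    pool_ptr = 0

    samples = samp.copy()
    blockpool = np.arange(nb)

    # candidate / best inner-tree buffers
    tvar = np.empty(cap, np.int64)
    tcut = np.empty(cap, np.float64)
    tleft = np.empty(cap, np.int64)
    tright = np.empty(cap, np.int64)
    tnn = np.empty(cap, np.int64)
    tnc = np.empty(cap, np.int64)
    tdelta = np.empty(cap, np.float64)
    tnode_of = np.empty(n, np.int64)
    bvar = np.empty(cap, np.int64)
    bcut2 = np.empty(cap, np.float64)
    bleft = np.empty(cap, np.int64)
    bright = np.empty(cap, np.int64)
    bnn = np.empty(cap, np.int64)
    bnc = np.empty(cap, np.int64)
    bdelta = np.empty(cap, np.float64)
    bnode_of = np.empty(n, np.int64)
    lprob = np.empty(cap, np.float64)
    lcnt = np.empty(cap, np.int64)
    lcas = np.empty(cap, np.int64)
    lid = np.empty(cap, np.int64)
    sbuf = np.empty(n, np.int64)

    stack_node = np.empty(max_outer, np.int64)
    stack_lo = np.empty(max_outer, np.int64)
    stack_hi = np.empty(max_outer, np.int64)
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        k = hi - lo
        cases = 0
        for i in range(lo, hi):
            cases += y[samples[i]]
        onn[node] = k
        onc[node] = cases
        if cases == 0 or cases == k or k < n_min or k < 2:
            continue

        m_eff = m_try if m_try < nb else nb
        for i in range(nb):
            blockpool[i] = i
        cand = _partial_shuffle(blockpool, m_eff)

        best_delta = -1.0
        best_block = -1
        best_cutpt = 0.0
        best_nnodes = 0
        for ci in range(m_eff):
            b = cand[ci]
            bcols = bsnps[boff[b] : boff[b + 1]]
            nni, ntest = grow_inner_tree(
                X, y, samples, lo, hi, bcols, ic, k_int,
                tvar, tcut, tleft, tright, tnn, tnc, tdelta, tnode_of,
            )
            if ntest == 0:
                continue
            # leaf scores
            n_leaves = 0
            for t in range(nni):
                if tvar[t] < 0:
                    lid[n_leaves] = t
                    lcnt[n_leaves] = tnn[t]
                    lcas[n_leaves] = tnc[t]
                    lprob[n_leaves] = (tnc[t] + laplace) / (tnn[t] + 2.0 * laplace)
                    n_leaves += 1
            d, cut = _best_cut_on_scores(lprob, lcnt, lcas, n_leaves, k, cases)
            if d <= 0.0:
                continue
            if d > best_delta or (d == best_delta and b < best_block):
                best_delta = d
                best_block = b
                best_cutpt = cut
                best_nnodes = nni
                for t in range(nni):
                    bvar[t] = tvar[t]
                    bcut2[t] = tcut[t]
                    bleft[t] = tleft[t]
                    bright[t] = tright[t]
                    bnn[t] = tnn[t]
                    bnc[t] = tnc[t]
                    bdelta[t] = tdelta[t]
                for i in range(k):
                    bnode_of[i] = tnode_of[i]

        if best_block < 0:
            continue

        # stable partition by inner score <= cut
        nl = 0
        nr = 0
        for i in range(k):
            t = bnode_of[i]
            score = (bnc[t] + laplace) / (bnn[t] + 2.0 * laplace)
            if score <= best_cutpt:
                sbuf[nl] = samples[lo + i]
                nl += 1
        for i in range(k):
            t = bnode_of[i]
            score = (bnc[t] + laplace) / (bnn[t] + 2.0 * laplace)
            if score > best_cutpt:
                sbuf[nl + nr] = samples[lo + i]
                nr += 1
        if nl == 0 or nr == 0:
            continue
        for i in range(k):
            samples[lo + i] = sbuf[i]

        oblk[node] = best_block
        ocut[node] = best_cutpt
        odelta[node] = best_delta
        oioff[node] = pool_ptr
        oin[node] = best_nnodes
        for t in range(best_nnodes):
            pvar[pool_ptr + t] = bvar[t]
            pcut[pool_ptr + t] = bcut2[t]
            pleft[pool_ptr + t] = bleft[t]
            pright[pool_ptr + t] = bright[t]
            pnn[pool_ptr + t] = bnn[t]
            pnc[pool_ptr + t] = bnc[t]
            pdelta[pool_ptr + t] = bdelta[t]
        pool_ptr += best_nnodes

        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        oleft[node] = lchild
        oright[node] = rchild
        stack_node[top] = lchild
        stack_lo[top] = lo
        stack_hi[top] = lo + nl
        top += 1
        stack_node[top] = rchild
        stack_lo[top] = lo + nl
        stack_hi[top] = hi
        top += 1

    return (
        oblk[:n_nodes],
        ocut[:n_nodes],
        oleft[:n_nodes],
        oright[:n_nodes],
        onn[:n_nodes],
        onc[:n_nodes],
        odelta[:n_nodes],
        oioff[:n_nodes],
        oin[:n_nodes],
        pvar[:pool_ptr],
        pcut[:pool_ptr],
        pleft[:pool_ptr],
        pright[:pool_ptr],
        pnn[:pool_ptr],
        pnc[:pool_ptr],
        pdelta[:pool_ptr],
    )


@njit(cache=True)
def predict_ttree(
    oblk, ocut, oleft, oright, onn, onc, oioff,
    pvar, pcut, pleft, pright, pnn, pnc, laplace, X,
):
    out = np.empty(X.shape[0], np.float64)
    for i in range(X.shape[0]):
        node = 0
        while oblk[node] >= 0:
            off = oioff[node]
            t = 0
            while pvar[off + t] >= 0:
                if X[i, pvar[off + t]] <= pcut[off + t]:
                    t = pleft[off + t]
                else:
                    t = pright[off + t]
            score = (pnc[off + t] + laplace) / (pnn[off + t] + 2.0 * laplace)
            if score <= ocut[node]:
                node = oleft[node]
            else:
                node = oright[node]
        out[i] = onc[node] / onn[node]
    return out
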