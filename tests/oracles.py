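"""Independent reference implementations used only by the tests.

These deliberately use different algorithms from the package: the coalescent
density is computed by edge-interval overlap integration rather than epoch
sweeps, and the JC likelihood by the two-sequence closed form / matrix
exponential.
"""

import math

import numpy as np
from scipy.linalg import expm


def pop_at_oracle(sp_parent, sp_tau, base, t):
    p = base
    while sp_parent[p] >= 0 and sp_tau[sp_parent[p]] <= t:
        p = sp_parent[p]
    return p


def msc_log_density_oracle(gt, st) -> float:
    """Log density of a gene tree under the serially sampled MSC.

    Computed by summing, for every population and every sub-interval between
    breakpoints, -k(k-1)/theta times the interval length where k counts the
    gene-tree edges passing through the population during that interval,
    plus log(2/theta) per coalescence.  Independent of the package's epoch
    bookkeeping.
    """
    sp_parent = st.parent
    sp_tau = st.tau
    n_tips = gt.n_tips
    n_nodes = gt.n_nodes

    # recompute species base of every node from scratch
    base = np.full(n_nodes, -1, dtype=int)
    order = sorted(range(n_nodes), key=lambda v: gt.age[v])
    children = {v: [] for v in range(n_nodes)}
    for v in range(n_nodes):
        if gt.parent[v] >= 0:
            children[int(gt.parent[v])].append(v)
    for v in order:
        if v < n_tips:
            base[v] = gt.tip_species[v]
        else:
            a, b = children[v]
            x, anc = int(base[a]), set()
            while x >= 0:
                anc.add(x)
                x = int(sp_parent[x])
            x = int(base[b])
            while x not in anc:
                x = int(sp_parent[x])
            base[v] = x

    logp = 0.0
    for p in range(st.n_nodes):
        lo = float(sp_tau[p])
        hi = st.parent_tau(p)
        theta = float(st.theta[p])
        # edges: (child v, parent) alive on [age v, age parent); the root
        # edge of the gene tree extends to +infinity but contributes no
        # lineage once a single ancestor remains
        points = {lo}
        for v in range(n_nodes):
            for t in (float(gt.age[v]),):
                if lo < t < hi:
                    points.add(t)
        if math.isfinite(hi):
            points.add(hi)
        else:
            points.add(max(float(gt.age.max()), lo))
        grid = sorted(points)
        for a, b in zip(grid[:-1], grid[1:]):
            mid = 0.5 * (a + b)
            k = 0
            for v in range(n_nodes):
                par = int(gt.parent[v])
                if par < 0:
                    continue
                if float(gt.age[v]) <= a and float(gt.age[par]) >= b:
                    if pop_at_oracle(sp_parent, sp_tau, int(base[v]), mid) == p:
                        k += 1
            logp += -(k * (k - 1) / theta) * (b - a)
        for v in range(n_tips, n_nodes):
            t = float(gt.age[v])
            if pop_at_oracle(sp_parent, sp_tau, int(base[v]), t) == p:
                logp += math.log(2.0 / theta)
    return logp


def jc_pair_site_likelihood(t_total: float, same: bool) -> float:
    """Closed-form per-site likelihood for two sequences on a path t_total."""
    e = math.exp(-4.0 * t_total / 3.0)
    if same:
        return 0.25 * (0.25 + 0.75 * e)
    return 0.25 * (0.25 - 0.25 * e)


def jc_matrix_expm(t: float) -> np.ndarray:
    """JC transition matrix via the matrix exponential of the rate matrix."""
    Q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(Q, -1.0)
    return expm(Q * t)


def mu_move_logdet_fd(mu, c, ys_tips, t_nodes, b_fn, tau, h=1e-7):
    """Finite-difference log |det| of the (mu, t) -> (mu*, t*) move map.

    ``b_fn(tip_ages)`` returns per node the age of its oldest descendant
    sample given the vector of tip ages; ``tau`` is the population's parent
    divergence time.  The map is mu* = c mu; t_i* = tau - h_i (tau - b_i*)
    with h_i = (tau - t_i)/(tau - b_i), b computed from tips ys*mu.
    """

    def forward(x):
        m = x[0]
        ts = np.asarray(ys_tips) * m * c
        b_new = b_fn(ts)
        b_old = b_fn(np.asarray(ys_tips) * m)
        t = np.asarray(x[1:])
        hh = (tau - t) / (tau - b_old)
        return np.concatenate([[m * c], tau - hh * (tau - b_new)])

    x0 = np.concatenate([[mu], t_nodes])
    n = len(x0)
    J = np.empty((n, n))
    for j in range(n):
        dx = np.zeros(n)
        step = h * max(abs(x0[j]), 1e-12)
        dx[j] = step
        J[:, j] = (forward(x0 + dx) - forward(x0 - dx)) / (2 * step)
    sign, logdet = np.linalg.slogdet(J)
    assert sign > 0
    return logdet
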