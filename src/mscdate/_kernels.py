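"""Numerical kernels for the MCMC inner loop.

Compiled with numba when available; a pure-NumPy/Python fallback with the
same semantics is used otherwise.  The kernels recompute population
assignments from node ages and species bases on the fly, so callers only
need to keep ``base`` (species MRCA of descendants) current.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def msc_log_density_pops(
    n_tips,
    age,
    base,
    tip_species,
    sp_parent,
    sp_tau,
    sp_theta,
    sp_is_tip,
    desc,
    sp_root,
    pops_todo,
    out,
):
    """Per-population log density terms of the serially sampled MSC.

    Writes ``out[p]`` for every p in ``pops_todo``; returns True on a valid
    configuration and False if the gene tree is inconsistent with the
    species tree (a coalescence with < 2 lineages, an age outside its
    population interval, or uncoalesced root lineages).
    """
    n_nodes = 2 * n_tips - 1
    times = np.empty(n_nodes + 1, dtype=np.float64)
    is_add = np.empty(n_nodes + 1, dtype=np.int64)
    for ip in range(pops_todo.shape[0]):
        p = pops_todo[ip]
        lo = sp_tau[p]
        par = sp_parent[p]
        hi = np.inf if par < 0 else sp_tau[par]
        theta = sp_theta[p]
        m = 0
        entering = 0
        if sp_is_tip[p]:
            for j in range(n_tips):
                if tip_species[j] == p:
                    t = age[j]
                    if t < lo or t >= hi:
                        return False
                    times[m] = t
                    is_add[m] = 1
                    m += 1
        else:
            t_count = 0
            c_count = 0
            for j in range(n_tips):
                if desc[p, tip_species[j]]:
                    t_count += 1
            for v in range(n_tips, n_nodes):
                if desc[p, base[v]] and age[v] < lo:
                    c_count += 1
            entering = t_count - c_count
        for v in range(n_tips, n_nodes):
            q = base[v]
            a = age[v]
            while sp_parent[q] >= 0 and sp_tau[sp_parent[q]] <= a:
                q = sp_parent[q]
            if q == p:
                if a < lo:
                    return False
                times[m] = a
                is_add[m] = 0
                m += 1
        # insertion sort by time; additions precede coalescences at ties so a
        # coalescence exactly at a sampling time has a zero waiting time
        for i in range(1, m):
            t = times[i]
            k = is_add[i]
            j = i - 1
            while j >= 0 and (times[j] > t or (times[j] == t and is_add[j] < k)):
                times[j + 1] = times[j]
                is_add[j + 1] = is_add[j]
                j -= 1
            times[j + 1] = t
            is_add[j + 1] = k
        k_lin = entering
        t_prev = lo
        logp = 0.0
        total = entering
        for i in range(m):
            t = times[i]
            logp += -(k_lin * (k_lin - 1) / theta) * (t - t_prev)
            if is_add[i] == 1:
                k_lin += 1
                total += 1
            else:
                if k_lin < 2:
                    return False
                logp += math.log(2.0 / theta)
                k_lin -= 1
            t_prev = t
        if p == sp_root:
            if total > 0 and k_lin != 1:
                return False
        else:
            logp += -(k_lin * (k_lin - 1) / theta) * (hi - t_prev)
        out[p] = logp
    return True


@njit(cache=True)
def jc_site_log_likelihoods(n_tips, left, right, age, root, tip_part, out):
    """Per-pattern log likelihood under Jukes-Cantor with a strict clock.

    ``tip_part`` is (n_tips, 4, P) with all-ones columns for ambiguous or
    missing states; root base frequencies are uniform (1/4).  Returns False
    if a negative branch length is encountered.
    """
    n_nodes = 2 * n_tips - 1
    P = tip_part.shape[2]
    part = np.empty((n_nodes, 4, P), dtype=np.float64)
    for v in range(n_tips):
        for x in range(4):
            for s in range(P):
                part[v, x, s] = tip_part[v, x, s]
    logscale = np.zeros(P, dtype=np.float64)
    # iterative postorder
    order = np.empty(n_nodes, dtype=np.int64)
    stack = np.empty(2 * n_nodes, dtype=np.int64)
    state = np.empty(2 * n_nodes, dtype=np.int64)
    top = 0
    stack[top] = root
    state[top] = 0
    top += 1
    cnt = 0
    while top > 0:
        top -= 1
        v = stack[top]
        st = state[top]
        if v < n_tips or st == 1:
            order[cnt] = v
            cnt += 1
        else:
            stack[top] = v
            state[top] = 1
            top += 1
            stack[top] = right[v]
            state[top] = 0
            top += 1
            stack[top] = left[v]
            state[top] = 0
            top += 1
    tmp = np.empty((4, P), dtype=np.float64)
    for oi in range(cnt):
        v = order[oi]
        if v < n_tips:
            continue
        first = True
        for ci in range(2):
            c = left[v] if ci == 0 else right[v]
            b = age[v] - age[c]
            if b < 0:
                return False
            e = math.exp(-4.0 * b / 3.0)
            a = 0.25 * (1.0 - e)
            for s in range(P):
                su = (
                    part[c, 0, s]
                    + part[c, 1, s]
                    + part[c, 2, s]
                    + part[c, 3, s]
                )
                for x in range(4):
                    tmp[x, s] = a * su + e * part[c, x, s]
            if first:
                for s in range(P):
                    for x in range(4):
                        part[v, x, s] = tmp[x, s]
                first = False
            else:
                for s in range(P):
                    for x in range(4):
                        part[v, x, s] *= tmp[x, s]
        # rescale per pattern to avoid underflow
        for s in range(P):
            mx = part[v, 0, s]
            for x in range(1, 4):
                if part[v, x, s] > mx:
                    mx = part[v, x, s]
            if mx <= 0.0:
                return False
            for x in range(4):
                part[v, x, s] /= mx
            logscale[s] += math.log(mx)
    for s in range(P):
        tot = 0.0
        for x in range(4):
            tot += part[root, x, s]
        out[s] = math.log(0.25 * tot) + logscale[s]
    return True


@njit(cache=True)
def locus_log_likelihood(n_tips, left, right, age, root, tip_part, weights, site_out):
    ok = jc_site_log_likelihoods(n_tips, left, right, age, root, tip_part, site_out)
    if not ok:
        return False, 0.0
    tot = 0.0
    for s in range(site_out.shape[0]):
        tot += site_out[s] * weights[s]
    return True, tot


@njit(cache=True)
def oldest_descendant_ages(n_tips, left, right, age, out_b):
    """Per node, age of the oldest descendant tip (children precede parents
    in age order, so an age-sorted pass is a valid bottom-up traversal)."""
    n_nodes = 2 * n_tips - 1
    idx = np.argsort(age)
    for i in range(n_nodes):
        v = idx[i]
        if v < n_tips:
            out_b[v] = age[v]
        else:
            a = out_b[left[v]]
            b = out_b[right[v]]
            out_b[v] = a if a > b else b


@njit(cache=True)
def mu_rescale_ages(
    n_tips,
    parent,
    age_old,
    age_new,
    pop,
    ys_tips,
    mu_new,
    ratio,
    dated_pop,
    sp_parent,
    sp_tau,
):
    """Joint tip-age / coalescent-time rescaling for the substitution-rate move.

    Tips move to ys*mu_new; each internal node inside a dated tip population
    keeps its relative position between the oldest descendant sample age b
    and the population's parent divergence time tau:
    t* = tau - h (tau - b*), h = (tau - t)/(tau - b), b* = b * ratio.
    Returns (ok, log Jacobian term sum log[(tau-b*)/(tau-b)]); ok is False
    when the rescaled ages violate parent > child ordering.
    """
    n_nodes = 2 * n_tips - 1
    b = np.empty(n_nodes, dtype=np.float64)
    # oldest descendant tip age on the *old* scale: visiting nodes in age
    # order guarantees children push their (final) maxima before parents
    idx = np.argsort(age_old)
    for i in range(n_nodes):
        v = idx[i]
        if v < n_tips:
            b[v] = age_old[v]
        else:
            b[v] = 0.0
    for i in range(n_nodes):
        v = idx[i]
        p = parent[v]
        if p >= 0 and b[v] > b[p]:
            b[p] = b[v]
    logj = 0.0
    for v in range(n_tips):
        age_new[v] = ys_tips[v] * mu_new
    for v in range(n_tips, n_nodes):
        q = pop[v]
        if dated_pop[q]:
            taup = sp_tau[sp_parent[q]]
            bo = b[v]
            bn = bo * ratio
            h = (taup - age_old[v]) / (taup - bo)
            age_new[v] = taup - h * (taup - bn)
            logj += math.log((taup - bn) / (taup - bo))
        else:
            age_new[v] = age_old[v]
    for v in range(n_nodes):
        p = parent[v]
        if p >= 0 and age_new[p] <= age_new[v]:
            return False, 0.0
    return True, logj


@njit(cache=True)
def spr_candidates(
    n_nodes,
    parent,
    age,
    base,
    in_sub,
    p_excl,
    remroot,
    base_u,
    t,
    sp_parent,
    sp_tau,
    cand,
):
    """Feasible reattachment branches at time t after pruning a subtree.

    A branch is feasible if it spans t (the branch above the remaining root
    extends to infinity) and its lineage occupies the same population at t
    as the pruned subtree's root lineage.  Fills ``cand`` and returns the
    count.
    """
    qu = base_u
    while sp_parent[qu] >= 0 and sp_tau[sp_parent[qu]] <= t:
        qu = sp_parent[qu]
    cnt = 0
    for c in range(n_nodes):
        if in_sub[c] or c == p_excl:
            continue
        if c == remroot:
            if t <= age[c]:
                continue
        else:
            par = parent[c]
            if par < 0:
                continue
            if not (age[c] < t < age[par]):
                continue
        qc = base[c]
        while sp_parent[qc] >= 0 and sp_tau[sp_parent[qc]] <= t:
            qc = sp_parent[qc]
        if qc == qu:
            cand[cnt] = c
            cnt += 1
    return cnt


@njit(cache=True)
def _node_partial(v, left, right, age, part):
    """Recompute the conditional-likelihood vectors of internal node v."""
    P = part.shape[2]
    for ci in range(2):
        c = left[v] if ci == 0 else right[v]
        b = age[v] - age[c]
        e = math.exp(-4.0 * b / 3.0)
        a = 0.25 * (1.0 - e)
        if ci == 0:
            for s in range(P):
                su = part[c, 0, s] + part[c, 1, s] + part[c, 2, s] + part[c, 3, s]
                for x in range(4):
                    part[v, x, s] = a * su + e * part[c, x, s]
        else:
            for s in range(P):
                su = part[c, 0, s] + part[c, 1, s] + part[c, 2, s] + part[c, 3, s]
                for x in range(4):
                    part[v, x, s] *= a * su + e * part[c, x, s]


@njit(cache=True)
def _root_loglik(root, part, weights):
    P = part.shape[2]
    tot = 0.0
    for s in range(P):
        su = part[root, 0, s] + part[root, 1, s] + part[root, 2, s] + part[root, 3, s]
        if su <= 0.0:
            return np.nan
        tot += weights[s] * math.log(0.25 * su)
    return tot


@njit(cache=True)
def age_sweep(
    n_tips,
    left,
    right,
    parent,
    age,
    base,
    pop,
    root,
    tip_species,
    sp_parent,
    sp_tau,
    sp_theta,
    sp_is_tip,
    desc,
    sp_root,
    tip_part,
    weights,
    usedata,
    nodes,
    steps,
    urand,
    age_ceiling,
    dens_vec,
    loglik_in,
    part,
    cache_valid,
    saved,
    saved_idx,
):
    """Sequential sliding-window updates of internal node ages for one locus.

    Each move reflects the age into (max(child ages, tau of the node's
    species base), parent age) -- the root reflects at a large ceiling --
    and is accepted by the coalescent-density x likelihood ratio (the
    proposal is symmetric).  The likelihood uses the shared partial cache:
    only the path from the moved node to the root is recomputed, and the
    cache is left consistent with the final state.  ``age``, ``pop`` and
    ``dens_vec`` are updated in place; returns (accept count, log
    likelihood) with accept count -1 signalling a zero-likelihood state.
    """
    n_pops = sp_tau.shape[0]
    all_pops = np.arange(n_pops)
    new_dens = np.empty(n_pops, dtype=np.float64)
    loglik = loglik_in
    changed1 = np.empty(1, dtype=np.int64)
    if usedata and not cache_valid:
        loglik = full_partials_loglik(
            n_tips, left, right, age, root, tip_part, weights, part
        )
        if math.isnan(loglik):
            return -1, loglik_in
    n_acc = 0
    for i in range(nodes.shape[0]):
        v = nodes[i]
        lo = age[left[v]]
        if age[right[v]] > lo:
            lo = age[right[v]]
        if sp_tau[base[v]] > lo:
            lo = sp_tau[base[v]]
        par = parent[v]
        hi = age[par] if par >= 0 else age_ceiling
        if hi <= lo:
            continue
        told = age[v]
        width = hi - lo
        y = (told + steps[i] - lo) % (2.0 * width)
        if y > width:
            y = 2.0 * width - y
        age[v] = lo + y
        for p in range(n_pops):
            new_dens[p] = 0.0
        ok = msc_log_density_pops(
            n_tips, age, base, tip_species, sp_parent, sp_tau, sp_theta,
            sp_is_tip, desc, sp_root, all_pops, new_dens,
        )
        if not ok:
            age[v] = told
            continue
        delta = 0.0
        for p in range(n_pops):
            delta += new_dens[p] - dens_vec[p]
        newlik = loglik
        cnt = 0
        if usedata:
            changed1[0] = v
            cnt, newlik = path_update_loglik(
                n_tips, left, right, parent, age, root, weights, part,
                changed1, 1, saved, saved_idx,
            )
            if math.isnan(newlik):
                restore_partial_rows(part, saved, saved_idx, cnt)
                age[v] = told
                continue
            delta += newlik - loglik
        if math.log(urand[i]) < delta:
            n_acc += 1
            loglik = newlik
            for p in range(n_pops):
                dens_vec[p] = new_dens[p]
            q = base[v]
            a = age[v]
            while sp_parent[q] >= 0 and sp_tau[sp_parent[q]] <= a:
                q = sp_parent[q]
            pop[v] = q
        else:
            age[v] = told
            if usedata:
                restore_partial_rows(part, saved, saved_idx, cnt)
    return n_acc, loglik


@njit(cache=True)
def tau_rubber_ages(
    n_tips,
    parent,
    age_old,
    age_new,
    pop,
    c1,
    c2,
    p,
    L,
    U,
    t_old,
    t_new,
    is_root,
):
    """Rubber-band rescale of gene node ages for a divergence-time move.

    Nodes in the daughter populations with age in (L, t_old) map linearly
    into (L, t_new); nodes in population p map into (t_new, U) (translated
    by t_new - t_old for the root).  Returns (ok, n_below, n_above).
    """
    n_nodes = 2 * n_tips - 1
    rb = (t_new - L) / (t_old - L)
    ra = 1.0 if is_root else (U - t_new) / (U - t_old)
    shift = t_new - t_old
    n_below = 0
    n_above = 0
    for v in range(n_nodes):
        a = age_old[v]
        if v >= n_tips:
            q = pop[v]
            if (q == c1 or q == c2) and a > L:
                age_new[v] = L + (a - L) * rb
                n_below += 1
                continue
            if q == p:
                if is_root:
                    age_new[v] = a + shift
                else:
                    age_new[v] = U - (U - a) * ra
                n_above += 1
                continue
        age_new[v] = a
    if n_below + n_above > 0:
        for v in range(n_nodes):
            g = parent[v]
            if g >= 0 and age_new[g] <= age_new[v]:
                return False, n_below, n_above
    return True, n_below, n_above


@njit(cache=True)
def mu_stretch_ages(
    n_tips,
    age_old,
    age_new,
    pop,
    ys_tips,
    mu_old,
    mu_new,
    dated_pop,
    sp_parent,
    sp_tau,
    anchor_ys,
    anchor_off,
):
    """Monotone piecewise-linear age map for an auxiliary substitution-rate move.

    Within each dated tip population the interval (0, tau) is mapped onto
    itself by moving the sample-age anchors from ys*mu_old to ys*mu_new and
    interpolating linearly between consecutive anchors (tau is a fixed
    point).  The map is strictly increasing, so parent-child order is always
    preserved; tips land exactly on their new ages ys*mu_new.  Returns the
    log Jacobian (sum of log segment slopes over internal nodes moved).
    """
    logj = 0.0
    for v in range(n_tips):
        age_new[v] = ys_tips[v] * mu_new
    n_nodes = 2 * n_tips - 1
    for v in range(n_tips, n_nodes):
        q = pop[v]
        if not dated_pop[q]:
            age_new[v] = age_old[v]
            continue
        tau = sp_tau[sp_parent[q]]
        t = age_old[v]
        lo_old = 0.0
        lo_new = 0.0
        hi_old = tau
        hi_new = tau
        for i in range(anchor_off[q], anchor_off[q + 1]):
            s_old = anchor_ys[i] * mu_old
            if s_old <= t:
                lo_old = s_old
                lo_new = anchor_ys[i] * mu_new
            else:
                hi_old = s_old
                hi_new = anchor_ys[i] * mu_new
                break
        slope = (hi_new - lo_new) / (hi_old - lo_old)
        age_new[v] = lo_new + (t - lo_old) * slope
        logj += math.log(slope)
    return logj


@njit(cache=True)
def theta_scale_ages(n_tips, parent, age_old, age_new, pop, p, lo, hi, c):
    """Scale coalescent times inside population p toward/away from its start.

    Node ages with pop == p map to lo + c*(age - lo); the move is rejected
    (ok=False) if a scaled age reaches the population's end boundary or
    breaks parent > child order against unscaled neighbours.  Population
    membership is preserved, so the reverse move scales the same node set.
    Returns (ok, number of scaled nodes).
    """
    n_nodes = 2 * n_tips - 1
    n_scaled = 0
    for v in range(n_nodes):
        if v >= n_tips and pop[v] == p and age_old[v] > lo:
            t = lo + c * (age_old[v] - lo)
            if t >= hi:
                return False, n_scaled
            age_new[v] = t
            n_scaled += 1
        else:
            age_new[v] = age_old[v]
    if n_scaled > 0:
        for v in range(n_nodes):
            g = parent[v]
            if g >= 0 and age_new[g] <= age_new[v]:
                return False, n_scaled
    return True, n_scaled


@njit(cache=True)
def spr_time_floor(
    n_nodes,
    parent,
    age,
    base,
    in_sub,
    p_excl,
    remroot,
    base_u,
    sp_parent,
    sp_tau,
    desc,
):
    """Earliest time at which any outside branch can host the pruned lineage.

    For each remaining branch (and the open-ended branch above the remaining
    root) the earliest co-occurrence time with the pruned subtree's lineage
    is max(child age, tau of the species MRCA of the two lineages); branches
    that end before that time can never host.  The minimum over branches is
    a valid reattachment-time floor: it depends only on the pruned
    configuration and lies at or below every feasible attachment time, so
    the reflected window proposal is reversible.
    """
    best = np.inf
    for c in range(n_nodes):
        if in_sub[c] or c == p_excl:
            continue
        par = parent[c]
        if par < 0 and c != remroot:
            continue
        q = base_u
        while not desc[q, base[c]]:
            q = sp_parent[q]
        t = sp_tau[q]
        if age[c] > t:
            t = age[c]
        if c != remroot and age[par] <= t:
            continue
        if t < best:
            best = t
    return best


@njit(cache=True)
def full_partials_loglik(n_tips, left, right, age, root, tip_part, weights, part):
    """Fill the conditional-likelihood cache bottom-up; return the log
    likelihood (no per-node rescaling: adequate for the tree sizes and
    divergences this sampler targets)."""
    n_nodes = 2 * n_tips - 1
    P = tip_part.shape[2]
    for v in range(n_tips):
        for x in range(4):
            for s in range(P):
                part[v, x, s] = tip_part[v, x, s]
    order = np.argsort(age)
    for i in range(n_nodes):
        v = order[i]
        if v >= n_tips:
            _node_partial(v, left, right, age, part)
    return _root_loglik(root, part, weights)


@njit(cache=True)
def path_update_loglik(
    n_tips, left, right, parent, age, root, weights, part,
    changed, n_changed, saved, saved_idx,
):
    """Recompute cached partials only for ancestors of the changed nodes.

    Previous rows are copied into ``saved`` (indices in ``saved_idx``) so a
    rejected proposal can be undone with :func:`restore_partial_rows`.
    Returns (count of saved rows, new log likelihood).
    """
    n_nodes = 2 * n_tips - 1
    P = part.shape[2]
    mark = np.zeros(n_nodes, dtype=np.bool_)
    for i in range(n_changed):
        v = changed[i]
        while v >= 0 and not mark[v]:
            if v >= n_tips:
                mark[v] = True
            v = parent[v]
    cnt = 0
    for v in range(n_tips, n_nodes):
        if mark[v]:
            saved_idx[cnt] = v
            cnt += 1
    # order affected nodes by age so children precede parents
    for i in range(1, cnt):
        v = saved_idx[i]
        a = age[v]
        j = i - 1
        while j >= 0 and age[saved_idx[j]] > a:
            saved_idx[j + 1] = saved_idx[j]
            j -= 1
        saved_idx[j + 1] = v
    for j in range(cnt):
        v = saved_idx[j]
        for x in range(4):
            for s in range(P):
                saved[j, x, s] = part[v, x, s]
        _node_partial(v, left, right, age, part)
    return cnt, _root_loglik(root, part, weights)


@njit(cache=True)
def restore_partial_rows(part, saved, saved_idx, cnt):
    P = part.shape[2]
    for j in range(cnt):
        v = saved_idx[j]
        for x in range(4):
            for s in range(P):
                part[v, x, s] = saved[j, x, s]


@njit(cache=True)
def theta_scale_eval(
    n_tips,
    left,
    right,
    parent,
    age,
    age_buf,
    base,
    pop,
    root,
    tip_species,
    sp_parent,
    sp_tau,
    sp_theta_prop,
    sp_is_tip,
    desc,
    sp_root,
    p,
    lo,
    hi,
    c,
    usedata,
    weights,
    part,
    saved,
    saved_idx,
):
    """One-locus evaluation of the joint (theta, within-population ages) move.

    Scales the locus's population-p node ages into ``age_buf``, computes the
    population-p density term under the proposed theta and, when requested,
    the proposed log likelihood by a path update of the partial cache (the
    cache then reflects the proposal; the caller restores it via
    :func:`restore_partial_rows` with the returned count on rejection).
    Returns (ok, n_scaled, saved_count, lik_new, dens_p_new).
    """
    ok, n_scaled = theta_scale_ages(
        n_tips, parent, age, age_buf, pop, p, lo, hi, c
    )
    if not ok:
        return False, n_scaled, 0, 0.0, 0.0
    pops_todo = np.empty(1, dtype=np.int64)
    pops_todo[0] = p
    dens_out = np.zeros(sp_tau.shape[0])
    okd = msc_log_density_pops(
        n_tips, age_buf, base, tip_species, sp_parent, sp_tau, sp_theta_prop,
        sp_is_tip, desc, sp_root, pops_todo, dens_out,
    )
    if not okd:
        return False, n_scaled, 0, 0.0, 0.0
    lik_new = 0.0
    cnt = 0
    if usedata and n_scaled > 0:
        n_nodes = 2 * n_tips - 1
        changed = np.empty(n_scaled, dtype=np.int64)
        m = 0
        for v in range(n_tips, n_nodes):
            if age_buf[v] != age[v]:
                changed[m] = v
                m += 1
        cnt, lik_new = path_update_loglik(
            n_tips, left, right, parent, age_buf, root, weights, part,
            changed, m, saved, saved_idx,
        )
        if math.isnan(lik_new):
            restore_partial_rows(part, saved, saved_idx, cnt)
            return False, n_scaled, 0, 0.0, 0.0
    return True, n_scaled, cnt, lik_new, dens_out[p]


@njit(cache=True)
def msc_suffstats_pop(
    n_tips,
    age,
    base,
    tip_species,
    sp_parent,
    sp_tau,
    sp_is_tip,
    desc,
    sp_root,
    p,
):
    """Sufficient statistics of population p for theta: (n_coal, S).

    The population's density term is n_coal * log(2/theta) - S / theta with
    S = sum over inter-event intervals of k(k-1) * dt; the theta full
    conditional under a Gamma(a, b) prior is therefore generalized inverse
    Gaussian with exponent a - n_coal and weights (2S, 2b).
    """
    n_nodes = 2 * n_tips - 1
    times = np.empty(n_nodes + 1, dtype=np.float64)
    is_add = np.empty(n_nodes + 1, dtype=np.int64)
    lo = sp_tau[p]
    par = sp_parent[p]
    hi = np.inf if par < 0 else sp_tau[par]
    m = 0
    entering = 0
    if sp_is_tip[p]:
        for j in range(n_tips):
            if tip_species[j] == p:
                times[m] = age[j]
                is_add[m] = 1
                m += 1
    else:
        t_count = 0
        c_count = 0
        for j in range(n_tips):
            if desc[p, tip_species[j]]:
                t_count += 1
        for v in range(n_tips, n_nodes):
            if desc[p, base[v]] and age[v] < lo:
                c_count += 1
        entering = t_count - c_count
    for v in range(n_tips, n_nodes):
        q = base[v]
        a = age[v]
        while sp_parent[q] >= 0 and sp_tau[sp_parent[q]] <= a:
            q = sp_parent[q]
        if q == p:
            times[m] = a
            is_add[m] = 0
            m += 1
    for i in range(1, m):
        t = times[i]
        k = is_add[i]
        j = i - 1
        while j >= 0 and (times[j] > t or (times[j] == t and is_add[j] < k)):
            times[j + 1] = times[j]
            is_add[j + 1] = is_add[j]
            j -= 1
        times[j + 1] = t
        is_add[j + 1] = k
    k_lin = entering
    t_prev = lo
    n_coal = 0
    S = 0.0
    for i in range(m):
        t = times[i]
        S += k_lin * (k_lin - 1) * (t - t_prev)
        if is_add[i] == 1:
            k_lin += 1
        else:
            n_coal += 1
            k_lin -= 1
        t_prev = t
    if p != sp_root:
        S += k_lin * (k_lin - 1) * (hi - t_prev)
    return n_coal, S
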