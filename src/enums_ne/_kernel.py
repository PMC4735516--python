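"""Numba kernels for the skyline MCMC.

Everything here operates on flat arrays: tips 0..n-1 at height 0, internal
nodes n..2n-2, `parent`/`left`/`right` int32 topology arrays, `heights` in
substitutions/site.  The Metropolis–Hastings loop, the JC69 pruning
likelihood and the grouped-skyline coalescent prior all live in one jitted
translation unit so a multi-million-step chain runs in seconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# move indices for the acceptance diagnostics
MOVE_NAMES = (
    "node_height",      # uniform slide of one non-root internal node
    "root_scale",       # multiplicative scale of the root height
    "narrow_exchange",  # swap a node with its uncle
    "theta_scale",      # multiplicative scale of one group's theta
    "group_shift",      # move one coalescent interval between adjacent groups
    "joint_scale",      # scale all heights and all thetas together
    "theta_gibbs",      # exact conditional (inverse-gamma) draw of one theta
)
N_MOVES = len(MOVE_NAMES)


@njit(cache=True)
def jc69_loglik(tip_pat, counts, left, right, heights, n_tips):
    """Felsenstein pruning under JC69 with pattern weights.

    tip_pat: (n_tips, P) int8 nucleotide states 0..3; counts: (P,) pattern
    multiplicities; branch length = height difference (strict clock folded
    into the height unit).
    """
    P = tip_pat.shape[1]
    total = 2 * n_tips - 1
    partial = np.empty((total, P, 4))
    for t in range(n_tips):
        for p in range(P):
            for a in range(4):
                partial[t, p, a] = 0.0
            partial[t, p, tip_pat[t, p]] = 1.0
    # internal nodes in height order: children always strictly lower
    order = np.argsort(heights[n_tips:]) + n_tips
    for oi in range(order.shape[0]):
        u = order[oi]
        for p in range(P):
            for a in range(4):
                partial[u, p, a] = 1.0
        for ci in range(2):
            c = left[u] if ci == 0 else right[u]
            tb = heights[u] - heights[c]
            e = np.exp(-4.0 * tb / 3.0)
            psame = 0.25 + 0.75 * e
            pdiff = 0.25 - 0.25 * e
            for p in range(P):
                s = (partial[c, p, 0] + partial[c, p, 1]
                     + partial[c, p, 2] + partial[c, p, 3])
                for a in range(4):
                    partial[u, p, a] *= pdiff * s + (psame - pdiff) * partial[c, p, a]
    root = order[order.shape[0] - 1]
    ll = 0.0
    for p in range(P):
        site = 0.25 * (partial[root, p, 0] + partial[root, p, 1]
                       + partial[root, p, 2] + partial[root, p, 3])
        ll += counts[p] * np.log(site)
    return ll


@njit(cache=True)
def coalescent_log_density(heights, n_tips, group_sizes, thetas):
    """Grouped piecewise-constant skyline coalescent density of the genealogy.

    Interval ending in the i-th coalescence has k = n - i lineages and is
    governed by the theta of its group; each contributes
    ln(k(k-1)/(2 theta)) - k(k-1) dt / (2 theta).
    """
    n1 = n_tips - 1
    ct = np.sort(heights[n_tips:])
    lp = 0.0
    g = 0
    used = 0
    prev = 0.0
    for i in range(n1):
        k = n_tips - i
        dt = ct[i] - prev
        if dt < 0.0:
            return -np.inf
        th = thetas[g]
        rate = k * (k - 1) / (2.0 * th)
        lp += np.log(rate) - rate * dt
        prev = ct[i]
        used += 1
        if used == group_sizes[g] and g < group_sizes.shape[0] - 1:
            g += 1
            used = 0
    return lp


@njit(cache=True)
def _theta_log_prior(thetas, lo, hi):
    """Independent uniform-on-log priors with hard bounds."""
    lp = 0.0
    for g in range(thetas.shape[0]):
        if thetas[g] < lo or thetas[g] > hi:
            return -np.inf
        lp -= np.log(thetas[g])
    return lp


@njit(cache=True)
def _log_prior(heights, n_tips, group_sizes, thetas, lo, hi):
    lt = _theta_log_prior(thetas, lo, hi)
    if lt == -np.inf:
        return -np.inf
    return lt + coalescent_log_density(heights, n_tips, group_sizes, thetas)


@njit(cache=True)
def run_chain(
    tip_pat, counts,
    parent, left, right, heights,
    thetas, group_sizes,
    n_steps, thin, seed,
    move_weights, lam_theta, lam_root, lam_joint,
    theta_lo, theta_hi,
    sample_prior,
):
    """Metropolis–Hastings over (genealogy, skyline thetas, grouping).

    Returns raw samples recorded every `thin` steps (no burn-in trim):
    coalescent times (sorted), thetas, group sizes, plus per-move
    acceptance and attempt counts.  State arrays are modified in place.
    """
    np.random.seed(seed)
    n_tips = tip_pat.shape[0]
    m = thetas.shape[0]
    n_int = n_tips - 1
    root = -1
    for u in range(parent.shape[0]):
        if parent[u] == -1:
            root = u

    cum_w = np.cumsum(move_weights / np.sum(move_weights))

    if sample_prior:
        cur_ll = 0.0
    else:
        cur_ll = jc69_loglik(tip_pat, counts, left, right, heights, n_tips)
    cur_lp = _log_prior(heights, n_tips, group_sizes, thetas, theta_lo, theta_hi)

    n_samples = n_steps // thin
    out_ct = np.empty((n_samples, n_int))
    out_th = np.empty((n_samples, m))
    out_gs = np.empty((n_samples, m), dtype=np.int64)
    acc = np.zeros(N_MOVES, dtype=np.int64)
    tries = np.zeros(N_MOVES, dtype=np.int64)

    si = 0
    for step in range(1, n_steps + 1):
        u01 = np.random.random()
        mv = 0
        while cum_w[mv] < u01:
            mv += 1
        tries[mv] += 1
        log_hastings = 0.0
        new_ll = cur_ll
        valid = True
        # undo bookkeeping
        saved_a = 0.0
        saved_b = 0.0
        node_a = -1
        node_b = -1
        old_thetas = thetas.copy()
        old_gs0 = 0
        old_gs1 = 0
        gs_i = -1

        if mv == 0:
            # uniform slide of one non-root internal node
            v = n_tips + np.random.randint(n_int)
            while v == root:
                v = n_tips + np.random.randint(n_int)
            lo_h = max(heights[left[v]], heights[right[v]])
            hi_h = heights[parent[v]]
            saved_a = heights[v]
            node_a = v
            heights[v] = lo_h + np.random.random() * (hi_h - lo_h)
        elif mv == 1:
            # scale the root height
            s = np.exp(lam_root * (np.random.random() - 0.5))
            saved_a = heights[root]
            node_a = root
            newh = heights[root] * s
            if newh <= max(heights[left[root]], heights[right[root]]):
                valid = False
            else:
                heights[root] = newh
                log_hastings = np.log(s)
        elif mv == 2:
            # narrow exchange: swap a random child of p with p's sibling
            p = n_tips + np.random.randint(n_int)
            while p == root:
                p = n_tips + np.random.randint(n_int)
            g = parent[p]
            unc = left[g] if right[g] == p else right[g]
            c = left[p] if np.random.random() < 0.5 else right[p]
            if heights[p] <= heights[unc]:
                valid = False
            else:
                node_a = c
                node_b = unc
                # detach/attach
                if left[p] == c:
                    left[p] = unc
                else:
                    right[p] = unc
                if left[g] == unc:
                    left[g] = c
                else:
                    right[g] = c
                parent[c] = g
                parent[unc] = p
        elif mv == 3:
            # scale one group's theta
            gi = np.random.randint(m)
            s = np.exp(lam_theta * (np.random.random() - 0.5))
            thetas[gi] = thetas[gi] * s
            log_hastings = np.log(s)
        elif mv == 4:
            # shift one interval between adjacent groups
            if m < 2:
                valid = False
            else:
                b = np.random.randint(m - 1)
                gs_i = b
                old_gs0 = group_sizes[b]
                old_gs1 = group_sizes[b + 1]
                if np.random.random() < 0.5:
                    group_sizes[b] += 1
                    group_sizes[b + 1] -= 1
                else:
                    group_sizes[b] -= 1
                    group_sizes[b + 1] += 1
                if group_sizes[b] < 1 or group_sizes[b + 1] < 1:
                    valid = False
        elif mv == 5:
            # joint scale of all heights and thetas
            s = np.exp(lam_joint * (np.random.random() - 0.5))
            for w in range(n_tips, 2 * n_tips - 1):
                heights[w] *= s
            for gi in range(m):
                thetas[gi] *= s
            saved_a = s
            log_hastings = (n_int + m) * np.log(s)
        else:
            # Gibbs: theta_g | genealogy is inverse-gamma(c_g, A_g), where
            # c_g counts coalescences in the group and A_g sums
            # k(k-1) dt / 2 over its intervals; the likelihood does not
            # involve theta, so the conditional is exact (bounds enforced
            # by rejection)
            gi = np.random.randint(m)
            ct = np.sort(heights[n_tips:])
            lo_i = 0
            for gg in range(gi):
                lo_i += group_sizes[gg]
            hi_i = lo_i + group_sizes[gi]
            a_sum = 0.0
            prev = ct[lo_i - 1] if lo_i > 0 else 0.0
            for i in range(lo_i, hi_i):
                k = n_tips - i
                a_sum += k * (k - 1) * (ct[i] - prev) / 2.0
                prev = ct[i]
            c_g = float(group_sizes[gi])
            if a_sum <= 0.0:
                valid = False
            else:
                gam = np.random.gamma(c_g, 1.0 / a_sum)
                if gam <= 0.0:
                    valid = False
                else:
                    thetas[gi] = 1.0 / gam

        if valid:
            if not sample_prior and (mv == 0 or mv == 1 or mv == 2 or mv == 5):
                new_ll = jc69_loglik(tip_pat, counts, left, right, heights, n_tips)
            new_lp = _log_prior(heights, n_tips, group_sizes, thetas,
                                theta_lo, theta_hi)
            if mv == 6:
                # exact conditional draw: accept whenever inside the bounds
                if new_lp > -np.inf:
                    cur_lp = new_lp
                    acc[mv] += 1
                else:
                    valid = False
            else:
                log_alpha = (new_ll - cur_ll) + (new_lp - cur_lp) + log_hastings
                if new_lp > -np.inf and (
                    log_alpha >= 0.0 or np.log(np.random.random()) < log_alpha
                ):
                    cur_ll = new_ll
                    cur_lp = new_lp
                    acc[mv] += 1
                else:
                    valid = False

        if not valid:
            # revert
            if mv == 0 or mv == 1:
                if node_a >= 0:
                    heights[node_a] = saved_a
            elif mv == 2:
                if node_a >= 0:
                    c = node_a
                    unc = node_b
                    g = parent[c]
                    p = parent[unc]
                    if left[p] == unc:
                        left[p] = c
                    else:
                        right[p] = c
                    if left[g] == c:
                        left[g] = unc
                    else:
                        right[g] = unc
                    parent[c] = p
                    parent[unc] = g
            elif mv == 3 or mv == 6:
                for gi in range(m):
                    thetas[gi] = old_thetas[gi]
            elif mv == 4:
                if gs_i >= 0:
                    group_sizes[gs_i] = old_gs0
                    group_sizes[gs_i + 1] = old_gs1
            elif mv == 5:
                s = saved_a
                for w in range(n_tips, 2 * n_tips - 1):
                    heights[w] /= s
                for gi in range(m):
                    thetas[gi] = old_thetas[gi]

        if step % thin == 0 and si < n_samples:
            ct = np.sort(heights[n_tips:])
            for i in range(n_int):
                out_ct[si, i] = ct[i]
            for gi in range(m):
                out_th[si, gi] = thetas[gi]
                out_gs[si, gi] = group_sizes[gi]
            si += 1

    return out_ct, out_th, out_gs, acc, tries
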