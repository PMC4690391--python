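"""Numba kernels: meiosis/Wright-Fisher forward simulation and the SSVS Gibbs chain.

All kernels take an explicit integer seed and call ``np.random.seed`` at
entry, so every chain/simulation is reproducible independently of global
NumPy state.  Seeds must be < 2**31.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _gamete(h0, h1, chrom_start, chrom_end, chrom_len, gpos, out):
    """Recombine two parental haplotypes into one gamete.

    Crossover count per chromosome is Poisson with mean equal to the map
    length in Morgan (Haldane: no interference); crossover positions are
    uniform on the genetic map.
    """
    n_chrom = chrom_start.shape[0]
    for c in range(n_chrom):
        lo = chrom_start[c]
        hi = chrom_end[c]
        n_x = np.random.poisson(chrom_len[c])
        phase = 0
        if np.random.random() < 0.5:
            phase = 1
        if n_x == 0:
            if phase == 0:
                for k in range(lo, hi):
                    out[k] = h0[k]
            else:
                for k in range(lo, hi):
                    out[k] = h1[k]
        else:
            xpos = np.sort(np.random.random(n_x) * chrom_len[c])
            xi = 0
            for k in range(lo, hi):
                g = gpos[k]
                while xi < n_x and xpos[xi] < g:
                    xi += 1
                    phase = 1 - phase
                if phase == 0:
                    out[k] = h0[k]
                else:
                    out[k] = h1[k]


@njit(cache=True)
def wf_generations(haps, n_gen, n_ind_out, chrom_start, chrom_end, chrom_len,
                   gpos, seed):
    """Evolve a diploid population by Wright-Fisher random mating.

    ``haps`` holds 2N haplotypes (rows 2i, 2i+1 belong to individual i).
    Runs ``n_gen`` generations at constant size, then returns the
    haplotypes of the final generation (same size as input).
    """
    np.random.seed(seed)
    n_hap, m = haps.shape
    n_ind = n_hap // 2
    cur = haps.copy()
    nxt = np.empty_like(cur)
    for g in range(n_gen):
        for i in range(n_ind):
            sire = np.random.randint(n_ind)
            dam = np.random.randint(n_ind)
            while dam == sire:
                dam = np.random.randint(n_ind)
            _gamete(cur[2 * sire], cur[2 * sire + 1], chrom_start, chrom_end,
                    chrom_len, gpos, nxt[2 * i])
            _gamete(cur[2 * dam], cur[2 * dam + 1], chrom_start, chrom_end,
                    chrom_len, gpos, nxt[2 * i + 1])
        tmp = cur
        cur = nxt
        nxt = tmp
    return cur


@njit(cache=True)
def drop_offspring(parent_haps, sire_ids, dam_ids, chrom_start, chrom_end,
                   chrom_len, gpos, seed):
    """Produce one offspring haplotype pair per (sire, dam) mating."""
    np.random.seed(seed)
    n_off = sire_ids.shape[0]
    m = parent_haps.shape[1]
    out = np.empty((2 * n_off, m), dtype=parent_haps.dtype)
    for i in range(n_off):
        s = sire_ids[i]
        d = dam_ids[i]
        _gamete(parent_haps[2 * s], parent_haps[2 * s + 1], chrom_start,
                chrom_end, chrom_len, gpos, out[2 * i])
        _gamete(parent_haps[2 * d], parent_haps[2 * d + 1], chrom_start,
                chrom_end, chrom_len, gpos, out[2 * i + 1])
    return out


@njit(cache=True)
def ssvs_chain(Xt, y, group, n_groups, pi_large, ratio, n_iter, burn_in,
               prior_df, prior_scale, s2b0, s2e0, seed, fix_gamma, fix_var,
               random_order):
    """Gibbs chain for the mixture-prior SNP effect model.

    Right-hand-side updating: the residual vector is maintained
    incrementally; each marker update forms X_j'e + X_j'X_j beta_j,
    samples the indicator from its Bernoulli full conditional (computed
    in log space) and the effect from its normal full conditional.

    Xt is the (m, n) transposed, column-centered genotype matrix.
    fix_gamma = 1 forces all indicators to 1 (ridge limit);
    fix_var = 1 freezes s2b0/s2e0 (no variance updates).
    Returns posterior sums plus the final state for residual checks.
    """
    np.random.seed(seed)
    m, n = Xt.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx[j] = s
    gsize = np.zeros(n_groups)
    for i in range(n):
        gsize[group[i]] += 1.0

    beta = np.zeros(m)
    gamma = np.zeros(m, dtype=np.int8)
    mu = np.zeros(n_groups)
    e = y.copy()
    s2b = s2b0
    s2e = s2e0

    beta_sum = np.zeros(m)
    gamma_sum = np.zeros(m)
    mu_sum = np.zeros(n_groups)
    s2b_sum = 0.0
    s2e_sum = 0.0
    n_kept = 0
    fail_iter = -1

    log_pi_small = np.log(1.0 - pi_large)
    log_pi_big = np.log(pi_large)
    order = np.arange(m)

    for it in range(n_iter):
        for g in range(n_groups):
            r = 0.0
            for i in range(n):
                if group[i] == g:
                    r += e[i]
            new_mu = mu[g] + r / gsize[g] \
                + np.random.standard_normal() * np.sqrt(s2e / gsize[g])
            d = new_mu - mu[g]
            mu[g] = new_mu
            for i in range(n):
                if group[i] == g:
                    e[i] -= d

        if random_order == 1:
            order = np.random.permutation(m)
        for jj in range(m):
            j = order[jj]
            bj = beta[j]
            r = np.dot(Xt[j], e) + xtx[j] * bj
            v1 = s2b
            v0 = s2b / ratio
            lhs1 = xtx[j] + s2e / v1
            lhs0 = xtx[j] + s2e / v0
            ll1 = -0.5 * (np.log(v1) + np.log(lhs1)) \
                + r * r / (2.0 * s2e * lhs1)
            ll0 = -0.5 * (np.log(v0) + np.log(lhs0)) \
                + r * r / (2.0 * s2e * lhs0)
            if fix_gamma == 1:
                g1 = 1
            else:
                z = (ll0 + log_pi_small) - (ll1 + log_pi_big)
                if z > 35.0:
                    p1 = 0.0
                elif z < -35.0:
                    p1 = 1.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(z))
                g1 = 1 if np.random.random() < p1 else 0
            lhs = lhs1 if g1 == 1 else lhs0
            bnew = r / lhs + np.random.standard_normal() * np.sqrt(s2e / lhs)
            diff = bnew - bj
            if diff != 0.0:
                for i in range(n):
                    e[i] -= Xt[j, i] * diff
            beta[j] = bnew
            gamma[j] = g1

        if fix_var == 0:
            ssq = 0.0
            for j in range(m):
                if gamma[j] == 1:
                    ssq += beta[j] * beta[j]
                else:
                    ssq += beta[j] * beta[j] * ratio
            s2b = (prior_df * prior_scale + ssq) \
                / np.random.chisquare(prior_df + m)
            ee = 0.0
            for i in range(n):
                ee += e[i] * e[i]
            s2e = ee / np.random.chisquare(n)
            if not (np.isfinite(s2e) and np.isfinite(s2b)):
                fail_iter = it
                break

        if it >= burn_in:
            n_kept += 1
            for j in range(m):
                beta_sum[j] += beta[j]
                gamma_sum[j] += gamma[j]
            for g in range(n_groups):
                mu_sum[g] += mu[g]
            s2b_sum += s2b
            s2e_sum += s2e

    return (beta_sum, gamma_sum, mu_sum, s2b_sum, s2e_sum, n_kept, e, beta,
            mu, fail_iter)
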