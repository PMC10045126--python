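"""Numba kernels for the structured coalescent, the stepwise
microsatellite mutation layer, and microsatellite summary statistics.

These are the hot loops behind the ABC reference tables (tens of
thousands of multi-locus simulations), kept free of Python objects.
All randomness uses numba's global RNG, seeded once per top-level
kernel call, so results are bit-reproducible for a given seed.

Demographic events are encoded as parallel arrays sorted by time:
``ev_type`` 0 = split (all lineages of pop ``a`` move to ``b``),
1 = admixture (each lineage of ``a`` moves to ``b`` with probability
``p`` else to ``c``), 2 = size change (haploid size of ``a`` becomes
``p``).  Sizes are haploid gene-copy numbers; the coalescence rate for
k lineages in a population of haploid size s is k(k-1)/2 / s per
generation (continuous-time Kingman approximation).
"""

import numpy as np
from numba import njit

EV_SPLIT = 0
EV_ADMIX = 1
EV_RESIZE = 2


@njit(cache=True)
def _coal_core(pop_of, sizes_in, ev_time, ev_type, ev_a, ev_b, ev_c, ev_p):
    n = pop_of.shape[0]
    npop = sizes_in.shape[0]
    sizes = sizes_in.copy()
    tot = 2 * n - 1
    parent = np.full(tot, -1, np.int64)
    ntime = np.zeros(tot)
    members = np.empty((npop, n), np.int64)
    k = np.zeros(npop, np.int64)
    for i in range(n):
        p = pop_of[i]
        members[p, k[p]] = i
        k[p] += 1
    t = 0.0
    nev = ev_time.shape[0]
    ei = 0
    next_node = n
    n_act = n
    while n_act > 1:
        rate = 0.0
        for p in range(npop):
            if k[p] >= 2:
                rate += k[p] * (k[p] - 1) * 0.5 / sizes[p]
        t_ev = ev_time[ei] if ei < nev else np.inf
        if rate > 0.0:
            wait = np.random.exponential(1.0 / rate)
        else:
            wait = np.inf
        if t + wait < t_ev:
            t += wait
            u = np.random.random() * rate
            acc = 0.0
            cp = -1
            for p in range(npop):
                if k[p] >= 2:
                    acc += k[p] * (k[p] - 1) * 0.5 / sizes[p]
                    if u <= acc:
                        cp = p
                        break
            if cp < 0:
                for p in range(npop - 1, -1, -1):
                    if k[p] >= 2:
                        cp = p
                        break
            i1 = np.random.randint(0, k[cp])
            i2 = np.random.randint(0, k[cp] - 1)
            if i2 >= i1:
                i2 += 1
            c1 = members[cp, i1]
            c2 = members[cp, i2]
            parent[c1] = next_node
            parent[c2] = next_node
            ntime[next_node] = t
            hi = i1 if i1 > i2 else i2
            lo = i2 if i1 > i2 else i1
            members[cp, hi] = members[cp, k[cp] - 1]
            k[cp] -= 1
            members[cp, lo] = members[cp, k[cp] - 1]
            k[cp] -= 1
            members[cp, k[cp]] = next_node
            k[cp] += 1
            next_node += 1
            n_act -= 1
        else:
            if ei >= nev:
                return parent, ntime, False  # stranded lineages
            t = t_ev
            typ = ev_type[ei]
            a = ev_a[ei]
            b = ev_b[ei]
            if typ == EV_SPLIT:
                for j in range(k[a]):
                    members[b, k[b]] = members[a, j]
                    k[b] += 1
                k[a] = 0
            elif typ == EV_ADMIX:
                c = ev_c[ei]
                pr = ev_p[ei]
                for j in range(k[a]):
                    lin = members[a, j]
                    if np.random.random() < pr:
                        members[b, k[b]] = lin
                        k[b] += 1
                    else:
                        members[c, k[c]] = lin
                        k[c] += 1
                k[a] = 0
            else:
                sizes[a] = ev_p[ei]
            ei += 1
    return parent, ntime, True


@njit(cache=True)
def _smm_core(parent, ntime, n, mu, p_gsm, amin, amax, root_allele):
    """Drop stepwise mutations on a genealogy; returns leaf allele sizes.

    Steps are +-1 (strict SMM) or +-(1 + Geometric(P)) (GSM), reflected
    at the allele bounds mutation by mutation.
    """
    tot = parent.shape[0]
    val = np.empty(tot, np.int64)
    val[tot - 1] = root_allele
    for v in range(tot - 2, -1, -1):
        pa = parent[v]
        cur = val[pa]
        blen = ntime[pa] - ntime[v]
        nm = np.random.poisson(mu * blen)
        for _ in range(nm):
            if p_gsm > 0.0:
                step = np.random.geometric(1.0 - p_gsm)
            else:
                step = 1
            if np.random.random() < 0.5:
                step = -step
            cur += step
            while cur < amin or cur > amax:
                if cur < amin:
                    cur = 2 * amin - cur
                else:
                    cur = 2 * amax - cur
        val[v] = cur
    return val[:n]


@njit(cache=True)
def sim_genealogy_seeded(seed, pop_of, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_p):
    np.random.seed(seed)
    return _coal_core(pop_of, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_p)


@njit(cache=True)
def smm_seeded(seed, parent, ntime, n, mu, p_gsm, amin, amax, root_allele):
    np.random.seed(seed)
    return _smm_core(parent, ntime, n, mu, p_gsm, amin, amax, root_allele)


@njit(cache=True)
def sim_msat_seeded(seed, pop_of, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_p,
                    mu_loc, p_loc, amin, amax, root_allele):
    """Simulate a full diploid multi-locus dataset (independent
    genealogy + mutations per locus).  Lineages 2i and 2i+1 form
    individual i.  Returns (alleles (n_ind, L, 2) sorted, ok)."""
    np.random.seed(seed)
    n = pop_of.shape[0]
    L = mu_loc.shape[0]
    out = np.zeros((n // 2, L, 2), np.int64)
    for l in range(L):
        parent, ntime, ok = _coal_core(pop_of, sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_p)
        if not ok:
            return out, False
        vals = _smm_core(parent, ntime, n, mu_loc[l], p_loc[l], amin, amax, root_allele)
        for i in range(n // 2):
            a = vals[2 * i]
            b = vals[2 * i + 1]
            if a <= b:
                out[i, l, 0] = a
                out[i, l, 1] = b
            else:
                out[i, l, 0] = b
                out[i, l, 1] = a
    return out, True


@njit(cache=True)
def msat_stats(alleles, groups, n_groups, max_allele):
    """Summary-statistic vector for a diploid microsatellite dataset.

    Per group: mean (over loci) number of alleles, unbiased expected
    heterozygosity, allele-size variance.  Per group pair: multi-locus
    Weir-Cockerham theta (ratio of summed variance components), an
    allele-sharing distance 1 - mean_l sum_a min(p1, p2), and Goldstein's
    (delta mu)^2.  Genotype (0,0) is treated as missing.  Returns
    (stats, ok); ok is False when any statistic is undefined.
    """
    n, L, _ = alleles.shape
    counts = np.zeros((n_groups, L, max_allele + 1), np.int64)
    hetc = np.zeros((n_groups, L, max_allele + 1), np.int64)
    het = np.zeros((n_groups, L), np.int64)
    nsc = np.zeros((n_groups, L), np.int64)
    for i in range(n):
        g = groups[i]
        for l in range(L):
            a = alleles[i, l, 0]
            b = alleles[i, l, 1]
            if a == 0 and b == 0:
                continue
            counts[g, l, a] += 1
            counts[g, l, b] += 1
            nsc[g, l] += 1
            if a != b:
                het[g, l] += 1
                hetc[g, l, a] += 1
                hetc[g, l, b] += 1
    npair = n_groups * (n_groups - 1) // 2
    out = np.zeros(3 * n_groups + 3 * npair)
    ok = True
    means = np.zeros((n_groups, L))
    pos = 0
    for g in range(n_groups):
        na_s = 0.0
        he_s = 0.0
        va_s = 0.0
        nl = 0
        for l in range(L):
            m = nsc[g, l]
            if m == 0:
                ok = False
                continue
            tot = 2.0 * m
            na = 0
            s1 = 0.0
            s2 = 0.0
            sp2 = 0.0
            for a in range(1, max_allele + 1):
                c = counts[g, l, a]
                if c > 0:
                    na += 1
                    s1 += c * a
                    s2 += c * a * a
                    f = c / tot
                    sp2 += f * f
            mean = s1 / tot
            means[g, l] = mean
            if tot > 1:
                va = (s2 - tot * mean * mean) / (tot - 1.0)
                he = (tot / (tot - 1.0)) * (1.0 - sp2)
            else:
                va = 0.0
                he = 0.0
            na_s += na
            he_s += he
            va_s += va
            nl += 1
        if nl == 0:
            ok = False
            nl = 1
        out[pos] = na_s / nl
        out[pos + 1] = he_s / nl
        out[pos + 2] = va_s / nl
        pos += 3
    for g1 in range(n_groups):
        for g2 in range(g1 + 1, n_groups):
            num = 0.0
            den = 0.0
            das = 0.0
            dmu = 0.0
            nl = 0
            for l in range(L):
                m1 = nsc[g1, l]
                m2 = nsc[g2, l]
                if m1 == 0 or m2 == 0:
                    continue
                nbar = (m1 + m2) / 2.0
                if nbar <= 1.0:
                    continue
                nl += 1
                nc = (2.0 * nbar - (m1 * m1 + m2 * m2) / (2.0 * nbar))
                shared = 0.0
                for a in range(1, max_allele + 1):
                    c1 = counts[g1, l, a]
                    c2 = counts[g2, l, a]
                    if c1 + c2 == 0:
                        continue
                    p1 = c1 / (2.0 * m1)
                    p2 = c2 / (2.0 * m2)
                    if p1 < p2:
                        shared += p1
                    else:
                        shared += p2
                    h1 = hetc[g1, l, a] / m1
                    h2 = hetc[g2, l, a] / m2
                    pbar = (m1 * p1 + m2 * p2) / (2.0 * nbar)
                    s2v = (m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2) / nbar
                    hbar = (m1 * h1 + m2 * h2) / (2.0 * nbar)
                    aa = (nbar / nc) * (
                        s2v - (pbar * (1.0 - pbar) - 0.5 * s2v - hbar / 4.0) / (nbar - 1.0)
                    )
                    bb = (nbar / (nbar - 1.0)) * (
                        pbar * (1.0 - pbar) - 0.5 * s2v
                        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
                    )
                    cc = hbar / 2.0
                    num += aa
                    den += aa + bb + cc
                das += 1.0 - shared
                d = means[g1, l] - means[g2, l]
                dmu += d * d
            if nl == 0 or den == 0.0:
                ok = False
                nl = 1
                theta = 0.0
            else:
                theta = num / den
            out[pos] = theta
            out[pos + 1] = das / nl
            out[pos + 2] = dmu / nl
            pos += 3
    return out, ok
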