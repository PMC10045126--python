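"""Sequence and microsatellite summary statistics.

Covers the descriptive side of the pipeline: haplotype/nucleotide
diversity, Kimura two-parameter distances, Tajima's D and Fu's Fs
neutrality tests, distance-based Phi_ST (AMOVA) for sequences, and
observed/expected heterozygosity, F_IS and Weir-Cockerham theta for
microsatellites.

Site handling: positions where either sequence of a pair carries ``N``
or ``-`` are excluded from that pair's comparison ("pairwise
deletion", the Arlequin convention).  Statistics that are undefined
for an input (e.g. Tajima's D with no segregating site) return NaN
rather than 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, SequenceAlignment

__all__ = [
    "DiversitySummary",
    "NeutralitySummary",
    "collapse_and_diversity",
    "k2p_distance",
    "pairwise_differences",
    "tajimas_d",
    "fus_fs",
    "ewens_log_pmf",
    "phist_matrix",
    "haplotype_fst_matrix",
    "msat_summaries",
    "wc_fst",
    "SaturationError",
]

_PURINES = frozenset(b"AG")
_PYRIMIDINES = frozenset(b"CT")
_AMBIG = frozenset(b"N-")


class SaturationError(ValueError):
    """K2P correction undefined: too many differences (log of <= 0)."""


@dataclass
class DiversitySummary:
    k: int          # unique haplotypes after removing gap columns
    K: int          # unique haplotypes on the full alignment
    h: float        # haplotype diversity
    s: int          # segregating sites
    pi: float       # nucleotide diversity per site
    d: float        # mean pairwise differences per sequence
    n: int


@dataclass
class NeutralitySummary:
    tajima_d: float
    fu_fs: float


def _seq_bytes(aln: SequenceAlignment) -> np.ndarray:
    return aln.matrix()


def _pair_diff_and_sites(a: bytes, b: bytes) -> tuple[int, int]:
    """(differences, comparable sites) for one pair under pairwise deletion."""
    diff = sites = 0
    for x, y in zip(a, b):
        if x in _AMBIG or y in _AMBIG:
            continue
        sites += 1
        if x != y:
            diff += 1
    return diff, sites


def pairwise_differences(aln: SequenceAlignment) -> np.ndarray:
    """Matrix of pairwise nucleotide differences (pairwise deletion)."""
    M = _seq_bytes(aln)
    good = ~np.isin(M, [b"N", b"-"])
    n = aln.n
    D = np.zeros((n, n))
    for i in range(n):
        ok = good[i] & good[i + 1:]
        D[i, i + 1:] = ((M[i] != M[i + 1:]) & ok).sum(axis=1)
    return D + D.T


def collapse_and_diversity(aln: SequenceAlignment) -> DiversitySummary:
    """Haplotype and nucleotide diversity indices for one alignment.

    ``k`` counts unique haplotypes after removing columns that contain
    a gap in any sequence; ``K`` counts them on the full alignment.
    ``h`` uses the unbiased estimator n(1 - sum p_i^2)/(n - 1) on the
    full-alignment haplotype frequencies.
    """
    if aln.n == 0:
        raise ValueError("empty alignment")
    M = _seq_bytes(aln)
    gap_col = (M == b"-").any(axis=0)
    k = len({bytes(r) for r in M[:, ~gap_col]}) if (~gap_col).any() else 1
    haplos = [bytes(r) for r in M]
    K = len(set(haplos))
    n = aln.n
    if n < 2:
        return DiversitySummary(k, K, math.nan, _seg_sites(M), math.nan, math.nan, n)
    counts = pd.Series(haplos).value_counts().to_numpy()
    p = counts / n
    h = n * (1.0 - float(p @ p)) / (n - 1)
    D = pairwise_differences(aln)
    iu = np.triu_indices(n, 1)
    d = float(D[iu].mean())
    # per-site: divide each pair by its comparable-site count
    good = ~np.isin(M, [b"N", b"-"])
    pis = []
    for i, j in zip(*iu):
        sites = int((good[i] & good[j]).sum())
        pis.append(D[i, j] / sites if sites else np.nan)
    pi = float(np.nanmean(pis))
    return DiversitySummary(k, K, h, _seg_sites(M), pi, d, n)


def _seg_sites(M: np.ndarray) -> int:
    s = 0
    for col in M.T:
        bases = {c for c in bytes(col) if c not in _AMBIG}
        if len(bases) > 1:
            s += 1
    return s


def k2p_distance(s1: str, s2: str) -> float:
    """Kimura (1980) two-parameter distance between two aligned sequences.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P and Q the
    transition and transversion proportions over comparable sites.
    """
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned (equal length)")
    a, b = s1.upper().encode(), s2.upper().encode()
    ts = tv = sites = 0
    for x, y in zip(a, b):
        if x in _AMBIG or y in _AMBIG:
            continue
        sites += 1
        if x == y:
            continue
        both_pur = x in _PURINES and y in _PURINES
        both_pyr = x in _PYRIMIDINES and y in _PYRIMIDINES
        if both_pur or both_pyr:
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / sites, tv / sites
    w1, w2 = 1.0 - 2 * P - Q, 1.0 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("K2P distance saturated")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(aln: SequenceAlignment) -> np.ndarray:
    n = aln.n
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = k2p_distance(aln.sequences[i], aln.sequences[j])
    return D


# ---------------------------------------------------------------------------
# Neutrality tests


def tajimas_d(aln: SequenceAlignment) -> float:
    """Tajima (1989) D. NaN when there is no segregating site."""
    n = aln.n
    if n < 2:
        return math.nan
    M = _seq_bytes(aln)
    s = _seg_sites(M)
    if s == 0:
        return math.nan
    D = pairwise_differences(aln)
    iu = np.triu_indices(n, 1)
    pi_seq = float(D[iu].mean())
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:  # degenerate (e.g. n = 2, where the variance vanishes)
        return math.nan
    return (pi_seq - s / a1) / math.sqrt(var)


def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |S(n, k)|, k=0..n.

    Recurrence |S(n,k)| = |S(n-1,k-1)| + (n-1)|S(n-1,k)| carried in log
    space for overflow safety at large n.
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        coef = math.log(m - 1) if m > 1 else -np.inf
        with np.errstate(invalid="ignore"):
            new[1:m + 1] = np.logaddexp(row[0:m], coef + row[1:m + 1])
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) under the Ewens sampling distribution,
    for k = 0..n (k=0 has probability zero)."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ls = _log_stirling_row(n)
    lt = math.log(theta)
    log_rising = sum(math.log(theta + i) for i in range(n))
    k = np.arange(n + 1)
    return ls + k * lt - log_rising


def fus_fs(aln: SequenceAlignment) -> float:
    """Fu (1997) Fs using theta-hat = mean pairwise differences.

    Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta, n) from the
    Ewens sampling distribution.  Returns -inf/+inf when S' hits 1 or 0
    numerically, NaN when the mean pairwise difference is 0.
    """
    n = aln.n
    M = _seq_bytes(aln)
    iu = np.triu_indices(n, 1)
    d = float(pairwise_differences(aln)[iu].mean()) if n >= 2 else 0.0
    if d <= 0:
        return math.nan
    k_obs = len({bytes(r) for r in M})
    logp = ewens_log_pmf(n, d)
    from scipy.special import logsumexp

    s_prime = float(np.exp(logsumexp(logp[k_obs:])))
    s_prime = min(max(s_prime, 0.0), 1.0)
    if s_prime >= 1.0:
        return math.inf
    if s_prime <= 0.0:
        return -math.inf
    return math.log(s_prime / (1.0 - s_prime))


def neutrality(aln: SequenceAlignment) -> NeutralitySummary:
    return NeutralitySummary(tajimas_d(aln), fus_fs(aln))


# ---------------------------------------------------------------------------
# Population differentiation: sequences (AMOVA Phi_ST)


def _amova_phist(D2: np.ndarray, groups: np.ndarray) -> float:
    """Phi_ST from a two-level AMOVA on a squared-distance matrix."""
    N = len(groups)
    labels, counts = np.unique(groups, return_counts=True)
    P = len(labels)
    iu = np.triu_indices(N, 1)
    ssd_total = float(D2[iu].sum()) / N
    ssd_wp = 0.0
    for g, ng in zip(labels, counts):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 2:
            continue
        sub = D2[np.ix_(idx, idx)]
        ssd_wp += float(sub[np.triu_indices(len(idx), 1)].sum()) / ng
    df_ap = P - 1
    df_wp = N - P
    sigma_w = ssd_wp / df_wp if df_wp > 0 else 0.0
    msd_ap = (ssd_total - ssd_wp) / df_ap
    n_prime = (N - float((counts**2).sum()) / N) / df_ap
    sigma_a = (msd_ap - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    return sigma_a / denom if denom != 0 else 0.0


def phist_matrix(
    aln: SequenceAlignment,
    distance: str = "k2p",
    n_permutations: int = 0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise Phi_ST between populations from AMOVA on squared
    genetic distances.

    ``distance`` is ``"k2p"`` or ``"diff"`` (raw difference counts).
    Negative estimates are reported as computed (not truncated).  With
    ``n_permutations`` > 0, permutation p-values (random reassignment
    of individuals to the two populations) are also returned.
    """
    pops = aln.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    D = k2p_matrix(aln) if distance == "k2p" else pairwise_differences(aln)
    D2 = D**2
    labels = np.asarray(aln.pop_labels)
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops) if n_permutations else None
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(pops, 2):
        idx = np.flatnonzero((labels == a) | (labels == b))
        sub = D2[np.ix_(idx, idx)]
        grp = labels[idx]
        obs = _amova_phist(sub, grp)
        out.loc[a, b] = out.loc[b, a] = obs
        if n_permutations:
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(grp)
                if _amova_phist(sub, perm) >= obs:
                    hits += 1
            p = (hits + 1) / (n_permutations + 1)
            pvals.loc[a, b] = pvals.loc[b, a] = p
    return out, pvals


def haplotype_fst_matrix(aln: SequenceAlignment) -> pd.DataFrame:
    """Haplotype-frequency F_ST (distances replaced by 0/1 identity).

    Exposed alongside the distance-based Phi_ST because mtDNA 'pairwise
    F_ST' can mean either; Phi_ST is the package default.
    """
    pops = aln.populations
    M = _seq_bytes(aln)
    ident = np.array([[0.0 if bytes(x) == bytes(y) else 1.0 for y in M] for x in M])
    labels = np.asarray(aln.pop_labels)
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        idx = np.flatnonzero((labels == a) | (labels == b))
        out.loc[a, b] = out.loc[b, a] = _amova_phist(
            ident[np.ix_(idx, idx)], labels[idx]
        )
    return out


# ---------------------------------------------------------------------------
# Microsatellites


def msat_summaries(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-population descriptive table: sample size, total and mean
    alleles per locus, observed and unbiased expected heterozygosity,
    and F_IS = 1 - Ho/He (NaN where He = 0)."""
    rows = []
    for pop, idx in G.group_indices().items():
        sub = G.alleles[idx]            # (m, L, 2)
        miss = (sub == 0).all(axis=2)   # (m, L)
        na_per_locus = []
        ho_per_locus = []
        he_per_locus = []
        for l in range(G.n_loci):
            a = sub[~miss[:, l], l, :]
            if a.size == 0:
                na_per_locus.append(np.nan)
                ho_per_locus.append(np.nan)
                he_per_locus.append(np.nan)
                continue
            vals, counts = np.unique(a.ravel(), return_counts=True)
            na_per_locus.append(len(vals))
            p = counts / counts.sum()
            n_ind = a.shape[0]
            he = (2 * n_ind / (2 * n_ind - 1)) * (1 - float(p @ p)) if n_ind > 0 else np.nan
            if 2 * n_ind - 1 == 0:
                he = np.nan
            he_per_locus.append(he)
            ho_per_locus.append(float((a[:, 0] != a[:, 1]).mean()))
        ho = float(np.nanmean(ho_per_locus))
        he = float(np.nanmean(he_per_locus))
        fis = 1.0 - ho / he if he > 0 else math.nan
        rows.append(
            {
                "population": pop,
                "n": len(idx),
                "Na": float(np.nansum(na_per_locus)),
                "mean_alleles_per_locus": float(np.nanmean(na_per_locus)),
                "Ho": ho,
                "He": he,
                "FIS": fis,
            }
        )
    return pd.DataFrame(rows).set_index("population")


def _wc_components(alleles_a: np.ndarray, alleles_b: np.ndarray) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) summed over
    alleles at one locus for two populations.

    Each input is an (n_i, 2) array of scored genotypes (no missing).
    """
    r = 2
    pops = [alleles_a, alleles_b]
    n_i = np.array([p.shape[0] for p in pops], dtype=float)
    if (n_i == 0).any():
        return math.nan, math.nan, math.nan
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    states = np.unique(np.concatenate([p.ravel() for p in pops]))
    A = B = C = 0.0
    for s in states:
        p_i = np.array([(p == s).mean() for p in pops])
        h_i = np.array([((p[:, 0] == s) ^ (p[:, 1] == s)).mean() for p in pops])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        if nbar > 1:
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        else:
            a = b = math.nan
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return A, B, C


def wc_fst(G: GenotypeMatrix, grouping: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Pairwise multi-locus Weir-Cockerham theta (ratio of summed
    variance components over loci); missing genotypes excluded per locus."""
    groups = G.group_indices(grouping)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 populations")
    out = pd.DataFrame(0.0, index=names, columns=names)
    miss = G.missing_mask
    for ga, gb in itertools.combinations(names, 2):
        ia, ib = groups[ga], groups[gb]
        num = den = 0.0
        any_locus = False
        for l in range(G.n_loci):
            aa = G.alleles[ia[~miss[ia, l]], l, :]
            bb = G.alleles[ib[~miss[ib, l]], l, :]
            if aa.shape[0] == 0 or bb.shape[0] == 0:
                continue
            a, b, c = _wc_components(aa, bb)
            if math.isnan(a):
                continue
            any_locus = True
            num += a
            den += a + b + c
        theta = num / den if any_locus and den != 0 else math.nan
        out.loc[ga, gb] = out.loc[gb, ga] = theta
    return out


def diversity_table(aln: SequenceAlignment) -> pd.DataFrame:
    """Per-population diversity and neutrality table (CSV-ready),
    with columns mirroring the usual report layout: N, Hs (haplotype
    count), Tajima's D, Fu's Fs, plus h, s, pi and d."""
    rows = []
    for pop, sub in aln.by_population().items():
        div = collapse_and_diversity(sub)
        rows.append(
            {
                "population": pop,
                "N": div.n,
                "Hs": div.K,
                "k_nogap": div.k,
                "h": div.h,
                "s": div.s,
                "pi": div.pi,
                "d": div.d,
                "tajimas_D": tajimas_d(sub),
                "fus_Fs": fus_fs(sub),
            }
        )
    return pd.DataFrame(rows).set_index("population")
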