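"""Exact tests: Hardy-Weinberg equilibrium, two-locus linkage
disequilibrium, haplotype tables, Bonferroni thresholds.

The HWE test is the exact conditional test: under HWE, given the observed
allele counts, every pairing of the allele pool into genotypes is equally
likely, which induces the classical conditional distribution over genotype
tables.  The p-value is the total conditional probability of tables no more
probable than the observed one.  Small tables are enumerated completely;
otherwise the null is sampled exactly by re-pairing the allele pool at
random (an iid sampler with the same stationary law as the classical
genotype-switching Markov chain, without dememorization or mixing
concerns).

LD tests: for male X haplotypes (phase known) the likelihood-ratio G
statistic on the two-locus contingency table with a permutation null; for
female diploid genotypes (phase unknown) haplotype frequencies are fitted
by EM under linkage and compared against independence by likelihood ratio,
again with a permutation null.  Permutation p-values use (b+1)/(n+1).
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .io import StrpopError, GenotypeTable, sort_alleles


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_samples: int  # Monte-Carlo replicates, permutations, or tables enumerated
    seed: int | None
    method: str
    note: str = ""


def bonferroni(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if m < 1:
        raise StrpopError("number of tests m must be >= 1")
    return alpha / m


# -- HWE exact test ---------------------------------------------------------


def _encode_genotypes(genotypes: Sequence[tuple[str, str]]):
    alleles = sort_alleles(a for g in genotypes for a in g)
    index = {a: i for i, a in enumerate(alleles)}
    pairs = np.array(
        [sorted((index[a], index[b])) for a, b in genotypes], dtype=np.int64
    )
    return pairs, len(alleles)


def _table_log_prob_variable(het: int, cell_counts: np.ndarray) -> float:
    """Variable part of log P(table | allele counts): h log 2 - sum log G!"""
    return het * math.log(2.0) - float(gammaln(cell_counts + 1.0).sum())


def _observed_stat(pairs: np.ndarray, k: int) -> float:
    het = int((pairs[:, 0] != pairs[:, 1]).sum())
    codes = pairs[:, 0] * k + pairs[:, 1]
    counts = np.bincount(codes, minlength=k * k)
    return _table_log_prob_variable(het, counts)


def _enumerate_genotype_tables(m: list[int]):
    """All symmetric genotype count tables with allele counts ``m``.

    Yields (het_count, flat cell counts of the upper triangle).
    """
    k = len(m)
    G = np.zeros((k, k), dtype=np.int64)
    rem = list(m)
    out = []

    def fill_row(i: int):
        if i == k:
            cells = G[np.triu_indices(k)]
            het = int(G.sum() - np.trace(G))
            out.append((het, cells.copy()))
            return
        ri = rem[i]
        js = list(range(i + 1, k))

        def comp(jpos: int, left: int):
            if jpos == len(js):
                if left == 0:
                    fill_row(i + 1)
                return
            j = js[jpos]
            for x in range(min(left, rem[j]) + 1):
                G[i, j] = x
                rem[j] -= x
                comp(jpos + 1, left - x)
                rem[j] += x
            G[i, j] = 0

        for gii in range(ri // 2 + 1):
            G[i, i] = gii
            comp(0, ri - 2 * gii)
        G[i, i] = 0

    fill_row(0)
    return out


def _hwe_enumerate(pairs: np.ndarray, k: int) -> tuple[float, int]:
    m = np.bincount(pairs.ravel(), minlength=k).tolist()
    obs = _observed_stat(pairs, k)
    log_probs = []
    for het, cells in _enumerate_genotype_tables(m):
        log_probs.append(het * math.log(2.0) - float(gammaln(cells + 1.0).sum()))
    log_probs = np.array(log_probs)
    # normalize within the enumeration (the constant factors cancel)
    w = np.exp(log_probs - log_probs.max())
    w /= w.sum()
    p = float(w[log_probs <= obs + 1e-9].sum())
    return min(p, 1.0), len(log_probs)


def _hwe_monte_carlo(
    pairs: np.ndarray, k: int, n_mc: int, rng: np.random.Generator
) -> tuple[float, int]:
    obs = _observed_stat(pairs, k)
    pool = pairs.ravel()
    n = len(pairs)
    # sample in batches to bound memory
    batch = max(1, min(n_mc, int(5e6 / max(pool.size, 1))))
    worse = 0
    done = 0
    while done < n_mc:
        b = min(batch, n_mc - done)
        sim = np.tile(pool, (b, 1))
        sim = rng.permuted(sim, axis=1)
        a1, a2 = sim[:, 0::2], sim[:, 1::2]
        lo = np.minimum(a1, a2)
        hi = np.maximum(a1, a2)
        het = (lo != hi).sum(axis=1)
        codes = lo * k + hi
        flat = (np.arange(b)[:, None] * (k * k) + codes).ravel()
        counts = np.bincount(flat, minlength=b * k * k).reshape(b, k * k)
        stat = het * math.log(2.0) - gammaln(counts + 1.0).sum(axis=1)
        worse += int(np.sum(stat <= obs + 1e-9))
        done += b
    return (worse + 1) / (n_mc + 1), n_mc


def hwe_exact(
    genotypes: Sequence[tuple[str, str]],
    n_mc: int = 10_000,
    seed: int = 0,
    method: str = "auto",
) -> TestResult:
    """Exact test of Hardy-Weinberg proportions at one multi-allelic locus.

    ``method``: 'enum' (complete enumeration), 'mc' (Monte-Carlo exact), or
    'auto' (enumeration for <=3 alleles and <=50 individuals).
    The statistic reported is the variable part of the observed table's
    conditional log-probability (smaller = less probable under HWE).
    """
    gts = [g for g in genotypes if len(g) == 2]
    if len(gts) < 5:
        raise StrpopError("need at least 5 diploid genotypes for the HWE test")
    pairs, k = _encode_genotypes(gts)
    if k < 2:
        return TestResult(
            statistic=0.0, p_value=1.0, n_samples=0, seed=seed,
            method="monomorphic", note="monomorphic locus: HWE test undefined, p=1",
        )
    obs = _observed_stat(pairs, k)
    if method == "auto":
        method = "enum" if (k <= 3 and len(gts) <= 50) else "mc"
    if method == "enum":
        p, n_tab = _hwe_enumerate(pairs, k)
        return TestResult(obs, p, n_tab, None, "enum")
    if method == "mc":
        rng = np.random.default_rng(seed)
        p, n = _hwe_monte_carlo(pairs, k, n_mc, rng)
        return TestResult(obs, p, n, seed, "mc")
    raise ValueError(f"unknown method {method!r}")


# -- haplotype tables (male X) ---------------------------------------------


def haplotype_frequencies(
    table: GenotypeTable, loci: tuple[str, str]
) -> dict[tuple[str, str], tuple[int, float]]:
    """Two-locus haplotype counts and frequencies from male X calls."""
    l1, l2 = loci
    counts: dict[tuple[str, str], int] = {}
    for s in table.samples:
        if s.sex != "M":
            continue
        g1 = table.calls.get((s.sample_id, l1))
        g2 = table.calls.get((s.sample_id, l2))
        if g1 is None or g2 is None or len(g1) != 1 or len(g2) != 1:
            continue
        key = (g1[0], g2[0])
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {
        key: (c, c / total)
        for key, c in sorted(counts.items())
    }


# -- LD tests ---------------------------------------------------------------


def _g_statistic(codes1: np.ndarray, codes2: np.ndarray, k1: int, k2: int) -> float:
    n = len(codes1)
    tab = np.bincount(codes1 * k2 + codes2, minlength=k1 * k2).astype(float)
    r1 = np.bincount(codes1, minlength=k1).astype(float)
    r2 = np.bincount(codes2, minlength=k2).astype(float)
    expected = np.outer(r1, r2).ravel() / n
    mask = tab > 0
    return float(2.0 * np.sum(tab[mask] * np.log(tab[mask] / expected[mask])))


def _ld_male(haps1, haps2, n_perm: int, rng: np.random.Generator) -> TestResult:
    a1 = sort_alleles(haps1)
    a2 = sort_alleles(haps2)
    i1 = {a: i for i, a in enumerate(a1)}
    i2 = {a: i for i, a in enumerate(a2)}
    c1 = np.array([i1[a] for a in haps1])
    c2 = np.array([i2[a] for a in haps2])
    obs = _g_statistic(c1, c2, len(a1), len(a2))
    worse = 0
    for _ in range(n_perm):
        perm = rng.permutation(c2)
        if _g_statistic(c1, perm, len(a1), len(a2)) >= obs - 1e-12:
            worse += 1
    return TestResult(obs, (worse + 1) / (n_perm + 1), n_perm, None, "perm_g")


def _em_haplotypes(
    g1: list[tuple[str, str]],
    g2: list[tuple[str, str]],
    max_iter: int = 200,
    tol: float = 1e-10,
):
    """EM haplotype-frequency estimation for two loci from unphased diploid
    genotypes.  Returns (haplotype freq dict, log-likelihood under linkage,
    log-likelihood under independence)."""
    a1 = sort_alleles(a for g in g1 for a in g)
    a2 = sort_alleles(a for g in g2 for a in g)
    i1 = {a: i for i, a in enumerate(a1)}
    i2 = {a: i for i, a in enumerate(a2)}
    k1, k2 = len(a1), len(a2)
    n = len(g1)

    combos: dict[tuple, int] = {}
    for ga, gb in zip(g1, g2):
        key = (tuple(sorted(ga)), tuple(sorted(gb)))
        combos[key] = combos.get(key, 0) + 1

    # resolutions: for genotype ({a,b},{c,d}) the phase sets {(a,c),(b,d)}
    # and {(a,d),(b,c)} (identical when either locus is homozygous)
    resolutions = []
    for (ga, gb), cnt in combos.items():
        a, b = i1[ga[0]], i1[ga[1]]
        c, d = i2[gb[0]], i2[gb[1]]
        pairs = {tuple(sorted(((a, c), (b, d)))), tuple(sorted(((a, d), (b, c))))}
        resolutions.append((cnt, sorted(pairs)))

    # allele frequencies -> independence haplotype frequencies
    f1 = np.zeros(k1)
    f2 = np.zeros(k2)
    for ga, gb in zip(g1, g2):
        for a in ga:
            f1[i1[a]] += 1
        for b in gb:
            f2[i2[b]] += 1
    f1 /= f1.sum()
    f2 /= f2.sum()
    h0 = np.outer(f1, f2)

    def loglik(h) -> float:
        ll = 0.0
        for cnt, res in resolutions:
            p = 0.0
            for (x, y) in res:
                px = h[x[0], x[1]] * h[y[0], y[1]]
                p += px if x == y else 2.0 * px
            ll += cnt * math.log(max(p, 1e-300))
        return ll

    h = h0.copy()
    prev = -np.inf
    for _ in range(max_iter):
        new = np.zeros_like(h)
        for cnt, res in resolutions:
            ps = []
            for (x, y) in res:
                px = h[x[0], x[1]] * h[y[0], y[1]]
                ps.append(px if x == y else 2.0 * px)
            tot = sum(ps)
            if tot <= 0:
                continue
            for (x, y), p in zip(res, ps):
                w = cnt * p / tot
                new[x[0], x[1]] += w
                new[y[0], y[1]] += w
        h = new / (2.0 * n)
        ll = loglik(h)
        if ll - prev < tol:
            break
        prev = ll
    hap_freqs = {
        (a1[i], a2[j]): float(h[i, j])
        for i in range(k1)
        for j in range(k2)
        if h[i, j] > 0
    }
    return hap_freqs, loglik(h), loglik(h0)


def _ld_female(g1, g2, n_perm: int, rng: np.random.Generator) -> TestResult:
    _, l_full, l_null = _em_haplotypes(g1, g2)
    obs = 2.0 * (l_full - l_null)
    idx = np.arange(len(g2))
    worse = 0
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        g2p = [g2[i] for i in perm]
        _, lf, ln = _em_haplotypes(g1, g2p)
        if 2.0 * (lf - ln) >= obs - 1e-12:
            worse += 1
    return TestResult(obs, (worse + 1) / (n_perm + 1), n_perm, None, "perm_em_lr")


def ld_test(
    calls1: Sequence[tuple[str, ...]],
    calls2: Sequence[tuple[str, ...]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Two-locus LD test on paired calls from the same individuals.

    Single-allele calls at both loci (male X) run the haplotypic G-test;
    diploid calls at both loci run the EM likelihood-ratio test.  Both use
    a permutation null that shuffles the second locus across individuals.
    """
    if n_perm < 100:
        raise StrpopError("n_perm must be at least 100")
    if len(calls1) != len(calls2):
        raise StrpopError("both loci must be typed in the same individuals")
    pairs = [(g1, g2) for g1, g2 in zip(calls1, calls2) if g1 and g2]
    if not pairs:
        raise StrpopError("no individuals typed at both loci")
    lens = {(len(g1), len(g2)) for g1, g2 in pairs}
    rng = np.random.default_rng(seed)
    res: TestResult
    if lens == {(1, 1)}:
        res = _ld_male([g[0][0] for g in pairs], [g[1][0] for g in pairs], n_perm, rng)
    elif lens == {(2, 2)}:
        res = _ld_female([g[0] for g in pairs], [g[1] for g in pairs], n_perm, rng)
    else:
        raise StrpopError(
            "mixed haploid/diploid calls: run males and females separately"
        )
    res.seed = seed
    return res


def em_haplotype_frequencies(
    g1: Sequence[tuple[str, str]], g2: Sequence[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Maximum-likelihood two-locus haplotype frequencies (EM) from unphased
    diploid genotypes."""
    freqs, _, _ = _em_haplotypes(list(g1), list(g2))
    return freqs


def ld_test_all_pairs(
    table: GenotypeTable,
    loci: Sequence[str],
    sex: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], TestResult]:
    """LD tests for every pair of the given loci, on one sex's calls."""
    out = {}
    for a, b in itertools.combinations(loci, 2):
        ids = [
            s.sample_id
            for s in table.samples
            if s.sex == sex
            and (s.sample_id, a) in table.calls
            and (s.sample_id, b) in table.calls
        ]
        calls1 = [table.calls[(i, a)] for i in ids]
        calls2 = [table.calls[(i, b)] for i in ids]
        pair_seed = (seed * 1_000_003 + zlib.crc32(f"{a}|{b}".encode())) % 2**31
        out[(a, b)] = ld_test(calls1, calls2, n_perm=n_perm, seed=pair_seed)
    return out
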