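"""Per-locus and combined forensic parameters for autosomal and X STRs.

Conventions follow the ones forensic STR reports use:

* He is the unbiased expected heterozygosity n/(n-1) * (1 - sum p_i^2) with
  n the number of sampled allele copies.
* PE and TPI are the Brenner-style functions of the observed heterozygote
  fraction h (H = 1 - h): PE = h^2 (1 - 2 h H^2), TPI = 1/(2H).
* MP/PD default to observed-genotype mode (sum of squared observed genotype
  proportions); an expected (HWE) mode is available.
* The mean exclusion chance (MEC) family is defined operationally by an
  exact pedigree-enumeration engine; the published closed forms are
  verified against it and used as fast equivalents.

Power sums a_k = sum_i p_i^k carry all the frequency information these
formulas need.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GenotypeTable, LocusFrequencies, StrpopError

AUTOSOMAL_TRIO = "autosomal_trio"
X_TRIO_DAUGHTER = "x_trio_daughter"
X_DUO_FATHER_DAUGHTER = "x_duo_father_daughter"

MEC_SCENARIOS = (AUTOSOMAL_TRIO, X_TRIO_DAUGHTER, X_DUO_FATHER_DAUGHTER)

_ENUM_MAX_ALLELES = 60


def _freq_array(freqs) -> np.ndarray:
    if isinstance(freqs, LocusFrequencies):
        p = np.array(list(freqs.freqs.values()), dtype=float)
    elif isinstance(freqs, Mapping):
        p = np.array(list(freqs.values()), dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
    if p.size == 0 or abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise StrpopError("frequency vector must be non-negative and sum to 1")
    return p


def power_sums(freqs, ks: Sequence[int] = (2, 3, 4, 5)) -> dict[int, float]:
    """a_k = sum_i p_i^k."""
    p = _freq_array(freqs)
    return {k: float(np.sum(p**k)) for k in ks}


@dataclass
class LocusForensicStats:
    locus: str
    n_alleles_sampled: int
    n_genotypes: int
    Ho: float
    He: float
    PIC: float
    MP: float
    PD: float
    PE: float
    TPI: float
    power_sums: dict[int, float]


@dataclass
class XLocusForensicStats:
    locus: str
    n_alleles_sampled: int
    gene_diversity_HD: float
    PIC: float
    PD_male: float
    PD_female: float
    MEC_autosomal_trio: float
    MEC_x_trio_daughter: float
    MEC_x_duo: float


@dataclass
class CombinedStats:
    """Multi-locus combinations: CPM is the product of per-locus MP,
    CPD = 1 - CPM, and exclusion-type powers combine as one minus the
    product of complements."""

    n_loci: int
    CPM: float
    CPD: float
    CPE: float


@dataclass
class CombinedXStats:
    n_loci: int
    CPD_male: float
    CPD_female: float
    CMEC_autosomal_trio: float
    CMEC_x_trio_daughter: float
    CMEC_x_duo: float


# -- per-locus building blocks --------------------------------------------


def heterozygosities(genotypes: Sequence[tuple[str, str]]) -> tuple[float, float]:
    """(Ho, He) from diploid genotypes at one locus.

    He carries the unbiased n/(n-1) correction on the number of sampled
    allele copies n = 2 * (number of genotypes).
    """
    gts = [g for g in genotypes if len(g) == 2]
    if len(gts) < 2:
        raise StrpopError("need at least 2 diploid genotypes")
    ho = sum(1 for a, b in gts if a != b) / len(gts)
    counts: dict[str, int] = {}
    for g in gts:
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    n = 2 * len(gts)
    a2 = sum((c / n) ** 2 for c in counts.values())
    he = n / (n - 1) * (1.0 - a2)
    return ho, he


def pic(freqs) -> float:
    """Polymorphism information content, 1 - a2 - a2^2 + a4."""
    a = power_sums(freqs, (2, 4))
    return 1.0 - a[2] - a[2] ** 2 + a[4]


def match_and_discrimination(
    data, mode: str = "observed"
) -> tuple[float, float]:
    """(MP, PD) at one locus.

    observed mode: ``data`` is a sequence of diploid genotypes, MP is the
    sum of squared observed genotype proportions.  expected mode: ``data``
    is a frequency vector, MP sums squared HWE genotype probabilities.
    PD = 1 - MP either way.
    """
    if mode == "observed":
        gts = [tuple(sorted(g)) for g in data if len(g) == 2]
        if not gts:
            raise StrpopError("need at least 1 diploid genotype")
        counts: dict[tuple, int] = {}
        for g in gts:
            counts[g] = counts.get(g, 0) + 1
        mp = sum((c / len(gts)) ** 2 for c in counts.values())
    elif mode == "expected":
        p = _freq_array(data)
        probs = []
        for i in range(len(p)):
            probs.append(p[i] ** 2)
            for j in range(i + 1, len(p)):
                probs.append(2 * p[i] * p[j])
        mp = float(np.sum(np.array(probs) ** 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return mp, 1.0 - mp


def exclusion_and_tpi(genotypes: Sequence[tuple[str, str]]) -> tuple[float, float]:
    """(PE, TPI) from the observed heterozygote fraction.

    At Ho = 1 the homozygote fraction is 0 and TPI is reported as +inf
    with a warning.
    """
    gts = [g for g in genotypes if len(g) == 2]
    if not gts:
        raise StrpopError("need at least 1 diploid genotype")
    h = sum(1 for a, b in gts if a != b) / len(gts)
    H = 1.0 - h
    pe = h * h * (1.0 - 2.0 * h * H * H)
    if H == 0.0:
        warnings.warn("all genotypes heterozygous: TPI is infinite")
        return pe, math.inf
    return pe, 1.0 / (2.0 * H)


def x_discrimination(freqs, n_alleles_sampled: int | None = None):
    """(PD_male, PD_female, gene diversity HD) for an X locus.

    PD_male = 1 - a2 (hemizygous match probability); PD_female =
    1 - 2 a2^2 + a4, which equals one minus the sum of squared HWE genotype
    probabilities.  HD applies the unbiased correction when a sample size
    is supplied, otherwise equals 1 - a2.
    """
    a = power_sums(freqs, (2, 4))
    pd_m = 1.0 - a[2]
    pd_f = 1.0 - 2.0 * a[2] ** 2 + a[4]
    if n_alleles_sampled is not None and n_alleles_sampled > 1:
        hd = n_alleles_sampled / (n_alleles_sampled - 1) * (1.0 - a[2])
    else:
        hd = 1.0 - a[2]
    return pd_m, pd_f, hd


# -- mean exclusion chance: enumeration engine + closed forms --------------


def mec_enumerate(freqs, scenario: str) -> float:
    """Exact mean exclusion chance by enumeration over pedigree genotype
    configurations weighted by HWE/random-mating probabilities.

    x_duo_father_daughter: the daughter's genotype alone constrains the
    alleged father's single X allele; he is excluded iff it matches
    neither daughter allele.

    x_trio_daughter: mother and daughter genotypes determine the set of
    alleles the true father could have passed; an alleged father (one X
    allele) is excluded iff his allele is outside that set.

    autosomal_trio: mother and child determine the obligate paternal
    allele set; a random diploid man is excluded iff neither of his
    alleles is in the set.
    """
    p = _freq_array(freqs)
    k = len(p)
    if k > _ENUM_MAX_ALLELES:
        raise StrpopError(
            f"{k} alleles exceeds the enumeration limit ({_ENUM_MAX_ALLELES}); "
            "use mec_closed_form"
        )
    if scenario == X_DUO_FATHER_DAUGHTER:
        # daughter {a,b} under HWE; random man's allele c excluded iff c not in {a,b}
        total = 0.0
        for a in range(k):
            total += p[a] ** 2 * (1.0 - p[a])
            for b in range(a + 1, k):
                total += 2 * p[a] * p[b] * (1.0 - p[a] - p[b])
        return total
    if scenario == X_TRIO_DAUGHTER:
        return _mec_x_trio(p)
    if scenario == AUTOSOMAL_TRIO:
        return _mec_autosomal_trio(p)
    raise ValueError(f"unknown scenario {scenario!r}")


def _paternal_allele_set(mother: tuple[int, int], child: tuple[int, int]) -> set[int]:
    """Child alleles that the father could have contributed, given that the
    other child allele must have come from the mother."""
    out = set()
    for i, cand in enumerate(child):
        other = child[1 - i]
        if other in mother:
            out.add(cand)
    return out


def _mec_x_trio(p: np.ndarray) -> float:
    k = len(p)
    total = 0.0
    for m1 in range(k):
        for m2 in range(m1, k):
            pm = p[m1] ** 2 if m1 == m2 else 2 * p[m1] * p[m2]
            # maternal transmitted allele: each of the two (uniform)
            for mt, w_mt in ((m1, 0.5), (m2, 0.5)):
                for f in range(k):  # true father's X allele
                    daughter = (mt, f)
                    S = _paternal_allele_set((m1, m2), daughter)
                    excl = 1.0 - sum(p[c] for c in S)
                    total += pm * w_mt * p[f] * excl
    return total


def _mec_autosomal_trio(p: np.ndarray) -> float:
    k = len(p)
    total = 0.0
    for m1 in range(k):
        for m2 in range(m1, k):
            pm = p[m1] ** 2 if m1 == m2 else 2 * p[m1] * p[m2]
            for mt, w_mt in ((m1, 0.5), (m2, 0.5)):
                for f in range(k):  # paternal transmitted allele
                    child = (mt, f)
                    S = _paternal_allele_set((m1, m2), child)
                    ps = sum(p[c] for c in S)
                    # random man {x,y}: excluded iff neither allele in S
                    total += pm * w_mt * p[f] * (1.0 - ps) ** 2
    return total


def mec_closed_form(freqs, scenario: str) -> float:
    """Closed-form mean exclusion chances in the power sums a_k.

    Equal to :func:`mec_enumerate` to within numerical round-off; the
    enumeration engine is the definitional authority.
    """
    a = power_sums(freqs, (2, 3, 4, 5))
    if scenario == X_DUO_FATHER_DAUGHTER:
        return 1.0 - 2.0 * a[2] + a[3]
    if scenario == X_TRIO_DAUGHTER:
        return 1.0 - a[2] - a[2] ** 2 + a[4]
    if scenario == AUTOSOMAL_TRIO:
        return (
            1.0
            - 2.0 * a[2]
            + a[3]
            + 3.0 * a[2] * a[3]
            - 3.0 * a[5]
            - 2.0 * a[2] ** 2
            + 2.0 * a[4]
        )
    raise ValueError(f"unknown scenario {scenario!r}")


# -- table-level drivers ---------------------------------------------------


def locus_stats(table: GenotypeTable, locus: str) -> LocusForensicStats:
    """All autosomal forensic parameters at one locus (diploid calls)."""
    gts = table.diploid_genotypes_at(locus)
    if len(gts) < 2:
        raise StrpopError(f"locus {locus}: need at least 2 diploid genotypes")
    ho, he = heterozygosities(gts)
    counts: dict[str, int] = {}
    for g in gts:
        for al in g:
            counts[al] = counts.get(al, 0) + 1
    n = 2 * len(gts)
    p = np.array([c / n for c in counts.values()])
    a = power_sums(p)
    mp, pd = match_and_discrimination(gts, mode="observed")
    pe, tpi = exclusion_and_tpi(gts)
    return LocusForensicStats(
        locus=locus,
        n_alleles_sampled=n,
        n_genotypes=len(gts),
        Ho=ho,
        He=he,
        PIC=pic(p),
        MP=mp,
        PD=pd,
        PE=pe,
        TPI=tpi,
        power_sums=a,
    )


def x_locus_stats(table: GenotypeTable, locus: str) -> XLocusForensicStats:
    """X-STR parameters from pooled allele frequencies (males 1 copy,
    females 2)."""
    counts = table.allele_counts(locus, sex_mode="pooled")
    n = sum(counts.values())
    if n == 0:
        raise StrpopError(f"locus {locus}: no typed samples")
    p = np.array([c / n for c in counts.values()])
    pd_m, pd_f, hd = x_discrimination(p, n_alleles_sampled=n)
    return XLocusForensicStats(
        locus=locus,
        n_alleles_sampled=n,
        gene_diversity_HD=hd,
        PIC=pic(p),
        PD_male=pd_m,
        PD_female=pd_f,
        MEC_autosomal_trio=mec_closed_form(p, AUTOSOMAL_TRIO),
        MEC_x_trio_daughter=mec_closed_form(p, X_TRIO_DAUGHTER),
        MEC_x_duo=mec_closed_form(p, X_DUO_FATHER_DAUGHTER),
    )


def combine(stats: Iterable[LocusForensicStats]) -> CombinedStats:
    stats = list(stats)
    if not stats:
        raise StrpopError("need at least 1 locus")
    cpm = 1.0
    cpe_comp = 1.0
    for s in stats:
        cpm *= s.MP
        cpe_comp *= 1.0 - s.PE
    return CombinedStats(
        n_loci=len(stats), CPM=cpm, CPD=1.0 - cpm, CPE=1.0 - cpe_comp
    )


def combine_x(stats: Iterable[XLocusForensicStats]) -> CombinedXStats:
    stats = list(stats)
    if not stats:
        raise StrpopError("need at least 1 locus")
    prod = {
        "pdm": 1.0,
        "pdf": 1.0,
        "trio_a": 1.0,
        "trio_x": 1.0,
        "duo": 1.0,
    }
    for s in stats:
        prod["pdm"] *= 1.0 - s.PD_male
        prod["pdf"] *= 1.0 - s.PD_female
        prod["trio_a"] *= 1.0 - s.MEC_autosomal_trio
        prod["trio_x"] *= 1.0 - s.MEC_x_trio_daughter
        prod["duo"] *= 1.0 - s.MEC_x_duo
    return CombinedXStats(
        n_loci=len(stats),
        CPD_male=1.0 - prod["pdm"],
        CPD_female=1.0 - prod["pdf"],
        CMEC_autosomal_trio=1.0 - prod["trio_a"],
        CMEC_x_trio_daughter=1.0 - prod["trio_x"],
        CMEC_x_duo=1.0 - prod["duo"],
    )
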