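"""Theta-corrected random match probabilities and the d-statistic audit.

The per-locus random match probability (RMP) uses the Balding-Nichols
subpopulation correction with coancestry parameter F (theta):

    homozygote AA:   [2F + (1-F)p_A][3F + (1-F)p_A] / [(1+F)(1+2F)]
    heterozygote AB: 2[F + (1-F)p_A][F + (1-F)p_B] / [(1+F)(1+2F)]

At F = 0 these reduce to the product-rule p_A^2 and 2 p_A p_B.  A profile's
RMP is the product over its typed panel loci.

The audit compares, per individual, the RMP computed from a cognate
(own-population) database against the RMP from a non-cognate database via

    d = log10(RMP_cognate / RMP_noncognate)

so that d > 0 flags an overstatement of the weight of evidence by the
non-cognate reference.  The cognate side is computed at F = 0 by default
(no subpopulation correction is needed against one's own database); the
non-cognate side is computed at each F in the requested list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import AlleleFrequencyTable, GenotypeTable, StrpopError

logger = logging.getLogger(__name__)


class UnseenAlleleError(StrpopError):
    pass


@dataclass
class RmpResult:
    sample_id: str
    per_locus: dict[str, float]
    total: float
    database: str
    F: float


@dataclass
class DStatReport:
    """Distribution summary of per-sample d values at one correction F.

    ``proportions`` maps threshold -> percent of samples with d strictly
    above it; they are non-increasing in the threshold.
    """

    F: float
    d_values: dict[str, float]
    thresholds: tuple[float, ...]
    proportions: dict[float, float]
    mean_d: float
    sd_d: float
    n: int
    note: str = ""


def rmp_locus(
    genotype: Sequence[str],
    freqs,
    F: float,
    rare_allele_floor: float | None = None,
) -> float:
    """Theta-corrected single-locus RMP for a diploid genotype.

    ``freqs`` is a LocusFrequencies entry or a plain allele -> frequency
    mapping.  With ``rare_allele_floor`` set, alleles missing from (or at
    zero frequency in) the database take that floor frequency instead of
    raising :class:`UnseenAlleleError`.
    """
    if not (0.0 <= F < 1.0):
        raise StrpopError(f"F must be in [0, 1), got {F}")
    if len(genotype) != 2:
        raise StrpopError("RMP is defined for diploid genotypes")
    fmap = freqs.freqs if hasattr(freqs, "freqs") else dict(freqs)

    def freq_of(allele: str) -> float:
        p = fmap.get(allele, 0.0)
        if p <= 0.0:
            if rare_allele_floor is not None:
                logger.info("allele %s not in database; using floor %g", allele, rare_allele_floor)
                return rare_allele_floor
            raise UnseenAlleleError(f"allele {allele!r} absent from database")
        return p

    a, b = genotype
    denom = (1.0 + F) * (1.0 + 2.0 * F)
    if a == b:
        pa = freq_of(a)
        return (2.0 * F + (1.0 - F) * pa) * (3.0 * F + (1.0 - F) * pa) / denom
    pa, pb = freq_of(a), freq_of(b)
    return 2.0 * (F + (1.0 - F) * pa) * (F + (1.0 - F) * pb) / denom


def rmp_profile(
    profile: dict[str, tuple[str, ...]],
    freq_db: AlleleFrequencyTable,
    F: float,
    panel_loci: Sequence[str],
    rare_allele_floor: float | None = None,
    database: str = "",
    sample_id: str = "",
) -> RmpResult:
    """Product of per-locus RMPs over the typed panel loci of one profile.

    Loci the profile lacks, or the database does not cover, are skipped
    with a log entry; having no usable locus is an error.
    """
    per_locus: dict[str, float] = {}
    for locus in panel_loci:
        g = profile.get(locus)
        if g is None or len(g) != 2:
            logger.info("sample %s: locus %s untyped; skipped", sample_id, locus)
            continue
        if locus not in freq_db:
            logger.info("database lacks locus %s; skipped", locus)
            continue
        per_locus[locus] = rmp_locus(g, freq_db[locus], F, rare_allele_floor)
    if not per_locus:
        raise StrpopError(f"sample {sample_id}: no usable loci for RMP")
    total = math.prod(per_locus.values())
    return RmpResult(sample_id, per_locus, total, database, F)


def filter_unseen(
    profiles: GenotypeTable,
    reference: AlleleFrequencyTable,
    panel_loci: Sequence[str] | None = None,
) -> tuple[GenotypeTable, dict[str, list[tuple[str, str]]]]:
    """Split a cohort into profiles fully covered by a reference database
    and profiles carrying alleles the database has never seen.

    Returns (kept table, removed: sample_id -> list of (locus, allele)).
    """
    loci = list(panel_loci) if panel_loci is not None else [
        l.name for l in profiles.panel if l.name in reference.loci
    ]
    removed: dict[str, list[tuple[str, str]]] = {}
    for s in profiles.samples:
        hits = []
        for locus in loci:
            g = profiles.calls.get((s.sample_id, locus))
            if g is None or locus not in reference:
                continue
            fmap = reference[locus].freqs
            for a in g:
                if fmap.get(a, 0.0) <= 0.0:
                    hits.append((locus, a))
        if hits:
            removed[s.sample_id] = hits
    kept_ids = [s.sample_id for s in profiles.samples if s.sample_id not in removed]
    return profiles.subset(sample_ids=kept_ids), removed


def d_statistic(rmp_cognate: float, rmp_noncognate: float) -> float:
    """d = log10(RMP_cognate / RMP_noncognate); d > 0 means the non-cognate
    database overstates the weight of the evidence."""
    if rmp_cognate <= 0 or rmp_noncognate <= 0:
        raise StrpopError("RMPs must be positive")
    return math.log10(rmp_cognate / rmp_noncognate)


DEFAULT_THRESHOLDS = (0.0, 0.5, 1.0, 2.0)


def d_summary(
    d_values: dict[str, float] | Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    F: float = float("nan"),
) -> DStatReport:
    """Threshold-exceedance proportions (percent), mean, and sample SD of
    the d values.  With a single value the SD is undefined and reported as
    0 with a note."""
    if isinstance(d_values, dict):
        dmap = dict(d_values)
    else:
        dmap = {str(i): float(v) for i, v in enumerate(d_values)}
    if not dmap:
        raise StrpopError("need at least one d value")
    vals = np.array(list(dmap.values()), dtype=float)
    thresholds = tuple(sorted(thresholds))
    props = {t: float(100.0 * np.mean(vals > t)) for t in thresholds}
    note = ""
    if len(vals) > 1:
        sd = float(np.std(vals, ddof=1))
    else:
        sd = 0.0
        note = "single d value: SD undefined, reported as 0"
    return DStatReport(
        F=F,
        d_values=dmap,
        thresholds=thresholds,
        proportions=props,
        mean_d=float(vals.mean()),
        sd_d=sd,
        n=len(vals),
        note=note,
    )


def audit(
    cohort: GenotypeTable,
    cognate_db: AlleleFrequencyTable,
    noncognate_db: AlleleFrequencyTable,
    F_list: Sequence[float],
    panel_loci: Sequence[str] | None = None,
    cognate_F: float = 0.0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    filter_cohort: bool = True,
) -> list[DStatReport]:
    """The cognate vs non-cognate RMP audit.

    For each F in ``F_list``: per-sample RMPs are computed with the cognate
    database at ``cognate_F`` (default 0) and with the non-cognate database
    at F; d = log10(cognate/non-cognate) is summarized over the cohort.
    Profiles carrying alleles unseen by the non-cognate database are removed
    first (unless ``filter_cohort`` is False).
    """
    if panel_loci is None:
        panel_loci = [
            l.name
            for l in cohort.panel
            if not l.is_x and l.name in cognate_db.loci and l.name in noncognate_db.loci
        ]
    if filter_cohort:
        cohort, removed = filter_unseen(cohort, noncognate_db, panel_loci)
        if removed:
            logger.info(
                "removed %d profiles with alleles unseen by the non-cognate database",
                len(removed),
            )
        cohort2, removed2 = filter_unseen(cohort, cognate_db, panel_loci)
        if removed2:
            logger.info(
                "removed %d further profiles with alleles unseen by the cognate database",
                len(removed2),
            )
        cohort = cohort2
    profiles = {
        s.sample_id: {
            locus: cohort.calls[(s.sample_id, locus)]
            for locus in panel_loci
            if (s.sample_id, locus) in cohort.calls
        }
        for s in cohort.samples
    }
    cognate_rmp = {
        sid: rmp_profile(prof, cognate_db, cognate_F, panel_loci,
                         database="cognate", sample_id=sid).total
        for sid, prof in profiles.items()
    }
    reports = []
    for F in F_list:
        d_vals = {}
        for sid, prof in profiles.items():
            non = rmp_profile(prof, noncognate_db, F, panel_loci,
                              database="noncognate", sample_id=sid).total
            d_vals[sid] = d_statistic(cognate_rmp[sid], non)
        reports.append(d_summary(d_vals, thresholds=thresholds, F=F))
    return reports
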