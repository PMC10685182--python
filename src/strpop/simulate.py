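"""Simulation of structured STR populations.

Subpopulation allele frequencies follow the Balding-Nichols model: given an
ancestral frequency vector p and a divergence parameter F (theta), the
subpopulation vector q is one Dirichlet draw with concentrations
alpha_i = p_i (1-F)/F, so E[q_i] = p_i and Var[q_i] = F p_i (1-p_i).  This
is exactly the model under which the theta-corrected match-probability
formulas hold, which makes the downstream RMP audit self-consistent.

Within a subpopulation genotypes are drawn under Hardy-Weinberg
equilibrium: two independent allele draws per diploid individual (autosomes
and female X), one draw per male X.  One frequency draw is shared by all
individuals of a (subpopulation, locus) pair - the model captures drift,
not family structure or inbreeding within individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    AUTOSOMAL,
    X,
    AlleleFrequencyTable,
    GenotypeTable,
    LocusDef,
    Sample,
    StrpopError,
    allele_key,
    sort_alleles,
)

# 21 autosomal loci used for the RMP audit panel, plus the 19 X-STR loci of
# a linkage-free X kit; allele-count spans at X loci run from 5 to 22.
AUTOSOMAL_LOCI = (
    "CSF1PO", "D10S1248", "D12S391", "D13S317", "D16S539", "D18S51",
    "D19S433", "D21S11", "D2S1338", "D2S441", "D3S1358", "D5S818",
    "D6S1043", "D7S820", "D8S1179", "FGA", "PentaD", "PentaE", "TH01",
    "TPOX", "vWA",
)
X_LOCI = (
    "DXS6795", "DXS6803", "DXS6807", "DXS9907", "DXS7423", "GATA172D05",
    "DXS101", "DXS9902", "DXS7133", "DXS6810", "GATA31E08", "DXS6800",
    "DXS981", "DXS10162", "DXS6809", "GATA165B12", "DXS10079", "DXS10135",
    "HPRTB",
)


@dataclass
class PopulationModel:
    """Ancestral frequencies plus per-subpopulation divergence and sizes.

    ``subpop_F`` maps subpopulation name -> F (0 <= F < 1); ``sex_counts``
    maps subpopulation name -> (n_male, n_female).
    """

    panel: list[LocusDef]
    ancestral_freqs: dict[str, dict[str, float]]
    subpop_F: dict[str, float]
    sex_counts: dict[str, tuple[int, int]]
    seed: int = 0

    def __post_init__(self):
        for locus, freqs in self.ancestral_freqs.items():
            s = sum(freqs.values())
            if abs(s - 1.0) > 1e-9:
                raise StrpopError(f"ancestral frequencies at {locus} sum to {s}")
        for name, F in self.subpop_F.items():
            if not (0.0 <= F < 1.0):
                raise StrpopError(f"subpopulation {name}: F must be in [0, 1)")
            nm, nf = self.sex_counts[name]
            if nm < 0 or nf < 0:
                raise StrpopError(f"subpopulation {name}: negative sex counts")

    @property
    def subpop_names(self) -> list[str]:
        return list(self.subpop_F)


def draw_subpop_frequencies(
    ancestral: np.ndarray, F: float, rng: np.random.Generator | int
) -> np.ndarray:
    """One Balding-Nichols frequency draw.

    Alleles with ancestral frequency 0 keep frequency 0 (a Dirichlet
    concentration of 0 is undefined, and an allele absent ancestrally
    cannot drift into existence under this model).
    """
    if not (0.0 <= F < 1.0):
        raise StrpopError(f"F must be in [0, 1), got {F}")
    p = np.asarray(ancestral, dtype=float)
    if F < 1e-12:
        return p.copy()
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    q = np.zeros_like(p)
    nz = p > 0
    q[nz] = rng.dirichlet(p[nz] * (1.0 - F) / F)
    return q


def simulate_population(model: PopulationModel) -> GenotypeTable:
    """Draw a genotype table from a :class:`PopulationModel`.

    Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    samples: list[Sample] = []
    calls: dict[tuple[str, str], tuple[str, ...]] = {}
    for pop in model.subpop_names:
        F = model.subpop_F[pop]
        n_male, n_female = model.sex_counts[pop]
        pop_samples = [
            Sample(f"{pop}_M{i:04d}", "M", pop) for i in range(n_male)
        ] + [Sample(f"{pop}_F{i:04d}", "F", pop) for i in range(n_female)]
        samples.extend(pop_samples)
        for locus in model.panel:
            anc = model.ancestral_freqs[locus.name]
            labels = sort_alleles(anc)
            p = np.array([anc[a] for a in labels])
            q = draw_subpop_frequencies(p, F, rng)
            for s in pop_samples:
                k = 1 if (locus.is_x and s.sex == "M") else 2
                idx = rng.choice(len(labels), size=k, p=q)
                alleles = tuple(sorted((labels[i] for i in idx), key=allele_key))
                calls[(s.sample_id, locus.name)] = alleles
    return GenotypeTable(samples, calls, list(model.panel))


def inject_unseen_alleles(
    table: GenotypeTable,
    reference: AlleleFrequencyTable,
    rate: float,
    seed: int,
) -> GenotypeTable:
    """Give a Bernoulli(rate) subset of samples one allele absent from the
    reference database (emulating off-ladder alleles a non-cognate database
    has never seen).  The replacement label is two repeat units above the
    largest allele the reference knows at that locus."""
    if not (0.0 <= rate <= 1.0):
        raise StrpopError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    calls = dict(table.calls)
    loci = [l for l in table.panel if l.name in reference.loci]
    for s in table.samples:
        if rng.random() >= rate:
            continue
        typed = [l for l in loci if (s.sample_id, l.name) in calls]
        if not typed:
            continue
        locus = typed[rng.integers(len(typed))]
        known = reference[locus.name].freqs
        top = max(int(float(a)) for a in known if a != "OL")
        novel = str(top + 2)
        g = list(calls[(s.sample_id, locus.name)])
        g[rng.integers(len(g))] = novel
        calls[(s.sample_id, locus.name)] = tuple(sorted(g, key=allele_key))
    return GenotypeTable(list(table.samples), calls, list(table.panel))


def _random_freqs(rng: np.random.Generator, n_alleles: int, start: int = 8) -> dict[str, float]:
    """Ancestral frequency vector over consecutive repeat-count labels.

    Dirichlet(1) mass, floored at 0.0025 (the smallest frequency a single
    observation in a ~200-sample database produces) and renormalized.
    """
    raw = rng.dirichlet(np.ones(n_alleles))
    raw = np.maximum(raw, 0.0025)
    raw /= raw.sum()
    labels = [str(start + i) for i in range(n_alleles)]
    return dict(zip(labels, raw.tolist()))


def default_panel(
    n_autosomal: int = 21,
    n_x: int = 19,
    seed: int = 2023,
    min_alleles: int = 5,
    max_alleles: int = 22,
) -> tuple[list[LocusDef], dict[str, dict[str, float]]]:
    """A toy typing panel with ancestral frequencies.

    Uses the real kit locus names; per-locus allele counts are drawn
    uniformly from [min_alleles, max_alleles], mirroring the 5-22 span
    observed at X-STRs in the kind of kit this emulates.
    """
    if n_autosomal > len(AUTOSOMAL_LOCI) or n_x > len(X_LOCI):
        raise StrpopError("not enough named loci for the requested panel size")
    rng = np.random.default_rng(seed)
    panel: list[LocusDef] = []
    freqs: dict[str, dict[str, float]] = {}
    for name in AUTOSOMAL_LOCI[:n_autosomal]:
        k = int(rng.integers(min_alleles, max_alleles + 1))
        f = _random_freqs(rng, k)
        panel.append(LocusDef(name, AUTOSOMAL, tuple(f)))
        freqs[name] = f
    for name in X_LOCI[:n_x]:
        k = int(rng.integers(min_alleles, max_alleles + 1))
        f = _random_freqs(rng, k)
        panel.append(LocusDef(name, X, tuple(f)))
        freqs[name] = f
    return panel, freqs


def default_model(
    seed: int = 0,
    F: float = 0.01,
    n_autosomal: int = 21,
    n_x: int = 19,
    cognate_sex_counts: tuple[int, int] = (333, 88),
    noncognate_sex_counts: tuple[int, int] = (1000, 1000),
    panel_seed: int = 2023,
) -> PopulationModel:
    """The bundled two-subpopulation study model.

    A cognate subpopulation with the study cohort's sex structure
    (333 male / 88 female by default) and a larger non-cognate reference
    population, both diverged from a common ancestral frequency vector at
    the same F.
    """
    panel, anc = default_panel(n_autosomal=n_autosomal, n_x=n_x, seed=panel_seed)
    return PopulationModel(
        panel=panel,
        ancestral_freqs=anc,
        subpop_F={"cognate": F, "noncognate": F},
        sex_counts={
            "cognate": cognate_sex_counts,
            "noncognate": noncognate_sex_counts,
        },
        seed=seed,
    )
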