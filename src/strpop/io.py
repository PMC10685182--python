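"""Genotype tables, allele-frequency tables, and panel configuration.

STR calls are stored as strings ("15", "9.3", or the off-ladder sentinel
"OL") and compared through parsed (repeat, microvariant) keys, so that
microvariant alleles never hit float-equality traps.  A genotype table holds
diploid calls for autosomal loci and female X loci, and single-allele
hemizygous calls for male X loci.  Missing calls are simply absent and are
excluded from every denominator.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

OL = "OL"

AUTOSOMAL = "autosomal"
X = "X"

_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")


class StrpopError(Exception):
    """Base class for all package errors."""


class ParseError(StrpopError):
    pass


class ValidationError(StrpopError):
    pass


def allele_key(label: str) -> tuple[int, int]:
    """Sort key for an STR allele label.

    "15" -> (15, 0); "9.3" -> (9, 3); "OL" sorts after every numeric label.
    Raises :class:`ParseError` for anything else.
    """
    label = str(label).strip()
    if label == OL:
        return (10**9, 0)
    m = _ALLELE_RE.match(label)
    if not m:
        raise ParseError(f"malformed allele label {label!r}")
    return (int(m.group(1)), int(m.group(2) or 0))


def lenient_allele_key(label: str):
    """Like :func:`allele_key` but orders non-STR labels lexically after
    the numeric ones instead of raising (the pure statistics functions
    accept arbitrary hashable allele labels)."""
    try:
        return (0, allele_key(label), "")
    except ParseError:
        return (1, (0, 0), str(label))


def sort_alleles(labels: Iterable[str]) -> list[str]:
    return sorted(set(labels), key=lenient_allele_key)


@dataclass(frozen=True)
class LocusDef:
    """A locus in a typing panel.

    ``allele_labels`` is the kit's allelic ladder; when None the locus is
    open (any parseable label is accepted).  Calls outside the ladder are
    treated as off-ladder.
    """

    name: str
    chromosome_class: str  # AUTOSOMAL or X
    allele_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.chromosome_class not in (AUTOSOMAL, X):
            raise ValidationError(
                f"locus {self.name}: chromosome class must be "
                f"{AUTOSOMAL!r} or {X!r}, got {self.chromosome_class!r}"
            )
        if self.allele_labels is not None:
            ordered = tuple(sort_alleles(self.allele_labels))
            object.__setattr__(self, "allele_labels", ordered)

    @property
    def is_x(self) -> bool:
        return self.chromosome_class == X


@dataclass(frozen=True)
class Sample:
    sample_id: str
    sex: str  # "M" or "F"
    population: str = "pop"

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValidationError(
                f"sample {self.sample_id}: sex must be 'M' or 'F', got {self.sex!r}"
            )


@dataclass
class GenotypeTable:
    """Samples x loci STR calls with sex and population labels.

    ``calls`` maps (sample_id, locus_name) to a tuple of allele labels:
    length 2 for diploid calls (unordered), length 1 for hemizygous male X
    calls.  Loci a sample was not typed at have no entry.
    """

    samples: list[Sample]
    calls: dict[tuple[str, str], tuple[str, ...]]
    panel: list[LocusDef]

    def __post_init__(self):
        self._by_id = {s.sample_id: s for s in self.samples}
        if len(self._by_id) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        self._loci = {l.name: l for l in self.panel}
        if len(self._loci) != len(self.panel):
            raise ValidationError("duplicate locus names in panel")
        for (sid, locus), alleles in self.calls.items():
            if sid not in self._by_id:
                raise ValidationError(f"call references unknown sample {sid!r}")
            if locus not in self._loci:
                raise ValidationError(f"call references unknown locus {locus!r}")
            for a in alleles:
                allele_key(a)  # raises ParseError if malformed
            sex = self._by_id[sid].sex
            ld = self._loci[locus]
            expected = 1 if (ld.is_x and sex == "M") else 2
            if len(alleles) != expected:
                raise ValidationError(
                    f"sample {sid} at {locus}: expected {expected} allele(s), "
                    f"got {len(alleles)} ({'/'.join(alleles)})"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    def locus(self, name: str) -> LocusDef:
        return self._loci[name]

    def sample(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def subset(
        self,
        populations: Sequence[str] | None = None,
        sexes: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        keep = [
            s
            for s in self.samples
            if (populations is None or s.population in populations)
            and (sexes is None or s.sex in sexes)
            and (sample_ids is None or s.sample_id in set(sample_ids))
        ]
        ids = {s.sample_id for s in keep}
        calls = {k: v for k, v in self.calls.items() if k[0] in ids}
        return GenotypeTable(keep, calls, list(self.panel))

    def genotypes_at(
        self,
        locus: str,
        populations: Sequence[str] | None = None,
        sexes: Sequence[str] | None = None,
    ) -> list[tuple[str, ...]]:
        """All calls at a locus (diploid pairs and/or hemizygous singles)."""
        out = []
        for s in self.samples:
            if populations is not None and s.population not in populations:
                continue
            if sexes is not None and s.sex not in sexes:
                continue
            g = self.calls.get((s.sample_id, locus))
            if g is not None:
                out.append(g)
        return out

    def diploid_genotypes_at(self, locus: str, **kw) -> list[tuple[str, str]]:
        return [g for g in self.genotypes_at(locus, **kw) if len(g) == 2]

    def allele_counts(
        self, locus: str, sex_mode: str = "pooled", populations=None
    ) -> dict[str, int]:
        """Raw allele counts at a locus.

        sex_mode: 'pooled' (all calls; males contribute 1 X allele),
        'male_only', 'female_only'.
        """
        sexes = {"pooled": None, "male_only": ["M"], "female_only": ["F"]}[sex_mode]
        counts: dict[str, int] = {}
        for g in self.genotypes_at(locus, populations=populations, sexes=sexes):
            for a in g:
                counts[a] = counts.get(a, 0) + 1
        return {a: counts[a] for a in sort_alleles(counts)}

    # -- writers -----------------------------------------------------------

    def write_wide(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            header = ["sample_id", "sex", "population"]
            for l in self.panel:
                header += [f"{l.name}_1", f"{l.name}_2"]
            w.writerow(header)
            for s in self.samples:
                row = [s.sample_id, s.sex, s.population]
                for l in self.panel:
                    g = self.calls.get((s.sample_id, l.name))
                    if g is None:
                        row += ["", ""]
                    elif len(g) == 1:
                        row += [g[0], ""]
                    else:
                        row += list(g)
                w.writerow(row)

    def write_long(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["sample_id", "sex", "population", "locus", "allele"])
            for s in self.samples:
                for l in self.panel:
                    g = self.calls.get((s.sample_id, l.name))
                    if g is None:
                        continue
                    for a in g:
                        w.writerow([s.sample_id, s.sex, s.population, l.name, a])


def _normalize_pair(a1: str, a2: str) -> tuple[str, str]:
    a, b = sorted((a1.strip(), a2.strip()), key=allele_key)
    return (a, b)


def read_genotypes(
    path: str | Path, dialect: str = "wide", panel: list[LocusDef] | None = None
) -> GenotypeTable:
    """Read a genotype table from TSV.

    wide dialect: one row per sample; columns sample_id, sex, population and
    two columns "<locus>_1"/"<locus>_2" per locus (X-male leaves _2 empty).
    long dialect: one row per (sample, locus, allele).

    Without an explicit ``panel`` the loci are inferred from the header
    (wide) or rows (long): a locus whose male calls are all single-allele
    and which has at least one male call is classed X, otherwise autosomal.
    Supplying the panel is the reliable route.
    """
    path = Path(path)
    if not path.exists():
        raise StrpopError(f"no such file: {path}")
    if dialect == "wide":
        return _read_wide(path, panel)
    if dialect == "long":
        return _read_long(path, panel)
    raise ValueError(f"unknown dialect {dialect!r}")


def _check_label(label: str, where: str) -> str:
    label = label.strip()
    try:
        allele_key(label)
    except ParseError:
        raise ParseError(f"malformed allele label {label!r} at {where}") from None
    return label


def _read_wide(path: Path, panel: list[LocusDef] | None) -> GenotypeTable:
    with path.open() as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    if header[:3] != ["sample_id", "sex", "population"]:
        raise ParseError(
            f"{path}: wide header must start with sample_id, sex, population"
        )
    locus_names: list[str] = []
    for i in range(3, len(header), 2):
        c1 = header[i]
        c2 = header[i + 1] if i + 1 < len(header) else None
        if not c1.endswith("_1") or c2 != c1[:-2] + "_2":
            raise ParseError(f"{path}: bad locus column pair {c1!r}/{c2!r}")
        locus_names.append(c1[:-2])

    samples: list[Sample] = []
    raw_calls: dict[tuple[str, str], tuple[str, ...]] = {}
    for r, row in enumerate(rows[1:], start=2):
        sid, sex, pop = row[0], row[1], row[2]
        samples.append(Sample(sid, sex, pop))
        for j, locus in enumerate(locus_names):
            a1 = row[3 + 2 * j].strip() if 3 + 2 * j < len(row) else ""
            a2 = row[4 + 2 * j].strip() if 4 + 2 * j < len(row) else ""
            if not a1 and not a2:
                continue
            if a1 and a2:
                where = f"{path}:{r} ({sid}, {locus})"
                raw_calls[(sid, locus)] = _normalize_pair(
                    _check_label(a1, where), _check_label(a2, where)
                )
            elif a1:
                raw_calls[(sid, locus)] = (_check_label(a1, f"{path}:{r} ({sid}, {locus})"),)
            else:
                raise ParseError(f"{path}:{r} ({sid}, {locus}): _1 empty but _2 set")
    if panel is None:
        panel = _infer_panel(locus_names, samples, raw_calls)
    return GenotypeTable(samples, raw_calls, panel)


def _read_long(path: Path, panel: list[LocusDef] | None) -> GenotypeTable:
    with path.open() as fh:
        rd = csv.reader(fh, delimiter="\t")
        header = next(rd, None)
        if header is None or header[:5] != ["sample_id", "sex", "population", "locus", "allele"]:
            raise ParseError(
                f"{path}: long header must be sample_id, sex, population, locus, allele"
            )
        samples: dict[str, Sample] = {}
        acc: dict[tuple[str, str], list[str]] = {}
        order: list[str] = []
        for r, row in enumerate(rd, start=2):
            sid, sex, pop, locus, allele = row[:5]
            if sid not in samples:
                samples[sid] = Sample(sid, sex, pop)
            allele = _check_label(allele, f"{path}:{r} ({sid}, {locus})")
            acc.setdefault((sid, locus), []).append(allele)
            if locus not in order:
                order.append(locus)
    calls = {}
    for key, alleles in acc.items():
        if len(alleles) == 2:
            calls[key] = _normalize_pair(*alleles)
        elif len(alleles) == 1:
            calls[key] = (alleles[0],)
        else:
            raise ParseError(f"{path}: sample {key[0]} has {len(alleles)} rows at {key[1]}")
    sample_list = list(samples.values())
    if panel is None:
        panel = _infer_panel(order, sample_list, calls)
    return GenotypeTable(sample_list, calls, panel)


def _infer_panel(locus_names, samples, calls) -> list[LocusDef]:
    male_ids = {s.sample_id for s in samples if s.sex == "M"}
    panel = []
    for locus in locus_names:
        male_calls = [v for (sid, l), v in calls.items() if l == locus and sid in male_ids]
        is_x = bool(male_calls) and all(len(g) == 1 for g in male_calls)
        panel.append(LocusDef(locus, X if is_x else AUTOSOMAL))
    return panel


# -- allele-frequency tables ----------------------------------------------


@dataclass
class LocusFrequencies:
    """Allele frequencies at one locus of a reference database."""

    freqs: dict[str, float]
    n_alleles_sampled: int
    source_population: str = ""

    def __post_init__(self):
        if self.n_alleles_sampled <= 0:
            raise ValidationError("n_alleles_sampled must be positive")
        for a, f in self.freqs.items():
            allele_key(a)
            if f < 0:
                raise ValidationError(f"negative frequency {f} for allele {a}")
        self.freqs = {a: self.freqs[a] for a in sort_alleles(self.freqs)}

    def get(self, allele: str) -> float | None:
        return self.freqs.get(allele)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele -> frequency maps with sample sizes.

    This is the reference-database object: it houses the p_A, p_B that the
    match-probability formulas consume.
    """

    loci: dict[str, LocusFrequencies] = field(default_factory=dict)

    def __contains__(self, locus: str) -> bool:
        return locus in self.loci

    def __getitem__(self, locus: str) -> LocusFrequencies:
        return self.loci[locus]

    def locus_names(self) -> list[str]:
        return list(self.loci)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["locus", "allele", "frequency", "n"])
            for locus, lf in self.loci.items():
                for a, f in lf.freqs.items():
                    w.writerow([locus, a, repr(f), lf.n_alleles_sampled])


SUM_TOLERANCE = 0.005  # per-locus frequency sums within 0.5% of 1 are renormalized


def read_frequencies(path: str | Path, source_population: str = "") -> AlleleFrequencyTable:
    """Read a TSV with columns locus, allele, frequency, n.

    Per-locus sums within 0.5% of 1 are renormalized (with a logged
    warning); larger deviations are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise StrpopError(f"no such file: {path}")
    acc: dict[str, dict[str, float]] = {}
    ns: dict[str, int] = {}
    with path.open() as fh:
        rd = csv.reader(fh, delimiter="\t")
        header = next(rd, None)
        if header is None or [h.strip() for h in header[:4]] != ["locus", "allele", "frequency", "n"]:
            raise ParseError(f"{path}: header must be locus, allele, frequency, n")
        for r, row in enumerate(rd, start=2):
            locus, allele, freq, n = row[:4]
            allele = _check_label(allele, f"{path}:{r}")
            f = float(freq)
            if f < 0:
                raise ValidationError(f"{path}:{r}: negative frequency {f}")
            acc.setdefault(locus, {})[allele] = f
            ns[locus] = int(n)
    table = AlleleFrequencyTable()
    for locus, freqs in acc.items():
        total = sum(freqs.values())
        if abs(total - 1.0) > SUM_TOLERANCE:
            raise ValidationError(
                f"{path}: locus {locus} frequencies sum to {total:.4f} "
                f"(>0.5% from 1); rejected"
            )
        if abs(total - 1.0) > 1e-9:
            logger.warning(
                "locus %s frequencies sum to %.6f; renormalizing", locus, total
            )
            freqs = {a: f / total for a, f in freqs.items()}
        table.loci[locus] = LocusFrequencies(freqs, ns[locus], source_population)
    return table


def frequencies_from_table(
    table: GenotypeTable,
    locus: str | LocusDef,
    sex_mode: str = "pooled",
    populations: Sequence[str] | None = None,
    source_population: str = "",
) -> LocusFrequencies:
    """Estimate allele frequencies at one locus by direct counting.

    For X loci in pooled mode each male contributes one allele and each
    female two, so the denominator is n_m + 2*n_f.
    """
    name = locus.name if isinstance(locus, LocusDef) else locus
    counts = table.allele_counts(name, sex_mode=sex_mode, populations=populations)
    total = sum(counts.values())
    if total == 0:
        raise ValidationError(f"no typed samples at locus {name}")
    return LocusFrequencies(
        {a: c / total for a, c in counts.items()}, total, source_population
    )


def frequency_table_from_genotypes(
    table: GenotypeTable,
    sex_mode: str = "pooled",
    populations: Sequence[str] | None = None,
    source_population: str = "",
) -> AlleleFrequencyTable:
    out = AlleleFrequencyTable()
    for l in table.panel:
        try:
            out.loci[l.name] = frequencies_from_table(
                table, l, sex_mode=sex_mode, populations=populations,
                source_population=source_population,
            )
        except ValidationError:
            continue  # untyped locus: omit rather than fabricate
    return out


# -- panel config ----------------------------------------------------------


def read_panel(path: str | Path) -> list[LocusDef]:
    """Read a panel config: YAML mapping ``loci`` to a list of
    {name, chromosome} entries, chromosome one of autosomal|X."""
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "loci" not in doc:
        raise ParseError(f"{path}: panel config must contain a 'loci' list")
    panel = []
    for entry in doc["loci"]:
        name = entry["name"]
        chrom = str(entry["chromosome"])
        if chrom not in (AUTOSOMAL, X):
            raise ValidationError(
                f"{path}: locus {name}: chromosome must be autosomal or X"
            )
        labels = entry.get("alleles")
        panel.append(LocusDef(name, chrom, tuple(labels) if labels else None))
    return panel


def write_panel(panel: Sequence[LocusDef], path: str | Path) -> None:
    doc = {
        "loci": [
            {
                "name": l.name,
                "chromosome": l.chromosome_class,
                **({"alleles": list(l.allele_labels)} if l.allele_labels else {}),
            }
            for l in panel
        ]
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
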