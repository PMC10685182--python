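"""End-to-end study pipeline: simulate (or load) -> forensic stats ->
HWE/LD -> Fst/PCoA -> RMP audit, driven by one YAML config.

Every stage draws its seed deterministically from the root seed and the
stage name, so identical configs give byte-identical outputs and any stage
can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import assoc, forensic, popstruct, rmp, simulate
from .io import (
    GenotypeTable,
    StrpopError,
    frequency_table_from_genotypes,
    read_frequencies,
    read_genotypes,
    read_panel,
)

logger = logging.getLogger(__name__)


class PipelineError(StrpopError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    simulation: dict[str, Any] | None = None
    genotypes: Path | None = None
    panel: Path | None = None
    cognate_frequencies: Path | None = None
    noncognate_frequencies: Path | None = None
    hwe: dict[str, Any] = field(default_factory=dict)
    ld: dict[str, Any] = field(default_factory=dict)
    fst: dict[str, Any] = field(default_factory=dict)
    audit: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            doc = yaml.safe_load(fh)
        base = path.parent

        def respath(key):
            if doc.get(key) is None:
                return None
            p = Path(doc[key])
            return p if p.is_absolute() else base / p

        cfg = cls(
            seed=int(doc.get("seed", 0)),
            outdir=Path(doc.get("outdir", "out")),
            simulation=doc.get("simulation"),
            genotypes=respath("genotypes"),
            panel=respath("panel"),
            cognate_frequencies=respath("cognate_frequencies"),
            noncognate_frequencies=respath("noncognate_frequencies"),
            hwe=doc.get("hwe", {}) or {},
            ld=doc.get("ld", {}) or {},
            fst=doc.get("fst", {}) or {},
            audit=doc.get("audit", {}) or {},
        )
        if cfg.simulation is None and cfg.genotypes is None:
            raise StrpopError("config needs either 'simulation' or 'genotypes'")
        for key in ("genotypes", "panel", "cognate_frequencies", "noncognate_frequencies"):
            p = getattr(cfg, key)
            if p is not None and not p.exists():
                raise StrpopError(f"config {key} file does not exist: {p}")
        for F in cfg.audit.get("f_values", []):
            if not (0.0 <= float(F) < 1.0):
                raise StrpopError(f"audit F value {F} outside [0, 1)")
        return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % 2**31


def _fmt(x: float) -> str:
    return f"{x:.6g}" if isinstance(x, float) else str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Context that renames this stage's outputs to .partial on failure."""

    def __init__(self, name: str, outputs: list[Path]):
        self.name = name
        self.outputs = outputs
        self.t0 = 0.0

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        self.t0 = time.monotonic()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.monotonic() - self.t0
        if exc is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
            return False
        for p in self.outputs:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        logger.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
        raise PipelineError(self.name, exc)


def run_all(config: RunConfig) -> dict[str, str]:
    """Run the whole pipeline; returns the manifest (file -> sha256)."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("strpop")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: list[Path] = []
    try:
        table = _stage_data(config, out, outputs)
        _stage_stats(config, table, out, outputs)
        _stage_hwe(config, table, out, outputs)
        _stage_ld(config, table, out, outputs)
        fst_df = _stage_fst(config, table, out, outputs)
        _stage_pcoa(fst_df, out, outputs)
        _stage_audit(config, table, out, outputs)
    finally:
        root.removeHandler(handler)
        handler.close()
    manifest = {p.name: _sha256(p) for p in sorted(outputs)}
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_data(config: RunConfig, out: Path, outputs: list[Path]) -> GenotypeTable:
    pop_path = out / "pop.tsv"
    with _Stage("data", [pop_path]):
        if config.simulation is not None:
            sim = config.simulation
            pops = sim.get("populations") or {
                "cognate": {"male": 120, "female": 60},
                "noncognate": {"male": 300, "female": 300},
            }
            model = simulate.PopulationModel(
                *_panel_and_freqs(sim),
                subpop_F={name: float(sim.get("fst", 0.01)) for name in pops},
                sex_counts={
                    name: (int(v.get("male", 0)), int(v.get("female", 0)))
                    for name, v in pops.items()
                },
                seed=stage_seed(config.seed, "simulate"),
            )
            table = simulate.simulate_population(model)
            table.write_wide(pop_path)
            outputs.append(pop_path)
            return table
        panel = read_panel(config.panel) if config.panel else None
        return read_genotypes(config.genotypes, dialect="wide", panel=panel)


def _panel_and_freqs(sim: dict):
    panel, anc = simulate.default_panel(
        n_autosomal=int(sim.get("n_autosomal_loci", 21)),
        n_x=int(sim.get("n_x_loci", 19)),
        seed=int(sim.get("panel_seed", 2023)),
    )
    return panel, anc


def _stage_stats(config, table: GenotypeTable, out: Path, outputs: list[Path]) -> None:
    path = out / "stats.tsv"
    with _Stage("stats", [path]):
        header = [
            "locus", "chromosome", "n", "Ho", "He", "PIC", "MP", "PD", "PE",
            "TPI", "HD", "PD_male", "PD_female", "MEC_autosomal_trio",
            "MEC_x_trio_daughter", "MEC_x_duo",
        ]
        rows: list[list] = []
        a_stats, x_stats = [], []
        for locus in table.panel:
            if locus.is_x:
                s = forensic.x_locus_stats(table, locus.name)
                x_stats.append(s)
                rows.append([
                    s.locus, "X", s.n_alleles_sampled, "", "", s.PIC, "", "",
                    "", "", s.gene_diversity_HD, s.PD_male, s.PD_female,
                    s.MEC_autosomal_trio, s.MEC_x_trio_daughter, s.MEC_x_duo,
                ])
            else:
                s = forensic.locus_stats(table, locus.name)
                a_stats.append(s)
                rows.append([
                    s.locus, "autosomal", s.n_alleles_sampled, s.Ho, s.He,
                    s.PIC, s.MP, s.PD, s.PE, s.TPI, "", "", "", "", "", "",
                ])
        if a_stats:
            c = forensic.combine(a_stats)
            rows.append([
                "COMBINED_AUTOSOMAL", "autosomal", c.n_loci, "", "", "",
                c.CPM, c.CPD, c.CPE, "", "", "", "", "", "", "",
            ])
        if x_stats:
            cx = forensic.combine_x(x_stats)
            rows.append([
                "COMBINED_X", "X", cx.n_loci, "", "", "", "", "", "", "", "",
                cx.CPD_male, cx.CPD_female, cx.CMEC_autosomal_trio,
                cx.CMEC_x_trio_daughter, cx.CMEC_x_duo,
            ])
        _write_tsv(path, header, rows)
        outputs.append(path)


def _stage_hwe(config, table: GenotypeTable, out: Path, outputs: list[Path]) -> None:
    path = out / "hwe.tsv"
    with _Stage("hwe", [path]):
        n_mc = int(config.hwe.get("mc_samples", 10_000))
        seed = stage_seed(config.seed, "hwe")
        rows = []
        m = len(table.panel)
        thr = assoc.bonferroni(0.05, m)
        for i, locus in enumerate(table.panel):
            # X loci: HWE is testable only in diploid (female) data
            gts = table.diploid_genotypes_at(
                locus.name, sexes=["F"] if locus.is_x else None
            )
            if len(gts) < 5:
                continue
            res = assoc.hwe_exact(gts, n_mc=n_mc, seed=seed + i)
            rows.append([
                locus.name, locus.chromosome_class, len(gts), res.p_value,
                res.method, res.n_samples, round(thr, 4), thr,
            ])
        _write_tsv(
            path,
            ["locus", "chromosome", "n_genotypes", "p_value", "method",
             "n_replicates", "bonferroni_0.05", "bonferroni_full"],
            rows,
        )
        outputs.append(path)


def _stage_ld(config, table: GenotypeTable, out: Path, outputs: list[Path]) -> None:
    path = out / "ld.tsv"
    with _Stage("ld", [path]):
        n_perm = int(config.ld.get("permutations", 1000))
        max_pairs = config.ld.get("max_pairs")
        x_loci = [l.name for l in table.panel if l.is_x]
        results = []
        if len(x_loci) >= 2:
            all_res = assoc.ld_test_all_pairs(
                table, x_loci, sex="M", n_perm=n_perm,
                seed=stage_seed(config.seed, "ld"),
            )
            items = list(all_res.items())
            if max_pairs is not None:
                items = items[: int(max_pairs)]
            for (a, b), r in items:
                results.append([a, b, "M", r.statistic, r.p_value, r.n_samples, r.method])
        m = max(len(results), 1)
        thr = assoc.bonferroni(0.05, m)
        rows = [r + [round(thr, 4)] for r in results]
        _write_tsv(
            path,
            ["locus1", "locus2", "sex", "statistic", "p_value",
             "n_permutations", "method", "bonferroni_0.05"],
            rows,
        )
        outputs.append(path)


def _stage_fst(config, table: GenotypeTable, out: Path, outputs: list[Path]):
    path = out / "fst.tsv"
    with _Stage("fst", [path]):
        loci = [l.name for l in table.panel if not l.is_x]
        res = popstruct.pairwise_fst(
            table,
            loci=loci,
            n_permutations=int(config.fst.get("permutations", 1000)),
            seed=stage_seed(config.seed, "fst"),
        )
        rows = []
        pops = res.populations
        for i, pa in enumerate(pops):
            for pb in pops[i + 1:]:
                rows.append([pa, pb, res.fst.loc[pa, pb], res.p_values.loc[pa, pb]])
        _write_tsv(path, ["pop1", "pop2", "fst", "p_value"], rows)
        outputs.append(path)
        return res.fst


def _stage_pcoa(fst_df, out: Path, outputs: list[Path]) -> None:
    path = out / "coords.tsv"
    with _Stage("pcoa", [path]):
        D = fst_df.clip(lower=0.0)
        np.fill_diagonal(D.values, 0.0)
        res = popstruct.pcoa(D)
        rows = [
            [pop] + [res.coordinates.loc[pop, c] for c in res.coordinates.columns]
            for pop in res.coordinates.index
        ]
        _write_tsv(path, ["population"] + list(res.coordinates.columns), rows)
        outputs.append(path)


def _stage_audit(config, table: GenotypeTable, out: Path, outputs: list[Path]) -> None:
    path = out / "table2.tsv"
    with _Stage("audit", [path]):
        f_values = [float(F) for F in config.audit.get(
            "f_values", [0.0, 0.0016, 0.0108, 0.0170]
        )]
        cognate_pop = config.audit.get("cognate_population", "cognate")
        noncognate_pop = config.audit.get("noncognate_population", "noncognate")
        if config.cognate_frequencies is not None:
            cog_db = read_frequencies(config.cognate_frequencies, "cognate")
            non_db = read_frequencies(config.noncognate_frequencies, "noncognate")
            cohort = table
        else:
            pops = table.populations
            if cognate_pop not in pops or noncognate_pop not in pops:
                raise StrpopError(
                    f"audit populations {cognate_pop!r}/{noncognate_pop!r} not in table"
                )
            cohort = table.subset(populations=[cognate_pop])
            cog_db = frequency_table_from_genotypes(
                table, populations=[cognate_pop], source_population=cognate_pop
            )
            non_db = frequency_table_from_genotypes(
                table, populations=[noncognate_pop], source_population=noncognate_pop
            )
        reports = rmp.audit(cohort, cog_db, non_db, f_values)
        rows = [
            [
                r.F,
                r.proportions[0.0], r.proportions[0.5],
                r.proportions[1.0], r.proportions[2.0],
                r.mean_d, r.sd_d, r.n,
            ]
            for r in reports
        ]
        _write_tsv(
            path,
            ["F", "pct_d_gt_0", "pct_d_gt_0.5", "pct_d_gt_1", "pct_d_gt_2",
             "mean_d", "sd_d", "n"],
            rows,
        )
        outputs.append(path)
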