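"""End-to-end orchestration: simulate/load -> QC -> scan -> multi-locus ->
epistasis -> phenotype descriptives, with a reproducible run report.

Every intermediate is persisted as TSV/JSON; the final report is
emitted as both JSON and Markdown.  All outputs are pure functions of
(inputs, config, seed): timing information goes to the log stream
only, never into report files, so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as omio
from .containers import EmptyPanelError, GenotypeMatrix, KinshipMatrix, check_phenotypes
from .epistasis import pairwise_screen
from .lmem import ScanResult, multilocus_select, single_locus_scan
from .phenostats import dichotomize_onset, group_tests, select_mixture
from .qc import QCThresholds, apply_qc, estimate_kinship
from .rng import spawn_int
from .simdata import SimConfig, CausalVariant, default_emulation_config, simulate_cohort

log = logging.getLogger("onsetmod")


@dataclass
class PipelineConfig:
    """Schema-validated configuration for a full pipeline run."""

    mode: str = "synthetic"  # synthetic | files
    out_dir: str = "onsetmod_run"
    seed: int = 0
    # synthetic mode
    sim: dict = field(default_factory=dict)  # overrides for default_emulation_config
    # files mode
    genotypes: str | None = None
    genotype_format: str | None = None
    phenotypes: str | None = None
    kinship_file: str | None = None
    # analysis options
    kinship_source: str = "grm"  # grm | pedigree | file
    min_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_alpha: float | None = None  # None -> 0.05/m
    coding: str = "dominant"
    reference: str = "minor"
    covariates: tuple[str, ...] = ("sex", "edu_years")
    max_steps: int = 10
    criterion: str = "ebic"
    B: int = 10_000
    evt_perms: int = 1000
    alpha: float = 0.05
    mixture_k: tuple[int, ...] = (1, 2, 3)
    cutoff: float = 48.0
    min_cell_n: int = 3

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if cfg.mode == "files" and (cfg.genotypes is None or cfg.phenotypes is None):
            raise ValueError("files mode requires genotype and phenotype paths")
        if cfg.kinship_source not in ("grm", "pedigree", "file"):
            raise ValueError("kinship_source must be grm|pedigree|file")
        cfg.covariates = tuple(cfg.covariates)
        cfg.mixture_k = tuple(cfg.mixture_k)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["mixture_k"] = list(self.mixture_k)
        return d


@dataclass
class RunReport:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> summary dict
    timings: dict = field(default_factory=dict)  # logged only, not persisted

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "seed": self.seed,
                           "stages": self.stages}, indent=2, sort_keys=True,
                          default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _load_inputs(cfg: PipelineConfig):
    if cfg.mode == "synthetic":
        sim = dict(cfg.sim)
        causal = sim.pop("causal_spec", None)
        base = default_emulation_config(seed=cfg.seed, **sim)
        if causal is not None:
            base = dataclasses.replace(
                base, causal_spec=tuple(CausalVariant(**c) for c in causal))
        cohort = simulate_cohort(base)
        return cohort.genotypes, cohort.phenotypes, cohort.kinship_true, base
    geno = omio.read_genotypes(cfg.genotypes, cfg.genotype_format)
    phen = omio.read_phenotypes(cfg.phenotypes)
    gset, pset = set(geno.samples), set(phen["sample_id"])
    if gset != pset:
        only_g = sorted(gset - pset)[:10]
        only_p = sorted(pset - gset)[:10]
        raise ValueError(
            f"genotype/phenotype sample mismatch; only in genotypes: {only_g}; "
            f"only in phenotypes: {only_p}")
    phen = phen.set_index("sample_id").loc[geno.samples].reset_index()
    phen = check_phenotypes(phen)
    kin = omio.read_kinship(cfg.kinship_file).align(geno.samples) \
        if cfg.kinship_file else None
    return geno, phen, kin, None


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in order, persisting each intermediate.

    Partial failure stops at the failing stage with prior outputs
    intact on disk.  An empty post-QC panel aborts cleanly with the QC
    report persisted.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_echo = cfg.to_dict()
    cfg_echo.pop("out_dir")  # keep reports location-independent
    report = RunReport(config=cfg_echo, seed=cfg.seed)

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, *exc):
                dt = time.perf_counter() - self.t0
                report.timings[name] = dt
                log.info("stage %s: done in %.2fs", name, dt)
        return _T()

    # -- inputs -------------------------------------------------------------
    with stage("inputs"):
        geno, phen, kin_true, sim_cfg = _load_inputs(cfg)
        if cfg.mode == "synthetic":
            omio.write_vcf(geno, out / "genotypes.vcf")
            omio.write_wide_tsv(geno, out / "genotypes.tsv")
            omio.write_phenotypes(phen, out / "phenotypes.tsv")
            omio.write_kinship(kin_true, out / "kinship_true.tsv")
        report.stages["inputs"] = {"n_samples": geno.n_samples,
                                   "n_markers": geno.n_markers,
                                   "mode": cfg.mode}

    # -- QC -----------------------------------------------------------------
    with stage("qc"):
        thr = QCThresholds(hwe_alpha=cfg.hwe_alpha, min_call_rate=cfg.min_call_rate,
                           min_maf=cfg.min_maf)
        geno_qc, qc_report = apply_qc(geno, thr)
        qc_report.table.to_csv(out / "qc_report.tsv", sep="\t",
                               float_format="%.6g")
        _write_json(qc_report.to_json_dict(), out / "qc_summary.json")
        report.stages["qc"] = qc_report.to_json_dict()
    if geno_qc.n_markers == 0:
        raise EmptyPanelError(
            f"no markers survived QC; report persisted at {out / 'qc_report.tsv'}")

    # -- kinship ------------------------------------------------------------
    with stage("kinship"):
        if cfg.kinship_source == "pedigree":
            if kin_true is None:
                raise ValueError("kinship_source='pedigree' needs synthetic mode")
            K = kin_true
        elif cfg.kinship_source == "file":
            if cfg.mode == "files":
                K = omio.read_kinship(cfg.kinship_file).align(geno_qc.samples)
            elif kin_true is not None:
                K = kin_true
            else:
                raise ValueError("kinship_source='file' needs kinship_file")
        else:
            K = estimate_kinship(geno_qc)
        omio.write_kinship(K, out / "kinship_used.tsv")
        report.stages["kinship"] = {"source": cfg.kinship_source, "n": K.n}

    # -- single-locus scan ---------------------------------------------------
    with stage("scan"):
        scan = single_locus_scan(geno_qc, phen, K, coding=cfg.coding,
                                 reference=cfg.reference, covariates=cfg.covariates,
                                 evt_perms=cfg.evt_perms,
                                 seed=spawn_int(cfg.seed, "scan"))
        scan.table.to_csv(out / f"scan_{cfg.coding}.tsv", sep="\t", index=False,
                          float_format="%.6g")
        top = scan.table.dropna(subset=["p"]).nsmallest(5, "p")
        report.stages["scan"] = {
            "coding": cfg.coding,
            "n_tested": int(scan.table["p"].notna().sum()),
            "top_markers": top[["snp", "beta", "se", "p", "p_fdr"]]
            .round(6).to_dict("records"),
        }

    # -- multi-locus model ---------------------------------------------------
    with stage("multilocus"):
        model = multilocus_select(geno_qc, phen, K, coding=cfg.coding,
                                  reference=cfg.reference, covariates=cfg.covariates,
                                  max_steps=cfg.max_steps, criterion=cfg.criterion)
        _write_json(model.to_json_dict(), out / "multilocus.json")
        report.stages["multilocus"] = model.to_json_dict()

    # -- epistasis -----------------------------------------------------------
    with stage("epistasis"):
        if len(model.markers) >= 2:
            epi = pairwise_screen(model.markers, geno_qc, phen, B=cfg.B,
                                  seed=spawn_int(cfg.seed, "epistasis"),
                                  covariates=cfg.covariates,
                                  min_cell_n=cfg.min_cell_n)
            epi.to_csv(out / "epistasis.tsv", sep="\t", index=False,
                       float_format="%.6g")
            report.stages["epistasis"] = {
                "n_pairs": int(len(epi[["marker_a", "marker_b"]].drop_duplicates())),
                "n_contrasts": int(len(epi)),
                "verdicts": epi.groupby(["marker_a", "marker_b"])["verdict"]
                .first().to_dict() and {
                    f"{a}x{b}": v for (a, b), v in
                    epi.groupby(["marker_a", "marker_b"])["verdict"].first().items()
                },
            }
        else:
            report.stages["epistasis"] = {"n_pairs": 0, "note":
                                          "fewer than 2 selected markers"}

    # -- phenotype descriptives ----------------------------------------------
    with stage("phenostats"):
        y = phen["adaoo"].to_numpy()
        best, bics = select_mixture(y, cfg.mixture_k,
                                    seed=spawn_int(cfg.seed, "mixture"))
        dich = dichotomize_onset(y, cfg.cutoff)
        tests = {}
        for design in ("sex", "edu_group", "edu_years"):
            try:
                gc = group_tests(phen, design)
                tests[design] = {"test": gc.test, "statistic": gc.statistic,
                                 "df": gc.df, "p": gc.p}
            except ValueError as exc:
                tests[design] = {"error": str(exc)}
        pheno_summary = {
            "adaoo_mean": float(y.mean()), "adaoo_sd": float(y.std(ddof=1)),
            "mixture_bic": {str(k): float(v) for k, v in bics.items()},
            "mixture_best": best.to_json_dict(),
            "dichotomy": {"cutoff": cfg.cutoff,
                          "n_early": int((dich.labels == "early").sum()),
                          "n_late": int((dich.labels == "late").sum()),
                          "summary": dich.summary.round(4).to_dict()},
            "group_tests": tests,
        }
        _write_json(pheno_summary, out / "phenostats.json")
        report.stages["phenostats"] = pheno_summary

    # -- report ---------------------------------------------------------------
    with stage("report"):
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: RunReport) -> str:
    s = report.stages
    lines = ["# onsetmod run report", ""]
    lines += [f"- seed: {report.seed}", f"- mode: {s['inputs']['mode']}",
              f"- samples: {s['inputs']['n_samples']}",
              f"- markers: {s['inputs']['n_markers']}", ""]
    qc = s.get("qc", {})
    lines += ["## QC", f"- pass: {qc.get('n_pass')} / {qc.get('n_markers')}",
              f"- HWE alpha: {qc.get('hwe_alpha'):.3g}", ""]
    sc = s.get("scan", {})
    lines += [f"## Single-locus scan ({sc.get('coding')})",
              f"- markers tested: {sc.get('n_tested')}"]
    for row in sc.get("top_markers", []):
        lines.append(f"  - {row['snp']}: beta={row['beta']:.3g} "
                     f"se={row['se']:.3g} p={row['p']:.3g} p_fdr={row['p_fdr']:.3g}")
    ml = s.get("multilocus", {})
    lines += ["", "## Multi-locus model",
              f"- selected: {ml.get('markers')}",
              f"- total variance explained: {ml.get('total_pve'):.3f}"
              if ml.get("total_pve") is not None else "- no markers selected"]
    ph = s.get("phenostats", {})
    if ph:
        mb = ph["mixture_best"]
        lines += ["", "## Onset distribution",
                  f"- mean {ph['adaoo_mean']:.2f}, sd {ph['adaoo_sd']:.2f} years",
                  f"- mixture: k={mb['k']} means="
                  + ", ".join(f"{m:.1f}" for m in mb["means"]),
                  f"- early/late at {ph['dichotomy']['cutoff']:g}y: "
                  f"{ph['dichotomy']['n_early']}/{ph['dichotomy']['n_late']}"]
    return "\n".join(lines) + "\n"
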