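"""End-to-end orchestration: data (simulated or ingested) -> QC -> PBLUP ->
corrected phenotypes -> GBLUP -> weighted-GBLUP iterations -> validation report.

`run_study` is the library entry point returning in-memory results;
`run_pipeline` wraps it with config parsing, output files and a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evalmod import ValidationReport, evaluate_trace, split_by_date
from .geno_qc import QCReport, run_qc
from .genotypes import GenotypeMatrix, read_dosage_text
from .lmm import (
    EvaluationResult,
    ModelSpec,
    VarianceComponents,
    build_design,
    correct_phenotypes,
    fit_blup,
    reml_variance,
)
from .pedigree import Pedigree, build_A, read_pedigree
from .relmat import RelationshipMatrix, center_genotypes, condition_G, build_weighted_G
from .simdata import BASE_DATE, DAYS_PER_GENERATION, SimConfig, SimOutput, simulate
from .weighting import IterationTrace, WeightScheme, run_wgblup

log = logging.getLogger("wgblup")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Flat run configuration; exactly one of ``simulation`` / input paths."""

    simulation: SimConfig | None = None
    genotypes_path: str | None = None  # PLINK prefix or .tsv dosage file
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    qc: dict = field(default_factory=dict)
    schemes: list[dict] = field(
        default_factory=lambda: [{"kind": "nonlinearA", "ct": 1.25, "exponent_limit": 20}]
    )
    cutoff_date: str | None = None
    n_iterations: int = 10
    blend: float = 0.05
    blend_with_pedigree: bool = True
    outdir: str = "wgblup_run"
    seed: int = 0

    def __post_init__(self) -> None:
        has_inputs = any(
            p is not None
            for p in (self.genotypes_path, self.pedigree_path, self.phenotypes_path)
        )
        if self.simulation is not None and has_inputs:
            raise ConfigError("config supplies both a simulation block and input paths")
        if self.simulation is None and not has_inputs:
            raise ConfigError("config must supply a simulation block or input paths")
        if self.simulation is None:
            for name in ("genotypes_path", "pedigree_path", "phenotypes_path"):
                if getattr(self, name) is None:
                    raise ConfigError(f"input mode requires {name}")
        if not self.schemes:
            raise ConfigError("at least one weighting scheme is required")
        for s in self.schemes:
            if s.get("kind") not in ("gblup", "linear", "nonlinearA"):
                raise ConfigError(f"unknown scheme kind: {s.get('kind')!r}")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        model = raw.pop("model", None)
        kwargs = {}
        if sim is not None:
            if "founder_maf_range" in sim:
                sim["founder_maf_range"] = tuple(sim["founder_maf_range"])
            if "matings_per_generation" in sim and isinstance(
                sim["matings_per_generation"], list
            ):
                sim["matings_per_generation"] = tuple(sim["matings_per_generation"])
            kwargs["simulation"] = SimConfig(**sim)
        if model is not None:
            kwargs["model"] = ModelSpec(**model)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)


@dataclass
class StudyResult:
    """In-memory results of one full evaluation run."""

    report: ValidationReport
    qc_report: QCReport
    vc_pedigree: VarianceComponents
    vc_genomic: VarianceComponents
    yc: pd.Series
    split: "object"
    traces: dict[str, IterationTrace]
    pblup: EvaluationResult
    freqs: np.ndarray
    sim: SimOutput | None = None


def default_cutoff(sim_config: SimConfig) -> pd.Timestamp:
    """Cut-off that places the last simulated generation in validation."""
    return BASE_DATE + pd.Timedelta(
        days=DAYS_PER_GENERATION * (sim_config.n_generations - 1) - 1
    )


def _scheme_from_dict(s: dict) -> tuple[str, WeightScheme | None]:
    kind = s["kind"]
    if kind == "gblup":
        return "GBLUP", None
    ws = WeightScheme(
        kind=kind,
        ct=float(s.get("ct", 1.25)),
        exponent_limit=float(s.get("exponent_limit", 20)),
    )
    return ws.label, ws


def run_study(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    model: ModelSpec,
    schemes: list[dict],
    cutoff_date,
    qc_kwargs: dict | None = None,
    n_iterations: int = 10,
    blend: float = 0.05,
    blend_with_pedigree: bool = True,
) -> StudyResult:
    """Run the full method comparison on one dataset.

    Sequence: genotype QC -> pedigree REML + PBLUP (training fit for EBV, full
    fit for fixed effects) -> corrected phenotypes Yc -> genomic REML on the
    training animals -> GBLUP / weighted-GBLUP traces -> per-iteration
    accuracy and bias on the validation animals.  The accuracy denominator
    sqrt(h2) uses the pedigree-model REML estimate from the training data.
    """
    qc_kwargs = qc_kwargs or {}
    g_qc, qc_report = run_qc(genotypes, pedigree=pedigree, **qc_kwargs)
    log.info(qc_report.summary())

    phenos = phenotypes.copy()
    phenos["animal"] = phenos["animal"].astype(str)
    genotyped = set(g_qc.animal_ids)
    phenos = phenos[phenos["animal"].isin(genotyped)].reset_index(drop=True)

    split = split_by_date(phenos, cutoff_date)
    train_phenos = phenos[phenos["animal"].isin(split.training_ids)]

    # pedigree-based model: variance components and EBV from training data,
    # fixed effects for Yc from all phenotyped animals
    A = build_A(pedigree)
    A_rel = RelationshipMatrix(A.values, "A", A.ids)
    design_train = build_design(train_phenos, model, A.ids)
    vc_a = reml_variance(design_train.X, design_train.Z, design_train.y, A_rel)
    log.info(
        "pedigree REML: sigma_a2=%.4g sigma_e2=%.4g h2=%.3f",
        vc_a.sigma_a2, vc_a.sigma_e2, vc_a.h2,
    )
    pblup_train = fit_blup(train_phenos, model, A_rel, vc=vc_a, design=design_train)
    pblup_full = fit_blup(phenos, model, A_rel, vc=vc_a)
    yc_table = correct_phenotypes(pblup_full, phenos)
    yc = yc_table.set_index("animal")["yc"]

    # genomic kernel over QC'd genotyped animals
    cg = center_genotypes(g_qc)
    A22 = None
    if blend_with_pedigree:
        idx = [A.ids.index(a) for a in cg.animal_ids]
        A22 = RelationshipMatrix(A.values[np.ix_(idx, idx)], "A", list(cg.animal_ids))

    train_geno = [a for a in split.training_ids if a in set(cg.animal_ids)]
    yc_train = yc.loc[train_geno]

    # genomic variance components on the iteration-1 (unweighted) kernel
    G1 = condition_G(build_weighted_G(cg, np.ones(cg.n_snps)), A22=A22, blend=blend)
    pos = {a: i for i, a in enumerate(cg.animal_ids)}
    Zg = np.zeros((len(train_geno), cg.n_animals))
    for r, a in enumerate(train_geno):
        Zg[r, pos[a]] = 1.0
    Xg = np.ones((len(train_geno), 1))
    vc_g = reml_variance(Xg, Zg, yc_train.to_numpy(float), G1)
    log.info(
        "genomic REML: sigma_a2=%.4g sigma_e2=%.4g h2=%.3f",
        vc_g.sigma_a2, vc_g.sigma_e2, vc_g.h2,
    )

    h2_acc = vc_a.h2
    valid_geno = [a for a in split.validation_ids if a in set(cg.animal_ids)]

    rows = []
    # PBLUP row (single, iteration 0 = not iterative)
    from .evalmod import accuracy as _acc, bias as _bias

    ebv_valid = pblup_train.ebv.loc[valid_geno].to_numpy(float)
    yv = yc.loc[valid_geno].to_numpy(float)
    rows.append(
        {
            "method": "PBLUP",
            "iteration": 0,
            "accuracy": _acc(ebv_valid, yv, h2_acc),
            "bias": _bias(ebv_valid, yv),
            "n_validation": len(valid_geno),
        }
    )

    traces: dict[str, IterationTrace] = {}
    gblup_done = False
    for s in schemes:
        label, ws = _scheme_from_dict(s)
        if ws is None:
            t_run, scheme = 1, WeightScheme()
        else:
            t_run, scheme = int(s.get("n_iterations", n_iterations)), ws
        trace = run_wgblup(
            cg, yc_train, vc_g, scheme, n_iterations=t_run, blend=blend, A22=A22
        )
        traces[label] = trace
        rows.append(evaluate_trace(trace, yc, valid_geno, h2_acc, method=label))
        if not gblup_done and t_run >= 1 and label != "GBLUP":
            # iteration 1 of any weighting trace IS plain GBLUP
            rows.append(
                evaluate_trace(
                    IterationTrace(scheme, trace.snp_ids, trace.iterations[:1]),
                    yc, valid_geno, h2_acc, method="GBLUP",
                )
            )
            gblup_done = True
        elif label == "GBLUP":
            gblup_done = True

    tidy = pd.concat(
        [r if isinstance(r, pd.DataFrame) else pd.DataFrame([r]) for r in rows],
        ignore_index=True,
    )
    report = ValidationReport(
        rows=tidy,
        h2=float(h2_acc),
        cutoff_date=pd.Timestamp(cutoff_date),
        extra={"n_training": len(train_geno), "n_validation": len(valid_geno)},
    )
    return StudyResult(
        report=report,
        qc_report=qc_report,
        vc_pedigree=vc_a,
        vc_genomic=vc_g,
        yc=yc,
        split=split,
        traces=traces,
        pblup=pblup_train,
        freqs=cg.freqs,
    )


def compare_methods(
    reports: list[ValidationReport] | ValidationReport,
    select_iteration: dict[str, int] | str = "best",
) -> pd.DataFrame:
    """Wide method x {accuracy, bias} table with % accuracy change vs GBLUP.

    ``select_iteration`` picks the reported iteration per method: "best" takes
    each method's maximum-accuracy iteration, "last" the final one, or pass an
    explicit {method: iteration} mapping.  Percent change is
    100 (acc - acc_GBLUP) / acc_GBLUP.
    """
    from .evalmod import ValidationError

    if isinstance(reports, ValidationReport):
        reports = [reports]
    cutoffs = {str(r.cutoff_date) for r in reports}
    if len(cutoffs) > 1:
        raise ValidationError(
            f"reports use different validation splits: {sorted(cutoffs)}"
        )
    rows = pd.concat([r.rows for r in reports], ignore_index=True)
    out = []
    for method, grp in rows.groupby("method", sort=False):
        if isinstance(select_iteration, dict):
            it = select_iteration.get(method)
            sel = grp[grp["iteration"] == it] if it is not None else grp.iloc[[0]]
            if sel.empty:
                raise ConfigError(f"method {method} has no iteration {it}")
            sel = sel.iloc[0]
        elif select_iteration == "last":
            sel = grp.loc[grp["iteration"].idxmax()]
        else:  # best accuracy
            sel = grp.loc[grp["accuracy"].idxmax()]
        out.append(
            {
                "method": method,
                "iteration": int(sel["iteration"]),
                "accuracy": float(sel["accuracy"]),
                "bias": float(sel["bias"]),
            }
        )
    table = pd.DataFrame(out)
    if (table["method"] == "GBLUP").any() and len(table) > 1:
        acc_g = float(table.loc[table["method"] == "GBLUP", "accuracy"].iloc[0])
        table["pct_accuracy_change_vs_gblup"] = (
            100.0 * (table["accuracy"] - acc_g) / acc_g
        )
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analysis and write all outputs under ``outdir``.

    Returns the manifest (also written as manifest.json).  Outputs are
    deterministic given the config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")

    sim = None
    if config.simulation is not None:
        sim_cfg = config.simulation
        if sim_cfg.seed != config.seed:
            from dataclasses import replace

            sim_cfg = replace(sim_cfg, seed=config.seed)
        sim = simulate(sim_cfg)
        pedigree, genotypes, phenotypes = sim.pedigree, sim.genotypes, sim.phenotypes
        cutoff = config.cutoff_date or default_cutoff(sim_cfg)
    else:
        pedigree = read_pedigree(config.pedigree_path)
        gp = Path(config.genotypes_path)
        if gp.suffix in (".tsv", ".txt", ".csv"):
            genotypes = read_dosage_text(gp)
        else:
            from .plink import read_plink

            genotypes = read_plink(gp)
        phenotypes = pd.read_csv(config.phenotypes_path)
        phenotypes["birth_date"] = pd.to_datetime(phenotypes["birth_date"])
        if config.cutoff_date is None:
            raise ConfigError("cutoff_date is required with input paths")
        cutoff = config.cutoff_date

    result = run_study(
        pedigree,
        genotypes,
        phenotypes,
        config.model,
        config.schemes,
        cutoff,
        qc_kwargs=config.qc,
        n_iterations=config.n_iterations,
        blend=config.blend,
        blend_with_pedigree=config.blend_with_pedigree,
    )

    result.report.to_csv(outdir / "validation_report.csv")
    result.report.to_json(outdir / "validation_report.json")
    result.qc_report.to_json(outdir / "qc_report.json")
    comparison = compare_methods(result.report)
    comparison.to_csv(outdir / "method_comparison.csv", index=False)
    for label, trace in result.traces.items():
        safe = label.replace("*", "").replace("/", "_")
        trace.to_frame(result.freqs).to_csv(outdir / f"trace_{safe}.csv", index=False)
        trace.gebv_frame().to_csv(outdir / f"gebv_{safe}.csv", index_label="animal")
    if sim is not None:
        sim.write(outdir / "simdata")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "cutoff_date": str(cutoff),
        "qc_thresholds": result.qc_report.thresholds,
        "n_snps_post_qc": result.qc_report.n_snps_out,
        "n_animals_post_qc": result.qc_report.n_animals_out,
        "n_training": len(result.split.training_ids),
        "n_validation": len(result.split.validation_ids),
        "variance_components": {
            "pedigree": {
                "sigma_a2": result.vc_pedigree.sigma_a2,
                "sigma_e2": result.vc_pedigree.sigma_e2,
                "h2": result.vc_pedigree.h2,
            },
            "genomic": {
                "sigma_a2": result.vc_genomic.sigma_a2,
                "sigma_e2": result.vc_genomic.sigma_e2,
                "h2": result.vc_genomic.h2,
            },
        },
        "schemes": config.schemes,
        "n_iterations": config.n_iterations,
        "blend": config.blend,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _setup_logging(logfile) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(sh)
    # one file handler per run directory
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    log.addHandler(fh)
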