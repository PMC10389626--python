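"""Reproducible end-to-end runs: simulate -> fit -> select -> validate -> predict.

Each run consumes a single seed, split hierarchically per stage, writes every
artifact under one output directory, and records a manifest (stages, seed,
package version, file list).  ``reproduce_worked_example`` recomputes the
published calculator's illustration patient from the shipped coefficients.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, PatientRecord, read_cohort, summarize_cohort, write_cohort
from .encoding import EncodingConfig, encode_design
from .likelihood import DAY, ModelParameters, fit_mle, published_parameters
from .prediction import conditional_cif, risk_table
from .selection import SelectionConfig, stability_selection
from .simulate import SimulationConfig, simulate_cohort, validation_like
from .validation import validate_model

#: the published calculator's illustration patient: 65-year-old man, 9 years
#: of education, stage 0-I squamous cell carcinoma, no neoadjuvant therapy,
#: R0 margins, no reoperation.
EXAMPLE_PROFILE = PatientRecord(
    patient_id="example", age=65.0, sex="male", education_gt12="no",
    comorbidity="0", histology="squamous_cell_carcinoma",
    chemoradiotherapy="no", stage="0-i", margin="r0", reoperation_30d="no",
    time=1.0, event=0)

#: published calculator outputs for that patient, in percent:
#: (t0 post-surgery years, horizon years, all-cause %, cancer %)
PUBLISHED_EXAMPLE_RISKS = (
    (1.0, 2.0, 30.4, 21.7),
    (2.6, 0.5, 5.8, 3.7),
)


def reproduce_worked_example(params: ModelParameters | None = None,
                             encoding: EncodingConfig | None = None,
                             tolerance_pp: float = 0.5) -> pd.DataFrame:
    """Recompute the published calculator example and compare.

    Returns one row per published number with the computed value, the
    published value, the absolute deviation in percentage points, and whether
    it falls within ``tolerance_pp`` (0.5 pp by default, the forward error
    induced by coefficients printed to two decimals).
    """
    params = params or published_parameters()
    design = encode_design(EXAMPLE_PROFILE, encoding)
    rows = []
    for t0_post, horizon, pub_all, pub_cancer in PUBLISHED_EXAMPLE_RISKS:
        r = conditional_cif(horizon, t0_post - 1.0, design, params)
        for quantity, computed, published in (
                ("all-cause", 100.0 * r.cif_allcause, pub_all),
                ("cancer", 100.0 * r.cif_cancer, pub_cancer)):
            dev = abs(computed - published)
            rows.append({
                "t0_post_surgery_years": t0_post,
                "horizon_years": horizon,
                "quantity": quantity,
                "computed_pct": computed,
                "published_pct": published,
                "abs_deviation_pp": dev,
                "within_tolerance": bool(dev <= tolerance_pp),
            })
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "fit", "validate", "predict")
    # simulate
    n: int = 1000
    preset: str = "derivation"          # or "validation"
    cohort_path: str | None = None      # load instead of simulating
    # model
    family: str = "loglogistic"
    age_center: float = 65.1
    age_scale: float = 10.0
    delta: float = DAY
    # selection
    selection: dict = field(default_factory=dict)
    # validation
    validation: dict = field(default_factory=dict)
    # prediction
    predict_t0: float = 1.0
    predict_horizons: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "predict_horizons"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    encoding = EncodingConfig(age_center=config.age_center,
                              age_scale=config.age_scale)
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {name: int(child.generate_state(1)[0] % (2**31))
                  for name, child in zip(
                      ("simulate", "fit", "select", "validate", "predict"),
                      ss.spawn(5))}

    manifest: dict = {"package": "condsurv", "version": __version__,
                      "seed": config.seed, "stages": [], "artifacts": [],
                      "timings_s": {}}

    def record(stage: str, t0: float, *paths: Path):
        manifest["stages"].append(stage)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        manifest["artifacts"].extend(str(p.relative_to(outdir)) for p in paths)

    cohort: Cohort | None = None
    params: ModelParameters = published_parameters()

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        if config.preset == "validation":
            sim = validation_like(n=config.n, seed=stage_seed["simulate"])
        else:
            sim = SimulationConfig(n=config.n, seed=stage_seed["simulate"])
        cohort = simulate_cohort(sim, encoding=encoding)
        p_csv = write_cohort(cohort, outdir / "cohort.csv")
        sidecar = outdir / "cohort.config.json"
        sidecar.write_text(json.dumps(
            {"seed": sim.seed, "n": sim.n, "preset": config.preset},
            indent=2, sort_keys=True) + "\n")
        p_sum = outdir / "cohort_summary.csv"
        summarize_cohort(cohort).to_csv(p_sum, index=False)
        record("simulate", t0, p_csv, sidecar, p_sum)
    elif config.cohort_path:
        cohort = read_cohort(config.cohort_path)

    if "fit" in config.stages:
        if cohort is None:
            raise RuntimeError("stage 'fit' needs a cohort (simulate or cohort_path)")
        t0 = time.perf_counter()
        fit = fit_mle(cohort, encoding=encoding, family=config.family,
                      delta=config.delta, seed=stage_seed["fit"])
        if not fit.converged:
            raise RuntimeError("stage 'fit' failed: optimizer did not converge")
        params = fit.params
        p_model = fit.params.save(outdir / "model.txt")
        p_coef = outdir / "coefficients.csv"
        fit.coef_table().to_csv(p_coef, index=False)
        (outdir / "fit.json").write_text(json.dumps(
            {"loglik": fit.loglik, "aic": fit.aic, "converged": fit.converged,
             "n_obs": fit.n_obs, "monotone_warning": fit.monotone_warning},
            indent=2, sort_keys=True) + "\n")
        record("fit", t0, p_model, p_coef, outdir / "fit.json")

    if "select" in config.stages:
        if cohort is None:
            raise RuntimeError("stage 'select' needs a cohort")
        t0 = time.perf_counter()
        sel_cfg = SelectionConfig(seed=stage_seed["select"],
                                  **config.selection)
        result = stability_selection(cohort, sel_cfg, encoding)
        p_counts = outdir / "selection_counts.csv"
        result.counts.to_csv(p_counts, index=False)
        (outdir / "selection_final.json").write_text(json.dumps(
            {k: list(v) for k, v in result.final.items()},
            indent=2, sort_keys=True) + "\n")
        record("select", t0, p_counts, outdir / "selection_final.json")

    if "validate" in config.stages:
        if cohort is None:
            raise RuntimeError("stage 'validate' needs a cohort")
        t0 = time.perf_counter()
        val_kwargs = dict(config.validation)
        report = validate_model(cohort, params, encoding,
                                seed=stage_seed["validate"], **val_kwargs)
        paths = []
        p = outdir / "auc_curve.csv"
        report.auc_curve.to_csv(p, index=False)
        paths.append(p)
        if report.auc_summary is not None:
            p = outdir / "auc_bootstrap.csv"
            report.auc_summary.to_csv(p, index=False)
            paths.append(p)
        hl_rows = []
        for (h, outcome), res in report.hl.items():
            hl_rows.append({"horizon": h, "outcome": outcome,
                            "statistic": res.statistic, "df": res.df,
                            "pvalue": res.pvalue})
            p = outdir / f"calibration_{outcome}_{h:g}y.csv"
            res.table.to_csv(p, index=False)
            paths.append(p)
        p = outdir / "hosmer_lemeshow.csv"
        pd.DataFrame(hl_rows).to_csv(p, index=False)
        paths.append(p)
        if report.gof is not None:
            p = outdir / "gof_km_vs_f5.csv"
            report.gof.to_frame().to_csv(p, index=False)
            paths.append(p)
            manifest["gof_discrepancy"] = report.gof.discrepancy
        record("validate", t0, *paths)

    if "predict" in config.stages:
        t0 = time.perf_counter()
        table = risk_table(EXAMPLE_PROFILE, config.predict_t0,
                           list(config.predict_horizons), params, encoding)
        p = outdir / "risk_table.csv"
        table.to_csv(p, index=False)
        record("predict", t0, p)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
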