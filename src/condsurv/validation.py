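"""Discrimination and calibration assessment of the fitted model.

Discrimination uses the time-dependent AUC: the marker is the model-predicted
cumulative incidence at a horizon (total CIF for all-cause mortality,
cancer-specific CIF for disease-specific mortality); cases are patients with
the outcome event by the horizon, controls are patients event-free and still
under observation at the horizon, and records censored before the horizon are
excluded.  Both cohorts emulated here have complete potential follow-up to
the cap, so such exclusions are administrative only and no IPCW reweighting
is applied.

Calibration uses Hosmer-Lemeshow decile tables, and overall goodness of fit
compares the intercept-only model's mixture survival f5 with the
Kaplan-Meier estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .encoding import EncodingConfig, design_matrices
from scipy.special import expit

from .likelihood import (DAY, FitResult, ModelParameters, _sf, fit_mle,
                         published_parameters)

OUTCOMES = ("allcause", "cancer")


def predicted_risks(cohort: Cohort, params: ModelParameters, horizon: float,
                    outcome: str = "allcause",
                    encoding: EncodingConfig | None = None) -> np.ndarray:
    """Model-predicted CIF at the horizon for every patient."""
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    mats = design_matrices(cohort.table, encoding)
    u = horizon if params.family == "gompertz" else np.log(horizon)
    p1 = expit(mats.Xa @ params.alpha)
    v2 = mats.Xe @ params.eta + u * (mats.Xp @ params.phi)
    v1 = v2 + mats.Xg @ params.gamma + u * (mats.Xr @ params.rho)
    s1 = _sf(v1, params.family)
    s2 = _sf(v2, params.family)
    cif_cancer = (1.0 - s1) * p1
    if outcome == "cancer":
        return cif_cancer
    return cif_cancer + (1.0 - s2) * (1.0 - p1)


def _case_control_masks(t: np.ndarray, d: np.ndarray, horizon: float,
                        outcome: str) -> tuple[np.ndarray, np.ndarray]:
    if outcome == "allcause":
        cases = (d > 0) & (t <= horizon)
    else:
        cases = (d == 1) & (t <= horizon)
    # records censored exactly at the horizon (e.g. the administrative cap)
    # were observed event-free through it and count as controls
    controls = (t > horizon) | ((d == 0) & (t >= horizon))
    return cases, controls


def _auc_from_marker(marker: np.ndarray, cases: np.ndarray,
                     controls: np.ndarray) -> float:
    """Pairwise concordance with 0.5 credit for ties (Mann-Whitney form)."""
    n1 = int(cases.sum())
    n0 = int(controls.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(
            f"AUC undefined: {n1} case(s) and {n0} control(s) at this horizon")
    keep = cases | controls
    m = marker[keep]
    y = cases[keep]
    ranks = stats.rankdata(m)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def time_dependent_auc(cohort: Cohort, params: ModelParameters,
                       horizon: float, outcome: str = "allcause",
                       encoding: EncodingConfig | None = None,
                       marker: np.ndarray | None = None) -> float:
    """AUC for predicting event status by the horizon (landmark-years).

    ``marker`` may supply precomputed per-patient risks (otherwise the
    model-predicted CIF at the horizon is used).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    t = cohort.table["time"].to_numpy(float)
    d = cohort.table["event"].to_numpy(int)
    if marker is None:
        marker = predicted_risks(cohort, params, horizon, outcome, encoding)
    cases, controls = _case_control_masks(t, d, horizon, outcome)
    return _auc_from_marker(np.asarray(marker, float), cases, controls)


def auc_curve(cohort: Cohort, params: ModelParameters, grid,
              outcomes=OUTCOMES,
              encoding: EncodingConfig | None = None) -> pd.DataFrame:
    """Apparent AUC at each horizon of a grid, per outcome."""
    rows = []
    for h in np.atleast_1d(np.asarray(grid, float)):
        for outcome in outcomes:
            try:
                a = time_dependent_auc(cohort, params, float(h), outcome,
                                       encoding)
            except ValueError:
                a = np.nan
            rows.append({"horizon": float(h), "outcome": outcome, "auc": a})
    return pd.DataFrame(rows)


@dataclass
class BootstrapAUC:
    """Median AUC with 2.5-97.5% bootstrap quantile intervals."""

    summary: pd.DataFrame      # outcome, horizon, median, ci_low, ci_high, n_ok
    samples: pd.DataFrame      # replicate-level AUCs
    mode: str
    n_boot: int


def bootstrap_auc_cv(cohort: Cohort, encoding: EncodingConfig | None = None,
                     horizons=(2.0, 4.0), outcomes=OUTCOMES,
                     n_boot: int = 1000, mode: str = "out_of_bag",
                     seed: int = 0, family: str = "loglogistic",
                     delta: float = DAY,
                     fit_kwargs: dict | None = None) -> BootstrapAUC:
    """Bootstrap cross-validated AUC: resample, refit, evaluate.

    ``mode="apparent"`` evaluates each refit on its own bootstrap resample
    (the literal cross-validation wording); ``"out_of_bag"`` (default)
    evaluates on the records left out of the resample, guarding optimism.
    """
    if mode not in ("apparent", "out_of_bag"):
        raise ValueError("mode must be 'apparent' or 'out_of_bag'")
    horizons = tuple(float(h) for h in np.atleast_1d(horizons))
    encoding = encoding or EncodingConfig()
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_starts", 1)
    rng = np.random.default_rng(seed)
    n = len(cohort)

    full_fit = fit_mle(cohort, encoding=encoding, family=family, delta=delta,
                       compute_se=False, **{k: v for k, v in fit_kwargs.items()
                                            if k != "init"})
    warm = full_fit.params if full_fit.converged else None

    rows = []
    n_fail = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        train = cohort.subset(idx, label=f"{cohort.label}-b{b}")
        try:
            fit = fit_mle(train, encoding=encoding, family=family,
                          delta=delta, init=warm, compute_se=False,
                          **fit_kwargs)
            if not fit.converged:
                raise RuntimeError("fit did not converge")
        except Exception:
            n_fail += 1
            continue
        if mode == "apparent":
            eval_cohort = train
        else:
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size == 0:
                n_fail += 1
                continue
            eval_cohort = cohort.subset(oob)
        for h in horizons:
            for outcome in outcomes:
                try:
                    a = time_dependent_auc(eval_cohort, fit.params, h,
                                           outcome, encoding)
                except ValueError:
                    a = np.nan
                rows.append({"replicate": b, "horizon": h,
                             "outcome": outcome, "auc": a})
    if n_boot and n_fail > 0.1 * n_boot:
        import warnings
        warnings.warn(f"{n_fail}/{n_boot} bootstrap refits failed",
                      stacklevel=2)

    samples = pd.DataFrame(rows)
    summary_rows = []
    for (outcome, h), grp in samples.groupby(["outcome", "horizon"]):
        vals = grp["auc"].dropna().to_numpy()
        if vals.size == 0:
            continue
        summary_rows.append({
            "outcome": outcome, "horizon": h,
            "median": float(np.median(vals)),
            "ci_low": float(np.quantile(vals, 0.025)),
            "ci_high": float(np.quantile(vals, 0.975)),
            "n_ok": int(vals.size)})
    return BootstrapAUC(summary=pd.DataFrame(summary_rows), samples=samples,
                        mode=mode, n_boot=n_boot)


def auc_difference_ci(cohort_internal: Cohort, cohort_external: Cohort,
                      params: ModelParameters, horizons=(2.0, 4.0),
                      outcomes=OUTCOMES, n_boot: int = 200, seed: int = 0,
                      encoding: EncodingConfig | None = None) -> pd.DataFrame:
    """Bootstrap CI for the internal-minus-external AUC difference.

    Both cohorts are resampled with replacement per replicate; the fitted
    model is held fixed and its predictions scored on each resample.  The CI
    is the 2.5-97.5% quantile interval over replicate differences.
    """
    if len(cohort_internal) == 0 or len(cohort_external) == 0:
        raise ValueError("both cohorts must be non-empty")
    horizons = tuple(float(h) for h in np.atleast_1d(horizons))
    rng = np.random.default_rng(seed)

    pre = {}
    for label, cohort in (("int", cohort_internal), ("ext", cohort_external)):
        t = cohort.table["time"].to_numpy(float)
        d = cohort.table["event"].to_numpy(int)
        markers = {(h, o): predicted_risks(cohort, params, h, o, encoding)
                   for h in horizons for o in outcomes}
        pre[label] = (t, d, markers, len(cohort))

    diffs: dict[tuple[float, str], list[float]] = {
        (h, o): [] for h in horizons for o in outcomes}
    for _ in range(n_boot):
        idx_i = rng.integers(0, pre["int"][3], pre["int"][3])
        idx_e = rng.integers(0, pre["ext"][3], pre["ext"][3])
        for h in horizons:
            for o in outcomes:
                try:
                    t, d, mk, _ = pre["int"]
                    ci_mask, co_mask = _case_control_masks(t[idx_i], d[idx_i], h, o)
                    a_int = _auc_from_marker(mk[(h, o)][idx_i], ci_mask, co_mask)
                    t, d, mk, _ = pre["ext"]
                    ce_mask, cx_mask = _case_control_masks(t[idx_e], d[idx_e], h, o)
                    a_ext = _auc_from_marker(mk[(h, o)][idx_e], ce_mask, cx_mask)
                except ValueError:
                    continue
                diffs[(h, o)].append(a_int - a_ext)

    rows = []
    for (h, o), vals in diffs.items():
        arr = np.asarray(vals)
        if arr.size == 0:
            continue
        rows.append({"outcome": o, "horizon": h,
                     "median_diff": float(np.median(arr)),
                     "ci_low": float(np.quantile(arr, 0.025)),
                     "ci_high": float(np.quantile(arr, 0.975)),
                     "n_ok": int(arr.size)})
    return pd.DataFrame(rows)


@dataclass
class HLResult:
    """Hosmer-Lemeshow decile table and chi-square test."""

    table: pd.DataFrame
    statistic: float
    df: int
    pvalue: float


def hosmer_lemeshow(predicted, observed, n_groups: int = 10) -> HLResult:
    """Hosmer-Lemeshow test over quantile groups of predicted risk.

    statistic = sum_g (O_g - E_g)^2 / [E_g (1 - pbar_g)], df = groups - 2.
    Groups whose variance term vanishes are merged with a neighbor.  The
    p-value uses max(df, 1) so degenerate groupings still return a value
    (a zero statistic gives p = 1 regardless).
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have the same length")
    if np.any((predicted < 0) | (predicted > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")

    edges = np.unique(np.quantile(predicted, np.linspace(0, 1, n_groups + 1)))
    if edges.size < 2:
        group = np.zeros(predicted.size, dtype=int)
    else:
        group = np.clip(np.searchsorted(edges, predicted, side="right") - 1,
                        0, edges.size - 2)

    rows = []
    for g in np.unique(group):
        m = group == g
        rows.append({"n": int(m.sum()),
                     "observed_events": float(observed[m].sum()),
                     "expected_events": float(predicted[m].sum()),
                     "mean_predicted": float(predicted[m].mean()),
                     "observed_prop": float(observed[m].mean())})

    # merge groups with a vanishing variance term E_g (1 - pbar_g) into a
    # neighbor so the statistic stays defined
    def var_term(row):
        return row["expected_events"] * (1.0 - row["mean_predicted"])

    cleaned: list[dict] = []
    for row in rows:
        if cleaned and var_term(row) <= 0:
            prev = cleaned[-1]
            n_tot = prev["n"] + row["n"]
            prev["observed_events"] += row["observed_events"]
            prev["expected_events"] += row["expected_events"]
            prev["mean_predicted"] = (
                prev["mean_predicted"] * prev["n"]
                + row["mean_predicted"] * row["n"]) / n_tot
            prev["observed_prop"] = (
                prev["observed_prop"] * prev["n"]
                + row["observed_prop"] * row["n"]) / n_tot
            prev["n"] = n_tot
        else:
            cleaned.append(dict(row))
    if len(cleaned) > 1 and var_term(cleaned[0]) <= 0:
        nxt = cleaned[1]
        first = cleaned.pop(0)
        n_tot = first["n"] + nxt["n"]
        nxt["observed_events"] += first["observed_events"]
        nxt["expected_events"] += first["expected_events"]
        nxt["mean_predicted"] = (first["mean_predicted"] * first["n"]
                                 + nxt["mean_predicted"] * nxt["n"]) / n_tot
        nxt["observed_prop"] = (first["observed_prop"] * first["n"]
                                + nxt["observed_prop"] * nxt["n"]) / n_tot
        nxt["n"] = n_tot

    stat = 0.0
    for row in cleaned:
        v = var_term(row)
        if v > 0:
            stat += (row["observed_events"] - row["expected_events"]) ** 2 / v
    g = len(cleaned)
    df = g - 2
    pvalue = float(stats.chi2.sf(stat, max(df, 1)))
    table = pd.DataFrame(cleaned)
    table.insert(0, "group", np.arange(1, g + 1))
    return HLResult(table=table, statistic=float(stat), df=df, pvalue=pvalue)


@dataclass
class GofResult:
    """Kaplan-Meier vs model mixture-survival overlay."""

    grid: np.ndarray
    km: np.ndarray
    model_f5: np.ndarray
    discrepancy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.grid, "km": self.km,
                             "model_f5": self.model_f5})


def km_vs_model_gof(cohort: Cohort, fit: FitResult | ModelParameters,
                    encoding: EncodingConfig | None = None) -> GofResult:
    """Sup-norm discrepancy between KM all-cause survival and model f5.

    ``fit`` must be an intercept-only model (no candidate predictors), so a
    single f5 curve describes every patient.
    """
    from lifelines import KaplanMeierFitter

    params = fit.params if isinstance(fit, FitResult) else fit
    if params.dims != (1, 1, 1, 1, 1):
        raise ValueError("goodness-of-fit overlay requires an intercept-only fit")
    encoding = encoding or EncodingConfig()
    enc0 = encoding.with_terms({})

    t = cohort.table["time"].to_numpy(float)
    d = cohort.table["event"].to_numpy(int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=(d > 0).astype(int))
    grid = np.unique(t)
    km = kmf.survival_function_at_times(grid).to_numpy(dtype=float)

    mats = design_matrices(cohort.table.iloc[[0]], enc0)
    design = mats.row(0)
    from .likelihood import censored_survival_f5
    f5 = np.asarray(censored_survival_f5(grid, design, params), float)
    disc = float(np.max(np.abs(km - f5)))
    return GofResult(grid=grid, km=km, model_f5=f5, discrepancy=disc)


@dataclass
class ValidationReport:
    """Bundle of discrimination, calibration and GOF results."""

    auc_curve: pd.DataFrame
    auc_summary: pd.DataFrame | None
    hl: dict[tuple[float, str], HLResult]
    gof: GofResult | None
    auc_difference: pd.DataFrame | None = None


def validate_model(cohort: Cohort, params: ModelParameters | None = None,
                   encoding: EncodingConfig | None = None,
                   horizons=(2.0, 4.0), grid=None, n_boot: int = 0,
                   seed: int = 0, external: Cohort | None = None,
                   fit_kwargs: dict | None = None) -> ValidationReport:
    """One-stop validation: AUC curve, bootstrap CIs, HL calibration, GOF.

    Horizons are landmark-years (2 and 4 correspond to 3 and 5 post-surgery
    years).  ``n_boot`` > 0 adds bootstrap cross-validated AUC CIs; an
    ``external`` cohort adds the AUC-difference CI (fixed 200 replicates).
    """
    params = params or published_parameters()
    encoding = encoding or EncodingConfig()
    horizons = tuple(float(h) for h in np.atleast_1d(horizons))
    if grid is None:
        grid = np.round(np.linspace(0.5, max(horizons), 8), 6)

    curve = auc_curve(cohort, params, grid, encoding=encoding)

    summary = None
    if n_boot > 0:
        summary = bootstrap_auc_cv(cohort, encoding, horizons=horizons,
                                   n_boot=n_boot, seed=seed,
                                   fit_kwargs=fit_kwargs).summary

    hl: dict[tuple[float, str], HLResult] = {}
    t = cohort.table["time"].to_numpy(float)
    d = cohort.table["event"].to_numpy(int)
    for h in horizons:
        for outcome in OUTCOMES:
            pred = predicted_risks(cohort, params, h, outcome, encoding)
            obs = ((d > 0) & (t <= h)) if outcome == "allcause" \
                else ((d == 1) & (t <= h))
            hl[(h, outcome)] = hosmer_lemeshow(pred, obs.astype(float))

    gof = None
    try:
        fit0 = fit_mle(cohort, encoding=encoding.with_terms({}),
                       compute_se=False, n_starts=1)
        if fit0.converged:
            gof = km_vs_model_gof(cohort, fit0, encoding)
    except Exception:
        gof = None

    diff = None
    if external is not None:
        diff = auc_difference_ci(cohort, external, params, horizons=horizons,
                                 seed=seed, encoding=encoding)
    return ValidationReport(auc_curve=curve, auc_summary=summary, hl=hl,
                            gof=gof, auc_difference=diff)
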