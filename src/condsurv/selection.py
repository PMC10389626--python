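"""Bootstrap stability variable selection.

Candidate predictors are tested one at a time against the accumulating model,
parameter by parameter in a fixed order (eta, alpha, phi, gamma, rho), and
retained when the Wald p-value falls below the significance level.  Within
each parameter except rho, pairwise interactions of the retained terms are
then tested the same way.  The whole procedure is repeated on bootstrap
resamples of the cohort; a term enters the final model when it is selected in
more than half of the replicates.  Age and sex are forced in a priori (age
and sex in eta, age in alpha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .encoding import EncodingConfig, PARAM_NAMES, param_coef_names
from .likelihood import FitResult, fit_mle

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES = ("education_gt12", "cci", "scc", "chemo", "stage",
                      "margin", "reoperation")


def _default_forced() -> dict[str, tuple[str, ...]]:
    return {"eta": ("age", "female"), "alpha": ("age",)}


@dataclass(frozen=True, eq=False)
class SelectionConfig:
    """Candidates, forced-in terms, test order and bootstrap settings."""

    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    forced: Mapping[str, tuple[str, ...]] = field(default_factory=_default_forced)
    order: tuple[str, ...] = ("eta", "alpha", "phi", "gamma", "rho")
    level: float = 0.05
    n_boot: int = 100
    threshold: int | None = None       # selected when count > threshold
    test_interactions: bool = True
    statistic: str = "wald"            # or "lr"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.threshold is not None and not (0 < self.threshold <= self.n_boot):
            raise ValueError("threshold must be in (0, n_boot]")
        if self.statistic not in ("wald", "lr"):
            raise ValueError("statistic must be 'wald' or 'lr'")

    @property
    def effective_threshold(self) -> int:
        return self.threshold if self.threshold is not None else self.n_boot // 2


def wald_pvalue(fit: FitResult, term) -> float:
    """Two-sided Wald p-value for one coefficient or a coefficient group.

    ``term`` is a flat coefficient name (e.g. "eta.margin") or a sequence of
    them; groups use the multi-df quadratic form with the covariance block.
    """
    if not fit.se_available or fit.cov is None:
        raise ValueError("fit covariance unavailable: cannot compute Wald test")
    names = [term] if isinstance(term, str) else list(term)
    idx = [fit.index_of(n) for n in names]
    theta = fit.params.flat()[idx]
    if len(idx) == 1:
        se = fit.se[idx[0]]
        if not np.isfinite(se) or se <= 0:
            raise ValueError(f"standard error unavailable for {names[0]}")
        z = theta[0] / se
        return float(2.0 * stats.norm.sf(abs(z)))
    C = fit.cov[np.ix_(idx, idx)]
    stat = float(theta @ np.linalg.solve(C, theta))
    return float(stats.chi2.sf(stat, df=len(idx)))


def lr_pvalue(loglik_full: float, loglik_base: float, df: int) -> float:
    stat = max(0.0, 2.0 * (loglik_full - loglik_base))
    return float(stats.chi2.sf(stat, df=df))


@dataclass
class SelectionPath:
    """Outcome of one pass of the sequential procedure."""

    selected: dict[str, tuple[str, ...]]
    log: list[str] = field(default_factory=list)


def _extended_init(base_fit: FitResult | None, encoding: EncodingConfig
                   ) -> np.ndarray | None:
    """Warm start: copy matching coefficients, zero the new ones."""
    if base_fit is None:
        return None
    target_names = []
    for p in PARAM_NAMES:
        for n in param_coef_names(p, encoding.terms.get(p, ()), encoding):
            target_names.append(f"{p}.{n}")
    src = dict(zip(base_fit.names, base_fit.params.flat()))
    return np.array([src.get(n, 0.0) for n in target_names])


def _term_flat_names(param: str, term: str, cfg: EncodingConfig) -> list[str]:
    from .encoding import term_columns
    return [f"{param}.{n}" for n, _ in term_columns(term, param, cfg)]


def select_once(cohort: Cohort, config: SelectionConfig | None = None,
                encoding: EncodingConfig | None = None,
                fit_kwargs: dict | None = None) -> SelectionPath:
    """One pass of the sequential per-parameter testing procedure."""
    config = config or SelectionConfig()
    base_encoding = encoding or EncodingConfig()
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_starts", 1)

    current: dict[str, list[str]] = {
        p: list(config.forced.get(p, ())) for p in PARAM_NAMES}
    log: list[str] = []

    def enc_for(terms: Mapping[str, Sequence[str]]) -> EncodingConfig:
        return base_encoding.with_terms(terms)

    def fit_model(terms, init):
        enc = enc_for(terms)
        need_se = config.statistic == "wald"
        fit = fit_mle(cohort, encoding=enc,
                      init=_extended_init(init, enc),
                      compute_se=need_se, **fit_kwargs)
        if not fit.converged:
            raise RuntimeError("fit did not converge")
        return fit

    try:
        base_fit = fit_model(current, None)
    except Exception as exc:
        log.append(f"base fit failed: {exc}")
        return SelectionPath(
            selected={p: tuple(v) for p, v in current.items()}, log=log)

    def test_term(param: str, term: str) -> None:
        nonlocal base_fit
        trial = {p: list(v) for p, v in current.items()}
        trial[param].append(term)
        enc = enc_for(trial)
        try:
            fit = fit_model(trial, base_fit)
            coef_names = _term_flat_names(param, term, enc)
            if config.statistic == "wald":
                p_val = wald_pvalue(fit, coef_names)
            else:
                p_val = lr_pvalue(fit.loglik, base_fit.loglik,
                                  df=len(coef_names))
        except Exception as exc:
            log.append(f"{param}+{term}: fit failed ({exc}); not selected")
            return
        if p_val < config.level:
            current[param].append(term)
            base_fit = fit
            log.append(f"{param}+{term}: p={p_val:.4g} -> retained")
        else:
            log.append(f"{param}+{term}: p={p_val:.4g} -> dropped")

    for param in config.order:
        for term in config.candidates:
            if term in current[param]:
                continue
            test_term(param, term)
        if param != "rho" and config.test_interactions:
            for t1, t2 in combinations(list(current[param]), 2):
                test_term(param, f"{t1}:{t2}")

    return SelectionPath(selected={p: tuple(v) for p, v in current.items()},
                         log=log)


@dataclass
class SelectionResult:
    """Inclusion counts over bootstrap replicates and the final term sets."""

    counts: pd.DataFrame          # columns: parameter, term, count
    final: dict[str, tuple[str, ...]]
    n_boot: int
    threshold: int

    def count(self, param: str, term: str) -> int:
        m = (self.counts["parameter"] == param) & (self.counts["term"] == term)
        sub = self.counts.loc[m, "count"]
        return int(sub.iloc[0]) if len(sub) else 0


def stability_selection(cohort: Cohort, config: SelectionConfig | None = None,
                        encoding: EncodingConfig | None = None,
                        fit_kwargs: dict | None = None) -> SelectionResult:
    """Repeat :func:`select_once` on seeded bootstrap resamples.

    Resamples are drawn with replacement at the cohort size.  A term enters
    the final model when its inclusion count exceeds the threshold (default:
    more than half of the replicates).  Forced-in terms are always final.
    """
    config = config or SelectionConfig()
    n = len(cohort)
    rng = np.random.default_rng(config.seed)
    counts: dict[tuple[str, str], int] = {}
    for param in PARAM_NAMES:
        for term in config.candidates:
            counts[(param, term)] = 0

    for b in range(config.n_boot):
        idx = rng.integers(0, n, n)
        sub = cohort.subset(idx, label=f"{cohort.label}-boot{b}")
        path = select_once(sub, config, encoding, fit_kwargs)
        for param, terms in path.selected.items():
            for term in terms:
                counts[(param, term)] = counts.get((param, term), 0) + 1

    threshold = config.effective_threshold
    final: dict[str, tuple[str, ...]] = {}
    for param in PARAM_NAMES:
        forced = list(config.forced.get(param, ()))
        chosen = [t for (p, t), c in counts.items()
                  if p == param and c > threshold and t not in forced]
        final[param] = tuple(forced + chosen)

    table = pd.DataFrame(
        [{"parameter": p, "term": t, "count": c}
         for (p, t), c in sorted(counts.items())])
    return SelectionResult(counts=table, final=final, n_boot=config.n_boot,
                           threshold=threshold)
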