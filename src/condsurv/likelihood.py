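"""Competing-risks mixture likelihood for survival beyond the 1-year landmark.

The model factorizes each patient's contribution into a logistic
cause-assignment probability and a cause-conditional parametric survival
function on the landmark time scale:

* f2(d=1 | x) = expit(x_alpha' alpha) is the probability that the eventual
  death is from esophageal cancer (d=2, other causes, gets the complement);
* S4(t | d, x) = link(v) with the time index
  v(t | d, x) = 1{d=1} x_gamma' gamma + x_eta' eta
                + u(t) x_phi' phi + 1{d=1} u(t) x_rho' rho,
  where u(t) = log t for the log-logistic and Weibull families and u(t) = t
  for the Gompertz family.  The log-logistic link is the inverse logit,
  S4 = expit(v); the alternatives use the complementary log-log link
  S4 = exp(-exp(-v)) and exist for AIC comparison only.

Observed deaths are interval censored to the recording resolution (one day by
default) and contribute f2(d | x) * [S4(t) - S4(t + delta)]; censored records
contribute the mixture survival f5(t | x) = sum_j S4(t | j, x) f2(j | x).

S4 decreases in t whenever the log-time (resp. time) slope is negative for
both causes: phi0 < 0 and phi0 + rho0 < 0 for the intercept-only time terms.
Fits violating this are flagged, not rejected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .cohort import Cohort
from .encoding import (DesignMatrices, DesignVectors, EncodingConfig,
                       PARAM_NAMES, design_matrices)

#: default interval width for daily interval censoring, in landmark-years
DAY = 1.0 / 365.25

FAMILIES = ("loglogistic", "weibull", "gompertz")

_INVALID = 1e12  # objective value returned to the optimizer off the support


@dataclass
class ModelParameters:
    """Full coefficient set (alpha, eta, phi, gamma, rho) plus family.

    ``names`` optionally carries the coefficient names per parameter block in
    the same order as the arrays (intercept first).
    """

    alpha: np.ndarray
    eta: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    rho: np.ndarray
    family: str = "loglogistic"
    names: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self):
        for p in PARAM_NAMES:
            setattr(self, p, np.atleast_1d(np.asarray(getattr(self, p), float)))
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(getattr(self, p).size for p in PARAM_NAMES)

    @property
    def n_coef(self) -> int:
        return sum(self.dims)

    def block(self, param: str) -> np.ndarray:
        return getattr(self, param)

    def flat(self) -> np.ndarray:
        return np.concatenate([getattr(self, p) for p in PARAM_NAMES])

    def flat_names(self) -> tuple[str, ...]:
        out = []
        for p in PARAM_NAMES:
            nm = (self.names or {}).get(p)
            if nm is None:
                nm = tuple(f"b{i}" for i in range(getattr(self, p).size))
            out.extend(f"{p}.{n}" for n in nm)
        return tuple(out)

    def with_flat(self, theta: np.ndarray) -> "ModelParameters":
        theta = np.asarray(theta, float)
        if theta.size != self.n_coef:
            raise ValueError("flat vector length mismatch")
        parts = np.split(theta, np.cumsum(self.dims)[:-1])
        return ModelParameters(*parts, family=self.family, names=self.names)

    def monotone_ok(self) -> bool:
        """True when S4 is decreasing in t for both causes (intercept check)."""
        b2 = self.phi[0]
        b1 = self.phi[0] + self.rho[0]
        return bool(b2 < 0 and b1 < 0)

    # -- flat key-value text serialization -------------------------------
    def to_text(self) -> str:
        lines = [f"family = {self.family}"]
        for name, val in zip(self.flat_names(), self.flat()):
            lines.append(f"{name} = {float(val)!r}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_text())
        return path

    @classmethod
    def from_text(cls, text: str) -> "ModelParameters":
        family = "loglogistic"
        blocks: dict[str, list[float]] = {p: [] for p in PARAM_NAMES}
        names: dict[str, list[str]] = {p: [] for p in PARAM_NAMES}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "family":
                family = val
                continue
            block, _, coef = key.partition(".")
            if block not in PARAM_NAMES:
                raise ValueError(f"unknown coefficient {key!r}")
            blocks[block].append(float(val))
            names[block].append(coef)
        return cls(*(np.asarray(blocks[p]) for p in PARAM_NAMES),
                   family=family,
                   names={p: tuple(names[p]) for p in PARAM_NAMES})

    @classmethod
    def load(cls, path) -> "ModelParameters":
        return cls.from_text(Path(path).read_text())


def published_parameters() -> ModelParameters:
    """The published final-model coefficients shipped with the package."""
    text = resources.files("condsurv").joinpath("data/published_model.txt") \
        .read_text()
    return ModelParameters.from_text(text)


# ---------------------------------------------------------------------------
# elementary model functions
# ---------------------------------------------------------------------------

def _time_u(t, family: str):
    return np.asarray(t, float) if family == "gompertz" else np.log(t)


def _sf(v, family: str):
    if family == "loglogistic":
        return expit(v)
    with np.errstate(over="ignore", under="ignore"):
        return np.exp(-np.exp(-np.asarray(v, float)))


def _dsf_dv(v, family: str):
    """Derivative of the survival link with respect to v."""
    if family == "loglogistic":
        s = expit(v)
        return s * (1.0 - s)
    with np.errstate(over="ignore", under="ignore"):
        ev = np.exp(-np.asarray(v, float))
        return np.exp(-ev) * ev


def cause_probability(x_alpha: np.ndarray, alpha: np.ndarray):
    """f2(d=1 | x): probability that the eventual death is cancer-related."""
    x_alpha = np.asarray(x_alpha, float)
    alpha = np.asarray(alpha, float)
    if x_alpha.shape[-1] != alpha.shape[-1]:
        raise ValueError(
            f"design length {x_alpha.shape[-1]} != coefficient length "
            f"{alpha.shape[-1]}")
    return expit(x_alpha @ alpha)


def time_index_v(t, d: int, design: DesignVectors, params: ModelParameters):
    """The linear time index v(t | d, x); t may be scalar or array, > 0."""
    t = np.asarray(t, float)
    if np.any(t <= 0):
        raise ValueError("t must be positive (landmark-years)")
    if d not in (1, 2):
        raise ValueError("cause d must be 1 or 2")
    for p in ("eta", "phi", "gamma", "rho"):
        if design.vector(p).shape[-1] != params.block(p).size:
            raise ValueError(f"design/coefficient length mismatch for {p}")
    u = _time_u(t, params.family)
    v = design.x_eta @ params.eta + u * (design.x_phi @ params.phi)
    if d == 1:
        v = v + design.x_gamma @ params.gamma + u * (design.x_rho @ params.rho)
    return v


def survival_S4(t, d: int, design: DesignVectors, params: ModelParameters):
    """Cause-conditional survival S4(t | d, x)."""
    return _sf(time_index_v(t, d, design, params), params.family)


def interval_death_density_f4(t, d: int, design: DesignVectors,
                              params: ModelParameters, delta: float = DAY):
    """Interval mass S4(t) - S4(t + delta) of dying in [t, t + delta)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    out = survival_S4(t, d, design, params) - \
        survival_S4(np.asarray(t, float) + delta, d, design, params)
    if np.any(out < -1e-15):
        raise FloatingPointError(
            "negative interval mass: S4 is not decreasing at these parameters")
    return out


def censored_survival_f5(t, design: DesignVectors, params: ModelParameters):
    """Mixture survival f5(t | x) = sum_j S4(t | j, x) f2(j | x)."""
    p1 = cause_probability(design.x_alpha, params.alpha)
    s1 = survival_S4(t, 1, design, params)
    s2 = survival_S4(t, 2, design, params)
    return p1 * s1 + (1.0 - p1) * s2


# ---------------------------------------------------------------------------
# log-likelihood and analytic gradient on design matrices
# ---------------------------------------------------------------------------

def _loglik_grad(theta: np.ndarray, mats: DesignMatrices, family: str,
                 delta: float, want_grad: bool = True):
    """Sum of per-record log contributions and its gradient.

    Returns (-inf, None) when any contribution is non-positive (e.g. a
    non-monotone S4 makes an interval mass negative).
    """
    ka, ke, kp, kg, kr = mats.dims
    a, e, p, g, r = np.split(theta, np.cumsum([ka, ke, kp, kg])[:4])
    t = mats.t
    d = mats.d
    lin_a = mats.Xa @ a
    p1 = expit(lin_a)

    with np.errstate(over="ignore", under="ignore", divide="ignore",
                     invalid="ignore"):
        u = t.copy() if family == "gompertz" else np.log(t)
        xe = mats.Xe @ e
        xp = mats.Xp @ p
        xg = mats.Xg @ g
        xr = mats.Xr @ r
        v2 = xe + u * xp
        v1 = v2 + xg + u * xr

        ev = d > 0
        cz = ~ev
        te = t[ev]
        u2e = (te + delta) if family == "gompertz" else np.log(te + delta)
        v2b = xe[ev] + u2e * xp[ev]
        v1b = v2b + xg[ev] + u2e * xr[ev]
        is1 = d[ev] == 1
        w = np.where(is1, v1[ev], v2[ev])
        wb = np.where(is1, v1b, v2b)
        s = _sf(w, family)
        sb = _sf(wb, family)
        f4 = s - sb
        pe = np.where(is1, p1[ev], 1.0 - p1[ev])

        s1 = _sf(v1[cz], family)
        s2 = _sf(v2[cz], family)
        p1c = p1[cz]
        f5 = p1c * s1 + (1.0 - p1c) * s2

        bad = ((f4.size > 0 and float(f4.min()) <= 0.0)
               or (f5.size > 0 and float(f5.min()) <= 0.0)
               or (pe.size > 0 and float(pe.min()) <= 0.0))
        if bad:
            return -np.inf, None
        ll = float(np.log(pe).sum() + np.log(f4).sum() + np.log(f5).sum())
        if not math.isfinite(ll):
            return -np.inf, None
        if not want_grad:
            return ll, None

        # gradient ---------------------------------------------------------
        inv4 = 1.0 / f4
        inv5 = 1.0 / f5
        A = _dsf_dv(w, family)
        Ab = _dsf_dv(wb, family)
        A1 = _dsf_dv(v1[cz], family)
        A2 = _dsf_dv(v2[cz], family)
        ue = u[ev]
        uc = u[cz]
        one1 = is1.astype(float)

        wa_ev = one1 - p1[ev]
        wa_cz = (s1 - s2) * p1c * (1.0 - p1c) * inv5
        ga = mats.Xa[ev].T @ wa_ev + mats.Xa[cz].T @ wa_cz

        we_eta = (A - Ab) * inv4
        we_phi = (A * ue - Ab * u2e) * inv4
        we_gam = one1 * we_eta
        we_rho = one1 * we_phi
        wc_eta = (p1c * A1 + (1.0 - p1c) * A2) * inv5
        wc_phi = wc_eta * uc
        wc_gam = p1c * A1 * inv5
        wc_rho = wc_gam * uc

        ge = mats.Xe[ev].T @ we_eta + mats.Xe[cz].T @ wc_eta
        gp = mats.Xp[ev].T @ we_phi + mats.Xp[cz].T @ wc_phi
        gg = mats.Xg[ev].T @ we_gam + mats.Xg[cz].T @ wc_gam
        gr = mats.Xr[ev].T @ we_rho + mats.Xr[cz].T @ wc_rho
        grad = np.concatenate([ga, ge, gp, gg, gr])
        if not np.all(np.isfinite(grad)):
            return -np.inf, None
    return ll, grad


def _check_dims(mats: DesignMatrices, params: ModelParameters):
    if mats.dims != params.dims:
        raise ValueError(
            f"design dims {mats.dims} do not match coefficient dims "
            f"{params.dims}")


def log_likelihood(cohort: Cohort, params: ModelParameters,
                   encoding: EncodingConfig | None = None,
                   delta: float = DAY) -> float:
    """Model log-likelihood of a cohort; -inf off the support."""
    mats = design_matrices(cohort.table, encoding)
    _check_dims(mats, params)
    ll, _ = _loglik_grad(params.flat(), mats, params.family, delta,
                         want_grad=False)
    return ll


# ---------------------------------------------------------------------------
# maximum likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A converged (or not) maximum-likelihood fit."""

    params: ModelParameters
    loglik: float
    aic: float
    names: tuple[str, ...]
    converged: bool
    n_iter: int
    grad_norm: float
    monotone_warning: bool
    se: np.ndarray | None = None
    cov: np.ndarray | None = None
    se_available: bool = False
    message: str = ""
    n_obs: int = 0

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def coef_table(self) -> pd.DataFrame:
        se = self.se if self.se is not None else np.full(len(self.names), np.nan)
        return pd.DataFrame({"coefficient": list(self.names),
                             "estimate": self.params.flat(),
                             "se": se})


def _default_init(mats: DesignMatrices) -> np.ndarray:
    ka, ke, kp, kg, kr = mats.dims
    a = np.zeros(ka)
    e = np.zeros(ke)
    e[0] = 1.0
    p = np.zeros(kp)
    p[0] = -0.5
    g = np.zeros(kg)
    r = np.zeros(kr)
    r[0] = -0.1
    return np.concatenate([a, e, p, g, r])


def _numeric_hessian(fun_grad, theta: np.ndarray) -> np.ndarray:
    """Hessian of the objective by central differences of its gradient."""
    k = theta.size
    H = np.zeros((k, k))
    for i in range(k):
        h = 1e-5 * (1.0 + abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        if gp is None or gm is None:
            return np.full((k, k), np.nan)
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_mle(cohort: Cohort, encoding: EncodingConfig | None = None,
            family: str = "loglogistic",
            init: ModelParameters | np.ndarray | None = None,
            delta: float = DAY, n_starts: int = 3, jitter: float = 0.1,
            seed: int = 0, tol: float = 1e-8, max_iter: int = 1000,
            compute_se: bool = True) -> FitResult:
    """Maximize the mixture likelihood by quasi-Newton (BFGS) iteration.

    Several jittered starting points (default 3) guard against local maxima;
    standard errors come from the inverted observed-information matrix
    (numeric Hessian of the negative log-likelihood at the optimum).
    """
    if len(cohort) == 0:
        raise ValueError("cannot fit an empty cohort")
    encoding = encoding or EncodingConfig()
    mats = design_matrices(cohort.table, encoding)
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    for cause in (1, 2):
        if not np.any(mats.d == cause):
            warnings.warn(f"no deaths of cause {cause}: fit may be degenerate",
                          stacklevel=2)

    if init is None:
        x0 = _default_init(mats)
    elif isinstance(init, ModelParameters):
        x0 = init.flat()
    else:
        x0 = np.asarray(init, float)
    if x0.size != sum(mats.dims):
        raise ValueError("init length does not match the encoding")

    def fun_grad(theta):
        return _loglik_grad(theta, mats, family, delta, want_grad=True)

    def neg(theta):
        ll, g = fun_grad(theta)
        if not math.isfinite(ll):
            return _INVALID, np.zeros_like(theta)
        return -ll, -g

    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0.0, jitter, x0.size)
                     for _ in range(max(0, n_starts - 1))]

    best = None
    for s in starts:
        f0, _ = neg(s)
        gtol = max(tol * (1.0 + abs(f0 if f0 < _INVALID else 0.0)), 1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(neg, s, jac=True, method="BFGS",
                                    options={"gtol": gtol,
                                             "maxiter": max_iter})
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    ll = -float(best.fun)
    grad_norm = float(np.max(np.abs(best.jac)))
    converged = bool(best.success) or grad_norm < 1e-4 * (1.0 + abs(best.fun))
    if ll <= -_INVALID / 2:
        converged = False

    k = theta.size
    parts = np.split(theta, np.cumsum(mats.dims)[:-1])
    params = ModelParameters(*parts, family=family,
                             names={p: mats.names[p] for p in PARAM_NAMES})
    names = params.flat_names()

    se = cov = None
    se_available = False
    if compute_se and converged:
        H = _numeric_hessian(lambda th: neg(th), theta)
        with np.errstate(all="ignore"):
            try:
                cov = np.linalg.inv(H)
                diag = np.diag(cov)
                if np.all(np.isfinite(diag)) and np.all(diag > 0):
                    se = np.sqrt(diag)
                    se_available = True
                else:
                    raise np.linalg.LinAlgError("non-positive variance")
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
                diag = np.diag(cov)
                se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
                se_available = False

    return FitResult(
        params=params, loglik=ll, aic=2.0 * k - 2.0 * ll, names=names,
        converged=converged, n_iter=int(best.nit), grad_norm=grad_norm,
        monotone_warning=not params.monotone_ok(),
        se=se, cov=cov, se_available=se_available,
        message=str(best.message), n_obs=len(cohort))


def compare_families(cohort: Cohort, encoding: EncodingConfig | None = None,
                     families: Sequence[str] = FAMILIES,
                     **fit_kwargs) -> pd.DataFrame:
    """Fit each candidate time-distribution family and rank them by AIC."""
    rows = []
    for family in families:
        try:
            fit = fit_mle(cohort, encoding=encoding, family=family,
                          compute_se=False, **fit_kwargs)
            rows.append({"family": family, "k": fit.params.n_coef,
                         "loglik": fit.loglik, "aic": fit.aic,
                         "converged": fit.converged})
        except Exception as exc:  # fit failures are reported per family
            rows.append({"family": family, "k": np.nan, "loglik": np.nan,
                         "aic": np.nan, "converged": False,
                         "error": str(exc)})
    out = pd.DataFrame(rows)
    return out.sort_values("aic", na_position="last").reset_index(drop=True)
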