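"""Cumulative incidence and conditional-risk prediction (the calculator core).

Cause-specific cumulative incidence under the mixture model:

    CIF_cancer(t) = [1 - S4(t | d=1, x)] f2(d=1 | x)
    CIF_other(t)  = [1 - S4(t | d=2, x)] [1 - f2(d=1 | x)]
    CIF(t)        = CIF_cancer(t) + CIF_other(t) = 1 - f5(t | x)

and, for a patient who has already survived t0 landmark-years, the
conditional risks over an additional horizon t:

    CIF_cancer(t | t > t0) = [CIF_cancer(t + t0) - CIF_cancer(t0)] / [1 - CIF(t0)]
    CIF(t | t > t0)        = 1 - [1 - CIF(t + t0)] / [1 - CIF(t0)]

The time origin is the 1-year post-surgery landmark; the public risk-table
interface accepts post-surgery years (>= 1) and shifts internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .encoding import DesignVectors, EncodingConfig, encode_design
from .likelihood import ModelParameters, cause_probability, survival_S4

#: calculator support in post-surgery years
T0_MIN_POST_SURGERY = 1.0
HORIZON_MAX_POST_SURGERY = 5.0


def cif(t, design: DesignVectors, params: ModelParameters):
    """(cif_cancer, cif_other, cif_total) at time t (scalar or array, >= 0).

    t = 0 is the landmark itself, where all incidences are 0 by definition.
    """
    t_arr = np.asarray(t, float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative (landmark-years)")
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    pos = t_arr > 0
    s1 = np.ones_like(t_arr)
    s2 = np.ones_like(t_arr)
    if pos.any():
        s1[pos] = survival_S4(t_arr[pos], 1, design, params)
        s2[pos] = survival_S4(t_arr[pos], 2, design, params)
    p1 = cause_probability(design.x_alpha, params.alpha)
    cifc = (1.0 - s1) * p1
    cifo = (1.0 - s2) * (1.0 - p1)
    cift = cifc + cifo
    if scalar:
        return float(cifc[0]), float(cifo[0]), float(cift[0])
    return cifc, cifo, cift


@dataclass
class CIFCurves:
    """Cause-specific and total cumulative incidence on a time grid."""

    time: np.ndarray
    cif_cancer: np.ndarray
    cif_other: np.ndarray
    cif_total: np.ndarray
    profile: DesignVectors | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time,
                             "cif_cancer": self.cif_cancer,
                             "cif_other": self.cif_other,
                             "cif_total": self.cif_total})


def cif_curves(design: DesignVectors, params: ModelParameters,
               grid: np.ndarray) -> CIFCurves:
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    cc, co, ct = cif(grid, design, params)
    return CIFCurves(time=grid, cif_cancer=cc, cif_other=co, cif_total=ct,
                     profile=design)


@dataclass
class ConditionalRisk:
    """Conditional risks over an extra horizon, given survival to t0."""

    t0: float                    # landmark-years already survived
    horizon: float               # additional years
    cif_cancer: float
    cif_allcause: float


def conditional_cif(t_add: float, t0: float, design: DesignVectors,
                    params: ModelParameters) -> ConditionalRisk:
    """Conditional cancer-specific and all-cause risks.

    ``t0`` is on the landmark scale; t0 = 0 means "survived exactly one
    post-surgery year" and reduces to the unconditional CIF at ``t_add``.
    """
    if t0 < 0 or t_add < 0:
        raise ValueError("t0 and t_add must be non-negative")
    if t_add == 0:
        return ConditionalRisk(t0=t0, horizon=0.0, cif_cancer=0.0,
                               cif_allcause=0.0)
    cc0, _, ct0 = cif(t0, design, params)
    if ct0 >= 1.0 - 1e-12:
        raise ValueError(f"CIF({t0}) is numerically 1: no survivors to condition on")
    cc1, _, ct1 = cif(t0 + t_add, design, params)
    denom = 1.0 - ct0
    return ConditionalRisk(
        t0=t0, horizon=t_add,
        cif_cancer=(cc1 - cc0) / denom,
        cif_allcause=1.0 - (1.0 - ct1) / denom)


def risk_table(profile: PatientRecord, t0_post_surgery: float,
               horizons, params: ModelParameters,
               encoding: EncodingConfig | None = None,
               allow_beyond_cap: bool = False) -> pd.DataFrame:
    """Tabulate conditional risks for a patient profile.

    ``t0_post_surgery`` is in post-surgery years (the calculator's public
    scale, >= 1); horizons are additional years.  The supported domain is
    t0 + horizon <= 5 post-surgery years, the follow-up on which the model
    was developed; set ``allow_beyond_cap`` to extrapolate (with a warning).
    """
    horizons = np.atleast_1d(np.asarray(horizons, float))
    if t0_post_surgery < T0_MIN_POST_SURGERY:
        raise ValueError(
            f"t0 must be at least {T0_MIN_POST_SURGERY} post-surgery year "
            f"(supported domain 1-{HORIZON_MAX_POST_SURGERY} years)")
    if t0_post_surgery + float(horizons.max()) > HORIZON_MAX_POST_SURGERY + 1e-9:
        if not allow_beyond_cap:
            raise ValueError(
                f"t0 + horizon exceeds the {HORIZON_MAX_POST_SURGERY}-year "
                "post-surgery support of the model "
                f"(supported domain 1-{HORIZON_MAX_POST_SURGERY} years)")
        warnings.warn("extrapolating beyond the 5-year post-surgery support",
                      stacklevel=2)
    design = encode_design(profile, encoding)
    t0 = t0_post_surgery - 1.0
    rows = []
    for h in horizons:
        r = conditional_cif(float(h), t0, design, params)
        rows.append({
            "t0_post_surgery_years": t0_post_surgery,
            "horizon_years": float(h),
            "conditional_allcause": r.cif_allcause,
            "conditional_cancer": r.cif_cancer,
            "conditional_allcause_pct": 100.0 * r.cif_allcause,
            "conditional_cancer_pct": 100.0 * r.cif_cancer,
        })
    return pd.DataFrame(rows)


def plot_cif_curves(curves: CIFCurves, path=None, title: str | None = None):
    """Plot the three incidence curves; returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curves.time, curves.cif_total, label="all-cause", color="k")
    ax.plot(curves.time, curves.cif_cancer, label="esophageal cancer")
    ax.plot(curves.time, curves.cif_other, label="other causes")
    ax.set_xlabel("years since 1-year post-surgery landmark")
    ax.set_ylabel("cumulative incidence")
    ax.set_ylim(0, 1)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
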