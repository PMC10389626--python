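"""Covariate encoding into the design vectors used by each model parameter.

Each of the five linear predictors (alpha, eta, phi, gamma, rho) has its own
design vector with an intercept first.  The final published model uses

    x_alpha = (1, age_scaled, SCC, chemo, stage II, stage III, stage IV, R1R2)
    x_eta   = (1, age_scaled, female, education>12, SCC, stage III, stage IV,
               R1R2, reoperation)          # stage II merged with 0-I
    x_phi = x_gamma = x_rho = (1,)

with age_scaled = (age - age_center) / age_scale.  Term names are symbolic
("age", "stage", "margin", ...); a name that matches no known term is taken
as a raw numeric column of the cohort table, which is how simulated extra
predictors enter selection studies.  "a:b" denotes the within-parameter
interaction of two terms (all pairwise column products).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

PARAM_NAMES = ("alpha", "eta", "phi", "gamma", "rho")

#: term sets of the final published model
FINAL_MODEL_TERMS: Mapping[str, tuple[str, ...]] = {
    "alpha": ("age", "scc", "chemo", "stage", "margin"),
    "eta": ("age", "female", "education_gt12", "scc", "stage", "margin",
            "reoperation"),
    "phi": (),
    "gamma": (),
    "rho": (),
}


def _final_terms() -> dict[str, tuple[str, ...]]:
    return {k: tuple(v) for k, v in FINAL_MODEL_TERMS.items()}


@dataclass(frozen=True, eq=False)
class EncodingConfig:
    """Age transform constants plus the term set entering each parameter.

    ``age_center`` defaults to the derivation-cohort median age (65.1 years)
    and ``age_scale`` to 10 years, so the age coefficient is per decade.
    ``merge_stage_ii_in_eta`` applies the published convention that in eta
    stage II shares the 0-I reference level.
    """

    age_center: float = 65.1
    age_scale: float = 10.0
    terms: Mapping[str, tuple[str, ...]] = field(default_factory=_final_terms)
    merge_stage_ii_in_eta: bool = True

    def with_terms(self, terms: Mapping[str, Sequence[str]]) -> "EncodingConfig":
        return EncodingConfig(
            age_center=self.age_center, age_scale=self.age_scale,
            terms={p: tuple(terms.get(p, ())) for p in PARAM_NAMES},
            merge_stage_ii_in_eta=self.merge_stage_ii_in_eta)


ColumnBuilder = Callable[[pd.DataFrame, EncodingConfig], np.ndarray]

_SIMPLE_TERMS: dict[str, ColumnBuilder] = {
    "age": lambda df, c: (df["age"].to_numpy(float) - c.age_center) / c.age_scale,
    "female": lambda df, c: (df["sex"] == "female").to_numpy(float),
    "education_gt12": lambda df, c: (df["education_gt12"] == "yes").to_numpy(float),
    "scc": lambda df, c: (df["histology"] == "squamous_cell_carcinoma").to_numpy(float),
    "chemo": lambda df, c: (df["chemoradiotherapy"] == "yes").to_numpy(float),
    "margin": lambda df, c: (df["margin"] == "r1r2").to_numpy(float),
    "reoperation": lambda df, c: (df["reoperation_30d"] == "yes").to_numpy(float),
}


def term_columns(term: str, param: str, cfg: EncodingConfig
                 ) -> list[tuple[str, ColumnBuilder]]:
    """Expand a symbolic term into named column builders for one parameter."""
    if ":" in term:
        left, right = term.split(":", 1)
        cols = []
        for n1, f1 in term_columns(left, param, cfg):
            for n2, f2 in term_columns(right, param, cfg):
                cols.append((f"{n1}:{n2}",
                             (lambda df, c, a=f1, b=f2: a(df, c) * b(df, c))))
        return cols
    if term in _SIMPLE_TERMS:
        return [(term, _SIMPLE_TERMS[term])]
    if term == "stage":
        levels = ("iii", "iv") if (param == "eta" and cfg.merge_stage_ii_in_eta) \
            else ("ii", "iii", "iv")
        return [(f"stage_{lev}",
                 (lambda df, c, L=lev: (df["stage"] == L).to_numpy(float)))
                for lev in levels]
    if term == "cci":
        return [("cci_1", lambda df, c: (df["cci"] == "1").to_numpy(float)),
                ("cci_2plus", lambda df, c: (df["cci"] == "2+").to_numpy(float))]
    # fallback: raw numeric column of the cohort table
    return [(term, (lambda df, c, name=term: df[name].to_numpy(float)))]


def param_coef_names(param: str, terms: Sequence[str],
                     cfg: EncodingConfig) -> tuple[str, ...]:
    names = ["intercept"]
    for term in terms:
        names.extend(n for n, _ in term_columns(term, param, cfg))
    return tuple(names)


def design_matrix(table: pd.DataFrame, param: str, cfg: EncodingConfig
                  ) -> tuple[np.ndarray, tuple[str, ...]]:
    """(n, k) design matrix for one parameter, intercept first."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in cfg.terms.get(param, ()):
        for name, fn in term_columns(term, param, cfg):
            names.append(name)
            cols.append(np.asarray(fn(table, cfg), dtype=float))
    return np.column_stack(cols), tuple(names)


@dataclass
class DesignVectors:
    """Encoded covariate vectors of a single patient, one per parameter."""

    x_alpha: np.ndarray
    x_eta: np.ndarray
    x_phi: np.ndarray
    x_gamma: np.ndarray
    x_rho: np.ndarray
    names: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def vector(self, param: str) -> np.ndarray:
        return getattr(self, f"x_{param}")


@dataclass
class DesignMatrices:
    """Stacked design vectors plus follow-up for a whole cohort."""

    Xa: np.ndarray
    Xe: np.ndarray
    Xp: np.ndarray
    Xg: np.ndarray
    Xr: np.ndarray
    names: dict[str, tuple[str, ...]]
    t: np.ndarray
    d: np.ndarray

    @property
    def dims(self) -> tuple[int, ...]:
        return (self.Xa.shape[1], self.Xe.shape[1], self.Xp.shape[1],
                self.Xg.shape[1], self.Xr.shape[1])

    def matrix(self, param: str) -> np.ndarray:
        return {"alpha": self.Xa, "eta": self.Xe, "phi": self.Xp,
                "gamma": self.Xg, "rho": self.Xr}[param]

    def row(self, i: int) -> DesignVectors:
        return DesignVectors(self.Xa[i], self.Xe[i], self.Xp[i], self.Xg[i],
                             self.Xr[i], names=self.names)


def design_matrices(table: pd.DataFrame, cfg: EncodingConfig | None = None
                    ) -> DesignMatrices:
    cfg = cfg or EncodingConfig()
    mats = {}
    names = {}
    for param in PARAM_NAMES:
        X, nm = design_matrix(table, param, cfg)
        mats[param] = X
        names[param] = nm
    t = table["time"].to_numpy(float) if "time" in table else np.ones(len(table))
    d = table["event"].to_numpy(int) if "event" in table else np.zeros(len(table), int)
    return DesignMatrices(Xa=mats["alpha"], Xe=mats["eta"], Xp=mats["phi"],
                          Xg=mats["gamma"], Xr=mats["rho"], names=names,
                          t=t, d=d)


def encode_design(record, cfg: EncodingConfig | None = None) -> DesignVectors:
    """Encode one :class:`~condsurv.cohort.PatientRecord` into design vectors.

    Reference levels contribute 0; vectors are ordered to match the
    coefficient order of :class:`~condsurv.likelihood.ModelParameters`.
    """
    cfg = cfg or EncodingConfig()
    row = {
        "patient_id": record.patient_id, "age": record.age, "sex": record.sex,
        "education_gt12": record.education_gt12, "cci": record.comorbidity,
        "histology": record.histology,
        "chemoradiotherapy": record.chemoradiotherapy, "stage": record.stage,
        "margin": record.margin, "reoperation_30d": record.reoperation_30d,
        "time": record.time, "event": record.event,
    }
    row.update(record.extras)
    mats = design_matrices(pd.DataFrame([row]), cfg)
    return mats.row(0)
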