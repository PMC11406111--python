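"""Quantitative silicosis risk: closed-form cumulative hazard and incidence.

A fitted proportional-hazards exposure-response model is frozen into a
:class:`PredictionFormula`: baseline cumulative hazard H0 and baseline
survival S0 at the 10/20/30-year horizons, the gender and cumulative-exposure
coefficients, and the covariate means used for centering.  For a male/female
indicator ``gender`` and cumulative silica exposure ``D`` (mg/m3-years),

    H_tau = H0(tau) * exp(b_g * (gender - mean_g) + b_D * (D - mean_D))
    I_tau = 1 - S0(tau) ** exp(b_g * (gender - mean_g) + b_D * (D - mean_D))

Two published formula sets are shipped: ``TOTAL_DUST_FORMULA`` (cumulative
exposure to total silica dust, D_t) and ``RESPIRABLE_DUST_FORMULA``
(respirable silica dust, D_r).  Risk projections over a dust survey assume
constant future exposure, D(tau) = current silica concentration x tau years.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HORIZONS",
    "PredictionFormula",
    "TOTAL_DUST_FORMULA",
    "RESPIRABLE_DUST_FORMULA",
    "UnknownHorizonError",
    "cumulative_hazard",
    "cumulative_incidence",
    "project_risk",
]

HORIZONS = (10, 20, 30)


class UnknownHorizonError(KeyError):
    """The requested horizon is not part of the formula."""


@dataclass(frozen=True)
class PredictionFormula:
    """Frozen exposure-response model evaluated at fixed horizons (years).

    ``baseline_H[tau]`` and ``baseline_S[tau]`` are the cumulative hazard and
    survival of the reference profile (covariates at their centering means).
    When both come from a fit, S0 = exp(-H0) exactly; when transcribed from
    rounded published constants they may disagree by up to 0.01.
    """

    model: str
    baseline_H: Mapping[int, float]
    baseline_S: Mapping[int, float]
    beta_gender: float
    beta_D: float
    mean_gender: float
    mean_D: float
    source: str = "fitted"

    def __post_init__(self) -> None:
        taus = sorted(self.baseline_H)
        if sorted(self.baseline_S) != taus:
            raise ValueError("baseline_H and baseline_S horizons differ")
        hs = [self.baseline_H[t] for t in taus]
        ss = [self.baseline_S[t] for t in taus]
        if any(b < a for a, b in zip(hs, hs[1:])):
            raise ValueError("baseline cumulative hazard must be nondecreasing")
        if any(b > a for a, b in zip(ss, ss[1:])):
            raise ValueError("baseline survival must be nonincreasing")
        if any(not (0.0 < s <= 1.0) for s in ss):
            raise ValueError("baseline survival must lie in (0, 1]")
        for t in taus:
            if abs(self.baseline_S[t] - math.exp(-self.baseline_H[t])) > 0.01:
                raise ValueError(
                    f"baseline S({t}) inconsistent with exp(-H({t})) "
                    f"beyond rounding (|diff| > 0.01)"
                )

    @property
    def horizons(self) -> tuple[int, ...]:
        return tuple(sorted(self.baseline_H))

    def linear_predictor(self, gender, D):
        g = np.asarray(gender, dtype=float)
        d = np.asarray(D, dtype=float)
        return self.beta_gender * (g - self.mean_gender) + self.beta_D * (
            d - self.mean_D
        )

    def hazard_ratios(self) -> dict[str, float]:
        return {
            "gender": math.exp(self.beta_gender),
            "D": math.exp(self.beta_D),
        }

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_H"] = {str(k): v for k, v in self.baseline_H.items()}
        d["baseline_S"] = {str(k): v for k, v in self.baseline_S.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PredictionFormula":
        return cls(
            model=d["model"],
            baseline_H={int(k): float(v) for k, v in d["baseline_H"].items()},
            baseline_S={int(k): float(v) for k, v in d["baseline_S"].items()},
            beta_gender=float(d["beta_gender"]),
            beta_D=float(d["beta_D"]),
            mean_gender=float(d["mean_gender"]),
            mean_D=float(d["mean_D"]),
            source=d.get("source", "fitted"),
        )

    @classmethod
    def from_json(cls, path) -> "PredictionFormula":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Published total-silica-dust model: H/I over 10/20/30 years driven by
#: gender and cumulative total silica exposure D_t (mg/m3-years).
TOTAL_DUST_FORMULA = PredictionFormula(
    model="total",
    baseline_H={10: 0.09, 20: 0.27, 30: 0.50},
    baseline_S={10: 0.92, 20: 0.76, 30: 0.61},
    beta_gender=1.60,
    beta_D=0.07,
    mean_gender=0.95,
    mean_D=8.01,
    source="published",
)

#: Published respirable-silica-dust model (cumulative exposure D_r).
RESPIRABLE_DUST_FORMULA = PredictionFormula(
    model="respirable",
    baseline_H={10: 0.09, 20: 0.27, 30: 0.50},
    baseline_S={10: 0.92, 20: 0.76, 30: 0.61},
    beta_gender=1.58,
    beta_D=0.24,
    mean_gender=0.95,
    mean_D=2.64,
    source="published",
)


def _check_horizon(formula: PredictionFormula, horizon: int) -> None:
    if horizon not in formula.baseline_H:
        raise UnknownHorizonError(
            f"horizon {horizon} not in {formula.horizons}"
        )


def cumulative_hazard(formula: PredictionFormula, gender, D, horizon: int):
    """Cumulative hazard H_tau = H0(tau) * exp(linear predictor)."""
    _check_horizon(formula, horizon)
    d = np.asarray(D, dtype=float)
    if np.any(d < 0):
        raise ValueError("cumulative exposure D must be nonnegative")
    out = formula.baseline_H[horizon] * np.exp(
        formula.linear_predictor(gender, d)
    )
    return float(out) if out.ndim == 0 else out


def cumulative_incidence(formula: PredictionFormula, gender, D, horizon: int):
    """Cumulative incidence I_tau = 1 - S0(tau) ** exp(linear predictor).

    Returned as a fraction in (0, 1); multiply by 100 to report percent.
    """
    _check_horizon(formula, horizon)
    d = np.asarray(D, dtype=float)
    if np.any(d < 0):
        raise ValueError("cumulative exposure D must be nonnegative")
    out = 1.0 - formula.baseline_S[horizon] ** np.exp(
        formula.linear_predictor(gender, d)
    )
    return float(out) if out.ndim == 0 else out


def _summaries(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(values)),
        float(np.quantile(values, 0.25)),
        float(np.quantile(values, 0.75)),
    )


def project_risk(
    formula: PredictionFormula,
    samples: pd.DataFrame,
    conc_col: str = "silica_concentration",
    by: Sequence[str] | None = None,
    gender: int = 1,
    horizons: Sequence[int] = HORIZONS,
) -> pd.DataFrame:
    """Project H and I per stratum from per-sample silica concentrations.

    Each sample's projected exposure is D(tau) = concentration x tau years
    (constant future exposure at the surveyed level); H and I are evaluated
    per sample and summarised as median and IQR over the stratum's samples.
    ``gender`` defaults to 1 (male) as the workforce is predominantly male.
    Returns a long DataFrame with one row per (stratum, horizon); empty
    strata are omitted.  Incidence columns are in percent, unrounded.
    """
    if conc_col not in samples.columns:
        raise KeyError(f"column {conc_col!r} missing from samples")
    groups: list[tuple[str, str, pd.DataFrame]] = [
        ("overall", "overall", samples)
    ]
    for key in by or []:
        for label, sub in samples.groupby(key, observed=True):
            if len(sub):
                groups.append((key, str(label), sub))
    rows = []
    for key, label, sub in groups:
        conc = sub[conc_col].to_numpy(dtype=float)
        for tau in horizons:
            d = conc * tau
            h = cumulative_hazard(formula, gender, d, tau)
            i = 100.0 * cumulative_incidence(formula, gender, d, tau)
            h_med, h_q1, h_q3 = _summaries(np.atleast_1d(h))
            i_med, i_q1, i_q3 = _summaries(np.atleast_1d(i))
            rows.append(
                {
                    "stratum_key": key,
                    "stratum": label,
                    "horizon": tau,
                    "n": len(sub),
                    "H_median": h_med,
                    "H_q1": h_q1,
                    "H_q3": h_q3,
                    "I_median_pct": i_med,
                    "I_q1_pct": i_q1,
                    "I_q3_pct": i_q3,
                }
            )
    return pd.DataFrame(rows)
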