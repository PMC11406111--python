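"""Survival machinery for the exposure-response model, written from scratch.

Kaplan-Meier product-limit estimation, the k-sample log-rank test, Cox
proportional-hazards regression with Breslow tie handling and a damped
Newton solver, and the Breslow baseline cumulative hazard.  The time scale
throughout is years since first silica exposure: every subject enters at 0
and exits at diagnosis (event = 1) or censoring (left/retired/died/end of
follow-up, event = 0).

Cumulative silica exposure enters the Cox model as a time-varying covariate:
each subject carries a piecewise-constant concentration path and D_i(t) is
evaluated at every event time (``time_varying=False`` freezes D at exit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .risk_quant import PredictionFormula

__all__ = [
    "ExposurePath",
    "SubjectRecord",
    "KaplanMeierFit",
    "SurvFit",
    "TestResult",
    "StepFunction",
    "ConvergenceError",
    "ExtrapolationError",
    "kaplan_meier",
    "logrank_test",
    "cox_fit",
    "breslow_baseline",
    "build_prediction_formula",
    "life_table_check",
]

_PATH_HORIZON = 1e6  # sentinel final knot so D(t) extrapolates linearly


class ConvergenceError(RuntimeError):
    """The partial-likelihood maximiser failed to converge."""


class ExtrapolationError(ValueError):
    """A horizon lies beyond the last observed event time."""


@dataclass(frozen=True)
class ExposurePath:
    """Piecewise-constant silica concentration over time since first exposure.

    ``times`` are segment start times (first must be 0); ``rates`` the
    concentrations (mg/m3) holding from each start until the next.  The last
    segment extends indefinitely.  ``cumulative(t)`` integrates the path, so
    D(t) is in mg/m3-years.
    """

    times: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if len(t) != len(r) or len(t) == 0:
            raise ValueError("times and rates must be non-empty, same length")
        if t[0] != 0.0:
            raise ValueError("exposure path must start at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("segment start times must be increasing")
        if np.any(r < 0):
            raise ValueError("concentrations must be nonnegative")

    @classmethod
    def constant(cls, rate: float) -> "ExposurePath":
        return cls((0.0,), (float(rate),))

    def rate_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.rates[max(idx, 0)]

    def cumulative(self, t):
        """D(t): concentration integrated from 0 to t (vectorised)."""
        knots = np.append(np.asarray(self.times, float), _PATH_HORIZON)
        seg = np.diff(knots) * np.asarray(self.rates, float)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        out = np.interp(np.asarray(t, dtype=float), knots, cum)
        return float(out) if out.ndim == 0 else out


@dataclass
class SubjectRecord:
    """One cohort worker on the years-since-first-exposure scale."""

    subject_id: str
    gender: int
    exit_time: float
    event: int
    path: ExposurePath = field(default_factory=lambda: ExposurePath.constant(0.0))
    entry_time: float = 0.0

    def __post_init__(self) -> None:
        if self.gender not in (0, 1):
            raise ValueError("gender must be 0 (female) or 1 (male)")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if not self.exit_time > self.entry_time >= 0:
            raise ValueError("need exit_time > entry_time >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous nondecreasing step function, 0 before the first jump."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __call__(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[0.0], np.asarray(self.values, float)])
        out = vals[idx]
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierFit:
    """Product-limit survival estimate with its risk-set table."""

    times: np.ndarray       # distinct event times
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.survival])
        out = vals[idx]
        return float(out) if out.ndim == 0 else out

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def kaplan_meier(records: Sequence[SubjectRecord]) -> KaplanMeierFit:
    """Kaplan-Meier product-limit estimator; S(0) = 1, drops at event times."""
    if not records:
        raise ValueError("at least one record is required")
    exit_t = np.array([r.exit_time for r in records])
    event = np.array([r.event for r in records])
    if event.sum() == 0:
        warnings.warn("all subjects censored: survival is identically 1")
        return KaplanMeierFit(
            np.empty(0), np.empty(0), np.empty(0, int), np.empty(0, int)
        )
    times = np.unique(exit_t[event == 1])
    at_risk = np.array([(exit_t >= t).sum() for t in times])
    d = np.array([((exit_t == t) & (event == 1)).sum() for t in times])
    surv = np.cumprod(1.0 - d / at_risk)
    return KaplanMeierFit(times, surv, at_risk, d)


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def logrank_test(
    records: Sequence[SubjectRecord],
    groups: Sequence,
) -> TestResult:
    """k-sample log-rank test over the shared event times.

    At each event time the observed group-wise deaths are compared with
    their hypergeometric expectation given the risk sets; the chi-square
    statistic uses the generalised O-E form with the multivariate
    hypergeometric covariance, df = k - 1.
    """
    if len(groups) != len(records):
        raise ValueError("groups must align with records")
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    exit_t = np.array([r.exit_time for r in records])
    event = np.array([r.event for r in records])
    group_idx = np.searchsorted(uniq, labels)

    times = np.unique(exit_t[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in times:
        risk = exit_t >= t
        n_t = risk.sum()
        if n_t == 0:
            continue
        dead = risk & (exit_t == t) & (event == 1)
        d_t = dead.sum()
        n_kt = np.bincount(group_idx[risk], minlength=k).astype(float)
        O += np.bincount(group_idx[dead], minlength=k)
        E += d_t * n_kt / n_t
        if n_t > 1:
            frac = n_kt / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            V += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return TestResult(stat, df, p)


# ---------------------------------------------------------------------------
# Cox regression (Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class SurvFit:
    """A converged Cox fit: coefficients, SEs, loglik and centering means."""

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    covariate_means: dict[str, float]
    converged: bool
    n_iter: int
    time_varying: bool

    def hazard_ratios(self) -> dict[str, float]:
        return dict(zip(self.names, np.exp(self.beta)))

    def p_values(self) -> dict[str, float]:
        z = self.beta / self.se
        return dict(zip(self.names, 2.0 * stats.norm.sf(np.abs(z))))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "hr": np.exp(self.beta),
                "p": [round(p, 3) for p in self.p_values().values()],
            },
            index=list(self.names),
        )


def _design_at_event_times(
    records: Sequence[SubjectRecord],
    time_varying: bool,
):
    """Precompute, per event time, the risk-set design matrix and dead sums."""
    exit_t = np.array([r.exit_time for r in records])
    event = np.array([r.event for r in records])
    gender = np.array([float(r.gender) for r in records])
    event_times = np.unique(exit_t[event == 1])
    d_exit = np.array([r.path.cumulative(r.exit_time) for r in records])
    if time_varying:
        # n x J matrix of D_i(t_j)
        d_mat = np.vstack([r.path.cumulative(event_times) for r in records])
    else:
        d_mat = np.repeat(d_exit[:, None], len(event_times), axis=1)

    blocks = []
    for j, t in enumerate(event_times):
        risk = exit_t >= t
        dead = risk & (exit_t == t) & (event == 1)
        X = np.column_stack([gender[risk], d_mat[risk, j]])
        Xd = np.column_stack([gender[dead], d_mat[dead, j]])
        blocks.append((X, Xd.sum(axis=0), int(dead.sum())))
    means = {"gender": float(gender.mean()), "D": float(d_exit.mean())}
    return event_times, blocks, means, event, gender, d_exit


def _breslow_loglik_exact(beta: np.ndarray, blocks) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial loglik, score and observed information."""
    p = len(beta)
    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    for X, s_dead, d in blocks:
        eta = X @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        s0 = w.sum()
        s1 = w @ X
        xbar = s1 / s0
        s2 = (X * w[:, None]).T @ X
        ll += s_dead @ beta - d * (np.log(s0) + shift)
        U += s_dead - d * xbar
        I += d * (s2 / s0 - np.outer(xbar, xbar))
    return ll, U, I


def cox_fit(
    records: Sequence[SubjectRecord],
    time_varying: bool = True,
    max_iter: int = 100,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
) -> SurvFit:
    """Cox proportional-hazards fit with Breslow tie handling.

    Covariates are the male indicator and cumulative silica exposure D,
    evaluated at each event time from the subject's exposure path
    (``time_varying=True``, default) or frozen at exit.  The Breslow partial
    likelihood is maximised by damped Newton iterations; convergence when
    max |score| < ``tol_score`` or the relative loglik change drops below
    ``tol_loglik``.  A diverging coefficient (monotone likelihood, e.g.
    perfect separation) raises :class:`ConvergenceError` naming the
    covariate; a covariate constant across subjects is dropped with a
    warning.
    """
    n = len(records)
    event = np.array([r.event for r in records])
    if event.sum() < 2:
        raise ValueError("Cox fit requires at least 2 events")
    event_times, blocks, means, _, gender, d_exit = _design_at_event_times(
        records, time_varying
    )

    names = ["gender", "D"]
    keep = []
    for idx, (name, col) in enumerate(zip(names, [gender, d_exit])):
        if np.ptp(col) == 0.0:
            warnings.warn(f"covariate {name!r} is constant; dropped from fit")
        else:
            keep.append(idx)
    if not keep:
        raise ValueError("no varying covariates to fit")
    names = tuple(names[i] for i in keep)
    blocks = [(X[:, keep], s[np.array(keep)], d) for X, s, d in blocks]

    p = len(keep)
    beta = np.zeros(p)
    ll, U, I = _breslow_loglik_exact(beta, blocks)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}")
        # damped update: halve until the loglik does not decrease
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll_new, U_new, I_new = _breslow_loglik_exact(cand, blocks)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        rel = abs(ll_new - ll) / max(abs(ll), 1.0)
        beta, ll, U, I = cand, ll_new, U_new, I_new
        if np.max(np.abs(beta)) > 15.0:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"coefficient for {worst!r} diverges (monotone likelihood / "
                f"perfect separation)"
            )
        if np.max(np.abs(U)) < tol_score or rel < tol_loglik:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")

    cov = np.linalg.inv(I)
    se = np.sqrt(np.diag(cov))
    return SurvFit(
        names=names,
        beta=beta,
        se=se,
        cov=cov,
        loglik=float(ll),
        loglik_null=float(ll_null),
        n=n,
        n_events=int(event.sum()),
        covariate_means=means,
        converged=converged,
        n_iter=it,
        time_varying=time_varying,
    )


def breslow_baseline(
    fit: SurvFit,
    records: Sequence[SubjectRecord],
) -> StepFunction:
    """Breslow baseline cumulative hazard H0(t), centered at covariate means.

    H0(t) = sum over event times t_j <= t of d_j / sum_{i at risk}
    exp((x_i(t_j) - xbar)' beta), so H0 refers to the mean-covariate profile.
    """
    event_times, blocks, means, *_ = _design_at_event_times(
        records, fit.time_varying
    )
    all_names = ("gender", "D")
    keep = [i for i, nm in enumerate(all_names) if nm in fit.names]
    xbar = np.array([means[nm] for nm in fit.names])
    increments = []
    for X, _, d in blocks:
        Xc = X[:, keep] - xbar
        denom = np.exp(Xc @ fit.beta).sum()
        increments.append(d / denom)
    values = np.cumsum(increments)
    return StepFunction(tuple(event_times), tuple(values))


def build_prediction_formula(
    fit: SurvFit,
    records: Sequence[SubjectRecord],
    horizons: Sequence[int] = (10, 20, 30),
    model: str = "total",
) -> PredictionFormula:
    """Freeze a fit into a :class:`PredictionFormula` at the given horizons.

    Extracts H0(tau) from the Breslow baseline and S0(tau) = exp(-H0(tau)).
    A horizon beyond the last observed event time raises
    :class:`ExtrapolationError`.
    """
    h0 = breslow_baseline(fit, records)
    last_event = h0.times[-1] if h0.times else 0.0
    for tau in horizons:
        if tau > last_event:
            raise ExtrapolationError(
                f"horizon {tau} y beyond last event time {last_event:g} y"
            )
    baseline_H = {int(t): float(h0(t)) for t in horizons}
    baseline_S = {t: float(np.exp(-h)) for t, h in baseline_H.items()}
    beta = dict(zip(fit.names, fit.beta))
    return PredictionFormula(
        model=model,
        baseline_H=baseline_H,
        baseline_S=baseline_S,
        beta_gender=float(beta.get("gender", 0.0)),
        beta_D=float(beta.get("D", 0.0)),
        mean_gender=fit.covariate_means["gender"],
        mean_D=fit.covariate_means["D"],
        source="fitted",
    )


# ---------------------------------------------------------------------------
# life-table consistency
# ---------------------------------------------------------------------------

def life_table_check(rows: pd.DataFrame) -> dict:
    """Consistency report for an exposure-binned life table.

    ``rows`` needs columns L (participants reaching the bin), W (lost or
    terminated) and D (cases), ordered by exposure bin.  L is checked to be
    monotone nonincreasing and each bin's W + D not to exceed its L; bin
    totals are summarised.  Note L counts participants *reaching* each bin,
    so L_{k+1} = L_k - W_k - D_k is not required to hold.
    """
    issues = []
    L = rows["L"].to_numpy()
    W = rows["W"].to_numpy()
    D = rows["D"].to_numpy()
    if np.any(np.diff(L) > 0):
        bad = int(np.argmax(np.diff(L) > 0))
        issues.append(f"L increases from bin {bad} to {bad + 1}")
    over = np.nonzero(W + D > L)[0]
    for k in over:
        issues.append(f"bin {int(k)}: W + D = {int(W[k] + D[k])} exceeds L = {int(L[k])}")
    if np.any(L < 0) or np.any(W < 0) or np.any(D < 0):
        issues.append("negative counts present")
    return {
        "consistent": not issues,
        "issues": issues,
        "n_bins": len(rows),
        "total_cases": int(D.sum()),
        "total_withdrawn": int(W.sum()),
    }
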