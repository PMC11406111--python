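"""End-to-end orchestration: exposure -> qualitative + quantitative assessment.

``run_pipeline`` reduces a dust survey (synthetic or loaded from CSV) to an
:class:`AssessmentReport`: per-stratum exposure levels with exceedance
percentages, ICMM/INDEX weighted scores with band classifications, and
projected 10/20/30-year cumulative hazard and incidence.  Exclusion rules
are applied as logged filters before any statistic is computed:

* samples whose bulk free-silica content is below 10% (not silica dust),
* air samples above an outlier concentration threshold (default 50 mg/m3
  total dust),
* respirable samples exceeding their paired total concentration, together
  with their same-site-day companions.

Every reported figure is recomputable from the intermediate tables; rounding
is applied only when rendering.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import exposure as exp
from . import risk_qual as rq
from . import risk_quant as quant
from . import simulate as sim
from . import survival as surv

__all__ = ["RunConfig", "AssessmentReport", "run_pipeline", "render_tables",
           "read_cohort", "write_cohort"]

logger = logging.getLogger("silicarisk")

STRATA = ("category", "scale", "method", "job")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one assessment run."""

    seed: int = 0
    n_mines: int = 126
    jobs_per_mine: int = 4
    formula_source: str = "paper"       # "paper" or "fit"
    pairing: str = "site-day"
    outlier_total_max: float = 50.0
    by: tuple[str, ...] = STRATA
    gender: int = 1
    cohort_n: int = 2000                # used only when formula_source="fit"

    def __post_init__(self) -> None:
        if self.formula_source not in ("paper", "fit"):
            raise ValueError("formula_source must be 'paper' or 'fit'")
        unknown = set(self.by) - set(STRATA)
        if unknown:
            raise ValueError(f"unknown stratification keys: {sorted(unknown)}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AssessmentReport:
    """All assessment tables of one run, unrounded, plus run metadata."""

    exposure: pd.DataFrame       # one row per retained air sample
    exclusions: pd.DataFrame     # logged filter decisions
    exceedance: pd.DataFrame
    qualitative: pd.DataFrame    # stratum x dust x method scores and bands
    quantitative: pd.DataFrame   # project_risk output per dust type
    metadata: dict


def _air_concentration_table(
    samples: Sequence[exp.GravimetricSample],
    mines: pd.DataFrame,
    pairing: str,
) -> pd.DataFrame:
    frame = sim.samples_to_frame(samples)
    air = frame[frame["fraction"].isin(exp.AIR_FRACTIONS)].copy()
    bulk_rows = [s for s in samples if s.fraction == "bulk"]
    air["concentration"] = [
        exp.twa_concentration(s) for s in samples if s.fraction != "bulk"
    ]
    bulk = pd.DataFrame(
        {
            "mine_id": [s.mine_id for s in bulk_rows],
            "job": [s.job for s in bulk_rows],
            "day_index": [s.day_index for s in bulk_rows],
            "free_silica": [exp.free_silica_content(s) for s in bulk_rows],
        }
    )
    if bulk.empty:
        raise exp.PairingError("no bulk samples: free silica cannot be resolved")
    air = exp.pair_free_silica(air, bulk, method=pairing)
    meta_cols = [c for c in ("category", "scale", "method") if c in mines.columns]
    air = air.merge(mines[["mine_id", *meta_cols]], on="mine_id", how="left")
    return air


def _apply_filters(air: pd.DataFrame, config: RunConfig):
    """Logged exclusions; returns (retained air table, exclusion log)."""
    log: list[dict] = []

    def exclude(mask: pd.Series, reason: str) -> pd.Series:
        for sid in air.loc[mask, "sample_id"]:
            log.append({"sample_id": sid, "reason": reason})
        return ~mask

    keep = exclude(air["free_silica"] < 10.0, "free silica < 10%: not silica dust")
    keep &= exclude(
        (air["fraction"] == "total")
        & (air["concentration"] > config.outlier_total_max),
        f"total concentration > {config.outlier_total_max} mg/m3 (outlier rule)",
    )
    # respirable > paired same-site-day total: drop the pair
    key = ["mine_id", "job", "day_index"]
    totals = (
        air[air["fraction"] == "total"]
        .set_index(key)["concentration"]
        .rename("paired_total")
    )
    resp = air[air["fraction"] == "respirable"].join(totals, on=key)
    bad_keys = set(
        map(tuple, resp.loc[
            resp["paired_total"].notna()
            & (resp["concentration"] > resp["paired_total"]), key
        ].itertuples(index=False))
    )
    if bad_keys:
        bad_mask = air[key].apply(tuple, axis=1).isin(bad_keys)
        keep &= exclude(
            bad_mask, "respirable exceeds paired total: site-day pair excluded"
        )
    retained = air.loc[keep].copy()
    return retained, pd.DataFrame(log, columns=["sample_id", "reason"])


def _qualitative_tables(
    air: pd.DataFrame,
    by: Sequence[str],
    icmm: rq.RatingConfig,
    index: rq.RatingConfig,
) -> pd.DataFrame:
    rows = []
    for fraction in exp.AIR_FRACTIONS:
        sub = air[air["fraction"] == fraction]
        groups = [("overall", "overall", sub)] + [
            (key, str(label), g)
            for key in by
            for label, g in sub.groupby(key, observed=True)
            if len(g)
        ]
        for key, label, g in groups:
            scores = {}
            for cfg in (icmm, index):
                codes = [
                    int(rq.rate_sample(cfg, c, o))
                    for c, o in zip(g["concentration"], g["oel"])
                ]
                dist = rq.risk_distribution(codes, stratum=label)
                s = rq.weighted_score(dist)
                scores[cfg.method] = s
                rows.append(
                    {
                        "dust": fraction,
                        "stratum_key": key,
                        "stratum": label,
                        "method": cfg.method,
                        "n": dist.n,
                        "S_weighted": s,
                        "band": rq.classify_weighted(s),
                        "comprehensive_band": None,
                    }
                )
            combined = rq.comprehensive_level(scores["ICMM"], scores["INDEX"])
            for r in rows[-2:]:
                r["comprehensive_band"] = combined
    return pd.DataFrame(rows)


def _formulas(config: RunConfig):
    if config.formula_source == "paper":
        return quant.TOTAL_DUST_FORMULA, quant.RESPIRABLE_DUST_FORMULA
    out = []
    for model, cfg in (
        ("total", sim.CohortSimConfig.total(n_subjects=config.cohort_n)),
        ("respirable", sim.CohortSimConfig.respirable(n_subjects=config.cohort_n)),
    ):
        records = sim.generate_cohort(cfg, seed=config.seed + 1)
        fit = surv.cox_fit(records)
        out.append(surv.build_prediction_formula(fit, records, model=model))
    return tuple(out)


def run_pipeline(
    config: RunConfig,
    survey: tuple[pd.DataFrame, list] | None = None,
) -> AssessmentReport:
    """Run the full assessment; idempotent for fixed inputs and seed."""
    logger.info("run %s: starting (seed=%d)", config.digest(), config.seed)
    if survey is None:
        survey = sim.generate_survey(
            sim.SurveySimConfig(
                n_mines=config.n_mines, jobs_per_mine=config.jobs_per_mine
            ),
            seed=config.seed,
        )
    mines, samples = survey

    air = _air_concentration_table(samples, mines, config.pairing)
    logger.info("computed concentrations for %d air samples", len(air))
    air, exclusions = _apply_filters(air, config)
    logger.info("retained %d samples after %d exclusions", len(air), len(exclusions))

    air["silica_concentration"] = exp.silica_concentration(
        air["concentration"].to_numpy(), air["free_silica"].to_numpy()
    )
    air["oel"] = [
        exp.oel_lookup(fs).limit(frac)
        for fs, frac in zip(air["free_silica"], air["fraction"])
    ]
    air["exposure_ratio"] = air["concentration"] / air["oel"]

    by = [k for k in config.by if k in air.columns]
    exc_frames = []
    overall = exp.exceedance_summary(air)
    overall.insert(0, "stratum_key", "overall")
    overall.insert(1, "stratum", "overall")
    exc_frames.append(overall)
    for key in by:
        part = exp.exceedance_summary(air, by=key)
        part = part.rename(columns={key: "stratum"})
        part.insert(0, "stratum_key", key)
        exc_frames.append(part)
    exceed = pd.concat(exc_frames, ignore_index=True)
    qual = _qualitative_tables(
        air, by, rq.RatingConfig.default_icmm(), rq.RatingConfig.default_index()
    )

    f_total, f_resp = _formulas(config)
    quant_frames = []
    for fraction, formula in (("total", f_total), ("respirable", f_resp)):
        sub = air[air["fraction"] == fraction]
        proj = quant.project_risk(
            formula, sub, conc_col="silica_concentration", by=by,
            gender=config.gender,
        )
        proj.insert(0, "dust", fraction)
        quant_frames.append(proj)
    quantitative = pd.concat(quant_frames, ignore_index=True)

    metadata = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "formula_source": config.formula_source,
        "formula_versions": {f_total.model: f_total.source,
                             f_resp.model: f_resp.source},
        "n_air_samples": int(len(air)),
        "n_excluded": int(len(exclusions)),
        "assumptions": {
            "gender_fixed_to": config.gender,
            "projection": "constant future exposure, D(tau) = conc x tau",
            "combined_band_rule": "max band unless the >=3.01/>=4.01 rule fires",
            "score_gap_resolution": "round to 2 decimals before banding",
        },
    }
    logger.info("run %s: done", config.digest())
    return AssessmentReport(air, exclusions, exceed, qual, quantitative, metadata)


def _fmt(x: float, nd: int) -> str:
    return f"{x:.{nd}f}"


def _med_iqr(med: float, q1: float, q3: float, nd: int) -> str:
    return f"{_fmt(med, nd)} ({_fmt(q1, nd)}-{_fmt(q3, nd)})"


def render_tables(report: AssessmentReport, out_dir) -> dict[str, Path]:
    """Write one CSV per report section; medians rendered as 'x.xx (q1-q3)'.

    Concentrations are rounded to 2 decimals, percentages to 1 decimal, all
    at render time only.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # exposure levels (dust-sample medians and exceedance), Table-3 shape
    rows = []
    air = report.exposure
    keys = [("overall", "overall", air)] + [
        (k, str(lbl), g)
        for k in ("category", "scale", "method", "job")
        if k in air.columns
        for lbl, g in air.groupby(k, observed=True)
        if len(g)
    ]
    for key, label, g in keys:
        rec = {"stratum_key": key, "stratum": label}
        for fraction in exp.AIR_FRACTIONS:
            sub = g[g["fraction"] == fraction]
            if not len(sub):
                continue
            conc = sub["concentration"]
            sil = sub["silica_concentration"]
            rec[f"{fraction}_n"] = len(sub)
            rec[f"{fraction}_conc"] = _med_iqr(
                conc.median(), conc.quantile(0.25), conc.quantile(0.75), 2
            )
            rec[f"{fraction}_silica_conc"] = _med_iqr(
                sil.median(), sil.quantile(0.25), sil.quantile(0.75), 2
            )
        rows.append(rec)
    paths["exposure_levels"] = out / "exposure_levels.csv"
    pd.DataFrame(rows).to_csv(paths["exposure_levels"], index=False)

    paths["exceedance"] = out / "exceedance.csv"
    report.exceedance.to_csv(paths["exceedance"], index=False)

    qual = report.qualitative.copy()
    qual["S_weighted"] = qual["S_weighted"].map(lambda s: _fmt(s, 2))
    paths["qual_report"] = out / "qual_report.csv"
    qual.to_csv(paths["qual_report"], index=False)

    qrows = []
    for rec in report.quantitative.to_dict("records"):
        qrows.append(
            {
                "dust": rec["dust"],
                "stratum_key": rec["stratum_key"],
                "stratum": rec["stratum"],
                "horizon": rec["horizon"],
                "n": rec["n"],
                "H": _med_iqr(rec["H_median"], rec["H_q1"], rec["H_q3"], 2),
                "I_pct": _med_iqr(
                    rec["I_median_pct"], rec["I_q1_pct"], rec["I_q3_pct"], 1
                ),
            }
        )
    paths["projection"] = out / "projection.csv"
    pd.DataFrame(qrows).to_csv(paths["projection"], index=False)

    paths["exclusions"] = out / "exclusions.csv"
    report.exclusions.to_csv(paths["exclusions"], index=False)
    paths["metadata"] = out / "metadata.json"
    with open(paths["metadata"], "w") as fh:
        json.dump(report.metadata, fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# cohort CSV round trip
# ---------------------------------------------------------------------------

def write_cohort(records: Sequence[surv.SubjectRecord], path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "gender": [r.gender for r in records],
            "exit_years": [r.exit_time for r in records],
            "event": [r.event for r in records],
            "exposure_path_json": [
                json.dumps({"times": list(r.path.times), "rates": list(r.path.rates)})
                for r in records
            ],
        }
    )
    df.to_csv(path, index=False)


def read_cohort(path) -> list[surv.SubjectRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples():
        spec = json.loads(row.exposure_path_json)
        records.append(
            surv.SubjectRecord(
                subject_id=str(row.subject_id),
                gender=int(row.gender),
                exit_time=float(row.exit_years),
                event=int(row.event),
                path=surv.ExposurePath(
                    tuple(spec["times"]), tuple(spec["rates"])
                ),
            )
        )
    return records
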