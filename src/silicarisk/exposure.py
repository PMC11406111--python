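"""Sample-level silica-dust exposure metrics.

Gravimetric air samples (total and respirable dust fractions) and bulk
dustfall samples are reduced to:

* 8-hour time-weighted average (TWA) concentrations in mg/m3,
* free crystalline silica content in percent (pyrophosphate digestion),
* silica-dust concentrations (dust concentration x free-silica fraction),
* exceedance counts against the Chinese free-silica-dependent occupational
  exposure limits (OELs) and the ACGIH recommended exposure limit for
  respirable crystalline silica (0.025 mg/m3),
* cumulative exposure in mg/m3-years from a job exposure matrix (JEM).

Conventions: filter weights in mg, bulk/crucible weights in g, flow in
L/minute, duration in minutes, concentrations in mg/m3, free silica in
percent of bulk dust mass.  Exceedance comparisons are strict (a value
equal to its limit is compliant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACGIH_REL_RESPIRABLE",
    "GravimetricSample",
    "JobExposure",
    "OelPair",
    "InvalidSampleError",
    "NegativeMassError",
    "NotSilicaDustError",
    "PairingError",
    "MissingJEMError",
    "twa_concentration",
    "twa_from_segments",
    "free_silica_content",
    "estimate_respirable_from_total",
    "silica_concentration",
    "oel_lookup",
    "oel_for",
    "pair_free_silica",
    "exceedance_summary",
    "cumulative_exposure",
    "projected_exposure",
]

#: ACGIH recommended exposure limit for respirable crystalline silica, mg/m3.
ACGIH_REL_RESPIRABLE = 0.025

AIR_FRACTIONS = ("total", "respirable")
WORKDAY_HOURS = 8.0


class InvalidSampleError(ValueError):
    """A sample's physical parameters are inconsistent with its type."""


class NegativeMassError(InvalidSampleError):
    """Post-sampling weight below pre-sampling weight."""


class NotSilicaDustError(ValueError):
    """Free silica below 10%: the dust does not qualify as silica dust."""


class PairingError(ValueError):
    """Air samples could not be matched to any bulk free-silica result."""


class MissingJEMError(KeyError):
    """An exposure spell is not covered by any job exposure matrix cell."""


@dataclass(frozen=True)
class OelPair:
    """Chinese OELs (mg/m3) for a free-silica content band.

    Bands: ``low`` 10-50%, ``mid`` >50-80%, ``high`` >80%.
    """

    total_oel: float
    respirable_oel: float
    silica_band: str

    def limit(self, fraction: str) -> float:
        if fraction == "total":
            return self.total_oel
        if fraction == "respirable":
            return self.respirable_oel
        raise ValueError(f"no OEL for fraction {fraction!r}")


_OEL_LOW = OelPair(1.0, 0.7, "low")
_OEL_MID = OelPair(0.7, 0.3, "mid")
_OEL_HIGH = OelPair(0.5, 0.2, "high")


@dataclass
class GravimetricSample:
    """One gravimetric dust sample (air filter or bulk dustfall).

    For air samples (``fraction`` in {"total", "respirable"}) the weights are
    the pre/post filter weights in mg and ``flow_rate``/``duration`` must be
    positive.  For bulk samples (``fraction == "bulk"``) ``pre_weight`` is the
    crucible weight m3 (g), ``post_weight`` the crucible + free silica weight
    m4 (g), and ``bulk_mass`` the digested dust mass m (g).
    """

    sample_id: str
    mine_id: str
    job: str
    fraction: str
    pre_weight: float
    post_weight: float
    site_type: str = "fixed"
    sampling_mode: str = "area"
    bulk_mass: float | None = None
    flow_rate: float | None = None
    duration: float | None = None
    day_index: int = 1
    segment_hours: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.fraction not in AIR_FRACTIONS + ("bulk",):
            raise InvalidSampleError(
                f"{self.sample_id}: unknown fraction {self.fraction!r}"
            )
        if self.post_weight < self.pre_weight:
            raise NegativeMassError(
                f"{self.sample_id}: post-sampling weight {self.post_weight} "
                f"below pre-sampling weight {self.pre_weight}"
            )
        if self.day_index not in (1, 2, 3):
            raise InvalidSampleError(
                f"{self.sample_id}: day_index must be 1-3, got {self.day_index}"
            )
        if self.fraction == "bulk":
            if self.bulk_mass is None or self.bulk_mass <= 0:
                raise InvalidSampleError(
                    f"{self.sample_id}: bulk sample requires bulk_mass > 0"
                )
        else:
            if not self.flow_rate or self.flow_rate <= 0:
                raise InvalidSampleError(
                    f"{self.sample_id}: air sample requires flow_rate > 0"
                )
            if not self.duration or self.duration <= 0:
                raise InvalidSampleError(
                    f"{self.sample_id}: air sample requires duration > 0"
                )


@dataclass
class JobExposure:
    """One job exposure matrix cell: a job at a mine over a calendar period."""

    mine_id: str
    job: str
    start_year: int
    end_year: int
    total_conc: float
    respirable_conc: float
    free_silica: float
    respirable_estimated: bool = False

    def __post_init__(self) -> None:
        if self.total_conc < 0 or self.respirable_conc < 0:
            raise ValueError("concentrations must be nonnegative")
        if not 0.0 <= self.free_silica <= 100.0:
            raise ValueError("free silica must be within 0-100%")
        if (
            self.respirable_conc > self.total_conc
            and not self.respirable_estimated
        ):
            raise ValueError(
                "measured respirable concentration exceeds total concentration"
            )


# ---------------------------------------------------------------------------
# concentration arithmetic
# ---------------------------------------------------------------------------

def twa_from_segments(segments: Iterable[tuple[float, float]]) -> float:
    """8-h TWA from (concentration mg/m3, hours) exposure segments."""
    total = 0.0
    for conc, hours in segments:
        if hours < 0:
            raise InvalidSampleError("segment hours must be nonnegative")
        total += conc * hours
    return total / WORKDAY_HOURS


def twa_concentration(sample: GravimetricSample) -> float:
    """Gravimetric dust concentration of an air sample, mg/m3.

    c = (m2 - m1) / (V * t) * 1000 with weights in mg, flow in L/minute and
    duration in minutes (1000 L per m3).  When the sample carries explicit
    exposure segments the 8-h TWA  sum(c_i * T_i) / 8  is returned instead.
    """
    if sample.fraction not in AIR_FRACTIONS:
        raise InvalidSampleError(
            f"{sample.sample_id}: TWA is defined for air samples only"
        )
    if sample.segment_hours:
        return twa_from_segments(sample.segment_hours)
    volume_l = sample.flow_rate * sample.duration
    return (sample.post_weight - sample.pre_weight) / volume_l * 1000.0


def free_silica_content(sample: GravimetricSample) -> float:
    """Free silica content of a bulk sample in percent: (m4 - m3) / m * 100.

    Results above 100% (weighing error) are clamped to 100 with a warning.
    """
    if sample.fraction != "bulk":
        raise InvalidSampleError(
            f"{sample.sample_id}: free silica is determined on bulk samples"
        )
    pct = (sample.post_weight - sample.pre_weight) / sample.bulk_mass * 100.0
    if pct > 100.0 * (1.0 + 1e-12):
        warnings.warn(
            f"{sample.sample_id}: free silica {pct:.1f}% > 100%, clamped",
            stacklevel=2,
        )
        pct = 100.0
    return pct


def estimate_respirable_from_total(total_conc):
    """Back-estimate a respirable concentration from a total concentration.

    Historical (pre-1992) linear model: 0.30 x total + 0.08 mg/m3.  Records
    derived this way must carry ``respirable_estimated=True`` downstream.
    Accepts scalars or arrays.
    """
    arr = np.asarray(total_conc, dtype=float)
    if np.any(arr < 0):
        raise ValueError("total concentration must be nonnegative")
    out = 0.30 * arr + 0.08
    return float(out) if np.isscalar(total_conc) else out


def silica_concentration(dust_conc, free_silica):
    """Silica-dust concentration: dust concentration x free-silica fraction."""
    conc = np.asarray(dust_conc, dtype=float)
    fs = np.asarray(free_silica, dtype=float)
    if np.any(conc < 0):
        raise ValueError("dust concentration must be nonnegative")
    if np.any((fs < 0) | (fs > 100)):
        raise ValueError("free silica must be within 0-100%")
    out = conc * fs / 100.0
    return float(out) if out.ndim == 0 else out


def oel_lookup(free_silica: float) -> OelPair:
    """Chinese total/respirable dust OELs for a free-silica content.

    10-50% -> (1.0, 0.7); >50-80% -> (0.7, 0.3); >80% -> (0.5, 0.2) mg/m3.
    Below 10% the dust is not silica dust and must be excluded upstream.
    """
    if free_silica < 10.0:
        raise NotSilicaDustError(
            f"free silica {free_silica}% < 10%: not silica dust"
        )
    if free_silica > 100.0:
        raise ValueError("free silica must be within 0-100%")
    if free_silica <= 50.0:
        return _OEL_LOW
    if free_silica <= 80.0:
        return _OEL_MID
    return _OEL_HIGH


def oel_for(free_silica: float, fraction: str) -> float:
    """Convenience: the fraction-specific OEL for a free-silica content."""
    return oel_lookup(free_silica).limit(fraction)


# ---------------------------------------------------------------------------
# bulk-to-air pairing
# ---------------------------------------------------------------------------

def pair_free_silica(
    air: pd.DataFrame,
    bulk: pd.DataFrame,
    method: str = "site-day",
) -> pd.DataFrame:
    """Attach a free-silica content to every air sample.

    ``air`` needs columns mine_id, job, day_index; ``bulk`` needs mine_id,
    job, day_index, free_silica.  With ``method="site-day"`` each air sample
    is matched to the bulk sample of the same (mine, job, day); a day with no
    bulk result falls back to the job's median free silica across days
    (mirroring the "same or similar job" convention used for historical
    back-estimation).  ``method="job-median"`` uses the job median directly.
    Air samples that resolve to nothing raise :class:`PairingError` listing
    the orphans.
    """
    if method not in ("site-day", "job-median"):
        raise ValueError(f"unknown pairing method {method!r}")
    out = air.copy()
    job_median = (
        bulk.groupby(["mine_id", "job"])["free_silica"].median().rename("fs_job")
    )
    if method == "site-day":
        day_fs = (
            bulk.groupby(["mine_id", "job", "day_index"])["free_silica"]
            .median()
            .rename("fs_day")
        )
        out = out.merge(
            day_fs, how="left", left_on=["mine_id", "job", "day_index"],
            right_index=True,
        )
    else:
        out["fs_day"] = np.nan
    out = out.merge(
        job_median, how="left", left_on=["mine_id", "job"], right_index=True
    )
    out["free_silica"] = out["fs_day"].fillna(out["fs_job"])
    out["free_silica_fallback"] = out["fs_day"].isna() & out["fs_job"].notna()
    out = out.drop(columns=["fs_day", "fs_job"])
    orphans = out.loc[out["free_silica"].isna()]
    if len(orphans):
        ids = orphans.get("sample_id", orphans.index.to_series()).tolist()
        raise PairingError(
            f"{len(orphans)} air sample(s) have no matching bulk sample: {ids}"
        )
    return out


# ---------------------------------------------------------------------------
# exceedance
# ---------------------------------------------------------------------------

def exceedance_summary(
    samples: pd.DataFrame,
    by: str | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Counts and percentages of air samples above their limits, per stratum.

    ``samples`` needs columns fraction, concentration, free_silica (used to
    resolve the OEL tier).  Comparison is strict (concentration > limit).
    Respirable rows are additionally compared with the ACGIH REL.  Empty
    strata are simply absent from the output.  Percentages are rounded to 1
    decimal.
    """
    df = samples.loc[samples["fraction"].isin(AIR_FRACTIONS)].copy()
    df["oel"] = [
        oel_lookup(fs).limit(frac)
        for fs, frac in zip(df["free_silica"], df["fraction"])
    ]
    df["exceed_oel"] = df["concentration"] > df["oel"]
    df["exceed_rel"] = (df["fraction"] == "respirable") & (
        df["concentration"] > ACGIH_REL_RESPIRABLE
    )

    if by is None:
        keys = []
    elif isinstance(by, str):
        keys = [by]
    else:
        keys = list(by)

    rows = []
    group_keys = keys + ["fraction"]
    for label, sub in df.groupby(group_keys, observed=True):
        if not isinstance(label, tuple):
            label = (label,)
        rec = dict(zip(group_keys, label))
        n = len(sub)
        n_exc = int(sub["exceed_oel"].sum())
        rec.update(
            n_total=n,
            n_exceed_oel=n_exc,
            pct_exceed_oel=round(100.0 * n_exc / n, 1),
        )
        if rec["fraction"] == "respirable":
            n_rel = int(sub["exceed_rel"].sum())
            rec["n_exceed_rel"] = n_rel
            rec["pct_exceed_rel"] = round(100.0 * n_rel / n, 1)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cumulative exposure
# ---------------------------------------------------------------------------

def _spell_tuple(spell) -> tuple[str, str, float, float]:
    if isinstance(spell, Mapping):
        return (
            spell["mine_id"], spell["job"],
            float(spell["start_year"]), float(spell["end_year"]),
        )
    mine_id, job, start, end = spell
    return mine_id, job, float(start), float(end)


def cumulative_exposure(
    jem: pd.DataFrame,
    history: Iterable,
) -> dict[str, float]:
    """Cumulative silica exposure D (mg/m3-years) over a worker's job spells.

    ``jem`` needs columns mine_id, job, start_year, end_year, total_mgm3,
    respirable_mgm3, free_silica_pct.  ``history`` is an iterable of spells,
    each a mapping or (mine_id, job, start_year, end_year) tuple; spells must
    not overlap and every spell year must be covered by a JEM cell, else
    :class:`MissingJEMError` names the offending job and period.

    Returns ``{"total": D_t, "respirable": D_r}`` where each D sums the
    spell's silica concentration (dust concentration x free-silica fraction)
    times the years spent in the cell.
    """
    spells = sorted((_spell_tuple(s) for s in history), key=lambda s: s[2])
    for (a, b) in zip(spells, spells[1:]):
        if b[2] < a[3] - 1e-9:
            raise ValueError(
                f"overlapping spells: {a[1]} [{a[2]}, {a[3]}) and "
                f"{b[1]} [{b[2]}, {b[3]})"
            )
    d_total = 0.0
    d_resp = 0.0
    for mine_id, job, start, end in spells:
        if end < start:
            raise ValueError(f"spell for {job} ends before it starts")
        cells = jem.loc[(jem["mine_id"] == mine_id) & (jem["job"] == job)]
        covered = 0.0
        for cell in cells.itertuples():
            ov = min(end, float(cell.end_year)) - max(start, float(cell.start_year))
            if ov <= 0:
                continue
            covered += ov
            fs = cell.free_silica_pct / 100.0
            d_total += cell.total_mgm3 * fs * ov
            d_resp += cell.respirable_mgm3 * fs * ov
        if covered < (end - start) - 1e-9:
            raise MissingJEMError(
                f"job {job!r} at mine {mine_id!r} over [{start}, {end}) is "
                f"covered for only {covered:g} of {end - start:g} years"
            )
    return {"total": d_total, "respirable": d_resp}


def projected_exposure(concentration: float, years: float) -> float:
    """Projected cumulative exposure D(tau) = concentration x tau years."""
    if concentration < 0 or years < 0:
        raise ValueError("concentration and years must be nonnegative")
    return concentration * years
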