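"""Qualitative silicosis risk: ICMM / INDEX ratings and the weighted score.

Each dust sample receives a 5-level risk code (1 tolerable/no hazard ...
5 intolerable/extreme) from a rating scheme driven by the sample's exposure
ratio (concentration / OEL):

* ICMM-style: a likelihood band (from the exposure ratio) crossed with a
  consequence/severity class, the product banded back to codes 1-5;
* INDEX-style: a hazard-class weight times an exposure-ratio weight, the
  index banded to codes 1-5.

The exact rating rules of the two published schemes are not specified here;
they are supplied as declarative :class:`RatingConfig` tables (with shipped
defaults) so that the downstream arithmetic - the weighted score

    S_weighted = sum_i p_i * i      (p_i = share of samples at code i)

and its band classification (very low <= 1.00 < low <= 2.00 < medium <= 3.00
< high <= 4.00 < very high) - is exercised on any admissible rule set.
Scores are rounded to 2 decimals before banding, which also resolves the
gaps the closed band intervals leave (e.g. 2.004).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RiskLevel",
    "RatingConfig",
    "RiskDistribution",
    "RatingError",
    "UndefinedScoreError",
    "BANDS",
    "rate_sample",
    "risk_distribution",
    "weighted_score",
    "classify_weighted",
    "comprehensive_level",
]

BANDS = ("very low", "low", "medium", "high", "very high")


class RatingError(ValueError):
    """A sample cannot be rated (e.g. missing OEL)."""


class UndefinedScoreError(ValueError):
    """Weighted score requested on an empty distribution."""


class RiskLevel(IntEnum):
    """Per-sample qualitative risk code, shared by both rating schemes."""

    TOLERABLE = 1      # tolerable risk / no hazard
    POTENTIAL = 2      # potential risk / mild hazard
    HIGH = 3           # high risk / moderate hazard
    VERY_HIGH = 4      # very high risk / severe hazard
    INTOLERABLE = 5    # intolerable risk / extreme hazard

    @property
    def label(self) -> str:
        return {
            1: "tolerable/no hazard",
            2: "potential/mild",
            3: "high/moderate",
            4: "very high/severe",
            5: "intolerable/extreme",
        }[int(self)]


@dataclass(frozen=True)
class RatingConfig:
    """Declarative rating rule mapping an exposure ratio to a 1-5 code.

    ``ratio_edges`` are the four upper edges of the exposure-ratio bands
    (band 5 is everything above the last edge).  For ``method="ICMM"`` the
    band (likelihood) is multiplied by the ``severity`` consequence class
    and the product banded by ``product_edges``; for ``method="INDEX"`` the
    band weight is multiplied by ``hazard_weight`` and banded the same way.
    Both constructions are monotone in the exposure ratio by design, which
    is validated on load.
    """

    method: str
    ratio_edges: tuple[float, float, float, float] = (0.1, 0.5, 1.0, 2.0)
    severity: int = 4            # silicosis: severe irreversible disease
    hazard_weight: int = 4       # crystalline silica hazard class (INDEX)
    product_edges: tuple[float, float, float, float] = (4.0, 8.0, 12.0, 16.0)

    def __post_init__(self) -> None:
        if self.method not in ("ICMM", "INDEX"):
            raise ValueError("method must be 'ICMM' or 'INDEX'")
        if list(self.ratio_edges) != sorted(self.ratio_edges):
            raise ValueError("ratio_edges must be increasing")
        if list(self.product_edges) != sorted(self.product_edges):
            raise ValueError("product_edges must be increasing")
        if not 1 <= self.severity <= 5:
            raise ValueError("severity must be a class 1-5")
        if not 1 <= self.hazard_weight <= 5:
            raise ValueError("hazard_weight must be 1-5")

    @classmethod
    def default_icmm(cls) -> "RatingConfig":
        return cls(method="ICMM")

    @classmethod
    def default_index(cls) -> "RatingConfig":
        return cls(method="INDEX", hazard_weight=3)

    # -- serialisation ----------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RatingConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["ratio_edges"] = tuple(d["ratio_edges"])
        d["product_edges"] = tuple(d["product_edges"])
        return cls(**d)

    # -- the rule ---------------------------------------------------------
    def ratio_band(self, ratio: float) -> int:
        """Exposure-ratio band 1-5 (1 for ratio 0; 5 above the last edge)."""
        if ratio < 0:
            raise RatingError("exposure ratio must be nonnegative")
        return 1 + int(np.searchsorted(self.ratio_edges, ratio, side="left"))

    def code(self, ratio: float, severity: int | None = None) -> RiskLevel:
        band = self.ratio_band(ratio)
        weight = severity if severity is not None else (
            self.severity if self.method == "ICMM" else self.hazard_weight
        )
        product = band * weight
        return RiskLevel(
            1 + int(np.searchsorted(self.product_edges, product, side="left"))
        )


def rate_sample(
    config: RatingConfig,
    concentration: float,
    oel: float,
    severity: int | None = None,
) -> RiskLevel:
    """Rate one sample from its exposure ratio concentration / OEL."""
    if oel is None or not np.isfinite(oel) or oel <= 0:
        raise RatingError("exposure ratio undefined: missing or invalid OEL")
    return config.code(concentration / oel, severity)


@dataclass
class RiskDistribution:
    """Per-stratum counts of samples at each risk code 1-5."""

    stratum: str
    counts: tuple[int, int, int, int, int]

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def proportions(self) -> tuple[float, ...]:
        if self.n == 0:
            raise UndefinedScoreError(f"stratum {self.stratum!r} is empty")
        return tuple(c / self.n for c in self.counts)


def risk_distribution(codes: Iterable[int], stratum: str = "overall") -> RiskDistribution:
    """Tally risk codes 1-5 into a :class:`RiskDistribution`."""
    arr = np.asarray(list(codes), dtype=int)
    if arr.size and (arr.min() < 1 or arr.max() > 5):
        raise ValueError("risk codes must be within 1-5")
    counts = tuple(int((arr == i).sum()) for i in range(1, 6))
    return RiskDistribution(stratum, counts)


def weighted_score(dist: RiskDistribution | Sequence[int]) -> float:
    """S_weighted = sum_i p_i * i over the five risk codes; lies in [1, 5]."""
    if not isinstance(dist, RiskDistribution):
        dist = RiskDistribution("", tuple(int(c) for c in dist))
    p = dist.proportions
    return float(sum((i + 1) * pi for i, pi in enumerate(p)))


def _round2(s: float) -> float:
    # round half away from zero at 2 decimals, so 2.005 -> 2.01
    return float(np.floor(s * 100.0 + 0.5) / 100.0)


def classify_weighted(s: float) -> str:
    """Band a weighted score: the published closed 1-unit intervals.

    Scores are rounded to 2 decimals first, which also classifies values in
    the gaps between the printed interval endpoints.
    """
    if not 0.0 <= s <= 5.0:
        raise ValueError(f"weighted score {s} outside [0, 5]")
    r = _round2(s)
    eps = 1e-9
    if r <= 1.0 + eps:
        return "very low"
    if r <= 2.0 + eps:
        return "low"
    if r <= 3.0 + eps:
        return "medium"
    if r <= 4.0 + eps:
        return "high"
    return "very high"


def comprehensive_level(s_icmm: float, s_index: float) -> str:
    """Combine the two schemes' weighted scores into one band.

    Special rule: if both scores are >= 3.01, or either is >= 4.01, the
    combined level is "high" (the rule names that level explicitly).
    Otherwise the combined band is the band of the larger score.
    """
    for s in (s_icmm, s_index):
        if not 0.0 <= s <= 5.0:
            raise ValueError(f"weighted score {s} outside [0, 5]")
    r1, r2 = _round2(s_icmm), _round2(s_index)
    eps = 1e-9
    if (r1 >= 3.01 - eps and r2 >= 3.01 - eps) or r1 >= 4.01 - eps or r2 >= 4.01 - eps:
        return "high"
    return classify_weighted(max(s_icmm, s_index))
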