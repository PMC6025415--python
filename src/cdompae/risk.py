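"""Phthalate composition statistics and USEPA drinking-water risk metrics.

Non-cancer risk follows the standard ingestion-route model: the average
daily dose of a congener at water concentration C (mg/L) is

    ADD = (C · DR · EF · ED) / (BW · AT)      [mg · kg⁻¹ · day⁻¹]

with DR the daily water consumption (L/day), EF the exposure frequency
(days/year), ED the exposure duration (years), BW body weight (kg) and AT
the averaging time (days).  The hazard quotient is HQ = ADD / RfD against
the congener's oral reference dose, and the hazard index HI = Σ HQ across
congeners; HI < 1 is read as low non-cancer risk, HI > 1 as high.

Carcinogenic risk (CR = ADD · CSF, RI = Σ CR with tiers at 1e-6 and 1e-4)
is implemented for generality but left not-evaluated when no cancer slope
factor is configured — DMP, DEP and DBP are treated as non-cancer
compounds.

Default parameterisation: DR 2 L/day, BW 60 kg, EF 350 days/year, ED 30
years, AT 26,280 days, RfD 1.0 / 0.8 / 0.1 mg·kg⁻¹·day⁻¹ for DMP / DEP /
DBP.  AT is used exactly as stated (26,280 days = 72 years, not ED·365);
``strict_averaging_time=True`` recomputes AT = ED·365 for sensitivity.

China's surface-water quality limit for DBP (3 µg/L, GB3838-2002) is a
concentration screening threshold, not a dose RfD, and is exposed
separately as ``DBP_SURFACE_WATER_LIMIT_MG_PER_L``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .dataio import PAE_CONGENERS, SampleRecord
from .exceptions import ValidationError

__all__ = [
    "RiskParams",
    "RiskResult",
    "average_daily_dose",
    "hazard_quotient",
    "hazard_index",
    "carcinogenic_risk",
    "risk_index",
    "assess_sample",
    "pae_composition",
    "composition_shares",
    "DBP_SURFACE_WATER_LIMIT_MG_PER_L",
]

DBP_SURFACE_WATER_LIMIT_MG_PER_L = 0.003


@dataclass(frozen=True)
class RiskParams:
    """Exposure parameters and per-congener toxicity values (all in mg-based units)."""

    dr_l_per_day: float = 2.0
    ef_days_per_year: float = 350.0
    ed_years: float = 30.0
    bw_kg: float = 60.0
    at_days: float = 26280.0
    rfd_mg_per_kg_day: Mapping[str, float] = field(
        default_factory=lambda: {"DMP": 1.0, "DEP": 0.8, "DBP": 0.1})
    csf_per_mg_per_kg_day: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("dr_l_per_day", "ef_days_per_year", "ed_years", "bw_kg", "at_days"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        for congener, rfd in self.rfd_mg_per_kg_day.items():
            if not rfd > 0:
                raise ValidationError(f"RfD for {congener} must be positive")

    def with_strict_averaging_time(self) -> "RiskParams":
        """Sensitivity variant with AT recomputed as ED·365 days."""
        return replace(self, at_days=self.ed_years * 365.0)


def average_daily_dose(c_mg_per_l: float, params: RiskParams = RiskParams()) -> float:
    """ADD = (C·DR·EF·ED)/(BW·AT) in mg·kg⁻¹·day⁻¹; linear in C."""
    if c_mg_per_l < 0:
        raise ValidationError("concentration must be non-negative")
    return (c_mg_per_l * params.dr_l_per_day * params.ef_days_per_year
            * params.ed_years) / (params.bw_kg * params.at_days)


def hazard_quotient(add: float, rfd: float, congener: str = "") -> float:
    """HQ = ADD / RfD (both mg·kg⁻¹·day⁻¹)."""
    if rfd is None or not rfd > 0:
        raise ValidationError(
            f"no positive RfD configured for congener {congener or '<unknown>'}")
    return add / rfd


def hazard_index(hqs: Sequence[float]) -> tuple[float, str]:
    """HI = Σ HQ with the low/high non-cancer classification."""
    hqs = list(hqs)
    if not hqs:
        raise ValidationError("hazard_index needs at least one hazard quotient")
    hi = float(sum(hqs))
    if hi < 1.0:
        label = "low non-cancer risk"
    elif hi > 1.0:
        label = "high non-cancer risk"
    else:
        label = "boundary"
    return hi, label


def carcinogenic_risk(add: float, csf: float) -> float:
    """CR = ADD · CSF (dimensionless lifetime excess risk)."""
    if csf < 0:
        raise ValidationError("cancer slope factor must be non-negative")
    return add * csf


def risk_index(crs: Sequence[float]) -> tuple[float, str]:
    """RI = Σ CR with tiers: <1e-6 very low, >1e-4 unacceptable, else intermediate."""
    ri = float(sum(crs))
    if ri < 1e-6:
        tier = "very low"
    elif ri > 1e-4:
        tier = "unacceptable"
    else:
        tier = "intermediate"
    return ri, tier


@dataclass
class RiskResult:
    """Per-sample risk summary across congeners."""

    sample_id: str = ""
    add_mg_per_kg_day: dict = field(default_factory=dict)
    hq: dict = field(default_factory=dict)
    hi: float = math.nan
    classification: str = ""
    cr: dict | None = None
    ri: float | None = None
    carcinogenic_tier: str = "not evaluated"


def assess_sample(concentrations_mg_per_l: Mapping[str, float],
                  params: RiskParams = RiskParams(),
                  sample_id: str = "") -> RiskResult:
    """Full non-cancer (and, when CSFs exist, cancer) assessment of one sample.

    Congeners with missing (NaN) concentrations are skipped; an empty set
    after filtering is an error.
    """
    adds: dict[str, float] = {}
    hqs: dict[str, float] = {}
    for congener, conc in concentrations_mg_per_l.items():
        if conc is None or (isinstance(conc, float) and math.isnan(conc)):
            continue
        add = average_daily_dose(conc, params)
        adds[congener] = add
        hqs[congener] = hazard_quotient(add, params.rfd_mg_per_kg_day.get(congener),
                                        congener)
    if not hqs:
        raise ValidationError("no congener concentrations to assess")
    hi, label = hazard_index(list(hqs.values()))
    result = RiskResult(sample_id=sample_id, add_mg_per_kg_day=adds, hq=hqs,
                        hi=hi, classification=label)
    csfs = {c: params.csf_per_mg_per_kg_day.get(c) for c in adds}
    if any(v is not None for v in csfs.values()):
        crs = {c: carcinogenic_risk(adds[c], csf) for c, csf in csfs.items()
               if csf is not None}
        result.cr = crs
        result.ri, result.carcinogenic_tier = risk_index(list(crs.values()))
    return result


def composition_shares(means_mg_per_l: Mapping[str, float]) -> dict[str, float]:
    """Percentage share of each congener mean in the summed mean (Σ = 100)."""
    total = float(sum(means_mg_per_l.values()))
    if not total > 0:
        raise ValidationError("summed mean concentration must be positive")
    return {c: 100.0 * v / total for c, v in means_mg_per_l.items()}


def pae_composition(samples: Sequence[SampleRecord],
                    grouping: str = "season") -> pd.DataFrame:
    """Per-congener mean/median/max, summed means and percentage shares.

    ``grouping="season"`` summarises June and October separately plus an
    ``overall`` group; ``grouping="overall"`` pools everything.  Overall
    means are plain means over all samples, i.e. sample-size-weighted
    across seasons.  Returns a tidy frame indexed by (group, congener) with
    a ``SUM`` row per group carrying the summed mean and share 100.
    """
    if not samples:
        raise ValidationError("pae_composition needs at least one sample")
    frame = pd.DataFrame(
        {"season": [s.season for s in samples],
         "DMP": [s.dmp_mg_per_l for s in samples],
         "DEP": [s.dep_mg_per_l for s in samples],
         "DBP": [s.dbp_mg_per_l for s in samples]})
    if grouping == "season":
        groups = [(season, frame[frame["season"] == season])
                  for season in frame["season"].unique().tolist()]
        groups.append(("overall", frame))
    elif grouping == "overall":
        groups = [("overall", frame)]
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    rows = []
    for name, sub in groups:
        if sub.empty:
            continue
        means = {c: float(sub[c].mean()) for c in PAE_CONGENERS}
        shares = composition_shares(means)
        for c in PAE_CONGENERS:
            rows.append({"group": name, "congener": c, "n": int(sub[c].notna().sum()),
                         "mean_mg_per_l": means[c],
                         "median_mg_per_l": float(sub[c].median()),
                         "max_mg_per_l": float(sub[c].max()),
                         "share_pct": shares[c]})
        rows.append({"group": name, "congener": "SUM", "n": int(len(sub)),
                     "mean_mg_per_l": float(sum(means.values())),
                     "median_mg_per_l": math.nan, "max_mg_per_l": math.nan,
                     "share_pct": 100.0})
    return pd.DataFrame(rows).set_index(["group", "congener"])
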