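"""USEPA inhalation health-risk assessment for heavy metals in PM2.5.

For a metal concentration C (mg/m3) the average daily inhaled dose is

    Dinh = C * IR * EF * ED / (BW * AT)        [mg/(kg d)]

with respiration rate IR (m3/d), exposure frequency EF (d/yr), exposure
duration ED (yr), body weight BW (kg) and averaging time AT (d).  The
non-carcinogenic hazard quotient and the incremental lifetime cancer
risk follow as

    HQ   = Dinh / RfD
    ILCR = Dinh * SF

where RfD is the inhalation reference dose (mg/(kg d)) and SF the cancer
slope factor ((mg/(kg d))^-1).  HQ > 1 flags potential non-cancer
effects; ILCR between 1e-6 and 1e-4 is the conventional acceptable band.

So that risk can enter a receptor model alongside concentrations, HQ and
ILCR are mapped onto a concentration-like scale by the equivalent
conversion

    x_conv = 10 / (-log10 x),        0 < x < 1,

which sends 10^-k to 10/k; for ambient risks (1e-6..1e-1) the converted
indices have the same order of magnitude as trace-element concentrations
in ng/m3.

Note on Cr: the default slope factor (42) is a Cr(VI) value but is
applied to measured *total* Cr, since routine speciation data do not
resolve oxidation state.  Risks for Cr are therefore upper-bound-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .speciation_io import RISK_METALS, SpeciesTable

#: ng/m3 -> mg/m3 (1 mg = 1e6 ng)
MG_PER_NG_M3 = 1e-6

#: conventional ILCR decision thresholds
ILCR_SAFE = 1e-6
ILCR_UPPER = 1e-4

#: equivalent-conversion domain guards: inputs at or above CONV_CLIP are
#: clipped (the map diverges at 1), inputs at or below CONV_FLOOR are
#: reported missing.
CONV_CLIP = 0.99
CONV_FLOOR = 1e-30

CONV_FLAG_OK = 0
CONV_FLAG_CLIPPED = 1
CONV_FLAG_MISSING = 2


@dataclass
class ExposureParameters:
    """Pooled-population inhalation exposure parameters.

    Defaults are all-age averages: IR 17.6 m3/d, EF 255 d/yr, ED 70 yr,
    BW 60 kg, AT 70*365 d (used for carcinogens and non-carcinogens
    alike).
    """

    inhalation_rate: float = 17.6          # m3/d
    exposure_frequency: float = 255.0      # d/yr
    exposure_duration: float = 70.0        # yr
    body_weight: float = 60.0              # kg
    averaging_time: float = 70.0 * 365.0   # d

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"exposure parameter {name} must be positive, got {v}")
        if self.averaging_time < self.exposure_frequency * self.exposure_duration:
            raise ValueError("averaging_time (d) must cover EF (d/yr) x ED (yr) total exposure days")

    @property
    def dose_factor(self) -> float:
        """Dose per unit concentration: (mg/(kg d)) per (mg/m3)."""
        return (self.inhalation_rate * self.exposure_frequency * self.exposure_duration
                / (self.body_weight * self.averaging_time))


@dataclass
class ToxicityTable:
    """Per-metal inhalation reference doses and cancer slope factors."""

    rfd: dict[str, float] = field(default_factory=dict)   # mg/(kg d)
    sf: dict[str, float] = field(default_factory=dict)    # (mg/(kg d))^-1

    def __post_init__(self) -> None:
        for m, v in self.rfd.items():
            if not v > 0:
                raise ValueError(f"RfD({m}) must be > 0, got {v}")
        for m, v in self.sf.items():
            if v < 0:
                raise ValueError(f"SF({m}) must be >= 0, got {v}")

    @classmethod
    def default(cls) -> "ToxicityTable":
        return cls(
            rfd={"Cr": 2.86e-5, "Ni": 2.06e-2, "As": 3.01e-4, "Cd": 1.00e-3},
            sf={"Cr": 42.0, "Ni": 0.84, "As": 15.1, "Cd": 6.3},
        )

    def require(self, metals: Sequence[str]) -> None:
        missing = [m for m in metals if m not in self.rfd or m not in self.sf]
        if missing:
            raise KeyError(f"toxicity table missing metals: {missing}")


def daily_dose(concentration_mg_m3, params: ExposureParameters):
    """Average daily inhaled dose, mg/(kg d), for C in mg/m3 (linear in C)."""
    c = np.asarray(concentration_mg_m3, dtype=float)
    if np.any(np.isfinite(c) & (c < 0)):
        raise ValueError("negative concentration in daily_dose")
    out = c * params.dose_factor
    return float(out) if out.ndim == 0 else out


def hazard_quotient(dinh, rfd: float):
    """HQ = Dinh / RfD (unitless)."""
    if not rfd > 0:
        raise ValueError(f"RfD must be > 0, got {rfd}")
    out = np.asarray(dinh, dtype=float) / rfd
    return float(out) if out.ndim == 0 else out


def cancer_risk(dinh, sf: float):
    """ILCR = Dinh * SF (unitless lifetime probability)."""
    if sf < 0:
        raise ValueError(f"SF must be >= 0, got {sf}")
    out = np.asarray(dinh, dtype=float) * sf
    return float(out) if out.ndim == 0 else out


def ilcr_category(ilcr: float) -> str:
    """Three-level flag against the 1e-6 / 1e-4 thresholds."""
    if ilcr < ILCR_SAFE:
        return "negligible"
    if ilcr <= ILCR_UPPER:
        return "acceptable"
    return "elevated"


def convert_risk_index(x, clip_high: float = CONV_CLIP, floor: float = CONV_FLOOR):
    """Equivalent conversion x -> 10 / (-log10 x) on (0, 1).

    Returns ``(values, flags)``.  Inputs <= ``floor`` (including 0 and
    NaN) give NaN with flag 2; inputs >= ``clip_high`` are clipped there
    and flagged 1.  The map is strictly increasing and sends 10^-k to
    10/k exactly.
    """
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    flags = np.zeros(arr.shape, dtype=int)

    missing = ~(arr > floor)          # catches NaN, zeros, negatives, tiny
    clipped = (~missing) & (arr >= clip_high)
    flags[missing] = CONV_FLAG_MISSING
    flags[clipped] = CONV_FLAG_CLIPPED

    safe = np.where(missing, 0.5, np.where(clipped, clip_high, arr))
    out = 10.0 / (-np.log10(safe))
    out[missing] = np.nan
    if scalar:
        return float(out[0]), int(flags[0])
    return out, flags


@dataclass
class RiskSeries:
    """Per-sample, per-metal dose and risk indices (all unitless except
    dose, mg/(kg d)); ``*_conv`` are the equivalent-converted values."""

    dose: pd.DataFrame
    hq: pd.DataFrame
    ilcr: pd.DataFrame
    hq_conv: pd.DataFrame
    ilcr_conv: pd.DataFrame
    conv_flags: pd.DataFrame

    @property
    def metals(self) -> list[str]:
        return list(self.dose.columns)

    @property
    def n_samples(self) -> int:
        return len(self.dose)


def risk_series(table: SpeciesTable,
                metals: Sequence[str] | None = None,
                params: ExposureParameters | None = None,
                tox: ToxicityTable | None = None) -> RiskSeries:
    """Per-sample Dinh, HQ, ILCR and converted indices for each metal.

    By linearity of the dose/risk equations, campaign-mean HQ and ILCR
    equal the values computed from campaign-mean concentrations.
    """
    metals = list(metals) if metals is not None else list(RISK_METALS)
    params = params or ExposureParameters()
    tox = tox or ToxicityTable.default()
    tox.require(metals)
    absent = [m for m in metals if m not in table.species]
    if absent:
        raise KeyError(f"metals not present in table: {absent}")

    idx = table.timestamps
    dose, hq, ilcr = {}, {}, {}
    hq_conv, ilcr_conv, flags = {}, {}, {}
    for m in metals:
        c_mg = table.data[m].to_numpy(dtype=float) * MG_PER_NG_M3
        d = daily_dose(np.nan_to_num(c_mg, nan=0.0), params)
        d = np.where(np.isnan(c_mg), np.nan, d)
        h = hazard_quotient(d, tox.rfd[m])
        r = cancer_risk(d, tox.sf[m])
        hc, hf = convert_risk_index(h)
        rc, rf = convert_risk_index(r)
        dose[m], hq[m], ilcr[m] = d, h, r
        hq_conv[m], ilcr_conv[m] = hc, rc
        flags[f"HQ_{m}"] = hf
        flags[f"ILCR_{m}"] = rf

    mk = lambda d: pd.DataFrame(d, index=idx)
    return RiskSeries(mk(dose), mk(hq), mk(ilcr), mk(hq_conv), mk(ilcr_conv), mk(flags))


def risk_summary(table: SpeciesTable,
                 metals: Sequence[str] | None = None,
                 params: ExposureParameters | None = None,
                 tox: ToxicityTable | None = None) -> pd.DataFrame:
    """Campaign-mean HQ and ILCR per metal with totals, percentage shares
    and threshold flags.  Shares sum to 100%."""
    rs = risk_series(table, metals, params, tox)
    mean_c = table.data[rs.metals].mean()
    mean_hq = rs.hq.mean()
    mean_ilcr = rs.ilcr.mean()
    tot_hq = float(mean_hq.sum())
    tot_ilcr = float(mean_ilcr.sum())

    rows = []
    for m in rs.metals:
        rows.append({
            "metal": m,
            "mean_concentration_ng_m3": float(mean_c[m]),
            "mean_dose_mg_kg_d": float(rs.dose[m].mean()),
            "mean_hq": float(mean_hq[m]),
            "hq_share_pct": 100.0 * float(mean_hq[m]) / tot_hq if tot_hq > 0 else np.nan,
            "mean_ilcr": float(mean_ilcr[m]),
            "ilcr_share_pct": 100.0 * float(mean_ilcr[m]) / tot_ilcr if tot_ilcr > 0 else np.nan,
            "hq_exceeds_1": bool(mean_hq[m] > 1),
            "ilcr_category": ilcr_category(float(mean_ilcr[m])),
        })
    rows.append({
        "metal": "total",
        "mean_concentration_ng_m3": float(mean_c.sum()),
        "mean_dose_mg_kg_d": float(rs.dose.mean().sum()),
        "mean_hq": tot_hq,
        "hq_share_pct": 100.0,
        "mean_ilcr": tot_ilcr,
        "ilcr_share_pct": 100.0,
        "hq_exceeds_1": bool(tot_hq > 1),
        "ilcr_category": ilcr_category(tot_ilcr),
    })
    return pd.DataFrame(rows).set_index("metal")
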