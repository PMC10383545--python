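"""Reading, writing and validation of speciated PM2.5 campaign data.

All concentrations are held internally in ng/m3.  Files may mix units
(carbon and ions are customarily reported in ug/m3, trace elements in
ng/m3); each column carries a unit suffix in its header, e.g.
``OC (ug/m3)``, and is converted on read.  The conversion is lossless,
so a write/read round trip reproduces the table exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("sourcerisk")

INTERNAL_UNIT = "ng/m3"

#: measured species of the default campaign: OC/EC, three water-soluble
#: inorganic ions, and 13 elements.
DEFAULT_SPECIES: list[str] = [
    "OC", "EC",
    "NO3-", "SO42-", "K+",
    "Fe", "Si", "Ca", "Mn", "Pb", "Ba", "Cu", "As", "Cr", "Cd", "Ni", "Hg", "V",
]

#: heavy metals assessed for inhalation health risk.
RISK_METALS: list[str] = ["Cr", "Ni", "As", "Cd"]

ION_SPECIES: list[str] = ["NO3-", "SO42-", "K+"]
ELEMENT_SPECIES: list[str] = [
    "Fe", "Si", "Ca", "Mn", "Pb", "Ba", "Cu", "As", "Cr", "Cd", "Ni", "Hg", "V",
]

_UNIT_FACTORS = {"ng/m3": 1.0, "ug/m3": 1e3, "mg/m3": 1e6}


def normalize_unit(unit: str) -> str:
    return (
        unit.strip()
        .lower()
        .replace("µ", "u")   # micro sign
        .replace("μ", "u")   # greek mu
        .replace("³", "3")
        .replace(" ", "")
    )


def unit_factor(unit: str) -> float:
    """Multiplicative factor converting ``unit`` to the internal ng/m3."""
    u = normalize_unit(unit)
    if u not in _UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit {unit!r}")
    return _UNIT_FACTORS[u]


def _first_negative_cell(df: pd.DataFrame):
    vals = df.to_numpy(dtype=float)
    neg = np.asarray(vals < 0)
    if neg.any():
        i, j = np.argwhere(neg)[0]
        return df.index[i], df.columns[j], vals[i, j]
    return None


@dataclass
class SpeciesTable:
    """Samples x species concentration matrix with timestamps.

    ``data`` is indexed by a strictly increasing :class:`pandas.DatetimeIndex`
    with one column per species, values in ng/m3 (NaN marks a missing
    observation).  ``units`` records the unit each species was *read* in.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("SpeciesTable requires a DatetimeIndex")
        idx = self.data.index
        if len(idx) > 1 and not (idx.is_monotonic_increasing and idx.is_unique):
            raise ValueError("timestamps must be strictly increasing")
        hit = _first_negative_cell(self.data)
        if hit is not None:
            t, s, v = hit
            raise ValueError(f"negative concentration {v!r} for {s} at {t}")
        self.units = {s: self.units.get(s, INTERNAL_UNIT) for s in self.data.columns}

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    def subset(self, species: Sequence[str]) -> "SpeciesTable":
        missing = [s for s in species if s not in self.data.columns]
        if missing:
            raise KeyError(f"species not in table: {missing}")
        return SpeciesTable(self.data[list(species)].copy(),
                            {s: self.units[s] for s in species},
                            self.provenance)


def read_species_table(path: str | Path) -> SpeciesTable:
    """Read a speciation CSV (timestamp column first, unit-suffixed headers).

    Headers of the form ``Name (unit)`` are converted to ng/m3; a bare
    header is taken to be ng/m3 already.  Negative cells and unparseable
    timestamps are rejected with their location.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected a timestamp column plus species columns")
    tcol = raw.columns[0]
    try:
        ts = pd.to_datetime(raw[tcol], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp in column {tcol!r}: {exc}") from exc

    data: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for col in raw.columns[1:]:
        name, unit = col, INTERNAL_UNIT
        if "(" in col and col.rstrip().endswith(")"):
            name, rest = col.split("(", 1)
            name = name.strip()
            unit = rest.rsplit(")", 1)[0]
        factor = unit_factor(unit)
        vals = pd.to_numeric(raw[col], errors="coerce").to_numpy(dtype=float)
        bad = np.isfinite(vals) & (vals < 0)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"{path}: negative concentration {vals[i]!r} for species "
                f"{name!r} at row {i} ({ts.iloc[i]})"
            )
        data[name] = vals * factor
        units[name] = unit
        if factor != 1.0:
            logger.debug("converted %s from %s to %s (x%g)", name, unit, INTERNAL_UNIT, factor)
    df = pd.DataFrame(data, index=pd.DatetimeIndex(ts, name="timestamp"))
    return SpeciesTable(df, units, provenance=str(path))


def write_species_table(table: SpeciesTable, path: str | Path) -> None:
    """Write a table in the internal unit with explicit unit suffixes."""
    df = table.data.copy()
    df.columns = [f"{s} ({INTERNAL_UNIT})" for s in df.columns]
    df.index.name = "timestamp"
    out = df.reset_index()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# campaign configuration


@dataclass
class CampaignConfig:
    """Everything needed to reproduce a run: exposure and toxicity
    parameters, the uncertainty model, the factorization settings and the
    master seed."""

    exposure: Any = None          # health_risk.ExposureParameters
    toxicity: Any = None          # health_risk.ToxicityTable
    uncertainty: Any = None       # uncertainty_model.UncertaintySpec
    factor_range: tuple[int, int] = (1, 10)
    n_starts: int = 10
    seed: int = 0
    mass_species: list[str] = field(default_factory=lambda: list(DEFAULT_SPECIES))
    risk_metals: list[str] = field(default_factory=lambda: list(RISK_METALS))
    pseudo_uncertainty_inflation: float = 1.0


def default_config(species: Sequence[str] | None = None,
                   cv: float = 0.1, seed: int = 0) -> CampaignConfig:
    from .health_risk import ExposureParameters, ToxicityTable
    from .uncertainty_model import UncertaintySpec

    species = list(species) if species is not None else list(DEFAULT_SPECIES)
    return CampaignConfig(
        exposure=ExposureParameters(),
        toxicity=ToxicityTable.default(),
        uncertainty=UncertaintySpec.uniform(species, cv=cv),
        mass_species=species,
        seed=seed,
    )


def config_from_dict(d: Mapping[str, Any]) -> CampaignConfig:
    """Build a config from a (possibly partial) nested mapping, filling
    defaults for anything absent."""
    from .health_risk import ExposureParameters, ToxicityTable
    from .uncertainty_model import UncertaintySpec

    d = dict(d or {})
    mass_species = list(d.get("mass_species", DEFAULT_SPECIES))
    exp = ExposureParameters(**(d.get("exposure") or {}))
    toxd = d.get("toxicity") or {}
    if toxd:
        tox = ToxicityTable(rfd=dict(toxd["rfd"]), sf=dict(toxd["sf"]))
    else:
        tox = ToxicityTable.default()
    und = d.get("uncertainty") or {}
    if und:
        cv = und.get("cv", {})
        dl = und.get("dl", {})
        if isinstance(cv, (int, float)):
            cv = {s: float(cv) for s in mass_species}
        spec = UncertaintySpec(dl={s: float(dl.get(s, 0.0)) for s in mass_species},
                               cv={s: float(cv.get(s, 0.1)) for s in mass_species})
    else:
        spec = UncertaintySpec.uniform(mass_species, cv=0.1)
    fr = d.get("factor_range", (1, 10))
    cfg = CampaignConfig(
        exposure=exp, toxicity=tox, uncertainty=spec,
        factor_range=(int(fr[0]), int(fr[1])),
        n_starts=int(d.get("n_starts", 10)),
        seed=int(d.get("seed", 0)),
        mass_species=mass_species,
        risk_metals=list(d.get("risk_metals", RISK_METALS)),
        pseudo_uncertainty_inflation=float(d.get("pseudo_uncertainty_inflation", 1.0)),
    )
    return validate_config(cfg)


def validate_config(config: CampaignConfig | Mapping[str, Any]) -> CampaignConfig:
    """Check all config invariants; accepts a mapping for convenience."""
    if isinstance(config, Mapping):
        return config_from_dict(config)
    lo, hi = config.factor_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid factor_range {config.factor_range}: need 1 <= lo <= hi")
    if config.n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if config.pseudo_uncertainty_inflation <= 0:
        raise ValueError("pseudo_uncertainty_inflation must be positive")
    for metal in config.risk_metals:
        if metal not in config.toxicity.rfd or metal not in config.toxicity.sf:
            raise ValueError(f"toxicity table missing entry for risk metal {metal!r}")
    config.uncertainty.require(config.mass_species)
    return config


def load_config(path: str | Path) -> CampaignConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return config_from_dict(d)


def dump_config(config: CampaignConfig, path: str | Path) -> None:
    d = {
        "exposure": vars(config.exposure).copy(),
        "toxicity": {"rfd": dict(config.toxicity.rfd), "sf": dict(config.toxicity.sf)},
        "uncertainty": {"dl": dict(config.uncertainty.dl), "cv": dict(config.uncertainty.cv)},
        "factor_range": list(config.factor_range),
        "n_starts": config.n_starts,
        "seed": config.seed,
        "mass_species": list(config.mass_species),
        "risk_metals": list(config.risk_metals),
        "pseudo_uncertainty_inflation": config.pseudo_uncertainty_inflation,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
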