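"""Per-cell measurement-uncertainty model for receptor fitting.

Each cell of the speciation matrix gets an uncertainty

    u_ij = sqrt(DL_j^2 + (CV_j * x_ij)^2)

from a species detection limit DL_j (twice the field-blank standard
deviation) and a coefficient of variation CV_j.  Below-detection and
missing observations follow the usual receptor-modelling conventions:
values below DL are replaced by DL/2 with u = (5/6) DL, missing values
by the species median with u = 4 x median; every replacement is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .speciation_io import SpeciesTable

#: strictly positive floor preventing division by zero in the weighted
#: objective (internal ng/m3 units)
U_FLOOR = 1e-12

FLAG_OBSERVED = 0
FLAG_BELOW_DL = 1
FLAG_MISSING = 2


@dataclass
class UncertaintySpec:
    """Per-species detection limits (internal units) and CVs."""

    dl: dict[str, float] = field(default_factory=dict)
    cv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.dl.items():
            if v < 0:
                raise ValueError(f"DL({name}) must be >= 0, got {v}")
        for name, v in self.cv.items():
            if v < 0:
                raise ValueError(f"CV({name}) must be >= 0, got {v}")

    @classmethod
    def uniform(cls, species: Sequence[str], cv: float = 0.1,
                dl: float | Mapping[str, float] = 0.0) -> "UncertaintySpec":
        if isinstance(dl, Mapping):
            dlmap = {s: float(dl.get(s, 0.0)) for s in species}
        else:
            dlmap = {s: float(dl) for s in species}
        return cls(dl=dlmap, cv={s: float(cv) for s in species})

    def require(self, species: Sequence[str]) -> None:
        missing = [s for s in species if s not in self.dl or s not in self.cv]
        if missing:
            raise KeyError(f"uncertainty spec missing species: {missing}")


def detection_limit_from_blanks(blanks: pd.DataFrame | Mapping[str, Sequence[float]]
                                ) -> dict[str, float]:
    """DL_j = 2 x sample standard deviation of the field blanks of species j."""
    df = pd.DataFrame(blanks)
    if len(df) < 2:
        raise ValueError("need at least 2 field blanks to estimate a standard deviation")
    return {s: 2.0 * float(df[s].std(ddof=1)) for s in df.columns}


@dataclass
class UncertaintyMatrix:
    """n x m uncertainties aligned with a species table, plus per-cell
    policy flags (0 observed, 1 below-DL replaced, 2 missing replaced)."""

    values: pd.DataFrame
    flags: pd.DataFrame

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def replacement_counts(self) -> dict[str, int]:
        f = self.flags.to_numpy()
        return {"below_dl": int((f == FLAG_BELOW_DL).sum()),
                "missing": int((f == FLAG_MISSING).sum())}


def cell_uncertainty(x, dl: float, cv: float, floor: float = U_FLOOR):
    """sqrt(DL^2 + (CV x)^2), floored strictly positive."""
    u = np.sqrt(dl ** 2 + (cv * np.asarray(x, dtype=float)) ** 2)
    return np.maximum(u, floor)


def uncertainty_matrix(table: SpeciesTable, spec: UncertaintySpec,
                       floor: float = U_FLOOR) -> UncertaintyMatrix:
    """Evaluate u_ij on observed cells (NaN cells stay NaN; use
    :func:`apply_missing_policy` for campaigns with gaps)."""
    spec.require(table.species)
    u = pd.DataFrame(index=table.timestamps, columns=table.species, dtype=float)
    for s in table.species:
        x = table.data[s].to_numpy(dtype=float)
        us = cell_uncertainty(np.nan_to_num(x, nan=0.0), spec.dl[s], spec.cv[s], floor)
        u[s] = np.where(np.isnan(x), np.nan, us)
    flags = pd.DataFrame(FLAG_OBSERVED, index=table.timestamps,
                         columns=table.species, dtype=int)
    return UncertaintyMatrix(u, flags)


def apply_missing_policy(table: SpeciesTable, spec: UncertaintySpec,
                         floor: float = U_FLOOR
                         ) -> tuple[SpeciesTable, UncertaintyMatrix, pd.DataFrame]:
    """Replace below-DL and missing cells and build the full uncertainty
    matrix.

    Policy: x < DL -> DL/2 with u = (5/6) DL; missing -> species median
    of observed values with u = 4 x median.  Returns the adjusted table,
    the uncertainty matrix (strictly positive everywhere) and the flag
    frame.
    """
    spec.require(table.species)
    newdata = table.data.copy()
    u = pd.DataFrame(index=table.timestamps, columns=table.species, dtype=float)
    flags = pd.DataFrame(FLAG_OBSERVED, index=table.timestamps,
                         columns=table.species, dtype=int)
    for s in table.species:
        x = table.data[s].to_numpy(dtype=float)
        obs = np.isfinite(x)
        if not obs.any():
            raise ValueError(f"species {s!r} has no observed values")
        dl, cv = spec.dl[s], spec.cv[s]
        median = float(np.median(x[obs]))

        below = obs & (x < dl)
        miss = ~obs
        xs = x.copy()
        xs[below] = dl / 2.0
        xs[miss] = median

        us = cell_uncertainty(xs, dl, cv, floor)
        us[below] = max(5.0 / 6.0 * dl, floor)
        us[miss] = max(4.0 * median, floor)

        newdata[s] = xs
        u[s] = us
        col = flags[s].to_numpy()
        col[below] = FLAG_BELOW_DL
        col[miss] = FLAG_MISSING
        flags[s] = col

    adjusted = SpeciesTable(newdata, dict(table.units), table.provenance)
    return adjusted, UncertaintyMatrix(u, flags), flags
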