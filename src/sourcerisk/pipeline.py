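"""End-to-end campaign analysis: combined matrix, fit, attribution.

The combined input matrix appends the eight equivalent-converted risk
indices (ILCR and HQ for each assessed metal) to the measured species,
so the factorization apportions health risk alongside mass.  Pseudo-
species uncertainties are proportional (the parent metal's CV, no
detection limit, optionally inflated); converted values that are
undefined (risk of exactly zero) are treated like missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import apportionment as app
from .health_risk import RiskSeries, risk_series
from .receptor_model import FactorModel, best_fit
from .speciation_io import CampaignConfig, SpeciesTable
from .uncertainty_model import (FLAG_MISSING, U_FLOOR, UncertaintyMatrix,
                                apply_missing_policy)


@dataclass
class CombinedCampaign:
    """A ready-to-fit campaign: data, uncertainties, and the risk series
    the pseudo-species came from."""

    X: pd.DataFrame                  # n x (m + 8)
    U: pd.DataFrame
    flags: pd.DataFrame
    table: SpeciesTable              # adjusted (policy-applied) species table
    risk: RiskSeries
    mass_species: list[str]
    risk_columns: list[str]

    @property
    def mass_index(self) -> np.ndarray:
        cols = list(self.X.columns)
        return np.array([cols.index(s) for s in self.mass_species])


def build_combined_matrix(table: SpeciesTable, config: CampaignConfig
                          ) -> CombinedCampaign:
    """Apply the below-DL/missing policy, compute per-sample risk, and
    assemble the combined species + risk-index matrix with uncertainties."""
    adjusted, umat, flags = apply_missing_policy(table, config.uncertainty)
    risk = risk_series(adjusted, config.risk_metals, config.exposure, config.toxicity)

    X = adjusted.data.copy()
    U = umat.values.copy()
    fl = flags.copy()
    risk_columns: list[str] = []
    infl = config.pseudo_uncertainty_inflation
    for prefix, frame in (("ILCR_conv", risk.ilcr_conv), ("HQ_conv", risk.hq_conv)):
        for m in config.risk_metals:
            col = f"{prefix}_{m}"
            vals = frame[m].to_numpy(dtype=float).copy()
            cv = config.uncertainty.cv[m]
            u = np.maximum(cv * infl * np.abs(vals), U_FLOOR)
            fcol = np.zeros(len(vals), dtype=int)
            miss = ~np.isfinite(vals)
            if miss.any():                       # undefined conversion -> missing policy
                med = float(np.median(vals[~miss])) if (~miss).any() else 0.0
                vals[miss] = med
                u[miss] = max(4.0 * med, U_FLOOR)
                fcol[miss] = FLAG_MISSING
            X[col] = vals
            U[col] = u
            fl[col] = fcol
            risk_columns.append(col)

    return CombinedCampaign(X=X, U=U, flags=fl, table=adjusted, risk=risk,
                            mass_species=[s for s in config.mass_species
                                          if s in table.species],
                            risk_columns=risk_columns)


def fit_campaign(table: SpeciesTable, config: CampaignConfig, K: int = 7,
                 n_starts: int | None = None, seed: int | None = None,
                 **fit_kwargs) -> tuple[FactorModel, CombinedCampaign]:
    """Build the combined matrix and fit the best-of-starts K-factor model."""
    combined = build_combined_matrix(table, config)
    model = best_fit(combined.X, combined.U, K,
                     n_starts=n_starts if n_starts is not None else config.n_starts,
                     seed=seed if seed is not None else config.seed,
                     mass_index=combined.mass_index, **fit_kwargs)
    return model, combined


def attribute_sources(model: FactorModel, combined: CombinedCampaign,
                      rules: Sequence[app.TracerRule] | None = None
                      ) -> app.SourceAttribution:
    """Label factors and compute mass, ILCR and HQ shares plus the
    lifetime-risk index series."""
    rules = list(rules) if rules is not None else app.default_tracer_rules()
    labels = app.label_factors(model, rules)
    mass = app.mass_shares(model, combined.mass_species, labels=labels)
    ilcr, hq = app.risk_shares(model, combined.risk, labels=labels)
    return app.SourceAttribution(
        labels=labels, mass_share=mass, ilcr_share=ilcr, hq_share=hq,
        lifetime_index=app.lifetime_risk_index(combined.risk),
    )
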