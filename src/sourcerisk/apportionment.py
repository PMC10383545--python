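"""Factor labelling and source-resolved mass and health-risk shares.

Factors from the receptor model are identified with emission source
types through tracer rules ("high loading" of a species means the
factor holds at least 40% of that species' explained variation and more
than any other factor).  Once labelled, each source gets its percentage
of the modelled mass, of the carcinogenic risk (ILCR) and of the
non-carcinogenic risk (HQ); the per-sample lifetime-risk index is the
sum of the eight equivalent-converted HQ and ILCR values of the four
assessed metals.

Because converted indices are not additive in risk space, risk shares
are aggregated across metals by weighting each metal's pseudo-species
with its campaign-mean *original* (unconverted) ILCR or HQ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .health_risk import RiskSeries
from .receptor_model import FactorModel
from .speciation_io import ELEMENT_SPECIES, ION_SPECIES, SpeciesTable

#: minimum explained-variation share for a "high loading" call
HIGH_LOADING_THRESHOLD = 0.40

UNASSIGNED = "unassigned"


@dataclass
class TracerRule:
    """Tracer signature of a source type."""

    source: str
    required: list[str]                      # high loading needed on all of these
    moderate: list[str] = field(default_factory=list)  # supporting species (tie-breaks)

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError(f"rule {self.source!r} needs at least one required species")


def default_tracer_rules() -> list[TracerRule]:
    """Rules for the seven canonical winter-suburb source types."""
    return [
        TracerRule("secondary", ["NO3-", "SO42-"]),
        TracerRule("biomass_burning", ["K+"], moderate=["Ba"]),
        TracerRule("traffic", ["Cr"], moderate=["Mn", "Ni", "Fe", "EC"]),
        TracerRule("fugitive_dust", ["Ca", "Si"], moderate=["Fe", "Ba"]),
        TracerRule("industry", ["Cd"], moderate=["Si", "Hg"]),
        TracerRule("coal_combustion", ["As"], moderate=["Pb"]),
        TracerRule("heavy_oil", ["V"], moderate=["Ni"]),
    ]


def _columns(model: FactorModel, columns: Sequence[str] | None) -> list[str]:
    cols = list(columns) if columns is not None else model.columns
    if cols is None:
        raise ValueError("species names unavailable: pass columns= or fit a DataFrame")
    if len(cols) != model.F.shape[1]:
        raise ValueError("column list does not match the fitted profile width")
    return cols


def explained_variation(model: FactorModel,
                        columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Share of each species' modelled mass attributed to each factor.

    ev[k, j] = sum_i G_ik F_kj / sum_i sum_k' G_ik' F_k'j; columns sum
    to 1 (species with zero modelled mass get all-zero shares).
    """
    cols = _columns(model, columns)
    g_tot = model.G.sum(axis=0)
    M = g_tot[:, None] * model.F
    denom = M.sum(axis=0)
    ev = np.divide(M, denom[None, :], out=np.zeros_like(M), where=denom > 0)
    return pd.DataFrame(ev, columns=cols)


def label_factors(model: FactorModel, rules: Sequence[TracerRule],
                  columns: Sequence[str] | None = None,
                  ev: pd.DataFrame | None = None,
                  threshold: float = HIGH_LOADING_THRESHOLD) -> dict[int, str]:
    """Assign each factor a source name via the tracer rules.

    Rules are applied most-specific first (more required species first).
    A factor satisfies a rule when, for every required species, it is the
    top factor by explained variation and holds at least ``threshold`` of
    it.  Among ties the candidate with the larger summed share (required
    plus moderate species) wins, with a warning.  Factors matching no
    rule are labelled ``"unassigned"``.
    """
    if ev is None:
        ev = explained_variation(model, columns)
    K = ev.shape[0]
    labels = {k: UNASSIGNED for k in range(K)}
    taken: set[int] = set()
    for rule in sorted(rules, key=lambda r: -len(r.required)):
        missing = [s for s in rule.required if s not in ev.columns]
        if missing:
            raise KeyError(f"rule {rule.source!r} requires species absent from the "
                           f"model: {missing}")
        candidates = []
        for k in range(K):
            shares = ev.loc[k, rule.required].to_numpy(dtype=float)
            argmax_ok = all(ev[s].idxmax() == k or
                            np.isclose(ev.loc[k, s], ev[s].max())
                            for s in rule.required)
            if argmax_ok and np.all(shares >= threshold):
                bonus = sum(float(ev.loc[k, s]) for s in rule.moderate if s in ev.columns)
                candidates.append((float(shares.sum()) + bonus, k))
        if not candidates:
            continue
        if len(candidates) > 1:
            warnings.warn(f"{len(candidates)} factors claim rule {rule.source!r}; "
                          "keeping the one with the larger summed share",
                          stacklevel=2)
        candidates.sort(reverse=True)
        for _, k in candidates:
            if k in taken:
                warnings.warn(f"factor {k} already labelled {labels[k]!r}; rule "
                              f"{rule.source!r} left unmatched", stacklevel=2)
                continue
            labels[k] = rule.source
            taken.add(k)
            break
    return labels


def _group_by_label(values: np.ndarray, labels: Mapping[int, str] | None) -> pd.Series:
    if labels is None:
        idx = [f"factor_{k + 1}" for k in range(len(values))]
        return pd.Series(values, index=idx)
    s = pd.Series(values, index=[labels[k] for k in range(len(values))])
    return s.groupby(level=0).sum()


def mass_shares(model: FactorModel, mass_species: Sequence[str] | None = None,
                columns: Sequence[str] | None = None,
                labels: Mapping[int, str] | None = None) -> pd.Series:
    """Percentage of total modelled mass per source (sums to 100)."""
    cols = _columns(model, columns)
    if mass_species is None:
        midx = np.arange(len(cols))
    else:
        midx = np.array([cols.index(s) for s in mass_species])
    per_factor = model.G.sum(axis=0) * model.F[:, midx].sum(axis=1)
    shares = 100.0 * per_factor / per_factor.sum()
    return _group_by_label(shares, labels)


def weekly_contributions(model: FactorModel, timestamps: pd.DatetimeIndex,
                         mass_species: Sequence[str] | None = None,
                         columns: Sequence[str] | None = None,
                         labels: Mapping[int, str] | None = None) -> pd.DataFrame:
    """Mean mass contribution of each source per ISO week."""
    cols = _columns(model, columns)
    midx = (np.arange(len(cols)) if mass_species is None
            else np.array([cols.index(s) for s in mass_species]))
    contrib = model.G * model.F[:, midx].sum(axis=1)[None, :]
    names = ([labels[k] for k in range(model.K)] if labels is not None
             else [f"factor_{k + 1}" for k in range(model.K)])
    df = pd.DataFrame(contrib, index=timestamps, columns=names)
    df = df.T.groupby(level=0).sum().T       # merge same-label factors
    iso = df.index.isocalendar()
    return df.groupby([iso.year, iso.week]).mean()


def risk_shares(model: FactorModel, risk: RiskSeries,
                columns: Sequence[str] | None = None,
                labels: Mapping[int, str] | None = None,
                basis: str = "metal_ev") -> tuple[pd.Series, pd.Series]:
    """Per-source percentages of carcinogenic (ILCR) and non-carcinogenic
    (HQ) risk, from a model fitted on the combined species + risk-index
    matrix.

    Per-metal factor shares are combined across metals weighted by the
    campaign-mean original (unconverted) ILCR (resp. HQ) of that metal.
    With ``basis="metal_ev"`` (default) the factor share of each metal's
    risk is its explained variation of the metal *concentration* — exact,
    because dose and risk are linear in concentration.  With
    ``basis="conv_ev"`` the share is the explained variation of the
    converted pseudo-species instead; the log-compression of the
    conversion makes that allocation much flatter and noisier (see
    docs/methods.md), so it is kept as a diagnostic variant.  The basis
    used is recorded in the returned Series' ``attrs``.
    """
    if basis not in ("metal_ev", "conv_ev"):
        raise ValueError(f"unknown risk-share basis {basis!r}")
    cols = _columns(model, columns)
    ev = explained_variation(model, cols)
    absent = [m for m in risk.metals
              if f"ILCR_conv_{m}" not in ev.columns or f"HQ_conv_{m}" not in ev.columns]
    if absent:
        raise ValueError(
            f"model was fitted without the risk pseudo-species for {absent}; "
            "fit the combined species + risk-index matrix (see "
            "pipeline.build_combined_matrix)")
    out = []
    for conv_prefix, weights in (("ILCR_conv", risk.ilcr.mean()),
                                 ("HQ_conv", risk.hq.mean())):
        w = weights / weights.sum()
        share = np.zeros(ev.shape[0])
        for m in risk.metals:
            col = m if basis == "metal_ev" else f"{conv_prefix}_{m}"
            share += float(w[m]) * ev[col].to_numpy(dtype=float)
        s = _group_by_label(100.0 * share, labels)
        s.attrs["basis"] = basis
        out.append(s)
    return out[0], out[1]


def lifetime_risk_index(risk: RiskSeries) -> pd.Series:
    """Per-sample sum of the eight converted HQ and ILCR values (missing
    conversions count as zero)."""
    idx = (risk.hq_conv.fillna(0.0).sum(axis=1)
           + risk.ilcr_conv.fillna(0.0).sum(axis=1))
    idx.name = "lifetime_risk_index"
    return idx


@dataclass
class SourceAttribution:
    """Labelled factors with their mass and risk shares."""

    labels: dict[int, str]
    mass_share: pd.Series
    ilcr_share: pd.Series
    hq_share: pd.Series
    lifetime_index: pd.Series


def summary_statistics(table: SpeciesTable,
                       ion_species: Sequence[str] | None = None,
                       element_species: Sequence[str] | None = None) -> dict:
    """Campaign summary: per-species mean +- sd and range, each inorganic
    constituent's share of the summed ions + elements, and the elements
    ranked by mean concentration."""
    ions = [s for s in (ion_species or ION_SPECIES) if s in table.species]
    elements = [s for s in (element_species or ELEMENT_SPECIES) if s in table.species]

    per_species = pd.DataFrame({
        "mean": table.data.mean(),
        "sd": table.data.std(ddof=1),
        "min": table.data.min(),
        "max": table.data.max(),
    })
    inorganic = ions + elements
    tot = per_species.loc[inorganic, "mean"].sum() if inorganic else np.nan
    inorganic_share = 100.0 * per_species.loc[inorganic, "mean"] / tot
    ranking = per_species.loc[elements].sort_values("mean", ascending=False)
    total = table.data.sum(axis=1)
    return {
        "per_species": per_species,
        "inorganic_share_pct": inorganic_share,
        "element_ranking": ranking,
        "total_mean": float(total.mean()),
        "total_sd": float(total.std(ddof=1)),
        "total_min": float(total.min()),
        "total_max": float(total.max()),
    }
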