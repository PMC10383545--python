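# sourcerisk

Joint source apportionment and inhalation health-risk assessment for
speciated PM2.5 campaigns.

Receptor models resolve a speciation time series x (samples × species)
into non-negative source profiles F and contributions G by minimizing
the uncertainty-weighted objective

    Q = Σᵢⱼ ((xᵢⱼ − (GF)ᵢⱼ) / uᵢⱼ)²,   uᵢⱼ = √(DLⱼ² + (CVⱼ·xᵢⱼ)²),

with detection limits DLⱼ = 2 × sd(field blanks) and per-species
coefficients of variation CVⱼ.  `sourcerisk` couples this factorization
with the USEPA inhalation risk equations for heavy metals (Cr, Ni, As,
Cd):

    Dinh = C·IR·EF·ED / (BW·AT),   HQ = Dinh/RfD,   ILCR = Dinh·SF,

and appends the equivalent-converted indices 10/(−log₁₀ x) of per-sample
HQ and ILCR to the species matrix, so the factorization apportions
health risk alongside mass.  Factors are labelled by tracer rules
(V → heavy-oil combustion, K⁺ → biomass burning, Cd → industry, As →
coal, Cr → traffic, NO₃⁻/SO₄²⁻ → secondary, Ca/Si → fugitive dust) and
each source receives its percentage of total mass, of carcinogenic risk
(ILCR) and of non-carcinogenic risk (HQ).

A seeded synthetic-campaign generator (seven tracer-dominated sources
with lognormal AR(1) contributions and the DL/CV noise model) provides
ground truth for every stage, so the whole pipeline is testable without
any field data.

## Worked example

```python
from sourcerisk import (simulate_default_campaign, default_config,
                        risk_summary, fit_campaign, attribute_sources)

table, truth, unc = simulate_default_campaign(seed=1, n_samples=800)
print(table.values.shape)                  # (800, 18)

summary = risk_summary(table)              # campaign-mean HQ / ILCR per metal
cfg = default_config(seed=1); cfg.uncertainty = unc
model, combined = fit_campaign(table, cfg, K=7, seed=7)
attr = attribute_sources(model, combined)
```

On this campaign the run prints a mean total concentration of
48.6 µg/m³ and the risk summary gives a total HQ of 0.067 (below the
threshold of 1) and a total ILCR of 1.0 × 10⁻⁴, dominated by Cr
(88.2% of HQ, 64.8% of ILCR) — i.e. residents face an appreciable
carcinogenic burden within the conventional 10⁻⁶–10⁻⁴ band.  The
seven-factor fit reaches Q/Qexp = 1.66 and the attribution shows the
pipeline's central behaviour: `secondary` dominates mass (54.2%) while
`traffic` — the Cr carrier with only a 10.8% mass share — tops the
carcinogenic-risk allocation at 55.5%.  Emission control that targeted
mass alone would miss the main source of health risk.

The same analyses are available from the shell:

```sh
sourcerisk simulate --out sim --seed 1 --n-samples 800
sourcerisk risk     --table sim/species.csv --config sim/config.yaml --out risk
sourcerisk scan     --table sim/species.csv --config sim/config.yaml --out scan
sourcerisk report   --table sim/species.csv --config sim/config.yaml --out report --k 7
```

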