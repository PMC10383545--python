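# Methods

## Inhalation health risk

For each assessed metal (Cr, Ni, As, Cd) and each sample, the average
daily inhaled dose is

    Dinh = C · IR · EF · ED / (BW · AT)    [mg/(kg·d)],

with C the concentration in mg/m³ (internal storage is ng/m³; the
conversion is ×10⁻⁶).  Defaults are pooled all-age averages: respiration
rate IR = 17.6 m³/d, exposure frequency EF = 255 d/yr, exposure duration
ED = 70 yr, body weight BW = 60 kg, averaging time AT = 70 × 365 d (used
for carcinogens and non-carcinogens alike).  ED enters in years: with EF
in d/yr and AT in days this is the only dimensionally consistent
combination.  Non-carcinogenic risk is HQ = Dinh/RfD, carcinogenic risk
ILCR = Dinh·SF, with inhalation reference doses (mg/(kg·d)) of
2.86×10⁻⁵, 2.06×10⁻², 3.01×10⁻⁴, 1.00×10⁻³ and slope factors
((mg/(kg·d))⁻¹) of 42, 0.84, 15.1, 6.3 for Cr, Ni, As, Cd.  The Cr
values are hexavalent-chromium toxicology applied to measured *total*
Cr (routine speciation data do not resolve oxidation state), so Cr risk
is upper-bound-like.  All equations are linear in concentration, so
campaign-mean risk equals the risk of the campaign-mean concentration;
the tests exploit this identity.

To let risk enter the receptor model alongside concentrations, HQ and
ILCR are mapped by the equivalent conversion y = 10/(−log₁₀ x), which
sends 10⁻ᵏ to 10/k and places ambient risks (10⁻⁶–10⁻¹) on the ng/m³
magnitude scale of the trace elements.  The map diverges at x → 1:
inputs ≥ 0.99 are clipped there (y ≈ 2291) and flagged; inputs ≤ 10⁻³⁰
(including exact zeros) give a missing value with a flag.  Per-sample
indices are converted (not period means): the factorization needs
per-sample pseudo-species.

## Uncertainty model

Each cell receives u = √(DL² + (CV·x)²), with DL = 2 × the sample
standard deviation of the field blanks and per-species CVs (default
0.1 — a declared assumption, not a measured value).  Values below DL
are replaced by DL/2 with u = (5/6)·DL; missing values by the species
median with u = 4 × median; both replacements are flagged and counted.
A floor of 10⁻¹² (internal units) keeps every weight finite.  The eight
converted risk indices get proportional uncertainties: the parent
metal's CV times the converted value, no DL, times a configurable
inflation factor (default 1).  No first-order propagation through the
conversion is attempted; the consequences of this choice are discussed
under *Model misspecification* below.

## Receptor model

The solver minimizes the weighted objective with multiplicative
updates (Lee–Seung form with per-cell weights 1/u²), which preserve
non-negativity and never increase Q — the monotone-descent invariant is
assertable at every iteration in test mode.  Defaults: max 2000
iterations (5000 in the recovery benchmarks), convergence when the
relative ΔQ stays below 10⁻⁶ for 10 consecutive iterations, 10 random
starts sub-seeded from one integer, initialization by folded Gaussian
draws scaled to each column's mean.  The scale ambiguity is fixed by
normalizing each profile row to sum 1 over the mass species (risk
pseudo-species excluded) and folding the scale into G.  Rotational
ambiguity is acknowledged, not resolved: no constrained rotations are
offered, and reproducibility comes from seed logging.

The expected objective is taken as Qexp = n·m − K·(n+m), the
degrees-of-freedom convention; the factor-number scan tabulates best-of-
starts Q/Qexp over K = 1…10 and an elbow rule selects the smallest K
whose improvement to K+1 falls below a configurable fraction (default
10%).  Fit quality is summarized by the OLS slope and R² of
reconstructed-vs-input over all modelled cells.  For benchmarking,
estimated factors are matched to known profiles by maximizing summed
cosine similarity (Hungarian assignment).

## Source labelling and shares

Explained variation of species j by factor k is Σᵢ Gᵢₖ Fₖⱼ normalized
over factors.  A tracer rule fires when its factor is the top holder of
every required species with at least 40% of its explained variation
(both configurable); rules are applied most-specific first, collisions
resolved toward the larger summed share with a warning, and unmatched
factors stay "unassigned".  Mass shares divide each labelled factor's
modelled mass (over the mass species) by the total.

Risk shares aggregate per-metal factor shares with weights equal to
each metal's campaign-mean *original* (unconverted) ILCR or HQ, since
converted values are not additive in risk space.  The per-metal factor
share itself has two bases.  The default, `metal_ev`, uses the factor's
explained variation of the metal *concentration*: because dose and risk
are linear in concentration, a factor holding 88% of Cr mass causes 88%
of Cr's risk — the allocation is exact.  The variant `conv_ev` uses the
explained variation of the converted pseudo-species instead; the
logarithmic compression of the conversion concentrates most of a
converted column in a baseline that a bilinear model can attribute to
any stable combination of factors, so this allocation is flat and
seed-sensitive even when the contributions are known exactly (verified
by weighted-NNLS attribution against ground truth).  The basis used is
recorded in the output's metadata.  The per-sample lifetime-risk index
is the sum of the eight converted HQ and ILCR values.

## Synthetic campaigns

The generator emulates a three-month hourly winter campaign at a
suburban receptor (default n = 2622 samples from 2018-11-20, 18
measured species: OC, EC, NO₃⁻, SO₄²⁻, K⁺ and 13 elements).  Seven
sources with tracer-dominated profiles are built in: secondary aerosol
(NO₃⁻/SO₄²⁻), biomass burning (K⁺, Ba), traffic (Cr, EC>OC, Mn, Ni),
fugitive dust (Ca, Si, Fe), industry (Cd, Si, Hg), coal combustion
(As, Pb, OC/EC) and heavy-oil combustion (V, Ni).  Mean contributions
and profile weights were fixed once so the campaign-average composition
matches a polluted winter suburb: total ≈ 49 µg/m³ with secondary ≈ 60%,
coal ≈ 13.5%, industry ≈ 10%, dust ≈ 2% of mass; NO₃⁻ ≈ 15.3 and
SO₄²⁻ ≈ 8 µg/m³; element ordering Fe > Si > Ca > Mn > Pb > Ba > Cu >
As > Cr > Cd > Ni > Hg with Fe+Si+Ca ≈ 90% of elements; metal levels
that put the campaign ILCR near 10⁻⁴ dominated by Cr (~62%) and the HQ
total near 0.06 dominated by Cr (~87%).  Two deliberate departures from
typical ambient profiles keep every declared primary tracer the row
maximum of its profile (a generator contract): biomass burning carries
slightly more K⁺ than OC, and fugitive dust slightly more Ca than Fe.

Contributions are exponentiated stationary Gaussian AR(1) series,
z ~ N(0, σ²) with lag-1 correlation φ, G = mean·exp(z − σ²/2), giving
lognormal marginals with the requested mean and episodic multi-hour
pollution peaks; defaults φ = 0.9, σ = 0.8 (total-mass CV ≈ 0.6,
comparable to polluted winter campaigns).  Noise is Gaussian with sd
u evaluated at the noiseless value; negative draws are truncated at
zero (as instruments report) and counted — under the defaults the
truncated fraction is ≪ 1%.  Detection limits are derived the way a
campaign derives them: synthetic field blanks with sd = 2% of each
species mean, DL = 2 × blank sd.  An optional missingness fraction
blanks random cells; no particular gap pattern is claimed faithful.
All randomness flows from one campaign seed via documented sub-seeding,
and seeded generation is bit-reproducible.

What the generator does *not* emulate: meteorology, chemistry
(secondary formation is only a latent factor), correlated source
activity (weekday/holiday cycles), instrument drift, or heavy-tailed
outliers.  Passing recovery tests therefore show that the estimator is
correct under its assumed statistical model, not that real campaigns
are this benign.

## Model misspecification and identifiability limits

Two structural facts shape what the benchmarks can and cannot show.

First, the converted risk indices are *not* bilinear in the sources:
y = 10/(−log₁₀ x) of a linear combination is not a linear combination.
Even with contributions fixed at the truth, the best non-negative
profile rows leave residuals of ≈ 3 uncertainty units per pseudo-cell.
Consequently the combined 26-column fit settles near Q/Qexp ≈ 1.9 at
K = 7 (the measured-species fit, whose uncertainties are correct by
construction, sits at Q/Qexp ≈ 1.0), and with the default pseudo-
species weighting the joint optimum reshapes one factor's time series
into a carrier for the pseudo-columns' compressed shape.  Recovery
statistics (profile cosines, contribution correlations, mass shares,
the Q/Qexp ≈ 1 check) are therefore measured on the measured-species
fit, while labelling and risk allocation use the combined fit the
pipeline is built around.  A related consequence: the factor-number
scan on the synthetic campaign prefers K = 8, the extra factor
absorbing the conversion nonlinearity.

Second, minor-source profile components are not identifiable.  A source
at 2% of total mass (fugitive dust here) contributes <1% of the OC,
NO₃⁻ and SO₄²⁻ columns — far below one measurement-uncertainty unit —
so the ~35% of its profile sitting in those species is essentially
unconstrained by the data, and its full-profile cosine similarity
fluctuates in the 0.79–0.93 range across seeds even though its tracer
signature (hence its label), its contribution time series (r > 0.98)
and its mass share (within ~4 points) all recover well.  This is a
property of the inference problem, not of the solver, and it bounds
what any receptor model can say about the minor constituents of minor
sources.

## Benchmark problem sizes

The recovery benchmark runs the full n = 2622 campaign with 10 starts
and up to 5000 iterations at K = 7; the factor-number scan uses 10
starts and 1500 iterations per K over K = 1…10.  The tiny-instance
oracle check compares best-of-10 multiplicative updates against 500
random restarts of alternating weighted NNLS on a 20 × 4, K = 2
problem, agreeing within 1%.
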