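# Methods

This note documents the models implemented by `cdompae`, the choices made
where conventions differ between laboratories, and what the synthetic
survey generator does and does not emulate.

## EEM preprocessing

An EEM is intensity on a rectangular grid, by default excitation 220–450 nm
at 5 nm and emission 250–600 nm at 1 nm (the acquisition settings of the
kind of bench fluorometer survey the package targets); arbitrary regular
grids are accepted.

Corrections run in the default order **blank → inner-filter → scatter**
(configurable). The order is a genuine degree of freedom in practice;
blank-first is chosen so the inner-filter rescaling is not applied to the
instrument's dark/water signal.

* **Blank subtraction** is elementwise; negative residuals are floored at
  zero and counted in the log. Rationale: regional volumes are sums of
  intensities and should not be eroded by negative noise cells.
* **Inner-filter correction** multiplies each cell by
  `10^((A(λex)+A(λem))/2)` where A is the decadic optical density as
  measured. No path-length renormalisation is applied because absorbance
  and fluorescence are both acquired in 1 cm cells. The correction is
  exact for dilute, homogeneous samples and right-angle geometry; it never
  decreases an intensity. Wavelengths outside the measured absorbance
  range are an error — no extrapolation.
* **Scatter excision** removes first-order (`|λem−λex| ≤ w₁`) and
  second-order (`|λem−2λex| ≤ w₂`) Rayleigh bands, `w₁ = w₂ = 15 nm` by
  default — a common choice for 5 nm excitation steps. Excised cells are
  refilled by linear interpolation **along the emission axis only**
  between the nearest retained neighbours (zero where a band touches a
  spectrum edge), or zeroed. One-dimensional interpolation is
  deterministic and easy to verify against an exhaustive oracle, which is
  why it is preferred to 2-D inpainting. Raman normalisation and lamp
  drift correction are out of scope; intensities stay in instrument units
  and the pipeline is unit-agnostic.

## Fluorescence regional integration

The five-region scheme splits the EEM at excitation 250 nm and emission
330/380/550 nm, with region 1–3 below excitation 250 nm (tyrosine-like,
tryptophan-like, fulvic-like) and regions 4–5 above it (microbial
protein-like, humic-like). The printed boundaries of the scheme overlap at
the shared edges; this implementation uses half-open intervals
`[low, high)` on both axes so every grid point belongs to at most one
region, `ΣPᵢ = 1` exactly, and the allochthonous/autochthonous sums
partition the total. Volumes are plain Riemann sums `Σ I·Δλex·Δλem`
(intensity·nm²); the area-normalisation multiplication factors some
authors apply are available behind a flag but off by default, keeping the
raw-volume definition.

Regions extending below the measured grid (the schemes' 200–220 nm
excitation corner) are clipped — no extrapolated intensity. Grid cells
outside all five regions (emission 250–280 and 550–600 nm, excitation
above 400 nm) are reported as an explicit `unassigned` volume rather than
silently dropped.

Integration refuses an EEM that has not been blank-corrected and
de-scattered unless forced, since scatter ridges otherwise masquerade as
R1/R4 signal.

## Absorption metrics

`a(λ) = 2.303·OD(λ)/γ` with γ the cuvette path (0.01 m default). The
spectral slope is fitted by ordinary least squares on `ln a(λ)` over the
closed window (275–295 nm by default), dropping non-positive
coefficients and requiring five points; OLS on the log is deterministic
and agrees with a nonlinear exponential fit over windows this narrow. No
baseline-offset subtraction is applied by default because the coefficient
definition has none; both are available as options. SUVA254 divides the
**Napierian** coefficient by DOC — the convention under which the ratio of
survey-scale means (16.06 m⁻¹ / 26.08 mg L⁻¹ = 0.62) is internally
consistent. The slope ratio S_R is S275–295/S350–400.

FI370 (<1.4 terrestrial, >1.9 microbial) and FI310 (<0.7 low, 0.7–0.8
intermediate, >0.8 high autochthonous contribution) are read directly off
the corrected grid; a non-positive denominator (e.g. a zeroed scatter
cell) yields a missing value with a warning rather than an error.

## Exposure model

The drinking-water ingestion model uses ADD = C·DR·EF·ED/(BW·AT) with
defaults DR 2 L/day, BW 60 kg, EF 350 days/year, ED 30 years and
AT 26,280 days, and oral reference doses 1.0/0.8/0.1 mg·kg⁻¹·day⁻¹ for
DMP/DEP/DBP. AT = 26,280 days corresponds to a 72-year averaging period
rather than ED·365; it is kept verbatim as the study parameterisation,
with `with_strict_averaging_time()` recomputing AT = ED·365 for
sensitivity (it raises every dose by ×2.4, which changes no
classification at these concentrations). All concentrations are mg/L and
all doses mg·kg⁻¹·day⁻¹ internally; µg-based reference doses are
converted once at config load. China's GB3838-2002 DBP surface-water
limit (3 µg/L) is a concentration screening value, not a dose RfD, and is
exposed as a separate constant. Only the dietary route is modelled; the
three congeners carry no cancer slope factors by default, so carcinogenic
outputs are marked not-evaluated.

Composition statistics report per-congener mean/median/max by season and
overall (overall means are plain pooled means, i.e. sample-size-weighted
across seasons) and percentage shares of the summed mean.

## Association layer

Pearson correlations are computed pairwise-complete (missing covariates
are carried as NaN, never zero-filled) with two-tailed p-values from the
t-transform; both r and r² are always emitted because survey reports in
this area are inconsistent about which they print. No multiple-testing
correction is applied by default — matching common practice in the
source literature — with Benjamini–Hochberg available as an option.
Simple regression is OLS via `scipy.stats.linregress`; one-way ANOVA is
the classical F test, with the all-identical degenerate case defined as
(F = 0, p = 1).

## Synthetic survey generator

The generator emulates a two-season lake survey: 25 June + 20 October
samples at fixed sites. Each sample draws a terrestrial latent T and an
autochthonous latent A (log-normal, means per season: October has 1.78×
the June T and 0.45× the June A, following the DEP and chlorophyll
seasonal contrasts of the surveyed system). The EEM is a sum of five 2-D
Gaussian fluorophores whose amplitudes load on T (weights 0.95/0.90/0.95
for R3/R4/R5) or A (R1/R2), with per-region log-normal jitter, plus
Rayleigh ridges, a dark offset shared with the generated blank, and
additive noise. Absorption is single-exponential with a350 ∝ T and
seasonal slopes (0.0207/0.0165 nm⁻¹) chosen so the implied a254/a350
matches the surveyed seasonal means; DEP = 0.299·T + ε.

Calibrated quantities (fixed as study conditions):

* the June-mean regional shares are solved exactly from a 5×5 cross-mass
  matrix (cross-region Gaussian leakage included) to hit P5 = 0.50 and
  P(3+5) = 0.824, rising emergently to ≈0.87 in October;
* the humic-like emission centre per season (461.7/469.7 nm, σ = 45 nm)
  places the cohort-mean FI370 at 1.39 (June) and 1.14 (October)
  analytically, since FI370 is a single-component emission ratio at
  excitation 370 nm;
* the DEP noise scale (ε sd 0.066 mg/L) is calibrated by Monte-Carlo so
  the pooled pipeline-recovered r²(Φ₃, DEP) has median ≈0.78 — DEP is
  deliberately linked to the latent T, not to Φ₃ itself, so the observed
  correlation is mediated by the whole generate→preprocess→integrate
  chain.

What the generator does **not** emulate: absolute fluorescence magnitudes
(instrument-unit dependent — the total volume scale is arbitrary at
5×10⁶ AU·nm²); FI310, which under a five-Gaussian mixture with a dominant
humic peak settles near 0.35–0.39 rather than field-typical 0.8–1.0
(a single Gaussian humic component cannot simultaneously carry half the
total volume and leave the 310/380 nm cell brighter than 310/430 nm), and
which therefore keeps only the June > October ordering; real spectral
shapes of fluorophores; spatial site effects; and within-site temporal
autocorrelation. Passing end-to-end tests therefore demonstrate that the
pipeline recovers known structure of this class — seasonal contrasts,
exponential slopes, share patterns, a latent-mediated Φ₃–DEP link — not
that it reproduces any particular lake.

## Numerical notes

* Wavelengths are exact grid labels (1e-6 nm tolerance); both
  instruments sample integer grids, so no fuzzy matching is needed.
* Regional integration requires regular axis spacing and infers
  Δλex/Δλem from it; irregular grids are an error instructing resampling.
* Riemann point sums of Gaussian peaks on these grids are spectrally
  accurate; the residual discrepancy against the closed-form (erf)
  truncated masses comes from the half-cell offset at region boundaries,
  which is why ground-truth comparisons in the tests keep peaks ≥3σ from
  boundaries or extend the analytic box by half a step.
* File writers use `%.17g`, so write→read round-trips are bit-exact and
  the generator is byte-deterministic for a given seed.
* Test and analysis problem sizes: one cohort is 45 EEMs of 47×351 cells;
  Monte-Carlo checks use 50 seeds (50 cohorts through the full pipeline,
  a few seconds total), chosen to keep the whole suite fast while the
  binomial/median tolerances stated in the tests remain meaningful.

## Known limitations

* Scatter interpolation is 1-D along emission; wide bands near the
  emission edges are zero-filled, which biases FI-type ratios if their
  cells fall inside a band (they do not, on the default grid and widths).
* The spectral-slope magnitudes reported by some surveys (∼0.25 nm⁻¹) are
  an order of magnitude above the exponential-decay values this package
  computes (∼0.02 nm⁻¹); slopes here are always the fitted exponential
  decay constant in nm⁻¹ and no attempt is made to reproduce such tables.
* The published total-volume unit "nm" for F_SUM is dimensionally
  inconsistent with a two-axis Riemann sum; volumes are reported in
  intensity·nm².
* No PARAFAC decomposition, no Raman-unit normalisation, no dermal or
  inhalation exposure routes, no Monte-Carlo exposure uncertainty.
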