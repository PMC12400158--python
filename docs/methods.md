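# Methods

## Scope and model of the data

`herbqc` analyses HPLC-UV fingerprints and tandem mass spectra of herbal
materials rich in caffeoylquinic acids (CQAs) and flavonoids. Its reference
study design is 18 batches of dried leaf from two producing regions (labelled
HN and HB, nine batches each), 18 common fingerprint peaks, isochlorogenic
acid C as internal standard/reference peak, and eight compounds with
published batch contents. The package ships those published tables
(per-condition correction factors, per-condition relative retention times,
per-batch ESM/QAMS contents) as CSV fixtures and reproduces all quantities
derivable from them; everything else is exercised on synthetic data from
`herbqc.synth`.

## MS2 fragmentation rules

Masses are monoisotopic sums over C/H/N/O/S; ions are [M−H]⁻ / [M+H]⁺ with a
proton mass of 1.007276 Da. Matching uses a ppm tolerance (default 10 ppm —
Orbitrap-class accuracy; the worst instrument value quoted for the encoded
compounds deviates by ~9.7 ppm at m/z 135). Nominal-mass anchors ("m/z 179",
"173", "191") are resolved to exact masses within ±0.01 Da before abundance
comparison.

* **CQAs**: the caffeoylation degree n ∈ {1,2,3} is established by the chain
  of n successive caffeoyl losses (C₉H₆O₃, 162.03169 Da) from [M−H]⁻
  terminating at the quinate anion (191.0561), with caffeate (179.0350),
  decarboxylated caffeate (135.0452) and dehydrated quinate (173.0455) as
  support ions. Positional isomers share all ions; they are discriminated by
  relative abundances. Mono-CQAs: base peak at 173 ⇒ cryptochlorogenic; base
  191 with abundance(179) ≥ 20% ⇒ neochlorogenic, ≤ 10% ⇒ chlorogenic.
  Di-CQAs: base 191 ⇒ the symmetric 1,5-diester; base 353 with
  abundance(173) ≥ 35% ⇒ isomer B, 10–35% ⇒ isomer C, ≤ 5% ⇒ isomer A.
  The thresholds are guard bands around the single measured values available
  per isomer (52.54 vs 1.09% at m/z 179; 44.28 / 29.35 / 1.26% at m/z 173):
  each band keeps ≥ 2× separation from its neighbour and any abundance
  falling into a gap returns "ambiguous" rather than a guess. At 10%
  multiplicative abundance noise the closest call (B vs C at the 35%
  boundary, ~1.5 combined σ away) misassigns a few percent of spectra —
  the closed-loop accuracy stays above 95%.
* **Flavonoids**: aglycones are recognised by their retro Diels–Alder A-ring
  ions, stored per aglycone class rather than derived from substitution
  patterns (luteolin/apigenin class: 151.0037 / 149.0244 / 107.0139;
  quercetin class: 178.9986 and its −CO product 151.0037). *O*-glycosides
  lose the sugar intact (hexosyl 162.0528, deoxyhexosyl 146.0579, rutinosyl
  308.1107) to an aglycone ion that itself shows RDA ions; *C*-glycosides
  show ≥ 2 cross-ring losses from {60.0211, 90.0317, 120.0423} (or sums) and
  no RDA requirement. Both kinds of evidence exist only in negative mode, so
  positive-mode spectra always score lower — callers are pointed to
  negative-mode acquisition.
* **Annotation** scores each library compound whose quasi-molecular ion
  matches the precursor: score = satisfied / total over {precursor match,
  each diagnostic fragment, isomer-call consistency}; ties break on mean
  |ppm|. A spectrum matching nothing returns one class-"none" hypothesis.

One quoted fragment (m/z 332.80417 for the C-glycoside) matches no plausible
composition and is treated as a transcription artifact; it is not part of
the concordance table. The quoted m/z 107.0125 values for the 0,4A⁻ ion
deviate ~12 ppm from C₆H₃O₂⁻ and are matched through the 0.01 Da nominal
window instead of the ppm gate.

## Peak detection and fingerprints

Detection runs on a flat-baseline assumption (guaranteed by the generator;
baseline estimated as the trace median): local maxima above height and
prominence thresholds, bounds at flanking valleys or the return to baseline
(0.1% of apex height), areas by trapezoid integration on the native grid,
widths from the half-height width (σ = FWHM/2.3548). A peak is flagged
unresolved when the valley to a neighbour stays above 50% of the lower apex.
The asymmetry factor is b/a at 10% height (the pharmacopoeial convention,
consistent with the published 0.98–1.15 range); resolution is
2Δt/(w₁+w₂) with w = 4σ.

Peaks are matched across batches on the RRT scale (tolerance 2% relative —
about twice the largest published RRT RSD, 1.258%), which cancels uniform
retention shifts. The internal standard is located first among peaks within
±5% of its expected absolute retention; because a neighbouring peak sits
only 4% away in retention, candidates below half the largest candidate area
are discarded and the remaining one closest to the expected time wins
(pure largest-area choice occasionally mis-locks onto that neighbour under
area noise). Equidistant RRT ties go to the larger area. Fingerprint
similarity is the congruence (cosine) coefficient against the mean profile
(Pearson correlation available as an option). No similarity acceptance
threshold is enforced — the score is reported per batch.

With zero noise a batch is identical to its region mean (similarity 1.0);
against the mixed-study grand mean the planted regional contrast alone fixes
the cosine at ≈ 0.98, which is why the suite checks ≥ 0.99 within region and
≥ 0.97 against the grand mean.

## Chemometrics

Preprocessing is column-wise centering with unit-variance (autoscale,
default — the common chemometrics convention), Pareto, or no scaling;
parameters are retained for re-application. PCA is by SVD of the
preprocessed matrix with explainedₐ = σₐ²/Σσ² and a Hotelling T² 95% ellipse
for score plots; it is verified against a covariance eigendecomposition
oracle at rtol 1e−8.

OPLS-DA removes `n_orthogonal` (default 1) components of X-variation
orthogonal to the ±1 class coding, then fits one NIPALS PLS1 predictive
component; with `n_orthogonal = 0` it is exactly single-component PLS1
(verified against an independent PLS implementation). R²Y comes from the
fitted sum of squares, Q² = 1 − PRESS/TSS from stratified k-fold
cross-validation (k = 7 by convention, reduced to the smaller class size
when needed; folds are deterministic). VIP over the single predictive
component is √p·|w_j|, so mean VIP² = 1 identically. The S-plot reports
(cov(t, x_j), corr(t, x_j)); zero-variance variables get NaN correlation.
The permutation test refits the model for 200 permutations of y, regresses
R²Y and Q² on |corr(y, y_perm)| (unpermuted point anchored at 1.0) and
reports the intercepts. Markers are peaks with VIP > 1 **and** two-sided
Welch-t p < 0.05 on the raw (unscaled) areas; no multiplicity correction by
default (Benjamini–Hochberg available behind a flag). The class coding is
+1 = HB, −1 = HN (alphabetical), which fixes S-plot signs.

## QAMS

f = (A_s/C_s)/(A_i/C_i); multi-level estimates are averaged arithmetically
(the published "Average value" rows are arithmetic means of the 19 printed
conditions — verified by recomputation). ESM calibration is OLS with free
intercept; inverse predictions below zero clip to 0 with a warning. Contents
convert to mg/g through sample mass 0.2 g / extract volume 25 mL. Method
agreement uses RD% = |Δ|/(C_ESM + C_QAMS) × 100: the conventional |Δ|/C_ESM
form gives values twice the published ones, while the sum-denominator form
reproduces them within 3-decimal rounding (e.g. 0.269 vs printed 0.270;
0.108 vs 0.112), so the sum form is the default and the conventional form
sits behind a flag. Batch totals sum the seven non-internal-standard
analytes (verified: the HN2 published total equals that sum exactly).
Published contents are printed at 3 decimals, so quantities recomputed from
them inherit a quantifiable rounding band — e.g. recomputed RD on a
0.03 mg/g content can shift by ±1.5 percentage points; checks against the
sub-1% agreement claim allow exactly 100·0.001/(ESM+QAMS) of slack and are
exact wherever that slack is negligible.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuned per run:

* **Region means** for the eight compounds with published contents are the
  published per-region means; non-marker compounds get the pooled mean in
  both regions. Seven peaks are planted as genuine markers (chlorogenic
  acid, isochlorogenic acids A/B/C, the 1,5-dicaffeoyl and tricaffeoyl
  esters, eupatilin) — the marker set actually confirmed by the screening
  criterion. Neochlorogenic acid, although discussed among high-loading
  peaks, was not among the seven selected markers and is planted flat.
  The published region means for isochlorogenic acid B are indistinguishable
  (1.825 vs 1.768 mg/g), so that marker is planted with an invented contrast
  at the scale of the other marker contrasts (2.20 / 1.40 mg/g). Peaks
  without published contents use fixed values of 0.25–2.6 mg/g with the
  documented HN-rich/HB-rich directions.
* **Noise** is multiplicative lognormal with mean 1 on areas
  (concentrations are positive and relative SDs are the natural error
  scale); the default batch-to-batch CV is 0.10 — the scale of a moderately
  variable raw material on top of a < 3% analytical method. At that CV the
  weakest planted contrast (isochlorogenic acid C, ratio 1.28) has a
  standardised effect of ~2.4 SD, large enough for reliable selection at
  n = 9 + 9, while false selections are limited by the joint VIP > 1 ∧
  p < 0.05 requirement. Exact recovery of all seven markers and nothing
  else still fails in roughly one study in ten from pure n = 18 sampling
  noise (a borderline VIP crossing 1.0); that rate is intrinsic to the
  design, not a generator artifact.
* **Chromatograms** are sums of Gaussians on a flat baseline (the published
  asymmetry range 0.98–1.15 is near-symmetric; an optional tailing
  parameter skews the back half-width). Retention times come from the RRT
  template (published averages where available, interpolated placements
  elsewhere) anchored at 12.0 min for the internal standard — the published
  gradient table is typographically corrupted and is not modelled. The
  sampling step must stay below σ/5; isolated-peak integrals reproduce the
  specified areas to well under 1%.
* **Response factors** are fixed per compound: 500 area·mL/mg for the
  internal standard and 500/f̄ for the seven analytes (f̄ = published mean
  correction factors), so the correction factors recomputed downstream land
  at the published magnitudes (0.6–1.3); other roster compounds use nearby
  fixed values.
* **Robustness sweeps** perturb detector response by a common ±5% factor
  (shared by analyte and internal standard — the instrument/column/flow
  effects that cancel in the ratio) plus a ±2% differential factor, and
  retention by ±2% common / ±0.5% differential, keeping the RSDs of f and
  RRT below 3% as the ratio formulation promises.
* **Determinism**: every simulate_* call takes a seed; identical seeds give
  bit-identical outputs.

What the generator does **not** emulate: baseline drift and gradient
artifacts, retention-time warping between batches, co-elution/shoulder
peaks beyond the fixed template spacing, isotope patterns and in-source
fragmentation, heteroscedastic detector noise, and correlated biosynthetic
covariation among compounds. Passing tests therefore demonstrate the
correctness of the computations and their closed-loop consistency, not
field performance on instrument data with those artifacts.

## Numerical choices and degenerate inputs

Spectra must carry exactly one 100% base peak; abundances are percent of
base peak. Zero-variance columns are rejected under autoscaling (named in
the error), reported as missing in the S-plot. Matching reports unassigned
common peaks per batch and refuses double assignments (both claimants
listed). RD is undefined at zero total content; aggregation requires ≥ 2
values; calibration requires ≥ 2 distinct concentrations. RSDs use the n−1
denominator. CSV output uses 6 significant digits, except batch-content
reports which use 3 decimals to match the published precision.

## Known limitations

The published chemometric statistics (R²X 0.865 for 4-component PCA, OPLS-DA
R²Y 0.950 / Q² 0.651) depend on the unpublished raw 18 × 18 area matrix and
cannot be reproduced, only mirrored qualitatively on synthetic studies (where
the planted effects are stronger and both statistics run higher). The
fragment-rule library covers the compounds whose fragmentation is worked out
in detail — 14 compounds across six classes — not a full herbal metabolome;
flavonoid RDA tables are class-specific and do not generalise to arbitrary
substitution patterns. Between-region variance is modelled as independent
lognormal noise per peak; real batches show correlated variation that OPLS-DA
orthogonal components would absorb.
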