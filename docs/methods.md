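# Methods

## Scope and design

The package replays the statistical analysis of a serum NMR case-control
study of de novo drug-naive Parkinson's disease (dn²PD) against healthy
controls (CTR), with an advanced-PD (advPD) group for progression checks.
Raw spectra of such studies are typically not deposited, so the package
ships a generative model of the study population; every stage downstream of
spectral processing (bucketing → OPLS-DA → 2CV → projection → univariate →
biomarker → heatmap) is implemented against that substrate and tested
against independent oracles. FID processing (apodisation, phasing, baseline,
calibration) is out of scope: the generator emits already processed,
calibrated spectra.

## Synthetic cohorts

**Concentrations.** Each of 138 analytes (27 metabolites, 111 lipoprotein
parameters) is log-normal: log C = μ + s·ln2 + σ·z, with per-analyte
baseline μ anchored at typical serum levels, σ = 0.25 for metabolites and
0.30 for lipoprotein parameters (≈25–30% biological CV), and s the log₂
group/sex shift relative to the CTR baseline. Effects are therefore
multiplicative (2^s), matching the log₂-fold-change reporting scale. The 111
lipoprotein parameters additionally share one latent Gaussian factor with
squared loading ρ = 0.5, reproducing the block-correlated co-movement of
lipoprotein panels; metabolites are independent given the shifts. Ratio
parameters (e.g. LDLChol/HDLChol) are simulated as analytes in their own
right, not recomputed from their parents — a simplification that preserves
the marginal behaviour used downstream.

**Effect table.** Male dn²PD: acetone, ornithine and phenylalanine at
+0.55 log₂; the 23-parameter LDL panel (cholesterol, LDL fractions 4/5 and
their lipid/ApoB contents, the two clinical ratios) at −0.5 — the planted
magnitude of |log₂FC| ≥ 0.5 at the study's stratum sizes (40 vs 36 males) is
the stated recovery condition for the univariate stage. Progression analytes
(citric acid, methionine, N,N-dimethylglycine, ApoA1/HDL parameters) fall at
−0.2 in dn²PD and −0.4 in advPD (monotone along CTR > dn²PD > advPD); formic
acid and histidine rise (+0.4) in dn²PD only. Female shifts are the male
shifts damped by 0.25 — large enough to leave a weak multivariate
fingerprint, small enough that the univariate stage finds nothing at n =
32 vs 23, which is the study's female result. advPD extends the male
signature by 1.6×, applied to both sexes. Group/sex counts follow the study:
training 72 dn²PD (40 M) vs 59 CTR (36 M); validation 156 dn²PD (83 M),
20 CTR (8 M), 22 advPD (15 M).

Because the planting magnitude follows the ≥0.5 recovery condition while the
baseline CVs stay at 25–30%, per-analyte separations (AUCs ≈ 0.9, odds
ratios ≫ 10 for the metabolites) are stronger than a real cohort's; the
generator is calibrated to the stated conditions, not fitted to the
published effect table.

**Spectra.** Each spectrum is Σ_analytes C × Σ Lorentzians + a fixed
anomeric-glucose reference singlet at 5.24 ppm + i.i.d. Gaussian noise
(sd 5·10⁻⁴) on a uniform 16,384-point grid over 0.0–10.2 ppm. Metabolites
carry 1–5 narrow resonances at conventional serum shifts (acetone singlet at
2.22 ppm, formate at 8.46, etc.); no J-coupling multiplet structure is
modelled. Lipoprotein parameters contribute broad methyl/methylene envelopes
whose centre and width depend on density class and subclass (HDL upfield and
narrow through VLDL downfield and broad), plus species resonances (glyceryl
for triglycerides, sterol methyls for cholesterol, choline for
phospholipids) — the lineshape differences that make subclass quantification
from 1D serum spectra possible at all. The envelopes remain far more
collinear in bucket space than real subclass signals, with consequences
noted under Limitations.

## Numerical and procedural choices

- **Bucket value = integral** of the piecewise-linear interpolant over the
  half-open tile (exact, preserves linearity in concentration); buckets
  partially overlapping an exclusion window are dropped whole; columns in
  descending-ppm order labelled by bucket centre; a 1e-9 ppm tolerance
  guards float tiling edges. Edge tiles are half-open ([low, low+width)),
  the documented reading of an unstated convention.
- **Scaling.** Rows are never normalised. Unit-variance column scaling is
  applied for PCA and inside the OPLS-DA model (stored and reapplied at
  prediction); "no prior normalization" is read as no row normalisation.
  Zero-variance columns are dropped with a warning and skipped at prediction.
- **PCA** by SVD of the centered (scaled) matrix; sign fixed by making each
  loading's largest-magnitude element positive.
- **OPLS-DA.** Class coding control = −1 / case = +1, decision threshold 0,
  ties to control (arbitrary, documented). NIPALS-style single-response
  algorithm; with n_ortho = 0 the model is exactly one-component PLS1, and
  with k orthogonal components its predictions equal (k+1)-component PLS1 —
  verified against an independent PLS implementation in the tests.
- **2CV.** Inner fraction 80/20 (unstated in the scheme's description;
  chosen once), 50 repetitions, candidates 0–5 orthogonal components, ties
  to the smallest; the same inner splits score all candidates (paired
  comparison). Outer 90/10 stratified, 100 repetitions; stratification keeps
  both classes in every partition (a documented deviation from plain random
  splitting, needed for small strata). Percentile (2.5/97.5) intervals;
  degenerate splits are resampled with a log record. One master seed; each
  repetition and stage draws a deterministic child seed, so results are
  byte-identical given (config, seed).
- **Balanced subsampling** for unequal groups: larger group subsampled
  without replacement to the smaller size, one outer 2CV repetition per
  balanced draw, 100 draws averaged. Blind projection uses a single model
  fitted on the full training stratum with the inner loop choosing n_ortho
  (the alternative — averaging over the 100 balanced models — is not
  implemented).
- **Wilcoxon** switches from exact enumeration to the tie/continuity-
  corrected normal approximation at combined n > 20 or any tie. **BH-FDR**
  is computed over all 138 analytes per stratum (family definition chosen
  once; the biomarker panel re-adjusts over its own analytes, matching the
  structure of a per-panel table). **Cliff's delta** counts ties as zero.
  **Log₂FC** of medians raises on non-positive medians rather than adding an
  epsilon.
- **Logistic regression** by IRLS (GLM/binomial), convergence tol 1e-10,
  max 50 iterations; separation flagged at |β₁| > 20 on the 2-SD scale and
  surfaced, never silently reported. Wald CIs (exp(β₁ ± 1.96·se)).
  Validation-cohort standardisation reuses the training mean/sd (keeps the
  prediction blind); per-cohort re-standardisation is available behind a
  flag.
- **Heatmap ranking**: the named two-sample t-test is applied to a
  three-group figure as the smallest pairwise Welch p per analyte (one-way
  ANOVA would be the alternative); analytes are z-scored across all samples
  before group averaging so one colour scale applies; distance is 1 − r,
  not 1 − |r|.

## Problem sizes

The shipped drivers and the acceptance script run the full stated repetition
counts (100 outer × 50 inner, 100 balanced models) at the study's cohort
sizes; a complete acceptance run is a few minutes on one CPU. The test suite
uses reduced repetition counts for the generic contracts and full counts for
the null-control and recovery checks.

## What passing tests do and do not show

The generator reproduces the study's *structure*: sample sizes, sex-specific
effect directions, a correlated lipoprotein block, spectra whose buckets are
linear in concentration. It does not reproduce peak overlap complexity,
chemical-shift drift, baseline artefacts, covariate structure (age, BMI,
medication) or the true analyte covariance, and its planted effects are
stronger per-analyte than the published ones. Passing tests therefore
demonstrate correctness of the statistical machinery under known truth —
recovery of planted signal, honest null behaviour, leak-free validation —
not clinical validity of the fingerprint on real sera.

## Known limitations

- One predictive component cannot remove confound variance lying along the
  predictive direction; with the shared lipoprotein factor partially
  collinear (in bucket space) with the planted LDL-panel shift, bucket-level
  models retain irreducible within-group score spread. The same projection
  on the concentration table separates perfectly — a useful illustration of
  what quantified parameters add over raw buckets.
- The female stratum is simulated as a damped copy of the male signature;
  any genuinely sex-specific biology is outside the generator.
- Ratio analytes are independent log-normals, so their arithmetic
  consistency with numerator/denominator analytes is not enforced.
- Exact Wilcoxon enumeration is limited to small tie-free samples, as
  documented; all study-sized comparisons use the corrected approximation.
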