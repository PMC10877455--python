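# Methods

`depstrat` implements a two-stage case-control analysis of lifetime-
depression phenotyping criteria against voxel-wise brain measures, together
with a synthetic cohort generator that makes every stage testable without
access to restricted cohort data. This note records the models, the
defaults and why they were chosen, and the limits of what the synthetic
experiments demonstrate.

## Phenotype model

Six binary criteria define lifetime exposure to depression (help seeking,
self-report, antidepressant use, the Smith definition, hospital ICD-10
F32/F33 codes, a CIDI-SF score). Cases are stratified by the *exact* number
of criteria met (k = 1..6), giving six disjoint strata; each case also
belongs to exactly one of the 63 non-empty criteria subsets
("constellations"), encoded as a 6-bit integer with bit i = criterion i.

The generator draws the criteria from a single-factor probit model: subject
severity `z ~ N(0,1)`, criterion i fires when
`loading*z + sqrt(1-loading^2)*e_i > Phi^-1(1 - p_i)`. Marginals are exact
(`p_i`), and the common factor produces the strong positive co-occurrence
seen in real cohorts. Defaults: `p = (0.417, 0.102, 0.092, 0.069, 0.035,
0.078)` — the criterion marginals implied by the published group counts
over the pooled imaged sample — and `loading = 0.75`, which reproduces the
qualitative shape of the published exact-k distribution (counts falling
monotonically from k=1 to k=6). No claim is made that the single-factor
model is the true dependence structure of any real cohort; it is the
simplest model with the right marginals and a tunable overlap.

Controls meet no criterion by construction. Demographics: female share
0.617 in cases / 0.447 in controls, age ~ N(63.9, 7.7) (cases) or
N(65.1, 7.7) (controls) clipped to 45–80 years, education ~ N(16.7, 3.8)
years, TIV ~ N(1550, 120) mL for males and N(1400, 120) mL for females —
all patterned on the published group-level summaries (see
`depstrat.demographics`).

## Image model

All volumes live on one grid; the default is 24^3 voxels at 4 mm with a
spherical analysis mask (radius 10.5 voxels, ~4.8k in-mask voxels) — small
enough that the full pipeline runs in seconds per subject, large enough for
clusters to have room. Functional series have 120 timepoints at TR 0.735 s,
placing the 0.008–0.09 Hz band comfortably below Nyquist (0.68 Hz).

Baseline functional data are white Gaussian noise (SD 1) plus a
subject-level global signal added to every in-mask voxel with weight 0.4,
which gives a positive baseline global correlation to modulate. Each
modality has a spherical effect region and a signed per-criterion amplitude
vector; a subject's effect strength is the sum of the amplitudes of the
criteria they meet, so effects accumulate with k. The mechanisms:

* **fALFF** — an added sinusoid: out-of-band (0.25 Hz) for negative
  strength (inflates the denominator, lowering the low-frequency fraction),
  in-band (0.04 Hz) for positive strength. Voxel-random phases keep the
  planted signal out of the correlation measures.
* **LCOR** — a region-wide shared signal raises neighborhood correlation;
  a checkerboard sign flip plants anticorrelation between neighbors.
* **GCOR** — the planted strength adds to the global-signal coupling
  weight inside the region.
* **GMV** — an additive gray-matter density offset.

Default amplitudes attach functional decreases to the antidepressant-use
and ICD-10 criteria only, with weak bidirectional structural offsets. Not
modeled: hemodynamics, motion, physiological noise, spatial autocorrelation
of the baseline noise (smoothing is applied to the measure maps instead),
registration error. Consequently, passing recovery tests show that the
*statistical chain* behaves correctly under known truth — not that the
pipeline is robust to real acquisition artifacts.

## Measures

* **fALFF**: per voxel, the share of FFT spectral content in the band
  relative to all positive frequencies, after mean and linear-trend
  removal. The default uses the *power* spectrum; with the amplitude
  spectrum, spectral leakage from a non-bin-centered pure oscillation
  spreads heavy 1/|Δk| tails across the spectrum and even a clean in-band
  sinusoid cannot exceed ~0.75, whereas power concentrates >0.95 in-band.
  Both conventions are exposed (`spectrum="power" | "amplitude"`). Band
  edges are inclusive by bin center. Constant series map to 0 with a
  warning.
* **LCOR**: Gaussian-weighted mean Pearson correlation with in-mask
  neighbors (self excluded), computed exactly by spatially filtering the
  unit-norm standardized series. The kernel FWHM defaults to 25 mm; the
  definition's source gives no kernel size, so this is a config default,
  not a reproduced value.
* **GCOR**: mean correlation with all other in-mask voxels via the
  summed-standardized-signal identity (O(V·T)); an O(V^2) brute force is
  kept in the tests as the oracle.
* **Relative GMV**: voxel volume × summed gray-matter density / TIV
  (scalar), with the voxel-wise map passed to smoothing for the group
  analysis; TIV additionally enters stage 1 as a covariate.
* **Smoothing**: mask-aware Gaussian (renormalized within the mask) so
  small synthetic masks are not edge-attenuated; FWHM 0 is the identity.
  All measure maps are smoothed with the same 8-mm kernel before group
  statistics. Because of the mask renormalization, the global image sum is
  preserved only away from the mask boundary.

## Stage 1 — voxel-wise inference

Per contrast (stratum × modality × direction; 6 × 4 × 2 = 48 per control
strategy): measure maps are residualized on `[1, age_c, age_c^2, sex,
TIV]` fitted on the combined sample (age is centered for conditioning; the
group indicator is never in the design), then a Welch unequal-variance
two-sample t map with Satterthwaite df is formed, signed
depression-minus-control. Voxels with one-sided p < .001 (per-voxel df)
form candidate clusters under 26-connectivity (18/6 selectable).

Cluster-level family-wise error is controlled by a max-cluster-extent
permutation null: group labels are permuted on the *residualized* data
(Freedman–Lane style), the same cluster-forming rule is applied, and the
corrected p of an observed cluster of size s is
`(1 + #{perm max >= s}) / (1 + n_perm)` — never below `1/(n_perm+1)`.
Clusters with corrected p < .05 form the binary significance mask. This is
a deliberate substitution for random-field-theory cluster correction: the
permutation test is exact under exchangeability at any grid size, whereas
RFT's smoothness estimation is neither needed nor reliable at this scale.
No equivalence with RFT p-values is claimed. Null calibration (60 vs 60,
500 permutations, 200 replicates) puts the empirical family-wise
false-positive rate per direction inside the binomial 95% interval around
0.05; the test suite re-runs this check.

Control strategies: the pooled control group (primary) compares each
stratum with all controls; the matched strategy pairs each stratum 1:1
with controls matched exactly on sex and nearest-neighbor on z-scored age
and education (seeded random case order; Hungarian assignment available
via `method="optimal"`). The matching distance and order are not specified
by the analysis design this follows; greedy nearest-neighbor was chosen
for transparency.

## Stage 2 — effect sizes and attribution

For each surviving mask, each subject is reduced to their mean map value
over the mask. Cohen's d with the pooled SD quantifies each exact-k stratum
and each constellation against the pooled controls; constellations with
fewer than 10 cases are excluded (logged). The 95% CI is a seeded
percentile bootstrap over subjects (1000 resamples default); a noncentral-t
analytic CI and the Hedges small-sample correction are available behind
flags but off by default, since the upstream design states neither.

Attribution: for each mask and criterion, the *difference in effect size*
is the unweighted mean d of retained constellations containing the
criterion minus the unweighted mean of those lacking it (six values per
mask). Unweighted means across constellations are the implemented
definition; a subject-count-weighted variant exists for sensitivity
analysis only, and a test pins the default to the unweighted form. Pairs
with an empty side are reported as undefined, never imputed. Summaries over
a mask family report median and quartiles with linear interpolation.

## Reference experiments and problem sizes

* **Null calibration**: 24^3 grid, 60 cases / 60 controls, measure maps
  simulated directly as smoothed Gaussian noise (the calibration concerns
  the inference stage; simulating full 4D series adds nothing to the null),
  500 permutations, 200 replicates in the test suite (100 in the
  acceptance script).
* **Recovery**: the full pipeline — 4D simulation → fALFF → stage 1 →
  stage 2 → attribution — on cohorts of 600 cases / 150 controls with
  equal criterion prevalences (0.45) and loading 0.45, decrease direction,
  300 permutations, 20 replicates (5 in the acceptance script). The
  balanced prevalences are deliberate: with the biobank-shaped defaults a
  desk-scale cohort retains almost no constellation lacking the dominant
  help-seeking criterion, leaving the attribution split one-sided. Cohort
  size was chosen from a table-only power analysis of constellation
  retention (each criterion needs retained constellations on both sides of
  its with/without split).

## Known limitations

* The permutation null assumes exchangeability of residualized maps across
  groups; heavy covariate model misspecification would degrade it.
* Greedy matching is order-dependent (hence seeded); the optimal variant
  removes this at O(n^3) cost.
* The latent-factor criteria model cannot express negative dependence
  between criteria.
* Effect mechanisms are additive and stationary; no interaction between
  modalities' planted effects is modeled, and region overlap between
  mechanisms is possible but not used in the defaults.
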