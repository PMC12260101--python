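# Methods

## The signature model

Blood plasma is a mixture of thousands of proteins whose individual
concentrations vary too much between people to make robust single-protein
biomarkers. The Amino Acid Concentration Signature (AACS) sidesteps this by
embedding the whole mixture into a small residue space. A protein with
residue counts `a_1 … a_n` over a chosen set of channels, present at molar
concentration `θ`, contributes the vector

    v = ⟨a_1 θ, …, a_n θ⟩            (residue µM per channel)

and a mixture of `α` proteins is embedded as the molar-fraction-weighted
sum

    E_n = Σ_i a_{n,i} β_i,   β_i = θ_i / Σ θ,

the mean number of channel-`n` residues per protein molecule. The package
calls this the **normalized** mode. Multiplying by the total molar
concentration gives the **absolute** mode — total residue concentrations
in µM, which is what a fluorescence measurement actually reports. Both
modes are first-class outputs with the mode recorded alongside the values;
the classification layer consumes absolute concentrations because the
calibration inversion natively yields µM, but every normalized-mode
identity (scale invariance, `absolute = normalized × Σθ`) is enforced by
tests.

The default channels are Lys, Trp, Tyr, total cysteine (Cys_T) and free
cysteine (Cys_R = Cys_T − 2 × disulfide bonds). Channel counting needs
only a sequence, except Cys_R, which needs a disulfide-bond annotation;
records lacking one default to the conservative upper bound Cys_R = Cys_T
and carry an explicit provenance flag. Ambiguous letters (B, Z, X, U, O)
are rejected by default — the counts feed quantitative concentrations and
silent guessing would corrupt units — with an opt-in ignore-with-flag mode.

`rank_axes` generalizes the channel choice: any of the 20 canonical
residues (plus Cys_R) can be scored by the between-class spread of its
normalized embedding, using the coefficient of range `(max − min)/mean`
(0 when the mean is 0). The statistic is deliberately simple and
reproducible; ties order alphabetically by channel name.

## Calibration and measurement

Each channel is measured with a fluorogenic label whose corrected well
intensity is linear in the residue concentration of the (diluted) well.
Standards of known sequence and concentration give points
(residue µM, intensity); the curve is a free-intercept ordinary least
squares fit (a through-origin variant is a switch), accepted only when the
slope is positive and R² ≥ 0.98 (configurable; a config default, not a
literature value). Replicate standard wells of one concentration are
averaged before fitting — with multiplicative read noise, fitting raw
replicates would let the acceptance gate reject a few percent of perfectly
good plates.

Background model: a sample well holds buffer + unreacted label +
diluted-plasma autofluorescence + signal. Subtracting the label-only and
plasma-only blanks removes the buffer baseline twice, so it is restored
once:

    corrected = raw − label_blank − plasma_blank + buffer_blank.

A plain two-blank subtraction is available as a switch. Negative corrected
intensities clip to zero with a `negative_corrected` QC flag rather than
erroring, keeping cohorts complete while leaving quality auditable.

Inversion is `(intensity − intercept)/slope`, scaled by the channel's
dilution (defaults: 1:60 for Lys/Trp/Tyr/Cys_T, 1:6 for Cys_R). Diluted
concentrations outside the standard range (±10% of its span) are flagged
`extrapolated`. Per sample and channel the replicate mean and CV are
reported; CV above 20% (config default) is flagged. Mixed dilution factors
within one replicate set are an error, never averaged — unit safety beats
convenience. `recommend_dilution` picks the smallest factor from the
ladder (1, 2, 6, 10, 20, 60, 120) that places an expected concentration
range inside a curve's quantitative range.

## What the synthetic cohorts emulate — and what they do not

No machine-readable patient dataset accompanies the study design this
package implements, so the generator produces everything downstream stages
need: labelled plasma compositions, exact true signatures, and simulated
96-well plate reads.

* **Panel.** A fixed ~10-protein panel (albumin, transferrin, five
  assembled immunoglobulin classes, fibrinogen, haptoglobin,
  alpha-1-antitrypsin) plus three calibration standards. Except for hen
  lysozyme (canonical mature sequence), the sequences are synthetic
  stand-ins with realistic lengths and channel compositions — see the
  FASTA headers. The Ig class stand-ins are given deliberately distinct
  K/W/Y/C compositions so class switching has a per-channel signature,
  which is the premise of the whole approach.
* **Disease profiles.** Each profile is a center of a composition
  distribution: an immunoglobulin molar fraction (0.38 in health,
  interpreted on the molar basis matching the embedding's θ semantics),
  within-Ig class proportions, and non-Ig multipliers (e.g. acute-phase
  fibrinogen in infection). Breast/prostate share a "hormonal" class mix
  and colorectal/pancreatic an IgA-rich "abdominal" mix, so coarse
  tumour-site grouping has structure to find. All effect sizes are
  documented package constructs — not measurements of real patients — and
  users should treat them as tunable placeholders.
* **Sampling.** Total protein is uniform on 60–80 mg/mL, converted to a
  total molar concentration via sequence-derived molecular weights; panel
  proportions are Dirichlet-distributed about the profile center with
  precision 500 (≈2% SD on the Ig fraction, ≈20% CV on minor proteins;
  `inf` gives a point mass). Technical noise is multiplicative lognormal
  on intensity (default CV 0.05) applied to every emitted well. Seeds
  split into named substreams (composition, plate) so biological and
  technical noise vary independently; identical config + seed reproduces
  byte-identical tables.
* **Plates.** One plate per channel per batch of ≤25 patients: 3 blanks,
  6 standard concentrations in triplicate (0.2×–2× the healthy-center
  diluted concentration), then replicate sample wells, A1–H12.

At zero technical noise the plate decode reproduces every true absolute
signature to machine precision; this identity anchors the end-to-end
tests. What passing tests on this generator do **not** show: that real
plasma follows a 10-protein Dirichlet model, that real disease shifts are
as large or as clean as the profile constructs, or that real calibration
is perfectly linear. Plate spatial artifacts, autofluorescence spectra and
batch effects are out of scope.

## Statistics

* **MANOVA** uses Wilks' Λ = det(W)/det(W+B) with Rao's F approximation
  (exact for ≤2 groups or ≤2 channels), computed from scatter matrices via
  log-determinants. A label-permutation p-value is available for small or
  non-normal samples; singular scatter raises with that recommendation.
  Patient means (not replicates) are the default analysis unit, matching
  the replicate-collapse rule of the CV layer.
* **ANOVA ranking** is one-way F per channel, explicitly labelled a
  ranking rather than inference; no multiplicity correction is applied and
  the output says so.
* **Friedman rank stability** midranks each fold's feature importances
  and applies the standard tie correction; an all-tied matrix returns
  χ² = 0, p = 1, and k = 2 features is supported (χ² with k−1 df) even
  though scipy's implementation requires k ≥ 3.
* **Linear SHAP** is the closed form φ_j(x) = w_j (x_j − μ_j), exact for
  linear decision functions with an independence background; the
  background μ is always the training fold's mean, keeping attributions
  fold-honest. Normalized importances are mean |φ| scaled to sum to 1.

## Classification

Base learners are linear/quadratic discriminants (equal priors by
default; ridge/shrinkage switches for singular covariance),
distance-weighted KNN, and an L2-regularized hinge-loss linear SVM
(C = 1.0, standardized on the training fold; the model's weights are
exposed in the original feature space for SHAP). KNN standardizes its
inputs on the training data: channels span ~200× in scale and unscaled
Euclidean distance would see only the largest channel.

The random-subspace ensemble draws, for each of B = 30 weak learners,
m = 3 of the d = 5 channels uniformly without replacement (seeded,
independent across learners), fits the base learner on those columns, and
averages class *posterior probabilities* — averaging raw discriminant
scores across different subspaces would mix incomparable scales, and a
posterior-scale ensemble score gives decision thresholds on [0, 1].
Prediction is argmax with lowest-class-index tie-break (ties genuinely
occur with small ensembles). With B = 1 and m = d the ensemble reduces
exactly to its base learner, which is tested.

Cross-validation collapses technical replicates to patient means *before*
any split, then stratifies by label with a seeded shuffle; each patient
appears in exactly one validation fold and the fold-assignment table makes
that auditable. Leave-one-out is the `k="loo"` plan. The ROC operating
point maximizes sensitivity subject to a specificity floor (1.0 for the
screening use case); at equal sensitivity the most permissive threshold is
chosen, placed at the midpoint between the lowest admitted score and the
highest score below it.

## Numerical choices and problem sizes

All concentrations are µM internally; conversions happen at I/O edges.
Embedding identities are asserted at 1e-12 relative, zero-noise round
trips at 1e-9, OLS against its closed form at 1e-10. The acceptance
script and tests run cohorts of 50–100 patients, 2,000-replicate MANOVA
nulls, and 20 × 10,000-shuffle permutation comparisons — sizes chosen to
make the statistical assertions sharp at desk scale. At n = 12 per
permutation instance the exact permutation null has only 462 distinct
splits, so single-instance gaps between the Rao-F and permutation p-values
of a few hundredths are expected even for a correct implementation; the
agreement check therefore bounds the mean gap.

## Known limitations

Linear calibration only (no quench/saturation models); no instrument
vendor file parsing; no plate spatial effects; per-disease Ig class
proportions are placeholders, not epidemiology; the tumour-site and
CDKi-response tasks demonstrate the pipeline on generator constructs and
say nothing quantitative about real patients.
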