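# Methods

## The measurement problem

In dopamine-transporter (DAT) SPECT, presynaptic striatal uptake falls as
Parkinson's disease progresses.  Two complementary descriptions are
computed per scan: the *shape* of the whole-brain count histogram (the
striatal hot tail shrinks with disease, shifting skewness and kurtosis)
and the *striatal activity volume* obtained by region growing from the
hottest voxel.  Both are cheap, anatomical-atlas-free measurements that
work on count images alone.

## Segmentation

**Whole-brain ROI.** A voxel belongs to the brain sample when its count
strictly exceeds a fixed threshold (default 15 counts, the background
level at the periphery of the head in the imaging regime we emulate).
The threshold is applied to raw counts; the mask is antitone in the
threshold by construction.

**Striatal ROI.** Seed = the global count maximum inside the brain mask
(ties broken lexicographically); since the striatum is the hottest DAT
structure, no operator interaction is needed.  An explicit seed can be
supplied for pathological cases.  Growth includes every voxel connected
to the seed (26-neighbourhood by default; 6 available) whose count is at
least `include_fraction` × seed count.  The inclusion fraction defaults
to 0.5: the 50%-of-maximum isocontour is the standard nuclear-medicine
volumetric convention.  An optional absolute floor guards against
low-contrast leakage.  The implementation is connected-component
labelling of the super-threshold set, so the result is independent of
traversal order; tests verify equality with an explicit breadth-first
flood fill.

## Features

Formulas use n−1 denominators throughout (sample moments, sample SD);
the whole-brain sample houses the xᵢ.

- **SK** (skewness) and **KUR** (kurtosis): moment ratios as printed in
  the README table.  Kurtosis defaults to the *non-excess* convention
  (normal benchmark 3); the excess variant (−3) is available via
  `kurtosis_excess=True`.  Cohort-level kurtosis values in the
  literature for this measurement are discussed against the benchmark 3,
  which is why non-excess is the default.
- **CSK** (Cyhelsky's skewness coefficient): (n_below − n_above)/n_total,
  where values exactly equal to the mean count in neither n_below nor
  n_above but remain in n_total — the only reading under which the
  formula is well-defined for all inputs.  Bounded in [−1, 1].
- **MES** (Pearson's median skewness): 3(x̄ − Md)/SD, bounded in [−3, 3];
  the median of an even-sized sample is the midpoint of the two central
  order statistics.
- **DTAV**: Σ over axial slices of (member area × slice thickness),
  algebraically equal to member-voxel count × voxel volume; reported in
  mL in the feature table.
- **DTAM**: by default the maximum voxel count inside the grown region
  (`max_count`), which matches the count-scale magnitudes reported for
  this quantity in patient cohorts; `max_slice_volume` (largest
  single-slice area × thickness) implements the literal
  volume-per-slice reading and is retained because the two definitions
  circulate side by side.

Degenerate inputs raise: constant samples (SD = 0) for SK/KUR/MES, empty
regions for DTAV/DTAM, an empty brain mask (threshold too high) for the
pipeline, a zero-count seed for region growing.

## Group statistics

Per feature and stage: n, mean, 95% CI (mean ± t₀.₉₇₅,ₙ₋₁·sd/√n — the t
interval matters at the tiny healthy-group sizes of retrospective
cohorts), SD, min, max.  Group comparison uses the tie-corrected
Kruskal–Wallis H (chi-square reference, k−1 df) and Dunn's pairwise z
tests on pooled mean ranks with the pooled tie-corrected SE; two-sided
normal p-values are Bonferroni-multiplied by the number of pairs and
capped at 1.  Tie correction is applied everywhere because count-derived
features tie heavily.  Mann–Whitney U uses the tie-corrected normal
approximation without continuity correction, so two identical samples
give p = 1 exactly.  Exact small-sample permutation p-values are out of
scope.

## Classification

A single stratified 50/50 split (ceil/floor sizes; stratification
preserves stage proportions up to rounding, and a stage with < 2
subjects falls back to a plain random split with a warning).  The
healthy group is split like any other class.

- **LR**: multinomial logistic regression, unpenalized with intercept,
  on raw features — the softmax generalization of
  P(X) = e^f(x)/(1+e^f(x)), f(x) = β₀ + Σβₖxₖ.  If the optimizer fails
  to converge (the signature of separation) the fit is repeated with an
  L2 ridge penalty and a note is logged.
- **SVM**: RBF kernel, one-vs-one multiclass, features standardized with
  training statistics; defaults C = 1 and gamma = 1/(d·Var) ("scale") —
  conventional defaults in the absence of a stated protocol.

**Validity panel.** From the test-half confusion matrix (rows truth):
per-class one-vs-rest sensitivity/specificity/PPV/NPV plus
prevalence-weighted averages; accuracy = trace/total; macro one-vs-rest
AUC via the rank (Mann–Whitney) formulation; Cohen's kappa
(p_o − p_e)/(1 − p_e).  Single-number sensitivity/specificity for a
three-class problem requires an averaging convention, and published
tables for this kind of model often do not state one (some are
internally inconsistent, e.g. NPV = 1.000 alongside specificity =
0.500); we therefore always report the per-class breakdown beside the
averages.  Classes absent from the test half are flagged and excluded
from averages; degenerate single-cell matrices define kappa as 0 with a
warning.

## The phantom

### What it emulates

A head-centred ellipsoidal brain (semi-axes 70 × 85 × 55 mm) of uniform
background 90 counts; two disjoint striatal ellipsoids at x =
±(semi-axis + 1.5 mm), y = +15 mm (anterior), with per-stage semi-axes
chosen so the bilateral pair volume matches cohort-level DTAV means
reported for patient groups (33.7 / 15.8 / 10.1 mL) and per-stage peaks
400 / 330 / 270 counts; isotropic Gaussian blur σ = 4 mm emulating
reconstruction resolution; then (optionally) independent Poisson draws
per voxel.  Grid 128×128×64 at 3.9 mm isotropic voxels — the matrix size
of the emulated acquisition; the physical voxel size of such studies is
rarely reported, so 3.9 mm (≈50 cm FOV / 128) is a documented
assumption.  Cohort generation adds per-subject lognormal jitter: 6% CV
per striatal semi-axis (≈10% volume CV) and 10% CV on peak uptake, with
per-subject seeds spawned from the master seed.

Two mechanisms make the histogram features behave like the clinical
pattern.  The blurred brain edge contributes a fixed low-count left tail
to the whole-brain sample; the striatal region contributes a
stage-dependent high-count right tail.  As the striatum shrinks and dims
with stage, skewness falls from clearly positive (healthy) through
mildly positive to ≈0/negative (severe), and kurtosis falls in parallel
— the orderings, and the sign pattern of SK, reproduce the clinical
observation.  Decreasing peak uptake with stage is deliberate (DAT
density falls with progression); it is also what keeps the skewness
ordering stable, because with a *brighter* mild than healthy striatum
the third-moment contribution of the hot tail would invert the ordering.
A consequence is that the phantom's DTAM decreases monotonically with
stage, whereas small patient cohorts have reported a non-monotone DTAM
pattern; DTAM ordering is therefore not something the phantom claims to
reproduce.

The 3 mm inter-striatal gap keeps the two ellipsoids analytically
disjoint while letting the blurred bridge between them stay above the
50%-of-seed growth cut at every stage, so one region grow captures the
bilateral pair, and the grown volume of the healthy default phantom
matches the analytic pair volume to within ~5%.  At lower stage contrast
the 50% cut sits closer to background and the grown boundary dilates
(severe is over-measured by ~35–45%) — the same bias a fixed-percentage
isocontour shows on real low-uptake scans; stage ordering of DTAV is
unaffected.

### What it does not emulate

No filtered back projection (streaks, filter ringing), no attenuation or
scatter, no comma-shaped striatal anatomy or left/right asymmetry, no
cortical uptake gradients.  Real whole-brain histograms are shaped by
smoothly varying cortical uptake, so the phantom's absolute SK/KUR
magnitudes (e.g. healthy SK ≈ 3 instead of ≈0.5) are larger than
clinical values even though the stage orderings match.  Passing tests
therefore demonstrate that the *pipeline* recovers the group structure
built into the data — they do not certify clinical accuracy on patient
scans.

## Problem sizes and numerical choices

Tests and the acceptance script use 30 subjects per stage for the
separated cohort and 40 per stage for the negative control — large
enough that group orderings and classifier recovery are stable, small
enough to run on a laptop in minutes.  The negative-control accuracy is
reported as the mean over 3 independent 50/50 splits of one cohort,
which reduces split-to-split variance of a single stochastic check.
Determinism: every stochastic step (phantom noise, subject jitter,
splits) is driven by explicit integer seeds; fixed seeds give
bit-identical volumes and byte-identical feature tables.  Oracle
agreement for the shape statistics is asserted at 1e−9 relative
tolerance; region growing is asserted bit-exact against the flood-fill
oracle.

## Known limitations

- The phantom's histogram-feature magnitudes are not clinically
  calibrated (orderings only, see above).
- DTAV measurement bias grows as striatal contrast approaches
  background; no partial-volume correction is attempted.
- The 50%-of-seed growth rule is a convention, not an estimate of the
  true isocontour; the stopping rule of the emulated operator protocol
  is not recoverable and alternatives are exposed via `GrowConfig`.
- Single percentage-split validation (no cross-validation, no
  hyperparameter search) mirrors the emulated protocol and inherits its
  variance.
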