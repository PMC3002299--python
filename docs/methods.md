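# Methods

This note documents the models, numerical choices and calibration behind
`gelbands`, and what the synthetic cohorts do and do not establish.

## Lane model and alignment

A lane trace is a column-mean densitometric profile of a gel image
(rows = migration axis, Rf increasing with row index; >1000 pixels per
lane). Alignment proceeds in two stages anchored on the synthetic
standard (SS), a fixed mixture producing 24 equally spaced bands across
Rf 0.05–0.95, loaded in ≥4 lanes per gel including both outermost lanes:

1. **Within-gel correction.** SS band maxima are peak-picked per SS lane
   (sub-pixel apex via a parabola through the peak and its neighbours)
   and matched to the reference ordering by rank. For each SS band, its
   displacement from the gel-mean position is fitted as a polynomial in
   lane index (default degree 2 — the lowest degree that captures gel
   "smile"; the degree is reduced with a warning if fewer SS lanes than
   coefficients are available). The displacement field at an arbitrary
   position is linearly interpolated across the SS band positions and
   held constant beyond the outermost anchors; each lane is resampled by
   subtracting it.
2. **Between-gel alignment.** Each block of data bounded by SS bands is
   linearly stretched or shrunk so the gel's anchors land on the global
   (all-gel) mean anchor positions; beyond the outermost anchors the
   adjacent block's linear map is *extended* (not clamped), which
   preserves strict monotonicity of the composite warp. The result is
   resampled by linear interpolation onto the canonical grid of 1001
   points (index i ↔ Rf = i/1000).

Aligned lanes are truncated to the closed window Rf ∈ [0.09, 0.82]
(grid indices 90…820, 731 points) and then min–max scaled to [0, 1];
scaling after truncation prevents the discarded, highly variable gel
extremes from setting the scale. A constant truncated lane makes
scaling undefined; such lanes are rejected with a reason.

Assumptions: distortions are smooth, per-lane and one-dimensional
(position-dependent shifts), monotone in Rf; SS bands are detectable in
every usable SS lane. Anchor crossing or a non-monotone warp is an
error naming the gel and lane.

## Band statistics

* **Peak picking**: bands are local maxima of the scaled profile above a
  user-defined threshold (default 0.02 of the scaled intensity), with a
  minimum separation of 0.004 Rf enforced greedily by descending height;
  exact ties keep the lower Rf. The threshold default is set below the
  generator's abundance floor (see *Calibration*) so every planted band
  is detectable; raising it toward 0.05 suppresses genuinely faint bands
  and is left to the user for noisy real-world gels.
* **Shannon index**: H = −Σ pᵢ ln pᵢ over relative band intensities,
  natural log (the control-group target 3.25 < ln 45 ≈ 3.81 is only
  consistent with natural log, which is also the ecological convention).
* **Dice similarity**: 100·2m/(n_a+n_b) with m the size of a one-to-one
  matching of band positions within ±0.008 Rf, built greedily over
  ascending pair distance. At realistic band spacings this equals the
  exhaustive maximum matching; the test-suite verifies the equivalence
  by brute force for all instances with ≤8 bands per set.
* **Replicate handling**: duplicate (or triplicate) lanes of a sample
  are averaged before statistics — scalars arithmetically, aligned
  vectors elementwise. Similarity summaries are computed on band sets
  peak-picked from the replicate-averaged vectors.
* **Group tests**: one-way ANOVA plus pooled-variance pairwise t tests
  with Bonferroni multiplication at α = 0.01; Shapiro–Wilk and Levene
  pre-checks are reported, not enforced.

## Chemometrics

`PLSDAClassifier` is a NIPALS PLS2 regression of column-centered
profiles onto centered one-hot class indicators; no column autoscaling
is applied (lanes are already 0–1 scaled, and autoscaling would inflate
empty grid regions). Weight vectors are unit norm, score vectors
mutually orthogonal; prediction maps through the rotation
W(PᵀW)⁻¹Qᵀ and assigns the argmax class. Requesting more components
than min(n−1, p) or than the data rank raises an error.

Cross-validation is leave-sample-out: all replicate lanes of one sample
form a held-out segment; their predicted indicator vectors are averaged
and the sample assigned the argmax, so the success rate counts samples,
not lanes (the sample is the statistical unit; a per-lane variant is
deliberately not offered). The model size is chosen as the *first local
maximum* of the success-rate curve over 1…10 components, ties toward
fewer components. A segment that would remove an entire class from
training is an error.

The permutation test scrambles labels at the sample level (replicates
keep their sample's permuted label) and recomputes the cross-validated
success at the chosen component count. The empirical p is
(1 + #{null ≥ observed})/(n_resamples + 1); because a finite resample
count cannot resolve smaller p values, a Gaussian fit to the null is
reported alongside as a tail estimate. Under the null the success rate
sits near the chance rate but not exactly at 1/3: unbalanced groups and
the pessimism of cross-validation under scrambled labels shift it by a
few points.

CVA takes the first K PLS score columns (default K = 4, a parsimonious
model for this data shape) and solves the symmetric generalized
eigenproblem of between- versus within-group scatter; at most
groups − 1 = 2 canonical variates exist. A singular within-group
scatter receives a ridge of 10⁻⁸·trace with a warning. The
cross-validated projection maps each held-out sample through its
training fold's PLS and CVA.

Discriminant bands are ranked by the mean absolute first-component
loading across all cross-validation training segments (fold loadings
sign-aligned to the first fold before averaging), peak-picked with the
band-separation rule; per-band min–max ranges across folds quantify
stability, and the consistency flag records whether the same top-n
positions (±0.008 Rf) lead in every segment.

## Synthetic cohort: what it emulates

The generator draws, per channel, a **band atlas**: a near-regular grid
of candidate Rf positions in [0.095, 0.815] with ≥0.0095 spacing and
±0.0003 jitter, into which four fixed marker positions
(0.236, 0.259, 0.273, 0.421 — the control-enriched Bacteroides /
Parabacteroides phylotypes of the reference study) are planted exactly.
Group structure:

* a shared core (20 bands) common to all groups;
* the control core adds the four markers plus ten further bands
  (34 total); the two patient cores (24/23) are nested within each
  other, so the patient groups are mutually confusable while both
  differ from controls — reproducing the observed error structure
  (misclassifications almost exclusively UC ↔ IBS) and the CVA
  geometry (patient centroids far from the control centroid, close to
  each other);
* markers are excluded from the patient accessory pools and receive a
  +1.5 log-abundance boost in control subjects, making them the
  dominant discriminators — the reference analysis found its four
  top-ranked loading bands consistent across all cross-validation
  passes and prominent enough to excise, and that structure only exists
  if the marker bands are prominent;
* per subject: band count ~ round(Normal(μ, σ)) clipped at the core
  size; bands = core ∪ uniform draw from the group's accessory pool;
  abundances ∝ exp(Normal(0, s)), floored at 3 % of the subject's
  maximum and normalized. The floor guarantees that every planted
  band's rendered, 0–1 scaled peak clears the 0.02 detection threshold.

Lanes are rendered as sums of Gaussian bands (σ = 0.0025 Rf) over a
flat baseline on an 1100-pixel grid, with per-lane brightness jitter
(±20 %), additive Gaussian noise (0.002 of the amplitude scale) and
per-gel distortions: shift |δ| ∈ [0.008, 0.02] Rf (large enough that
unaligned between-gel profiles fail Dice matching at the ±0.008
tolerance), stretch up to ±2 %, quadratic smile up to 0.01 Rf.
Subjects' duplicate lanes always land on different gels (12 sample
lanes + 4 SS lanes per gel, 8 gels per channel for the 46-subject
cohort); images are 16-bit grayscale.

### Calibration

Free generator parameters were frozen by Monte Carlo
(`gelbands.calibrate`), targeting the reference cohort summaries:

* **Intensity spread s** per group by bisection so the expected latent
  Shannon index matches the target given the group's band-count
  distribution (control 1.02 with the marker boost included, UC 1.39,
  IBS 1.62). A structural constraint fixes the detection threshold at
  0.02 rather than a more conventional 0.05: with every band floored at
  fraction r of the tallest, the *minimum* achievable expected Shannon
  index for ~37–39 bands at r = 0.05 is ≈ 2.96–3.03, above the patient
  targets 2.94/2.90 — so detectability-by-construction and the patient
  diversity targets are jointly satisfiable only with a lower floor
  (0.03) and threshold (0.02).
* **Core and pool sizes** per group by scanning the median latent
  within-group Dice (control 34/36, UC 24/40, IBS 23/43; Bacteroides
  channel 7/40, 3/60, 7/50). The Rf window holds only ~70 positions at
  non-cross-matching spacing, which caps the accessory pool sizes; the
  scan lands the latent medians within ~1 point of the 82.9/76.1/73.8 %
  (and 58.8/36.4/55.2 %) targets.

Pipeline-level recovery at these settings (seeds 1–4): control counts
43–46, control Shannon 3.27–3.32, control Dice median 82.6–83.3 %,
cross-validated success 74–83 % at the first local maximum. Group means
of the n = 13 and n = 11 patient groups carry standard errors of
1.4–1.8 bands, so seed-to-seed excursions of ±2 bands around the
nominal means are inherent to the cohort size.

### What the generator does not emulate

No PCR amplification bias, heteroduplex artefacts, co-migration of
distinct taxa to one band, staining saturation, or 2-D image distortion
(rubber-sheeting); distortions are 1-D per lane by construction, and
lane extraction assumes known column spans. Passing tests therefore
show that the *pipeline* recovers known ground truth under realistic
positional distortion and noise — not that the biological conclusions
of any particular study would survive those wet-lab artefacts.

## Problem sizes and determinism

The standard run is the full cohort (46 subjects × 2 lanes + SS lanes,
8 gels per channel, 92 × 731 aligned matrix) with 200 permutation
resamples — about two minutes on one CPU; the permutation count is a
config knob (`n_resamples`) and 10⁴ resamples reproduce the empirical
floor p ≈ 10⁻⁴ regime with the Gaussian tail extending below it. All
randomness flows from one master seed through hierarchically spawned
generators (cohort / layout / rendering / permutation), so identical
configs give byte-identical reports and any stage can be rerun in
isolation.

## Known limitations

* The within-gel correction is position-interpolated (not a per-lane
  scalar); a scalar variant is not offered.
* Alignment warps only against SS anchors, never against sample bands;
  gels whose SS lanes fail quality control are unalignable by design.
* The greedy Dice matcher is exact only at realistic band densities
  (verified to ≤8 bands per set by brute force); pathological
  ultra-dense profiles could in principle defeat it.
* Absolute Rf positions after alignment retain a small experiment-wide
  offset (the mean of the per-gel distortions); all within-experiment
  comparisons are unaffected.
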