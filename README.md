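# gelbands

Analysis of DGGE (denaturing gradient gel electrophoresis) community
fingerprints: synthetic-standard anchored lane alignment, band-level
diversity and similarity statistics, and cross-validated PLS-DA / CVA
group discrimination — together with a calibrated synthetic gel
generator that provides ground-truth cohorts for testing every stage.

## The problem

PCR-DGGE of the 16S rRNA V3 region turns a faecal sample's predominant
bacterial community into a lane of bands: one band per dominant sequence
variant, at a migration position (Rf, scaled 0–1) set by its melting
behaviour. Comparing such fingerprints between subject groups — here a
cohort of 22 healthy controls, 13 ulcerative-colitis (UC) and 11
irritable-bowel-syndrome (IBS) patients, each sample run in duplicate on
different gels — is dominated by two nuisances:

* **positional distortion**: within-gel band curvature ("smile") and
  between-gel shifts/stretches larger than the spacing between distinct
  phylotypes, and
* **intensity variation** between gels and lanes.

The package implements the remedy used in practice: a **synthetic
standard (SS)** — one fixed multi-band mixture — is loaded in at least
four lanes of every gel, including both outermost lanes. Its band maxima
are peak-picked as anchors; polynomial fitting of anchor displacement
versus lane index removes within-gel curvature, and piecewise linear
interpolation between anchors (onto the global mean anchor positions)
aligns gels to each other. Every lane lands on a canonical 1001-point Rf
grid, is truncated to the 731 points covering Rf 0.09–0.82 (the gel
extremes are unreliable), and min–max scaled to [0, 1].

## The statistics

On aligned profiles the package computes, per lane and per sample
(replicates averaged before statistics):

* **band count** — local maxima above a user-defined threshold;
* **Shannon diversity** `H = −Σ pᵢ ln pᵢ` over relative band
  intensities, a joint measure of band number and evenness;
* **Dice similarity** `D = 100 · 2m / (n_a + n_b)` where `m` counts
  one-to-one position matches within ±0.008 Rf;
* one-way ANOVA with Bonferroni-adjusted pairwise comparisons for the
  group effects;
* **PLS-DA** (NIPALS PLS2 against one-hot class indicators) with
  *leave-sample-out* cross-validation — all replicate lanes of a sample
  are held out together, and the sample is the unit of success;
* a **y-scrambling permutation test** of the classification success
  rate (labels permuted at sample level), reporting the empirical p and
  a Gaussian tail estimate;
* **CVA** of the PLS scores for the optimal 2-D view of the three-group
  structure, and a ranking of the bands driving the first PLS loading
  across all cross-validation segments.

The chemometric estimators (`PLSDAClassifier`, `CanonicalVariateAnalysis`)
follow scikit-learn conventions (`fit`/`predict`/`transform`,
`get_params`) and compose with sklearn tooling; the NIPALS implementation
is the package's own and is verified against an independent PLS
implementation in the test-suite.

## The synthetic cohort

No public gel images exist for this kind of study, so `gelbands.simulate`
renders them: group-structured latent band sets (a group core plus an
accessory pool on a shared band atlas), log-normal band abundances,
Gaussian band profiles on a >1000-pixel lane, per-gel shift/stretch/smile
distortions, noise, duplicate lanes per subject across gels, and SS lanes
in four positions per gel. The presets in `gelbands.presets` are
calibrated (see `gelbands.calibrate` and `docs/methods.md`) so the
pipeline-measured group statistics reproduce the reference cohort values:
mean band counts 45/37/39, Shannon 3.25/2.94/2.90, within-group median
Dice 82.9/76.1/73.8 % for control/UC/IBS, and the analogous summaries of
a Bacteroides-specific primer channel.

## Worked example

```python
from gelbands import RunConfig, run_study

report = run_study(RunConfig(seed=1))
uni = report.channels["universal"].group_summaries
for g in ("control", "UC", "IBS"):
    s = uni[g]
    print(f"{g:>8}: {s.band_count_mean:5.1f} ± {s.band_count_sd:3.1f} bands   "
          f"H = {s.shannon_mean:4.2f} ± {s.shannon_sd:4.2f}   "
          f"Dice {s.dice_median:4.1f}% (IQR {s.dice_iqr[0]:4.1f}–{s.dice_iqr[1]:4.1f})")
cv = report.cv
print(f"CV success {100 * cv.success_rates[cv.best_k - 1]:.1f}% at K = {cv.best_k}; "
      f"permutation p = {report.permutation.p_empirical:.4f}")
print(report.band_ranking.table.round(3).to_string(index=False))
```

prints

```
 control:  46.0 ± 2.7 bands   H = 3.32 ± 0.14   Dice 82.6% (IQR 80.5–85.0)
      UC:  35.4 ± 4.5 bands   H = 2.90 ± 0.20   Dice 76.9% (IQR 74.2–79.8)
     IBS:  37.2 ± 7.6 bands   H = 2.92 ± 0.21   Dice 74.4% (IQR 72.7–77.9)
CV success 73.9% at K = 1; permutation p = 0.0050
 rank    rf  mean_loading  range_low  range_high
    1 0.235         0.262      0.250       0.275
    2 0.258         0.218      0.202       0.235
    3 0.272         0.174      0.153       0.188
    4 0.420         0.127      0.105       0.138
```

Controls carry more bands and higher diversity than either patient
group; patients are more variable (lower within-group Dice); the
cross-validated classifier separates healthy from diseased far above
the 1/3 chance rate (permutation p at the resolution floor of 200
resamples); and the four top-ranked discriminant bands sit at the Rf
positions of the planted control-enriched marker phylotypes
(0.236/0.259/0.273/0.421), consistently across all cross-validation
segments.

A command line mirrors the library:

```bash
gelbands simulate --channel universal --seed 1 --out gels/
gelbands extract --images gels/ --metadata gels/metadata.csv --out traces.csv
gelbands report --seed 1 --out run1/
gelbands check --report run1/report.json
```

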