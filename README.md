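# ctaperv

Measurement of thrombus perviousness and the CTA-index from paired
non-contrast CT (NCCT) and CT-angiography (CTA) head volumes, together
with the synthetic phantoms, cohort simulator and statistical battery
needed to exercise the whole pipeline end-to-end without patient data.

## What it does

Given an NCCT/CTA pair (NIfTI) and a vessel centerline (JSON), the
imaging pipeline:

1. rigidly registers the NCCT onto the CTA (FFT cross-correlation
   initializer + multi-resolution Powell refinement of a windowed
   mutual-information metric; deterministic, no random state);
2. locates the contrast stop along the centerline (smoothed HU profile
   falling below a relative or absolute threshold with a persistence
   requirement);
3. places a circular ROI 1.5 mm distal to the stop (occlusion site T)
   and a mirrored ROI on the contralateral vessel (C);
4. extracts mean HU in both ROIs on both scans and derives

   * attenuation change `delta = HU_CTA - HU_NCCT` per site,
   * void fraction `epsilon = delta_T / delta_C`,
   * CTA-index `(HU_T - HU_C) / (HU_T + HU_C)` on the CTA alone.

The statistics module provides the cohort exclusion filter, two-sample
rank-sum comparison (exact for small tie-free samples), OLS
residualization, Spearman and partial correlations, covariate-adjusted
logistic regression with Nagelkerke/Cox-Snell pseudo-R², and two-rater
ICC(2,1) with its F-based confidence interval.

The simulator renders tubular-vessel phantoms with a thrombus of known
baseline density and contrast uptake (ground truth ledger included) and
draws cohorts whose per-outcome-group CTA-index distributions match the
published group means/SDs and sizes, plus a two-rater noise model.

## CLI

A single entry point `ctaperv` with subcommands:

```bash
ctaperv simulate-phantom --seed 1 --out phantom/          # NCCT+CTA+centerline+truth
ctaperv simulate-cohort  --seed 1 --out cohort.csv --raters-out raters.csv
ctaperv measure phantom/ncct.nii.gz phantom/cta.nii.gz phantom/centerline.json \
        --out result.json                                  # one patient
ctaperv analyze-cohort cohort.csv --raters raters.csv --out report.json
ctaperv reproduce --seed 1 --out study.json               # full synthetic study
```

`measure` exits with a stage-specific code on failure (2 input,
3 registration, 4 localization, 5 ROI placement, 6 sampling,
7 metrics). Config files are YAML; flags override file values, which
override defaults. Every output embeds the effective config.

## Layout

```
src/ctaperv/
  imaging/        volumes, rigid geometry, registration, ROI sampling
  simulate/       phantom renderer and cohort/rater simulators
  metrics.py      CTA-index, attenuation change, void fraction
  stats.py        cohort statistics and exclusion filter
  study.py        cohort -> phantoms -> measurement -> statistics
  cli.py          click CLI
tests/            pytest suite; test_acceptance.py holds the binding criteria
```
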