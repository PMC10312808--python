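# normgain

Computational pipeline linking cortical surface area to motion-perception
thresholds:

- **`normgain.model`** — spatial divisive-normalization model (1-D space ×
  two motion-direction channels) with a multiplicative top-down gain field.
  Predicted duration thresholds are inversely proportional to the peak of
  the population response image. The two manipulated widths are the
  excitatory drive (3 vs 4.5 a.u.) and the attention field (3 vs 7 a.u.).
- **`normgain.psychometrics`** — Bayesian adaptive (Psi) staircase
  simulation, Weibull psychometric fitting with fixed guess (50%) and lapse
  (4%) rates, 80%-correct threshold extraction (median of four runs), and
  staircase quality control (a staircase is flagged when the mean of its
  last 5 running estimates exceeds 0.8× the mean of its first 10; a subject
  with ≥4 flags is excluded).
- **`normgain.anatomy`** — parcel surface-area tables (tidy TSV or
  FreeSurfer `mris_anatomical_stats`-style files), per-hemisphere
  normalization to percent, named-region sums (right-parietal 7AL/VIP/LIPd/
  IP1/IP2, left-frontal 11l), rank-based group splits, and parcel-wise
  brain–behavior correlation screening (negative sign, p < 0.01
  uncorrected by default).
- **`normgain.fmri`** — block-design ROI response extraction: 12-sample
  windows (−4…18 s at TR = 2 s), percent signal change against the 3
  pre-onset samples, 8–12 s response magnitude, framewise-displacement
  (> 0.9 mm) block exclusion and run-level QC (hit rate < 60%, more than
  half of a condition's blocks lost).
- **`normgain.cohort`** — seeded synthetic-study generator: 180-parcel
  surface-area tables, model widths linked (affine-decreasing, clipped) to
  parietal/frontal normalized area, trial-level staircase behavior with a
  minority of "rising-staircase" inattentive observers, and block-design
  timecourses whose amplitude tracks frontal area.
- **`normgain.pipeline`** — config-driven end-to-end runs (`run_exp1`,
  `run_exp2`, `run_exp4`, `run_model_comparison`) producing JSON + TSV
  reports that are byte-reproducible under a fixed seed.

## CLI

```bash
# predicted thresholds over widths x sizes x contrasts
normgain model sweep -e 3 -e 4.5 -a 3 -a 7 -o sweep.tsv

# generate a synthetic study (presets: exp1, exp2, exp4, null)
normgain simulate --preset exp1 --seed 1 -o study/

# thresholds + staircase QC from a trial TSV
normgain thresholds --trials study/trials.tsv

# parcel screening and region group splits
normgain screen --parcels study/parcels.tsv --trials study/trials.tsv --alpha 0.01
normgain regions --parcels study/parcels.tsv --fraction 0.3333

# fMRI block-response extraction
normgain fmri --timecourses study/timecourses.tsv --blocks study/blocks.tsv

# full configured run
normgain run --config run.json --experiment exp1
```

A run config is a JSON object validated on load, e.g.

```json
{
  "seed": 1,
  "simulate": {"preset": "exp1"},
  "screening": {"alpha": 0.01, "sign": "negative"},
  "split_fraction": 0.3333,
  "outdir": "out"
}
```

(`inputs` with `parcels`/`trials`/`timecourses`/`blocks` paths may replace
`simulate`; exactly one of the two must be present.)

## File formats

All I/O is headered TSV: trials
(`subject_id condition run trial duration_ms correct running_estimate_ms`),
parcels (`subject_id hemi parcel surfarea_mm2`), timecourses
(`subject_id run tr_index signal fd_mm`), blocks
(`subject_id run onset_index condition hit_rate`), plus JSON reports.
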