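# opticpath

Along-tract analysis of the anterior optic pathway (optic nerve → chiasm →
optic tract) from multishell diffusion MRI derivatives, plus a synthetic
phantom generator so the whole pipeline is testable without acquired data.

## What it does

- **compartments** — normalizes raw three-tissue (WM/GM/CSF) spherical-
  deconvolution intensities into four unit-sum fractions (nWM, nGM, nCSF,
  nBG); voxels whose total intensity falls below 0.075 gain a "background"
  component filling the deficit.
- **tensor** — log-linear least-squares diffusion tensor fit, FA/MD scalar
  maps, and the validity mask (FA in (0, 1), MD in (0, 0.005) mm²/s, open
  intervals).
- **masking** — streamline → voxel fibre-density maps (binary visitation per
  streamline), the per-coronal-slice 40%-of-maximum threshold, the
  background exclusion mask, and an iterative threshold loop that adjusts
  the nBG cutoff until a 26-connected component joins the LGN seed to the
  postorbital waypoint. Piecewise pre/post-chiasm union is supported for
  tracts that fail as a whole.
- **geometry** — anatomy-scaled 10 + 7 segment binning (≈4 mm segments),
  the optic-tract / chiasm / optic-nerve ROI partition, decussation fraction
  by weighted fibre volume, Dice overlap, and the tractography success
  verdict (continuity, overlap, ≈50% decussation).
- **stats** — per-slice means with validity filtering, voxel-count-weighted
  segment/ROI summaries, Welch's t-test (from summaries or cohorts) with
  Hochberg step-up FWE correction, and eye-mapped Pearson correlations with
  clinical covariates (visual acuity, RNFL, disease duration).
- **phantom** — generates the ground truth: four smooth centerlines
  (left/right × crossing/noncrossing) converging at a chiasm with a
  configurable decussation fraction, jittered streamlines, compartment /
  tensor / DWI volumes whose derived statistics hit reference group
  profiles exactly at zero noise, clinical tables with planted
  correlations, and cohort draws for power studies.

## CLI

```sh
# synthetic dataset (NIfTI volumes, TCK streamlines, clinical TSV)
opticpath phantom --out data/ --group control --n-subjects 3 --seed 1

# density map -> thresholded, continuity-checked tract mask -> segments
opticpath mask --tck data/sub-001/streamlines.tck \
    --fractions data/sub-001/fractions.nii.gz \
    --seed-roi seed.nii.gz --waypoint-roi waypoint.nii.gz \
    --chiasm-slice 16 --out out/

# Welch + Hochberg group table from a long-format per-subject stats TSV
opticpath stats --stats-file stats.tsv --out out/

# exploratory clinical correlations (uncorrected p)
opticpath correlate --stats-file stats.tsv --clinical data/clinical.tsv --out out/
```

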