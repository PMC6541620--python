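# cellquant

Quantitative single-cell image analysis and cell-motility analytics for
fluorescence microscopy of cultured cancer cells, with a synthetic
ground-truth generator that makes every measurement verifiable.

The package is aimed at cell biologists quantifying how a protein of
interest (POI) redistributes when cells switch from rounded to
protrusive, motile states — for example cortical recruitment of
centrosomal kinases during exosome/WNT-stimulated breast-cancer-cell
migration — and at anyone analysing manually tracked 2D cell
trajectories or scratch-wound closure.

## What it computes

**Image quantification** (per cell, from a 4-channel stack — actin,
DAPI, pericentrin, POI):

- cell outline by adaptive (local-mean) thresholding of the
  average-projected actin signal; nucleus from DAPI; both as binary
  masks with holes filled and the largest component kept;
- the **cortical ring**, the ~2 µm band just inside the outline,
  obtained by eroding the cell mask with a rasterized disk
  (`ring = cell ⊖ disk(t/px)` subtracted from the cell);
- mean POI intensity (maximum projection) under protrusion ROI boxes or
  under seeded random cortical boxes placed away from the
  dilated nucleus; the **cortical enrichment fold**
  E = mean(ring)/mean(interior);
- total POI intensity under the pericentrin-derived centrosome mask;
- the **N/C ratio** ρ = mean(nucleus)/mean(cytoplasm), cytoplasm being
  the whole cell minus the nucleus;
- cell **aspect ratio** from second moments of the mask;
- per-batch normalisation to control cells (control folds average to 1);
- mask-based **colocalization**: Pearson correlation of two channels
  over the union of their Otsu foreground masks, normalised by a
  self-reference coefficient r_norm = r_obs / r_ref.

**Motility** (tracks sampled every 10 min, typically 16 h):

- per-cell average speed and hourly running-average speed (µm/h);
- ensemble time-averaged mean-squared displacement
  MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩ with OLS fit; for a pure 2D random walk
  MSD = 4Dτ, so R² ≈ 1 identifies total random movement and slope/4
  estimates D;
- motion classification from the log–log slope α (diffusive α≈1,
  ballistic α≈2);
- washout/inhibition kinetics by fitting running speeds to
  S(t) = S∞ + (S0 − S∞)·2^(−t/t½), reporting the half-life t½.

**Wound healing**: the cell-free scratch is segmented by local-variance
(texture) thresholding and reported as residual area, percent of t = 0.

**Synthetic data**: cell phantoms with exact masks and prescribed E and
ρ, four trajectory models (random walk, ballistic, persistent,
decaying-speed), and closing-wound image series — all pure functions of
(spec, seed).

## Worked example

```python
from cellquant import (CellPhantomSpec, make_cell_image, project,
                       segment_cell, segment_nucleus, cortical_ring, nc_ratio)

spec = CellPhantomSpec(cortical_enrichment_fold=2.0, nc_ratio=0.65,
                       noise_sd_frac=0.05, seed=7)
stack, truth = make_cell_image(spec)
cell = segment_cell(project(stack, "actin", "average"))
nucleus = segment_nucleus(project(stack, "dapi", "average"), cell)
ring = cortical_ring(cell, spec.pixel_size_um)          # 2 um band
poi = project(stack, "poi", "max")
E = poi.image[ring].mean() / poi.image[cell & ~ring].mean()
print(f"E = {E:.3f}, N/C = {nc_ratio(nucleus, cell, poi):.3f}")
```

prints

```
E = 1.998, N/C = 0.650
```

— the segmentation-based pipeline recovers the phantom's true cortical
enrichment (2.0) and N/C ratio (0.65) to within 0.2% at 5% noise.
For trajectories:

```python
from cellquant import TrajectorySpec, simulate_tracks, msd, fit_msd_linear
from cellquant.motility import estimate_diffusion

tracks, _ = simulate_tracks(TrajectorySpec(model="random_walk", n_tracks=40, seed=0))
fit = fit_msd_linear(msd(tracks))
print(f"R^2 = {fit.r_squared:.4f}, D = {estimate_diffusion(tracks):.1f} um^2/h")
```

```
R^2 = 0.9995, D = 38.8 um^2/h
```

(true D = 37.5 µm²/h; R² ≈ 1 is the random-walk signature, and the
short-lag estimator recovers D within a few percent).

A YAML-configured end-to-end run (`cellquant run --config run.yaml`)
generates phantoms, tracks and wound frames, quantifies them, and writes
long-format CSVs plus a JSON sidecar with the config hash and seeds;
rerunning the same config reproduces the CSVs byte for byte.

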