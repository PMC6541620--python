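# Methods

## Conventions

Images are `(channel, z, y, x)` arrays of non-negative intensities with
an isotropic x/y pixel size in micrometres; pixel coordinates are
0-based and ROI boxes half-open. Time is kept in hours; track tables
given as frame indices are converted with a configured frame interval
(default 10 min, the standard live-imaging cadence for these assays).
Deconvolution is not reimplemented: the pipeline consumes raw or
vendor-deconvolved stacks. Average projections feed segmentation
(actin, DAPI); maximum projections feed intensity measurements (POI,
pericentrin).

## Segmentation

Cell and nucleus masks come from adaptive local-mean thresholding
(`pixel > local_mean + offset`), with the window defaulting to twice
the expected object diameter and the offset expressed as a fraction
(default 0.05) of the image intensity span so it is scale-free. The
result is closed with a 2-px disk, hole-filled, and reduced to the
largest connected component; an empty result raises "no cell detected".
These defaults were chosen on phantoms; both are exposed in the config,
since acquisition settings vary.

The cortical ring of thickness t (default 2 µm) is
`cell AND NOT erode(cell, disk(round(t/px)))` — a constant-thickness
inward walk from the outline implemented as morphological erosion by a
rasterized disk. An alternative construction thresholding the Euclidean
distance transform of the cell mask is available behind
`ring_method="edt"`; the two differ by at most a pixel of band width.
No mask-space construction can reproduce an *independently* rasterized
inner disk exactly: on a radius-20 disk with a 4-px band, boundary
pixels of the naive inner disk and of the eroded mask interleave in
their distances to the background, so the erosion definition itself is
the ground truth the tests enumerate by brute force.

Centrosome foci are thresholded from the maximum-projected pericentrin
signal (Otsu by default) with small components removed; an empty mask
is a valid outcome because PLK4-inhibited cells genuinely lack
centrosomes. Protrusion regions are supplied as manually drawn boxes
and intersected with the ring. For rounded cells, two random reference
boxes (default edge 3.88 µm, the only printed protrusion-box dimension
in the source imagery conventions we follow; configurable) are drawn by
seeded rejection sampling from ring pixels outside the dilated nucleus
(dilation radius defaulting to the ring thickness, 2 µm), enforcing
pairwise non-overlap; the seed is recorded in run metadata and
`max_attempts` defaults to 10,000.

## Intensity measurements

Regional means and totals are plain pixel arithmetic under the masks.
The N/C ratio divides the nuclear mean by the cytoplasmic mean
(cytoplasm = cell minus nucleus). The aspect ratio derives from central
second moments with each pixel treated as a unit square (adding 1/12
per axis), which makes a w×h rectangle yield exactly w/h and avoids a
zero minor axis for line-like masks. Normalisation to control divides
each raw value by the mean of control cells within the same batch and
measurement type, so control folds average to exactly 1 per batch;
folds are stored as ratios and ×100 display is left to reports.

Colocalization is Pearson correlation over the *union* of the two
channels' Otsu foreground masks. Union rather than intersection was a
genuine design choice: intersection discards signal present in only one
channel, whereas the coefficient is meant to reflect both overlap and
intensity covariation; intersection remains available. The observed
coefficient is divided by a self-reference coefficient (one signal
imaged via two secondary antibodies) to express colocalization relative
to the achievable maximum; a non-positive reference is an error.

## Motility

Speed is the mean step displacement divided by the sampling interval;
the hourly running average assigns steps to 1-h windows by midpoint
(trailing partial windows dropped). MSD is time-averaged over all
ordered same-track pairs — overlapping windows, chosen for variance
reduction, with a non-overlapping option — then ensemble-averaged with
equal track weights; the default maximum lag is 25% of the shortest
track, the usual guard against noisy high-lag estimates. The linear
fit includes an intercept to absorb localisation noise (through-origin
available). Motion class uses the log–log slope α with tolerance 0.1.

For estimating D specifically, the package fits only the first four
lags (`estimate_diffusion`): for noise-free uniformly sampled tracks
the variance of the fitted slope is minimised by a small number of fit
points, and empirically the short-lag estimator keeps the per-ensemble
error under ~5% at 40 tracks × 96 steps where the full-range OLS slope
scatters several-fold wider.

Inhibition/washout kinetics are modelled as an exponential approach to
a plateau written in base 2, `S(t) = S∞ + (S0 − S∞)·2^(−(t−t_drug)/t½)`,
so the fitted parameter is the literal half-life; the functional form is
a declared modelling choice. The fit is nonlinear least squares with
non-negativity bounds; a near-constant series is flagged unidentifiable
rather than fitted.

## Wound healing

Cell monolayers are textured while the scratch is locally smooth, so
the wound is pixels whose local standard deviation (7-px uniform
window) falls below a threshold (default 5 intensity units, matched to
the generator's texture contrast; Otsu fallback when unset), cleaned by
opening and reduced to the largest component. Residual area is
area(t)/area(0)×100; the boundary blur of the sliding window shrinks
the measured band by roughly half a window on each side, which cancels
almost entirely in the ratio (observed ≤ ~1 point of residual).

## Synthetic data

Phantoms are piecewise-constant: disk cell (optional capsule-shaped
protrusion arms), offset disk nucleus, Gaussian pericentrin foci, over
a flat background of 10 with cytoplasm at 100 (arbitrary units).
Because the ring is part of the cytoplasm and the nucleus part of the
ring's complement, prescribing both E = mean(ring)/mean(interior) and
ρ = mean(nucleus)/mean(cytoplasm) couples the ring and nucleus levels;
the generator solves the resulting 2×2 linear system so both ratios
hold *exactly* on the true masks, and rejects combinations with no
positive-intensity solution. The truth ring uses the same erosion
construction as the segmentation stage. Default geometry: 192-px image
at 0.2 µm/px, cell radius 12 µm, nucleus 5 µm, defaults E = 2 and
ρ = 0.65 — magnitudes typical of the cortical-recruitment and
nuclear-depletion effects these assays measure. Noise is Gaussian with
sd expressed as a fraction of the cytoplasm level (default 5%), with a
Poisson option; images are clipped at zero.

Trajectories: random walk (per-axis step variance 2·D·dt, default
D = 37.5 µm²/h, the diffusivity matching a 30 µm/h step speed at 10-min
sampling), ballistic (fixed random heading), persistent
(wrapped-Gaussian heading increments with per-step correlation p; used
for property tests only), and decaying-speed (fresh random heading each
step, step length S(t)·dt with the base-2 half-life form; optional
multiplicative speed noise). Defaults: dt = 1/6 h, 16 h duration, 40
tracks — the standard tracking protocol for these assays.

Wound series: a vertical smooth band of width max(0, w0 − rate·t)
inside a textured field; true areas follow the closed form w(t)·height.

What the phantoms do *not* emulate: optical PSF blur, uneven
illumination, touching cells, intensity-dependent (shot-dominated)
noise except via the Poisson option, and z-structure (default one
plane, as for pre-projected stacks). Passing recovery tests therefore
demonstrates correctness of the measurement arithmetic and robustness
to pixel noise at realistic contrast, not performance on crowded or
low-SNR real images.

## Group statistics

Box summaries use linear-interpolation quartiles with min/max whiskers.
The omnibus comparison is Kruskal–Wallis with Dunn's rank-based
post-hoc z-tests against the named control (tie-corrected pooled-rank
variance, Bonferroni adjustment over the comparisons, per Dunn's
procedure); pairwise two-tailed Mann–Whitney U and a two-way ANOVA
(type II) with Bonferroni-adjusted Welch post-tests are provided for
two-group and time×condition designs respectively.

## Problem sizes

Default test and acceptance workloads — 40 tracks × 96 steps, 20
phantoms per intensity level at 192² px, five wound frames at 300×600 —
were chosen as the smallest ensembles at which the estimators'
sampling error sits comfortably inside the tolerances stated above.

## Known limitations

Adaptive-threshold defaults are tuned on phantoms and will need
adjustment for real acquisitions; watershed separation of touching
cells and automated protrusion detection are out of scope (protrusions
arrive as manual ROIs); wound measurement assumes a single dominant
scratch per frame; the decay model assumes a monotone approach to a
plateau and will flag, not fit, non-monotone recoveries.
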