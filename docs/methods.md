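# Methods

This note records the measurement definitions the package implements, the
models behind the synthetic-data generators, and the numerical and design
choices made where the underlying procedures left them open.

## Conventions

Image axes are `(channel, time, z, y, x)` with y increasing downward,
0-based pixel indices, and a pixel's site at its center. Areas are
`pixel_count × pixel_size_nm²`. All intensity thresholds are strict
(`value > threshold`), so a perfectly uniform image contains no detected
structure; distance criteria are inclusive (`distance ≤ bound`). Connected
components default to 8-connectivity (the behavior of the interactive
particle-analysis tools these procedures originated in) and are labeled in
raster order of their anchor pixel, making labeling deterministic.
Background subtraction removes a per-plane scalar — the mean of a
designated background region when one is available, otherwise the 1st
percentile of the plane (the source procedures say only
"background-subtracted"; the percentile default is a stand-in and is
flagged in configuration) — and clamps negatives to zero.

## Measurements

**EM contact sites.** A profile is a closed phagosome boundary polyline
plus open ER polylines, in nm. The detector resamples each ER polyline at
1 nm arc steps, computes each sample's Euclidean distance to the boundary,
and reports maximal runs with distance ≤ 30 nm as contacts, with length
measured along the ER polyline. Runs shorter than `min_run_nm = 20` nm
(about one EM section thickness) are discarded to suppress single-sample
grazing artifacts. Only profiles with diameter strictly greater than 1 µm
are scored. ER membranes are abstracted as cisterna midlines: the
electron-density/morphology judgement a human microscopist applies is out
of scope, so the generator emits only valid ER structures. The
equal-variance F-test on pooled contact lengths uses the larger/smaller
sample-variance ratio with a two-sided p-value from the F distribution.

**Ring puncta.** The ring is the set of pixels outside a phagosome within
0.2 µm of its border (4 px at 50 nm pitch), with contested pixels assigned
to the nearer phagosome. Puncta are 8-connected components of
above-threshold ring pixels with area strictly greater than 0.01 µm²
(i.e. ≥ 5 px at 50 nm pitch; the "> 0.01 µm² / 4 pixel" convention is
internally inconsistent at that pitch since 4 px = 0.01 µm² exactly, and
the strict reading is adopted). The original procedure thresholded each
cell manually; for reproducibility the default threshold is cytosolic
mean + 2 SD, with a manual override available. Counting is done on the max
projection (whether the original counts used a single slice or a
projection is unstated; projection is the default and configurable).

**Ca²⁺.** SOCE metrics operate on per-cell F340/F380 traces sampled every
3 s: baseline is the mean over a pre-re-addition window, peak amplitude is
the post-re-addition maximum minus baseline, and max slope is the largest
least-squares slope over 5-sample sliding windows. The windowed slope
attenuates a true instantaneous slope (for an exponential rise with
τ = 20 s, a 12-s window recovers ~75% of it); amplitude is
offset-invariant. Hotspots are detected on a 6-s temporal average
(2 frames): components ≥ 4 px above cytosolic mean + 2 SD, lying mostly
outside the phagosome, whose sub-pixel centroid is within 750 nm
(exact Euclidean distance to the nearest border pixel, KD-tree) of a
phagosome border. Hotspot "frequency" is reported per phagosome per
analyzed frame-set. Whether a candidate region straddling the border
counts is resolved by majority: a component more than half inside the
phagosome is not periphagosomal.

**TIRF kinetics.** Puncta per frame are components with area > 4 px above
whole-cell mean + 1 SD, recomputed per frame (holding the baseline-frame
threshold fixed is available by configuration). Cells with any punctum
above 500 nm² at frame 0 are excluded. Counts and mean areas are fitted
with `y(t) = A1 + (A2−A1)/(1+exp((t50−t)/slope))`; initialization is
A1 = min(y), A2 = max(y), t50 at the half-range crossing,
slope = (t90 − t10)/4.4, with slope bounded positive; a constant series
returns a degenerate flag instead of a fit. Note that a mean + 1 SD
threshold is only meaningful when real structure dominates within-cell
variance: on pure Gaussian noise ~16% of pixels exceed it and spurious
components appear at any noise amplitude. Image-level TIRF tests therefore
run at zero rendering noise, and noisy-fit robustness is tested in track
space (SNR 10), where median parameter errors stay below 10%.

**Lipid enrichment.** `E(t) = mean F over the phagosome at t / mean F over
the whole cell at the first analyzed frame − 1`, on background-subtracted
max projections, 1 frame/min. The "initial peak" is the global maximum of
E within 10 min of ingestion start. Window metrics are anchored
explicitly per probe: the PI(4)P window (5–25 min) to the peak, the
PI(3)P window (5–10 min) to ingestion start, and the PS metric is the
full-observation mean (the source mixes anchorings; each metric's anchor
is declared in its scenario).

**PLF index.** Per cell: pixel-wise FRET/green ratio averaged over each
phagosome's pixels, summed across the cell's phagosomes, divided by the
cell's total red fluorescence on the max projection. Pixel-wise ratio
before averaging was chosen (ratio-of-means is the configurable
alternative); zero-green pixels are excluded and a phagosome with > 50%
exclusions is flagged; a cell without phagosomes yields NaN (undefined),
never zero. The index is invariant to joint FRET+red scaling and scales
inversely with donor gain — a documented sensitivity of the assay. The
donor-independent `fret_ratio` (phagosomal FRET sum / total red) is
reported alongside.

**pH.** Per-buffer mean excitation ratios are fitted with a monotone
Boltzmann of ratio vs pH (≥ 4 buffers spanning ≥ 3 pH units; direction
auto-detected; non-monotone buffer means reject the fit). The inverse is
analytic; out-of-range ratios clamp to the calibrated range with a
warning, and every accepted fit must round-trip the buffer points within
0.1 pH units.

**Antigen.** Percent remaining = 100 × mean ingested-bead ROI intensity /
mean over all free-bead ROI pixels, on sum projections; invariant to
global illumination scaling.

## Synthetic data model

Each generator consumes a `ScenarioConfig` (seeded; identical configs give
bit-identical outputs) and returns ground truth alongside the data.
Presets encode the condition contrasts between control and knockdown as
generator truth, so the full pipelines can be asked to recover them.

*Counts.* Per-entity counts use fixed-cohort-total multinomial allocation:
the cohort total is `round(rate × n)` and events are assigned uniformly at
random. Marginal counts are binomial(T, 1/n) — indistinguishable from
Poisson at these sizes, and the empirical mean/variance match Poisson
moments within 3 SE at n = 2000 — but the cohort mean is pinned to the
configured rate, so recovery error measures the detection pipeline rather
than count-sampling noise. Structured subpopulations (the 3% very-large
contacts, the fluctuating lipid-track fraction) use exact
`round(fraction × N)` allocation for the same reason.

*EM profiles.* Circular boundaries of diameter 1.5–3 µm; contact arc
lengths are lognormal with the configured median and shape σ = 0.4 (no
distributional form is given by the source; lognormal reproduces the
printed medians with a heavy right tail), with the large-contact
subpopulation drawn uniform on [400, 600] nm. Contacts are rendered as
arcs 5–25 nm off the boundary with exactly the drawn arc length;
distractor ER arcs sit 60–300 nm away. Detected lengths therefore match
truth to sampling precision (< 2 nm).

*Ring puncta.* Gaussian puncta (σ = 2 px, truncated at 2σ) with amplitude
max(5 × noise SD, 0.2 × background) centered mid-ring, placed at
stratified angles with a ≥ 9 px minimum separation (a hard-core process:
unconstrained placement merges ~10% of puncta at the control rate, which
would bias the knockdown/control ratio; real reporter puncta counted as
discrete are resolvable by construction). Counts above the separation
capacity are clamped, with the placed count recorded as truth. Control and
knockdown rates (6.0 and 3.0 puncta/phagosome) are not printed by the
source, which reports only the ~50% contrast; the values were chosen once
as realistic per-phagosome counts.

*Hotspots.* 2×2 px blocks at max(3 × noise SD, 0.25 × background) above
background, centered 1–1.7 px outside the border (≤ 750 nm at 250 nm
pitch). The amplitude floor keeps generated hotspots detectable by the
mean + 2 SD rule at zero noise, where the literal "+3 SD" amplitude would
vanish. At the default noise the 4-px minimum area costs some recall
(~75%), identically across conditions — consistent with the observation
that hotspot frequency does not differ between them.

*Lipid tracks.* Every track shares a peak at 2 min post-ingestion (linear
rise, exponential decay with τ = 2 min) of height `lipid_peak × (1 ± 10%)`.
A fixed fraction of tracks then fluctuates (±25% sinusoid, 8-min period,
random phase) around a plateau; the rest decay to a residual of 0.02. The
plateau level is solved analytically on the measurement's own sampling
grid so that the cohort expectation of the configured window metric equals
`lipid_window_level` exactly, including the deterministic peak-tail
contribution. The fluctuating fractions (0.3 control, 0.6 knockdown) are
free parameters — the source states only that the fluctuating minority
grows — set once to reproduce the printed window contrast. Rendering
paints the phagosome disk at `F₀(1+E(t))` inside a uniform cell, so the
enrichment formula recovers E(t) up to noise; the track-space and
image-space paths agree within 5%.

*PLF stacks.* Three registered channels per cell: uniform red (acceptor)
loading at a fixed level identical across conditions (as measured), donor
green in phagosome disks, and FRET = green × v per phagosome, with v
scaled so the true per-cell index equals `plf_level`. Out-of-focus planes
carry 50%-attenuated signal so the max projection recovers the in-focus
plane.

*pH, SOCE, antigen.* Calibration image pairs follow a ground-truth
ascending Boltzmann (A1 = 0.3, A2 = 2.0, pKa = 6.3, slope = 0.8) over the
buffer series 4.0–9.0 in 0.5 steps; test phagosomes are imaged at the
scenario's true pH against cytosol at resting pH 7.2. Fura traces rise
exponentially (τ = 20 s) to baseline + `soce_peak` after Ca²⁺ re-addition.
Antigen beads are uniform disks with ingested beads at the configured
percentage of free-bead intensity.

*What the generators do not emulate:* optics (PSF, TIRF evanescent-field
physics), photobleaching, cell motility, segmentation error (ground-truth
masks are emitted and used directly — the measurement statistics, not
segmentation, are the subject), or EM texture. Passing recovery tests
therefore demonstrates correctness of the measurement pipelines under
known geometry and noise, not robustness to segmentation or optical
artifacts in real data.

## Cohort sizes and runtime

Recovery runs use 500 EM profiles, 200 ring-puncta phagosomes, 60 lipid
tracks and 40 FRET cells per arm — sizes at which Monte-Carlo error is
well below half of each tested effect, while a full reproduction run
completes in about a minute on one CPU. Bootstrap confidence intervals use
10⁴ resamples (4 × 10³ inside the test suite), seeded.

## Known limitations

- The mean + 1 SD TIRF threshold is not noise-robust on structure-free
  images (see above); it is retained for fidelity to the source procedure.
- Hotspot recall at default noise is ~75% (condition-independent); the
  size-vs-frequency distinction of hotspots under BAPTA loading is not
  modeled.
- The percentile background default is a stand-in where the source leaves
  the method unstated.
- `condition_contrast` reports descriptive summaries and bootstrap CIs;
  inferential group testing beyond the length-variance F-test is out of
  scope.
- Phagosome tracking across frames assumes static masks (synthetic
  phagosomes do not move); nearest-centroid linking would be needed for
  motile real data.
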