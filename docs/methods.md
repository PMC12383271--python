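# Methods

`phenotrack` quantifies the motility and morphology of swimming microalgae
from video microscopy and classifies each tracked cell into one of two
phenotypes of the coccolithophore *Gephyrocapsa huxleyi*: the fast,
near-spherical haploid swimmer and the slow, elongated, directionally
persistent amoeboid morphotype.  Every stage can be exercised against a
synthetic scene generator with known ground truth, so the pipeline is
verifiable by parameter recovery without any external data.

## Motility model

Trajectories are modeled as two-dimensional rotational diffusion with
constant per-cell speed.  The heading angle θ performs a Brownian walk,

    dθ = sqrt(2 dt / τ_c) ξ,    ξ ~ N(0, 1),

and the position advances by v·dt along the heading.  This is the simplest
generative model whose directional correlation

    C(τ) = ⟨cos(θ(t+τ) − θ(t))⟩ = exp(−τ / τ_c)

is a single exponential, matching what the analysis fits.  Per-cell speeds
are drawn once per track from a normal truncated at zero; speed does not
fluctuate within a track, because the phenotype presets carry
population-level speed SDs, not within-track variability.

Preset parameters (defaults of the generator, all configurable):

| parameter | haploid | amoeboid | units |
|---|---|---|---|
| mean speed | 26.3 | 7.1 | µm/s |
| speed SD (population) | 5.6 | 0.3 | µm/s |
| persistence time τ_c | 2.8 | 7.2 | s |
| body eccentricity ε (moment) | 0.10 | 0.943 (3:1 axes) | – |
| body length | 4.5 | 9.0 | µm |

The time step must satisfy dt ≤ 0.2 τ_c, otherwise the heading walk is
under-resolved and a `ResolutionError` is raised.  Randomness uses one root
seed with per-cell child streams spawned in cell order
(`numpy.random.SeedSequence`), so output is reproducible bit-for-bit and any
one cell can be re-simulated in isolation.

## Shape-transition model

The haploid→amoeboid metamorphosis is modeled as a saturating exponential in
the eccentricity,

    ε(t) = ε_final − (ε_final − ε_start) · exp(−t / τ_shape),

with τ_shape = 15 min, ε_start = 0.10, ε_final = 0.94 and additive Gaussian
noise (SD 0.05) by default, clipped into [0, 1).  `fit_shape_transition`
recovers the three parameters by bounded nonlinear least squares with the
time origin at the first analyzed frame; a series whose range is below the
noise floor (default 0.02) carries no timescale information and is returned
non-converged rather than with an arbitrary τ.

## Rendering

Cells are rendered as elliptical Gaussian intensity blobs — bright on a dark
background, i.e. the magnitude image that temporal-median background
subtraction produces from phase-contrast video.  The blob axis ratio is set
by the instantaneous moment eccentricity and the long axis follows the
heading, so segmentation plus moment analysis of a rendered cell recovers
the ground-truth ε.  The default pixel scale is 0.65 µm/px (10× objective
with 6.5 µm camera pixels) and the default frame rate 25 fps.  A clip can be
specified by duration (frame count = round(duration·fps)) or by an explicit
frame count, in which case the frame count is authoritative and the
effective duration is frames/fps; both values are recorded in the scene
config.  Cells that swim out of the field of view are truncated, not
reflected, as in real imaging.  Frames are rendered one at a time so long
clips do not exhaust memory.

An optional `wobble_amplitude` adds a periodic apparent-eccentricity
modulation emulating the body rotation ("wriggling") of the amoeboid phase;
it defaults to 0 so that ground-truth shape is constant unless requested.

## Tracking

1. **Background removal** — per-pixel absolute difference from the temporal
   median over the full clip.  Static structure cancels exactly; only moving
   cells survive.  Slow cells linger within their own footprint and leave a
   faint residue in the median; on defaults this perturbs localization by
   ≲0.2 px and inflates near-zero eccentricities by up to ~0.1 (it is the
   dominant error for the slow phenotype; it does not affect classification,
   where speed separates the phenotypes long before the ε threshold
   matters).
2. **Detection** — band-pass (Gaussian smoothing minus a uniform local
   background at the 17-px feature diameter), local maxima above a
   threshold, sub-pixel refinement by intensity-weighted centroid inside the
   feature footprint, then minimum-separation suppression (51 px) keeping
   the brighter of any close pair; equal brightness breaks ties toward lower
   (y, x).  The threshold is the larger of the 99.5th intensity percentile
   and 6× a robust (MAD-based) noise scale of the unclipped band-pass
   residual; the percentile alone fails on sparse scenes, where cells cover
   far less than 0.5% of the frame.
3. **Linking** — per-frame optimal assignment (Hungarian algorithm) on
   squared displacement, with links valid only below 17 px per elapsed
   frame; a track missing for more than 2 consecutive frames is terminated.
4. **Filtering** — tracks with fewer than 10 detections are discarded.

Coordinates are 0-based frames, x = column, y = row, at pixel centers.

## Motility statistics

Speeds are frame-to-frame displacements over the true elapsed time (bridged
gaps use the actual gap duration), converted to µm/s and boxcar-averaged
over five frames (centered, ends truncated).  For persistence analysis,
positions are first smoothed with a second-order Savitzky–Golay filter
(five-frame window; endpoints evaluate the quadratic fitted to the nearest
full window), headings are taken from consecutive displacement vectors and
unwrapped, and C(τ) = ⟨cos Δθ⟩ is fitted with exp(−τ/τ_c) over lags up to
min(track duration/2, 15 s).  A literal autocorrelation of the raw angle
series is available as a comparison mode (`mode="raw_angle"`); it is not
exponential under rotational diffusion and is origin-dependent, so the
directional correlation is the default.  An additive-offset fit term is
available but off by default.

**Aggregation.**  Mean speed: per-track means → replicate means → grand mean
with SEM across replicates (never across tracks).  Persistence time:
per-track fits → per-replicate **median** → mean across replicates.  The
median is used deliberately: single-track exponential fits are strongly
right-skewed (an upward-fluctuating correlation tail can fit an arbitrarily
long time while the fit is bounded below by zero), so the per-replicate mean
overestimates τ_c by 40–55% under the default study conditions, while the
median is accurate to a few percent (measured at τ_c = 2.8 s and 7.2 s over
multiple seeds).  Per-track fits are reported in the summary table so any
other aggregation can be recomputed.

Straight tracks whose correlation never leaves 1 are flagged with infinite
persistence and excluded from averages with a logged count.

## Shape measurement

Cells are segmented by Otsu thresholding of a local window (3× the feature
size) around each detection, keeping the connected component containing the
detection.  Eccentricity comes from the second central moments of the
segmented cell.  The default metric is the moment eccentricity
ε = sqrt(1 − (b/a)²) (0 for a sphere, 0.943 for 3:1 axes); elongation
(1 − b/a) and axis-ratio deficit ((a−b)/(a+b)) are selectable, the raw axes
are always returned, and the metric name is recorded in every output so
thresholds are interpreted against the configured metric.  Note that the
0.2 classification threshold is permissive under the moment metric and
strict under elongation.

Two numerical choices matter near ε = 0, where the metric has an infinite
derivative in the axis ratio:

- moments are intensity-weighted within the segmented region rather than
  computed on the binary mask (mask-boundary pixelation alone injects ~1%
  axis anisotropy, which the square root amplifies to ~0.15 spurious ε);
- the mask is dilated by 6 px before weighting so the region boundary falls
  in the faint tail of the intensity profile rather than at ~30% of peak.

Otsu on a mostly-empty window thresholds near 29% of the blob peak (not
half-maximum), so masks are ~1.8× the half-max footprint; this is
intentional — the threshold is parameter-free — and harmless given the
weighted moments.

## Classification

A track is **amoeboid** if mean speed ≤ 8 µm/s *and* ε ≥ 0.2 (both
inclusive, as stated); **non-motile** if mean speed < 2 µm/s (the motility
floor separating swimmers from immotile or drifting cells — a choice this
package makes explicit and configurable); otherwise **non-amoeboid motile**.
The headline statistic is the amoeboid fraction among motile tracks
(non-motile excluded from the denominator), aggregated per replicate with
SEM across replicates.  Treatment values can be normalized against a control
group by ratio (default) or difference; the mode is recorded in the output.
Whether the per-track ε entering the rule is the mean or the maximum over
frames is configurable (mean by default).

## Assay formulas

- MATH hydrophobicity: (A₀ − A₁)/A₀ × 100 from aqueous-layer counts.
- PAM photophysiology: Fv/Fm = (Fm − F0)/Fm, φ = (Fm′ − F)/Fm′,
  rETR = PAR × φ; rapid light curves require strictly increasing PAR.
- Population metrics: percent change ((N_start − N_end)/N_start × 100,
  positive = decline), fold change (N_end/N_start, flagged infinite when
  N_start = 0) and fraction of the total algal population (haploid +
  amoeboid by default; bacteria excluded, denominator configurable).  Raw
  values are stored alongside display-rounded companions; rounding never
  alters the raw fields.

The count generator pairs an exponential haploid decline with a saturating
amoeboid rise; defaults reproduce a 1.4×10⁶ → 1×10⁵ cells/ml crash over
three days alongside a 7×10² → 2.5×10⁴ cells/ml (≈36-fold) rise.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
exponential directional decorrelation, per-cell speed heterogeneity,
saturating shape transitions, Gaussian cell images on a static background
with additive camera noise, and Poisson-disc-style initial placement.  It
does **not** emulate hydrodynamics, cell–cell interactions, flagellar beat,
3-D motion, out-of-focus blur, illumination flicker or debris.  Passing
recovery tests therefore demonstrates that the estimators are correct for
the assumed model at realistic noise levels — not that the model captures
every artifact of real video.

## Problem sizes and test design

The recovery suites use 8 replicates × 50 tracks of 30 s at dt = 0.04 s per
phenotype, 100 noisy shape series (45 min sampled every 30 s), and one
rendered 600-frame 768×768 px mixed scene with 3 amoeboid + 5 haploid
cells — sizes at which the estimator SEs are several times smaller than the
test tolerances.  The end-to-end check compares the recovered amoeboid
fraction among motile tracks with the injected fraction within the binomial
95% CI of the recovered count; track-level fractions slightly undercount the
fast phenotype's cells when they exit the field of view and fragment, which
is inherent to track-based statistics and stays well inside the CI at these
sizes.

## Known limitations

- Temporal-median ghosting biases shape and position estimates of cells
  that move less than their own body length over the clip; use longer clips
  or report ε from well-separated frames for very slow cells.
- Per-track persistence fits need ≥ 20 heading samples and tracks several
  times longer than τ_c; at 30 s tracks the median estimator is accurate to
  ~5% for τ_c ≤ 8 s and degrades toward ~15% by τ_c ≈ 12 s.
- The linker resolves crossings by assignment cost only; prolonged
  encounters closer than the 51-px suppression radius merge detections and
  can split or swap identities.
- No drift correction, no 3-D linking, no multi-channel handling.
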