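# Methods

`nanocoloc` quantifies nanoparticle uptake by cells from two-channel
fluorescence images. The measurement principle: cells are stained with a
nuclear dye (DAPI channel) and incubated with fluorescent nanoparticles
(TRITC channel); if a cell population adheres and internalizes particles,
particle fluorescence co-occurs spatially with the cellular signal, and the
degree of co-occurrence — colocalization — acts as a per-image proxy for
per-cell particle load. The package provides (i) a synthetic image generator
with full ground truth, (ii) nuclei counting and field-of-view (FOV) quality
control, (iii) per-FOV colocalization statistics, and (iv) condition-level
aggregation and significance testing.

## Colocalization statistics

All statistics are computed over the full FOV, with no cell mask and no
intensity threshold. The nuclei channel is a cell-position proxy; no claim
about subcellular compartments is made.

Let x_i be the particle-channel and y_i the nuclei-channel intensity of
pixel i (raw integer ADU, double-precision accumulation):

* **Pearson coefficient** r = Σ(x−x̄)(y−ȳ) / √(Σ(x−x̄)² Σ(y−ȳ)²) — the
  primary statistic, reported per FOV and aggregated per condition.
* **Overlap coefficient (Manders' R)** = Σxy / √(Σx² Σy²); insensitive to
  mean offsets.
* **Scatter fit**: ordinary least-squares slope and intercept of particle
  intensity regressed on nuclei intensity.
* **Section cross-correlation (CC)**: the raster is divided into n equal
  sections (default n = 100, as a 10×10 grid of equal tiles; the image is
  center-cropped to the largest multiple of the grid size, identically in
  both channels). With per-section intensity sums x_k, y_k,

      CC = [nΣxy − ΣxΣy] / √([nΣx² − (Σx)²][nΣy² − (Σy)²]),

  which is algebraically the Pearson correlation of the two section-sum
  vectors (asserted to 1e−12 in the tests). CC serves as a coarse-scale
  confirmation of the pixel-level Pearson coefficient. Whether the original
  sectioning was a 10×10 grid or strips is not documented anywhere we could
  rely on; the square grid is our choice.

Degenerate inputs are explicit errors, not NaNs: a constant channel has no
Pearson correlation or OLS fit, an all-zero channel no overlap coefficient,
and a constant section vector no CC (`UndefinedStatisticError`, distinct
from shape/precondition `ValidationError`s).

An optional constant background subtraction exists (`background_subtract`)
but defaults to 0: raw intensities are the documented behavior, and no pixel
(e.g. saturated) is excluded by default.

## Synthetic data generator

The generator emulates a high-content plate-imaging experiment: three cell
phenotypes — high-metastatic (HM), low-metastatic (LM) and benign — dosed
with ~2000 particles/cell of 100 nm or 200 nm carboxylate-modified
fluorospheres for a short incubation, washed, and imaged at one FOV scale.
It is first-class, tested code: every downstream stage is validated against
its ground truth.

**Geometry.** Cells are disks (radius 8–15 µm uniform) with concentric disk
nuclei (nucleus/cell radius ratio 0.5), centers uniform over the FOV,
rejection-sampled so that nucleus disks keep ≥5 px clearance (cells may
overlap; nuclei stay individually resolvable under the imaging blur, which
is what "non-overlapping" must mean for a counting oracle). Cells per FOV ~
round(Normal(20, 10)) clipped at 0. The default raster is 256×256 px at
1.4 µm/px ≈ 0.128 mm², the FOV area of the emulated instrument; this is a
coarser sampling than the physical camera (which is not documented for the
emulated system) — all statistics are sampling-rate agnostic, and the
coarse grid keeps simulation cheap.

**Particles.** Per-cell particle counts are Poisson with mean
`particles_per_cell_mean × base_uptake_rate × multiplier(phenotype) ×
factor(temperature)`, scaled by a per-FOV lognormal heterogeneity (CV 0.3).
Default multipliers HM:LM:benign = 2.5:1.3:0.1 encode the phenotype uptake
ordering; the 4 °C factor is 0.02 (endocytosis is energy-dependent and
essentially abolished in the cold). Each particle is **internalized**
(placed inside the cell with area density ∝ (r/R)^3 — uptake concentrates
near the cell edge), **adhered** (annulus at 0.85–0.97 R, i.e. on the cell
surface and inside the footprint), or **free** (uniform over the FOV).
Default status fractions are size-specific: 100 nm particles barely adhere
(adhered fraction 0), 200 nm particles adhere firmly (0.3). FOVs of the
particles-without-cells control plant Poisson(500) free particles.

**Washes** act on the ground truth before rendering: trypsin removes adhered
and free particles (it digests the surface proteins trapping particles),
PBS removes free particles only; both leave a 5% carryover of free
particles. `none` is the identity.

**Rendering.** Particles are point emitters (per-particle lognormal
brightness, mean 70 ADU for 100 nm, 110 ADU for 200 nm — the larger sphere
carries more dye) deposited bilinearly; nuclei are disks (3000 ADU ± 15%)
plus a diffuse whole-cell component at 30% of the nuclear amplitude
(cytoplasmic dye background and out-of-focus light of a widefield system).
Both canvases are convolved with a Gaussian PSF (σ = 1 µm). The particle
channel additionally receives 0.25% of the blurred nuclei channel —
spectral bleed-through of the bright nuclear stain. Expected intensities
are modulated by a shared illumination profile: a fixed 5% radial vignette
times a per-FOV smooth random field with half-normal amplitude (rel. SD
0.05), common to both channels. Finally Poisson shot noise, Gaussian read
noise (SD 10 ADU), rounding, and clipping to the 16-bit range.

**Why the background mechanisms matter.** In the emulated experiment the
two control classes (particles without cells; cells without particles) show
a *nonzero and mutually indistinguishable* background colocalization, which
is pooled and used as the normalization denominator — uptake conditions
land at only ~2–2.5× that background. Planted particles alone cannot
produce this: both controls would sit at r ≈ 0 and any nonzero benign
uptake would be trivially detectable at n > 100 FOVs. The two mechanisms
that generate realistic background are channel-shared illumination
structure (dominates the particles-only control) and nuclear-stain
bleed-through (dominates the cells-only control). Their default strengths
were calibrated jointly so the two control classes match — a property of
the emulated experiment, not a free dial.

**Why dim-dense rather than few-bright particles.** With sparse bright
spots the pixel-level Pearson coefficient saturates at the spatial
pattern-correlation asymptote; adding adhered (boundary-ring) particles
then *lowers* r, because ring pixels carry less nuclei-channel signal per
unit particle variance — inverting the wash contrast the generator must
reproduce (PBS retains adhered 200 nm particles, so PBS-washed FOVs
colocalize more than trypsin-washed ones). In the dim-dense default regime
the particle channel stays noise-limited and Pearson rises monotonically
with co-located signal, restoring the contrast. `base_uptake_rate` 0.016 of
the 2000/cell dose gives ~80 associated particles per unit-multiplier cell.

**Determinism.** A `(config, seed)` pair reproduces bit-identical rasters
and ground truth. Experiment batches derive per-FOV seeds (< 2³¹) from a
master seed via a dedicated PCG64 stream.

**What the generator does not emulate** — hence what passing tests do not
show about real data: cell shape and confluency structure (disks only),
3D/Z-stacks, photobleaching, transmitted light, spot-width differences
between particle sizes (both are sub-resolution; size enters only through
uptake/adhesion/brightness), colony-edge effects in benign cells, real
instrument vignetting/PSF profiles, and expert-judged image artifacts. The
headline recoveries (phenotype ordering, wash contrast) demonstrate that
the *pipeline* detects planted effects of realistic size, not that the
planted effect sizes equal the real ones. In particular, default fold
ratios between HM and LM land near 1.3 (the emulated study reported up to
~2.2) and LM's section-CC level sits above the reported 0.2–0.4 band:
tile-level statistics saturate sooner in the simulation than in the real
images.

## Segmentation and quality control

Nuclei counting: Gaussian smoothing (σ = 1 px), global Otsu threshold, a
foreground/background contrast guard (≥4 background SDs, so noise-only
rasters return zero nuclei rather than speckle), hole filling, 8-connected
components, area filter (defaults 8–400 px). Constant rasters return zero
nuclei, not an error.

FOV inclusion rules: (i) ≥5 cells ("more than four"), bypassed for the
no-cell control; (ii) particle-channel saturation fraction ≤1% (proxy for
overexposure artifacts); (iii) variance-of-Laplacian focus score of the
nuclei channel ≥50 (proxy for focal-depth artifacts). The latter two
operationalize artifact classes that were originally excluded by expert
inspection without a stated criterion; thresholds are configurable, and
every FOV gets a report with explicit rejection codes.

## Statistics

The analysis unit is the FOV. Per condition: mean, SEM (= SD/√n; SEM is the
reported dispersion), median, and a D'Agostino–Pearson omnibus normality
p-value (NaN for n < 8 or degenerate values). The two control classes are
compared by a Welch t-test and pooled when p ≥ α (default 0.05); on refusal
both groups are reported separately with the p-value. Condition means are
normalized to the pooled control mean (control ≡ 1), with first-order
error propagation for the ratio of independent means. Fold differences
between conditions are ratios of mean Pearson coefficients. Significance:
global one-way ANOVA, then all pairwise Welch t-tests with Bonferroni
adjustment. The original analysis names a "general linear mixed model"
without a recoverable random-effect structure; ANOVA + pairwise Welch +
Bonferroni is the assumption-light, reproducible stand-in, and the
replicate id is retained in the data model so a mixed model can be slotted
in later. Under a simulated global null the family-wise false-positive
rate stays at the nominal level (≤0.07 asserted over 500 replicates).

## Numerical choices

* Double-precision accumulation everywhere; numpy pairwise summation
  stabilizes the CC formula's cancellation.
* 0-based (row, col) pixel coordinates, pixel centers at integers.
* Center crop for sectioning discards ⌊rem/2⌋ leading and ⌈rem/2⌉ trailing
  rows/columns.
* Welch tests throughout (no equal-variance assumption); identical groups
  short-circuit to p = 1 rather than 0/0.
* Cell placement retries 200× per cell before raising a placement error
  naming the failing cell.

## Problem sizes

Default test and acceptance runs use 110–130 FOVs per condition at 256×256
px — the per-condition FOV count of the emulated design at a reduced raster
— and 500 replicate experiments for the null calibration. A full two-size
acceptance run (18 conditions, 2340 FOVs) completes in about 1–2 minutes on
one CPU.
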