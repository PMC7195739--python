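# Methods

This note documents the models implemented in `coxpet`, their
assumptions, the numerical choices behind them, and what the synthetic
data generators do and do not emulate. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Kinetic forward model

Tissue kinetics follow the reversible two-tissue compartment model

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2,

driven by the metabolite-corrected parent plasma concentration `Cp(t)`.
`K1` (mL cm⁻³ min⁻¹) is delivery, `k2` (min⁻¹) efflux, `k3`/`k4`
(min⁻¹) exchange with the specifically bound pool. The total
distribution volume is

    V_T = (K1/k2) * (1 + k3/k4),

reducing to `K1/k2` for the one-tissue case (`k3 = 0`). `K1 = 0` is
allowed and yields an identically zero tissue curve (no delivery). All
concentrations are assumed decay-corrected to injection time; no
radioactive-decay term is modeled anywhere, which is consistent with
reporting SUV and V_T.

The measured PET signal optionally mixes in fractional blood volume:
`(1 − vB)·C_tissue + vB·C_wholeblood`. `vB` defaults to 0 — whether the
original regional curves were blood-volume corrected is not stated in
the source methods, so the term is exposed as a parameter rather than
assumed.

**Numerics.** The convolution of the input with the compartmental
impulse response (closed-form mono-/bi-exponential) is evaluated by
trapezoidal quadrature on a 0.1-min grid; frames are sampled by their
within-frame mean of that fine grid. Quadrature error at this
resolution is well below 1% for all parameter ranges exercised.

**Blocking.** A blocking condition at occupancy `o` maps
`V_T → V_ND + (1 − o)(V_T − V_ND)`, implemented by rescaling `k3`
(the specific-binding step) with `K1`, `k2`, `k4` unchanged. Regions
whose total V_T sits below the shared V_ND (low local nonspecific
uptake, as seen in necrotic lesions) are representable in the demo by a
reduced region-specific `K1/k2`.

## Arterial input model

The parent curve is a peaked tri-exponential — two decaying terms and
one shared rising term:

    Cp(t) = A_f e^(−λ_f t) + A_s e^(−λ_s t) − (A_f + A_s) e^(−λ_r t),

with `λ_r > λ_f, λ_s`, so the curve starts at zero, peaks within the
first ~1 min, and decays; defaults (`A_f = 30`, `A_s = 1.5` kBq/mL,
`λ_f = 0.4`, `λ_s = 0.0015`, `λ_r = 3.0` min⁻¹) give a ~20 kBq/mL peak
and a slowly decaying tail so that late-scan tissue/plasma ratios
approach the equilibrium V_T on a 120-min scan. The source study
measures rather than models its input; this form is generator plumbing
chosen for having a closed form and a single early peak.

**Parent fraction.** The metabolite model is a plateau-exponential
`pf(t) = (1 − c)e^(−λt) + c`, `0 ≤ c ≤ 1`: monotone non-increasing,
equal to 1 at injection, two parameters. It is fit to measured
fractions by bounded least squares (`scipy.optimize.curve_fit`); the
functional form used for the original monkeys is not stated, so this is
a documented, swappable default. The input function is built as
`plasma(t)·pf(t)` at sample times with linear interpolation between
samples (splines overshoot on the sparse late schedule) and a linear
run from (0, 0) before the first sample. Plasma free fraction is
carried as metadata only. Sampling default: 15-s draws for the first
120 s, then 3, 5, 10, 30, 60, 90, 120 min.

**Frame noise.** Optional zero-mean Gaussian noise with
`SD = coefficient · value / sqrt(frame duration)`, mimicking
count-statistics scaling without modeling decay. Seeds are explicit
arguments; there is no hidden global random state.

## Logan graphical analysis

With `x(t) = ∫₀ᵗ Cp / C_tissue(t)` and `y(t) = ∫₀ᵗ C_tissue /
C_tissue(t)`, reversible kinetics become linear for `t ≥ t*` and the
slope is V_T. Choices:

- Frame time is the frame midpoint. Both integrals are accumulated by
  trapezoid on the grid `[0, mid₁, …, midₙ]` with the input resampled to
  midpoints; using the same quadrature for numerator and denominator
  makes a TAC exactly proportional to the input yield slope = V, zero
  intercept and r² = 1 identically.
- The fit is unweighted OLS (`scipy.stats.linregress`); the weighting
  used by the original commercial package is unreported.
- `t*` default is 30 min. The automatic rule (`select_t_star`) fits a
  reference line to the final third of the Logan points and returns the
  earliest midpoint after which all later points deviate by at most 10%
  relative, falling back to mid-scan with a warning.
- Non-positive tissue values inside the fit window and windows with
  fewer than three frames are rejected with the offending frame named.

**Known bias.** Logan on noise-free reversible data underestimates V_T
when the slowest tissue eigenvalue has not equilibrated by `t*`. For
the reference parameters (K1 = 0.1, k2 = 0.1, k3 = 0.05, k4 = 0.05;
V_T = 2) the error at `t* = 30` on a 120-min scan is < 0.3%. At the
slow-dissociation extreme (k3/k4 = 5 with k4 = 0.02 min⁻¹) the slowest
eigenvalue's time constant (~164 min) exceeds the scan and the bias is
~3.5%, shrinking monotonically with later `t*`. This is intrinsic to
the graphical method at finite scan length, so the test suite asserts
the underestimate-or-match property everywhere and the 2% accuracy
bound for kinetics that equilibrate within the scan
(slowest eigenvalue × scan length ≥ 2).

## SUV measures

SUV = mean concentration over the window (duration-weighted across
frames, partial overlaps pro-rated) divided by injected dose per gram
of body weight, under the 1 mL ≡ 1 g convention (no density
correction). Specific uptake without arterial data is the drop of the
brain/blood SUV ratio between baseline and self-blocked conditions over
60–90 min.

## Lassen occupancy plot

Regressing `y = V_T(baseline) − V_T(blocked)` on `x = V_T(baseline)`
across regions gives occupancy as the slope and V_ND as the x-intercept
(`−intercept/slope`). Assumptions: V_ND uniform across regions and
occupancy uniform across regions; violations bend the plot. The
quality gate marks a fit unreliable when `r² < 0.5` or the slope is
non-positive — operationalizing the narrative rejection of plots whose
point clouds do not support a straight line; the threshold is
config-exposed. The slope p-value is the standard two-sided t test on
an OLS slope. The same construction on SUV instead of V_T is provided
as an explicitly flagged surrogate: it is valid only insofar as SUV is
proportional to V_T across regions, which cannot be checked without
arterial data. Occupancy is a fraction internally and a percentage at
presentation.

## Outcome arithmetic and presentation rounding

`bp_nd`, `percent_change`, `group_mean` and `rl_ratio` are exact
formulas; rounding happens only at presentation, with half-up rounding
(`present`), the convention under which the mean of 3.71 and 3.48
prints as 3.60.

Two printed values are *not* reproducible from their printed inputs and
are deliberately not forced: a 42% V_T rise whose printed inputs
(3.76 → 5.32) give 41.5% (presents as 41), and a binding potential
printed as 0.21 where the printed inputs (5.32, 4.3) give
(V_T − V_ND)/V_ND = 0.237. Both are consistent with the source having
used unrounded values; the worked-examples table flags them instead of
adjusting them.

## Synthetic FISH scenes

Each scene is a three-channel 16-bit image (DAPI, Cy3 = Cox2,
Cy5 = Eno2) with full ground truth:

- **Nuclei** are rotated ellipses (radius 3.5 ± 0.25 µm, clipped at
  −2/+3 SD so every nucleus clears the 20 µm² area filter), placed by
  rejection sampling with an in-frame margin; a configurable fraction
  (default 25%) is placed as touching pairs at 0.85× the summed radii
  to exercise watershed splitting.
- **Dots** are Gaussian blobs (σ = 1.0 px at 0.31 µm/px — close to a
  diffraction-limited dot at this sampling; peak amplitude =
  SNR × noise SD, default 10 × 10 counts over a 100-count background)
  placed uniformly inside the nucleus with a 6-px minimum separation
  between all dots of a cell across both channels. Crowded cells relax
  the separation gradually (6 → 4 → 3 px) rather than ever stacking
  dots. The separation keeps two dots from bridging above the
  detection threshold in sparse scenes and keeps within-cell
  cross-channel coincidences above the 2-px autofluorescence tolerance.
- **Per-cell counts** are Poisson. Under the default `neuron_weighted`
  coexpression model a neuron subpopulation (60%) carries the Eno2
  signal (λ = 6 vs 0.2 background) and the Cox2 rate is reweighted
  between neurons and non-neurons — preserving the marginal mean — so
  that the *expected* Cox2⁺∩Eno2⁺/Cox2⁺ fraction equals a direct
  parameter (default 0.75). The achievable colocalization range is
  bounded (an almost-universally-expressing channel cannot colocalize
  at 0.75 with a 60% subpopulation); out-of-range targets clamp with a
  warning. An `independent` model (plain Poisson in each channel) is
  also provided and is used by the fold-change scenarios.
- **Autofluorescence**: blobs rendered at *identical* coordinates in
  Cy3 and Cy5 (σ 1.5×, amplitude 1.1× a dot) — the artifact signature
  the cross-channel exclusion removes.

**What the generator does not emulate**: optics beyond Gaussian blobs
(no PSF tails, no chromatic offset between channels), intensity
variation across the field (no vignetting or uneven illumination),
tissue autofluorescence textures, 3-D structure/stacks, photobleaching,
or segmentation-hostile chromatin texture inside nuclei. Passing the
recovery tests therefore shows the pipeline's logic is correct and
well-calibrated for resolvable dots at SNR ~10; it does not certify
performance on real tissue scans.

**Fold-change scenarios.** Control/treated parameter pairs are
calibrated by solving `P(N ≥ 2) = target` for λ so the *expected*
expressing-fraction ratio is exactly 6 (0.13 → 0.78) or 20
(0.048 → 0.96). These mirror the induction magnitudes the pipeline is
meant to resolve; they are synthetic anchors, not reproductions of the
tissue data (no images were deposited). Scenario scenes use the
independent coexpression model — the colocalization constraint caps the
achievable expressing fraction near 0.79, which the 20-fold treated
condition must exceed.

## Quantification pipeline

Deterministic throughout (all randomness lives in the generator):

1. **Segmentation** — Gaussian smoothing (σ = 1 px), Otsu threshold,
   hole filling, debris removal. A foreground/background contrast gate
   (Otsu class separation ≥ 4 background SDs) treats unstained or empty
   fields as containing no cells rather than thresholding noise.
   Components flagged as clusters (area > 1.5× the median component
   area, or solidity < 0.92) are split by watershed on the smoothed
   distance transform with peaks at least 0.8× a typical nucleus radius
   apart. Masks outside the area bounds are dropped — default
   (20 µm², ∞): the literal reading of the source's size rule (exclude
   > 20 µm²) would discard essentially all real nuclei, so the bound's
   direction is configurable and the literal reading remains available
   as (0, 20 µm²). Edge-touching masks are removed. Survivors are
   dilated by 2 µm into search regions; contested pixels go to the
   nearest nucleus centroid (the source is silent on ties), and core
   pixels always stay with their own nucleus.
2. **Spot detection** — threshold = median + 2 SD of the pixel
   population over the union of search regions (config-switchable to
   the whole image); above-threshold 4-connected components are
   candidates; components outside [4, 50] px are discarded; survivors
   are assigned to the search region containing their centroid.
   A constant image (SD = 0) yields zero spots with a logged note.
   The size minimum of 4 px is the noise rejection the source
   attributes to its "size criteria": in a sparse channel the
   median + 2 SD threshold sits at ~2σ of pure background noise, which
   produces abundant 1–3-px components, while rendered dots are ≥ 5 px
   (size histograms show a clean gap); both bounds are config-exposed.
3. **Autofluorescence exclusion** — greedy nearest-pair matching of Cy3
   vs Cy5 centroids within 2 px (the "overlapped spatially" tolerance
   is not quantified at source); each spot is removable at most once;
   ties at equal distance break on the lower spot index.
4. **Scoring** — a cell expresses a channel at ≥ 2 dots in its search
   region. Summaries report expressing fractions, colocalization
   (Cox2⁺∩Eno2⁺/Cox2⁺, missing when no cell is Cox2⁺), and fold change
   against a reference result. Counts are pooled across images
   (per-image means can be formed from per-image results).

## Problem sizes and recovery performance

The recovery study (`workbench.fish_recovery_study`, also run by
`scripts/acceptance.py`) uses 20 scenes: 6 default-coexpression scenes
(384², 80 nuclei) for colocalization and per-cell classification, plus
3 + 3 six-fold and 4 + 4 twenty-fold scenario scenes (1024², 700
nuclei). Scenario scenes are sized so a pooled condition holds a few
thousand cells — as a real per-area quantification does — because the
control expressing fraction (0.048 in the 20-fold scenario) otherwise
carries ~10% relative sampling SD, which would dominate the fold
estimate. With these sizes the suite verifies per-channel cell
classification sensitivity and specificity ≥ 0.9 (observed ≈ 0.99),
colocalization within ±0.08 of the 0.75 parameter, and both fold
changes within ±25% relative.

The kinetic recovery scenario simulates six regions with elevated V_T
spread over 3.5–6.5 mL cm⁻³ sharing V_ND = 4.3 mL cm⁻³, blocked at
occupancy 0.78; Logan fits on both conditions followed by the Lassen
plot recover occupancy within ±0.03 and V_ND within ±0.15 noise-free,
and the 100-replicate median occupancy stays within ±0.05 under
per-region V_T noise of SD 0.3 mL cm⁻³.

## Known limitations

- No dispersion/delay correction of the arterial line; no HPLC-level
  metabolite processing; no compartmental NLS fitting of K1…k4; no
  reference-tissue models or voxelwise parametric imaging.
- The Lassen plot assumes region-uniform V_ND and occupancy; the
  quality gate detects gross violations but cannot diagnose their
  cause.
- The SUV-surrogate occupancy inherits every caveat of SUV ∝ V_T.
- FISH quantification is 2-D and single-plane; the 3-plex positive
  control probes, slide stitching, and histology/immunofluorescence
  workflows are out of scope.
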