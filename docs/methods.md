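# Methods

This note documents the models implemented in `lysoquant`, the defaults of
the synthetic-data generators, the numerical choices, and what the
closed-loop validation does and does not demonstrate.

## Single-lysosome emission pipeline

### Spectral model and fit

Emission spectra are modeled as a five-parameter Weibull peak

    f(λ) = y0 + a · (u/k)^(c−1) · exp(k^c − u^c),
    u = (λ − x0)/b + k,   k = ((c−1)/c)^(1/c),   f = y0 for u ≤ 0,

with baseline `y0` (a.u.), amplitude `a > 0` (a.u.), peak position `x0`
(nm), width `b > 0` (nm) and shape `c > 1`. This peak-normalized
parameterization satisfies the identity `f(x0) = y0 + a`, which doubles as a
fit sanity check. Several five-parameter "Weibull peak" forms circulate in
curve-fitting software; this one was chosen for its testable identity and
interpretable amplitude, and no claim is made that other software uses the
identical algebraic arrangement.

Fitting is nonlinear least squares (Levenberg–Marquardt) on an
unconstrained re-parameterization `a = exp(α)`, `b = exp(β)`,
`c = 1 + exp(γ)`, which enforces the positivity/shape constraints smoothly
and runs an order of magnitude faster than bounded trust-region iterations
at identical accuracy. Initialization is multi-start: `x0` at the argmax
sample, `b` at half the spectral span, `y0` at the minimum intensity, `a`
at the intensity range, and `c ∈ {1.5, 2.2, 3.0}`; the lowest residual sum
of squares wins, and a `converged` flag plus the RSS are reported. Flat
spectra raise a "no peak" error; a spectrum needs at least 8 samples for a
5-parameter fit.

### Ratio and calibration

The pH readout is the fitted-curve ratio `R = f(470)/f(524)`. Calibration
standards (lysosomes clamped to known pH with monensin/nigericin, default
levels 4.0/4.5/5.0/5.5) are pushed through the same fit-and-ratio pipeline,
and an ordinary-least-squares line `R = m·pH + q` is fitted. The fit is
rejected as "not invertible" if the standard ratios are not strictly
monotone in pH, and as "underdetermined" with fewer than two distinct
levels. Inversion `pH = (R − q)/m` clamps estimates to the calibrated range
(default 4.0–5.5) with a `clamped` flag; a 1e-6 tolerance keeps exact
boundary hits (a standard's own ratio) from being flagged. Clamping mirrors
the behaviour of ratiometric probes at the edge of their dynamic range.

### Distributions and classification

Per-lysosome pH values are histogrammed in 0.1-unit bins anchored at pH 4.0
(bin edges at 4.0, 4.1, ...), separately per condition and ApoD class; the
reported mode is the center of the most populated bin, with ties broken
toward lower pH. ApoD classification thresholds the mean immunofluorescence
intensity within each lysosome ROI. The histograms pool lysosomes across
cells; per-cell weighting is not implemented.

## Population excitation pipeline

Whole-well lysosomal pH uses the LysoSensor excitation ratio F340/F390
(535 nm emission). The six replicate readings per well are averaged per
wavelength before forming the ratio (ratio of means, not mean of ratios,
matching how plate readers integrate light). Inversion goes through
monotone piecewise-linear interpolation of the clamp standards (default pH
4.0–6.0 in 0.5 steps) rather than a parametric sigmoid: interpolation makes
no shape assumption and is exact wherever the true dye response is locally
linear. Out-of-range ratios clamp with a flag. The excitation wavelength
pair 340/390 nm is used throughout.

## Colocalization

Both channels are smoothed with a Gaussian (σ = 1 voxel by default) and
thresholded per channel (Otsu by default; manual values accepted — the
original acquisition-time LUT thresholds of a microscope session are not
reproducible offline). Stacks are treated as single 3D volumes, not
slice-wise.

*ICQ.* Over the analysis domain, the intensity correlation quotient is the
fraction of voxels whose deviations from the domain means covary
positively, minus one half. "Referenced to channel A" is made operational
by computing ICQ (and the means) over the A-positive domain when no
explicit ROI is supplied. Voxels with an exactly zero deviation product
carry no covariation information and are excluded from numerator and
denominator by default; a flag (`count_zero_products`) counts them as
non-positive instead. ICQ is symmetric in the two channels once the domain
is fixed; `|2·ICQ| < 0.1` is the conventional chance criterion, and
independent random channels satisfy it in ≥95% of replicates at 10⁴-voxel
domains.

*Overlap.* Percent pixel overlap referenced to A is `100·|A∩B|/|A|` on the
thresholded masks; it is invariant to intensity rescaling and monotone in
the other channel's mask. Triple colocalization is the voxelwise
conjunction of three masks, which can then be fed to the object counter.

## Object and particle analysis

3D connected components use 26-connectivity by default (the common default
of 3D object counters; 6 and 18 available), with volumes reported in voxels
and physical volume as a derived column when the voxel size is supplied.
The spec of a minimum object volume is exposed (`object_summary`); no
watershed splitting of touching objects is attempted. 2D particle fields
threshold, label 8-connected components and drop particles below
`min_size` (default 4 px, to suppress single-pixel noise). Per-cell raw
integrated intensity sums the signal within disjoint cell masks; group
fold changes divide group means by a reference-group mean.

## Feature-table PCA

Per-cell feature tables mix indices, percents, counts and volumes, so
variables are standardized to unit variance by default (a constant column
is an error naming the column). Components come from a full PCA
(scikit-learn SVD), sign-fixed so each component's largest-magnitude
loading is positive; explained-variance fractions are non-negative,
non-increasing and sum to 1. "Informative" components default to the
Kaiser rule (eigenvalue > 1 on standardized data). Variable selection ranks
variables by their maximum absolute loading across the leading components
whose cumulative explained variance reaches a configurable threshold
(default 0.55) — invariant to loading sign flips. The group comparison is a
two-factor ANOVA on first-component scores with Holm–Sidak-adjusted
pairwise t-tests; with identically drawn groups it stays non-significant in
≥94% of replicates at α = 0.05. The package reproduces this *procedure*;
published variance percentages from any particular study depend on raw
per-cell data and are not reproduction targets.

## Eye-surface regularity

Ommatidia are local intensity maxima above a relative threshold with a
minimum mutual distance (default 0.6 × expected spacing). The regularity
index is the composite `IREG = n_spots / (1 + CV)` with CV the coefficient
of variation (sample sd / mean) of nearest-neighbour distances. Published
regularity indices are defined in tool-specific ways; this composite is
this package's own stand-in, chosen because it responds to both
degeneration signatures — ommatidial loss (smaller `n_spots`) and lattice
disorder (larger CV) — and its validation here is property-based
(translation/rotation/scale invariance, monotone decrease with jitter),
not value-matching against any published genotype table. IREG can be
normalized to a control genotype, and percent recovery linearly rescales
between a degenerated reference (0%) and a control reference (100%).

## Synthetic data: what it emulates, and what not

*Vesicle scenes* place vesicles with an ellipsoidal minimum-separation
constraint (rejection sampling; infeasible requests raise a placement
error) in a stack with confocal-like anisotropic voxels (0.06 × 0.06 ×
0.3777 µm). Exactly `round(coloc_fraction · n_A)` channel-A vesicles sit at
channel-B positions, and core intensities at shared positions covary with
a designed correlation (Gaussian copula, 150 ± 15 a.u.). Vesicles are
rendered as finite-size solid ellipsoid cores (half-axes 1.5/4/4 voxels)
convolved with a Gaussian PSF (σ = 0.5/1/1 voxels): finite cores make a
vesicle's suprathreshold extent geometry-dominated rather than
brightness-dominated, which is what lets the measured percent overlap track
the designed colocalization fraction within ±5 points; pure point-blob
rendering was tried first and biased overlap low by ~12 points at full
colocalization. An optional stylized plasma-membrane shell adds channel-A
signal at the field border. Gaussian read noise only — no Poisson–Gaussian
mixing, no spectral bleed-through, no cell shapes.

*Spectra.* True per-lysosome pH is drawn from a normal distribution
truncated to [4.0, 6.0]. Condition defaults (mode, sd): control and
low-serum — ApoD+ (4.7, 0.25), ApoD− (4.4, 0.08); 2 h paraquat — ApoD+
(5.2, 0.25), ApoD− (4.6, 0.08); 24 h paraquat — ApoD+ reverses to (4.7,
0.25), ApoD− persists at (4.6, 0.08). The spreads are configuration, not
measurements: they encode "narrow" ApoD-negative vs "broad" ApoD-positive
pools, with no published numeric dispersion to match. Spectra are Weibull-5
peaks (y0 = 5, a = 100, b = 60, c = 2.2) whose position shifts red with pH,
sampled on the 420–700/10 nm grid with additive Gaussian noise (sd 2 a.u.,
2% of the peak). The peak position is solved numerically per lysosome so
that the designed 470/524 ratio is an *exactly linear*, strictly decreasing
function of pH, anchored to peak positions 470 nm at pH 4.0 and 506 nm at
pH 6.0 (18 nm per pH unit at the anchors). An affine pH→position map was
considered and rejected: it makes the ratio visibly convex in pH, so a
linear calibration inherits up to ~0.1 pH of systematic error and the
noiseless round trip cannot close; with the linear-ratio construction the
calibration is unbiased and the noiseless round trip recovers true pH to
1e-3. Consequence to keep in mind: the generator is, by design, the regime
in which the linear-calibration assumption is exact — passing closed-loop
tests shows the estimator chain is correct, not that any real dye is
linear.

*Population assay.* The synthetic dye response is linear, F340/F390 = 1.8 −
0.4·(pH − 4), decreasing over pH 4–6; per-well replicate readings get
multiplicative Gaussian noise. True well pH defaults per condition:
control/low-serum 4.5, paraquat (2 h and 24 h) 5.0, chloroquine 5.5 —
configuration values chosen to represent a typical acidic baseline and a
0.5-unit oxidative alkalinization.

*Lattices* are hexagonal spot grids (row pitch √3/2 × spacing, alternate
rows offset half a spacing) with Gaussian spots, optional positional jitter
and Bernoulli dropout; truth coordinates of surviving spots are returned.
*Particle fields* place non-overlapping disks with normal radii and record
each disk's exact rasterized pixel area as truth.

All generators are deterministic given their seed (verified bit-identical).

## Validation strategy and problem sizes

Closed-loop at zero noise: estimators recover generator truth exactly (pH
round trip to 1e-3, object counts, particle areas, spot counts). At the
default noise, recovery is statistical, and one point needs care: the modal
bin of a 30-lysosome histogram is a noisy statistic, and the population
modes 4.4/4.7 sit exactly on bin edges, where the two abutting bins tie in
expectation. A single 30-sample experiment misses the mode-abutting bins by
more than one bin width ~3% of the time for the narrow pool and picks a
center a full bin from the mode ~40% of the time for the broad
(sd 0.25) pool. Reported modal quantities are therefore averaged over
seeded replicates of the 30-lysosome experiment (101 in the acceptance
script, 25 in the test suite); the mean is used rather than the median
because the per-replicate modal center lives on the 0.1-unit bin grid,
making the sample median of a modest number of replicates flip between
grid values. Averaging pins the recovered modal pH (≈4.7 ApoD+, ≈4.4
ApoD−) and the modal shifts (+0.2 ApoD−, +0.5 ApoD+) to a standard error
of a few hundredths of a pH unit. Estimates that clamp at the calibration
boundary are excluded from modal summaries: a population near the top of
the calibrated range (e.g. 2 h paraquat, ApoD+, mode 5.2) sends ~11% of
lysosomes past pH 5.5, and their pile-up at the boundary would otherwise
masquerade as a modal bin — the `clamped` flag exists to mark exactly
these dynamic-range artifacts. Within single experiments, the tie rule
(lower pH wins) means the modal center often lands in the bin just *below*
an edge-sitting population mode (e.g. 4.35 rather than 4.45 for a mode of
4.4); this is a deterministic consequence of edge-aligned binning, not an
estimator bias — the mean
*signed* estimation error per lysosome is below 0.01 pH units at the
default noise (the mean absolute error is ~0.04).

Oracles are independent re-implementations inside the test suite: a
brute-force per-pixel sign count for ICQ, an exhaustive between-class
variance scan for Otsu, BFS flood fill for connected components, a
grid-refined least-squares search (linear in baseline/amplitude) for the
Weibull fit, closed-form OLS normal equations for the calibration, and
hand-enumerated examples throughout.

## Known limitations

- The synthetic spectral and dye models are constructed to be exactly
  invertible by the implemented calibrations; they validate the pipeline's
  correctness, not real-dye behaviour (no photobleaching, loading kinetics
  or pH drift during acquisition).
- Manders coefficients, Costes randomization and Pearson correlation maps
  are out of scope, as are watershed splitting and cell segmentation (cell
  masks are inputs).
- The IREG composite is a documented stand-in, not a published formula.
- Thresholds are data-driven (Otsu) or manual; acquisition-time LUT-based
  thresholding cannot be reproduced offline.
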