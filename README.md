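# lysoquant

Quantitative pipelines for fluorescence-microscopy studies of the
endolysosomal compartment: single-lysosome and population lysosomal pH from
ratiometric LysoSensor readouts, pixel- and object-based colocalization of a
labeled protein (e.g. Apolipoprotein D) with organelle markers, per-cell
intensity and particle readouts, PCA-based variable selection over per-cell
feature tables, and ommatidial-lattice regularity for Drosophila eye
degeneration assays.

The package is aimed at cell-biology image analysts who want these readouts
as tested, scriptable functions rather than interactive plugin workflows.
Because raw confocal data for such studies are rarely deposited, `lysoquant`
ships a first-class synthetic-data module that generates every input the
pipelines consume — vesicle stacks with a designed colocalization fraction,
pH-coded emission spectra, ionophore-clamped calibration standards, jittered
hexagonal lattices, particle fields — with known ground truth, so every
stage is validated closed-loop.

## The quantitative core

**Single-lysosome pH.** Each lysosome ROI yields an emission spectrum
(lambda scan 420–700 nm, 10 nm steps, 405 nm excitation). The spectrum is
fitted with a five-parameter Weibull peak

```
f(λ) = y0 + a · (u/k)^(c−1) · exp(k^c − u^c),   u = (λ−x0)/b + k,
k = ((c−1)/c)^(1/c)       (f = y0 where u ≤ 0)
```

which attains its maximum `y0 + a` at `λ = x0`. The fitted-curve ratio
`R = f(470)/f(524)` is mapped to pH by inverting an ordinary-least-squares
line `R = m·pH + q` fitted to ionophore-clamped standards (monensin +
nigericin, pH 4.0/4.5/5.0/5.5); estimates outside the calibrated range are
clamped and flagged. Lysosomes are classed ApoD-positive/negative by mean
immunofluorescence in the ROI, and per-class pH distributions use 0.1-unit
bins anchored at pH 4.0, reporting the modal bin center (ties toward lower
pH).

**Population pH.** Plate-reader excitation ratios `F340/F390` (535 nm
emission, six replicate readings averaged per well) are inverted through
monotone piecewise-linear interpolation of clamp standards spanning pH
4.0–6.0.

**Colocalization.** After Gaussian smoothing (σ = 1) and per-channel
thresholding (Otsu by default), two readouts are computed over the
reference-channel domain: the intensity correlation quotient
`ICQ = N[(A−Ā)(B−B̄) > 0] / N[(A−Ā)(B−B̄) ≠ 0] − 0.5 ∈ [−0.5, 0.5]`,
with `|2·ICQ| < 0.1` treated as chance, and the percent pixel overlap
referenced to channel A, `100·|A∩B|/|A|`. 3D objects are labeled under
6/18/26-connectivity with voxel volumes; 2D particle fields use 8-connected
components with a minimum-size filter.

**Eye regularity.** Ommatidia are detected as local intensity maxima;
`IREG = n_spots / (1 + CV)` with CV the coefficient of variation of
nearest-neighbour distances, optionally normalized to a control genotype;
`percent recovery = 100·(IREG_x − IREG_degenerated)/(IREG_control −
IREG_degenerated)`.

## Worked example

```python
from lysoquant import pipelines, lysoph

# linear emission calibration from simulated clamp standards (pH 4.0–5.5),
# each standard run through the full Weibull-fit/ratio pipeline
curve = pipelines.build_emission_calibration()
print(f"ratio = {curve.slope:.3f} * pH + {curve.intercept:.3f}  "
      f"(R^2 = {curve.fit_r2:.4f})")

# simulate 30 control-condition lysosomes per ApoD class and estimate pH
for cls in ("ApoD+", "ApoD-"):
    est, true = pipelines.estimate_condition_ph("control", cls, curve, seed=42)
    _, _, mode = lysoph.ph_histogram(est)
    print(f"control {cls}: n=30, modal bin center {mode:.2f}, "
          f"mean |est-true| = {abs(est - true).mean():.3f}")

# modal pH shift after 2 h paraquat, ApoD-positive pool
shift = pipelines.modal_shift("control", "PQ2h", "ApoD+", curve,
                              seed=42, replicates=25)
print(f"PQ 2h modal shift (ApoD+): +{shift:.1f} pH units")
```

prints

```
ratio = -1.846 * pH + 11.427  (R^2 = 1.0000)
control ApoD+: n=30, modal bin center 4.65, mean |est-true| = 0.037
control ApoD-: n=30, modal bin center 4.45, mean |est-true| = 0.049
PQ 2h modal shift (ApoD+): +0.5 pH units
```

The calibration is exactly linear by construction of the synthetic spectral
model, so R² = 1 at zero noise. The control populations show the two pH
domains (a broad ApoD-positive pool with its modal bin at pH ~4.7 and a
narrow ApoD-negative pool at ~4.4; modal bin centers sit at the half-bin
positions 4.65/4.75 and 4.35/4.45 because the population modes lie exactly
on bin edges), and oxidative stress shifts the ApoD-positive mode by +0.5 pH
units. Per-lysosome estimation error at the default spectral noise is ~0.04
pH units.

The same workflows are available from the shell:

```
lysoquant lysoph run --seed 1 --out out/        # records, histograms, modes
lysoquant coloc run --seed 1 --out out/         # ICQ + overlap on a scene
lysoquant eye run --seed 1 --out out/           # lattice IREG
lysoquant stats run --seed 1 --out out/         # two-round PCA + ANOVA
```

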