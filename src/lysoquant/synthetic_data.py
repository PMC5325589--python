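"""Synthetic microscopy and spectroscopy data with known ground truth.

Every input the analysis stages consume can be generated here: two/three
channel vesicle stacks with a controlled colocalization fraction, pH-coded
single-lysosome emission spectra, ionophore-clamped calibration standards,
plate-reader excitation ratios, jittered hexagonal ommatidial lattices and
random particle fields.  All generators are deterministic given their seed.

The spectral ground truth emulates the LysoSensor regime: each lysosome's
emission spectrum is a five-parameter Weibull peak whose position shifts red
with rising pH, arranged so that the fitted 470/524 nm ratio is an exactly
linear, strictly decreasing function of pH across the probe range — the
regime in which a linear emission calibration is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.stats import truncnorm

from .errors import PlacementError
from .lysoph import EmissionSpectrum, weibull5, RATIO_NUM_NM, RATIO_DEN_NM

__all__ = [
    "VesicleSceneSpec",
    "SpectrumGroundTruth",
    "LatticeSpec",
    "ParticleFieldSpec",
    "CONDITION_PH_DEFAULTS",
    "POPULATION_PH_DEFAULTS",
    "make_vesicle_scene",
    "make_spectra",
    "make_calibration_standards",
    "make_excitation_readings",
    "excitation_ratio_model",
    "make_lattice_image",
    "make_particle_field",
]

#: Per-condition (mode, sd) of the true single-lysosome pH distribution,
#: by ApoD class.  Control/low-serum: ApoD+ 4.7 (broad), ApoD- 4.4 (narrow);
#: 2h paraquat: +0.5 and +0.2 shifts; 24h: ApoD+ reverses, ApoD- persists.
CONDITION_PH_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {"ApoD+": (4.7, 0.25), "ApoD-": (4.4, 0.08)},
    "LS": {"ApoD+": (4.7, 0.25), "ApoD-": (4.4, 0.08)},
    "PQ2h": {"ApoD+": (5.2, 0.25), "ApoD-": (4.6, 0.08)},
    "PQ24h": {"ApoD+": (4.7, 0.25), "ApoD-": (4.6, 0.08)},
}

#: True whole-well (population-average) lysosomal pH per condition for the
#: plate-reader excitation assay.
POPULATION_PH_DEFAULTS: dict[str, float] = {
    "control": 4.5,
    "LS": 4.5,
    "PQ2h": 5.0,
    "PQ24h": 5.0,
    "CQ": 5.5,
}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class VesicleSceneSpec:
    """Two-channel 3D vesicle scene with a designed colocalization fraction."""

    shape: tuple[int, int, int] = (16, 160, 160)
    voxel_size: tuple[float, float, float] = (0.3777, 0.06, 0.06)
    n_vesicles_a: int = 40
    n_vesicles_b: int = 40
    coloc_fraction: float = 0.5
    intensity_rho: float = 0.5
    psf_sigma: tuple[float, float, float] = (0.5, 1.0, 1.0)
    vesicle_radius: tuple[float, float, float] = (1.5, 4.0, 4.0)
    noise_sd: float = 1.0
    membrane_ring: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if not -1.0 <= self.intensity_rho <= 1.0:
            raise ValueError("intensity_rho must be in [-1, 1]")
        if self.n_vesicles_a < 0 or self.n_vesicles_b < 0:
            raise ValueError("vesicle counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SpectrumGroundTruth:
    """Ground truth for a population of single-lysosome emission spectra."""

    condition: str = "control"
    apod_class: str = "ApoD+"
    ph_mode: float = 4.7
    ph_sd: float = 0.25
    peak_map_slope: float = 18.0   # nm per pH unit (anchor slope)
    peak_map_intercept: float = 470.0  # peak position at pH 4.0, nm
    weibull_a: float = 100.0
    weibull_b: float = 60.0
    weibull_c: float = 2.2
    weibull_y0: float = 5.0
    noise_sd: float = 2.0
    n_lysosomes: int = 30
    seed: int = 0

    def validate(self) -> None:
        if not 4.0 <= self.ph_mode <= 6.0:
            raise ValueError("ph_mode must lie within [4.0, 6.0]")
        if self.weibull_c <= 1:
            raise ValueError("weibull_c must be > 1")
        if self.n_lysosomes < 1:
            raise ValueError("n_lysosomes must be >= 1")
        if self.ph_sd < 0 or self.noise_sd < 0:
            raise ValueError("spreads must be >= 0")

    @classmethod
    def for_condition(
        cls, condition: str, apod_class: str, n_lysosomes: int = 30,
        seed: int = 0, **overrides
    ) -> "SpectrumGroundTruth":
        """Ground truth preset for a study condition and ApoD class."""
        mode, sd = CONDITION_PH_DEFAULTS[condition][apod_class]
        return cls(
            condition=condition, apod_class=apod_class, ph_mode=mode,
            ph_sd=sd, n_lysosomes=n_lysosomes, seed=seed, **overrides,
        )


@dataclass
class LatticeSpec:
    """Jittered hexagonal spot lattice emulating an ommatidial field."""

    rows: int = 10
    cols: int = 10
    spacing: float = 20.0
    jitter_sd: float = 0.0
    dropout_fraction: float = 0.0
    spot_sigma: float = 2.0
    spot_amplitude: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ValueError("dropout_fraction must be in [0, 1]")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.spacing <= 0 or self.spot_sigma <= 0:
            raise ValueError("spacing and spot_sigma must be > 0")


@dataclass
class ParticleFieldSpec:
    """Random field of non-overlapping disks (ingested-particle fixture)."""

    image_shape: tuple[int, int] = (256, 256)
    n_particles: int = 20
    radius_mean: float = 4.0
    radius_sd: float = 1.0
    intensity: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be > 0")


# ---------------------------------------------------------------------------
# vesicle scenes
# ---------------------------------------------------------------------------

def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int, int],
    margin: np.ndarray,
    min_sep: np.ndarray,
    existing: list[np.ndarray],
    max_tries_per_point: int = 400,
) -> list[np.ndarray]:
    """Rejection-sample points with an ellipsoidal separation constraint."""
    if any(margin[ax] > shape[ax] - 1 - margin[ax] for ax in range(3)):
        raise PlacementError(
            "could not place vesicles: field smaller than the required margins"
        )
    placed: list[np.ndarray] = []
    for _ in range(n):
        for attempt in range(max_tries_per_point):
            p = np.array(
                [rng.uniform(margin[ax], shape[ax] - 1 - margin[ax]) for ax in range(3)]
            )
            ok = True
            for q in existing + placed:
                if np.sum(((p - q) / min_sep) ** 2) < 1.0:
                    ok = False
                    break
            if ok:
                placed.append(p)
                break
        else:
            raise PlacementError(
                "could not place vesicles: field too small for the requested "
                "count and separation"
            )
    return placed


def _render_vesicles(
    shape, points: Sequence[np.ndarray], amps: Sequence[float], radius, psf_sigma
) -> np.ndarray:
    """Render finite-size vesicles (solid ellipsoid cores convolved with the
    PSF), so the suprathreshold extent of a vesicle is set by its geometry
    rather than its brightness."""
    img = np.zeros(shape, dtype=float)
    rv = np.broadcast_to(np.asarray(radius, dtype=float), (3,))
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    for p, a in zip(points, amps):
        d = (
            ((zz - p[0]) / rv[0]) ** 2
            + ((yy - p[1]) / rv[1]) ** 2
            + ((xx - p[2]) / rv[2]) ** 2
        )
        img[d <= 1.0] += a
    return ndimage.gaussian_filter(img, sigma=psf_sigma)


def make_vesicle_scene(
    spec: VesicleSceneSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate aligned channel-A/channel-B stacks plus a ground-truth table.

    Exactly ``round(coloc_fraction * n_vesicles_a)`` channel-A vesicles share
    their position with a channel-B vesicle; core intensities at shared
    positions covary with correlation ``intensity_rho`` (Gaussian copula).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    sig = np.broadcast_to(np.asarray(spec.psf_sigma, dtype=float), (3,))
    rv = np.broadcast_to(np.asarray(spec.vesicle_radius, dtype=float), (3,))
    margin = np.ceil(rv + 3 * sig) + 1
    min_sep = 2 * rv + 6 * np.maximum(sig, 0.5)

    n_shared = int(round(spec.coloc_fraction * spec.n_vesicles_a))
    if n_shared > spec.n_vesicles_b:
        raise ValueError("coloc_fraction requires more B vesicles than available")

    pos_b = _place_points(rng, spec.n_vesicles_b, shape, margin, min_sep, [])
    shared_pos = pos_b[:n_shared]
    pos_a_extra = _place_points(
        rng, spec.n_vesicles_a - n_shared, shape, margin, min_sep, pos_b
    )
    pos_a = shared_pos + pos_a_extra

    # core intensities ~ 150 +/- 15 a.u.; correlated at shared positions
    rho = spec.intensity_rho
    z_a = rng.standard_normal(spec.n_vesicles_a)
    z_b = rng.standard_normal(spec.n_vesicles_b)
    z_b[:n_shared] = rho * z_a[:n_shared] + np.sqrt(max(0.0, 1 - rho**2)) * z_b[:n_shared]
    amp_a = np.clip(150.0 + 15.0 * z_a, 110.0, None)
    amp_b = np.clip(150.0 + 15.0 * z_b, 110.0, None)

    stack_a = _render_vesicles(shape, pos_a, amp_a, rv, sig)
    stack_b = _render_vesicles(shape, pos_b, amp_b, rv, sig)

    if spec.membrane_ring:
        # stylized plasma-membrane shell: a thin lateral frame in channel A
        ring = np.zeros(shape, dtype=float)
        zc = slice(shape[0] // 4, 3 * shape[0] // 4)
        ring[zc, 1:3, :] = ring[zc, -3:-1, :] = 60.0
        ring[zc, :, 1:3] = ring[zc, :, -3:-1] = 60.0
        stack_a = stack_a + ndimage.gaussian_filter(ring, sigma=sig)

    if spec.noise_sd > 0:
        stack_a = stack_a + rng.normal(0.0, spec.noise_sd, shape)
        stack_b = stack_b + rng.normal(0.0, spec.noise_sd, shape)
    stack_a = np.clip(stack_a, 0.0, None)
    stack_b = np.clip(stack_b, 0.0, None)

    rows = []
    for i, (p, a) in enumerate(zip(pos_a, amp_a)):
        rows.append(
            {"channel": "A", "index": i, "z": p[0], "y": p[1], "x": p[2],
             "amplitude": a, "shared": i < n_shared,
             "pair_id": i if i < n_shared else -1}
        )
    for i, (p, a) in enumerate(zip(pos_b, amp_b)):
        rows.append(
            {"channel": "B", "index": i, "z": p[0], "y": p[1], "x": p[2],
             "amplitude": a, "shared": i < n_shared,
             "pair_id": i if i < n_shared else -1}
        )
    return stack_a, stack_b, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

#: Lambda-scan sampling: 420-700 nm in 10 nm steps.
SCAN_WAVELENGTHS = np.arange(420.0, 700.0 + 1e-9, 10.0)


def _ratio_at_x0(x0: float, gt: SpectrumGroundTruth) -> float:
    f = weibull5(
        np.array([RATIO_NUM_NM, RATIO_DEN_NM]),
        gt.weibull_y0, gt.weibull_a, x0, gt.weibull_b, gt.weibull_c,
    )
    return float(f[0] / f[1])


def _ratio_anchors(gt: SpectrumGroundTruth) -> tuple[float, float]:
    """Designed 470/524 ratio at the pH-range anchors 4.0 and 6.0."""
    x0_lo = gt.peak_map_intercept
    x0_hi = gt.peak_map_intercept + gt.peak_map_slope * 2.0
    return _ratio_at_x0(x0_lo, gt), _ratio_at_x0(x0_hi, gt)


def true_ratio(gt: SpectrumGroundTruth, ph) -> np.ndarray:
    """The generator's designed ratio-pH line (exactly linear over 4.0-6.0)."""
    r4, r6 = _ratio_anchors(gt)
    return r4 + (r6 - r4) * (np.asarray(ph, dtype=float) - 4.0) / 2.0


def peak_position(gt: SpectrumGroundTruth, ph: float) -> float:
    """Peak wavelength for a true pH: solves the spectral model so that the
    470/524 ratio lies exactly on the designed line.

    The map is strictly increasing in pH and coincides with the affine anchor
    map ``intercept + slope*(pH - 4)`` at pH 4.0 and 6.0.
    """
    target = float(true_ratio(gt, ph))
    lo = gt.peak_map_intercept - 1.0
    hi = gt.peak_map_intercept + gt.peak_map_slope * 2.0 + 1.0
    return float(
        optimize.brentq(lambda x0: _ratio_at_x0(x0, gt) - target, lo, hi, xtol=1e-10)
    )


def _draw_ph(gt: SpectrumGroundTruth, rng: np.random.Generator) -> np.ndarray:
    if gt.ph_sd == 0:
        return np.full(gt.n_lysosomes, gt.ph_mode)
    a = (4.0 - gt.ph_mode) / gt.ph_sd
    b = (6.0 - gt.ph_mode) / gt.ph_sd
    return truncnorm.rvs(
        a, b, loc=gt.ph_mode, scale=gt.ph_sd, size=gt.n_lysosomes, random_state=rng
    )


def make_spectra(
    gt: SpectrumGroundTruth,
) -> tuple[list[EmissionSpectrum], np.ndarray]:
    """Sample ``n_lysosomes`` true pH values (truncated normal on [4, 6]) and
    emit one noisy Weibull-peak lambda-scan spectrum per lysosome.

    Returns the spectra and the true pH of each lysosome.
    """
    gt.validate()
    rng = np.random.default_rng(gt.seed)
    true_ph = _draw_ph(gt, rng)
    spectra = []
    for i, ph in enumerate(true_ph):
        x0 = peak_position(gt, float(ph))
        inten = weibull5(
            SCAN_WAVELENGTHS, gt.weibull_y0, gt.weibull_a, x0, gt.weibull_b, gt.weibull_c
        )
        if gt.noise_sd > 0:
            inten = inten + rng.normal(0.0, gt.noise_sd, inten.shape)
        spectra.append(
            EmissionSpectrum(
                wavelengths=SCAN_WAVELENGTHS.copy(),
                intensities=inten,
                lysosome_id=i,
                condition=gt.condition,
            )
        )
    return spectra, true_ph


def make_calibration_standards(
    gt: SpectrumGroundTruth,
    ph_levels: Sequence[float] = (4.0, 4.5, 5.0, 5.5),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, EmissionSpectrum]]:
    """Ionophore-clamp standards: one (pH, spectrum) pair per clamp level,
    noiseless by default, using the same spectral model as :func:`make_spectra`."""
    if len(ph_levels) == 0:
        raise ValueError("ph_levels must be non-empty")
    if any(not 4.0 <= p <= 6.0 for p in ph_levels):
        raise ValueError("ph_levels must lie within [4.0, 6.0]")
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    out = []
    for j, ph in enumerate(ph_levels):
        x0 = peak_position(gt, float(ph))
        inten = weibull5(
            SCAN_WAVELENGTHS, gt.weibull_y0, gt.weibull_a, x0, gt.weibull_b, gt.weibull_c
        )
        if noise_sd > 0:
            inten = inten + rng.normal(0.0, noise_sd, inten.shape)
        out.append(
            (
                float(ph),
                EmissionSpectrum(
                    wavelengths=SCAN_WAVELENGTHS.copy(),
                    intensities=inten,
                    lysosome_id=j,
                    condition=f"clamp_pH{ph:g}",
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# plate-reader excitation assay
# ---------------------------------------------------------------------------

def excitation_ratio_model(ph) -> np.ndarray:
    """Designed F340/F390 dye response: linear, decreasing, 1.8 at pH 4.0 to
    1.0 at pH 6.0 (locally linear approximation of the ratiometric probe)."""
    return 1.8 - 0.4 * (np.asarray(ph, dtype=float) - 4.0)


def make_excitation_readings(
    well_ph: Sequence[float],
    n_replicates: int = 6,
    base_f390: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Simulated per-well F340/F390 replicate readings for true well pHs.

    ``noise_sd`` is the relative (fractional) sd of each reading.
    """
    rng = np.random.default_rng(seed)
    f340, f390 = [], []
    for ph in well_ph:
        r = float(excitation_ratio_model(ph))
        b = base_f390 * (1.0 + noise_sd * rng.standard_normal(n_replicates))
        a = base_f390 * r * (1.0 + noise_sd * rng.standard_normal(n_replicates))
        f340.append(a)
        f390.append(b)
    return f340, f390


def make_excitation_standards(
    ph_levels: Sequence[float] = (4.0, 4.5, 5.0, 5.5, 6.0),
) -> list[tuple[float, float]]:
    """Noiseless clamp standards (pH, F340/F390 ratio) for the plate assay."""
    return [(float(p), float(excitation_ratio_model(p))) for p in ph_levels]


# ---------------------------------------------------------------------------
# lattices and particle fields
# ---------------------------------------------------------------------------

def make_lattice_image(spec: LatticeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Hexagonal lattice of Gaussian spots with jitter and dropout.

    Returns the rendered image and the true (row, col) coordinates of the
    spots that survived dropout.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    row_pitch = spec.spacing * np.sqrt(3.0) / 2.0
    pad = spec.spacing  # border so spots stay inside
    coords = []
    for i in range(spec.rows):
        for j in range(spec.cols):
            y = pad + i * row_pitch
            x = pad + j * spec.spacing + (spec.spacing / 2.0 if i % 2 else 0.0)
            coords.append((y, x))
    coords = np.asarray(coords, dtype=float)
    if spec.jitter_sd > 0:
        coords = coords + rng.normal(0.0, spec.jitter_sd, coords.shape)
    keep = rng.random(len(coords)) >= spec.dropout_fraction
    coords = coords[keep]

    h = int(np.ceil(2 * pad + (spec.rows - 1) * row_pitch))
    w = int(np.ceil(2 * pad + (spec.cols - 0.5) * spec.spacing))
    img = np.zeros((h, w), dtype=float)
    r = int(np.ceil(4 * spec.spot_sigma))
    for y, x in coords:
        iy, ix = int(round(y)), int(round(x))
        ys = slice(max(0, iy - r), min(h, iy + r + 1))
        xs = slice(max(0, ix - r), min(w, ix + r + 1))
        yy, xx = np.mgrid[ys, xs]
        img[ys, xs] += spec.spot_amplitude * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * spec.spot_sigma**2)
        )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return img, coords


def make_particle_field(
    spec: ParticleFieldSpec, max_tries_per_particle: int = 500
) -> tuple[np.ndarray, pd.DataFrame]:
    """Field of non-overlapping rasterized disks with a per-particle truth
    table (center, radius, exact pixel area)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    img = np.zeros((h, w), dtype=float)
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.n_particles):
        for attempt in range(max_tries_per_particle):
            r = max(0.5, float(rng.normal(spec.radius_mean, spec.radius_sd)))
            cy = rng.uniform(r + 1, h - r - 2)
            cx = rng.uniform(r + 1, w - r - 2)
            if all(
                np.hypot(cy - py, cx - px) > r + pr + 2.0 for py, px, pr in placed
            ):
                placed.append((cy, cx, r))
                break
        else:
            raise PlacementError(
                "could not place particles without overlap: field too crowded"
            )
    rows = []
    for pid, (cy, cx, r) in enumerate(placed):
        yy, xx = np.mgrid[0:h, 0:w]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[disk] = spec.intensity
        rows.append(
            {"particle_id": pid, "y": cy, "x": cx, "radius": r,
             "area_px": int(disk.sum())}
        )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    truth = pd.DataFrame(
        rows, columns=["particle_id", "y", "x", "radius", "area_px"]
    )
    return img, truth
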