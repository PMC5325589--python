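"""End-to-end workflows tying the synthetic generators to the estimators.

These are the closed-loop experiments the package's validation rests on:
simulate single-lysosome spectra under a study condition, build the emission
calibration from clamp standards, estimate every lysosome's pH, and
summarise per-class modal pH (with seeded replication of the whole
experiment, since the modal bin of a 30-lysosome histogram is itself a
noisy statistic).
"""

from __future__ import annotations

import numpy as np

from . import synthetic_data as synth
from . import lysoph

__all__ = [
    "build_emission_calibration",
    "estimate_condition_ph",
    "modal_ph",
    "modal_shift",
    "excitation_ph_shift",
]

CALIBRATION_LEVELS = (4.0, 4.5, 5.0, 5.5)


def build_emission_calibration(
    gt: synth.SpectrumGroundTruth | None = None,
    ph_levels=CALIBRATION_LEVELS,
    noise_sd: float = 0.0,
) -> lysoph.CalibrationCurve:
    """Simulate clamp standards, run each through the Weibull-fit/ratio
    pipeline, and fit the linear emission calibration."""
    if gt is None:
        gt = synth.SpectrumGroundTruth()
    standards = synth.make_calibration_standards(gt, ph_levels, noise_sd=noise_sd)
    pts = []
    for ph, spec in standards:
        params = lysoph.fit_weibull5(spec)
        pts.append((ph, lysoph.emission_ratio(params)))
    return lysoph.fit_emission_calibration(pts)


def estimate_condition_ph(
    condition: str,
    apod_class: str,
    curve: lysoph.CalibrationCurve,
    n_lysosomes: int = 30,
    seed: int = 0,
    **gt_overrides,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one condition/class population and estimate each lysosome's
    pH through the full fit -> ratio -> calibration pipeline.

    Returns (estimated pH, true pH).
    """
    gt = synth.SpectrumGroundTruth.for_condition(
        condition, apod_class, n_lysosomes=n_lysosomes, seed=seed, **gt_overrides
    )
    spectra, true_ph = synth.make_spectra(gt)
    records = lysoph.estimate_ph(spectra, curve)
    return np.array([r.ph for r in records]), true_ph


def _replicate_modal_center(
    condition: str,
    apod_class: str,
    curve: lysoph.CalibrationCurve,
    n_lysosomes: int,
    seed: int,
    bin_width: float,
    exclude_clamped: bool,
) -> float:
    """Modal bin center of one simulated experiment.

    Estimates that clamp at the calibration boundary are excluded by
    default: they mark lysosomes outside the probe's dynamic range, and
    their pile-up at the boundary value would otherwise masquerade as a
    modal bin.
    """
    gt = synth.SpectrumGroundTruth.for_condition(
        condition, apod_class, n_lysosomes=n_lysosomes, seed=seed
    )
    spectra, _ = synth.make_spectra(gt)
    records = lysoph.estimate_ph(spectra, curve)
    ph = [r.ph for r in records if not (exclude_clamped and r.clamped)]
    if not ph:  # every lysosome out of range: fall back to the clamped values
        ph = [r.ph for r in records]
    _, _, modal = lysoph.ph_histogram(ph, bin_width)
    return modal


def modal_ph(
    condition: str,
    apod_class: str,
    curve: lysoph.CalibrationCurve,
    n_lysosomes: int = 30,
    seed: int = 0,
    replicates: int = 1,
    bin_width: float = 0.1,
    exclude_clamped: bool = True,
) -> float:
    """Modal bin center of the recovered pH distribution for one
    condition/class, summarised over seeded replicates of the experiment.

    Each replicate simulates ``n_lysosomes`` spectra and histograms the
    estimated pH values (``bin_width`` bins anchored at 4.0); the mean of
    the per-replicate modal bin centers is returned (the per-replicate modal
    center is a discrete statistic, so the mean is a far more stable summary
    than the median).  With ``replicates=1``
    this is a single experiment's modal bin center.
    """
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    modes = [
        _replicate_modal_center(
            condition, apod_class, curve, n_lysosomes, int(s), bin_width,
            exclude_clamped,
        )
        for s in seeds
    ]
    return float(np.mean(modes))


def modal_shift(
    condition_from: str,
    condition_to: str,
    apod_class: str,
    curve: lysoph.CalibrationCurve,
    n_lysosomes: int = 30,
    seed: int = 0,
    replicates: int = 1,
    bin_width: float = 0.1,
    exclude_clamped: bool = True,
) -> float:
    """Difference of modal bin centers (``condition_to`` minus
    ``condition_from``), averaged over paired seeded replicates."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * replicates) % (2**31)
    diffs = []
    for i in range(replicates):
        m0 = _replicate_modal_center(
            condition_from, apod_class, curve, n_lysosomes,
            int(seeds[2 * i]), bin_width, exclude_clamped,
        )
        m1 = _replicate_modal_center(
            condition_to, apod_class, curve, n_lysosomes,
            int(seeds[2 * i + 1]), bin_width, exclude_clamped,
        )
        diffs.append(m1 - m0)
    return float(np.mean(diffs))


def excitation_ph_shift(
    condition_from: str = "control",
    condition_to: str = "PQ2h",
    n_wells: int = 6,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> float:
    """Population pipeline: mean per-well pH of ``condition_to`` wells minus
    mean of ``condition_from`` wells, using interpolated clamp calibration."""
    standards = synth.make_excitation_standards(np.arange(4.0, 6.01, 0.5))
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    means = []
    for cond, s in zip((condition_from, condition_to), ss):
        ph = synth.POPULATION_PH_DEFAULTS[cond]
        f340, f390 = synth.make_excitation_readings(
            [ph] * n_wells, noise_sd=noise_sd, seed=int(s)
        )
        res = lysoph.population_ph_excitation(f340, f390, standards)
        means.append(float(res["ph"].mean()))
    return means[1] - means[0]
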