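"""Lysosomal pH estimation from ratiometric LysoSensor readouts.

Two acquisition modes are supported:

* **Single-lysosome emission mode** — a confocal lambda scan (420--700 nm,
  10 nm steps) is recorded per lysosome ROI, fitted with a five-parameter
  Weibull peak, and the fitted-curve intensity ratio I(470)/I(524) is mapped
  to pH through a linear calibration built from ionophore-clamped standards
  (pH 4.0--5.5).
* **Population excitation mode** — plate-reader F340/F390 excitation ratios
  (535 nm emission) per well, mapped to pH by monotone piecewise-linear
  interpolation through clamped standards spanning pH 4.0--6.0.

Lysosomes are classified as ApoD-positive or ApoD-negative by the mean
immunofluorescence intensity within each ROI, and per-class pH frequency
distributions (0.1-unit bins anchored at pH 4.0) summarise the populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .errors import CalibrationError, DomainError, NoPeakError

__all__ = [
    "EmissionSpectrum",
    "Weibull5Params",
    "CalibrationCurve",
    "LysosomeRecord",
    "weibull5",
    "fit_weibull5",
    "emission_ratio",
    "fit_emission_calibration",
    "ratio_to_ph",
    "classify_apod",
    "ph_histogram",
    "ph_distribution",
    "apod_lysosome_fractions",
    "population_ph_excitation",
    "estimate_ph",
    "read_spectra_csv",
    "write_spectra_csv",
]

#: Default emission ratio wavelengths (nm).
RATIO_NUM_NM = 470.0
RATIO_DEN_NM = 524.0

#: pH range where the ratiometric probe is informative.
PROBE_PH_RANGE = (4.0, 6.0)


@dataclass
class EmissionSpectrum:
    """Emission intensities of one lysosome ROI across a lambda scan."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    lysosome_id: int = 0
    cell_id: int | None = None
    condition: str = "control"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass
class Weibull5Params:
    """Parameters of the five-parameter Weibull peak fit.

    The fitted curve attains its maximum ``y0 + a`` at ``x0`` (peak-normalized
    parameterization), so the amplitude is directly interpretable.
    """

    y0: float
    a: float
    x0: float
    b: float
    c: float
    rss: float = np.nan
    converged: bool = False

    def __call__(self, lam) -> np.ndarray:
        return weibull5(lam, self.y0, self.a, self.x0, self.b, self.c)


@dataclass
class CalibrationCurve:
    """Monotone map between dye ratio and pH with a validity range.

    ``mode='emission_linear'`` stores an OLS line ``ratio = slope*pH +
    intercept``; ``mode='excitation_interp'`` stores the (pH, ratio) knots and
    inverts by piecewise-linear interpolation.
    """

    mode: str
    slope: float | None = None
    intercept: float | None = None
    knots: list[tuple[float, float]] | None = None
    valid_ph_range: tuple[float, float] = PROBE_PH_RANGE
    fit_r2: float | None = None

    def ph_from_ratio(self, ratio: float) -> tuple[float, bool]:
        """Invert the curve; values outside ``valid_ph_range`` are clamped.

        A small numeric tolerance keeps exact boundary hits (e.g. a
        calibration standard's own ratio) from being flagged as clamped.
        """
        lo, hi = self.valid_ph_range
        tol = 1e-6
        if self.mode == "emission_linear":
            ph = (ratio - self.intercept) / self.slope
            clamped = ph < lo - tol or ph > hi + tol
        elif self.mode == "excitation_interp":
            knot_ph = np.array([k[0] for k in self.knots])
            knot_r = np.array([k[1] for k in self.knots])
            order = np.argsort(knot_r)
            r_sorted = knot_r[order]
            ph = float(np.interp(ratio, r_sorted, knot_ph[order]))
            clamped = ratio < r_sorted[0] - tol or ratio > r_sorted[-1] + tol
        else:  # pragma: no cover - guarded at construction
            raise CalibrationError(f"unknown calibration mode {self.mode!r}")
        return float(min(max(ph, lo), hi)), bool(clamped)

    def to_yaml(self, path) -> None:
        payload = {
            "mode": self.mode,
            "slope": self.slope,
            "intercept": self.intercept,
            "knots": [list(map(float, k)) for k in self.knots] if self.knots else None,
            "valid_ph_range": list(self.valid_ph_range),
            "fit_r2": self.fit_r2,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        knots = [tuple(k) for k in d["knots"]] if d.get("knots") else None
        return cls(
            mode=d["mode"],
            slope=d.get("slope"),
            intercept=d.get("intercept"),
            knots=knots,
            valid_ph_range=tuple(d["valid_ph_range"]),
            fit_r2=d.get("fit_r2"),
        )


@dataclass
class LysosomeRecord:
    """One lysosome's ratio, estimated pH and ApoD class."""

    lysosome_id: int
    ratio_470_524: float
    ph: float
    apod_positive: bool | None = None
    condition: str = "control"
    clamped: bool = False


def weibull5(lam, y0: float, a: float, x0: float, b: float, c: float) -> np.ndarray:
    """Five-parameter Weibull peak function.

    ``f(lam) = y0 + a * (u/k)**(c-1) * exp(k**c - u**c)`` with
    ``u = (lam - x0)/b + k`` and ``k = ((c-1)/c)**(1/c)`` where ``u > 0``,
    and ``f = y0`` otherwise.  The curve peaks at ``f(x0) = y0 + a``.
    """
    lam = np.asarray(lam, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    k = ((c - 1.0) / c) ** (1.0 / c)
    u = (lam - x0) / b + k
    out = np.full(lam.shape, y0, dtype=float)
    pos = u > 0
    out[pos] = y0 + a * (u[pos] / k) ** (c - 1.0) * np.exp(k**c - u[pos] ** c)
    return out[0] if scalar else out


def _weibull_residuals(theta, lam, intensity):
    y0, a, x0, b, c = theta
    return weibull5(lam, y0, a, x0, b, c) - intensity


def _weibull_residuals_log(theta, lam, intensity):
    # unconstrained parameterization: a = exp(la), b = exp(lb), c = 1 + exp(lc)
    y0, la, x0, lb, lc = theta
    la, lb, lc = (np.clip(v, -50.0, 50.0) for v in (la, lb, lc))
    return weibull5(lam, y0, np.exp(la), x0, np.exp(lb), 1.0 + np.exp(lc)) - intensity


def fit_weibull5(
    spectrum: EmissionSpectrum | tuple,
    init: Weibull5Params | None = None,
    c_starts: Sequence[float] = (1.5, 2.2, 3.0),
) -> Weibull5Params:
    """Least-squares fit of the Weibull-5 peak to an emission spectrum.

    Multi-start strategy: the peak position starts at the argmax sample, the
    width at half the spectral span, the baseline at the minimum intensity and
    the amplitude at the intensity range, with each shape value in
    ``c_starts`` tried in turn; the fit with the lowest residual sum of
    squares wins.  An explicit ``init`` is tried first.

    Raises :class:`NoPeakError` for flat spectra; a fit that never converges
    returns the best-so-far parameters with ``converged=False``.
    """
    if isinstance(spectrum, EmissionSpectrum):
        lam, inten = spectrum.wavelengths, spectrum.intensities
    else:
        lam, inten = (np.asarray(v, dtype=float) for v in spectrum)
    if lam.size < 8:
        raise ValueError("at least 8 samples are required for a 5-parameter fit")
    rng_int = float(np.ptp(inten))
    if rng_int <= 0:
        raise NoPeakError("no peak: spectrum has zero intensity range")

    span = float(lam[-1] - lam[0])
    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(
            np.array([init.y0, np.log(max(init.a, 1e-12)), init.x0,
                      np.log(max(init.b, 1e-12)),
                      np.log(max(init.c - 1.0, 1e-12))])
        )
    x0_guess = float(lam[int(np.argmax(inten))])
    for c0 in c_starts:
        starts.append(
            np.array([float(inten.min()), np.log(rng_int), x0_guess,
                      np.log(span / 2.0), np.log(c0 - 1.0)])
        )

    best = None
    for theta0 in starts:
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                res = optimize.least_squares(
                    _weibull_residuals_log,
                    theta0,
                    args=(lam, inten),
                    method="lm",
                    max_nfev=5000,
                )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if np.isfinite(rss) and (best is None or rss < best[0]):
            best = (rss, res)
    if best is None:  # pragma: no cover - least_squares is robust
        raise NoPeakError("no peak: all fit attempts failed")
    rss, res = best
    y0, la, x0, lb, lc = res.x
    return Weibull5Params(
        y0=float(y0), a=float(np.exp(la)), x0=float(x0),
        b=float(np.exp(lb)), c=float(1.0 + np.exp(lc)),
        rss=rss, converged=bool(res.success),
    )


def emission_ratio(
    params: Weibull5Params,
    num_nm: float = RATIO_NUM_NM,
    den_nm: float = RATIO_DEN_NM,
) -> float:
    """Fitted-curve intensity ratio I(num_nm)/I(den_nm), default 470/524."""
    num = float(params(num_nm))
    den = float(params(den_nm))
    if den <= 0:
        raise ValueError("invalid denominator: fitted intensity at "
                         f"{den_nm} nm is {den:g}")
    return num / den


def _check_monotone(ratios: np.ndarray) -> None:
    diffs = np.diff(ratios)
    if np.any(diffs == 0) or not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise CalibrationError("calibration not invertible: standards are not "
                              "strictly monotone in pH")


def fit_emission_calibration(
    standards: Iterable[tuple[float, float]],
) -> CalibrationCurve:
    """OLS line ``ratio = slope*pH + intercept`` through clamp standards.

    Requires at least two distinct pH levels and strictly monotone ratios.
    """
    pts = sorted((float(p), float(r)) for p, r in standards)
    ph = np.array([p for p, _ in pts])
    ratio = np.array([r for _, r in pts])
    if np.unique(ph).size < 2:
        raise CalibrationError("underdetermined: need >= 2 distinct pH levels")
    _check_monotone(ratio)
    fit = stats.linregress(ph, ratio)
    if fit.slope == 0:
        raise CalibrationError("calibration not invertible: zero slope")
    return CalibrationCurve(
        mode="emission_linear",
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        valid_ph_range=(float(ph.min()), float(ph.max())),
        fit_r2=float(fit.rvalue**2),
    )


def ratio_to_ph(curve: CalibrationCurve, ratio: float) -> tuple[float, bool]:
    """pH for a measured ratio; out-of-range values clamp to the boundary."""
    return curve.ph_from_ratio(ratio)


def classify_apod(lysosome_roi: np.ndarray, apod_image: np.ndarray,
                  threshold: float) -> bool:
    """ApoD-positive iff the mean ApoD intensity inside the ROI exceeds
    ``threshold``."""
    roi = np.asarray(lysosome_roi, dtype=bool)
    if roi.shape != np.asarray(apod_image).shape:
        raise ValueError("ROI and image shapes differ")
    if not roi.any():
        raise DomainError("empty ROI")
    return bool(float(np.mean(np.asarray(apod_image)[roi])) > threshold)


def ph_histogram(
    values: Sequence[float], bin_width: float = 0.1, anchor: float = 4.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram pH values on bins aligned to multiples of ``bin_width``
    starting at ``anchor``; ties for the modal bin break toward lower pH.

    Returns ``(bin_centers, counts, modal_center)``.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values to bin")
    idx = np.floor((v - anchor) / bin_width + 1e-9).astype(int)
    lo = int(idx.min())
    counts = np.bincount(idx - lo)
    centers = anchor + (np.arange(lo, lo + counts.size) + 0.5) * bin_width
    modal_center = float(centers[int(np.argmax(counts))])  # argmax: lowest bin wins ties
    return centers, counts, modal_center


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "lysosome_id": [r.lysosome_id for r in records],
            "ratio_470_524": [r.ratio_470_524 for r in records],
            "ph": [r.ph for r in records],
            "apod_positive": [r.apod_positive for r in records],
            "condition": [r.condition for r in records],
            "clamped": [r.clamped for r in records],
        }
    )


def ph_distribution(
    records, bin_width: float = 0.1
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Per-(condition, ApoD class) pH frequency distributions.

    Returns a long-format histogram table and a dict mapping
    ``(condition, class_label)`` to the modal bin center.  Classes with no
    records are omitted with a warning.
    """
    df = _records_frame(records)
    rows = []
    modes: dict[tuple[str, str], float] = {}
    for (cond, pos), grp in df.groupby(["condition", "apod_positive"], dropna=False):
        label = "ApoD+" if pos else ("ApoD-" if pos is not None else "unclassified")
        if grp.empty:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"class {label} in {cond} has no records; omitted")
            continue
        centers, counts, modal = ph_histogram(grp["ph"].to_numpy(), bin_width)
        modes[(str(cond), label)] = modal
        for c, n in zip(centers, counts):
            rows.append(
                {"condition": cond, "class": label, "bin_center": c, "count": int(n)}
            )
    return pd.DataFrame(rows), modes


def apod_lysosome_fractions(records) -> pd.DataFrame:
    """Proportion of ApoD-positive / negative lysosomes per condition."""
    df = _records_frame(records)
    out = []
    for cond, grp in df.groupby("condition"):
        n = len(grp)
        pos = int(grp["apod_positive"].sum())
        out.append(
            {
                "condition": cond,
                "n": n,
                "frac_positive": pos / n,
                "frac_negative": (n - pos) / n,
            }
        )
    return pd.DataFrame(out)


def population_ph_excitation(
    f340: Sequence[Sequence[float]],
    f390: Sequence[Sequence[float]],
    standards: Iterable[tuple[float, float]],
) -> pd.DataFrame:
    """Per-well population pH from F340/F390 excitation ratios.

    Each well's replicate readings (nominally six) are averaged per
    wavelength before forming the ratio ``mean(F340)/mean(F390)``; pH is
    obtained by monotone piecewise-linear inverse interpolation through the
    ionophore-clamp standards, with out-of-range ratios clamped and flagged.
    """
    if len(f340) != len(f390):
        raise ValueError("f340 and f390 must list the same wells")
    pts = sorted((float(p), float(r)) for p, r in standards)
    ph_knots = np.array([p for p, _ in pts])
    r_knots = np.array([r for _, r in pts])
    if ph_knots.size < 3:
        raise CalibrationError("underdetermined: need >= 3 standard levels")
    _check_monotone(r_knots)
    curve = CalibrationCurve(
        mode="excitation_interp",
        knots=pts,
        valid_ph_range=(float(ph_knots.min()), float(ph_knots.max())),
    )
    rows = []
    for well, (a, b) in enumerate(zip(f340, f390)):
        ma = float(np.mean(np.asarray(a, dtype=float)))
        mb = float(np.mean(np.asarray(b, dtype=float)))
        if mb == 0:
            raise ValueError(f"zero F390 mean in well {well}")
        ratio = ma / mb
        ph, clamped = curve.ph_from_ratio(ratio)
        rows.append({"well": well, "ratio": ratio, "ph": ph, "clamped": clamped})
    return pd.DataFrame(rows)


def estimate_ph(
    spectra: Sequence[EmissionSpectrum],
    curve: CalibrationCurve,
    apod_flags: Sequence[bool] | None = None,
) -> list[LysosomeRecord]:
    """Full single-lysosome pipeline: Weibull fit -> 470/524 ratio -> pH."""
    records = []
    for i, sp in enumerate(spectra):
        params = fit_weibull5(sp)
        ratio = emission_ratio(params)
        ph, clamped = curve.ph_from_ratio(ratio)
        records.append(
            LysosomeRecord(
                lysosome_id=sp.lysosome_id,
                ratio_470_524=ratio,
                ph=ph,
                apod_positive=None if apod_flags is None else bool(apod_flags[i]),
                condition=sp.condition,
                clamped=clamped,
            )
        )
    return records


def write_spectra_csv(path, spectra: Sequence[EmissionSpectrum]) -> None:
    """Long-format CSV: lysosome_id, condition, wavelength_nm, intensity."""
    rows = []
    for sp in spectra:
        for w, i in zip(sp.wavelengths, sp.intensities):
            rows.append(
                {
                    "lysosome_id": sp.lysosome_id,
                    "condition": sp.condition,
                    "wavelength_nm": w,
                    "intensity": i,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spectra_csv(path) -> list[EmissionSpectrum]:
    df = pd.read_csv(path, comment="#")
    out = []
    for lid, grp in df.groupby("lysosome_id"):
        grp = grp.sort_values("wavelength_nm")
        cond = str(grp["condition"].iloc[0]) if "condition" in grp else "control"
        out.append(
            EmissionSpectrum(
                wavelengths=grp["wavelength_nm"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                lysosome_id=int(lid),
                condition=cond,
            )
        )
    return out
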