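"""Pixel-level colocalization of two fluorescence channels.

The workflow mirrors common confocal practice: Gaussian smoothing (sigma 1),
per-channel thresholding, then two complementary readouts computed over the
reference-channel domain — the intensity correlation quotient (ICQ), a
sign-based covariation statistic in [-0.5, 0.5], and the percent pixel
overlap referenced to channel A (fraction of A-positive voxels that are also
B-positive).  ``2*ICQ`` below 0.1 in magnitude is conventionally treated as
chance-level colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DomainError

__all__ = [
    "ChannelPair",
    "ColocResult",
    "gaussian_preprocess",
    "threshold_channel",
    "icq",
    "overlap_pct",
    "triple_mask",
    "coloc_analysis",
]


@dataclass
class ChannelPair:
    """Two aligned intensity stacks plus an optional analysis ROI."""

    stack_a: np.ndarray
    stack_b: np.ndarray
    roi_mask: np.ndarray | None = None
    names: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.stack_a = np.asarray(self.stack_a, dtype=float)
        self.stack_b = np.asarray(self.stack_b, dtype=float)
        if self.stack_a.shape != self.stack_b.shape:
            raise ValueError("channel stacks must have identical shapes")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.stack_a.shape:
                raise ValueError("roi_mask shape must match the stacks")


@dataclass
class ColocResult:
    """Colocalization readouts for one cell/ROI."""

    icq: float
    two_icq: float
    overlap_pct_ref_a: float | None = None
    n_pixels_used: int = 0
    thresholds: tuple[float, float] | None = None


def gaussian_preprocess(stack: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian-smoothed copy of the stack; ``sigma=0`` returns the input
    unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    stack = np.asarray(stack, dtype=float)
    if sigma == 0:
        return stack
    return ndimage.gaussian_filter(stack, sigma=sigma)


def threshold_channel(stack: np.ndarray, method="otsu") -> tuple[np.ndarray, float]:
    """Boolean mask of voxels above a threshold.

    ``method`` is ``"otsu"``, ``"manual:<value>"`` or a number.  Returns the
    mask and the threshold used.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.size == 0:
        raise ValueError("empty stack")
    if isinstance(method, str) and method == "otsu":
        if np.ptp(stack) == 0:
            raise DomainError("no separable classes: constant image")
        t = float(threshold_otsu(stack))
    elif isinstance(method, str) and method.startswith("manual:"):
        t = float(method.split(":", 1)[1])
    else:
        t = float(method)
    return stack > t, t


def icq(
    pair: ChannelPair,
    domain: np.ndarray | None = None,
    count_zero_products: bool = False,
) -> ColocResult:
    """Intensity correlation quotient over the analysis domain.

    ICQ = (number of voxels whose intensity deviations from the domain means
    covary positively) / (number of voxels with a nonzero deviation product)
    - 0.5.  By default, voxels with an exactly zero product carry no
    covariation information and are excluded from both counts; with
    ``count_zero_products`` they enter the denominator as non-positive.

    The domain is, in order of precedence: the explicit ``domain`` argument,
    the pair's ``roi_mask``, else the Otsu mask of the reference channel A
    (the "referenced to A" reading).
    """
    if domain is None:
        domain = pair.roi_mask
    if domain is None:
        domain, _ = threshold_channel(pair.stack_a, "otsu")
    domain = np.asarray(domain, dtype=bool)
    a = pair.stack_a[domain]
    b = pair.stack_b[domain]
    if a.size < 2:
        raise DomainError("analysis domain must contain >= 2 voxels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DomainError("undefined covariation: constant channel in domain")
    prod = (a - a.mean()) * (b - b.mean())
    n_pos = int(np.sum(prod > 0))
    n_used = int(prod.size if count_zero_products else np.sum(prod != 0))
    if n_used == 0:
        raise DomainError("undefined covariation: all deviation products zero")
    val = n_pos / n_used - 0.5
    return ColocResult(icq=val, two_icq=2 * val, n_pixels_used=n_used)


def overlap_pct(mask_ref: np.ndarray, mask_other: np.ndarray) -> float:
    """Percent of reference-mask voxels that are also in the other mask."""
    mask_ref = np.asarray(mask_ref, dtype=bool)
    mask_other = np.asarray(mask_other, dtype=bool)
    if mask_ref.shape != mask_other.shape:
        raise ValueError("masks must have identical shapes")
    n_ref = int(mask_ref.sum())
    if n_ref == 0:
        raise DomainError("reference domain empty")
    return 100.0 * int((mask_ref & mask_other).sum()) / n_ref


def triple_mask(mask_a, mask_b, mask_c) -> np.ndarray:
    """Voxelwise conjunction of three masks (triple colocalization domain)."""
    a, b, c = (np.asarray(m, dtype=bool) for m in (mask_a, mask_b, mask_c))
    if not (a.shape == b.shape == c.shape):
        raise ValueError("masks must have identical shapes")
    return a & b & c


def coloc_analysis(
    pair: ChannelPair,
    sigma: float = 1.0,
    method="otsu",
    count_zero_products: bool = False,
) -> ColocResult:
    """Full pixel-level pipeline for one cell/ROI: smooth both channels,
    threshold, then ICQ and percent overlap referenced to channel A."""
    sm = ChannelPair(
        gaussian_preprocess(pair.stack_a, sigma),
        gaussian_preprocess(pair.stack_b, sigma),
        roi_mask=pair.roi_mask,
        names=pair.names,
    )
    mask_a, t_a = threshold_channel(sm.stack_a, method)
    mask_b, t_b = threshold_channel(sm.stack_b, method)
    domain = sm.roi_mask if sm.roi_mask is not None else mask_a
    res = icq(sm, domain=domain, count_zero_products=count_zero_products)
    res.overlap_pct_ref_a = overlap_pct(mask_a, mask_b)
    res.thresholds = (t_a, t_b)
    return res
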