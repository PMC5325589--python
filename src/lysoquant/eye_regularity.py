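"""Ommatidial-lattice regularity for compound-eye degeneration assays.

A healthy Drosophila eye surface is a near-perfect hexagonal lattice of
ommatidia; degeneration both removes ommatidia and disorders the lattice.
The quantification detects local intensity maxima, computes each spot's
nearest-neighbour distance, and summarises lattice order with a regularity
index IREG = n_spots / (1 + CV), where CV is the coefficient of variation of
the nearest-neighbour distances.  The index responds to both ommatidial loss
(fewer spots) and disorder (larger CV); it is typically normalized to a
control genotype, and genotype effects are expressed as percent recovery
between a degenerated (0%) and a control (100%) reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = [
    "OmmatidialField",
    "detect_maxima",
    "nn_distances",
    "iregularity",
    "percent_recovery",
    "analyze_field",
]


@dataclass
class OmmatidialField:
    """Detected lattice spots with their regularity summary."""

    coordinates: np.ndarray  # (n, 2) as (row, col)
    nn_dist: np.ndarray
    n_spots: int
    ireg: float
    ireg_normalized: float | None = None


def detect_maxima(
    image: np.ndarray, min_distance: int = 5, rel_threshold: float = 0.3
) -> np.ndarray:
    """Local intensity maxima above ``rel_threshold * max(image)``, no two
    closer than ``min_distance`` pixels, returned in row-major order as
    (row, col) coordinates."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    coords = peak_local_max(
        image, min_distance=min_distance, threshold_rel=rel_threshold,
        exclude_border=False,
    )
    if coords.size == 0:
        return coords.reshape(0, 2)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    return coords[order]


def nn_distances(coordinates: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to its nearest other point."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need >= 2 points")
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return d[:, 1]


def iregularity(
    coordinates: np.ndarray, normalize_to: float | None = None
) -> float:
    """Regularity index IREG = n_spots / (1 + CV of nearest-neighbour
    distances), optionally divided by a reference IREG (control genotype)."""
    d = nn_distances(coordinates)
    mean = d.mean()
    if mean == 0:
        raise ValueError("all nearest-neighbour distances are zero")
    cv = d.std(ddof=1) / mean
    ireg = len(d) / (1.0 + cv)
    if normalize_to is not None:
        if normalize_to <= 0:
            raise ValueError("normalize_to must be > 0")
        ireg /= normalize_to
    return float(ireg)


def percent_recovery(
    ireg_x: float, ireg_degenerated: float, ireg_control: float
) -> float:
    """Linear rescaling with the degenerated mean at 0% and the control at
    100%."""
    denom = ireg_control - ireg_degenerated
    if denom == 0:
        raise ValueError("control and degenerated references coincide")
    return 100.0 * (ireg_x - ireg_degenerated) / denom


def analyze_field(
    image: np.ndarray,
    min_distance: int = 5,
    rel_threshold: float = 0.3,
    normalize_to: float | None = None,
) -> OmmatidialField:
    """Detect maxima and summarise the lattice in one step."""
    coords = detect_maxima(image, min_distance, rel_threshold)
    d = nn_distances(coords)
    ireg = iregularity(coords)
    return OmmatidialField(
        coordinates=coords,
        nn_dist=d,
        n_spots=len(coords),
        ireg=ireg,
        ireg_normalized=None if normalize_to is None else ireg / normalize_to,
    )
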