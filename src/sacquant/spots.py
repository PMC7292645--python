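"""Kinetochore spot-fluorescence quantification.

Budding yeast kinetochores cluster into two groups of 16 in metaphase, so
a cluster's integrated fluorescence is proportional to the number of
kinetochores it contains.  The measurement convention implemented here:
sum the z-stack, take the 6x6-pixel box anchored on the maximum-intensity
pixel, and subtract 36 times the median of the background region (the
one-pixel ring immediately surrounding the box, or a caller-designated
nearby 6x6 area).

The unattached-kinetochore estimator compares the corrected intensity of
the off-axis (checkpoint-protein-marked) cluster with the total corrected
kinetochore fluorescence: estimate = round(N * f_u / (f_u + f_s)) with N
kinetochores in total (default 32).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .stats import mean_sem

__all__ = [
    "SpotStack",
    "SpotMeasurement",
    "KinetochoreCountEstimate",
    "SpotQuantifier",
    "locate_spot",
    "measure_spot",
    "normalize_intensities",
    "estimate_unattached_count",
    "summarize_counts",
]

BOX = 6  # side length, pixels, of the integration box
ANCHOR = 2  # the max pixel sits at box position (ANCHOR, ANCHOR)


@dataclass
class SpotStack:
    """A fluorescence z-stack: planes indexed (z, row, col)."""

    planes: np.ndarray
    z_step: float = 200.0  # nm between adjacent planes
    pixel_size: float | None = None  # nm per pixel, metadata only
    channel: str = ""

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim == 2:
            self.planes = self.planes[None]
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError("SpotStack needs at least one 2-D plane")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    def projected(self, zmode: str = "sum") -> np.ndarray:
        """Combine planes: 'sum' (default; preserves total signal),
        'max' projection, or 'brightest' single plane."""
        if zmode == "sum":
            return self.planes.sum(axis=0)
        if zmode == "max":
            return self.planes.max(axis=0)
        if zmode == "brightest":
            idx = int(np.argmax(self.planes.sum(axis=(1, 2))))
            return self.planes[idx]
        raise ValueError(f"unknown zmode {zmode!r}")


@dataclass
class SpotMeasurement:
    center: tuple[int, int]
    raw_integral: float
    background_per_pixel: float
    corrected_intensity: float
    flagged: bool = False  # corrected below -3 sigma of the background estimate


@dataclass
class KinetochoreCountEstimate:
    f_unattached: float
    f_spindle: float
    total_kinetochores: int
    estimate: int


def locate_spot(
    stack: SpotStack,
    roi: tuple[int, int, int, int] | None = None,
    zmode: str = "sum",
) -> tuple[int, int]:
    """Maximum-intensity pixel of the plane-combined image.

    ``roi`` is (row0, col0, row1, col1), half-open.  Ties break to the
    smallest (row, col) in lexicographic order; an all-equal image warns
    and returns the ROI origin.
    """
    img = stack.projected(zmode)
    r0 = c0 = 0
    if roi is not None:
        r0, c0, r1, c1 = roi
        if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
            raise ValueError(f"roi {roi} outside image {img.shape}")
        img = img[r0:r1, c0:c1]
    if img.max() == img.min():
        warnings.warn("image is constant; returning tie-broken origin", stacklevel=2)
    flat = int(np.argmax(img))  # C order = first smallest (row, col)
    r, c = divmod(flat, img.shape[1])
    return r + r0, c + c0


def _box_slices(center: tuple[int, int], box: int) -> tuple[slice, slice]:
    r, c = center
    anchor = box // 2 - 1 if box % 2 == 0 else box // 2
    return slice(r - anchor, r - anchor + box), slice(c - anchor, c - anchor + box)


def measure_spot(
    stack: SpotStack,
    center: tuple[int, int],
    box: int = BOX,
    zmode: str = "sum",
    background_area: tuple[int, int] | None = None,
) -> SpotMeasurement:
    """Integrated, background-corrected spot intensity.

    ``raw_integral`` sums the plane-combined image over the ``box`` x
    ``box`` region anchored so that ``center`` occupies box position
    (2, 2) for the default even box.  The background per pixel is the
    median of the one-pixel ring around the box, or — when
    ``background_area`` gives the top-left corner of a nearby box-sized
    region — the median of that region.  corrected = raw - box**2 *
    background.  The measurement is flagged when corrected falls below
    -3 sigma of the background-region scatter propagated to the box sum.
    """
    img = stack.projected(zmode)
    rows, cols = _box_slices(center, box)
    ring_rows = slice(rows.start - 1, rows.stop + 1)
    ring_cols = slice(cols.start - 1, cols.stop + 1)
    if ring_rows.start < 0 or ring_cols.start < 0 or ring_rows.stop > img.shape[0] or ring_cols.stop > img.shape[1]:
        raise ValueError(
            f"{box}x{box} box at {center} (plus background ring) exceeds image "
            f"bounds {img.shape}; supply background_area for an edge spot"
        )
    raw = float(img[rows, cols].sum())

    if background_area is None:
        outer = img[ring_rows, ring_cols].copy()
        outer[1:-1, 1:-1] = np.nan
        ring = outer[~np.isnan(outer)]
        bg_pixels = ring
    else:
        br, bc = background_area
        if br < 0 or bc < 0 or br + box > img.shape[0] or bc + box > img.shape[1]:
            raise ValueError("background_area outside image")
        bg_pixels = img[br : br + box, bc : bc + box].ravel()
    background = float(np.median(bg_pixels))
    corrected = raw - box * box * background
    # scatter of the box sum if it contained only background
    sigma = float(np.std(bg_pixels)) * box
    return SpotMeasurement(
        center=tuple(center),
        raw_integral=raw,
        background_per_pixel=background,
        corrected_intensity=corrected,
        flagged=corrected < -3.0 * sigma,
    )


def normalize_intensities(values, reference) -> np.ndarray:
    """Divide each value by the arithmetic mean of the reference set.

    This is the convention used for cross-strain fluorescence scatter
    plots: signals are reported relative to the average signal of a
    control population (e.g. wild type, or nocodazole-treated cells).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference set is empty")
    mean = ref.mean()
    if mean <= 0:
        raise ValueError(f"reference mean {mean} must be positive")
    return np.asarray(values, dtype=float) / mean


def estimate_unattached_count(
    f_unattached: float,
    f_spindle: float,
    total_kinetochores: int = 32,
) -> KinetochoreCountEstimate:
    """Number of kinetochores in the unattached cluster from its share of
    the total kinetochore fluorescence.

    estimate = round(N * f_u / (f_u + f_s)), banker's rounding, with N the
    total kinetochore count (default 32: two metaphase clusters of 16).
    Negative corrected intensities are clipped to zero with a warning.
    """
    if f_unattached < 0 or f_spindle < 0:
        warnings.warn("negative corrected intensity clipped to 0", stacklevel=2)
        f_unattached = max(0.0, f_unattached)
        f_spindle = max(0.0, f_spindle)
    total = f_unattached + f_spindle
    if total == 0:
        raise ValueError("both intensities are zero; estimate undefined")
    est = round(total_kinetochores * f_unattached / total)
    return KinetochoreCountEstimate(
        f_unattached=f_unattached,
        f_spindle=f_spindle,
        total_kinetochores=total_kinetochores,
        estimate=int(est),
    )


def summarize_counts(estimates) -> dict:
    """Mean, sample sd, and relative-frequency histogram over integer bins."""
    x = np.asarray(estimates)
    if x.size == 0:
        raise ValueError("no estimates to summarize")
    counts = np.bincount(x.astype(int))
    freqs = counts / x.size
    mean, sem = mean_sem(x)
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return {
        "mean": mean,
        "sd": sd,
        "sem": sem,
        "n": int(x.size),
        "bins": np.arange(counts.size),
        "frequency": freqs,
    }


class SpotQuantifier(BaseEstimator):
    """Locate-and-measure facade with sklearn-style parameters.

    Parameters
    ----------
    box : int
        Integration box side length (pixels).
    zmode : {"sum", "max", "brightest"}
        How z-planes are combined before locating and integrating.
    total_kinetochores : int
        Total kinetochore count used by :meth:`unattached_count`.
    """

    def __init__(self, box: int = BOX, zmode: str = "sum", total_kinetochores: int = 32):
        self.box = box
        self.zmode = zmode
        self.total_kinetochores = total_kinetochores

    def fit(self, X=None, y=None):
        return self

    def measure(
        self,
        stack: SpotStack,
        roi: tuple[int, int, int, int] | None = None,
        background_area: tuple[int, int] | None = None,
    ) -> SpotMeasurement:
        center = locate_spot(stack, roi=roi, zmode=self.zmode)
        return measure_spot(
            stack, center, box=self.box, zmode=self.zmode, background_area=background_area
        )

    def unattached_count(
        self, unattached: SpotMeasurement, spindle: SpotMeasurement
    ) -> KinetochoreCountEstimate:
        return estimate_unattached_count(
            unattached.corrected_intensity,
            spindle.corrected_intensity,
            self.total_kinetochores,
        )
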