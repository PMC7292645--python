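"""Colony counting and red-sector classification for chromosome-loss plates.

Implements the plate-photograph pipeline of the colony color (sectoring)
assay: yeast carrying a nonessential chromosome fragment are plated on
low-adenine medium; cells that lose the fragment give rise to red or
half-red/half-white sectored colonies, so the frequency of fully red or
at-least-half-sectored colonies per 1000 plated reads out the chromosome
missegregation rate.

The pipeline is: background flattening (median + white top-hat on a
single intensity channel), intensity thresholding, watershed separation of
touching colonies, per-colony red-pixel classification along the a*
(red-green) axis of L*a*b colour space, and exact binomial statistics on
the pooled counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import color as skcolor
from skimage import feature, filters, morphology, segmentation
from sklearn.base import BaseEstimator

from .stats import ContingencyTable2x2, binomial_ci, fisher_exact

__all__ = [
    "PlateImage",
    "ColonyRecord",
    "PlateResult",
    "LossRateEstimate",
    "RateComparison",
    "ColonyCounter",
    "preprocess_plate",
    "segment_colonies",
    "classify_sectoring",
    "summarize_plate",
    "estimate_loss_rate",
    "compare_loss_rates",
]

CLASS_WHITE = "white"
CLASS_HALF = "half_sectored"
CLASS_RED = "red"


@dataclass
class PlateImage:
    """An 8-bit RGB plate photograph."""

    pixels: np.ndarray
    name: str = "plate"
    pixel_size: float | None = None  # mm per pixel, metadata only

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("PlateImage requires an RGB raster with three channels")
        if self.pixels.size == 0:
            raise ValueError("PlateImage is empty")


@dataclass
class ColonyRecord:
    label: int
    centroid: tuple[float, float]  # 0-based (row, col)
    area: int  # pixels
    red_fraction: float = 0.0
    class_label: str = CLASS_WHITE


@dataclass
class PlateResult:
    """Per-plate tallies.  loss_events counts colonies scored as chromosome
    missegregation events: fully red plus at-least-half-sectored colonies."""

    n_total: int
    n_white: int
    n_half: int
    n_red: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_white + self.n_half + self.n_red:
            raise ValueError("class tallies must sum to n_total")

    @property
    def loss_events(self) -> int:
        return self.n_half + self.n_red


@dataclass
class LossRateEstimate:
    events: int
    n: int
    rate_per_1000: float
    ci95: tuple[float, float]  # per-1000 scale


@dataclass
class RateComparison:
    ratio: float
    ratio_defined: bool
    p_two_sided: float
    table: ContingencyTable2x2


# ---------------------------------------------------------------------------
# pipeline stages


def preprocess_plate(
    plate: PlateImage,
    median_radius: int = 2,
    tophat_radius: int = 25,
    channel: str = "red",
) -> np.ndarray:
    """Background-flattened single-channel raster.

    The chosen intensity channel is median-filtered (disk of
    ``median_radius``), then white-top-hat with a disk of
    ``tophat_radius`` — which must exceed the largest expected colony
    radius so that colonies survive the filter while slowly varying
    illumination is removed.  Returns floats in [0, 1].

    ``channel`` defaults to the red channel rather than luminance: the
    pigmented (red) colonies this assay exists to count absorb green
    light, so in luminance they sit barely above the agar and segment
    asymmetrically, whereas in the red channel cream and red colonies
    have nearly equal contrast.  ``channel="luminance"`` is available for
    unpigmented assays.
    """
    img = plate.pixels
    if min(img.shape[:2]) <= 2 * tophat_radius + 1:
        raise ValueError(
            f"image {img.shape[:2]} smaller than top-hat footprint "
            f"(radius {tophat_radius})"
        )
    if channel == "red":
        gray = img[..., 0].astype(float) / 255.0
    elif channel == "luminance":
        gray = skcolor.rgb2gray(img)  # float in [0, 1]
    else:
        raise ValueError("channel must be 'red' or 'luminance'")
    gray = filters.median(gray, footprint=morphology.disk(median_radius))
    # decomposed disk keeps grey morphology tractable on full-size plates
    foot = morphology.disk(tophat_radius, decomposition="sequence")
    return morphology.white_tophat(gray, footprint=foot)


def _median_colony_radius(distance: np.ndarray, mask: np.ndarray) -> float:
    """Median colony-radius estimate: the per-component maximum of the
    distance transform (the inscribed radius), which stays close to the
    true colony radius even when touching colonies merge into one
    component — unlike an area-based estimate, which a merged blob
    inflates."""
    lab, n = ndi.label(mask)
    if n == 0:
        return 1.0
    peak_r = ndi.labeled_comprehension(distance, lab, np.arange(1, n + 1), np.max, float, 0.0)
    return float(np.median(peak_r))


def segment_colonies(
    flattened: np.ndarray,
    min_area: int = 30,
    peak_sep_frac: float = 0.8,
    threshold: float | None = None,
    threshold_scale: float = 0.45,
    min_threshold: float = 0.05,
) -> tuple[np.ndarray, list[ColonyRecord]]:
    """Threshold + watershed segmentation of the flattened plate.

    Foreground defaults to ``threshold_scale`` times the global Otsu split
    of the flattened raster: Otsu lands midway between agar and colonies,
    and scaling it down includes the dimmer rim of dark-red colonies
    symmetrically with cream ones.  ``min_threshold`` is an absolute floor
    (in flattened intensity units, [0, 1]) so a blank plate yields no
    foreground; an explicit ``threshold`` bypasses both.

    Touching colonies are split by watershed on the negated distance
    transform, seeded at distance-map peaks separated by at least
    ``peak_sep_frac`` times the median colony-radius estimate.  Minimum
    peak separation, rather than a depth (h-maxima) criterion, is what
    makes the split robust: rasterised overlapping colonies produce
    spurious shallow maxima in the neck whose prominence overlaps that of
    true peaks, but those always lie closer to a true peak than a colony
    radius and are suppressed spatially.  Components below ``min_area``
    pixels are discarded.  Returns the label map (background 0) and
    per-colony record stubs.
    """
    flattened = np.asarray(flattened, dtype=float)
    if flattened.max() <= 0:
        return np.zeros(flattened.shape, dtype=np.int32), []
    if threshold is None:
        thr = max(threshold_scale * filters.threshold_otsu(flattened), min_threshold)
    else:
        thr = threshold
    mask = flattened > thr
    if not mask.any():
        return np.zeros(flattened.shape, dtype=np.int32), []

    distance = ndi.distance_transform_edt(mask)
    r_med = _median_colony_radius(distance, mask)
    min_dist = max(3, int(round(peak_sep_frac * r_med)))
    coords = feature.peak_local_max(
        distance, min_distance=min_dist, threshold_abs=1.5, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if len(coords) == 0:
        markers, _ = ndi.label(mask)
    labels = segmentation.watershed(-distance, markers, mask=mask)

    # drop sub-minimum fragments produced by the split, then relabel densely
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area)
    small = small[small > 0]
    if small.size:
        labels[np.isin(labels, small)] = 0
    labels = _relabel_dense(labels)

    records = _records_from_labels(labels)
    return labels, records


def _relabel_dense(labels: np.ndarray) -> np.ndarray:
    ids, inverse = np.unique(labels, return_inverse=True)
    lut = np.zeros(ids.size, dtype=np.int32)
    lut[ids > 0] = np.arange(1, int((ids > 0).sum()) + 1)
    return lut[inverse].reshape(labels.shape)


def _records_from_labels(labels: np.ndarray) -> list[ColonyRecord]:
    n = int(labels.max())
    if n == 0:
        return []
    ids = np.arange(1, n + 1)
    centroids = ndi.center_of_mass(np.ones_like(labels), labels, ids)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return [
        ColonyRecord(int(i), (float(r), float(c)), int(a))
        for i, (r, c), a in zip(ids, centroids, areas)
    ]


def classify_sectoring(
    plate: PlateImage,
    labels: np.ndarray,
    records: list[ColonyRecord] | None = None,
    red_threshold: float | str = "otsu",
    half_threshold: float = 0.45,
    red_class_threshold: float = 0.9,
    fallback_red_a: float = 15.0,
    otsu_valid_range: tuple[float, float] = (8.0, 35.0),
) -> list[ColonyRecord]:
    """Per-colony red-pixel fraction along the a* (red-green) axis.

    The plate image is transformed to L*a*b; a pixel is red when its a*
    value exceeds the red threshold.  The default threshold is Otsu over
    all colony pixels' a* values, accepted only when it falls inside
    ``otsu_valid_range`` (a plate with no red — or only red — colonies has
    a unimodal a* distribution on which Otsu returns a spurious split);
    otherwise the fixed ``fallback_red_a`` is used, and a float
    ``red_threshold`` bypasses Otsu entirely.

    Class assignment: red_fraction >= ``red_class_threshold`` -> red;
    >= ``half_threshold`` -> half_sectored; else white.  The half threshold
    defaults to 0.45 rather than 0.50 so exactly-half sectors survive
    pixelisation jitter.

    red_fraction is computed over each colony's one-pixel-eroded interior:
    rim pixels blend colony and agar colour, which would otherwise bias
    the red fraction of sectored colonies downward.
    """
    if labels.shape != plate.pixels.shape[:2]:
        raise ValueError("label map and plate image shapes differ")
    lab_img = skcolor.rgb2lab(plate.pixels)
    a_star = lab_img[..., 1]

    interior = ndi.binary_erosion(labels > 0, structure=np.ones((3, 3)))
    interior_labels = np.where(interior, labels, 0)
    if not interior_labels.any():  # degenerate: colonies too small to erode
        interior_labels = labels

    if isinstance(red_threshold, str):
        if red_threshold != "otsu":
            raise ValueError("red_threshold must be a float or 'otsu'")
        vals = a_star[interior_labels > 0]
        thr = fallback_red_a
        if vals.size and vals.min() < vals.max():
            cand = float(filters.threshold_otsu(vals))
            if otsu_valid_range[0] <= cand <= otsu_valid_range[1]:
                thr = cand
    else:
        thr = float(red_threshold)

    if records is None:
        records = _records_from_labels(labels)
    n = int(labels.max())
    flat = interior_labels.ravel()
    red_counts = np.bincount(flat, weights=(a_star > thr).ravel(), minlength=n + 1)
    member_counts = np.bincount(flat, minlength=n + 1)
    out = []
    for rec in records:
        denom = member_counts[rec.label] if member_counts[rec.label] else rec.area
        red = float(red_counts[rec.label]) / max(1, denom)
        if red >= red_class_threshold:
            cls = CLASS_RED
        elif red >= half_threshold:
            cls = CLASS_HALF
        else:
            cls = CLASS_WHITE
        out.append(
            ColonyRecord(
                label=rec.label,
                centroid=rec.centroid,
                area=rec.area,
                red_fraction=red,
                class_label=cls,
            )
        )
    return out


def summarize_plate(records: list[ColonyRecord]) -> PlateResult:
    """Tally colony classes; loss events are half-sectored plus fully red
    colonies, the assay's scoring rule for missegregation in the first
    division after plating."""
    n_white = sum(r.class_label == CLASS_WHITE for r in records)
    n_half = sum(r.class_label == CLASS_HALF for r in records)
    n_red = sum(r.class_label == CLASS_RED for r in records)
    return PlateResult(
        n_total=n_white + n_half + n_red,
        n_white=n_white,
        n_half=n_half,
        n_red=n_red,
    )


def estimate_loss_rate(
    results: list[PlateResult] | tuple[int, int],
    include_full_red: bool = True,
) -> LossRateEstimate:
    """Pooled chromosome-loss rate per 1000 colonies with exact 95% CI.

    Accepts either a list of :class:`PlateResult` (pooled across plates)
    or a raw ``(events, n)`` pair.  The interval is Clopper-Pearson,
    appropriate for the tiny event counts typical of this assay.
    """
    if isinstance(results, tuple):
        events, n = results
    else:
        if not results:
            raise ValueError("at least one plate required")
        if include_full_red:
            events = sum(r.loss_events for r in results)
        else:
            events = sum(r.n_half for r in results)
        n = sum(r.n_total for r in results)
    if n <= 0:
        raise ValueError("total colony count must be positive")
    lo, hi = binomial_ci(events, n, level=0.95)
    return LossRateEstimate(
        events=events,
        n=n,
        rate_per_1000=1000.0 * events / n,
        ci95=(1000.0 * lo, 1000.0 * hi),
    )


def compare_loss_rates(a: LossRateEstimate, b: LossRateEstimate) -> RateComparison:
    """Rate ratio a/b and two-sided exact p from the pooled 2x2 table."""
    if a.n <= 0 or b.n <= 0:
        raise ValueError("both estimates need n > 0")
    table = ContingencyTable2x2(a.events, a.n - a.events, b.events, b.n - b.events)
    res = fisher_exact(table)
    if b.events > 0:
        ratio, defined = a.rate_per_1000 / b.rate_per_1000, True
    else:
        ratio, defined = math.inf, False
    return RateComparison(
        ratio=ratio, ratio_defined=defined, p_two_sided=res.p_two_sided, table=table
    )


# ---------------------------------------------------------------------------
# estimator facade


class ColonyCounter(BaseEstimator):
    """Plate-photograph colony counter as a parameterised transformer.

    Stateless apart from its parameters; ``fit`` is a no-op so the counter
    composes with sklearn pipelines, and :meth:`analyze` (or ``transform``)
    maps a :class:`PlateImage` to its per-colony records and tallies.

    Parameters
    ----------
    median_radius, tophat_radius : int
        Background-flattening filter sizes (pixels).
    min_area : int
        Minimum colony area in pixels; smaller components are debris.
    peak_sep_frac : float
        Minimum watershed-seed separation as a fraction of the median
        colony radius.
    red_threshold : float or "otsu"
        a* cutoff for red pixels.
    half_threshold, red_class_threshold : float
        red_fraction cutoffs for half-sectored / fully red classes.
    include_full_red : bool
        Count fully red colonies as loss events (the assay default); set
        False to score only half-sectored (first-division) events.
    """

    def __init__(
        self,
        median_radius: int = 2,
        tophat_radius: int = 25,
        min_area: int = 30,
        peak_sep_frac: float = 0.8,
        red_threshold: float | str = "otsu",
        half_threshold: float = 0.45,
        red_class_threshold: float = 0.9,
        include_full_red: bool = True,
    ):
        self.median_radius = median_radius
        self.tophat_radius = tophat_radius
        self.min_area = min_area
        self.peak_sep_frac = peak_sep_frac
        self.red_threshold = red_threshold
        self.half_threshold = half_threshold
        self.red_class_threshold = red_class_threshold
        self.include_full_red = include_full_red

    def fit(self, X=None, y=None):
        return self

    def analyze(self, plate: PlateImage) -> tuple[list[ColonyRecord], PlateResult]:
        flat = preprocess_plate(plate, self.median_radius, self.tophat_radius)
        labels, stubs = segment_colonies(flat, self.min_area, self.peak_sep_frac)
        records = classify_sectoring(
            plate,
            labels,
            stubs,
            red_threshold=self.red_threshold,
            half_threshold=self.half_threshold,
            red_class_threshold=self.red_class_threshold,
        )
        return records, summarize_plate(records)

    def transform(self, X) -> list[PlateResult]:
        """Map a list of :class:`PlateImage` to :class:`PlateResult` tallies."""
        return [self.analyze(p)[1] for p in X]

    def loss_rate(self, plates: list[PlateImage]) -> LossRateEstimate:
        return estimate_loss_rate(self.transform(plates), self.include_full_red)

    @staticmethod
    def records_frame(records: list[ColonyRecord]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.label for r in records],
                "centroid_row": [r.centroid[0] for r in records],
                "centroid_col": [r.centroid[1] for r in records],
                "area_px": [r.area for r in records],
                "red_fraction": [r.red_fraction for r in records],
                "class": [r.class_label for r in records],
            }
        )
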