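"""Synthetic data with known ground truth for the three assay pipelines.

Every downstream stage of this package — colony counting, spot
quantification, doubling-time fitting — is validated against data built
here: agar plates bearing a few hundred partially overlapping colonies of
which a known fraction are fully red or half-sectored; diffraction-limited
fluorescent spots on noisy background in ten-plane z-stacks; and logistic
OD600 trajectories with known doubling time.

All randomness flows from one explicit integer seed per call (no global
RNG state), so identical arguments produce bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .colony import CLASS_HALF, CLASS_RED, CLASS_WHITE, PlateImage
from .growth import GrowthCurve
from .spots import SpotStack

__all__ = [
    "Colony",
    "PlateTruth",
    "SpotTruth",
    "GrowthModel",
    "PackingError",
    "PlacementError",
    "label_for_fraction",
    "generate_plate",
    "generate_sector_plate",
    "match_records_to_truth",
    "render_plate",
    "generate_spot_stack",
    "generate_growth_curve",
    "generate_kinetochore_pair",
    "write_plate",
    "write_stack",
    "write_growth_curve",
]

# plate appearance (8-bit RGB); chosen so that the L*a*b red/green axis
# separates sectors cleanly: cream has a* ~ 0, the red pigment a* >> 0
AGAR_RGB = np.array([48.0, 38.0, 32.0])
CREAM_RGB = np.array([235.0, 228.0, 205.0])
RED_RGB = np.array([190.0, 62.0, 58.0])


class PackingError(RuntimeError):
    """Requested colonies cannot be placed within the attempt budget."""


class PlacementError(ValueError):
    """A spot violates the required margin inside the image."""


def label_for_fraction(sector_fraction: float) -> str:
    """Generator-side labeling rule: 0 -> white, [0.5, 0.9) -> half_sectored,
    >= 0.9 -> red.  Fractions in (0, 0.5) are sub-half sectors and are not
    scored as loss events, hence labeled white."""
    if sector_fraction >= 0.9:
        return CLASS_RED
    if sector_fraction >= 0.5:
        return CLASS_HALF
    return CLASS_WHITE


@dataclass(frozen=True)
class Colony:
    center: tuple[float, float]  # (row, col), pixels
    radius: float  # pixels
    sector_fraction: float  # fraction of area rendered red
    class_label: str
    wedge_start: float = 0.0  # radians; where the red wedge begins


@dataclass
class PlateTruth:
    colonies: list[Colony]
    image_size: int
    seed: int | None = None

    @property
    def n_loss(self) -> int:
        return sum(c.class_label != CLASS_WHITE for c in self.colonies)

    def class_counts(self) -> dict[str, int]:
        out = {CLASS_WHITE: 0, CLASS_HALF: 0, CLASS_RED: 0}
        for c in self.colonies:
            out[c.class_label] += 1
        return out


@dataclass
class SpotTruth:
    """Ground truth for a fluorescence z-stack.

    ``spots`` holds (position, total_intensity) pairs; positions are
    sub-pixel (z, row, col) coordinates in plane/pixel units and the
    intensity is the photon count the spot integrates to over the whole
    stack before noise.
    """

    spots: list[tuple[tuple[float, float, float], float]] = field(default_factory=list)
    background_level: float = 0.0  # photons per pixel per plane
    psf_sigma: float = 1.2  # pixels, isotropic in array coordinates
    n_planes: int = 10
    z_step_nm: float = 200.0

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.n_planes < 1:
            raise ValueError("background_level >= 0 and n_planes >= 1 required")
        for (_, _, _), intensity in self.spots:
            if intensity < 0:
                raise ValueError("spot intensities must be non-negative")


@dataclass
class GrowthModel:
    """Logistic culture-growth model for a static 96-well culture.

    OD(t) = capacity / (1 + ((capacity - od0)/od0) * 2**(-t/doubling_time)).
    Defaults match routine practice: inoculate at OD600 0.05, read every
    20 minutes for 24 hours.
    """

    od0: float = 0.05
    doubling_time: float = 144.0  # minutes
    capacity: float = 1.0  # OD600 plateau; math.inf gives pure exponential growth
    noise_sd: float = 0.005  # additive Gaussian, OD units
    interval: float = 20.0  # minutes between readings
    duration: float = 1440.0  # minutes

    def __post_init__(self) -> None:
        if not (self.od0 > 0 and self.doubling_time > 0):
            raise ValueError("od0 and doubling_time must be positive")
        if self.capacity < self.od0:
            raise ValueError("capacity must be at least od0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def od_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if math.isinf(self.capacity):  # exponential-phase limit
            return self.od0 * np.power(2.0, t / self.doubling_time)
        ratio = (self.capacity - self.od0) / self.od0
        return self.capacity / (1.0 + ratio * np.power(2.0, -t / self.doubling_time))


# ---------------------------------------------------------------------------
# plates


def _sample_colonies(
    n_colonies: int,
    loss_fraction: float,
    half_given_loss: float,
    radius_range: tuple[float, float],
    image_size: int,
    rng: np.random.Generator,
    min_sep_factor: float,
    max_attempts: int,
) -> list[Colony]:
    placed: list[tuple[float, float, float]] = []
    colonies: list[Colony] = []
    attempts = 0
    while len(placed) < n_colonies:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed only {len(placed)} of {n_colonies} colonies after "
                f"{max_attempts} attempts; lower the count or separation"
            )
        attempts += 1
        r = rng.uniform(*radius_range)
        margin = r + 2.0
        row = rng.uniform(margin, image_size - margin)
        col = rng.uniform(margin, image_size - margin)
        ok = all(
            math.hypot(row - pr, col - pc) >= min_sep_factor * (r + prr)
            for pr, pc, prr in placed
        )
        if not ok:
            continue
        placed.append((row, col, r))
        is_loss = rng.random() < loss_fraction
        if is_loss:
            frac = 0.5 if rng.random() < half_given_loss else 1.0
        else:
            frac = 0.0
        colonies.append(
            Colony(
                center=(row, col),
                radius=r,
                sector_fraction=frac,
                class_label=label_for_fraction(frac),
                wedge_start=rng.uniform(0.0, 2.0 * math.pi),
            )
        )
    return colonies


def render_plate(
    truth: PlateTruth,
    gradient: float = 0.0,
    brightness_jitter: np.ndarray | None = None,
) -> PlateImage:
    """Render a PlateTruth to an 8-bit RGB image.

    Colonies are anti-aliased cream disks on dark agar; a colony's red
    sector is the circular wedge of angular fraction ``sector_fraction``
    starting at its ``wedge_start``.  ``gradient`` adds a left-to-right
    linear illumination ramp of that many 8-bit counts across the image.
    """
    size = truth.image_size
    img = np.tile(AGAR_RGB, (size, size, 1))
    for i, colony in enumerate(truth.colonies):
        r0, c0 = colony.center
        rad = colony.radius
        jitter = 1.0 if brightness_jitter is None else brightness_jitter[i]
        lo_r = max(0, int(math.floor(r0 - rad - 2)))
        hi_r = min(size, int(math.ceil(r0 + rad + 2)))
        lo_c = max(0, int(math.floor(c0 - rad - 2)))
        hi_c = min(size, int(math.ceil(c0 + rad + 2)))
        rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        dist = np.hypot(rr - r0, cc - c0)
        cov = np.clip(rad + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
        body = CREAM_RGB * jitter
        patch = np.tile(body, (*cov.shape, 1))
        if colony.sector_fraction > 0:
            theta = np.mod(np.arctan2(rr - r0, cc - c0) - colony.wedge_start, 2 * math.pi)
            in_wedge = theta < 2 * math.pi * colony.sector_fraction
            patch[in_wedge] = RED_RGB * jitter
        tile = img[lo_r:hi_r, lo_c:hi_c]
        img[lo_r:hi_r, lo_c:hi_c] = tile * (1 - cov[..., None]) + patch * cov[..., None]
    if gradient:
        ramp = np.linspace(0.0, gradient, size)
        img = img + ramp[None, :, None]
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return PlateImage(pixels=img, name="synthetic")


def generate_plate(
    n_colonies: int,
    loss_fraction: float = 0.004,
    half_given_loss: float = 0.5,
    radius_range: tuple[float, float] = (8.0, 14.0),
    image_size: int = 1024,
    seed: int = 0,
    min_sep_factor: float = 1.2,
    gradient: float = 0.0,
    max_attempts: int | None = None,
) -> tuple[PlateImage, PlateTruth]:
    """Synthetic sectoring-assay plate with ground truth.

    ``loss_fraction`` is the per-colony probability of a chromosome-loss
    event; ``half_given_loss`` the conditional probability the event is a
    first-division (half-sectored) one rather than a fully red colony.
    ``min_sep_factor`` scales the minimum allowed center distance,
    ``min_sep_factor * (r_i + r_j)``: 1.2 yields well-separated colonies,
    0.8 produces touching pairs that stress the watershed split.
    """
    if n_colonies < 0:
        raise ValueError("n_colonies must be non-negative")
    for p in (loss_fraction, half_given_loss):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if radius_range[0] <= 0 or radius_range[1] >= image_size / 4:
        raise ValueError("radii must be positive and smaller than image_size/4")
    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = max(1000, 400 * n_colonies)
    colonies = _sample_colonies(
        n_colonies, loss_fraction, half_given_loss, radius_range,
        image_size, rng, min_sep_factor, max_attempts,
    )
    truth = PlateTruth(colonies=colonies, image_size=image_size, seed=seed)
    jitter = rng.uniform(0.95, 1.05, size=max(1, n_colonies))
    image = render_plate(truth, gradient=gradient, brightness_jitter=jitter)
    return image, truth


def generate_sector_plate(
    n_colonies: int,
    fractions,
    seed: int,
    image_size: int = 512,
    radius: float = 10.0,
    min_sep: float = 30.0,
) -> tuple[PlateImage, PlateTruth]:
    """A plate whose colonies carry prescribed sector fractions (cycled).

    Unlike :func:`generate_plate`, sectoring is deterministic rather than
    binomial — useful for classification validation where every class must
    be represented a known number of times.
    """
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    budget = 200 * n_colonies + 1000
    while len(centers) < n_colonies:
        attempts += 1
        if attempts > budget:
            raise PackingError(f"could not place {n_colonies} colonies at {min_sep} px spacing")
        margin = radius + 2
        p = rng.uniform(margin, image_size - margin, size=2)
        if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in centers):
            centers.append((float(p[0]), float(p[1])))
    colonies = [
        Colony(
            center=centers[i],
            radius=radius,
            sector_fraction=fractions[i % len(fractions)],
            class_label=label_for_fraction(fractions[i % len(fractions)]),
            wedge_start=rng.uniform(0, 2 * math.pi),
        )
        for i in range(n_colonies)
    ]
    truth = PlateTruth(colonies=colonies, image_size=image_size, seed=seed)
    jitter = rng.uniform(0.95, 1.05, size=max(1, n_colonies))
    return render_plate(truth, brightness_jitter=jitter), truth


def match_records_to_truth(records, truth: PlateTruth):
    """Pair each detected colony record with its nearest ground-truth
    colony; yields (record, truth_colony, centroid_distance)."""
    from scipy.spatial import cKDTree

    centers = np.array([c.center for c in truth.colonies])
    tree = cKDTree(centers)
    out = []
    for rec in records:
        dist, idx = tree.query(rec.centroid)
        out.append((rec, truth.colonies[int(idx)], float(dist)))
    return out


# ---------------------------------------------------------------------------
# spot stacks


def _axis_profile(n: int, mu: float, sigma: float) -> np.ndarray:
    """Integral of a unit 1-D Gaussian over each unit-width voxel [i, i+1)
    centred at i + 0 (voxel i spans [i - 0.5, i + 0.5))."""
    from scipy.special import erf

    edges = np.arange(n + 1) - 0.5
    cdf = 0.5 * (1.0 + erf((edges - mu) / (sigma * math.sqrt(2.0))))
    return np.diff(cdf)


def generate_spot_stack(
    truth: SpotTruth,
    noise: str = "none",
    image_size: int = 64,
    seed: int = 0,
) -> SpotStack:
    """Render a SpotTruth into a z-stack.

    Each spot contributes an isotropic (in array coordinates) Gaussian
    whose integral over the entire stack equals its total_intensity before
    noise; the constant background is added to every pixel of every plane,
    and per-pixel Poisson noise is applied when ``noise="poisson"``.
    """
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    margin = 3.0 * truth.psf_sigma
    stack = np.full((truth.n_planes, image_size, image_size), float(truth.background_level))
    for (z, row, col), intensity in truth.spots:
        if not (margin <= row <= image_size - 1 - margin and margin <= col <= image_size - 1 - margin):
            raise PlacementError(
                f"spot at ({z}, {row}, {col}) violates the 3-sigma margin "
                f"({margin:.1f} px) inside a {image_size}-px image"
            )
        if not 0 <= z <= truth.n_planes - 1:
            raise PlacementError(f"spot plane {z} outside stack of {truth.n_planes}")
        pz = _axis_profile(truth.n_planes, z, truth.psf_sigma)
        pr = _axis_profile(image_size, row, truth.psf_sigma)
        pc = _axis_profile(image_size, col, truth.psf_sigma)
        stack += intensity * pz[:, None, None] * pr[None, :, None] * pc[None, None, :]
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        stack = rng.poisson(stack).astype(float)
    return SpotStack(planes=stack, z_step=truth.z_step_nm)


def generate_kinetochore_pair(
    n_unattached: int,
    total_kinetochores: int = 32,
    intensity_per_kinetochore: float = 2000.0,
    background: float = 100.0,
    psf_sigma: float = 1.2,
    noise: str = "none",
    image_size: int = 64,
    seed: int = 0,
) -> tuple[SpotStack, dict]:
    """One synthetic cell: an unattached kinetochore cluster plus the
    spindle-axis cluster holding the remaining kinetochores.

    The two clusters are rendered as single spots (kinetochores within a
    cluster are diffraction-unresolved) whose intensities are proportional
    to their kinetochore counts.  Returns the stack and a dict with the
    true count and an ROI around each cluster for measurement.
    """
    if not 0 <= n_unattached <= total_kinetochores:
        raise ValueError("n_unattached must lie in [0, total_kinetochores]")
    rng = np.random.default_rng(seed)
    z_mid = (10 - 1) / 2.0
    quarter = image_size / 4.0
    pos_u = (
        z_mid + rng.uniform(-0.5, 0.5),
        quarter + rng.uniform(-2, 2),
        image_size / 2.0 + rng.uniform(-2, 2),
    )
    pos_s = (
        z_mid + rng.uniform(-0.5, 0.5),
        3 * quarter + rng.uniform(-2, 2),
        image_size / 2.0 + rng.uniform(-2, 2),
    )
    spots = []
    if n_unattached > 0:
        spots.append((pos_u, n_unattached * intensity_per_kinetochore))
    n_spindle = total_kinetochores - n_unattached
    if n_spindle > 0:
        spots.append((pos_s, n_spindle * intensity_per_kinetochore))
    truth = SpotTruth(spots=spots, background_level=background, psf_sigma=psf_sigma)
    stack = generate_spot_stack(
        truth, noise=noise, image_size=image_size, seed=int(rng.integers(2**31))
    )
    half = image_size // 2
    return stack, {
        "n_unattached": n_unattached,
        "total_kinetochores": total_kinetochores,
        "roi_unattached": (0, 0, half, image_size),
        "roi_spindle": (half, 0, image_size, image_size),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# growth curves


def generate_growth_curve(
    model: GrowthModel,
    seed: int = 0,
    well: str = "A1",
    strain: str = "",
    condition: str = "",
) -> GrowthCurve:
    """Sample the logistic trajectory every ``model.interval`` minutes with
    additive Gaussian read noise, truncated at zero."""
    t = np.arange(0.0, model.duration + 0.5 * model.interval, model.interval)
    od = model.od_at(t)
    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, model.noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    return GrowthCurve(times=t, od=od, well=well, strain=strain, condition=condition)


# ---------------------------------------------------------------------------
# sidecar output


def write_plate(image: PlateImage, truth: PlateTruth, out_dir, stem: str = "plate") -> dict:
    """PNG image + ground-truth CSV (one row per colony) + JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    png = out / f"{stem}.png"
    iio.imwrite(png, image.pixels)
    df = pd.DataFrame(
        {
            "center_row": [c.center[0] for c in truth.colonies],
            "center_col": [c.center[1] for c in truth.colonies],
            "radius_px": [c.radius for c in truth.colonies],
            "sector_fraction": [c.sector_fraction for c in truth.colonies],
            "class": [c.class_label for c in truth.colonies],
        }
    )
    csv = out / f"{stem}_truth.csv"
    df.to_csv(csv, index=False)
    meta = {"seed": truth.seed, "image_size": truth.image_size, "n_colonies": len(truth.colonies)}
    meta_path = out / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"image": png, "truth": csv, "meta": meta_path}


def write_stack(stack: SpotStack, truth: SpotTruth, out_dir, stem: str = "stack") -> dict:
    """Plane-ordered 16-bit grayscale TIFF + spot CSV + JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif = out / f"{stem}.tif"
    data = np.clip(np.round(stack.planes), 0, 65535).astype(np.uint16)
    tifffile.imwrite(tif, data, metadata={"z_step_nm": stack.z_step})
    df = pd.DataFrame(
        {
            "z": [p[0] for p, _ in truth.spots],
            "row": [p[1] for p, _ in truth.spots],
            "col": [p[2] for p, _ in truth.spots],
            "total_intensity": [i for _, i in truth.spots],
        }
    )
    csv = out / f"{stem}_truth.csv"
    df.to_csv(csv, index=False)
    meta = {
        "background_level": truth.background_level,
        "psf_sigma": truth.psf_sigma,
        "n_planes": truth.n_planes,
        "z_step_nm": truth.z_step_nm,
    }
    meta_path = out / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"stack": tif, "truth": csv, "meta": meta_path}


def write_growth_curve(curve: GrowthCurve, model: GrowthModel, out_dir, stem: str = "growth") -> dict:
    """Long-format CSV (time_min, well, od) + JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv = out / f"{stem}.csv"
    pd.DataFrame({"time_min": curve.times, "well": curve.well, "od": curve.od}).to_csv(
        csv, index=False
    )
    meta = {
        "od0": model.od0,
        "doubling_time": model.doubling_time,
        "capacity": model.capacity,
        "noise_sd": model.noise_sd,
        "interval": model.interval,
        "duration": model.duration,
    }
    meta_path = out / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"curve": csv, "meta": meta_path}
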