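"""Readers for the file formats the CLI consumes."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .colony import PlateImage
from .growth import GrowthCurve
from .spots import SpotStack


def read_plate_image(path) -> PlateImage:
    """Load a PNG/TIFF/JPEG plate photograph as an RGB PlateImage."""
    path = Path(path)
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:  # drop alpha
        img = img[..., :3]
    return PlateImage(pixels=img, name=path.stem)


def read_stack(path, z_step: float = 200.0, channel: str = "") -> SpotStack:
    """Load a plane-ordered grayscale TIFF as a SpotStack."""
    data = tifffile.imread(Path(path))
    return SpotStack(planes=np.asarray(data, dtype=float), z_step=z_step, channel=channel)


def read_growth_curves(path, plate_map=None) -> list[GrowthCurve]:
    """Load OD600 time series from CSV.

    Long format needs columns (time_min, well, od); any other layout is
    treated as a wide plate-reader export with a time column first and one
    column per well.  ``plate_map`` is an optional CSV path with columns
    (well, strain, condition).
    """
    df = pd.read_csv(path)
    mapping = {}
    if plate_map is not None:
        m = pd.read_csv(plate_map)
        for _, row in m.iterrows():
            mapping[str(row["well"])] = (
                str(row.get("strain", "")),
                str(row.get("condition", "")),
            )
    curves = []
    cols = {c.lower() for c in df.columns}
    if {"time_min", "well", "od"} <= cols:
        df.columns = [c.lower() for c in df.columns]
        for well, grp in df.groupby("well", sort=True):
            grp = grp.sort_values("time_min")
            strain, condition = mapping.get(str(well), ("", ""))
            curves.append(
                GrowthCurve(
                    times=grp["time_min"].to_numpy(),
                    od=grp["od"].to_numpy(),
                    well=str(well),
                    strain=strain,
                    condition=condition,
                )
            )
    else:  # wide export: first column time, remaining columns wells
        tcol = df.columns[0]
        for well in df.columns[1:]:
            strain, condition = mapping.get(str(well), ("", ""))
            curves.append(
                GrowthCurve(
                    times=df[tcol].to_numpy(dtype=float),
                    od=df[well].to_numpy(dtype=float),
                    well=str(well),
                    strain=strain,
                    condition=condition,
                )
            )
    return curves
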