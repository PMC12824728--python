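"""Domain types, label conventions, calibration, and file I/O.

Label convention used throughout the package: 0 = background, 1 = root hair,
2 = root.  Coordinates are row-major with the origin at the top-left corner;
the row index increases downwards, so a root whose tip "points down" has its
tip at the maximum row index.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InputError, LabelConventionError

#: legal mask labels
BACKGROUND, HAIR, ROOT = 0, 1, 2
VALID_LABELS = frozenset((BACKGROUND, HAIR, ROOT))

#: fixed column order of the summary table
SUMMARY_COLUMNS = (
    "name",
    "batch_id",
    "mean_rhl",
    "max_rhl",
    "min_rhl",
    "total_rha",
    "max_rhl_delta",
    "max_rhl_delta_pos",
    "max_rha_delta",
    "max_rha_delta_pos",
    "ez_distance",
    "ez_start",
    "ez_end",
    "ez_gradient",
    "root_thickness",
    "captured_root_length",
    "rh_pixel_intensity_mean",
    "background_pixel_intensity_mean",
    "rh_background_ratio",
)

#: fixed column order of the raw per-bin table
RAW_COLUMNS = (
    "name",
    "bin_index",
    "side",
    "distance_mm",
    "rhl_mm",
    "rha_mm2",
    "root_width_mm",
)


@dataclass(frozen=True)
class RawImage:
    """An 8-bit RGB microscope image, shape (height, width, 3)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"expected an RGB (H, W, 3) array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError("image must contain at least one pixel")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def grayscale(self) -> np.ndarray:
        """Channel-mean grayscale intensity, float64 in [0, 255]."""
        return self.pixels.mean(axis=2)


@dataclass(frozen=True)
class LabeledMask:
    """A per-pixel label grid with values in {0, 1, 2}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise InputError(f"expected a 2D label grid, got shape {lab.shape}")
        bad = np.setdiff1d(np.unique(lab), sorted(VALID_LABELS))
        if bad.size:
            raise LabelConventionError(
                f"mask contains labels outside {{0, 1, 2}}: {bad.tolist()}"
            )
        object.__setattr__(self, "labels", lab.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def root(self) -> np.ndarray:
        return self.labels == ROOT

    def hair(self) -> np.ndarray:
        return self.labels == HAIR

    def background(self) -> np.ndarray:
        return self.labels == BACKGROUND


@dataclass(frozen=True)
class CalibrationConfig:
    """Pixel-to-physical calibration and spatial binning.

    Parameters
    ----------
    conv
        Pixels per millimetre.  All reported lengths are px / conv and areas
        px^2 / conv^2.
    resolution
        Sliding-window bin size along the root, in pixels (rows of the
        straightened root per bin).
    length_cutoff
        If set, only the first ``length_cutoff`` millimetres from the root
        tip enter the summary statistics and the raw table.
    """

    conv: float = 102.0
    resolution: int = 20
    length_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.conv > 0:
            raise InputError(f"conv must be positive, got {self.conv}")
        if int(self.resolution) != self.resolution or self.resolution < 1:
            raise InputError(f"resolution must be a positive integer, got {self.resolution}")
        if self.length_cutoff is not None and not self.length_cutoff > 0:
            raise InputError(f"length_cutoff must be positive, got {self.length_cutoff}")

    @property
    def bin_mm(self) -> float:
        """Width of one bin in millimetres."""
        return self.resolution / self.conv


@dataclass
class TraitSummary:
    """Per-image summary traits, in millimetres / square millimetres.

    Intensity fields are ``nan`` when no raw image was supplied; they are
    written as empty CSV cells (zero is a legal intensity).
    """

    name: str
    batch_id: str
    mean_rhl: float = math.nan
    max_rhl: float = math.nan
    min_rhl: float = math.nan
    total_rha: float = math.nan
    max_rhl_delta: float = math.nan
    max_rhl_delta_pos: float = math.nan
    max_rha_delta: float = math.nan
    max_rha_delta_pos: float = math.nan
    ez_distance: float = math.nan
    ez_start: float = math.nan
    ez_end: float = math.nan
    ez_gradient: float = math.nan
    root_thickness: float = math.nan
    captured_root_length: float = math.nan
    rh_pixel_intensity_mean: float = math.nan
    background_pixel_intensity_mean: float = math.nan
    rh_background_ratio: float = math.nan

    def as_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def read_image(path: str | os.PathLike) -> RawImage:
    """Read an 8-bit PNG/TIFF/JPEG image; grayscale inputs are replicated to RGB."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder errors vary by backend
        raise InputError(f"could not decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]  # drop alpha
    else:
        raise InputError(f"unsupported image layout {arr.shape} in {path}")
    return RawImage(arr)


def write_image(image: RawImage, path: str | os.PathLike) -> None:
    iio.imwrite(Path(path), image.pixels)


def read_mask(path: str | os.PathLike) -> LabeledMask:
    """Read a single-channel PNG mask and validate the {0, 1, 2} convention."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"mask file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise InputError(f"could not decode mask {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # accept single-channel images saved with redundant channels
        if not (arr == arr[:, :, :1]).all():
            raise LabelConventionError(f"mask {path} is not single-channel")
        arr = arr[:, :, 0]
    return LabeledMask(arr)


def write_mask(mask: LabeledMask, path: str | os.PathLike) -> None:
    """Write a mask as single-channel PNG with literal values 0/1/2."""
    iio.imwrite(Path(path), mask.labels)


def summaries_frame(summaries: Iterable[TraitSummary]) -> pd.DataFrame:
    rows = [s.as_row() for s in summaries]
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def raw_frame(profiles: Sequence) -> pd.DataFrame:
    """Long-format per-(image, bin, side) table from BinProfile objects."""
    records = []
    for prof in profiles:
        for side in ("left", "right"):
            rhl = prof.rhl_left if side == "left" else prof.rhl_right
            rha = prof.rha_left if side == "left" else prof.rha_right
            for i in range(len(prof.distance_mm)):
                records.append(
                    {
                        "name": prof.name,
                        "bin_index": i,
                        "side": side,
                        "distance_mm": prof.distance_mm[i],
                        "rhl_mm": rhl[i],
                        "rha_mm2": rha[i],
                        "root_width_mm": prof.root_width_mm[i],
                    }
                )
    return pd.DataFrame(records, columns=list(RAW_COLUMNS))


def write_tables(
    summaries: Sequence[TraitSummary],
    raw: Sequence,
    out_dir: str | os.PathLike,
    batch_id: str,
) -> tuple[Path, Path]:
    """Write ``summary.csv`` and ``raw.csv`` under ``out_dir/batch_id``.

    Returns the two file paths.  Missing values are written as empty cells.
    """
    out = Path(out_dir) / batch_id
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from exc
    summary_path = out / "summary.csv"
    raw_path = out / "raw.csv"
    try:
        summaries_frame(summaries).to_csv(summary_path, index=False, na_rep="")
        raw_frame(raw).to_csv(raw_path, index=False, na_rep="")
    except OSError as exc:
        raise InputError(f"cannot write tables under {out}: {exc}") from exc
    return summary_path, raw_path
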