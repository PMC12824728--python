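"""Batch orchestration: configuration, per-image processing, QC, logging.

Each image is processed independently; a failure is recorded in the status
log with its stage and taxonomised error code and never aborts the batch.
Outputs land under ``<output>/<batch_id>/``: ``summary.csv``, ``raw.csv``,
``qc.csv``, ``run.log`` and optional per-image figures.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, rfc, traits
from .errors import InputError, RootFringeError
from .io import (
    CalibrationConfig,
    LabeledMask,
    RawImage,
    TraitSummary,
    read_image,
    read_mask,
    write_tables,
)

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class RunConfig:
    input: Path
    output: Path
    batch_id: str
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    masks: Path | None = None          # directory of masks paired by stem
    rfc_model: Path | None = None      # predict masks with a trained forest
    plot_summary: bool = False
    plot_segmentation: bool = False
    plot_transformation: bool = False
    seed: int = 0
    lowess_frac: float = 0.1
    qc_z_threshold: float = 3.0

    def __post_init__(self) -> None:
        self.input = Path(self.input)
        self.output = Path(self.output)
        if not self.batch_id:
            raise InputError("batch_id must be non-empty")
        if not self.input.exists():
            raise InputError(f"input path does not exist: {self.input}")
        if self.masks is not None and self.rfc_model is not None:
            raise InputError("choose one mask source: --masks or --rfc-model")


@dataclass
class ImageStatus:
    name: str
    ok: bool
    stage: str = "done"
    code: str = ""
    message: str = ""
    seconds: float = 0.0


def _list_inputs(d: Path) -> list[Path]:
    files = sorted(p for p in d.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not files:
        raise InputError(f"no image files found in {d}")
    return files


def process_image(
    mask: LabeledMask,
    image: RawImage | None,
    name: str,
    batch_id: str,
    cal: CalibrationConfig,
    lowess_frac: float = 0.1,
) -> tuple[TraitSummary, traits.BinProfile, geometry.StraightenedScene]:
    """Run geometry + trait extraction for one mask (and optional image)."""
    density = (
        traits.density_proxy(image, mask)
        if image is not None
        else (float("nan"),) * 3
    )
    scene = geometry.normalize(mask, cal)
    profile = traits.bin_profile(scene, cal, name=name)
    _, length = traits.root_metrics(scene, cal)
    summary = traits.summarize(
        profile,
        cal,
        name=name,
        batch_id=batch_id,
        captured_length_mm=length,
        density=density,
        lowess_frac=lowess_frac,
    )
    if cal.length_cutoff is not None:
        profile = profile.truncate(cal.length_cutoff)
    return summary, profile, scene


def run_batch(config: RunConfig) -> tuple[Path, Path, list[ImageStatus]]:
    """Process every input image/mask; write tables, QC and the status log."""
    out_dir = config.output / config.batch_id
    out_dir.mkdir(parents=True, exist_ok=True)
    cal = config.calibration

    model = rfc.load_model(config.rfc_model) if config.rfc_model else None
    inputs = _list_inputs(config.input)

    summaries: list[TraitSummary] = []
    profiles: list[traits.BinProfile] = []
    statuses: list[ImageStatus] = []

    for path in inputs:
        name = path.stem
        t0 = time.perf_counter()
        stage = "read"
        try:
            image: RawImage | None = None
            if model is not None:
                image = read_image(path)
                stage = "segment"
                mask = rfc.predict_mask(model, image)
            elif config.masks is not None:
                image = read_image(path)
                mpath = _paired_mask(config.masks, name)
                mask = read_mask(mpath)
            else:  # masks-only mode: the inputs are the masks
                mask = read_mask(path)
            stage = "traits"
            summary, profile, scene = process_image(
                mask, image, name, config.batch_id, cal, config.lowess_frac
            )
            summaries.append(summary)
            profiles.append(profile)
            statuses.append(
                ImageStatus(name, True, seconds=time.perf_counter() - t0)
            )
            _maybe_plot(config, out_dir, name, mask, scene, profile, cal)
        except RootFringeError as exc:
            statuses.append(
                ImageStatus(
                    name,
                    False,
                    stage=stage,
                    code=exc.code,
                    message=str(exc),
                    seconds=time.perf_counter() - t0,
                )
            )

    summary_path, raw_path = write_tables(summaries, profiles, config.output, config.batch_id)
    qc = qc_report(summaries, config.qc_z_threshold)
    qc.to_csv(out_dir / "qc.csv", index=False)
    with open(out_dir / "run.log", "w") as fh:
        for st in statuses:
            fh.write(json.dumps(vars(st)) + "\n")
    return summary_path, raw_path, statuses


def _paired_mask(masks_dir: Path, stem: str) -> Path:
    for suffix in (".png", "_mask.png"):
        cand = Path(masks_dir) / f"{stem}{suffix}"
        if cand.is_file():
            return cand
    raise InputError(f"no mask found for image stem {stem!r} in {masks_dir}")


def _maybe_plot(config, out_dir, name, mask, scene, profile, cal) -> None:
    if not (config.plot_summary or config.plot_segmentation or config.plot_transformation):
        return
    from . import plotting

    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    if config.plot_segmentation:
        plotting.plot_segmentation(mask, fig_dir / f"{name}_segmentation.png")
    if config.plot_transformation:
        plotting.plot_transformation(mask, scene.mask, fig_dir / f"{name}_transformation.png")
    if config.plot_summary:
        try:
            ez = traits.elongation_zone(
                profile.mean_rhl_series(), profile.distance_mm, cal, config.lowess_frac
            )
        except RootFringeError:
            ez = None
        plotting.plot_summary(profile, ez, fig_dir / f"{name}_summary.png")


def qc_report(summaries: list[TraitSummary], z_threshold: float = 3.0) -> pd.DataFrame:
    """Flag images whose background intensity deviates from the batch.

    Consistent backlighting shows up as a low coefficient of variation of the
    background mean; images beyond ``z_threshold`` standard deviations are
    flagged as lighting outliers.
    """
    if not summaries:
        raise InputError("qc_report needs at least one summary")
    bg = np.array([s.background_pixel_intensity_mean for s in summaries], dtype=float)
    names = [s.name for s in summaries]
    valid = np.isfinite(bg)
    if not valid.any():
        return pd.DataFrame(
            columns=["name", "background_mean", "batch_mean", "batch_sd", "batch_cv", "zscore", "flagged"]
        )
    mean = bg[valid].mean()
    sd = bg[valid].std(ddof=1) if valid.sum() > 1 else float("nan")
    cv = sd / mean if mean and np.isfinite(sd) else float("nan")
    if np.isfinite(sd) and sd > 0:
        z = (bg - mean) / sd
    else:
        z = np.full_like(bg, np.nan)
    flagged = np.isfinite(z) & (np.abs(z) > z_threshold)
    return pd.DataFrame(
        {
            "name": names,
            "background_mean": bg,
            "batch_mean": mean,
            "batch_sd": sd,
            "batch_cv": cv,
            "zscore": z,
            "flagged": flagged,
        }
    )
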