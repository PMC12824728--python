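"""Per-bin root-hair profiles and per-image summary traits.

All measurements operate on a straightened, tip-down scene.  Rows of the
straightened root are tiled into consecutive bins of ``resolution`` rows
starting at the tip; per bin and per side the pipeline records

* RHL (root-hair length): the maximum per-row lateral extent of the hair
  fringe measured from the root boundary column — i.e. the width of the hair
  mask, which does not follow the curvature of individual hairs;
* RHA (root-hair area): the hair pixel count in the bin.

The elongation zone is the longest run of bins over which the
LOWESS-smoothed mean profile keeps rising; heterogeneity traits record the
largest left/right asymmetry and where along the root it occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DegenerateRootError, InputError
from .geometry import StraightenedScene
from .io import CalibrationConfig, LabeledMask, RawImage, TraitSummary


@dataclass
class BinProfile:
    """Per-bin, per-side measurements, ordered by distance from the tip."""

    name: str
    distance_mm: np.ndarray      # bin centres, mm from the tip
    rhl_left: np.ndarray         # mm
    rhl_right: np.ndarray
    rha_left: np.ndarray         # mm^2
    rha_right: np.ndarray
    root_width_mm: np.ndarray
    hair_px_left: np.ndarray = field(repr=False, default=None)   # exact counts
    hair_px_right: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.distance_mm)

    def mean_rhl_series(self) -> np.ndarray:
        return (self.rhl_left + self.rhl_right) / 2.0

    def truncate(self, cutoff_mm: float) -> "BinProfile":
        """Keep only bins whose centre lies within ``cutoff_mm`` of the tip."""
        keep = self.distance_mm <= cutoff_mm
        if not keep.any():
            raise DegenerateRootError(
                f"length cutoff {cutoff_mm} mm retains no bins "
                f"(first bin centre at {self.distance_mm[0]:.3f} mm)"
            )
        return BinProfile(
            name=self.name,
            distance_mm=self.distance_mm[keep],
            rhl_left=self.rhl_left[keep],
            rhl_right=self.rhl_right[keep],
            rha_left=self.rha_left[keep],
            rha_right=self.rha_right[keep],
            root_width_mm=self.root_width_mm[keep],
            hair_px_left=self.hair_px_left[keep],
            hair_px_right=self.hair_px_right[keep],
        )


@dataclass
class ElongationZone:
    """Boundaries (mm from tip) and gradient of the hair elongation zone."""

    start: float
    end: float
    distance: float
    gradient: float
    side: str = "mean"


def _row_extents(scene: StraightenedScene, side_mask: np.ndarray, left: bool) -> np.ndarray:
    """Per-row lateral hair extent (px) from the root boundary, full height."""
    H = scene.mask.height
    ext = np.zeros(H)
    rr, cc = np.nonzero(side_mask)
    if rr.size == 0:
        return ext
    bound = scene.c_min[rr] if left else scene.c_max[rr]
    reach = (bound - cc) if left else (cc - bound)
    np.maximum.at(ext, rr, np.maximum(reach, 0))
    return ext


def bin_profile(scene: StraightenedScene, cal: CalibrationConfig, name: str = "") -> BinProfile:
    """Tile the straightened root into bins and measure RHL/RHA per side.

    Bin ``i`` covers rows ``(tip - (i+1)*res, tip - i*res]``; hair pixels
    below the tip row (stray warp output) are folded into bin 0 so that the
    binned areas partition the hair mask exactly.
    """
    res = cal.resolution
    tip_row = scene.tip[0]
    nbins = (tip_row - scene.top_row) // res + 1
    if nbins < 2:
        raise DegenerateRootError("root spans fewer than 2 bins")

    H = scene.mask.height
    all_rows = np.arange(H)
    bin_of = np.maximum(tip_row - all_rows, 0) // res  # rows below tip -> bin 0
    ext_l = _row_extents(scene, scene.left_hair, left=True)
    ext_r = _row_extents(scene, scene.right_hair, left=False)

    rhl_l = np.zeros(nbins)
    rhl_r = np.zeros(nbins)
    cnt_l = np.zeros(nbins, dtype=int)
    cnt_r = np.zeros(nbins, dtype=int)
    width = np.zeros(nbins)

    row_cnt_l = scene.left_hair.sum(axis=1)
    row_cnt_r = scene.right_hair.sum(axis=1)
    root_rows = scene.root_rows()
    row_width = scene.row_width()
    width_bin = bin_of[root_rows]

    for b in range(nbins):
        rows_b = all_rows[(bin_of == b) & (all_rows >= scene.top_row)]
        if rows_b.size:
            rhl_l[b] = ext_l[rows_b].max()
            rhl_r[b] = ext_r[rows_b].max()
            cnt_l[b] = row_cnt_l[rows_b].sum()
            cnt_r[b] = row_cnt_r[rows_b].sum()
        wsel = width_bin == b
        if wsel.any():
            width[b] = row_width[wsel].mean()

    centres = (np.arange(nbins) + 0.5) * res / cal.conv
    return BinProfile(
        name=name,
        distance_mm=centres,
        rhl_left=rhl_l / cal.conv,
        rhl_right=rhl_r / cal.conv,
        rha_left=cnt_l / cal.conv**2,
        rha_right=cnt_r / cal.conv**2,
        root_width_mm=width / cal.conv,
        hair_px_left=cnt_l,
        hair_px_right=cnt_r,
    )


def elongation_zone(
    mean_rhl_mm: np.ndarray,
    distance_mm: np.ndarray,
    cal: CalibrationConfig,
    lowess_frac: float = 0.1,
    grad_floor_px: float = 0.5,
    lowess_it: int = 0,
) -> ElongationZone:
    """Locate the elongation zone on a per-bin mean RHL profile.

    The profile is smoothed with LOWESS, its finite-difference gradient
    taken, and the longest run of bins with gradient above a sub-pixel floor
    (``grad_floor_px`` px of fitted rise per bin — smaller changes are below
    the measurement quantum) selected; ties go to the run nearest the tip.
    The gradient trait is the fitted rise across the zone divided by the
    zone length.  A profile with no rising run yields an empty zone
    (distance 0, gradient nan).

    Robustifying LOWESS iterations default to 0: the per-bin profile is an
    envelope (max) statistic, and reweighting systematically pulls the fit
    off the envelope near the transition to the mature zone, biasing the
    detected zone end.
    """
    y = np.asarray(mean_rhl_mm, dtype=float)
    x = np.asarray(distance_mm, dtype=float)
    if len(y) < 5:
        raise DegenerateRootError("elongation zone needs at least 5 bins")
    frac = max(lowess_frac, 3.0 / len(y))  # at least 3 points per window
    fit = lowess(y, x, frac=frac, it=lowess_it, return_sorted=False)
    # backward differences: rise into each bin.  A central-difference
    # gradient would extend every run one bin past the last real rise.
    rise = np.diff(fit) / np.diff(x)
    floor = (grad_floor_px / cal.conv) / cal.bin_mm  # mm per mm
    pos = rise > floor

    best = (0, 0)  # [i0, i1) run of rising diffs
    i = 0
    n = len(pos)
    while i < n:
        if pos[i]:
            j = i
            while j < n and pos[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    if best[1] - best[0] < 1:
        return ElongationZone(math.nan, math.nan, 0.0, math.nan)
    s, e = best[0], best[1]  # zone spans bins s .. e inclusive
    # hinge refinement: the smoother's boundary tail decays over about half
    # its window, so trim boundary bins rising at under 30% of the zone's
    # median rate — they belong to the tail, not the zone
    thr = 0.3 * float(np.median(rise[best[0] : best[1]]))
    while e - 1 >= s and rise[e - 1] < thr:
        e -= 1
    while s < e and rise[s] < thr:
        s += 1
    if e <= s:
        return ElongationZone(math.nan, math.nan, 0.0, math.nan)
    seg = fit[s : e + 1]
    dist = x[e] - x[s]
    return ElongationZone(
        start=float(x[s]),
        end=float(x[e]),
        distance=float(dist),
        gradient=float((seg.max() - seg.min()) / dist),
    )


def heterogeneity(profile: BinProfile) -> tuple[float, float, float, float]:
    """(max RHL delta, its position, max RHA delta, its position), mm units.

    Deltas are per-bin |left - right|; the position is the centre of the
    maximising bin, ties broken toward the tip.
    """
    if len(profile) == 0:
        raise InputError("empty profile")
    d_rhl = np.abs(profile.rhl_left - profile.rhl_right)
    d_rha = np.abs(profile.rha_left - profile.rha_right)
    k_l = int(np.argmax(d_rhl))  # argmax returns the first (tip-most) maximum
    k_a = int(np.argmax(d_rha))
    return (
        float(d_rhl[k_l]),
        float(profile.distance_mm[k_l]),
        float(d_rha[k_a]),
        float(profile.distance_mm[k_a]),
    )


def root_metrics(scene: StraightenedScene, cal: CalibrationConfig) -> tuple[float, float]:
    """(root thickness mm, captured root length mm).

    Thickness is the mean over ``resolution``-row windows of the mean root
    width; captured length is the straightened root's row extent.
    """
    widths = scene.row_width()
    rows = scene.root_rows()
    bins = (scene.tip[0] - rows) // cal.resolution
    window_means = [widths[bins == b].mean() for b in np.unique(bins)]
    thickness = float(np.mean(window_means)) / cal.conv
    length = (scene.tip[0] - scene.full_top_row + 1) / cal.conv
    return thickness, float(length)


def density_proxy(
    image: RawImage | None, mask: LabeledMask
) -> tuple[float, float, float]:
    """(hair mean intensity, background mean intensity, hair/background ratio).

    Intensities are channel-mean grayscale over the label regions of the raw
    image.  In backlit imaging denser hairs block more light, so a lower
    ratio proxies a higher hair density.  Returns nans without an image; the
    ratio is nan when the background mean is zero.
    """
    if image is None:
        return math.nan, math.nan, math.nan
    if image.pixels.shape[:2] != mask.labels.shape:
        raise InputError(
            f"image {image.pixels.shape[:2]} and mask {mask.labels.shape} shapes differ"
        )
    gray = image.grayscale()
    hair = mask.hair()
    bg = mask.background()
    if not hair.any() or not bg.any():
        raise InputError("density proxy needs at least one hair and one background pixel")
    h = float(gray[hair].mean())
    b = float(gray[bg].mean())
    ratio = h / b if b > 0 else math.nan
    return h, b, ratio


def summarize(
    profile: BinProfile,
    cal: CalibrationConfig,
    name: str = "",
    batch_id: str = "",
    captured_length_mm: float | None = None,
    density: tuple[float, float, float] = (math.nan, math.nan, math.nan),
    lowess_frac: float = 0.1,
) -> TraitSummary:
    """Aggregate a BinProfile into the per-image trait record.

    When a length cutoff is configured, bins beyond it are discarded before
    every statistic (profiles, heterogeneity, elongation zone, thickness),
    standardising traits across images of unequal captured root length.
    """
    if cal.length_cutoff is not None:
        if cal.length_cutoff < cal.bin_mm:
            raise DegenerateRootError(
                f"length cutoff {cal.length_cutoff} mm is smaller than one bin ({cal.bin_mm} mm)"
            )
        profile = profile.truncate(cal.length_cutoff)

    both = np.concatenate([profile.rhl_left, profile.rhl_right])
    total_rha = float(profile.rha_left.sum() + profile.rha_right.sum())
    d_rhl, p_rhl, d_rha, p_rha = heterogeneity(profile)
    try:
        ez = elongation_zone(
            profile.mean_rhl_series(), profile.distance_mm, cal, lowess_frac
        )
    except DegenerateRootError:
        ez = ElongationZone(math.nan, math.nan, 0.0, math.nan)

    length = captured_length_mm
    if length is not None and cal.length_cutoff is not None:
        length = min(length, cal.length_cutoff)

    return TraitSummary(
        name=name or profile.name,
        batch_id=batch_id,
        mean_rhl=float(both.mean()),
        max_rhl=float(both.max()),
        min_rhl=float(both.min()),
        total_rha=total_rha,
        max_rhl_delta=d_rhl,
        max_rhl_delta_pos=p_rhl,
        max_rha_delta=d_rha,
        max_rha_delta_pos=p_rha,
        ez_distance=ez.distance,
        ez_start=ez.start,
        ez_end=ez.end,
        ez_gradient=ez.gradient,
        root_thickness=float(profile.root_width_mm[profile.root_width_mm > 0].mean())
        if (profile.root_width_mm > 0).any()
        else math.nan,
        captured_root_length=length if length is not None else math.nan,
        rh_pixel_intensity_mean=density[0],
        background_pixel_intensity_mean=density[1],
        rh_background_ratio=density[2],
    )
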