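"""Geometric normalisation of a segmented root.

The stages, in pipeline order:

1. ``clean_mask``       – keep one root component, fill its holes, drop
                          hair debris not adjacent to the root.
2. ``skeletonize_root`` – thin the root to one pixel width and prune spurs.
3. ``estimate_midline`` – per-window median of skeleton columns, smoothly
                          interpolated into a midline trace.
4. ``orient_tip_down``  – rotate the whole mask so the midline runs
                          vertically with the tip at the bottom.
5. ``straighten``       – piecewise affine warp that maps the (re-estimated)
                          midline onto a vertical line, with destination rows
                          spaced by arc length so the root keeps its length.
6. ``locate_tip``       – endpoint of the straightened skeleton found by
                          3x3 kernel convolution; the lowest endpoint wins.
7. ``split_hair_segments`` – partition hair pixels into the left and right
                          fringe relative to the root column interval.

``normalize`` chains all of the above.  All label resampling is
nearest-neighbour: interpolation would invent fractional labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator
from skimage.morphology import skeletonize
from skimage.transform import PiecewiseAffineTransform, SimilarityTransform, warp

from .errors import DegenerateRootError, GeometryError, NoRootError
from .io import BACKGROUND, HAIR, ROOT, CalibrationConfig, LabeledMask

_NEIGH = np.ones((3, 3), dtype=np.uint8)


@dataclass(frozen=True)
class MidlineTrace:
    """Ordered midline points (row, col), one per integer row, top to tip."""

    points: np.ndarray          # (N, 2) float, rows strictly increasing
    tangent_deg: np.ndarray     # (N,) local tangent angle vs. the row axis

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise DegenerateRootError("midline needs at least 2 points")

    @property
    def rows(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.points[:, 1]

    def arc_length(self) -> np.ndarray:
        """Cumulative arc length from the first point."""
        seg = np.hypot(np.diff(self.rows), np.diff(self.cols))
        return np.concatenate(([0.0], np.cumsum(seg)))


@dataclass
class StraightenedScene:
    """A straightened, tip-down mask with its tip and per-side hair masks."""

    mask: LabeledMask
    tip: tuple[int, int]
    top_row: int                # top of the binned (complete-window) region
    left_hair: np.ndarray       # bool, same shape as mask
    right_hair: np.ndarray
    c_min: np.ndarray           # per-row root column interval; -1 where no root
    c_max: np.ndarray
    full_top_row: int | None = None  # topmost root row incl. the partial window

    def __post_init__(self) -> None:
        if self.full_top_row is None:
            self.full_top_row = self.top_row

    def root_rows(self) -> np.ndarray:
        return np.arange(self.top_row, self.tip[0] + 1)

    def row_width(self) -> np.ndarray:
        """Root width (px) per row from top_row to tip row."""
        rows = self.root_rows()
        return (self.c_max[rows] - self.c_min[rows] + 1).astype(float)


# --------------------------------------------------------------------------


def clean_mask(
    mask: LabeledMask,
    adjacency_radius: int = 5,
    min_root_area: int = 100,
) -> LabeledMask:
    """Remove segmentation noise: keep the largest 8-connected root component
    (holes filled) and only hair components adjacent to it.

    Hair components survive if they intersect the root dilated by
    ``adjacency_radius`` px.  Never adds pixels outside the filled root.
    """
    root = mask.root()
    if not root.any():
        raise NoRootError("mask contains no root (label 2) pixels")
    lab, n = ndimage.label(root, structure=_NEIGH)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        best_size = sizes.max()
        candidates = np.flatnonzero(sizes == best_size) + 1
        if len(candidates) > 1:
            # tie: anchor = topmost-then-leftmost pixel of each component
            anchors = []
            for c in candidates:
                rr, cc = np.nonzero(lab == c)
                k = np.lexsort((cc, rr))[0]
                anchors.append((rr[k], cc[k], c))
            keep = min(anchors)[2]
        else:
            keep = candidates[0]
        root = lab == keep
    root = ndimage.binary_fill_holes(root)
    if root.sum() < min_root_area:
        raise DegenerateRootError(
            f"retained root has {int(root.sum())} px, below the minimum {min_root_area}"
        )

    hair = mask.hair() & ~root
    if hair.any():
        dil = ndimage.binary_dilation(
            root, structure=_NEIGH, iterations=max(1, adjacency_radius)
        )
        hlab, hn = ndimage.label(hair, structure=_NEIGH)
        touching = np.unique(hlab[dil & (hlab > 0)])
        hair = np.isin(hlab, touching[touching > 0])

    out = np.zeros(mask.labels.shape, dtype=np.uint8)
    out[hair] = HAIR
    out[root] = ROOT
    return LabeledMask(out)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGH, mode="constant") - skel


def _prune_spurs(skel: np.ndarray, prune_len: int) -> np.ndarray:
    """Remove skeleton side branches shorter than ``prune_len`` px."""
    sk = skel.copy()
    for _ in range(8):  # a few passes resolve nested spurs
        nb = _neighbor_counts(sk)
        endpoints = np.argwhere(sk & (nb == 1))
        removed_any = False
        for ep in endpoints:
            path = [tuple(ep)]
            prev, cur = None, tuple(ep)
            hit_branch = False
            for _ in range(prune_len):
                r, c = cur
                neigh = [
                    (rr, cc)
                    for rr in range(r - 1, r + 2)
                    for cc in range(c - 1, c + 2)
                    if (rr, cc) != cur
                    and 0 <= rr < sk.shape[0]
                    and 0 <= cc < sk.shape[1]
                    and sk[rr, cc]
                    and (rr, cc) != prev
                ]
                if len(neigh) != 1:
                    hit_branch = len(neigh) > 1
                    break
                nxt = neigh[0]
                if nb[nxt] >= 3:
                    hit_branch = True
                    break
                path.append(nxt)
                prev, cur = cur, nxt
            if hit_branch and len(path) < prune_len:
                for p in path:
                    sk[p] = False
                removed_any = True
        if not removed_any:
            break
    return sk


def skeletonize_root(root_mask: np.ndarray, prune_len: int | None = None) -> np.ndarray:
    """Thin the root to a single-pixel-wide curve, pruning short spurs.

    The default prune length adapts to the root's inradius: the medial axis
    of a blunt-ended band forks into legs of about half the root width, and
    those legs (and any noise spurs) are shorter than inradius + 5 px.
    """
    root_mask = np.asarray(root_mask, dtype=bool)
    if not root_mask.any():
        raise NoRootError("empty root mask")
    dist = ndimage.distance_transform_edt(root_mask)
    if dist.max() < 1.5:
        warnings.warn("root is thinner than 2 px everywhere; skipping thinning")
        return root_mask
    if prune_len is None:
        prune_len = int(np.ceil(dist.max() * 1.5)) + 5
    sk = skeletonize(root_mask)
    sk = _prune_spurs(sk, prune_len)
    if not sk.any():  # pruning ate everything (tiny root)
        sk = skeletonize(root_mask)
    return sk


def estimate_midline(skeleton: np.ndarray, window: int = 20) -> MidlineTrace:
    """Median-of-window midline through the skeleton.

    Skeleton pixels are grouped into row windows of ``window`` px; the median
    column of each window, placed at the window-centre row, defines a set of
    knots through which a monotone cubic (PCHIP) curve is interpolated and
    evaluated at every integer row the skeleton spans.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    rr, cc = np.nonzero(skeleton)
    if rr.size == 0:
        raise NoRootError("empty skeleton")
    rmin, rmax = rr.min(), rr.max()
    knots_r, knots_c = [], []
    for lo in range(rmin, rmax + 1, window):
        hi = min(lo + window, rmax + 1)
        m = (rr >= lo) & (rr < hi)
        if m.any():
            knots_r.append((lo + hi - 1) / 2.0)
            knots_c.append(np.median(cc[m]))
    if len(knots_r) < 2:
        raise DegenerateRootError(
            f"root spans fewer than 2 midline windows of {window} px"
        )
    if len(knots_r) >= 4:
        # end windows overlap the medial-axis end forks; their medians (and
        # hence the end tangents) are biased, so interpolate through the
        # interior knots and extrapolate to the skeleton's full row range
        knots_r, knots_c = knots_r[1:-1], knots_c[1:-1]
    interp = PchipInterpolator(knots_r, knots_c, extrapolate=True)
    rows = np.arange(rmin, rmax + 1, dtype=float)
    cols = interp(rows)
    dc = np.gradient(cols, rows)
    angle = np.degrees(np.arctan(dc))
    return MidlineTrace(points=np.column_stack([rows, cols]), tangent_deg=angle)


# --------------------------------------------------------------------------
# orientation


def _hair_mass_near(mask: LabeledMask, point: np.ndarray, radius: float) -> int:
    hr, hc = np.nonzero(mask.hair())
    if hr.size == 0:
        return 0
    return int(((hr - point[0]) ** 2 + (hc - point[1]) ** 2 <= radius**2).sum())


def detect_tip_end(mask: LabeledMask, midline: MidlineTrace) -> int:
    """Index (0 or -1) of the midline endpoint taken to be the root tip.

    Root hairs emerge behind the elongation zone, so the tip end has less
    hair nearby; when the two ends are indistinguishable (within 10%), the
    end with the larger row index wins.
    """
    p0, p1 = midline.points[0], midline.points[-1]
    n = len(midline.points)
    radius = max(60.0, 0.25 * n)
    m0 = _hair_mass_near(mask, p0, radius)
    m1 = _hair_mass_near(mask, p1, radius)
    scale = max(m0, m1, 1)
    if abs(m0 - m1) > 0.1 * scale:
        return 0 if m0 < m1 else -1
    return 0 if p0[0] > p1[0] else -1


def _rotation_transform(
    shape: tuple[int, int], v_row: float, v_col: float
) -> tuple[SimilarityTransform, float]:
    """Similarity transform (in x=col, y=row coords) rotating content about
    the canvas centre so direction (v_row, v_col) points straight down."""
    alpha = np.pi / 2.0 - np.arctan2(v_row, v_col)  # math angle in (x, y)
    H, W = shape
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    t = (
        SimilarityTransform(translation=(-cx, -cy))
        + SimilarityTransform(rotation=alpha)
        + SimilarityTransform(translation=(cx, cy))
    )
    return t, np.degrees(alpha)


def orient_tip_down(
    mask: LabeledMask, midline: MidlineTrace
) -> tuple[LabeledMask, float]:
    """Rotate the mask so the midline end-to-end vector points down with the
    tip at the bottom.  Returns the rotated mask and the applied angle (deg).

    The canvas is padded to the diagonal before rotating so nothing clips;
    labels are resampled nearest-neighbour.  Downstream stages re-skeletonise
    and re-estimate the midline on the result.
    """
    tip_idx = detect_tip_end(mask, midline)
    tip_p = midline.points[tip_idx]
    other = midline.points[0 if tip_idx == -1 else -1]
    v = tip_p - other  # (drow, dcol) pointing toward the tip
    tform, angle = _rotation_transform(mask.labels.shape, v[0], v[1])
    if abs(angle) < 0.1:
        return mask, 0.0
    H, W = mask.labels.shape
    diag = int(np.ceil(np.hypot(H, W)))
    pr, pc = (diag - H) // 2 + 1, (diag - W) // 2 + 1
    lab = np.pad(mask.labels, ((pr, pr), (pc, pc)), constant_values=0)
    tform, angle = _rotation_transform(lab.shape, v[0], v[1])
    rot = warp(
        lab, tform.inverse, order=0, preserve_range=True, cval=BACKGROUND
    ).astype(np.uint8)
    return LabeledMask(rot), angle


# --------------------------------------------------------------------------
# straightening


def _lateral_reach(mask: LabeledMask, midline: MidlineTrace) -> float:
    """Largest lateral distance (px) from the midline column to any
    non-background pixel in the midline's row range."""
    rr, cc = np.nonzero(mask.labels > 0)
    mid_col = np.interp(rr, midline.rows, midline.cols)
    if rr.size == 0:
        return 0.0
    return float(np.abs(cc - mid_col).max())


def straighten(
    mask: LabeledMask,
    midline: MidlineTrace,
    control_spacing: int = 50,
    lateral_offset: float | None = None,
) -> LabeledMask:
    """Piecewise affine warp mapping the midline onto a vertical line.

    Source control points are midline samples every ``control_spacing`` rows
    with lateral companions offset perpendicular to the local tangent;
    destination points sit on the vertical line at the midline's mean column,
    with destination rows spaced by cumulative arc length so the root keeps
    its length.  The lateral offset defaults to covering the widest hair
    fringe so every foreground pixel lies inside the control mesh.
    """
    n = len(midline.points)
    if n < 2 * control_spacing + 2:
        idx = np.unique(np.linspace(0, n - 1, 5).astype(int))
    else:
        idx = np.arange(0, n, control_spacing)
        if idx[-1] != n - 1:
            idx = np.append(idx, n - 1)
    if len(idx) < 3:
        raise DegenerateRootError("midline too short for a straightening mesh")

    rows = midline.rows[idx]
    cols = midline.cols[idx]
    slopes = np.tan(np.radians(midline.tangent_deg[idx]))  # dcol/drow
    arc = midline.arc_length()[idx]

    # the skeleton (hence the midline) stops about half a root-width short of
    # the root ends; extend the mesh with the end tangents so the whole
    # foreground lies inside it
    fg_rows = np.flatnonzero((mask.labels > 0).any(axis=1))
    ext_top = rows[0] - fg_rows.min() + 2.0
    ext_bot = fg_rows.max() - rows[-1] + 2.0
    if ext_top > 0:
        ds = np.sqrt(1.0 + slopes[0] ** 2)
        rows = np.concatenate(([rows[0] - ext_top], rows))
        cols = np.concatenate(([cols[0] - slopes[0] * ext_top], cols))
        slopes = np.concatenate(([slopes[0]], slopes))
        arc = np.concatenate(([arc[0] - ext_top * ds], arc))
    if ext_bot > 0:
        ds = np.sqrt(1.0 + slopes[-1] ** 2)
        rows = np.concatenate((rows, [rows[-1] + ext_bot]))
        cols = np.concatenate((cols, [cols[-1] + slopes[-1] * ext_bot]))
        slopes = np.concatenate((slopes, [slopes[-1]]))
        arc = np.concatenate((arc, [arc[-1] + ext_bot * ds]))

    reach = _lateral_reach(mask, midline)
    if lateral_offset is None:
        lateral_offset = 1.3 * reach + 10.0
    # guard against mesh folding where the midline curves, but never shrink
    # the mesh below the hair reach or hairs would fall outside it
    curv = np.abs(np.gradient(np.gradient(midline.cols, midline.rows), midline.rows))
    ccap = np.percentile(curv, 97)
    if ccap > 0:
        lateral_offset = max(min(lateral_offset, 0.8 / ccap), reach + 5.0)

    # normals in (x=col, y=row) coordinates
    norm = np.sqrt(1.0 + slopes**2)
    nx, ny = 1.0 / norm, -slopes / norm

    c_straight = float(np.mean(midline.cols))
    r0 = float(midline.rows[0])

    src_pts, dst_pts = [], []  # src = straight output coords, dst = input coords
    for k in range(len(rows)):
        for off in (-lateral_offset, 0.0, lateral_offset):
            src_pts.append((c_straight + off, r0 + arc[k]))
            dst_pts.append((cols[k] + off * nx[k], rows[k] + off * ny[k]))
    tform = PiecewiseAffineTransform.from_estimate(
        np.array(src_pts), np.array(dst_pts)
    )
    if not tform:
        raise GeometryError("piecewise affine estimation failed")

    out_h = max(mask.height, int(np.ceil(r0 + arc[-1])) + 5)
    warped = warp(
        mask.labels,
        tform,
        output_shape=(out_h, mask.width),
        order=0,
        preserve_range=True,
        cval=BACKGROUND,
    ).astype(np.uint8)
    return LabeledMask(warped)


def refine_tip(root_mask: np.ndarray, tip: tuple[int, int]) -> tuple[int, int]:
    """Descend from a skeleton endpoint through the root mask to its true
    bottom row (thinning stops about half a root-width short of the end)."""
    root_mask = np.asarray(root_mask, dtype=bool)
    H = root_mask.shape[0]
    r, c = tip
    while r + 1 < H:
        lo = max(0, c - 3)
        cols = np.flatnonzero(root_mask[r + 1, lo : c + 4])
        if cols.size == 0:
            break
        r += 1
        c = lo + int(cols[len(cols) // 2])
    return r, c


def locate_tip(straight_root_skeleton: np.ndarray) -> tuple[int, int]:
    """Tip = lowest skeleton endpoint, found by 3x3 all-ones convolution.

    Endpoints are skeleton pixels whose convolution value is 2 (self plus one
    neighbour); an isolated pixel (value 1) also counts.  Ties broken toward
    the larger column.
    """
    sk = np.asarray(straight_root_skeleton, dtype=bool)
    conv = ndimage.convolve(sk.astype(np.uint8), _NEIGH, mode="constant")
    ends = sk & (conv <= 2)
    rr, cc = np.nonzero(ends)
    if rr.size == 0:
        # thinning can leave a pixel clump instead of a clean endpoint at a
        # blunt end; for a tip-down (path-like, near-vertical) skeleton the
        # lowest pixel still identifies the tip.  A closed curve — row extent
        # far below the pixel count — is a genuine geometry failure.
        rr, cc = np.nonzero(sk)
        if rr.max() - rr.min() + 1 < 0.8 * rr.size:
            raise GeometryError("no skeleton endpoint found (cyclic skeleton?)")
    k = np.lexsort((-cc, -rr))[0]
    return int(rr[k]), int(cc[k])


def split_hair_segments(
    straight_mask: LabeledMask,
    tip: tuple[int, int],
    top_row: int | None = None,
) -> StraightenedScene:
    """Partition hair pixels into left/right fringes of the straightened root.

    Per root row the interval [c_min, c_max] spans the root; hair left of it
    joins the left segment, right of it the right segment.  Hair inside the
    interval (warp artefacts) goes to the nearer boundary, ties left.  Hair
    below the tip row is assigned by the tip column; rows above ``top_row``
    (default: the topmost root row) are discarded — the top of the captured
    root is cut by the field of view, so callers may pass a lower boundary to
    keep only complete measurement windows.
    """
    lab = straight_mask.labels
    H, W = lab.shape
    root = lab == ROOT
    hair = lab == HAIR
    tip_row, tip_col = tip

    c_min = np.full(H, -1, dtype=int)
    c_max = np.full(H, -1, dtype=int)
    rows_with_root = np.flatnonzero(root.any(axis=1))
    full_top_row = int(rows_with_root.min())
    top_row = full_top_row if top_row is None else int(top_row)
    for r in rows_with_root:
        cols = np.nonzero(root[r])[0]
        c_min[r], c_max[r] = cols[0], cols[-1]
    # fill gap rows between top and tip with the previous known interval
    last = None
    for r in range(top_row, tip_row + 1):
        if c_min[r] < 0:
            if last is not None:
                c_min[r], c_max[r] = last
        else:
            last = (c_min[r], c_max[r])
    # rows below the tip (hairs curling past it, or single-row warp spill)
    # measure against the tip row's root interval
    below = np.arange(tip_row + 1, H)
    if last is not None:
        c_min[below], c_max[below] = last
    else:
        c_min[below] = c_max[below] = tip_col

    left = np.zeros_like(hair)
    right = np.zeros_like(hair)
    hr, hc = np.nonzero(hair)
    keep = hr >= top_row
    hr, hc = hr[keep], hc[keep]
    lo, hi = c_min[hr], c_max[hr]
    is_left = (hc < lo) | ((hc >= lo) & (hc <= hi) & ((hc - lo) <= (hi - hc)))
    left[hr[is_left], hc[is_left]] = True
    right[hr[~is_left], hc[~is_left]] = True
    return StraightenedScene(
        mask=straight_mask,
        tip=(tip_row, tip_col),
        top_row=top_row,
        left_hair=left,
        right_hair=right,
        c_min=c_min,
        c_max=c_max,
        full_top_row=full_top_row,
    )


# --------------------------------------------------------------------------


def normalize(
    mask: LabeledMask,
    cal: CalibrationConfig | None = None,
    adjacency_radius: int = 5,
    min_root_area: int = 100,
    prune_len: int | None = None,
    control_spacing: int = 50,
) -> StraightenedScene:
    """Full geometric normalisation chain; see module docstring."""
    cal = cal or CalibrationConfig()
    window = cal.resolution
    cleaned = clean_mask(mask, adjacency_radius, min_root_area)
    sk = skeletonize_root(cleaned.root(), prune_len)
    midline = estimate_midline(sk, window)
    rotated, angle = orient_tip_down(cleaned, midline)
    if angle != 0.0:
        rotated = clean_mask(rotated, adjacency_radius, min_root_area)
        sk = skeletonize_root(rotated.root(), prune_len)
        midline = estimate_midline(sk, window)
    else:
        rotated = cleaned
    straight = straighten(rotated, midline, control_spacing)
    straight = clean_mask(straight, adjacency_radius, min_root_area)
    sk2 = skeletonize_root(straight.root(), prune_len)
    tip = refine_tip(straight.root(), locate_tip(sk2))
    # bin only complete measurement windows: the top of the captured root is
    # an oblique field-of-view cut that contaminates a partial window
    full_top = int(np.flatnonzero(straight.root().any(axis=1)).min())
    n_complete = (tip[0] - full_top + 1) // window
    if n_complete < 2:
        raise DegenerateRootError("straightened root spans fewer than 2 bins")
    eff_top = tip[0] - n_complete * window + 1
    return split_hair_segments(straight, tip, top_row=eff_top)
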