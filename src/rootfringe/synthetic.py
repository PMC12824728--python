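"""Synthetic root fixtures with analytically known traits.

The generator renders a single downward-growing root — a vertical or
sinusoidally curved midline of constant width — flanked on both sides by
root-hair fringes whose lateral extent is a configurable function of the
distance from the root tip.  Because hairs are rendered as solid per-row
runs, every trait the pipeline measures (per-bin hair length and area,
thickness, elongation zone, left/right heterogeneity) has a closed-form
value, which makes the generated (image, mask) pairs usable as a ground-truth
oracle.  A "filament" style renders regularly spaced 1-px hairs in the image
(the mask keeps the solid fringe) for the density-proxy and classifier tests.

Geometry conventions match the rest of the package: row-major, origin
top-left, tip at the maximum row.  For curved midlines the ground truth
accounts for the two geometric effects of straightening: along-root
positions are arc-length distances, and horizontally rendered runs are
foreshortened by cos(theta) of the local midline slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .errors import SpecificationError
from .io import BACKGROUND, HAIR, ROOT, LabeledMask, RawImage


# --------------------------------------------------------------------------
# hair-extent profiles


@dataclass(frozen=True)
class ConstantProfile:
    """Hair extent independent of position: extent(d) = value (px)."""

    value: float

    def __call__(self, d: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(d, dtype=float), float(self.value))


@dataclass(frozen=True)
class RampProfile:
    """Linear ramp from 0 at the tip to ``plateau`` px at ``ramp_end`` px,
    constant beyond."""

    ramp_end: float
    plateau: float

    def __post_init__(self) -> None:
        if not self.ramp_end > 0:
            raise SpecificationError(f"ramp_end must be positive, got {self.ramp_end}")

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return np.clip(d / self.ramp_end, 0.0, 1.0) * self.plateau


@dataclass(frozen=True)
class BumpProfile:
    """A base profile plus ``extra`` px of extent on d in [start, end)."""

    base: Callable[[np.ndarray], np.ndarray]
    extra: float
    start: float
    end: float

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = np.asarray(self.base(d), dtype=float).copy()
        out[(d >= self.start) & (d < self.end)] += self.extra
        return out


# --------------------------------------------------------------------------
# specification and ground truth


@dataclass(frozen=True)
class SyntheticRootSpec:
    image_height: int = 1200
    image_width: int = 400
    amplitude: float = 0.0       # px; 0 = straight vertical midline
    wavelength: float = 800.0    # px, of the sinusoidal midline
    root_width: int = 21         # px, odd
    top_row: int = 10
    tip_row: int = 1150
    center_col: int | None = None
    hair_profile_left: Callable[[np.ndarray], np.ndarray] = ConstantProfile(30)
    hair_profile_right: Callable[[np.ndarray], np.ndarray] = ConstantProfile(30)
    root_intensity: float = 40.0
    hair_intensity: float = 120.0
    background_intensity: float = 230.0
    noise_sd: float = 0.0
    seed: int = 0
    hair_style: str = "solid"    # "solid" or "filament"
    filament_spacing: int = 4    # rows between 1-px filaments

    def __post_init__(self) -> None:
        if self.root_width % 2 == 0 or self.root_width < 1:
            raise SpecificationError(f"root_width must be a positive odd integer, got {self.root_width}")
        if not (0 <= self.top_row < self.tip_row < self.image_height):
            raise SpecificationError("require 0 <= top_row < tip_row < image_height")
        if self.hair_style not in ("solid", "filament"):
            raise SpecificationError(f"unknown hair_style {self.hair_style!r}")

    # --- analytic midline -------------------------------------------------
    @property
    def centre(self) -> int:
        return self.image_width // 2 if self.center_col is None else self.center_col

    def rows(self) -> np.ndarray:
        return np.arange(self.top_row, self.tip_row + 1)

    def midline_col(self, rows: np.ndarray) -> np.ndarray:
        """Analytic midline column (float) for given rows."""
        if self.amplitude == 0:
            return np.full(np.shape(rows), float(self.centre))
        phase = 2.0 * np.pi * (self.tip_row - np.asarray(rows, float)) / self.wavelength
        return self.centre + self.amplitude * np.sin(phase)

    def midline_slope(self, rows: np.ndarray) -> np.ndarray:
        """d(col)/d(row) of the analytic midline."""
        if self.amplitude == 0:
            return np.zeros(np.shape(rows))
        phase = 2.0 * np.pi * (self.tip_row - np.asarray(rows, float)) / self.wavelength
        return -self.amplitude * (2.0 * np.pi / self.wavelength) * np.cos(phase)

    def extents(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer rendered hair extents (left, right) per row, tip-distance order
        following ``rows()`` (top to tip)."""
        d = (self.tip_row - self.rows()).astype(float)
        el = np.rint(np.maximum(self.hair_profile_left(d), 0.0)).astype(int)
        er = np.rint(np.maximum(self.hair_profile_right(d), 0.0)).astype(int)
        return el, er


@dataclass
class GroundTruth:
    """Analytic trait values implied by a SyntheticRootSpec at a given conv."""

    mean_rhl: float
    max_rhl: float
    min_rhl: float
    total_rha: float
    root_thickness: float
    captured_root_length: float
    ez_start: float
    ez_end: float
    ez_distance: float
    ez_gradient: float
    max_rhl_delta: float
    max_rhl_delta_pos: float
    rh_background_ratio: float
    bin_rhl_left: np.ndarray = field(default=None, repr=False)
    bin_rhl_right: np.ndarray = field(default=None, repr=False)
    bin_centres_mm: np.ndarray = field(default=None, repr=False)


def _render(spec: SyntheticRootSpec) -> tuple[RawImage, LabeledMask]:
    H, W = spec.image_height, spec.image_width
    labels = np.zeros((H, W), dtype=np.uint8)
    img = np.full((H, W), float(spec.background_intensity))
    rows = spec.rows()
    cols = np.rint(spec.midline_col(rows)).astype(int)
    half = spec.root_width // 2
    el, er = spec.extents()
    d = spec.tip_row - rows
    for r, c, e_l, e_r, dd in zip(rows, cols, el, er, d):
        lo, hi = c - half, c + half
        if lo - e_l < 1 or hi + e_r > W - 2:
            raise SpecificationError(
                f"root + hairs exceed the frame at row {r} (cols {lo - e_l}..{hi + e_r})"
            )
        labels[r, lo : hi + 1] = ROOT
        img[r, lo : hi + 1] = spec.root_intensity
        if e_l > 0:
            labels[r, lo - e_l : lo] = HAIR
        if e_r > 0:
            labels[r, hi + 1 : hi + 1 + e_r] = HAIR
        draw_hairs = spec.hair_style == "solid" or dd % spec.filament_spacing == 0
        if draw_hairs:
            if e_l > 0:
                img[r, lo - e_l : lo] = spec.hair_intensity
            if e_r > 0:
                img[r, hi + 1 : hi + 1 + e_r] = spec.hair_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RawImage(np.stack([img] * 3, axis=-1)), LabeledMask(labels)


def _ground_truth(spec: SyntheticRootSpec, mask: LabeledMask, conv: float, resolution: int) -> GroundTruth:
    rows = spec.rows()
    slope = spec.midline_slope(rows)
    cos_t = 1.0 / np.sqrt(1.0 + slope**2)
    ds = np.sqrt(1.0 + slope**2)  # arc length per unit row
    # arc distance from the tip for each row (tip row -> 0)
    s = np.concatenate(([0.0], np.cumsum(ds[::-1][:-1])))[::-1]
    el, er = spec.extents()
    eff_l = el * cos_t  # foreshortened extent after straightening
    eff_r = er * cos_t

    bins = (s // resolution).astype(int)
    # only complete measurement windows: the pipeline drops the partial
    # window at the top of the captured root (field-of-view cut)
    nbin = int((s.max() + 1.0) // resolution)
    rhl_l = np.zeros(nbin)
    rhl_r = np.zeros(nbin)
    for b in range(nbin):
        m = bins == b
        if m.any():
            rhl_l[b] = eff_l[m].max()
            rhl_r[b] = eff_r[m].max()
    centres_mm = (np.arange(nbin) + 0.5) * resolution / conv

    both = np.concatenate([rhl_l, rhl_r]) / conv
    hair_px = int(mask.hair().sum())
    delta = np.abs(rhl_l - rhl_r)
    k = int(np.argmax(delta))

    # elongation zone: longest run of per-bin rises above the same
    # half-pixel quantisation floor the pipeline uses
    mean_prof = (rhl_l + rhl_r) / 2.0
    inc = np.diff(mean_prof) > 0.5
    best = (0, 0)
    i = 0
    while i < len(inc):
        if inc[i]:
            j = i
            while j < len(inc) and inc[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    if best[1] - best[0] < 1:
        ez_start = ez_end = ez_grad = float("nan")
        ez_dist = 0.0
    else:
        s0, s1 = best[0], best[1]  # zone spans bins s0 .. s1 inclusive
        rises = np.diff(mean_prof)
        thr = 0.3 * float(np.median(rises[best[0] : best[1]]))
        while s1 - 1 >= s0 and rises[s1 - 1] < thr:
            s1 -= 1
        while s0 < s1 and rises[s0] < thr:
            s0 += 1
        ez_start = centres_mm[s0]
        ez_end = centres_mm[s1]
        ez_dist = ez_end - ez_start
        seg = mean_prof[s0 : s1 + 1]
        ez_grad = (seg.max() - seg.min()) / conv / ez_dist

    return GroundTruth(
        mean_rhl=float(both.mean()),
        max_rhl=float(both.max()),
        min_rhl=float(both.min()),
        total_rha=hair_px / conv**2,
        root_thickness=float(spec.root_width * cos_t.mean() / conv),
        captured_root_length=float((s.max() + 1.0) / conv),
        ez_start=float(ez_start),
        ez_end=float(ez_end),
        ez_distance=float(ez_dist),
        ez_gradient=float(ez_grad),
        max_rhl_delta=float(delta[k] / conv),
        max_rhl_delta_pos=float(centres_mm[k]) if delta[k] > 0 else 0.0,
        rh_background_ratio=float(spec.hair_intensity / spec.background_intensity),
        bin_rhl_left=rhl_l / conv,
        bin_rhl_right=rhl_r / conv,
        bin_centres_mm=centres_mm,
    )


def generate(
    spec: SyntheticRootSpec, conv: float = 102.0, resolution: int = 20
) -> tuple[RawImage, LabeledMask, GroundTruth]:
    """Render a synthetic root and derive its analytic ground truth.

    Deterministic for a fixed spec (the only randomness is the image noise,
    driven by ``spec.seed``).  Total RHA ground truth equals the rendered
    hair-pixel count / conv^2 exactly; all other values are closed-form
    functions of the spec.
    """
    image, mask = _render(spec)
    truth = _ground_truth(spec, mask, conv, resolution)
    return image, mask, truth


def rotate_fixture(
    image: RawImage, mask: LabeledMask, angle: float
) -> tuple[RawImage, LabeledMask]:
    """Rotate an (image, mask) pair by ``angle`` degrees on a padded canvas.

    Nearest-neighbour resampling keeps labels crisp; the canvas is padded to
    the diagonal so no foreground pixel is clipped.  The image is padded with
    its own corner intensity so the background stays uniform.
    """
    if angle % 360 == 0:
        return image, mask
    H, W = mask.height, mask.width
    diag = int(np.ceil(np.hypot(H, W)))
    pr, pc = (diag - H) // 2 + 1, (diag - W) // 2 + 1
    lab = np.pad(mask.labels, ((pr, pr), (pc, pc)), constant_values=0)
    fill = int(image.pixels[0, 0, 0])
    px = np.pad(image.pixels, ((pr, pr), (pc, pc), (0, 0)), constant_values=fill)
    lab_r = _sk_rotate(lab, angle, resize=False, order=0, preserve_range=True, cval=0)
    px_r = _sk_rotate(px, angle, resize=False, order=0, preserve_range=True, cval=fill)
    return (
        RawImage(np.rint(px_r).astype(np.uint8)),
        LabeledMask(np.rint(lab_r).astype(np.uint8)),
    )


# --------------------------------------------------------------------------
# named presets (used by the fixture CLI and the acceptance machinery)


def preset(name: str, seed: int = 0) -> SyntheticRootSpec:
    """Build one of the named fixture presets."""
    presets = {
        # straight root, uniform 30 px fringes both sides
        "straight-constant": SyntheticRootSpec(seed=seed),
        # straight root, hair ramp 0 -> 100 px over the first 500 px, then flat
        "straight-ramp": SyntheticRootSpec(
            image_height=1400,
            tip_row=1350,
            hair_profile_left=RampProfile(500, 100),
            hair_profile_right=RampProfile(500, 100),
            seed=seed,
        ),
        # gently curved root with ramp fringes
        "curved-ramp": SyntheticRootSpec(
            image_height=1400,
            image_width=500,
            amplitude=35.0,
            wavelength=1000.0,
            tip_row=1350,
            hair_profile_left=RampProfile(450, 90),
            hair_profile_right=RampProfile(450, 90),
            seed=seed,
        ),
        # asymmetric fringes
        "asymmetric": SyntheticRootSpec(
            image_height=1400,
            tip_row=1350,
            hair_profile_left=RampProfile(400, 80),
            hair_profile_right=RampProfile(600, 50),
            seed=seed,
        ),
        # single-bin left/right difference of 66 px centred 15.5 mm from the
        # tip at conv = 100 px/mm, resolution 20 px
        "worked-example": SyntheticRootSpec(
            image_height=1700,
            image_width=360,
            root_width=21,
            top_row=39,
            tip_row=1660,
            hair_profile_left=BumpProfile(RampProfile(400, 60), 66, 1540, 1560),
            hair_profile_right=RampProfile(400, 60),
            seed=seed,
        ),
        # well-separated class intensities for classifier training
        "rfc-separable": SyntheticRootSpec(
            image_height=600,
            image_width=300,
            tip_row=560,
            hair_profile_left=RampProfile(200, 60),
            hair_profile_right=RampProfile(200, 60),
            root_intensity=40,
            hair_intensity=120,
            background_intensity=230,
            noise_sd=5.0,
            seed=seed,
        ),
        # filamented fringes for the density-proxy monotonicity check
        "filament-sparse": SyntheticRootSpec(
            image_height=600,
            image_width=300,
            tip_row=560,
            hair_style="filament",
            filament_spacing=8,
            seed=seed,
        ),
        "filament-dense": SyntheticRootSpec(
            image_height=600,
            image_width=300,
            tip_row=560,
            hair_style="filament",
            filament_spacing=4,
            seed=seed,
        ),
    }
    try:
        return presets[name]
    except KeyError:
        raise SpecificationError(f"unknown preset {name!r}; choose from {sorted(presets)}")


PRESET_NAMES = (
    "straight-constant",
    "straight-ramp",
    "curved-ramp",
    "asymmetric",
    "worked-example",
    "rfc-separable",
    "filament-sparse",
    "filament-dense",
)


def randomized_specs(n: int, seed: int, resolution: int = 20) -> list[SyntheticRootSpec]:
    """Draw ``n`` seeded specs spanning straight/curved roots, constant/ramp
    profiles and asymmetric sides, for parameter-recovery studies.

    Curvature stays in the gentle gravitropic regime of agar-grown seedlings
    (midline slope below ~0.15): roots selected for plate phenotyping grow
    close to plumb, and that is the regime the straightening mesh is built
    for.  Asymmetry is a localised one-window bump of extra hair on one side
    in the mature zone — a unilateral hair patch — which gives the
    heterogeneity traits a well-defined position to recover.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        curved = rng.random() < 0.5
        amplitude = float(rng.uniform(10, 25)) if curved else 0.0
        wavelength = float(rng.uniform(1100, 1500))
        root_width = int(rng.integers(7, 14)) * 2 + 1  # 15..27 odd
        height = int(rng.integers(1100, 1500))
        tip_row = height - int(rng.integers(20, 60))
        top_row = int(rng.integers(5, 40))
        plateau = float(rng.uniform(50, 100))
        ramp_end = float(rng.uniform(300, 600))
        if rng.random() < 0.3:
            base = ConstantProfile(plateau)
            first_mature = 0.0
        else:
            base = RampProfile(ramp_end, plateau)
            first_mature = ramp_end
        root_len = tip_row - top_row + 1
        # one-window bump of extra hair on a random side, placed clear of the
        # elongation-zone corner (beyond the smoother's half window) and of
        # the top cut so it neither merges with the zone nor gets clipped
        k_lo = int(first_mature // resolution) + 10
        k_hi = root_len // resolution - 4
        left, right = base, base
        if k_hi > k_lo:
            k = int(rng.integers(k_lo, k_hi))
            bump = BumpProfile(
                base, float(rng.uniform(40, 80)), k * resolution, (k + 1) * resolution
            )
            if rng.random() < 0.5:
                left = bump
            else:
                right = bump
        reach = plateau + 80 + amplitude + root_width
        margin = int(np.ceil(reach)) + 20
        specs.append(
            SyntheticRootSpec(
                image_height=height,
                image_width=2 * margin,
                amplitude=amplitude,
                wavelength=wavelength,
                root_width=root_width,
                top_row=top_row,
                tip_row=tip_row,
                hair_profile_left=left,
                hair_profile_right=right,
                noise_sd=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
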