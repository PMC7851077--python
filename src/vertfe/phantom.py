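"""Synthetic vertebra phantoms: image/mask pairs, contrast, slice thickness, cohorts.

The phantom stands in for a segmented vertebra from a clinical CT: an
elliptic-cylinder vertebral body with a dense cortical shell and a noisy,
spatially correlated trabecular interior, optionally with a simplified
posterior arch (two pedicles, a lamina plate and a spinous process) attached
to the posterior face.  All randomness is seeded and every output is
bit-reproducible for a fixed spec.

The trabecular field is a stationary Gaussian random field: white noise
smoothed with a Gaussian kernel whose width is the correlation length, then
standardized over the interior voxels and rescaled, so the interior sample
mean and sd equal the requested values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image import ImageVolume, LabelMask

__all__ = [
    "PhantomSpec",
    "ContrastSpec",
    "CohortSpec",
    "CohortMember",
    "DEFAULT_SPEC",
    "generate_vertebra_phantom",
    "apply_contrast",
    "resample_slice_thickness",
    "resample_mask_slice_thickness",
    "generate_cohort",
]

BACKGROUND_HU = -80.0  # soft tissue / fat surround
POSTERIOR_HU_FRACTION = 0.75  # posterior arch HU relative to the cortical shell


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one vertebra phantom.

    Lengths in mm, intensities in HU.  ``body_half_axes`` are the x (left–
    right) and y (anterior–posterior) half-axes of the elliptical body
    cross-section; z is superior–inferior.
    """

    body_half_axes: tuple[float, float] = (18.0, 14.0)
    body_height: float = 28.0
    shell_thickness: float = 1.5
    shell_hu: float = 600.0
    trab_hu_mean: float = 180.0
    trab_hu_sd: float = 50.0
    trab_correlation_length: float = 3.0
    include_posterior: bool = False
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.body_half_axes
        if a <= 0 or b <= 0 or self.body_height <= 0 or self.shell_thickness <= 0:
            raise ValueError("all geometric fields must be > 0")
        if self.shell_thickness >= min(a, b):
            raise ValueError("shell_thickness must be < min(body_half_axes)")
        if self.trab_hu_sd < 0:
            raise ValueError("trab_hu_sd must be >= 0")
        if self.trab_correlation_length <= 0:
            raise ValueError("trab_correlation_length must be > 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing components must be > 0")


@dataclass(frozen=True)
class ContrastSpec:
    """Additive intravenous-contrast enhancement of labeled voxels."""

    hu_offset_mean: float = 30.0
    hu_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hu_offset_mean < 0:
            raise ValueError("hu_offset_mean must be >= 0 (contrast raises attenuation)")
        if self.hu_offset_sd < 0:
            raise ValueError("hu_offset_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Paired healthy / weakened phantom cohort."""

    n_pairs: int = 9
    strength_decrement_fraction: float = 0.15
    base_spec: PhantomSpec = PhantomSpec()
    between_pair_cv: float = 0.10  # lognormal-ish jitter of trabecular HU across pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not (0.0 <= self.strength_decrement_fraction < 1.0):
            raise ValueError("strength_decrement_fraction must be in [0, 1)")


@dataclass
class CohortMember:
    image: ImageVolume
    mask: LabelMask
    pair_id: int
    group: str  # "healthy" or "weakened"
    spec: PhantomSpec


DEFAULT_SPEC = PhantomSpec()

MARGIN_VOX = 2


def _grid_for(spec: PhantomSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    a, b = spec.body_half_axes
    sx, sy, sz = spec.voxel_spacing
    post_extent = _posterior_dims(spec)["total_y"] if spec.include_posterior else 0.0
    ext_x, ext_y, ext_z = 2 * a, 2 * b + post_extent, spec.body_height
    for name, ext, s in (("x", 2 * a, sx), ("y", 2 * b, sy), ("z", spec.body_height, sz)):
        if ext / s < 3:
            raise ValueError(
                f"grid too small along {name}: extent {ext} mm spans fewer than 3 voxels "
                f"at spacing {s} mm"
            )
    shape = (
        int(np.ceil(ext_x / sx)) + 2 * MARGIN_VOX,
        int(np.ceil(ext_y / sy)) + 2 * MARGIN_VOX,
        int(np.ceil(ext_z / sz)) + 2 * MARGIN_VOX,
    )
    # body center in world coords (origin at 0)
    center = np.array(
        [
            MARGIN_VOX * sx + a,
            MARGIN_VOX * sy + b,
            MARGIN_VOX * sz + spec.body_height / 2.0,
        ]
    )
    return shape, center


def _posterior_dims(spec: PhantomSpec) -> dict:
    a, b = spec.body_half_axes
    h = spec.body_height
    return {
        "pedicle_rx": 0.16 * a,  # half-width in x
        "pedicle_rz": 0.30 * h,  # half-height in z
        "pedicle_x": 0.45 * a,  # offset of each pedicle center from midline
        "pedicle_len": 0.5 * b,  # extent in +y beyond the body surface
        "lamina_thick": 0.15 * b,
        "spinous_len": 0.5 * b,
        "spinous_rx": 0.12 * a,
        "spinous_rz": 0.30 * h,
        "total_y": 0.5 * b + 0.15 * b + 0.5 * b,
    }


def _correlated_field(shape, spacing, corr_len, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    sigma = [corr_len / s for s in spacing]
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")


def generate_vertebra_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelMask]:
    """Build one phantom image/mask pair (deterministic for a fixed spec)."""
    shape, center = _grid_for(spec)
    spacing = spec.voxel_spacing
    a, b = spec.body_half_axes
    h = spec.body_height
    t = spec.shell_thickness

    xs = (np.arange(shape[0]) + 0.5) * spacing[0]
    ys = (np.arange(shape[1]) + 0.5) * spacing[1]
    zs = (np.arange(shape[2]) + 0.5) * spacing[2]
    dx = (xs - center[0])[:, None, None]
    dy = (ys - center[1])[None, :, None]
    dz = (zs - center[2])[None, None, :]

    body = ((dx / a) ** 2 + (dy / b) ** 2 <= 1.0) & (np.abs(dz) <= h / 2.0)
    inner = (
        ((dx / (a - t)) ** 2 + (dy / (b - t)) ** 2 <= 1.0)
        & (np.abs(dz) <= h / 2.0 - t)
    )
    shell = body & ~inner

    labels = np.zeros(shape, dtype=np.uint8)
    labels[body] = 1

    values = np.full(shape, BACKGROUND_HU, dtype=np.float64)
    values[shell] = spec.shell_hu

    rng = np.random.default_rng(spec.seed)
    field = _correlated_field(shape, spacing, spec.trab_correlation_length, rng)
    if spec.trab_hu_sd > 0 and inner.sum() > 1:
        f = field[inner]
        f = (f - f.mean()) / f.std()
        values[inner] = spec.trab_hu_mean + spec.trab_hu_sd * f
    else:
        values[inner] = spec.trab_hu_mean

    if spec.include_posterior:
        p = _posterior_dims(spec)
        y_face = center[1] + b
        post = np.zeros(shape, dtype=bool)
        # two pedicles: columns along y with elliptical x-z cross-section,
        # starting slightly inside the body so they attach to the shell
        ped_y = (ys[None, :, None] >= y_face - 0.1 * b) & (
            ys[None, :, None] <= y_face + p["pedicle_len"]
        )
        for sign in (-1.0, 1.0):
            cx = sign * p["pedicle_x"]
            ped = (
                ((dx - cx) / p["pedicle_rx"]) ** 2 + (dz / p["pedicle_rz"]) ** 2 <= 1.0
            ) & ped_y
            post |= ped
        # lamina plate bridging the pedicles
        lam = (
            (np.abs(dx) <= p["pedicle_x"] + p["pedicle_rx"])
            & (np.abs(dz) <= p["pedicle_rz"])
            & (ys[None, :, None] >= y_face + p["pedicle_len"])
            & (ys[None, :, None] <= y_face + p["pedicle_len"] + p["lamina_thick"])
        )
        post |= lam
        # spinous process behind the lamina
        spin = (
            (np.abs(dx) <= p["spinous_rx"])
            & (np.abs(dz) <= p["spinous_rz"])
            & (ys[None, :, None] >= y_face + p["pedicle_len"] + p["lamina_thick"])
            & (ys[None, :, None] <= y_face + p["total_y"])
        )
        post |= spin
        post &= ~body
        labels[post] = 2
        values[post] = POSTERIOR_HU_FRACTION * spec.shell_hu

    img = ImageVolume(values, spacing, (0.0, 0.0, 0.0))
    mask = LabelMask(labels, spacing, (0.0, 0.0, 0.0))
    return img, mask


def apply_contrast(img: ImageVolume, mask: LabelMask, c: ContrastSpec) -> ImageVolume:
    """Add a smooth random HU offset to labeled voxels (background unchanged).

    The offset field is standardized over the labeled voxels, so its sample
    mean there equals ``hu_offset_mean`` exactly and its sample sd equals
    ``hu_offset_sd`` exactly.
    """
    mask.check_grid(img)
    labeled = mask.labels > 0
    out = img.copy()
    if not labeled.any():
        return out
    if c.hu_offset_sd > 0 and labeled.sum() > 1:
        rng = np.random.default_rng(c.seed)
        field = _correlated_field(img.shape, img.spacing, 5.0, rng)
        f = field[labeled]
        f = (f - f.mean()) / f.std()
        out.values[labeled] += c.hu_offset_mean + c.hu_offset_sd * f
    else:
        out.values[labeled] += c.hu_offset_mean
    return out


def _check_resample(n: int, factor: int) -> None:
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor > n:
        raise ValueError(f"factor {factor} exceeds slice count {n}")


def resample_slice_thickness(img: ImageVolume, axis: int, factor: int) -> ImageVolume:
    """Average consecutive groups of `factor` slices (partial-volume model).

    Spacing along the axis is multiplied by ``factor``; trailing slices that
    do not fill a group are dropped.
    """
    _check_resample(img.shape[axis], factor)
    if factor == 1:
        return img.copy()
    n = img.shape[axis] // factor
    sl = [slice(None)] * 3
    sl[axis] = slice(0, n * factor)
    vals = np.moveaxis(img.values[tuple(sl)], axis, 0)
    vals = vals.reshape(n, factor, *vals.shape[1:]).mean(axis=1)
    vals = np.moveaxis(vals, 0, axis)
    spacing = list(img.spacing)
    spacing[axis] *= factor
    return ImageVolume(vals, tuple(spacing), img.origin)


def resample_mask_slice_thickness(mask: LabelMask, axis: int, factor: int) -> LabelMask:
    """Majority-vote label resampling matched to :func:`resample_slice_thickness`.

    Ties between background and a foreground label go to the foreground;
    ties between body and posterior go to the body.
    """
    _check_resample(mask.shape[axis], factor)
    if factor == 1:
        return mask.copy()
    n = mask.shape[axis] // factor
    sl = [slice(None)] * 3
    sl[axis] = slice(0, n * factor)
    lab = np.moveaxis(mask.labels[tuple(sl)], axis, 0)
    lab = lab.reshape(n, factor, *lab.shape[1:])
    counts = np.stack([(lab == v).sum(axis=1) for v in (0, 1, 2)])  # (3, n, ...)
    n0, n1, n2 = counts[0], counts[1], counts[2]
    out = np.zeros(n1.shape, dtype=np.uint8)
    fg = n1 + n2 >= n0  # tie with background -> foreground
    body = n1 >= n2  # tie between labels -> body
    out[fg & body] = 1
    out[fg & ~body] = 2
    out = np.moveaxis(out, 0, axis)
    spacing = list(mask.spacing)
    spacing[axis] *= factor
    return LabelMask(out, tuple(spacing), mask.origin)


# Exponent used to translate a target strength decrement into an apparent-
# density scale factor; the strength limits grow like rho_ash^~1.8 (the two
# power laws have exponents 1.72-1.93), so scaling rho_app by (1-d)^(1/1.8)
# scales strength by approximately (1-d).
_STRENGTH_EXPONENT = 1.8


def weakened_spec(spec: PhantomSpec, decrement: float) -> PhantomSpec:
    """Spec whose predicted failure load is ~``(1-decrement)`` of ``spec``'s."""
    if not (0.0 <= decrement < 1.0):
        raise ValueError("decrement must be in [0, 1)")
    scale = (1.0 - decrement) ** (1.0 / _STRENGTH_EXPONENT)

    def scale_hu(hu: float) -> float:
        rho = 47.0 + 1.122 * hu
        return (rho * scale - 47.0) / 1.122

    new_mean = scale_hu(spec.trab_hu_mean)
    sd_ratio = new_mean / spec.trab_hu_mean if spec.trab_hu_mean != 0 else 1.0
    return replace(
        spec,
        trab_hu_mean=new_mean,
        trab_hu_sd=spec.trab_hu_sd * abs(sd_ratio),
        shell_hu=scale_hu(spec.shell_hu),
    )


def generate_cohort(c: CohortSpec) -> list[CohortMember]:
    """Paired healthy/weakened phantoms with between-pair HU variability.

    Both members of a pair share the same noise seed, so the weakened member
    is the healthy phantom with its HU field scaled down — a matched design.
    """
    rng = np.random.default_rng(c.seed)
    members: list[CohortMember] = []
    for i in range(c.n_pairs):
        eta = float(np.clip(rng.standard_normal(), -2.0, 2.0))
        jitter = 1.0 + c.between_pair_cv * eta
        pair_seed = int(rng.integers(0, 2**31 - 1))
        healthy_spec = replace(
            c.base_spec,
            trab_hu_mean=c.base_spec.trab_hu_mean * jitter,
            trab_hu_sd=c.base_spec.trab_hu_sd * jitter,
            seed=pair_seed,
        )
        weak_spec = weakened_spec(healthy_spec, c.strength_decrement_fraction)
        img_h, mask_h = generate_vertebra_phantom(healthy_spec)
        img_w, mask_w = generate_vertebra_phantom(weak_spec)
        members.append(CohortMember(img_h, mask_h, i, "healthy", healthy_spec))
        members.append(CohortMember(img_w, mask_w, i, "weakened", weak_spec))
    return members
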