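"""Digital phantoms and synthetic subject cohorts for brain perfusion SPECT.

The physical objects used to calibrate inter-camera compensation maps are
emulated here as paired activity / attenuation grids on a common voxel grid:

* a Hoffman-style phantom (interleaved gray/white laminae inside an
  ellipsoidal brain support, conventional ~4:1 gray:white fill contrast),
* a 3D-brain-style phantom (same support, bone-equivalent skull shell,
  tracer confined to gray matter),
* a uniform pool phantom (structureless fill over the same support),
* a "normal brain" base for simulated subjects, sharing the gray/white
  laminar distribution at physiological contrast plus a cortical-shell
  weighting, intrinsically smoothed,
* cohorts of normal subjects derived from a base by multiplicative global
  and smooth local variability,
* a lesion operator that reduces counts inside a disease VOI (the
  Alzheimer-type simulation).

All volumes are generated already aligned on one common grid (default
64x64x64 at 3.5 mm isotropic); anatomical standardization is replaced by
construction-time alignment. Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "DigitalPhantom",
    "SubjectVolume",
    "LABEL_BACKGROUND",
    "LABEL_GRAY",
    "LABEL_WHITE",
    "LABEL_SKULL",
    "LABEL_POOL",
    "SOFT_TISSUE_MU",
    "brain_support_mask",
    "make_hoffman_like",
    "make_3dbrain_like",
    "make_pool",
    "make_normal_brain",
    "make_subject_cohort",
    "apply_ad_lesion",
]

LABEL_BACKGROUND = 0
LABEL_GRAY = 1
LABEL_WHITE = 2
LABEL_SKULL = 3
LABEL_POOL = 4

#: soft-tissue linear attenuation coefficient (cm^-1) used throughout; this is
#: also the coefficient assumed by the first-order Chang correction.
SOFT_TISSUE_MU = 0.1

# Ellipsoid semi-axes as fractions of the grid extent per axis. Chosen so the
# brain support fills roughly a fifth of the grid, leaving air around the head.
_BRAIN_AXES_FRACTION = (0.36, 0.42, 0.34)
_WHITE_CORE_SCALE = 0.45
_MIN_SHAPE = 32


@dataclass
class DigitalPhantom:
    """Paired activity / attenuation grids with tissue labels.

    Attributes
    ----------
    activity : ndarray
        3-D activity concentration per voxel (arbitrary units, >= 0).
    attenuation : ndarray
        3-D linear attenuation coefficient per voxel (cm^-1, >= 0).
    labels : ndarray
        3-D integer tissue labels (0 background, 1 gray, 2 white, 3 skull,
        4 pool fill).
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm.
    name : str
        Identifier used in provenance records.
    """

    activity: np.ndarray
    attenuation: np.ndarray
    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    name: str

    def __post_init__(self) -> None:
        if not (self.activity.shape == self.attenuation.shape == self.labels.shape):
            raise ValueError("activity, attenuation and labels must share one shape")
        if not np.all(np.isfinite(self.activity)) or np.any(self.activity < 0):
            raise ValueError("activity must be finite and non-negative")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.activity.shape

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of labelled (non-background) voxels."""
        return self.labels != LABEL_BACKGROUND

    @property
    def brain_mask(self) -> np.ndarray:
        """Boolean mask of brain-tissue voxels (gray, white or pool fill)."""
        return np.isin(self.labels, (LABEL_GRAY, LABEL_WHITE, LABEL_POOL))

    def copy(self) -> "DigitalPhantom":
        return DigitalPhantom(
            self.activity.copy(),
            self.attenuation.copy(),
            self.labels.copy(),
            self.voxel_size_mm,
            self.name,
        )


@dataclass
class SubjectVolume:
    """A reconstructed SPECT volume on the pipeline's common grid."""

    counts: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    subject_id: str
    camera_id: str
    attenuation_corrected: bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.counts.shape

    def with_counts(self, counts: np.ndarray, **meta_updates) -> "SubjectVolume":
        """Return a copy carrying new counts and (optionally) extra provenance."""
        return SubjectVolume(
            counts,
            self.voxel_size_mm,
            self.subject_id,
            self.camera_id,
            self.attenuation_corrected,
            {**self.meta, **meta_updates},
        )


def _check_shape(shape) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < _MIN_SHAPE for s in shape):
        raise ValueError(f"grid shape must be 3-D with every axis >= {_MIN_SHAPE}, got {shape}")
    return shape


def _ellipsoid_mask(shape, scale: float = 1.0) -> np.ndarray:
    """Boolean ellipsoid centred on the grid, semi-axes a fixed grid fraction."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2.0 for s in shape]
    semi = [f * s * scale for f, s in zip(_BRAIN_AXES_FRACTION, shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def brain_support_mask(shape) -> np.ndarray:
    """Outer brain support shared by every phantom kind on this grid."""
    return _ellipsoid_mask(_check_shape(shape))


def _lamina_gray_mask(shape, thickness: int) -> np.ndarray:
    """Axial alternation of gray/white laminae, mimicking stacked slice plates."""
    z = np.arange(shape[2])
    gray_z = (z // thickness) % 2 == 0
    return np.broadcast_to(gray_z, shape)


def _hoffman_fields(shape, gm_wm_ratio, fill, soft_mu, lamina_thickness):
    support = _ellipsoid_mask(shape)
    core = _ellipsoid_mask(shape, scale=_WHITE_CORE_SCALE)
    gray = support & _lamina_gray_mask(shape, lamina_thickness) & ~core
    labels = np.zeros(shape, dtype=np.int16)
    labels[support] = LABEL_WHITE
    labels[gray] = LABEL_GRAY
    activity = np.zeros(shape)
    activity[labels == LABEL_WHITE] = fill
    activity[labels == LABEL_GRAY] = fill * gm_wm_ratio
    attenuation = np.where(support, soft_mu, 0.0)
    return activity, attenuation, labels


def make_hoffman_like(
    shape=(64, 64, 64),
    voxel_size_mm=(3.5, 3.5, 3.5),
    gm_wm_ratio: float = 4.0,
    seed: int = 0,
    *,
    fill: float = 0.3,
    soft_mu: float = SOFT_TISSUE_MU,
    lamina_thickness: int = 2,
) -> DigitalPhantom:
    """Hoffman-style layered brain phantom.

    Interleaved gray/white laminae (``lamina_thickness`` voxels each) inside an
    ellipsoidal brain support with a central white core. Gray-voxel activity is
    ``gm_wm_ratio`` times white-voxel activity; attenuation is uniform soft
    tissue inside the support; there is no skull compartment.

    Parameters
    ----------
    gm_wm_ratio : float
        Gray:white activity contrast (> 0; the conventional design value is 4).
    fill : float
        White-matter activity concentration (arbitrary units; the default 0.3
        mirrors a 0.3 MBq/ml fill).
    seed : int
        Accepted for interface uniformity; the construction is deterministic.
    """
    shape = _check_shape(shape)
    if not np.isfinite(gm_wm_ratio) or gm_wm_ratio <= 0:
        raise ValueError(f"gm_wm_ratio must be positive, got {gm_wm_ratio}")
    if fill <= 0:
        raise ValueError("fill must be positive")
    activity, attenuation, labels = _hoffman_fields(
        shape, gm_wm_ratio, fill, soft_mu, lamina_thickness
    )
    return DigitalPhantom(activity, attenuation, labels, voxel_size_mm, "hoffman")


def make_3dbrain_like(
    shape=(64, 64, 64),
    voxel_size_mm=(3.5, 3.5, 3.5),
    gm_only: bool = True,
    skull_mu: float = 0.15,
    seed: int = 0,
    *,
    gm_wm_ratio: float = 4.0,
    fill: float = 0.3,
    soft_mu: float = SOFT_TISSUE_MU,
    lamina_thickness: int = 2,
) -> DigitalPhantom:
    """Anatomical brain phantom with a bone-equivalent skull shell.

    Same brain support and laminar construction as :func:`make_hoffman_like`,
    plus a closed skull shell (label 3) of attenuation ``skull_mu`` and zero
    activity surrounding the brain. With ``gm_only`` (the default, matching a
    phantom whose white compartment cannot hold tracer) white-matter voxels
    carry no activity.
    """
    shape = _check_shape(shape)
    if skull_mu <= soft_mu:
        raise ValueError(
            f"skull_mu ({skull_mu}) must exceed the soft-tissue coefficient ({soft_mu})"
        )
    activity, attenuation, labels = _hoffman_fields(
        shape, gm_wm_ratio, fill, soft_mu, lamina_thickness
    )
    # Skull: a shell just outside the brain ellipsoid, ~2 voxels thick.
    outer = _ellipsoid_mask(shape, scale=1.0 + 2.0 / (min(shape) * min(_BRAIN_AXES_FRACTION)))
    shell = outer & ~_ellipsoid_mask(shape)
    labels[shell] = LABEL_SKULL
    attenuation[shell] = skull_mu
    activity[shell] = 0.0
    if gm_only:
        activity[labels == LABEL_WHITE] = 0.0
    return DigitalPhantom(activity, attenuation, labels, voxel_size_mm, "brain3d")


def make_pool(
    shape=(64, 64, 64),
    voxel_size_mm=(3.5, 3.5, 3.5),
    *,
    fill: float = 0.3,
    soft_mu: float = SOFT_TISSUE_MU,
) -> DigitalPhantom:
    """Uniform pool phantom: structureless fill over the shared brain support."""
    shape = _check_shape(shape)
    if fill <= 0:
        raise ValueError("fill must be positive")
    support = _ellipsoid_mask(shape)
    labels = np.where(support, LABEL_POOL, LABEL_BACKGROUND).astype(np.int16)
    activity = np.where(support, fill, 0.0)
    attenuation = np.where(support, soft_mu, 0.0)
    return DigitalPhantom(activity, attenuation, labels, voxel_size_mm, "pool")


def make_normal_brain(
    shape=(64, 64, 64),
    voxel_size_mm=(3.5, 3.5, 3.5),
    *,
    gm_wm_ratio: float = 2.0,
    shell_boost: float = 0.5,
    shell_thickness_frac: float = 0.25,
    intrinsic_smoothing_mm: float = 4.0,
    fill: float = 0.3,
    soft_mu: float = SOFT_TISSUE_MU,
    lamina_thickness: int = 2,
) -> DigitalPhantom:
    """Base activity distribution for simulated normal subjects.

    A brain, unlike any calibration phantom, is neither a stack of crisp
    plates nor a uniform pool. This base therefore shares the laminar
    gray/white geometry of the Hoffman-style phantom at a physiological
    (lower) contrast, adds a cortical-shell weighting (outer rim of the
    support boosted by ``shell_boost``) that the plate phantom lacks, and is
    intrinsically smoothed: closer in count distribution to the Hoffman-style
    phantom than to the pool, identical to neither.
    """
    shape = _check_shape(shape)
    activity, attenuation, labels = _hoffman_fields(
        shape, gm_wm_ratio, fill, soft_mu, lamina_thickness
    )
    support = labels != LABEL_BACKGROUND
    inner = _ellipsoid_mask(shape, scale=1.0 - shell_thickness_frac)
    shell = support & ~inner
    activity[shell] *= 1.0 + shell_boost
    if intrinsic_smoothing_mm > 0:
        sigma = [
            intrinsic_smoothing_mm / 2.3548 / v for v in (float(x) for x in voxel_size_mm)
        ]
        activity = gaussian_filter(activity, sigma=sigma)
        activity[~support] = 0.0
        np.clip(activity, 0.0, None, out=activity)
    return DigitalPhantom(activity, attenuation, labels, voxel_size_mm, "normal_brain")


def make_subject_cohort(
    base: DigitalPhantom,
    n: int,
    between_subject_cv: float = 0.08,
    field_smoothness_mm: float = 20.0,
    seed: int = 0,
    *,
    local_cv: float = 0.05,
) -> list[DigitalPhantom]:
    """Derive ``n`` subjects from a base phantom by multiplicative variability.

    Each subject's activity is the base activity times a log-normal global
    scalar (coefficient of variation ``between_subject_cv``, unit mean) times
    a smooth positive multiplicative field (Gaussian-smoothed log-field of
    correlation length ``field_smoothness_mm`` and pointwise CV ``local_cv``,
    normalized to unit mean over the support). Attenuation and labels are
    copied from the base. Deterministic under a fixed seed.
    """
    if n < 2:
        raise ValueError("a cohort needs n >= 2 subjects (an NDB needs an SD)")
    if not 0 <= between_subject_cv < 0.5:
        raise ValueError("between_subject_cv must lie in [0, 0.5)")
    if local_cv < 0:
        raise ValueError("local_cv must be non-negative")
    rng = np.random.default_rng(seed)
    support = base.support
    sigma_g = float(np.sqrt(np.log1p(between_subject_cv**2)))
    sigma_l = float(np.sqrt(np.log1p(local_cv**2)))
    sigma_vox = [
        max(field_smoothness_mm / 2.3548 / v, 1e-6) for v in base.voxel_size_mm
    ]
    subjects = []
    for i in range(n):
        g = float(rng.lognormal(mean=-0.5 * sigma_g**2, sigma=sigma_g))
        noise = rng.standard_normal(base.shape)
        smooth = gaussian_filter(noise, sigma=sigma_vox)
        sd = smooth.std()
        if sd > 0 and sigma_l > 0:
            fld = np.exp(sigma_l * (smooth / sd))
            fld /= fld[support].mean()
        else:
            fld = np.ones(base.shape)
        activity = base.activity * g * fld
        activity[~support] = 0.0
        subjects.append(
            DigitalPhantom(
                activity,
                base.attenuation.copy(),
                base.labels.copy(),
                base.voxel_size_mm,
                f"{base.name}_s{i:02d}",
            )
        )
    return subjects


def apply_ad_lesion(subject, voi_mask: np.ndarray, reduction_fraction: float):
    """Reduce activity/counts inside a VOI by ``reduction_fraction``.

    Emulates the Alzheimer-type digital simulation: every voxel inside the
    disease-specific VOI is multiplied by ``1 - reduction_fraction`` (a 0.2
    fraction reproduces the canonical 20% count decrease); voxels outside are
    untouched. Accepts either a :class:`DigitalPhantom` (lesion in activity)
    or a :class:`SubjectVolume` (lesion in reconstructed counts) and returns a
    new object of the same type.
    """
    if not 0 < reduction_fraction < 1:
        raise ValueError("reduction_fraction must lie strictly between 0 and 1")
    voi = np.asarray(voi_mask).astype(bool)
    target = subject.activity if isinstance(subject, DigitalPhantom) else subject.counts
    if voi.shape != target.shape:
        raise ValueError("voi_mask shape does not match the volume")
    if not voi.any():
        warnings.warn("empty lesion VOI: returning the input unchanged", stacklevel=2)
        factor = np.ones(target.shape)
    else:
        factor = np.where(voi, 1.0 - reduction_fraction, 1.0)
    if isinstance(subject, DigitalPhantom):
        out = subject.copy()
        out.activity = out.activity * factor
        out.name = f"{subject.name}_ad{reduction_fraction:g}"
        return out
    return subject.with_counts(
        subject.counts * factor,
        lesion_fraction=reduction_fraction,
        lesion_voxels=int(voi.sum()),
    )
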