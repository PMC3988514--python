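"""Global count normalization, normal database (NDB) and Z-score mapping.

The NDB holds the voxel-wise mean and sample SD of a cohort of normal
subjects after identical preprocessing: Gaussian smoothing (default 12 mm
FWHM) followed by proportional global normalization of the brain-mask mean
to a fixed target (default 50). A subject scored against the NDB must be
preprocessed identically; its Z-score map is

    z = (NDB mean - subject) / NDB SD

on the brain mask, so positive z flags a count decrease (hypoperfusion).
The voxel-wise SD is floored at a fraction of its mask-wide mean to keep the
division total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantoms import SubjectVolume

__all__ = [
    "NDB",
    "ZScoreMap",
    "global_normalize",
    "smooth_subject",
    "preprocess_subject",
    "build_ndb",
    "zscore_map",
    "threshold_zmap",
]


@dataclass
class NDB:
    """Voxel-wise mean and SD of a normalized normal cohort."""

    mean: np.ndarray
    sd: np.ndarray
    n: int
    brain_mask: np.ndarray
    normalization_target: float
    smoothing_fwhm_mm: float
    camera_id: str = ""
    voxel_size_mm: tuple[float, float, float] = (3.5, 3.5, 3.5)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if not (self.mean.shape == self.sd.shape == self.brain_mask.shape):
            raise ValueError("mean, sd and brain_mask must share one shape")
        if self.n < 2:
            raise ValueError("an NDB needs n >= 2")
        if np.any(self.sd[self.brain_mask] <= 0):
            raise ValueError("sd must be strictly positive on the brain mask")


@dataclass
class ZScoreMap:
    """Voxel-wise Z-score map; positive = count decrease (hypoperfusion)."""

    z: np.ndarray
    brain_mask: np.ndarray
    subject_id: str = ""
    ndb_id: str = ""
    positive_is_decrease: bool = True

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.z.shape != self.brain_mask.shape:
            raise ValueError("z and brain_mask must share one shape")
        if not np.all(np.isfinite(self.z[self.brain_mask])):
            raise ValueError("z must be finite on the brain mask")


def global_normalize(
    subject: SubjectVolume, brain_mask: np.ndarray, target: float = 50.0
) -> SubjectVolume:
    """Proportionally scale counts so the brain-mask mean equals ``target``."""
    mask = np.asarray(brain_mask).astype(bool)
    if mask.shape != subject.counts.shape:
        raise ValueError("brain_mask shape does not match the subject")
    if not mask.any():
        raise ValueError("brain_mask is empty")
    mean = subject.counts[mask].mean()
    if mean <= 0:
        raise ValueError("mean counts over the brain mask must be positive")
    return subject.with_counts(
        subject.counts * (target / mean), normalization_target=float(target)
    )


def smooth_subject(subject: SubjectVolume, fwhm_mm: float) -> SubjectVolume:
    """Gaussian-smooth a subject volume (FWHM in mm; 0 is the identity)."""
    if fwhm_mm <= 0:
        return subject
    sigma = [fwhm_mm / 2.3548 / v for v in subject.voxel_size_mm]
    return subject.with_counts(
        gaussian_filter(subject.counts, sigma=sigma), smoothing_fwhm_mm=float(fwhm_mm)
    )


def preprocess_subject(
    subject: SubjectVolume,
    brain_mask: np.ndarray,
    smoothing_fwhm_mm: float,
    target: float = 50.0,
) -> SubjectVolume:
    """The NDB preprocessing chain: smooth, then globally normalize."""
    return global_normalize(smooth_subject(subject, smoothing_fwhm_mm), brain_mask, target)


def build_ndb(
    subjects: list[SubjectVolume],
    brain_mask: np.ndarray,
    smoothing_fwhm_mm: float = 12.0,
    sd_floor_fraction: float = 0.1,
    target: float = 50.0,
    camera_id: str = "",
) -> NDB:
    """Construct the normal database from a cohort of subject volumes.

    Each subject is smoothed and globally normalized, then the voxel-wise
    mean and sample SD (n-1 denominator) are taken. The SD is floored at
    ``sd_floor_fraction`` times its mean over the brain mask, so Z-scores
    cannot blow up at near-deterministic voxels.
    """
    if len(subjects) < 2:
        raise ValueError("an NDB needs at least 2 subjects")
    mask = np.asarray(brain_mask).astype(bool)
    stack = np.stack(
        [
            preprocess_subject(s, mask, smoothing_fwhm_mm, target).counts
            for s in subjects
        ]
    )
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    mean_sd = sd[mask].mean()
    floor = sd_floor_fraction * mean_sd
    if mean_sd <= 1e-9 * target:
        # Degenerate cohort (numerically identical subjects): an absolute
        # floor keeps Z-scores finite instead of amplifying rounding noise.
        floor = 1e-9 * target
    sd = np.maximum(sd, floor)
    return NDB(
        mean,
        sd,
        n=len(subjects),
        brain_mask=mask,
        normalization_target=float(target),
        smoothing_fwhm_mm=float(smoothing_fwhm_mm),
        camera_id=camera_id,
        voxel_size_mm=subjects[0].voxel_size_mm,
    )


def zscore_map(subject: SubjectVolume, ndb: NDB) -> ZScoreMap:
    """Z-score a preprocessed subject against the NDB.

    The caller is responsible for preprocessing the subject identically to
    the NDB cohort (same smoothing, then global normalization to the NDB
    target); :func:`preprocess_subject` does exactly that.
    """
    if subject.counts.shape != ndb.mean.shape:
        raise ValueError("subject and NDB grids must match")
    z = np.zeros_like(ndb.mean)
    m = ndb.brain_mask
    z[m] = (ndb.mean[m] - subject.counts[m]) / ndb.sd[m]
    return ZScoreMap(
        z,
        ndb.brain_mask,
        subject_id=subject.subject_id,
        ndb_id=ndb.camera_id,
    )


def threshold_zmap(zmap: ZScoreMap, z_min: float) -> ZScoreMap:
    """Zero out |z| below ``z_min`` (the display/noise threshold, e.g. 1.5)."""
    if z_min < 0:
        raise ValueError("z_min must be non-negative")
    z = np.where(np.abs(zmap.z) >= z_min, zmap.z, 0.0)
    return ZScoreMap(
        z, zmap.brain_mask.copy(), zmap.subject_id, zmap.ndb_id, zmap.positive_is_decrease
    )
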