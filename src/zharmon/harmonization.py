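"""Voxel-wise count-ratio compensation maps between two gamma cameras.

A compensation map is the voxel-wise ratio of a common calibration object
imaged on the reference camera to the same object imaged on the target
camera; multiplying a target-camera subject scan by the map harmonizes it
toward the reference camera. Maps are built from the per-camera mean of one
or more acquisitions (averaging repeated scans suppresses ratio noise) and
carry a validity mask: voxels where either mean falls below a floor fraction
of its support mean are excluded and the ratio is the neutral value 1 there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantoms import SubjectVolume

__all__ = ["CompensationMap", "build_compensation_map", "apply_compensation"]


@dataclass
class CompensationMap:
    """Voxel-wise reference/target count ratio with validity mask."""

    ratio: np.ndarray
    valid_mask: np.ndarray
    source: str
    n_acquisitions: int
    smoothing_fwhm_mm: float
    voxel_size_mm: tuple[float, float, float] = (3.5, 3.5, 3.5)

    def __post_init__(self) -> None:
        self.valid_mask = np.asarray(self.valid_mask).astype(bool)
        if self.ratio.shape != self.valid_mask.shape:
            raise ValueError("ratio and valid_mask must share one shape")
        on = self.ratio[self.valid_mask]
        if on.size and (not np.all(np.isfinite(on)) or np.any(on <= 0)):
            raise ValueError("ratio must be finite and positive on the valid mask")

    def inverse(self) -> "CompensationMap":
        """The target/reference map: ratio inverted on the valid mask."""
        ratio = np.ones_like(self.ratio)
        ratio[self.valid_mask] = 1.0 / self.ratio[self.valid_mask]
        return CompensationMap(
            ratio,
            self.valid_mask.copy(),
            f"{self.source}_inverse",
            self.n_acquisitions,
            self.smoothing_fwhm_mm,
            self.voxel_size_mm,
        )


def _mean_counts(imgs: list[SubjectVolume]) -> np.ndarray:
    return np.mean([img.counts for img in imgs], axis=0)


def build_compensation_map(
    reference_imgs: list[SubjectVolume],
    target_imgs: list[SubjectVolume],
    count_floor: float = 0.05,
    smoothing_fwhm_mm: float = 0.0,
    source: str = "unknown",
) -> CompensationMap:
    """Build a reference/target count-ratio map from paired acquisitions.

    Per camera, acquisitions are averaged voxel-wise (repeated scans of the
    calibration object); both means may optionally be Gaussian-smoothed
    before the ratio is formed (off by default: the correction multiplies
    every voxel as measured). The ratio is taken only where both means reach
    ``count_floor`` times their own whole-support mean; elsewhere the ratio
    is 1 and the voxel is outside the validity mask.
    """
    if not reference_imgs or not target_imgs:
        raise ValueError("at least one acquisition per camera is required")
    shapes = {img.counts.shape for img in reference_imgs + target_imgs}
    if len(shapes) != 1:
        raise ValueError("all acquisitions must share the common grid")
    if not 0 <= count_floor < 1:
        raise ValueError("count_floor must lie in [0, 1)")
    voxel = reference_imgs[0].voxel_size_mm
    ref_mean = _mean_counts(reference_imgs)
    tgt_mean = _mean_counts(target_imgs)
    if smoothing_fwhm_mm > 0:
        sigma = [smoothing_fwhm_mm / 2.3548 / v for v in voxel]
        ref_mean = gaussian_filter(ref_mean, sigma=sigma)
        tgt_mean = gaussian_filter(tgt_mean, sigma=sigma)
    ref_support = ref_mean > 0
    tgt_support = tgt_mean > 0
    if not (ref_support & tgt_support).any():
        raise ValueError("reference and target supports do not overlap")
    ref_floor = count_floor * ref_mean[ref_support].mean()
    tgt_floor = count_floor * tgt_mean[tgt_support].mean()
    valid = (ref_mean >= max(ref_floor, np.finfo(float).tiny)) & (
        tgt_mean >= max(tgt_floor, np.finfo(float).tiny)
    )
    ratio = np.ones_like(ref_mean)
    ratio[valid] = ref_mean[valid] / tgt_mean[valid]
    return CompensationMap(
        ratio,
        valid,
        source,
        n_acquisitions=len(reference_imgs) + len(target_imgs),
        smoothing_fwhm_mm=float(smoothing_fwhm_mm),
        voxel_size_mm=voxel,
    )


def apply_compensation(subject: SubjectVolume, comp: CompensationMap) -> SubjectVolume:
    """Multiply a subject volume voxel-wise by the compensation ratio."""
    if subject.counts.shape != comp.ratio.shape:
        raise ValueError("subject and compensation map grids must match")
    return subject.with_counts(
        subject.counts * comp.ratio, compensation_source=comp.source
    )
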