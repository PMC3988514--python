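"""Specific volume-of-interest analysis (SVA) indices.

Three diagnosis-support indices are computed from a Z-score map and a
disease-specific VOI mask, under the convention that positive z marks a
count decrease:

* Severity  - mean z over VOI voxels with z >= threshold (0 if none),
* Extent    - percentage of VOI voxels with z >= threshold,
* Ratio     - suprathreshold fraction inside the VOI divided by the
              suprathreshold fraction over the whole brain mask (each as a
              fraction of its own region; 0 when the whole-brain fraction
              is 0).

The default threshold is z >= 2. Ratio is reported as the dimensionless
quotient of two fractions; a percentage rendering is available via
``SVAResult.ratio_percent``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .zscore import ZScoreMap

__all__ = ["SVAResult", "sva_indices", "make_sva_mask"]


@dataclass
class SVAResult:
    severity: float
    extent: float
    ratio: float
    z_threshold: float
    voi_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.extent <= 100.0):
            raise ValueError("extent must lie in [0, 100]")
        if not np.isfinite(self.severity) or not np.isfinite(self.ratio):
            raise ValueError("severity and ratio must be finite")
        if self.ratio < 0:
            raise ValueError("ratio must be non-negative")
        # severity is a mean of values >= z_threshold, hence non-negative for
        # the usual non-negative thresholds (or 0 when nothing survives)
        if self.z_threshold >= 0 and self.severity < 0:
            raise ValueError("severity must be non-negative at a non-negative threshold")

    @property
    def ratio_percent(self) -> float:
        """The Ratio rendered as a percentage."""
        return 100.0 * self.ratio


def sva_indices(
    zmap: ZScoreMap,
    voi_mask: np.ndarray,
    z_threshold: float = 2.0,
    voi_id: str = "",
) -> SVAResult:
    """Compute Severity, Extent and Ratio for a Z-map and disease VOI."""
    voi = np.asarray(voi_mask).astype(bool)
    if voi.shape != zmap.z.shape:
        raise ValueError("voi_mask shape does not match the Z-map")
    if not voi.any():
        raise ValueError("the VOI is empty")
    if np.any(voi & ~zmap.brain_mask):
        raise ValueError("the VOI must lie inside the brain mask")
    z = zmap.z
    supra_voi = voi & (z >= z_threshold)
    n_voi = int(voi.sum())
    n_supra = int(supra_voi.sum())
    severity = float(z[supra_voi].mean()) if n_supra else 0.0
    extent = 100.0 * n_supra / n_voi
    brain = zmap.brain_mask
    brain_frac = float((brain & (z >= z_threshold)).sum()) / float(brain.sum())
    ratio = (extent / 100.0) / brain_frac if brain_frac > 0 else 0.0
    return SVAResult(severity, extent, ratio, float(z_threshold), voi_id)


def make_sva_mask(atlas: np.ndarray, region_ids) -> np.ndarray:
    """Union of atlas regions as a binary VOI mask."""
    atlas = np.asarray(atlas)
    ids = [int(r) for r in np.atleast_1d(region_ids)]
    if not ids:
        raise ValueError("region_ids must not be empty")
    present = set(np.unique(atlas).tolist())
    missing = [r for r in ids if r not in present]
    if missing:
        raise ValueError(f"region ids not present in the atlas: {missing}")
    return np.isin(atlas, ids)
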