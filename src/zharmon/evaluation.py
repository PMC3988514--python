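"""Correction-quality measurements.

Reimplements the evaluation toolbox of the harmonization study:

* voxel-wise two-sample t "Decrease"/"Increase" maps with an uncorrected
  height threshold and a cluster-extent threshold,
* a reproducible central/marginal partition of the brain mask (radial
  half-volume rule),
* region-wise mean Z summaries,
* region-wise Pearson correlation of corrected vs reference counts over a
  six-region lobe-level atlas (a packaged synthetic sector/core partition
  stands in for an anatomical label scheme; user atlases are accepted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .phantoms import SubjectVolume
from .zscore import ZScoreMap

__all__ = [
    "DiffMap",
    "two_sample_tmap",
    "partition_central_marginal",
    "region_mean_z",
    "region_correlation",
    "region_correlation_table",
    "make_region_atlas",
    "ATLAS_LABELS",
    "standard_regions",
]

#: label scheme of the packaged synthetic lobe-level atlas
ATLAS_LABELS = {
    "frontal": 1,
    "occipital": 2,
    "temporal": 3,
    "anterior": 4,
    "sublobar": 5,
}

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class DiffMap:
    """Thresholded two-sample t result: t grid plus Decrease/Increase masks."""

    t: np.ndarray
    decrease_mask: np.ndarray
    increase_mask: np.ndarray
    height_p: float
    extent_voxels: int
    df: int

    def __post_init__(self) -> None:
        self.decrease_mask = np.asarray(self.decrease_mask).astype(bool)
        self.increase_mask = np.asarray(self.increase_mask).astype(bool)
        if np.any(self.decrease_mask & self.increase_mask):
            raise ValueError("decrease and increase masks must be disjoint")


def _counts_stack(group: list[SubjectVolume]) -> np.ndarray:
    shapes = {g.counts.shape for g in group}
    if len(shapes) != 1:
        raise ValueError("group volumes must share the common grid")
    return np.stack([g.counts for g in group])


def _filter_extent(mask: np.ndarray, extent_voxels: int, connectivity: int) -> np.ndarray:
    """Drop connected components smaller than the extent threshold."""
    if extent_voxels <= 1 or not mask.any():
        return mask
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask
    sizes = np.bincount(labeled.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= extent_voxels
    return keep[labeled]


def two_sample_tmap(
    group_a: list[SubjectVolume],
    group_b: list[SubjectVolume],
    brain_mask: np.ndarray,
    height_p: float = 0.05,
    extent_voxels: int = 50,
    connectivity: int = 26,
) -> DiffMap:
    """Voxel-wise pooled-variance two-sample t map with height/extent thresholds.

    ``group_a`` is the reference group, ``group_b`` the group under test;
    t = (mean_a - mean_b) / SE, so the "Decrease" mask marks voxels where the
    test group's counts are significantly *lower* than the reference's (one-
    sided p < ``height_p``, uncorrected) and "Increase" where they are
    significantly higher. Suprathreshold clusters smaller than
    ``extent_voxels`` (default 50, 26-connectivity) are removed.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 volumes")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    mask = np.asarray(brain_mask).astype(bool)
    a = _counts_stack(group_a)
    b = _counts_stack(group_b)
    if a.shape[1:] != mask.shape or b.shape[1:] != mask.shape:
        raise ValueError("groups and brain mask must share the common grid")
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.zeros_like(ma)
    nz = se > 0
    t[nz] = (ma[nz] - mb[nz]) / se[nz]
    t[~mask] = 0.0
    t_crit = float(stats.t.isf(height_p, df))
    decrease = _filter_extent((t >= t_crit) & mask, extent_voxels, connectivity)
    increase = _filter_extent((t <= -t_crit) & mask, extent_voxels, connectivity)
    return DiffMap(t, decrease, increase, float(height_p), int(extent_voxels), int(df))


def partition_central_marginal(
    brain_mask: np.ndarray,
    diff_mask: np.ndarray | None = None,
    voxel_size_mm=(3.5, 3.5, 3.5),
    radius_quantile: float = 0.5,
):
    """Split the brain mask into a deep central and a peripheral marginal part.

    Voxels are ranked by Euclidean distance (mm) from the brain-mask
    centroid; the inner ``radius_quantile`` of the volume (default: half) is
    central, the rest marginal. If a significant-difference mask is given,
    both parts are intersected with it. Returns ``(central, marginal)``.
    """
    mask = np.asarray(brain_mask).astype(bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    coords = np.indices(mask.shape, dtype=float)
    scale = np.asarray([float(v) for v in voxel_size_mm]).reshape(3, 1, 1, 1)
    coords = coords * scale
    centroid = coords[:, mask].mean(axis=1).reshape(3, 1, 1, 1)
    r = np.sqrt(((coords - centroid) ** 2).sum(axis=0))
    r_cut = np.quantile(r[mask], radius_quantile)
    central = mask & (r <= r_cut)
    marginal = mask & (r > r_cut)
    if diff_mask is not None:
        diff = np.asarray(diff_mask).astype(bool)
        central = central & diff
        marginal = marginal & diff
    return central, marginal


def region_mean_z(zmap: ZScoreMap, region_mask: np.ndarray) -> float:
    """Arithmetic mean of z over a non-empty region."""
    region = np.asarray(region_mask).astype(bool)
    if region.shape != zmap.z.shape:
        raise ValueError("region mask shape does not match the Z-map")
    if not region.any():
        raise ValueError("region is empty")
    return float(zmap.z[region].mean())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def standard_regions(atlas: np.ndarray) -> dict[str, np.ndarray]:
    """Named region masks of the lobe atlas, led by the whole-brain union."""
    atlas = np.asarray(atlas)
    regions: dict[str, np.ndarray] = {"all": atlas > 0}
    for name, rid in ATLAS_LABELS.items():
        regions[name] = atlas == rid
    return regions


def region_correlation(
    subject_corrected: SubjectVolume,
    subject_reference: SubjectVolume,
    atlas: np.ndarray,
    region_ids=None,
    min_voxels: int = 3,
) -> pd.Series:
    """Pearson correlation of two volumes of one subject, per atlas region.

    ``region_ids`` may list integer labels and/or the key ``"all"`` (union of
    all labelled voxels); by default every standard region plus "all" is
    reported. Zero-variance regions yield NaN (flagged, excluded from cohort
    summaries); regions below ``min_voxels`` are an error.
    """
    atlas = np.asarray(atlas)
    x = subject_corrected.counts
    y = subject_reference.counts
    if x.shape != y.shape or x.shape != atlas.shape:
        raise ValueError("volumes and atlas must share the common grid")
    if region_ids is None:
        masks = standard_regions(atlas)
    else:
        masks = {}
        present = set(np.unique(atlas).tolist())
        for rid in region_ids:
            if rid == "all":
                masks["all"] = atlas > 0
            else:
                rid = int(rid)
                if rid not in present:
                    raise ValueError(f"region id {rid} not present in the atlas")
                masks[str(rid)] = atlas == rid
    out = {}
    for name, m in masks.items():
        if int(m.sum()) < min_voxels:
            raise ValueError(f"region '{name}' has fewer than {min_voxels} voxels")
        out[name] = _pearson(x[m], y[m])
    return pd.Series(out, name=subject_corrected.subject_id)


def region_correlation_table(
    pairs: list[tuple[SubjectVolume, SubjectVolume]],
    atlas: np.ndarray,
    region_ids=None,
) -> pd.DataFrame:
    """Per-subject region correlations plus cohort mean and SD rows.

    Rows are subjects (then ``mean`` and ``sd``), columns regions. NaN
    (zero-variance) entries are excluded from the summaries.
    """
    rows = [
        region_correlation(corr, ref, atlas, region_ids) for corr, ref in pairs
    ]
    table = pd.DataFrame(rows)
    table.loc["mean"] = table.mean(skipna=True)
    table.loc["sd"] = table.iloc[:-1].std(skipna=True)
    return table


def make_region_atlas(brain_mask: np.ndarray, voxel_size_mm=(3.5, 3.5, 3.5)) -> np.ndarray:
    """Synthetic six-region lobe-level label volume on the brain mask.

    A deterministic concentric/sector partition standing in for an anatomical
    label scheme: a deep central core ("sublobar"), an anterior sector
    ("frontal"), a posterior sector ("occipital"), inferior-lateral sectors
    ("temporal") and the remaining tissue ("anterior"). The union of all
    labels is exactly the brain mask; the whole-brain region ("all lobes") is
    their union.
    """
    mask = np.asarray(brain_mask).astype(bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    coords = np.indices(mask.shape, dtype=float)
    scale = np.asarray([float(v) for v in voxel_size_mm]).reshape(3, 1, 1, 1)
    coords = coords * scale
    centroid = coords[:, mask].mean(axis=1).reshape(3, 1, 1, 1)
    rel = coords - centroid
    # normalize each axis by the mask's own half-extent along it
    half = np.asarray(
        [max(np.abs(rel[i][mask]).max(), 1e-9) for i in range(3)]
    ).reshape(3, 1, 1, 1)
    xn, yn, zn = (rel / half)[0], (rel / half)[1], (rel / half)[2]
    r = np.sqrt(xn**2 + yn**2 + zn**2)
    atlas = np.zeros(mask.shape, dtype=np.int16)
    atlas[mask] = ATLAS_LABELS["anterior"]  # remainder bucket
    temporal = mask & (np.abs(xn) > 0.5) & (zn < 0.1)
    atlas[temporal] = ATLAS_LABELS["temporal"]
    occipital = mask & (yn < -0.35)
    atlas[occipital] = ATLAS_LABELS["occipital"]
    frontal = mask & (yn > 0.15)
    atlas[frontal] = ATLAS_LABELS["frontal"]
    sublobar = mask & (r < 0.4)
    atlas[sublobar] = ATLAS_LABELS["sublobar"]
    return atlas
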