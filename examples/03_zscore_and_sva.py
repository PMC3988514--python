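"""Normal database, Z-score map and SVA indices for a lesioned subject.

Builds an NDB from a simulated cohort on the reference camera, lesions a
held-out subject by 20% inside a posterior disease VOI, scores it against
the NDB and prints the three SVA indices.
"""

from zharmon import (
    acquire,
    apply_ad_lesion,
    build_ndb,
    default_ad_voi,
    default_cameras,
    make_normal_brain,
    make_subject_cohort,
    preprocess_subject,
    sva_indices,
    threshold_zmap,
    zscore_map,
)

base = make_normal_brain()
cohort = make_subject_cohort(base, n=11, seed=42)
cam = default_cameras(base.voxel_size_mm)["ecam"]
scans = [acquire(s, cam, True, seed=i) for i, s in enumerate(cohort)]

mask = base.brain_mask
ndb = build_ndb(scans[:-1], mask, smoothing_fwhm_mm=12.0)
print(f"NDB from {ndb.n} subjects, brain mask {int(mask.sum())} voxels")

voi = default_ad_voi(mask, base.voxel_size_mm)
lesioned = apply_ad_lesion(scans[-1], voi, reduction_fraction=0.2)
pre = preprocess_subject(lesioned, mask, ndb.smoothing_fwhm_mm, ndb.normalization_target)
zm = zscore_map(pre, ndb)

display = threshold_zmap(zm, 1.5)  # the display threshold used for reading maps
print(f"VOI: {int(voi.sum())} voxels; mean z inside VOI = {zm.z[voi].mean():.2f}")
print(f"voxels surviving the 1.5 display threshold: {int((display.z != 0).sum())}")

res = sva_indices(zm, voi, z_threshold=2.0)
print(
    f"SVA: severity={res.severity:.2f}  extent={res.extent:.1f}%  ratio={res.ratio:.2f}"
)
print("(severity = mean suprathreshold z in the VOI; extent = % of VOI voxels")
print(" with z >= 2; ratio = VOI suprathreshold fraction over the whole-brain one)")
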