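"""The cavernous-angioma scenario: a lesion bright on MR but cold on PET.

The anatomical prior sees a strong edge around the lesion; a badly behaved
prior could paint MR structure into the PET image ("hallucinate" uptake).
The parallel-level-sets penalty only relaxes smoothing along shared edges,
so the reconstructed lesion must stay cold.
"""

import mrgpet as m

activity, prior, tissue = m.generate_brain_phantom((128, 128), 1.2, seed=0)
lesion = m.LesionSpec(
    center=(40, 64), radius_mm=6.0, pet_multiplier=0.25, mr_multiplier=2.0
)
activity, prior, rois = m.insert_lesion(activity, prior, tissue, lesion)
label = rois.label_for_role("lesion_1")
print(
    f"lesion: {int(rois.mask(label).sum())} voxels in WM, "
    f"true activity {activity.values[rois.mask(label)].mean():.2f} "
    f"(WM = 1.0), MR intensity x2"
)

model = m.SystemModel(n_angles=120, n_radial_bins=128, bin_spacing_mm=1.2, psf_fwhm_mm=3.0)
model, ybar = m.calibrate_to_counts(model, activity, 2.0e6)
y = m.add_poisson_noise(ybar, seed=7)

cfg = m.ReconConfig(n_subsets=20, n_iterations=6, save_every_iteration=False)
u_osem = m.osem(y, model, cfg, grid=activity)[-1]
pen = m.PenaltyParams(
    2.0,
    m.default_alpha(4.0, activity.spacing_mm),
    m.default_eta(prior),
    weight_scale=m.auto_weight_scale(model, activity),
)
u_mrg = m.mrg_reconstruct(y, model, prior, pen, cfg)[-1]

mean_osem = m.roi_stats(u_osem, rois, label).mean
mean_mrg = m.roi_stats(u_mrg, rois, label).mean
print(f"OSEM lesion mean: {mean_osem:.3f}")
print(f"MRg  lesion mean: {mean_mrg:.3f}  (ratio {mean_mrg / mean_osem:.2f})")
print(
    "\nA ratio <= 1 shows the MR-bright prior did not inject uptake into the "
    "PET-cold lesion; the penalized image keeps (and sharpens) the cold spot."
)
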