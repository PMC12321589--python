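"""Reconstruct one noisy low-dose sinogram with OSEM and the MR-guided method.

Simulates a 12.5%-dose acquisition (binomial thinning of a 2e6-count scan),
reconstructs with OSEM (with and without the 3 mm Gaussian post-filter) and
with the parallel-level-sets penalized method at beta = 2, then prints the
phantom image-quality metrics.  Lower COV at preserved contrast is the
hallmark of the anatomical prior.
"""

import mrgpet as m

activity, prior, tissue = m.generate_brain_phantom((128, 128), 1.2, seed=0)
rois = m.place_rois(tissue)

model = m.SystemModel(n_angles=120, n_radial_bins=128, bin_spacing_mm=1.2, psf_fwhm_mm=3.0)
model, ybar = m.calibrate_to_counts(model, activity, total_counts=2.0e6)
y = m.thin_counts(m.add_poisson_noise(ybar, seed=1), fraction=0.125, seed=2)
print(f"simulated counts at 12.5% dose: {int(y.values.sum())}")

cfg = m.ReconConfig(n_subsets=20, n_iterations=6, save_every_iteration=False)
u_osem = m.osem(y, model, cfg, grid=activity)[-1]
u_gf = m.gaussian_postfilter(u_osem, 3.0)

pen = m.PenaltyParams(
    beta=2.0,
    alpha=m.default_alpha(4.0, activity.spacing_mm),
    eta=m.default_eta(prior),
    weight_scale=m.auto_weight_scale(model, activity),
)
u_mrg = m.mrg_reconstruct(y, model, prior, pen, cfg)[-1]

print(f"{'method':>12} {'CRC':>6} {'COV':>6} {'GM/WM':>6} {'GM-CSF':>7}")
for name, img in (("OSEM", u_osem), ("OSEM+GF", u_gf), ("MRg b=2", u_mrg)):
    gm = m.roi_stats(img, rois, "GM")
    wm = m.roi_stats(img, rois, "WM")
    csf = m.roi_stats(img, rois, "CSF")
    gm_wm, gm_csf = m.tissue_contrasts(gm, wm, csf)
    print(
        f"{name:>12} {m.crc(gm, wm):6.3f} {m.cov(wm):6.3f} "
        f"{gm_wm:6.2f} {gm_csf:7.3f}"
    )
print("\nCRC = 1 and COV = 0 would be perfect recovery of the 4:1:0 phantom.")
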