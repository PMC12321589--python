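# Methods

This note records the models, numerical choices and limitations behind
`mrgpet`, at the level of detail a user needs to interpret results and a
maintainer needs to change them safely.

## Forward model

The projector is a 2-D parallel-beam line-integral model.  For each of
`n_angles` directions uniformly spaced over 180° and `n_radial_bins` radial
offsets, the intersection length of the ray with every pixel is computed
exactly by Siddon-style grid traversal and assembled into a sparse matrix
`A`.  Forward and back projection are `A` and `Aᵀ` applied to the same
matrix, so the adjoint identity holds to machine precision by construction
— a property the EM updates rely on.  Expected counts are
`ȳ = n ⊙ A·blur(u) + r` with per-LOR normalization `n` (default 1; also
carries the count-level calibration) and additive background `r` (default
0, standing in for scatter and randoms).

Resolution is modelled as an isotropic image-space Gaussian
(`psf_fwhm_mm`, default 3 mm — a typical clinical PET resolution; the
scanner's true resolution kernel is not modelled).  The blur uses a
symmetric kernel with symmetric (Neumann) boundary, which makes it
self-adjoint and flat-preserving, keeping the full forward/backward pair an
exact adjoint pair and conserving total image sum.

Counting statistics: `add_poisson_noise` draws element-wise Poisson counts;
`thin_counts` applies element-wise binomial thinning with keep-probability
`f`, which is distributionally identical to acquiring a fraction `f` of the
listmode events — this is how the dose levels {100, 50, 25, 12.5}% are
emulated.  Thinning a Poisson sinogram is again Poisson with mean `f·ȳ`
(verified distributionally in the tests).  All randomness flows through
explicit integer seeds; there is no hidden global state.

A `total_counts` calibration (default 2×10⁶ for a 128×128 slice — a
desk-scale stand-in for a 10-minute brain acquisition) scales the
normalization so the full-dose noise level is controlled and reproducible.

## Digital brain phantom

The phantom emulates a Hoffman-type brain insert: outer CSF rim, cortical
grey-matter ribbon, white-matter core with two ventricles, and two deep
grey nuclei providing interior WM-GM interfaces for line-profile analysis.
The GM/WM interface carries a sinusoidal "gyral" perturbation whose phases
and secondary amplitude come from the seed; seeds change only this
geometry, never the activity levels.  Activity is exactly GM:WM:CSF =
4:1:0; the anatomical prior uses T1-like levels WM = 1.0, GM = 0.6,
CSF = 0.1 (configurable constants).  Both images are functions of the same
label map, so every tissue boundary is shared voxel-for-voxel — the
idealized premise of anatomical guidance.  Lesions are disks with
independent PET and MR multipliers, which makes modality-mismatched cases
(PET-cold, MR-bright) one-liners.  The true Hoffman insert geometry is
licensed and is not reproduced; any convoluted 4:1:0 geometry serves the
same purpose here.

Measurement ROIs are circles auto-placed at local maxima of each tissue's
Euclidean distance transform (the deepest interior points), shrunk to stay
strictly inside the tissue, with a minimum separation of one diameter.
This stands in for manual ROI placement on a central slice; published ROI
schemes for this phantom are not fully specified, so the placement rule is
the package's own and is deterministic.

## Reconstruction

MLEM/OSEM uses the standard multiplicative update with interleaved angular
subsets (angle `j` → subset `j mod n_subsets`) processed in bit-reversed
order for balanced coverage; an "iteration" is one full pass over all
subsets and per-iteration snapshots can be retained.  Voxels outside the
scanner's field of view (zero sensitivity) are masked.  With consistent
noise-free data the phantom is recovered to a few percent NRMSE within a
couple of hundred MLEM iterations, and on noisy data the Poisson
log-likelihood is non-decreasing and total counts are conserved
(`Σ s_j u_j = Σ y_i`) at every iteration — both are regression-tested.

The MR-guided variant is one-step-late (OSL) MAP-EM: the PLS penalty
gradient, evaluated at the current estimate, is added to the EM denominator
with weight `β·κ/n_subsets`, and the denominator is floored at
`epsilon_floor · s_subset` (default 1e-3).  The discrete gradient is a
forward difference per axis divided by the voxel spacing with replicate
boundary; the divergence is its exact negative adjoint, so the analytic
penalty gradient is the exact derivative of the discrete penalty (matched
against central finite differences to <1e-4 relative error in the tests).
OSL monotonicity is not guaranteed in general; it is verified empirically
for one subset on the shipped problems.  A De Pierro-style provably
convergent variant would be a natural extension.

### Penalty parameterization

Commercial systems expose a dimensionless penalty strength with an
undisclosed internal normalization; the package defines its own and
records it in every output:

- **κ (weight scale).**  The PLS gradient obeys the hard bound
  `|∂P/∂u| ≤ 2·ndim/min(spacing)` (each flux component is bounded by 1).
  Setting `κ = s̄ · min(spacing) / (2·ndim·H)` with `s̄` the mean FOV
  sensitivity and headroom `H = 8` guarantees a positive OSL denominator
  for every `β < 8` — four times the largest clinically used `β = 2` — so
  the quoted range β ∈ {0.5, 1, 2} spans mild to strong regularization
  inside the provably stable regime.  κ depends on the calibrated model
  only, not on the (thinned) data, so a fixed β regularizes relatively
  more at lower dose, which is the regime where anatomical guidance pays
  off.  (An earlier weight without the headroom factor allowed the
  denominator to cross zero at β ≥ 1 and was replaced for this stability
  reason.)
- **α (integrand smoothing)** defaults to 1% of the activity scale per
  mean voxel size — small enough to keep edges, large enough to keep the
  penalty gradient Lipschitz at the count levels used.
- **η (MR edge threshold)** defaults to 5% of the 99th-percentile prior
  gradient magnitude: tissue boundaries give `|ξ| ≈ 1` (guidance on),
  interpolation-level prior variation gives `|ξ| ≈ 0` (guidance off).

`objective_value` reports `Σ(ȳ − y log ȳ) + β·weight_scale·P` with the
convention `y log ȳ = 0` where `y = 0`; `weight_scale` defaults to 1 so
the objective is literally linear in β unless the calibrated κ is passed.

Post-filtering policy follows clinical practice: the 3 mm FWHM Gaussian
post-filter (σ = FWHM/(2√(2 ln 2))) is applied to OSEM output only; the
penalized reconstruction is never post-filtered.

## Metrics

All standard deviations are sample SDs (ddof = 1).  CRC uses ROI means:
`(GM/WM − 1)/(4 − 1)` for the 4:1 design.  COV is WM SD/mean.  Contrasts
are `GM/WM` and `(GM − CSF)/GM`.  CNR is `(GM − WM)/WM_SD`.  The edge
sharpness index is the maximum absolute slope of a line profile expressed
in percent of the profile maximum per mm.  Lesion metrics (SBR, SNR, CBR,
CNR) and SUVR operate on activity values rather than SUV — with no
injected dose or body weight in synthetic mode the SUV scale factor is a
global constant that cancels in every ratio, so the values are exact.
Line profiles are linear interpolations along a segment given in mm
relative to the image centre.

## Study conditions and problem sizes

The shipped experiments run a 128×128 single slice at 1.2 mm voxels,
120 angles × 128 radial bins, 2×10⁶ full-dose counts, 20 subsets and 6–8
iterations — sizes chosen so a full dose × algorithm × β sweep completes
in seconds while keeping >200 counts per LOR at full dose in the brain.
The qualitative findings these conditions support (and the tests assert):
at 12.5% dose and matched iterations, MRg with β = 2 yields several-fold
lower WM COV than unfiltered OSEM and higher GM-WM contrast than 3-mm
filtered OSEM, with COV non-increasing in β; and the MR-bright/PET-cold
lesion never gains activity from the prior.

## What the synthetic data does and does not show

The phantom shares every boundary between PET and MR exactly, has
piecewise-constant tissues, uses a matched forward model for simulation
and reconstruction (an "inverse crime"), and contains no attenuation,
scatter, randoms, motion, or MR-segmentation error.  Passing tests
therefore validate the algorithmic contracts (operator exactness, penalty
calculus, EM behaviour, metric definitions) and the qualitative dose/β
trends — not clinical performance.  Effects that depend on boundary
mismatch between modalities are probed only through the mismatch-lesion
fixture.

A known behaviour worth flagging: for a small PET-cold lesion the
penalized reconstruction converges faster than OSEM (which approaches cold
values very slowly, from above) and at strong β settles slightly below the
true level — cold-spot bias.  Consequently MRg and OSEM lesion means can
differ by 10–30% at matched early iterations even though the prior never
*adds* uptake; interpret cold-lesion quantification at strong β with care.

## Other numerical conventions

- Images are float64 in memory and float32 on disk (NIfTI, spacing in the
  header); label maps are int16 with a JSON legend; sinograms are `.npz`
  plus a JSON sidecar with the full geometry, so reconstruction can resume
  from files alone.
- The physical origin is the image centre; ray offsets, lesion centres and
  profile endpoints all use it.
- EM ratio terms use `y/ȳ = 0` where `ȳ = 0`; measured counts on a
  zero-expectation LOR raise an error rather than being silently dropped.
- Experiments are deterministic given their config (hashed into every
  artifact); an interrupted sweep is resumed by re-running it.
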