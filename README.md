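# mrgpet — MR-guided penalized PET reconstruction

`mrgpet` is a desk-scale laboratory for **anatomically guided brain-PET
reconstruction** on integrated PET/MR systems.  It is aimed at researchers
who want to study how an MR prior changes PET image quality — contrast,
noise, edge sharpness, lesion conspicuity — under dose reduction, without
access to scanner raw data: everything runs on a built-in digital brain
phantom.

## The method

Emission data are Poisson counts $y_i$ on lines of response $i$ with
expectation $\bar y_i(u) = n_i [A\,u]_i + r_i$ for activity image $u$
(projection matrix $A$ with exact ray–pixel intersection lengths, image-space
Gaussian PSF, per-LOR normalization $n_i$ and additive background $r_i$).
The MR-guided reconstruction (MRg) solves the penalized-likelihood problem

$$\hat u = \arg\min_u \sum_i \big(\bar y_i(u) - y_i \log \bar y_i(u)\big) + \beta\, P(u, v)$$

with the **parallel level sets (PLS)** penalty driven by the T1-weighted MR
prior $v$:

$$P(u,v) = \sum_x \sqrt{\alpha^2 + |\nabla u(x)|^2 - (\nabla u(x) \cdot \xi(x))^2},
\qquad
\xi = \frac{\nabla v}{\sqrt{|\nabla v|^2 + \eta^2}} .$$

Where the MR image has a strong edge, $|\xi| \to 1$ and PET gradients
aligned with it are barely penalized; where the MR is flat, $\xi \to 0$ and
the penalty reduces to a smoothed total variation.  The optimizer is
one-step-late MAP-EM inside an ordered-subsets loop; $\beta = 0$ reduces it
exactly to OSEM, and one subset to MLEM.  $\alpha$ smooths the integrand,
$\eta$ sets the MR edge threshold, and $\beta$ the penalty strength
(clinically useful range $\beta \in \{0.5, 1, 2\}$).

The package also provides the Hoffman-type phantom (GM:WM:CSF activity
4:1:0 with a shared-boundary T1-like prior and optional matched or
modality-mismatched lesions), binomial count thinning for dose-reduction
studies ({100, 50, 25, 12.5}%), and the standard image-quality metrics:
CRC, COV, GM-WM and GM-CSF contrast, CNR, edge-sharpness index from line
profiles, lesion SBR/SNR/CBR/CNR, and SUVR.

## Worked example

`examples/02_osem_vs_mrg.py` simulates a 12.5%-dose scan (binomial thinning
of a 2×10⁶-count acquisition of the 128×128 phantom) and reconstructs it
three ways (20 subsets, 6 iterations):

```
simulated counts at 12.5% dose: 249910
      method    CRC    COV  GM/WM  GM-CSF
        OSEM  1.323  0.530   4.97   0.978
     OSEM+GF  1.174  0.308   4.52   0.973
     MRg b=2  1.050  0.106   4.15   0.973
```

CRC = 1, COV = 0, GM/WM = 4 and GM-CSF = 1 would be perfect recovery of the
phantom.  Unfiltered OSEM is noisy (COV 0.53) and noise-biased high in
contrast; the 3 mm Gaussian post-filter trades noise for contrast; the
MR-guided reconstruction reaches a far lower noise level while keeping the
contrast close to truth — the behaviour that motivates anatomical priors at
low dose.  The other examples generate the phantom, sweep dose × algorithm
× iteration into a metric table, and demonstrate that an MR-bright but
PET-cold lesion is **not** painted into the PET image by the prior
(`examples/04_mismatched_lesion_guard.py`).

A thin CLI mirrors the library: `mrgpet phantom | simulate | recon |
metrics | sweep | plot` (see `mrgpet --help`).

## Layout

- `src/mrgpet/phantom.py` — digital brain phantom, lesions, ROI placement
- `src/mrgpet/projection.py` — system matrix, PSF, Poisson noise, thinning
- `src/mrgpet/recon.py` — MLEM/OSEM, PLS penalty and gradient, MAP-EM
- `src/mrgpet/metrics.py` — image-quality metrics and line profiles
- `src/mrgpet/io.py`, `experiment.py`, `cli.py` — NIfTI/sinogram I/O,
  reproducible sweeps, command-line interface
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
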