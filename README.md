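# pseudopet

Personalized MR-informed diffusion priors for low-count PET image
reconstruction — with the training data synthesized by **registration, not
generation**: other subjects' PET images are carried into the target
subject's anatomy through MR-derived transforms ("pseudo-PET"), and a
slice-conditional diffusion model trained on those images serves as the
prior inside a decomposed-diffusion-sampling reconstruction loop.

The package is aimed at researchers studying anatomically-guided PET
reconstruction who want a fully self-contained, CPU-scale testbed: it ships
its own multi-subject brain phantom generator, PET forward model, classical
reconstructions (MLEM/OSEM, BSREM with an asymmetric Bowsher-weighted
relative-difference prior), registration stack, diffusion prior, sampler and
evaluation harness. No external data, GPUs or deep-learning frameworks are
required; the small neural networks are implemented in numpy with
hand-written backpropagation and are gradient-checked in the test suite.

## The model

PET measurements are Poisson counts with mean

```
q = A x + b
```

where `x` is the radiotracer image, `A` the system model (projection,
attenuation, normalization) and `b` known scatter/randoms. Classical
reconstruction maximizes the Poisson log-likelihood

```
L(x | m) = Σ_i  m_i log q_i − q_i − log m_i!
```

by (ordered-subset) EM, optionally penalized with an anatomical prior
(BSREM with an asymmetric Bowsher-weighted relative-difference prior: each
voxel is smoothed only toward the 4 patch neighbors most similar in the
co-registered MR image).

**Pseudo-PET synthesis.** Given paired PET–MR volumes of other subjects and
the target's MR, each source PET is mapped into the target anatomy through

```
B_target⁻¹ ∘ φ_i ∘ B_i
```

with `B_i` an affine MR-to-common-space map and `φ_i = φ(B_target MR_target,
B_i MR_i)` a learned dense deformation. Because all transformed images share
one anatomy, randomized convex sums of them (number of summands N drawn with
P(N=n) ∝ 1/n, weights uniform then normalized) yield an unlimited stream of
diverse, less-noisy, subject-specific training images.

**Prior and sampler.** A variance-preserving denoising diffusion model is
trained slice-wise on the normalized pseudo-PET images, conditioned on the
timestep and on the slice position in [0, 1] (and optionally on the MR slice
with classifier-free guidance, unconditional probability 0.1).
Reconstruction interleaves, per diffusion step: slice-wise denoising and a
Tweedie posterior-mean estimate; rescaling to measurement units by a
measurement-derived factor c; `p` data-consistency ascent steps on the
subset objective

```
Φ_j(x) = L_j(x) − (1/n_sub) [ λ_RDP · RDP_z(x) + λ_DDS ‖x − x⁰‖² ]
```

(axial RDP for slice consistency, quadratic anchor to the prior output);
and re-noising to the next noise level. Defaults follow standard practice
for this sampler: 100 diffusion steps, 10 consistency steps each, step size
δ = 0.2, λ_RDP = 5·10⁻⁴, 21 subsets.

## Worked example

The end-to-end simulation study — 5 synthetic subjects, a lesioned target,
2.5% low-count data, OSEM versus diffusion-prior reconstruction with a
personalized (pseudo-PET-trained) and an unpersonalized prior — runs in a
few minutes on one CPU core:

```python
from pseudopet import pipeline as pl
from pseudopet import metrics

cfg = pl.ExperimentConfig(master_seed=0, output_dir="scratch/demo")
report = pl.run_simulation_study(cfg)
for row in report["rows"]:
    print(f"{row['method']:>20}  h={row['hyperparameter']:<5} "
          f"NRMSE={row['nrmse']:.3f}  CRC={row['crc']:.3f}  CoV={row['cov']:.3f}")
crc_star, cov_p, cov_u = metrics.cov_at_matched_crc(
    report["rows"], "dds_personalized", "dds_unpersonalized")
print(f"matched CRC {crc_star:.3f}: personalized CoV {cov_p:.3f} "
      f"vs unpersonalized {cov_u:.3f}")
```

prints

```
                osem  h=2     NRMSE=0.633  CRC=1.234  CoV=0.827
                osem  h=5     NRMSE=0.961  CRC=1.464  CoV=1.504
    dds_personalized  h=1.0   NRMSE=0.489  CRC=0.580  CoV=0.356
    dds_personalized  h=3.0   NRMSE=0.490  CRC=0.558  CoV=0.354
    dds_personalized  h=10.0  NRMSE=0.495  CRC=0.488  CoV=0.348
    dds_personalized  h=30.0  NRMSE=0.516  CRC=0.362  CoV=0.340
  dds_unpersonalized  h=1.0   NRMSE=0.536  CRC=0.621  CoV=0.429
  dds_unpersonalized  h=3.0   NRMSE=0.537  CRC=0.598  CoV=0.426
  dds_unpersonalized  h=10.0  NRMSE=0.540  CRC=0.527  CoV=0.418
  dds_unpersonalized  h=30.0  NRMSE=0.634  CRC=0.140  CoV=0.851
matched CRC 0.471: personalized CoV 0.347 vs unpersonalized 0.480
```

Reading the table: `h` is the swept hyperparameter (OSEM iterations, or the
prior-anchoring strength λ_DDS). NRMSE is the masked reconstruction error
against the ground-truth activity; CRC the lesion contrast-recovery
coefficient against the uniform white-matter background (1 = perfect, and
noisy OSEM means can overshoot 1); CoV the background coefficient of
variation (a noise proxy). Both diffusion priors suppress noise far below
OSEM; the personalized prior reaches a lower CoV than the unpersonalized
one at every matched contrast level, and a lower NRMSE overall — the
motivating property of pseudo-PET training data.

A CLI mirrors the library (`pseudopet phantom`, `simulate`, `recon`,
`register-affine`, `dds-recon`, `run-study`, `bias-variance`; see
`pseudopet --help`).

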