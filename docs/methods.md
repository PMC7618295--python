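# Methods

This note records the models, conventions and numerical choices behind
`pseudopet`, in the order the pipeline uses them.

## Synthetic subjects

Each subject is a smoothly deformed variant of one anatomical template: an
elliptical head with a CSF rim, a cortical gray-matter ribbon, a
white-matter core and two ventricles. Anatomical variability between
subjects comes from warping the template label map with a seeded smooth
random displacement field (Gaussian-filtered white noise, default RMS 1.5
voxels at a 6-voxel correlation scale). PET activity, MR intensity and the
attenuation map all derive from the same label map, so PET and MR structure
agree by construction.

Defaults (all configurable through `PhantomConfig`):

| parameter | default | rationale |
|---|---|---|
| grid / voxel | 64×64×32 at 2 mm (tests use 32×32×16) | desk-scale stand-in for clinical 128×128×120 grids |
| activity GM:WM:CSF | 4 : 1 : 0.1 | typical FDG gray/white contrast |
| attenuation | 0.0096 mm⁻¹ uniform in head | water at 511 keV; no bone/air structure |
| MR noise / bias | σ = 0.02, ±10 % smooth bias field | mild, so registration is nontrivial but solvable |

Lesions are uniform spheres at 1.5× the gray-matter activity, rasterized on
a supersampled grid and block-averaged to the PET grid, which produces
partial-volume edge voxels. The MR is deliberately left untouched: lesions
are PET-MR mismatches and are excluded from all training data.

What the generator does **not** emulate: realistic MR sequences or
T1-dependent tissue texture, positron range / detector blurring, bone or
air in the attenuation map, inter-subject uptake variability beyond
geometry. Passing tests therefore demonstrate the algorithmic machinery
under controlled conditions, not clinical performance.

## Forward model

The scanner is modeled as independent transverse planes viewed by a 2D
parallel-beam geometry (angles uniform in [0, π), radial bins at one voxel
pitch covering the diagonal). The per-plane projection matrix is
pixel-driven with a linear radial footprint: each voxel center projects
onto the detector axis and splits its value between the two nearest bins.
Because the triangle kernel is a partition of unity at unit bin spacing, a
unit voxel's projection sums to exactly one at every angle, and for smooth
images bin values approximate chord-length line integrals. The back
projector is the matrix transpose, so the adjoint identity holds to
rounding. Attenuation factors are `exp(−∫ μ dl)` computed with the same
matrix; normalization factors default to one.

Poisson data are simulated by globally rescaling the activity so the
expected prompts `q = Ax + b` sum to the requested count level (defaults:
6×10⁸ at full dose). The background `b` is spatially constant with
`sum(b) = 0.3 · sum(q)` exactly, and is passed to every reconstruction as
known contamination. Low-count data are obtained by drawing exactly
`round(f · total)` recorded events without replacement (multivariate
hypergeometric across bins; default f = 0.025), with `b` scaled by `f`.
Subsets partition angles by stride (maximal angular spacing within each
subset), with the processing order bit-reversed so consecutive subsets are
angularly far apart.

Reconstructions from thinned data estimate activity at the low-dose scale;
comparisons against a full-dose reference divide by the dose fraction.

## Classical reconstruction

MLEM/OSEM use the standard multiplicative update; voxels with zero subset
sensitivity are left at zero. BSREM maximizes `L(x|m) − β·RDP_aBOW(x)` with
EM-preconditioned block updates `x ← x + α_k (x/s_j)(∇L_j − (β/n_sub)∇R)`,
relaxation `α_k = 1/(1 + k/20)`, and nonnegativity projection; with β = 0
and α = 1 a block update coincides exactly with the OSEM update. A
sustained objective decrease (3 consecutive passes) raises a diagnostic
error rather than returning silently.

The anatomical prior is the relative-difference penalty
`Σ w_jk (x_j−x_k)² / (x_j+x_k+γ|x_j−x_k|+ε)` with γ = 2 and ε = 10⁻⁸,
weighted by asymmetric Bowsher selection: each voxel selects the 4
neighbors of its 3×3×3 patch with smallest absolute MR difference (ties
broken lexicographically by offset; the directed weights are used as-is,
which is what makes the prior asymmetric; a symmetrized variant is a flag).
Gradients are analytic and verified against finite differences.

## Registration

Affine registration maximizes global NCC over a 3-level pyramid with a
derivative-free Powell search on a 7-parameter similarity transform
(translation mm, Euler angles, isotropic scale), deterministically
initialized at identity. Maps are stored as 4×4 world-mm matrices.

Deformable registration is a function φ(fixed, moving) → dense displacement
(voxel units, fixed grid, backward/pull warping with linear interpolation).
Two interchangeable engines:

* **cnn** — a shallow 3D convolutional predictor operating at half
  resolution with a zero-initialized output head (untrained model = identity
  field), trained by gradient descent on −NCC(fixed, moving∘φ) over the
  moving set, registration to the target only, no smoothness penalty by
  default (an optional weight exists). The loss gradient flows through the
  warp via interpolated image gradients, then through the network with the
  package's hand-written backprop. Global NCC is used rather than windowed
  local NCC so the analytic gradient stays exact and cheap.
* **demons** — a classical multi-scale demons optimizer (per-pair, no
  training), with forces computed on lightly smoothed images (σ = 1 voxel)
  so image noise does not drive spurious displacement. This is the default
  engine in the pipeline: at desk scale it is faster and needs no training
  budget, while the cnn engine exercises the learned-registration path.

## Pseudo-PET synthesis

Each source PET image follows the chain `B_target⁻¹ ∘ φ_i ∘ B_i`, with
interpolation overshoot clamped at zero. Random summing draws the number of
images N with P(N=n) ∝ 1/n (harmonic normalization), selects without
replacement, draws U[0,1] weights and normalizes them to sum to one. Epoch
generation derives one child seed per output image from a root seed, so
regeneration is reproducible independent of iteration order. Summed images
are not renormalized to a common count level before weighting — the convex
combination itself keeps intensities in range; a practitioner can normalize
upstream if sources differ in dose.

## Diffusion prior

Variance-preserving schedule, 1000 training steps, linear β from 10⁻⁴ to
0.02, ε-prediction. The denoiser is a two-level convolutional U-net
(default 16 base channels) with single-head global self-attention at the
coarsest resolution, FiLM-style per-channel biases injected from the
conditioning embedding at every block. Timestep and slice position (index /
(n−1) ∈ [0,1]) use identical sinusoidal-embedding + two-layer projections,
summed; the optional MR condition enters as a second input channel whose
null value is zero (classifier-free guidance: the condition is dropped with
probability 0.1 per training sample).

Training volumes are normalized by their mean over the nonzero support and
empty transverse slices are removed; each slice's magnitude is divided by
u ~ U[0.5, 1.5] afresh every epoch. Random in-plane affine augmentation
(≤5 % scale, ≤5 voxel shift, ≤5° rotation) is applied only to
*non-registered* training data — pseudo-PET slices already live in the
target space. Adam with batch 16; checkpoints are selected by validation
loss on held-out subjects. The pipeline's desk-scale defaults (8 base
channels, 80 epochs, learning rate 10⁻³, one validation subject) trade the
reference-scale settings (16 channels, lr 10⁻⁴, three validation subjects,
thousands of epochs) for minutes of CPU time; both are plain configuration.

## Sampling loop

Per outer step (100 by default, spaced uniformly over the training
schedule): slice-wise ε-prediction and Tweedie estimate
`(x_t − √(1−ᾱ)ε̂)/√ᾱ`; division by the scale
`c = (training mean intensity) / (support mean of a 1-pass OSEM)` to reach
measurement units; `p = 10` data-consistency steps; multiplication by `c`;
DDIM-style re-noising `x_s = √ᾱ_s x + √(1−ᾱ_s) ε` with fresh noise (a
deterministic σ = 0 variant is a flag). The subset index advances by one
per inner step and by `p` per outer step, wrapping modulo `n_sub`.

Each data-consistency step ascends
`Φ_j = L_j − (1/n_sub)(λ_RDP RDP_z + λ_DDS‖x−x⁰‖²)` with the EM
preconditioner `x/s_j` and step δ = 0.2 — explicit in the likelihood and
axial-RDP terms, **implicit (proximal)** in the quadratic anchor:
`x ← (x' + γ x⁰)/(1+γ)` with `γ = 2δλ_DDS (x/s_j)/n_sub`. The implicit form
has the same fixed points as explicit ascent but remains stable for
arbitrarily large λ_DDS and converges to the anchor in that limit; a fully
explicit step diverges once `2δλ_DDS/n_sub` exceeds the preconditioned
curvature. The RDP term's sign is chosen so that increasing λ_RDP increases
axial smoothness (a penalty inside a maximized objective); the opposite
reading is switchable. Nonnegativity is enforced in the measurement domain
only; diffusion-domain iterates may be signed.

MR guidance at sampling time uses `(1+λ_MR)·conditional − λ_MR·unconditional`
with the zero-MR null condition as the unconditional branch.

## Evaluation

* NRMSE masked to nonzero ground truth (plus lesion-only and
  agreement-patch variants).
* SSIM per patch with a single Gaussian-weighted window (σ = 1.5) and
  constants (0.01 L)², (0.03 L)², L = global reference max. With these
  constants the sign-flip identity saturates at ≈ −0.9991, not −1; the
  closed form is asserted in tests.
* CRC = mean over lesions of `(lesion mean / background mean − 1)/(C − 1)`,
  with C the true lesion-to-*background* activity ratio and lesion masks
  restricted to voxels fully inside each sphere so partial-volume edges do
  not bias the mean (this is what makes CRC = 1 on the ground truth).
  Lesion means, not peaks, are used.
* CoV = std/mean over an eroded uniform white-matter background away from
  lesions. Agreement patches are drawn seeded from lesion-free brain with
  gray-matter fraction matched to each lesion patch.
* Bias–variance over noise realizations uses the normalized-percentage
  convention `bias = 100‖x̄−ref‖/‖ref‖`,
  `sd = 100√(mean_r‖x_r−x̄‖²)/‖ref‖`, isolated in one function so an
  alternative norm is a one-line change; the ensemble mean is computed
  anchored to the first realization so identical inputs give sd = 0 exactly.

The matched-CRC comparison interpolates each method's CoV-vs-CRC sweep
curve at the midpoint of their overlapping CRC ranges.

## Known limitations

* The forward model is 2D-stacked parallel-beam without detector physics;
  absolute noise levels and resolution do not transfer to a clinical
  scanner geometry.
* The numpy networks are small by design; the diffusion prior learns
  coarse anatomy and noise statistics, not fine cortical texture.
* BSREM's β and the DDS λ ranges are count-level dependent and were chosen
  for the default simulation conditions; other dose levels need re-tuning.
* Affine registration assumes a similarity transform suffices between
  subjects (true for the warped-template generator; real heads may need
  full affine, which the parameterization can be extended to).
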