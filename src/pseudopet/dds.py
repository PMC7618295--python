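"""Diffusion-prior PET reconstruction by decomposed diffusion sampling.

Each outer iteration: (1) denoise the current iterate slice-by-slice with
the score network and form the Tweedie posterior-mean estimate of the
clean volume; (2) map it to measurement scale with the normalization
factor c; (3) take p data-consistency steps on the subset sub-objective

    Phi_j(x) = L_j(x) - (1/n_sub) (lambda_rdp RDP_z(x)
                                   + lambda_dds ||x - x0||^2),

maximized with EM-preconditioned steps that are explicit in the
likelihood/RDP terms and implicit (proximal) in the quadratic anchor —
the implicit anchor keeps the update stable for arbitrarily large
lambda_dds and pins the iterate to the prior trajectory in that limit;
(4) map back to diffusion scale and re-noise to the next (lower) noise
level.  MR guidance uses the classifier-free combination
(1 + lambda_mr) * conditional - lambda_mr * unconditional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffusion import NoiseSchedule
from .projector import SinogramSet, SystemModel, partition_subsets
from .recon import RDPConfig, SubsetOps, osem, rdp_value_grad


@dataclass
class DDSConfig:
    """All sampling-loop hyperparameters."""

    lambda_dds: float = 1.0       # anchoring strength toward the prior output
    lambda_rdp: float = 5e-4      # axial slice-consistency RDP strength
    delta: float = 0.2            # data-consistency step size
    p: int = 10                   # gradient steps per diffusion step
    n_sub: int = 21               # likelihood subsets
    n_diffusion_steps: int = 100
    lambda_mr: float = 0.0        # classifier-free guidance strength
    seed: int = 0
    stochastic_renoise: bool = True   # False: deterministic (DDIM, sigma=0)
    rdp_smoothing_sign: float = 1.0   # +1: lambda_rdp smooths (penalty)
    rdp_gamma: float = 2.0

    def __post_init__(self):
        if min(self.lambda_dds, self.lambda_rdp, self.lambda_mr) < 0:
            raise ValueError("strengths must be nonnegative")
        if self.p < 1 or self.n_diffusion_steps < 1:
            raise ValueError("p and n_diffusion_steps must be >= 1")


@dataclass
class NormalizationScale:
    """Measurement-to-diffusion intensity scale: x_diffusion = c * x_measurement."""

    c: float
    derivation: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError("scale c must be positive")


# ---------------------------------------------------------------------------
# slice-wise score application


def _volume_to_slices(x: np.ndarray) -> np.ndarray:
    # (nx, ny, nz) -> batch of transverse slices (nz, nx, ny)
    return np.moveaxis(x, 2, 0)


def _slices_to_volume(s: np.ndarray) -> np.ndarray:
    return np.moveaxis(s, 0, 2)


def _slice_positions(nz: int) -> np.ndarray:
    return np.arange(nz) / max(nz - 1, 1)


def guided_score(model, x_t: np.ndarray, t: int, slice_pos: np.ndarray,
                 mr_slice: np.ndarray | None, lambda_mr: float) -> np.ndarray:
    """Classifier-free-guided epsilon estimate for a batch of slices.

    Returns (1 + lambda_mr) * conditional - lambda_mr * unconditional; with
    lambda_mr = 0 the conditional prediction alone.  The unconditional
    branch is the null (zero) MR condition the model saw during dropout
    training.
    """
    t_arr = np.full(x_t.shape[0], t)
    if mr_slice is None or lambda_mr == 0.0:
        if mr_slice is not None and not model.mr_conditional:
            raise ValueError("model is not MR-conditional")
        return model.predict_eps(x_t, t_arr, slice_pos, mr=mr_slice)
    if not model.mr_conditional:
        raise ValueError("MR guidance requires an MR-conditional model "
                         "(no unconditional branch available)")
    cond = model.predict_eps(x_t, t_arr, slice_pos, mr=mr_slice)
    uncond = model.predict_eps(x_t, t_arr, slice_pos, mr=None)
    return (1.0 + lambda_mr) * cond - lambda_mr * uncond


def _predict_eps_volume(model, x_t: np.ndarray, t: int,
                        mr: np.ndarray | None, lambda_mr: float) -> np.ndarray:
    slices = _volume_to_slices(x_t)
    pos = _slice_positions(slices.shape[0])
    mr_slices = None if mr is None else _volume_to_slices(mr)
    eps = guided_score(model, slices, t, pos, mr_slices, lambda_mr)
    return _slices_to_volume(eps)


def tweedie_estimate(x_t: np.ndarray, t: int, model,
                     schedule: NoiseSchedule,
                     mr: np.ndarray | None = None,
                     lambda_mr: float = 0.0) -> np.ndarray:
    """Posterior-mean estimate E[x_0 | x_t] under the VP schedule.

    The score network runs independently on each transverse slice with its
    slice-position condition; the estimate is
    (x_t - noise_coeff(t) * eps_hat) / signal_coeff(t).
    """
    sc = float(schedule.signal_coeff(t))
    if sc < 1e-6:
        raise ValueError(f"signal coefficient {sc:.2e} at t={t} is too small "
                         "for a stable Tweedie inversion")
    eps = _predict_eps_volume(model, x_t, t, mr, lambda_mr)
    return (x_t - float(schedule.noise_coeff(t)) * eps) / sc


# ---------------------------------------------------------------------------
# measurement normalization


def compute_scale(sino: SinogramSet, system: SystemModel,
                  train_mean_intensity: float,
                  osem_iters: int = 1) -> NormalizationScale:
    """c = (training mean slice intensity) / (support mean of a quick OSEM).

    The support is taken as voxels above 1% of the OSEM estimate's maximum.
    Deterministic given the sinogram.
    """
    if sino.prompts.sum() == 0:
        raise ValueError("cannot derive a scale from a zero-count sinogram")
    x = osem(sino, system, n_iter=osem_iters)
    support = x > 0.01 * x.max()
    meas_mean = float(x[support].mean())
    c = train_mean_intensity / meas_mean
    return NormalizationScale(c, {
        "train_mean_intensity": train_mean_intensity,
        "osem_support_mean": meas_mean,
        "osem_iters": osem_iters,
    })


# ---------------------------------------------------------------------------
# sub-objective


def dds_subobjective(x: np.ndarray, x0_anchor: np.ndarray,
                     sino: SinogramSet, system: SystemModel, subset: int,
                     cfg: DDSConfig,
                     subsets: SubsetOps | None = None
                     ) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the subset sub-objective Phi_j.

    Phi_j = L_j(x) - (1/n_sub)(lambda_rdp RDP_z(x) + lambda_dds ||x-x0||^2),
    with the RDP sign chosen so lambda_rdp smooths axially
    (``rdp_smoothing_sign`` flips it to the literal-pseudocode reading).
    """
    subsets = subsets or SubsetOps(
        system, partition_subsets(system.geometry.n_angles, cfg.n_sub)
    )
    m, b = subsets.subset_data(subset, sino)
    q = subsets.forward(subset, x) + b
    pos = q > 0
    mpos = np.asarray(m, dtype=float)
    from scipy.special import gammaln

    value = float(
        np.sum(mpos[pos] * np.log(q[pos]) - q[pos] - gammaln(mpos[pos] + 1.0))
        - q[~pos].sum()
    )
    ratio = np.divide(m, q, out=np.zeros_like(q), where=pos)
    grad = subsets.back(subset, ratio) - subsets.sensitivity(subset)

    n_sub = subsets.n_sub
    if cfg.lambda_rdp > 0:
        rv, rg = rdp_value_grad(
            x, None, RDPConfig(gamma=cfg.rdp_gamma, axial_only=True)
        )
        value -= cfg.rdp_smoothing_sign * cfg.lambda_rdp / n_sub * rv
        grad -= cfg.rdp_smoothing_sign * cfg.lambda_rdp / n_sub * rg
    if cfg.lambda_dds > 0:
        diff = x - x0_anchor
        value -= cfg.lambda_dds / n_sub * float(np.sum(diff * diff))
        grad -= 2.0 * cfg.lambda_dds / n_sub * diff
    return value, grad


# ---------------------------------------------------------------------------
# main loop


def reconstruct(sino: SinogramSet, system: SystemModel, model,
                cfg: DDSConfig, mr: np.ndarray | None = None,
                schedule: NoiseSchedule | None = None,
                scale: NormalizationScale | None = None) -> np.ndarray:
    """Full sampling loop; returns the final nonnegative activity volume.

    Reconstruction timesteps are spaced uniformly over the training
    schedule.  The subset index advances by one per inner step and the
    outer starting subset by p per outer step, cycling modulo n_sub.
    Fully deterministic given (cfg.seed, model, data).
    """
    schedule = schedule or model.schedule
    if mr is not None and not model.mr_conditional:
        raise ValueError("MR image supplied but model is not MR-conditional")
    scale = scale or compute_scale(sino, system, model.train_mean_intensity)
    c = scale.c
    rng = np.random.default_rng(cfg.seed)
    subsets = SubsetOps(
        system, partition_subsets(system.geometry.n_angles, cfg.n_sub)
    )

    ts = np.unique(
        np.linspace(0, schedule.n_steps - 1, cfg.n_diffusion_steps).astype(int)
    )[::-1]
    abar = schedule.alpha_bar
    x_t = rng.standard_normal(system.image_shape)
    x_meas = None
    j = 0
    for step_i, t in enumerate(ts):
        x0_diff = tweedie_estimate(x_t, int(t), model, schedule, mr=mr,
                                   lambda_mr=cfg.lambda_mr)
        anchor = x0_diff / c                       # measurement scale
        x = np.maximum(anchor, 0.0)
        for i in range(cfg.p):
            x = _dc_step(x, anchor, sino, system, (j + i) % cfg.n_sub,
                         cfg, subsets)
        j = (j + cfg.p) % cfg.n_sub
        x_meas = x
        if not np.all(np.isfinite(x_meas)):
            raise FloatingPointError(
                f"non-finite iterate at outer step {step_i} (t={t})"
            )
        if step_i + 1 < len(ts):
            s = ts[step_i + 1]
            x_diff = c * x_meas
            noise = (rng.standard_normal(x_t.shape)
                     if cfg.stochastic_renoise else
                     _predict_eps_volume(model, x_t, int(t), mr, cfg.lambda_mr))
            x_t = np.sqrt(abar[s]) * x_diff + np.sqrt(1 - abar[s]) * noise
    return x_meas


def _dc_step(x: np.ndarray, anchor: np.ndarray, sino: SinogramSet,
             system: SystemModel, subset: int, cfg: DDSConfig,
             subsets: SubsetOps) -> np.ndarray:
    """One EM-preconditioned ascent step on Phi_j, implicit in the anchor."""
    m, b = subsets.subset_data(subset, sino)
    q = subsets.forward(subset, x) + b
    ratio = np.divide(m, q, out=np.zeros_like(q), where=q > 0)
    sens = subsets.sensitivity(subset)
    grad = subsets.back(subset, ratio) - sens
    if cfg.lambda_rdp > 0:
        _, rg = rdp_value_grad(
            x, None, RDPConfig(gamma=cfg.rdp_gamma, axial_only=True)
        )
        grad = grad - cfg.rdp_smoothing_sign * cfg.lambda_rdp / cfg.n_sub * rg
    precond = np.divide(x, sens, out=np.zeros_like(x), where=sens > 0)
    x_new = np.maximum(x + cfg.delta * precond * grad, 0.0)
    if cfg.lambda_dds > 0:
        gamma = 2.0 * cfg.delta * cfg.lambda_dds / cfg.n_sub * precond
        x_new = (x_new + gamma * anchor) / (1.0 + gamma)
        x_new = np.maximum(x_new, 0.0)
    return x_new
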