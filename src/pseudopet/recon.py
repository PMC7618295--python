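"""Poisson likelihood, MLEM/OSEM and BSREM with an anatomical prior.

The penalized objective maximized by BSREM is the Poisson log-likelihood
minus ``beta`` times a relative-difference prior (RDP) whose pairwise
weights are the asymmetric Bowsher selection: each PET voxel is smoothed
only toward the patch neighbors most similar in the co-registered MR
image.  The same likelihood/RDP machinery is reused by the diffusion
sampler's data-consistency steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import gammaln

from .projector import SinogramSet, SystemModel, partition_subsets


# ---------------------------------------------------------------------------
# subset-restricted projections


class SubsetOps:
    """Per-subset slices of the system matrix and factors, cached once."""

    def __init__(self, system: SystemModel, subset_of_angle: np.ndarray):
        self.system = system
        self.subset_of_angle = np.asarray(subset_of_angle)
        self.n_sub = int(self.subset_of_angle.max()) + 1
        g = system.geometry
        n_r = g.n_radial_bins
        nz = g.n_planes
        self._mats, self._factors, self._angle_idx = [], [], []
        fac = system.factors.reshape(g.n_angles * n_r, nz)
        for j in range(self.n_sub):
            angles = np.nonzero(self.subset_of_angle == j)[0]
            rows = (angles[:, None] * n_r + np.arange(n_r)[None, :]).ravel()
            self._angle_idx.append(angles)
            self._mats.append(system.plane_matrix[rows])
            self._factors.append(fac[rows])
        self._sens = [None] * self.n_sub

    def angles(self, j: int) -> np.ndarray:
        return self._angle_idx[j]

    def forward(self, j: int, x: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.system.image_shape
        y = self._mats[j] @ x.reshape(nx * ny, nz)
        return y * self._factors[j]

    def back(self, j: int, y: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.system.image_shape
        x = self._mats[j].T @ (y * self._factors[j])
        return x.reshape(self.system.image_shape)

    def sensitivity(self, j: int) -> np.ndarray:
        if self._sens[j] is None:
            ones = np.ones((self._mats[j].shape[0],
                            self.system.geometry.n_planes))
            self._sens[j] = self.back(j, ones)
        return self._sens[j]

    def subset_data(self, j: int, sino: SinogramSet):
        """(prompts, background) restricted to subset j, as (rays, planes)."""
        g = self.system.geometry
        n_r = g.n_radial_bins
        angles = self._angle_idx[j]
        m = sino.prompts[angles].reshape(len(angles) * n_r, -1)
        b = sino.background[angles].reshape(len(angles) * n_r, -1)
        return m, b


def _resolve_subsets(sino: SinogramSet, system: SystemModel,
                     n_sub: int | None) -> SubsetOps:
    part = sino.subset_of_angle
    if n_sub is not None and n_sub != int(part.max()) + 1:
        part = partition_subsets(system.geometry.n_angles, n_sub)
    return SubsetOps(system, part)


# ---------------------------------------------------------------------------
# likelihood


def poisson_loglik(x: np.ndarray, sino: SinogramSet, system: SystemModel,
                   subset: int | None = None,
                   subsets: SubsetOps | None = None) -> float:
    """Poisson log-likelihood sum_i m_i log q_i - q_i - log(m_i!), q = Ax + b.

    With ``subset`` given, the sum is restricted to that subset's bins, so
    the subset values partition the full likelihood.
    """
    from .projector import forward_project

    if subset is None:
        q = forward_project(system, x) + sino.background
        m = sino.prompts
    else:
        subsets = subsets or SubsetOps(system, sino.subset_of_angle)
        m, b = subsets.subset_data(subset, sino)
        q = subsets.forward(subset, x) + b
    m = np.asarray(m, dtype=float)
    bad = (q <= 0) & (m > 0)
    if np.any(bad):
        warnings.warn("zero expected counts on bins with observed prompts; "
                      "log-likelihood is -inf")
        return -np.inf
    pos = q > 0
    return float(np.sum(m[pos] * np.log(q[pos]) - q[pos] - gammaln(m[pos] + 1.0))
                 - q[~pos].sum())


# ---------------------------------------------------------------------------
# MLEM / OSEM


def mlem(sino: SinogramSet, system: SystemModel, n_iter: int,
         x_init: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative EM for the Poisson likelihood; monotone and nonnegative."""
    return osem(sino, system, n_sub=1, n_iter=n_iter, x_init=x_init)


def osem(sino: SinogramSet, system: SystemModel, n_sub: int | None = None,
         n_iter: int = 1, x_init: np.ndarray | None = None,
         subsets: SubsetOps | None = None) -> np.ndarray:
    """Ordered-subset EM; one iteration is one pass over all subsets.

    With a single subset this is exactly MLEM.  Voxels with zero subset
    sensitivity are left at zero (the EM update is undefined there).
    """
    subsets = subsets or _resolve_subsets(sino, system, n_sub)
    x = (np.ones(system.image_shape) if x_init is None else x_init.copy())
    if np.any(x < 0):
        raise ValueError("x_init must be nonnegative")
    for _ in range(n_iter):
        for j in range(subsets.n_sub):
            x = _em_subset_update(x, j, sino, subsets)
    return x


def _em_subset_update(x: np.ndarray, j: int, sino: SinogramSet,
                      subsets: SubsetOps) -> np.ndarray:
    m, b = subsets.subset_data(j, sino)
    q = subsets.forward(j, x) + b
    ratio = np.divide(m, q, out=np.zeros_like(q), where=q > 0)
    sens = subsets.sensitivity(j)
    upd = subsets.back(j, ratio)
    ok = sens > 0
    out = np.zeros_like(x)
    out[ok] = x[ok] * upd[ok] / sens[ok]
    return out


# ---------------------------------------------------------------------------
# Bowsher weights and relative-difference prior


def _patch_offsets(patch_size: tuple[int, int, int]) -> np.ndarray:
    """All nonzero offsets of the patch, in lexicographic order."""
    half = [p // 2 for p in patch_size]
    offs = [o for o in product(*[range(-h, h + 1) for h in half]) if o != (0, 0, 0)]
    return np.array(offs, dtype=int)


def _shifted(arr: np.ndarray, off: np.ndarray, fill: float) -> np.ndarray:
    """arr evaluated at voxel + off, constant fill outside the grid."""
    out = np.full_like(arr, fill, dtype=float)
    src = tuple(
        slice(max(o, 0), arr.shape[a] + min(o, 0)) for a, o in enumerate(off)
    )
    dst = tuple(
        slice(max(-o, 0), arr.shape[a] - max(o, 0)) for a, o in enumerate(off)
    )
    out[dst] = arr[src]
    return out


@dataclass
class BowsherWeights:
    """Directed neighbor selection: selected[k, v] says voxel v smooths
    toward its patch neighbor at offsets[k]."""

    offsets: np.ndarray          # (n_off, 3), lexicographic order
    selected: np.ndarray         # (n_off, *image shape), boolean
    patch_size: tuple[int, int, int]
    n_neighbors: int


def bowsher_weights(mr: np.ndarray, patch_size: tuple[int, int, int] = (3, 3, 3),
                    n_neighbors: int = 4) -> BowsherWeights:
    """Select, per voxel, the patch neighbors most similar in MR intensity.

    Ties break deterministically by lexicographic offset order (stable
    sort).  Out-of-grid neighbors are never selected; every interior voxel
    selects exactly ``n_neighbors``.
    """
    if any(p % 2 == 0 for p in patch_size):
        raise ValueError("patch_size must be odd per axis")
    offs = _patch_offsets(patch_size)
    if n_neighbors >= len(offs) + 1:
        raise ValueError("n_neighbors must be smaller than the patch volume - 1")
    diffs = np.empty((len(offs), *mr.shape))
    for k, off in enumerate(offs):
        diffs[k] = np.abs(_shifted(mr, off, np.inf) - mr)
    order = np.argsort(diffs, axis=0, kind="stable")
    ranks = np.argsort(order, axis=0, kind="stable")
    selected = (ranks < n_neighbors) & np.isfinite(diffs)
    return BowsherWeights(offs, selected, tuple(patch_size), n_neighbors)


@dataclass(frozen=True)
class RDPConfig:
    """Relative-difference prior parameters.

    gamma controls edge preservation (larger = stronger transition
    penalty damping); epsilon guards zero denominators; axial_only
    restricts pairs to +z neighbors (the slice-consistency prior used
    inside the diffusion sampler).
    """

    gamma: float = 2.0
    epsilon: float = 1e-8
    axial_only: bool = False
    asymmetric: bool = True

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


def rdp_value_grad(x: np.ndarray, weights: BowsherWeights | None = None,
                   cfg: RDPConfig = RDPConfig()) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the (Bowsher-weighted) RDP.

    R(x) = sum over directed pairs w_jk (x_j - x_k)^2 /
           (x_j + x_k + gamma |x_j - x_k| + eps).

    With ``weights`` None and axial_only=True, pairs are the +z neighbor
    pairs with unit weight (RDP_z); with weights None and axial_only=False,
    the 6-connected face neighborhood (each undirected pair counted once).
    """
    if weights is not None:
        offs = weights.offsets
        wsel = weights.selected.astype(float)
        if not cfg.asymmetric:
            # symmetrize: a pair contributes if either direction selects it
            sym = wsel.copy()
            for k, off in enumerate(offs):
                k_rev = _reverse_offset_index(offs, off)
                sym[k] = np.maximum(
                    wsel[k], _shifted(wsel[k_rev], -off, 0.0)
                )
            wsel = sym
    elif cfg.axial_only:
        offs = np.array([[0, 0, 1]])
        wsel = np.ones((1, *x.shape))
    else:
        offs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        wsel = np.ones((3, *x.shape))

    value = 0.0
    grad = np.zeros_like(x, dtype=float)
    for k, off in enumerate(offs):
        xk = _shifted(x, off, 0.0)
        valid = _shifted(np.ones_like(x), off, 0.0)
        w = wsel[k] * valid
        d = x - xk
        s = x + xk + cfg.gamma * np.abs(d) + cfg.epsilon
        psi = np.divide(d * d, s, out=np.zeros_like(s), where=s > 0)
        value += float(np.sum(w * psi))
        sgn = np.sign(d)
        da = np.divide(2 * d * s - d * d * (1 + cfg.gamma * sgn), s * s,
                       out=np.zeros_like(s), where=s > 0)
        db = np.divide(-2 * d * s - d * d * (1 - cfg.gamma * sgn), s * s,
                       out=np.zeros_like(s), where=s > 0)
        grad += w * da
        grad += _shifted(w * db, -off, 0.0)
    return value, grad


def _reverse_offset_index(offs: np.ndarray, off: np.ndarray) -> int:
    rev = -np.asarray(off)
    hit = np.nonzero((offs == rev).all(axis=1))[0]
    return int(hit[0])


# ---------------------------------------------------------------------------
# BSREM


class BsremDivergence(RuntimeError):
    pass


def bsrem(sino: SinogramSet, system: SystemModel, mr: np.ndarray | None = None,
          beta: float = 0.0, n_iter: int = 10,
          cfg: RDPConfig = RDPConfig(), n_sub: int | None = None,
          x_init: np.ndarray | None = None,
          weights: BowsherWeights | None = None,
          relaxation_alpha0: float = 1.0, relaxation_K: float = 20.0,
          return_log: bool = False):
    """Block-sequential ascent on L(x|m) - beta * RDP_aBOW(x).

    EM-preconditioned subset gradient steps with diminishing relaxation
    alpha_k = alpha0 / (1 + k/K); with beta = 0 and relaxation 1 a block
    update coincides with the OSEM update.  Raises
    :class:`BsremDivergence` if the objective drops for three consecutive
    full passes.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    subsets = _resolve_subsets(sino, system, n_sub)
    if beta > 0 and weights is None:
        if mr is None:
            raise ValueError("anatomical BSREM needs an MR image or weights")
        weights = bowsher_weights(mr)
    x = (np.ones(system.image_shape) if x_init is None else x_init.copy())

    def objective(img):
        val = poisson_loglik(img, sino, system)
        if beta > 0:
            r, _ = rdp_value_grad(img, weights, cfg)
            val -= beta * r
        return val

    log = [objective(x)] if (return_log or n_iter > 0) else []
    drops = 0
    for k in range(n_iter):
        alpha = relaxation_alpha0 / (1.0 + k / relaxation_K)
        for j in range(subsets.n_sub):
            m, b = subsets.subset_data(j, sino)
            q = subsets.forward(j, x) + b
            ratio = np.divide(m, q, out=np.zeros_like(q), where=q > 0)
            grad = subsets.back(j, ratio) - subsets.sensitivity(j)
            if beta > 0:
                _, gr = rdp_value_grad(x, weights, cfg)
                grad = grad - (beta / subsets.n_sub) * gr
            sens = subsets.sensitivity(j)
            precond = np.divide(x, sens, out=np.zeros_like(x), where=sens > 0)
            x = np.maximum(x + alpha * precond * grad, 0.0)
        obj = objective(x)
        log.append(obj)
        if obj < log[-2] - 1e-6 * abs(log[-2]):
            drops += 1
            if drops >= 3:
                raise BsremDivergence(
                    f"objective decreased for 3 consecutive passes at pass {k}: "
                    f"{log[-4:]} (beta={beta}, alpha={alpha:.3g})"
                )
        else:
            drops = 0
    if return_log:
        return x, log
    return x
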