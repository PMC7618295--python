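"""PET forward model: stacked-plane parallel-beam projector with attenuation.

The scanner is modeled as independent transverse planes, each viewed by a
2D parallel-beam geometry.  Line integrals use bilinear (Joseph-style)
interpolation sampled at unit-voxel steps along each ray, assembled once
into a sparse matrix per plane — so the back projector is the exact
transpose and the adjoint identity <Ax, y> = <x, A^T y> holds to rounding.

The full system model composes the geometric projector with per-bin
attenuation factors exp(-line integral of mu) and optional normalization
factors, as in q = Ax + b with b a known additive background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .phantom import Phantom


def _bit_reversal_order(n: int) -> np.ndarray:
    """Permutation of range(n) by base-2 radical-inverse (van der Corput) value."""
    vdc = np.zeros(n)
    for i in range(n):
        f, x, v = 0.5, i, 0.0
        while x:
            v += f * (x & 1)
            x >>= 1
            f *= 0.5
        vdc[i] = v
    return np.argsort(vdc, kind="stable")


@dataclass(frozen=True)
class Geometry:
    """2D parallel-beam geometry replicated over transverse planes.

    Radial spacing is in units of the in-plane voxel size; angles span
    [0, pi) and must be strictly increasing.
    """

    n_angles: int
    n_radial_bins: int
    n_planes: int
    angles: np.ndarray = None
    radial_spacing_vox: float = 1.0

    def __post_init__(self):
        if self.angles is None:
            object.__setattr__(
                self, "angles",
                np.arange(self.n_angles) * np.pi / self.n_angles,
            )
        angles = np.asarray(self.angles, dtype=float)
        if len(angles) != self.n_angles:
            raise ValueError("angle list length mismatch")
        if np.any(np.diff(angles) <= 0) or angles[0] < 0 or angles[-1] >= np.pi:
            raise ValueError("angles must be strictly increasing in [0, pi)")
        object.__setattr__(self, "angles", angles)

    @classmethod
    def for_image(cls, shape: tuple[int, int, int],
                  n_angles: int | None = None) -> "Geometry":
        nx, ny, nz = shape
        n_angles = n_angles or max(nx, ny)
        n_radial = int(np.ceil(np.hypot(nx, ny))) + 1
        return cls(n_angles=n_angles, n_radial_bins=n_radial, n_planes=nz)

    @property
    def n_rays(self) -> int:
        return self.n_angles * self.n_radial_bins


def _plane_matrix(geometry: Geometry, nx: int, ny: int) -> sparse.csr_matrix:
    """Sparse (n_rays, nx*ny) projection matrix, lengths in voxel units.

    Pixel-driven with a linear (triangular) radial footprint: each voxel
    center projects onto the radial detector axis and deposits its value
    into the two nearest bins with interpolation weights.  Because the
    triangle kernel is a partition of unity at unit bin spacing, a unit
    voxel's projection sums to exactly one at every angle, and for smooth
    images the bin values approximate chord-length line integrals.
    """
    if geometry.n_radial_bins < np.hypot(nx, ny):
        raise ValueError("n_radial_bins must cover the image diagonal")
    n_r = geometry.n_radial_bins
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    vx = (ix - cx).ravel()
    vy = (iy - cy).ravel()
    voxel_idx = np.arange(nx * ny)

    rows, cols, vals = [], [], []
    for ia, theta in enumerate(geometry.angles):
        ux, uy = np.cos(theta), np.sin(theta)  # radial axis
        rho = (vx * ux + vy * uy) / geometry.radial_spacing_vox + (n_r - 1) / 2.0
        b0 = np.floor(rho).astype(int)
        f = rho - b0
        for db, w in ((0, 1.0 - f), (1, f)):
            b = b0 + db
            ok = (b >= 0) & (b < n_r) & (w > 0)
            rows.append(ia * n_r + b[ok])
            cols.append(voxel_idx[ok])
            vals.append((w / geometry.radial_spacing_vox)[ok])

    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geometry.n_rays, nx * ny),
    )
    return mat.tocsr()


@dataclass
class SystemModel:
    """Geometric projector with attenuation and normalization factors.

    ``factors`` multiplies the geometric forward projection bin-wise:
    y = factors * (P x), with factors = attenuation * normalization,
    attenuation in (0, 1] and normalization > 0.
    """

    geometry: Geometry
    plane_matrix: sparse.csr_matrix
    image_shape: tuple[int, int, int]
    voxel_size_mm: np.ndarray
    attenuation_factors: np.ndarray  # (n_angles, n_radial, n_planes)
    normalization_factors: np.ndarray

    @classmethod
    def build(cls, image_shape: tuple[int, int, int],
              voxel_size_mm=(2.0, 2.0, 2.0),
              mu_map: np.ndarray | None = None,
              geometry: Geometry | None = None,
              normalization: np.ndarray | None = None) -> "SystemModel":
        nx, ny, nz = image_shape
        voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
        if abs(voxel_size_mm[0] - voxel_size_mm[1]) > 1e-9:
            raise ValueError("in-plane voxels must be square")
        geometry = geometry or Geometry.for_image(image_shape)
        if geometry.n_planes != nz:
            raise ValueError("geometry plane count does not match image")
        mat = _plane_matrix(geometry, nx, ny)

        shape3 = (geometry.n_angles, geometry.n_radial_bins, nz)
        if mu_map is None:
            att = np.ones(shape3)
        else:
            if mu_map.shape != image_shape:
                raise ValueError("mu_map shape mismatch")
            # line integral of mu (per mm) along each ray, in mm
            mu_flat = mu_map.reshape(nx * ny, nz)
            line = (mat @ mu_flat) * voxel_size_mm[0]
            att = np.exp(-line).reshape(shape3)
        norm = np.ones(shape3) if normalization is None else np.asarray(normalization)
        if np.any(att <= 0) or np.any(att > 1):
            raise ValueError("attenuation factors must lie in (0, 1]")
        if np.any(norm <= 0):
            raise ValueError("normalization factors must be positive")
        return cls(geometry, mat, tuple(image_shape), voxel_size_mm, att, norm)

    @classmethod
    def from_phantom(cls, phantom: Phantom,
                     geometry: Geometry | None = None) -> "SystemModel":
        return cls.build(
            phantom.shape, phantom.voxel_size, mu_map=phantom.mu_map,
            geometry=geometry,
        )

    @property
    def factors(self) -> np.ndarray:
        return self.attenuation_factors * self.normalization_factors

    @property
    def sino_shape(self) -> tuple[int, int, int]:
        g = self.geometry
        return (g.n_angles, g.n_radial_bins, g.n_planes)


def forward_project(system: SystemModel, x: np.ndarray) -> np.ndarray:
    """Expected (background-free) sinogram A x; linear and nonnegative for x >= 0."""
    if x.shape != system.image_shape:
        raise ValueError(f"image shape {x.shape} != {system.image_shape}")
    nx, ny, nz = system.image_shape
    flat = x.reshape(nx * ny, nz)
    y = system.plane_matrix @ flat
    y = y.reshape(system.sino_shape)
    return y * system.factors


def back_project(system: SystemModel, y: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`forward_project`."""
    if y.shape != system.sino_shape:
        raise ValueError(f"sinogram shape {y.shape} != {system.sino_shape}")
    nx, ny, nz = system.image_shape
    weighted = (y * system.factors).reshape(system.geometry.n_rays, nz)
    x = system.plane_matrix.T @ weighted
    return x.reshape(system.image_shape)


@dataclass
class SinogramSet:
    """Measured prompts, known additive background and subset bookkeeping."""

    prompts: np.ndarray          # integer counts, (n_angles, n_radial, n_planes)
    background: np.ndarray       # expected scatter+randoms per bin, noiseless
    angles: np.ndarray
    subset_of_angle: np.ndarray  # subset id per angle index
    dose_fraction: float = 1.0
    seed: int | None = None
    activity_scale: float = 1.0  # ground-truth activity multiplier used

    def __post_init__(self):
        if np.any(self.prompts < 0):
            raise ValueError("prompts must be nonnegative")
        if np.any(self.background < 0):
            raise ValueError("background must be nonnegative")

    @property
    def n_subsets(self) -> int:
        return int(self.subset_of_angle.max()) + 1

    def subset_angles(self, j: int) -> np.ndarray:
        return np.nonzero(self.subset_of_angle == j)[0]

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("prompts", data=self.prompts)
            f.create_dataset("background", data=self.background)
            f.create_dataset("angles", data=self.angles)
            f.create_dataset("partition", data=self.subset_of_angle)
            f.attrs["dose_fraction"] = self.dose_fraction
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["activity_scale"] = self.activity_scale

    @classmethod
    def load(cls, path: str | Path) -> "SinogramSet":
        import h5py

        with h5py.File(path, "r") as f:
            seed = int(f.attrs["seed"])
            return cls(
                prompts=f["prompts"][()],
                background=f["background"][()],
                angles=f["angles"][()],
                subset_of_angle=f["partition"][()],
                dose_fraction=float(f.attrs["dose_fraction"]),
                seed=None if seed < 0 else seed,
                activity_scale=float(f.attrs["activity_scale"]),
            )


def partition_subsets(n_angles: int, n_sub: int) -> np.ndarray:
    """Subset id per angle: strided subsets in bit-reversed processing order.

    Angle k belongs to stride class k mod n_sub (maximal angular spacing
    within each subset); classes are then relabelled in bit-reversed order
    so that consecutively processed subsets are angularly far apart.
    Deterministic; subset sizes differ by at most one.
    """
    if not 1 <= n_sub <= n_angles:
        raise ValueError(f"n_sub={n_sub} must be in [1, n_angles={n_angles}]")
    order = _bit_reversal_order(n_sub)       # processing order of stride classes
    rank = np.empty(n_sub, dtype=int)
    rank[order] = np.arange(n_sub)
    return rank[np.arange(n_angles) % n_sub]


def simulate_prompts(system: SystemModel, phantom: Phantom,
                     total_counts: float, background_fraction: float = 0.3,
                     seed: int = 0, n_sub: int | None = None) -> SinogramSet:
    """Poisson sinogram at a target count level with constant known background.

    The activity is globally rescaled so the expected prompts q = Ax + b sum
    to ``total_counts``; the background b is spatially constant with
    sum(b) = background_fraction * sum(q) exactly, and is stored noiselessly
    as known contamination.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must be in [0, 1)")
    ax = forward_project(system, phantom.activity)
    ax_sum = float(ax.sum())
    if ax_sum <= 0:
        raise ValueError("phantom projects to an empty sinogram")
    scale = (1.0 - background_fraction) * total_counts / ax_sum
    q = scale * ax
    b_value = background_fraction * total_counts / q.size
    b = np.full(q.shape, b_value)
    rng = np.random.default_rng(seed)
    m = rng.poisson(q + b)

    if n_sub is None:
        n_sub = min(21, system.geometry.n_angles)
    part = partition_subsets(system.geometry.n_angles, n_sub)
    return SinogramSet(
        prompts=m.astype(np.int64), background=b, angles=system.geometry.angles,
        subset_of_angle=part, dose_fraction=1.0, seed=seed, activity_scale=scale,
    )


def thin_counts(sino: SinogramSet, fraction: float, seed: int = 0) -> SinogramSet:
    """Low-dose sinogram by sampling counts without replacement.

    Exactly round(fraction * total) events are drawn from the recorded
    count multiset (multivariate hypergeometric across bins), emulating
    retrospective count reduction; the known background scales by the same
    fraction.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    total = int(sino.prompts.sum())
    n_draw = int(round(fraction * total))
    if fraction == 1.0:
        thinned = sino.prompts.copy()
    else:
        rng = np.random.default_rng(seed)
        flat = sino.prompts.ravel().astype(np.int64)
        thinned = rng.multivariate_hypergeometric(
            flat, n_draw, method="marginals"
        ).reshape(sino.prompts.shape)
    return SinogramSet(
        prompts=thinned.astype(np.int64),
        background=sino.background * fraction,
        angles=sino.angles,
        subset_of_angle=sino.subset_of_angle.copy(),
        dose_fraction=sino.dose_fraction * fraction,
        seed=seed,
        activity_scale=sino.activity_scale,
    )
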