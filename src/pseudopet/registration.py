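"""Affine and deformable registration for pseudo-PET synthesis.

Affine registration maximizes global normalized cross-correlation (NCC)
over a multi-resolution pyramid with a deterministic direct-search
optimizer.  Deformable registration is a learned function phi(fixed,
moving) -> dense displacement field: a small 3D convolutional predictor
trained on the affine-registered dataset with an NCC loss (no smoothness
penalty by default), with a classical multi-scale demons optimizer
available as a drop-in engine behind the same interface.

Displacement fields are stored in voxel units on the fixed grid and
applied by backward (pull) warping with linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from . import nn


# ---------------------------------------------------------------------------
# similarity


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Global normalized cross-correlation in [-1, 1]."""
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0:
        return 0.0
    return float(np.dot(ac.ravel(), bc.ravel()) / denom)


def _ncc_grad_wrt_b(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """NCC(a, b) and its gradient with respect to b (mean-centering included)."""
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        return 0.0, np.zeros_like(b)
    val = float(np.dot(ac.ravel(), bc.ravel()) / (na * nb))
    g = ac / (na * nb) - val * bc / nb**2
    return val, g - g.mean()


# ---------------------------------------------------------------------------
# affine maps


@dataclass
class AffineMap:
    """4x4 homogeneous world-mm transform (moving -> fixed)."""

    matrix: np.ndarray
    voxel_size: np.ndarray
    converged: bool = True
    final_ncc: float = np.nan

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if np.linalg.cond(self.matrix) > 1e6:
            raise ValueError("affine matrix is numerically singular")

    @classmethod
    def identity(cls, voxel_size=(2.0, 2.0, 2.0)) -> "AffineMap":
        return cls(np.eye(4), np.asarray(voxel_size, dtype=float))

    def inverse(self) -> "AffineMap":
        return AffineMap(np.linalg.inv(self.matrix), self.voxel_size,
                         self.converged, self.final_ncc)

    def compose(self, other: "AffineMap") -> "AffineMap":
        """self after other: (self âˆ˜ other)(x) = self(other(x))."""
        return AffineMap(self.matrix @ other.matrix, self.voxel_size)

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, header="world-mm affine (moving -> fixed)")

    @classmethod
    def load(cls, path: str | Path, voxel_size=(2.0, 2.0, 2.0)) -> "AffineMap":
        return cls(np.loadtxt(path), np.asarray(voxel_size, dtype=float))


def _world_affine(voxel_size: np.ndarray) -> np.ndarray:
    w = np.eye(4)
    w[:3, :3] = np.diag(voxel_size)
    w[:3, 3] = 0.5 * voxel_size
    return w


def apply_affine(amap: AffineMap, image: np.ndarray,
                 direction: str = "forward") -> np.ndarray:
    """Resample ``image`` through the map with linear interpolation.

    ``forward`` places the moving image into the fixed frame
    (out(y) = image(B^-1 y)); ``inverse`` applies B^-1 instead.  Voxels
    mapping outside the grid are zero.
    """
    B = amap.matrix if direction == "forward" else np.linalg.inv(amap.matrix)
    w = _world_affine(amap.voxel_size)
    t_vox = np.linalg.inv(w) @ np.linalg.inv(B) @ w
    return ndimage.affine_transform(
        image, t_vox[:3, :3], offset=t_vox[:3, 3], order=1,
        mode="constant", cval=0.0,
    )


def _params_to_matrix(params: np.ndarray, center_mm: np.ndarray) -> np.ndarray:
    """[tx ty tz rx ry rz s] (mm, degrees, scale) -> 4x4 about the image centre."""
    t = params[:3]
    rx, ry, rz = np.deg2rad(params[3:6])
    s = params[6]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    A = s * (Rz @ Ry @ Rx)
    B = np.eye(4)
    B[:3, :3] = A
    B[:3, 3] = t + center_mm - A @ center_mm
    return B


@dataclass(frozen=True)
class AffineConfig:
    pyramid_levels: tuple[int, ...] = (4, 2, 1)
    max_iter_per_level: int = 120
    xtol: float = 1e-4


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, factor / 2.0, mode="nearest")
    return ndimage.zoom(sm, 1.0 / factor, order=1)


def affine_register(moving: np.ndarray, fixed: np.ndarray,
                    voxel_size=(2.0, 2.0, 2.0),
                    config: AffineConfig = AffineConfig()) -> AffineMap:
    """Similarity-transform registration maximizing NCC, coarse to fine.

    Deterministic: fixed identity initialization and a derivative-free
    Powell search per pyramid level.  If the final NCC is not an
    improvement over identity, the map is flagged unconverged.
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share a grid")
    voxel_size = np.asarray(voxel_size, dtype=float)
    center = 0.5 * voxel_size * np.asarray(moving.shape)
    params = np.array([0, 0, 0, 0, 0, 0, 1.0])
    scales = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.02])

    for level in config.pyramid_levels:
        mov_l = _downsample(moving, level)
        fix_l = _downsample(fixed, level)
        vs_l = voxel_size * level
        cen_l = 0.5 * vs_l * np.asarray(mov_l.shape)

        def neg_ncc(p):
            B = _params_to_matrix(p * scales + params, cen_l)
            amap = AffineMap(B, vs_l)
            return -ncc(fix_l, apply_affine(amap, mov_l))

        res = optimize.minimize(
            neg_ncc, np.zeros(7), method="Powell",
            options={"maxiter": config.max_iter_per_level,
                     "xtol": config.xtol, "ftol": 1e-8},
        )
        params = res.x * scales + params

    B = _params_to_matrix(params, center)
    amap = AffineMap(B, voxel_size)
    final = ncc(fixed, apply_affine(amap, moving))
    amap.final_ncc = final
    amap.converged = final >= ncc(fixed, moving) - 1e-9
    return amap


# ---------------------------------------------------------------------------
# dense deformation


@dataclass
class DeformationField:
    """Per-voxel displacement (3, *grid) in voxel units on the fixed grid."""

    displacement: np.ndarray

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
            raise ValueError("displacement must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite")

    def save(self, path: str | Path, voxel_size=(2.0, 2.0, 2.0)) -> None:
        import nibabel as nib

        aff = _world_affine(np.asarray(voxel_size, dtype=float))
        # store as 4D NIfTI, vector components on the last axis
        nib.save(
            nib.Nifti1Image(np.moveaxis(self.displacement, 0, -1), aff), str(path)
        )

    @classmethod
    def load(cls, path: str | Path) -> "DeformationField":
        import nibabel as nib

        arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        return cls(np.moveaxis(arr, -1, 0))


def warp(fld: DeformationField, image: np.ndarray) -> np.ndarray:
    """Backward warp: out(v) = image(v + u(v)), linear interpolation, zero fill."""
    if fld.displacement.shape[1:] != image.shape:
        raise ValueError("field and image grids differ")
    coords = np.indices(image.shape, dtype=float) + fld.displacement
    return ndimage.map_coordinates(image, coords, order=1, mode="constant",
                                   cval=0.0)


def _warp_with_grad(image: np.ndarray, disp: np.ndarray):
    """Warped image and spatial gradient of the image at warped coordinates."""
    coords = np.indices(image.shape, dtype=float) + disp
    warped = ndimage.map_coordinates(image, coords, order=1, mode="constant",
                                     cval=0.0)
    grads = np.gradient(image)
    g_at = np.stack([
        ndimage.map_coordinates(g, coords, order=1, mode="nearest")
        for g in grads
    ])
    return warped, g_at


# ---------------------------------------------------------------------------
# predictor network and demons engine


class RegUNet(nn.Layer):
    """Shallow 3D conv predictor of a half-resolution displacement field.

    Zero-initialized output layer: the untrained model predicts the
    identity (zero) field.  Input channels are the fixed and moving
    images, each scaled by its own mean absolute intensity.
    """

    def __init__(self, channels: int = 8, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        C = channels
        self.pool = nn.AvgPool(3)
        self.conv1 = nn.ConvNd(3, 2, C, rng)
        self.act1 = nn.SiLU()
        self.conv2 = nn.ConvNd(3, C, C, rng)
        self.act2 = nn.SiLU()
        self.conv3 = nn.ConvNd(3, C, 3, rng, zero_init=True)
        self.up = nn.Upsample(3)

    def children(self):
        return [self.pool, self.conv1, self.act1, self.conv2, self.act2,
                self.conv3, self.up]

    def forward(self, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
        def norm(v):
            return v / (np.mean(np.abs(v)) + 1e-12)

        x = np.stack([norm(fixed), norm(moving)])[None]
        h = self.pool.forward(x)
        h = self.act1.forward(self.conv1.forward(h))
        h = self.act2.forward(self.conv2.forward(h))
        h = self.conv3.forward(h)
        # upsample predicted field back to full resolution; displacement is
        # predicted in full-resolution voxel units
        return self.up.forward(h)[0]

    def backward(self, dfield: np.ndarray) -> None:
        dh = self.up.backward(dfield[None])
        dh = self.conv3.backward(dh)
        dh = self.conv2.backward(self.act2.backward(dh))
        dh = self.conv1.backward(self.act1.backward(dh))
        # input images receive no gradient (they are data, not parameters)


@dataclass(frozen=True)
class DemonsConfig:
    levels: tuple[int, ...] = (2, 1)
    iters_per_level: int = 30
    update_sigma: float = 1.0
    field_sigma: float = 1.5
    #: pre-smoothing of both images before force computation, so image
    #: noise does not drive spurious displacement
    image_sigma: float = 1.0


@dataclass
class RegistrationModel:
    """Trained deformable registration predictor phi(fixed, moving)."""

    engine: str                      # "cnn" or "demons"
    net: RegUNet | None = None
    demons: DemonsConfig = field(default_factory=DemonsConfig)
    training_log: list = field(default_factory=list)
    grid_shape: tuple | None = None


def _demons_field(fixed: np.ndarray, moving: np.ndarray,
                  cfg: DemonsConfig) -> np.ndarray:
    """Classical multi-scale demons: deterministic per-pair optimization."""
    scale_f = 1.0 / max(np.abs(fixed).max(), 1e-12)
    disp = None
    for level in cfg.levels:
        f = _downsample(fixed, level) * scale_f
        m = _downsample(moving, level) * scale_f
        if cfg.image_sigma > 0:
            f = ndimage.gaussian_filter(f, cfg.image_sigma)
            m = ndimage.gaussian_filter(m, cfg.image_sigma)
        if disp is None:
            disp = np.zeros((3, *f.shape))
        else:
            disp = np.stack([
                ndimage.zoom(d, np.array(f.shape) / np.array(d.shape), order=1)
                for d in disp
            ]) * 2.0
        for _ in range(cfg.iters_per_level):
            warped, g = _warp_with_grad(m, disp)
            diff = f - warped
            gmag2 = np.sum(g * g, axis=0)
            denom = gmag2 + diff**2 + 1e-9
            upd = g * (diff / denom)[None]
            upd = np.stack([
                ndimage.gaussian_filter(u, cfg.update_sigma) for u in upd
            ])
            disp = disp + upd
            disp = np.stack([
                ndimage.gaussian_filter(d, cfg.field_sigma) for d in disp
            ])
    if cfg.levels[-1] != 1:
        full = np.array(fixed.shape)
        disp = np.stack([
            ndimage.zoom(d, full / np.array(disp.shape[1:]), order=1)
            for d in disp
        ]) * cfg.levels[-1]
    return disp


def train_deformable(target_fixed: np.ndarray,
                     moving_set: list[np.ndarray], epochs: int = 100,
                     seed: int = 0, engine: str = "cnn",
                     learning_rate: float = 1e-3, channels: int = 8,
                     smoothness_weight: float = 0.0) -> RegistrationModel:
    """Train phi(fixed, moving) on registration to the target only.

    Loss is -NCC(fixed, moving o phi) averaged over the moving set, with an
    optional displacement-smoothness penalty (off by default).  The demons
    engine needs no training; it is returned immediately with the same
    interface.
    """
    if engine == "demons":
        return RegistrationModel(engine="demons",
                                 grid_shape=target_fixed.shape)
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    net = RegUNet(channels=channels, seed=seed)
    opt = nn.Adam(net, lr=learning_rate)
    model = RegistrationModel(engine="cnn", net=net,
                              grid_shape=target_fixed.shape)
    for epoch in range(epochs):
        losses = []
        for moving in moving_set:
            disp = net.forward(target_fixed, moving)
            warped, g = _warp_with_grad(moving, disp)
            val, dncc = _ncc_grad_wrt_b(target_fixed, warped)
            loss = -val
            dfield = -dncc[None] * g
            if smoothness_weight > 0:
                for a in range(3):
                    for ax in range(3):
                        d2 = np.diff(disp[a], axis=ax, prepend=disp[a].take([0], axis=ax))
                        loss += smoothness_weight * float(np.sum(d2**2)) / disp[a].size
                        dfield[a] -= smoothness_weight * 2.0 * np.gradient(
                            np.gradient(disp[a], axis=ax), axis=ax
                        ) / disp[a].size
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN registration loss at epoch {epoch}"
                )
            net.backward(dfield)
            opt.step()
            losses.append(loss)
        model.training_log.append(float(np.mean(losses)))
    return model


def predict_deformation(model: RegistrationModel, fixed: np.ndarray,
                        moving: np.ndarray) -> DeformationField:
    """Deterministic displacement field mapping moving into the fixed frame."""
    if model.grid_shape is not None and fixed.shape != tuple(model.grid_shape):
        raise ValueError(
            f"grid {fixed.shape} does not match model grid {model.grid_shape}"
        )
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share a grid")
    if model.engine == "cnn":
        if model.net is None:
            raise ValueError("cnn engine has no trained network")
        disp = model.net.forward(fixed, moving)
    elif model.engine == "demons":
        disp = _demons_field(fixed, moving, model.demons)
    else:
        raise ValueError(f"unknown engine {model.engine!r}")
    return DeformationField(disp)
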