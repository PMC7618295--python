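"""Synthetic multi-subject brain phantoms.

Each subject is a smoothly deformed variant of a shared template: an
elliptical head with a CSF rim, a cortical gray-matter ribbon, a
white-matter interior and CSF ventricles.  PET activity, MR intensity and
the attenuation map are all derived from the same tissue-label map, so PET
and MR structure agree by construction — except where out-of-distribution
spherical lesions are inserted afterwards into the activity only, creating
deliberate PET-MR mismatches.

Tissue codes: 0 background, 1 CSF, 2 gray matter, 3 white matter, 4 lesion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

BACKGROUND, CSF, GRAY, WHITE, LESION = 0, 1, 2, 3, 4

#: linear attenuation coefficient of water at 511 keV, per mm
MU_WATER_MM = 0.0096


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, tissue contrast and variability of the synthetic subjects.

    Activity is in arbitrary units; only ratios matter because sinogram
    simulation rescales to a target count level.  The default gray:white:CSF
    activity ratio of 4:1:0.1 is typical of FDG brain uptake.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    activity: dict[int, float] = field(
        default_factory=lambda: {CSF: 0.1, GRAY: 4.0, WHITE: 1.0}
    )
    mr_intensity: dict[int, float] = field(
        default_factory=lambda: {CSF: 0.2, GRAY: 0.6, WHITE: 1.0}
    )
    mr_noise_sigma: float = 0.02
    mr_bias_amplitude: float = 0.1
    #: std-dev, in voxels, of the random anatomical warp between subjects
    warp_amplitude_vox: float = 1.5
    #: smoothing scale, in voxels, of the random warp
    warp_smoothness_vox: float = 6.0
    mu_tissue_mm: float = MU_WATER_MM

    def __post_init__(self):
        if min(self.shape) < 16:
            raise ValueError(
                f"grid shape {self.shape} too small: every axis must be >= 16"
            )

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dict):
                v = ",".join(f"{k}:{x}" for k, x in sorted(v.items()))
            elif isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PhantomConfig":
        kw = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key in ("activity", "mr_intensity"):
                kw[key] = {
                    int(p.split(":")[0]): float(p.split(":")[1])
                    for p in raw.split(",")
                }
            elif key == "shape":
                kw[key] = tuple(int(x) for x in raw.split(","))
            elif key == "voxel_size_mm":
                kw[key] = tuple(float(x) for x in raw.split(","))
            else:
                kw[key] = float(raw)
        return cls(**kw)


@dataclass
class Phantom:
    """Paired ground-truth volumes for one synthetic subject.

    All grids share one shape and voxel size; axis order is (x, y, z) with
    0-based indices and world coordinates ``voxel_size * (index + 0.5)``.
    """

    activity: np.ndarray
    mr: np.ndarray
    labels: np.ndarray
    mu_map: np.ndarray
    voxel_size: np.ndarray
    subject_seed: int

    def __post_init__(self):
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        shapes = {self.activity.shape, self.mr.shape, self.labels.shape, self.mu_map.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes disagree: {shapes}")
        if np.any(self.activity < 0):
            raise ValueError("activity must be nonnegative")
        if np.any(self.mu_map < 0):
            raise ValueError("mu_map must be nonnegative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.activity.shape

    def copy(self) -> "Phantom":
        return Phantom(
            self.activity.copy(), self.mr.copy(), self.labels.copy(),
            self.mu_map.copy(), self.voxel_size.copy(), self.subject_seed,
        )

    def world_affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm map (half-voxel centre offset)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = 0.5 * self.voxel_size
        return aff

    def save(self, prefix: str | Path) -> None:
        """Write one NIfTI file per channel: <prefix>_{activity,mr,labels,mu}.nii."""
        import nibabel as nib

        aff = self.world_affine()
        prefix = str(prefix)
        for name, arr in [
            ("activity", self.activity),
            ("mr", self.mr),
            ("labels", self.labels.astype(np.int16)),
            ("mu", self.mu_map),
        ]:
            nib.save(nib.Nifti1Image(np.asarray(arr), aff), f"{prefix}_{name}.nii")

    @classmethod
    def load(cls, prefix: str | Path, subject_seed: int = -1) -> "Phantom":
        import nibabel as nib

        prefix = str(prefix)
        vols = {}
        for name in ("activity", "mr", "labels", "mu"):
            img = nib.load(f"{prefix}_{name}.nii")
            vols[name] = np.asarray(img.dataobj, dtype=float)
        voxel_size = np.abs(np.diag(img.affine)[:3])
        return cls(
            vols["activity"], vols["mr"], vols["labels"].astype(np.int16),
            vols["mu"], voxel_size, subject_seed,
        )


@dataclass(frozen=True)
class LesionSpec:
    """A uniform hot sphere, specified in world millimetres."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    contrast: float  # multiplier of the gray-matter activity level

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.contrast <= 0:
            raise ValueError("lesion contrast must be positive")


# ---------------------------------------------------------------------------
# template anatomy


def _elliptical_radius(shape: tuple[int, int, int], semi_axes: np.ndarray,
                       center: np.ndarray) -> np.ndarray:
    idx = np.indices(shape, dtype=float) + 0.5
    r2 = np.zeros(shape)
    for a in range(3):
        r2 += ((idx[a] - center[a]) / semi_axes[a]) ** 2
    return np.sqrt(r2)


def _template_labels(shape: tuple[int, int, int]) -> np.ndarray:
    """Elliptical head: CSF rim, cortical GM ribbon, WM core, CSF ventricles."""
    n = np.asarray(shape, dtype=float)
    center = n / 2.0
    head_axes = n * np.array([0.42, 0.46, 0.44])
    r = _elliptical_radius(shape, head_axes, center)

    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= 1.0] = CSF          # outer subarachnoid rim
    labels[r <= 0.92] = GRAY        # cortical ribbon
    labels[r <= 0.72] = WHITE       # deep white matter

    # two lateral-ventricle ellipsoids inside the white matter
    for side in (-1.0, 1.0):
        vc = center + np.array([side * 0.10 * n[0], 0.04 * n[1], 0.0])
        v_axes = n * np.array([0.05, 0.14, 0.10])
        rv = _elliptical_radius(shape, v_axes, vc)
        labels[(rv <= 1.0) & (labels == WHITE)] = CSF
    return labels


def _random_displacement(shape: tuple[int, int, int], rng: np.random.Generator,
                         amplitude_vox: float, smoothness_vox: float) -> np.ndarray:
    """Smooth random field, shape (3, *shape), ~amplitude_vox RMS per axis."""
    disp = np.empty((3, *shape))
    for a in range(3):
        noise = rng.standard_normal(shape)
        sm = ndimage.gaussian_filter(noise, smoothness_vox, mode="nearest")
        rms = np.sqrt(np.mean(sm**2))
        disp[a] = sm * (amplitude_vox / max(rms, 1e-12))
    return disp


def _warp_nearest(labels: np.ndarray, disp: np.ndarray) -> np.ndarray:
    idx = np.indices(labels.shape, dtype=float)
    coords = idx + disp
    return ndimage.map_coordinates(labels, coords, order=0, mode="nearest")


def synthesize_mr(labels: np.ndarray, config: PhantomConfig,
                  seed: int = 0) -> np.ndarray:
    """Piecewise-constant MR from labels, with smooth bias field and noise.

    Lesion voxels image as their underlying tissue would (gray matter) so
    that lesions stay PET-only features.
    """
    rng = np.random.default_rng(seed)
    mr = np.zeros(labels.shape, dtype=float)
    for code, intensity in config.mr_intensity.items():
        mr[labels == code] = intensity
    mr[labels == LESION] = config.mr_intensity[GRAY]

    if config.mr_bias_amplitude > 0:
        raw = rng.standard_normal(labels.shape)
        sm = ndimage.gaussian_filter(raw, max(labels.shape) / 4.0, mode="nearest")
        sm = sm / max(np.abs(sm).max(), 1e-12)
        mr = mr * (1.0 + config.mr_bias_amplitude * sm)
    if config.mr_noise_sigma > 0:
        mr = mr + config.mr_noise_sigma * rng.standard_normal(labels.shape)
    return mr


def _activity_from_labels(labels: np.ndarray, config: PhantomConfig) -> np.ndarray:
    act = np.zeros(labels.shape, dtype=float)
    for code, level in config.activity.items():
        act[labels == code] = level
    return act


def sample_subject(subject_seed: int, config: PhantomConfig | None = None) -> Phantom:
    """Deterministic synthetic subject: template warped by a seeded smooth field.

    Different seeds give smoothly deformed anatomical variants; the same seed
    always returns the identical phantom.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(subject_seed)
    labels = _template_labels(config.shape)
    if config.warp_amplitude_vox > 0:
        disp = _random_displacement(
            config.shape, rng, config.warp_amplitude_vox, config.warp_smoothness_vox
        )
        labels = _warp_nearest(labels, disp)

    activity = _activity_from_labels(labels, config)
    mr = synthesize_mr(labels, config, seed=subject_seed + 1)
    mu = np.where(labels != BACKGROUND, config.mu_tissue_mm, 0.0)
    return Phantom(
        activity=activity, mr=mr, labels=labels, mu_map=mu,
        voxel_size=np.asarray(config.voxel_size_mm), subject_seed=subject_seed,
    )


def insert_lesions(phantom: Phantom, lesions: list[LesionSpec],
                   supersample_factor: int = 4,
                   config: PhantomConfig | None = None) -> Phantom:
    """Insert uniform hot spheres into the activity map only.

    Spheres are rasterized on a ``supersample_factor``-times finer grid and
    block-averaged back to the phantom grid, so edge voxels carry fractional
    (partial-volume) activity.  The MR image is untouched: lesions are
    PET-MR mismatches by construction.  Voxels whose majority volume lies
    inside a sphere are relabelled as lesion.
    """
    if supersample_factor < 1:
        raise ValueError("supersample_factor must be >= 1")
    config = config or PhantomConfig()
    gm_level = config.activity[GRAY]

    out = phantom.copy()
    vs = out.voxel_size
    shape = np.asarray(out.shape)
    s = int(supersample_factor)

    for lesion in lesions:
        c = np.asarray(lesion.center_mm, dtype=float)
        r = float(lesion.radius_mm)
        lo_mm, hi_mm = c - r, c + r
        lo = np.floor(lo_mm / vs).astype(int)
        hi = np.ceil(hi_mm / vs).astype(int)
        if np.any(lo < 0) or np.any(hi > shape):
            raise ValueError(f"lesion at {lesion.center_mm} extends outside the grid")
        cvox = np.floor(c / vs).astype(int)
        if out.labels[tuple(cvox)] == BACKGROUND:
            raise ValueError(f"lesion center {lesion.center_mm} is outside the head")

        box = hi - lo
        # fine-grid world coordinates of supersampled cell centres
        fine = [
            (lo[a] + (np.arange(box[a] * s) + 0.5) / s) * vs[a] for a in range(3)
        ]
        fx, fy, fz = np.meshgrid(*fine, indexing="ij")
        inside = ((fx - c[0]) ** 2 + (fy - c[1]) ** 2 + (fz - c[2]) ** 2) <= r * r
        frac = inside.astype(float).reshape(
            box[0], s, box[1], s, box[2], s
        ).mean(axis=(1, 3, 5))

        sl = tuple(slice(lo[a], hi[a]) for a in range(3))
        lesion_act = lesion.contrast * gm_level
        out.activity[sl] = (1.0 - frac) * out.activity[sl] + frac * lesion_act
        out.labels[sl] = np.where(frac > 0.5, LESION, out.labels[sl])

    return out
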