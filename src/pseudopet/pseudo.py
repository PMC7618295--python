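"""Pseudo-PET synthesis: other subjects' PET uptake in the target anatomy.

Each source subject's PET image is carried into the target reference space
by the transform chain B_target^-1 o phi_i o B_i, where B_i is the affine
map of subject i's MR into the common affine space, phi_i the learned
dense deformation from the affine-registered source MR onto the target MR,
and B_target the target's own affine map.  Because all transformed images
share one anatomy, randomized convex sums of them form an unlimited stream
of diverse, less-noisy, subject-specific training images:

1. draw the number of images N with P(N = n) proportional to 1/n,
2. pick N transformed images without replacement,
3. draw weights w_i ~ U[0, 1],
4. normalize the weights to sum to one,
5. sum the weighted images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .registration import (
    AffineMap,
    RegistrationModel,
    apply_affine,
    predict_deformation,
    warp,
)


@dataclass
class PseudoPETDataset:
    """Transformed PET images in the target space, with provenance."""

    transformed_pets: list[np.ndarray]
    provenance: list[dict] = field(default_factory=list)
    max_sum: int | None = None  # default: dataset size

    def __post_init__(self):
        shapes = {im.shape for im in self.transformed_pets}
        if len(shapes) > 1:
            raise ValueError(f"images are on different grids: {shapes}")
        for im in self.transformed_pets:
            if np.any(im < 0):
                raise ValueError("transformed PET images must be nonnegative")

    def __len__(self) -> int:
        return len(self.transformed_pets)

    def save(self, directory: str | Path, voxel_size=(2.0, 2.0, 2.0)) -> None:
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aff = np.diag([*voxel_size, 1.0])
        for k, im in enumerate(self.transformed_pets):
            nib.save(nib.Nifti1Image(im, aff),
                     str(directory / f"pseudo_pet_{k:03d}.nii"))
        (directory / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2)
        )


def build_transformed_set(pet_images: list[np.ndarray],
                          subject_ids: list,
                          affine_maps: list[AffineMap],
                          target_map: AffineMap,
                          target_mr_affine: np.ndarray,
                          source_mrs_affine: list[np.ndarray],
                          reg_model: RegistrationModel) -> PseudoPETDataset:
    """Transform every source PET into the target space.

    ``target_mr_affine`` and ``source_mrs_affine`` are MR images already in
    the common affine space (B applied); the deformation for subject i is
    predicted as phi(B_target x_target^MR, B_i x_i^MR) and applied to the
    affinely-resampled PET, followed by B_target^-1.  Interpolation
    overshoot is clamped at zero to preserve nonnegativity.
    """
    if not (len(pet_images) == len(affine_maps) == len(source_mrs_affine)
            == len(subject_ids)):
        raise ValueError("per-subject inputs must have equal length "
                         "(missing affine map or MR?)")
    transformed, provenance = [], []
    for sid, pet, amap, mr_aff in zip(subject_ids, pet_images, affine_maps,
                                      source_mrs_affine):
        pet_aff = apply_affine(amap, pet, direction="forward")
        fld = predict_deformation(reg_model, target_mr_affine, mr_aff)
        pet_warped = warp(fld, pet_aff)
        pet_target = apply_affine(target_map, pet_warped, direction="inverse")
        transformed.append(np.maximum(pet_target, 0.0))
        provenance.append({
            "source_subject": sid,
            "chain": ["B_i", "phi_i", "B_target^-1"],
            "mean_displacement_vox": float(
                np.mean(np.linalg.norm(fld.displacement, axis=0))
            ),
        })
    return PseudoPETDataset(transformed, provenance)


def sample_sum_count(max_n: int, rng: np.random.Generator) -> int:
    """Number of images to sum, with P(N = n) proportional to 1/n for
    n = 1..max_n (harmonic-number normalization)."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    weights = 1.0 / np.arange(1, max_n + 1)
    return int(rng.choice(np.arange(1, max_n + 1), p=weights / weights.sum()))


def random_weighted_sum(images: list[np.ndarray], rng: np.random.Generator,
                        max_n: int | None = None,
                        return_record: bool = False):
    """One randomized convex combination of the transformed images.

    Selection is without replacement; raw weights are U[0, 1] rescaled to
    sum to one (resampled in the measure-zero event that all are zero).
    The output is a voxelwise convex combination of the selected images.
    """
    if not images:
        raise ValueError("images must be nonempty")
    max_n = len(images) if max_n is None else min(max_n, len(images))
    n = sample_sum_count(max_n, rng)
    chosen = rng.choice(len(images), size=n, replace=False)
    w = rng.uniform(0.0, 1.0, size=n)
    while w.sum() == 0.0:
        w = rng.uniform(0.0, 1.0, size=n)
    w = w / w.sum()
    out = np.zeros_like(images[0], dtype=float)
    for wi, ci in zip(w, chosen):
        out += wi * images[ci]
    if return_record:
        return out, {"selected": chosen.tolist(), "weights": w.tolist(), "n": n}
    return out


def generate_epoch(dataset: PseudoPETDataset, size: int | None = None,
                   seed: int = 0) -> list[np.ndarray]:
    """A fresh online epoch of randomly summed pseudo-PET images.

    Defaults to the dataset's own size, matching the convention that each
    epoch is as large as the plain transformed-image dataset.  Each image
    uses its own derived substream, so regeneration is reproducible
    independent of iteration order.
    """
    if size is None:
        size = len(dataset)
    if size < 1:
        raise ValueError("size must be >= 1")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(size)
    return [
        random_weighted_sum(dataset.transformed_pets,
                            np.random.default_rng(streams[k]),
                            max_n=dataset.max_sum)
        for k in range(size)
    ]
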