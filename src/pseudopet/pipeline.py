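"""End-to-end experiment orchestration at desk scale.

Two templates: a simulation study (multi-subject phantoms -> pseudo-PET ->
personalized prior -> low-count reconstruction with every configured
method -> trade-off table) and an ensemble bias-variance study.  Every
stage's randomness derives deterministically from one master seed, and
heavyweight artifacts are cached on disk keyed by a hash of the
configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import dds, diffusion, metrics, phantom, projector, pseudo, recon
from . import registration as reg

log = logging.getLogger("pseudopet.pipeline")


@dataclass
class ExperimentConfig:
    """One config object drives the whole study."""

    n_subjects: int = 5
    target_subject: int = 0
    phantom_config: phantom.PhantomConfig = field(
        default_factory=lambda: phantom.PhantomConfig(shape=(32, 32, 16))
    )
    total_counts: float = 2e6
    background_fraction: float = 0.3
    low_dose_fraction: float = 0.025
    n_sub: int = 7                      # subsets (21 needs >= 21 angles)
    lesions: tuple = (
        phantom.LesionSpec((22.0, 32.0, 16.0), 5.0, 1.5),
    )
    # method name -> hyperparameter grid
    osem_iters: tuple = (2, 5)
    bsrem_betas: tuple = ()
    dds_lambdas: tuple = (1.0, 3.0, 10.0, 30.0)
    dds_steps: int = 25
    dds_p: int = 4
    include_unpersonalized: bool = True
    use_random_summing: bool = False
    prior_epochs: int = 80
    prior_channels: int = 8
    reg_engine: str = "demons"          # "demons" or "cnn"
    reg_epochs: int = 40
    master_seed: int = 0
    output_dir: str = "scratch/study"

    def stage_hash(self, *fields_used: str) -> str:
        payload = {k: repr(getattr(self, k)) for k in sorted(fields_used)}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


class _Cache:
    def __init__(self, root: Path):
        self.root = root
        root.mkdir(parents=True, exist_ok=True)

    def path(self, name: str, key: str) -> Path:
        return self.root / f"{name}_{key}.npz"

    def load(self, name: str, key: str):
        p = self.path(name, key)
        if p.exists():
            return np.load(p, allow_pickle=True)
        return None

    def save(self, name: str, key: str, **arrays) -> None:
        np.savez(self.path(name, key), **arrays)


def _timed(stage: str):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.time()
            out = fn(*a, **kw)
            log.info("stage=%s wall=%.1fs", stage, time.time() - t0)
            return out

        return wrapped

    return deco


# ---------------------------------------------------------------------------
# stages


def make_subjects(cfg: ExperimentConfig) -> list[phantom.Phantom]:
    return [phantom.sample_subject(s, cfg.phantom_config)
            for s in range(cfg.n_subjects)]


def training_pet_images(cfg: ExperimentConfig,
                        subjects: list[phantom.Phantom],
                        seeds: list[int]) -> list[np.ndarray]:
    """Full-count OSEM reconstructions of the non-target subjects: the
    image-quality level available as training data in practice."""
    images = []
    for i, subj in enumerate(subjects):
        if i == cfg.target_subject:
            images.append(None)
            continue
        system = projector.SystemModel.from_phantom(subj)
        sino = projector.simulate_prompts(
            system, subj, cfg.total_counts, cfg.background_fraction,
            seed=seeds[i], n_sub=cfg.n_sub,
        )
        images.append(recon.osem(sino, system, n_iter=2))
    return images


def build_pseudo_pet(cfg: ExperimentConfig, subjects, pet_images,
                     seed: int) -> pseudo.PseudoPETDataset:
    target = subjects[cfg.target_subject]
    source_ids = [i for i in range(cfg.n_subjects) if i != cfg.target_subject]
    affine_maps = []
    mrs_affine = []
    for i in source_ids:
        amap = reg.affine_register(subjects[i].mr, target.mr,
                                   voxel_size=target.voxel_size)
        affine_maps.append(amap)
        mrs_affine.append(reg.apply_affine(amap, subjects[i].mr))
    target_map = reg.AffineMap.identity(target.voxel_size)

    if cfg.reg_engine == "cnn":
        model = reg.train_deformable(
            target.mr, mrs_affine, epochs=cfg.reg_epochs, seed=seed,
            engine="cnn",
        )
    else:
        model = reg.train_deformable(target.mr, mrs_affine, engine="demons")

    return pseudo.build_transformed_set(
        [pet_images[i] for i in source_ids], source_ids, affine_maps,
        target_map, target.mr, mrs_affine, model,
    )


def train_prior(volumes: list[np.ndarray], cfg: ExperimentConfig, seed: int,
                affine_aug: bool) -> diffusion.ScoreModel:
    data = diffusion.normalize_training_images(volumes)
    n_val = min(1, len(volumes) - 1)
    vol_ids = np.unique(data.volume_ids)
    tc = diffusion.TrainConfig(
        epochs=cfg.prior_epochs, base_channels=cfg.prior_channels,
        affine_augmentation=affine_aug,
        val_volume_ids=tuple(vol_ids[-n_val:]) if n_val else (),
        select_by_validation=n_val > 0, seed=seed,
        learning_rate=1e-3,
    )
    return diffusion.train_score_model(data, tc)


# ---------------------------------------------------------------------------
# studies


def run_simulation_study(cfg: ExperimentConfig) -> dict:
    """Phantoms -> pseudo-PET -> priors -> low-count recon -> trade-off table.

    Returns a report dict with the sweep rows and file paths; stages are
    cached under ``cfg.output_dir`` so hyperparameter changes reuse models.
    """
    out = Path(cfg.output_dir)
    cache = _Cache(out / "cache")
    seeds = _stage_seeds(cfg.master_seed, 8)
    subjects = make_subjects(cfg)
    target = subjects[cfg.target_subject]

    # ground truth with lesions + low-count data for the target
    truth = phantom.insert_lesions(target, list(cfg.lesions),
                                   config=cfg.phantom_config)
    system = projector.SystemModel.from_phantom(truth)
    sino_full = projector.simulate_prompts(
        system, truth, cfg.total_counts, cfg.background_fraction,
        seed=seeds[0], n_sub=cfg.n_sub,
    )
    sino_low = projector.thin_counts(sino_full, cfg.low_dose_fraction,
                                     seed=seeds[1])
    # reconstructions from thinned data estimate activity at low-dose scale
    reference = truth.activity * sino_full.activity_scale * cfg.low_dose_fraction
    regions = metrics.build_region_set(truth, list(cfg.lesions),
                                       patch_size=min(10, truth.shape[0] // 3),
                                       seed=seeds[2])

    methods: dict = {}
    methods["osem"] = (
        lambda it: recon.osem(sino_low, system, n_iter=int(it)),
        list(cfg.osem_iters),
    )
    if cfg.bsrem_betas:
        methods["bsrem"] = (
            lambda beta: recon.bsrem(sino_low, system, mr=truth.mr, beta=beta,
                                     n_iter=5),
            list(cfg.bsrem_betas),
        )

    needs_training = bool(cfg.dds_lambdas)
    report: dict = {"config": asdict_safe(cfg)}
    if needs_training:
        key = cfg.stage_hash(
            "n_subjects", "target_subject", "phantom_config", "total_counts",
            "background_fraction", "n_sub", "reg_engine", "reg_epochs",
            "prior_epochs", "prior_channels", "use_random_summing",
            "master_seed",
        )
        pet_images = training_pet_images(cfg, subjects, seeds=_stage_seeds(
            cfg.master_seed + 1, cfg.n_subjects))
        dataset = build_pseudo_pet(cfg, subjects, pet_images, seed=seeds[3])
        train_vols = list(dataset.transformed_pets)
        if cfg.use_random_summing:
            train_vols = pseudo.generate_epoch(dataset, seed=seeds[4])

        pers_model = _cached_prior(cache, f"pers_{key}", train_vols, cfg,
                                   seeds[5], affine_aug=False)
        methods["dds_personalized"] = (
            _dds_method(sino_low, system, pers_model, cfg), list(cfg.dds_lambdas)
        )
        if cfg.include_unpersonalized:
            raw_vols = [im for i, im in enumerate(pet_images)
                        if i != cfg.target_subject]
            unp_model = _cached_prior(cache, f"unpers_{key}", raw_vols, cfg,
                                      seeds[6], affine_aug=True)
            methods["dds_unpersonalized"] = (
                _dds_method(sino_low, system, unp_model, cfg),
                list(cfg.dds_lambdas),
            )
        report["n_pseudo_pet"] = len(dataset)

    # lesion contrast relative to the white-matter background region
    act = cfg.phantom_config.activity
    true_contrast = float(
        cfg.lesions[0].contrast * act[phantom.GRAY] / act[phantom.WHITE]
    )
    rows = metrics.tradeoff_sweep(methods, reference, regions, true_contrast)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "tradeoff.csv"
    metrics.write_sweep_csv(rows, csv_path)
    report.update({"rows": rows, "csv": str(csv_path)})
    return report


def _cached_prior(cache: _Cache, name: str, volumes, cfg, seed, affine_aug):
    import tempfile

    hit = cache.load("prior", name)
    if hit is not None:
        with tempfile.NamedTemporaryFile(suffix=".npz") as tmp:
            Path(tmp.name).write_bytes(hit["blob"].tobytes())
            return diffusion.ScoreModel.load(tmp.name)
    model = train_prior(volumes, cfg, seed, affine_aug)
    with tempfile.NamedTemporaryFile(suffix=".npz", delete=False) as tmp:
        model.save(tmp.name)
        blob = np.frombuffer(Path(tmp.name).read_bytes(), dtype=np.uint8)
    cache.save("prior", name, blob=blob)
    Path(tmp.name).unlink()
    return model


def _dds_method(sino, system, model, cfg: ExperimentConfig):
    def run(lam):
        dcfg = dds.DDSConfig(
            lambda_dds=float(lam), n_sub=cfg.n_sub,
            n_diffusion_steps=cfg.dds_steps, p=cfg.dds_p,
            seed=cfg.master_seed,
        )
        return dds.reconstruct(sino, system, model, dcfg)

    return run


def run_bias_variance_study(cfg: ExperimentConfig,
                            n_realizations: int = 10,
                            osem_iters: int = 2) -> dict:
    """Ensemble bias/sd of OSEM over independent noise realizations.

    The reference is the noiseless expected-data OSEM limit: the full-count
    reconstruction convention, scaled to low-count conditions.
    """
    subjects = make_subjects(cfg)
    target = subjects[cfg.target_subject]
    truth = phantom.insert_lesions(target, list(cfg.lesions),
                                   config=cfg.phantom_config)
    system = projector.SystemModel.from_phantom(truth)
    sino_full = projector.simulate_prompts(
        system, truth, cfg.total_counts, cfg.background_fraction,
        seed=cfg.master_seed, n_sub=cfg.n_sub,
    )
    reference = recon.osem(sino_full, system, n_iter=osem_iters)

    low_counts = cfg.total_counts * cfg.low_dose_fraction

    def gen(seed):
        return projector.simulate_prompts(
            system, truth, low_counts, cfg.background_fraction,
            seed=seed, n_sub=cfg.n_sub,
        )

    def rec(sino):
        # dose-fraction correction puts low-count estimates on the
        # full-count intensity scale of the reference
        return recon.osem(sino, system, n_iter=osem_iters) / cfg.low_dose_fraction

    bias, sd, records = metrics.bias_variance(
        rec, gen, n_realizations, reference, base_seed=cfg.master_seed + 100,
    )
    return {
        "method": "osem", "bias_percent": bias, "sd_percent": sd,
        "n_realizations": n_realizations, "records": records,
    }


def asdict_safe(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    d["lesions"] = [asdict(l) if not isinstance(l, dict) else l
                    for l in d.get("lesions", [])]
    return d
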