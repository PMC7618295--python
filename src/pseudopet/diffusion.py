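"""Slice-conditional denoising diffusion prior for PET volumes.

A variance-preserving (DDPM-style) schedule with epsilon-prediction: the
denoiser is a small U-shaped convolutional network conditioned on the
diffusion timestep and on the transverse slice position (both via
sinusoidal embeddings through identical two-layer projections), with
single-head self-attention at the coarsest resolution.  Optionally the
co-registered MR slice enters as a second input channel; classifier-free
guidance is enabled by replacing it with a null (zero) condition with
probability ``p_uncond`` per training sample.

Training images are normalized per volume by the mean intensity over the
nonzero support, empty transverse slices are dropped, and each slice's
global magnitude is re-randomized every epoch by dividing by u ~ U[0.5, 1.5].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn


# ---------------------------------------------------------------------------
# noise schedule


@dataclass(frozen=True)
class NoiseSchedule:
    """Variance-preserving schedule: x_t = signal(t) x_0 + noise(t) eps,
    with signal^2 + noise^2 = 1 at every step."""

    n_steps: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02

    @property
    def betas(self) -> np.ndarray:
        return np.linspace(self.beta_start, self.beta_end, self.n_steps)

    @property
    def alpha_bar(self) -> np.ndarray:
        return np.cumprod(1.0 - self.betas)

    def signal_coeff(self, t) -> np.ndarray:
        return np.sqrt(self.alpha_bar[t])

    def noise_coeff(self, t) -> np.ndarray:
        return np.sqrt(1.0 - self.alpha_bar[t])

    def validate(self) -> None:
        nc = self.noise_coeff(np.arange(self.n_steps))
        assert np.all(np.diff(nc) > 0), "noise must increase strictly in t"
        sc = self.signal_coeff(np.arange(self.n_steps))
        np.testing.assert_allclose(sc**2 + nc**2, 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# score network


class ScoreUNet(nn.Layer):
    """Two-level U-net, FiLM-conditioned on (timestep, slice position).

    Input (B, C_in, H, W) with H, W divisible by 4; output epsilon estimate
    of shape (B, 1, H, W).  C_in is 1, or 2 when MR-conditional.
    """

    def __init__(self, base_channels: int = 16, emb_dim: int = 32,
                 mr_conditional: bool = False, seed: int = 0,
                 attention: bool = True):
        super().__init__()
        rng = np.random.default_rng(seed)
        C, E = base_channels, emb_dim
        self.base_channels, self.emb_dim = C, E
        self.mr_conditional = mr_conditional
        self.attention = attention
        in_ch = 2 if mr_conditional else 1

        self.t_mlp1 = nn.Dense(E, E, rng)
        self.t_act = nn.SiLU()
        self.t_mlp2 = nn.Dense(E, E, rng)
        self.s_mlp1 = nn.Dense(E, E, rng)
        self.s_act = nn.SiLU()
        self.s_mlp2 = nn.Dense(E, E, rng)

        self.conv_in = nn.ConvNd(2, in_ch, C, rng)
        self.film1 = nn.EmbedBias(E, C, rng)
        self.act1 = nn.SiLU()
        self.conv_e1 = nn.ConvNd(2, C, C, rng)
        self.pool1 = nn.AvgPool(2)
        self.conv_e2 = nn.ConvNd(2, C, 2 * C, rng)
        self.film2 = nn.EmbedBias(E, 2 * C, rng)
        self.act2 = nn.SiLU()
        self.conv_e3 = nn.ConvNd(2, 2 * C, 2 * C, rng)
        self.pool2 = nn.AvgPool(2)

        self.conv_m1 = nn.ConvNd(2, 2 * C, 2 * C, rng)
        self.film3 = nn.EmbedBias(E, 2 * C, rng)
        self.act3 = nn.SiLU()
        self.attn = nn.SelfAttention2d(2 * C, rng) if attention else None
        self.conv_m2 = nn.ConvNd(2, 2 * C, 2 * C, rng)
        self.act4 = nn.SiLU()

        self.up2 = nn.Upsample(2)
        self.conv_d2 = nn.ConvNd(2, 4 * C, 2 * C, rng)
        self.film4 = nn.EmbedBias(E, 2 * C, rng)
        self.act5 = nn.SiLU()
        self.up1 = nn.Upsample(2)
        self.conv_d1 = nn.ConvNd(2, 3 * C, C, rng)
        self.film5 = nn.EmbedBias(E, C, rng)
        self.act6 = nn.SiLU()
        self.conv_out = nn.ConvNd(2, C, 1, rng, zero_init=True)

    def children(self):
        out = [
            self.t_mlp1, self.t_act, self.t_mlp2,
            self.s_mlp1, self.s_act, self.s_mlp2,
            self.conv_in, self.film1, self.act1, self.conv_e1, self.pool1,
            self.conv_e2, self.film2, self.act2, self.conv_e3, self.pool2,
            self.conv_m1, self.film3, self.act3,
        ]
        if self.attn is not None:
            out.append(self.attn)
        out += [
            self.conv_m2, self.act4, self.up2, self.conv_d2, self.film4,
            self.act5, self.up1, self.conv_d1, self.film5, self.act6,
            self.conv_out,
        ]
        return out

    def _embed(self, t_frac: np.ndarray, slice_pos: np.ndarray) -> np.ndarray:
        te = nn.sinusoidal_embedding(t_frac, self.emb_dim)
        se = nn.sinusoidal_embedding(slice_pos, self.emb_dim)
        t_out = self.t_mlp2.forward(self.t_act.forward(self.t_mlp1.forward(te)))
        s_out = self.s_mlp2.forward(self.s_act.forward(self.s_mlp1.forward(se)))
        return t_out + s_out

    def forward(self, x: np.ndarray, t_frac: np.ndarray,
                slice_pos: np.ndarray, mr: np.ndarray | None = None
                ) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None]
        if self.mr_conditional:
            if mr is None:
                mr = np.zeros_like(x[:, 0])
            x = np.concatenate([x, mr[:, None]], axis=1)
        emb = self._embed(t_frac, slice_pos)

        h = self.conv_in.forward(x)
        h = self.film1.forward(h, emb)
        h = self.act1.forward(h)
        s1 = self.conv_e1.forward(h)
        h = self.pool1.forward(s1)
        h = self.conv_e2.forward(h)
        h = self.film2.forward(h, emb)
        h = self.act2.forward(h)
        s2 = self.conv_e3.forward(h)
        h = self.pool2.forward(s2)

        h = self.conv_m1.forward(h)
        h = self.film3.forward(h, emb)
        h = self.act3.forward(h)
        if self.attn is not None:
            h = self.attn.forward(h)
        h = self.conv_m2.forward(h)
        h = self.act4.forward(h)

        h = self.up2.forward(h)
        h = np.concatenate([h, s2], axis=1)
        h = self.conv_d2.forward(h)
        h = self.film4.forward(h, emb)
        h = self.act5.forward(h)
        h = self.up1.forward(h)
        h = np.concatenate([h, s1], axis=1)
        h = self.conv_d1.forward(h)
        h = self.film5.forward(h, emb)
        h = self.act6.forward(h)
        return self.conv_out.forward(h)[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        C = self.base_channels
        dh = self.conv_out.backward(dout[:, None])
        dh = self.act6.backward(dh)
        dh, demb = self.film5.backward(dh)
        dh = self.conv_d1.backward(dh)
        dh, ds1 = dh[:, : 2 * C], dh[:, 2 * C:]
        dh = self.up1.backward(dh)
        dh = self.act5.backward(dh)
        dh, de = self.film4.backward(dh)
        demb += de
        dh = self.conv_d2.backward(dh)
        dh, ds2 = dh[:, : 2 * C], dh[:, 2 * C:]
        dh = self.up2.backward(dh)

        dh = self.act4.backward(dh)
        dh = self.conv_m2.backward(dh)
        if self.attn is not None:
            dh = self.attn.backward(dh)
        dh = self.act3.backward(dh)
        dh, de = self.film3.backward(dh)
        demb += de
        dh = self.conv_m1.backward(dh)

        dh = self.pool2.backward(dh)
        ds2 = ds2 + dh
        dh = self.conv_e3.backward(ds2)
        dh = self.act2.backward(dh)
        dh, de = self.film2.backward(dh)
        demb += de
        dh = self.conv_e2.backward(dh)
        dh = self.pool1.backward(dh)
        ds1 = ds1 + dh
        dh = self.conv_e1.backward(ds1)
        dh = self.act1.backward(dh)
        dh, de = self.film1.backward(dh)
        demb += de
        self.conv_in.backward(dh)

        dt = self.t_mlp2.backward(demb)
        dt = self.t_act.backward(dt)
        self.t_mlp1.backward(dt)
        ds = self.s_mlp2.backward(demb)
        ds = self.s_act.backward(ds)
        self.s_mlp1.backward(ds)


@dataclass
class ScoreModel:
    """Trained denoiser plus its schedule, normalization and training log."""

    net: ScoreUNet
    schedule: NoiseSchedule
    train_mean_intensity: float = 1.0  # mean slice intensity of training data
    training_log: list = field(default_factory=list)

    @property
    def mr_conditional(self) -> bool:
        return self.net.mr_conditional

    def predict_eps(self, x: np.ndarray, t: np.ndarray, slice_pos: np.ndarray,
                    mr: np.ndarray | None = None) -> np.ndarray:
        """Epsilon estimate for noisy slices x at integer timesteps t."""
        t = np.atleast_1d(np.asarray(t))
        t_frac = t / max(self.schedule.n_steps - 1, 1)
        slice_pos = np.broadcast_to(np.atleast_1d(slice_pos), t.shape)
        return self.net.forward(x, t_frac, slice_pos, mr=mr)

    def save(self, path: str | Path) -> None:
        layers = self.net.all_layers()
        arrays = {
            f"p{i}_{k}": v for i, l in enumerate(layers)
            for k, v in l.params.items()
        }
        np.savez(
            path, **arrays,
            _meta=np.array([
                self.net.base_channels, self.net.emb_dim,
                int(self.net.mr_conditional), int(self.net.attention),
                self.schedule.n_steps,
            ], dtype=float),
            _sched=np.array([self.schedule.beta_start, self.schedule.beta_end]),
            _mean=np.array([self.train_mean_intensity]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScoreModel":
        data = np.load(path)
        meta = data["_meta"]
        net = ScoreUNet(
            base_channels=int(meta[0]), emb_dim=int(meta[1]),
            mr_conditional=bool(meta[2]), attention=bool(meta[3]), seed=0,
        )
        for i, layer in enumerate(net.all_layers()):
            for k in layer.params:
                layer.params[k][...] = data[f"p{i}_{k}"]
        sched = NoiseSchedule(int(meta[4]), *data["_sched"])
        return cls(net, sched, float(data["_mean"][0]))


class GaussianScoreModel:
    """Analytic epsilon-predictor for a Gaussian prior N(mu, s^2 I).

    Closed-form stand-in for a trained network, used to test sampling and
    Tweedie machinery exactly: under the VP forward process the marginal of
    x_t is N(sqrt(abar) mu, (abar s^2 + 1 - abar) I), whose score gives
    eps_hat = noise_coeff(t) * (x_t - sqrt(abar) mu) / (abar s^2 + 1 - abar).
    """

    mr_conditional = False

    def __init__(self, mean: float | np.ndarray, std: float,
                 schedule: NoiseSchedule):
        self.mean, self.std, self.schedule = mean, std, schedule
        self.train_mean_intensity = float(np.mean(mean))

    def predict_eps(self, x, t, slice_pos, mr=None):
        t = np.atleast_1d(np.asarray(t))
        abar = self.schedule.alpha_bar[t].reshape(-1, *([1] * (x.ndim - 1)))
        var = abar * self.std**2 + (1.0 - abar)
        return np.sqrt(1.0 - abar) * (x - np.sqrt(abar) * self.mean) / var


# ---------------------------------------------------------------------------
# training data preparation


@dataclass
class NormalizedSlices:
    """Stacked transverse slices with provenance and inversion scales."""

    slices: np.ndarray        # (N, H, W)
    positions: np.ndarray     # (N,) slice index / (n_slices - 1), in [0, 1]
    volume_ids: np.ndarray    # (N,) source volume index
    slice_index: np.ndarray   # (N,) original z index in the source volume
    scales: np.ndarray        # per-volume normalization scale

    @property
    def mean_intensity(self) -> float:
        """Mean over the nonzero support (~1 after per-volume normalization)."""
        nz = self.slices != 0
        return float(self.slices[nz].mean()) if nz.any() else 0.0


def normalize_training_images(volumes: list[np.ndarray]
                              ) -> NormalizedSlices:
    """Per-volume intensity normalization + empty-slice removal.

    Each volume is divided by the mean of its nonzero support; transverse
    (z) slices that are entirely zero are dropped.  Slice positions are
    recorded as index / (n_slices - 1) of the original volume, so the same
    conditioning applies at reconstruction time.
    """
    slices, positions, vol_ids, z_idx, scales = [], [], [], [], []
    for vid, vol in enumerate(volumes):
        support = vol > 0
        if not support.any():
            warnings.warn(f"volume {vid} is all zero; skipped")
            scales.append(np.nan)
            continue
        scale = float(vol[support].mean())
        scales.append(scale)
        norm = vol / scale
        nz = vol.shape[2]
        for k in range(nz):
            sl = norm[:, :, k]
            if not np.any(sl != 0):
                continue
            slices.append(sl)
            positions.append(k / max(nz - 1, 1))
            vol_ids.append(vid)
            z_idx.append(k)
    if not slices:
        raise ValueError("no nonempty slices in any volume")
    return NormalizedSlices(
        np.stack(slices), np.array(positions), np.array(vol_ids),
        np.array(z_idx), np.array(scales),
    )


def augment_intensity(slice_img: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Divide the slice by u ~ U[0.5, 1.5] (global magnitude augmentation)."""
    return slice_img / rng.uniform(0.5, 1.5)


def augment_affine(slice_img: np.ndarray, rng: np.random.Generator,
                   max_scale: float = 0.05, max_shift_vox: float = 5.0,
                   max_rot_deg: float = 5.0) -> np.ndarray:
    """Random in-plane similarity transform within the stated ranges.

    Used only for non-registered training data; pseudo-PET slices are
    already in the target space and are not augmented spatially.
    """
    scale = 1.0 + rng.uniform(-max_scale, max_scale)
    shift = rng.uniform(-max_shift_vox, max_shift_vox, size=2)
    theta = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg))
    c, s = np.cos(theta), np.sin(theta)
    mat = scale * np.array([[c, -s], [s, c]])
    center = (np.asarray(slice_img.shape) - 1) / 2.0
    # pull transform: input coords = mat^-1 (out - center - shift) + center
    inv = np.linalg.inv(mat)
    offset = center - inv @ (center + shift)
    return ndimage.affine_transform(slice_img, inv, offset=offset, order=1,
                                    mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Hyperparameters of denoising-score-matching training."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-4
    p_uncond: float = 0.1              # classifier-free condition-drop rate
    intensity_augmentation: bool = True
    affine_augmentation: bool = False  # only for non-registered data
    base_channels: int = 16
    emb_dim: int = 32
    attention: bool = True
    mr_conditional: bool = False
    val_volume_ids: tuple = ()
    select_by_validation: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_uncond <= 1.0:
            raise ValueError("p_uncond must be in [0, 1]")


def assemble_batch(data: NormalizedSlices, idx: np.ndarray,
                   rng: np.random.Generator, cfg: TrainConfig,
                   mr_slices: np.ndarray | None = None):
    """One training batch with augmentation and condition dropout.

    Returns (x0, slice_pos, mr, drop_mask); dropped samples have their MR
    condition replaced by the null (zero) condition.  This is the single
    data path used by every training epoch, so its dropout statistics are
    exactly those of training.
    """
    x0 = data.slices[idx].copy()
    for i in range(len(idx)):
        if cfg.intensity_augmentation:
            x0[i] = augment_intensity(x0[i], rng)
        if cfg.affine_augmentation:
            x0[i] = augment_affine(x0[i], rng)
    mr = None
    drop = np.zeros(len(idx), dtype=bool)
    if cfg.mr_conditional:
        if mr_slices is None:
            raise ValueError("mr_conditional training needs MR slices")
        mr = mr_slices[idx].copy()
        drop = rng.random(len(idx)) < cfg.p_uncond
        mr[drop] = 0.0
    return x0, data.positions[idx], mr, drop


def dsm_loss(model: ScoreModel, x0: np.ndarray, slice_pos: np.ndarray,
             rng: np.random.Generator, mr: np.ndarray | None = None,
             backward: bool = False) -> float:
    """Denoising score-matching loss: E ||eps_hat - eps||^2 over random t."""
    sched = model.schedule
    B = x0.shape[0]
    t = rng.integers(0, sched.n_steps, size=B)
    eps = rng.standard_normal(x0.shape)
    sc = sched.signal_coeff(t).reshape(-1, 1, 1)
    ncf = sched.noise_coeff(t).reshape(-1, 1, 1)
    x_t = sc * x0 + ncf * eps
    pred = model.predict_eps(x_t, t, slice_pos, mr=mr)
    resid = pred - eps
    loss = float(np.mean(resid**2))
    if not np.isfinite(loss):
        raise FloatingPointError("NaN/Inf in score-matching loss")
    if backward:
        model.net.backward(2.0 * resid / resid.size)
    return loss


def train_score_model(data: NormalizedSlices, cfg: TrainConfig,
                      mr_slices: np.ndarray | None = None,
                      schedule: NoiseSchedule | None = None) -> ScoreModel:
    """Train the denoiser; checkpoint selection by validation loss.

    Validation slices are those whose source volume id is in
    ``cfg.val_volume_ids``; with checkpoint selection requested the
    validation set must be nonempty.
    """
    schedule = schedule or NoiseSchedule()
    rng = np.random.default_rng(cfg.seed)
    net = ScoreUNet(cfg.base_channels, cfg.emb_dim, cfg.mr_conditional,
                    seed=cfg.seed, attention=cfg.attention)
    model = ScoreModel(net, schedule, train_mean_intensity=data.mean_intensity)
    opt = nn.Adam(net, lr=cfg.learning_rate)

    is_val = np.isin(data.volume_ids, cfg.val_volume_ids)
    train_idx = np.nonzero(~is_val)[0]
    val_idx = np.nonzero(is_val)[0]
    if len(train_idx) == 0:
        raise ValueError("no training slices left after validation split")
    if cfg.select_by_validation and len(val_idx) == 0:
        raise ValueError("validation-based selection requested but the "
                         "validation set is empty")

    best_val, best_state = np.inf, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x0, pos, mr, _ = assemble_batch(data, idx, rng, cfg, mr_slices)
            loss = dsm_loss(model, x0, pos, rng, mr=mr, backward=True)
            opt.step()
            train_losses.append(loss)
        val_loss = np.nan
        if len(val_idx) > 0:
            vrng = np.random.default_rng(cfg.seed + 10_000)
            mrv = mr_slices[val_idx] if cfg.mr_conditional else None
            val_loss = dsm_loss(model, data.slices[val_idx],
                                data.positions[val_idx], vrng, mr=mrv)
            if cfg.select_by_validation and val_loss < best_val:
                best_val = val_loss
                best_state = nn.get_state(net)
        model.training_log.append(
            {"epoch": epoch, "train_loss": float(np.mean(train_losses)),
             "val_loss": float(val_loss)}
        )
    if cfg.select_by_validation and best_state is not None:
        nn.set_state(net, best_state)
    return model


# ---------------------------------------------------------------------------
# unconditional sampling


def sample_prior(model, schedule: NoiseSchedule, n_steps: int,
                 slice_pos: float, rng: np.random.Generator,
                 shape: tuple[int, int] = None, eta: float = 1.0,
                 mr: np.ndarray | None = None) -> np.ndarray:
    """Ancestral sampling of one slice from pure noise.

    Steps are spaced uniformly over the training schedule; ``n_steps = 0``
    returns the initial Gaussian draw.  eta = 1 gives DDPM-like stochastic
    steps, eta = 0 deterministic DDIM.
    """
    if shape is None:
        shape = (32, 32)
    x = rng.standard_normal((1, *shape))
    if n_steps == 0:
        return x[0]
    ts = np.unique(np.linspace(0, schedule.n_steps - 1, n_steps).astype(int))[::-1]
    abar = schedule.alpha_bar
    pos = np.array([slice_pos])
    for i, t in enumerate(ts):
        eps_hat = model.predict_eps(x, np.array([t]), pos, mr=mr)
        x0_hat = (x - np.sqrt(1 - abar[t]) * eps_hat) / np.sqrt(abar[t])
        if i + 1 < len(ts):
            s = ts[i + 1]
            sigma = eta * np.sqrt((1 - abar[s]) / (1 - abar[t])) * np.sqrt(
                1 - abar[t] / abar[s]
            )
            dir_coeff = np.sqrt(max(1 - abar[s] - sigma**2, 0.0))
            x = (np.sqrt(abar[s]) * x0_hat + dir_coeff * eps_hat
                 + sigma * rng.standard_normal(x.shape))
        else:
            x = x0_hat
    return x[0]
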