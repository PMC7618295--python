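"""Diffusion-sampling reconstruction: analytic limits and determinism."""

import numpy as np
import pytest

import pseudopet as pp
from pseudopet import dds, recon
from pseudopet import diffusion as df


@pytest.fixture(scope="module")
def schedule():
    return df.NoiseSchedule()


class TestTweedie:
    def test_zero_eps_oracle_reduces_to_rescaling(self, schedule):
        class ZeroModel:
            mr_conditional = False

            def predict_eps(self, x, t, pos, mr=None):
                return np.zeros_like(x)

        rng = np.random.default_rng(0)
        x_t = rng.standard_normal((6, 6, 4))
        t = 300
        out = dds.tweedie_estimate(x_t, t, ZeroModel(), schedule)
        np.testing.assert_allclose(
            out, x_t / schedule.signal_coeff(t), rtol=1e-12
        )

    def test_conjugate_gaussian_posterior_mean(self, schedule):
        mu, s = 0.7, 0.4
        model = df.GaussianScoreModel(mu, s, schedule)
        rng = np.random.default_rng(1)
        x_t = rng.standard_normal((6, 6, 4))
        for t in (50, 500, 950):
            abar = schedule.alpha_bar[t]
            closed = ((np.sqrt(abar) * s**2 * x_t + (1 - abar) * mu)
                      / (abar * s**2 + 1 - abar))
            out = dds.tweedie_estimate(x_t, t, model, schedule)
            np.testing.assert_allclose(out, closed, atol=1e-6)

    def test_low_noise_limit_stays_near_iterate(self, schedule):
        model = df.GaussianScoreModel(0.5, 1.0, schedule)
        rng = np.random.default_rng(2)
        x_t = rng.standard_normal((6, 6, 4))
        out = dds.tweedie_estimate(x_t, 0, model, schedule)
        eps = model.predict_eps(x_t[None], np.array([0]),
                                np.array([0.5]))[0]
        bound = schedule.noise_coeff(0) * np.abs(eps).max() * 2 + 1e-6
        assert np.abs(out - x_t).max() <= bound

    def test_vanishing_signal_rejected(self):
        sched = df.NoiseSchedule(n_steps=10, beta_start=0.9, beta_end=0.999)
        model = df.GaussianScoreModel(0.0, 1.0, sched)
        with pytest.raises(ValueError, match="signal coefficient"):
            dds.tweedie_estimate(np.zeros((4, 4, 4)), 9, model, sched)


class TestComputeScale:
    def test_positive_and_self_consistent(self, sino, system):
        x1 = recon.osem(sino, system, n_iter=1)
        support_mean = x1[x1 > 0.01 * x1.max()].mean()
        scale = dds.compute_scale(sino, system, support_mean)
        assert scale.c > 0
        assert scale.c == pytest.approx(1.0, rel=0.10)

    def test_zero_count_sinogram_rejected(self, sino, system):
        from pseudopet.projector import SinogramSet

        empty = SinogramSet(
            prompts=np.zeros_like(sino.prompts),
            background=sino.background, angles=sino.angles,
            subset_of_angle=sino.subset_of_angle,
        )
        with pytest.raises(ValueError, match="zero-count"):
            dds.compute_scale(empty, system, 1.0)

    def test_scale_tracks_count_level(self, sino, system):
        # doubling the recorded counts doubles the quick-OSEM intensity and
        # therefore halves c (intensity ratio convention)
        from pseudopet.projector import SinogramSet

        double = SinogramSet(
            prompts=2 * sino.prompts, background=2 * sino.background,
            angles=sino.angles, subset_of_angle=sino.subset_of_angle,
        )
        c1 = dds.compute_scale(sino, system, 1.0).c
        c2 = dds.compute_scale(double, system, 1.0).c
        assert c2 == pytest.approx(0.5 * c1, rel=0.02)


class TestSubobjective:
    def test_reduces_to_subset_likelihood(self, sino, system, subject):
        cfg = dds.DDSConfig(lambda_dds=0.0, lambda_rdp=0.0, n_sub=7)
        x = subject.activity + 0.1
        v, _ = dds.dds_subobjective(x, x, sino, system, 3, cfg)
        assert v == pytest.approx(
            recon.poisson_loglik(x, sino, system, subset=3), rel=1e-12
        )

    def test_anchor_contributes_zero_at_anchor(self, sino, system, subject):
        cfg0 = dds.DDSConfig(lambda_dds=0.0, lambda_rdp=0.0, n_sub=7)
        cfg1 = dds.DDSConfig(lambda_dds=5.0, lambda_rdp=0.0, n_sub=7)
        x = subject.activity + 0.1
        v0, _ = dds.dds_subobjective(x, x, sino, system, 0, cfg0)
        v1, _ = dds.dds_subobjective(x, x, sino, system, 0, cfg1)
        assert v1 == pytest.approx(v0, rel=1e-12)

    def test_gradient_matches_finite_differences(self, sino, system, rng):
        cfg = dds.DDSConfig(lambda_dds=0.7, lambda_rdp=0.3, n_sub=7)
        x = rng.random(system.image_shape) + 0.5
        x0 = rng.random(system.image_shape) + 0.5
        _, g = dds.dds_subobjective(x, x0, sino, system, 2, cfg)
        eps = 1e-5
        for idx in [(10, 12, 7), (5, 20, 3)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            vp, _ = dds.dds_subobjective(xp, x0, sino, system, 2, cfg)
            vm, _ = dds.dds_subobjective(xm, x0, sino, system, 2, cfg)
            assert g[idx] == pytest.approx((vp - vm) / (2 * eps), rel=1e-4)


@pytest.fixture(scope="module")
def cond_model(schedule):
    net = df.ScoreUNet(base_channels=4, emb_dim=8, mr_conditional=True,
                       seed=0, attention=False)
    return df.ScoreModel(net, schedule)


class TestGuidedScore:
    def test_zero_guidance_equals_conditional(self, cond_model, rng):
        x = rng.standard_normal((2, 8, 8))
        mr = rng.standard_normal((2, 8, 8))
        pos = np.array([0.2, 0.8])
        a = dds.guided_score(cond_model, x, 100, pos, mr, 0.0)
        b = cond_model.predict_eps(x, np.full(2, 100), pos, mr=mr)
        np.testing.assert_array_equal(a, b)

    def test_unit_guidance_formula(self, cond_model, rng):
        x = rng.standard_normal((2, 8, 8))
        mr = rng.standard_normal((2, 8, 8))
        pos = np.array([0.2, 0.8])
        cond = cond_model.predict_eps(x, np.full(2, 100), pos, mr=mr)
        uncond = cond_model.predict_eps(x, np.full(2, 100), pos, mr=None)
        out = dds.guided_score(cond_model, x, 100, pos, mr, 1.0)
        np.testing.assert_allclose(out, 2 * cond - uncond, atol=1e-12)

    def test_null_condition_cancels_guidance(self, cond_model, rng):
        x = rng.standard_normal((2, 8, 8))
        pos = np.array([0.2, 0.8])
        zero_mr = np.zeros((2, 8, 8))
        a = dds.guided_score(cond_model, x, 50, pos, zero_mr, 0.0)
        b = dds.guided_score(cond_model, x, 50, pos, zero_mr, 3.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_unconditional_model_rejected(self, schedule, rng):
        model = df.GaussianScoreModel(0.0, 1.0, schedule)
        with pytest.raises(ValueError, match="MR-conditional"):
            dds.guided_score(model, rng.standard_normal((1, 8, 8)), 10,
                             np.array([0.5]), np.zeros((1, 8, 8)), 1.0)


class TestReconstruct:
    def test_data_consistency_limit_matches_osem_likelihood(
            self, sino, system, schedule):
        model = df.GaussianScoreModel(1.0, 1.0, schedule)
        cfg = dds.DDSConfig(lambda_dds=0.0, lambda_rdp=0.0, p=100, n_sub=7,
                            n_diffusion_steps=30, seed=0)
        x = dds.reconstruct(sino, system, model, cfg, schedule=schedule,
                            scale=dds.NormalizationScale(1.0))
        pll = recon.poisson_loglik(x, sino, system)
        pll_osem = recon.poisson_loglik(
            recon.osem(sino, system, n_iter=20), sino, system
        )
        assert abs(pll - pll_osem) <= 0.005 * abs(pll_osem)

    def test_anchoring_limit_pins_to_prior(self, sino, system, schedule,
                                           monkeypatch):
        anchors = []
        orig = dds.tweedie_estimate

        def spy(*args, **kwargs):
            out = orig(*args, **kwargs)
            anchors.append(out)
            return out

        monkeypatch.setattr(dds, "tweedie_estimate", spy)
        model = df.GaussianScoreModel(0.5, 0.3, schedule)
        cfg = dds.DDSConfig(lambda_dds=1e4, lambda_rdp=0.0, p=5, n_sub=7,
                            n_diffusion_steps=20, seed=0,
                            stochastic_renoise=False)
        x = dds.reconstruct(sino, system, model, cfg, schedule=schedule,
                            scale=dds.NormalizationScale(1.0))
        rel = (np.linalg.norm(x - anchors[-1])
               / np.linalg.norm(anchors[-1]))
        assert rel < 0.01

    def test_bitwise_determinism(self, low_sino, system, schedule):
        model = df.GaussianScoreModel(0.5, 0.5, schedule)
        cfg = dds.DDSConfig(lambda_dds=1.0, p=3, n_sub=7,
                            n_diffusion_steps=10, seed=11)
        a = dds.reconstruct(low_sino, system, model, cfg, schedule=schedule,
                            scale=dds.NormalizationScale(1.0))
        b = dds.reconstruct(low_sino, system, model, cfg, schedule=schedule,
                            scale=dds.NormalizationScale(1.0))
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= 0)

    def test_mr_without_conditional_model_rejected(self, sino, system,
                                                   schedule):
        model = df.GaussianScoreModel(0.5, 0.5, schedule)
        cfg = dds.DDSConfig(n_sub=7)
        with pytest.raises(ValueError, match="MR"):
            dds.reconstruct(sino, system, model, cfg, schedule=schedule,
                            mr=np.zeros(system.image_shape))
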