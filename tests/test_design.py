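"""Synthetic-session generator: design structure, latents, epochs, behavior,
pupil, determinism and persistence."""

import numpy as np
import pandas as pd
import pytest

from prestim.containers import PupilTrace
from prestim.design import (
    DesignSpec,
    GeneratorParams,
    generate_design,
    make_patterns,
    simulate_behavior,
    simulate_epochs,
    simulate_latents,
    simulate_pupil,
    simulate_session,
)
from prestim.io import read_session, write_session
from prestim.preprocess import detect_blinks


class TestGenerateDesign:
    def test_default_counts(self):
        design = generate_design(DesignSpec(), seed=0)
        assert len(design) == 360
        assert int(design["is_real"].sum()) == 300
        assert int((~design["is_real"]).sum()) == 60
        real = design[design["is_real"]]
        assert real["image_id"].nunique() == 20
        assert (design["image_id"].value_counts() == 15).all()

    def test_single_repeat_trial_count(self):
        assert len(generate_design(DesignSpec(repeats=1), seed=0)) == 24

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_every_image_repeated_exactly(self, seed):
        spec = DesignSpec(repeats=7)
        design = generate_design(spec, seed=seed)
        assert (design["image_id"].value_counts() == 7).all()

    def test_counts_conserve(self):
        spec = DesignSpec(images_per_category=3, scrambled_per_category=2, repeats=4)
        design = generate_design(spec, seed=3)
        n_real = int(design["is_real"].sum())
        n_scr = int((~design["is_real"]).sum())
        assert n_real + n_scr == len(design) == spec.n_trials
        assert n_real == spec.n_real_trials and n_scr == spec.n_scrambled_trials

    def test_blocks_and_remainder_rule(self):
        design = generate_design(DesignSpec(), seed=0)
        sizes = design["block"].value_counts().sort_index()
        assert (sizes == 36).all()
        # 24*1 = 24 trials into 7 blocks: earlier blocks take the remainder
        short = generate_design(DesignSpec(repeats=1, n_blocks=7), seed=0)
        sizes = short["block"].value_counts().sort_index().to_list()
        assert sizes == [4, 4, 4, 3, 3, 3, 3]

    def test_seed_determinism_and_variation(self):
        a = generate_design(DesignSpec(), seed=5)
        b = generate_design(DesignSpec(), seed=5)
        c = generate_design(DesignSpec(), seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a["image_id"].equals(c["image_id"])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            DesignSpec(images_per_category=0)
        with pytest.raises(ValueError, match="positive"):
            DesignSpec(repeats=-1)

    def test_onsets_strictly_increasing(self):
        design = generate_design(DesignSpec(), seed=2)
        assert np.all(np.diff(design["prestim_onset"]) > 0)


class TestLatents:
    def test_shapes_and_determinism(self, tiny_spec):
        design = generate_design(tiny_spec, seed=0)
        params = GeneratorParams()
        a = simulate_latents(design, params, seed=4)
        b = simulate_latents(design, params, seed=4)
        assert a.g.shape == (len(design),)
        assert a.preferred_category.shape == (len(design),)
        assert np.array_equal(a.g, b.g)
        assert np.array_equal(a.preferred_category, b.preferred_category)

    def test_match_rate_near_quarter(self):
        design = generate_design(DesignSpec(repeats=50), seed=1)  # 1200 trials
        latents = simulate_latents(design, GeneratorParams(), seed=9)
        assert abs(latents.match.mean() - 0.25) < 0.04

    def test_ar1_marginal_variance(self):
        design = generate_design(DesignSpec(repeats=50), seed=1)
        latents = simulate_latents(design, GeneratorParams(latent_ar1=0.6), seed=2)
        assert abs(np.std(latents.g) - 1.0) < 0.1
        lag1 = np.corrcoef(latents.g[:-1], latents.g[1:])[0, 1]
        assert 0.45 < lag1 < 0.75


class TestEpochs:
    def test_noiseless_epochs_exact(self, tiny_spec):
        design = generate_design(tiny_spec, seed=0)
        params = GeneratorParams(noise_sd=0.0, drift_slope=0.0)
        latents = simulate_latents(design, params, seed=1)
        rng = np.random.default_rng(0)
        w_g, W_c = make_patterns(tiny_spec.n_sensors, 4, rng)
        epochs = simulate_epochs(design, latents, params, tiny_spec,
                                 seed=2, w_g=w_g, W_c=W_c)
        cats = list(tiny_spec.categories)
        for t in [0, 7, len(design) - 1]:
            expected = (params.signal_gain_g * latents.g[t] * w_g
                        + params.signal_gain_cat * W_c[cats.index(latents.preferred_category[t])])
            assert np.allclose(epochs.values[t], expected[:, None])

    def test_epoch_shape_matches_spec(self):
        spec = DesignSpec(repeats=1)
        design = generate_design(spec, seed=0)
        params = GeneratorParams()
        latents = simulate_latents(design, params, seed=0)
        epochs = simulate_epochs(design, latents, params, spec, seed=0)
        assert epochs.values.shape == (24, 64, 200)

    def test_pattern_dimension_mismatch(self, tiny_spec):
        design = generate_design(tiny_spec, seed=0)
        params = GeneratorParams()
        latents = simulate_latents(design, params, seed=0)
        with pytest.raises(ValueError, match="dimensions"):
            simulate_epochs(design, latents, params, tiny_spec, seed=0,
                            w_g=np.ones(3), W_c=np.ones((4, 3)))

    def test_pattern_overlap_cosine(self, rng):
        w_g, W_c = make_patterns(32, 4, rng, overlap=0.4)
        all_p = np.vstack([w_g, W_c])
        gram = all_p @ all_p.T
        off = gram[~np.eye(5, dtype=bool)]
        assert np.allclose(np.diag(gram), 1.0)
        assert np.allclose(off, 0.4, atol=1e-8)


class TestBehavior:
    def _design_latents(self, repeats=30, seed=0, **kw):
        spec = DesignSpec(repeats=repeats, n_sensors=8)
        design = generate_design(spec, seed=seed)
        params = GeneratorParams(**kw)
        latents = simulate_latents(design, params, seed=seed + 1)
        return design, latents, params

    def test_zero_coefficients_give_half(self):
        design, latents, params = self._design_latents(
            b0=0.0, b_real=0.0, b_g=0.0, b_match=0.0, b_match_scr=0.0)
        trials = simulate_behavior(design, latents, params, seed=3)
        rate = (trials["recognition_report"] == "yes").mean()
        assert abs(rate - 0.5) < 0.04  # 720 trials, ~3 sigma

    def test_pure_g_effect_symmetric(self):
        design, latents, params = self._design_latents(
            b0=0.0, b_real=0.0, b_g=1.0, b_match=0.0, b_match_scr=0.0)
        trials = simulate_behavior(design, latents, params, seed=3)
        assert abs((trials["recognition_report"] == "yes").mean() - 0.5) < 0.05

    def test_perfect_recognized_accuracy(self):
        design, latents, params = self._design_latents(
            p_correct_recognized=1.0, report_bias_strength=0.0)
        trials = simulate_behavior(design, latents, params, seed=5)
        rec_real = trials["is_real"] & (trials["recognition_report"] == "yes")
        reports = trials.loc[rec_real, "category_report"].to_numpy(dtype=str)
        truth = trials.loc[rec_real, "objective_category"].astype(str).to_numpy()
        assert (reports == truth).all()

    def test_accuracy_targets_recovered(self):
        design, latents, params = self._design_latents(repeats=80)
        trials = simulate_behavior(design, latents, params, seed=6)
        rec_real = trials["is_real"] & (trials["recognition_report"] == "yes")
        acc = (trials.loc[rec_real, "category_report"].to_numpy(dtype=str)
               == trials.loc[rec_real, "objective_category"].astype(str).to_numpy()).mean()
        assert abs(acc - params.p_correct_recognized) < 0.05

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            GeneratorParams(p_correct_recognized=1.2)

    def test_bias_incompatible_with_target(self):
        design, latents, params = self._design_latents(
            repeats=2, p_correct_recognized=0.05, report_bias_strength=0.9)
        with pytest.raises(ValueError, match="report_bias_strength"):
            simulate_behavior(design, latents, params, seed=0)

    def test_recognition_depends_more_on_g_as_b_g_grows(self):
        """Refitting the recognition model on the true latent recovers the
        ordering of the planted coupling strengths."""
        from sklearn.linear_model import LogisticRegression

        slopes = []
        for b_g in (0.3, 1.5):
            design, latents, params = self._design_latents(
                repeats=60, b0=0.0, b_real=0.0, b_g=b_g,
                b_match=0.0, b_match_scr=0.0)
            trials = simulate_behavior(design, latents, params, seed=8)
            y = (trials["recognition_report"] == "yes").to_numpy().astype(int)
            est = LogisticRegression(C=1e6).fit(latents.g[:, None], y)
            slopes.append(est.coef_[0, 0])
        assert slopes[1] > slopes[0] > 0


class TestPupil:
    def _pupil(self, **kw):
        spec = DesignSpec(repeats=2, n_sensors=8)
        design = generate_design(spec, seed=0)
        params = GeneratorParams(**kw)
        latents = simulate_latents(design, params, seed=1)
        return design, latents, params, spec

    def test_constant_trace_without_effects(self):
        design, latents, params, spec = self._pupil(
            pupil_gain=0.0, pupil_noise_sd=0.0, blink_rate=0.0)
        trace = simulate_pupil(design, latents, params, spec, seed=2)
        assert np.allclose(trace.diameter, 0.0)

    def test_noiseless_prestim_mean_equals_g(self):
        design, latents, params, spec = self._pupil(
            pupil_gain=1.0, pupil_noise_sd=0.0, blink_rate=0.0)
        trace = simulate_pupil(design, latents, params, spec, seed=2)
        t = trace.time
        for i, onset in enumerate(trace.onsets):
            sel = (t >= onset - spec.prestim_duration) & (t < onset)
            assert trace.diameter[sel].mean() == pytest.approx(latents.g[i], abs=1e-9)

    def test_blinks_detectable_at_published_threshold(self):
        design, latents, params, spec = self._pupil(
            pupil_noise_sd=0.05, blink_rate=6.0, blink_depth=5.0)
        trace = simulate_pupil(design, latents, params, spec, seed=3)
        blinks = detect_blinks(trace, drop_threshold=3.6)
        assert len(blinks) >= 1


class TestSession:
    def test_seed_reproducibility(self, tiny_spec):
        a = simulate_session(tiny_spec, seed=21)
        b = simulate_session(tiny_spec, seed=21)
        c = simulate_session(tiny_spec, seed=22)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        assert np.array_equal(a.epochs.values, b.epochs.values)
        assert np.array_equal(a.pupil.diameter, b.pupil.diameter)
        assert not a.trials["image_id"].equals(c.trials["image_id"])

    def test_without_pupil(self, tiny_spec):
        s = simulate_session(tiny_spec, seed=21, with_pupil=False)
        full = simulate_session(tiny_spec, seed=21)
        assert s.pupil is None
        assert np.array_equal(s.epochs.values, full.epochs.values)

    def test_io_roundtrip(self, tiny_spec, tmp_path):
        session = simulate_session(tiny_spec, seed=31)
        write_session(session, tmp_path / "sess")
        trials, epochs, pupil, manifest = read_session(tmp_path / "sess")
        assert manifest["seed"] == 31
        assert len(trials) == len(session.trials)
        assert list(trials["image_id"]) == list(session.trials["image_id"])
        assert np.allclose(epochs.values, session.epochs.values)
        assert np.allclose(pupil.diameter, session.pupil.diameter, atol=1e-5)
        assert isinstance(pupil, PupilTrace)
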