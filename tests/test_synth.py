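"""Generative contracts of the synthetic cohort module."""

import numpy as np
import pytest

from emgdisc.dataio import segment_by_indices
from emgdisc.features import WindowingConfig, featurize_template
from emgdisc.synth import (
    CohortConfig,
    Condition,
    GroupEffect,
    default_gesture_specs,
    enumerate_manifest,
    generate_cohort,
    inject_confound,
    make_user_profile,
    out_of_set_gesture_specs,
    synthesize_recording,
    _envelope,
    _rng,
)


def _cfg(**kw):
    base = dict(n_users=4, n_reps=3, seed=9)
    base.update(kw)
    return CohortConfig(**base)


class TestUserProfiles:
    def test_zero_dispersion_gives_unit_parameters(self):
        cfg = _cfg(inter_user_gain_sd=0.0, speed_factor_sd=0.0, rotation_sd=0.0)
        for i in range(cfg.n_users):
            p = make_user_profile(cfg, i)
            np.testing.assert_array_equal(p.channel_gains, np.ones(8))
            assert p.speed_factor == 1.0
            assert p.channel_rotation == 0.0

    def test_determinism(self):
        cfg = _cfg()
        a = make_user_profile(cfg, 2)
        b = make_user_profile(cfg, 2)
        np.testing.assert_array_equal(a.channel_gains, b.channel_gains)
        assert a.speed_factor == b.speed_factor
        assert a.demographics == b.demographics

    def test_demographic_proportions(self):
        # empirical share of the majority value within 3 binomial SEs
        cfg = _cfg(n_users=10_000,
                   demographic_mix={"group": {"A": 0.66, "B": 0.34}})
        share = np.mean([
            make_user_profile(cfg, i).demographics["group"] == "A"
            for i in range(cfg.n_users)
        ])
        se = np.sqrt(0.66 * 0.34 / cfg.n_users)
        assert abs(share - 0.66) < 3 * se

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to"):
            _cfg(demographic_mix={"group": {"A": 0.5, "B": 0.4}})

    def test_group_effects_shift_duration(self):
        cfg = _cfg(
            n_users=400,
            demographic_mix={"group": {"A": 0.5, "B": 0.5}},
            group_effects={"group": {"B": GroupEffect(duration_scale=1.3)}},
            speed_factor_sd=0.1,
        )
        speeds = {"A": [], "B": []}
        for i in range(cfg.n_users):
            p = make_user_profile(cfg, i)
            speeds[p.demographics["group"]].append(p.speed_factor)
        ratio = np.mean(speeds["B"]) / np.mean(speeds["A"])
        assert ratio == pytest.approx(1.3, rel=0.05)


class TestRecordings:
    def test_rest_is_pure_baseline_noise(self):
        cfg = _cfg(rest_sigma=2.0)
        profile = make_user_profile(cfg, 0)
        rest = [g for g in cfg.gesture_specs if g.gesture_id == "rest"][0]
        rec = synthesize_recording(profile, rest, config=cfg,
                                   rng=np.random.default_rng(0))
        sd = rec.samples.astype(float).std(axis=1)
        # quantized N(0, 2) noise over 1000 samples per channel
        assert np.all(np.abs(sd - 2.0) < 0.35)

    def test_integer_range_and_shape(self):
        cfg = _cfg()
        rec = synthesize_recording(
            make_user_profile(cfg, 1), cfg.gesture_specs[4], config=cfg,
            rng=np.random.default_rng(1),
        )
        assert rec.samples.shape == (8, 1000)
        assert rec.samples.dtype == np.int8
        assert 0 <= rec.start_index < rec.end_index <= 1000

    def test_windowed_rms_tracks_gain_times_envelope(self):
        """Per-window RMS over the active segment follows gain * envelope."""
        cfg = _cfg(rest_sigma=0.5)
        profile = make_user_profile(cfg, 0)
        spec = cfg.gesture_specs[3]  # hand_open: broad activation
        rel_errs = []
        for rep in range(50):
            rec = synthesize_recording(
                profile, spec, config=cfg, rep=rep,
                rng=np.random.default_rng(1000 + rep),
            )
            t = segment_by_indices(rec)
            env = _envelope(spec, profile, t.length)
            expected = profile.channel_gains[:, None] * env
            L = 25
            seq = featurize_template(t.samples, WindowingConfig(L, L), "RMS")
            for w in range(len(seq)):
                exp_rms = np.sqrt(
                    np.mean(expected[:, w * L : (w + 1) * L] ** 2, axis=1)
                    + cfg.rest_sigma ** 2
                )
                mask = exp_rms > 5  # compare where activation dominates
                if mask.any():
                    rel_errs.append(np.abs(
                        seq.values[w, : 8][mask] - exp_rms[mask]
                    ) / exp_rms[mask])
        assert np.mean(np.concatenate(rel_errs)) < 0.15

    def test_speed_multiplier_scales_duration(self):
        cfg = _cfg(speed_factor_sd=0.0)
        profile = make_user_profile(cfg, 0)
        spec = cfg.gesture_specs[1]
        lengths = {1.0: [], 1.5: []}
        for speed in lengths:
            cond = Condition(name=f"s{speed}", speed=speed)
            for rep in range(200):
                rec = synthesize_recording(
                    profile, spec, cond, config=cfg, rep=rep,
                    rng=np.random.default_rng(2000 + rep),
                )
                lengths[speed].append(rec.end_index - rec.start_index)
        ratio = np.mean(lengths[1.5]) / np.mean(lengths[1.0])
        assert ratio == pytest.approx(1.5, rel=0.05)

    def test_duration_distribution_mean(self):
        # mean active length within 3 SEs of nominal mean x mean speed factor
        cfg = _cfg(n_users=500, speed_factor_sd=0.15)
        spec = cfg.gesture_specs[2]
        lengths, speeds = [], []
        for i in range(cfg.n_users):
            p = make_user_profile(cfg, i)
            speeds.append(p.speed_factor)
            rec = synthesize_recording(
                p, spec, config=cfg, rng=np.random.default_rng(3000 + i)
            )
            lengths.append((rec.end_index - rec.start_index) / cfg.sampling_rate)
        expected = spec.nominal_duration_mean * np.mean(speeds)
        se = np.std(lengths) / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - expected) < 3 * se

    def test_overlong_gesture_rejected(self):
        cfg = _cfg(recording_length=1.0)
        profile = make_user_profile(cfg, 0)
        spec = default_gesture_specs()[1]
        with pytest.raises(ValueError, match="recording length"):
            synthesize_recording(profile, spec,
                                 Condition(name="slow", speed=5.0),
                                 config=cfg, rng=np.random.default_rng(0))


class TestConfounds:
    def _profile_with_days(self):
        cfg = _cfg(conditions=[Condition(), Condition("day2", day=2)],
                   day_effect_sd=0.2)
        return cfg, make_user_profile(cfg, 0)

    def test_identity_perturbation(self):
        cfg, p = self._profile_with_days()
        p.day_effects[2][...] = 1.0
        q = inject_confound(p, "day", 2)
        np.testing.assert_array_equal(q.channel_gains, p.channel_gains)

    def test_idempotence_relative_to_base(self):
        cfg, p = self._profile_with_days()
        once = inject_confound(p, "day", 2)
        # perturbations are absolute per level: re-deriving from the base
        # profile gives the same gains as the first application
        again = inject_confound(p, "day", 2)
        np.testing.assert_array_equal(once.channel_gains, again.channel_gains)
        # base profile untouched
        assert not np.allclose(once.channel_gains, p.channel_gains)

    def test_unknown_kind_or_level(self):
        _, p = self._profile_with_days()
        with pytest.raises(ValueError, match="unknown confound"):
            inject_confound(p, "weather", 2)
        with pytest.raises(ValueError, match="level"):
            inject_confound(p, "day", 9)

    def test_day_effect_dispersion(self):
        cfg = _cfg(n_users=500,
                   conditions=[Condition(), Condition("day2", day=2)],
                   day_effect_sd=0.2)
        diffs = []
        for i in range(cfg.n_users):
            p = make_user_profile(cfg, i)
            diffs.extend(np.log(p.day_effects[2]))
        assert np.std(diffs) == pytest.approx(0.2, rel=0.1)


class TestCohorts:
    def test_counting(self):
        cfg = _cfg(n_users=2, n_reps=3)
        cohort = generate_cohort(cfg)
        assert len(cohort.recordings) == 2 * 3 * 6

    def test_dry_run_enumerates_training_scale(self):
        # 306 users x 50 reps x 6 gestures: the full-scale training bank
        cfg = CohortConfig(n_users=306, n_reps=50, seed=0)
        assert len(enumerate_manifest(cfg)) == 91_800

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = _cfg(n_users=2, n_reps=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg, out_dir=d1)
        generate_cohort(cfg, out_dir=d2)
        f1 = sorted(p.relative_to(d1) for p in d1.rglob("*.csv"))
        f2 = sorted(p.relative_to(d2) for p in d2.rglob("*.csv"))
        assert f1 == f2
        for rel in f1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
        assert (d1 / "manifest.json").read_bytes() == (
            d2 / "manifest.json"
        ).read_bytes()

    def test_out_of_set_flagging(self):
        specs = default_gesture_specs() + out_of_set_gesture_specs()
        cfg = _cfg(gesture_specs=specs)
        assert {g.gesture_id for g in cfg.out_of_set_specs} == {
            "finger_snap", "thumbs_up", "index_point", "finger_gun"
        }
        assert len(cfg.in_set_specs) == 6


def test_separability_control():
    """Zero user variability: 1NN-DTW on RMS gets a perfect LORO score."""
    from emgdisc.evaluate import run_split, SplitSpec, cohort_templates

    cfg = CohortConfig(
        n_users=1, n_reps=10,
        inter_user_gain_sd=0, speed_factor_sd=0, rotation_sd=0, seed=4,
    )
    templates = cohort_templates(generate_cohort(cfg))
    report = run_split("dtw", templates, SplitSpec("leave_one_repetition_out"))
    assert report.accuracy == 1.0


def test_cohort_config_from_yaml(tmp_path):
    cfg_file = tmp_path / "cohort.yaml"
    cfg_file.write_text(
        "n_users: 3\n"
        "n_reps: 2\n"
        "seed: 11\n"
        "gesture_specs: default+out_of_set\n"
        "inter_user_gain_sd: 0.2\n"
        "conditions:\n"
        "  - {name: base}\n"
        "  - {name: slow, speed: 1.5}\n"
        "group_effects:\n"
        "  group:\n"
        "    B: {duration_scale: 1.2, extra_rotation: 0.5}\n"
    )
    cfg = CohortConfig.from_file(cfg_file)
    assert cfg.n_users == 3
    assert len(cfg.gesture_specs) == 10
    assert len(cfg.out_of_set_specs) == 4
    assert cfg.conditions[1].speed == 1.5
    assert cfg.group_effects["group"]["B"].duration_scale == 1.2
    # the file-built config generates identically to the equivalent in-code one
    code_cfg = CohortConfig(
        n_users=3, n_reps=2, seed=11,
        gesture_specs=default_gesture_specs() + out_of_set_gesture_specs(),
        inter_user_gain_sd=0.2,
        conditions=[Condition(), Condition("slow", speed=1.5)],
        group_effects={"group": {"B": GroupEffect(1.2, 0.5)}},
    )
    a = generate_cohort(cfg)
    b = generate_cohort(code_cfg)
    assert all(
        np.array_equal(x.samples, y.samples)
        for x, y in zip(a.recordings, b.recordings)
    )
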