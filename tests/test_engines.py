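"""Engine arithmetic, oracles, and streaming-vs-batch equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtnf.design import FeatureMask
from rtnf.engines import (BaselineTracker, ConnectivityEngine, DecoderModel,
                          RoiEngine, SvmFeedbackEngine, activation_map,
                          build_examples, cumulative_accuracy, decode_bin,
                          sigmoid_weights, sliding_correlation,
                          thermometer_scale, train_decoder)
from rtnf.runner import (_replay_connectivity, _replay_roi, _replay_svm,
                         SessionConfig)

SHAPE = (6, 6, 4)


def _vol(value, rng=None):
    base = np.full(SHAPE, float(value))
    if rng is not None:
        base += rng.standard_normal(SHAPE)
    return base


class TestBaselineTracker:
    def test_constant_block_mean(self):
        tr = BaselineTracker("REST")
        for i in range(5):
            tr.update(i, _vol(100.0), "REST", kept=True)
        tr.update(5, _vol(101.0), "TASK", kept=True)
        np.testing.assert_allclose(tr.state.mean, 100.0)
        assert tr.state.n_used == 5

    def test_discarded_volume_excluded_from_mean(self):
        tr = BaselineTracker("REST")
        tr.update(0, _vol(100.0), "REST", kept=True)
        tr.update(1, _vol(500.0), "REST", kept=False)   # motion spike
        tr.update(2, _vol(102.0), "REST", kept=True)
        tr.update(3, _vol(0.0), "TASK", kept=True)
        np.testing.assert_allclose(tr.state.mean, 101.0)
        assert tr.state.n_used == 2

    def test_second_block_replaces_first(self):
        tr = BaselineTracker("REST")
        for i, (v, lab) in enumerate([(100, "REST"), (0, "TASK"),
                                      (200, "REST"), (0, "TASK")]):
            tr.update(i, _vol(v), lab, kept=True)
        np.testing.assert_allclose(tr.state.mean, 200.0)
        assert tr.state.block_start == 2

    def test_fully_discarded_block_retains_previous_state(self):
        tr = BaselineTracker("REST")
        tr.update(0, _vol(100.0), "REST", kept=True)
        tr.update(1, _vol(0.0), "TASK", kept=True)
        tr.update(2, _vol(999.0), "REST", kept=False)
        tr.update(3, _vol(0.0), "TASK", kept=True)
        np.testing.assert_allclose(tr.state.mean, 100.0)
        assert len(tr.warnings) == 1


class TestRoiFeedback:
    def _engine(self, **kw):
        mask = np.zeros(SHAPE, dtype=bool)
        mask[2:4, 2:4, 1:3] = True
        return RoiEngine(mask, "REST", discard_initial=0, **kw), mask

    def test_printed_ratio_arithmetic(self):
        """baseline 100, current 101, full scale 2% -> raw 1%, level 50."""
        eng, _ = self._engine(r_max=0.02)
        for i in range(3):
            eng.update(i, _vol(100.0), "REST", True)
        s = eng.update(3, _vol(101.0), "TASK", True)
        assert s.raw == pytest.approx(0.01)
        assert s.level == pytest.approx(50.0)

    def test_null_change_gives_zero(self):
        eng, _ = self._engine()
        for i in range(3):
            eng.update(i, _vol(100.0), "REST", True)
        s = eng.update(3, _vol(100.0), "TASK", True)
        assert s.raw == 0.0
        assert s.level == 0.0

    def test_saturation_clips_at_100(self):
        eng, _ = self._engine(r_max=0.02)
        for i in range(3):
            eng.update(i, _vol(100.0), "REST", True)
        s = eng.update(3, _vol(104.0), "TASK", True)
        assert s.raw == pytest.approx(0.04)
        assert s.level == 100.0

    def test_zero_baseline_mean_rejected(self):
        eng, _ = self._engine()
        for i in range(3):
            eng.update(i, _vol(0.0), "REST", True)
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            eng.update(3, _vol(1.0), "TASK", True)


class TestActivationMap:
    def test_identical_to_baseline_gives_zero_map(self):
        base = _vol(100.0)
        np.testing.assert_array_equal(activation_map(base, base), 0.0)

    def test_single_voxel_injection(self):
        base = _vol(100.0)
        cur = base.copy()
        cur[3, 3, 2] *= 1.05
        m = activation_map(cur, base)
        assert m[3, 3, 2] == pytest.approx(0.05)
        assert np.abs(np.delete(m.ravel(), np.ravel_multi_index(
            (3, 3, 2), SHAPE))).max() == 0.0

    def test_thresholded_cluster_size_matches_injection(self):
        base = _vol(100.0)
        cur = base.copy()
        cur[1:4, 1:3, 1:3] *= 1.03     # 3*2*2 = 12 voxel cluster
        m = activation_map(cur, base)
        assert (np.abs(m) >= 0.02).sum() == 12

    def test_zero_baseline_voxels_masked(self):
        base = _vol(100.0)
        base[0, 0, 0] = 0.0
        cur = base + 1.0
        assert activation_map(cur, base)[0, 0, 0] == 0.0


class TestSlidingCorrelation:
    def test_perfect_correlation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 2.5])
        assert sliding_correlation(a, a) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 2.5])
        assert sliding_correlation(a, -a) == pytest.approx(-1.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_matches_two_pass_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 16))
        a = rng.standard_normal(L)
        b = rng.standard_normal(L)
        oracle = np.corrcoef(a, b)[0, 1]
        assert abs(sliding_correlation(a, b) - oracle) <= 1e-12

    def test_zero_variance_undefined(self):
        assert np.isnan(sliding_correlation(np.ones(5), np.arange(5.0)))


class TestThermometerScale:
    def test_weights_strictly_decreasing_logistic(self):
        w = sigmoid_weights(10)
        assert (np.diff(w) < 0).all()
        j = np.arange(10.0)
        np.testing.assert_allclose(w, 1.0 / (1.0 + np.exp(j - 5.0)))

    def test_constant_history_degenerate(self):
        assert thermometer_scale([0.5] * 8) is None

    def test_midline_between_bounds_and_level_endpoints(self):
        rho = [0.1, 0.3, 0.2, 0.5, 0.4, 0.6, 0.3, 0.2, 0.4, 0.5]
        midline, lower, upper = thermometer_scale(rho)
        assert lower < midline < upper
        sd = np.std(np.asarray(rho), ddof=1)
        assert upper - lower == pytest.approx(2 * sd)
        # ρ at the bounds maps to the scale endpoints
        level = np.clip((upper - lower) / (upper - lower), 0, 1) * 100
        assert level == 100.0

    def test_midline_weighs_recent_values_more(self):
        # history ending high -> midline above the plain mean
        rho = [0.0] * 8 + [0.8, 0.8]
        midline, _, _ = thermometer_scale(rho)
        assert midline > np.mean(rho)


class TestExamplesAndDecoder:
    def _mask(self):
        m = np.zeros(SHAPE, dtype=bool)
        m[1:5, 1:5, 1:3] = True
        return FeatureMask.from_bool(m)

    def _session(self, rng, n_rep=3, block=8, amp=0.3, window=3):
        """Two-class voxel patterns with disjoint active regions."""
        mask = self._mask()
        labels, vols = [], []
        for r in range(n_rep):
            for lab, sign in (("REST", 0), ("A", 1), ("REST", 0), ("B", -1)):
                for _ in range(block):
                    v = _vol(100.0, rng)
                    if sign > 0:
                        v[1:3, 1:3, 1:3] += amp * 100
                    elif sign < 0:
                        v[3:5, 3:5, 1:3] += amp * 100
                    vols.append(v)
                    labels.append(lab)
        kept = [True] * len(vols)
        return vols, labels, kept, mask

    def test_window_one_gives_single_volume_examples(self, rng):
        vols, labels, kept, mask = self._session(rng, n_rep=1)
        X, y, idx = build_examples(vols, labels, kept, mask, "REST",
                                   window=1, discard_initial=0)
        assert X.shape[1] == len(mask)
        # every non-baseline volume after the first completed baseline block
        assert len(y) == 16

    def test_block_example_count(self, rng):
        """A 22-volume block with window 3 yields 20 examples."""
        labels = ["REST"] * 10 + ["A"] * 22 + ["REST"] * 10 + ["A"] * 22
        vols = [_vol(100.0, rng) for _ in labels]
        kept = [True] * len(labels)
        X, y, idx = build_examples(vols, labels, kept, self._mask(), "REST",
                                   window=3, discard_initial=0)
        assert len(y) == 40

    def test_discarded_volume_skips_touching_windows(self, rng):
        labels = ["REST"] * 6 + ["A"] * 10
        vols = [_vol(100.0, rng) for _ in labels]
        kept = [True] * len(labels)
        kept[10] = False    # mid-block discard
        _, y_all, idx_all = build_examples(vols, labels, kept, self._mask(),
                                           "REST", window=3,
                                           discard_initial=0)
        # windows ending at 10, 11, 12 all touch the discarded volume
        assert set(idx_all) == {8, 9, 13, 14, 15}

    def test_separable_classes_train_to_100_percent(self, rng):
        vols, labels, kept, mask = self._session(rng)
        X, y, _ = build_examples(vols, labels, kept, mask, "REST",
                                 window=3, discard_initial=0)
        model = train_decoder(X, y, mask)
        assert model.training_accuracy == 100.0
        assert model.classes == ("A", "B")
        assert len(model.w) == len(mask)

    def test_label_flip_negates_hyperplane(self, rng):
        vols, labels, kept, mask = self._session(rng)
        X, y, _ = build_examples(vols, labels, kept, mask, "REST",
                                 window=3, discard_initial=0)
        m1 = train_decoder(X, y, mask)
        swap = {"A": "B", "B": "A"}
        m2 = train_decoder(X, [swap[l] for l in y], mask)
        np.testing.assert_allclose(m1.w, -m2.w, atol=1e-6)
        assert m1.b == pytest.approx(-m2.b, abs=1e-6)

    def test_held_out_decoding_accuracy(self, rng):
        vols, labels, kept, mask = self._session(rng, n_rep=2)
        X, y, _ = build_examples(vols, labels, kept, mask, "REST",
                                 window=3, discard_initial=0)
        model = train_decoder(X, y, mask)
        vols2, labels2, kept2, _ = self._session(np.random.default_rng(77),
                                                 n_rep=2)
        X2, y2, _ = build_examples(vols2, labels2, kept2, mask, "REST",
                                   window=3, discard_initial=0)
        pred = [model.predict(x) for x in X2]
        acc = 100.0 * np.mean([p == t for p, t in zip(pred, y2)])
        assert acc >= 95.0

    def test_decision_bins(self, rng):
        vols, labels, kept, mask = self._session(rng)
        X, y, _ = build_examples(vols, labels, kept, mask, "REST",
                                 window=3, discard_initial=0)
        model = train_decoder(X, y, mask)
        pos = model.classes[1]
        neg = model.classes[0]
        # on the hyperplane -> boundary bin (first bin of the upper half)
        assert decode_bin(0.0, pos, model, n_bins=5) == 5
        # full-scale decision toward the cued class -> smoothest figure
        assert decode_bin(model.d_max, pos, model, n_bins=5) == 9
        assert decode_bin(-model.d_max, neg, model, n_bins=5) == 9
        # confidently the wrong class -> most distorted figure
        assert decode_bin(-model.d_max, pos, model, n_bins=5) == 0

    def test_support_vector_sign_matches_label(self, rng):
        vols, labels, kept, mask = self._session(rng)
        X, y, _ = build_examples(vols, labels, kept, mask, "REST",
                                 window=3, discard_initial=0)
        model = train_decoder(X, y, mask)
        for x, lab in zip(X[:10], y[:10]):
            d = model.decision(x)
            assert (d >= 0) == (lab == model.classes[1])

    def test_single_class_rejected(self, rng):
        mask = self._mask()
        X = rng.standard_normal((6, len(mask)))
        with pytest.raises(ValueError, match="2 classes"):
            train_decoder(X, ["A"] * 6, mask)

    def test_model_json_round_trip(self, tmp_path, rng):
        vols, labels, kept, mask = self._session(rng, n_rep=1)
        X, y, _ = build_examples(vols, labels, kept, mask, "REST",
                                 window=3, discard_initial=0)
        model = train_decoder(X, y, mask)
        model.save(tmp_path / "m.json")
        back = DecoderModel.load(tmp_path / "m.json")
        np.testing.assert_allclose(back.w, model.w)
        assert back.classes == model.classes
        assert back.d_max == model.d_max
        x = X[0]
        assert back.decision(x) == pytest.approx(model.decision(x))

    def test_weight_map_supported_on_mask_only(self, rng):
        vols, labels, kept, mask = self._session(rng, n_rep=1)
        X, y, _ = build_examples(vols, labels, kept, mask, "REST",
                                 window=3, discard_initial=0)
        model = train_decoder(X, y, mask)
        grid = model.weight_volume()
        outside = np.ones(SHAPE, dtype=bool)
        outside.ravel()[mask.indices] = False
        assert np.abs(grid[outside]).max() == 0.0


class TestCumulativeAccuracy:
    def test_basic_fractions(self):
        assert cumulative_accuracy(4, 4) == 100.0
        assert cumulative_accuracy(3, 4) == 75.0
        with pytest.raises(ValueError):
            cumulative_accuracy(0, 0)


class TestStreamingBatchEquivalence:
    """The streamed engines and the independent offline replay agree to
    near machine precision on the identical kept-volume sequence."""

    def _arrays(self, rng, n=60, spikes=()):
        labels = [("REST" if (i // 10) % 2 == 0 else "TASK")
                  for i in range(n)]
        vols = []
        for i in range(n):
            v = _vol(100.0, rng)
            if labels[i] == "TASK":
                v[2:4, 2:4, 1:3] *= 1.02
            vols.append(v)
        kept = [i not in spikes for i in range(n)]
        return vols, labels, kept

    def _config(self, mode, **kw):
        defaults = dict(mode=mode, rfi="x", design="x", n_volumes=60,
                        baseline_name="REST", discard_initial=5)
        defaults.update(kw)
        return SessionConfig(**defaults)

    @pytest.mark.parametrize("spikes", [(), (17, 18, 33)])
    def test_roi_engine_matches_replay(self, rng, spikes):
        vols, labels, kept = self._arrays(rng, spikes=spikes)
        mask = np.zeros(SHAPE, dtype=bool)
        mask[2:4, 2:4, 1:3] = True
        eng = RoiEngine(mask, "REST", discard_initial=5)
        for i, (v, lab, k) in enumerate(zip(vols, labels, kept)):
            eng.update(i, v, lab, k)
        streamed = np.full(len(vols), np.nan)
        for s in eng.samples:
            if not s.frozen:
                streamed[s.index] = s.raw
        replayed = _replay_roi(vols, labels, kept, mask, self._config("roi"))
        both = np.isfinite(streamed) & np.isfinite(replayed)
        assert both.sum() > 20
        np.testing.assert_allclose(streamed[both], replayed[both],
                                   atol=1e-10)
        assert np.array_equal(np.isfinite(streamed), np.isfinite(replayed))

    @pytest.mark.parametrize("spikes", [(), (22, 23)])
    def test_connectivity_engine_matches_replay(self, rng, spikes):
        vols, labels, kept = self._arrays(rng, spikes=spikes)
        a = np.zeros(SHAPE, dtype=bool)
        b = np.zeros(SHAPE, dtype=bool)
        a[1:3, 1:3, 1:3] = True
        b[3:5, 3:5, 1:3] = True
        eng = ConnectivityEngine(a, b, window=10, discard_initial=5)
        for i, (v, lab, k) in enumerate(zip(vols, labels, kept)):
            eng.update(i, v, lab, k)
        streamed = np.full(len(vols), np.nan)
        for s in eng.samples:
            if not s.frozen:
                streamed[s.index] = s.raw
        replayed = _replay_connectivity(
            vols, labels, kept, a, b,
            self._config("connectivity", roi_a="a", roi_b="b"))
        both = np.isfinite(streamed) & np.isfinite(replayed)
        assert both.sum() > 20
        np.testing.assert_allclose(streamed[both], replayed[both],
                                   atol=1e-12)

    def test_svm_engine_matches_replay(self, rng):
        vols, labels, kept = self._arrays(rng, n=80, spikes=(37,))
        mask = np.zeros(SHAPE, dtype=bool)
        mask[1:5, 1:5, 1:3] = True
        fm = FeatureMask.from_bool(mask)
        X, y, _ = build_examples(vols, labels, kept, fm, "REST", window=3,
                                 discard_initial=5)
        y = ["TASK" if i % 2 else "ALT" for i in range(len(y))]  # two classes
        model = train_decoder(np.asarray(X), y, fm, window=3)
        eng = SvmFeedbackEngine(model, "REST", discard_initial=5)
        for i, (v, lab, k) in enumerate(zip(vols, labels, kept)):
            eng.update(i, v, lab, k)
        streamed = np.full(len(vols), np.nan)
        for s in eng.samples:
            if not s.frozen:
                streamed[s.index] = s.raw
        cfg = self._config("svm_feedback", n_volumes=80)
        replayed = _replay_svm(vols, labels, kept, model, cfg)
        both = np.isfinite(streamed) & np.isfinite(replayed)
        assert both.sum() > 10
        np.testing.assert_allclose(streamed[both], replayed[both],
                                   atol=1e-10)
        assert np.array_equal(np.isfinite(streamed), np.isfinite(replayed))
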