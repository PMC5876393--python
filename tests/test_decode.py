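"""Shrinkage LDA, fold normalization, cross-validation schemes, weights."""

import numpy as np
import pytest

from fnirsdecode import (normalize_fold, fit_lda, balanced_accuracy,
                         intra_block_loto, inter_block_cross, inter_block_loto,
                         aggregate_weights, TrialMatrix, PAIRS)
from fnirsdecode.decode import ledoit_wolf_gamma

from _reference import lda_explicit, loto_predictions_explicit


def _tm(values, labels, conditions=None, pid="p0"):
    values = np.asarray(values, dtype=float)
    if conditions is None:
        conditions = ["passive"] * len(labels)
    return TrialMatrix(values=values, labels=list(labels),
                       conditions=list(conditions),
                       feature_names=[f"c{i}_hbo" for i in
                                      range(values.shape[1])],
                       participant_id=pid)


class TestNormalizeFold:
    def test_two_point_column_sample_sd_convention(self):
        T = np.array([[1.0], [3.0]])
        t = np.array([[2.0]])
        Tn, tn, stats = normalize_fold(T, t)
        # sample (n-1) sd of [1, 3] is sqrt(2)
        assert np.allclose(Tn[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert tn[0, 0] == pytest.approx(0.0)
        assert stats.sd[0] == pytest.approx(np.sqrt(2))

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(0)
        T = rng.standard_normal((50, 6)) * 3 + 1
        Tn, _, _ = normalize_fold(T, T[:2])
        assert np.allclose(Tn.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Tn.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_test_rows_never_influence_stats(self):
        rng = np.random.default_rng(1)
        T = rng.standard_normal((10, 4))
        t1 = rng.standard_normal((3, 4))
        t2 = rng.standard_normal((3, 4)) * 100
        _, _, s1 = normalize_fold(T, t1)
        _, _, s2 = normalize_fold(T, t2)
        assert np.array_equal(s1.mean, s2.mean)
        assert np.array_equal(s1.sd, s2.sd)

    def test_constant_feature_guarded(self):
        T = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        Tn, tn, stats = normalize_fold(T, T[:1])
        assert stats.degenerate == (1,)
        assert np.all(np.isfinite(Tn)) and np.all(np.isfinite(tn))


class TestFitLda:
    def test_identity_covariance_gives_mean_difference_direction(self):
        rng = np.random.default_rng(2)
        XA = rng.standard_normal((200, 2)) + [0, 0]
        XB = rng.standard_normal((200, 2)) + [10, 0]
        X = np.vstack([XA, XB])
        y = ["A"] * 200 + ["B"] * 200
        model = fit_lda(X, y, ("A", "B"), gamma=1.0)
        direction = model.w / np.linalg.norm(model.w)
        diff = XB.mean(0) - XA.mean(0)
        diff /= np.linalg.norm(diff)
        assert abs(direction @ diff) > 1 - 1e-6

    def test_full_shrinkage_parallel_to_mean_difference(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 5)) @ rng.standard_normal((5, 5))
        y = ["A"] * 15 + ["B"] * 15
        model = fit_lda(X, y, ("A", "B"), gamma=1.0)
        diff = X[15:].mean(0) - X[:15].mean(0)
        cos = model.w @ diff / (np.linalg.norm(model.w) * np.linalg.norm(diff))
        assert cos == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("gamma", [0.2, 0.5, 0.9])
    def test_matches_explicit_solve_reference(self, gamma):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X = rng.standard_normal((6, 3))
            y = ["A", "A", "A", "B", "B", "B"]
            model = fit_lda(X, y, ("A", "B"), gamma=gamma)
            w_ref, b_ref = lda_explicit(X, y, ("A", "B"), gamma)
            assert np.allclose(model.w, w_ref, atol=1e-9)
            assert model.b == pytest.approx(b_ref, abs=1e-9)
            assert model.predict(X) == [
                "B" if d > 0 else "A"
                for d in X @ w_ref + b_ref]

    def test_singular_covariance_at_zero_gamma_raises(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 10))  # n < p
        y = ["A"] * 3 + ["B"] * 3
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fit_lda(X, y, ("A", "B"), gamma=0.0)

    def test_missing_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="present"):
            fit_lda(X, ["A"] * 4, ("A", "B"))

    def test_ledoit_wolf_gamma_bounds(self):
        rng = np.random.default_rng(6)
        g_small = ledoit_wolf_gamma(rng.standard_normal((5, 64)))
        # plenty of data, strongly anisotropic truth: little shrinkage
        g_large = ledoit_wolf_gamma(
            rng.standard_normal((5000, 3)) * np.array([1.0, 3.0, 9.0]))
        assert 0.0 <= g_small <= 1.0
        assert g_large < 0.1 < g_small


class TestBalancedAccuracy:
    @pytest.mark.parametrize("true,pred,expected", [
        (["A", "A", "B", "B"], ["A", "A", "B", "B"], (100, 100, 100)),
        (["A", "A", "B", "B"], ["A", "A", "A", "A"], (100, 0, 50)),
        (["A"] * 5 + ["B"] * 10,
         ["A"] * 4 + ["B"] + ["B"] * 8 + ["A"] * 2, (80, 80, 80)),
    ])
    def test_examples(self, true, pred, expected):
        assert balanced_accuracy(true, pred, "A", "B") == pytest.approx(expected)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            balanced_accuracy(["A", "C"], ["A", "A"], "A", "B")


class TestLotoSchemes:
    def test_fold_predictions_match_explicit_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            values = rng.standard_normal((8, 4))
            labels = ["positive"] * 3 + ["neutral"] * 5
            tm = _tm(values, labels)
            res = intra_block_loto(tm, ("positive", "neutral"), gamma=0.5)
            ref = loto_predictions_explicit(values, labels,
                                            ("positive", "neutral"), 0.5)
            assert res.y_pred == ref

    def test_strong_effect_recovered(self, montage):
        """Mean accuracy over a few participants at default study
        conditions recovers the planted valence effect."""
        from fnirsdecode.io import RunConfig, simulate_participant
        cfg = RunConfig(seed=11)
        bals = []
        for p in range(8):
            mats = simulate_participant(cfg, p, montage)
            res = intra_block_loto(mats["passive"], ("positive", "neutral"))
            bals.append(res.balanced)
        assert res.fold_weights.shape == (15, 64)
        assert np.mean(bals) > 70.0

    def test_scale_invariance_of_predictions(self, passive_matrix):
        scaled = _tm(passive_matrix.values * 1e4, passive_matrix.labels)
        base = _tm(passive_matrix.values, passive_matrix.labels)
        r1 = intra_block_loto(base, ("negative", "neutral"), gamma=0.5)
        r2 = intra_block_loto(scaled, ("negative", "neutral"), gamma=0.5)
        assert r1.y_pred == r2.y_pred

    def test_duplicated_features_leave_predictions_unchanged(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal((15, 6))
        labels = ["positive"] * 5 + ["neutral"] * 10
        r1 = intra_block_loto(_tm(values, labels), ("positive", "neutral"),
                              gamma=0.5)
        doubled = np.hstack([values, values])
        r2 = intra_block_loto(_tm(doubled, labels), ("positive", "neutral"),
                              gamma=0.5)
        assert r1.y_pred == r2.y_pred

    def test_minimum_trial_count(self):
        tm = _tm(np.zeros((3, 2)), ["positive", "neutral", "neutral"])
        with pytest.raises(ValueError, match="at least 4"):
            intra_block_loto(tm, ("positive", "neutral"))

    def test_label_permutation_null_calibration(self, passive_matrix):
        """Permuting labels of a real synthetic matrix gives ~50% mean."""
        rng = np.random.default_rng(9)
        sub = passive_matrix.select(labels={"positive", "neutral"})
        bals = []
        for _ in range(1000):
            perm = rng.permutation(sub.labels)
            tm = _tm(sub.values, list(perm))
            bals.append(intra_block_loto(tm, ("positive", "neutral"),
                                         gamma=0.5).balanced)
        assert 48.0 <= np.mean(bals) <= 52.0


class TestInterBlock:
    def test_train_equals_test_is_resubstitution(self, passive_matrix):
        res = inter_block_cross(passive_matrix, passive_matrix,
                                ("positive", "neutral"), gamma=0.5)
        sub = passive_matrix.select(labels={"positive", "neutral"})
        Tn, tn, _ = normalize_fold(sub.values, sub.values)
        model = fit_lda(Tn, sub.labels, ("positive", "neutral"), gamma=0.5)
        _, _, bal = balanced_accuracy(sub.labels, model.predict(tn),
                                      "positive", "neutral")
        assert res.balanced == pytest.approx(bal)

    @staticmethod
    def _quiet_block(montage, spec, sched_seed, sim_seed, condition="passive"):
        from fnirsdecode import NoiseSpec, preprocess_block, build_trial_matrix
        from fnirsdecode.synthdata import (make_schedule,
                                           simulate_concentrations,
                                           concentrations_to_od)
        noise = NoiseSpec(white_sd=0.05, cardiac=(1.2, 0.02),
                          respiratory=(0.3, 0.02), mayer=(0.1, 0.02))
        sched = make_schedule(condition, sched_seed)
        conc = simulate_concentrations(sched, montage, spec, noise,
                                       seed=sim_seed)
        return build_trial_matrix(preprocess_block(concentrations_to_od(conc)),
                                  "p0", montage.channel_names())

    def test_shared_pattern_transfers_across_blocks(self, montage):
        """Blocks with identical generative structure transfer well.

        Mean over several simulated block pairs at high SNR with full
        shrinkage (the stable choice at m = 15, p = 64); the ceiling
        is set by band-pass and hemodynamic-overlap structure, not by
        sensor noise.
        """
        from fnirsdecode import EffectSpec
        spec = EffectSpec.default("passive", jitter_cv=0.02)
        bals = []
        for k in range(8):
            train = self._quiet_block(montage, spec, 100 + 2 * k, 200 + 2 * k)
            test = self._quiet_block(montage, spec, 101 + 2 * k, 201 + 2 * k)
            bals.append(inter_block_cross(train, test,
                                          ("positive", "neutral"),
                                          gamma=1.0).balanced)
        assert np.mean(bals) > 80.0

    def test_feature_mismatch_rejected(self, passive_matrix):
        other = _tm(np.zeros((4, 3)), ["positive"] * 2 + ["neutral"] * 2)
        with pytest.raises(ValueError, match="feature"):
            inter_block_cross(passive_matrix, other, ("positive", "neutral"))

    def test_condition_decoding_with_condition_specific_patterns(
            self, montage):
        """Neutral trials with a response in one condition only are
        separable by condition with inter-block LOTO."""
        from fnirsdecode import EffectSpec
        planted = {"mOFC": {"neutral": (0.4, -0.13)},
                   "dmPFC": {"neutral": (0.3, -0.1)}}
        passive_spec = EffectSpec(amplitudes=planted, jitter_cv=0.02,
                                  workspace_mode=False)
        active_spec = EffectSpec.null()
        passive = self._quiet_block(montage, passive_spec, 300, 400,
                                    "passive")
        active = self._quiet_block(montage, active_spec, 301, 401, "active")
        combined = TrialMatrix.concatenate([passive, active])
        res = inter_block_loto(combined, "neutral")
        assert res.balanced > 70.0
        assert len(res.y_true) == 20  # m equals trial count

    def test_identical_conditions_near_chance(self, montage):
        """Same generative parameters in both blocks: condition decoding
        of neutral trials stays near chance."""
        from fnirsdecode import EffectSpec
        spec = EffectSpec.null()
        passive = self._quiet_block(montage, spec, 310, 410, "passive")
        active = self._quiet_block(montage, spec, 311, 411, "active")
        combined = TrialMatrix.concatenate([passive, active])
        res = inter_block_loto(combined, "neutral")
        assert 20.0 <= res.balanced <= 80.0  # single participant, m = 20

    def test_single_condition_rejected(self, passive_matrix):
        with pytest.raises(ValueError, match="condition"):
            inter_block_loto(passive_matrix, "neutral")


class TestWeights:
    def test_single_fold_map_is_identity(self):
        w = np.array([[1.0, -2.0, 0.5]])
        wm = aggregate_weights(w, ["a", "b", "c"])
        assert np.allclose(wm.mean_signed, w[0])
        assert np.allclose(wm.mean_abs, np.abs(w[0]))

    def test_signed_cancellation_absolute_retention(self):
        wm = aggregate_weights(np.array([[1.0], [-1.0]]), ["a"])
        assert wm.mean_signed[0] == pytest.approx(0.0)
        assert wm.mean_abs[0] == pytest.approx(1.0)

    def test_signed_bounded_by_absolute(self, participant_matrices):
        res = intra_block_loto(participant_matrices["passive"],
                               ("positive", "neutral"))
        wm = res.weight_map
        assert np.all(np.abs(wm.mean_signed) <= wm.mean_abs + 1e-12)
        assert np.all(wm.mean_abs >= 0)

    def test_planted_channels_get_top_weights(self, montage):
        """An HbR-only effect on two channels localizes to those features."""
        rng = np.random.default_rng(11)
        hits = 0
        runs = 20
        for r in range(runs):
            values = rng.standard_normal((15, 64)) * 0.1
            labels = ["positive"] * 5 + ["neutral"] * 10
            target = [32 + 3, 32 + 17]  # HbR features of channels 3 and 17
            for i in range(5):
                values[i, target] += 2.0
            tm = _tm(values, labels)
            res = intra_block_loto(tm, ("positive", "neutral"))
            top2 = set(np.argsort(res.weight_map.mean_abs)[-2:])
            hits += top2 == set(target)
        assert hits >= 0.9 * runs

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError):
            aggregate_weights(np.ones((2, 3)), ["a", "b"])
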