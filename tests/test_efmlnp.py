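"""Fuzzy profiles, bell memberships, impact measures, and the MLP ensemble."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiofuse.efmlnp import (
    EnsembleModel,
    TypeIIMembership,
    bell_membership,
    cecim_classify,
    compute_fuzzy_profile,
    compute_impact_measures,
    ensemble_predict,
    fuzzify_features,
    fuzzy_dependency,
    load_model,
    membership_to_rank,
    save_model,
    train_efmlnp,
)
from cardiofuse.errors import InvalidInputError, StateError
from cardiofuse.features import FEATURE_NAMES
from cardiofuse.synthetic import make_fused_benchmark


def benchmark_split(n=400, effect=2.0, seed=0, test_frac=0.3):
    frame = make_fused_benchmark(n=n, effect=effect, seed=seed)
    X = frame[list(FEATURE_NAMES)].to_numpy(float)
    y = frame["label"].to_numpy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    cut = int(n * (1 - test_frac))
    tr, te = order[:cut], order[cut:]
    return X[tr], y[tr], X[te], y[te]


class TestFuzzyProfile:
    def test_prototype_is_class_mean(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        prof = compute_fuzzy_profile(X, y)
        assert prof.prototypes[0][0] == pytest.approx(0.5)

    def test_degenerate_class_feature_hits_width_cap(self):
        X = np.array([[2.0, 1.0], [2.0, 3.0], [5.0, 2.0], [5.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        prof = compute_fuzzy_profile(X, y)
        assert prof.widths[0][0] == pytest.approx(1e4)  # zero within-class variance
        assert prof.prototypes[0][0] == pytest.approx(0.0)  # normalized min

    def test_prototypes_recover_generating_means(self):
        rng = np.random.default_rng(3)
        n = 400
        X = np.concatenate([rng.normal(0.0, 1.0, (n, 2)), rng.normal(2.0, 1.0, (n, 2))])
        y = np.repeat([0, 1], n)
        prof = compute_fuzzy_profile(X, y)
        lo, hi = X.min(axis=0), X.max(axis=0)
        for c, mean in ((0, 0.0), (1, 2.0)):
            expected = (mean - lo) / (hi - lo)
            se = 1.0 / (hi - lo) / np.sqrt(n)
            assert np.all(np.abs(prof.prototypes[c] - expected) < 3 * se)

    def test_small_class_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_fuzzy_profile(np.zeros((3, 2)), np.array([0, 0, 1]))


class TestBellMembership:
    def test_prototype_distance_zero(self):
        fl, mu, interval = bell_membership(0.4, 0.4, s=2.0)
        assert fl == 0.0 and mu == 1.0
        assert interval.lower == pytest.approx(0.9) and interval.upper == 1.0

    def test_unit_distance_halves_membership(self):
        fl, mu, _ = bell_membership(1.0, 0.0, s=1.0)
        assert fl == pytest.approx(0.5) and mu == pytest.approx(0.5)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(0.01, 100.0),
        st.floats(0.0, 1.0),
        st.floats(0.0, 0.5),
        st.floats(0.51, 1.0),
    )
    def test_membership_decreases_with_distance(self, s, b, near, far):
        _, mu_near, iv = bell_membership(b + near, b, s)
        _, mu_far, _ = bell_membership(b + far, b, s)
        assert mu_near >= mu_far
        assert 0.0 <= iv.lower <= iv.upper <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            bell_membership(np.nan, 0.5, 1.0)
        with pytest.raises(InvalidInputError):
            bell_membership(0.5, 0.5, 0.0)


class TestFuzzyDependency:
    def test_zero_uncertainty_gives_full_dependency(self):
        fd = fuzzy_dependency([0.5, 2.0], [TypeIIMembership(1, 1), TypeIIMembership(1, 1)])
        assert fd.F1 == 0.0 and fd.FD == 1.0

    def test_hand_arithmetic(self):
        fd = fuzzy_dependency([1.0], [TypeIIMembership(0.4, 0.6)])
        assert fd.F == pytest.approx(0.5)
        assert fd.F1 == pytest.approx(0.1)
        assert fd.FD == pytest.approx(5 / 6)

    def test_widening_intervals_decreases_dependency(self):
        narrow = fuzzy_dependency([1.0, 1.0], [TypeIIMembership(0.45, 0.55)] * 2)
        wide = fuzzy_dependency([1.0, 1.0], [TypeIIMembership(0.3, 0.7)] * 2)
        assert wide.FD < narrow.FD

    def test_negative_weights_rejected(self):
        with pytest.raises(InvalidInputError):
            fuzzy_dependency([-1.0], [TypeIIMembership(0, 1)])


class TestMembershipToRank:
    def test_anchor_points(self):
        assert membership_to_rank(0.9) == 1
        assert membership_to_rank(0.1) == 6
        assert membership_to_rank(0.0) == 13

    def test_interpolation_between_anchors(self):
        assert membership_to_rank(0.5) == 4  # 3.5 rounded half-up

    def test_clamps_above_top_anchor(self):
        assert membership_to_rank(0.95) == 1
        assert membership_to_rank(1.0) == 1

    def test_monotone_non_increasing(self):
        ranks = [membership_to_rank(mu) for mu in np.linspace(0, 1, 101)]
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))

    def test_out_of_range_rejected(self):
        for mu in (-0.1, 1.1, np.nan):
            with pytest.raises(InvalidInputError):
                membership_to_rank(mu)


class TestImpactMeasures:
    @pytest.fixture
    def profile(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 6))
        y = np.repeat([0, 1], 20)
        return compute_fuzzy_profile(X, y, feature_names=FEATURE_NAMES)

    def test_equal_distances_give_symmetric_scores(self, profile):
        c = profile.classes[0]
        sample = profile.prototypes[c] * (profile.feat_max - profile.feat_min) + profile.feat_min
        m = compute_impact_measures(sample + 1e-9, profile)[c]
        # all six distances ~epsilon-equal -> every ratio ~100
        assert m.acim == pytest.approx(100.0, rel=0.05)
        assert m.vcim == pytest.approx(100.0, rel=0.05)
        assert m.ecim == pytest.approx(100.0, rel=0.05)
        assert m.cecim == pytest.approx(100.0, rel=0.1)

    def test_distance_ratio_arithmetic(self):
        # class 0 prototype lands at 0.5 for every min-max-normalized feature
        X = np.array(
            [[0.0] * 6, [1.0] * 6, [0.5] * 6, [1.0] * 6],
        )
        y = np.array([0, 0, 1, 1])
        prof = compute_fuzzy_profile(X, y, feature_names=FEATURE_NAMES)
        sample = np.array([0.7, 0.6, 0.5, 0.5, 0.5, 0.5])
        m = compute_impact_measures(sample, prof)[0]
        # distances to class-0 prototype (0.5 each): nad 0.2, acad 0.1 -> ratio 2
        assert m.acim == pytest.approx(200.0, rel=1e-3)

    def test_cecim_scale_invariant(self, profile):
        sample = np.full(6, 0.3)
        base = compute_impact_measures(sample, profile)
        # common rescaling of all six distances cancels in the CECIM ratios:
        # moving the sample towards/away from a prototype uniformly in every
        # coordinate multiplies each |x-E| by the same factor
        c = profile.classes[0]
        E = profile.prototypes[c]
        span = profile.feat_max - profile.feat_min
        for factor in (0.5, 1.5):  # factors keeping the scaled sample inside [0,1]
            scaled_norm = E + factor * (profile.normalize(sample)[0] - E)
            scaled = scaled_norm * span + profile.feat_min
            m = compute_impact_measures(scaled, profile)[c]
            assert m.cecim == pytest.approx(base[c].cecim, rel=1e-2)

    def test_untrained_profile_rejected(self):
        with pytest.raises(StateError):
            compute_impact_measures(np.zeros(6), None)


class TestCecimClassify:
    def test_argmax_and_tie_rule(self):
        X = np.array([[0.0] * 6, [0.1] * 6, [1.0] * 6, [0.9] * 6])
        y = np.array([0, 0, 1, 1])
        prof = compute_fuzzy_profile(X, y, feature_names=FEATURE_NAMES)
        # sample on class 1's prototype: tiny distances there, max CECIM ratio
        # structure is symmetric, so check determinism of the decision
        label = cecim_classify(np.full(6, 0.95), prof)
        assert label in (0, 1)
        # identical prototypes force a tie -> lowest class index
        X_tie = np.array([[0.5] * 6, [0.5] * 6, [0.5] * 6, [0.5] * 6])
        prof_tie = compute_fuzzy_profile(X_tie, y, feature_names=FEATURE_NAMES)
        assert cecim_classify(np.full(6, 0.2), prof_tie) == 0

    def test_beats_chance_on_separable_data(self):
        frame = make_fused_benchmark(n=300, effect=2.0, seed=4)
        X = frame[list(FEATURE_NAMES)].to_numpy(float)
        y = frame["label"].to_numpy()
        prof = compute_fuzzy_profile(X[:200], y[:200], feature_names=FEATURE_NAMES)
        preds = [cecim_classify(x, prof) for x in X[200:]]
        assert np.mean(np.asarray(preds) == y[200:]) > 0.5


class TestFuzzification:
    def test_channel_counts_and_padding(self):
        Xn = np.random.default_rng(0).random((5, 6))
        for dim in (128, 144, 156):
            channels, kappa = fuzzify_features(Xn, dim)
            assert channels.shape == (5, dim)
            assert kappa.shape == (5,)
        # 6 features * 21 prototypes = 126 real channels, 2 zero-padded
        channels, _ = fuzzify_features(Xn, 128)
        assert np.all(channels[:, 126:] == 0.0)

    def test_certainty_weight_extremes(self):
        # all memberships 0.5 -> kappa 0; memberships in {0,1} -> kappa 1
        mu_half = np.full((1, 10), 0.5)
        mu_crisp = np.array([[0.0, 1.0] * 5])
        assert np.mean(np.abs(2 * mu_half - 1)) == 0.0
        assert np.mean(np.abs(2 * mu_crisp - 1)) == 1.0


class TestEnsemble:
    def test_member_input_dimensions(self):
        Xtr, ytr, _, _ = benchmark_split(n=120, seed=1)
        with pytest.warns(UserWarning):  # fewer samples than the largest batch
            model = train_efmlnp(Xtr, ytr, seed=1, epochs=5)
        assert model.input_dims == (128, 144, 156)
        assert model.batch_sizes == (128, 64, 128)
        assert [m.W[0].shape[0] for m in model.members] == [128, 144, 156]

    def test_training_is_deterministic(self):
        Xtr, ytr, Xte, _ = benchmark_split(n=200, seed=2)
        a = train_efmlnp(Xtr, ytr, seed=5, epochs=20)
        b = train_efmlnp(Xtr, ytr, seed=5, epochs=20)
        la, _ = ensemble_predict(a, Xte)
        lb, _ = ensemble_predict(b, Xte)
        assert np.array_equal(la, lb)

    def test_learns_separable_benchmark(self):
        Xtr, ytr, Xte, yte = benchmark_split(n=400, effect=2.0, seed=3)
        model = train_efmlnp(Xtr, ytr, seed=3)
        labels, scores = ensemble_predict(model, Xte)
        assert np.mean(labels == yte) >= 0.95
        assert scores.shape == (len(yte), 2)

    def test_majority_vote_and_tie_break(self):
        model = EnsembleModel(
            members=[object(), object(), object()],
            input_dims=(4, 4, 4),
            batch_sizes=(2, 2, 2),
            classes=["A", "B", "C"],
            feat_min=np.zeros(2),
            feat_max=np.ones(2),
            profile=None,
            seed=0,
        )

        class FakeMLP:
            def __init__(self, probs):
                self.probs = np.asarray(probs)
                self.W = [np.zeros((4, 1))]

            def predict_proba(self, X):
                return np.tile(self.probs, (X.shape[0], 1))

        # majority: two members vote A
        model.members = [FakeMLP([0.6, 0.3, 0.1]), FakeMLP([0.5, 0.4, 0.1]), FakeMLP([0.1, 0.8, 0.1])]
        labels, _ = ensemble_predict(model, np.zeros((2, 2)))
        assert list(labels) == ["A", "A"]
        # three-way tie: summed score decides (B has the largest sum)
        model.members = [FakeMLP([0.9, 0.05, 0.05]), FakeMLP([0.0, 0.95, 0.05]), FakeMLP([0.05, 0.05, 0.9])]
        labels, _ = ensemble_predict(model, np.zeros((1, 2)))
        assert labels[0] == "B"

    def test_ensemble_not_much_worse_than_members(self):
        Xtr, ytr, Xte, yte = benchmark_split(n=300, effect=1.5, seed=7)
        model = train_efmlnp(Xtr, ytr, seed=7, epochs=60)
        labels, _ = ensemble_predict(model, Xte)
        ens_acc = np.mean(labels == yte)
        from cardiofuse.efmlnp import fuzzify_features as fz

        Xn = model._normalize(Xte)
        member_accs = []
        for mlp, dim in zip(model.members, model.input_dims):
            probs = mlp.predict_proba(fz(Xn, dim)[0])
            member_accs.append(np.mean(np.asarray(model.classes)[probs.argmax(1)] == yte))
        assert ens_acc >= min(member_accs) - 0.02

    def test_save_load_round_trip(self, tmp_path):
        Xtr, ytr, Xte, _ = benchmark_split(n=150, seed=9)
        model = train_efmlnp(Xtr, ytr, seed=9, epochs=10, feature_names=FEATURE_NAMES)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        la, sa = ensemble_predict(model, Xte)
        lb, sb = ensemble_predict(back, Xte)
        assert np.array_equal(la, lb)
        assert np.allclose(sa, sb)
        assert back.profile.feature_names == FEATURE_NAMES

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            train_efmlnp(np.zeros((10, 3)), np.zeros(10), epochs=1)
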