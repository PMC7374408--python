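"""Transfer function, mass assignment, Dempster combination, beliefs, simplex."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitbelief as gb
from gaitbelief.cardiff_classifier import (
    VACUOUS,
    BeliefTriplet,
    BodyOfEvidence,
    ClassifierError,
    CombinationError,
    DegenerateFeatureError,
    TransferParams,
    belief_change,
    classify,
    combine_all,
    confidence_factor,
    dempster_combine,
    fit_transfer_params,
    simplex_coordinates,
    to_boe,
    train_classifier,
)
from gaitbelief.config import PipelineConfig

from conftest import random_boe


PARAMS = TransferParams(feature_id=("v", 1), k=1.0, theta=0.0, a=0.2, b=0.9)


def brute_force_combine(boes):
    """Independent oracle: enumerate all 3^n focal-element intersections.

    Each body of evidence places mass on {OA}, {NP} or Theta; an intersection
    is empty iff both singletons appear.  Conflict mass is renormalised away.
    """
    mass = {"OA": 0.0, "NP": 0.0, "U": 0.0}
    conflict = 0.0
    for assignment in itertools.product(range(3), repeat=len(boes)):
        weight = 1.0
        focal = set()
        for boe, choice in zip(boes, assignment):
            weight *= (boe.m_oa, boe.m_np, boe.m_u)[choice]
            focal.add(("OA", "NP", "U")[choice])
        if "OA" in focal and "NP" in focal:
            conflict += weight
        elif "OA" in focal:
            mass["OA"] += weight
        elif "NP" in focal:
            mass["NP"] += weight
        else:
            mass["U"] += weight
    norm = 1.0 - conflict
    return BodyOfEvidence(mass["OA"] / norm, mass["NP"] / norm, mass["U"] / norm)


class TestConfidenceFactor:
    def test_midpoint_gives_half(self):
        assert confidence_factor(PARAMS, 0.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        assert confidence_factor(PARAMS, math.log(3.0)) == pytest.approx(0.75)

    def test_sign_flip_mirrors_cf(self):
        flipped = TransferParams(("v", 1), k=-1.0, theta=0.0, a=0.2, b=0.9)
        for v in (-3.0, -0.5, 0.0, 1.2, 10.0):
            assert confidence_factor(flipped, v) == pytest.approx(
                1.0 - confidence_factor(PARAMS, v), abs=1e-12
            )

    def test_overflow_clamped_into_open_interval(self):
        steep = TransferParams(("v", 1), k=1e6, theta=0.0, a=0.2, b=0.9)
        assert 0.0 < confidence_factor(steep, -1e6)
        assert confidence_factor(steep, 1e6) < 1.0


class TestToBoe:
    def test_saturated_cf_puts_maximum_mass_on_oa(self):
        boe = to_boe(PARAMS, 1.0 - 1e-15)
        assert boe.m_oa == pytest.approx(0.9, abs=1e-12)
        assert boe.m_np == pytest.approx(0.0, abs=1e-12)
        assert boe.m_u == pytest.approx(0.1, abs=1e-12)

    def test_midpoint_is_symmetric(self):
        boe = to_boe(PARAMS, 0.5)
        assert boe.m_oa == pytest.approx(0.3375)
        assert boe.m_np == pytest.approx(0.3375)
        assert boe.m_u == pytest.approx(0.325)

    def test_cf_at_ignorance_margin_is_onset_of_oa_evidence(self):
        for b in (0.5, 0.9, 0.99):
            params = TransferParams(("v", 1), 1.0, 0.0, a=0.2, b=b)
            assert to_boe(params, 0.2).m_oa == 0.0

    @given(cf=st.floats(1e-6, 1 - 1e-6))
    @settings(deadline=None)
    def test_residual_uncertainty_never_below_1_minus_b(self, cf):
        boe = to_boe(PARAMS, cf)
        assert boe.m_u >= 1.0 - 0.9 - 1e-12
        assert boe.m_oa + boe.m_np + boe.m_u == pytest.approx(1.0, abs=1e-12)


class TestDempsterCombine:
    def test_hand_computed_example(self):
        combined = dempster_combine(BodyOfEvidence(0.6, 0.2, 0.2), BodyOfEvidence(0.5, 0.3, 0.2))
        assert combined.m_oa == pytest.approx(0.52 / 0.72)
        assert combined.m_np == pytest.approx(0.16 / 0.72)
        assert combined.m_u == pytest.approx(0.04 / 0.72)

    def test_vacuous_is_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            boe = random_boe(rng)
            combined = dempster_combine(boe, VACUOUS)
            assert combined.m_oa == pytest.approx(boe.m_oa, abs=1e-12)
            assert combined.m_np == pytest.approx(boe.m_np, abs=1e-12)

    def test_commutative_and_associative(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c = (random_boe(rng) for _ in range(3))
            ab = dempster_combine(a, b)
            ba = dempster_combine(b, a)
            assert ab.m_oa == pytest.approx(ba.m_oa, abs=1e-12)
            left = dempster_combine(dempster_combine(a, b), c)
            right = dempster_combine(a, dempster_combine(b, c))
            assert left.m_oa == pytest.approx(right.m_oa, abs=1e-10)
            assert left.m_np == pytest.approx(right.m_np, abs=1e-10)

    def test_total_conflict_raises(self):
        with pytest.raises(CombinationError):
            dempster_combine(BodyOfEvidence(1.0, 0.0, 0.0), BodyOfEvidence(0.0, 1.0, 0.0))

    def test_fold_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            boes = [random_boe(rng) for _ in range(rng.integers(1, 7))]
            fold = combine_all(boes)
            oracle = brute_force_combine(boes)
            assert abs(fold.m_oa - oracle.m_oa) < 1e-10
            assert abs(fold.m_np - oracle.m_np) < 1e-10
            assert abs(fold.m_u - oracle.m_u) < 1e-10


class TestFitTransferParams:
    CONFIG = PipelineConfig()

    def test_plug_in_of_explicit_rule(self):
        rng = np.random.default_rng(3)

        def sample(mean, sd, n):
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        params = fit_transfer_params(sample(0, 1, 20), sample(2, 1, 25), self.CONFIG, ("f", 1))
        assert params.theta == pytest.approx(1.0)
        assert params.k == pytest.approx(2.0)

    def test_zero_separation_is_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateFeatureError):
            fit_transfer_params(x, x, self.CONFIG)

    def test_zero_spread_is_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            fit_transfer_params(np.zeros(5), np.ones(5), self.CONFIG)

    def test_orientation_larger_oa_mean_gives_positive_slope(self):
        rng = np.random.default_rng(4)
        params = fit_transfer_params(rng.normal(0, 1, 20), rng.normal(3, 1, 20), self.CONFIG)
        assert params.k > 0
        low = to_boe(params, confidence_factor(params, -2.0))
        high = to_boe(params, confidence_factor(params, 5.0))
        assert high.m_oa > low.m_oa


class TestClassify:
    def make_classifier(self, n_features, a=0.2, rng=None):
        config = PipelineConfig(ignorance=a)
        rng = rng or np.random.default_rng(5)
        features = [(f"v{i}", 1) for i in range(n_features)]
        params = {
            f: TransferParams(f, k=float(rng.uniform(0.5, 2.0)) * (1 if i % 2 else -1),
                              theta=float(rng.normal()), a=a, b=0.9)
            for i, f in enumerate(features)
        }
        return gb.TrainedClassifier(features=features, params=params)

    def test_all_features_at_theta_with_zero_ignorance_is_on_boundary(self):
        clf = self.make_classifier(5, a=0.0)
        row = {f: clf.params[f].theta for f in clf.features}
        triplet = classify(clf, row)
        assert triplet.b_oa == pytest.approx(triplet.b_np, abs=1e-12)
        assert triplet.predicted is None

    def test_single_feature_classifier_returns_that_boe(self):
        clf = self.make_classifier(1)
        row = {clf.features[0]: 1.3}
        p = clf.params[clf.features[0]]
        boe = to_boe(p, confidence_factor(p, 1.3))
        triplet = classify(clf, row)
        assert triplet.b_oa == pytest.approx(boe.m_oa, abs=1e-12)
        assert triplet.u == pytest.approx(boe.m_u, abs=1e-12)

    def test_combination_order_invariance(self):
        rng = np.random.default_rng(6)
        clf = self.make_classifier(18, rng=rng)
        row = {f: float(rng.normal()) for f in clf.features}
        base = classify(clf, row)
        for _ in range(5):
            perm = list(clf.features)
            rng.shuffle(perm)
            shuffled = gb.TrainedClassifier(features=perm, params=clf.params)
            got = classify(shuffled, row)
            assert got.b_oa == pytest.approx(base.b_oa, abs=1e-10)
            assert got.b_np == pytest.approx(base.b_np, abs=1e-10)

    def test_monotone_in_a_positive_slope_feature(self):
        clf = self.make_classifier(4)
        f = next(f for f in clf.features if clf.params[f].k > 0)
        rng = np.random.default_rng(7)
        row = {g: float(rng.normal()) for g in clf.features}
        beliefs = []
        for v in np.linspace(clf.params[f].theta - 1, clf.params[f].theta + 1, 9):
            row[f] = float(v)
            beliefs.append(classify(clf, row).b_oa)
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(beliefs, beliefs[1:]))

    def test_missing_feature_raises(self):
        clf = self.make_classifier(3)
        with pytest.raises(ClassifierError, match="missing"):
            classify(clf, {clf.features[0]: 0.0})

    def test_combined_uncertainty_stays_positive(self, feature_matrix, labels, config):
        clf = train_classifier(feature_matrix, labels, config)
        for i in range(0, len(feature_matrix), 10):
            triplet = classify(clf, feature_matrix.iloc[i])
            assert triplet.u > 0.0


class TestSimplex:
    def test_pure_np_belief_maps_to_origin(self):
        assert simplex_coordinates(BeliefTriplet(0.0, 1.0, 0.0)) == (0.0, 0.0)

    def test_centroid(self):
        x, y = simplex_coordinates(BeliefTriplet(1 / 3, 1 / 3, 1 / 3))
        assert x == pytest.approx(0.5)
        assert y == pytest.approx(math.sqrt(3) / 6)

    @given(b_oa=st.floats(0, 1), frac=st.floats(0, 1))
    @settings(deadline=None)
    def test_equal_beliefs_lie_on_vertical_boundary(self, b_oa, frac):
        b_oa = min(b_oa, 0.5)
        triplet = BeliefTriplet(b_oa, b_oa, 1.0 - 2 * b_oa)
        x, _ = simplex_coordinates(triplet)
        assert x == pytest.approx(0.5, abs=1e-9)


class TestBeliefChange:
    def test_identical_triplets_give_zero(self):
        a = BeliefTriplet(0.4, 0.3, 0.3, "s1", "baseline")
        b = BeliefTriplet(0.4, 0.3, 0.3, "s1", "postop")
        assert belief_change(a, b) == 0.0

    def test_cohort_mean_change_matches_published_magnitude(self):
        base = BeliefTriplet(0.662, 0.046, 1 - 0.662 - 0.046, "s", "baseline")
        post = BeliefTriplet(0.511, 0.141, 1 - 0.511 - 0.141, "s", "postop")
        assert belief_change(base, post) == pytest.approx(-0.151)

    def test_worsening_is_positive(self):
        base = BeliefTriplet(0.3, 0.3, 0.4, "s", "baseline")
        post = BeliefTriplet(0.4, 0.2, 0.4, "s", "postop")
        assert belief_change(base, post) == pytest.approx(0.1)

    def test_visit_or_subject_mismatch_raises(self):
        a = BeliefTriplet(0.4, 0.3, 0.3, "s1", "baseline")
        with pytest.raises(ClassifierError):
            belief_change(a, BeliefTriplet(0.4, 0.3, 0.3, "s2", "postop"))
        with pytest.raises(ClassifierError):
            belief_change(a, BeliefTriplet(0.4, 0.3, 0.3, "s1", "baseline"))
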