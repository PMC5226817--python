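"""Contact, distance-restraint, FISH and ambiguous-restraint likelihoods."""

import numpy as np
import pytest

from chromisd import (
    ContactData,
    FishData,
    ambiguous_distance,
    classify_diploid_contacts,
    diploid_logistic_log_likelihood,
    fish_log_likelihood,
    gaussian_plateau_log_likelihood,
    logistic_log_likelihood,
    lognormal_log_likelihood,
)
from chromisd.likelihoods import (
    NuisanceParams,
    diploid_logistic_gradient,
    fish_gradient,
    gaussian_plateau_gradient,
    logistic_gradient,
    lognormal_gradient,
)

from conftest import finite_difference_gradient


def pair_at(d, n=2):
    """Two-bead conformation with the pair at distance d, plus the contact."""
    X = np.zeros((n, 3))
    X[1, 0] = d
    return X, ContactData.from_pairs([[0, 1]], n)


class TestContactData:
    def test_merging_and_ordering(self):
        c = ContactData.from_pairs([[3, 1], [1, 3], [0, 2]], 5)
        assert len(c) == 2
        assert c.counts[list(zip(c.i, c.j)).index((1, 3))] == 2.0

    def test_self_contacts_dropped_by_from_pairs(self):
        c = ContactData.from_pairs([[2, 2], [0, 1]], 4)
        assert len(c) == 1

    def test_self_contact_rejected_by_constructor(self):
        with pytest.raises(ValueError):
            ContactData(np.array([2]), np.array([2]), np.array([1.0]), 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ContactData.from_pairs([[0, 9]], 5)


class TestLogisticModel:
    def test_midpoint_is_log_half(self):
        X, c = pair_at(1.5)
        assert logistic_log_likelihood(X, c, alpha=200.0, d_c=1.5) == pytest.approx(
            np.log(0.5)
        )

    def test_violation_closed_form(self):
        # d = d_c + 0.05 a, alpha = 200/a: log(1/(1 + e^10))
        X, c = pair_at(1.55)
        expected = -np.logaddexp(0.0, 10.0)
        assert logistic_log_likelihood(X, c, 200.0, 1.5) == pytest.approx(expected)
        assert expected == pytest.approx(-10.0000454, abs=1e-6)

    def test_overflow_safe_far_violation(self):
        X, c = pair_at(100.0)
        val = logistic_log_likelihood(X, c, 200.0, 1.5)
        assert np.isfinite(val)
        assert val == pytest.approx(-200.0 * 98.5)

    def test_multiplicity_duplicates_restraint(self):
        X = np.zeros((2, 3))
        X[1, 0] = 1.7
        c1 = ContactData(np.array([0]), np.array([1]), np.array([1.0]), 2)
        c3 = ContactData(np.array([0]), np.array([1]), np.array([3.0]), 2)
        assert logistic_log_likelihood(X, c3, 200.0, 1.5) == pytest.approx(
            3 * logistic_log_likelihood(X, c1, 200.0, 1.5)
        )


class TestPlateauModel:
    def test_plateau_value_is_normalizer(self):
        X, c = pair_at(1.0)
        sigma = 0.1
        expected = -np.log(np.sqrt(2 * np.pi) * sigma + 0.4)
        assert gaussian_plateau_log_likelihood(X, c, 1.0, sigma) == pytest.approx(expected)

    def test_upper_branch_penalty(self):
        # gamma d = 1.3 a, w = 100: penalty (0.1)^2 * 50 below the plateau value
        X, c = pair_at(1.3)
        sigma = 0.1
        base = -np.log(np.sqrt(2 * np.pi) * sigma + 0.4)
        val = gaussian_plateau_log_likelihood(X, c, 1.0, sigma)
        assert val == pytest.approx(base - 0.1**2 * 50.0)

    def test_plateau_symmetry(self):
        Xa, c = pair_at(0.7)
        Xb, _ = pair_at(1.3)
        assert gaussian_plateau_log_likelihood(Xa, c, 1.0, 0.1) == pytest.approx(
            gaussian_plateau_log_likelihood(Xb, c, 1.0, 0.1)
        )


class TestLognormalModel:
    def test_mode_value(self):
        X, c = pair_at(1.0)
        sigma = 0.05
        assert lognormal_log_likelihood(X, c, 1.0, sigma) == pytest.approx(
            -np.log(np.sqrt(2 * np.pi) * sigma)
        )

    def test_one_sigma_point(self):
        sigma = 0.2
        X, c = pair_at(np.exp(sigma))
        mode = -np.log(np.sqrt(2 * np.pi) * sigma)
        assert lognormal_log_likelihood(X, c, 1.0, sigma) == pytest.approx(mode - 0.5)

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(10, 3)) * 2 + 5
        c = ContactData.from_pairs(rng.integers(0, 10, size=(15, 2)), 10,
                                   counts=rng.integers(1, 4, size=15))
        gamma, sigma = 0.8, 0.1
        expected = 0.0
        for i, j, n in zip(c.i, c.j, c.counts):
            d = np.linalg.norm(X[i] - X[j])
            expected += n * (
                -np.log(np.sqrt(2 * np.pi) * sigma)
                - np.log(1.0 / (gamma * d)) ** 2 / (2 * sigma**2)
            )
        assert lognormal_log_likelihood(X, c, gamma, sigma) == pytest.approx(expected)

    def test_zero_distance_rejected(self):
        X = np.zeros((2, 3))
        c = ContactData.from_pairs([[0, 1]], 2)
        with pytest.raises(ValueError):
            lognormal_log_likelihood(X, c, 1.0, 0.1)


class TestFishModel:
    def test_exact_match_leaves_only_constants(self):
        # R_g = s_bar / 2.58 zeroes the structure-dependent exponent
        fish = FishData(s_bar=2.58 * 1.5, delta_s=0.0, M=1, sigma_fish=0.3)
        X = np.array([[1.5, 0, 0], [-1.5, 0, 0]])  # R_g = 1.5
        expected = -np.log(np.sqrt(2 * np.pi) * 0.3)
        assert fish_log_likelihood(X, fish) == pytest.approx(expected)

    def test_one_sigma_mismatch(self):
        sigma_f = 0.25
        X = np.array([[1.0, 0, 0], [-1.0, 0, 0]])  # R_g = 1
        fish = FishData(s_bar=2.58 + sigma_f, delta_s=1e-12, M=1, sigma_fish=sigma_f)
        expected = -np.log(np.sqrt(2 * np.pi) * sigma_f) - 0.5
        assert fish_log_likelihood(X, fish) == pytest.approx(expected, rel=1e-6)

    def test_x_chromosome_defaults(self):
        fish = FishData()
        assert fish.s_bar == 3.7 and fish.delta_s == 0.3
        assert fish.sigma_fish == 0.3  # defaults to delta_s


class TestAmbiguousDistance:
    def test_equal_distances_closed_form(self):
        assert ambiguous_distance(2.0, 2.0) == pytest.approx(2 ** (-1 / 6) * 2.0)

    def test_single_copy_limit(self):
        assert ambiguous_distance(1.3, 1e9) == pytest.approx(1.3, rel=1e-6)

    def test_direct_evaluation(self):
        assert ambiguous_distance(1.0, 2.0) == pytest.approx(
            (1 + 2.0**-6) ** (-1 / 6)
        )
        assert ambiguous_distance(1.0, 2.0) == pytest.approx(0.99741, abs=1e-5)

    def test_symmetric_monotone_bounded(self, rng):
        for _ in range(20):
            d1, d2 = rng.uniform(0.1, 5.0, size=2)
            v = ambiguous_distance(d1, d2)
            assert v == pytest.approx(ambiguous_distance(d2, d1))
            assert v <= min(d1, d2) + 1e-12
            assert ambiguous_distance(d1 * 1.1, d2) > v

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ambiguous_distance(0.0, 1.0)


class TestDiploidLikelihood:
    def test_satisfied_in_one_copy_matches_single(self):
        d_c = 1.5
        X1, c = pair_at(d_c / 2)
        X2, _ = pair_at(10 * d_c)
        val = diploid_logistic_log_likelihood(X1, X2, c, 200.0, d_c)
        single = logistic_log_likelihood(X1, c, 200.0, d_c)
        assert val == pytest.approx(single, abs=1e-6)

    def test_both_copies_violating(self):
        d_c = 1.5
        X1, c = pair_at(2 * d_c)
        val = diploid_logistic_log_likelihood(X1, X1, c, 200.0, d_c)
        expected = -200.0 * (2 ** (-1 / 6) * 2 * d_c - d_c)  # logistic tail
        assert val == pytest.approx(expected, rel=1e-6)

    def test_swap_symmetry(self, rng):
        X1 = rng.normal(size=(8, 3)) * 2
        X2 = rng.normal(size=(8, 3)) * 2
        c = ContactData.from_pairs(rng.integers(0, 8, size=(10, 2)), 8)
        assert diploid_logistic_log_likelihood(X1, X2, c, 200.0, 1.5) == pytest.approx(
            diploid_logistic_log_likelihood(X2, X1, c, 200.0, 1.5)
        )

    def test_mismatched_copies_rejected(self):
        c = ContactData.from_pairs([[0, 1]], 3)
        with pytest.raises(ValueError):
            diploid_logistic_log_likelihood(np.zeros((3, 3)), np.zeros((4, 3)), c, 200.0, 1.5)


class TestClassification:
    def test_four_classes(self):
        c = ContactData.from_pairs([[0, 1], [0, 2], [1, 2], [0, 3]], 4)
        # engineered mean distances per copy
        X1 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5.0]])
        X2 = np.array([[0, 0, 0], [4, 0, 0], [0, 1, 0], [9, 9, 9.0]])
        labels = classify_diploid_contacts(X1, X2, c, d_c=1.5)
        by_pair = dict(zip(zip(c.i, c.j), labels))
        assert by_pair[(0, 1)] == "copy1"  # 1 vs 4
        assert by_pair[(0, 2)] == "both"  # 1 vs 1
        assert by_pair[(0, 3)] == "violated"

    def test_planted_demixing_on_means(self, rng):
        from chromisd import diploid_mixture_fixture

        Xa = np.column_stack([np.arange(12.0), np.zeros(12), np.zeros(12)])
        Xb = Xa.copy()
        Xb[:, 1] = 0.3 * np.sin(np.arange(12.0))  # different contact pattern
        Xb[6:, 0] -= 4.0
        pooled, labels = diploid_mixture_fixture(Xa, Xb, cutoff=1.5)
        # classifying with the generating structures recovers unique labels
        got = classify_diploid_contacts(Xa, Xb, pooled, d_c=1.5)
        for lab, truth in zip(got, labels):
            if truth == "a":
                assert lab == "copy1"
            elif truth == "b":
                assert lab == "copy2"
            else:
                assert lab == "both"


class TestLikelihoodGradients:
    def test_logistic_midpoint_force(self):
        # |dlogL/dd| = n alpha sigmoid(0) ... derivative of -log(1+e^z)
        X, c = pair_at(1.5)
        g = logistic_gradient(X, c, 200.0, 1.5)
        assert np.abs(g[1, 0]) == pytest.approx(200.0 / 2)
        c3 = ContactData(c.i, c.j, np.array([3.0]), 2)
        g3 = logistic_gradient(X, c3, 200.0, 1.5)
        assert np.abs(g3[1, 0]) == pytest.approx(3 * 200.0 / 2)

    def test_plateau_interior_zero_gradient(self):
        X, c = pair_at(1.0)
        g = gaussian_plateau_gradient(X, c, 1.0, 0.1)
        assert np.allclose(g, 0.0)

    @pytest.mark.parametrize("name", ["logistic", "plateau", "lognormal", "fish"])
    def test_finite_difference_agreement(self, name, rng):
        X = rng.normal(size=(10, 3)) * 2 + 4
        c = ContactData.from_pairs(rng.integers(0, 10, size=(14, 2)), 10,
                                   counts=rng.integers(1, 3, size=14))
        fish = FishData()
        fns = {
            "logistic": (
                lambda Y: logistic_log_likelihood(Y, c, 5.0, 1.5),
                lambda Y: logistic_gradient(Y, c, 5.0, 1.5),
            ),
            "plateau": (
                lambda Y: gaussian_plateau_log_likelihood(Y, c, 0.9, 0.1),
                lambda Y: gaussian_plateau_gradient(Y, c, 0.9, 0.1),
            ),
            "lognormal": (
                lambda Y: lognormal_log_likelihood(Y, c, 0.9, 0.05),
                lambda Y: lognormal_gradient(Y, c, 0.9, 0.05),
            ),
            "fish": (
                lambda Y: fish_log_likelihood(Y, fish, length_unit_um=0.43),
                lambda Y: fish_gradient(Y, fish, length_unit_um=0.43),
            ),
        }
        f, g = fns[name]
        ga = g(X)
        gf = finite_difference_gradient(f, X)
        scale = max(1.0, np.max(np.abs(gf)))
        assert np.max(np.abs(ga - gf)) < 1e-5 * scale

    def test_diploid_finite_differences(self, rng):
        X1 = rng.normal(size=(8, 3)) * 2
        X2 = rng.normal(size=(8, 3)) * 2
        c = ContactData.from_pairs(rng.integers(0, 8, size=(10, 2)), 8)
        g1, g2 = diploid_logistic_gradient(X1, X2, c, 5.0, 1.5)
        gf1 = finite_difference_gradient(
            lambda Y: diploid_logistic_log_likelihood(Y, X2, c, 5.0, 1.5), X1
        )
        gf2 = finite_difference_gradient(
            lambda Y: diploid_logistic_log_likelihood(X1, Y, c, 5.0, 1.5), X2
        )
        assert np.max(np.abs(g1 - gf1)) < 1e-5
        assert np.max(np.abs(g2 - gf2)) < 1e-5


class TestGlobalInvariants:
    @pytest.mark.parametrize("model", ["logistic", "plateau", "lognormal"])
    def test_moving_away_decreases_likelihood(self, model):
        vals = []
        for d in (1.6, 2.0, 3.0, 5.0):
            X, c = pair_at(d)
            if model == "logistic":
                vals.append(logistic_log_likelihood(X, c, 200.0, 1.5))
            elif model == "plateau":
                vals.append(gaussian_plateau_log_likelihood(X, c, 1.0, 0.1))
            else:
                vals.append(lognormal_log_likelihood(X, c, 1.0, 0.05))
        assert np.all(np.diff(vals) < 0)

    def test_mirror_invariance_of_all_likelihoods(self, rng):
        X = rng.normal(size=(10, 3)) * 2 + 3
        c = ContactData.from_pairs(rng.integers(0, 10, size=(12, 2)), 10)
        fish = FishData()
        for f in (
            lambda Y: logistic_log_likelihood(Y, c, 200.0, 1.5),
            lambda Y: gaussian_plateau_log_likelihood(Y, c, 0.9, 0.1),
            lambda Y: lognormal_log_likelihood(Y, c, 0.9, 0.05),
            lambda Y: fish_log_likelihood(Y, fish, length_unit_um=0.43),
        ):
            assert f(-X) == pytest.approx(f(X), rel=1e-12)

    def test_nuisance_params_validation(self):
        with pytest.raises(ValueError):
            NuisanceParams(gamma=-1.0)
        p = NuisanceParams(sigma=0.1)
        assert p.w == pytest.approx(100.0)
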