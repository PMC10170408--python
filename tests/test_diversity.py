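import numpy as np
import pytest

from tcrkit.diversity import (
    DEFAULT_Q_GRID,
    DiversityError,
    clonality_index,
    diversity_profile,
    evenness_profile,
    hill_diversity,
)


class TestHillDiversity:
    def test_uniform_repertoire_flat_profile(self):
        p = np.full(100, 0.01)
        D = hill_diversity(p, DEFAULT_Q_GRID)
        np.testing.assert_allclose(D, 100.0, atol=1e-9)

    def test_two_clone_closed_forms(self):
        p = np.array([0.9, 0.1])
        D = hill_diversity(p, np.array([0.0, 1.0, 2.0]))
        shannon = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        np.testing.assert_allclose(D, [2.0, np.exp(shannon), 1 / 0.82], rtol=1e-12)

    def test_single_clone_degenerate(self):
        D = hill_diversity(np.array([1.0]), DEFAULT_Q_GRID)
        np.testing.assert_allclose(D, 1.0, atol=1e-12)

    def test_monotone_nonincreasing_in_q(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(rng.integers(2, 50)))
            D = hill_diversity(p, DEFAULT_Q_GRID)
            assert np.all(np.diff(D) <= 1e-9)
            assert 1 - 1e-9 <= D[-1] <= D[0] + 1e-9

    def test_input_validation(self):
        with pytest.raises(DiversityError):
            hill_diversity(np.array([]))
        with pytest.raises(DiversityError):
            hill_diversity(np.array([0.5, 0.0, 0.5]))
        with pytest.raises(DiversityError):
            hill_diversity(np.array([0.5, 0.4]))


class TestEvenness:
    def test_uniform_is_one_everywhere(self):
        p = np.full(10, 0.1)
        D = hill_diversity(p, DEFAULT_Q_GRID)
        E = evenness_profile(D, D[0])
        np.testing.assert_allclose(E, 1.0, atol=1e-9)

    def test_two_clone_value(self):
        p = np.array([0.9, 0.1])
        D = hill_diversity(p, np.array([0.0, 2.0]))
        E = evenness_profile(D, D[0])
        assert E[0] == 1.0
        assert E[1] == pytest.approx((1 / 0.82) / 2, rel=1e-9)


class TestClonalityIndex:
    def test_uniform_repertoire_zero(self):
        E = np.ones_like(DEFAULT_Q_GRID)
        assert clonality_index(E, DEFAULT_Q_GRID) == pytest.approx(0.0, abs=1e-9)

    def test_exponential_profile_matches_analytic_integral(self):
        E = np.exp(-DEFAULT_Q_GRID)
        expected = 10 - (1 - np.exp(-10.0))
        assert clonality_index(E, DEFAULT_Q_GRID) == pytest.approx(expected, abs=1e-4)

    def test_monoclonal_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="monoclonal"):
            prof = diversity_profile(np.array([42]))
        assert prof.clonality == pytest.approx(0.0, abs=1e-9)
        assert prof.SR == 1

    def test_grid_validation(self):
        with pytest.raises(DiversityError):
            clonality_index(np.array([1.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(DiversityError):
            clonality_index(np.ones(4), np.array([0.0, 1.0, 3.0, 4.0]))


class TestProfileProperties:
    def test_scale_invariance_of_clonality(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 1000, size=rng.integers(5, 200))
            a = diversity_profile(counts).clonality
            b = diversity_profile(counts * int(rng.integers(2, 11))).clonality
            assert a == pytest.approx(b, abs=1e-9)

    def test_majorization_monotonicity(self, rng):
        """Moving mass from a smaller clone onto a larger one (same richness)
        never decreases clonality."""
        for _ in range(100):
            counts = rng.integers(2, 500, size=rng.integers(3, 40)).astype(float)
            order = np.argsort(counts)
            small, big = order[0], order[-1]
            shifted = counts.copy()
            transfer = counts[small] - 1  # keep every clone present
            shifted[small] -= transfer
            shifted[big] += transfer
            c0 = diversity_profile(counts).clonality
            c1 = diversity_profile(shifted).clonality
            assert c1 >= c0 - 1e-9

    def test_clonality_range(self, rng):
        for _ in range(30):
            counts = (rng.pareto(0.5, size=rng.integers(2, 300)) * 10 + 1).astype(int)
            c = diversity_profile(counts).clonality
            assert 0 <= c < 10
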