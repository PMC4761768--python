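"""Decay regression forms, halving distances, and permutation significance."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from distdecay.containers import PairwiseMatrix
from distdecay.decay import (
    DecayFit,
    attach_significance,
    fit_decay,
    halving_distance,
    initial_similarity,
    permutation_significance,
)


def matrices_from_xy(x_pairs: np.ndarray, y_pairs: np.ndarray, n: int):
    """Fold pair vectors back into valid similarity/distance matrices."""
    iu, ju = np.triu_indices(n, k=1)
    sim = np.eye(n)
    dist = np.zeros((n, n))
    sim[iu, ju] = sim[ju, iu] = y_pairs
    dist[iu, ju] = dist[ju, iu] = x_pairs
    ids = [f"s{i}" for i in range(n)]
    return (
        PairwiseMatrix(ids, sim, "similarity"),
        PairwiseMatrix(ids, dist, "distance"),
    )


def planted_dataset(form: str, a: float, b: float, n: int = 12, noise: float = 0.0,
                    rng=None):
    """Pairs lying exactly (or noisily) on one decay curve."""
    n_pairs = n * (n - 1) // 2
    x = np.linspace(50, 900, n_pairs)
    fit = DecayFit(form=form, a=a, b=b, r2=1.0, n_pairs=n_pairs)
    y = fit.predict(x)
    if noise and rng is not None:
        if form == "exponential":
            y = y * np.exp(rng.normal(0, noise, n_pairs))
        else:
            y = y + rng.normal(0, noise, n_pairs)
    y = np.clip(y, 1e-6, 1.0)
    return matrices_from_xy(x, y, n)


class TestFitExactness:
    @pytest.mark.parametrize(
        "form,a,b",
        [
            ("linear", -0.0005, 0.8),
            ("logarithmic", -0.12, 1.1),
            ("exponential", -0.002, 0.9),
        ],
    )
    def test_noiseless_points_recovered_exactly(self, form, a, b):
        sim, dist = planted_dataset(form, a, b)
        fit = fit_decay(sim, dist, form)
        assert fit.a == pytest.approx(a, abs=1e-9)
        assert fit.b == pytest.approx(b, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_two_se(self, rng):
        a, b, sigma = -0.0005, 0.85, 0.03
        n = 33  # 528 pairs
        sim, dist = planted_dataset("linear", a, b, n=n, noise=sigma, rng=rng)
        fit = fit_decay(sim, dist, "linear")
        x = np.linspace(50, 900, n * (n - 1) // 2)
        se_a = sigma / math.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(fit.a - a) < 2 * se_a

    def test_too_few_pairs_rejected(self):
        sim, dist = planted_dataset("linear", -0.0005, 0.8, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            fit_decay(sim, dist, "linear")

    def test_zero_distance_variance_rejected(self):
        n = 4
        iu_len = n * (n - 1) // 2
        sim, dist = matrices_from_xy(
            np.full(iu_len, 100.0), np.linspace(0.2, 0.8, iu_len), n
        )
        with pytest.raises(ValueError, match="variance"):
            fit_decay(sim, dist, "linear")

    def test_unusable_pairs_excluded_with_count(self):
        n = 6
        n_pairs = n * (n - 1) // 2
        x = np.linspace(0, 500, n_pairs)  # first distance is 0
        y = np.clip(-0.001 * x + 0.8, 0.01, 1.0)
        sim, dist = matrices_from_xy(x, y, n)
        fit = fit_decay(sim, dist, "logarithmic")
        assert fit.n_excluded == 1
        assert fit.n_pairs == n_pairs


class TestInitialSimilarity:
    def test_max_observed(self):
        sim, _ = planted_dataset("linear", -0.0004, 0.967)
        s0 = initial_similarity(sim)
        v = sim.values[np.triu_indices(sim.n_sites, k=1)]
        assert s0 == pytest.approx(v.max())

    def test_identical_pair_gives_one(self):
        ids = ["a", "b", "c"]
        v = np.array([[1, 1, 0.3], [1, 1, 0.3], [0.3, 0.3, 1.0]])
        sim = PairwiseMatrix(ids, v, "similarity")
        assert initial_similarity(sim) == 1.0

    def test_fixed_value_validated(self):
        sim, _ = planted_dataset("linear", -0.0004, 0.9)
        assert initial_similarity(sim, "fixed", 0.967) == 0.967
        with pytest.raises(ValueError):
            initial_similarity(sim, "fixed", 1.5)
        with pytest.raises(ValueError):
            initial_similarity(sim, "fixed", 0.0)


class TestHalvingDistance:
    def test_linear_closed_form(self):
        fit = DecayFit("linear", a=-0.5, b=1.0, r2=1.0, n_pairs=10)
        assert halving_distance(fit, 1.0) == pytest.approx(1.0)

    @given(
        st.sampled_from(["linear", "logarithmic", "exponential"]),
        st.floats(min_value=-0.01, max_value=-1e-4),
        st.floats(min_value=0.55, max_value=1.0),
        st.floats(min_value=0.6, max_value=1.0),
    )
    def test_roundtrip_model_of_hd_is_half_s0(self, form, a, b, s0):
        if form == "logarithmic":
            a = a * 50  # plausible per-ln-km slope
        fit = DecayFit(form, a=a, b=b, r2=1.0, n_pairs=10)
        try:
            hd = halving_distance(fit, s0)
        except ValueError:
            return  # legitimately unreachable half-similarity
        assert hd > 0
        assert float(fit.predict(hd)) == pytest.approx(s0 / 2, abs=1e-9)

    def test_no_decay_raises(self):
        fit = DecayFit("linear", a=0.001, b=0.5, r2=1.0, n_pairs=10)
        with pytest.raises(ValueError, match="no decay"):
            halving_distance(fit, 1.0)

    def test_unreachable_half_similarity_raises(self):
        fit = DecayFit("linear", a=-0.001, b=0.4, r2=1.0, n_pairs=10)
        with pytest.raises(ValueError, match="not reached"):
            halving_distance(fit, 1.0)
        fit = DecayFit("exponential", a=-0.001, b=0.4, r2=1.0, n_pairs=10)
        with pytest.raises(ValueError, match="not reached"):
            halving_distance(fit, 0.9)


class TestPermutationSignificance:
    def test_perfect_decay_reaches_minimum_p(self):
        sim, dist = planted_dataset("linear", -0.0006, 0.9, n=20)
        p = permutation_significance(sim, dist, "linear", n_perm=1000, seed=7)
        assert p == pytest.approx(1 / 1001)

    def test_exhaustive_enumeration_matches_oracle(self):
        """n=5 -> 120 relabelings; compare against a direct enumeration."""
        rng = np.random.default_rng(3)
        n = 5
        x = rng.uniform(50, 800, 10)
        y = np.clip(0.9 - 0.0008 * x + rng.normal(0, 0.05, 10), 0.05, 1.0)
        sim, dist = matrices_from_xy(x, y, n)

        p_pkg = permutation_significance(sim, dist, "linear", n_perm=1000)

        # oracle: enumerate site relabelings, squared Pearson r as R2
        iu, ju = np.triu_indices(n, k=1)
        obs = np.corrcoef(x, sim.values[iu, ju])[0, 1] ** 2
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            pm = sim.values[np.ix_(perm, perm)]
            r2 = np.corrcoef(x, pm[iu, ju])[0, 1] ** 2
            total += 1
            hits += r2 >= obs - 1e-12
        assert p_pkg == pytest.approx(hits / total)

    def test_exhaustive_consistent_with_monte_carlo(self):
        rng = np.random.default_rng(11)
        n = 5
        x = rng.uniform(50, 800, 10)
        y = np.clip(0.9 - 0.0008 * x + rng.normal(0, 0.08, 10), 0.05, 1.0)
        sim, dist = matrices_from_xy(x, y, n)
        p_exact = permutation_significance(sim, dist, "linear", n_perm=1000)
        p_mc = np.mean(
            [
                permutation_significance(sim, dist, "linear", n_perm=119, seed=s)
                for s in range(20)
            ]
        )
        assert abs(p_mc - p_exact) < 0.15

    def test_invariant_under_joint_site_relabeling(self):
        sim, dist = planted_dataset("linear", -0.0005, 0.85, n=5)
        order = np.array([3, 1, 4, 0, 2])
        p1 = permutation_significance(sim, dist, "linear", n_perm=1000)
        p2 = permutation_significance(
            sim.permute(order), dist.permute(order), "linear", n_perm=1000
        )
        assert p1 == pytest.approx(p2)

    def test_row_and_column_move_together(self):
        """A site relabeling must keep the matrix symmetric (rows-only would not)."""
        sim, _ = planted_dataset("linear", -0.0005, 0.85, n=8)
        order = np.random.default_rng(0).permutation(8)
        permuted = sim.permute(order)
        np.testing.assert_allclose(permuted.values, permuted.values.T, atol=1e-12)
        rows_only = sim.values[order, :]
        assert not np.allclose(rows_only, rows_only.T)

    def test_attach_significance_fills_p(self):
        sim, dist = planted_dataset("linear", -0.0006, 0.9, n=10)
        fit = fit_decay(sim, dist, "linear")
        assert fit.p_perm is None
        fit = attach_significance(fit, sim, dist, n_perm=99, seed=1)
        assert 0 < fit.p_perm <= 1
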