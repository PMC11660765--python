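"""MMD estimators: closed forms, brute-force oracles and metric properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kmereg as km
from conftest import random_unit_spectra


def naive_mmd2(xs, zs, spec, unbiased=False):
    """Triple-loop double-sum over fully expanded samples (oracle)."""
    xs = np.asarray(xs, float)
    zs = np.asarray(zs, float)
    n, m = xs.size, zs.size
    Kxx = spec.gram(xs, xs)
    Kzz = spec.gram(zs, zs)
    Kxz = spec.gram(xs, zs)
    if unbiased:
        xx = (Kxx.sum() - np.trace(Kxx)) / (n * (n - 1))
        zz = (Kzz.sum() - np.trace(Kzz)) / (m * (m - 1))
    else:
        xx = Kxx.sum() / n**2
        zz = Kzz.sum() / m**2
    return xx + zz - 2 * Kxz.sum() / (n * m)


class TestInnerKernel:
    @pytest.mark.parametrize(
        "spec,x,z,expected",
        [
            (km.InnerKernelSpec("rbf"), 7.3, 7.3, 1.0),
            (km.InnerKernelSpec("rbf", gamma=1.0), 0.0, 1.0, np.exp(-1.0)),
            (km.InnerKernelSpec("linear"), 10.0, 12.0, 120.0),
            (km.InnerKernelSpec("polynomial", degree=2, coef0=1.0), 1.0, 2.0, 9.0),
        ],
    )
    def test_closed_forms(self, spec, x, z, expected):
        assert km.inner_kernel_eval(x, z, spec) == pytest.approx(expected)
        assert km.inner_kernel_eval(z, x, spec) == pytest.approx(expected)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            km.InnerKernelSpec("rbf", gamma=0.0)
        with pytest.raises(ValueError):
            km.InnerKernelSpec("polynomial", degree=0)
        with pytest.raises(ValueError):
            km.InnerKernelSpec("sinc")


class TestDeterministicSample:
    def test_height_point_two_gives_fifth_of_budget(self):
        grid = km.FrequencyGrid(np.array([8.0, 10.0, 12.0, 14.0]), 2.0)
        s = km.ChannelSpectrum(grid, np.array([0.3, 0.2, 0.4, 0.1]))
        out = km.deterministic_sample(s, 1000)
        assert out.counts[1] == 200
        assert out.counts.sum() == 1000

    def test_single_bin_gets_everything(self):
        grid = km.FrequencyGrid(np.array([9.5]), 1.0)
        out = km.deterministic_sample(km.ChannelSpectrum(grid, np.array([1.0])), 7)
        assert list(out.counts) == [7]

    def test_largest_remainder_on_thirds(self):
        grid = km.FrequencyGrid(np.array([1.0, 2.0, 3.0]), 1.0)
        s = km.ChannelSpectrum(grid, np.ones(3) / 3)
        out = km.deterministic_sample(s, 10)
        assert out.counts.sum() == 10
        assert set(out.counts) <= {3, 4}
        assert out.counts[0] == 4  # tie broken toward the lower frequency

    def test_zero_weight_bins_get_zero(self):
        grid = km.FrequencyGrid(np.array([1.0, 2.0, 3.0]), 1.0)
        s = km.ChannelSpectrum(grid, np.array([0.5, 0.0, 0.5]))
        out = km.deterministic_sample(s, 11)
        assert out.counts[1] == 0

    @given(seed=st.integers(0, 2**16), n=st.integers(1, 500))
    @settings(max_examples=40, deadline=None)
    def test_counts_always_sum_to_budget(self, seed, n):
        rng = np.random.default_rng(seed)
        _, spectra = random_unit_spectra(rng, 1, n_bins=6)
        out = km.deterministic_sample(spectra[0], n)
        assert out.counts.sum() == n

    def test_rejects_bad_inputs(self):
        grid = km.FrequencyGrid(np.array([1.0, 2.0]), 1.0)
        s = km.ChannelSpectrum(grid, np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            km.deterministic_sample(s, 0)
        with pytest.raises(ValueError):
            km.deterministic_sample(km.ChannelSpectrum(grid, np.array([1.0, 1.0])), 5)


class TestMMDEstimators:
    @pytest.mark.parametrize("family", ["rbf", "linear", "polynomial"])
    @pytest.mark.parametrize("unbiased", [False, True])
    def test_matches_naive_expanded_double_sum(self, rng, family, unbiased):
        spec = km.InnerKernelSpec(family)
        for _ in range(10):
            _, spectra = random_unit_spectra(rng, 2, n_bins=6)
            n, m = rng.integers(5, 51, size=2)
            P = km.deterministic_sample(spectra[0], int(n))
            Q = km.deterministic_sample(spectra[1], int(m))
            fast = km.mmd_squared_samples(P, Q, spec, unbiased=unbiased)
            slow = naive_mmd2(P.expand(), Q.expand(), spec, unbiased=unbiased)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_weighted_equals_samples_when_counts_integral(self, rng):
        spec = km.InnerKernelSpec("rbf")
        grid = km.FrequencyGrid(2.0 + 0.5 * np.arange(6), 0.5)
        for _ in range(10):
            n = 1000
            cw = rng.multinomial(n, np.ones(6) / 6)
            cv = rng.multinomial(n, rng.dirichlet(np.ones(6)))
            P = km.ChannelSpectrum(grid, cw / n)
            Q = km.ChannelSpectrum(grid, cv / n)
            exact = km.mmd_squared_weighted(P, Q, spec)
            sampled = km.mmd_squared_samples(
                km.deterministic_sample(P, n), km.deterministic_sample(Q, n), spec
            )
            assert exact == pytest.approx(sampled, abs=1e-10)

    def test_identical_distributions_give_zero(self, rng):
        _, spectra = random_unit_spectra(rng, 1)
        P = spectra[0]
        for family in ("rbf", "linear", "polynomial"):
            spec = km.InnerKernelSpec(family)
            assert abs(km.mmd_squared_weighted(P, P, spec)) < 1e-12
            S = km.deterministic_sample(P, 100)
            assert abs(km.mmd_squared_samples(S, S, spec)) < 1e-12

    def test_linear_kernel_two_point_closed_form(self):
        grid = km.FrequencyGrid(np.array([10.0, 12.0]), 2.0)
        P = km.ChannelSpectrum(grid, np.array([1.0, 0.0]))
        Q = km.ChannelSpectrum(grid, np.array([0.0, 1.0]))
        spec = km.InnerKernelSpec("linear")
        # 10^2 + 12^2 - 2*10*12 = 4
        assert km.mmd_squared_weighted(P, Q, spec) == pytest.approx(4.0)
        S, T = km.deterministic_sample(P, 50), km.deterministic_sample(Q, 50)
        assert km.mmd_squared_samples(S, T, spec) == pytest.approx(4.0)

    def test_linear_kernel_is_mean_difference(self, rng):
        spec = km.InnerKernelSpec("linear")
        for _ in range(10):
            _, spectra = random_unit_spectra(rng, 2)
            P, Q = spectra
            d = np.sqrt(max(km.mmd_squared_weighted(P, Q, spec), 0.0))
            assert d == pytest.approx(
                abs(P.mean_frequency() - Q.mean_frequency()), abs=1e-9
            )

    def test_symmetry(self, rng):
        spec = km.InnerKernelSpec("rbf")
        _, spectra = random_unit_spectra(rng, 2)
        P, Q = spectra
        assert km.mmd_squared_weighted(P, Q, spec) == pytest.approx(
            km.mmd_squared_weighted(Q, P, spec), abs=1e-12
        )

    def test_rbf_separates_distinct_distributions(self, rng):
        spec = km.InnerKernelSpec("rbf")
        for _ in range(20):
            _, spectra = random_unit_spectra(rng, 2)
            P, Q = spectra
            if np.allclose(P.weights, Q.weights):
                continue
            assert km.mmd_squared_weighted(P, Q, spec) > 0

    def test_triangle_inequality_on_random_triples(self, rng):
        spec = km.InnerKernelSpec("rbf")

        def d(a, b):
            return np.sqrt(max(km.mmd_squared_weighted(a, b, spec), 0.0))

        for _ in range(100):
            _, spectra = random_unit_spectra(rng, 3)
            P, Q, R = spectra
            assert d(P, R) <= d(P, Q) + d(Q, R) + 1e-9

    def test_grid_mismatch_errors(self, rng):
        a = km.ChannelSpectrum(km.FrequencyGrid(np.array([1.0, 2.0]), 1.0),
                               np.array([0.5, 0.5]))
        b = km.ChannelSpectrum(km.FrequencyGrid(np.array([1.5, 2.5]), 1.0),
                               np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            km.mmd_squared_weighted(a, b, km.InnerKernelSpec())


class TestDistanceMatrix:
    def test_identical_spectra_give_zero_matrix(self):
        grid = km.FrequencyGrid(np.array([1.0, 2.0, 3.0]), 1.0)
        import pandas as pd

        meta = pd.DataFrame(
            {"subject_id": ["a", "b", "c"], "age": [1.0, 2.0, 3.0],
             "sex": ["F", "M", "F"], "site": ["X"] * 3}
        )
        W = np.tile(np.array([0.2, 0.3, 0.5]), (3, 1))
        cohort = km.Cohort(meta, ["C3"], grid, {"C3": W})
        D = km.distance_matrix(cohort, "C3")
        np.testing.assert_allclose(D.values, 0.0, atol=1e-12)

    def test_matches_pairwise_weighted_calls(self, small_cohort):
        spec = km.InnerKernelSpec("rbf")
        sub = small_cohort.take(np.arange(8))
        D = km.distance_matrix(sub, "Pz", spec)
        for i in range(8):
            for j in range(i, 8):
                expect = np.sqrt(
                    max(
                        km.mmd_squared_weighted(
                            km.ChannelSpectrum(sub.grid, sub.spectra["Pz"][i]),
                            km.ChannelSpectrum(sub.grid, sub.spectra["Pz"][j]),
                            spec,
                        ),
                        0.0,
                    )
                )
                assert D.values[i, j] == pytest.approx(expect, abs=1e-9)
        np.testing.assert_allclose(D.values, D.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D.values), 0.0, atol=1e-12)

    def test_sample_mode_converges_to_weighted(self, small_cohort):
        sub = small_cohort.take(np.arange(6))
        Dw = km.distance_matrix(sub, "Pz")
        errs = []
        for n in (100, 1000, 10000):
            Ds = km.distance_matrix(sub, "Pz", mode="samples", n=n)
            errs.append(np.max(np.abs(Ds.values - Dw.values)))
        assert errs[2] < errs[0]
        assert errs[2] < 1e-3

    def test_cache_hits_on_identical_request(self, small_cohort):
        cache = km.DistanceCache()
        D1 = km.distance_matrix(small_cohort, "Pz", cache=cache)
        D2 = km.distance_matrix(small_cohort, "Pz", cache=cache)
        assert cache.hits == 1 and cache.misses == 1
        assert D1 is D2

    def test_requires_unit_mass(self, small_cohort):
        bad = small_cohort.take(np.arange(4))
        bad.spectra["Pz"] = bad.spectra["Pz"] * 2.0
        with pytest.raises(ValueError, match="unit mass"):
            km.distance_matrix(bad, "Pz")

    def test_csv_round_trip(self, tmp_path, small_cohort):
        sub = small_cohort.take(np.arange(5))
        D = km.distance_matrix(sub, "Pz")
        D.to_csv(tmp_path / "d.csv")
        back = km.DistanceMatrix.from_csv(tmp_path / "d.csv")
        np.testing.assert_allclose(back.values, D.values, atol=1e-12)
        assert back.subject_ids == D.subject_ids
        assert back.kernel == D.kernel
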