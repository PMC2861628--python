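"""Template decoding, localization matrices, information and fits."""

import numpy as np
import pytest

from mossyinfo.decoding import (
    InfoEstimate,
    TemplateSet,
    average_curve,
    bias_correction,
    build_localization,
    build_templates,
    decode,
    decode_step,
    fit_info_curve,
    info_vs_sample_size,
    mutual_information,
)
from mossyinfo.errors import InvalidInputError, ParameterError


def template_set(means):
    means = np.asarray(means, dtype=float)
    return TemplateSet(means=means, visits=np.ones(means.shape[0], dtype=int))


class TestDecode:
    def test_exact_template_and_tie_break(self):
        tpl = template_set([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        assert decode_step(np.array([2.0, 3.0]), tpl) == 1
        equidistant = template_set([[1.0, 0.0], [0.0, 1.0]])
        assert decode_step(np.array([0.5, 0.5]), equidistant) == 0

    def test_matches_brute_force_argmin(self):
        rng = np.random.default_rng(0)
        tpl = template_set(rng.normal(size=(50, 7)))
        r = rng.normal(size=(200, 7))
        got = decode(r, tpl)
        dist = ((r[:, None, :] - tpl.means[None, :, :]) ** 2).sum(-1)
        np.testing.assert_array_equal(got, np.argmin(dist, axis=1))

    def test_dimension_mismatch_and_empty(self):
        tpl = template_set(np.ones((4, 3)))
        with pytest.raises(InvalidInputError):
            decode(np.ones((5, 2)), tpl)

    def test_unvisited_bins_get_population_mean(self):
        rates = np.ones((10, 2))
        bins = np.zeros(10, dtype=int)
        with pytest.warns(UserWarning, match="unvisited"):
            tpl = build_templates(rates, bins, 4)
        assert tpl.missing == (1, 2, 3)
        np.testing.assert_allclose(tpl.means, 1.0)


class TestLocalization:
    def test_perfect_decoding_is_diagonal(self):
        bins = np.arange(400)
        mat = build_localization(bins, bins, 20)
        assert mat.full.shape == (400, 400)  # 160,000 entries
        assert np.array_equal(mat.full, np.eye(400, dtype=int))
        assert mat.simplified[0, 0] == 400 and mat.simplified.sum() == 400

    def test_simplified_is_displacement_marginal_of_full(self):
        rng = np.random.default_rng(1)
        actual = rng.integers(0, 400, size=5000)
        decoded = rng.integers(0, 400, size=5000)
        mat = build_localization(actual, decoded, 20)
        # reduce the full matrix over displacements and compare
        reduced = np.zeros((20, 20), dtype=int)
        for a in range(400):
            row = mat.full[a]
            if not row.any():
                continue
            ar, ac = divmod(a, 20)
            for d in np.flatnonzero(row):
                dr, dc = divmod(d, 20)
                reduced[(dr - ar) % 20, (dc - ac) % 20] += row[d]
        assert np.array_equal(reduced, mat.simplified)
        assert mat.simplified.sum() == mat.n_events

    def test_bad_indices_rejected(self):
        with pytest.raises(InvalidInputError):
            build_localization([0, 400], [0, 1], 20)


class TestMutualInformation:
    def test_identity_matrix_uniform_occupancy(self):
        bins = np.repeat(np.arange(400), 3)
        est = mutual_information(build_localization(bins, bins, 20), "full")
        assert est.raw_bits == pytest.approx(np.log2(400))
        assert est.equivocation_bits == 0.0

    def test_independent_uniform_joint_is_zero(self):
        actual = np.repeat(np.arange(16), 16)
        decoded = np.tile(np.arange(16), 16)
        est = mutual_information(build_localization(actual, decoded, 4), "full")
        assert est.raw_bits == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_counts(self):
        # joint counts ((30,10),(10,30)) on a 2-bin space embedded in side 2
        actual = np.repeat([0, 1], 40)
        decoded = np.concatenate(
            [np.repeat([0, 1], [30, 10]), np.repeat([0, 1], [10, 30])]
        )
        est = mutual_information(build_localization(actual, decoded, 2), "full")
        h2 = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert est.raw_bits == pytest.approx(1.0 - h2, abs=1e-12)  # ~0.1887

    def test_identity_raw_equals_entropy_minus_equivocation(self):
        rng = np.random.default_rng(2)
        for which in ("full", "simplified"):
            actual = rng.integers(0, 100, size=3000)
            decoded = (actual + rng.integers(0, 5, size=3000)) % 100
            mat = build_localization(actual, decoded, 10)
            est = mutual_information(mat, which)
            assert est.raw_bits == pytest.approx(
                est.decoded_entropy_bits - est.equivocation_bits, abs=1e-12
            )


class TestBiasCorrection:
    def _noisy_matrix(self, n, seed=3):
        rng = np.random.default_rng(seed)
        actual = rng.integers(0, 16, size=n)
        decoded = (actual + rng.integers(0, 3, size=n)) % 16
        return build_localization(actual, decoded, 4)

    def test_vanishes_with_infinite_sampling(self):
        mat = self._noisy_matrix(400)
        big = build_localization(
            np.repeat(np.arange(16), 10000),
            np.repeat(np.arange(16), 10000),
            4,
        )
        est_small = bias_correction(mutual_information(mat, "full"), mat)
        est_big = bias_correction(mutual_information(big, "full"), big)
        assert est_small.bias_bits > est_big.bias_bits
        assert est_big.bias_bits == pytest.approx(0.0, abs=1e-4)
        assert est_big.corrected_bits == pytest.approx(est_big.raw_bits, abs=1e-4)

    def test_permutation_null_restored_to_zero(self):
        # well-sampled regime (the naive-counting first-order correction
        # is only consistent when response bins are adequately occupied)
        rng = np.random.default_rng(4)
        actual = rng.integers(0, 16, size=4000)
        decoded = (actual + rng.integers(0, 4, size=4000)) % 16
        vals = []
        for _ in range(20):
            shuffled = rng.permutation(decoded)
            mat = build_localization(actual, shuffled, 4)
            est = bias_correction(mutual_information(mat, "full"), mat)
            vals.append(est.raw_bits - est.bias_bits)  # pre-floor value
        vals = np.array(vals)
        assert abs(vals.mean()) <= 2 * vals.std(ddof=1) + 1e-3

    def test_bias_positive_when_rows_overoccupied(self):
        mat = self._noisy_matrix(200)
        est = bias_correction(mutual_information(mat, "full"), mat)
        assert est.bias_bits > 0


class TestFit:
    def test_exact_recovery(self):
        n = np.array([1, 2, 5, 10, 20, 50])
        bits = 3.0 * (1 - np.exp(-n * 0.2 / 3.0))
        i1, itot = fit_info_curve(n, bits)
        assert i1 == pytest.approx(0.2, abs=1e-4)
        assert itot == pytest.approx(3.0, abs=1e-4)

    def test_linear_data_recovers_slope(self):
        n = np.array([1, 2, 3, 4, 5])
        i1, itot = fit_info_curve(n, 0.1 * n)
        assert i1 == pytest.approx(0.1, rel=1e-3)
        assert itot > 10.0

    def test_needs_three_sizes(self):
        with pytest.raises(ParameterError):
            fit_info_curve([1, 2], [0.1, 0.2])


class TestInfoVsSampleSize:
    def test_curve_monotone_and_full_dominates(self, tiny_population):
        pop = tiny_population
        df = info_vs_sample_size(
            pop["rates"], pop["actual_bins"], pop["templates"],
            (2, 5, 10, 30), 6, 20, rng_seed=0,
        )
        full = average_curve(df, "full")
        simp = average_curve(df, "simplified")
        assert np.all(np.diff(full.bits) > -0.05)  # non-decreasing within noise
        assert np.all(full.bits >= simp.bits - 0.05)

    def test_full_population_sample_has_zero_variance(self, tiny_population):
        pop = tiny_population
        df = info_vs_sample_size(
            pop["rates"], pop["actual_bins"], pop["templates"],
            (30,), 4, 20, rng_seed=0,
        )
        assert df.groupby("which")["corrected_bits"].std().max() == 0.0

    def test_oversized_sample_rejected(self, tiny_population):
        pop = tiny_population
        with pytest.raises(ParameterError):
            info_vs_sample_size(
                pop["rates"], pop["actual_bins"], pop["templates"],
                (31,), 2, 20,
            )
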