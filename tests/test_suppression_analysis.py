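"""Function libraries, null distributions, KS comparison and P-values."""

import numpy as np
import pytest
from scipy import stats

from ftmscorr.correction import CorrectionFunction, profile_area
from ftmscorr.errors import InputError
from ftmscorr.suppression_analysis import (
    AnalysisConfig,
    FunctionLibrary,
    NullDistribution,
    assign_significance,
    build_function_library,
    default_template,
    experimental_null,
    fold_change_pvalue,
    intensity_bin,
    ks_compare,
    predict_null,
    suppression_statistics,
)
from ftmscorr.synthetic import DistortionSpec, RunSpec, generate_pair, generate_run_pair


def _correctable_pairs(n, gamma=1.5, seed0=0):
    pairs = []
    for i in range(n):
        pair, _ = generate_pair(
            true_apex=4e6, r=0.5,
            distortion=DistortionSpec("power_law", gamma, 1e6),
            noise_cv=0.0, seed=seed0 + i,
        )
        pairs.append(pair)
    return pairs


def _power_law_function(gamma, lo=1e3, threshold=1e6):
    """Correction function with knots exactly on a power-law curve."""
    ko = np.linspace(np.log10(lo), np.log10(threshold), 9)
    kt = np.log10(threshold) + (ko - np.log10(threshold)) / gamma
    return CorrectionFunction(ko, kt, threshold)


def _identity_library(n=4):
    return FunctionLibrary(
        [CorrectionFunction.identity() for _ in range(n)],
        [f"id{i}" for i in range(n)],
    )


class TestBuildFunctionLibrary:
    def test_all_correctable_pairs_fitted(self):
        lib = build_function_library(_correctable_pairs(5))
        assert len(lib) == 5
        assert not lib.skipped

    def test_uncorrectable_pairs_skipped_with_reason(self):
        pairs = _correctable_pairs(3)
        low, _ = generate_pair(true_apex=1e6, r=0.5, noise_cv=0.0, seed=50)
        off_ratio, _ = generate_pair(true_apex=2e7, r=0.1, noise_cv=0.0, seed=51)
        lib = build_function_library(pairs + [low, off_ratio])
        assert len(lib) == 3
        assert sorted(reason for _, reason in lib.skipped) == [
            "below_intensity_limit",
            "ratio_out_of_range",
        ]

    def test_no_correctable_pairs_is_an_error(self):
        low, _ = generate_pair(true_apex=1e6, r=0.5, noise_cv=0.0, seed=50)
        with pytest.raises(InputError, match="below_intensity_limit"):
            build_function_library([low])

    def test_shared_distortion_yields_agreeing_functions(self):
        lib = build_function_library(_correctable_pairs(4, gamma=1.5))
        lo = max(f.valid_range[0] for f in lib.functions)
        grid = np.logspace(np.log10(lo), 6.0, 30)
        reference = lib.functions[0](grid)
        for f in lib.functions[1:]:
            assert f(grid) == pytest.approx(reference, rel=0.05)


class TestSuppressionStatistics:
    def test_identity_library_has_unit_ratio_no_spread(self):
        stats_df = suppression_statistics(
            _identity_library(), default_template(), levels=[1e4, 1e5, 1e6]
        )
        assert stats_df["mean_ratio"].to_numpy() == pytest.approx([1.0] * 3)
        assert stats_df["sd"].to_numpy() == pytest.approx([0.0] * 3, abs=1e-12)

    def test_single_power_law_matches_numeric_integration(self):
        gamma = 1.5
        lib = FunctionLibrary([_power_law_function(gamma)], ["g"])
        template = default_template()
        level = 1e5
        stats_df = suppression_statistics(lib, template, [level])
        scaled = template.intensities * level
        distorted = np.where(
            scaled > 0, 1e6 * (scaled / 1e6) ** gamma, 0.0
        )  # fully below threshold at this level
        expected = np.trapezoid(distorted, template.times) / np.trapezoid(
            scaled, template.times
        )
        assert stats_df["mean_ratio"].iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_heterogeneous_library_spread_grows_at_low_intensity(self):
        lib = FunctionLibrary(
            [_power_law_function(g) for g in (1.2, 1.5, 1.8)], list("abc")
        )
        stats_df = suppression_statistics(
            lib, default_template(), levels=[1e5, 3e5, 3e6]
        )
        sds = stats_df["sd"].to_numpy()
        assert sds[0] > sds[1] > sds[2]
        assert sds[2] < 0.05


class TestExperimentalNull:
    def test_identical_runs_have_zero_log_ratios(self):
        spec = RunSpec(n_peptides=60, apex_low=2e6, apex_high=2e7,
                       sigma_log10=0.0, noise_cv=0.0, seed=1)
        run1, run2, _ = generate_run_pair(spec)
        null = experimental_null(run1.pairs, run2.pairs)
        assert null.kind == "experimental"
        assert null.log_ratios == pytest.approx(0.0, abs=1e-12)

    def test_global_scaling_shifts_all_ratios(self):
        spec = RunSpec(n_peptides=40, apex_low=3e6, apex_high=2e7,
                       sigma_log10=0.0, noise_cv=0.0, seed=2)
        run1, run2, _ = generate_run_pair(spec)
        for p in run2.pairs:
            p.y1 = p.y1.with_intensities(1.1 * p.y1.intensities)
        null = experimental_null(run1.pairs, run2.pairs)
        assert null.log_ratios == pytest.approx(np.log10(1.1), abs=1e-6)

    def test_lognormal_variation_recovered(self):
        spec = RunSpec(n_peptides=100, apex_low=3e6, apex_high=3e7,
                       distortion_family="identity", seed=3)
        run1, run2, _ = generate_run_pair(spec)
        null = experimental_null(run1.pairs, run2.pairs)
        assert null.sd == pytest.approx(0.05 * np.sqrt(2), rel=0.20)

    def test_too_few_matches_is_an_error(self):
        spec = RunSpec(n_peptides=10, apex_low=1e4, apex_high=1e5, seed=4)
        run1, run2, _ = generate_run_pair(spec)
        with pytest.raises(InputError, match="suppression-free"):
            experimental_null(run1.pairs, run2.pairs)


class TestPredictNull:
    def _exp_null(self, n=60, sd=0.07, seed=0):
        r = np.random.default_rng(seed)
        return NullDistribution(r.normal(0, sd, n), kind="experimental")

    def test_identity_library_reproduces_experimental_null(self):
        exp = self._exp_null()
        pred = predict_null(
            exp, _identity_library(), default_template(), level=1e5,
            n_draws=2000, seed=1,
        )
        _, p = ks_compare(pred, exp)
        assert p > 0.05

    def test_concentrated_null_maps_to_exactly_one(self):
        exp = NullDistribution(np.zeros(50), kind="experimental")
        lib = FunctionLibrary([_power_law_function(1.6)], ["g"])
        pred = predict_null(exp, lib, default_template(), 1e5, n_draws=100, seed=2)
        assert pred.log_ratios == pytest.approx(0.0, abs=1e-12)

    def test_suppressive_library_widens_low_intensity_null(self):
        exp = self._exp_null()
        lib = FunctionLibrary(
            [_power_law_function(g) for g in (1.3, 1.6, 1.9)], list("abc")
        )
        lo = predict_null(exp, lib, default_template(), 1e5, 500, seed=3)
        hi = predict_null(exp, lib, default_template(), 5e6, 500, seed=3)
        assert lo.sd > hi.sd

    def test_level_above_library_range_flagged(self):
        exp = self._exp_null()
        pred = predict_null(exp, _identity_library(), default_template(),
                            level=5e6, n_draws=100, seed=4)
        assert pred.warning is not None

    def test_seeded_determinism(self):
        exp = self._exp_null()
        lib = FunctionLibrary([_power_law_function(1.5)], ["g"])
        a = predict_null(exp, lib, default_template(), 1e5, 200, seed=9)
        b = predict_null(exp, lib, default_template(), 1e5, 200, seed=9)
        assert np.array_equal(a.log_ratios, b.log_ratios)

    def test_requires_experimental_kind(self):
        obs = NullDistribution(np.zeros(40), kind="observed")
        with pytest.raises(InputError, match="experimental"):
            predict_null(obs, _identity_library(), default_template(), 1e5)


class TestKsCompare:
    def test_identical_samples(self):
        a = NullDistribution(np.linspace(-1, 1, 50), kind="observed")
        b = NullDistribution(np.linspace(-1, 1, 50), kind="observed")
        d, p = ks_compare(a, b)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_shifted_distributions_rejected(self):
        r = np.random.default_rng(0)
        a = NullDistribution(r.normal(0, 1, 200), kind="observed")
        b = NullDistribution(r.normal(5, 1, 200), kind="observed")
        _, p = ks_compare(a, b)
        assert p < 1e-6

    def test_small_samples_rejected(self):
        a = NullDistribution(np.zeros(3), kind="observed")
        with pytest.raises(InputError, match="at least 5"):
            ks_compare(a, a)


class TestFoldChangePvalue:
    def _null(self, n=99, seed=0):
        r = np.random.default_rng(seed)
        return NullDistribution(r.normal(0.02, 0.1, n), kind="experimental")

    def test_fold_change_at_null_median_has_p_one(self):
        null = self._null()
        fc = 10.0 ** null.median
        assert fold_change_pvalue(fc, null) == 1.0

    def test_extreme_fold_change_add_one_rule(self):
        null = self._null(n=99)
        assert fold_change_pvalue(1e6, null) == pytest.approx(1 / 100)

    def test_monotone_in_deviation(self):
        null = self._null()
        fcs = 10.0 ** (null.median + np.linspace(0, 0.5, 12))
        ps = [fold_change_pvalue(fc, null) for fc in fcs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_null_drawn_fold_changes_give_uniform_pvalues(self):
        """Empirical P-values of fold changes drawn from the null itself are
        uniform on (0, 1] (KS test at alpha = 0.01, n = 500)."""
        r = np.random.default_rng(42)
        null = NullDistribution(r.normal(0, 0.08, 2000), kind="experimental")
        draws = 10.0 ** r.normal(0, 0.08, 500)
        ps = np.array([fold_change_pvalue(fc, null) for fc in draws])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_null_rejected(self):
        null = NullDistribution(np.zeros(10), kind="experimental")
        with pytest.raises(InputError, match="too small"):
            fold_change_pvalue(1.5, null)


class TestIntensityBin:
    def test_half_decade_bins(self):
        assert intensity_bin(10 ** 4.6) == pytest.approx(10 ** 4.75)
        assert intensity_bin(10 ** 5.0) == pytest.approx(10 ** 5.25)


class TestAssignSignificance:
    def test_unit_fold_changes_get_p_one(self):
        """A run compared against itself: every fold change is 1 and every
        P-value is 1."""
        spec = RunSpec(n_peptides=45, apex_low=2e6, apex_high=2e7,
                       sigma_log10=0.0, noise_cv=0.0, seed=21)
        run1, run2, _ = generate_run_pair(spec)
        lib = build_function_library(run1.pairs)
        null = experimental_null(run1.pairs, run2.pairs)
        results = assign_significance(run1.pairs, run2.pairs, lib, null)
        assert len(results) == 45
        ok = [r for r in results if not np.isnan(r.p_value)]
        assert len(ok) == 45
        for r in ok:
            assert r.fold_change == pytest.approx(1.0, rel=1e-6)
            assert r.p_value == 1.0

    def test_uncorrectable_peptide_judged_against_wider_null(self, qc_run_pair,
                                                             qc_library,
                                                             qc_exp_null):
        """The predicted null at low intensity is wider than the
        experimental null, so the same fold change is less significant."""
        pred = predict_null(
            qc_exp_null, qc_library, default_template(), 10 ** 4.75,
            n_draws=1000, seed=5,
        )
        assert pred.sd > qc_exp_null.sd
        fc = 10.0 ** (qc_exp_null.median + 0.15)
        assert fold_change_pvalue(fc, pred) > fold_change_pvalue(fc, qc_exp_null)

    def test_spiked_peptide_is_most_significant(self, qc_run_pair):
        run1, run2, truth = qc_run_pair
        lib = build_function_library(run1.pairs)
        null = experimental_null(run1.pairs, run2.pairs)
        # spike a high-intensity peptide 3x (in true abundance) in run 2;
        # the observed profile is the spiked true profile re-distorted
        from ftmscorr.synthetic import DistortionSpec, make_distortion

        idx = int(np.argmax([p.y1.apex_intensity for p in run1.pairs]))
        spiked = run2.pairs[idx]
        gamma = float(
            truth.loc[truth.sequence == spiked.peptide.sequence, "gamma"].iloc[0]
        )
        g, f = make_distortion(DistortionSpec("power_law", gamma, 1e6))
        spiked.y1 = spiked.y1.with_intensities(g(3.0 * f(spiked.y1.intensities)))
        spiked.y2 = spiked.y2.with_intensities(g(3.0 * f(spiked.y2.intensities)))
        results = assign_significance(run1.pairs, run2.pairs, lib, null)
        by_seq = {r.sequence: r for r in results if not np.isnan(r.p_value)}
        spiked_p = by_seq[spiked.peptide.sequence].p_value
        assert spiked_p == min(r.p_value for r in by_seq.values())

    def test_correctable_peptides_report_corrected_abundance(self, qc_run_pair):
        run1, run2, _ = qc_run_pair
        lib = build_function_library(run1.pairs)
        null = experimental_null(run1.pairs, run2.pairs)
        results = assign_significance(run1.pairs, run2.pairs, lib, null)
        corrected = [r for r in results if r.correctable]
        assert corrected, "expected some correctable peptides at defaults"
        for r in corrected:
            assert r.abundance_after[0] >= r.abundance_before[0] * 0.999
            assert r.abundance_after[1] >= r.abundance_before[1] * 0.999


class TestNullTsv:
    def test_round_trip(self, tmp_path):
        null = NullDistribution(np.array([-0.1, 0.0, 0.2]), kind="experimental")
        path = tmp_path / "null.tsv"
        null.to_tsv(path)
        back = NullDistribution.from_tsv(path)
        assert back.log_ratios == pytest.approx(null.log_ratios)
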