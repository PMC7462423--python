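import numpy as np
import pandas as pd
import pytest

from spikepid import (
    PipelineConfig,
    Recording,
    bootstrap_median_ci,
    compare_groups,
    decile_summarize,
    holm_correct,
    loglog_fit,
    network_stats,
    rank_sum_test,
    run_pipeline,
    saturation_point,
    signed_rank_test,
    term_correlation,
)
from spikepid.errors import ConfigurationError, ValidationError
from spikepid.regime_analysis import DecileSummary
from spikepid.synthetic_data import NetworkSpec, generate_network

from oracles import spearman_brute


def _triad_frame(mi, synergy=None, redundancy=None, mvte=None):
    mi = np.asarray(mi, dtype=float)
    synergy = np.asarray(synergy if synergy is not None else mi * 0.5)
    redundancy = np.asarray(redundancy if redundancy is not None else mi * 0.1)
    mvte = np.asarray(mvte if mvte is not None else synergy + redundancy)
    return pd.DataFrame(
        {"mi_norm": mi, "synergy": synergy, "redundancy": redundancy, "mvte": mvte}
    )


def _summary_from_rows(mi, synergy):
    frame = pd.DataFrame(
        {
            "decile": np.arange(1, 11),
            "n": 10,
            "mi_norm": mi,
            "synergy": synergy,
            "redundancy": synergy,
            "mvte": synergy,
            "transmission_minus_redundancy": synergy,
        }
    )
    return DecileSummary(frame=frame, usable=True, n_triads=100)


class TestDecileSummarize:
    def test_twenty_triads_give_pairwise_medians(self):
        summary = decile_summarize(_triad_frame(np.arange(1, 21)))
        assert summary.usable
        assert summary.frame["mi_norm"].tolist() == [1.5 + 2 * k for k in range(10)]
        assert summary.frame["n"].tolist() == [2] * 10

    def test_identical_triads_give_flat_deciles(self):
        summary = decile_summarize(_triad_frame(np.full(30, 0.2)))
        assert summary.frame["mi_norm"].nunique() == 1
        assert summary.frame["synergy"].nunique() == 1

    def test_monotone_synergy_preserved_across_deciles(self, rng):
        mi = np.sort(rng.random(173))
        summary = decile_summarize(_triad_frame(mi, synergy=mi**2))
        assert summary.frame["synergy"].is_monotonic_increasing
        assert summary.frame["mi_norm"].is_monotonic_increasing

    def test_remainder_spread_over_lowest_deciles_conserves_triads(self, rng):
        for n in (10, 73, 105, 999):
            summary = decile_summarize(_triad_frame(rng.random(n)))
            counts = summary.frame["n"].to_numpy()
            assert counts.sum() == n
            assert counts.max() - counts.min() <= 1
            assert np.all(np.diff(counts) <= 0)  # extras go to the lowest-MI bins

    def test_fewer_than_ten_triads_flagged_unusable(self):
        assert not decile_summarize(_triad_frame(np.arange(9))).usable


class TestCorrelationAndFits:
    def test_monotone_relationships_saturate_spearman(self):
        x = np.linspace(0.01, 0.1, 10)
        assert term_correlation(_summary_from_rows(x, x**2), "mi_norm", "synergy") == pytest.approx(1.0, abs=1e-12)
        assert term_correlation(_summary_from_rows(x, -x), "mi_norm", "synergy") == pytest.approx(-1.0, abs=1e-12)

    def test_spearman_matches_rank_oracle_on_noisy_curve(self, rng):
        x = np.linspace(0.01, 0.1, 10)
        y = x**0.5 * np.exp(rng.normal(0, 0.3, 10))
        r = term_correlation(_summary_from_rows(x, y), "mi_norm", "synergy")
        assert r == pytest.approx(spearman_brute(x, y), abs=1e-12)

    def test_power_law_slope_recovered_exactly(self):
        x = np.linspace(0.01, 0.1, 10)
        for c in (1.0, 7.3):
            fit = loglog_fit(_summary_from_rows(x, c * x**0.5), "mi_norm", "synergy")
            assert fit.slope == pytest.approx(0.5, abs=1e-10)

    def test_constant_y_gives_zero_slope(self):
        x = np.linspace(0.01, 0.1, 10)
        fit = loglog_fit(_summary_from_rows(x, np.full(10, 2.0)), "mi_norm", "synergy")
        assert fit.slope == pytest.approx(0.0, abs=1e-10)

    def test_linear_fit_without_log_scaling(self):
        x = np.linspace(0.01, 0.1, 10)
        fit = loglog_fit(_summary_from_rows(x, 2 * x), "mi_norm", "synergy", log_scale=False)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_medians_excluded_not_floored(self):
        x = np.linspace(0.01, 0.1, 10)
        y = x.copy()
        y[:3] = 0.0
        fit = loglog_fit(_summary_from_rows(x, y), "mi_norm", "synergy")
        assert fit.n_excluded == 3 and fit.n_points == 7

    def test_network_stats_table_shape(self):
        x = np.linspace(0.01, 0.1, 10)
        stats = network_stats(_summary_from_rows(x, x**0.46))
        assert {"spearman_r", "slope_loglog", "slope_linear"} <= set(stats.columns)
        assert len(stats) == 6


class TestBootstrap:
    def test_constant_vector_collapses_ci(self):
        med, lo, hi = bootstrap_median_ci(np.full(50, 3.0), n_boot=200, seed=1)
        assert med == lo == hi == 3.0

    def test_same_seed_reproduces_ci(self, rng):
        v = rng.normal(size=40)
        assert bootstrap_median_ci(v, 500, seed=9) == bootstrap_median_ci(v, 500, seed=9)

    def test_ci_covers_true_median_near_nominal_rate(self):
        root = np.random.default_rng(77)
        covered = 0
        for _ in range(200):
            v = root.normal(size=100)
            _, lo, hi = bootstrap_median_ci(v, n_boot=500, seed=root.integers(2**31))
            covered += lo <= 0 <= hi
        assert 0.85 <= covered / 200 <= 1.0


class TestRankTests:
    def test_signed_rank_symmetric_sample_is_null(self):
        v = np.concatenate([np.arange(1, 26), -np.arange(1, 26)])
        z, p = signed_rank_test(v, 0.0)
        assert abs(z) < 1e-12 and p == pytest.approx(1.0)

    def test_signed_rank_uniform_sign_hits_closed_form(self):
        n = 75
        z, p = signed_rank_test(np.arange(1, n + 1), 0.0)
        expected = (n * (n + 1) / 4) / np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        assert z == pytest.approx(expected, abs=1e-12)
        assert z == pytest.approx(7.52, abs=0.01)

    def test_signed_rank_antisymmetry(self, rng):
        v = rng.normal(0.3, 1.0, 40)
        z1, _ = signed_rank_test(v, 0.0)
        z2, _ = signed_rank_test(-v, 0.0)
        assert z1 == pytest.approx(-z2)

    def test_signed_rank_rejects_degenerate_input(self):
        with pytest.raises(ValidationError):
            signed_rank_test(np.zeros(10), 0.0)
        with pytest.raises(ValidationError):
            signed_rank_test([1.0, 2.0], 0.0)

    def test_rank_sum_identical_groups_is_null(self, rng):
        v = rng.normal(size=30)
        z, p = rank_sum_test(v, v)
        assert abs(z) < 1e-12

    def test_rank_sum_fully_separated_hits_closed_form(self):
        a, b = np.arange(100, 175), np.arange(75.0)
        z, p = rank_sum_test(a, b)
        n1 = n2 = 75
        expected = (n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert z == pytest.approx(expected, abs=1e-12)
        assert z == pytest.approx(10.57, abs=0.01)

    def test_rank_sum_label_swap_negates_z(self, rng):
        a, b = rng.normal(0.5, 1, 20), rng.normal(0, 1, 25)
        assert rank_sum_test(a, b)[0] == pytest.approx(-rank_sum_test(b, a)[0])

    def test_compare_groups_paired_and_unpaired(self, rng):
        a = rng.normal(0.9, 0.05, 20)
        b = rng.normal(-0.7, 0.05, 20)
        unpaired = compare_groups(a, b, n_boot=200, seed=0)
        paired = compare_groups(a, b, paired=True, n_boot=200, seed=0)
        assert unpaired.z > 5 and paired.z > 3
        assert unpaired.statistic_type == "rank_sum"
        assert paired.statistic_type == "signed_rank"


class TestHolm:
    def test_two_p_example(self):
        np.testing.assert_allclose(holm_correct([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_correct([0.2]), [0.2])

    def test_adjusted_dominates_raw_and_caps_at_one(self, rng):
        p = rng.random(12)
        adj = holm_correct(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        # adjusted values keep the ordering of the raw evidence (ties allowed)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_correct([0.5, 1.2])


class TestSaturation:
    def test_interior_peak_is_located(self):
        x = np.linspace(0.01, 0.13, 10)
        syn = -((x - x[6]) ** 2)
        res = saturation_point([_summary_from_rows(x, syn + 1.0)], n_boot=100, seed=0)
        assert res.median_mi == pytest.approx(x[6])
        assert not res.boundary_flags[0]

    def test_monotone_curve_flagged_at_boundary(self):
        x = np.linspace(0.01, 0.13, 10)
        res = saturation_point([_summary_from_rows(x, x)], n_boot=100, seed=0)
        assert res.median_mi == pytest.approx(x[-1])
        assert res.boundary_flags[0]


class TestPipeline:
    def test_missing_input_path_fails_before_compute(self, tmp_path):
        config = PipelineConfig(
            recordings=[tmp_path / "nope.tsv"], timescale_ids=[4], n_jitter=60, alpha=0.05
        )
        with pytest.raises(ConfigurationError):
            run_pipeline(config)

    def test_bundle_shape_on_synthetic_network(self, tmp_path):
        rec, _ = generate_network(
            NetworkSpec(n_neurons=12, n_edges=16, duration_s=60.0, seed=21,
                        reliability_range=(0.6, 0.9))
        )
        config = PipelineConfig(
            recordings=[rec], timescale_ids=[4, 7], out_dir=tmp_path,
            n_jitter=60, alpha=0.05, n_boot=100, seed=3,
        )
        result = run_pipeline(config)
        assert len(result.networks) == 2
        assert {nr.timescale_id for nr in result.networks} == {4, 7}
        for nr in result.networks:
            assert set(nr.triad_frame.columns) >= {"mi_norm", "synergy", "redundancy", "mvte"}
        assert (tmp_path / "manifest.json").exists()
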