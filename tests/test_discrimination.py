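"""Ratio statistics, rank tests, AUC, dose-response fits and falsification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from camnet.discrimination import (
    auc_trapezoid,
    classify_models,
    compute_ratios,
    fit_dose_response,
    mann_whitney_one_tailed,
    normalize_onbead,
    onbead_percent_binding,
    replicate_aucs,
)
from camnet.network import Concentrations, ModelVariant
from camnet.predictions import predict_table
from camnet.synthetic import NoiseModel, simulate_baseline, simulate_fret


def exact_mw_p_greater(sample, baseline):
    """Independent oracle: enumerate every assignment of pooled ranks."""
    pooled = list(sample) + list(baseline)
    n1 = len(sample)
    obs_u = sum(
        1 for x in sample for y in baseline if x > y
    ) + 0.5 * sum(1 for x in sample for y in baseline if x == y)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in combo]
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for x in grp for y in rest if x > y) + 0.5 * sum(
            1 for x in grp for y in rest if x == y
        )
        total += 1
        if u >= obs_u:
            count += 1
    return count / total


class TestComputeRatios:
    def test_elementwise_division_with_labels(self):
        df = pd.DataFrame(
            {"condition": ["a"], "replicate": [1], "ca_free_uM": [0.0],
             "em480": [50.0], "em535": [100.0]}
        )
        out = compute_ratios(df)
        assert out.loc[0, "ratio"] == 0.5
        assert list(out.columns) == ["condition", "replicate", "ca_free_uM", "ratio"]

    def test_nonpositive_intensity_rejected_and_logged(self, caplog):
        df = pd.DataFrame(
            {"condition": ["a", "a"], "replicate": [1, 2], "ca_free_uM": [0.0, 0.0],
             "em480": [50.0, -1.0], "em535": [100.0, 100.0]}
        )
        with caplog.at_level("WARNING"):
            out = compute_ratios(df)
        assert len(out) == 1
        assert "rejecting" in caplog.text

    def test_zero_calcium_wild_type_matches_baseline_without_noise(
        self, ref_params, ref_conc
    ):
        # no binding at zero Ca under the partially ordered model, so the
        # sample ratio at x=0 equals the reporter-only ratio exactly
        noise = NoiseModel(channel_cv=0.0)
        sample = compute_ratios(
            simulate_fret(ref_params, ModelVariant(2), ref_conc,
                          n_replicates=3, noise=noise, seed=0)
        )
        base = compute_ratios(simulate_baseline(n_replicates=3, noise=noise, seed=1))
        s0 = sample[sample["ca_free_uM"] == 0.0]["ratio"].to_numpy()
        b0 = base[base["ca_free_uM"] == 0.0]["ratio"].to_numpy()
        assert np.allclose(s0, b0)

    def test_series_length_equals_record_count(self, ref_params, ref_conc):
        ds = simulate_fret(ref_params, ModelVariant(1), ref_conc, n_replicates=4)
        assert len(compute_ratios(ds)) == len(ds.records)


class TestMannWhitney:
    def test_small_sample_p_matches_rank_enumeration(self):
        res = mann_whitney_one_tailed([3, 4], [1, 2], "greater")
        assert res.p_value == pytest.approx(1 / 6)
        assert res.method == "exact"

    @given(
        data=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=6, max_size=10, unique=True
        ),
        split=st.integers(2, 4),
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_exact_p_agrees_with_enumeration_oracle(self, data, split):
        sample, baseline = data[:split], data[split:]
        res = mann_whitney_one_tailed(sample, baseline, "greater")
        assert res.p_value == pytest.approx(exact_mw_p_greater(sample, baseline))

    def test_identical_samples_show_no_directional_evidence(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_one_tailed(vals, vals, "greater")
        assert res.p_value >= 0.5

    def test_p_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 1, 12), rng.normal(0, 1, 9)
        p_raw = mann_whitney_one_tailed(a, b).p_value
        p_exp = mann_whitney_one_tailed(np.exp(a), np.exp(b)).p_value
        p_aff = mann_whitney_one_tailed(3 * a + 7, 3 * b + 7).p_value
        assert p_raw == p_exp == p_aff

    def test_large_or_tied_samples_use_corrected_normal_approximation(self):
        a = list(range(25))
        b = list(range(5, 30))
        res = mann_whitney_one_tailed(a, b)
        assert res.method == "asymptotic"
        res_ties = mann_whitney_one_tailed([1, 1, 2], [1, 2, 2])
        assert res_ties.method == "asymptotic"

    def test_statistic_bounded_by_product_of_sizes(self):
        res = mann_whitney_one_tailed([5, 6, 7], [1, 2], "greater")
        assert 0 <= res.statistic <= res.n1 * res.n2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0])

    def test_simulated_high_calcium_signal_detected_in_nearly_all_seeds(
        self, ref_params, ref_conc
    ):
        # power check: WT ratios at 39 uM vs reporter-only baseline
        hits = 0
        for seed in range(100):
            sample = simulate_fret(
                ref_params, ModelVariant(2), ref_conc, n_replicates=15,
                noise=NoiseModel(channel_cv=0.02), seed=seed,
            )
            base = simulate_baseline(
                n_replicates=13, noise=NoiseModel(channel_cv=0.02), seed=10_000 + seed
            )
            s = compute_ratios(sample)
            b = compute_ratios(base)
            p = mann_whitney_one_tailed(
                s[s["ca_free_uM"] == 39.0]["ratio"],
                b[b["ca_free_uM"] == 39.0]["ratio"],
            ).p_value
            hits += p < 0.05
        assert hits >= 99


class TestAuc:
    def test_constant_series(self):
        assert auc_trapezoid([0, 1, 2], [3.0, 3.0, 3.0]) == pytest.approx(6.0)

    def test_triangle_by_hand(self):
        assert auc_trapezoid([0, 1, 2], [0, 1, 0]) == pytest.approx(1.0)

    def test_range_restriction_uses_only_inside_points(self):
        x = [0.0, 0.017, 0.038, 1.0, 39.0]
        y = [1.0, 1.0, 1.0, 100.0, 100.0]
        # the huge values beyond 0.038 must not leak into the low range
        assert auc_trapezoid(x, y, ca_range=(0.0, 0.038)) == pytest.approx(0.038)

    def test_additive_over_adjacent_ranges(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 10, 20))
        y = rng.uniform(0, 5, 20)
        whole = auc_trapezoid(x, y, (x[0], x[-1]))
        left = auc_trapezoid(x, y, (x[0], x[9]))
        right = auc_trapezoid(x, y, (x[9], x[-1]))
        assert whole == pytest.approx(left + right)

    def test_nonnegative_series_gives_nonnegative_area(self):
        assert auc_trapezoid([0, 1], [0.0, 2.0]) >= 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            auc_trapezoid([0.5], [1.0])


class TestOnBeadQuantification:
    def test_equal_bands_give_fifty_percent(self):
        assert onbead_percent_binding(100.0, 100.0, 0.0) == 50.0

    def test_zero_bound_gives_zero_percent(self):
        assert onbead_percent_binding(0.0, 80.0, 0.0) == 0.0

    def test_background_dominated_signal_flagged_as_nan(self):
        assert math.isnan(onbead_percent_binding(10.0, 10.0, 50.0))

    def test_normalization_pins_endpoints_and_preserves_monotonicity(self):
        out = normalize_onbead({0.0: 10.0, 3.0: 35.0, 39.0: 60.0})
        assert out[0.0] == 0.0
        assert out[39.0] == 100.0
        assert out[3.0] == pytest.approx(50.0)
        already = normalize_onbead({0.0: 0.0, 3.0: 50.0, 39.0: 100.0})
        assert already == {0.0: 0.0, 3.0: 50.0, 39.0: 100.0}

    def test_degenerate_normalization_rejected(self):
        with pytest.raises(ValueError):
            normalize_onbead({0.0: 5.0, 39.0: 5.0})


class TestDoseResponseFit:
    def test_exact_recovery_from_noise_free_hill_curve(self):
        x = np.array([0.0, 0.05, 0.2, 0.5, 1.0, 2.0, 5.0, 20.0, 39.0])
        bottom, top, ec50, n = 0.5, 1.0, 0.8, 1.7
        y = bottom + (top - bottom) * x ** n / (ec50 ** n + x ** n)
        fit = fit_dose_response(x, y)
        assert fit.converged
        assert fit.bottom == pytest.approx(bottom, rel=1e-6)
        assert fit.top == pytest.approx(top, rel=1e-6)
        assert fit.ec50 == pytest.approx(ec50, rel=1e-6)
        assert fit.hill_slope == pytest.approx(n, rel=1e-6)

    def test_flat_series_flagged_unidentifiable(self):
        fit = fit_dose_response([0, 1, 2, 3, 4], [2.0] * 5)
        assert not fit.converged
        assert math.isnan(fit.ec50)

    def test_simulated_titration_plateau_within_two_standard_errors(
        self, ref_params, ref_conc
    ):
        ds = simulate_fret(
            ref_params, ModelVariant(2), ref_conc, n_replicates=15,
            noise=NoiseModel(channel_cv=0.02), seed=11,
        )
        ratios = compute_ratios(ds)
        mean = ratios.groupby("ca_free_uM")["ratio"].mean()
        fit = fit_dose_response(mean.index.to_numpy(), mean.to_numpy())
        assert fit.converged
        top_obs = ratios[ratios["ca_free_uM"] == 39.0]["ratio"]
        se = top_obs.std(ddof=1) / np.sqrt(len(top_obs))
        assert abs((fit.top - fit.bottom) - 0.5 * 0.999) < 2 * se + 5e-3

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([0, 1, 1, 2], [0, 1, 1, 2])


OBSERVED = {
    ("WT", "zero_ca"): "NB", ("WT", "high_ca"): "B",
    ("Nmut", "zero_ca"): "NB", ("Nmut", "high_ca"): "B",
    ("Cmut", "zero_ca"): "NB", ("Cmut", "high_ca"): "NB",
}


class TestClassifyModels:
    def test_published_observed_column_counts(self, ref_params):
        report = classify_models(OBSERVED, predict_table(ref_params))
        assert report.n_falsified == {"model1": 2, "model2": 0, "model3": 1}
        assert report.n_correct["model2"] == 6
        assert report.unfalsified_models == ["model2"]

    def test_row_counts_partition_the_conditions(self, ref_params):
        report = classify_models(OBSERVED, predict_table(ref_params))
        for model in ("model1", "model2", "model3"):
            assert report.n_falsified_rows[model] + report.n_correct[model] == 6

    def test_observed_equal_to_model_predictions_gives_zero_falsified(self, ref_params):
        table = predict_table(ref_params)
        as_observed = dict(table.calls["model3"])
        report = classify_models(as_observed, table)
        assert report.n_falsified["model3"] == 0
        assert report.n_falsified_rows["model3"] == 0

    def test_all_binding_observed_falsifies_every_nb_row(self, ref_params):
        table = predict_table(ref_params)
        all_b = {idx: "B" for idx in table.calls.index}
        report = classify_models(all_b, table)
        n_nb = int((table.calls["model2"] == "NB").sum())
        assert report.n_falsified_rows["model2"] == n_nb

    def test_index_mismatch_rejected(self, ref_params):
        table = predict_table(ref_params)
        with pytest.raises(ValueError):
            classify_models({("WT", "zero_ca"): "NB"}, table)
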