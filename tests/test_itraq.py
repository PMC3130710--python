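"""Quantifier contracts: correction, regression, outliers, bias, compositing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyomic import itraq, simulate
from polyomic.errors import ConfigError, DataError


def make_rows(intensities: dict[str, list[float]], protein="P1", run="r1") -> pd.DataFrame:
    n = len(next(iter(intensities.values())))
    return pd.DataFrame({
        "run_id": [run] * n,
        "protein_id": [protein] * n,
        "peptide_key": [f"pep{i}" for i in range(n)],
        **intensities,
    })


def design2(correction=None) -> itraq.RunDesign:
    return itraq.RunDesign(run_id="r1", channel_to_sample={"114": "KO01"},
                           reference_channel="113", correction_matrix=correction)


class TestIsotopeCorrection:
    def test_identity_matrix_is_noop(self):
        rows = make_rows({"113": [100.0, 50.0], "114": [80.0, 20.0]})
        out = itraq.apply_isotope_correction(rows, design2(np.eye(2)))
        pd.testing.assert_frame_equal(out, rows)

    def test_all_zero_rows_stay_zero(self):
        rows = make_rows({"113": [0.0], "114": [0.0]})
        out = itraq.apply_isotope_correction(rows, design2([[0.9, 0.1], [0.1, 0.9]]))
        assert (out[["113", "114"]].to_numpy() == 0).all()

    def test_two_channel_spillover_solved_by_linear_system(self):
        # oracle: explicit 2x2 inversion of [[0.9,0.1],[0.1,0.9]]
        c = np.array([[0.9, 0.1], [0.1, 0.9]])
        true = np.array([90.0, 10.0])
        observed = c @ true
        rows = make_rows({"113": [100.0, observed[0]], "114": [100.0, observed[1]]})
        out = itraq.apply_isotope_correction(rows, design2(c))
        # (100, 100) is a fixed point of a doubly-stochastic mixing
        np.testing.assert_allclose(out.loc[0, ["113", "114"]].astype(float), [100.0, 100.0])
        np.testing.assert_allclose(out.loc[1, ["113", "114"]].astype(float), true)

    def test_negative_solutions_floored_at_zero(self):
        c = np.array([[0.9, 0.1], [0.1, 0.9]])
        rows = make_rows({"113": [0.0], "114": [50.0]})  # impossible under the model
        out = itraq.apply_isotope_correction(rows, design2(c))
        assert (out[["113", "114"]].to_numpy() >= 0).all()

    def test_singular_matrix_is_config_error(self):
        with pytest.raises(ConfigError):
            itraq.apply_isotope_correction(
                make_rows({"113": [1.0], "114": [1.0]}),
                design2([[0.5, 0.5], [0.5, 0.5]]))


class TestRatioPairs:
    def test_one_pair_per_spectrum(self):
        rows = make_rows({"113": [100.0, 200.0, 300.0], "114": [10.0, 20.0, 30.0]})
        pairs, keys, dropped = itraq.build_ratio_pairs(rows, design2(), "P1", "KO01")
        assert pairs.shape == (3, 2) and dropped == 0
        np.testing.assert_array_equal(pairs[:, 0], [100.0, 200.0, 300.0])

    def test_zero_reference_dropped_and_counted(self):
        rows = make_rows({"113": [100.0, 0.0], "114": [10.0, 20.0]})
        pairs, _, dropped = itraq.build_ratio_pairs(rows, design2(), "P1", "KO01")
        assert pairs.shape == (1, 2) and dropped == 1

    def test_unknown_sample_is_error(self):
        rows = make_rows({"113": [100.0], "114": [10.0]})
        with pytest.raises(DataError):
            itraq.build_ratio_pairs(rows, design2(), "P1", "nope")

    def test_noiseless_simulated_protein_at_ratio_two(self):
        cfg = simulate.SimConfig(n_proteins=3, peptides_min=4, noise_cv=0.0,
                                 outlier_fraction=0.0, max_channel_bias=1.0, seed=5)
        truth = simulate.make_protein_truth(cfg, effects=np.zeros(3))
        truth.protein_log2_ratio.loc["P00002", :] = 0.0
        truth.protein_log2_ratio.loc["P00002", "KO03"] = 1.0
        table, designs = simulate.simulate_itraq_run(cfg, truth, "A", 0)
        design = designs[0]
        sub = table[table["run_id"] == design.run_id]
        pairs, _, _ = itraq.build_ratio_pairs(sub, design, "P00002", "KO03")
        np.testing.assert_allclose(pairs[:, 1] / pairs[:, 0], 2.0)


class TestFit:
    @pytest.mark.parametrize(
        "pairs, slope, r2",
        [
            ([(100, 200), (200, 400), (400, 800)], 2.0, 1.0),
            ([(100, 100)], 1.0, 1.0),
        ],
    )
    def test_exact_proportionality(self, pairs, slope, r2):
        s, r = itraq.fit_protein_ratio(np.array(pairs, dtype=float))
        assert s == pytest.approx(slope)
        assert r == pytest.approx(r2)

    def test_noisy_pairs_match_closed_form(self):
        pairs = np.array([(100, 210), (200, 390), (400, 820)], dtype=float)
        x, y = pairs[:, 0], pairs[:, 1]
        expected = (x * y).sum() / (x * x).sum()  # independent closed form
        s, r = itraq.fit_protein_ratio(pairs)
        assert s == pytest.approx(expected)
        assert expected == pytest.approx(2.0333, abs=1e-4)
        assert 0.0 <= r <= 1.0

    def test_empty_pairs_is_error(self):
        with pytest.raises(DataError):
            itraq.fit_protein_ratio(np.empty((0, 2)))

    @given(st.lists(
        st.tuples(st.floats(1.0, 1e6), st.floats(0.0, 1e6)), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_slope_equals_brute_force_everywhere(self, pairs):
        """Invariant: the estimator is sum(xy)/sum(x^2) on every input."""
        arr = np.array(pairs, dtype=float)
        brute = sum(x * y for x, y in pairs) / sum(x * x for x, _ in pairs)
        s, _ = itraq.fit_protein_ratio(arr)
        assert s == pytest.approx(brute, rel=1e-12, abs=1e-12)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, c):
        """Scaling every y by c scales the slope by c and leaves R^2 unchanged."""
        pairs = np.array([(100, 210), (200, 390), (400, 820), (50, 95)], dtype=float)
        s0, r0 = itraq.fit_protein_ratio(pairs)
        scaled = pairs * np.array([1.0, c])
        s1, r1 = itraq.fit_protein_ratio(scaled)
        assert s1 == pytest.approx(c * s0, rel=1e-9)
        assert r1 == pytest.approx(r0, rel=1e-9)


class TestOutliers:
    def test_clean_data_untouched(self):
        pairs = np.array([(x, 2.0 * x) for x in (10, 20, 30, 40, 50)], dtype=float)
        keep, removed = itraq.remove_regression_outliers(pairs)
        assert removed == 0 and keep.all()

    def test_gross_outlier_removed(self):
        """Nine on-line pairs plus one at 8x the line: only that one goes."""
        x = np.arange(10.0, 100.0, 10.0)
        pairs = np.column_stack([x, 2.0 * x])
        pairs = np.vstack([pairs, [50.0, 800.0]])
        keep, removed = itraq.remove_regression_outliers(pairs)
        assert removed == 1
        assert not keep[-1]

    def test_minimum_points_guard(self):
        pairs = np.array([(10, 20), (20, 40), (30, 600)], dtype=float)
        keep, removed = itraq.remove_regression_outliers(pairs)
        assert removed == 0 and keep.all()

    def test_never_trims_below_three(self):
        pairs = np.array([(10, 20), (20, 400), (30, 900), (40, 1600)], dtype=float)
        keep, removed = itraq.remove_regression_outliers(pairs, max_rounds=5)
        assert keep.sum() >= 3


def synth_estimates(slopes_by_channel: dict[str, list[float]], r2=0.95, npep=3) -> pd.DataFrame:
    rows = []
    for channel, slopes in slopes_by_channel.items():
        for i, s in enumerate(slopes):
            rows.append({
                "protein_id": f"P{i}", "run_id": "r1", "replicate_id": "A",
                "sample_id": f"S_{channel}", "channel": channel, "slope": s,
                "r_squared": r2, "n_unique_peptides": npep, "n_observations": 2 * npep,
                "max_intensity": 1e4, "outliers_removed": 0,
            })
    return pd.DataFrame(rows)


class TestBiasAdjustment:
    def test_unit_slopes_give_unit_factors(self):
        est = synth_estimates({"114": [1.0, 1.0, 1.0]})
        adj, factors = itraq.adjust_channel_bias(est)
        assert factors["bias_factor"].tolist() == [1.0]
        np.testing.assert_allclose(adj["slope"], 1.0)

    def test_constant_slopes_fully_normalized(self):
        est = synth_estimates({"114": [2.0, 2.0, 2.0]})
        adj, factors = itraq.adjust_channel_bias(est)
        assert factors["bias_factor"].iloc[0] == pytest.approx(2.0)
        np.testing.assert_allclose(adj["slope"], 1.0)

    def test_geometric_mean_is_one_after_adjustment(self):
        est = synth_estimates({"114": [0.5, 2.0, 1.7, 0.9], "115": [3.0, 1.2, 0.4, 1.1]})
        adj, _ = itraq.adjust_channel_bias(est)
        for _, sub in adj.groupby("channel"):
            assert abs(np.log(sub["slope"]).mean()) < 1e-12

    def test_idempotent(self):
        est = synth_estimates({"114": [0.5, 2.0, 1.7, 0.9]})
        once, _ = itraq.adjust_channel_bias(est)
        twice, factors2 = itraq.adjust_channel_bias(once)
        pd.testing.assert_frame_equal(once, twice)
        np.testing.assert_allclose(factors2["bias_factor"], 1.0)

    def test_low_confidence_channel_warns_and_keeps_factor_one(self):
        est = synth_estimates({"114": [2.0, 2.0]}, r2=0.5)  # below the 0.9 cut
        with pytest.warns(UserWarning):
            adj, factors = itraq.adjust_channel_bias(est)
        assert factors["bias_factor"].iloc[0] == 1.0
        np.testing.assert_allclose(adj["slope"], 2.0)

    def test_planted_bias_recovered_on_synthetic_run(self):
        """Factors recovered within 5% of the planted bias at 200 proteins."""
        cfg = simulate.SimConfig(n_proteins=200, noise_cv=0.1, outlier_fraction=0.0,
                                 frac_de_protein=0.0, seed=31)
        truth = simulate.make_protein_truth(cfg)
        table, designs = simulate.simulate_itraq_run(cfg, truth, "A", 0)
        est = pd.concat([
            itraq.quantify_run(table[table["run_id"] == d.run_id], d)
            for d in designs], ignore_index=True)
        _, factors = itraq.adjust_channel_bias(est)
        planted = truth.channel_bias.loc["A"]
        for _, row in factors.iterrows():
            assert row["bias_factor"] == pytest.approx(planted[row["channel"]], rel=0.05)

    def test_arithmetic_mean_mode(self):
        est = synth_estimates({"114": [1.0, 3.0]})
        adj, factors = itraq.adjust_channel_bias(
            est, itraq.QuantParams(bias_mean="arithmetic"))
        assert factors["bias_factor"].iloc[0] == pytest.approx(2.0)
        assert adj["slope"].mean() == pytest.approx(1.0)


class TestFilter:
    @pytest.mark.parametrize(
        "r2, npep, nobs, kept",
        [
            (0.70, 3, 6, False),   # boundary R^2 is strictly rejected
            (0.95, 1, 5, False),   # single peptide
            (0.80, 2, 4, True),    # boundary counts satisfied
            (0.80, 2, 3, False),   # too few observations
        ],
    )
    def test_published_filter_bounds(self, r2, npep, nobs, kept):
        est = pd.DataFrame([{
            "protein_id": "P1", "run_id": "r1", "replicate_id": "A",
            "sample_id": "S1", "channel": "114", "slope": 1.0,
            "r_squared": r2, "n_unique_peptides": npep, "n_observations": nobs,
            "max_intensity": 1.0, "outliers_removed": 0,
        }])
        out = itraq.filter_estimates(est)
        assert (len(out) == 1) is kept


def comp_frame(slopes: dict[str, float], rep="A") -> pd.DataFrame:
    return pd.DataFrame(
        [{"protein_id": p, "sample_id": "S1", "slope": s, "replicate_id": rep}
         for p, s in slopes.items()],
        columns=["protein_id", "sample_id", "slope", "replicate_id"])


class TestComposite:
    def test_concordant_replicates_average(self):
        out = itraq.composite_ratios(comp_frame({"P1": 2.0}), comp_frame({"P1": 2.0}, "B"))
        row = out.iloc[0]
        assert row["ratio"] == pytest.approx(2.0)
        assert row["source"] == "both-replicates" and not row["mismatch_flag"]

    def test_geometric_mean_of_discordant_but_tolerable(self):
        out = itraq.composite_ratios(comp_frame({"P1": 2.0}), comp_frame({"P1": 3.0}, "B"))
        assert out["ratio"].iloc[0] == pytest.approx(np.sqrt(6.0))
        assert not out["mismatch_flag"].iloc[0]

    def test_single_replicate_value_used(self):
        out = itraq.composite_ratios(comp_frame({"P1": 1.5}), comp_frame({}, "B"))
        row = out.iloc[0]
        assert row["ratio"] == pytest.approx(1.5) and row["source"] == "single-replicate"

    def test_fourfold_disagreement_flagged(self):
        # |log2(4/1)| = 2 > 1 -> excluded
        out = itraq.composite_ratios(comp_frame({"P1": 4.0}), comp_frame({"P1": 1.0}, "B"))
        assert bool(out["mismatch_flag"].iloc[0])

    def test_duplicate_estimates_rejected(self):
        dup = pd.concat([comp_frame({"P1": 2.0})] * 2, ignore_index=True)
        with pytest.raises(DataError):
            itraq.composite_ratios(dup, comp_frame({"P1": 2.0}, "B"))


class TestQuantifyRunSet:
    def test_noiseless_identity(self, noiseless_config):
        """With no noise, no outliers and unit bias, the log2 matrix equals
        the planted truth exactly (construction fidelity, end to end)."""
        runs, truth = simulate.simulate_experiment(noiseless_config)
        matrix, comp, est, qc = itraq.quantify_run_set(
            runs, itraq.QuantParams(apply_bias=False))
        expected = truth.protein_log2_ratio.loc[matrix.values.index, matrix.values.columns]
        np.testing.assert_allclose(matrix.values, expected, atol=1e-12)
        assert qc["n_mismatch_excluded"] == 0

    def test_noiseless_identity_with_bias_adjustment(self, noiseless_config):
        """Planted channel bias is removed exactly in a null (no-DE) world."""
        cfg = noiseless_config.with_(max_channel_bias=1.5, frac_de_protein=0.0)
        runs, truth = simulate.simulate_experiment(cfg)
        matrix, *_ = itraq.quantify_run_set(runs)
        np.testing.assert_allclose(matrix.values.to_numpy(), 0.0, atol=1e-12)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            matrix, comp, est, qc = itraq.quantify_run_set([])
        assert matrix is None and comp.empty

    def test_replicate_concordance_slope_near_one(self, small_config):
        """After bias adjustment, replicate B regressed on replicate A through
        the origin has slope within [0.95, 1.05] (noise CV 0.2, bias <= 1.5x)."""
        cfg = small_config.with_(n_proteins=200, outlier_fraction=0.0, seed=17)
        runs, _ = simulate.simulate_experiment(cfg)
        _, _, est, _ = itraq.quantify_run_set(runs)
        kept = itraq.filter_estimates(est)
        slope, n = itraq.replicate_concordance_slope(kept)
        assert n > 100
        assert 0.95 <= slope <= 1.05

    def test_monotone_recovery_with_peptide_depth(self):
        """Expected per-protein RMSE falls as peptides/protein rises 2->4->8."""
        rmses = []
        for npep in (2, 4, 8):
            errs = []
            for seed in range(20):
                cfg = simulate.SimConfig(
                    n_proteins=40, peptides_min=npep, peptides_mean=float(npep),
                    extra_spectrum_prob=0.0, noise_cv=0.3, outlier_fraction=0.0,
                    max_channel_bias=1.0, n_per_group_protein=2, seed=100 + seed)
                runs, truth = simulate.simulate_experiment(cfg)
                m, *_ = itraq.quantify_run_set(
                    runs, itraq.QuantParams(apply_bias=False, min_observations=1,
                                            min_unique_peptides=1, min_r2=0.0))
                err = (m.values - truth.protein_log2_ratio.loc[
                    m.values.index, m.values.columns]).to_numpy()
                errs.append(np.nanmean(err ** 2))
            rmses.append(np.sqrt(np.mean(errs)))
        assert rmses[0] > rmses[1] > rmses[2]
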