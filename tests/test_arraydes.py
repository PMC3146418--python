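"""M/A computation, normalization, GLS fits, moderation and FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_bh, brute_force_gls
from crepipe import arraydes, simulate
from crepipe.arraydes import (
    ModerationParams,
    adjust_bh,
    classify,
    compute_ma,
    estimate_duplicate_correlation,
    estimate_moderation,
    fit_gene,
    fit_genes,
    moderate,
    normalize_between,
    normalize_within,
    ordinary_t,
)


def _spots(rows):
    return pd.DataFrame(rows, columns=["array_id", "spot_id", "probe_id", "locus", "ch1", "ch2", "excluded"])


def _design(rows):
    return pd.DataFrame(rows, columns=["array_id", "strain", "bio_replicate", "ribose_channel", "is_dye_swap"])


class TestComputeMA:
    def test_orientation_and_values(self):
        spots = _spots([("a1", "s1", "p1", "g1", 100.0, 400.0, 0)])
        design = _design([("a1", "S", 1, "ch2", 0)])
        ma = compute_ma(spots, design)
        assert ma.loc[0, "M"] == pytest.approx(2.0)
        assert ma.loc[0, "A"] == pytest.approx((np.log2(400) + np.log2(100)) / 2)

    def test_swapped_orientation_gives_same_m(self):
        # ribose intensity 400, glucose 100 in both cases
        fwd = compute_ma(
            _spots([("a1", "s1", "p1", "g1", 100.0, 400.0, 0)]),
            _design([("a1", "S", 1, "ch2", 0)]),
        )
        swp = compute_ma(
            _spots([("a2", "s1", "p1", "g1", 400.0, 100.0, 0)]),
            _design([("a2", "S", 1, "ch1", 1)]),
        )
        assert fwd.loc[0, "M"] == pytest.approx(swp.loc[0, "M"]) == pytest.approx(2.0)

    def test_equal_channels_give_zero(self):
        ma = compute_ma(
            _spots([("a1", "s1", "p1", "g1", 250.0, 250.0, 0)]),
            _design([("a1", "S", 1, "ch2", 0)]),
        )
        assert ma.loc[0, "M"] == 0.0

    def test_excluded_and_zero_intensity_spots_dropped(self):
        spots = _spots(
            [
                ("a1", "s1", "p1", "g1", 100.0, 400.0, 1),
                ("a1", "s2", "p2", "g2", 0.0, 400.0, 0),
                ("a1", "s3", "p3", "g3", 10.0, 40.0, 0),
            ]
        )
        ma = compute_ma(spots, _design([("a1", "S", 1, "ch2", 0)]))
        assert list(ma["locus"]) == ["g3"]


class TestNormalization:
    def test_centered_trendless_data_is_fixed_point(self):
        rng = np.random.default_rng(0)
        n = 500
        m = rng.normal(0, 0.05, n)
        m -= np.median(m)
        ma = pd.DataFrame({"array_id": "a1", "M": m, "A": rng.uniform(6, 14, n)})
        out = normalize_within(ma)
        assert np.max(np.abs(out["M"] - ma["M"])) < 0.05

    def test_planted_trend_removed(self):
        rng = np.random.default_rng(1)
        n = 2000
        a = rng.uniform(6, 14, n)
        trend = 0.8 * np.sin((a - 6) / 8 * np.pi)  # smooth, amplitude 0.8
        ma = pd.DataFrame({"array_id": "a1", "M": trend + rng.normal(0, 0.05, n), "A": a})
        out = normalize_within(ma)
        fitted_resid = out.groupby(pd.cut(a, 10), observed=True)["M"].mean()
        assert fitted_resid.abs().max() < 0.08  # < 10% of the planted amplitude

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(2)
        ma = pd.DataFrame({"array_id": "a1", "M": np.full(200, 1.3), "A": rng.uniform(6, 14, 200)})
        out = normalize_within(ma)
        assert np.allclose(out["M"], 0.0, atol=1e-6)

    def test_few_spots_fall_back_to_median_centering(self, caplog):
        ma = pd.DataFrame({"array_id": "a1", "M": [1.0, 2.0, 3.0], "A": [7.0, 8.0, 9.0]})
        out = normalize_within(ma)
        assert list(out["M"]) == [-1.0, 0.0, 1.0]

    def test_between_array_mads_equalized(self):
        rng = np.random.default_rng(3)
        m1 = rng.normal(0, 0.2, 400)
        ma = pd.concat(
            [
                pd.DataFrame({"array_id": "a1", "M": m1, "A": 10.0}),
                pd.DataFrame({"array_id": "a2", "M": 2 * m1, "A": 10.0}),
            ],
            ignore_index=True,
        )
        out = normalize_between(ma)
        from scipy.stats import median_abs_deviation

        mads = out.groupby("array_id")["M"].apply(median_abs_deviation)
        assert mads["a1"] == pytest.approx(mads["a2"])

    def test_identical_arrays_and_single_array_unchanged(self):
        rng = np.random.default_rng(4)
        m = rng.normal(0, 0.2, 100)
        two = pd.concat(
            [
                pd.DataFrame({"array_id": "a1", "M": m, "A": 10.0}),
                pd.DataFrame({"array_id": "a2", "M": m, "A": 10.0}),
            ],
            ignore_index=True,
        )
        assert np.allclose(normalize_between(two)["M"], two["M"])
        one = two[two["array_id"] == "a1"]
        assert np.allclose(normalize_between(one)["M"], one["M"])


class TestDuplicateCorrelation:
    @pytest.mark.parametrize("rho,tol", [(0.6, 0.1), (0.0, 0.1)])
    def test_recovery(self, rho, tol):
        spots, design, _ = simulate.simulate_array_experiment(
            n_genes=500, strains=["A"], rho=rho, seed=17, dye_effect=0.0
        )
        ma = compute_ma(spots, design)
        est = estimate_duplicate_correlation(ma)
        assert abs(est - rho) < tol

    def test_identical_replicates_approach_one(self):
        rng = np.random.default_rng(5)
        rows = []
        for g in range(100):
            for a in ("a1", "a2", "a3"):
                val = rng.normal(0, 1)
                for r in range(3):
                    rows.append({"array_id": a, "locus": f"g{g}", "M": val})
        est = estimate_duplicate_correlation(pd.DataFrame(rows))
        assert 0.99 <= est < 1.0

    def test_too_few_genes_raises(self):
        ma = pd.DataFrame({"array_id": ["a1"] * 4, "locus": ["g1"] * 4, "M": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="correlation"):
            estimate_duplicate_correlation(ma)


class TestFitGene:
    def test_constant_input(self):
        fit = fit_gene({"a1": [1.5] * 3, "a2": [1.5] * 3, "a3": [1.5] * 3}, rho=0.0)
        assert fit["beta_hat"] == pytest.approx(1.5)
        assert fit["s2"] == pytest.approx(0.0)

    def test_singletons_reduce_to_mean_and_variance(self):
        fit = fit_gene({"a1": [1.0], "a2": [2.0], "a3": [3.0]}, rho=0.0)
        assert fit["beta_hat"] == pytest.approx(2.0)
        assert fit["s2"] == pytest.approx(1.0)
        assert fit["df"] == 2
        assert fit["v"] == pytest.approx(1 / 3)

    def test_rho_zero_equals_grand_mean(self):
        rng = np.random.default_rng(6)
        data = {a: rng.normal(1, 0.3, 3) for a in ("a1", "a2", "a3")}
        fit = fit_gene(data, rho=0.0)
        assert fit["beta_hat"] == pytest.approx(np.mean(np.concatenate(list(data.values()))))

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.5, 0.8, -0.2])
    def test_matches_explicit_covariance_oracle(self, rho):
        rng = np.random.default_rng(7)
        for _ in range(20):
            data = {
                f"a{i}": rng.normal(0.5, 0.4, rng.integers(1, 5)) for i in range(rng.integers(2, 5))
            }
            got = fit_gene(data, rho=rho)
            want = brute_force_gls(data, rho=rho)
            for key in ("beta_hat", "s2", "v"):
                assert got[key] == pytest.approx(want[key], abs=1e-8)
            assert got["df"] == want["df"]

    def test_single_array_untestable(self):
        fit = fit_gene({"a1": [1.0, 2.0, 3.0]}, rho=0.0)
        assert not fit["testable"]
        assert np.isnan(fit["beta_hat"])

    def test_fit_genes_agrees_with_fit_gene(self):
        rng = np.random.default_rng(8)
        rows = []
        per_gene = {}
        for g in range(30):
            per_gene[f"g{g}"] = {}
            for a in ("a1", "a2", "a3", "a4"):
                vals = rng.normal(0, 0.5, 3)
                per_gene[f"g{g}"][a] = vals
                rows += [{"locus": f"g{g}", "array_id": a, "M": v} for v in vals]
        table = fit_genes(pd.DataFrame(rows), rho=0.4)
        for row in table.itertuples(index=False):
            want = fit_gene(per_gene[row.locus], rho=0.4)
            assert row.beta_hat == pytest.approx(want["beta_hat"], abs=1e-10)
            assert row.s2 == pytest.approx(want["s2"], abs=1e-10)
            assert row.v == pytest.approx(want["v"], abs=1e-10)


class TestModeration:
    def test_prior_recovery(self):
        rng = np.random.default_rng(9)
        d0, s0 = 4.0, 0.05
        sigma2 = s0 * d0 / rng.chisquare(d0, 2000)
        df = np.full(2000, 11.0)
        s2 = sigma2 * rng.chisquare(11, 2000) / 11.0
        params = estimate_moderation(s2, df)
        assert abs(params.d0 - d0) < 1.0
        assert abs(params.s0_2 - s0) / s0 < 0.2

    def test_no_moderation_limit_equals_ordinary_t(self):
        rng = np.random.default_rng(10)
        fits = pd.DataFrame(
            {
                "locus": [f"g{i}" for i in range(50)],
                "beta_hat": rng.normal(0, 1, 50),
                "s2": rng.chisquare(5, 50) / 5 * 0.05,
                "df": 8,
                "v": 1 / 9,
                "testable": True,
            }
        )
        # the d0 -> 0 limit of the posterior variance is s2 itself
        ord_t = ordinary_t(fits)
        params, mod = moderate(fits, ModerationParams(d0=1e-12, s0_2=0.05))
        assert np.allclose(mod["t_mod"], ord_t["t_mod"], rtol=1e-5)

    def test_identical_variances_give_infinite_d0(self):
        fits_s2 = np.full(100, 0.04)
        params = estimate_moderation(fits_s2, np.full(100, 10.0))
        assert np.isinf(params.d0)
        assert params.s0_2 == pytest.approx(0.04, rel=0.2)

    def test_fixed_point_at_prior_variance(self):
        fits = pd.DataFrame(
            {
                "locus": ["g"],
                "beta_hat": [1.0],
                "s2": [0.05],
                "df": [10_000_000],
                "v": [0.1],
                "testable": [True],
            }
        )
        _, mod = moderate(fits, ModerationParams(d0=4.0, s0_2=0.05))
        assert mod.loc[0, "s_tilde2"] == pytest.approx(0.05, rel=1e-6)

    def test_posterior_variance_between_prior_and_observed(self):
        fits = pd.DataFrame(
            {
                "locus": ["g1", "g2"],
                "beta_hat": [1.0, 1.0],
                "s2": [0.2, 0.01],
                "df": [10, 10],
                "v": [0.1, 0.1],
                "testable": [True, True],
            }
        )
        _, mod = moderate(fits, ModerationParams(d0=4.0, s0_2=0.05))
        assert 0.05 < mod.loc[0, "s_tilde2"] < 0.2
        assert 0.01 < mod.loc[1, "s_tilde2"] < 0.05


class TestBH:
    def test_hand_computed_example(self):
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert adjust_bh([1.0]) == pytest.approx([1.0])

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_matches_brute_force_oracle(self, ps):
        got = adjust_bh(ps)
        want = brute_force_bh(np.array(ps))
        assert np.allclose(got, want, atol=1e-12)

    def test_q_at_least_p_and_order_preserved(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=500)
        q = adjust_bh(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nan_passthrough(self):
        q = adjust_bh([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])


class TestClassify:
    @pytest.mark.parametrize(
        "q,fc,cls,strong",
        [
            (0.005, 0.5, "unchanged", False),  # strict > on the fold-change
            (0.005, 2.8, "up", True),
            (0.02, 3.0, "unchanged", True),  # fails FDR
            (0.005, -0.6, "down", False),
            (0.01, 0.6, "unchanged", False),  # strict < on q
            (np.nan, 2.0, "unchanged", True),
        ],
    )
    def test_thresholds(self, q, fc, cls, strong):
        res = classify(pd.DataFrame({"locus": ["g"], "log2fc": [fc], "q": [q]}))
        assert res.loc[0, "class"] == cls
        assert bool(res.loc[0, "strong"]) == strong


class TestEndToEnd:
    def test_dye_swap_invariance(self, small_experiment):
        spots, design, _ = small_experiment
        res = arraydes.de_per_strain(spots, design, rho=0.4)["A"]
        # move the swap to a different array: exchange its channels and
        # flip its recorded ribose channel -> identical M values
        design2 = design.copy()
        spots2 = spots.copy()
        for aid, new_orient in [("A_a2", "ch1"), ("A_a1_swap", "ch2")]:
            mask = spots2["array_id"] == aid
            spots2.loc[mask, ["ch1", "ch2"]] = spots2.loc[mask, ["ch2", "ch1"]].to_numpy()
            design2.loc[design2["array_id"] == aid, "ribose_channel"] = new_orient
        res2 = arraydes.de_per_strain(spots2, design2, rho=0.4)["A"]
        pd.testing.assert_frame_equal(res, res2)

    def test_estimation_consistency(self, small_experiment):
        spots, design, truth = small_experiment
        res = arraydes.de_per_strain(spots, design)["A"]
        merged = res.merge(truth.true_log2fc, on="locus")
        nonnull = merged[merged["beta"] != 0]
        assert abs((nonnull["log2fc"] - nonnull["beta"]).mean()) < 0.05

    def test_untestable_genes_reported_with_na(self):
        spots, design, _ = simulate.simulate_array_experiment(
            n_genes=60, strains=["A"], seed=19, exclude_rate=0.0
        )
        lone = spots["locus"] == "GENE0001"
        spots = spots[~lone | (spots["array_id"] == "A_a1")]
        res = arraydes.de_per_strain(spots, design, rho=0.4)["A"]
        row = res[res["locus"] == "GENE0001"].iloc[0]
        assert np.isnan(row["log2fc"]) and row["class"] == "unchanged"
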