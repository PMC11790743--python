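"""Normalization, dispersion, Wald testing, shrinkage and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import flydelay as fd
from flydelay.data_model import ComparisonSpec
from flydelay.de import _fit_dispersion_trend, adjust_bh, shrink_lfc
from flydelay.errors import BatteryError, ConfigError, EstimationError


def bh_step_up(p):
    """Brute-force Benjamini-Hochberg step-up: the independent oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = fd.ExpressionMatrix(pd.DataFrame([[3, 3], [7, 7]], index=["g1", "g2"],
                                             columns=["s1", "s2"]))
        factors = fd.size_factors_median_of_ratios(m)
        np.testing.assert_allclose(factors.to_numpy(), [1.0, 1.0])

    def test_worked_two_by_two(self):
        """[[2,4],[8,16]]: all per-gene ratios are 1/sqrt(2) and sqrt(2)."""
        m = fd.ExpressionMatrix(pd.DataFrame([[2, 4], [8, 16]], index=["g1", "g2"],
                                             columns=["s1", "s2"]))
        factors = fd.size_factors_median_of_ratios(m)
        np.testing.assert_allclose(
            factors.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_column_scaling_equivariance(self, seed):
        """Scaling one column by c multiplies exactly that factor by c."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 500, size=(50, 6))
        m = fd.ExpressionMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(50)],
                                             columns=[f"s{j}" for j in range(6)]))
        base = fd.size_factors_median_of_ratios(m)
        c = 3
        scaled = m.counts.copy()
        scaled["s2"] = scaled["s2"] * c
        f2 = fd.size_factors_median_of_ratios(fd.ExpressionMatrix(scaled))
        # the scaled sample's factor changes by ~c; geometric-mean reference shifts
        # cancel out in the ratio of factors
        ratio = (f2 / base).to_numpy()
        np.testing.assert_allclose(ratio[2], c * ratio[0], rtol=1e-9)
        np.testing.assert_allclose(ratio[[0, 1, 3, 4, 5]], ratio[0], rtol=1e-9)

    def test_gene_order_invariance(self, default_sim):
        matrix = default_sim[0]
        shuffled = fd.ExpressionMatrix(matrix.counts.sample(frac=1, random_state=0))
        pd.testing.assert_series_equal(
            fd.size_factors_median_of_ratios(matrix),
            fd.size_factors_median_of_ratios(shuffled),
        )

    def test_no_all_positive_gene_is_an_error(self):
        m = fd.ExpressionMatrix(pd.DataFrame([[0, 4], [8, 0]], index=["g1", "g2"],
                                             columns=["s1", "s2"]))
        with pytest.raises(EstimationError):
            fd.size_factors_median_of_ratios(m)


class TestNormalize:
    def test_unit_factors_identity(self, tiny_matrix):
        factors = pd.Series(1.0, index=tiny_matrix.sample_ids)
        out = fd.normalize(tiny_matrix, factors)
        np.testing.assert_allclose(out.to_numpy(), tiny_matrix.counts.to_numpy())

    def test_doubling_a_factor_halves_the_column(self, tiny_matrix):
        factors = pd.Series([1.0, 2.0], index=tiny_matrix.sample_ids)
        out = fd.normalize(tiny_matrix, factors)
        np.testing.assert_allclose(
            out["s2"].to_numpy(), tiny_matrix.counts["s2"].to_numpy() / 2.0
        )

    def test_worked_example_equalizes_column_sums(self):
        m = fd.ExpressionMatrix(pd.DataFrame([[2, 4], [8, 16]], index=["g1", "g2"],
                                             columns=["s1", "s2"]))
        out = fd.normalize(m, fd.size_factors_median_of_ratios(m))
        sums = out.sum(axis=0).to_numpy()
        np.testing.assert_allclose(sums[0], sums[1])


class TestDispersion:
    def test_poisson_data_near_zero_dispersion(self, small_design):
        rng = np.random.default_rng(4)
        mu = rng.lognormal(4, 1, size=2000)
        counts = rng.poisson(mu[:, None], size=(2000, 18))
        m = fd.ExpressionMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(2000)],
                                             columns=small_design.sample_ids))
        factors = pd.Series(1.0, index=small_design.sample_ids)
        alpha = fd.estimate_dispersion(m, small_design, factors)
        assert alpha.median() <= 0.05

    def test_constant_counts_give_zero(self, small_design):
        counts = np.full((5, 18), 7)
        m = fd.ExpressionMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(5)],
                                             columns=small_design.sample_ids))
        factors = pd.Series(1.0, index=small_design.sample_ids)
        alpha = fd.estimate_dispersion(m, small_design, factors)
        # trend shrinkage can only add a nonnegative trend term; with zero
        # variance everywhere the estimate collapses to zero
        np.testing.assert_allclose(alpha.to_numpy(), 0.0, atol=1e-12)

    def test_recovers_known_dispersion_at_20_reps(self):
        cfg = fd.SimConfig(n_genes=2000, replicates=20, class_fractions={},
                           dispersion_range=(0.2, 0.2), seed=8)
        matrix, design, _, truth = fd.simulate_dataset(cfg)
        factors = fd.size_factors_median_of_ratios(matrix)
        alpha = fd.estimate_dispersion(matrix, design, factors)
        assert 0.15 <= alpha.median() <= 0.25

    def test_single_replicate_everywhere_is_an_error(self):
        design = fd.SampleDesign(pd.DataFrame({
            "sample": ["a", "b"], "sex": ["F", "M"], "age_days": [3, 3],
            "replicate": [1, 1]}))
        m = fd.ExpressionMatrix(pd.DataFrame([[5, 6]], index=["g1"], columns=["a", "b"]))
        factors = pd.Series(1.0, index=["a", "b"])
        with pytest.raises(EstimationError):
            fd.estimate_dispersion(m, design, factors)


class TestWaldTest:
    def test_identical_groups_give_zero_lfc_unit_p(self, small_design):
        counts = np.tile(np.array([[5, 9, 13]]), (4, 6))  # same triplet per group
        m = fd.ExpressionMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(4)],
                                             columns=small_design.sample_ids))
        factors = pd.Series(1.0, index=small_design.sample_ids)
        alpha = pd.Series(0.1, index=m.gene_ids)
        res = fd.wald_test(m, small_design, factors, alpha,
                           ComparisonSpec.from_name("F3v7"))
        np.testing.assert_allclose(res.table["lfc"], 0.0, atol=1e-10)
        np.testing.assert_allclose(res.table["p_raw"], 1.0, atol=1e-9)

    def test_group_label_swap_negates_lfc(self, default_sim, default_sim_fitted):
        matrix, design, _, _ = default_sim
        factors, dispersions, _ = default_sim_fitted
        fwd = fd.wald_test(matrix, design, factors, dispersions,
                           ComparisonSpec.from_name("F3v7"))
        rev = fd.wald_test(matrix, design, factors, dispersions,
                           ComparisonSpec("rev", ("F", 7), ("F", 3)))
        mask = fwd.table["lfc"].notna()
        np.testing.assert_allclose(fwd.table["lfc"][mask], -rev.table["lfc"][mask],
                                   atol=1e-6)
        np.testing.assert_allclose(fwd.table["p_raw"][mask], rev.table["p_raw"][mask],
                                   atol=1e-8)

    def test_all_zero_genes_get_sentinel_and_unit_p(self, small_design):
        counts = np.vstack([np.zeros(18, int), np.full(18, 20)])
        m = fd.ExpressionMatrix(pd.DataFrame(counts, index=["gz", "g1"],
                                             columns=small_design.sample_ids))
        factors = pd.Series(1.0, index=small_design.sample_ids)
        alpha = pd.Series(0.1, index=m.gene_ids)
        res = fd.wald_test(m, small_design, factors, alpha,
                           ComparisonSpec.from_name("F3v7"))
        assert np.isnan(res.table.loc["gz", "lfc"])
        assert res.table.loc["gz", "p_raw"] == 1.0
        assert np.isfinite(res.table.loc["g1", "lfc"])

    def test_overlapping_groups_rejected(self, default_sim, default_sim_fitted):
        matrix, design, _, _ = default_sim
        factors, dispersions, _ = default_sim_fitted
        with pytest.raises(ConfigError):
            fd.wald_test(matrix, design, factors, dispersions,
                         ComparisonSpec("bad", ("F", 3), ("F", 3)))

    def test_agrees_with_reference_nb_glm_implementation(self):
        """Independent oracle: pydeseq2's Wald pipeline on the same counts."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        import warnings
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        matrix, design, _, _ = fd.simulate_dataset(fd.SimConfig(n_genes=400, seed=3))
        samples = design.samples_for("F", 3) + design.samples_for("F", 7)
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=matrix.counts[samples].T, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
            ds.summary()
        ref = ds.results_df
        factors = fd.size_factors_median_of_ratios(matrix)
        dispersions = fd.estimate_dispersion(matrix, design, factors)
        ours = fd.wald_test(matrix, design, factors, dispersions,
                            ComparisonSpec.from_name("F3v7")).table
        mask = ref["pvalue"].notna() & ours["p_raw"].notna()
        lfc_r = np.corrcoef(ref["log2FoldChange"][mask], ours["lfc"][mask])[0, 1]
        p_r = np.corrcoef(-np.log10(ref["pvalue"][mask] + 1e-300),
                          -np.log10(ours["p_raw"][mask] + 1e-300))[0, 1]
        assert lfc_r > 0.99      # same effect estimates
        assert p_r > 0.7         # same ranking despite different dispersion machinery


class TestShrinkage:
    def test_shrunk_never_exceeds_mle_and_keeps_sign(self, default_sim,
                                                     default_sim_fitted):
        matrix, design, _, _ = default_sim
        factors, dispersions, _ = default_sim_fitted
        res = fd.wald_test(matrix, design, factors, dispersions,
                           ComparisonSpec.from_name("F3v7"))
        res = shrink_lfc(res)
        t = res.table.dropna(subset=["lfc"])
        assert (t["lfc_shrunk"].abs() <= t["lfc"].abs() + 1e-12).all()
        assert ((t["lfc_shrunk"] * t["lfc"]) >= 0).all()

    def test_noninformative_gene_shrinks_to_zero(self):
        """A gene with se >> tau ends up with essentially no effect."""
        table = pd.DataFrame({
            "base_mean": 10.0,
            "lfc": np.concatenate([np.random.default_rng(0).normal(0, 0.1, 200), [3.0]]),
            "lfc_shrunk": np.nan,
            "se": np.concatenate([np.full(200, 0.05), [50.0]]),
            "wald_z": np.nan, "p_raw": 0.5, "p_adj": np.nan,
        }, index=[f"g{i}" for i in range(201)])
        res = fd.DEResult("toy", "later vs earlier age", ("F", 3), ("F", 7), table)
        res = shrink_lfc(res)
        assert abs(res.table["lfc_shrunk"].iloc[-1]) < 0.01

    def test_flat_prior_limit_changes_nothing(self):
        """When the spread of effects dwarfs the errors, shrinkage vanishes."""
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "base_mean": 10.0,
            "lfc": rng.normal(0, 10.0, 300),
            "lfc_shrunk": np.nan,
            "se": np.full(300, 1e-3),
            "wald_z": np.nan, "p_raw": 0.5, "p_adj": np.nan,
        }, index=[f"g{i}" for i in range(300)])
        res = fd.DEResult("toy", "later vs earlier age", ("F", 3), ("F", 7), table)
        res = shrink_lfc(res)
        np.testing.assert_allclose(res.table["lfc_shrunk"], res.table["lfc"], rtol=1e-4)

    def test_all_nan_se_skips_with_warning(self):
        table = pd.DataFrame({
            "base_mean": 1.0, "lfc": [1.0], "lfc_shrunk": np.nan, "se": [np.nan],
            "wald_z": np.nan, "p_raw": [0.5], "p_adj": np.nan}, index=["g1"])
        res = fd.DEResult("toy", "later vs earlier age", ("F", 3), ("F", 7), table)
        with pytest.warns(UserWarning):
            res = shrink_lfc(res)
        assert res.table["lfc_shrunk"].iloc[0] == 1.0


class TestAdjustBH:
    def test_worked_vector(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.37]), [0.37])

    def test_nan_propagates(self):
        out = adjust_bh([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            adjust_bh([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    def test_matches_brute_force_step_up(self, pvals):
        np.testing.assert_allclose(adjust_bh(pvals), bh_step_up(pvals), rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
    def test_bounds_and_monotonicity_vs_input(self, pvals):
        out = adjust_bh(pvals)
        assert ((out >= np.asarray(pvals) - 1e-15) & (out <= 1.0 + 1e-15)).all()


class TestBattery:
    def test_fifteen_named_results(self, default_sim, default_sim_fitted):
        matrix, design, _, _ = default_sim
        factors, dispersions, _ = default_sim_fitted
        results = fd.run_battery(matrix, design, factors, dispersions, shrink=False)
        assert len(results) == 15
        assert "F3v7" in results and "F14vM14" in results
        for res in results.values():
            t = res.table.dropna(subset=["p_raw", "p_adj"])
            assert (t["p_adj"] >= t["p_raw"] - 1e-15).all()

    def test_missing_group_is_named(self, default_sim, default_sim_fitted):
        matrix, design, _, _ = default_sim
        factors, dispersions, _ = default_sim_fitted
        partial = design.subset([s for s in design.sample_ids if not s.startswith("M14")])
        with pytest.raises(BatteryError, match="M.*14"):
            fd.run_battery(matrix, partial, factors, dispersions)

    def test_deterministic(self, default_sim, default_sim_fitted):
        matrix, design, _, _ = default_sim
        factors, dispersions, _ = default_sim_fitted
        r1 = fd.run_battery(matrix, design, factors, dispersions, shrink=False)
        r2 = fd.run_battery(matrix, design, factors, dispersions, shrink=False)
        for name in r1:
            pd.testing.assert_frame_equal(r1[name].table, r2[name].table)


def test_dispersion_trend_handles_degenerate_inputs():
    mean = np.array([10.0, 20.0, 0.0])
    raw = np.zeros(3)
    trend = _fit_dispersion_trend(mean, raw)
    assert (trend >= 0).all()
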