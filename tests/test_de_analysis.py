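"""Differential-expression stage: filtering, TMM, factorial OLS,
empirical-Bayes moderation, BH adjustment."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mpp_eqtl.de_analysis import (
    bh_adjust,
    ebayes_moderate,
    estimate_variance_prior,
    factorial_design,
    filter_low_expression,
    fit_factorial_de,
    log_cpm,
    tmm_factors,
    trigamma_inverse,
)
from mpp_eqtl.errors import (
    DegenerateInputError,
    InvalidArgumentError,
    RankDeficiencyError,
    ValidationError,
)
from mpp_eqtl.synthetic_data import simulate_sample_table

HAVE_RSCRIPT = shutil.which("Rscript") is not None


def _counts(rows, columns=None):
    df = pd.DataFrame(rows)
    df.index = [f"g{i}" for i in range(len(df))]
    if columns is not None:
        df.columns = columns
    return df


class TestFilter:
    def test_all_zero_gene_removed(self):
        counts = _counts([[0] * 50, [5] * 50])
        kept = filter_low_expression(counts, min_count=10, min_samples=47)
        assert "g0" not in kept.index

    def test_gene_at_exact_threshold_retained(self):
        row = [10] * 47 + [0] * 337
        counts = _counts([row, [100] * 384])
        kept = filter_low_expression(counts, min_count=10, min_samples=47)
        assert "g0" in kept.index

    def test_gene_below_count_threshold_everywhere_removed(self):
        counts = _counts([[9] * 384, [100] * 384])
        kept = filter_low_expression(counts, min_count=10, min_samples=47)
        assert kept.index.tolist() == ["g1"]

    def test_gene_order_preserved(self):
        counts = _counts([[100] * 50, [0] * 50, [50] * 50, [20] * 50])
        kept = filter_low_expression(counts, min_count=10, min_samples=47)
        assert kept.index.tolist() == ["g0", "g2", "g3"]

    def test_min_samples_exceeding_samples_rejected(self):
        counts = _counts([[5] * 10])
        with pytest.raises(InvalidArgumentError):
            filter_low_expression(counts, min_samples=47)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            filter_low_expression(pd.DataFrame())


def brute_force_tmm(counts: np.ndarray, logratio_trim=0.3, abs_trim=0.05) -> np.ndarray:
    """Loop-coded TMM oracle, written independently of the implementation."""
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    uq = np.array([np.quantile(counts[:, j], 0.75) / lib[j] for j in range(n_samples)])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(n_samples):
        rows = []
        for g in range(n_genes):
            o, r = counts[g, j], counts[g, ref_j]
            if o > 0 and r > 0:
                m = np.log2((o / lib[j]) / (r / lib[ref_j]))
                a = 0.5 * (np.log2(o / lib[j]) + np.log2(r / lib[ref_j]))
                w = (lib[j] - o) / (lib[j] * o) + (lib[ref_j] - r) / (lib[ref_j] * r)
                rows.append((m, a, w))
        ms = np.array([t[0] for t in rows])
        as_ = np.array([t[1] for t in rows])
        ws = np.array([t[2] for t in rows])
        if ms.size == 0 or np.max(np.abs(ms)) < 1e-6:
            factors.append(1.0)
            continue
        n = ms.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        rm = stats.rankdata(ms)
        ra = stats.rankdata(as_)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = 2.0 ** (np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep]))
        factors.append(f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = _counts(np.tile([[5], [80], [13], [200]], (1, 3)))
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_uniform_doubling_absorbed_by_library_size(self):
        base = np.array([5, 80, 13, 200, 44])
        counts = _counts(np.column_stack([base, 2 * base]))
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_matches_brute_force_oracle(self, rng):
        counts = rng.negative_binomial(4, 0.02, size=(200, 5))
        counts[rng.random(counts.shape) < 0.05] = 0
        df = _counts(counts)
        mine = tmm_factors(df).to_numpy()
        oracle = brute_force_tmm(counts.astype(float))
        np.testing.assert_allclose(mine, oracle, atol=1e-8)

    @pytest.mark.skipif(not HAVE_RSCRIPT, reason="Rscript unavailable")
    def test_matches_edger_reference(self, rng, tmp_path):
        counts = rng.negative_binomial(5, 0.05, size=(150, 6))
        counts[:15, 0] = 0
        df = _counts(counts)
        csv = tmp_path / "counts.csv"
        df.to_csv(csv)
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.csv("{csv}", row.names=1));'
            'cat(sprintf("%.12f\\n", calcNormFactors(x, method="TMM")))'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        edger = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(tmm_factors(df).to_numpy(), edger, atol=1e-9)

    def test_all_zero_sample_rejected(self):
        counts = _counts([[0, 5], [0, 8]])
        with pytest.raises(DegenerateInputError):
            tmm_factors(counts)


class TestFactorialFit:
    @pytest.fixture()
    def samples(self):
        return simulate_sample_table([f"s{i:02d}" for i in range(12)])

    def test_exact_linear_combination_recovered(self, samples):
        design = factorial_design(samples)
        rng = np.random.default_rng(1)
        beta = rng.standard_normal(design.shape[1])
        expr = pd.DataFrame(
            np.tile(design.to_numpy() @ beta, (3, 1)), columns=design.index,
            index=["a", "b", "c"],
        )
        fit = fit_factorial_de(expr, samples)
        np.testing.assert_allclose(fit.s2, 0.0, atol=1e-18)
        np.testing.assert_allclose(fit.coefficients.iloc[0], beta, atol=1e-10)

    def test_balanced_cell_design_yields_classical_contrasts(self):
        # one sample per 2x2x2 cell, single pool: coefficients must equal the
        # hand-computed factorial contrasts of the eight cell means
        rows = []
        for tissue in ("head", "gut"):
            for treatment in ("control", "copper"):
                for res in ("resistant", "sensitive"):
                    rows.append(
                        dict(sample_id=f"{tissue}_{treatment}_{res}",
                             strain=f"{treatment}_{res}", tissue=tissue,
                             treatment=treatment, resistance_class=res, pool="p1")
                    )
        samples = pd.DataFrame(rows)
        rng = np.random.default_rng(7)
        y = rng.standard_normal(8)
        cell = {(r.tissue, r.treatment, r.resistance_class): y[i]
                for i, r in enumerate(samples.itertuples())}
        expr = pd.DataFrame([y], index=["g"], columns=samples["sample_id"])
        fit = fit_factorial_de(expr, samples)

        def mean(fix: dict) -> float:
            vals = [v for k, v in cell.items()
                    if all(k[i] == val for i, val in fix.items())]
            return float(np.mean(vals))

        coef = fit.coefficients.loc["g"]
        assert np.isclose(coef["tissue[gut-head]"], mean({0: "gut"}) - mean({0: "head"}))
        assert np.isclose(coef["treatment[copper-control]"],
                          mean({1: "copper"}) - mean({1: "control"}))
        # interaction: difference of tissue differences across treatment
        d_cu = mean({0: "gut", 1: "copper"}) - mean({0: "head", 1: "copper"})
        d_ct = mean({0: "gut", 1: "control"}) - mean({0: "head", 1: "control"})
        assert np.isclose(coef["tissue:treatment"], d_cu - d_ct)

    def test_pool_confounded_with_tissue_raises(self):
        samples = simulate_sample_table([f"s{i:02d}" for i in range(8)])
        samples["pool"] = samples["tissue"]  # pool labels now alias tissue
        expr = pd.DataFrame(
            np.zeros((2, len(samples))), columns=samples["sample_id"],
            index=["a", "b"],
        )
        with pytest.raises(RankDeficiencyError, match="pool"):
            fit_factorial_de(expr, samples)

    def test_matches_per_gene_ols_oracle(self, samples, rng):
        design = factorial_design(samples)
        expr = pd.DataFrame(
            rng.standard_normal((50, len(samples))), columns=design.index,
            index=[f"g{i}" for i in range(50)],
        )
        fit = fit_factorial_de(expr, samples)
        X = design.to_numpy()
        for g in range(0, 50, 7):
            beta, res, *_ = np.linalg.lstsq(X, expr.iloc[g].to_numpy(), rcond=None)
            np.testing.assert_allclose(fit.coefficients.iloc[g], beta, atol=1e-8)
            r = expr.iloc[g].to_numpy() - X @ beta
            np.testing.assert_allclose(
                fit.s2.iloc[g], (r @ r) / (len(samples) - X.shape[1]), atol=1e-8
            )


class TestEbayes:
    def test_identical_variances_are_fixed_point(self):
        s2 = pd.Series([2.0] * 10)
        mod = ebayes_moderate(s2, df=5)
        np.testing.assert_allclose(mod.s2_post, 2.0, rtol=1e-6)

    def test_degenerate_spread_shrinks_fully_to_prior(self):
        # variances drawn with essentially no spread beyond chi-square noise
        # would give evar <= 0; construct the exact-degenerate case
        s2 = pd.Series(np.full(100, 3.0))
        mod = ebayes_moderate(s2, df=50)
        assert mod.d0 >= 1e5
        np.testing.assert_allclose(mod.s2_post, mod.s0_sq, rtol=1e-4)

    def test_hyperparameter_recovery_from_simulated_prior(self):
        rng = np.random.default_rng(3)
        d0_true, s0_true, df = 4.0, 2.0, 10
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=1000)
        s2 = sigma2 * rng.chisquare(df, size=1000) / df
        d0, s0 = estimate_variance_prior(s2, df)
        assert 3.0 < d0 < 5.0
        assert 1.8 < s0 < 2.2

    @pytest.mark.skipif(not HAVE_RSCRIPT, reason="Rscript unavailable")
    def test_matches_limma_squeeze_var(self, rng, tmp_path):
        s2 = rng.chisquare(6, size=400) / 6 * (1 + rng.random(400))
        path = tmp_path / "s2.txt"
        np.savetxt(path, s2)
        script = (
            'suppressMessages(library(limma));'
            f's2 <- scan("{path}", quiet=TRUE);'
            'out <- squeezeVar(s2, df=6);'
            'cat(sprintf("%.12f %.12f\\n", out$df.prior, out$var.prior))'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        d0_l, s0_l = (float(v) for v in res.stdout.split())
        d0, s0 = estimate_variance_prior(s2, 6)
        np.testing.assert_allclose([d0, s0], [d0_l, s0_l], rtol=1e-8)

    def test_trigamma_inverse_round_trips(self):
        from scipy.special import polygamma

        for y in (1e-5, 0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert np.isclose(float(polygamma(1, x)), y, rtol=1e-8)

    def test_too_few_genes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            estimate_variance_prior(np.array([1.0, 2.0]), 4)


class TestBH:
    def test_single_p_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_adjusted_values_bounded_and_order_consistent(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestLogCpm:
    def test_columns_sum_to_million_scale(self, rng):
        counts = _counts(rng.poisson(50, size=(100, 4)))
        expr = log_cpm(counts)
        total = (2.0 ** expr).sum(axis=0)
        np.testing.assert_allclose(total, 1e6, rtol=0.05)
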