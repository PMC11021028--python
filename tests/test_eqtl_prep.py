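"""Trait preparation: quantile normalization, Response construction,
PC removal, inverse-normal transform, pipeline composition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpp_eqtl.eqtl_prep import (
    compute_response,
    inverse_normal_transform,
    log2_quantile_normalize,
    prepare_response_dataset,
    prepare_treatment_dataset,
    quantile_normalize_columns,
    regress_out_pcs,
    select_technical_pcs,
    signed_normalize,
)
from mpp_eqtl.errors import (
    DegenerateInputError,
    InvalidArgumentError,
    MissingPairError,
    RankDeficiencyError,
)
from mpp_eqtl.synthetic_data import simulate_study


def _df(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestQuantileNormalization:
    def test_hand_computed_two_by_two(self):
        counts = _df([[1, 3], [7, 15]])
        out = log2_quantile_normalize(counts, offset=1.0)
        # log2 gives [[1,2],[3,4]]; reference distribution (1.5, 3.5)
        np.testing.assert_allclose(out.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_are_fixed_point(self):
        counts = _df(np.tile([[3], [15], [63]], (1, 4)))
        out = log2_quantile_normalize(counts, offset=1.0)
        np.testing.assert_allclose(out.to_numpy(), np.log2(counts.to_numpy() + 1))

    def test_all_columns_share_reference_distribution(self, rng):
        # tie-free input: every column's sorted values equal the reference
        X = rng.standard_normal((60, 7))
        out = quantile_normalize_columns(X)
        ref = np.sort(X, axis=0).mean(axis=1)
        for j in range(7):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            log2_quantile_normalize(_df([[1], [2]]))


class TestResponse:
    def test_signed_difference(self):
        cu = _df([[12, 3]])
        ct = _df([[4, 10]])
        out = compute_response(cu, ct)
        np.testing.assert_allclose(out.to_numpy(), [[8, -7]])

    def test_equal_treatments_give_zero(self):
        cu = _df([[5, 6], [7, 8]])
        out = compute_response(cu, cu.copy())
        assert (out.to_numpy() == 0).all()

    def test_unpaired_strain_reported(self):
        cu = _df(np.ones((2, 3)))
        ct = _df(np.ones((2, 2)))
        with pytest.raises(MissingPairError, match="s2"):
            compute_response(cu, ct)

    def test_column_order_mismatch_is_aligned_by_strain(self):
        cu = _df([[10, 20]])
        ct = pd.DataFrame([[5, 2]], index=["g0"], columns=["s1", "s0"])
        out = compute_response(cu, ct)
        np.testing.assert_allclose(out.to_numpy(), [[8, 15]])


class TestSignedNormalize:
    def test_sign_pattern_preserved(self, rng):
        d = _df(rng.normal(0, 50, size=(10, 6)).round())
        out = signed_normalize(d)
        np.testing.assert_array_equal(np.sign(out.to_numpy()), np.sign(d.to_numpy()))

    def test_all_positive_matches_plain_normalization(self, rng):
        d = _df(rng.poisson(30, size=(8, 4)) + 1.0)
        np.testing.assert_allclose(
            signed_normalize(d).to_numpy(),
            log2_quantile_normalize(d).to_numpy(),
        )

    def test_negating_one_strain_flips_signs_keeps_magnitudes(self, rng):
        d = _df(rng.normal(0, 40, size=(5, 5)).round())
        flipped = d.copy()
        flipped.iloc[:, 2] = -flipped.iloc[:, 2]
        a = signed_normalize(d).to_numpy()
        b = signed_normalize(flipped).to_numpy()
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-12)
        np.testing.assert_allclose(b[:, 2], -a[:, 2], atol=1e-12)

    def test_zeros_map_to_zero(self):
        d = _df([[0, 5], [-3, 0]])
        out = signed_normalize(d).to_numpy()
        assert out[0, 0] == 0.0 and out[1, 1] == 0.0


def _expr_with_shares(shares, n_strains=20, n_genes=40, seed=0):
    """Strain x gene data whose PC variance shares are exactly `shares`."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_strains, len(shares))))
    v, _ = np.linalg.qr(rng.standard_normal((n_genes, len(shares))))
    sv = np.sqrt(np.asarray(shares))
    X = q @ np.diag(sv) @ v.T  # strains x genes, centered up to q's means
    X -= X.mean(axis=0)
    return _df(X.T)


class TestPCSelection:
    def test_variance_share_rule(self):
        expr = _expr_with_shares([0.50, 0.30, 0.015, 0.01, 0.008])
        sel = select_technical_pcs(expr, var_fraction=0.02)
        assert sel.indices == [0, 1]
        assert sel.variance_shares[0] > sel.variance_shares[1] > 0.02

    def test_covariate_associated_pc_added(self):
        expr = _expr_with_shares([0.60, 0.30])
        # append a tiny-variance component that perfectly separates two pools
        pools = np.array(["a"] * 10 + ["b"] * 10)
        bump = np.where(pools == "a", 1.0, -1.0) * 0.005
        expr.iloc[0] = expr.iloc[0] + bump  # inject along one gene
        cov = pd.DataFrame({"pool": pools}, index=expr.columns)
        sel = select_technical_pcs(expr, covariates=cov, var_fraction=0.02)
        extra = [i for i in sel.indices if sel.variance_shares[i] <= 0.02]
        assert extra, "pool-separating low-variance PC should be selected"

    def test_var_fraction_one_and_no_covariates_selects_nothing(self, rng):
        expr = _df(rng.standard_normal((30, 15)))
        sel = select_technical_pcs(expr, var_fraction=1.0)
        assert sel.indices == []

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            select_technical_pcs(_df(np.ones((5, 6))))


class TestRegressOut:
    def test_empty_selection_centers_genes(self, rng):
        expr = _df(rng.standard_normal((6, 10)))
        out = regress_out_pcs(expr, np.empty((10, 0)))
        np.testing.assert_allclose(
            out.to_numpy(), expr.to_numpy() - expr.to_numpy().mean(axis=1, keepdims=True),
            atol=1e-12,
        )

    def test_expression_equal_to_score_vanishes(self, rng):
        score = rng.standard_normal(12)
        expr = _df(np.tile(score, (3, 1)))
        out = regress_out_pcs(expr, score)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_scores_and_match_ols_oracle(self, rng):
        expr = _df(rng.standard_normal((50, 20)))
        scores = rng.standard_normal((20, 3))
        out = regress_out_pcs(expr, scores)
        np.testing.assert_allclose(out.to_numpy() @ scores, 0.0, atol=1e-8)
        X = np.column_stack([np.ones(20), scores])
        for g in range(0, 50, 11):
            beta, *_ = np.linalg.lstsq(X, expr.iloc[g].to_numpy(), rcond=None)
            np.testing.assert_allclose(
                out.iloc[g].to_numpy(), expr.iloc[g].to_numpy() - X @ beta, atol=1e-10
            )

    def test_collinear_scores_rejected(self, rng):
        expr = _df(rng.standard_normal((4, 10)))
        s = rng.standard_normal(10)
        with pytest.raises(RankDeficiencyError):
            regress_out_pcs(expr, np.column_stack([s, 2 * s]))


class TestInverseNormal:
    def test_three_strain_closed_form(self):
        out = inverse_normal_transform(_df([[5, 1, 9]]))
        np.testing.assert_allclose(
            out.to_numpy()[0], [0.0, -0.9674, 0.9674], atol=5e-5
        )

    def test_monotone_transform_invariance(self, rng):
        x = _df(rng.standard_normal((4, 15)))
        y = _df(np.exp(3 * x.to_numpy()) + 7)
        np.testing.assert_allclose(
            inverse_normal_transform(x).to_numpy(),
            inverse_normal_transform(y).to_numpy(),
            atol=1e-12,
        )

    def test_per_gene_mean_zero(self, rng):
        out = inverse_normal_transform(_df(rng.standard_normal((6, 21))))
        np.testing.assert_allclose(out.to_numpy().mean(axis=1), 0.0, atol=1e-12)

    def test_too_few_strains_rejected(self):
        with pytest.raises(InvalidArgumentError):
            inverse_normal_transform(_df([[1, 2]]))


class TestPreparationPipeline:
    def test_provenance_records_step_order(self, rng):
        counts = _df(rng.poisson(60, size=(40, 12)))
        tm = prepare_treatment_dataset(counts, "Gut-Control")
        steps = [s.split("(")[0] for s in tm.provenance]
        assert steps == ["log2_quantile_normalize", "regress_out_pcs", "inverse_normal_transform"]

        resp = prepare_response_dataset(counts, _df(rng.poisson(60, size=(40, 12))),
                                        "Gut-Response")
        steps = [s.split("(")[0] for s in resp.provenance]
        assert steps == ["compute_response", "signed_normalize",
                         "regress_out_pcs", "inverse_normal_transform"]

    def test_planted_pool_batch_effect_removed(self):
        # an additive log2 shift on every gene of one pool must be absorbed
        # by normalization + PC removal: before preparation the pool factor
        # dominates most genes, afterwards its per-gene F-test is null
        data = simulate_study(None, n_strains=40, n_background_genes=300,
                              batch_sd=1.5, seed=21)
        sub = data.samples[(data.samples["tissue"] == "gut")
                           & (data.samples["treatment"] == "control")]
        counts = data.counts.loc[:, sub["sample_id"]]
        counts.columns = sub["strain"].tolist()
        cov = pd.DataFrame({"pool": sub["pool"].tolist()}, index=sub["strain"].tolist())
        tm = prepare_treatment_dataset(counts, "Gut-Control", covariates=cov)

        pool = (sub["pool"] == "pool1").to_numpy(dtype=float)
        pool = (pool - pool.mean())[:, None]
        n = len(sub)

        def pool_r2(matrix: np.ndarray) -> np.ndarray:
            centered = matrix - matrix.mean(axis=1, keepdims=True)
            resid = centered - centered @ pool @ np.linalg.pinv(pool)
            return 1.0 - (resid**2).sum(axis=1) / (centered**2).sum(axis=1)

        before = pool_r2(np.log2(counts.to_numpy(dtype=float) + 1.0))
        assert np.median(before) > 0.15  # batch visible across most raw genes
        after = pool_r2(tm.values.to_numpy())
        f = after / (1.0 - after) * (n - 2)
        pvals = stats.f.sf(f, 1, n - 2)
        sig = float((pvals < 0.05).mean())
        assert sig <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(pvals))
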