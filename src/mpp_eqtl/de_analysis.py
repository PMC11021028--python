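"""Differential expression: filtering, TMM normalization, factorial fit,
empirical-Bayes moderation, BH correction.

The gene-wise model is ``log2 CPM ~ tissue * treatment * resistance_class +
pool`` fitted by ordinary least squares with the three factors coded +-1/2,
so each coefficient directly equals the classical factorial contrast of cell
means (main effects averaged over the other factors, interactions as
differences of differences).  Variances are shrunk toward a common prior by
moment matching on log variances, and per-contrast p-values use the
moderated t distribution with augmented degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from scipy.special import digamma, polygamma

from .datatypes import validate_counts, validate_sample_table
from .errors import DegenerateInputError, InvalidArgumentError, RankDeficiencyError

#: Contrast coefficients reported by default (everything except nuisance terms).
HEADLINE_TERMS = (
    "tissue[gut-head]",
    "treatment[copper-control]",
    "resistance[sensitive-resistant]",
    "tissue:treatment",
    "tissue:resistance",
    "treatment:resistance",
    "tissue:treatment:resistance",
)

D0_CAP = 1e6  # prior df cap representing "infinite" (fully shrunk)


def filter_low_expression(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 47
) -> pd.DataFrame:
    """Drop genes with all-zero counts and genes lacking at least
    ``min_count`` counts in at least ``min_samples`` samples.

    The default (10 counts in 47 samples) keeps genes expressed in at least
    one full three-way design cell of a 96-strain factorial study.  Gene
    order is preserved.
    """
    validate_counts(counts)
    if min_samples > counts.shape[1]:
        raise InvalidArgumentError(
            f"min_samples={min_samples} exceeds number of samples ({counts.shape[1]})"
        )
    arr = counts.to_numpy()
    nonzero = arr.sum(axis=1) > 0
    expressed = (arr >= min_count).sum(axis=1) >= min_samples
    return counts.loc[nonzero & expressed]


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, logratio_trim: float, abs_trim: float
) -> float:
    """Two-sample TMM factor of ``obs`` against reference ``ref``.

    Doubly trimmed (by log-ratio M and average log-abundance A) weighted mean
    of M values; weights are inverse asymptotic variances of M under the
    binomial approximation.  Genes with zero counts in either sample drop out
    of the trimmed mean through the finiteness filter.
    """
    nO, nR = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        logR = np.log2((obs / nO) / (ref / nR))
        absE = (np.log2(obs / nO) + np.log2(ref / nR)) / 2.0
        v = (nO - obs) / (nO * obs) + (nR - ref) / (nR * ref)
    fin = np.isfinite(logR) & np.isfinite(absE) & (absE > -1e10)
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = stats.rankdata(logR)
    rank_s = stats.rankdata(absE)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame, logratio_trim: float = 0.3, abs_trim: float = 0.05
) -> pd.Series:
    """Weighted trimmed-mean-of-M-values scaling factor per sample.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction.  Factors are centered so
    they multiply to one (geometric-mean normalization); effective library
    size is ``library size * factor``.
    """
    validate_counts(counts)
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if np.any(lib <= 0):
        bad = [counts.columns[i] for i in np.where(lib <= 0)[0]]
        raise DegenerateInputError(f"samples with zero total count: {bad[:5]}")
    f75 = np.quantile(arr, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = arr[:, ref_idx]
    raw = np.array(
        [_tmm_pair_factor(arr[:, j], ref, logratio_trim, abs_trim) for j in range(arr.shape[1])]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with TMM-adjusted effective library sizes
    and a small prior count guarding against zeros."""
    validate_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    return np.log2(
        (counts + prior_count).div(lib + 2 * prior_count, axis=1) * 1e6
    )


def factorial_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Full-factorial design matrix with +-1/2 effect coding plus pool dummies.

    Columns: intercept, three main effects, three two-way interactions, the
    three-way interaction, and one 0/1 dummy per pool beyond the first.
    With this coding each factorial coefficient equals the corresponding
    contrast of cell means (e.g. the tissue coefficient is mean(gut) -
    mean(head) averaged over treatment and resistance class).
    """
    validate_sample_table(samples)
    t = np.where(samples["tissue"].to_numpy() == "gut", 0.5, -0.5)
    c = np.where(samples["treatment"].to_numpy() == "copper", 0.5, -0.5)
    r = np.where(samples["resistance_class"].to_numpy() == "sensitive", 0.5, -0.5)
    cols = {
        "intercept": np.ones(len(samples)),
        "tissue[gut-head]": t,
        "treatment[copper-control]": c,
        "resistance[sensitive-resistant]": r,
        "tissue:treatment": t * c,
        "tissue:resistance": t * r,
        "treatment:resistance": c * r,
        "tissue:treatment:resistance": t * c * r,
    }
    pools = sorted(samples["pool"].unique())
    for p in pools[1:]:
        cols[f"pool[{p}]"] = (samples["pool"].to_numpy() == p).astype(float)
    return pd.DataFrame(cols, index=samples["sample_id"].tolist())


@dataclass
class FactorialFit:
    """Per-gene OLS results on a common design.

    ``stdev_unscaled`` holds sqrt of the diagonal of (X'X)^-1: multiplying
    by a gene's residual standard deviation gives coefficient standard
    errors.  ``df_residual`` is shared by all genes.
    """

    coefficients: pd.DataFrame  # genes x terms
    s2: pd.Series  # residual variance per gene
    df_residual: int
    stdev_unscaled: pd.Series  # per term
    design: pd.DataFrame


def fit_factorial_de(log_expr: pd.DataFrame, samples: pd.DataFrame) -> FactorialFit:
    """Ordinary least squares of every gene on the factorial design.

    Raises :class:`RankDeficiencyError` naming the confounded columns when
    the design is not full rank (e.g. a pool perfectly nested in tissue).
    """
    design = factorial_design(samples)
    missing = [s for s in design.index if s not in log_expr.columns]
    if missing:
        raise InvalidArgumentError(f"expression matrix missing samples: {missing[:5]}")
    X = design.to_numpy()
    n, p = X.shape
    if n < p:
        raise InvalidArgumentError(f"need at least as many samples ({n}) as design columns ({p})")
    # rank diagnosis via pivoted QR so the error can name dependent columns
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(n, p) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < p:
        dependent = [design.columns[i] for i in piv[rank:]]
        raise RankDeficiencyError(
            f"design is rank deficient (rank {rank} < {p}); confounded columns: {dependent}"
        )
    Y = log_expr.loc[:, design.index].to_numpy(dtype=float)  # genes x samples
    Q, Rf = np.linalg.qr(X)
    beta = scipy.linalg.solve_triangular(Rf, Q.T @ Y.T)  # p x genes
    resid = Y.T - X @ beta
    df = n - p
    # saturated designs (df == 0) fit exactly; variance is undefined, not inf
    s2 = (resid**2).sum(axis=0) / df if df > 0 else np.zeros(Y.shape[0])
    Rinv = scipy.linalg.solve_triangular(Rf, np.eye(p))
    unscaled = np.sqrt((Rinv**2).sum(axis=1))
    return FactorialFit(
        coefficients=pd.DataFrame(beta.T, index=log_expr.index, columns=design.columns),
        s2=pd.Series(s2, index=log_expr.index, name="s2"),
        df_residual=df,
        stdev_unscaled=pd.Series(unscaled, index=design.columns, name="stdev_unscaled"),
        design=design,
    )


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        raise InvalidArgumentError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Under the hierarchical model ``s2_g ~ s0^2 * chi^2_df / df`` with prior
    df ``d0``, ``log s2_g`` has known mean/variance expressible through
    digamma/trigamma; matching the empirical mean and variance of
    ``log s2_g`` yields closed-form estimates (Newton inversion of the
    trigamma function).  Degenerate spread returns ``d0`` capped at 1e6.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 3:
        raise InvalidArgumentError("need at least 3 genes with positive variance")
    z = np.log(pos)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.mean((e - emean) ** 2) * n / (n - 1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = min(2.0 * trigamma_inverse(evar), D0_CAP)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # observed spread is below pure sampling noise: treat the prior as a
        # point mass at the geometric mean, so identical variances are an
        # exact fixed point of the shrinkage formula
        d0 = D0_CAP
        s0_sq = float(np.exp(z.mean()))
    return float(d0), s0_sq


@dataclass
class ModeratedStats:
    d0: float
    s0_sq: float
    s2_post: pd.Series
    t: pd.DataFrame | None = None  # genes x terms
    p_value: pd.DataFrame | None = None
    df_total: float = np.nan


def ebayes_moderate(
    s2: pd.Series,
    df: float,
    coefficients: pd.DataFrame | None = None,
    stdev_unscaled: pd.Series | None = None,
) -> ModeratedStats:
    """Shrink per-gene variances toward the estimated prior and, when
    coefficients are supplied, compute moderated t statistics and two-sided
    p-values on ``df + d0`` degrees of freedom."""
    d0, s0_sq = estimate_variance_prior(np.asarray(s2, dtype=float), df)
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    out = ModeratedStats(d0=d0, s0_sq=s0_sq, s2_post=s2_post, df_total=df + d0)
    if coefficients is not None:
        if stdev_unscaled is None:
            raise InvalidArgumentError("stdev_unscaled required with coefficients")
        se = np.sqrt(np.outer(s2_post, stdev_unscaled.reindex(coefficients.columns) ** 2))
        t = coefficients / se
        p = 2.0 * stats.t.sf(np.abs(t.to_numpy()), df=min(out.df_total, D0_CAP))
        out.t = t
        out.p_value = pd.DataFrame(p, index=coefficients.index, columns=coefficients.columns)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    fdr: float = 0.05,
    min_count: int = 10,
    min_samples: int = 47,
) -> dict[str, pd.DataFrame]:
    """Full DE stage: filter, TMM, log-CPM, factorial fit, moderation, BH.

    Returns one table per factorial term (gene, logFC, t, p_value,
    adjusted_p, significant), adjusting within each term across genes.
    """
    filtered = filter_low_expression(counts, min_count=min_count, min_samples=min_samples)
    factors = tmm_factors(filtered)
    expr = log_cpm(filtered, factors)
    fit = fit_factorial_de(expr, samples)
    mod = ebayes_moderate(fit.s2, fit.df_residual, fit.coefficients, fit.stdev_unscaled)
    results = {}
    for term in HEADLINE_TERMS:
        p = mod.p_value[term].to_numpy()
        adj = bh_adjust(p)
        results[term] = pd.DataFrame(
            {
                "gene": fit.coefficients.index,
                "logFC": fit.coefficients[term].to_numpy(),
                "t": mod.t[term].to_numpy(),
                "p_value": p,
                "adjusted_p": adj,
                "significant": adj < fdr,
            }
        ).set_index("gene")
    return results
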