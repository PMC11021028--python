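"""Preparation of expression traits for haplotype genome scans.

Six datasets are prepared per study — {Head, Gut} x {Control, Copper,
Response} — each as: log2 + column-wise quantile normalization (for the two
treatment datasets) or signed normalization of the copper-minus-control
count difference (for Response), followed by removal of technical principal
components and a final per-gene rank-based inverse-normal transform.

Normalization conventions
-------------------------
* "Quantile normalization" of samples (step 1) maps every strain column onto
  the mean empirical distribution (Bolstad-style); ties receive the average
  of the reference quantiles at the tied ranks.
* The Response trait is the raw count difference copper - control per
  strain; positive values mean copper-induced expression.  Its normalization
  operates on |difference| and restores the sign afterwards, so zero
  differences map to exactly zero.
* The final per-gene transform (step 3) is the rank-based inverse-normal
  transform Phi^-1((rank - 0.5) / n) with average ranks for ties, the
  standard choice for eQTL trait matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats

from .datatypes import TraitMatrix, validate_counts
from .errors import (
    DegenerateInputError,
    InvalidArgumentError,
    MissingPairError,
    RankDeficiencyError,
)

LOG_OFFSET = 1.0  # default pseudo-count before log2; zeros are common


def quantile_normalize_columns(values: np.ndarray) -> np.ndarray:
    """Map every column onto the mean empirical distribution.

    After normalization the sorted values of every column are identical to
    the reference (column-mean of sorted values).  Ties within a column get
    the average of the reference quantiles spanned by their average rank.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise InvalidArgumentError("expected a 2-d matrix")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(n, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return out


def log2_quantile_normalize(counts: pd.DataFrame, offset: float = LOG_OFFSET) -> pd.DataFrame:
    """log2(count + offset), then column-wise quantile normalization."""
    validate_counts(counts)
    if counts.shape[1] < 2:
        raise InvalidArgumentError("quantile normalization needs at least 2 samples")
    logged = np.log2(counts.to_numpy(dtype=float) + offset)
    return pd.DataFrame(
        quantile_normalize_columns(logged), index=counts.index, columns=counts.columns
    )


def compute_response(
    copper_counts: pd.DataFrame, control_counts: pd.DataFrame
) -> pd.DataFrame:
    """Signed copper-response trait: copper counts minus control counts.

    Both inputs must be genes x strains with identical gene lists and the
    same strain set (columns are strain ids); strains present in only one
    treatment raise :class:`MissingPairError` listing the offenders.
    Positive values indicate copper-induced expression.
    """
    if list(copper_counts.index) != list(control_counts.index):
        raise InvalidArgumentError("gene lists differ between copper and control")
    cu, ct = set(copper_counts.columns), set(control_counts.columns)
    unpaired = sorted(cu.symmetric_difference(ct))
    if unpaired:
        raise MissingPairError(f"strains missing one treatment: {unpaired[:10]}")
    return copper_counts - control_counts.loc[:, copper_counts.columns]


def signed_normalize(response: pd.DataFrame, offset: float = LOG_OFFSET) -> pd.DataFrame:
    """Normalize the magnitude of a signed matrix, then restore the sign.

    ``log2(|d| + offset)`` is quantile normalized across strains as in
    :func:`log2_quantile_normalize` and multiplied by ``sign(d)``; exact
    zeros stay zero.  This preserves the induction/repression direction of
    every gene x strain response while putting magnitudes on a common scale.
    """
    d = response.to_numpy(dtype=float)
    mags = quantile_normalize_columns(np.log2(np.abs(d) + offset))
    return pd.DataFrame(np.sign(d) * mags, index=response.index, columns=response.columns)


@dataclass
class PCSelection:
    """Technical principal components chosen for removal.

    ``indices`` are 0-based PC indices in decreasing-variance order; the
    corresponding ``scores`` columns are the strain coordinates to regress
    out.  ``variance_shares`` covers all computed PCs; ``assoc_p`` holds the
    PC x covariate association p-values actually tested.
    """

    indices: list[int]
    scores: np.ndarray  # strains x selected
    variance_shares: np.ndarray
    assoc_p: pd.DataFrame = field(default_factory=pd.DataFrame)


def _pc_covariate_pvalue(score: np.ndarray, covariate: pd.Series) -> float:
    """One-way ANOVA for categorical covariates, Pearson for numeric."""
    if pd.api.types.is_numeric_dtype(covariate) and not pd.api.types.is_bool_dtype(covariate):
        x = covariate.to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(score) == 0:
            return 1.0
        return float(stats.pearsonr(score, x).pvalue)
    groups = [score[(covariate == level).to_numpy()] for level in pd.unique(covariate)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        return 1.0
    res = stats.f_oneway(*groups)
    return float(res.pvalue) if np.isfinite(res.pvalue) else 1.0


def select_technical_pcs(
    expr: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    var_fraction: float = 0.02,
    alpha: float = 0.05,
    n_assoc_pcs: int = 20,
) -> PCSelection:
    """PCs over strains that capture technical structure.

    A PC is selected when its variance share exceeds ``var_fraction``
    (default 2%) or when it associates with any supplied technical covariate
    at level ``alpha`` (per PC x covariate, no multiplicity correction).
    Covariate association is screened only for the ``n_assoc_pcs`` leading
    PCs: technical batch structure loads on high-variance components, and
    testing the full spectrum at level ``alpha`` would remove roughly
    ``alpha`` of all PCs by chance alone, eroding genetic signal.
    ``expr`` is genes x strains; ``covariates`` is indexed by strain.
    """
    if not (0 < alpha < 1):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    X = expr.to_numpy(dtype=float).T  # strains x genes
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise DegenerateInputError("expression matrix is constant; PCA undefined")
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    shares = sv**2 / np.sum(sv**2)
    scores_all = U * sv  # strain coordinates
    n_pc = int(np.sum(sv > sv[0] * 1e-12))
    selected = set(np.where(shares[:n_pc] > var_fraction)[0])
    assoc = {}
    if covariates is not None and not covariates.empty:
        cov = covariates.loc[list(expr.columns)]
        n_screen = min(n_pc, n_assoc_pcs)
        for k in range(n_screen):
            assoc[f"PC{k + 1}"] = {
                name: _pc_covariate_pvalue(scores_all[:, k], cov[name])
                for name in cov.columns
            }
        for k in range(n_screen):
            if any(p < alpha for p in assoc[f"PC{k + 1}"].values()):
                selected.add(k)
    indices = sorted(selected)
    return PCSelection(
        indices=indices,
        scores=scores_all[:, indices],
        variance_shares=shares,
        assoc_p=pd.DataFrame(assoc).T if assoc else pd.DataFrame(),
    )


def regress_out_pcs(expr: pd.DataFrame, scores: np.ndarray) -> pd.DataFrame:
    """Per-gene OLS residuals of expression on intercept + PC scores.

    With no scores this is mean-centering.  Residuals are orthogonal to
    every score vector.  Collinear scores raise
    :class:`RankDeficiencyError`.
    """
    scores = np.asarray(scores, dtype=float)
    n = expr.shape[1]
    if scores.size == 0:
        scores = np.empty((n, 0))
    elif scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] != n:
        raise InvalidArgumentError(
            f"score length {scores.shape[0]} does not match {n} strains"
        )
    X = np.column_stack([np.ones(n)] + [scores[:, k] for k in range(scores.shape[1])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("PC score vectors are collinear (with the intercept)")
    Y = expr.to_numpy(dtype=float).T  # strains x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)


def inverse_normal_transform(residuals: pd.DataFrame) -> pd.DataFrame:
    """Per-gene rank-based inverse normal transform across strains.

    Values become ``Phi^-1((rank - 0.5) / n)`` with average ranks for ties,
    so every gene is a permutation of fixed normal quantiles (mean exactly
    zero for tie-free genes) and any monotone transform of the input leaves
    the output unchanged.
    """
    n = residuals.shape[1]
    if n < 3:
        raise InvalidArgumentError("inverse normal transform needs at least 3 strains")
    vals = residuals.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, vals)
    return pd.DataFrame(
        stats.norm.ppf((ranks - 0.5) / n), index=residuals.index, columns=residuals.columns
    )


def _finalize(
    label: str,
    normalized: pd.DataFrame,
    covariates: pd.DataFrame | None,
    var_fraction: float,
    alpha: float,
    provenance: list[str],
) -> TraitMatrix:
    sel = select_technical_pcs(normalized, covariates, var_fraction=var_fraction, alpha=alpha)
    provenance.append(
        "regress_out_pcs(indices="
        + ",".join(str(i + 1) for i in sel.indices)
        + f"; var_fraction={var_fraction}; alpha={alpha})"
    )
    resid = regress_out_pcs(normalized, sel.scores)
    provenance.append("inverse_normal_transform")
    traits = inverse_normal_transform(resid)
    tm = TraitMatrix(label=label, values=traits, provenance=provenance)
    tm.pc_selection = sel  # stash for provenance sidecars
    return tm


def prepare_treatment_dataset(
    counts_by_strain: pd.DataFrame,
    label: str,
    covariates: pd.DataFrame | None = None,
    offset: float = LOG_OFFSET,
    var_fraction: float = 0.02,
    alpha: float = 0.05,
) -> TraitMatrix:
    """Control or Copper trait matrix: log2+quantile normalization, PC
    removal, inverse-normal transform.  ``counts_by_strain`` is genes x
    strains for one tissue x treatment."""
    provenance = [f"log2_quantile_normalize(offset={offset})"]
    normalized = log2_quantile_normalize(counts_by_strain, offset=offset)
    return _finalize(label, normalized, covariates, var_fraction, alpha, provenance)


def prepare_response_dataset(
    copper_by_strain: pd.DataFrame,
    control_by_strain: pd.DataFrame,
    label: str,
    covariates: pd.DataFrame | None = None,
    offset: float = LOG_OFFSET,
    var_fraction: float = 0.02,
    alpha: float = 0.05,
) -> TraitMatrix:
    """Response trait matrix: copper - control counts, signed normalization,
    PC removal, inverse-normal transform."""
    provenance = ["compute_response(copper-control)", f"signed_normalize(offset={offset})"]
    response = compute_response(copper_by_strain, control_by_strain)
    normalized = signed_normalize(response, offset=offset)
    return _finalize(label, normalized, covariates, var_fraction, alpha, provenance)
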