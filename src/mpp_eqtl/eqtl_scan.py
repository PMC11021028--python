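"""Haley-Knott genome scans on founder additive probabilities.

At each marker the full model regresses the trait on the F founder
probability columns with no separate intercept (the columns sum to one and
therefore span it); the null model is intercept-only.  The scan statistic is
the classical regression LOD

    LOD = (n / 2) * log10(RSS0 / RSS1)

Gene-specific significance thresholds come from permuting strain labels:
for each permutation the genome-wide maximum LOD is recorded and the
(1 - alpha) empirical order statistic over permutations is the threshold.
Permutation index sets are shared across genes by default (one shuffle per
round applied to every gene), which keeps the permutation scan a single
batched matrix product; fully independent per-gene permutations are
available by flag.

Numerics: each marker's probability matrix is reduced once to an
orthonormal column basis (SVD, rank-tolerant, so rank-deficient markers —
e.g. a founder absent among sampled strains — are handled by projection
onto the realized column space).  RSS1 below ``1e-12 * RSS0`` is treated as
a perfect fit and the LOD is capped (default 50) to avoid infinities on
noise-free fixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import FounderProbabilities, MarkerMap, ScanStudy, TraitMatrix
from .errors import AlignmentError, InvalidArgumentError, UnderdeterminedModelError

LOD_CAP = 50.0
_PERFECT_FIT = 1e-12


class HKEngine:
    """Precomputed scan operator for one strain-aligned probability array.

    Builds per-marker orthonormal bases once; scanning a genes x strains
    trait block is then a single matrix product per call, used identically
    for observed traits and permutation rounds.
    """

    def __init__(self, probs: FounderProbabilities, lod_cap: float = LOD_CAP):
        S, M, F = probs.P.shape
        if S < F + 1:
            raise UnderdeterminedModelError(
                f"need at least n_founders + 1 = {F + 1} strains, got {S}"
            )
        self.n = S
        self.n_markers = M
        self.n_founders = F
        self.lod_cap = lod_cap
        Q = np.zeros((M, S, F))
        for m in range(M):
            X = probs.P[:, m, :]
            U, sv, _ = np.linalg.svd(X, full_matrices=False)
            if sv.size and sv[0] > 0:
                r = int(np.sum(sv > sv[0] * max(S, F) * np.finfo(float).eps))
                Q[m, :, :r] = U[:, :r]
        # strains x (markers * founders), one GEMM per scan
        self._Q2 = Q.transpose(1, 0, 2).reshape(S, M * F)

    def lod(self, Y: np.ndarray) -> np.ndarray:
        """LOD curves for a genes x strains value block."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[1] != self.n:
            raise AlignmentError(f"trait block has {Y.shape[1]} strains, engine expects {self.n}")
        total = (Y**2).sum(axis=1)
        rss0 = total - Y.sum(axis=1) ** 2 / self.n
        B = Y @ self._Q2
        B = B.reshape(Y.shape[0], self.n_markers, self.n_founders)
        rss1 = total[:, None] - (B**2).sum(axis=2)
        return self._lod_from_rss(rss0, rss1)

    def _lod_from_rss(self, rss0: np.ndarray, rss1: np.ndarray) -> np.ndarray:
        perfect = rss1 <= _PERFECT_FIT * rss0[:, None]
        safe1 = np.where(perfect, 1.0, rss1)
        with np.errstate(divide="ignore"):
            lod = 0.5 * self.n * (np.log10(rss0[:, None]) - np.log10(safe1))
        lod = np.where(perfect, self.lod_cap, lod)
        lod[rss0 <= 0] = 0.0  # constant trait: nothing to explain
        return np.clip(lod, 0.0, self.lod_cap)


def hk_scan(
    trait: np.ndarray, probs: FounderProbabilities, lod_cap: float = LOD_CAP
) -> np.ndarray:
    """LOD curve of a single trait vector over all markers."""
    trait = np.asarray(trait, dtype=float)
    if trait.ndim != 1:
        raise InvalidArgumentError("trait must be a 1-d vector")
    if trait.shape[0] != probs.n_strains:
        raise AlignmentError(
            f"trait has {trait.shape[0]} values but probabilities cover "
            f"{probs.n_strains} strains"
        )
    if np.any(~np.isfinite(trait)):
        raise InvalidArgumentError("trait contains missing or non-finite values")
    return HKEngine(probs, lod_cap=lod_cap).lod(trait[None, :])[0]


def _aligned_engine_and_values(
    traits: TraitMatrix | pd.DataFrame, probs: FounderProbabilities, lod_cap: float
) -> tuple[HKEngine, np.ndarray, list[str]]:
    values = traits.values if isinstance(traits, TraitMatrix) else traits
    strain_order = list(values.columns)
    missing = sorted(set(strain_order) - set(probs.strains))
    extra = sorted(set(probs.strains) - set(strain_order))
    if missing:
        raise AlignmentError(f"strains missing from probabilities: {missing[:10]}")
    aligned = probs.reorder_strains(strain_order) if strain_order != probs.strains or extra else probs
    Y = values.to_numpy(dtype=float)
    if np.any(~np.isfinite(Y)):
        raise InvalidArgumentError("trait matrix contains missing or non-finite values")
    return HKEngine(aligned, lod_cap=lod_cap), Y, list(values.index)


def scan_all(
    traits: TraitMatrix | pd.DataFrame,
    probs: FounderProbabilities,
    marker_map: MarkerMap | None = None,
    lod_cap: float = LOD_CAP,
) -> ScanStudy:
    """Batched Haley-Knott scan of every gene in a trait matrix.

    Equals :func:`hk_scan` applied gene by gene (same basis, same batched
    algebra).  ``marker_map`` is carried for downstream peak calling; when
    omitted a bare map cannot be attached and peak calling needs one later.
    """
    engine, Y, genes = _aligned_engine_and_values(traits, probs, lod_cap)
    lod = engine.lod(Y)
    if marker_map is not None and marker_map.n_markers != probs.n_markers:
        raise AlignmentError(
            f"marker map has {marker_map.n_markers} markers, probabilities have "
            f"{probs.n_markers}"
        )
    return ScanStudy(
        genes=genes,
        marker_map=marker_map,
        lod=lod,
        n_strains=engine.n,
    )


def permutation_thresholds(
    traits: TraitMatrix | pd.DataFrame,
    probs: FounderProbabilities,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    shared_permutations: bool = True,
    lod_cap: float = LOD_CAP,
    return_max_lods: bool = False,
):
    """Gene-specific genome-wide LOD thresholds by strain-label permutation.

    The threshold is the empirical order statistic ``ceil((1 - alpha) *
    n_perm)`` of each gene's ``n_perm`` genome-wide maximum LODs.  With
    ``shared_permutations`` (default) one permuted strain order per round is
    applied to every gene; otherwise each gene is shuffled independently.
    Deterministic for a fixed integer seed.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100 for a stable 95% quantile")
    if not (0 < alpha < 1):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    engine, Y, genes = _aligned_engine_and_values(traits, probs, lod_cap)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G, n = Y.shape
    max_lods = np.empty((n_perm, G))
    for b in range(n_perm):
        if shared_permutations:
            Yp = Y[:, rng.permutation(n)]
        else:
            idx = np.argsort(rng.random((G, n)), axis=1)
            Yp = np.take_along_axis(Y, idx, axis=1)
        max_lods[b] = engine.lod(Yp).max(axis=1)
    k = int(np.ceil((1.0 - alpha) * n_perm))
    thresholds = np.sort(max_lods, axis=0)[k - 1]
    if return_max_lods:
        return thresholds, max_lods
    return thresholds


def scan_with_thresholds(
    traits: TraitMatrix | pd.DataFrame,
    probs: FounderProbabilities,
    marker_map: MarkerMap | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    shared_permutations: bool = True,
    lod_cap: float = LOD_CAP,
) -> ScanStudy:
    """Convenience wrapper: observed scan plus permutation thresholds."""
    study = scan_all(traits, probs, marker_map=marker_map, lod_cap=lod_cap)
    study.thresholds = permutation_thresholds(
        traits,
        probs,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        shared_permutations=shared_permutations,
        lod_cap=lod_cap,
    )
    return study
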