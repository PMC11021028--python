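"""Synthetic multiparental RIL study generator.

Emulates the structure of an 8-founder recombinant-inbred expression study:
a regular marker grid, strain genomes built as founder mosaics with
Poisson-distributed crossovers, additive founder probabilities, a factorial
sample layout (strain x tissue x treatment with pooling batches), and
negative-binomial expression counts carrying planted cis/trans and
treatment-specific eQTL.  The planted-truth table makes every downstream
stage testable without external data.

Design notes
------------
Recombination is modeled as Poisson breakpoints placed uniformly on the
genetic (cM) scale with no interference; consecutive mosaic segments always
switch founder, so each drawn breakpoint is a real ancestry transition.
Founder probabilities are smoothed one-hot vectors rather than HMM
posteriors: downstream regression only requires valid probability vectors,
and a single smoothing parameter emulates ancestry uncertainty.  Counts are
negative binomial with one dispersion parameter; batch effects are additive
log2 shifts shared by all genes in a pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    FounderProbabilities,
    MarkerMap,
    PlantedEqtl,
    validate_sample_table,
)
from .errors import InvalidArgumentError, InvalidReferenceError

_CHROM_NAMES = ("X", "2L", "2R", "3L", "3R")


def _chrom_name(i: int) -> str:
    return _CHROM_NAMES[i] if i < len(_CHROM_NAMES) else f"chr{i + 1}"


def simulate_marker_map(
    n_chromosomes: int,
    chrom_length_bp: int,
    spacing_bp: int,
    cM_per_Mb: float = 2.0,
) -> MarkerMap:
    """Regular marker grid: markers every ``spacing_bp`` from 0 to the
    chromosome end, with genetic position ``bp * cM_per_Mb / 1e6``.

    Mirrors a dense evenly spaced genotyping grid (e.g. one marker every
    10 kb); at desk scale a coarser spacing keeps scans fast.
    """
    if n_chromosomes < 1:
        raise InvalidArgumentError("n_chromosomes must be >= 1")
    if chrom_length_bp <= 0 or spacing_bp <= 0:
        raise InvalidArgumentError("chromosome length and spacing must be positive")
    if cM_per_Mb < 0:
        raise InvalidArgumentError("cM_per_Mb must be >= 0")
    rows = []
    for c in range(n_chromosomes):
        chrom = _chrom_name(c)
        for bp in range(0, chrom_length_bp + 1, spacing_bp):
            rows.append((f"{chrom}_{bp}", chrom, bp, bp * cM_per_Mb / 1e6))
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


def simulate_ril_genomes(
    marker_map: MarkerMap,
    n_strains: int,
    n_founders: int = 8,
    expected_crossovers_per_chrom: float = 2.0,
    prob_smoothing: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, FounderProbabilities]:
    """Draw founder-mosaic genomes and their additive probabilities.

    Each strain chromosome receives ``Poisson(expected_crossovers_per_chrom)``
    breakpoints uniform in cM; the founder changes at every breakpoint (next
    founder uniform among the other ``n_founders - 1``), so the stationary
    founder distribution at any marker is uniform.  Probabilities put
    ``1 - prob_smoothing`` on the true founder and spread the rest evenly.

    Returns
    -------
    assignments : DataFrame (strains x markers) of founder indices
    probs : FounderProbabilities
    """
    if n_founders < 2:
        raise InvalidArgumentError("n_founders must be >= 2")
    if not (0.0 <= prob_smoothing < 1.0):
        raise InvalidArgumentError("prob_smoothing must be in [0, 1)")
    if n_strains < 1:
        raise InvalidArgumentError("n_strains must be >= 1")
    if expected_crossovers_per_chrom < 0:
        raise InvalidArgumentError("expected_crossovers_per_chrom must be >= 0")

    rng = np.random.default_rng(seed)
    strains = [f"RIL{i:04d}" for i in range(1, n_strains + 1)]
    M = marker_map.n_markers
    assign = np.empty((n_strains, M), dtype=np.int64)
    cm_all = marker_map.df["pos_cM"].to_numpy(dtype=float)
    for chrom, sl in marker_map.chrom_slices().items():
        cm = cm_all[sl]
        lo, hi = float(cm[0]), float(cm[-1])
        for s in range(n_strains):
            k = int(rng.poisson(expected_crossovers_per_chrom))
            breaks = np.sort(rng.uniform(lo, hi, size=k))
            founders = np.empty(k + 1, dtype=np.int64)
            founders[0] = rng.integers(n_founders)
            for j in range(k):
                step = rng.integers(n_founders - 1)
                founders[j + 1] = (founders[j] + 1 + step) % n_founders
            seg = np.searchsorted(breaks, cm, side="right")
            assign[s, sl] = founders[seg]

    off = prob_smoothing / (n_founders - 1)
    P = np.full((n_strains, M, n_founders), off)
    su, mu = np.meshgrid(np.arange(n_strains), np.arange(M), indexing="ij")
    P[su, mu, assign] = 1.0 - prob_smoothing
    probs = FounderProbabilities(strains, marker_map.marker_ids, P)
    probs.validate()
    assignments = pd.DataFrame(assign, index=strains, columns=marker_map.marker_ids)
    return assignments, probs


def simulate_sample_table(
    strains: Sequence[str],
    n_pools_per_tissue: int = 2,
    tissues: Sequence[str] = ("head", "gut"),
    treatments: Sequence[str] = ("control", "copper"),
) -> pd.DataFrame:
    """Factorial sample layout: every strain in every tissue x treatment.

    Resistance classes alternate along the strain order (so both classes are
    evenly represented in every pooling batch, mirroring batch designs that
    balance phenotype classes).  Strains are split into ``n_pools_per_tissue``
    contiguous pooling batches shared by all of a strain's samples, so the
    pooling term crosses tissue and treatment and stays estimable alongside
    them in the factorial model (real plate pools are often tissue-specific,
    which confounds them with tissue).
    """
    strains = list(strains)
    n = len(strains)
    res = {s: ("resistant" if i % 2 == 0 else "sensitive") for i, s in enumerate(strains)}
    pool_of = {
        s: f"pool{min(i * n_pools_per_tissue // max(n, 1), n_pools_per_tissue - 1) + 1}"
        for i, s in enumerate(strains)
    }
    rows = []
    for tissue in tissues:
        for treatment in treatments:
            for s in strains:
                rows.append(
                    {
                        "sample_id": f"{s}_{tissue}_{treatment}",
                        "strain": s,
                        "tissue": tissue,
                        "treatment": treatment,
                        "resistance_class": res[s],
                        "pool": pool_of[s],
                    }
                )
    return validate_sample_table(pd.DataFrame(rows))


def _effect_sign(eqtl: PlantedEqtl, tissue: str, treatment: str) -> float:
    """Sign with which a planted effect enters a sample's log2 mean (0 = inactive)."""
    if eqtl.acts_in_tissue not in ("both", tissue):
        return 0.0
    a = eqtl.acts_in_treatment
    if a == "both" or a == treatment:
        return 1.0
    if a == "differential":
        return 1.0 if treatment == "copper" else 0.0
    return 0.0


def simulate_expression(
    truth: Sequence[PlantedEqtl],
    probs: FounderProbabilities,
    samples: pd.DataFrame,
    *,
    n_background_genes: int = 0,
    baseline_log2_mean: float = 5.0,
    gene_baseline_sd: float = 1.0,
    nb_dispersion: float = 0.05,
    batch_sd: float = 0.25,
    library_size_range: tuple[float, float] = (0.75, 1.25),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a genes x samples count matrix with the planted eQTL effects.

    Per sample the gene mean is ``2 ** (baseline_g + pool_shift + sum of
    active planted effects dotted with founder dosage)`` scaled by a
    per-sample library-size factor; counts are negative binomial with the
    given dispersion (variance ``mu + dispersion * mu**2``), Poisson in the
    ``dispersion -> 0`` limit.  Deterministic for a fixed seed.
    """
    if nb_dispersion < 0:
        raise InvalidArgumentError("nb_dispersion must be >= 0")
    if not (0 < library_size_range[0] <= library_size_range[1]):
        raise InvalidArgumentError("library_size_range must be positive and ordered")
    validate_sample_table(samples)
    strain_index = {s: i for i, s in enumerate(probs.strains)}
    unknown = sorted(set(samples["strain"]) - set(strain_index))
    if unknown:
        raise InvalidReferenceError(f"samples reference unknown strains: {unknown[:5]}")

    genes: list[str] = []
    for t in truth:
        if t.target_gene not in genes:
            genes.append(t.target_gene)
        if len(t.founder_effects) != probs.n_founders:
            raise InvalidReferenceError(
                f"effect vector for {t.target_gene!r} has {len(t.founder_effects)} "
                f"entries, expected {probs.n_founders}"
            )
        probs.marker_index(t.eqtl_marker)  # raises on unknown marker
    genes += [f"bg{i:04d}" for i in range(1, n_background_genes + 1)]
    if not genes:
        raise InvalidArgumentError("no genes to simulate (no truth and no background)")
    gene_index = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    G, N = len(genes), len(samples)
    baselines = baseline_log2_mean + gene_baseline_sd * rng.standard_normal(G)
    pools = sorted(samples["pool"].unique())
    pool_shift = dict(zip(pools, batch_sd * rng.standard_normal(len(pools))))
    lib = rng.uniform(library_size_range[0], library_size_range[1], size=N)

    log2_mean = np.tile(baselines[:, None], (1, N))
    sample_rows = list(samples.itertuples(index=False))
    for j, row in enumerate(sample_rows):
        log2_mean[:, j] += pool_shift[row.pool]
    for t in truth:
        g = gene_index[t.target_gene]
        m = probs.marker_index(t.eqtl_marker)
        dosage = probs.P[:, m, :] @ t.founder_effects  # per strain
        for j, row in enumerate(sample_rows):
            sign = _effect_sign(t, row.tissue, row.treatment)
            if sign:
                log2_mean[g, j] += sign * dosage[strain_index[row.strain]]

    mu = lib[None, :] * np.exp2(log2_mean)
    if nb_dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=genes, columns=samples["sample_id"].tolist())


def scaled_founder_effects(
    rng: np.random.Generator, n_founders: int, genetic_sd: float
) -> np.ndarray:
    """Random mean-centered founder-effect vector whose across-founder
    standard deviation equals ``genetic_sd`` (log2 units).

    With uniform founder ancestry this makes ``genetic_sd**2`` the genetic
    variance the locus contributes to the log2 trait, which is how planted
    effect sizes are expressed as a fraction of trait variance.
    """
    e = rng.standard_normal(n_founders)
    e -= e.mean()
    sd = e.std()
    if sd == 0:  # pragma: no cover - probability zero
        e[0], e[-1] = 1.0, -1.0
        e -= e.mean()
        sd = e.std()
    return e * (genetic_sd / sd)


def place_genes(
    truth: Sequence[PlantedEqtl],
    marker_map: MarkerMap,
    background_genes: Sequence[str],
    seed: int = 0,
    cis_offset_bp: int = 2_000,
    min_trans_cM: float = 10.0,
) -> pd.DataFrame:
    """Gene annotation consistent with each planted eQTL's expected class.

    Genes with ``expected_class == 'cis'`` are placed straddling their eQTL
    marker; ``trans`` genes are placed on another chromosome when one exists,
    otherwise at least ``min_trans_cM`` away on the same chromosome.
    Background genes get uniform random positions.  Coordinates are 1-based
    inclusive bp.
    """
    rng = np.random.default_rng(seed)
    mdf = marker_map.df
    slices = marker_map.chrom_slices()
    chrom_len = {c: int(mdf.iloc[sl]["pos_bp"].iloc[-1]) for c, sl in slices.items()}
    rows = []
    for t in truth:
        mrow = mdf.iloc[marker_map.index_of(t.eqtl_marker)]
        if t.expected_class == "cis":
            mid = int(mrow["pos_bp"])
            chrom = mrow["chrom"]
        else:
            others = [c for c in slices if c != mrow["chrom"]]
            if others:
                chrom = others[int(rng.integers(len(others)))]
                mid = int(rng.integers(0, chrom_len[chrom] + 1))
            else:
                chrom = mrow["chrom"]
                sub = mdf.iloc[slices[chrom]]
                far = sub[np.abs(sub["pos_cM"] - mrow["pos_cM"]) >= min_trans_cM]
                if far.empty:
                    raise InvalidArgumentError(
                        f"cannot place trans gene {t.target_gene!r}: chromosome "
                        f"{chrom} shorter than {min_trans_cM} cM around the eQTL"
                    )
                mid = int(far.iloc[int(rng.integers(len(far)))]["pos_bp"])
        rows.append((t.target_gene, chrom, max(1, mid - cis_offset_bp), mid + cis_offset_bp))
    for g in background_genes:
        chrom = marker_map.chromosomes[int(rng.integers(len(marker_map.chromosomes)))]
        mid = int(rng.integers(0, chrom_len[chrom] + 1))
        rows.append((g, chrom, max(1, mid - cis_offset_bp), mid + cis_offset_bp))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])


@dataclass
class StudyData:
    """Bundle of everything one simulated study produces."""

    marker_map: MarkerMap
    assignments: pd.DataFrame
    probs: FounderProbabilities
    samples: pd.DataFrame
    counts: pd.DataFrame
    truth: list[PlantedEqtl]
    gene_annotation: pd.DataFrame


def simulate_study(
    truth: Sequence[PlantedEqtl] | None = None,
    *,
    n_strains: int = 96,
    n_chromosomes: int = 2,
    chrom_length_bp: int = 10_000_000,
    marker_spacing_bp: int = 50_000,
    cM_per_Mb: float = 2.0,
    n_founders: int = 8,
    expected_crossovers_per_chrom: float = 2.0,
    prob_smoothing: float = 0.02,
    n_pools_per_tissue: int = 2,
    n_background_genes: int = 500,
    baseline_log2_mean: float = 5.0,
    gene_baseline_sd: float = 1.0,
    nb_dispersion: float = 0.05,
    batch_sd: float = 0.25,
    library_size_range: tuple[float, float] = (0.75, 1.25),
    seed: int = 0,
) -> StudyData:
    """One-call desk-scale study: 96 strains x 2 tissues x 2 treatments.

    Defaults give two 20 cM chromosomes with 201 markers each (50 kb
    spacing at 2 cM/Mb), ~500 genes, and library-level technical structure
    (two pooling batches per tissue, modest batch shifts).  Sub-seeds for
    genomes, expression and gene placement are derived deterministically
    from ``seed``.
    """
    truth = list(truth) if truth is not None else []
    ss = np.random.SeedSequence(seed)
    s_genome, s_expr, s_genes = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    marker_map = simulate_marker_map(n_chromosomes, chrom_length_bp, marker_spacing_bp, cM_per_Mb)
    assignments, probs = simulate_ril_genomes(
        marker_map,
        n_strains,
        n_founders=n_founders,
        expected_crossovers_per_chrom=expected_crossovers_per_chrom,
        prob_smoothing=prob_smoothing,
        seed=s_genome,
    )
    samples = simulate_sample_table(probs.strains, n_pools_per_tissue=n_pools_per_tissue)
    counts = simulate_expression(
        truth,
        probs,
        samples,
        n_background_genes=n_background_genes,
        baseline_log2_mean=baseline_log2_mean,
        gene_baseline_sd=gene_baseline_sd,
        nb_dispersion=nb_dispersion,
        batch_sd=batch_sd,
        library_size_range=library_size_range,
        seed=s_expr,
    )
    background = [g for g in counts.index if g.startswith("bg")]
    annotation = place_genes(truth, marker_map, background, seed=s_genes)
    return StudyData(marker_map, assignments, probs, samples, counts, list(truth), annotation)
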