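"""Simulation studies that measure the pipeline's operating characteristics.

Each function runs a self-contained synthetic experiment — null calibration
of the permutation thresholds, recovery of planted cis/trans eQTL,
genotype-by-treatment behavior of the Response datasets, and calibration
and power of the differential-expression stage — and returns the measured
rates.  Problem sizes default to desk scale (96 strains, one or two
20 cM chromosomes, a few hundred traits, 200 permutations) so a full
battery runs in minutes on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import PlantedEqtl
from .de_analysis import run_de
from .eqtl_prep import prepare_response_dataset, prepare_treatment_dataset
from .eqtl_scan import permutation_thresholds, scan_all, scan_with_thresholds
from .peak_calling import call_study_peaks
from .synthetic_data import (
    scaled_founder_effects,
    simulate_marker_map,
    simulate_ril_genomes,
    simulate_study,
)

#: Across-founder effect SD (log2 units) whose locus explains roughly 40%
#: of trait variance at the generator's default noise level — the planted
#: effect-size regime for the recovery studies.
DEFAULT_GENETIC_SD = 0.42


def null_scan_type_i_error(
    n_genes: int = 500,
    n_strains: int = 96,
    n_markers: int = 201,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Genome-wide per-gene false-positive rate at the permutation threshold.

    Traits are drawn independent of genotype, so each gene's probability of
    its observed maximum LOD exceeding its own (1 - alpha) permutation
    threshold should be alpha.
    """
    ss = np.random.SeedSequence(seed)
    s_map, s_trait, s_perm = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    marker_map = simulate_marker_map(1, (n_markers - 1) * 50_000, 50_000, 2.0)
    _, probs = simulate_ril_genomes(marker_map, n_strains, seed=s_map)
    rng = np.random.default_rng(s_trait)
    traits = pd.DataFrame(
        rng.standard_normal((n_genes, n_strains)),
        index=[f"null{i:04d}" for i in range(n_genes)],
        columns=probs.strains,
    )
    study = scan_all(traits, probs, marker_map)
    thresholds = permutation_thresholds(traits, probs, n_perm=n_perm, alpha=alpha, seed=s_perm)
    exceed = study.lod.max(axis=1) > thresholds
    return {
        "type_i_error": float(exceed.mean()),
        "n_genes": n_genes,
        "n_perm": n_perm,
        "alpha": alpha,
        "mean_threshold": float(thresholds.mean()),
    }


def _prepare_and_scan(study_data, label, n_perm, seed):
    """Prep one dataset from simulated counts and scan it with thresholds."""
    from .cli_io import _dataset_matrix, _tissue_covariates
    from .de_analysis import filter_low_expression

    tissue = label.split("-")[0].lower()
    kind = label.split("-")[1].lower()
    filtered = filter_low_expression(
        study_data.counts, min_count=10, min_samples=min(47, study_data.counts.shape[1])
    )
    cov = _tissue_covariates(study_data.samples, tissue)
    if kind == "response":
        traits = prepare_response_dataset(
            _dataset_matrix(filtered, study_data.samples, tissue, "copper"),
            _dataset_matrix(filtered, study_data.samples, tissue, "control"),
            label,
            covariates=cov,
        )
    else:
        traits = prepare_treatment_dataset(
            _dataset_matrix(filtered, study_data.samples, tissue, kind),
            label,
            covariates=cov,
        )
    study = scan_with_thresholds(
        traits, study_data.probs, marker_map=study_data.marker_map,
        n_perm=n_perm, seed=seed,
    )
    return traits, study


def planted_cis_trans_recovery(
    n_cis: int = 25,
    n_trans: int = 10,
    n_background: int = 965,
    genetic_sd: float = DEFAULT_GENETIC_SD,
    n_perm: int = 200,
    localization_cM: float = 3.0,
    seed: int = 0,
) -> dict:
    """Detection, localization and classification of planted eQTL.

    Plants cis and trans eQTL of the default effect size (about 40% of
    trait variance), runs the full preparation + scan + peak stage on the
    Gut-Copper dataset, and scores: fraction of planted genes with at least
    one surviving peak, fraction of detections whose strongest peak lies
    within ``localization_cM`` of the causal marker, and the cis/trans
    classification rates against the planted architecture.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_study, s_perm = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    rng = np.random.default_rng(s_truth)
    marker_ids_probe = simulate_marker_map(2, 10_000_000, 50_000, 2.0).marker_ids
    truth = []
    for i in range(n_cis + n_trans):
        cls = "cis" if i < n_cis else "trans"
        marker = marker_ids_probe[int(rng.integers(len(marker_ids_probe)))]
        truth.append(
            PlantedEqtl(
                target_gene=f"{cls}{i:03d}",
                eqtl_marker=marker,
                founder_effects=scaled_founder_effects(rng, 8, genetic_sd),
                acts_in_tissue="both",
                acts_in_treatment="both",
                expected_class=cls,
            )
        )
    data = simulate_study(truth, n_background_genes=n_background, seed=s_study)
    traits, study = _prepare_and_scan(data, "Gut-Copper", n_perm, s_perm)
    peaks = call_study_peaks(study, traits, data.probs, data.gene_annotation)
    by_gene: dict[str, list] = {}
    for p in peaks:
        by_gene.setdefault(p.gene, []).append(p)

    mdf = data.marker_map.df.set_index("marker_id")
    detected = localized = cis_as_cis = trans_as_trans = n_det_cis = n_det_trans = 0
    pct_cis = []
    for t in truth:
        gene_peaks = by_gene.get(t.target_gene, [])
        if not gene_peaks:
            continue
        detected += 1
        best = max(gene_peaks, key=lambda p: p.lod)
        causal = mdf.loc[t.eqtl_marker]
        if best.chrom == causal["chrom"] and abs(best.pos_cM - causal["pos_cM"]) <= localization_cM:
            localized += 1
        if t.expected_class == "cis":
            n_det_cis += 1
            if best.classification == "cis":
                cis_as_cis += 1
            pct_cis.append(best.percent_variance)
        else:
            n_det_trans += 1
            if best.classification == "trans":
                trans_as_trans += 1
    n_planted = len(truth)
    return {
        "detection_rate": detected / n_planted,
        "localization_rate": localized / detected if detected else 0.0,
        "cis_classified_cis": cis_as_cis / n_det_cis if n_det_cis else 0.0,
        "trans_classified_trans": trans_as_trans / n_det_trans if n_det_trans else 0.0,
        "mean_percent_variance_cis": float(np.mean(pct_cis)) if pct_cis else float("nan"),
        "n_planted": n_planted,
        "n_cis": n_cis,
        "n_trans": n_trans,
    }


def response_gxe_study(
    n_differential: int = 15,
    n_constant: int = 50,
    n_background: int = 935,
    genetic_sd: float = DEFAULT_GENETIC_SD,
    differential_genetic_sd: float = 0.6,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Genotype-by-treatment behavior of the Response dataset.

    Plants eQTL with treatment-differential effects (present under copper,
    absent under control) and eQTL with identical effects in both treatments,
    then scans the Gut-Control, Gut-Copper and Gut-Response datasets.
    Differential eQTL should surface in Response; constant eQTL should be
    detected in Control and Copper but appear in Response scans no more
    often than the nominal genome-wide false-positive rate, because the
    copper-minus-control trait cancels treatment-constant genetic effects.

    ``differential_genetic_sd`` sizes the GxE effects on the response scale:
    the response trait accumulates count noise from both treatments, so an
    effect explaining ~40% of the response-trait variance needs to be about
    sqrt(2) times the single-treatment effect SD.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_study, s_perm = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    rng = np.random.default_rng(s_truth)
    marker_ids_probe = simulate_marker_map(2, 10_000_000, 50_000, 2.0).marker_ids
    truth = []
    for i in range(n_differential + n_constant):
        kind = "differential" if i < n_differential else "both"
        tag = "gxe" if kind == "differential" else "const"
        truth.append(
            PlantedEqtl(
                target_gene=f"{tag}{i:03d}",
                eqtl_marker=marker_ids_probe[int(rng.integers(len(marker_ids_probe)))],
                founder_effects=scaled_founder_effects(
                    rng, 8, differential_genetic_sd if kind == "differential" else genetic_sd
                ),
                acts_in_tissue="both",
                acts_in_treatment=kind,
                expected_class="cis",
            )
        )
    data = simulate_study(truth, n_background_genes=n_background, seed=s_study)
    hits: dict[str, np.ndarray] = {}
    genes = None
    for j, label in enumerate(("Gut-Control", "Gut-Copper", "Gut-Response")):
        traits, study = _prepare_and_scan(data, label, n_perm, (s_perm + j) % 2**31)
        hits[label] = study.lod.max(axis=1) > study.thresholds
        genes = study.genes
    gidx = {g: i for i, g in enumerate(genes)}
    diff_genes = [t.target_gene for t in truth if t.acts_in_treatment == "differential"]
    const_genes = [t.target_gene for t in truth if t.acts_in_treatment == "both"]

    def rate(label: str, gene_list: list[str]) -> float:
        present = [g for g in gene_list if g in gidx]
        if not present:
            return 0.0
        return float(np.mean([hits[label][gidx[g]] for g in present]))

    return {
        "differential_detected_in_response": rate("Gut-Response", diff_genes),
        "constant_detected_in_control": rate("Gut-Control", const_genes),
        "constant_detected_in_copper": rate("Gut-Copper", const_genes),
        "constant_response_fp_rate": rate("Gut-Response", const_genes),
        "n_differential": len(diff_genes),
        "n_constant": len(const_genes),
    }


def de_null_calibration(
    n_genes: int = 1000,
    n_strains: int = 96,
    nb_dispersion: float = 0.05,
    fdr: float = 0.05,
    seed: int = 0,
) -> dict:
    """Global-null DE simulation: fraction of BH-significant genes per term.

    Counts are pure negative-binomial noise with no tissue, treatment,
    resistance or pool structure; under the null the BH-significant
    fraction should stay at or below the FDR level for every model term.
    """
    data = simulate_study(
        None,
        n_strains=n_strains,
        n_background_genes=n_genes,
        nb_dispersion=nb_dispersion,
        batch_sd=0.0,
        seed=seed,
    )
    de = run_de(data.counts, data.samples, fdr=fdr)
    fractions = {term: float(tab["significant"].mean()) for term, tab in de.items()}
    return {
        "max_significant_fraction": max(fractions.values()),
        "fractions": fractions,
        "n_genes_tested": int(len(next(iter(de.values())))),
    }


def de_power_study(
    n_genes: int = 1000,
    frac_de: float = 0.1,
    log2_fc: float = 2.0,
    n_strains: int = 96,
    nb_dispersion: float = 0.05,
    fdr: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power to flag a planted tissue effect at the stated FDR.

    A ``log2_fc`` shift is applied to gut samples for ``frac_de`` of the
    genes on top of the null generator — direction-balanced (half up, half
    down) so the trimmed-mean normalization stays centered; power is the
    fraction of planted genes called significant for the tissue term.
    """
    data = simulate_study(
        None,
        n_strains=n_strains,
        n_background_genes=n_genes,
        nb_dispersion=nb_dispersion,
        batch_sd=0.0,
        seed=seed,
    )
    counts = data.counts.copy().astype(float)
    n_de = int(round(frac_de * len(counts)))
    planted = list(counts.index[:n_de])
    up, down = planted[0::2], planted[1::2]
    gut_cols = data.samples.loc[data.samples["tissue"] == "gut", "sample_id"]
    counts.loc[up, gut_cols] = np.round(counts.loc[up, gut_cols] * 2.0**log2_fc)
    counts.loc[down, gut_cols] = np.round(counts.loc[down, gut_cols] * 2.0**-log2_fc)
    counts = counts.astype(int)
    de = run_de(counts, data.samples, fdr=fdr)
    tissue = de["tissue[gut-head]"]
    tested_planted = [g for g in planted if g in tissue.index]
    power = float(tissue.loc[tested_planted, "significant"].mean())
    others = tissue.drop(index=tested_planted)
    return {
        "power": power,
        "n_planted_tested": len(tested_planted),
        "background_positive_fraction": float(others["significant"].mean()),
    }
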