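"""Cross-dataset eQTL sharing, founder-effect correlations, and
hypergeometric set enrichment.

Sharing is decided per gene: a peak in dataset A matches a peak for the
same gene in dataset B when both lie on the same chromosome and either the
peak positions are within ``window_cM`` of each other or the support
intervals overlap (a literal disjunction; both clause outcomes are recorded
per matched pair).  Multi-peak ambiguity is resolved greedily by smallest
position distance, each peak matching at most once, which makes the
matching symmetric in A and B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Peak
from .de_analysis import bh_adjust
from .errors import InvalidArgumentError, UndefinedCorrelationError


@dataclass
class MatchedPair:
    gene: str
    peak_a: Peak
    peak_b: Peak
    distance_cM: float
    within_window: bool
    intervals_overlap: bool


@dataclass
class SharingReport:
    """Per-gene eQTL sharing between two peak sets."""

    window_cM: float
    matched: list[MatchedPair] = field(default_factory=list)
    unique_a: list[Peak] = field(default_factory=list)
    unique_b: list[Peak] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.matched:
            rows.append(
                {
                    "gene": m.gene,
                    "status": "shared",
                    "chrom": m.peak_a.chrom,
                    "pos_a_cM": m.peak_a.pos_cM,
                    "pos_b_cM": m.peak_b.pos_cM,
                    "distance_cM": m.distance_cM,
                    "within_window": m.within_window,
                    "intervals_overlap": m.intervals_overlap,
                    "class_a": m.peak_a.classification,
                    "class_b": m.peak_b.classification,
                }
            )
        for label, peaks in (("unique_a", self.unique_a), ("unique_b", self.unique_b)):
            for p in peaks:
                rows.append(
                    {
                        "gene": p.gene,
                        "status": label,
                        "chrom": p.chrom,
                        "pos_a_cM": p.pos_cM if label == "unique_a" else np.nan,
                        "pos_b_cM": p.pos_cM if label == "unique_b" else np.nan,
                        "distance_cM": np.nan,
                        "within_window": pd.NA,
                        "intervals_overlap": pd.NA,
                        "class_a": p.classification if label == "unique_a" else None,
                        "class_b": p.classification if label == "unique_b" else None,
                    }
                )
        return pd.DataFrame(rows)


def _pair_clauses(a: Peak, b: Peak, window_cM: float) -> tuple[float, bool, bool]:
    dist = abs(a.pos_cM - b.pos_cM)
    within = dist <= window_cM
    overlap = a.lo_cM <= b.hi_cM and b.lo_cM <= a.hi_cM
    return dist, within, overlap


def match_shared_eqtl(
    peaks_a: list[Peak], peaks_b: list[Peak], window_cM: float = 1.5
) -> SharingReport:
    """Greedy per-gene matching of two peak lists.

    Candidate pairs are same-gene, same-chromosome peaks satisfying
    position-within-window OR interval-overlap; pairs are consumed in order
    of increasing position distance (ties broken on marker ids so the
    result does not depend on input order).
    """
    report = SharingReport(window_cM=window_cM)
    genes = sorted({p.gene for p in peaks_a} | {p.gene for p in peaks_b})
    by_gene_a = {g: [p for p in peaks_a if p.gene == g] for g in genes}
    by_gene_b = {g: [p for p in peaks_b if p.gene == g] for g in genes}
    for gene in genes:
        pa, pb = by_gene_a[gene], by_gene_b[gene]
        candidates = []
        for i, a in enumerate(pa):
            for j, b in enumerate(pb):
                if a.chrom != b.chrom:
                    continue
                dist, within, overlap = _pair_clauses(a, b, window_cM)
                if within or overlap:
                    candidates.append((dist, a.marker_id, b.marker_id, i, j, within, overlap))
        candidates.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for dist, _, _, i, j, within, overlap in candidates:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            report.matched.append(
                MatchedPair(gene, pa[i], pb[j], float(dist), within, overlap)
            )
        report.unique_a.extend(p for i, p in enumerate(pa) if i not in used_a)
        report.unique_b.extend(p for j, p in enumerate(pb) if j not in used_b)
    return report


def founder_effect_correlation(effects_a: np.ndarray, effects_b: np.ndarray) -> float:
    """Pearson correlation of two founder-effect vectors."""
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidArgumentError("effect vectors must be 1-d and equal length")
    if a.size < 3:
        raise InvalidArgumentError("need at least 3 founders to correlate effects")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("effect vector has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def matched_effect_correlations(report: SharingReport) -> pd.DataFrame:
    """Founder-effect correlations for every matched peak pair that carries
    effect estimates on both sides."""
    rows = []
    for m in report.matched:
        if m.peak_a.founder_effects is None or m.peak_b.founder_effects is None:
            continue
        try:
            r = founder_effect_correlation(m.peak_a.founder_effects, m.peak_b.founder_effects)
        except UndefinedCorrelationError:
            r = np.nan
        rows.append(
            {
                "gene": m.gene,
                "chrom": m.peak_a.chrom,
                "pos_a_cM": m.peak_a.pos_cM,
                "pos_b_cM": m.peak_b.pos_cM,
                "effect_correlation": r,
            }
        )
    return pd.DataFrame(rows)


def hypergeom_enrichment(
    study: set[str],
    population: set[str],
    gene_sets: dict[str, set[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    For each term with ``K`` population genes, the p-value is
    ``P(X >= k)`` for ``k`` study genes in the term, drawing ``n = |study|``
    from ``N = |population|``; BH adjustment is applied across terms.
    Gene sets are intersected with the population before testing.
    """
    population = set(population)
    if not population:
        raise InvalidArgumentError("population is empty")
    study = set(study)
    if not study <= population:
        extra = sorted(study - population)
        raise InvalidArgumentError(f"study genes outside population: {extra[:5]}")
    N, n = len(population), len(study)
    rows = []
    for term, genes in sorted(gene_sets.items()):
        members = set(genes) & population
        K = len(members)
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "N": N, "K": K, "n": n, "k": k, "p_value": min(p, 1.0)})
    result = pd.DataFrame(rows)
    if not result.empty:
        result["adjusted_p"] = bh_adjust(result["p_value"].to_numpy())
        result["significant"] = result["adjusted_p"] < fdr
    return result
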