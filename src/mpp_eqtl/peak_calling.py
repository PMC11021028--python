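"""eQTL peak identification, support intervals, filters, cis/trans
classification, and founder-effect estimation.

Peaks are above-threshold local maxima of the LOD curve (leftmost marker on
plateaus).  Support intervals use the LOD-drop rule: extend outward from
the peak to the first marker whose LOD falls more than ``lod_drop`` (default
3) below the peak, including that flanking marker, clipped at chromosome
ends.  Secondary peaks on a chromosome are accepted only when separated
from every already-accepted peak by a valley at least ``lod_drop`` below the
lower of the two peaks.

Two published filters are applied afterwards: peaks whose above-threshold
run is a single marker are dropped, as are peaks lying outside their own
support interval.  A peak is *cis* when its target gene lies inside the
support interval or within ``cis_window_cM`` (default 1.5 cM) of either
boundary on the same chromosome; everything else — including any
cross-chromosome peak — is *trans*.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    FounderProbabilities,
    MarkerMap,
    Peak,
    ScanStudy,
    TraitMatrix,
    validate_gene_annotation,
)
from .errors import AlignmentError, InvalidArgumentError, InvalidReferenceError

logger = logging.getLogger(__name__)


def _local_maxima(lod: np.ndarray, threshold: float) -> list[int]:
    """Indices of above-threshold local maxima (leftmost marker on ties)."""
    idx = []
    m = len(lod)
    for i in range(m):
        if lod[i] <= threshold:
            continue
        left_ok = i == 0 or lod[i] > lod[i - 1]
        right_ok = i == m - 1 or lod[i] >= lod[i + 1]
        if left_ok and right_ok:
            idx.append(i)
    return idx


def _drop_interval(lod: np.ndarray, peak: int, lod_drop: float) -> tuple[int, int]:
    """Interval [lo, hi] around ``peak``: first flanking markers whose LOD
    drops more than ``lod_drop`` below the peak are included; clipped at the
    chromosome ends."""
    cut = lod[peak] - lod_drop
    lo = peak
    while lo > 0:
        lo -= 1
        if lod[lo] < cut:
            break
    hi = peak
    while hi < len(lod) - 1:
        hi += 1
        if lod[hi] < cut:
            break
    return lo, hi


def _above_run_length(lod: np.ndarray, peak: int, threshold: float) -> int:
    """Length of the contiguous above-threshold run containing the peak."""
    lo = peak
    while lo > 0 and lod[lo - 1] > threshold:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] > threshold:
        hi += 1
    return hi - lo + 1


def call_peaks(
    lod: np.ndarray,
    threshold: float,
    marker_map: MarkerMap,
    lod_drop: float = 3.0,
    gene: str = "",
) -> list[Peak]:
    """Raw peak list (no classification, no effects) for one LOD curve.

    Candidates are processed per chromosome in decreasing LOD order; a
    candidate is accepted when every already-accepted peak on the
    chromosome is separated from it by a valley at least ``lod_drop`` below
    the lower of the two peak LODs.  Returns an empty list when nothing
    exceeds the threshold.
    """
    lod = np.asarray(lod, dtype=float)
    if len(lod) != marker_map.n_markers:
        raise AlignmentError(
            f"LOD vector length {len(lod)} does not match map ({marker_map.n_markers})"
        )
    if lod_drop <= 0:
        raise InvalidArgumentError("lod_drop must be positive")
    mdf = marker_map.df
    peaks: list[Peak] = []
    for chrom, sl in marker_map.chrom_slices().items():
        sub = lod[sl]
        candidates = _local_maxima(sub, threshold)
        candidates.sort(key=lambda i: (-sub[i], i))
        accepted: list[int] = []
        for c in candidates:
            ok = True
            for a in accepted:
                lo, hi = (a, c) if a < c else (c, a)
                valley = sub[lo : hi + 1].min()
                if valley > min(sub[a], sub[c]) - lod_drop:
                    ok = False
                    break
            if ok:
                accepted.append(c)
        for c in sorted(accepted):
            lo, hi = _drop_interval(sub, c, lod_drop)
            row = mdf.iloc[sl.start + c]
            lo_row = mdf.iloc[sl.start + lo]
            hi_row = mdf.iloc[sl.start + hi]
            peaks.append(
                Peak(
                    gene=gene,
                    chrom=chrom,
                    marker_id=row["marker_id"],
                    pos_bp=int(row["pos_bp"]),
                    pos_cM=float(row["pos_cM"]),
                    lod=float(sub[c]),
                    threshold=float(threshold),
                    lo_marker=lo_row["marker_id"],
                    lo_cM=float(lo_row["pos_cM"]),
                    hi_marker=hi_row["marker_id"],
                    hi_cM=float(hi_row["pos_cM"]),
                    above_run_length=_above_run_length(sub, c, threshold),
                )
            )
    return peaks


def filter_peaks(peaks: list[Peak], lod: np.ndarray, threshold: float) -> list[Peak]:
    """Apply the single-marker and out-of-interval peak filters.

    Removes peaks whose above-threshold run is exactly one marker and peaks
    whose position falls outside their own support interval; survivors are
    returned unchanged.
    """
    kept = []
    for p in peaks:
        if p.above_run_length <= 1:
            continue
        if not (p.lo_cM <= p.pos_cM <= p.hi_cM):
            continue
        kept.append(p)
    return kept


def gene_cM_position(gene_row: pd.Series, marker_map: MarkerMap) -> float:
    """Gene genetic position: bp midpoint linearly interpolated on the map."""
    mid = (float(gene_row["start_bp"]) + float(gene_row["end_bp"])) / 2.0
    return marker_map.interp_cM(gene_row["chrom"], mid)


def classify_peak(
    peak: Peak,
    gene_chrom: str,
    gene_cM: float,
    cis_window_cM: float = 1.5,
) -> str:
    """cis when the gene sits inside the support interval or within
    ``cis_window_cM`` of either boundary on the peak's chromosome."""
    if peak.chrom != gene_chrom:
        return "trans"
    if peak.lo_cM <= gene_cM <= peak.hi_cM:
        return "cis"
    dist = min(abs(gene_cM - peak.lo_cM), abs(gene_cM - peak.hi_cM))
    return "cis" if dist <= cis_window_cM else "trans"


def founder_effects(
    trait: np.ndarray, probs_at_peak: np.ndarray
) -> tuple[np.ndarray, float]:
    """OLS founder effects at one marker plus percent variance explained.

    Effects are the coefficients of the trait on the F probability columns
    (pseudo-inverse when rank deficient, with a logged note), reported
    centered to mean zero; ``percent_variance = 100 * (1 - RSS1 / RSS0)``.
    """
    y = np.asarray(trait, dtype=float)
    X = np.asarray(probs_at_peak, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise AlignmentError("trait and probability rows differ in length")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.info("rank-deficient founder design at peak (rank %d < %d); using pseudo-inverse",
                    rank, X.shape[1])
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    centered = y - y.mean()
    rss0 = float(centered @ centered)
    pct = 0.0 if rss0 <= 0 else 100.0 * (1.0 - rss1 / rss0)
    return beta - beta.mean(), float(np.clip(pct, 0.0, 100.0))


def call_study_peaks(
    study: ScanStudy,
    traits: TraitMatrix | pd.DataFrame,
    probs: FounderProbabilities,
    annotation: pd.DataFrame,
    lod_drop: float = 3.0,
    cis_window_cM: float = 1.5,
) -> list[Peak]:
    """Full peak stage for a scanned study: call, filter, classify, and
    estimate founder effects for every gene with thresholds set.

    Genes absent from the annotation raise
    :class:`InvalidReferenceError`.
    """
    if study.thresholds is None:
        raise InvalidArgumentError("study has no permutation thresholds")
    if study.marker_map is None:
        raise InvalidArgumentError("study carries no marker map")
    validate_gene_annotation(annotation)
    ann = annotation.set_index("gene_id")
    values = traits.values if isinstance(traits, TraitMatrix) else traits
    aligned = probs.reorder_strains(list(values.columns))
    out: list[Peak] = []
    for i, gene in enumerate(study.genes):
        raw = call_peaks(
            study.lod[i], float(study.thresholds[i]), study.marker_map, lod_drop, gene=gene
        )
        kept = filter_peaks(raw, study.lod[i], float(study.thresholds[i]))
        if not kept:
            continue
        if gene not in ann.index:
            raise InvalidReferenceError(f"gene {gene!r} missing from annotation")
        grow = ann.loc[gene]
        gchrom = grow["chrom"]
        gcm = gene_cM_position(grow, study.marker_map)
        y = values.loc[gene].to_numpy(dtype=float)
        for p in kept:
            p.classification = classify_peak(p, gchrom, gcm, cis_window_cM)
            m = study.marker_map.index_of(p.marker_id)
            eff, pct = founder_effects(y, aligned.P[:, m, :])
            p.founder_effects = eff
            p.percent_variance = pct
            out.append(p)
    return out


def peaks_to_frame(peaks: list[Peak], n_founders: int | None = None) -> pd.DataFrame:
    """Flatten peaks into the on-disk table layout."""
    if n_founders is None:
        n_founders = (
            len(peaks[0].founder_effects)
            if peaks and peaks[0].founder_effects is not None
            else 8
        )
    rows = []
    for p in peaks:
        row = {
            "gene": p.gene,
            "chrom": p.chrom,
            "peak_marker": p.marker_id,
            "peak_bp": p.pos_bp,
            "peak_cM": p.pos_cM,
            "lod": p.lod,
            "threshold": p.threshold,
            "ci_lo_marker": p.lo_marker,
            "ci_lo_cM": p.lo_cM,
            "ci_hi_marker": p.hi_marker,
            "ci_hi_cM": p.hi_cM,
            "class": p.classification,
            "percent_variance": p.percent_variance,
        }
        eff = p.founder_effects if p.founder_effects is not None else [np.nan] * n_founders
        for f in range(n_founders):
            row[f"founder_effect_{f + 1}"] = eff[f]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_peaks(frame: pd.DataFrame) -> list[Peak]:
    """Rebuild Peak objects from the on-disk table layout."""
    eff_cols = sorted(
        [c for c in frame.columns if c.startswith("founder_effect_")],
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    peaks = []
    for _, r in frame.iterrows():
        peaks.append(
            Peak(
                gene=r["gene"],
                chrom=r["chrom"],
                marker_id=r["peak_marker"],
                pos_bp=int(r["peak_bp"]),
                pos_cM=float(r["peak_cM"]),
                lod=float(r["lod"]),
                threshold=float(r["threshold"]),
                lo_marker=r["ci_lo_marker"],
                lo_cM=float(r["ci_lo_cM"]),
                hi_marker=r["ci_hi_marker"],
                hi_cM=float(r["ci_hi_cM"]),
                classification=r.get("class"),
                founder_effects=np.array([r[c] for c in eff_cols]) if eff_cols else None,
                percent_variance=float(r["percent_variance"])
                if "percent_variance" in r and pd.notna(r["percent_variance"])
                else None,
            )
        )
    return peaks
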