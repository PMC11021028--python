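"""Shared domain containers.

The pipeline is pandas-centric: count matrices, sample tables and gene
annotations are plain :class:`pandas.DataFrame` objects with documented
columns, validated by the helpers below.  Objects with stronger invariants
(marker map ordering, founder probabilities summing to one) get thin wrapper
classes so the invariant is checked once at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidReferenceError, ValidationError

TISSUES = ("head", "gut")
TREATMENTS = ("control", "copper")
RESISTANCE_CLASSES = ("resistant", "sensitive")
#: The six analysis datasets: tissue x {control, copper, response}.
DATASET_LABELS = (
    "Head-Control",
    "Head-Copper",
    "Head-Response",
    "Gut-Control",
    "Gut-Copper",
    "Gut-Response",
)

SAMPLE_COLUMNS = ("sample_id", "strain", "tissue", "treatment", "resistance_class", "pool")


class MarkerMap:
    """Ordered genome grid with physical (bp) and genetic (cM) coordinates.

    Wraps a DataFrame with columns ``marker_id, chrom, pos_bp, pos_cM``.
    Within a chromosome markers must be strictly increasing in bp and
    non-decreasing in cM; marker ids must be globally unique.  Rows are
    stored grouped by chromosome in input order.
    """

    COLUMNS = ("marker_id", "chrom", "pos_bp", "pos_cM")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"marker map missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if df["marker_id"].duplicated().any():
            dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValidationError(f"duplicate marker ids: {dups[:5]}")
        if (df["pos_bp"] < 0).any() or (df["pos_cM"] < 0).any():
            raise ValidationError("marker positions must be non-negative")
        # chromosomes must form contiguous blocks
        chrom_first = df["chrom"].drop_duplicates()
        if len(chrom_first) != df["chrom"].nunique():  # pragma: no cover - defensive
            raise ValidationError("chromosome rows are not contiguous")
        for chrom, sub in df.groupby("chrom", sort=False):
            bp = sub["pos_bp"].to_numpy()
            cm = sub["pos_cM"].to_numpy(dtype=float)
            if not np.all(np.diff(bp) > 0):
                raise ValidationError(f"bp positions not strictly increasing on {chrom}")
            if not np.all(np.diff(cm) >= 0):
                raise ValidationError(f"cM positions not non-decreasing on {chrom}")
        self._df = df
        self._index = {m: i for i, m in enumerate(df["marker_id"])}

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def marker_ids(self) -> list[str]:
        return self._df["marker_id"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self._df)

    @property
    def chromosomes(self) -> list[str]:
        return self._df["chrom"].drop_duplicates().tolist()

    def index_of(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise InvalidReferenceError(f"unknown marker {marker_id!r}") from None

    def chrom_slices(self) -> dict[str, slice]:
        """Map chromosome name to the slice of marker rows it occupies."""
        out: dict[str, slice] = {}
        chroms = self._df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def interp_cM(self, chrom: str, pos_bp: float) -> float:
        """Genetic position of a physical coordinate, linearly interpolated
        between flanking markers (clipped at chromosome ends)."""
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            raise InvalidReferenceError(f"unknown chromosome {chrom!r}")
        sub = self._df.iloc[sl]
        return float(np.interp(pos_bp, sub["pos_bp"].to_numpy(), sub["pos_cM"].to_numpy()))

    def __len__(self) -> int:
        return self.n_markers

    def __repr__(self) -> str:
        return f"MarkerMap({self.n_markers} markers, {len(self.chromosomes)} chromosomes)"


@dataclass
class FounderProbabilities:
    """Additive founder-ancestry probabilities, strains x markers x founders.

    ``P[s, m, f]`` is the probability that strain ``s`` carries founder ``f``
    at marker ``m``.  Every founder vector must lie in [0, 1] and sum to one
    within 1e-9.
    """

    strains: list[str]
    markers: list[str]
    P: np.ndarray

    SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 3:
            raise ValidationError("P must be a 3-d array (strain x marker x founder)")
        if self.P.shape[:2] != (len(self.strains), len(self.markers)):
            raise ValidationError(
                f"P shape {self.P.shape} does not match {len(self.strains)} strains "
                f"x {len(self.markers)} markers"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_founders(self) -> int:
        return self.P.shape[2]

    def validate(self) -> None:
        if np.any(self.P < 0) or np.any(self.P > 1):
            bad = np.argwhere((self.P < 0) | (self.P > 1))[0]
            raise ValidationError(
                f"probability outside [0,1] at strain {self.strains[bad[0]]!r}, "
                f"marker {self.markers[bad[1]]!r}, founder {bad[2]}"
            )
        sums = self.P.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > self.SUM_TOL):
            s, m = np.argwhere(np.abs(sums - 1.0) > self.SUM_TOL)[0]
            raise ValidationError(
                f"founder probabilities sum to {sums[s, m]!r} (not 1) for strain "
                f"{self.strains[s]!r} at marker {self.markers[m]!r}"
            )

    def reorder_strains(self, strains: Sequence[str]) -> "FounderProbabilities":
        """Return a copy restricted/reordered to the given strains."""
        index = {s: i for i, s in enumerate(self.strains)}
        missing = [s for s in strains if s not in index]
        if missing:
            raise AlignmentError(f"strains absent from probabilities: {missing[:5]}")
        rows = [index[s] for s in strains]
        return FounderProbabilities(list(strains), list(self.markers), self.P[rows])

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.markers.index(marker_id)
        except ValueError:
            raise InvalidReferenceError(f"unknown marker {marker_id!r}") from None


@dataclass
class PlantedEqtl:
    """Ground-truth specification of one simulated eQTL.

    ``founder_effects`` are expression shifts in log2 units, one per founder,
    applied through the strain's founder dosage at ``eqtl_marker``.
    ``acts_in_treatment`` semantics: ``both`` applies the effect in control
    and copper; ``control``/``copper`` apply it in one treatment only;
    ``differential`` is a genotype-by-treatment architecture whose effect
    appears under copper but not control, so the copper-minus-control
    response trait carries the full effect while control expression carries
    none.
    """

    target_gene: str
    eqtl_marker: str
    founder_effects: np.ndarray
    acts_in_tissue: str = "both"  # head | gut | both
    acts_in_treatment: str = "both"  # control | copper | both | differential
    expected_class: str = "cis"  # cis | trans

    def __post_init__(self) -> None:
        self.founder_effects = np.asarray(self.founder_effects, dtype=float)
        if self.acts_in_tissue not in ("head", "gut", "both"):
            raise ValidationError(f"bad acts_in_tissue {self.acts_in_tissue!r}")
        if self.acts_in_treatment not in ("control", "copper", "both", "differential"):
            raise ValidationError(f"bad acts_in_treatment {self.acts_in_treatment!r}")
        if self.expected_class not in ("cis", "trans"):
            raise ValidationError(f"bad expected_class {self.expected_class!r}")


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check a sample table's columns, category levels and uniqueness."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    bad_tissue = set(samples["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValidationError(f"unknown tissue values: {sorted(bad_tissue)}")
    bad_trt = set(samples["treatment"]) - set(TREATMENTS)
    if bad_trt:
        raise ValidationError(f"unknown treatment values: {sorted(bad_trt)}")
    bad_res = set(samples["resistance_class"]) - set(RESISTANCE_CLASSES)
    if bad_res:
        raise ValidationError(f"unknown resistance_class values: {sorted(bad_res)}")
    if samples["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids")
    key = samples[["strain", "tissue", "treatment"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValidationError("duplicate (strain, tissue, treatment) combinations")
    if samples["pool"].isna().any() or (samples["pool"].astype(str) == "").any():
        raise ValidationError("empty pool labels")
    return samples


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples count matrix (non-negative, no missing)."""
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValidationError("empty count matrix")
    if counts.isna().any().any():
        raise ValidationError("count matrix contains missing values")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("count matrix contains negative entries")
    return counts


@dataclass
class TraitMatrix:
    """Analysis-ready expression traits for one dataset.

    ``values`` is genes x strains with no missing entries; ``provenance``
    records the preparation steps in application order.
    """

    label: str
    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("trait matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def strains(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class ScanResult:
    """Per-gene Haley-Knott genome scan: LOD per marker plus the gene's
    permutation significance threshold (None before thresholds are set)."""

    gene: str
    lod: np.ndarray
    threshold: float | None
    n_strains: int


@dataclass
class ScanStudy:
    """Batched scan over many genes sharing one marker map and strain set."""

    genes: list[str]
    marker_map: MarkerMap
    lod: np.ndarray  # genes x markers
    n_strains: int
    thresholds: np.ndarray | None = None  # per gene

    def result(self, gene: str) -> ScanResult:
        i = self.genes.index(gene)
        thr = None if self.thresholds is None else float(self.thresholds[i])
        return ScanResult(gene, self.lod[i], thr, self.n_strains)

    def __iter__(self) -> Iterator[ScanResult]:
        for g in self.genes:
            yield self.result(g)


@dataclass
class Peak:
    """One called eQTL peak with its 3-LOD-drop support interval.

    ``founder_effects`` are mean-centered trait shifts per founder haplotype;
    ``percent_variance`` is the share of trait variance explained by the
    founder model at the peak marker, in percent.
    """

    gene: str
    chrom: str
    marker_id: str
    pos_bp: int
    pos_cM: float
    lod: float
    threshold: float
    lo_marker: str
    lo_cM: float
    hi_marker: str
    hi_cM: float
    above_run_length: int = 0
    classification: str | None = None  # cis | trans
    founder_effects: np.ndarray | None = None
    percent_variance: float | None = None


def validate_gene_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a gene annotation table (gene_id, chrom, start_bp, end_bp)."""
    required = ("gene_id", "chrom", "start_bp", "end_bp")
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValidationError(f"gene annotation missing columns: {missing}")
    if (ann["start_bp"] > ann["end_bp"]).any():
        bad = ann.loc[ann["start_bp"] > ann["end_bp"], "gene_id"].tolist()
        raise ValidationError(f"gene start > end for: {bad[:5]}")
    if ann["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene ids in annotation")
    return ann
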