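"""Core record types shared across the pipeline.

Coordinates are 0-based, half-open throughout; BED conventions apply only at
file boundaries.  A gene's TSS is ``start`` on the + strand and ``end - 1`` on
the - strand; the 3' end is the opposite anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import pandas as pd

#: promoter window size, bases 5' of the TSS
PROMOTER_BP = 2_000
#: distal window size for upstream / downstream assignment
DISTAL_BP = 100_000

CATEGORIES = ("ingene", "promoter", "upstream", "downstream", "intergenic")

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]
PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "summit", "score", "pvalue", "fdr"]


class ValidationError(ValueError):
    """Raised when a record or table violates its schema."""


@dataclass(frozen=True)
class GeneModel:
    """One gene's coordinates and strand; anchors the TSS and 3' end."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    hepatic_flag: Optional[bool] = None
    de_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(f"gene {self.gene_id}: start must be < end ({self.start} >= {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Peak:
    """One binding interval with summit, score, p-value and FDR."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int
    score: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"peak {self.peak_id}: summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.score < 0:
            raise ValidationError(f"peak {self.peak_id}: negative score {self.score}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"peak {self.peak_id}: p-value {self.pvalue} outside (0, 1]")
        if not (0 <= self.fdr <= 1):
            raise ValidationError(f"peak {self.peak_id}: FDR {self.fdr} outside [0, 1]")


@dataclass(frozen=True)
class PeakGeneAssignment:
    """A peak's location call relative to one gene (or intergenic)."""

    peak_id: str
    gene_id: Optional[str]
    category: str
    distance: Optional[int]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if (self.category == "intergenic") != (self.gene_id is None):
            raise ValidationError("gene_id must be None exactly for intergenic assignments")


GeneInput = Union[pd.DataFrame, Iterable[GeneModel]]
PeakInput = Union[pd.DataFrame, Iterable[Peak]]


def as_gene_frame(genes: GeneInput) -> pd.DataFrame:
    """Normalize gene input (DataFrame or GeneModel iterable) to a DataFrame."""
    if isinstance(genes, pd.DataFrame):
        missing = [c for c in GENE_COLUMNS if c not in genes.columns]
        if missing:
            raise ValidationError(f"gene table missing columns: {missing}")
        return genes
    rows = [(g.gene_id, g.chrom, g.strand, g.start, g.end) for g in genes]
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def as_peak_frame(peaks: PeakInput) -> pd.DataFrame:
    if isinstance(peaks, pd.DataFrame):
        missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
        if missing:
            raise ValidationError(f"peak table missing columns: {missing}")
        return peaks
    rows = [
        (p.peak_id, p.chrom, p.start, p.end, p.summit, p.score, p.pvalue, p.fdr)
        for p in peaks
    ]
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def frame_to_genes(frame: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.start), int(r.end))
        for r in frame.itertuples(index=False)
    ]


def frame_to_peaks(frame: pd.DataFrame) -> list[Peak]:
    return [
        Peak(r.peak_id, r.chrom, int(r.start), int(r.end), int(r.summit),
             float(r.score), float(r.pvalue), float(r.fdr))
        for r in frame.itertuples(index=False)
    ]
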