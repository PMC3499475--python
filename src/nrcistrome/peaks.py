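"""Peak filtering and gene-relative location annotation.

A peak's location is decided by its summit, strand-aware relative to the
nearest gene model:

* ``ingene``   — summit inside the gene body ``[start, end)``;
* ``promoter`` — within 2 kb 5' of the TSS;
* ``upstream`` — within (2 kb, 100 kb] 5' of the TSS;
* ``downstream`` — within 100 kb 3' of the gene end;
* ``intergenic`` — none of the above for any gene.

When a summit falls in windows of several genes the primary call follows the
precedence ingene > promoter > upstream > downstream, with the nearest TSS
breaking remaining ties (then gene id, for determinism).  Besides the primary
call, an exhaustive per-(peak, gene) table is produced for gene-level counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from intervaltree import IntervalTree

from .core import (
    CATEGORIES,
    DISTAL_BP,
    PROMOTER_BP,
    GeneInput,
    GeneModel,
    Peak,
    PeakInput,
    ValidationError,
    as_gene_frame,
    as_peak_frame,
)

_PRECEDENCE = {"ingene": 0, "promoter": 1, "upstream": 2, "downstream": 3}


def filter_peaks(peaks: PeakInput, fdr_max: float = 0.1, p_max: float = 1e-5):
    """Retain peaks with ``fdr <= fdr_max`` and ``pvalue < p_max``, order kept.

    The FDR cut eliminates peaks *greater than* the threshold; the Poisson
    p-value cut retains peaks strictly *lower than* the threshold.
    """
    if not (0 < fdr_max <= 1) or not (0 < p_max <= 1):
        raise ValidationError("filter thresholds must lie in (0, 1]")
    if isinstance(peaks, pd.DataFrame):
        frame = as_peak_frame(peaks)
        keep = (frame["fdr"] <= fdr_max) & (frame["pvalue"] < p_max)
        return frame.loc[keep].reset_index(drop=True)
    return [p for p in peaks if p.fdr <= fdr_max and p.pvalue < p_max]


def _classify_summit(summit: int, strand: str, start: int, end: int):
    """Return (category, signed distance) for one summit vs one gene, or None.

    Signed distances are in the transcription direction: negative 5' of the
    TSS (promoter/upstream), >= 0 inside the gene (to the TSS), positive past
    the 3' end (downstream, to the 3' end).
    """
    if start <= summit < end:
        tss = start if strand == "+" else end - 1
        return "ingene", (summit - tss if strand == "+" else tss - summit)
    if strand == "+":
        d5 = start - summit  # distance 5' of TSS
        if 0 < d5 <= PROMOTER_BP:
            return "promoter", -d5
        if PROMOTER_BP < d5 <= DISTAL_BP:
            return "upstream", -d5
        d3 = summit - (end - 1)  # distance past 3' end
        if 0 < d3 <= DISTAL_BP:
            return "downstream", d3
    else:
        d5 = summit - (end - 1)
        if 0 < d5 <= PROMOTER_BP:
            return "promoter", -d5
        if PROMOTER_BP < d5 <= DISTAL_BP:
            return "upstream", -d5
        d3 = start - summit
        if 0 < d3 <= DISTAL_BP:
            return "downstream", d3
    return None


def assign_location(peak: Peak, gene: GeneModel) -> Optional[str]:
    """Classify one peak summit relative to one gene; None if out of range
    or on a different chromosome (intergenic at the annotation level)."""
    if peak.chrom != gene.chrom:
        return None
    hit = _classify_summit(peak.summit, gene.strand, gene.start, gene.end)
    return None if hit is None else hit[0]


@dataclass
class AnnotationResult:
    """Primary per-peak calls plus the exhaustive per-(peak, gene) table."""

    primary: pd.DataFrame  # peak_id, gene_id (None for intergenic), category, distance
    pairs: pd.DataFrame    # peak_id, gene_id, category, distance (non-intergenic only)


def annotate_peaks(peaks: PeakInput, genes: GeneInput) -> AnnotationResult:
    """Assign every peak its primary location category and emit all
    per-(peak, gene) window hits.

    Candidate genes are found through per-chromosome interval trees over gene
    envelopes extended by the distal window, then classified exactly.
    """
    peak_frame = as_peak_frame(peaks)
    gene_frame = as_gene_frame(genes)

    trees: dict[str, IntervalTree] = {}
    for g in gene_frame.itertuples(index=False):
        lo = int(g.start) - DISTAL_BP
        hi = int(g.end) + DISTAL_BP
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, (g.gene_id, g.strand, int(g.start), int(g.end)))

    primary_rows = []
    pair_rows = []
    for p in peak_frame.itertuples(index=False):
        summit = int(p.summit)
        best = None  # (precedence, |dist to tss|, gene_id, category, distance)
        tree = trees.get(p.chrom)
        if tree is not None:
            for iv in tree.at(summit):
                gene_id, strand, start, end = iv.data
                hit = _classify_summit(summit, strand, start, end)
                if hit is None:
                    continue
                category, dist = hit
                pair_rows.append((p.peak_id, gene_id, category, dist))
                tss = start if strand == "+" else end - 1
                key = (_PRECEDENCE[category], abs(summit - tss), gene_id)
                if best is None or key < best[0]:
                    best = (key, gene_id, category, dist)
        if best is None:
            primary_rows.append((p.peak_id, None, "intergenic", None))
        else:
            primary_rows.append((p.peak_id, best[1], best[2], best[3]))

    primary = pd.DataFrame(primary_rows, columns=["peak_id", "gene_id", "category", "distance"])
    pairs = pd.DataFrame(pair_rows, columns=["peak_id", "gene_id", "category", "distance"])
    return AnnotationResult(primary=primary, pairs=pairs)


def location_distribution(
    assignments: AnnotationResult | pd.DataFrame,
    gene_subset: Optional[Iterable[str]] = None,
) -> dict[str, float]:
    """Per-category fraction of peaks by primary call.

    With ``gene_subset`` the view is restricted to peaks whose primary gene
    lies in the subset and the intergenic category drops out (it has no gene);
    without it all five categories are reported.  Fractions sum to 1.
    """
    primary = assignments.primary if isinstance(assignments, AnnotationResult) else assignments
    if len(primary) == 0:
        raise ValidationError("no assignments to summarize")
    if gene_subset is None:
        view = primary
        cats = CATEGORIES
    else:
        subset = set(gene_subset)
        view = primary[primary["gene_id"].isin(subset)]
        cats = tuple(c for c in CATEGORIES if c != "intergenic")
        if len(view) == 0:
            raise ValidationError("no peaks assigned to the requested gene subset")
    counts = view["category"].value_counts()
    total = int(counts.sum())
    return {c: float(counts.get(c, 0) / total) for c in cats}


def chromosome_distribution(
    peaks: PeakInput,
    assignments: Optional[AnnotationResult | pd.DataFrame] = None,
    gene_subset: Optional[Iterable[str]] = None,
) -> dict[str, int]:
    """Exact peak counts per chromosome, optionally restricted to peaks whose
    primary gene lies in ``gene_subset`` (requires ``assignments``)."""
    frame = as_peak_frame(peaks)
    if gene_subset is not None:
        if assignments is None:
            raise ValidationError("gene_subset restriction requires assignments")
        primary = assignments.primary if isinstance(assignments, AnnotationResult) else assignments
        subset = set(gene_subset)
        keep_ids = set(primary.loc[primary["gene_id"].isin(subset), "peak_id"])
        frame = frame[frame["peak_id"].isin(keep_ids)]
    counts = frame["chrom"].value_counts()
    return {chrom: int(counts.get(chrom, 0)) for chrom in sorted(as_peak_frame(peaks)["chrom"].unique())}


def peaks_per_gene(assignments: AnnotationResult | pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-gene peak counts from the exhaustive table and their mean.

    The mean is total gene-level assignments (deduplicated per (peak, gene)
    pair) divided by the number of genes with at least one peak; report it
    rounded to one decimal.
    """
    pairs = assignments.pairs if isinstance(assignments, AnnotationResult) else assignments
    dedup = pairs.drop_duplicates(subset=["peak_id", "gene_id"])
    if len(dedup) == 0:
        raise ValidationError("no gene-level peak assignments: zero bound genes")
    counts = dedup.groupby("gene_id").size().sort_index()
    mean = float(len(dedup) / counts.size)
    return counts, mean


def mean_peaks_per_gene(counts: Mapping[str, int]) -> float:
    """Mean of a prepared per-gene peak-count mapping (genes with >= 1 peak)."""
    if len(counts) == 0:
        raise ValidationError("zero bound genes")
    return float(sum(counts.values()) / len(counts))


def bin_peak_score(score) -> str:
    """Bin a binding strength: strong (>= 200), medium ([100, 200)), weak (< 100)."""
    value = score.score if isinstance(score, Peak) else float(score)
    if value < 0:
        raise ValidationError(f"negative peak score {value}")
    if value >= 200:
        return "strong"
    if value >= 100:
        return "medium"
    return "weak"


def top_peak_windows(
    peaks: PeakInput,
    k: int = 500,
    flank: int = 100,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Summit-centred windows of the k strongest peaks for sequence extraction.

    Each interval is ``[summit - flank, summit + flank + 1)``, clipped to
    chromosome bounds when sizes are given.  Ties at rank k are broken by
    (chrom, start) order so repeated runs agree.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    frame = as_peak_frame(peaks)
    if len(frame) < k:
        warnings.warn(f"only {len(frame)} peaks available for top-{k} selection; using all")
    ranked = frame.sort_values(
        by=["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).head(k)
    rows = []
    for p in ranked.itertuples(index=False):
        lo = max(0, int(p.summit) - flank)
        hi = int(p.summit) + flank + 1
        if chrom_sizes is not None and p.chrom in chrom_sizes:
            hi = min(hi, int(chrom_sizes[p.chrom]))
        rows.append((p.peak_id, p.chrom, lo, hi, int(p.summit), float(p.score)))
    return pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "summit", "score"])
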