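"""Readers and writers for the pipeline's plain-text artifacts.

Formats: gene tables and expression matrices as TSV, peaks as BED6+ (columns
7-9 hold the summit offset from the interval start, the Poisson p-value and
the FDR), sequences as FASTA, term maps as two-column TSV, ground truth as
JSON.  Floats are written at full precision so a write/read round trip
reproduces identical in-memory values.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GENE_COLUMNS, PEAK_COLUMNS, ValidationError
from .expression import ExpressionMatrix
from .simulate import Truth

PathLike = Union[str, Path]

_FLOAT_FMT = "%.17g"


def write_genes(genes: pd.DataFrame, path: PathLike) -> None:
    genes.to_csv(path, sep="\t", index=False, columns=GENE_COLUMNS)


def read_genes(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in GENE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: gene table missing columns {missing}")
    bad = frame.index[frame["start"] >= frame["end"]]
    if len(bad):
        raise ValidationError(f"{path}: start >= end at line {int(bad[0]) + 2}")
    return frame


def write_peaks(peaks: pd.DataFrame, path: PathLike) -> None:
    """BED6+3: chrom, start, end, name, score, strand('.'), summit offset,
    p-value, FDR."""
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"],
            "end": peaks["end"],
            "name": peaks["peak_id"],
            "score": peaks["score"],
            "strand": ".",
            "summit_offset": peaks["summit"] - peaks["start"],
            "pvalue": peaks["pvalue"],
            "fdr": peaks["fdr"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False, float_format=_FLOAT_FMT)


def read_peaks(path: PathLike) -> pd.DataFrame:
    """Parse BED6+3 peaks; malformed records are reported with line numbers."""
    names = ["chrom", "start", "end", "name", "score", "strand", "summit_offset", "pvalue", "fdr"]
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=names,
                          dtype={"chrom": str, "name": str})
    except Exception as exc:  # noqa: BLE001 - surface parser failures with context
        raise ValidationError(f"{path}: cannot parse BED: {exc}") from exc
    if raw.isna().any().any():
        line = int(raw.index[raw.isna().any(axis=1)][0]) + 1
        raise ValidationError(f"{path}: missing field at line {line}")
    bad = raw.index[(raw["start"] < 0) | (raw["start"] > raw["end"])]
    if len(bad):
        raise ValidationError(f"{path}: invalid interval at line {int(bad[0]) + 1}")
    frame = pd.DataFrame(
        {
            "peak_id": raw["name"],
            "chrom": raw["chrom"],
            "start": raw["start"].astype(int),
            "end": raw["end"].astype(int),
            "summit": (raw["start"] + raw["summit_offset"]).astype(int),
            "score": raw["score"].astype(float),
            "pvalue": raw["pvalue"].astype(float),
            "fdr": raw["fdr"].astype(float),
        }
    )
    bad = frame.index[(frame["summit"] < frame["start"]) | (frame["summit"] >= frame["end"])]
    if len(bad):
        raise ValidationError(f"{path}: summit outside interval at line {int(bad[0]) + 1}")
    return frame[PEAK_COLUMNS]


def write_fasta(records: Iterable[SeqRecord], path: PathLike) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def sequences_from_strings(pairs: Mapping[str, str]) -> list[SeqRecord]:
    return [SeqRecord(Seq(s), id=name, description="") for name, s in pairs.items()]


def write_expression(matrix: ExpressionMatrix, path: PathLike) -> None:
    """Genes x samples TSV; sample headers carry the group label as the
    prefix before the final underscore (WT_1, ..., KO_1, ...)."""
    out = matrix.values.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_expression(path: PathLike) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in frame.columns:
        raise ValidationError(f"{path}: expression table must start with a gene_id column")
    frame = frame.set_index("gene_id")
    frame.index.name = None
    groups = {}
    for col in frame.columns:
        prefix = col.rsplit("_", 1)[0]
        if prefix not in ("WT", "KO"):
            raise ValidationError(
                f"{path}: sample column {col!r} lacks a WT/KO group prefix header"
            )
        groups[col] = prefix
    return ExpressionMatrix(values=frame, groups=pd.Series(groups))


def write_term_map(term_map: Mapping[str, Iterable[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{term}\t{gene}\n")


def read_term_map(path: PathLike) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}: expected 2 columns at line {lineno}")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_truth(truth: Truth, path: PathLike) -> None:
    payload = dataclasses.asdict(truth)
    payload["bound_genes"] = sorted(truth.bound_genes)
    payload["enriched_terms"] = sorted(truth.enriched_terms)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: PathLike) -> Truth:
    with open(path) as fh:
        payload = json.load(fh)
    return Truth(
        de_label_by_gene=dict(payload["de_label_by_gene"]),
        bound_genes=set(payload["bound_genes"]),
        planted_motif_by_peak=dict(payload["planted_motif_by_peak"]),
        enriched_terms=set(payload["enriched_terms"]),
        planted_location_by_peak=dict(payload.get("planted_location_by_peak", {})),
        anchor_gene_by_peak=dict(payload.get("anchor_gene_by_peak", {})),
        passes_filter_by_peak=dict(payload.get("passes_filter_by_peak", {})),
    )
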