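"""End-to-end orchestration: simulate (or load) -> filter -> annotate ->
scan/classify -> differential expression -> integrate -> enrich.

One run configuration (YAML-serializable) carries every module threshold and
a single seed; the seed fans out to per-stage substreams inside the
generators, so identical config + seed gives a byte-identical report.  Any
stage failure aborts the run with the failing stage named; artifacts written
before the failure are retained and listed in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .enrich import annotate_term_table
from .enrich import enrich as run_enrichment
from . import expression as expr_mod
from . import integrate as integrate_mod
from . import io as io_mod
from . import motifs as motifs_mod
from . import peaks as peaks_mod
from .core import ValidationError
from .simulate import SimulationConfig, simulate_all


class PipelineError(RuntimeError):
    """A stage failure; carries the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    seed: int = 0
    outdir: str = "nrc_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # input paths; when None the simulation stage generates them
    peaks_path: Optional[str] = None
    genes_path: Optional[str] = None
    expression_path: Optional[str] = None
    fasta_path: Optional[str] = None
    term_map_path: Optional[str] = None
    # module thresholds
    fdr_max: float = 0.1
    p_max: float = 1e-5
    detect_tau: float = 50.0
    alpha: float = 0.05
    max_spacer: int = 8
    half_site_consensus: str = "RGGTCA"
    top_k: int = 500
    flank: int = 100
    enrich_alpha: float = 0.05
    enrich_bonferroni_max: float = 0.1
    n_terms: int = 50
    planted_terms: int = 3

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        for name, value, lo, hi in (
            ("fdr_max", self.fdr_max, 0, 1),
            ("p_max", self.p_max, 0, 1),
            ("alpha", self.alpha, 0, 1),
            ("enrich_alpha", self.enrich_alpha, 0, 1),
            ("enrich_bonferroni_max", self.enrich_bonferroni_max, 0, 1),
        ):
            if not (lo < value <= hi):
                raise ValidationError(f"{name} must lie in ({lo}, {hi}], got {value}")
        if self.max_spacer < 0 or self.top_k < 1 or self.flank < 0:
            raise ValidationError("max_spacer/top_k/flank out of range")
        # the simulation inherits the run seed so one integer controls all
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulation"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self.simulation).items()
        }
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        sim = payload.get("simulation", {})
        for key in ("gene_length_range", "baseline_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        for key in ("location_mixture", "motif_mixture"):
            if key in sim and sim[key] is not None:
                sim[key] = dict(sim[key])
        payload["simulation"] = sim
        return cls(**payload)


def validate_inputs(paths: dict) -> list[dict]:
    """Schema-check input files; returns a list of diagnostics, each a dict
    with severity, file, and message (line-numbered where possible)."""
    readers = {
        "peaks": io_mod.read_peaks,
        "genes": io_mod.read_genes,
        "expression": io_mod.read_expression,
        "fasta": io_mod.read_fasta,
        "term_map": io_mod.read_term_map,
    }
    report = []
    for kind, path in paths.items():
        if path is None:
            continue
        reader = readers.get(kind)
        if reader is None:
            report.append({"severity": "warning", "file": str(path), "message": f"unknown input kind {kind!r}"})
            continue
        try:
            reader(path)
        except FileNotFoundError:
            report.append({"severity": "error", "file": str(path), "message": "file not found"})
        except ValidationError as exc:
            report.append({"severity": "error", "file": str(path), "message": str(exc)})
        except Exception as exc:  # noqa: BLE001
            report.append({"severity": "error", "file": str(path), "message": f"unreadable: {exc}"})
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write a report bundle to the output
    directory; returns the top-level report dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer, *args) -> Path:
        path = outdir / name
        writer(*args, path)
        written.append(path)
        return path

    def _finish_manifest() -> None:
        manifest = {p.name: _sha256(p) for p in written}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    # --- inputs: simulate or load (load failures are charged to the stage
    # that owns the input) ----------------------------------------------------
    if config.peaks_path is None:
        try:
            bundle = simulate_all(config.simulation, config.n_terms, config.planted_terms)
            genes, peaks, sequences = bundle.genes, bundle.peaks, bundle.sequences
            expression, term_map, truth = bundle.expression, bundle.term_map, bundle.truth
            _write("genes.tsv", io_mod.write_genes, genes)
            _write("peaks.bed", io_mod.write_peaks, peaks)
            _write("peak_sequences.fa", io_mod.write_fasta, sequences)
            _write("expression.tsv", io_mod.write_expression, expression)
            _write("terms.tsv", io_mod.write_term_map, term_map)
            _write("truth.json", io_mod.write_truth, truth)
        except Exception as exc:
            _finish_manifest()
            raise PipelineError("synthetic_data", exc) from exc
    else:
        loads = [
            ("peak_processing", "peaks", io_mod.read_peaks, config.peaks_path),
            ("peak_processing", "genes", io_mod.read_genes, config.genes_path),
            ("expression_analysis", "expression", io_mod.read_expression, config.expression_path),
            ("motif_model", "sequences", io_mod.read_fasta, config.fasta_path),
            ("enrichment", "term_map", io_mod.read_term_map, config.term_map_path),
        ]
        loaded: dict[str, object] = {"sequences": [], "term_map": {}}
        for stage, name, reader, path in loads:
            if path is None:
                continue
            try:
                loaded[name] = reader(path)
            except Exception as exc:
                _finish_manifest()
                raise PipelineError(stage, exc) from exc
        peaks, genes = loaded["peaks"], loaded["genes"]
        expression, sequences = loaded["expression"], loaded["sequences"]
        term_map, truth = loaded["term_map"], None

    # --- peak processing -----------------------------------------------------
    try:
        filtered = peaks_mod.filter_peaks(peaks, config.fdr_max, config.p_max)
        annotation = peaks_mod.annotate_peaks(filtered, genes)
        _write("assignments.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), annotation.primary)
        _write("assignment_pairs.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), annotation.pairs)
        location_all = peaks_mod.location_distribution(annotation)
        chrom_counts = peaks_mod.chromosome_distribution(filtered)
        score_bins = {
            b: int((filtered["score"].map(peaks_mod.bin_peak_score) == b).sum())
            for b in ("strong", "medium", "weak")
        }
    except Exception as exc:
        _finish_manifest()
        raise PipelineError("peak_processing", exc) from exc

    # --- motif analysis ------------------------------------------------------
    try:
        model = motifs_mod.build_half_site_model(config.half_site_consensus)
        by_id = {r.id: str(r.seq) for r in sequences}
        top = peaks_mod.top_peak_windows(filtered, k=min(config.top_k, len(filtered)),
                                         flank=config.flank)
        top_seqs = [by_id[pid] for pid in top["peak_id"] if pid in by_id]
        filtered_seqs = [by_id[pid] for pid in filtered["peak_id"] if pid in by_id]
        spectrum = (
            motifs_mod.arrangement_spectrum(filtered_seqs, model, config.max_spacer)
            if filtered_seqs else {}
        )
        overlapped_dr1 = sum(
            1 for s in top_seqs
            if motifs_mod.detect_overlapped_dr1(motifs_mod.scan_half_sites(s, model))
        )
        gc_box = sum(1 for s in top_seqs if motifs_mod.detect_gc_box(s))
    except Exception as exc:
        _finish_manifest()
        raise PipelineError("motif_model", exc) from exc

    # --- differential expression --------------------------------------------
    try:
        de = expr_mod.classify_de(expression, config.detect_tau, config.alpha)
        _write("de_results.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), de)
        sets = expr_mod.label_sets(de)
        hepatic = sets["UIK"] | sets["DIK"] | sets["unchanged"]
    except Exception as exc:
        _finish_manifest()
        raise PipelineError("expression_analysis", exc) from exc

    # --- integration ---------------------------------------------------------
    try:
        bound = set(annotation.pairs["gene_id"].unique())
        partition = integrate_mod.venn_partition(hepatic, sets["UIK"] | sets["DIK"], bound)
        summary = integrate_mod.summarize(partition, sets["UIK"], sets["DIK"], annotation)
        labels = dict(zip(de["gene_id"], de["label"]))
        crosstab = integrate_mod.crosstab_bound_by_label(partition, labels)
        loc_dependent = _safe_location(annotation, partition.dependent)
        loc_independent = _safe_location(annotation, partition.hepatic - partition.dependent)
        loc_nonhepatic = _safe_location(annotation, partition.V)
    except Exception as exc:
        _finish_manifest()
        raise PipelineError("integration", exc) from exc

    # --- enrichment ----------------------------------------------------------
    try:
        enrichment_table = []
        if term_map and partition.dependent:
            results = run_enrichment(
                partition.dependent, hepatic, term_map,
                alpha=config.enrich_alpha, bonferroni_max=config.enrich_bonferroni_max,
            )
            annotated = annotate_term_table(results, bound, labels)
            _write("enrichment.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False),
                   results.drop(columns=["genes"]))
            enrichment_table = annotated.to_dict(orient="records")
    except Exception as exc:
        _finish_manifest()
        raise PipelineError("enrichment", exc) from exc

    report = {
        "config": config.to_dict(),
        "n_peaks_input": int(len(peaks)),
        "n_peaks_filtered": int(len(filtered)),
        "score_bins": score_bins,
        "location_distribution": {
            "all": location_all,
            "dependent": loc_dependent,
            "independent_hepatic": loc_independent,
            "nonhepatic": loc_nonhepatic,
        },
        "chromosome_distribution": chrom_counts,
        "arrangement_spectrum": spectrum,
        "overlapped_dr1_sequences": int(overlapped_dr1),
        "gc_box_sequences": int(gc_box),
        "n_top_sequences": len(top_seqs),
        "de_label_counts": {k: int(len(v)) for k, v in sets.items()},
        "venn_counts": partition.counts(),
        "summary": summary.rounded(),
        "summary_raw": dataclasses.asdict(summary),
        "crosstab_bound_by_label": crosstab.reset_index().to_dict(orient="records"),
        "enrichment": enrichment_table,
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    written.append(report_path)
    _finish_manifest()
    return report


def _safe_location(annotation, subset) -> Optional[dict]:
    try:
        return peaks_mod.location_distribution(annotation, subset)
    except ValidationError:
        return None
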