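"""Synthetic cistrome and transcriptome generation with known ground truth.

The generators emulate the statistical structure the analysis assumes: gene
models on a small multi-chromosome genome, binding peaks whose summits
realize a configurable location-category mixture, summit-centred sequences
with planted DR/IR/ER response elements at configurable class proportions,
3-vs-3 WT/KO expression matrices with planted up/down effects, and
term-to-gene maps with planted enriched terms.  Every generator is
deterministic given the configuration seed; each stage draws from its own
named substream so stages can be rerun independently.

Genome layout: genes are placed in disjoint slots wide enough that each
gene's full annotation envelope (gene body plus 100 kb flanking windows)
stays clear of every other gene's, so a summit planted in a category window
is recovered as exactly that category.  Intergenic summits go to a reserved
zone near each chromosome start, far beyond any gene window.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DISTAL_BP, PROMOTER_BP, GENE_COLUMNS, PEAK_COLUMNS, ValidationError
from .expression import ExpressionMatrix
from .motifs import HALF_SITE_LEN, build_half_site_model, reverse_complement, scan_half_sites

#: clearance kept between a gene and its slot edge; > DISTAL_BP so adjacent
#: genes' annotation windows can never touch
GENE_CLEARANCE = DISTAL_BP + 5_000
#: reserved margin at each chromosome end (no genes)
END_MARGIN = 250_000
#: intergenic summit zone near the chromosome start, >= 100 kb from any gene
INTERGENIC_ZONE = (10_000, 140_000)

DEFAULT_LOCATION_MIXTURE = {
    "ingene": 0.49,
    "promoter": 0.13,
    "upstream": 0.15,
    "downstream": 0.15,
    "intergenic": 0.08,
}

# class proportions shaped like the observed liver spectrum: DR1 dominant,
# then DR4, IR1, DR3 and IR3, with a large motif-free remainder
DEFAULT_MOTIF_MIXTURE = {
    "DR1": 0.125,
    "DR4": 0.08,
    "IR1": 0.07,
    "DR3": 0.06,
    "IR3": 0.05,
    "DR0": 0.03,
    "DR2": 0.03,
    "DR5": 0.03,
    "IR0": 0.02,
    "ER1": 0.03,
    "ER3": 0.03,
    "ER8": 0.02,
    "none": 0.425,
}


class CapacityError(ValidationError):
    """Raised when the requested genes cannot be packed into the genome."""


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the run seed."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults mirror the study design being emulated: three replicates per
    genotype, roughly two thirds of array genes detected, ~8.5% / 7.7% of
    hepatic genes planted up / down in the knockout, a one-log2 effect, and
    location / motif mixtures shaped like the observed distributions (a
    plausible fixture, not ground truth).
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 30_000_000
    n_genes: int = 200
    frac_bound: float = 0.6
    peaks_per_gene_mean: float = 3.0
    location_mixture: dict = field(default_factory=lambda: dict(DEFAULT_LOCATION_MIXTURE))
    motif_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_MIXTURE))
    n_per_group: int = 3
    frac_uik: float = 0.085
    frac_dik: float = 0.077
    effect_log2fc: float = 1.0
    noise_sd: float = 40.0
    detect_tau: float = 50.0
    frac_undetected: float = 0.35
    frac_filter_fail: float = 0.1
    gene_length_range: tuple = (2_000, 20_000)
    baseline_range: tuple = (200.0, 2_000.0)
    seq_flank: int = 100
    clean_background: bool = False

    def validate(self) -> None:
        fracs = {
            "frac_bound": self.frac_bound,
            "frac_uik": self.frac_uik,
            "frac_dik": self.frac_dik,
            "frac_undetected": self.frac_undetected,
            "frac_filter_fail": self.frac_filter_fail,
        }
        for name, value in fracs.items():
            if not (0 <= value <= 1):
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_uik + self.frac_dik > 1:
            raise ValidationError("frac_uik + frac_dik exceeds 1")
        for name, mix in (("location_mixture", self.location_mixture),
                          ("motif_mixture", self.motif_mixture)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1 within 1e-9")
            if any(v < 0 for v in mix.values()):
                raise ValidationError(f"{name} has negative mass")
        unknown = set(self.location_mixture) - {"ingene", "promoter", "upstream",
                                                "downstream", "intergenic"}
        if unknown:
            raise ValidationError(f"unknown location categories: {sorted(unknown)}")
        for key in self.motif_mixture:
            if key != "none":
                _parse_motif_key(key)
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.detect_tau < 0:
            raise ValidationError("detect_tau must be >= 0")
        if self.gene_length_range[0] < 1 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValidationError("invalid gene_length_range")
        if self.n_genes > 0:
            if _genome_capacity(self) < self.n_genes:
                raise CapacityError(
                    f"cannot pack {self.n_genes} genes with {DISTAL_BP // 1000} kb window "
                    f"clearance into {self.n_chroms} x {self.chrom_length} bp"
                )
        max_elem = max(
            (2 * HALF_SITE_LEN + _parse_motif_key(k)[1] for k in self.motif_mixture if k != "none"),
            default=0,
        )
        if max_elem > 2 * self.seq_flank + 1:
            raise ValidationError(
                f"sequence window ({2 * self.seq_flank + 1} bp) shorter than the longest "
                f"planted element ({max_elem} bp)"
            )


def _parse_motif_key(key: str) -> tuple[str, int]:
    cls, spacer = key[:2], key[2:]
    if cls not in ("DR", "IR", "ER") or not spacer.isdigit():
        raise ValidationError(f"malformed motif class {key!r} (expect e.g. DR1, IR0, ER8)")
    return cls, int(spacer)


def _slot_width(config: SimulationConfig) -> int:
    return 2 * GENE_CLEARANCE + config.gene_length_range[1]


def _genome_capacity(config: SimulationConfig) -> int:
    usable = config.chrom_length - 2 * END_MARGIN
    if usable <= 0:
        return 0
    return config.n_chroms * (usable // _slot_width(config))


@dataclass
class Truth:
    """Ground truth recorded alongside the generated artifacts."""

    de_label_by_gene: dict = field(default_factory=dict)
    bound_genes: set = field(default_factory=set)
    planted_motif_by_peak: dict = field(default_factory=dict)
    enriched_terms: set = field(default_factory=set)
    # extra provenance useful for oracle tests
    planted_location_by_peak: dict = field(default_factory=dict)
    anchor_gene_by_peak: dict = field(default_factory=dict)
    passes_filter_by_peak: dict = field(default_factory=dict)


def generate_genes(config: SimulationConfig) -> pd.DataFrame:
    """Place non-overlapping genes with isolated annotation envelopes.

    Genes are distributed round-robin over chromosomes into disjoint slots
    and jittered within their slot, keeping >= 100 kb clearance to chromosome
    ends and to every other gene's windows.  Raises CapacityError when they
    cannot fit.
    """
    config.validate()
    if config.n_genes == 0:
        return pd.DataFrame(columns=GENE_COLUMNS)
    rng = _substream(config.seed, "genes")
    width = _slot_width(config)
    lo_len, hi_len = config.gene_length_range
    rows = []
    for i in range(config.n_genes):
        chrom_idx = i % config.n_chroms
        slot_idx = i // config.n_chroms
        slot_base = END_MARGIN + slot_idx * width
        length = int(rng.integers(lo_len, hi_len + 1))
        jitter_max = width - 2 * GENE_CLEARANCE - length
        start = slot_base + GENE_CLEARANCE + int(rng.integers(0, jitter_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"g{i:05d}", f"chr{chrom_idx + 1}", strand, start, start + length))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _category_window(category: str, strand: str, start: int, end: int) -> tuple[int, int]:
    """Half-open summit window realizing a location category for one gene."""
    if category == "ingene":
        return start, end
    if strand == "+":
        if category == "promoter":
            return start - PROMOTER_BP, start
        if category == "upstream":
            return start - DISTAL_BP, start - PROMOTER_BP
        if category == "downstream":
            return end, end + DISTAL_BP
    else:
        if category == "promoter":
            return end, end + PROMOTER_BP
        if category == "upstream":
            return end + PROMOTER_BP, end + DISTAL_BP
        if category == "downstream":
            return start - DISTAL_BP, start
    raise ValidationError(f"unknown category {category!r}")


def generate_peaks(
    genes: pd.DataFrame, config: SimulationConfig, truth: Optional[Truth] = None
) -> tuple[pd.DataFrame, Truth]:
    """Generate peaks whose true location categories follow the mixture.

    Each designated bound gene receives at least one filter-passing,
    non-intergenic peak (its anchor), so the realized bound-gene set equals
    the designated one after filtering; category draws beyond the anchors are
    i.i.d. from the mixture.  A ``frac_filter_fail`` fraction of the surplus
    peaks is planted to violate the FDR or Poisson-p threshold.
    """
    config.validate()
    truth = truth if truth is not None else Truth()
    rng = _substream(config.seed, "peaks")

    mixture = config.location_mixture
    cats = sorted(mixture)
    probs = np.array([mixture[c] for c in cats], dtype=float)
    if probs.sum() <= 0:
        raise ValidationError("location mixture has zero total mass")
    p_inter = mixture.get("intergenic", 0.0)

    n_genes = len(genes)
    if config.frac_bound > 0 and n_genes == 0:
        raise ValidationError("frac_bound > 0 requires a non-empty gene set")
    n_bound = int(round(config.frac_bound * n_genes))
    if n_bound == 0:
        truth.bound_genes = set()
        return pd.DataFrame(columns=PEAK_COLUMNS), truth
    if p_inter >= 1:
        raise ValidationError("location mixture has no non-intergenic mass but frac_bound > 0")

    gene_ids = list(genes["gene_id"])
    bound_genes = sorted(rng.choice(gene_ids, size=n_bound, replace=False))
    truth.bound_genes = set(bound_genes)
    gene_rows = {g.gene_id: g for g in genes.itertuples(index=False)}

    n_peaks = max(n_bound, int(round(n_bound * config.peaks_per_gene_mean / (1 - p_inter))))
    categories = list(rng.choice(cats, size=n_peaks, p=probs))

    # make sure there are enough non-intergenic peaks to anchor every bound
    # gene; convert surplus intergenic draws if a tiny simulation runs short
    non_inter = [i for i, c in enumerate(categories) if c != "intergenic"]
    deficit = n_bound - len(non_inter)
    if deficit > 0:
        non_inter_probs = np.array([mixture[c] if c != "intergenic" else 0.0 for c in cats])
        non_inter_probs = non_inter_probs / non_inter_probs.sum()
        converted = 0
        for i, c in enumerate(categories):
            if c == "intergenic":
                categories[i] = str(rng.choice(cats, p=non_inter_probs))
                converted += 1
                if converted == deficit:
                    break
        non_inter = [i for i, c in enumerate(categories) if c != "intergenic"]

    # anchor assignment: first one peak per bound gene (shuffled), then random
    anchor_order = list(rng.permutation(bound_genes))
    anchors: dict[int, str] = {}
    for j, idx in enumerate(non_inter):
        if j < n_bound:
            anchors[idx] = anchor_order[j]
        else:
            anchors[idx] = bound_genes[int(rng.integers(0, n_bound))]
    forced_pass = set(non_inter[:n_bound])

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    rows = []
    for i, category in enumerate(categories):
        peak_id = f"p{i:06d}"
        if category == "intergenic":
            chrom = str(rng.choice(chrom_names))
            summit = int(rng.integers(*INTERGENIC_ZONE))
            anchor = None
        else:
            gene = gene_rows[anchors[i]]
            chrom = gene.chrom
            lo, hi = _category_window(category, gene.strand, int(gene.start), int(gene.end))
            summit = int(rng.integers(lo, hi))
            anchor = gene.gene_id
        half_width = int(rng.integers(50, 201))
        start = max(0, summit - half_width)
        end = summit + half_width + 1

        # binding-strength bins: weak / medium / strong all represented
        bin_draw = rng.random()
        if bin_draw < 0.35:
            score = float(rng.uniform(10, 100))
        elif bin_draw < 0.70:
            score = float(rng.uniform(100, 200))
        else:
            score = float(rng.uniform(200, 500))

        passes = i in forced_pass or rng.random() >= config.frac_filter_fail
        if passes:
            fdr = float(rng.uniform(0, 0.1))
            pvalue = float(10 ** -rng.uniform(5.05, 12))
        else:
            mode = rng.random()
            fdr = float(rng.uniform(0.101, 0.6)) if mode < 0.7 else float(rng.uniform(0, 0.1))
            pvalue = float(10 ** -rng.uniform(1, 4.9)) if mode >= 0.3 else float(10 ** -rng.uniform(5.05, 12))

        rows.append((peak_id, chrom, start, end, summit, score, pvalue, fdr))
        truth.planted_location_by_peak[peak_id] = category
        truth.anchor_gene_by_peak[peak_id] = anchor
        truth.passes_filter_by_peak[peak_id] = bool(passes)

    return pd.DataFrame(rows, columns=PEAK_COLUMNS), truth


def _plant_element(cls: str, spacer: int, rng: np.random.Generator) -> str:
    """A planted response element: two consensus half-sites around a random
    spacer, oriented per the class geometry."""
    halves = [("A" if rng.random() < 0.5 else "G") + "GGTCA" for _ in range(2)]
    gap = "".join(rng.choice(list("ACGT"), size=spacer))
    if cls == "DR":
        left, right = halves[0], halves[1]
    elif cls == "IR":
        left, right = halves[0], reverse_complement(halves[1])
    else:  # ER, tail-to-tail
        left, right = reverse_complement(halves[0]), halves[1]
    return left + gap + right


def _scrub_spurious_hits(
    seq: list[str],
    planted: set[tuple[int, str]],
    protected: set[int],
    rng: np.random.Generator,
    model=None,
) -> None:
    """Mutate background bases until only the planted half-sites scan as hits.

    Used for noise-free plantings: guarantees classifier truth is exactly the
    planted arrangement.  Mutations never touch planted half-site bases.
    """
    if model is None:
        model = build_half_site_model("RGGTCA")
    for _ in range(200):
        hits = scan_half_sites("".join(seq), model)
        spurious = [h for h in hits if (h.position, h.strand) not in planted]
        if not spurious:
            return
        for h in spurious:
            free = [p for p in range(h.position, h.position + HALF_SITE_LEN) if p not in protected]
            if not free:  # cannot happen for consensus half-sites; guard anyway
                raise ValidationError("spurious half-site fully inside a planted element")
            pos = free[int(rng.integers(0, len(free)))]
            seq[pos] = str(rng.choice(list("ACGT")))
    raise ValidationError("failed to scrub spurious half-sites")


def generate_peak_sequences(
    peaks: pd.DataFrame, config: SimulationConfig, truth: Optional[Truth] = None
) -> tuple[list[SeqRecord], Truth]:
    """Summit-centred sequences with planted response elements.

    Each peak gets a ±flank window of i.i.d. uniform A/C/G/T background; with
    probability given by the motif mixture one arrangement of the designated
    class is planted centred in the window.  With ``clean_background`` the
    background is scrubbed of chance half-sites so the planted element is the
    only signal (noise-free plantings for recall tests).
    """
    config.validate()
    truth = truth if truth is not None else Truth()
    rng = _substream(config.seed, "sequences")
    keys = sorted(config.motif_mixture)
    probs = np.array([config.motif_mixture[k] for k in keys], dtype=float)
    width = 2 * config.seq_flank + 1
    scrub_model = build_half_site_model("RGGTCA") if config.clean_background else None

    records = []
    for p in peaks.itertuples(index=False):
        seq = list(rng.choice(list("ACGT"), size=width))
        key = str(rng.choice(keys, p=probs))
        planted: set[tuple[int, str]] = set()
        protected: set[int] = set()
        if key != "none":
            cls, spacer = _parse_motif_key(key)
            element = _plant_element(cls, spacer, rng)
            offset = (width - len(element)) // 2
            seq[offset : offset + len(element)] = list(element)
            left_strand, right_strand = {
                "DR": ("+", "+"), "IR": ("+", "-"), "ER": ("-", "+")
            }[cls]
            right_pos = offset + HALF_SITE_LEN + spacer
            planted = {(offset, left_strand), (right_pos, right_strand)}
            protected = set(range(offset, offset + HALF_SITE_LEN)) | set(
                range(right_pos, right_pos + HALF_SITE_LEN)
            )
        if config.clean_background:
            _scrub_spurious_hits(seq, planted, protected, rng, scrub_model)
        truth.planted_motif_by_peak[p.peak_id] = key
        records.append(SeqRecord(Seq("".join(seq)), id=p.peak_id, description=""))
    return records, truth


def generate_expression(
    genes: Union[pd.DataFrame, Sequence[str]],
    config: SimulationConfig,
    truth: Optional[Truth] = None,
) -> tuple[ExpressionMatrix, Truth]:
    """WT/KO expression matrix with planted effects and Gaussian noise.

    Detected genes draw a baseline from ``baseline_range``; UIK genes get the
    KO mean multiplied by 2**effect_log2fc, DIK genes divided by it.
    Undetected genes sit below ``detect_tau`` in both groups.  Label counts
    are exact (rounded fractions of the gene list), assigned by permutation.
    """
    config.validate()
    truth = truth if truth is not None else Truth()
    rng = _substream(config.seed, "expression")
    gene_ids = list(genes["gene_id"]) if isinstance(genes, pd.DataFrame) else list(genes)
    n = len(gene_ids)
    if n == 0:
        raise ValidationError("empty gene set")

    order = rng.permutation(n)
    n_undetected = int(round(config.frac_undetected * n))
    undetected_idx = set(order[:n_undetected].tolist())
    detected_order = [i for i in order.tolist() if i not in undetected_idx]
    n_detected = len(detected_order)
    n_uik = int(round(config.frac_uik * n_detected))
    n_dik = int(round(config.frac_dik * n_detected))
    labels = np.full(n, "unchanged", dtype=object)
    for i in order[:n_undetected]:
        labels[i] = "undetected"
    for i in detected_order[:n_uik]:
        labels[i] = "UIK"
    for i in detected_order[n_uik : n_uik + n_dik]:
        labels[i] = "DIK"

    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=n)
    undetected_mask = labels == "undetected"
    baseline[undetected_mask] = rng.uniform(0, config.detect_tau / 4, size=int(undetected_mask.sum()))

    effect = 2.0 ** config.effect_log2fc
    mean_ko = baseline.copy()
    mean_ko[labels == "UIK"] *= effect
    mean_ko[labels == "DIK"] /= effect

    n_rep = config.n_per_group
    wt = baseline[:, None] + rng.normal(0, config.noise_sd, size=(n, n_rep))
    ko = mean_ko[:, None] + rng.normal(0, config.noise_sd, size=(n, n_rep))
    values = np.clip(np.hstack([wt, ko]), 0, None)

    samples = [f"WT_{i + 1}" for i in range(n_rep)] + [f"KO_{i + 1}" for i in range(n_rep)]
    frame = pd.DataFrame(values, index=gene_ids, columns=samples)
    groups = pd.Series(["WT"] * n_rep + ["KO"] * n_rep, index=samples)
    truth.de_label_by_gene.update(dict(zip(gene_ids, labels)))
    return ExpressionMatrix(values=frame, groups=groups), truth


def generate_term_map(
    genes: Union[pd.DataFrame, Sequence[str]],
    truth: Truth,
    n_terms: int,
    planted_terms: int,
    seed: int,
    query_label: str = "UIK",
    term_size_range: tuple = (10, 30),
    planted_purity: float = 0.8,
) -> dict[str, set[str]]:
    """Term-to-gene map with ``planted_terms`` over-populated from one label.

    Planted terms draw ``planted_purity`` of their genes from the chosen DE
    label (UIK by default); the remaining terms sample the universe
    uniformly.  Planted term ids are recorded in ``truth.enriched_terms``.
    """
    if planted_terms > n_terms:
        raise ValidationError("planted_terms cannot exceed n_terms")
    gene_ids = list(genes["gene_id"]) if isinstance(genes, pd.DataFrame) else list(genes)
    if n_terms == 0:
        return {}
    if not gene_ids:
        raise ValidationError("empty gene universe")
    lo, hi = term_size_range
    if lo > len(gene_ids):
        raise ValidationError(f"term size {lo} exceeds universe of {len(gene_ids)} genes")
    rng = _substream(seed, "terms")
    label_genes = [g for g in gene_ids if truth.de_label_by_gene.get(g) == query_label]

    term_map: dict[str, set[str]] = {}
    for t in range(n_terms):
        term_id = f"T{t + 1:04d}"
        size = int(rng.integers(lo, min(hi, len(gene_ids)) + 1))
        if t < planted_terms and label_genes:
            n_label = min(int(round(planted_purity * size)), len(label_genes))
            members = set(rng.choice(label_genes, size=n_label, replace=False))
            rest = [g for g in gene_ids if g not in members]
            members |= set(rng.choice(rest, size=size - n_label, replace=False))
            truth.enriched_terms.add(term_id)
        else:
            members = set(rng.choice(gene_ids, size=size, replace=False))
        term_map[term_id] = members
    return term_map


@dataclass
class SimulationBundle:
    """All artifacts of one simulated study."""

    config: SimulationConfig
    genes: pd.DataFrame
    peaks: pd.DataFrame
    sequences: list
    expression: ExpressionMatrix
    term_map: dict
    truth: Truth


def simulate_all(
    config: SimulationConfig, n_terms: int = 50, planted_terms: int = 3
) -> SimulationBundle:
    """Run every generator under one configuration seed."""
    config.validate()
    truth = Truth()
    genes = generate_genes(config)
    peaks, truth = generate_peaks(genes, config, truth)
    sequences, truth = generate_peak_sequences(peaks, config, truth)
    expression, truth = generate_expression(genes, config, truth)
    term_map = generate_term_map(genes, truth, n_terms, planted_terms, config.seed)
    return SimulationBundle(
        config=config,
        genes=genes,
        peaks=peaks,
        sequences=sequences,
        expression=expression,
        term_map=term_map,
        truth=truth,
    )
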