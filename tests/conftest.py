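import numpy as np
import pandas as pd
import pytest

from nrcistrome import SimulationConfig, build_half_site_model, simulate_all


@pytest.fixture(scope="session")
def consensus_model():
    return build_half_site_model("RGGTCA")


@pytest.fixture
def small_config():
    """A compact simulated study used by several module tests."""
    return SimulationConfig(seed=7, n_chroms=2, chrom_length=12_000_000, n_genes=60)


@pytest.fixture(scope="session")
def small_bundle():
    cfg = SimulationConfig(seed=11, n_chroms=2, chrom_length=12_000_000, n_genes=60)
    return simulate_all(cfg)


def random_gene_frame(rng: np.random.Generator, n_genes: int, genome_length: int,
                      n_chroms: int = 2) -> pd.DataFrame:
    """Dense random gene models whose annotation windows overlap freely —
    adversarial input for annotation precedence and tie-breaks."""
    rows = []
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, genome_length - 30_000))
        length = int(rng.integers(1_000, 30_000))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"g{i:04d}", chrom, strand, start, start + length))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])


def random_peak_frame(rng: np.random.Generator, n_peaks: int, genome_length: int,
                      n_chroms: int = 2) -> pd.DataFrame:
    rows = []
    for i in range(n_peaks):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        summit = int(rng.integers(200, genome_length - 200))
        half = int(rng.integers(50, 200))
        rows.append((f"p{i:05d}", chrom, summit - half, summit + half + 1, summit,
                     float(rng.uniform(10, 400)), float(10 ** -rng.uniform(5.1, 9)),
                     float(rng.uniform(0, 0.1))))
    return pd.DataFrame(
        rows,
        columns=["peak_id", "chrom", "start", "end", "summit", "score", "pvalue", "fdr"],
    )


def oracle_category(summit: int, strand: str, start: int, end: int):
    """Independent re-derivation of the location windows by distance
    arithmetic in the transcription direction."""
    tss = start if strand == "+" else end - 1
    three_prime = end - 1 if strand == "+" else start
    sign = 1 if strand == "+" else -1
    if start <= summit < end:
        return "ingene"
    d_tss = sign * (summit - tss)  # >0 downstream of TSS in transcription direction
    d_3p = sign * (summit - three_prime)
    if -2000 <= d_tss < 0:
        return "promoter"
    if -100_000 <= d_tss < -2000:
        return "upstream"
    if 0 < d_3p <= 100_000:
        return "downstream"
    return None


def oracle_primary(peaks: pd.DataFrame, genes: pd.DataFrame):
    """All-pairs brute-force primary assignment (precedence, nearest TSS,
    gene id)."""
    precedence = {"ingene": 0, "promoter": 1, "upstream": 2, "downstream": 3}
    gene_rows = [
        (g.gene_id, g.chrom, g.strand, int(g.start), int(g.end))
        for g in genes.itertuples(index=False)
    ]
    out = {}
    for p in peaks.itertuples(index=False):
        summit = int(p.summit)
        best = None
        for gene_id, chrom, strand, start, end in gene_rows:
            if chrom != p.chrom:
                continue
            cat = oracle_category(summit, strand, start, end)
            if cat is None:
                continue
            tss = start if strand == "+" else end - 1
            key = (precedence[cat], abs(summit - tss), gene_id)
            if best is None or key < best[0]:
                best = (key, gene_id, cat)
        out[p.peak_id] = ("intergenic", None) if best is None else (best[2], best[1])
    return out
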