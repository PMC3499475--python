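"""Five-way partition of genes by expression detection, dependence and binding.

The three input sets — hepatic (detectable expression in either genotype),
dependent (differentially expressed between WT and KO), and bound (at least
one filtered peak assigned in any non-intergenic category) — partition genes
into five disjoint categories:

* I   — hepatic, independent, unbound
* II  — dependent but unbound
* III — dependent and bound
* IV  — hepatic, independent, bound
* V   — bound but non-hepatic

I+II+III+IV is the hepatic set, II+III the dependent set, III+IV+V the bound
set.  The summary statistics (bound fraction of hepatic genes, dependent
fraction, bound fractions of UIK and DIK genes, mean peaks per bound gene)
are reported both raw and at display rounding: one decimal for percentages,
two for the dependent fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .core import ValidationError
from .peaks import AnnotationResult, mean_peaks_per_gene, peaks_per_gene


@dataclass(frozen=True)
class VennPartition:
    """The five disjoint gene categories plus the input sets."""

    I: frozenset
    II: frozenset
    III: frozenset
    IV: frozenset
    V: frozenset
    hepatic: frozenset
    dependent: frozenset
    bound: frozenset

    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in ("I", "II", "III", "IV", "V")}

    def check(self) -> None:
        """Assert the partition algebra; raised defects indicate a bug."""
        parts = [self.I, self.II, self.III, self.IV]
        assert frozenset().union(*parts) == self.hepatic
        for i, a in enumerate(parts):
            for b in parts[i + 1 :]:
                assert not (a & b)
        assert not (self.V & self.hepatic)
        assert self.II | self.III == self.dependent
        assert self.III | self.IV | self.V == self.bound
        assert len(self.II) == len(self.dependent) - len(self.III)
        assert len(self.V) == len(self.bound) - len(self.III) - len(self.IV)


def venn_partition(
    hepatic: Iterable[str], dependent: Iterable[str], bound: Iterable[str]
) -> VennPartition:
    """Partition genes into categories I-V by set algebra.

    Dependent genes outside the hepatic set are contradictory (dependence is
    only defined for detected genes); they are dropped with a warning.
    """
    hepatic = frozenset(hepatic)
    dependent = frozenset(dependent)
    bound = frozenset(bound)
    if not hepatic:
        raise ValidationError("empty hepatic gene set")
    stray = dependent - hepatic
    if stray:
        warnings.warn(f"{len(stray)} dependent genes outside the hepatic set dropped")
        dependent = dependent - stray

    part = VennPartition(
        I=frozenset(hepatic - dependent - bound),
        II=frozenset(dependent - bound),
        III=frozenset(dependent & bound),
        IV=frozenset((hepatic - dependent) & bound),
        V=frozenset(bound - hepatic),
        hepatic=hepatic,
        dependent=dependent,
        bound=bound,
    )
    part.check()
    return part


@dataclass(frozen=True)
class IntegrationSummary:
    """Raw summary statistics of a binding/expression partition."""

    pct_hepatic_bound: float
    pct_hepatic_dependent: float
    pct_uik_bound: float
    pct_dik_bound: float
    n_dependent: int
    n_uik: int
    n_dik: int
    n_dependent_unbound: int
    n_bound_nonhepatic: int
    n_bound_total: int
    mean_peaks_per_gene: Optional[float]

    def rounded(self) -> dict[str, float | int]:
        """Display rounding: one decimal for percentages, two for the
        dependent fraction, one for mean peaks per gene."""
        out: dict[str, float | int] = {
            "pct_hepatic_bound": round(self.pct_hepatic_bound, 1),
            "pct_hepatic_dependent": round(self.pct_hepatic_dependent, 2),
            "pct_uik_bound": round(self.pct_uik_bound, 1),
            "pct_dik_bound": round(self.pct_dik_bound, 1),
            "n_dependent": self.n_dependent,
            "n_uik": self.n_uik,
            "n_dik": self.n_dik,
            "n_dependent_unbound": self.n_dependent_unbound,
            "n_bound_nonhepatic": self.n_bound_nonhepatic,
            "n_bound_total": self.n_bound_total,
        }
        if self.mean_peaks_per_gene is not None:
            out["mean_peaks_per_gene"] = round(self.mean_peaks_per_gene, 1)
        return out


def summarize(
    partition: VennPartition,
    uik_set: Iterable[str],
    dik_set: Iterable[str],
    peak_assignments: Optional[Union[AnnotationResult, pd.DataFrame, Mapping[str, int]]] = None,
) -> IntegrationSummary:
    """Compute the partition's summary statistics.

    ``peak_assignments`` may be an annotation result (its exhaustive
    per-(peak, gene) table is counted), or a prepared per-gene peak-count
    mapping; omitted, the mean peaks per gene is left out.
    """
    uik = frozenset(uik_set)
    dik = frozenset(dik_set)
    if not uik <= partition.dependent or not dik <= partition.dependent:
        raise ValidationError("UIK/DIK sets must be subsets of the dependent set")
    if uik & dik:
        raise ValidationError("UIK and DIK sets overlap")
    n_hepatic = len(partition.hepatic)
    if n_hepatic == 0 or not uik or not dik:
        raise ValidationError("zero denominator in summary percentages")

    bound_hepatic = partition.III | partition.IV
    mean_ppg: Optional[float] = None
    if peak_assignments is not None:
        if isinstance(peak_assignments, (AnnotationResult, pd.DataFrame)):
            _, mean_ppg = peaks_per_gene(peak_assignments)
        else:
            mean_ppg = mean_peaks_per_gene(peak_assignments)

    return IntegrationSummary(
        pct_hepatic_bound=100.0 * len(bound_hepatic) / n_hepatic,
        pct_hepatic_dependent=100.0 * len(partition.dependent) / n_hepatic,
        pct_uik_bound=100.0 * len(uik & partition.bound) / len(uik),
        pct_dik_bound=100.0 * len(dik & partition.bound) / len(dik),
        n_dependent=len(partition.dependent),
        n_uik=len(uik),
        n_dik=len(dik),
        n_dependent_unbound=len(partition.II),
        n_bound_nonhepatic=len(partition.V),
        n_bound_total=len(partition.bound),
        mean_peaks_per_gene=mean_ppg,
    )


def crosstab_bound_by_label(
    partition: VennPartition, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Counts and row percentages of bound/unbound genes per DE label.

    ``labels`` maps every hepatic gene to UIK / DIK / unchanged.  Rows appear
    only for labels present among the hepatic genes.
    """
    rows = []
    by_label: dict[str, set] = {}
    for gene in partition.hepatic:
        lab = labels.get(gene)
        if lab is None:
            raise ValidationError(f"hepatic gene {gene} missing a DE label")
        by_label.setdefault(lab, set()).add(gene)
    for lab in ("UIK", "DIK", "unchanged"):
        genes = by_label.get(lab)
        if not genes:
            continue
        bound = len(genes & partition.bound)
        rows.append((lab, len(genes), bound, len(genes) - bound, 100.0 * bound / len(genes)))
    return pd.DataFrame(rows, columns=["label", "n", "bound", "unbound", "pct_bound"]).set_index("label")
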