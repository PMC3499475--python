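"""Reference count fixtures.

The genome-wide RXRα liver study that motivates this pipeline reports only
summary cardinalities (no deposited accession): 9,068 hepatic genes of which
768 UIK and 696 DIK (1,464 dependent); 109,971 filtered peaks over 14,816
bound genes; 7,174 hepatic genes bound, including 657 UIK and 605 DIK.  The
fixture below rebuilds gene sets with exactly those cardinalities using
synthetic identifiers, so the integration summary arithmetic can be checked
against the printed statistics.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CountFixture:
    """Synthetic gene sets realizing the published summary cardinalities."""

    hepatic: frozenset
    uik: frozenset
    dik: frozenset
    bound: frozenset
    peaks_per_gene: dict  # gene -> peak count over all bound genes

    @property
    def dependent(self) -> frozenset:
        return self.uik | self.dik


# published cardinalities of the liver RXRα binding / expression integration
N_HEPATIC = 9_068
N_UIK = 768
N_DIK = 696
N_BOUND_HEPATIC = 7_174
N_UIK_BOUND = 657
N_DIK_BOUND = 605
N_BOUND_TOTAL = 14_816
N_PEAKS = 109_971


def reference_count_fixture() -> CountFixture:
    """Gene sets constructed to the published cardinalities.

    Identifiers are synthetic (``h…`` hepatic, ``nh…`` non-hepatic); only the
    set sizes and their intersections carry meaning.  Peak counts are spread
    as evenly as possible over the bound genes so they total the published
    peak count.
    """
    hepatic = [f"h{i:05d}" for i in range(N_HEPATIC)]
    uik = hepatic[:N_UIK]
    dik = hepatic[N_UIK : N_UIK + N_DIK]
    independent = hepatic[N_UIK + N_DIK :]

    n_independent_bound = N_BOUND_HEPATIC - N_UIK_BOUND - N_DIK_BOUND
    bound_hepatic = uik[:N_UIK_BOUND] + dik[:N_DIK_BOUND] + independent[:n_independent_bound]
    nonhepatic_bound = [f"nh{i:05d}" for i in range(N_BOUND_TOTAL - N_BOUND_HEPATIC)]
    bound = bound_hepatic + nonhepatic_bound

    base, extra = divmod(N_PEAKS, len(bound))
    counts = {g: base + (1 if i < extra else 0) for i, g in enumerate(bound)}
    assert sum(counts.values()) == N_PEAKS

    return CountFixture(
        hepatic=frozenset(hepatic),
        uik=frozenset(uik),
        dik=frozenset(dik),
        bound=frozenset(bound),
        peaks_per_gene=counts,
    )
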