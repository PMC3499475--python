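"""Hypergeometric term enrichment with Bonferroni control.

For a query of n genes drawn from a universe of N, a term covering K universe
genes and overlapping the query in k, the enrichment p-value is the
hypergeometric upper tail P[X >= k].  Terms are accepted when p < 0.05 and
the Bonferroni-corrected value (p times the number of terms tested) is below
0.1.  An EASE-style conservative variant (scoring k - 1) is available behind
a flag.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Union

import pandas as pd
from scipy.stats import hypergeom

from .core import ValidationError

TermMap = Union[Mapping[str, Iterable[str]], pd.DataFrame]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValidationError(f"inconsistent hypergeometric arguments (k={k}, K={K}, n={n}, N={N})")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _as_term_dict(term_map: TermMap) -> dict[str, set[str]]:
    if isinstance(term_map, pd.DataFrame):
        if term_map.shape[1] < 2:
            raise ValidationError("term map table needs (term_id, gene_id) columns")
        term_col, gene_col = term_map.columns[:2]
        out: dict[str, set[str]] = {}
        for term, gene in zip(term_map[term_col], term_map[gene_col]):
            out.setdefault(str(term), set()).add(str(gene))
        return out
    return {str(t): set(genes) for t, genes in term_map.items()}


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    term_map: TermMap,
    alpha: float = 0.05,
    bonferroni_max: float = 0.1,
    ease: bool = False,
) -> pd.DataFrame:
    """Test every term for over-representation of the query in the universe.

    Terms are intersected with the universe first; only terms retaining at
    least one universe gene are tested, and that count is the Bonferroni
    multiplier.  With ``ease=True`` the upper tail is computed at k - 1, the
    conservative variant used by some annotation servers.  Results come back
    sorted by p, with the per-term query-overlap gene sets kept in a
    ``genes`` column for downstream tabulation.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ValidationError("query and universe must be non-empty")
    if not query <= universe:
        raise ValidationError(f"{len(query - universe)} query genes outside the universe")

    terms = {t: genes & universe for t, genes in _as_term_dict(term_map).items()}
    terms = {t: genes for t, genes in terms.items() if genes}
    n_tested = len(terms)
    N, n = len(universe), len(query)

    rows = []
    for term, genes in sorted(terms.items()):
        K = len(genes)
        overlap = genes & query
        k = len(overlap)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_upper(k_eff, K, n, N)
        bonf = min(1.0, p * n_tested)
        rows.append((term, k, K, n, N, p, bonf, p < alpha and bonf < bonferroni_max,
                     frozenset(overlap)))
    out = pd.DataFrame(
        rows, columns=["term_id", "k", "K", "n", "N", "p", "bonferroni", "accepted", "genes"]
    )
    return out.sort_values(by=["p", "term_id"], kind="mergesort").reset_index(drop=True)


def annotate_term_table(
    results: pd.DataFrame,
    bound: Iterable[str],
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per accepted term: query gene count, bound count/percent, UIK and DIK
    counts — the layout used to report pathways of dependent genes."""
    bound = set(bound)
    rows = []
    for r in results.itertuples(index=False):
        if not r.accepted:
            continue
        genes = set(r.genes)
        n_genes = len(genes)
        n_bound = len(genes & bound)
        uik = sum(1 for g in genes if labels.get(g) == "UIK")
        dik = sum(1 for g in genes if labels.get(g) == "DIK")
        pct = 100.0 * n_bound / n_genes if n_genes else 0.0
        rows.append((r.term_id, n_genes, n_bound, pct, uik, dik, r.p, r.bonferroni))
    return pd.DataFrame(
        rows,
        columns=["term_id", "n_genes", "n_bound", "pct_bound", "n_uik", "n_dik", "p", "bonferroni"],
    )
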