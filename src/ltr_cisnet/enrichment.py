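"""Hypergeometric over-representation of functional terms in a gene set.

For a term annotated to K of N universe genes, observed in k of n target
genes, the enrichment p-value is the upper tail P(X >= k) of the
hypergeometric distribution, evaluated through scipy's log-space survival
function.  Significance is raw p < alpha (0.05 by default) with no
multiple-testing correction; a Benjamini-Hochberg column is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    pvalue: float
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(target_genes: Iterable[str],
           term_map: Mapping[str, Iterable[str]],
           universe: Iterable[str],
           alpha: float = DEFAULT_ALPHA,
           term_names: Mapping[str, str] | None = None,
           bh_correct: bool = False) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per term with >= 1 target member.

    Raises ValueError (listing offenders) if targets fall outside the
    universe.  Results are sorted by p-value, then term id.
    """
    universe = set(universe)
    targets = set(target_genes)
    stray = sorted(targets - universe)
    if stray:
        raise ValueError(f"target genes absent from universe: {stray[:10]}")
    n, N = len(targets), len(universe)
    names = term_names or {}
    rows = []
    for term, genes in term_map.items():
        members = set(genes) & universe
        k = len(members & targets)
        if k == 0:
            continue
        p = hypergeom_upper_tail(k, len(members), n, N)
        rows.append((term, names.get(term, ""), k, len(members), n, N, p))
    rows.sort(key=lambda r: (r[6], r[0]))
    if bh_correct and rows:
        adj = multipletests([r[6] for r in rows], method="fdr_bh")[1]
        return [EnrichmentResult(*r[:6], float(q), q < alpha)
                for r, q in zip(rows, adj)]
    return [EnrichmentResult(*r, r[6] < alpha) for r in rows]


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
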