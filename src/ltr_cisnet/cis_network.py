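"""Signed DEL-DEG cis-interaction network.

Differentially expressed LTR elements (DELs) are joined to differentially
expressed genes (DEGs) through their cis-neighborhood pairs; each resulting
edge is signed by fold-change concordance: positive when the two log2 fold
changes share a sign, negative otherwise.  With only two replicates per
group, sign concordance -- not a per-pair correlation coefficient -- is the
operational meaning of "positively/negatively correlated" here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class NetworkEdge:
    del_id: str
    deg_id: str
    del_log2fc: float
    deg_log2fc: float
    sign: str
    distance: int | None = None


def edge_sign(del_log2fc: float, deg_log2fc: float) -> str:
    product = del_log2fc * deg_log2fc
    if product == 0:
        raise ValueError("zero fold change cannot occur on DE-filtered input")
    return POSITIVE if product > 0 else NEGATIVE


def build_network(dels: Mapping[str, float],
                  degs: Mapping[str, float],
                  cis_pairs: Sequence,
                  strict: bool = False) -> list[NetworkEdge]:
    """One signed edge per cis pair whose element is a DEL and gene a DEG.

    `dels` / `degs` map feature id to log2fc (DE-passing features only).
    `cis_pairs` yields objects with element_id/gene_id (and optionally
    distance) or plain (element_id, gene_id[, distance]) tuples.  Pairs
    referencing unknown features are skipped (or raise when strict).
    """
    edges = []
    seen = set()
    for pair in cis_pairs:
        if hasattr(pair, "element_id"):
            eid, gid = pair.element_id, pair.gene_id
            dist = getattr(pair, "distance", None)
        else:
            eid, gid = pair[0], pair[1]
            dist = pair[2] if len(pair) > 2 else None
        if eid not in dels or gid not in degs:
            if strict and (eid not in dels) and (gid not in degs):
                raise KeyError(f"cis pair ({eid}, {gid}) references unknown features")
            continue
        if (eid, gid) in seen:
            continue
        seen.add((eid, gid))
        edges.append(NetworkEdge(eid, gid, dels[eid], degs[gid],
                                 edge_sign(dels[eid], degs[gid]), dist))
    edges.sort(key=lambda e: (e.del_id, e.deg_id))
    return edges


def network_summary(edges: Iterable[NetworkEdge]) -> dict[str, int]:
    edges = list(edges)
    return {
        "n_edges": len(edges),
        "n_dels": len({e.del_id for e in edges}),
        "n_degs": len({e.deg_id for e in edges}),
        "n_positive": sum(e.sign == POSITIVE for e in edges),
        "n_negative": sum(e.sign == NEGATIVE for e in edges),
    }
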