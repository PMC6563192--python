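"""Positional relationship of LTR elements to gene exons, and cis-targets.

Elements are classified against annotated exons into three categories:
``In`` (the element fully encompasses at least one exon), ``Part`` (an exon
overlaps the element boundary without being contained) and ``Stream`` (no
exon overlaps the element at all; the element is "independent").  In and
Part may co-occur for one element; Stream excludes both.

Independent (Stream) elements are then linked to putative cis-target genes:
any gene with an annotated exon (UTR or CDS) within a fixed window --
100 kb by default -- upstream or downstream of the element.  Windows are
strand-agnostic: upstream/downstream refer to genomic left/right.

All intervals here are 0-based half-open; GFF3 conversion happens in
:mod:`ltr_cisnet.cli_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

DEFAULT_WINDOW = 100_000

IN = "In"
PART = "Part"
STREAM = "Stream"


@dataclass(frozen=True)
class Exon:
    start: int
    end: int
    kind: str = "exon"   # exon | CDS | five_prime_UTR | three_prime_UTR

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty exon interval [{self.start}, {self.end})")


@dataclass
class GeneModel:
    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[Exon] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def exonic_intervals(self) -> list[Exon]:
        """Intervals counted as exon sequence.

        GFF3 dialects differ: when explicit ``exon`` features are present
        they are used; otherwise the union of CDS and UTR features stands in.
        """
        plain = [e for e in self.exons if e.kind == "exon"]
        return plain if plain else list(self.exons)


@dataclass
class PositionClass:
    element_id: str
    classes: frozenset
    no_gene_scaffold: bool = False

    def __post_init__(self):
        if not self.classes:
            raise ValueError("element must receive at least one class")
        if STREAM in self.classes and len(self.classes) > 1:
            raise ValueError("Stream is exclusive of In/Part")


@dataclass(frozen=True)
class CisPair:
    element_id: str
    gene_id: str
    distance: int
    side: str  # upstream | downstream | overlapping_window


def _genes_by_scaffold(gene_models: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        out.setdefault(g.scaffold_id, []).append(g)
    return out


def classify_position(element, gene_models: Sequence[GeneModel] | Mapping[str, list[GeneModel]]) -> PositionClass:
    """Classify one element (needs .id/.scaffold_id/.start/.end) as In/Part/Stream."""
    if isinstance(gene_models, Mapping):
        by_scaf = gene_models
    else:
        by_scaf = _genes_by_scaffold(gene_models)
    genes = by_scaf.get(element.scaffold_id)
    if not genes:
        return PositionClass(element.id, frozenset({STREAM}), no_gene_scaffold=True)
    classes = set()
    for gene in genes:
        for exon in gene.exonic_intervals():
            if exon.start >= element.end or exon.end <= element.start:
                continue  # no overlap
            if element.start <= exon.start and exon.end <= element.end:
                classes.add(IN)
            else:
                classes.add(PART)
    if not classes:
        classes = {STREAM}
    return PositionClass(element.id, frozenset(classes))


def classify_all(elements, gene_models: Sequence[GeneModel]) -> list[PositionClass]:
    by_scaf = _genes_by_scaffold(gene_models)
    return [classify_position(e, by_scaf) for e in elements]


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp gap between two half-open intervals; 0 when abutting, -1 on overlap."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return -1


def find_cis_targets(
    stream_elements,
    gene_models: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> list[CisPair]:
    """Genes with >=1 exon within `window` bp of an independent element.

    Each (element, gene) pair is reported once with the minimum exon-to-
    element distance (inclusive at the window boundary).  Raises ValueError
    if a supplied element overlaps exon sequence, i.e. is not Stream.
    """
    by_scaf = _genes_by_scaffold(gene_models)
    pairs: list[CisPair] = []
    for element in stream_elements:
        cls = classify_position(element, by_scaf)
        if STREAM not in cls.classes:
            raise ValueError(
                f"element {element.id} is {set(cls.classes)}, not Stream; "
                "only independent elements enter cis-target analysis"
            )
        for gene in by_scaf.get(element.scaffold_id, []):
            best = None
            sides = set()
            for exon in gene.exonic_intervals():
                gap = _gap(element.start, element.end, exon.start, exon.end)
                if gap < 0 or gap > window:
                    continue
                side = "upstream" if exon.end <= element.start else "downstream"
                sides.add(side)
                if best is None or gap < best:
                    best = gap
            if best is not None:
                side = sides.pop() if len(sides) == 1 else "overlapping_window"
                pairs.append(CisPair(element.id, gene.gene_id, best, side))
    pairs.sort(key=lambda p: (p.element_id, p.gene_id))
    return pairs
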