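"""Synthetic genomes with planted LTR elements, gene models and RNA-seq counts.

This module builds the controlled inputs for the rest of the pipeline:

* i.i.d. background scaffolds with configurable GC (no repeat background
  beyond the planted elements, which keeps detector false-positive analysis
  clean);
* planted LTR elements -- two direct repeat copies separated by an internal
  region, diverged by uniformly placed substitutions (avoiding the first and
  last 10 bp of each copy so boundary seeding is undegraded), flanked by an
  identical 4-6 bp target-site duplication, optionally carrying in-frame
  gag/pro/pol/env motif ORFs in the internal region;
* multi-exon gene models placed fully inside an element, straddling an
  element boundary, at an exact distance from an element, or freely;
* negative-binomial count matrices for a 2-control vs 2-infected design with
  planted log2 fold changes.

Every planted feature is returned as a truth record so that recovery can be
scored exactly.  All generation is reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_context import Exon, GeneModel
from .motifs import CODON_OF, DEFAULT_MOTIFS, back_translate

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthElement:
    """A planted LTR element, in emitted (0-based half-open) coordinates."""
    scaffold_id: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    planted_identity: float
    tsd_seq: str
    planted_domains: tuple[str, ...] = ()

    @property
    def id(self) -> str:
        return f"{self.scaffold_id}_{self.start + 1}_{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthEffect:
    feature_id: str
    planted_log2fc: float
    dispersion: float = 0.05
    baseline_mean: float = 100.0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")


@dataclass(frozen=True)
class GenePlacement:
    """Truth record of how a synthetic gene was placed."""
    gene_id: str
    kind: str                   # exon_in | exon_straddle | distance | free
    element_id: str | None = None
    distance: int | None = None
    side: str | None = None


def generate_genome(n_scaffolds: int,
                    scaffold_lengths: int | Sequence[int],
                    gc: float = 0.35,
                    seed: int = 0) -> dict[str, str]:
    """i.i.d. random scaffolds with the requested GC fraction.

    Scaffold ids are scf_1..scf_n; reproducible for a fixed seed.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    if np.isscalar(scaffold_lengths):
        lengths = [int(scaffold_lengths)] * n_scaffolds
    else:
        lengths = [int(x) for x in scaffold_lengths]
    if len(lengths) != n_scaffolds:
        raise ValueError("scaffold_lengths does not match n_scaffolds")
    if any(x < 1000 for x in lengths):
        raise ValueError("scaffold lengths must be >= 1000 bp")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: dict[str, str] = {}
    for i, length in enumerate(lengths, start=1):
        draw = rng.choice(_BASES, size=length, p=probs)
        genome[f"scf_{i}"] = draw.tobytes().decode()
    return genome


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _build_internal(rng: np.random.Generator, internal_len: int,
                    domains: Sequence[str],
                    motif_table: Mapping[str, str],
                    gap: int = 30) -> str:
    """Random internal region with one in-frame ORF per requested domain."""
    orfs = []
    for name in domains:
        if name not in motif_table:
            raise ValueError(f"unknown domain {name!r}")
        orfs.append("ATG" + back_translate(motif_table[name]) + "TAA")
    needed = gap + sum(len(o) + gap for o in orfs)
    if needed > internal_len:
        raise ValueError(
            f"internal region of {internal_len} bp cannot hold domains {list(domains)}")
    seq = list(_random_seq(rng, internal_len))
    pos = gap
    for orf in orfs:
        seq[pos:pos + len(orf)] = orf
        pos += len(orf) + gap
    return "".join(seq)


def plant_element(genome: Mapping[str, str],
                  scaffold_id: str,
                  position: int,
                  ltr_len: int = 300,
                  internal_len: int = 5000,
                  identity: float = 0.85,
                  tsd_len: int = 4,
                  domains: Sequence[str] = (),
                  seed: int = 0,
                  motif_table: Mapping[str, str] | None = None,
                  existing: Iterable[TruthElement] = (),
                  boundary_margin: int = 10) -> tuple[dict[str, str], TruthElement]:
    """Overwrite genome sequence at `position` with a planted LTR element.

    The element is written in place (the scaffold keeps its length), flanked
    on both sides by an identical randomly drawn TSD.  The 3' LTR is the 5'
    copy with substitutions placed uniformly without replacement, avoiding
    the first/last `boundary_margin` bp, so that the realised identity is
    within one substitution of the request.
    """
    if motif_table is None:
        motif_table = DEFAULT_MOTIFS
    if not 100 <= ltr_len <= 1000:
        raise ValueError("ltr_len must lie in [100, 1000]")
    if not 4 <= tsd_len <= 6:
        raise ValueError("tsd_len must lie in [4, 6]")
    if not 0 < identity <= 1:
        raise ValueError("identity must lie in (0, 1]")
    seq = genome[scaffold_id]
    elen = 2 * ltr_len + internal_len
    if position - tsd_len < 0 or position + elen + tsd_len > len(seq):
        raise ValueError(
            f"element of {elen} bp (+{tsd_len} bp TSD flanks) at {position} "
            f"overruns scaffold {scaffold_id}")
    for prev in existing:
        if prev.scaffold_id != scaffold_id:
            continue
        if position - tsd_len < prev.end + tsd_len and prev.start - tsd_len < position + elen + tsd_len:
            raise ValueError(f"element at {position} overlaps planted element {prev.id}")

    rng = np.random.default_rng(seed)
    n_sub = int(round((1 - identity) * ltr_len))
    eligible = np.arange(boundary_margin, ltr_len - boundary_margin)
    if n_sub > eligible.size:
        raise ValueError("requested divergence exceeds substitutable positions")
    ltr5 = list(_random_seq(rng, ltr_len))
    internal = list(_build_internal(rng, internal_len, domains, motif_table))
    tsd = _random_seq(rng, tsd_len)

    # Make the element boundary structurally unambiguous: a real integration
    # can admit an alternative reading in which a boundary base is traded
    # between the LTR and the TSD (or a flanking base extends the TSD).
    # Planted elements break all four score-neutral trades so that the truth
    # coordinates are the unique maximal-structure reading.
    def _differ(b: str) -> str:
        return next(c for c in "ACGT" if c != b)

    if internal[0] == tsd[0]:
        internal[0] = _differ(tsd[0])
    if internal[-1] == tsd[-1]:
        internal[-1] = _differ(tsd[-1])
    pre = seq[position - tsd_len - 1] if position - tsd_len - 1 >= 0 else None
    post = seq[position + elen + tsd_len] if position + elen + tsd_len < len(seq) else None
    if pre is not None and ltr5[-1] == pre:
        ltr5[-1] = _differ(pre)
    if post is not None and ltr5[0] == post:
        ltr5[0] = _differ(post)

    ltr3 = list(ltr5)
    for p in rng.choice(eligible, size=n_sub, replace=False):
        others = [b for b in "ACGT" if b != ltr5[p]]
        ltr3[p] = others[rng.integers(len(others))]
    ltr5 = "".join(ltr5)
    ltr3 = "".join(ltr3)
    internal = "".join(internal)

    element = ltr5 + internal + ltr3
    new_seq = (seq[:position - tsd_len] + tsd + element + tsd
               + seq[position + elen + tsd_len:])
    assert len(new_seq) == len(seq)
    out = dict(genome)
    out[scaffold_id] = new_seq
    truth = TruthElement(
        scaffold_id=scaffold_id,
        start=position, end=position + elen,
        ltr5_start=position, ltr5_end=position + ltr_len,
        ltr3_start=position + ltr_len + internal_len,
        ltr3_end=position + elen,
        planted_identity=(ltr_len - n_sub) / ltr_len,
        tsd_seq=tsd,
        planted_domains=tuple(domains),
    )
    return out, truth


# -- gene placement ---------------------------------------------------------

_EXON_LEN = 150
_INTRON_LEN = 100
_N_EXONS = 3


def _gene_span() -> int:
    return _N_EXONS * _EXON_LEN + (_N_EXONS - 1) * _INTRON_LEN


def _make_gene(gene_id: str, scaffold_id: str, strand: str, start: int) -> GeneModel:
    kinds = ["five_prime_UTR", "CDS", "three_prime_UTR"]
    if strand == "-":
        kinds.reverse()
    exons = []
    pos = start
    for kind in kinds:
        exons.append(Exon(pos, pos + _EXON_LEN, kind))
        pos += _EXON_LEN + _INTRON_LEN
    return GeneModel(gene_id, scaffold_id, strand, exons)


def _overlaps(occupied: list[tuple[str, int, int]], scaf: str, s: int, e: int) -> bool:
    return any(o_s < e and s < o_e for o_sc, o_s, o_e in occupied if o_sc == scaf)


def generate_gene_annotation(
    genome: Mapping[str, str],
    truth_elements: Sequence[TruthElement],
    n_genes: int,
    placement_spec: Sequence[Mapping] = (),
    seed: int = 0,
) -> tuple[list[GeneModel], list[GenePlacement]]:
    """Place gene models at controlled positions relative to planted elements.

    ``placement_spec`` is a list of requests, each a dict with key ``kind``:

    * ``exon_in``       -- gene fully inside the internal region of element
      ``element`` (index into truth_elements), so the element classifies In;
    * ``exon_straddle`` -- first exon crosses the element's right boundary
      (Part);
    * ``distance``      -- nearest exon at exactly ``distance`` bp from the
      element boundary on ``side`` ("left"/"right");
    * ``free``          -- unconstrained placement, optionally on scaffold
      ``scaffold``.

    Remaining genes up to ``n_genes`` are placed freely.  Raises ValueError
    when a request cannot be satisfied.
    """
    if len(placement_spec) > n_genes:
        raise ValueError("more placement requests than genes")
    rng = np.random.default_rng(seed)
    span = _gene_span()
    elem_occ: list[tuple[str, int, int]] = [
        (t.scaffold_id, t.start - 6, t.end + 6) for t in truth_elements
    ]
    gene_occ: list[tuple[str, int, int]] = []
    genes: list[GeneModel] = []
    placements: list[GenePlacement] = []

    def place(gene_id: str, scaf: str, start: int, truth: GenePlacement,
              allow_element_overlap: bool = False) -> None:
        if start < 0 or start + span > len(genome[scaf]):
            raise ValueError(f"gene {gene_id} does not fit on scaffold {scaf}")
        if _overlaps(gene_occ, scaf, start, start + span):
            raise ValueError(f"no room for gene {gene_id} at {scaf}:{start}")
        if not allow_element_overlap and _overlaps(elem_occ, scaf, start, start + span):
            raise ValueError(f"gene {gene_id} at {scaf}:{start} would hit an element")
        strand = "+" if rng.integers(2) == 0 else "-"
        genes.append(_make_gene(gene_id, scaf, strand, start))
        gene_occ.append((scaf, start, start + span))
        placements.append(truth)

    requests = list(placement_spec) + [{"kind": "free"}] * (n_genes - len(placement_spec))
    for i, req in enumerate(requests, start=1):
        gene_id = f"gene_{i:04d}"
        kind = req.get("kind", "free")
        if kind in {"exon_in", "exon_straddle", "distance"}:
            elem = truth_elements[req["element"]]
            scaf = elem.scaffold_id
            if kind == "exon_in":
                start = elem.ltr5_end + (elem.ltr3_start - elem.ltr5_end) // 2
                if start + span > elem.ltr3_start:
                    start = elem.ltr3_start - span
                if start < elem.ltr5_end:
                    raise ValueError(
                        f"internal region of {elem.id} too small for a gene")
                place(gene_id, scaf, start,
                      GenePlacement(gene_id, kind, elem.id),
                      allow_element_overlap=True)
            elif kind == "exon_straddle":
                start = elem.end - _EXON_LEN // 2
                place(gene_id, scaf, start,
                      GenePlacement(gene_id, kind, elem.id),
                      allow_element_overlap=True)
            else:
                dist = int(req["distance"])
                side = req.get("side", "right")
                if dist < 0:
                    raise ValueError("distance must be >= 0")
                if side == "right":
                    start = elem.end + dist
                elif side == "left":
                    start = elem.start - dist - span
                else:
                    raise ValueError(f"bad side {side!r}")
                place(gene_id, scaf, start,
                      GenePlacement(gene_id, kind, elem.id, dist, side))
        elif kind == "free":
            scaf = req.get("scaffold")
            for _ in range(200):
                sc = scaf or sorted(genome)[rng.integers(len(genome))]
                start = int(rng.integers(0, len(genome[sc]) - span))
                try:
                    place(gene_id, sc, start, GenePlacement(gene_id, "free"))
                    break
                except ValueError:
                    continue
            else:
                raise ValueError(f"could not place free gene {gene_id}")
        else:
            raise ValueError(f"unknown placement kind {kind!r}")
    return genes, placements


# -- count simulation -------------------------------------------------------

def simulate_counts(feature_lens: Mapping[str, int],
                    control_samples: Sequence[str],
                    infected_samples: Sequence[str],
                    effects: Sequence[TruthEffect] = (),
                    library_sizes: Mapping[str, float] | float = 2e7,
                    seed: int = 0,
                    default_dispersion: float = 0.05,
                    default_baseline: float = 100.0) -> pd.DataFrame:
    """Negative-binomial counts for a two-group replicated design.

    Per feature f and sample s the mean is

        mu = baseline_f * (len_f / 1 kb) * (lib_s / 1e6) * 2**(lfc_f * infected_s)

    with NB variance mu + dispersion_f * mu**2.  Features without an
    explicit TruthEffect get log2fc 0 at the default baseline/dispersion.
    """
    samples = list(control_samples) + list(infected_samples)
    if np.isscalar(library_sizes):
        lib = {s: float(library_sizes) for s in samples}
    else:
        lib = {s: float(library_sizes[s]) for s in samples}
    if any(v <= 0 for v in lib.values()):
        raise ValueError("library sizes must be > 0")
    by_id = {}
    for eff in effects:
        if eff.feature_id not in feature_lens:
            raise ValueError(f"effect for unknown feature {eff.feature_id!r}")
        by_id[eff.feature_id] = eff
    rng = np.random.default_rng(seed)
    rows = {}
    for fid in feature_lens:
        eff = by_id.get(fid, TruthEffect(fid, 0.0, default_dispersion, default_baseline))
        length = feature_lens[fid]
        if length <= 0:
            raise ValueError(f"feature {fid!r} has non-positive length")
        row = []
        for s in samples:
            infected = s in infected_samples
            mu = (eff.baseline_mean * (length / 1000.0) * (lib[s] / 1e6)
                  * 2.0 ** (eff.planted_log2fc if infected else 0.0))
            n = 1.0 / eff.dispersion
            row.append(rng.negative_binomial(n, n / (n + mu)))
        rows[fid] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples).astype(int)


# -- whole-study generator --------------------------------------------------

@dataclass
class SimulationConfig:
    """Default study conditions for an end-to-end synthetic run."""
    n_scaffolds: int = 3
    scaffold_length: int = 150_000
    gc: float = 0.35
    # one spec per planted element: (scaffold index, ltr_len, internal_len,
    # identity, tsd_len, domains)
    elements: tuple = (
        (0, 300, 4000, 0.90, 4, ("gag", "pol")),
        (0, 250, 3000, 0.88, 5, ("pol",)),
        (1, 350, 5000, 0.92, 4, ("gag", "pro", "pol", "env")),
        (1, 200, 2500, 0.86, 6, ()),
        (2, 300, 3500, 0.90, 4, ("pol",)),
    )
    n_genes: int = 24
    window: int = 100_000
    control_samples: tuple = ("CK1", "CK2")
    infected_samples: tuple = ("NPV1", "NPV2")
    library_size: float = 2e7
    dispersion: float = 0.05


@dataclass
class SyntheticStudy:
    genome: dict[str, str]
    truth_elements: list[TruthElement]
    genes: list[GeneModel]
    placements: list[GenePlacement]
    counts: pd.DataFrame
    feature_lens: dict[str, int]
    effects: list[TruthEffect]
    config: SimulationConfig


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a complete synthetic study: genome, elements, genes, counts."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    genome = generate_genome(cfg.n_scaffolds, cfg.scaffold_length, cfg.gc,
                             seed=int(rng.integers(2**31)))
    truths: list[TruthElement] = []
    cursor = {f"scf_{i+1}": 30_000 for i in range(cfg.n_scaffolds)}
    for scaf_i, ltr_len, internal_len, identity, tsd_len, domains in cfg.elements:
        scaf = f"scf_{scaf_i + 1}"
        pos = cursor[scaf]
        genome, t = plant_element(
            genome, scaf, pos, ltr_len, internal_len, identity, tsd_len,
            domains, seed=int(rng.integers(2**31)), existing=truths)
        truths.append(t)
        cursor[scaf] = t.end + 10_000
    spec = [
        {"kind": "exon_in", "element": 0},
        {"kind": "exon_straddle", "element": 1},
        {"kind": "distance", "element": 2, "distance": 5_000, "side": "right"},
        {"kind": "distance", "element": 2, "distance": 99_000, "side": "right"},
        {"kind": "distance", "element": 4, "distance": 20_000, "side": "left"},
    ]
    genes, placements = generate_gene_annotation(
        genome, truths, cfg.n_genes, spec, seed=int(rng.integers(2**31)))

    feature_lens = {g.gene_id: sum(e.end - e.start for e in g.exons) for g in genes}
    for t in truths:
        feature_lens[t.id] = t.length
    ids = sorted(feature_lens)
    effects = []
    for i, fid in enumerate(ids):
        if i % 3 == 0:
            lfc = float(rng.choice([-3.0, -2.0, 2.0, 3.0]))
        else:
            lfc = 0.0
        effects.append(TruthEffect(fid, lfc, cfg.dispersion,
                                   baseline_mean=float(rng.uniform(50, 500))))
    counts = simulate_counts(
        feature_lens, cfg.control_samples, cfg.infected_samples, effects,
        cfg.library_size, seed=int(rng.integers(2**31)),
        default_dispersion=cfg.dispersion)
    return SyntheticStudy(genome, truths, genes, placements, counts,
                          feature_lens, effects, cfg)
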