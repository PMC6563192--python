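"""Structural detection of LTR retrotransposons by paired-repeat search.

An LTR retrotransposon candidate is a pair of direct (same-strand) repeats
-- the two long terminal repeats -- whose inner separation lies in a
configurable range (1-15 kb by default), whose pairwise identity under a
global alignment is at least 80%, and which is flanked by an exact 4-6 bp
target-site duplication (TSD).  Candidates whose internal region encodes at
least one protein domain (gag/pro/pol/env motif in any of the six reading
frames) are categorised ``full_length``; candidates lacking all domains are
``solo``.

The search seeds on exact k-mer matches between forward-strand positions,
groups seeds by repeat offset, grows each seed cluster to the maximal
scoring ungapped segment (match +1, mismatch -1), and then refines the
element boundaries by scanning a small window for flanking TSDs, ranking
refinements by (ungapped identity, TSD length, smaller shift).  The final
reported identity comes from the global affine-gap alignment of the two
refined LTR copies.  Overlapping candidates are resolved deterministically:
highest identity, then longer element, then leftmost start.

Coordinates are 0-based half-open throughout; element ids follow the
``<scaffold>_<start1>_<end>`` convention with 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from ._alignment import global_identity
from .motifs import DEFAULT_MOTIFS

FULL_LENGTH = "full_length"
SOLO = "solo"


@dataclass(frozen=True)
class DomainHit:
    domain: str
    start: int       # genomic, 0-based half-open
    end: int
    frame: int       # +1,+2,+3,-1,-2,-3 relative to the forward strand


@dataclass
class LTRElement:
    """A detected (or truth-derived) LTR retrotransposon."""

    scaffold_id: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    ltr_identity: float
    tsd: str | None = None
    domain_hits: list[DomainHit] = field(default_factory=list)
    category: str | None = None

    def __post_init__(self):
        if not (self.start <= self.ltr5_start < self.ltr5_end
                <= self.ltr3_start < self.ltr3_end <= self.end):
            raise ValueError(f"inconsistent LTR intervals in {self.id}")

    @property
    def id(self) -> str:
        return f"{self.scaffold_id}_{self.start + 1}_{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def separation(self) -> int:
        """Inner distance between the two LTR copies (bp)."""
        return self.ltr3_start - self.ltr5_end


@dataclass(frozen=True)
class DetectionParams:
    min_ltr_len: int = 100
    max_ltr_len: int = 1000
    min_sep: int = 1000
    max_sep: int = 15000
    min_identity: float = 0.80
    tsd_len_range: tuple[int, int] = (4, 6)
    require_tsd: bool = True
    seed_k: int = 12
    refine_window: int = 30
    max_kmer_occurrences: int = 100

    def __post_init__(self):
        if self.min_sep >= self.max_sep:
            raise ValueError("min_sep must be < max_sep")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")
        if self.min_ltr_len < self.seed_k:
            raise ValueError("min_ltr_len must be >= seed_k")

    @property
    def min_element_len(self) -> int:
        return 2 * self.min_ltr_len + self.min_sep

    @property
    def max_element_len(self) -> int:
        return 2 * self.max_ltr_len + self.max_sep


def compute_ltr_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity between two LTR copies (symmetric)."""
    if not seq_a or not seq_b:
        raise ValueError("LTR identity requires two non-empty sequences")
    return global_identity(seq_a.upper(), seq_b.upper())


def detect_tsd(genome: Mapping[str, str], element: LTRElement,
               tsd_len_range: tuple[int, int] = (4, 6)) -> str | None:
    """Longest exact duplication flanking the element, or None.

    Scans lengths from max(tsd_len_range) down to min; the copies must
    immediately flank [start, end).  At a scaffold edge with no flank room
    the result is None.
    """
    seq = genome[element.scaffold_id]
    return _tsd_at(seq, element.start, element.end, tsd_len_range)


def _tsd_at(seq: str, start: int, end: int,
            tsd_len_range: tuple[int, int]) -> str | None:
    lo, hi = tsd_len_range
    for t in range(hi, lo - 1, -1):
        if start - t < 0 or end + t > len(seq):
            continue
        left = seq[start - t:start]
        if left == seq[end:end + t]:
            return left
    return None


def _seed_pairs(arr: np.ndarray, params: DetectionParams) -> dict[int, list[int]]:
    """Exact k-mer seed start positions of repeat pairs, grouped by offset."""
    k = params.seed_k
    n = arr.size
    if n < k:
        return {}
    # pack each k-mer into an integer key (2 bits/base would need clean ACGT;
    # use a rolling hash over the raw byte values instead, then verify)
    seen: dict[bytes, list[int]] = {}
    data = arr.tobytes()
    for i in range(n - k + 1):
        seen.setdefault(data[i:i + k], []).append(i)
    d_lo = params.min_ltr_len + params.min_sep - params.refine_window
    d_hi = params.max_ltr_len + params.max_sep + params.refine_window
    by_offset: dict[int, list[int]] = {}
    for positions in seen.values():
        if len(positions) < 2 or len(positions) > params.max_kmer_occurrences:
            continue
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if d_lo <= d <= d_hi:
                    by_offset.setdefault(d, []).append(positions[ai])
    return by_offset


def _max_scoring_segment(score: np.ndarray) -> tuple[int, int, int]:
    """Kadane: (start, end, score) of the maximal-sum contiguous segment."""
    best = (-1, 0, 0)   # score, start, end
    run = 0
    run_start = 0
    for i, s in enumerate(score):
        if run <= 0:
            run = 0
            run_start = i
        run += int(s)
        if run > best[0]:
            best = (run, run_start, i + 1)
    return best[1], best[2], best[0]


def _refine_candidate(seq: str, arr: np.ndarray, d: int, ks: int, ke: int,
                      params: DetectionParams):
    """Scan boundary shifts around a Kadane segment for a TSD-flanked element.

    Returns (s1, e1, tsd, hamming_identity) of the best refinement or None.
    Ranking: ungapped alignment score of the repeat pair (match +1,
    mismatch -1) plus the TSD length, then the shorter LTR, then leftmost.
    Extending a boundary over background has negative expected score, while
    shifting it into the TSD trades one TSD base for at best one chance
    match, so the planted boundary is a strict or tie-broken winner.
    """
    w = params.refine_window
    n = arr.size
    lo_s = max(0, ks - w)
    hi_s = min(ks + w, n - 1)
    lo_e = max(ke - w, lo_s + 1)
    hi_e = min(ke + w, n - d)
    if lo_e > hi_e:
        return None
    # prefix sums of the ungapped match indicator at this offset
    span_lo = lo_s
    span_hi = hi_e
    m = (arr[span_lo:span_hi] == arr[span_lo + d:span_hi + d]).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(m)])
    best = None
    for s1 in range(lo_s, hi_s + 1):
        for e1 in range(max(lo_e, s1 + params.min_ltr_len), hi_e + 1):
            ltr_len = e1 - s1
            if ltr_len > params.max_ltr_len:
                break
            sep = d - ltr_len
            if not (params.min_sep <= sep <= params.max_sep):
                continue
            tsd = _tsd_at(seq, s1, e1 + d, params.tsd_len_range)
            if params.require_tsd and tsd is None:
                continue
            matches = int(csum[e1 - span_lo] - csum[s1 - span_lo])
            ham = matches / ltr_len
            key = (2 * matches - ltr_len + (len(tsd) if tsd else 0), -ltr_len, -s1)
            if best is None or key > best[0]:
                best = (key, s1, e1, tsd, ham)
    if best is None:
        return None
    _, s1, e1, tsd, ham = best
    return s1, e1, tsd, ham


def _resolve_overlaps(elements: list[LTRElement]) -> list[LTRElement]:
    """Keep highest identity, then longer, then leftmost among overlaps."""
    ranked = sorted(elements,
                    key=lambda e: (-e.ltr_identity, -e.length, e.start, e.scaffold_id))
    kept: list[LTRElement] = []
    for cand in ranked:
        clash = any(k.scaffold_id == cand.scaffold_id
                    and cand.start < k.end and k.start < cand.end
                    for k in kept)
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda e: (e.scaffold_id, e.start))
    return kept


def find_ltr_pairs(genome: Mapping[str, str],
                   params: DetectionParams | None = None) -> list[LTRElement]:
    """Detect candidate LTR elements in a genome (domains not yet annotated)."""
    params = params or DetectionParams()
    min_score = max(params.seed_k,
                    int(0.5 * params.min_ltr_len * (2 * params.min_identity - 1)))
    found: list[LTRElement] = []
    for scaffold_id in sorted(genome):
        seq = genome[scaffold_id].upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for d, starts in sorted(_seed_pairs(arr, params).items()):
            starts = sorted(set(starts))
            # split seed runs separated by more than one LTR length
            clusters: list[list[int]] = [[starts[0]]]
            for pos in starts[1:]:
                if pos - clusters[-1][-1] > params.max_ltr_len:
                    clusters.append([pos])
                else:
                    clusters[-1].append(pos)
            for cluster in clusters:
                w0 = max(0, cluster[0] - params.max_ltr_len)
                w1 = min(arr.size - d, cluster[-1] + params.seed_k + params.max_ltr_len)
                if w1 <= w0:
                    continue
                match = (arr[w0:w1] == arr[w0 + d:w1 + d])
                score = np.where(match, 1, -1)
                ks, ke, sc = _max_scoring_segment(score)
                if sc < min_score:
                    continue
                refined = _refine_candidate(seq, arr, d, w0 + ks, w0 + ke, params)
                if refined is None:
                    continue
                s1, e1, tsd, _ham = refined
                identity = compute_ltr_identity(seq[s1:e1], seq[s1 + d:e1 + d])
                if identity < params.min_identity:
                    continue
                elem = LTRElement(
                    scaffold_id=scaffold_id,
                    start=s1, end=e1 + d,
                    ltr5_start=s1, ltr5_end=e1,
                    ltr3_start=s1 + d, ltr3_end=e1 + d,
                    ltr_identity=identity, tsd=tsd,
                )
                if params.min_element_len <= elem.length <= params.max_element_len:
                    found.append(elem)
    return _resolve_overlaps(found)


_FRAMES = (1, 2, 3, -1, -2, -3)


def annotate_domains(genome: Mapping[str, str], element: LTRElement,
                     motif_table: Mapping[str, str] | None = None) -> LTRElement:
    """Scan the internal region's six reading frames for domain motifs.

    A motif hit requires the peptide to occur without interruption by a stop
    codon in that frame.  Sets ``category`` to ``full_length`` iff at least
    one domain is found, else ``solo``.
    """
    if motif_table is None:
        motif_table = DEFAULT_MOTIFS
    if not motif_table:
        raise ValueError("empty motif table")
    internal = genome[element.scaffold_id][element.ltr5_end:element.ltr3_start].upper()
    hits: list[DomainHit] = []
    n = len(internal)
    for frame in _FRAMES:
        if frame > 0:
            off = frame - 1
            frame_seq = internal[off:]
        else:
            off = -frame - 1
            frame_seq = str(Seq(internal).reverse_complement())[off:]
        frame_seq = frame_seq[:len(frame_seq) - len(frame_seq) % 3]
        if not frame_seq:
            continue
        peptide = str(Seq(frame_seq).translate())
        for domain, motif in motif_table.items():
            pos = peptide.find(motif)
            while pos != -1:
                nt_a = off + 3 * pos
                nt_b = nt_a + 3 * len(motif)
                if frame > 0:
                    g_start = element.ltr5_end + nt_a
                    g_end = element.ltr5_end + nt_b
                else:
                    g_start = element.ltr5_end + (n - nt_b)
                    g_end = element.ltr5_end + (n - nt_a)
                hits.append(DomainHit(domain, g_start, g_end, frame))
                pos = peptide.find(motif, pos + 1)
    hits.sort(key=lambda h: (h.start, h.domain))
    return replace(element, domain_hits=hits,
                   category=FULL_LENGTH if hits else SOLO)


def detect(genome: Mapping[str, str],
           params: DetectionParams | None = None,
           motif_table: Mapping[str, str] | None = None) -> list[LTRElement]:
    """find_ltr_pairs + domain annotation in one call."""
    return [annotate_domains(genome, e, motif_table)
            for e in find_ltr_pairs(genome, params)]
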