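"""Fusion-peptide and furin cleavage-site scanning of env-like ORFs.

Insect endogenous retroviruses with a functional envelope carry, in the env
glycoprotein, a basic furin cleavage site (consensus R-x-x-R) immediately
upstream of a membrane-fusion peptide whose degenerate consensus is

    G-x(5)-G-x(3)-K-x(3)-G-x(2)-D-x(2)-D

shared with the F proteins of group II nucleopolyhedroviruses.  This module
finds ORFs in nucleotide sequences, scans translated peptides for the fusion
consensus, and classifies the upstream furin site as ``complete`` (both
anchor arginines present), ``incomplete`` (exactly one anchor), or
``absent``.  An env protein with a fusion hit and a complete furin site is
called fusion-competent.

Fixed consensus positions never match the ambiguity code X; all ``x``
positions are unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Seq import Seq

#: offsets of the fixed residues within the 21-aa fusion-peptide consensus
FUSION_FIXED = {0: "G", 6: "G", 10: "K", 14: "G", 17: "D", 20: "D"}
FUSION_LEN = 21
FURIN_LEN = 4
DEFAULT_FURIN_WINDOW = 30

_AA = set("ACDEFGHIKLMNPQRSTVWYX*")
_DNA = set("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif: str                   # fusion_peptide | furin
    start: int                   # 0-based aa offset
    matched_seq: str
    furin_status: str | None = None   # complete | incomplete | absent


@dataclass(frozen=True)
class Orf:
    frame: int                   # +1,+2,+3,-1,-2,-3
    start: int                   # nt interval on the forward strand, half-open
    end: int
    peptide: str


def find_orfs(dna: str, min_len_aa: int = 50) -> list[Orf]:
    """All maximal start-to-stop ORFs of >= min_len_aa residues, six frames.

    An ORF runs from the first ATG of a stop-delimited segment to the next
    in-frame stop codon (the stop is required and not part of the peptide).
    Intervals are reported on the forward strand; for minus-strand frames
    the interval covers the ORF's reverse-complement footprint.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    dna = dna.upper()
    bad = set(dna) - _DNA
    if bad:
        raise ValueError(f"non-IUPAC DNA characters: {sorted(bad)}")
    n = len(dna)
    rc = str(Seq(dna).reverse_complement())
    out: list[Orf] = []
    for strand, seq in ((1, dna), (-1, rc)):
        for off in range(3):
            frame = strand * (off + 1)
            trimmed = seq[off:off + ((n - off) // 3) * 3]
            if not trimmed:
                continue
            peptide = str(Seq(trimmed).translate())
            seg_start = 0
            for i, aa in enumerate(peptide + "*"):
                if aa != "*":
                    continue
                segment = peptide[seg_start:i]
                has_stop = i < len(peptide)
                m = segment.find("M")
                if has_stop and m != -1:
                    orf_pep = segment[m:]
                    if len(orf_pep) >= min_len_aa:
                        aa_start = seg_start + m
                        nt_a = off + 3 * aa_start
                        nt_b = off + 3 * (i + 1)     # include the stop codon
                        if strand == 1:
                            s, e = nt_a, nt_b
                        else:
                            s, e = n - nt_b, n - nt_a
                        out.append(Orf(frame, s, e, orf_pep))
                seg_start = i + 1
    out.sort(key=lambda o: (o.start, o.end, o.frame))
    return out


def scan_fusion_motif(peptide: str, protein_id: str = "") -> list[MotifHit]:
    """All offsets where the fusion-peptide consensus matches."""
    peptide = peptide.upper()
    hits = []
    for i in range(len(peptide) - FUSION_LEN + 1):
        window = peptide[i:i + FUSION_LEN]
        if all(window[p] == aa for p, aa in FUSION_FIXED.items()):
            hits.append(MotifHit(protein_id, "fusion_peptide", i, window))
    return hits


def scan_furin_site(peptide: str, fusion_hit: MotifHit | int,
                    search_window_aa: int = DEFAULT_FURIN_WINDOW,
                    protein_id: str = "") -> MotifHit:
    """Classify the furin site immediately upstream of a fusion hit.

    Scans RxxR frames whose last residue falls within `search_window_aa`
    residues upstream of the fusion peptide (window truncated at the peptide
    start).  ``complete``: both anchor arginines; ``incomplete``: exactly
    one anchor in an otherwise aligned site; ``absent`` otherwise.  The site
    nearest the fusion peptide wins.
    """
    if search_window_aa < 4:
        raise ValueError("search_window_aa must be >= 4")
    peptide = peptide.upper()
    fusion_start = fusion_hit.start if isinstance(fusion_hit, MotifHit) else int(fusion_hit)
    lo = max(0, fusion_start - search_window_aa)
    partial = None
    for i in range(fusion_start - FURIN_LEN, lo - 1, -1):
        if i < 0:
            break
        site = peptide[i:i + FURIN_LEN]
        n_anchor = (site[0] == "R") + (site[3] == "R")
        if n_anchor == 2:
            return MotifHit(protein_id, "furin", i, site, "complete")
        if n_anchor == 1 and partial is None:
            partial = MotifHit(protein_id, "furin", i, site, "incomplete")
    if partial is not None:
        return partial
    return MotifHit(protein_id, "furin", max(0, fusion_start - FURIN_LEN),
                    peptide[max(0, fusion_start - FURIN_LEN):fusion_start],
                    "absent")


def scan_env_protein(protein_id: str, peptide: str,
                     search_window_aa: int = DEFAULT_FURIN_WINDOW) -> list[MotifHit]:
    """Fusion hits plus the furin assessment for each; empty if no fusion."""
    hits: list[MotifHit] = []
    for fh in scan_fusion_motif(peptide, protein_id):
        hits.append(fh)
        hits.append(scan_furin_site(peptide, fh, search_window_aa, protein_id))
    return hits


def is_fusion_competent(hits: Iterable[MotifHit]) -> bool:
    """True iff there is a fusion hit with a complete upstream furin site."""
    hits = list(hits)
    has_fusion = any(h.motif == "fusion_peptide" for h in hits)
    has_furin = any(h.motif == "furin" and h.furin_status == "complete" for h in hits)
    return has_fusion and has_furin
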