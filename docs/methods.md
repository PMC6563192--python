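# Methods

## Element model and detection

An LTR retrotransposon candidate is modelled as two direct (same-strand)
repeats — the 5' and 3' long terminal repeats — separated by an internal
region, flanked by an exact target-site duplication (TSD). Defaults follow
the structure observed for full-length elements in saturniid genomes: LTR
length 100–1000 bp, inner separation ("separated by 1–15 kb" is read as the
distance between the 3' end of the 5' LTR and the start of the 3' LTR;
element-length bounds 1100–16100 bp follow from it), pairwise LTR identity
≥ 0.80, TSD length 4–6 bp. All internal coordinates are 0-based half-open;
GFF3 emission converts to 1-based inclusive, and round-trip tests pin both
conventions.

Detection proceeds in four steps:

1. **Seeding.** Exact k-mer matches (k = 12) between forward-strand
   positions are grouped by repeat offset *d*; k-mers occurring more than
   100 times are skipped. Within an offset, seed runs separated by more
   than one maximal LTR length form separate clusters.
2. **Ungapped growth.** Around each cluster the per-position match
   indicator at offset *d* is scored +1/−1 and the maximal-scoring segment
   (Kadane) is taken. Segments scoring below
   `max(k, 0.5·min_ltr_len·(2·min_identity−1))` are dropped; background
   matches drift at −0.5/bp, so random sequence essentially never reaches
   this bar (zero detections on 1 Mb of i.i.d. background is checked per
   seed batch).
3. **TSD-anchored boundary refinement.** Start and end are scanned over a
   ±30 bp window; each candidate must carry a flanking exact TSD
   (longest length in range wins at a fixed boundary). Candidates are
   ranked by *ungapped score + TSD length*, then shorter LTR, then
   leftmost. The score term is the decisive design choice: extending a
   boundary over background loses ~0.5/bp, and shifting it into the TSD
   trades one TSD base for at best one chance-matching column, so the true
   boundary wins outright or on the shorter-LTR tie-break. Ranking by
   identity fraction instead is subtly wrong — trimming an
   exactly-matching boundary column *raises* the fraction.
4. **Identity and overlap resolution.** The reported identity is
   matches/columns of a global affine-gap alignment of the two refined
   copies (match +1, mismatch −1, gap open −2, gap extend −1; a first gap
   column costs 3). Among co-optimal alignments the one with most matches,
   then fewest columns, defines the identity, which makes it a
   deterministic and symmetric function of the two sequences; the DP runs
   on a single int64 per cell encoding (score, matches, columns) in a
   mixed radix so plain `max` realises the lexicographic objective, and is
   row-vectorised with a prefix-maximum trick for the horizontal gap
   state. Overlapping candidates are resolved deterministically: highest
   identity, then longer element, then leftmost.

Domain annotation translates the internal region in all six frames and
searches fixed peptide motifs (one per domain: gag, pro, pol, env); a stop
codon inside the motif's frame voids the hit. An element with ≥ 1 hit is
`full_length`, otherwise `solo` (the solo definition here is an LTR pair
lacking internal domains, not an orphan single LTR). Profile-HMM domain
search is intentionally out of scope; the motif table is configurable.

## Positional classes and cis-targets

Classification is exon-based: `In` requires an exon fully inside the
element, `Part` an exon overlapping without containment, `Stream` no exon
overlap at all (introns never create `Part`); `In` and `Part` can co-occur
for one element, and elements on gene-free scaffolds are flagged. Windows
for cis-targets are strand-agnostic (upstream/downstream mean genomic
left/right), distance is measured exon-to-element with the 100-kb boundary
inclusive, and each (element, gene) pair is reported once with its minimum
distance. When a GFF3 provides explicit `exon` features those are used;
otherwise the union of CDS and UTR features stands in. Only `Stream`
elements enter cis-target analysis.

## Expression model

FPKM is `count·10⁹/(len·lib)` with the library size defaulting to the
column sum. Reported fold change is
`log2(max(mean_infected, 0.001)/max(mean_control, 0.001))`; the 0.001
floor mirrors the smallest values the reference dataset prints and keeps
zero means finite. One bundled row (AY_1247) prints a floored control mean,
so its printed fold change cannot be reproduced from the printed means;
it is excluded from exact-reproduction checks.

P-values come from a two-group negative-binomial exact test: counts are
scaled to the geometric-mean library size, group sums are modelled as NB
with size n_rep/φ, and the double tail sums all splits of the total no more
likely than the observed one. The common dispersion φ is pooled across
features by method of moments (`Σ(s²−m)/Σm²`, floored at 10⁻⁴) — with two
replicates per group, per-feature dispersion is not estimable. BH-FDR is
applied jointly over whatever feature set is tested together; features
with all-zero counts are removed before testing and before correction. A
call requires all three gates: |log₂FC| > 1, FDR < 0.05, and replicate
consistency (both infected FPKMs on the same side of both controls).

The replicate-consistency filter and the fold-change floor are the two
places where this stage deliberately departs from a stock GLM workflow:
the fold changes printed in the reference tables are plain ratios of mean
FPKMs, and the consistency rule reproduces the published removal of
elements with discordant replicates.

## Network and enrichment

An edge joins a DEL to a DEG through a cis pair; its sign is fold-change
concordance. With n = 2 per group a per-pair correlation coefficient is
not estimable, and concordance exactly reproduces the published 9
positive / 14 negative split over 7 DELs and 23 DEGs, so concordance is
the operational definition here. A zero fold change cannot occur on
DE-filtered input and is rejected.

Enrichment is the upper-tail hypergeometric probability P(X ≥ k) via
scipy's log-space survival function, significant at raw p < 0.05 with no
multiple-testing correction by default (a BH option exists). The universe
defaults to all annotated genes, configurable.

## env motif scanning

The fusion-peptide consensus is matched with fixed residues only at its six
literal positions (G, G, K, G, D, D); all x positions are unconstrained and
the ambiguity code X never matches a fixed position. The furin site is
sought in a 30-aa window immediately upstream of a fusion hit (the distance
between the two motifs is not fixed by the biology available here, so the
window is a configurable default): `complete` if an R-x-x-R frame matches,
`incomplete` if exactly one anchor arginine matches in an otherwise aligned
frame, `absent` otherwise; nearest-to-fusion wins and complete beats a
nearer incomplete. ORFs are maximal start-to-stop reading frames (first ATG
per stop-delimited segment, stop required) over all six frames.

## Synthetic data

The generator emulates the study conditions at desk scale: i.i.d.
background with configurable GC (0.35 by default, AT-rich as in
lepidopteran genomes) and no repeats beyond the planted elements, which
keeps false-positive analysis clean. Planted elements draw LTR length,
separation and identity from the detector's admissible ranges; divergence
is substitution-only, placed uniformly while avoiding the TSD and the
first/last 10 bp of each LTR copy so boundary seeding is undegraded. Domain
ORFs are deterministic back-translations of the motif table embedded
in-frame in the internal region; the env motif embeds a complete furin site
plus the fusion consensus so the env-scan stage is exercised end to end.

Two emulation choices matter for interpreting test results. First, planted
boundaries are made structurally unambiguous: the four boundary-adjacent
bases are adjusted so that no alternative reading trades a TSD base against
a chance-matching LTR column with equal structural score. Real
integrations can be genuinely ambiguous at 1–2 bp, so exact-boundary
recovery rates on synthetic data are an upper bound for real genomes.
Second, substitution-only divergence means Hamming and alignment identity
coincide, which is what lets an all-substring-pair Hamming oracle serve as
an independent check of the seeded detector; indel-diverged LTRs would be
found (the final identity is alignment-based) but are not part of the
planted truth.

Counts follow NB(mean, φ) with mean
`baseline·(len/1 kb)·(lib/10⁶)·2^(lfc·infected)`; defaults (baseline
50–500, φ = 0.05, library 2·10⁷) give count depths comparable to a
moderately sequenced insect RNA-seq library. The 2-vs-2 design matches the
study layout. Simulations in the test suite use 200–500 features per
operating-characteristic estimate and 50 planted-genome fixtures of 30 kb
per recovery estimate; the brute-force detector oracle runs on 3.5-kb
scaffolds with proportionally scaled length/separation parameters
(LTR 100–150 bp, separation 200–800 bp), the scale at which exhaustive
enumeration is tractable.

## Known limitations

* No nested or strand-reversed elements; only direct repeats are sought.
* No primer-binding-site / polypurine-tract prediction, no RT-based
  superfamily classification, no HMM domain models.
* The NB exact test assumes equal within-group library sizes after
  normalisation and a single common dispersion; with 2 replicates per
  group this is the best supportable model, and the null behaviour it
  yields is conservative.
* The synthetic background is i.i.d.; real genomes contain repeat families
  that would stress overlap resolution in ways these tests do not probe.
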