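# Methods

This note records the exact definitions, parameter choices and numerical
conventions implemented by the package, and what the synthetic-data
generator does and does not emulate.

## Tags and strand assignment

A **tag** represents one sequenced fragment: an aligned read pair counted
once, or an aligned singleton read. Libraries follow the **fr-secondstrand**
convention, so the fragment strand is the alignment strand of R1; for an
R2-only singleton it is the opposite of R2's alignment strand. Records
sharing a query name are joined into one tag; more than two alignments per
name is a hard error (multi-mapped input must be excluded upstream), and a
pair whose mates map to different scaffolds is represented by R1 alone with
a logged warning.

## Union-mode counting

Per scaffold, gene exon unions (merged exon blocks over all of a gene's
transcripts) are indexed in interval trees. For each tag the candidate genes
are those whose exon union overlaps any tag segment, filtered by strand —
the **sense** layer is tried first, then **antisense**. Within a layer:

- two or more candidate genes → the tag is **ambiguous** and counted for none;
- one candidate → assigned only if *every* aligned segment overlaps that
  gene's exon union, otherwise **unassigned** (e.g. a segment falling wholly
  inside an intron);
- no candidate in either layer → unassigned.

This yields the conservation identity used throughout the tests:
`sense + antisense + ambiguous + unassigned = total tags`.

## Library summary and method comparison

"Properly paired" requires both mates mapped to the same scaffold on
opposing strands with 3′ ends innermost and an inner mate distance within
`insert_mean ± 10·insert_sd` (defaults 0 ± 1000); each proper pair counts
two reads. Method comparison computes, per biological pair, the
percent-aligned difference (polyA − ribozero) from *unrounded* counts, then
its mean and median, plus the median aligned-read count over all libraries.

## rRNA accounting

rRNA sense totals are reported as percentages of total aligned tags;
non-rRNA sense counts are sense-assigned minus rRNA. All printed
percentages use two decimals with **round half away from zero**
(`decimal.ROUND_HALF_UP`), matching the published tables.

## Intron validation

Unique introns are the gaps between consecutive exons of each transcript,
deduplicated on (scaffold, strand, interval) with transcript contexts
(ordinal in transcription order) merged. Junctions are `N` gaps in spliced
alignments, keyed by fragment strand, with a minimum flanking-block overhang
(default 1). An intron is fully supported by junctions matching its
interval and strand exactly; validated-at-k means full support ≥ k
(thresholds 1 and 10, so validated-at-10 ⊆ validated-at-1). With zero full
support, a junction sharing only the donor coordinate gives class
**5′-only** (the acceptor is suspect); sharing only the acceptor gives
**3′-only**. Because a mis-annotated gene 5′ end perturbs the first
intron's *donor*, 3′-only introns are enriched for first introns, and
symmetrically 5′-only for last introns; `positional_bias` reports these
fractions (NaN for empty classes; single-intron transcripts count as both
first and last).

## Splice-boundary motifs

Windows of (10 exonic, 10 intronic) bases are stacked around each donor and
acceptor, reverse-complemented for minus-strand introns. Position 0 is the
first intron base at the 5′ end and the first exon base at the 3′ end.
Per-position information content is `2 + Σ p·log2 p` bits (0·log 0 = 0, so
values lie in [0, 2]); ambiguous bases are excluded from the denominator and
introns whose window leaves the scaffold are skipped and tallied.

## Transfrags

A deliberately simplified caller: tag footprint spans are merged per
(scaffold, strand) into coverage islands when separated by ≤ `max_gap`
(default 50) bases; islands with ≥ `min_frags` (default 100) fragments
become transfrags. A transfrag is **novel** if it has zero same-strand
overlap with any annotated gene span. No splice-graph assembly is
attempted.

## Normalization and composition comparison

Technical replicates are collapsed by the arithmetic mean (a group spanning
methods is an error); all-zero features are removed and counted. Sample
correlation uses Pearson r² on log2 counts with zeros replaced by ones;
the principal-component projection is the SVD of the feature-centered
matrix. **TMM** factors follow the published trimmed-mean-of-M-values
method: reference = sample whose upper-quartile/library-size ratio is
closest to the mean; M and A values on features nonzero in both samples;
double trim (30 % on M, 5 % on A, rank-based); inverse-asymptotic-variance
weights; factors rescaled to geometric mean 1; a sample identical (or
proportional) to the reference gets factor exactly 1. logCPM is
`log2((count + 0.5) / (effective library size + 1) × 1e6)` averaged over
samples; logFC is the log2 ratio of group-mean normalized abundances, NaN
with a **one-group-only** flag when either group mean is zero — formal
dispersion-based significance testing is deliberately out of scope.

GO enrichment is a two-sided Fisher's exact test per term (selected set vs
rest of background) with Benjamini–Hochberg adjustment within each GO
domain.

## Clustering and arm assignment

Greedy longest-first clustering (CD-HIT-like): records sorted by decreasing
length (input order breaks ties) join the first cluster whose
*representative* they match at ≥ the identity threshold (default 0.75),
else found a new cluster. Identity = maximal matches in a global alignment
(match 1, mismatch 0, gaps 0 — equivalently the longest-common-subsequence
length) divided by the shorter sequence's length. Clusters with exactly one
record per species yield 1:1 ortholog pairs. A scaffold is assigned to the
majority reference arm when supported by ≥ 5 orthologs; ties are left
unassigned and flagged; minority votes are reported as conflicts. The
whole-arm **2L↔3R translocation** between the two species (an involution;
X, 2R, 3L unchanged) is applied to the winning reference arm.

## Synthetic-data generator

`SynthConfig` defaults define the study-like conditions; all randomness
derives from `seed` (independent `numpy` generators salted per stream, so
the genome, each library and the ortholog fixture are separately
reproducible).

- Genome: 4 scaffolds × 30 kb, 40 genes (2 rRNA), 2–5 exons of 120–260 bp,
  introns 250–600 bp planted with GT..AG ends, GTAAGT-weighted donors
  (p = 0.85 per position beyond the forced GT) and pyrimidine-tract
  acceptors.
- Fragment allocation is multinomial over 20 000 fragments: rRNA mass 10 %
  (polyA) / 4 % (ribozero); under ribozero, 8 % intronic pre-mRNA
  background placed wholly within introns (thus unassigned by union
  counting); the remainder proportional to per-gene uniform(0.5, 1.5)
  weights, with 10 % of genes poly(A)⁻ (weight 0 under polyA).
- Noise: 5 % antisense-orientation errors (excluded from expected sense
  counts), 20 % singleton fragments (R2 unmapped), and 40 % extra
  pure-unmapped pairs mimicking unalignable reads. Reads are 80 bp with
  220 ± 25 bp inserts.
- Mis-annotation: 10 % of multi-intron genes get the *first* intron's donor
  shifted into the exon (a mis-annotated 5′ end → 3′-only support) and 10 %
  the *last* intron's acceptor (→ 5′-only); offsets 12–60 bp, capped to
  leave ≥ 20 bp of exon. The generator records the expected support class
  of every published intron.
- Ortholog fixture: 6 scaffolds × 6 orthologs plus one scaffold with only 4
  (below the 5-gene bar, hence unassignable), decoy singletons in each
  species, point mutations splitting the planted identity budget between the
  two copies, and arm truth recorded *after* the 2L↔3R translocation.

What it does **not** emulate: real sequence composition beyond splice-site
motifs, sequencing errors within reads, multi-mapping, overlapping genes,
alternative splicing beyond shared introns, fragment-length biases, or
genome-scale sizes — the fixture is meant to give exact ground truth at
desk scale, not realism.

## Numerical conventions

- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  and SAM are converted at the I/O boundary.
- Printed percentages round half away from zero to two decimals.
- Medians/means of alignment rates use exact (unrounded) intermediate
  values.
- All output tables are deterministic: features sorted by identifier,
  GFF3 written parents-before-children.
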