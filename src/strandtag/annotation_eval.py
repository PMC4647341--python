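"""Intron validation, splice-site motif matrices and simplified transfrag calling.

Annotated introns (gaps between consecutive exons of a transcript) are
validated against splice junctions observed as N gaps in spliced alignments.
An intron with no exactly-matching junction but at least one junction
sharing its donor coordinate is "5'-only" supported (the acceptor is
suspect); sharing only the acceptor gives "3'-only".  Because a
mis-annotated gene 5' end perturbs the first intron's donor, 3'-only
introns are expected to be enriched for first introns, and symmetrically
for 5'-only / last introns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, GenomeAnnotation, GenomicInterval
from .tag_counting import Tag, _fragment_strand, _merge_blocks

IntronKey = tuple[str, str, int, int]  # scaffold, strand, start, end


@dataclass
class Intron:
    scaffold: str
    start: int
    end: int
    strand: str
    # (transcript id, ordinal from 1 in transcription order, total introns)
    contexts: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def key(self) -> IntronKey:
        return (self.scaffold, self.strand, self.start, self.end)

    @property
    def donor(self) -> int:
        """First intron base on the transcript 5' side."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def acceptor(self) -> int:
        """Last intron base on the transcript 3' side."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def is_first(self) -> bool:
        return any(ordinal == 1 for _, ordinal, _ in self.contexts)

    @property
    def is_last(self) -> bool:
        return any(ordinal == total for _, ordinal, total in self.contexts)


@dataclass
class IntronRecord:
    intron: Intron
    full_support: int
    validated_at_10: bool
    validated_at_1: bool
    support_class: str  # full, 5p_only, 3p_only, none


@dataclass
class IntronValidation:
    records: list[IntronRecord]
    thresholds: tuple[int, int] = (1, 10)

    def counts(self) -> dict[str, int]:
        out = {"unique_introns": len(self.records)}
        out["validated_at_10"] = sum(r.validated_at_10 for r in self.records)
        out["validated_at_1"] = sum(r.validated_at_1 for r in self.records)
        for cls in ("full", "5p_only", "3p_only", "none"):
            out[cls] = sum(r.support_class == cls for r in self.records)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            i = r.intron
            rows.append(
                {
                    "scaffold": i.scaffold, "start": i.start, "end": i.end,
                    "strand": i.strand, "full_support": r.full_support,
                    "validated_at_10": r.validated_at_10,
                    "validated_at_1": r.validated_at_1,
                    "support_class": r.support_class,
                    "is_first": i.is_first, "is_last": i.is_last,
                    "contexts": ",".join(
                        f"{t}:{o}/{n}" for t, o, n in i.contexts
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class JunctionTable:
    counts: dict[IntronKey, int]
    skipped_no_flank: int = 0

    def donors(self) -> set[tuple[str, str, int]]:
        return {
            (s, st, a if st == "+" else b - 1) for (s, st, a, b) in self.counts
        }

    def acceptors(self) -> set[tuple[str, str, int]]:
        return {
            (s, st, b - 1 if st == "+" else a) for (s, st, a, b) in self.counts
        }

    def merge(self, other: "JunctionTable") -> "JunctionTable":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) + v
        return JunctionTable(merged, self.skipped_no_flank + other.skipped_no_flank)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"scaffold": s, "start": a, "end": b, "strand": st, "count": n}
            for (s, st, a, b), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class MotifMatrix:
    """Per-position base frequencies and information content around a splice site."""

    positions: list[int]
    frequencies: pd.DataFrame  # index positions, columns A C G T
    bits: pd.Series
    n_sequences: int
    skipped: int = 0

    def consensus(self) -> str:
        return "".join(self.frequencies.idxmax(axis=1))


@dataclass
class Transfrag:
    scaffold: str
    strand: str
    start: int
    end: int
    fragment_count: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.scaffold, self.start, self.end, self.strand)


# ---------------------------------------------------------------------------
# intron extraction


def extract_introns(annotation: GenomeAnnotation) -> list[Intron]:
    """Unique introns from consecutive exon pairs of every transcript.

    Deduplicated on (scaffold, strand, interval); transcript contexts are
    merged; ordinals count in transcription order (strand-aware).
    """
    by_key: dict[IntronKey, Intron] = {}
    for tid in annotation.transcript_ids():
        exons = annotation.exons_of(tid)
        for i in range(len(exons) - 1):
            if exons[i].interval.end > exons[i + 1].interval.start:
                raise ValueError(f"transcript {tid!r} has overlapping exons")
        n_introns = len(exons) - 1
        if n_introns < 1:
            continue
        strand = exons[0].interval.strand
        for i in range(n_introns):
            start = exons[i].interval.end
            end = exons[i + 1].interval.start
            ordinal = i + 1 if strand == "+" else n_introns - i
            key = (exons[i].interval.scaffold, strand, start, end)
            intron = by_key.get(key)
            if intron is None:
                intron = Intron(key[0], start, end, strand)
                by_key[key] = intron
            intron.contexts.append((tid, ordinal, n_introns))
    return [by_key[k] for k in sorted(by_key)]


# ---------------------------------------------------------------------------
# junction extraction


def extract_junctions(
    records: Iterable[AlignmentRecord], min_overhang: int = 1
) -> JunctionTable:
    """Collect splice junctions from N CIGAR gaps of mapped reads.

    The junction strand is the read's *fragment* strand (fr-secondstrand
    rule).  A gap whose flanking aligned blocks on either side are shorter
    than ``min_overhang`` is excluded and tallied.
    """
    counts: dict[IntronKey, int] = {}
    skipped = 0
    for rec in records:
        if not rec.mapped or not any(op == "N" for op, _ in rec.cigar):
            continue
        strand = _fragment_strand(rec)
        pos = rec.position
        # lengths of the aligned (ref-consuming, non-N) runs between gaps
        runs: list[int] = [0]
        gaps: list[tuple[int, int]] = []
        for op, n in rec.cigar:
            if op in ("M", "=", "X", "D"):
                runs[-1] += n
                pos += n
            elif op == "N":
                gaps.append((pos, pos + n))
                runs.append(0)
                pos += n
        for i, (a, b) in enumerate(gaps):
            if runs[i] >= min_overhang and runs[i + 1] >= min_overhang:
                key = (rec.scaffold, strand, a, b)
                counts[key] = counts.get(key, 0) + 1
            else:
                skipped += 1
    return JunctionTable(counts, skipped)


# ---------------------------------------------------------------------------
# validation


def validate_introns(
    introns: Sequence[Intron],
    junctions: JunctionTable,
    thresholds: tuple[int, int] = (1, 10),
) -> IntronValidation:
    """Flag introns by exact junction support and classify end-only support.

    Full support counts junctions whose interval and strand equal the intron
    exactly.  With zero full support, a junction sharing the donor but not
    the acceptor coordinate gives class 5'-only; the symmetric case 3'-only.
    """
    lo, hi = sorted(thresholds)
    donors = junctions.donors()
    acceptors = junctions.acceptors()
    records = []
    for intron in introns:
        full = junctions.counts.get(intron.key, 0)
        if full > 0:
            cls = "full"
        else:
            donor_hit = (intron.scaffold, intron.strand, intron.donor) in donors
            acceptor_hit = (intron.scaffold, intron.strand, intron.acceptor) in acceptors
            if donor_hit and not acceptor_hit:
                cls = "5p_only"
            elif acceptor_hit and not donor_hit:
                cls = "3p_only"
            else:
                cls = "none"
        records.append(
            IntronRecord(
                intron=intron,
                full_support=full,
                validated_at_10=full >= hi,
                validated_at_1=full >= lo,
                support_class=cls,
            )
        )
    return IntronValidation(records, (lo, hi))


def positional_bias(validation: IntronValidation) -> pd.DataFrame:
    """Among each end-only class: fraction of introns that are first / last.

    Single-intron transcripts count as both first and last.  Empty classes
    report NaN rather than zero.
    """
    rows = []
    for cls in ("5p_only", "3p_only"):
        members = [r.intron for r in validation.records if r.support_class == cls]
        n = len(members)
        rows.append(
            {
                "class": cls,
                "n": n,
                "first_fraction": (
                    sum(i.is_first for i in members) / n if n else math.nan
                ),
                "last_fraction": (
                    sum(i.is_last for i in members) / n if n else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# boundary motifs


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _information_content(freqs: np.ndarray) -> float:
    """2 + sum p log2 p with 0*log 0 = 0; in [0, 2] bits."""
    nz = freqs[freqs > 0]
    return 2.0 + float(np.sum(nz * np.log2(nz)))


def boundary_motifs(
    introns: Sequence[Intron],
    sequences: Mapping[str, str],
    window: tuple[int, int] = (10, 10),
) -> tuple[MotifMatrix, MotifMatrix]:
    """Position frequency/information matrices at the 5' and 3' intron ends.

    ``window = (exonic, intronic)`` bases per side.  At the 5' end position 0
    is the first intron base (exonic positions are negative).  At the 3' end
    position 0 is the first base of the following exon (intronic positions
    are negative).  Minus-strand introns are reverse-complemented; ambiguous
    bases are excluded from the position's denominator; introns whose window
    leaves the scaffold are skipped and tallied.
    """
    exonic, intronic = window
    width = exonic + intronic
    counts5 = np.zeros((width, 4), dtype=float)
    counts3 = np.zeros((width, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    n_used = 0
    skipped = 0
    for intron in introns:
        seq = sequences.get(intron.scaffold)
        if seq is None:
            skipped += 1
            continue
        if intron.strand == "+":
            w5 = (intron.start - exonic, intron.start + intronic)
            w3 = (intron.end - intronic, intron.end + exonic)
        else:
            w5 = (intron.end - intronic, intron.end + exonic)
            w3 = (intron.start - exonic, intron.start + intronic)
        if min(w5[0], w3[0]) < 0 or max(w5[1], w3[1]) > len(seq):
            skipped += 1
            continue
        s5, s3 = seq[w5[0] : w5[1]], seq[w3[0] : w3[1]]
        if intron.strand == "-":
            s5, s3 = _revcomp(s5), _revcomp(s3)
        for mat, s in ((counts5, s5), (counts3, s3)):
            for i, base in enumerate(s):
                j = base_idx.get(base)
                if j is not None:
                    mat[i, j] += 1
        n_used += 1

    def build(mat: np.ndarray, positions: list[int]) -> MotifMatrix:
        totals = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            freqs = np.where(totals > 0, mat / np.where(totals == 0, 1, totals), 0.0)
        df = pd.DataFrame(freqs, index=positions, columns=list("ACGT"))
        bits = pd.Series(
            [_information_content(freqs[i]) if totals[i, 0] > 0 else 0.0
             for i in range(len(positions))],
            index=positions,
        )
        return MotifMatrix(positions, df, bits, n_used, skipped)

    pos5 = list(range(-exonic, intronic))
    pos3 = list(range(-intronic, exonic))
    return build(counts5, pos5), build(counts3, pos3)


# ---------------------------------------------------------------------------
# transfrag calling


def call_transfrags(
    tags: Sequence[Tag], min_frags: int = 100, max_gap: int = 50
) -> list[Transfrag]:
    """Merge tag footprints into coverage islands per scaffold and strand.

    Footprints separated by gaps <= ``max_gap`` join one island; islands
    supported by >= ``min_frags`` fragments become transfrags.
    """
    by_group: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for tag in tags:
        span = (tag.segments[0][0], tag.segments[-1][1])
        by_group.setdefault((tag.scaffold, tag.strand), []).append(span)
    out: list[Transfrag] = []
    for (scaffold, strand), spans in sorted(by_group.items()):
        spans.sort()
        cur_start, cur_end, n = spans[0][0], spans[0][1], 1
        islands = []
        for a, b in spans[1:]:
            if a <= cur_end + max_gap:
                cur_end = max(cur_end, b)
                n += 1
            else:
                islands.append((cur_start, cur_end, n))
                cur_start, cur_end, n = a, b, 1
        islands.append((cur_start, cur_end, n))
        for a, b, n in islands:
            if n >= min_frags:
                out.append(Transfrag(scaffold, strand, a, b, n))
    return out


def novel_features(
    transfrags: Sequence[Transfrag], annotation: GenomeAnnotation
) -> list[Transfrag]:
    """Transfrags with zero same-strand overlap with any annotated gene span."""
    gene_spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for gene in annotation.genes:
        iv = gene.interval
        gene_spans.setdefault((iv.scaffold, iv.strand), []).append((iv.start, iv.end))
    novel = []
    for tf in transfrags:
        spans = gene_spans.get((tf.scaffold, tf.strand), [])
        if not any(a < tf.end and tf.start < b for a, b in spans):
            novel.append(tf)
    return novel
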