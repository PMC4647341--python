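"""Fragment-level tag assembly, strand-specific counting and library QC.

A *tag* is the representative of one sequenced fragment: an aligned read
pair counted once, or an aligned singleton read.  Under the fr-secondstrand
protocol the fragment strand is the alignment strand of R1 (for an R2-only
singleton, the opposite of its alignment strand).

Counting uses union mode: a tag is assigned to a gene when every aligned
segment overlaps that gene's exon union and no other gene's exons overlap
the tag on the assignment strand; tags touching exons of two or more genes
on that strand are ambiguous and counted for none.
"""

from __future__ import annotations

import logging
import statistics
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import AlignmentRecord, GenomeAnnotation

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used in the report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Tag:
    fragment_id: str
    scaffold: str
    segments: list[tuple[int, int]]  # sorted, non-overlapping
    strand: str  # '+' or '-'
    is_pair: bool


@dataclass
class TagCountMatrix:
    sense: pd.DataFrame  # features x samples
    antisense: pd.DataFrame
    ambiguous: dict[str, int]
    unassigned: dict[str, int]
    total_tags: dict[str, int]

    @property
    def samples(self) -> list[str]:
        return list(self.sense.columns)


@dataclass
class LibrarySummary:
    sample: str
    reads_to_align: int
    aligned: int
    aligned_r1: int
    aligned_r2: int
    aligned_in_pair: int
    properly_paired: int
    singletons: int

    @property
    def pct_aligned(self) -> float:
        return 100.0 * self.aligned / self.reads_to_align if self.reads_to_align else 0.0


@dataclass
class RrnaAccounting:
    per_gene: pd.DataFrame  # rRNA features x samples, sense counts
    rrna_total: dict[str, int]
    rrna_pct: dict[str, float]
    sense_assigned: dict[str, int]
    sense_assigned_pct: dict[str, float]
    non_rrna_sense: dict[str, int]
    non_rrna_sense_pct: dict[str, float]


# ---------------------------------------------------------------------------
# tag assembly


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    blocks = sorted(blocks)
    merged = [list(blocks[0])]
    for a, b in blocks[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def _fragment_strand(rec: AlignmentRecord) -> str:
    """fr-secondstrand: R1 maps sense; an R2 singleton maps antisense."""
    if rec.first_in_pair:
        return "-" if rec.reverse else "+"
    return "+" if rec.reverse else "-"


def assemble_tags(records: Iterable[AlignmentRecord]) -> list[Tag]:
    """Join mates by query name into one tag per fragment.

    Unmapped records are dropped (they carry no footprint); three or more
    alignments sharing a query name are a hard error, since multi-mapping is
    excluded upstream.
    """
    by_name: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if not rec.mapped:
            continue
        group = by_name.setdefault(rec.query_name, [])
        group.append(rec)
        if len(group) > 2:
            raise ValueError(
                f"query {rec.query_name!r} has >2 alignments; "
                "multi-mapped input is not supported"
            )
    tags: list[Tag] = []
    for name in by_name:
        group = by_name[name]
        if len(group) == 2 and group[0].scaffold == group[1].scaffold:
            r1 = group[0] if group[0].first_in_pair else group[1]
            blocks = group[0].aligned_blocks() + group[1].aligned_blocks()
            tags.append(
                Tag(name, group[0].scaffold, _merge_blocks(blocks),
                    _fragment_strand(r1), is_pair=True)
            )
        else:
            # singleton, or a discordant pair represented by R1 alone
            rec = group[0]
            if len(group) == 2:
                rec = group[0] if group[0].first_in_pair else group[1]
                logger.warning("mates of %s on different scaffolds; using R1", name)
            tags.append(
                Tag(name, rec.scaffold, _merge_blocks(rec.aligned_blocks()),
                    _fragment_strand(rec), is_pair=False)
            )
    return tags


# ---------------------------------------------------------------------------
# counting


def _gene_exon_trees(
    annotation: GenomeAnnotation,
) -> tuple[dict[str, IntervalTree], dict[str, str]]:
    """Per-scaffold interval trees over gene exon unions; gene -> strand."""
    by_gene_blocks: dict[str, list[tuple[int, int]]] = {}
    gene_strand: dict[str, str] = {}
    gene_scaffold: dict[str, str] = {}
    for gene in annotation.genes:
        blocks: list[tuple[int, int]] = []
        for tr in annotation.transcripts_of(gene.id):
            for exon in annotation.exons_of(tr.id):
                blocks.append((exon.interval.start, exon.interval.end))
        if not blocks:
            blocks = [(gene.interval.start, gene.interval.end)]
        by_gene_blocks[gene.id] = _merge_blocks(blocks)
        gene_strand[gene.id] = gene.interval.strand
        gene_scaffold[gene.id] = gene.interval.scaffold
    trees: dict[str, IntervalTree] = {}
    for gid, blocks in by_gene_blocks.items():
        tree = trees.setdefault(gene_scaffold[gid], IntervalTree())
        for a, b in blocks:
            tree[a:b] = gid
    return trees, gene_strand


def count_tags(
    tags_by_sample: Mapping[str, list[Tag]], annotation: GenomeAnnotation
) -> TagCountMatrix:
    """Union-mode strand-specific counting of tags against gene exon unions."""
    trees, gene_strand = _gene_exon_trees(annotation)
    gene_ids = sorted(gene_strand)
    samples = list(tags_by_sample)
    sense = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=int)
    antisense = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=int)
    ambiguous: dict[str, int] = {}
    unassigned: dict[str, int] = {}
    totals: dict[str, int] = {}
    warned_scaffolds: set[str] = set()

    for sample, tags in tags_by_sample.items():
        n_amb = n_un = 0
        for tag in tags:
            tree = trees.get(tag.scaffold)
            if tree is None:
                if tag.scaffold not in warned_scaffolds:
                    warnings.warn(
                        f"scaffold {tag.scaffold!r} absent from annotation; "
                        "tags there are unassigned"
                    )
                    warned_scaffolds.add(tag.scaffold)
                n_un += 1
                continue
            per_seg_hits = [
                {iv.data for iv in tree.overlap(a, b)} for a, b in tag.segments
            ]
            hit_any = set().union(*per_seg_hits)
            layer = None
            for orientation, frame in (("sense", sense), ("antisense", antisense)):
                if orientation == "sense":
                    cand = {g for g in hit_any if gene_strand[g] == tag.strand}
                else:
                    cand = {g for g in hit_any if gene_strand[g] != tag.strand}
                if not cand:
                    continue
                if len(cand) > 1:
                    layer = "ambiguous"
                else:
                    g = next(iter(cand))
                    if all(g in hits for hits in per_seg_hits):
                        frame.loc[g, sample] += 1
                        layer = orientation
                    else:
                        layer = "unassigned"
                break
            if layer == "ambiguous":
                n_amb += 1
            elif layer in (None, "unassigned"):
                n_un += 1
        ambiguous[sample] = n_amb
        unassigned[sample] = n_un
        totals[sample] = len(tags)
    return TagCountMatrix(sense, antisense, ambiguous, unassigned, totals)


# ---------------------------------------------------------------------------
# library summary


def summarize_library(
    records: Iterable[AlignmentRecord],
    sample: str = "sample",
    insert_mean: float = 0.0,
    insert_sd: float = 100.0,
    window_sds: float = 10.0,
) -> LibrarySummary:
    """Alignment metrics per library.

    "Properly paired" requires both mates mapped to the same scaffold on
    opposing strands with 3' ends innermost and an inner mate distance
    within ``insert_mean +/- window_sds * insert_sd``.
    """
    reads = aligned = r1 = r2 = in_pair = singles = 0
    mapped_pairs: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        reads += 1
        if not rec.mapped:
            continue
        aligned += 1
        if rec.first_in_pair:
            r1 += 1
        else:
            r2 += 1
        if rec.paired and rec.mate_mapped:
            in_pair += 1
            mapped_pairs.setdefault(rec.query_name, []).append(rec)
        else:
            singles += 1

    proper = 0
    lo = insert_mean - window_sds * insert_sd
    hi = insert_mean + window_sds * insert_sd
    for pair in mapped_pairs.values():
        if len(pair) != 2:
            continue
        a, b = pair
        if a.scaffold != b.scaffold or a.reverse == b.reverse:
            continue
        fwd, rev = (a, b) if not a.reverse else (b, a)
        f_end, r_start = fwd.reference_end(), rev.position
        # 3' ends innermost: neither read extends past its mate's outer end
        if fwd.position > rev.position or f_end > rev.reference_end():
            continue
        inner = r_start - f_end
        if lo <= inner <= hi:
            proper += 2
    return LibrarySummary(sample, reads, aligned, r1, r2, in_pair, proper, singles)


# ---------------------------------------------------------------------------
# rRNA accounting


def rrna_accounting(
    matrix: TagCountMatrix, rrna_ids: Iterable[str]
) -> RrnaAccounting:
    """Per-sample rRNA sense totals and percentages of total aligned tags."""
    rrna_ids = list(rrna_ids)
    missing = [r for r in rrna_ids if r not in matrix.sense.index]
    if missing:
        raise KeyError(f"rRNA feature ids absent from count matrix: {missing}")
    per_gene = matrix.sense.loc[rrna_ids]
    rrna_total = {s: int(per_gene[s].sum()) for s in matrix.samples}
    sense_assigned = {s: int(matrix.sense[s].sum()) for s in matrix.samples}
    out_pct = {}
    sense_pct = {}
    non_rrna = {}
    non_rrna_pct = {}
    for s in matrix.samples:
        total = matrix.total_tags[s]
        out_pct[s] = round_half_away(100.0 * rrna_total[s] / total, 2) if total else 0.0
        sense_pct[s] = (
            round_half_away(100.0 * sense_assigned[s] / total, 2) if total else 0.0
        )
        non_rrna[s] = sense_assigned[s] - rrna_total[s]
        non_rrna_pct[s] = (
            round_half_away(100.0 * non_rrna[s] / total, 2) if total else 0.0
        )
    return RrnaAccounting(
        per_gene, rrna_total, out_pct, sense_assigned, sense_pct, non_rrna, non_rrna_pct
    )


def rrna_accounting_from_counts(
    per_gene: pd.DataFrame, total_tags: Mapping[str, int],
    sense_assigned: Mapping[str, int] | None = None,
) -> RrnaAccounting:
    """rRNA accounting directly from tabulated counts (report arithmetic).

    Used when per-gene rRNA tag counts, per-sample totals and (optionally)
    sense-assigned totals come from an existing counting run or a published
    table rather than a TagCountMatrix.
    """
    samples = list(per_gene.columns)
    rrna_total = {s: int(per_gene[s].sum()) for s in samples}
    rrna_pct = {
        s: round_half_away(100.0 * rrna_total[s] / total_tags[s], 2) for s in samples
    }
    if sense_assigned is None:
        sense_assigned = rrna_total
    sa = {s: int(sense_assigned[s]) for s in samples}
    sa_pct = {s: round_half_away(100.0 * sa[s] / total_tags[s], 2) for s in samples}
    non = {s: sa[s] - rrna_total[s] for s in samples}
    non_pct = {s: round_half_away(100.0 * non[s] / total_tags[s], 2) for s in samples}
    return RrnaAccounting(per_gene, rrna_total, rrna_pct, sa, sa_pct, non, non_pct)


# ---------------------------------------------------------------------------
# alignment-rate comparison


@dataclass
class RateComparison:
    per_pair_diff: dict[str, float]  # biological pair -> polyA% - ribozero%
    mean_diff: float
    median_diff: float
    median_aligned: float  # median aligned-read count across all samples
    pairs: list[str] = field(default_factory=list)


def compare_alignment_rates(
    summaries: Mapping[str, LibrarySummary],
    design: Mapping[str, tuple[str, str]],  # sample -> (method, biological pair)
) -> RateComparison:
    """Per-pair percent-aligned differences (polyA - ribozero) from unrounded
    counts, with their mean and median, plus the overall median aligned count.
    """
    by_pair: dict[str, dict[str, LibrarySummary]] = {}
    for sample, summ in summaries.items():
        if sample not in design:
            raise KeyError(f"sample {sample!r} missing from design")
        method, pair = design[sample]
        by_pair.setdefault(pair, {})[method] = summ
    diffs: dict[str, float] = {}
    for pair, d in sorted(by_pair.items()):
        if set(d) != {"polyA", "ribozero"}:
            raise ValueError(f"biological pair {pair!r} lacks a method partner")
        diffs[pair] = d["polyA"].pct_aligned - d["ribozero"].pct_aligned
    values = list(diffs.values())
    aligned_counts = [s.aligned for s in summaries.values()]
    return RateComparison(
        per_pair_diff=diffs,
        mean_diff=statistics.fmean(values),
        median_diff=statistics.median(values),
        median_aligned=statistics.median(aligned_counts),
        pairs=sorted(by_pair),
    )
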