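"""Readers/writers for GFF3, FASTA and SAM plus the internal coordinate model.

All internal coordinates are 0-based, half-open.  GFF3 (1-based, inclusive)
and SAM (1-based leftmost) positions are converted at the I/O boundary, so
no other module ever handles a 1-based coordinate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator
from urllib.parse import quote, unquote

import pysam
from Bio import SeqIO

# GFF3 feature types given first-class treatment; anything else is "other"
# and survives a round trip unchanged.
KNOWN_TYPES = {"gene", "mRNA", "exon", "rRNA", "ncRNA"}

TRANSCRIPT_TYPES = {"mRNA", "rRNA", "ncRNA"}

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

REF_CONSUMING = {"M", "D", "N", "=", "X"}
ALIGNED_OPS = {"M", "=", "X", "D"}


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    strand: str = "."  # '+', '-' or '.' (unstranded)

    def __post_init__(self) -> None:
        if not self.scaffold:
            raise ValueError("scaffold must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Feature:
    id: str
    type: str  # gene, mRNA, exon, rRNA, ncRNA, other
    interval: GenomicInterval
    parent: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)


class GenomeAnnotation:
    """Hierarchical gene -> transcript -> exon feature set."""

    def __init__(
        self,
        features: Iterable[Feature] = (),
        scaffold_lengths: dict[str, int] | None = None,
    ) -> None:
        self.features: dict[str, Feature] = {}
        self.children: dict[str, list[str]] = {}
        self.scaffold_lengths: dict[str, int] = dict(scaffold_lengths or {})
        for feat in features:
            self.add(feat)

    def add(self, feature: Feature) -> None:
        if feature.id in self.features:
            raise ValueError(f"duplicate feature id {feature.id!r}")
        self.features[feature.id] = feature
        if feature.parent is not None:
            self.children.setdefault(feature.parent, []).append(feature.id)

    def validate(self) -> None:
        for feat in self.features.values():
            if feat.parent is not None and feat.parent not in self.features:
                raise ValueError(
                    f"feature {feat.id!r} has unresolvable Parent {feat.parent!r}"
                )

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features.values() if f.type == ftype]

    @property
    def genes(self) -> list[Feature]:
        return self.of_type("gene")

    def transcripts_of(self, gene_id: str) -> list[Feature]:
        return [
            self.features[c]
            for c in self.children.get(gene_id, [])
            if self.features[c].type in TRANSCRIPT_TYPES
        ]

    def exons_of(self, transcript_id: str) -> list[Feature]:
        """Exons of one transcript, sorted by coordinate."""
        exons = [
            self.features[c]
            for c in self.children.get(transcript_id, [])
            if self.features[c].type == "exon"
        ]
        return sorted(exons, key=lambda e: e.interval.start)

    def transcript_ids(self) -> list[str]:
        return [f.id for f in self.features.values() if f.type in TRANSCRIPT_TYPES]

    def __len__(self) -> int:
        return len(self.features)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self.features == other.features


@dataclass
class AlignmentRecord:
    """One SAM alignment line with decoded flags and parsed CIGAR."""

    query_name: str
    paired: bool
    first_in_pair: bool
    mapped: bool
    mate_mapped: bool
    reverse: bool
    mate_reverse: bool
    scaffold: str | None
    position: int  # 0-based leftmost reference coordinate; -1 if unmapped
    cigar: list[tuple[str, int]]
    mate_scaffold: str | None = None
    mate_position: int = -1
    template_length: int = 0

    def reference_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.position + sum(n for op, n in self.cigar if op in REF_CONSUMING)

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Reference blocks covered by M/=/X/D ops, split at N gaps."""
        blocks: list[tuple[int, int]] = []
        pos = self.position
        block_start: int | None = None
        for op, n in self.cigar:
            if op in ALIGNED_OPS:
                if block_start is None:
                    block_start = pos
                pos += n
            elif op == "N":
                if block_start is not None:
                    blocks.append((block_start, pos))
                    block_start = None
                pos += n
            # I, S, H, P consume no reference
        if block_start is not None:
            blocks.append((block_start, pos))
        return blocks


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[unquote(key)] = unquote(value)
    return attrs


def _format_attributes(attrs: dict[str, str]) -> str:
    safe = ":/ "  # characters GFF3 allows unescaped in values
    return ";".join(
        f"{quote(k, safe=safe)}={quote(v, safe=safe)}" for k, v in attrs.items()
    )


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Parse a GFF3 file into a GenomeAnnotation.

    Coordinates are converted to 0-based half-open.  ``##sequence-region``
    directives populate scaffold lengths; an embedded ##FASTA section is
    ignored.  Unknown feature types are preserved as "other".
    """
    ann = GenomeAnnotation()
    anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    ann.scaffold_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            scaffold, _source, ftype, start, end, _score, strand, _phase, attr = cols
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(
                    f"{path}:{lineno}: start {start_i} > end {end_i}"
                )
            attrs = _parse_attributes(attr)
            fid = attrs.get("ID")
            if fid is None:
                anon += 1
                fid = f"_anon{anon}"
            parent = attrs.get("Parent")
            interval = GenomicInterval(
                scaffold, start_i - 1, end_i, strand if strand in "+-" else "."
            )
            extra = {
                k: v for k, v in attrs.items() if k not in ("ID", "Parent")
            }
            if ftype not in KNOWN_TYPES:
                extra.setdefault("original_type", ftype)
                ftype = "other"
            ann.add(Feature(fid, ftype, interval, parent, extra))
    ann.validate()
    return ann


def _gff3_sort_key(ann: GenomeAnnotation, fid: str) -> tuple:
    f = ann.features[fid]
    return (f.interval.scaffold, f.interval.start, f.id)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Serialise to GFF3: 1-based inclusive, parents before children,
    ordered by (scaffold, start, id) at each hierarchy level — deterministic.
    """
    annotation.validate()
    lines = ["##gff-version 3"]
    for scaffold in sorted(annotation.scaffold_lengths):
        length = annotation.scaffold_lengths[scaffold]
        lines.append(f"##sequence-region {scaffold} 1 {length}")

    def emit(fid: str) -> None:
        f = annotation.features[fid]
        ftype = f.attributes.get("original_type", f.type) if f.type == "other" else f.type
        attrs = {"ID": f.id}
        if f.parent is not None:
            attrs["Parent"] = f.parent
        attrs.update({k: v for k, v in f.attributes.items() if k != "original_type"})
        lines.append(
            "\t".join(
                [
                    f.interval.scaffold,
                    "strandtag",
                    ftype,
                    str(f.interval.start + 1),
                    str(f.interval.end),
                    ".",
                    f.interval.strand if f.interval.strand in "+-" else ".",
                    ".",
                    _format_attributes(attrs),
                ]
            )
        )
        for child in sorted(
            annotation.children.get(fid, []), key=lambda c: _gff3_sort_key(annotation, c)
        ):
            emit(child)

    roots = [f.id for f in annotation.features.values() if f.parent is None]
    for fid in sorted(roots, key=lambda c: _gff3_sort_key(annotation, c)):
        emit(fid)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: upper-cased sequence}; duplicate ids are an error."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA identifier {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM


def parse_cigar(text: str) -> list[tuple[str, int]]:
    if text == "*":
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if "".join(f"{n}{op}" for op, n in ops) != text:
        raise ValueError(f"malformed CIGAR {text!r}")
    return ops


def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = []
    if seg.cigartuples:
        cigar = [("MIDNSHP=XB"[op], n) for op, n in seg.cigartuples]
    return AlignmentRecord(
        query_name=seg.query_name,
        paired=seg.is_paired,
        first_in_pair=seg.is_read1 if seg.is_paired else True,
        mapped=not seg.is_unmapped,
        mate_mapped=seg.is_paired and not seg.mate_is_unmapped,
        reverse=seg.is_reverse,
        mate_reverse=seg.is_paired and seg.mate_is_reverse,
        scaffold=seg.reference_name,
        position=seg.reference_start if not seg.is_unmapped else -1,
        cigar=cigar,
        mate_scaffold=seg.next_reference_name,
        mate_position=seg.next_reference_start,
        template_length=seg.template_length,
    )


def read_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from SAM (or BAM) — unmapped records included."""
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            yield _from_pysam(seg)


def write_sam(
    records: Iterable[AlignmentRecord],
    scaffold_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write AlignmentRecords as SAM text with @SQ lines from scaffold_lengths."""
    names = sorted(scaffold_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": scaffold_lengths[n]} for n in names],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.query_name
            flag = 0
            if rec.paired:
                flag |= 0x1
                flag |= 0x40 if rec.first_in_pair else 0x80
                if not rec.mate_mapped:
                    flag |= 0x8
                if rec.mate_reverse:
                    flag |= 0x20
            if not rec.mapped:
                flag |= 0x4
            if rec.reverse:
                flag |= 0x10
            seg.flag = flag
            if rec.mapped:
                seg.reference_name = rec.scaffold
                seg.reference_start = rec.position
                seg.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
                seg.mapping_quality = 50
            else:
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            if rec.paired and rec.mate_mapped and rec.mate_scaffold is not None:
                seg.next_reference_name = rec.mate_scaffold
                seg.next_reference_start = rec.mate_position
            elif rec.paired and rec.mapped:
                # convention: unmapped mate placed at this record's position
                seg.next_reference_name = rec.scaffold
                seg.next_reference_start = rec.position
            seg.template_length = rec.template_length
            read_len = sum(n for op, n in rec.cigar if op in "MIS=X") or 1
            seg.query_sequence = "N" * read_len
            seg.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            out.write(seg)
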