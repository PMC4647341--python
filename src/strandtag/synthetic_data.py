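"""Synthetic genome, annotation, stranded spliced alignments and ortholog fixtures.

The generator emulates the study conditions of a paired-end, fr-secondstrand
(ScriptSeq-style) RNA-seq experiment run with two mRNA-enrichment protocols:

* ``polyA``    — poly(A) selection: rRNA carry-through around 10 % of tags,
  poly(A)- transcripts absent (zero leakage by default), no pre-mRNA
  background.
* ``ribozero`` — rRNA depletion: lower rRNA carry-through, poly(A)-
  transcripts present, plus an intronic (immature-transcript) background.

Every true intron starts with a GT donor whose first six bases are drawn
from a GTAAGT-weighted profile and ends with AG preceded by a
pyrimidine-rich tract, so splice-motif recovery is testable.  A configured
fraction of gene models in the *published* annotation have a mis-annotated
5' end (first intron's donor shifted into the exon, leaving only the
acceptor supported: 3'-only) or 3' end (last intron's acceptor shifted,
leaving 5'-only support).

All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AlignmentRecord,
    Feature,
    GenomeAnnotation,
    GenomicInterval,
)

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DONOR_MOTIF = "GTAAGT"
ARMS = ("X", "2R", "2L", "3R", "3L")

#: whole-arm translocation between the two species: reference 2L <-> target 3R
TRANSLOCATION = {"2L": "3R", "3R": "2L", "X": "X", "2R": "2R", "3L": "3L"}


@dataclass
class SynthConfig:
    """Parameters of the toy experiment.

    Defaults are chosen to mirror the study conditions: ~10 % rRNA tags under
    poly(A) selection vs ~4 % under ribo-depletion, a modest poly(A)- gene
    complement visible only in ribo-depleted libraries, an intronic
    (pre-mRNA) background only under ribo-depletion, and a small antisense
    error rate giving sense >> antisense assignment.
    """

    seed: int
    n_scaffolds: int = 4
    scaffold_length: int = 30_000
    n_genes: int = 40
    n_rrna_genes: int = 2
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (120, 260)
    intron_length: tuple[int, int] = (250, 600)
    intergenic_gap: tuple[int, int] = (150, 400)
    rrna_tag_fraction: dict[str, float] = field(
        default_factory=lambda: {"polyA": 0.10, "ribozero": 0.04}
    )
    polya_minus_fraction: float = 0.10
    polya_minus_leakage: float = 0.0
    ribozero_intronic_background: float = 0.08
    fragment_count: int = 20_000
    read_length: int = 80
    insert_mean: float = 220.0
    insert_sd: float = 25.0
    mis5_fraction: float = 0.10
    mis3_fraction: float = 0.10
    antisense_error_rate: float = 0.05
    singleton_fraction: float = 0.20
    unaligned_fraction: float = 0.40
    # ortholog / clustering fixture
    ortho_scaffolds: int = 6
    ortho_genes_per_scaffold: int = 6
    ortho_decoys: int = 3
    peptide_length: tuple[int, int] = (80, 150)
    peptide_mutation_rate: float = 0.08

    def __post_init__(self) -> None:
        for name in (
            "polya_minus_fraction",
            "polya_minus_leakage",
            "ribozero_intronic_background",
            "mis5_fraction",
            "mis3_fraction",
            "antisense_error_rate",
            "singleton_fraction",
            "unaligned_fraction",
            "peptide_mutation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for frac in self.rrna_tag_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("rRNA tag fractions must be in [0,1]")
        for name in ("n_scaffolds", "scaffold_length", "n_genes", "fragment_count",
                     "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GeneModel:
    """Internal bookkeeping for one planted gene."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, sorted
    kind: str  # 'mRNA', 'rRNA'
    polya_minus: bool = False

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class TruthSet:
    true_annotation: GenomeAnnotation
    published_annotation: GenomeAnnotation
    genes: dict[str, GeneModel]
    rrna_ids: set[str]
    polya_minus_ids: set[str]
    expression_weights: dict[str, float]
    # published-annotation introns keyed (scaffold, strand, start, end) ->
    # expected support class under saturating junction coverage
    intron_classes: dict[tuple[str, str, int, int], str]
    mis5_genes: set[str]
    mis3_genes: set[str]
    # filled by simulate_library
    expected_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    error_fragments: dict[str, int] = field(default_factory=dict)
    intronic_fragments: dict[str, int] = field(default_factory=dict)
    unaligned_fragments: dict[str, int] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length)]


def _plant_donor(rng: np.random.Generator, intron: list[str]) -> None:
    # first two bases strictly GT; the rest of GTAAGT strongly weighted
    intron[0], intron[1] = "G", "T"
    for i in range(2, min(6, len(intron))):
        if rng.random() < 0.85:
            intron[i] = DONOR_MOTIF[i]


def _plant_acceptor(rng: np.random.Generator, intron: list[str]) -> None:
    intron[-2], intron[-1] = "A", "G"
    # pyrimidine-rich tract upstream of the AG
    for i in range(max(6, len(intron) - 12), len(intron) - 2):
        if rng.random() < 0.85:
            intron[i] = "C" if rng.random() < 0.5 else "T"


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def generate_genome(config: SynthConfig) -> tuple[dict[str, str], TruthSet]:
    """Lay out genes without overlap on random scaffolds and build truth.

    Returns the scaffold sequences and a TruthSet whose published annotation
    carries the configured fraction of mis-annotated gene ends.
    """
    rng = np.random.default_rng(config.seed)
    scaffold_names = [f"scaf{i + 1}" for i in range(config.n_scaffolds)]
    scaffolds = {name: _random_seq(rng, config.scaffold_length) for name in scaffold_names}
    cursors = {name: 0 for name in scaffold_names}

    genes: dict[str, GeneModel] = {}
    n_polya_minus = round(config.polya_minus_fraction * (config.n_genes - config.n_rrna_genes))
    for gi in range(config.n_genes):
        gene_id = f"gene{gi + 1:03d}"
        is_rrna = gi < config.n_rrna_genes
        if is_rrna:
            n_exons = 1
        else:
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            for _ in range(n_exons)
        ]
        intron_lens = [
            int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        span = sum(exon_lens) + sum(intron_lens)

        scaffold = scaffold_names[gi % config.n_scaffolds]
        start = cursors[scaffold] + gap
        if start + span > config.scaffold_length:
            raise ValueError(
                "gene layout impossible: requested gene density exceeds scaffold space"
            )
        cursors[scaffold] = start + span

        # build gene-local sequence in transcript orientation with planted motifs
        local: list[str] = []
        exon_bounds_local: list[tuple[int, int]] = []
        pos = 0
        for i, elen in enumerate(exon_lens):
            exon_bounds_local.append((pos, pos + elen))
            local.extend(_random_seq(rng, elen))
            pos += elen
            if i < n_exons - 1:
                intron = _random_seq(rng, intron_lens[i])
                _plant_donor(rng, intron)
                _plant_acceptor(rng, intron)
                local.extend(intron)
                pos += intron_lens[i]
        local_seq = "".join(local)

        if strand == "+":
            genomic_seq = local_seq
            exons = [(start + a, start + b) for a, b in exon_bounds_local]
        else:
            genomic_seq = _revcomp(local_seq)
            exons = sorted(
                (start + span - b, start + span - a) for a, b in exon_bounds_local
            )
        scaffolds[scaffold][start : start + span] = list(genomic_seq)

        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            scaffold=scaffold,
            strand=strand,
            exons=exons,
            kind="rRNA" if is_rrna else "mRNA",
        )

    # flag poly(A)- genes among the non-rRNA genes
    coding = [g for g in genes.values() if g.kind == "mRNA"]
    pm_idx = rng.choice(len(coding), size=n_polya_minus, replace=False)
    for i in pm_idx:
        coding[int(i)].polya_minus = True

    # choose genes for mis-annotated ends (disjoint sets, multi-exon only)
    n_mis5 = round(config.mis5_fraction * config.n_genes)
    n_mis3 = round(config.mis3_fraction * config.n_genes)
    eligible = [g.gene_id for g in genes.values() if len(g.exons) >= 2]
    if n_mis5 + n_mis3 > len(eligible):
        raise ValueError("not enough multi-exon genes for requested mis-annotation")
    picked = rng.permutation(eligible)
    mis5 = set(picked[:n_mis5].tolist())
    mis3 = set(picked[n_mis5 : n_mis5 + n_mis3].tolist())

    true_ann = _to_annotation(genes, {s: config.scaffold_length for s in scaffold_names})
    pub_genes, intron_classes = _publish(genes, mis5, mis3, rng)
    pub_ann = _to_annotation(
        pub_genes, {s: config.scaffold_length for s in scaffold_names}
    )

    weights = {
        g.gene_id: float(rng.uniform(0.5, 1.5)) for g in genes.values()
    }

    sequences = {name: "".join(scaffolds[name]) for name in scaffold_names}
    truth = TruthSet(
        true_annotation=true_ann,
        published_annotation=pub_ann,
        genes=genes,
        rrna_ids={g.gene_id for g in genes.values() if g.kind == "rRNA"},
        polya_minus_ids={g.gene_id for g in genes.values() if g.polya_minus},
        expression_weights=weights,
        intron_classes=intron_classes,
        mis5_genes=mis5,
        mis3_genes=mis3,
    )
    return sequences, truth


def _publish(
    genes: dict[str, GeneModel],
    mis5: set[str],
    mis3: set[str],
    rng: np.random.Generator,
) -> tuple[dict[str, GeneModel], dict[tuple[str, str, int, int], str]]:
    """Derive the published (possibly mis-annotated) gene models.

    A mis-annotated 5' gene end shifts the first intron's donor into the
    flanking exon, so RNA-seq junctions share only the acceptor (3'-only
    support).  A mis-annotated 3' end shifts the last intron's acceptor
    (5'-only support).  Shift offsets are 12-60 bp, capped to keep the
    truncated exon at least 20 bp long.
    """
    published: dict[str, GeneModel] = {}
    classes: dict[tuple[str, str, int, int], str] = {}
    for gid, g in genes.items():
        exons = [list(e) for e in g.exons]
        shifted_intron_idx: dict[int, str] = {}
        if gid in mis5 and len(exons) >= 2:
            # first intron in transcription order
            if g.strand == "+":
                exon_i = 0  # its upstream exon is the leftmost
                d = _offset(rng, exons[exon_i][1] - exons[exon_i][0])
                exons[exon_i][1] -= d  # donor moves left into the exon
                shifted_intron_idx[0] = "3p_only"
            else:
                exon_i = len(exons) - 1  # transcription starts at the right
                d = _offset(rng, exons[exon_i][1] - exons[exon_i][0])
                exons[exon_i][0] += d  # donor moves right into the exon
                shifted_intron_idx[len(exons) - 2] = "3p_only"
        if gid in mis3 and len(exons) >= 2:
            if g.strand == "+":
                exon_i = len(exons) - 1
                d = _offset(rng, exons[exon_i][1] - exons[exon_i][0])
                exons[exon_i][0] += d  # acceptor moves right into the exon
                shifted_intron_idx[len(exons) - 2] = "5p_only"
            else:
                exon_i = 0
                d = _offset(rng, exons[exon_i][1] - exons[exon_i][0])
                exons[exon_i][1] -= d
                shifted_intron_idx[0] = "5p_only"
        pg = dataclasses.replace(g, exons=[tuple(e) for e in exons])
        published[gid] = pg
        for i, (istart, iend) in enumerate(pg.introns):
            key = (g.scaffold, g.strand, istart, iend)
            classes[key] = shifted_intron_idx.get(i, "full")
    return published, classes


def _offset(rng: np.random.Generator, exon_len: int) -> int:
    hi = min(60, exon_len - 20)
    if hi < 12:
        raise ValueError("exon too short to host a mis-annotation shift")
    return int(rng.integers(12, hi + 1))


def _to_annotation(
    genes: dict[str, GeneModel], scaffold_lengths: dict[str, int]
) -> GenomeAnnotation:
    ann = GenomeAnnotation(scaffold_lengths=scaffold_lengths)
    for gid in sorted(genes):
        g = genes[gid]
        span = g.span
        ann.add(
            Feature(
                gid,
                "gene",
                GenomicInterval(g.scaffold, span[0], span[1], g.strand),
                attributes={"biotype": "rRNA" if g.kind == "rRNA" else
                            ("polyA_minus" if g.polya_minus else "protein_coding")},
            )
        )
        tid = f"{gid}.t1"
        ann.add(
            Feature(
                tid,
                g.kind if g.kind == "rRNA" else "mRNA",
                GenomicInterval(g.scaffold, span[0], span[1], g.strand),
                parent=gid,
            )
        )
        for i, (a, b) in enumerate(g.exons):
            ann.add(
                Feature(
                    f"{tid}.e{i + 1}",
                    "exon",
                    GenomicInterval(g.scaffold, a, b, g.strand),
                    parent=tid,
                )
            )
    return ann


# ---------------------------------------------------------------------------
# read simulation


def _transcript_to_genomic(
    g: GeneModel, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval onto genomic exon blocks (sorted)."""
    # transcript coordinates run 5'->3'; exons in transcript order
    exons = g.exons if g.strand == "+" else list(reversed(g.exons))
    blocks: list[tuple[int, int]] = []
    offset = 0
    for (a, b) in exons:
        elen = b - a
        lo = max(t_start, offset)
        hi = min(t_end, offset + elen)
        if lo < hi:
            if g.strand == "+":
                blocks.append((a + (lo - offset), a + (hi - offset)))
            else:
                blocks.append((b - (hi - offset), b - (lo - offset)))
        offset += elen
    return sorted(blocks)


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for i, (a, b) in enumerate(blocks):
        if i > 0:
            cigar.append(("N", a - blocks[i - 1][1]))
        cigar.append(("M", b - a))
    return cigar


def _read_pair(
    qname: str,
    scaffold: str,
    blocks1: list[tuple[int, int]],
    blocks2: list[tuple[int, int]],
    r1_reverse: bool,
    r1_unmapped: bool = False,
    r2_unmapped: bool = False,
) -> list[AlignmentRecord]:
    """Build the two mate records; R1 and R2 are on opposite strands."""
    recs = []
    left = min(blocks1[0][0], blocks2[0][0])
    right = max(blocks1[-1][1], blocks2[-1][1])
    tlen = right - left
    for first, blocks, reverse, unmapped, mate_blocks, mate_reverse, mate_unmapped in (
        (True, blocks1, r1_reverse, r1_unmapped, blocks2, not r1_reverse, r2_unmapped),
        (False, blocks2, not r1_reverse, r2_unmapped, blocks1, r1_reverse, r1_unmapped),
    ):
        if unmapped:
            recs.append(
                AlignmentRecord(
                    query_name=qname, paired=True, first_in_pair=first,
                    mapped=False, mate_mapped=not mate_unmapped,
                    reverse=False, mate_reverse=mate_reverse,
                    scaffold=None if mate_unmapped else scaffold,
                    position=-1 if mate_unmapped else mate_blocks[0][0],
                    cigar=[],
                    mate_scaffold=None if mate_unmapped else scaffold,
                    mate_position=-1 if mate_unmapped else mate_blocks[0][0],
                    template_length=0,
                )
            )
            continue
        pos = blocks[0][0]
        sign = -1 if pos > mate_blocks[0][0] or (pos == mate_blocks[0][0] and reverse) else 1
        recs.append(
            AlignmentRecord(
                query_name=qname, paired=True, first_in_pair=first,
                mapped=True, mate_mapped=not mate_unmapped,
                reverse=reverse, mate_reverse=mate_reverse,
                scaffold=scaffold, position=pos,
                cigar=_blocks_to_cigar(blocks),
                mate_scaffold=scaffold,
                mate_position=mate_blocks[0][0] if not mate_unmapped else pos,
                template_length=0 if mate_unmapped else sign * tlen,
            )
        )
    return recs


def simulate_library(
    sequences: dict[str, str],
    truth: TruthSet,
    method: str,
    config: SynthConfig,
) -> list[AlignmentRecord]:
    """Simulate one stranded paired-end library as alignment records.

    Fragments are allocated multinomially: an rRNA mass at the configured
    per-method fraction, an intronic pre-mRNA background (ribozero only),
    and the remainder over transcripts proportional to expression weights
    (poly(A)- transcripts excluded under polyA up to the leakage setting).
    Fills ``truth.expected_counts[method]`` with the per-gene sense-assignable
    exonic fragment counts.
    """
    if method not in ("polyA", "ribozero"):
        raise ValueError(f"unknown library method {method!r}")
    rng = np.random.default_rng([config.seed, 11 if method == "polyA" else 23])

    genes = truth.genes
    w = truth.expression_weights
    rrna = [g for g in genes.values() if g.kind == "rRNA"]
    normal = [g for g in genes.values() if g.kind != "rRNA"]

    rrna_mass = config.rrna_tag_fraction[method]
    intron_mass = config.ribozero_intronic_background if method == "ribozero" else 0.0

    # sources for the intronic background: multi-exon genes, weight-proportional
    intron_sources = [g for g in normal if len(g.exons) >= 2]

    sources: list[tuple[str, GeneModel]] = []
    probs: list[float] = []
    wsum_rrna = sum(w[g.gene_id] for g in rrna) or 1.0
    for g in rrna:
        sources.append(("exonic", g))
        probs.append(rrna_mass * w[g.gene_id] / wsum_rrna)
    if intron_mass > 0 and intron_sources:
        wsum_i = sum(w[g.gene_id] for g in intron_sources)
        for g in intron_sources:
            sources.append(("intronic", g))
            probs.append(intron_mass * w[g.gene_id] / wsum_i)
    else:
        intron_mass = 0.0

    def expr_weight(g: GeneModel) -> float:
        if g.polya_minus and method == "polyA":
            return config.polya_minus_leakage * w[g.gene_id]
        return w[g.gene_id]

    wsum_n = sum(expr_weight(g) for g in normal)
    remaining = 1.0 - rrna_mass - intron_mass
    for g in normal:
        if expr_weight(g) > 0:
            sources.append(("exonic", g))
            probs.append(remaining * expr_weight(g) / wsum_n)

    probs_arr = np.asarray(probs)
    probs_arr = probs_arr / probs_arr.sum()
    counts = rng.multinomial(config.fragment_count, probs_arr)

    records: list[AlignmentRecord] = []
    expected: dict[str, int] = {gid: 0 for gid in genes}
    n_err = n_intronic = 0
    frag_no = 0
    for (kind, g), n in zip(sources, counts):
        for _ in range(int(n)):
            frag_no += 1
            qname = f"{method}_frag{frag_no:07d}"
            flen = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            if kind == "exonic":
                tlen = g.transcript_length
                flen = max(config.read_length, min(flen, tlen))
                t0 = int(rng.integers(0, tlen - flen + 1))
                rlen = min(config.read_length, flen)
                b1 = _transcript_to_genomic(g, t0, t0 + rlen)
                b2 = _transcript_to_genomic(g, t0 + flen - rlen, t0 + flen)
                # fr-secondstrand: R1 aligns sense to the transcript
                r1_reverse = g.strand == "-"
                antisense = rng.random() < config.antisense_error_rate
                if antisense:
                    # fragment emitted from the wrong strand: swap mate roles
                    b1, b2 = b2, b1
                    r1_reverse = not r1_reverse
                    n_err += 1
                else:
                    expected[g.gene_id] += 1
                r2_unmapped = rng.random() < config.singleton_fraction
                records.extend(
                    _read_pair(qname, g.scaffold, b1, b2, r1_reverse,
                               r2_unmapped=r2_unmapped)
                )
            else:  # intronic pre-mRNA background, wholly inside one intron
                introns = g.introns
                ilens = np.array([b - a for a, b in introns], dtype=float)
                idx = int(rng.choice(len(introns), p=ilens / ilens.sum()))
                a, b = introns[idx]
                flen = max(config.read_length, min(flen, b - a))
                start = int(rng.integers(a, b - flen + 1))
                rlen = min(config.read_length, flen)
                b1 = [(start, start + rlen)] if g.strand == "+" else [
                    (start + flen - rlen, start + flen)
                ]
                b2 = [(start + flen - rlen, start + flen)] if g.strand == "+" else [
                    (start, start + rlen)
                ]
                records.extend(
                    _read_pair(qname, g.scaffold, b1, b2, g.strand == "-")
                )
                n_intronic += 1

    n_unaligned = round(config.unaligned_fraction * config.fragment_count)
    for i in range(n_unaligned):
        qname = f"{method}_unal{i + 1:07d}"
        for first in (True, False):
            records.append(
                AlignmentRecord(
                    query_name=qname, paired=True, first_in_pair=first,
                    mapped=False, mate_mapped=False, reverse=False,
                    mate_reverse=False, scaffold=None, position=-1, cigar=[],
                )
            )

    truth.expected_counts[method] = expected
    truth.error_fragments[method] = n_err
    truth.intronic_fragments[method] = n_intronic
    truth.unaligned_fragments[method] = n_unaligned
    return records


# ---------------------------------------------------------------------------
# ortholog / clustering fixture


@dataclass
class OrthologFixture:
    species_a: dict[str, str]  # peptide id -> sequence
    species_b: dict[str, str]
    a_scaffold: dict[str, str]  # A peptide id -> scaffold
    b_arm: dict[str, str]  # B peptide id -> reference chromosome arm
    ortholog_pairs: list[tuple[str, str]]  # planted 1:1 (A id, B id)
    arm_truth: dict[str, str | None]  # scaffold -> target arm (post-translocation)
    scaffold_lengths: dict[str, int]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[int(rng.integers(0, len(AMINO_ACIDS)))]
    return "".join(out)


def generate_ortholog_fixture(config: SynthConfig) -> OrthologFixture:
    """Plant 1:1 ortholog pairs plus one-to-many decoy paralogs.

    Species-B peptides carry reference chromosome-arm labels; the truth arm
    for each species-A scaffold is the reference arm mapped through the
    2L<->3R whole-arm translocation.  One extra scaffold gets fewer orthologs
    than the assignment threshold of 5 and is recorded as unassignable.
    """
    rng = np.random.default_rng([config.seed, 47])
    species_a: dict[str, str] = {}
    species_b: dict[str, str] = {}
    a_scaffold: dict[str, str] = {}
    b_arm: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    arm_truth: dict[str, str | None] = {}
    scaffold_lengths: dict[str, int] = {}

    def new_peptide() -> str:
        length = int(rng.integers(config.peptide_length[0], config.peptide_length[1] + 1))
        return "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, len(AMINO_ACIDS), length))

    counter = 0
    scaffolds = [f"KB{i + 1:04d}" for i in range(config.ortho_scaffolds + 1)]
    for si, scaf in enumerate(scaffolds):
        ref_arm = ARMS[si % len(ARMS)]
        # last scaffold gets too few orthologs to clear the min-genes bar
        n_orth = config.ortho_genes_per_scaffold if si < config.ortho_scaffolds else 4
        scaffold_lengths[scaf] = int(rng.integers(200_000, 2_000_000))
        for _ in range(n_orth):
            counter += 1
            base = new_peptide()
            aid, bid = f"AFUN{counter:05d}-PA", f"AGAP{counter:05d}-PA"
            species_a[aid] = _mutate(rng, base, config.peptide_mutation_rate / 2)
            species_b[bid] = _mutate(rng, base, config.peptide_mutation_rate / 2)
            a_scaffold[aid] = scaf
            b_arm[bid] = ref_arm
            pairs.append((aid, bid))
        arm_truth[scaf] = (
            TRANSLOCATION[ref_arm] if n_orth >= 5 else None
        )

    # decoy paralogs: clusters with two A copies and one B record -> not 1:1
    for _ in range(config.ortho_decoys):
        counter += 1
        base = new_peptide()
        scaf = scaffolds[int(rng.integers(0, len(scaffolds)))]
        ref_arm = ARMS[int(rng.integers(0, len(ARMS)))]
        a1, a2, bid = (
            f"AFUN{counter:05d}-PA",
            f"AFUN{counter:05d}-PB",
            f"AGAP{counter:05d}-PA",
        )
        species_a[a1] = _mutate(rng, base, config.peptide_mutation_rate / 2)
        species_a[a2] = _mutate(rng, base, config.peptide_mutation_rate / 2)
        species_b[bid] = _mutate(rng, base, config.peptide_mutation_rate / 2)
        a_scaffold[a1] = a_scaffold[a2] = scaf
        b_arm[bid] = ref_arm

    return OrthologFixture(
        species_a=species_a,
        species_b=species_b,
        a_scaffold=a_scaffold,
        b_arm=b_arm,
        ortholog_pairs=pairs,
        arm_truth=arm_truth,
        scaffold_lengths=scaffold_lengths,
    )
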