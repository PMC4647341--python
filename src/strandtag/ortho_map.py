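"""Greedy identity clustering, 1:1 ortholog detection and arm assignment.

Clustering follows the incremental longest-first scheme: records are sorted
by decreasing length (input order breaks ties) and each joins the first
cluster whose representative it matches at or above the identity threshold,
else founds a new cluster.  Identity is the maximal number of matched
positions in a global alignment divided by the shorter sequence's length.

Scaffolds of the target species are assigned to chromosome arms when at
least ``min_genes`` 1:1 orthologs point to the same reference arm, after
which the whole-arm 2L<->3R translocation between the species is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .tag_counting import round_half_away

#: reference arm -> target-species arm (2L and 3R exchanged by a whole-arm
#: translocation; X, 2R and 3L carry over unchanged)
TRANSLOCATION = {"X": "X", "2R": "2R", "2L": "3R", "3R": "2L", "3L": "3L"}


@dataclass
class SequenceRecord:
    id: str
    dataset: str
    sequence: str
    location: str | None = None  # scaffold (species A) or chromosome arm (species B)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Cluster:
    representative: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    identity_threshold: float
    alphabet: str = "protein"

    def membership(self) -> dict[str, str]:
        """record id -> representative id."""
        return {
            m.id: c.representative.id for c in self.clusters for m in c.members
        }


def _match_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


def sequence_identity(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Matches in the match-maximizing global alignment over the shorter length."""
    if not a or not b:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = _match_aligner()
    matches = aligner.score(a, b)
    return matches / min(len(a), len(b))


def greedy_cluster(
    records: Sequence[SequenceRecord],
    identity_threshold: float,
    alphabet: str = "protein",
) -> ClusterSet:
    """Longest-first greedy clustering against cluster representatives only."""
    if not records:
        raise ValueError("no records to cluster")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity threshold must be in (0, 1]")
    aligner = _match_aligner()
    order = sorted(
        range(len(records)), key=lambda i: (-records[i].length, i)
    )
    clusters: list[Cluster] = []
    for i in order:
        rec = records[i]
        for cluster in clusters:
            ident = sequence_identity(rec.sequence, cluster.representative.sequence, aligner)
            if ident >= identity_threshold:
                cluster.members.append(rec)
                break
        else:
            clusters.append(Cluster(rec, [rec]))
    return ClusterSet(clusters, identity_threshold, alphabet)


def dataset_overlap(cluster_set: ClusterSet) -> pd.DataFrame:
    """Per dataset: sequence count, distinct clusters, clusters shared with
    each other dataset."""
    datasets = sorted({m.dataset for c in cluster_set.clusters for m in c.members})
    cluster_datasets = [
        {m.dataset for m in c.members} for c in cluster_set.clusters
    ]
    rows = []
    for ds in datasets:
        n_seq = sum(
            sum(m.dataset == ds for m in c.members) for c in cluster_set.clusters
        )
        own = [s for s in cluster_datasets if ds in s]
        row = {"dataset": ds, "sequences": n_seq, "clusters": len(own)}
        for other in datasets:
            if other != ds:
                row[f"shared_with_{other}"] = sum(other in s for s in own)
        rows.append(row)
    return pd.DataFrame(rows)


def one_to_one_orthologs(
    cluster_set: ClusterSet, species_a: str, species_b: str
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Clusters with exactly one record per species yield an ortholog pair."""
    pairs = []
    for cluster in cluster_set.clusters:
        a = [m for m in cluster.members if m.dataset == species_a]
        b = [m for m in cluster.members if m.dataset == species_b]
        if len(a) == 1 and len(b) == 1:
            pairs.append((a[0], b[0]))
    return pairs


@dataclass
class ArmCall:
    scaffold: str
    arm: str | None  # target-species arm after translocation; None if unassigned
    support: int
    conflicts: dict[str, int]
    tied: bool = False


def assign_arms(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    min_genes: int = 5,
    translocation: Mapping[str, str] = TRANSLOCATION,
) -> dict[str, ArmCall]:
    """Majority-arm assignment per scaffold with the translocation applied.

    The A record of each pair carries a scaffold, the B record a reference
    arm.  A scaffold is assigned when its majority reference arm has at
    least ``min_genes`` supporting orthologs; a tie at or above the
    threshold leaves it unassigned and flagged.  Minority-arm counts are
    kept as the conflict report.
    """
    votes: dict[str, dict[str, int]] = {}
    for a, b in pairs:
        if a.location is None or b.location is None:
            raise ValueError("ortholog pair lacks scaffold or arm label")
        votes.setdefault(a.location, {})
        votes[a.location][b.location] = votes[a.location].get(b.location, 0) + 1
    calls: dict[str, ArmCall] = {}
    for scaffold, arm_counts in sorted(votes.items()):
        best = max(arm_counts.values())
        top = [arm for arm, n in arm_counts.items() if n == best]
        winner = top[0] if len(top) == 1 else None
        conflicts = {arm: n for arm, n in arm_counts.items() if arm != winner}
        if best < min_genes:
            calls[scaffold] = ArmCall(scaffold, None, best, conflicts)
        elif len(top) > 1:
            calls[scaffold] = ArmCall(scaffold, None, best, conflicts, tied=True)
        else:
            calls[scaffold] = ArmCall(
                scaffold, translocation[top[0]], best, conflicts
            )
    return calls


def summarize_arm_rows(
    per_arm: Mapping[str, tuple[int, int]],
    genome_length: int | None = None,
    total_scaffolds: int | None = None,
    arm_order: Sequence[str] = ("X", "2R", "2L", "3R", "3L"),
) -> pd.DataFrame:
    """Totals and assigned fractions from per-arm (scaffold count, length) rows.

    Percentages of the genome length and of all scaffolds are reported to two
    decimals when the denominators are given.
    """
    rows = []
    total_n = total_len = 0
    for arm in arm_order:
        n, length = per_arm.get(arm, (0, 0))
        rows.append({"arm": arm, "scaffolds": n, "total_length": length})
        total_n += n
        total_len += length
    total_row = {"arm": "Total", "scaffolds": total_n, "total_length": total_len}
    if total_scaffolds:
        total_row["pct_of_scaffolds"] = round_half_away(
            100.0 * total_n / total_scaffolds, 2
        )
    if genome_length:
        total_row["pct_of_genome_length"] = round_half_away(
            100.0 * total_len / genome_length, 2
        )
    rows.append(total_row)
    return pd.DataFrame(rows)


def summarize_arms(
    assignment: Mapping[str, ArmCall],
    scaffold_lengths: Mapping[str, int],
    genome_length: int | None = None,
    total_scaffolds: int | None = None,
    arm_order: Sequence[str] = ("X", "2R", "2L", "3R", "3L"),
) -> pd.DataFrame:
    """Per-arm scaffold counts and summed lengths, with totals and, when the
    genome size is known, assigned fractions (percentages to 2 decimals)."""
    per_arm: dict[str, tuple[int, int]] = {}
    for arm in arm_order:
        scaffolds = [c.scaffold for c in assignment.values() if c.arm == arm]
        missing = [s for s in scaffolds if s not in scaffold_lengths]
        if missing:
            raise KeyError(f"missing scaffold lengths: {missing}")
        per_arm[arm] = (len(scaffolds), sum(scaffold_lengths[s] for s in scaffolds))
    return summarize_arm_rows(per_arm, genome_length, total_scaffolds, arm_order)
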