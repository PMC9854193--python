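"""Screen transcripts for clusters of near-identical ~20-nt repeats.

Multi-copy dCas13 targeting needs transcripts carrying several copies of a
short motif so that one guide RNA recruits many fluorescent protein copies
to a single mRNA.  The screen finds, per transcript, maximal clusters of
non-overlapping k-mer occurrences whose pairwise Hamming distances are at
most ``max_mismatch`` (default 1), removes clusters whose motif recurs in a
different gene (off-target risk), and flags transcripts with at least
``min_repeats`` copies as labeling candidates.

Matching is on the sense strand only (dCas13 targets the mRNA); U equals T;
N never matches.  Coordinates are 0-based half-open internally and reported
1-based inclusive in TSV output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "Transcript",
    "RepeatCluster",
    "ScreenResult",
    "find_repeat_clusters",
    "screen_transcripts",
    "cross_gene_uniqueness_filter",
    "select_candidates",
    "expression_summary",
]

_VALID = set("ACGTN")


@dataclass
class Transcript:
    transcript_id: str
    sequence: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"{self.transcript_id}: invalid characters {sorted(bad)}"
            )
        if self.gene_id is None:
            self.gene_id = self.transcript_id


@dataclass
class RepeatCluster:
    """A set of non-overlapping, near-identical k-mer occurrences."""

    transcript_id: str
    gene_id: str
    motif: str                      # sequence of the first occurrence
    k: int
    occurrences: list               # (start, mismatches_vs_motif)
    occurrence_seqs: list
    max_pairwise_mismatch: int

    @property
    def starts(self) -> list[int]:
        return [s for s, _ in self.occurrences]

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)


@dataclass
class ScreenResult:
    """Clusters per transcript plus candidate flags and summary counts."""

    clusters: dict = field(default_factory=dict)     # transcript_id -> list
    gene_of: dict = field(default_factory=dict)      # transcript_id -> gene_id
    candidates: set = field(default_factory=set)
    min_repeats: int | None = None
    summary: dict = field(default_factory=dict)

    def all_clusters(self):
        for tid in self.clusters:
            yield from self.clusters[tid]

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "transcript_id": c.transcript_id,
                "gene_id": c.gene_id,
                "motif": c.motif,
                "n_occurrences": c.n_occurrences,
                # 1-based inclusive start positions in reports
                "starts": ";".join(str(s + 1) for s in c.starts),
                "max_pairwise_mismatch": c.max_pairwise_mismatch,
                "candidate": c.transcript_id in self.candidates,
            }
            for c in self.all_clusters()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "transcript_id", "gene_id", "motif", "n_occurrences",
                "starts", "max_pairwise_mismatch", "candidate",
            ],
        )


def _hamming(a: str, b: str, limit: int) -> int:
    """Hamming distance, counting N as a mismatch; stops above ``limit``."""
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
            if d > limit:
                return d
    return d


def _near_pairs(kmers: list[str], max_mismatch: int):
    """Index pairs (i, j), i<j, with Hamming distance <= max_mismatch.

    Pigeonhole seeding: a k-mer is split into ``max_mismatch + 1`` chunks;
    two k-mers within distance d share at least one chunk exactly, so exact
    chunk matches enumerate all candidate pairs without an O(n^2) scan.
    """
    if not kmers:
        return
    k = len(kmers[0])
    n_chunks = max_mismatch + 1
    bounds = [round(c * k / n_chunks) for c in range(n_chunks + 1)]
    seen = set()
    for c in range(n_chunks):
        lo, hi = bounds[c], bounds[c + 1]
        index: dict[str, list[int]] = {}
        for i, km in enumerate(kmers):
            index.setdefault(km[lo:hi], []).append(i)
        for group in index.values():
            if len(group) < 2:
                continue
            for i, j in combinations(group, 2):
                if (i, j) in seen:
                    continue
                if _hamming(kmers[i], kmers[j], max_mismatch) <= max_mismatch:
                    seen.add((i, j))
                    yield i, j


def find_repeat_clusters(
    transcript: Transcript,
    k: int = 20,
    max_mismatch: int = 1,
    topology: str = "pairwise",
) -> list[RepeatCluster]:
    """Find maximal clusters of non-overlapping near-identical k-mers.

    Clusters are grown greedily left to right: the leftmost unclustered
    occurrence seeds a cluster, and each later non-overlapping occurrence
    joins if it is within ``max_mismatch`` of every current member
    (``topology="pairwise"``) or of the seed alone (``topology="star"``).
    Clusters need at least two occurrences.
    """
    if topology not in ("pairwise", "star"):
        raise ValueError("topology must be 'pairwise' or 'star'")
    if k < 8:
        raise ValueError("k must be >= 8")
    seq = transcript.sequence
    if len(seq) == 0:
        warnings.warn(f"{transcript.transcript_id}: empty sequence", stacklevel=2)
        return []
    if k > len(seq):
        warnings.warn(
            f"{transcript.transcript_id}: k={k} exceeds sequence length", stacklevel=2
        )
        return []

    starts = list(range(len(seq) - k + 1))
    kmers = [seq[s : s + k] for s in starts]
    partners: dict[int, set[int]] = {}
    for i, j in _near_pairs(kmers, max_mismatch):
        partners.setdefault(i, set()).add(j)
        partners.setdefault(j, set()).add(i)

    clusters: list[RepeatCluster] = []
    used: set[int] = set()
    for i in range(len(starts)):
        if i in used or i not in partners:
            continue
        members = [i]
        last_end = starts[i] + k
        for j in sorted(partners[i]):
            if j in used or starts[j] < last_end:
                continue
            ref = members if topology == "pairwise" else [i]
            if all(_hamming(kmers[j], kmers[m], max_mismatch) <= max_mismatch
                   for m in ref):
                members.append(j)
                last_end = starts[j] + k
        if len(members) < 2:
            continue
        used.update(members)
        motif = kmers[members[0]]
        occurrences = [
            (starts[m], _hamming(kmers[m], motif, k)) for m in members
        ]
        max_pw = max(
            _hamming(kmers[a], kmers[b], k) for a, b in combinations(members, 2)
        )
        clusters.append(
            RepeatCluster(
                transcript_id=transcript.transcript_id,
                gene_id=transcript.gene_id,
                motif=motif,
                k=k,
                occurrences=occurrences,
                occurrence_seqs=[kmers[m] for m in members],
                max_pairwise_mismatch=max_pw,
            )
        )
    return clusters


def screen_transcripts(
    transcripts: list[Transcript],
    k: int = 20,
    max_mismatch: int = 1,
    topology: str = "pairwise",
) -> ScreenResult:
    """Run the repeat screen over a set of transcripts."""
    result = ScreenResult()
    for tr in transcripts:
        result.gene_of[tr.transcript_id] = tr.gene_id
        clusters = find_repeat_clusters(tr, k, max_mismatch, topology)
        if clusters:
            result.clusters[tr.transcript_id] = clusters
    return result


def cross_gene_uniqueness_filter(
    result: ScreenResult, tolerant: bool = True, max_mismatch: int = 1
) -> ScreenResult:
    """Drop clusters whose repeat unit recurs in a cluster of another gene.

    With ``tolerant=True`` (default) two clusters collide when any of their
    occurrence sequences are within ``max_mismatch`` of each other; with
    ``tolerant=False`` only exact sequence identity collides.  Isoforms of
    the same gene never trigger removal.
    """
    entries = []  # (gene, cluster, occurrence sequence)
    for cluster in result.all_clusters():
        for s in cluster.occurrence_seqs:
            entries.append((cluster.gene_id, cluster, s))

    doomed: set[int] = set()
    if tolerant:
        seqs = [e[2] for e in entries]
        for i, j in _near_pairs(seqs, max_mismatch):
            if entries[i][0] != entries[j][0]:
                doomed.add(id(entries[i][1]))
                doomed.add(id(entries[j][1]))
    else:
        by_seq: dict[str, list] = {}
        for gene, cluster, s in entries:
            by_seq.setdefault(s, []).append((gene, cluster))
        for hits in by_seq.values():
            if len({g for g, _ in hits}) > 1:
                doomed.update(id(c) for _, c in hits)

    filtered = ScreenResult(gene_of=dict(result.gene_of))
    for tid, clusters in result.clusters.items():
        kept = [c for c in clusters if id(c) not in doomed]
        if kept:
            filtered.clusters[tid] = kept
    return filtered


def select_candidates(result: ScreenResult, min_repeats: int = 8) -> ScreenResult:
    """Flag transcripts having >= ``min_repeats`` occurrences in one cluster;
    record counts at thresholds 2 and ``min_repeats``."""
    out = ScreenResult(
        clusters=dict(result.clusters),
        gene_of=dict(result.gene_of),
        min_repeats=min_repeats,
    )
    best = {
        tid: max(c.n_occurrences for c in clusters)
        for tid, clusters in result.clusters.items()
    }
    out.candidates = {tid for tid, n in best.items() if n >= min_repeats}
    out.summary = {
        "n_transcripts_ge_2": sum(1 for n in best.values() if n >= 2),
        f"n_transcripts_ge_{min_repeats}": len(out.candidates),
        "min_repeats": min_repeats,
    }
    return out


def expression_summary(
    counts: pd.DataFrame, cell_labels: pd.Series, transcripts: list[str] | None = None
) -> pd.DataFrame:
    """Per cell-type mean of library-size-normalized counts.

    ``counts`` is cells x genes (non-negative); each cell is scaled to the
    median library size before averaging within each label.  Returns a
    cell-type x transcript table.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    cell_labels = pd.Series(cell_labels)
    if not counts.index.equals(cell_labels.index):
        if len(cell_labels) != len(counts):
            raise ValueError("cell_labels do not match the counts rows")
        cell_labels.index = counts.index
    totals = counts.sum(axis=1)
    scale = totals.median() if totals.median() > 0 else 1.0
    norm = counts.div(totals.replace(0, np.inf), axis=0) * scale
    if transcripts is not None:
        missing = set(transcripts) - set(counts.columns)
        if missing:
            raise ValueError(f"transcripts absent from counts: {sorted(missing)}")
        norm = norm[transcripts]
    return norm.groupby(cell_labels).mean()
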