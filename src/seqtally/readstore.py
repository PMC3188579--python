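"""Read preprocessing and the unique-read store.

Raw per-replicate read files (FASTA or 4-line FASTQ) are trimmed by fixed
position, reads containing ambiguity codes are excluded, and the survivors
are collapsed to unique sequences with per-replicate occurrence counts.
FASTQ qualities are read and discarded: trimming is positional only.

The conservation identity holds per replicate:
``sum(occurrences) + dropped + ambiguous == raw read count``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

ACGT = frozenset("ACGT")

#: Default minimum post-trim length; must exceed the aligner's seed pair.
DEFAULT_MIN_LENGTH = 20


@dataclass(frozen=True)
class Replicate:
    replicate_id: str
    treatment: str
    path: str | None = None


@dataclass
class ExperimentDesign:
    """Ordered replicates with treatment labels.

    A two-group test requires at least two distinct treatment labels.
    """

    replicates: list[Replicate]

    def __post_init__(self) -> None:
        ids = [r.replicate_id for r in self.replicates]
        if len(ids) != len(set(ids)):
            raise ValueError("replicate ids must be unique")
        if any(not r.treatment for r in self.replicates):
            raise ValueError("every replicate needs a treatment label")

    @property
    def treatments(self) -> list[str]:
        seen: list[str] = []
        for r in self.replicates:
            if r.treatment not in seen:
                seen.append(r.treatment)
        return seen

    def replicates_of(self, treatment: str) -> list[str]:
        return [
            r.replicate_id for r in self.replicates if r.treatment == treatment
        ]

    @classmethod
    def from_manifest(cls, path) -> "ExperimentDesign":
        """Read a delimited manifest: replicate_id <tab> treatment <tab> path."""
        reps = []
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                rid, trt = row[0], row[1]
                p = row[2] if len(row) > 2 else None
                reps.append(Replicate(rid, trt, p))
        return cls(reps)


@dataclass(frozen=True)
class UniqueRead:
    read_id: int
    sequence: str
    occurrences: dict[str, int] = field(hash=False)

    def total(self) -> int:
        return sum(self.occurrences.values())


@dataclass
class ReplicateStats:
    raw: int = 0
    kept: int = 0
    dropped: int = 0     # too short after trimming
    ambiguous: int = 0   # contained non-ACGT symbols


@dataclass
class ReadStore:
    reads: list[UniqueRead]
    design: ExperimentDesign
    stats: dict[str, ReplicateStats]

    def occurrences_of(self, read_id: int) -> dict[str, int]:
        return self.reads[read_id].occurrences


def trim_reads(
    reads: list[str], head: int, tail: int, min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[str], int]:
    """Trim ``head`` nt from 5' and ``tail`` nt from 3' of every read.

    Reads whose trimmed length falls below ``min_length`` (including reads
    fully consumed by the trim) are dropped and tallied.

    Returns (kept reads, dropped count).
    """
    if head < 0 or tail < 0:
        raise ValueError("head and tail must be >= 0")
    kept: list[str] = []
    dropped = 0
    for r in reads:
        t = r[head: len(r) - tail if tail else len(r)]
        if len(t) < max(min_length, 1):
            dropped += 1
        else:
            kept.append(t)
    return kept, dropped


def _read_sequences(path) -> list[str]:
    """Read FASTA or FASTQ sequences; format sniffed from the first byte."""
    p = Path(path)
    with open(p) as fh:
        first = fh.read(1)
        fh.seek(0)
        if not first:
            return []
        fmt = "fastq" if first == "@" else "fasta"
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]


def collapse_reads(
    design: ExperimentDesign,
    head: int = 0,
    tail: int = 0,
    min_length: int = DEFAULT_MIN_LENGTH,
    reads_by_replicate: dict[str, list[str]] | None = None,
) -> ReadStore:
    """Trim, filter and collapse per-replicate reads into a unique-read store.

    Sequences are collapsed across replicates: one :class:`UniqueRead` per
    distinct post-trim sequence, with per-replicate occurrence counts.
    ``read_id`` is assigned in lexicographic sequence order, so a store built
    from the same reads is byte-reproducible regardless of input order.

    ``reads_by_replicate`` bypasses file I/O (used by tests and the synthetic
    generator); otherwise each replicate's ``path`` from the design is read.
    """
    if head < 0 or tail < 0:
        raise ValueError("head and tail must be >= 0")
    occ: dict[str, dict[str, int]] = {}
    stats: dict[str, ReplicateStats] = {}
    for rep in design.replicates:
        if reads_by_replicate is not None:
            raw = reads_by_replicate.get(rep.replicate_id, [])
        else:
            if rep.path is None:
                raise ValueError(f"replicate {rep.replicate_id} has no path")
            raw = _read_sequences(rep.path)
        st = ReplicateStats(raw=len(raw))
        kept: list[str] = []
        for r in raw:
            t = r[head: len(r) - tail if tail else len(r)]
            if len(t) < max(min_length, 1):
                st.dropped += 1
            elif set(t) - ACGT:
                st.ambiguous += 1
            else:
                kept.append(t)
        st.kept = len(kept)
        for seq in kept:
            occ.setdefault(seq, {})[rep.replicate_id] = (
                occ.setdefault(seq, {}).get(rep.replicate_id, 0) + 1
            )
        stats[rep.replicate_id] = st
    reads = [
        UniqueRead(read_id=i, sequence=seq, occurrences=occ[seq])
        for i, seq in enumerate(sorted(occ))
    ]
    return ReadStore(reads=reads, design=design, stats=stats)
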