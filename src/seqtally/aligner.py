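"""Exhaustive short-read alignment over a 2-bit hashed seed index.

The index hashes every reference position by its leading *preamble* k-mer
(default 12 nt) into containers; within a container entries are sorted by a
64-bit key packing the 16 nt that follow the preamble, so exact words can be
located by binary search. Bases are packed 2 bits each (A=00, C=01, G=10,
T=11). Empty preamble containers are never stored.

Alignment uses two equal-length seeds — the first and second preamble-length
windows of the read. A placement with at most ``k`` total mismatches must
leave one seed with at most ``k // 2`` mismatches (pigeonhole over two
seeds), so enumerating every variant of each seed up to that depth and fully
verifying each candidate window base-by-base finds *all* placements on
either strand with Hamming distance <= k. Over-enumeration is harmless:
verification is exact.

Minus-strand hits are found by querying the reverse-complemented read; a hit
at position ``p`` on strand ``-`` means the reverse complement of the read
matches the forward reference at ``p``.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pysam

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

SUFFIX_LENGTH = 16  # nt packed into the sorted 64-bit container key


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode_2bit(seq: str) -> int:
    """Pack a sequence big-endian-in-sequence, 2 bits per base.

    ``"ACGT"`` -> 0b00011011 = 27. Ambiguity codes are an error; callers
    exclude such reads.
    """
    v = 0
    try:
        for c in seq:
            v = (v << 2) | _CODE[c]
    except KeyError as e:
        raise ValueError(f"cannot 2-bit encode base {e.args[0]!r}") from None
    return v


def decode_2bit(value: int, length: int) -> str:
    out = []
    for i in range(length - 1, -1, -1):
        out.append(_BASE[(value >> (2 * i)) & 3])
    return "".join(out)


@dataclass
class TwoBitIndex:
    """Hashed, suffix-sorted index of the forward strand of every sequence.

    ``containers`` maps a preamble integer to parallel arrays
    ``(suffix_keys, seq_idx, positions)`` sorted by suffix key. Positions
    within ``SUFFIX_LENGTH`` of a sequence end are indexed with the available
    suffix bases left-aligned in the key (missing bases pack as zero); all
    candidate hits are verified against the residue strings, so truncated
    keys never produce spurious hits.
    """

    preamble_length: int
    seq_ids: list[str]
    sequences: dict[str, str]
    containers: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    skipped: list[str]

    @property
    def word_length(self) -> int:
        return self.preamble_length + SUFFIX_LENGTH

    def n_positions(self) -> int:
        return sum(len(c[2]) for c in self.containers.values())

    def lookup(self, preamble: int, suffix_key: int) -> list[tuple[str, int]]:
        """Binary-search one exact word; returns (seq_id, pos) coordinates."""
        cont = self.containers.get(preamble)
        if cont is None:
            return []
        keys, sidx, pos = cont
        lo = bisect_left(keys, suffix_key)
        out = []
        n = len(keys)
        while lo < n and keys[lo] == suffix_key:
            out.append((self.seq_ids[sidx[lo]], int(pos[lo])))
            lo += 1
        return out


def build_index(sequences: dict[str, str], preamble_length: int = 12) -> TwoBitIndex:
    """Build the hashed 2-bit index over the forward strand of ``sequences``.

    Every position where a full preamble of ACGT bases fits is indexed;
    windows containing non-ACGT bases are skipped and never produce hits.
    Sequences shorter than the preamble are skipped with a note.
    """
    if not 1 <= preamble_length <= 28:
        raise ValueError("preamble_length must be in [1, 28]")
    p = preamble_length
    seq_ids = sorted(sequences)
    containers: dict[int, list] = {}
    skipped: list[str] = []
    pre_pow = 4 ** np.arange(p - 1, -1, -1, dtype=np.int64)
    suf_pow = 4 ** np.arange(SUFFIX_LENGTH - 1, -1, -1, dtype=np.int64)
    for si, sid in enumerate(seq_ids):
        seq = sequences[sid]
        if len(seq) < p:
            skipped.append(sid)
            continue
        code = np.frombuffer(seq.encode(), dtype=np.uint8)
        num = np.full(len(code), -1, dtype=np.int64)
        for b, v in _CODE.items():
            num[code == ord(b)] = v
        valid = num >= 0
        # preamble value at each start position
        wins = np.lib.stride_tricks.sliding_window_view(num, p)
        ok = np.lib.stride_tricks.sliding_window_view(valid, p).all(axis=1)
        pre_vals = wins @ pre_pow
        # suffix key: next 16 bases, zero-padded past the end; non-ACGT -> 0
        padded = np.concatenate(
            [np.where(valid, num, 0), np.zeros(SUFFIX_LENGTH, dtype=np.int64)]
        )
        suf_wins = np.lib.stride_tricks.sliding_window_view(
            padded, SUFFIX_LENGTH
        )[p: p + len(pre_vals)]
        suf_vals = suf_wins @ suf_pow
        starts = np.nonzero(ok)[0]
        for st in starts:
            containers.setdefault(int(pre_vals[st]), []).append(
                (int(suf_vals[st]), si, int(st))
            )
    packed: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for key, entries in containers.items():
        entries.sort()
        arr = np.array(entries, dtype=np.int64)
        packed[key] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return TwoBitIndex(
        preamble_length=p,
        seq_ids=seq_ids,
        sequences=dict(sequences),
        containers=packed,
        skipped=skipped,
    )


@dataclass(frozen=True)
class AlignmentHit:
    read_id: int
    seq_id: str
    pos: int
    strand: str
    mismatches: int
    target_kind: str = "genome"

    def key(self) -> tuple:
        return (self.seq_id, self.pos, self.strand)


def _seed_variants(value: int, length: int, depth: int) -> list[int]:
    """All integers within ``depth`` base substitutions of a packed seed."""
    out = [value]
    if depth >= 1:
        singles = []
        for i in range(length):
            shift = 2 * (length - 1 - i)
            orig = (value >> shift) & 3
            for b in range(4):
                if b != orig:
                    singles.append(value + ((b - orig) << shift))
        out.extend(singles)
        if depth >= 2:
            for i in range(length):
                shift_i = 2 * (length - 1 - i)
                orig_i = (value >> shift_i) & 3
                for bi in range(4):
                    if bi == orig_i:
                        continue
                    v1 = value + ((bi - orig_i) << shift_i)
                    for j in range(i + 1, length):
                        shift_j = 2 * (length - 1 - j)
                        orig_j = (value >> shift_j) & 3
                        for bj in range(4):
                            if bj != orig_j:
                                out.append(v1 + ((bj - orig_j) << shift_j))
    return out


def _hamming_leq(a: str, b: str, k: int) -> int:
    """Hamming distance if <= k, else -1 (early exit)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > k:
                return -1
    return d


def align_read(
    sequence: str,
    index: TwoBitIndex,
    max_mismatch: int = 2,
    read_id: int = -1,
    target_kind: str = "genome",
) -> list[AlignmentHit]:
    """Return every placement of the read with Hamming distance <= k.

    Both strands are searched; hits are sorted by (seq_id, pos, strand).
    A read shorter than the two seeds (2 x preamble length) cannot be
    aligned and returns no hits.
    """
    if max_mismatch > 2:
        raise ValueError("mismatch enumeration supports k <= 2")
    p = index.preamble_length
    if len(sequence) < 2 * p:
        return []
    depth = max_mismatch // 2
    hits: dict[tuple, AlignmentHit] = {}
    for strand, read in (("+", sequence), ("-", revcomp(sequence))):
        L = len(read)
        seeds = (
            (0, encode_2bit(read[:p])),
            (p, encode_2bit(read[p: 2 * p])),
        )
        seen: set[tuple[int, int]] = set()
        for offset, seed_val in seeds:
            for variant in _seed_variants(seed_val, p, depth):
                cont = index.containers.get(variant)
                if cont is None:
                    continue
                _, sidx, positions = cont
                for si, ref_pos in zip(sidx, positions):
                    start = int(ref_pos) - offset
                    if start < 0:
                        continue
                    cand = (int(si), start)
                    if cand in seen:
                        continue
                    seen.add(cand)
                    seq_id = index.seq_ids[si]
                    ref = index.sequences[seq_id]
                    if start + L > len(ref):
                        continue
                    window = ref[start: start + L]
                    d = _hamming_leq(read, window, max_mismatch)
                    if d > 0 and any(c not in _CODE for c in window):
                        d = -1  # non-ACGT reference positions never produce hits
                    if d >= 0:
                        h = AlignmentHit(
                            read_id=read_id, seq_id=seq_id, pos=start,
                            strand=strand, mismatches=d,
                            target_kind=target_kind,
                        )
                        hits[h.key()] = h
    return sorted(hits.values(), key=lambda h: (h.seq_id, h.pos, h.strand))


def best_stratum(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep only the hits with the minimal mismatch count (perfect before
    1-mismatch before 2-mismatch). Idempotent; empty in -> empty out."""
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    return [h for h in hits if h.mismatches == best]


def brute_force_align(
    sequence: str, references: dict[str, str], max_mismatch: int
) -> set[tuple[str, int, str, int]]:
    """Independent exhaustive Hamming scan over every window and strand.

    Returns ``{(seq_id, pos, strand, mismatches)}``; the oracle the seed
    aligner is validated against. Windows containing non-ACGT reference
    bases never match (such positions are unindexable).
    """
    out = set()
    L = len(sequence)
    for strand, read in (("+", sequence), ("-", revcomp(sequence))):
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        for sid, ref in references.items():
            if len(ref) < L:
                continue
            rarr = np.frombuffer(ref.encode(), dtype=np.uint8)
            wins = np.lib.stride_tricks.sliding_window_view(rarr, L)
            acgt = np.isin(rarr, np.frombuffer(b"ACGT", dtype=np.uint8))
            winok = np.lib.stride_tricks.sliding_window_view(acgt, L).all(axis=1)
            d = (wins != arr).sum(axis=1)
            for pos in np.nonzero((d <= max_mismatch) & winok)[0]:
                out.add((sid, int(pos), strand, int(d[pos])))
    return out


# ---------------------------------------------------------------------------
# SAM I/O


def _sam_header(sequences: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": sid, "LN": len(sequences[sid])}
                for sid in sorted(sequences)
            ],
        }
    )


def write_sam(
    hits_by_read: dict[int, list[AlignmentHit]],
    read_sequences: dict[int, str],
    sequences: dict[str, str],
    path,
) -> None:
    """Write hits as SAM: NM carries the mismatch count, extra hits of a read
    are flagged secondary (0x100), minus-strand records store the reverse
    complement per the SAM convention. Unmapped reads are emitted with 0x4."""
    header = _sam_header(sequences)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rid in sorted(hits_by_read):
            seq = read_sequences[rid]
            hits = hits_by_read[rid]
            if not hits:
                a = pysam.AlignedSegment(header)
                a.query_name = f"read{rid}"
                a.flag = 0x4
                a.query_sequence = seq
                out.write(a)
                continue
            for i, h in enumerate(
                sorted(hits, key=lambda h: (h.mismatches, h.seq_id, h.pos, h.strand))
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = f"read{rid}"
                a.flag = (0x10 if h.strand == "-" else 0) | (
                    0x100 if i > 0 else 0
                )
                a.reference_name = h.seq_id
                a.reference_start = h.pos
                a.mapping_quality = 255
                a.cigarstring = f"{len(seq)}M"
                a.query_sequence = revcomp(seq) if h.strand == "-" else seq
                a.set_tag("NM", h.mismatches)
                out.write(a)


def read_sam(path, sequences: dict[str, str] | None = None):
    """Read SAM into ``(hits_by_read, read_sequences, rejects)``.

    Mismatch counts come from the NM tag (recomputed against ``sequences``
    when the tag is absent and references are supplied). Records naming an
    unknown reference are rejected with their line number.
    """
    hits_by_read: dict[int, list[AlignmentHit]] = {}
    read_sequences: dict[int, str] = {}
    rejects: list[tuple[int, str]] = []
    known = set(sequences) if sequences is not None else None
    # pysam silently downgrades records naming an unknown reference to
    # unmapped; pre-scan the text so they are rejected with a line number.
    reject_lines: set[int] = set()
    with open(path) as fh:
        sq = set()
        for n, line in enumerate(fh, start=1):
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for field in line.rstrip("\n").split("\t"):
                        if field.startswith("SN:"):
                            sq.add(field[3:])
                continue
            rname = line.split("\t", 3)[2]
            bad = rname != "*" and (
                rname not in sq
                or (known is not None and rname not in known)
            )
            if bad:
                rejects.append((n, f"unknown reference {rname!r}"))
                reject_lines.add(n)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        header_lines = str(fh.header).count("\n")
        for n, rec in enumerate(fh, start=header_lines + 1):
            if n in reject_lines:
                continue
            name = rec.query_name or ""
            rid = int(name[4:]) if name.startswith("read") else hash(name) & 0x7FFFFFFF
            if rec.is_unmapped:
                hits_by_read.setdefault(rid, [])
                if rec.query_sequence:
                    read_sequences[rid] = rec.query_sequence
                continue
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence or ""
            fwd = revcomp(seq) if rec.is_reverse else seq
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif sequences is not None:
                ref = sequences[rec.reference_name]
                window = ref[rec.reference_start: rec.reference_start + len(seq)]
                nm = sum(a != b for a, b in zip(seq, window))
            else:
                nm = 0
            hits_by_read.setdefault(rid, []).append(
                AlignmentHit(
                    read_id=rid,
                    seq_id=rec.reference_name,
                    pos=rec.reference_start,
                    strand=strand,
                    mismatches=nm,
                )
            )
            if not rec.is_secondary and fwd:
                read_sequences[rid] = fwd
    return hits_by_read, read_sequences, rejects
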