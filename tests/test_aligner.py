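"""2-bit encoding, the hashed seed index, exhaustive alignment, SAM I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqtally import aligner
from seqtally.aligner import (
    AlignmentHit,
    align_read,
    best_stratum,
    brute_force_align,
    build_index,
    decode_2bit,
    encode_2bit,
    read_sam,
    revcomp,
    write_sam,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=32)


class TestEncoding:
    @pytest.mark.parametrize(
        "seq,value", [("ACGT", 0b00011011), ("AAAA", 0), ("T", 3), ("GA", 8)]
    )
    def test_packing_convention(self, seq, value):
        assert encode_2bit(seq) == value

    @settings(max_examples=100, derandomize=True)
    @given(seq=dna)
    def test_round_trip(self, seq):
        assert decode_2bit(encode_2bit(seq), len(seq)) == seq

    def test_ambiguity_code_rejected(self):
        with pytest.raises(ValueError, match="N"):
            encode_2bit("ACGN")


class TestIndex:
    def test_positions_indexed_wherever_preamble_fits(self):
        seq = "".join(
            "ACGT"[i % 4] for i in range(100)
        )
        idx = build_index({"s": seq}, preamble_length=10)
        assert idx.n_positions() == 100 - 10 + 1

    def test_low_complexity_single_container(self):
        idx = build_index({"s": "A" * 50}, preamble_length=8)
        assert list(idx.containers) == [0]
        keys, _, pos = idx.containers[0]
        assert len(pos) == 50 - 8 + 1
        assert (np.diff(keys) >= 0).all()  # suffix-sorted

    def test_containers_sorted_and_nonempty(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        idx = build_index({"s": seq}, preamble_length=6)
        for key, (keys, _, _) in idx.containers.items():
            assert len(keys) > 0
            assert (np.diff(keys) >= 0).all()

    def test_short_sequence_skipped_with_note(self):
        idx = build_index({"tiny": "ACGT", "ok": "ACGT" * 10},
                          preamble_length=8)
        assert idx.skipped == ["tiny"]

    def test_membership_via_binary_search_vs_linear_scan(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        p = 8
        idx = build_index({"s": seq}, preamble_length=p)
        for _ in range(50):
            start = int(rng.integers(0, len(seq) - idx.word_length))
            word = seq[start: start + idx.word_length]
            found = idx.lookup(encode_2bit(word[:p]), encode_2bit(word[p:]))
            # linear-scan oracle over every window
            expect = [
                ("s", i)
                for i in range(len(seq) - idx.word_length + 1)
                if seq[i: i + idx.word_length] == word
            ]
            assert sorted(found) == sorted(expect)

    def test_non_acgt_positions_not_indexed(self):
        seq = "ACGTACGTACGT" + "N" + "ACGTACGTACGT"
        idx = build_index({"s": seq}, preamble_length=6)
        # no indexed preamble window may cover the N at position 12
        for keys, sidx, pos in idx.containers.values():
            for st_ in pos:
                assert not (st_ <= 12 < st_ + 6)


class TestAlignment:
    def test_exact_hits_both_strands(self):
        # palindromic-ish toy: read occurs twice forward and twice as revcomp
        idx = build_index({"g": "ACGTACGTACGT"}, preamble_length=2)
        hits = align_read("ACGTA", idx, max_mismatch=0)
        got = {(h.pos, h.strand) for h in hits}
        assert got == {(0, "+"), (4, "+"), (3, "-"), (7, "-")}
        assert all(h.mismatches == 0 for h in hits)

    def test_one_mismatch_enumeration(self):
        idx = build_index({"g": "AAATAAA"}, preamble_length=2)
        hits = align_read("AAAAA", idx, max_mismatch=1)
        fwd = {(h.pos, h.mismatches) for h in hits if h.strand == "+"}
        assert fwd == {(0, 1), (1, 1), (2, 1)}

    def test_source_window_always_recovered(self):
        rng = np.random.default_rng(2)
        g = "".join(rng.choice(list("ACGT"), size=500))
        idx = build_index({"g": g}, preamble_length=10)
        read = g[100:130]
        hits = align_read(read, idx, max_mismatch=0)
        assert ("g", 100, "+") in {(h.seq_id, h.pos, h.strand) for h in hits}

    def test_too_short_read_unmapped(self):
        idx = build_index({"g": "ACGT" * 20}, preamble_length=12)
        assert align_read("ACGTACGT", idx, max_mismatch=2) == []

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), k=st.integers(0, 2))
    def test_matches_brute_force_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        g = "".join(rng.choice(list("ACGT"), size=int(rng.integers(300, 1500))))
        idx = build_index({"g": g}, preamble_length=9)
        rl = int(rng.integers(20, 37))
        if rng.random() < 0.7:
            pos = int(rng.integers(0, len(g) - rl + 1))
            read = list(g[pos: pos + rl])
            for mpos in rng.choice(rl, size=k, replace=False):
                read[mpos] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
        else:
            read = "".join(rng.choice(list("ACGT"), size=rl))
        got = {
            (h.seq_id, h.pos, h.strand, h.mismatches)
            for h in align_read(read, idx, k)
        }
        assert got == brute_force_align(read, {"g": g}, k)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        g = "".join(rng.choice(list("ACGT"), size=800))
        idx = build_index({"g": g}, preamble_length=8)
        read = g[200:228]
        fwd = align_read(read, idx, 2)
        rev = align_read(revcomp(read), idx, 2)
        flip = {"+": "-", "-": "+"}
        assert {(h.pos, flip[h.strand], h.mismatches) for h in fwd} == {
            (h.pos, h.strand, h.mismatches) for h in rev
        }


class TestBestStratum:
    def hit(self, mm, pos=0):
        return AlignmentHit(0, "g", pos, "+", mm)

    def test_perfect_beats_mismatched(self):
        hits = [self.hit(0, 5), self.hit(1, 1), self.hit(1, 2), self.hit(1, 3)]
        assert best_stratum(hits) == [self.hit(0, 5)]

    def test_uniform_stratum_kept_whole(self):
        hits = [self.hit(2, i) for i in range(4)]
        assert best_stratum(hits) == hits

    def test_empty_and_idempotent(self):
        assert best_stratum([]) == []
        hits = [self.hit(1, 1), self.hit(2, 2)]
        once = best_stratum(hits)
        assert best_stratum(once) == once
        assert len(once) <= len(hits)


class TestSAM:
    def test_round_trip_and_conventions(self, tmp_path):
        rng = np.random.default_rng(4)
        refs = {"c1": "".join(rng.choice(list("ACGT"), size=400)),
                "c2": "".join(rng.choice(list("ACGT"), size=300))}
        idx = build_index(refs, preamble_length=8)
        reads = {}
        hits = {}
        for rid in range(30):
            src = "c1" if rid % 2 else "c2"
            pos = int(rng.integers(0, len(refs[src]) - 30))
            seq = refs[src][pos: pos + 30]
            if rid % 3 == 0:
                seq = revcomp(seq)
            reads[rid] = seq
            hits[rid] = align_read(seq, idx, 2, read_id=rid)
        path = tmp_path / "out.sam"
        write_sam(hits, reads, refs, path)
        back, seqs, rejects = read_sam(path, refs)
        assert rejects == []
        for rid in hits:
            assert {(h.seq_id, h.pos, h.strand, h.mismatches)
                    for h in back[rid]} == {
                (h.seq_id, h.pos, h.strand, h.mismatches) for h in hits[rid]
            }
            assert seqs[rid] == reads[rid]
        # byte-stable: rewriting what was read reproduces the file
        path2 = tmp_path / "out2.sam"
        write_sam(back, seqs, refs, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_sam_one_based_and_reverse_flag(self, tmp_path):
        refs = {"c": "ACGTACGTACGTACGTACGTACGTACGT"}
        hits = {7: [AlignmentHit(7, "c", 0, "+", 0),
                    AlignmentHit(7, "c", 3, "-", 1)]}
        path = tmp_path / "two.sam"
        write_sam(hits, {7: "ACGTACGTACGTACGTACGT"}, refs, path)
        lines = [l for l in path.read_text().splitlines()
                 if not l.startswith("@")]
        f0 = lines[0].split("\t")
        f1 = lines[1].split("\t")
        assert f0[3] == "1" and int(f0[1]) & 0x10 == 0
        assert int(f1[1]) & 0x10  # reverse strand bit
        assert int(f1[1]) & 0x100  # secondary
        assert f1[9] == revcomp("ACGTACGTACGTACGTACGT")

    def test_unknown_reference_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:c\tLN:50\n"
            "read0\t0\tc\t1\t255\t5M\t*\t0\t0\tACGTA\t*\tNM:i:0\n"
            "read1\t0\tghost\t1\t255\t5M\t*\t0\t0\tACGTA\t*\tNM:i:0\n"
        )
        hits, seqs, rejects = read_sam(path, {"c": "A" * 50})
        assert len(hits) == 1
        assert len(rejects) == 1
        assert "ghost" in rejects[0][1]
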