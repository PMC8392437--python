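"""Primer screening, UMI handling, pair merging, families, consensus."""

import numpy as np
import pytest

from plasmacall._dna import revcomp
from plasmacall.read_engine import (
    EngineConfig,
    FastqPairError,
    ReadFamily,
    ReadPair,
    TaggedRead,
    build_consensus,
    consensus_from_pairs,
    extract_umi,
    group_families,
    merge_pair,
    read_fastq_pairs,
    screen_primer,
)


def _write_fastq(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


class TestFastqPairs:
    def test_pairs_in_order(self, tmp_path):
        _write_fastq(tmp_path / "r1.fq", [("a", "ACGT"), ("b", "GGCC")])
        _write_fastq(tmp_path / "r2.fq", [("a", "TTTT"), ("b", "AAAA")])
        pairs = list(read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))
        assert [p.read_id for p in pairs] == ["a", "b"]
        assert pairs[0].seq2 == "TTTT"

    def test_mate_count_mismatch(self, tmp_path):
        _write_fastq(tmp_path / "r1.fq", [("a", "ACGT"), ("b", "GGCC"), ("c", "ACAC")])
        _write_fastq(tmp_path / "r2.fq", [("a", "TTTT"), ("b", "AAAA")])
        with pytest.raises(FastqPairError, match="pair 3"):
            list(read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))

    def test_empty_files(self, tmp_path):
        (tmp_path / "r1.fq").write_text("")
        (tmp_path / "r2.fq").write_text("")
        assert list(read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq")) == []

    def test_gzip_input(self, tmp_path):
        import gzip

        with gzip.open(tmp_path / "r1.fq.gz", "wt") as fh:
            fh.write("@a\nACGT\n+\nIIII\n")
        with gzip.open(tmp_path / "r2.fq.gz", "wt") as fh:
            fh.write("@a\nTTTT\n+\nIIII\n")
        pairs = list(read_fastq_pairs(tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"))
        assert len(pairs) == 1


class TestExtractUmi:
    def test_umi_is_read2_prefix(self):
        pair = ReadPair("r", "ACGT", "IIII", "AACCGGTTAACC" + "GATTACA", "I" * 19)
        umi, trimmed = extract_umi(pair, 12)
        assert umi == "AACCGGTTAACC"
        assert trimmed.seq2 == "GATTACA"

    def test_short_read2_rejected(self):
        pair = ReadPair("r", "ACGT", "IIII", "ACGTACGT", "I" * 8)
        assert extract_umi(pair, 12) is None

    def test_zero_length_umi_degenerate_mode(self):
        pair = ReadPair("r", "ACGT", "IIII", "GATTACA", "I" * 7)
        umi, trimmed = extract_umi(pair, 0)
        assert umi == ""
        assert trimmed.seq2 == "GATTACA"


class TestScreenPrimer:
    def test_exact_primer_assigns_target(self, toy_panel):
        t0 = toy_panel.targets[0]
        pair = ReadPair("r", t0.amplicon_seq[:30], "I" * 30, "ACGT", "IIII")
        target_id, trimmed = screen_primer(pair, toy_panel, 2)
        assert target_id == "T0"
        assert trimmed.seq1 == t0.amplicon_seq[10:30]

    def test_too_many_mismatches_rejected(self, toy_panel):
        t0 = toy_panel.targets[0]
        primer = list(t0.amplicon_seq[:10])
        for i in (0, 3, 6):
            primer[i] = "A" if primer[i] != "A" else "C"
        pair = ReadPair("r", "".join(primer) + t0.amplicon_seq[10:30], "I" * 30, "AC", "II")
        assert screen_primer(pair, toy_panel, 2) == "no_primer"

    def test_tie_between_primers_is_ambiguous(self):
        from plasmacall.panel import Panel, TargetRegion

        a = TargetRegion("A", "c1", 0, 30, "+", "AAAAAAAAAA", "AAAAAAAAAA" + "C" * 20)
        b = TargetRegion("B", "c2", 0, 30, "+", "AAAAAAAAAT", "AAAAAAAAAT" + "G" * 20)
        panel = Panel(targets=(a, b), whitelist=())
        # read prefix at distance 1 from both primers
        pair = ReadPair("r", "AAAAAAAAAG" + "C" * 20, "I" * 30, "AC", "II")
        assert screen_primer(pair, panel, 2) == "ambiguous_primer"


class TestMergePair:
    CFG = EngineConfig(min_overlap=10, max_overlap_mismatch_fraction=0.1)

    def test_identical_full_overlap(self):
        seq = "ACGTACGTACGTACGTACGT"
        pair = ReadPair("r", seq, "I" * 20, revcomp(seq), "I" * 20)
        merged, qual = merge_pair(pair, self.CFG)
        assert merged == seq

    def test_read2_extends_merged_sequence(self):
        template = "A" * 0 + "ACGGATTACAGATTACACGT" + "GGCCTTAAGGCCTTAACCGG" + "TTGACCACGT"
        read1 = template[:30]
        read2_rc_region = template[10:]  # overlaps read1's last 20, extends 20
        pair = ReadPair("r", read1, "I" * 30, revcomp(read2_rc_region), "I" * len(read2_rc_region))
        merged, _ = merge_pair(pair, self.CFG)
        assert merged == template

    def test_disjoint_mates_fail(self):
        pair = ReadPair("r", "A" * 30, "I" * 30, "C" * 30, "I" * 30)
        assert merge_pair(pair, self.CFG) is None

    def test_low_quality_read1_base_complemented_by_read2(self):
        seq = "ACGTACGTACGTACGTACGT"
        broken = "T" + seq[1:]
        qual1 = chr(33 + 2) + "I" * 19  # first base Phred 2
        pair = ReadPair("r", broken, qual1, revcomp(seq), "I" * 20)
        merged, _ = merge_pair(pair, self.CFG)
        assert merged == seq  # read 2 rescued the bad base


class TestGroupFamilies:
    @staticmethod
    def _reads(keys):
        return [TaggedRead(f"r{i}", t, u, "ACGT", "IIII") for i, (t, u) in enumerate(keys)]

    def test_grouped_by_target_and_umi(self):
        reads = self._reads([("T0", "AAAA")] * 3 + [("T0", "CCCC")] * 2)
        families = group_families(reads)
        assert sorted(f.size for f in families) == [2, 3]

    def test_same_umi_different_targets_stay_separate(self):
        reads = self._reads([("T0", "AAAA"), ("T1", "AAAA")])
        assert len(group_families(reads)) == 2

    def test_directional_one_mismatch_merge(self):
        reads = self._reads([("T0", "AAAA")] * 10 + [("T0", "AAAT")])
        families = group_families(reads, merge_one_mismatch=True)
        assert len(families) == 1
        assert families[0].size == 11

    def test_directional_merge_respects_size_rule(self):
        # 3 vs 2: 3 < 2*2-1 is false -> merge allowed; 2 vs 2: 2 >= 3 false -> kept
        reads = self._reads([("T0", "AAAA")] * 2 + [("T0", "AAAT")] * 2)
        families = group_families(reads, merge_one_mismatch=True)
        assert len(families) == 2


class TestBuildConsensus:
    @staticmethod
    def _family(seqs, target="T0", umi="AAAA"):
        members = [TaggedRead(f"r{i}", target, umi, s, "I" * len(s)) for i, s in enumerate(seqs)]
        return ReadFamily(target, umi, members)

    def test_identical_members(self):
        fam = self._family(["ACGTACGT"] * 3)
        frag = build_consensus(fam, 3, 0.75, 0.1)
        assert frag.seq == "ACGTACGT"
        assert np.all(frag.per_position_agreement == 1.0)

    def test_three_to_one_majority_retained(self):
        fam = self._family(["ACGT", "ACGT", "ACGT", "AAGT"])
        frag = build_consensus(fam, 3, 0.75, 0.1)
        assert frag.seq == "ACGT"  # 3/4 = 0.75 >= min_agreement

    def test_tie_column_becomes_n(self):
        fam = self._family(["ACGT", "ACGT", "AAGT", "AAGT"])
        frag = build_consensus(fam, 3, 0.5, 0.5)
        assert frag.seq[1] == "N"

    def test_small_family_rejected(self):
        fam = self._family(["ACGT", "ACGT"])
        assert build_consensus(fam, 3, 0.75, 0.1) == "small_family"

    def test_too_many_n_rejected(self):
        fam = self._family(["AAAA", "CCCC", "GGGG"])
        assert build_consensus(fam, 3, 0.75, 0.1) == "high_n_fraction"


class TestConservation:
    def test_every_pair_accounted_once(self, toy_panel):
        t0 = toy_panel.targets[0]
        amp = t0.amplicon_seq
        good = []
        for i in range(6):
            r1 = amp[:40]
            r2 = "AACCGGTTAACC" + revcomp(amp)[:30]
            good.append(ReadPair(f"g{i}", r1, "I" * len(r1), r2, "I" * len(r2)))
        bad_primer = ReadPair("bad", "T" * 40, "I" * 40, "AACCGGTTAACC" + "A" * 20, "I" * 32)
        short2 = ReadPair("short", amp[:40], "I" * 40, "ACGT", "IIII")
        pairs = good + [bad_primer, short2]
        result = consensus_from_pairs(pairs, toy_panel, EngineConfig(min_overlap=10))
        assert sum(result.tally.values()) == len(pairs)
        assert result.tally["rejected:no_primer"] == 1
        assert result.tally["rejected:short_read2"] == 1
        assert result.tally["consensus_member"] == 6

    def test_order_invariance(self, toy_panel):
        t0 = toy_panel.targets[0]
        amp = t0.amplicon_seq
        pairs = []
        for umi in ("AAAACCCCGGGG", "TTTTGGGGCCCC"):
            for i in range(3):
                r1 = amp[:40]
                r2 = umi + revcomp(amp)[:30]
                pairs.append(ReadPair(f"{umi}:{i}", r1, "I" * len(r1), r2, "I" * len(r2)))
        fwd = consensus_from_pairs(list(pairs), toy_panel, EngineConfig(min_overlap=10))
        rev = consensus_from_pairs(list(reversed(pairs)), toy_panel, EngineConfig(min_overlap=10))
        assert [f.seq for f in fwd.fragments] == [f.seq for f in rev.fragments]
        assert [f.fragment_id for f in fwd.fragments] == [f.fragment_id for f in rev.fragments]
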