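"""Pseudo-transcript construction, ORF scanning, canonical matching and
GFF export."""

import random

import pytest

from orfclass import (AlignedRead, CanonicalFeature, GroupKey,
                      TranscriptGroup, annotate_group,
                      build_pseudo_transcript, dominant_transcripts,
                      load_feature_table, match_canonical, orf_usage_table,
                      revcomp, scan_orfs, write_gff)
from orfclass.orf_annotation import parse_gff_exons
from orfclass.read_model import Junction


def group(strand, tss, junctions, tts, counts=None):
    key = GroupKey(strand=strand, tss_cluster=tss,
                   junctions=tuple(Junction(d, a, strand)
                                   for d, a in junctions),
                   tts_cluster=tts)
    return TranscriptGroup(key=key, counts=counts or {"s1": 1})


class TestPseudoTranscript:
    def test_direct_splice_no_extension(self):
        genome = "AAATGCCCGGGTTT"
        g = group("+", 3, [(5, 9)], 11)
        pt = build_pseudo_transcript(g, genome, extension=0)
        assert pt.sequence == "ATGGGG"
        assert pt.coord_map == [3, 4, 5, 9, 10, 11]
        assert pt.extension == 0

    def test_extension_prepends_upstream_genome(self):
        genome = "ACGT" * 600
        g = group("+", 1715, [], 2000)
        pt = build_pseudo_transcript(g, genome, extension=10)
        assert pt.coord_map[0] == 1705
        assert pt.extension == 10
        assert pt.sequence[:10] == genome[1704:1714]

    def test_extension_clipped_at_genome_start(self):
        genome = "ACGT" * 10
        g = group("+", 4, [], 20)
        pt = build_pseudo_transcript(g, genome, extension=10)
        assert pt.coord_map[0] == 1
        assert pt.extension == 3

    def test_minus_strand_sequence_and_monotone_map(self):
        genome = "AAATGCCCGGGTTT"
        g = group("-", 11, [(9, 5)], 3)
        pt = build_pseudo_transcript(g, genome, extension=0)
        # transcript is revcomp of spliced plus-strand sequence
        assert pt.sequence == revcomp("ATGGGG")
        assert pt.coord_map == [11, 10, 9, 5, 4, 3]
        assert all(a > b for a, b in zip(pt.coord_map, pt.coord_map[1:]))

    def test_exon_outside_genome_fatal(self):
        with pytest.raises(ValueError, match="outside genome"):
            build_pseudo_transcript(group("+", 5, [], 100), "ACGT" * 10)


class TestScanOrfs:
    def make_pt(self, seq, strand="+"):
        g = group(strand, 1, [], len(seq))
        coords = list(range(1, len(seq) + 1)) if strand == "+" else \
            list(range(len(seq), 0, -1))
        from orfclass.orf_annotation import PseudoTranscript
        return PseudoTranscript(group=g, sequence=seq, coord_map=coords,
                                extension=0)

    def test_simple_complete_orf(self):
        calls = scan_orfs(self.make_pt("GGATGAAATAGCC"), min_aa=2)
        (c,) = calls
        assert (c.tx_start, c.tx_end, c.complete, c.aa_len) == (3, 11, True, 2)

    def test_no_aug_no_calls(self):
        assert scan_orfs(self.make_pt("GGCCTTAACCGG")) == []

    def test_short_orf_dropped_unless_canonical(self):
        pt = self.make_pt("GGATGAAATAGCC")
        assert scan_orfs(pt, min_aa=10) == []
        assert len(scan_orfs(pt, min_aa=10, canonical_starts={3})) == 1

    def test_incomplete_orf_flagged(self):
        (c,) = scan_orfs(self.make_pt("ATG" + "GCA" * 12), min_aa=5)
        assert not c.complete and c.aa_len == 13

    def test_ranks_follow_transcript_order(self):
        seq = "ATG" + "GCA" * 12 + "TAA" + "CC" + "ATG" + "AAA" * 11 + "TGA"
        calls = scan_orfs(self.make_pt(seq), min_aa=5)
        assert [c.rank for c in calls] == [1, 2]
        assert calls[0].tx_start < calls[1].tx_start

    def test_genomic_blocks_reproduce_sequence(self, noise_free_sim,
                                               noise_free_run):
        """Concatenating genome bases over an ORF's blocks reproduces the
        transcript subsequence exactly (strand-aware)."""
        genome = noise_free_sim["truth"].genome
        for ann in noise_free_run.annotations:
            for call in ann.orf_calls[:3]:
                strand = ann.group.key.strand
                parts = [genome[s - 1:e] for s, e in call.genomic_blocks]
                if strand == "+":
                    spliced = "".join(parts)
                else:
                    spliced = "".join(revcomp(p) for p in reversed(parts))
                pt = build_pseudo_transcript(ann.group, genome, extension=10)
                assert spliced == pt.sequence[call.tx_start - 1:call.tx_end]

    def test_extension_monotonicity(self):
        """Growing the extension can only add 5' sequence: existing AUGs
        keep or worsen (never improve) their rank, and their genomic starts
        are preserved."""
        rng = random.Random(21)
        bases = "ACGT"
        for _ in range(20):
            genome = "".join(rng.choice(bases) for _ in range(600))
            g = group("+", 200, [(280, 351)], 500)
            prev_positions = None
            for ext in (0, 5, 10, 20):
                pt = build_pseudo_transcript(g, genome, extension=ext)
                calls = scan_orfs(pt, min_aa=3)
                positions = [c.start_genomic for c in calls]
                if prev_positions is not None:
                    # previously seen starts remain, in the same relative
                    # order, possibly after newly-gained upstream starts
                    kept = [p for p in positions if p in set(prev_positions)]
                    assert kept == prev_positions
                    new = [p for p in positions if p not in set(prev_positions)]
                    assert all(positions.index(p) <
                               (positions.index(kept[0]) if kept else
                                len(positions)) for p in new)
                prev_positions = positions


class TestCanonicalMatching:
    FEATURES = [CanonicalFeature("F", "+", 100, expected_aa=50)]

    def call(self, start_genomic, aa_len, complete=True):
        from orfclass.orf_annotation import ORFCall
        return ORFCall(tx_start=1, tx_end=3 * aa_len + 3, complete=complete,
                       aa_len=aa_len, start_genomic=start_genomic,
                       genomic_blocks=((start_genomic,
                                        start_genomic + 3 * aa_len + 2),))

    def test_positional_match_full_length(self):
        assert match_canonical(self.call(100, 50), "+", self.FEATURES) == \
            ("F", False)

    def test_short_orf_is_truncated(self):
        assert match_canonical(self.call(100, 30), "+", self.FEATURES) == \
            ("F", True)

    def test_no_positional_match(self):
        name, _ = match_canonical(self.call(101, 50), "+", self.FEATURES)
        assert name is None

    def test_strand_must_match(self):
        name, _ = match_canonical(self.call(100, 50), "-", self.FEATURES)
        assert name is None

    def test_duplicate_start_codons_fatal_at_load(self, tmp_path):
        p = tmp_path / "features.tsv"
        p.write_text("name\tstrand\tstart_codon_pos\tcds_end\n"
                     "A\t+\t100\t250\nB\t+\t100\t400\n")
        with pytest.raises(ValueError, match="share start codon"):
            load_feature_table(str(p))


class TestAnnotateAndSummaries:
    def test_designed_second_methionine_isoform(self, noise_free_sim,
                                                noise_free_run):
        truth = noise_free_sim["truth"]
        by_key = {iso.group_key(): iso for iso in truth.isoforms}
        seen = False
        for ann in noise_free_run.annotations:
            iso = by_key[ann.group.key]
            if "second_methionine" in iso.expected_flags:
                seen = True
                assert ann.matched_feature == iso.feature
                assert ann.match_rank >= 2
                assert "second_methionine" in ann.flags
        assert seen

    def test_no_known_orf_flagged(self, noise_free_sim, noise_free_run):
        truth = noise_free_sim["truth"]
        by_key = {iso.group_key(): iso for iso in truth.isoforms}
        flagged = [ann for ann in noise_free_run.annotations
                   if "no_known_orf" in by_key[ann.group.key].expected_flags]
        assert flagged
        assert all(ann.matched_feature is None and
                   "no_known_orf" in ann.flags for ann in flagged)

    def test_dominant_is_count_argmax(self):
        genome = "C" * 50 + "ATG" + "GCAGAAGCTAAAGCCGAAGCTAAAGCCGAA" + "TAA" + "C" * 50
        feats = [CanonicalFeature("F", "+", 51, expected_aa=10)]
        g_big = group("+", 40, [], 120, counts={"s1": 120})
        g_small = group("+", 45, [], 130, counts={"s1": 7})
        anns = [annotate_group(g, genome, feats, extension=12, min_aa=5)
                for g in (g_big, g_small)]
        assert all(a.matched_feature == "F" and a.match_rank == 1
                   for a in anns)
        dom = dominant_transcripts(anns)
        assert dom["F"] is g_big

    def test_dominant_tie_prefers_smaller_tss(self):
        genome = "C" * 50 + "ATG" + "GCA" * 10 + "TAA" + "C" * 50
        feats = [CanonicalFeature("F", "+", 51)]
        g1 = group("+", 45, [], 120, counts={"s1": 9})
        g2 = group("+", 40, [], 130, counts={"s1": 9})
        anns = [annotate_group(g, genome, feats, extension=12, min_aa=5)
                for g in (g1, g2)]
        assert dominant_transcripts(anns)["F"].key.tss_cluster == 40

    def test_usage_percentages_definition(self):
        genome = ("C" * 50 + "ATG" + "GCA" * 10 + "TAA" + "C" * 444)
        feats = [CanonicalFeature("X", "+", 51)]
        coding = [group("+", 48, [], 120, counts={"s1": 6})]
        noncoding = [group("+", 300, [], 420, counts={"s1": 3})]
        anns = [annotate_group(g, genome, feats, extension=5, min_aa=50)
                for g in coding + noncoding]
        table = orf_usage_table(anns, ["s1"])
        assert table["X"]["s1"] == pytest.approx(100 * 6 / 9)
        assert table["no known ORF"]["s1"] == pytest.approx(100 * 3 / 9)

    def test_gff_roundtrip(self, noise_free_run, tmp_path):
        path = tmp_path / "groups.gff3"
        write_gff(noise_free_run.annotations, str(path), mode="all")
        models = parse_gff_exons(str(path))
        expect = {}
        for i, ann in enumerate(sorted(noise_free_run.annotations,
                                       key=lambda a: a.group.key.sort_key()),
                                start=1):
            expect[f"group{i}"] = (ann.group.key.strand,
                                   tuple(ann.group.exon_model()))
        assert models == expect

    def test_gff_lines_are_valid(self, noise_free_run, tmp_path):
        path = tmp_path / "groups.gff3"
        write_gff(noise_free_run.annotations, str(path), mode="all")
        lines = [l.split("\t") for l in path.read_text().splitlines()
                 if l and not l.startswith("#")]
        assert lines
        for f in lines:
            assert len(f) == 9
            assert int(f[3]) <= int(f[4])
            assert f[6] in "+-"
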