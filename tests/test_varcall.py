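from __future__ import annotations

import math
from functools import lru_cache

import pytest
from cyvcf2 import VCF

from mipkit.genomic_io import ReferenceSequence, TargetRegion
from mipkit.readproc import MoleculeGroup
from mipkit.varcall import (
    CallerError,
    CallerParams,
    PileupColumn,
    align_insert,
    call_variants,
    genotype,
    pileup,
    variant_calls,
    write_vcf,
)


def group(probe_id, insert, tag="AAAAAAAA"):
    return MoleculeGroup(
        probe_id=probe_id,
        tag=tag,
        member_pair_ids=["m0"],
        member_inserts=[insert],
        consensus_insert=insert,
    )


class TestAlignInsert:
    def test_identity_is_all_match_score_zero(self):
        a = align_insert("ACGTACGT", "ACGTACGT")
        assert a.cigar == (("=", 8),)
        assert a.score == 0

    def test_single_substitution(self):
        a = align_insert("ACGAACGT", "ACGTACGT")
        assert a.cigar == (("=", 3), ("X", 1), ("=", 4))
        assert a.score == 1

    def test_single_deletion_is_one_contiguous_run(self):
        a = align_insert("ACGTCGT", "ACGTACGT")
        assert a.score == 1
        assert sum(1 for op, _ in a.cigar if op == "D") == 1
        assert sum(n for op, n in a.cigar if op == "D") == 1

    def test_multibase_deletion_stays_contiguous(self):
        ref = "ACGTAACCGGTTACGT"
        ins = ref[:5] + ref[11:]
        a = align_insert(ins, ref)
        assert a.score == 6
        d_runs = [n for op, n in a.cigar if op == "D"]
        assert d_runs == [6]

    def test_deletion_in_homopolymer_is_leftmost(self):
        a = align_insert("GAAAC", "GAAAAC")
        (op0, n0), (op1, n1), *_ = a.cigar
        # the single D run must sit at the start of the A run
        ops = []
        for op, n in a.cigar:
            ops.extend([op] * n)
        assert "D" in ops
        first_d = ops.index("D")
        assert first_d == 1  # G matches, then the gap opens at the first A

    def test_empty_insert_rejected(self):
        with pytest.raises(CallerError):
            align_insert("", "ACGT")

    def test_band_violation_rejected(self):
        with pytest.raises(CallerError):
            align_insert("A", "A" * 20, band=12)

    def test_matches_enumeration_oracle_on_small_strings(self):
        @lru_cache(maxsize=None)
        def edit(a: str, b: str) -> int:
            if not a:
                return len(b)
            if not b:
                return len(a)
            return min(
                edit(a[1:], b[1:]) + (a[0] != b[0]),
                edit(a[1:], b) + 1,
                edit(a, b[1:]) + 1,
            )

        strings = [
            "".join(s)
            for n in range(1, 5)
            for s in __import__("itertools").product("AC", repeat=n)
        ]
        for a in strings:
            for b in strings:
                assert align_insert(a, b, band=12).score == edit(a, b)


def make_reference(seq="ACGT" * 40):
    return {"c": ReferenceSequence("c", seq)}


def make_probe(gap_start, gap_end, seq, probe_id="p0"):
    from mipkit.panel_design import MipProbe

    return MipProbe(
        probe_id=probe_id,
        contig="c",
        scan_strand="+",
        ext_arm_seq=seq[gap_start - 16 : gap_start],
        ext_arm_start=gap_start - 16,
        ext_arm_end=gap_start,
        lig_arm_seq=seq[gap_end : gap_end + 20],
        lig_arm_start=gap_end,
        lig_arm_end=gap_end + 20,
        gap_start=gap_start,
        gap_end=gap_end,
        tag_len=8,
        backbone="",
    )


class TestPileup:
    def test_single_molecule_gives_unit_depth_across_span(self):
        ref = make_reference()
        seq = ref["c"].sequence
        probe = make_probe(20, 60, seq)
        targets = [TargetRegion("c", 0, 160)]
        cols = pileup([group("p0", seq[20:60])], [probe], ref, targets)
        assert len(cols) == 40
        assert all(col.depth == 1 for col in cols)
        assert all(col.counts[col.ref_base] == 1 for col in cols)

    def test_uncovered_positions_have_no_column(self):
        ref = make_reference()
        seq = ref["c"].sequence
        probe = make_probe(20, 60, seq)
        targets = [TargetRegion("c", 0, 160)]
        cols = pileup([group("p0", seq[20:60])], [probe], ref, targets)
        positions = {c.pos for c in cols}
        assert positions == set(range(20, 60))

    def test_deletion_allele_anchored_at_left_normalized_position(self):
        from mipkit.capture_sim import left_normalize, random_reference

        contig = random_reference("c", 160, seed=3)
        ref = {"c": contig}
        seq = contig.sequence
        probe = make_probe(20, 60, seq)
        targets = [TargetRegion("c", 0, 160)]
        insert = seq[20:40] + seq[43:60]  # drop 3 bases at ref pos 40..42
        norm_pos, norm_ref, _ = left_normalize(contig, 39, seq[39:43], seq[39])
        cols = {c.pos: c for c in pileup([group("p0", insert)], [probe], ref, targets)}
        assert cols[norm_pos].counts == {f"-{norm_ref[1:]}": 1}
        # deleted span contributes no base observations
        for pos in range(norm_pos + 1, norm_pos + 4):
            assert pos not in cols

    def test_insertion_allele_anchored_at_left_normalized_position(self):
        from mipkit.capture_sim import left_normalize, random_reference

        contig = random_reference("c", 160, seed=3)
        ref = {"c": contig}
        seq = contig.sequence
        probe = make_probe(20, 60, seq)
        targets = [TargetRegion("c", 0, 160)]
        inserted = "TTT" if seq[39] != "T" and seq[40] != "T" else "GGG"
        insert = seq[20:40] + inserted + seq[40:60]
        norm_pos, _, norm_alt = left_normalize(
            contig, 39, seq[39], seq[39] + inserted
        )
        cols = {c.pos: c for c in pileup([group("p0", insert)], [probe], ref, targets)}
        assert cols[norm_pos].counts == {f"+{norm_alt[1:]}": 1}
        assert cols[40].counts == {seq[40]: 1}


def likelihood_oracle(n_ref, n_alt, e):
    """Direct evaluation of the three genotype likelihood products."""
    p_match, p_err = 1 - e, e / 3
    p_het = 0.5 * p_match + 0.5 * p_err
    return {
        "0/0": n_ref * math.log(p_match) + n_alt * math.log(p_err),
        "0/1": (n_ref + n_alt) * math.log(p_het),
        "1/1": n_ref * math.log(p_err) + n_alt * math.log(p_match),
    }


class TestGenotype:
    def test_overwhelming_ref_evidence_is_hom_ref(self):
        col = PileupColumn("c", 5, "A", {"A": 30})
        call = genotype(col)
        assert call.genotype == "0/0" and call.alt is None

    def test_balanced_counts_match_likelihood_oracle(self):
        col = PileupColumn("c", 5, "A", {"A": 12, "G": 13})
        call = genotype(col)
        logs = likelihood_oracle(12, 13, 0.01)
        assert max(logs, key=logs.get) == "0/1"
        assert call.genotype == "0/1"
        assert (call.ref_depth, call.alt_depth) == (12, 13)

    def test_depth_below_eight_is_no_call(self):
        col = PileupColumn("c", 5, "A", {"G": 7})
        assert genotype(col) is None

    def test_hom_alt_called(self):
        col = PileupColumn("c", 5, "A", {"G": 25})
        call = genotype(col)
        assert call.genotype == "1/1" and call.alt == "G"

    def test_single_discordant_read_cannot_flip_confident_hom(self):
        """At depth 30 with default error rate, one discordant observation
        leaves the homozygous-reference call in place."""
        col = PileupColumn("c", 5, "A", {"A": 29, "G": 1})
        call = genotype(col)
        assert call is not None and call.genotype == "0/0"

    def test_marginal_column_is_no_call_not_false_het(self):
        # depth exactly 8 with one discordant: posterior too flat to emit
        col = PileupColumn("c", 5, "A", {"A": 7, "G": 1})
        assert genotype(col) is None

    def test_indel_allele_formatted_as_vcf_pair(self):
        col = PileupColumn("c", 9, "T", {"T": 10, "-ACG": 10})
        call = genotype(col)
        assert call.genotype == "0/1"
        assert (call.ref, call.alt) == ("TACG", "T")


class TestWriteVcf:
    def _call(self, **kw):
        from mipkit.varcall import GenotypeCall

        defaults = dict(
            contig="c", pos=0, ref="A", alt="G", genotype="0/1",
            depth=20, ref_depth=10, alt_depth=10, gq=99.0,
        )
        defaults.update(kw)
        return GenotypeCall(**defaults)

    def test_internal_zero_becomes_pos_one(self, tmp_path):
        ref = make_reference("AGT" * 20)
        path = tmp_path / "o.vcf"
        write_vcf(path, [self._call()], ref)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert line.split("\t")[1] == "1"

    def test_hand_constructed_record_equality(self, tmp_path):
        ref = make_reference("AGT" * 20)
        path = tmp_path / "o.vcf"
        write_vcf(path, [self._call(pos=4, ref="A", alt="ATT")], ref, sample_id="S1")
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert line == "c\t5\t.\tA\tATT\t99\tPASS\t.\tGT:DP:AD:GQ\t0/1:20:10,10:99"

    def test_round_trip_through_cyvcf2(self, tmp_path):
        ref = make_reference("AGT" * 20)
        calls = [
            self._call(pos=2),
            self._call(pos=10, ref="G", alt="GAC", genotype="1/1"),
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(path, calls, ref)
        records = list(VCF(str(path)))
        assert [(r.POS, r.REF, r.ALT[0]) for r in records] == [
            (3, "A", "G"),
            (11, "G", "GAC"),
        ]
        gts = ["/".join(map(str, sorted(r.genotypes[0][:-1]))) for r in records]
        assert gts == ["0/1", "1/1"]

    def test_unsorted_calls_rejected(self, tmp_path):
        ref = make_reference("AGT" * 20)
        with pytest.raises(CallerError):
            write_vcf(tmp_path / "x.vcf", [self._call(pos=9), self._call(pos=2)], ref)
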