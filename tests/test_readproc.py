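from __future__ import annotations

import random
from collections import defaultdict

import numpy as np
import pytest

from mipkit.capture_sim import SimConfig, plant_variants, simulate_capture
from mipkit.genomic_io import revcomp
from mipkit.readproc import (
    Assignment,
    PanelError,
    Unassigned,
    assign_read_pair,
    build_probe_index,
    consensus,
    dedup_molecules,
    merge_insert,
    process_read_pairs,
)


def brute_force_assign(r1, r2, probes, tag_len, max_mismatch=1):
    """Oracle: exhaustive Hamming comparison over every probe."""
    hits = []
    r2_after = r2[tag_len:]
    for p in probes:
        ext, ligrc = p.ext_arm_seq, revcomp(p.lig_arm_seq)
        d1 = sum(a != b for a, b in zip(r1[: len(ext)], ext))
        d2 = sum(a != b for a, b in zip(r2_after[: len(ligrc)], ligrc))
        if d1 <= max_mismatch and d2 <= max_mismatch:
            hits.append((p.probe_id, d1 + d2))
    return hits


def perfect_pair(probe, insert, tag, read_len=100):
    r1 = (probe.ext_arm_seq + insert)[:read_len].ljust(read_len, "N")
    r2 = (tag + revcomp(insert + probe.lig_arm_seq))[:read_len].ljust(read_len, "N")
    return r1, r2


class TestProbeIndex:
    def test_self_lookup_returns_own_probe(self, small_panel, small_reference):
        probes, _ = small_panel
        index = build_probe_index(probes)
        seq = small_reference["chrS"].sequence
        for p in probes:
            insert = seq[p.gap_start : p.gap_end]
            r1, r2 = perfect_pair(p, insert, "A" * p.tag_len)
            result = assign_read_pair("q", r1, r2, index)
            assert isinstance(result, Assignment)
            assert result.probe_id == p.probe_id
            assert result.arm_mismatches == 0

    def test_duplicate_arm_pair_rejected(self, small_panel):
        probes, _ = small_panel
        with pytest.raises(PanelError, match="identical"):
            build_probe_index(list(probes) + [probes[0]])

    def test_random_queries_match_linear_scan_oracle(self, small_panel, small_reference):
        probes, _ = small_panel
        index = build_probe_index(probes)
        seq = small_reference["chrS"].sequence
        rng = np.random.default_rng(17)
        bases = "ACGT"
        for _ in range(100):
            p = probes[rng.integers(len(probes))]
            insert = seq[p.gap_start : p.gap_end]
            r1, r2 = perfect_pair(p, insert, "ACGTACGT")
            # sprinkle 0-3 substitutions anywhere in the reads
            r1, r2 = list(r1), list(r2)
            for _ in range(int(rng.integers(0, 4))):
                which = r1 if rng.random() < 0.5 else r2
                i = int(rng.integers(len(which)))
                which[i] = bases[int(rng.integers(4))]
            r1, r2 = "".join(r1), "".join(r2)
            hits = brute_force_assign(r1, r2, probes, index.tag_len)
            result = assign_read_pair("q", r1, r2, index)
            if len(hits) == 1:
                assert isinstance(result, Assignment)
                assert result.probe_id == hits[0][0]
                assert result.arm_mismatches == hits[0][1]
            elif not hits:
                assert isinstance(result, Unassigned) and result.reason == "no_match"
            else:
                assert isinstance(result, Unassigned) and result.reason == "ambiguous"


class TestAssignReadPair:
    def test_one_arm_substitution_tolerated_two_rejected(self, small_panel, small_reference):
        probes, _ = small_panel
        index = build_probe_index(probes)
        seq = small_reference["chrS"].sequence
        p = probes[0]
        insert = seq[p.gap_start : p.gap_end]
        r1, r2 = perfect_pair(p, insert, "ACGTACGT")
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        r1_one = flip[r1[0]] + r1[1:]
        result = assign_read_pair("q", r1_one, r2, index)
        assert isinstance(result, Assignment) and result.arm_mismatches == 1
        r1_two = flip[r1[0]] + flip[r1[1]] + r1[2:]
        result = assign_read_pair("q", r1_two, r2, index)
        assert isinstance(result, Unassigned) and result.reason == "no_match"

    def test_short_read_unassigned(self, small_panel):
        probes, _ = small_panel
        index = build_probe_index(probes)
        result = assign_read_pair("q", "ACGT", "ACGT", index)
        assert isinstance(result, Unassigned) and result.reason == "short"

    def test_inserts_contain_no_arm_bases(self, small_panel, small_reference):
        probes, _ = small_panel
        index = build_probe_index(probes)
        seq = small_reference["chrS"].sequence
        p = probes[3]
        insert = seq[p.gap_start : p.gap_end]
        r1, r2 = perfect_pair(p, insert, "GGGGCCCC")
        a = assign_read_pair("q", r1, r2, index)
        assert insert.startswith(a.insert_r1)
        assert insert.endswith(a.insert_r2)
        assert a.tag == "GGGGCCCC"


class TestMergeInsert:
    def test_reconstructs_full_insert_from_fragments(self, small_panel, small_reference):
        probes, _ = small_panel
        index = build_probe_index(probes)
        seq = small_reference["chrS"].sequence
        for p in probes[:6]:
            insert = seq[p.gap_start : p.gap_end]
            r1, r2 = perfect_pair(p, insert, "ACACACAC")
            a = assign_read_pair("q", r1, r2, index)
            assert merge_insert(a, len(insert)) == insert

    def test_reconstructs_deletion_shortened_insert(self, small_panel, small_reference):
        probes, _ = small_panel
        index = build_probe_index(probes)
        seq = small_reference["chrS"].sequence
        p = probes[2]
        ref_insert = seq[p.gap_start : p.gap_end]
        mutated = ref_insert[:50] + ref_insert[58:]  # 8 nt deletion
        r1, r2 = perfect_pair(p, mutated, "ACACACAC")
        a = assign_read_pair("q", r1, r2, index)
        assert merge_insert(a, len(ref_insert)) == mutated


class TestDedup:
    def test_identical_pairs_collapse_to_one_group(self, small_panel, small_reference):
        probes, _ = small_panel
        index = build_probe_index(probes)
        seq = small_reference["chrS"].sequence
        p = probes[0]
        insert = seq[p.gap_start : p.gap_end]
        r1, r2 = perfect_pair(p, insert, "AACCGGTT")
        a1 = assign_read_pair("q1", r1, r2, index)
        a2 = assign_read_pair("q2", r1, r2, index)
        groups = dedup_molecules([a1, a2], index)
        assert len(groups) == 1
        assert groups[0].n_members == 2
        assert groups[0].consensus_insert == insert

    def test_group_count_matches_ledger_distinct_keys(self, small_simulation):
        groups, unassigned = process_read_pairs(
            small_simulation["r1"],
            small_simulation["r2"],
            small_simulation["probes"],
        )
        assert not unassigned
        ledger_keys = {
            (row.probe_id, row.tag) for row in small_simulation["ledger"]
        }
        assert len(groups) == len(ledger_keys)
        assert {(g.probe_id, g.tag) for g in groups} == ledger_keys

    def test_group_count_independent_of_duplication_mean(
        self, small_reference, small_panel
    ):
        probes, _ = small_panel
        haps, _ = plant_variants(small_reference, [])
        counts = []
        for dup in (1.0, 3.0):
            config = SimConfig(
                molecules_per_probe=40, duplication_mean=dup, seed=23
            )
            r1, r2, _ = simulate_capture(probes, haps, config)
            groups, _ = process_read_pairs(r1, r2, probes)
            counts.append({(g.probe_id, g.tag) for g in groups})
        assert counts[0] == counts[1]

    def test_group_set_invariant_under_read_order(self, small_simulation):
        r1, r2 = list(small_simulation["r1"]), list(small_simulation["r2"])
        pairs = list(zip(r1, r2))
        random.Random(5).shuffle(pairs)
        shuffled_r1, shuffled_r2 = [a for a, _ in pairs], [b for _, b in pairs]
        base, _ = process_read_pairs(r1, r2, small_simulation["probes"])
        shuf, _ = process_read_pairs(shuffled_r1, shuffled_r2, small_simulation["probes"])
        assert {(g.probe_id, g.tag, g.consensus_insert) for g in base} == {
            (g.probe_id, g.tag, g.consensus_insert) for g in shuf
        }

    def test_no_arm_leakage_into_consensus(self, small_simulation):
        groups, _ = process_read_pairs(
            small_simulation["r1"],
            small_simulation["r2"],
            small_simulation["probes"],
        )
        by_id = {p.probe_id: p for p in small_simulation["probes"]}
        for g in groups:
            p = by_id[g.probe_id]
            assert not g.consensus_insert.startswith(p.ext_arm_seq)
            assert not g.consensus_insert.endswith(p.lig_arm_seq)


def directional_cluster_oracle(counts: dict[str, int]) -> dict[str, str]:
    """All-pairs Hamming oracle for the directional tag-merge rule."""
    parent = {}
    tags = list(counts)
    for tag in sorted(tags, key=lambda t: (counts[t], t)):
        candidates = [
            t
            for t in tags
            if t != tag
            and t not in parent
            and sum(a != b for a, b in zip(tag, t)) == 1
            and 2 * counts[tag] <= counts[t]
        ]
        if candidates:
            parent[tag] = max(candidates, key=lambda t: (counts[t], t))
    return parent


class TestTagClustering:
    def _assignments_with_tag_errors(self, small_panel, small_reference, rate, seed):
        probes, _ = small_panel
        index = build_probe_index(probes)
        seq = small_reference["chrS"].sequence
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        assignments, true_keys = [], set()
        qid = 0
        for p in probes[:4]:
            insert = seq[p.gap_start : p.gap_end]
            for m in range(30):
                tag = "".join(bases[i] for i in rng.integers(0, 4, size=8))
                true_keys.add((p.probe_id, tag))
                for _ in range(int(rng.integers(4, 9))):  # duplicates
                    noisy = list(tag)
                    for i in range(8):
                        if rng.random() < rate:
                            noisy[i] = bases[int(rng.integers(4))]
                    r1, r2 = perfect_pair(p, insert, "".join(noisy))
                    assignments.append(
                        assign_read_pair(f"q{qid}", r1, r2, index)
                    )
                    qid += 1
        return assignments, true_keys, index

    def test_clustering_recovers_true_molecules(self, small_panel, small_reference):
        assignments, true_keys, index = self._assignments_with_tag_errors(
            small_panel, small_reference, rate=0.05, seed=31
        )
        groups = dedup_molecules(assignments, index, cluster_hamming1=True)
        got = {(g.probe_id, g.tag) for g in groups}
        recovered = len(got & true_keys) / len(true_keys)
        assert recovered >= 0.99

    def test_merge_decisions_match_all_pairs_oracle(self, small_panel, small_reference):
        assignments, _, index = self._assignments_with_tag_errors(
            small_panel, small_reference, rate=0.05, seed=37
        )
        raw = defaultdict(int)
        for a in assignments:
            raw[(a.probe_id, a.tag)] += 1
        expected_keys = set()
        for probe_id in {a.probe_id for a in assignments}:
            counts = {t: n for (pid, t), n in raw.items() if pid == probe_id}
            merged = directional_cluster_oracle(counts)
            expected_keys |= {
                (probe_id, t) for t in counts if t not in merged
            }
        groups = dedup_molecules(assignments, index, cluster_hamming1=True)
        assert {(g.probe_id, g.tag) for g in groups} == expected_keys


class TestConsensus:
    def test_single_member_identity(self):
        assert consensus(["ACGT"]) == "ACGT"

    def test_two_member_disagreement_becomes_n(self):
        assert consensus(["ACGT", "ACTT"]) == "ACNT"

    def test_majority_corrects_single_error(self):
        members = ["ACGTACGT"] * 4 + ["ACGTACTT"]
        # column-tally oracle
        expected = "".join(
            max("ACGT", key=lambda b: sum(m[i] == b for m in members))
            for i in range(8)
        )
        assert consensus(members) == expected == "ACGTACGT"

    def test_n_votes_are_ignored(self):
        assert consensus(["ANGT", "ACGT", "ACGT"]) == "ACGT"

    def test_modal_length_wins(self):
        assert consensus(["ACGT", "ACGT", "ACG"]) == "ACGT"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            consensus([])
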