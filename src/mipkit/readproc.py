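"""Arm-anchored read processing: probe assignment, tag extraction,
molecular-tag deduplication, and per-molecule consensus.

For a targeted panel with known arm sequences, matching read prefixes
against the arms replaces genome-wide alignment: read 1 must start with a
probe's extension arm and read 2 (after the molecular tag) with the reverse
complement of its ligation arm.  Reads sharing a (probe, tag) key are PCR
duplicates of one captured molecule and are collapsed to a single consensus
insert, so downstream depth and genotype evidence is counted once per
molecule.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .capture_sim import FastqRecord
from .genomic_io import revcomp
from .panel_design import MipProbe


class PanelError(ValueError):
    """Raised when a panel cannot support unambiguous read assignment."""


@dataclass(frozen=True)
class _ArmRecord:
    probe_id: str
    ext_arm: str          # expected read-1 prefix
    lig_arm_rc: str       # expected read-2 prefix after the tag
    gap_start: int
    gap_end: int
    contig: str


class ProbeIndex:
    """Exact-lookup plus Hamming-fallback index from arm prefixes to probes."""

    def __init__(self, panel: Sequence[MipProbe]):
        if not panel:
            raise PanelError("empty panel")
        tag_lens = {p.tag_len for p in panel}
        if len(tag_lens) != 1:
            raise PanelError("probes disagree on tag length")
        self.tag_len = tag_lens.pop()
        self.records: list[_ArmRecord] = []
        seen: dict[tuple[str, str], str] = {}
        for p in panel:
            key = (p.ext_arm_seq, p.lig_arm_seq)
            if key in seen:
                raise PanelError(
                    f"probes {seen[key]} and {p.probe_id} share an identical "
                    "(ext_arm, lig_arm) pair; assignment would be unresolvable"
                )
            seen[key] = p.probe_id
            self.records.append(
                _ArmRecord(
                    probe_id=p.probe_id,
                    ext_arm=p.ext_arm_seq,
                    lig_arm_rc=revcomp(p.lig_arm_seq),
                    gap_start=p.gap_start,
                    gap_end=p.gap_end,
                    contig=p.contig,
                )
            )
        self.by_id = {r.probe_id: r for r in self.records}
        # exact dictionaries per (ext_len, lig_len) combination for the fast path
        self._combos = sorted(
            {(len(r.ext_arm), len(r.lig_arm_rc)) for r in self.records}
        )
        self._exact: dict[tuple[int, int], dict[tuple[str, str], _ArmRecord]] = {
            combo: {} for combo in self._combos
        }
        for r in self.records:
            combo = (len(r.ext_arm), len(r.lig_arm_rc))
            self._exact[combo][(r.ext_arm, r.lig_arm_rc)] = r
        self.max_arm_len = max(max(len(r.ext_arm), len(r.lig_arm_rc)) for r in self.records)
        # If any two probes have near-identical arms, an exact hit does not
        # rule out a second candidate within the mismatch budget, so the
        # exact fast path must defer to the full scan.
        self.ambiguous = False
        for i, a in enumerate(self.records):
            for b in self.records[i + 1 :]:
                me = min(len(a.ext_arm), len(b.ext_arm))
                ml = min(len(a.lig_arm_rc), len(b.lig_arm_rc))
                de = _hamming_leq(a.ext_arm[:me], b.ext_arm[:me], 2)
                if de is None:
                    continue
                dl = _hamming_leq(a.lig_arm_rc[:ml], b.lig_arm_rc[:ml], 2)
                if dl is not None:
                    self.ambiguous = True
                    break
            if self.ambiguous:
                break

    def lookup_exact(self, r1: str, r2_after_tag: str) -> _ArmRecord | None:
        for combo in self._combos:
            el, ll = combo
            rec = self._exact[combo].get((r1[:el], r2_after_tag[:ll]))
            if rec is not None:
                return rec
        return None


def _hamming_leq(a: str, b: str, limit: int) -> int | None:
    """Hamming distance of equal-length strings, or None if above limit."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


@dataclass(frozen=True)
class Assignment:
    pair_id: str
    probe_id: str
    tag: str
    insert_r1: str  # plus-strand insert prefix (arm removed)
    insert_r2: str  # plus-strand insert suffix (tag and arm removed)
    arm_mismatches: int


@dataclass(frozen=True)
class Unassigned:
    pair_id: str
    reason: str  # "short" | "no_match" | "ambiguous"


def assign_read_pair(
    pair_id: str,
    r1_seq: str,
    r2_seq: str,
    index: ProbeIndex,
    max_mismatch: int = 1,
) -> Assignment | Unassigned:
    """Assign one read pair to a probe by arm matching.

    The pair is assigned iff exactly one probe matches both arms within
    ``max_mismatch`` substitutions each; several matching probes yield
    ``Unassigned("ambiguous")``.  Trailing N padding is stripped from the
    recovered insert fragments.
    """
    tag_len = index.tag_len
    if len(r1_seq) < index.max_arm_len + 1 or len(r2_seq) < tag_len + index.max_arm_len + 1:
        return Unassigned(pair_id, "short")
    tag = r2_seq[:tag_len]
    r2_after_tag = r2_seq[tag_len:]

    rec = None if index.ambiguous else index.lookup_exact(r1_seq, r2_after_tag)
    mismatches = 0
    if rec is None:
        hits: list[tuple[_ArmRecord, int]] = []
        for cand in index.records:
            d1 = _hamming_leq(r1_seq[: len(cand.ext_arm)], cand.ext_arm, max_mismatch)
            if d1 is None:
                continue
            d2 = _hamming_leq(
                r2_after_tag[: len(cand.lig_arm_rc)], cand.lig_arm_rc, max_mismatch
            )
            if d2 is None:
                continue
            hits.append((cand, d1 + d2))
        if not hits:
            return Unassigned(pair_id, "no_match")
        if len(hits) > 1:
            return Unassigned(pair_id, "ambiguous")
        rec, mismatches = hits[0]

    insert_r1 = r1_seq[len(rec.ext_arm) :].rstrip("N")
    insert_r2_rc = r2_after_tag[len(rec.lig_arm_rc) :].rstrip("N")
    return Assignment(
        pair_id=pair_id,
        probe_id=rec.probe_id,
        tag=tag,
        insert_r1=insert_r1,
        insert_r2=revcomp(insert_r2_rc),
        arm_mismatches=mismatches,
    )


def build_probe_index(panel: Sequence[MipProbe]) -> ProbeIndex:
    return ProbeIndex(panel)


def merge_insert(
    assignment: Assignment, expected_len: int, band: int = 12
) -> str:
    """Reconstruct the molecule insert from the two trimmed read fragments.

    ``insert_r1`` is a prefix and ``insert_r2`` a suffix of the insert.  The
    insert length L is searched within ``band`` of the probe's reference
    gap-fill length; for each candidate L the fragments' implied overlap is
    scored by mismatches (N is a wildcard) and the best-supported L wins
    (ties resolved toward the expected length, then the shorter insert).
    Overlap disagreements between the fragments become N.
    """
    p_frag = assignment.insert_r1
    s_frag = assignment.insert_r2
    p, s = len(p_frag), len(s_frag)
    lo = max(p, s, expected_len - band)
    hi = min(p + s, expected_len + band)
    if lo > hi:
        lo = hi = max(p, s)
    best: tuple[int, int, int] | None = None  # (mismatches, |L-expected|, L)
    for cand_len in range(lo, hi + 1):
        off = cand_len - s  # index in insert where suffix starts
        mism = 0
        for i in range(off, p):
            a, b = p_frag[i], s_frag[i - off]
            if a != b and a != "N" and b != "N":
                mism += 1
        key = (mism, abs(cand_len - expected_len), cand_len)
        if best is None or key < best:
            best = key
    assert best is not None
    length = best[2]
    off = length - s
    out = list(p_frag) + ["N"] * (length - p)
    for i in range(off, length):
        b = s_frag[i - off]
        if i < p:
            a = p_frag[i]
            if a == "N":
                out[i] = b
            elif b != "N" and a != b:
                out[i] = "N"
        else:
            out[i] = b
    return "".join(out)


@dataclass
class MoleculeGroup:
    """Reads sharing a (probe, molecular tag) key, collapsed to one insert."""

    probe_id: str
    tag: str
    member_pair_ids: list[str]
    member_inserts: list[str]
    consensus_insert: str = ""

    @property
    def n_members(self) -> int:
        return len(self.member_pair_ids)


def consensus(inserts: Sequence[str]) -> str:
    """Per-position majority base over members of the modal insert length.

    N votes are treated as missing data; an exact tie (or no informative
    vote) yields N.  The consensus length is the modal member length
    (smaller length wins a modal tie).
    """
    if not inserts:
        raise ValueError("consensus of empty group")
    lengths = Counter(len(s) for s in inserts)
    top = max(lengths.values())
    length = min(l for l, c in lengths.items() if c == top)
    members = [s for s in inserts if len(s) == length]
    if len(members) == 1:
        return members[0]
    out = []
    for i in range(length):
        tally = Counter(s[i] for s in members if s[i] != "N")
        if not tally:
            out.append("N")
            continue
        ranked = tally.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out.append("N")
        else:
            out.append(ranked[0][0])
    return "".join(out)


def dedup_molecules(
    assignments: Iterable[Assignment],
    index: ProbeIndex,
    cluster_hamming1: bool = False,
    band: int = 12,
) -> list[MoleculeGroup]:
    """Group assignments by (probe, tag) and build per-molecule consensus.

    With ``cluster_hamming1`` a directional rule merges a tag into a
    Hamming-1 neighbor when its read count is at most half the neighbor's,
    absorbing tag sequencing errors into the true molecule.  Groups are
    returned sorted by (probe_id, tag) so the result is independent of read
    order.
    """
    buckets: dict[tuple[str, str], list[Assignment]] = defaultdict(list)
    for a in assignments:
        buckets[(a.probe_id, a.tag)].append(a)

    if cluster_hamming1:
        by_probe: dict[str, list[str]] = defaultdict(list)
        for probe_id, tag in buckets:
            by_probe[probe_id].append(tag)
        for probe_id, tags in by_probe.items():
            counts = {t: len(buckets[(probe_id, t)]) for t in tags}
            # visit small tags first; candidates ranked by size then tag
            for tag in sorted(tags, key=lambda t: (counts[t], t)):
                parents = [
                    t
                    for t in tags
                    if t != tag
                    and (probe_id, t) in buckets
                    and _hamming_leq(tag, t, 1) == 1
                    and 2 * counts[tag] <= counts[t]
                ]
                if not parents:
                    continue
                parent = max(parents, key=lambda t: (counts[t], t))
                buckets[(probe_id, parent)].extend(buckets.pop((probe_id, tag)))

    groups: list[MoleculeGroup] = []
    for (probe_id, tag) in sorted(buckets):
        members = sorted(buckets[(probe_id, tag)], key=lambda a: a.pair_id)
        rec = index.by_id[probe_id]
        expected = rec.gap_end - rec.gap_start
        inserts = [merge_insert(a, expected, band=band) for a in members]
        groups.append(
            MoleculeGroup(
                probe_id=probe_id,
                tag=tag,
                member_pair_ids=[a.pair_id for a in members],
                member_inserts=inserts,
                consensus_insert=consensus(inserts),
            )
        )
    return groups


def process_read_pairs(
    r1: Sequence[FastqRecord],
    r2: Sequence[FastqRecord],
    panel: Sequence[MipProbe],
    max_mismatch: int = 1,
    cluster_hamming1: bool = False,
) -> tuple[list[MoleculeGroup], list[Unassigned]]:
    """Assign, deduplicate, and build consensus for a full sample."""
    if len(r1) != len(r2):
        raise ValueError("read files differ in record count")
    index = build_probe_index(panel)
    assignments: list[Assignment] = []
    unassigned: list[Unassigned] = []
    for rec1, rec2 in zip(r1, r2):
        if rec1.name != rec2.name:
            raise ValueError(f"read pair name mismatch: {rec1.name} vs {rec2.name}")
        result = assign_read_pair(rec1.name, rec1.sequence, rec2.sequence, index, max_mismatch)
        if isinstance(result, Assignment):
            assignments.append(result)
        else:
            unassigned.append(result)
    groups = dedup_molecules(assignments, index, cluster_hamming1=cluster_hamming1)
    return groups, unassigned


def write_molecule_table(path: str | Path, groups: Iterable[MoleculeGroup]) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\ttag\tn_members\tconsensus\n")
        for g in groups:
            fh.write(f"{g.probe_id}\t{g.tag}\t{g.n_members}\t{g.consensus_insert}\n")


def read_molecule_table(path: str | Path) -> list[MoleculeGroup]:
    groups: list[MoleculeGroup] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            probe_id, tag, n, cons = line.rstrip("\n").split("\t")
            groups.append(
                MoleculeGroup(
                    probe_id=probe_id,
                    tag=tag,
                    member_pair_ids=[f"member{i}" for i in range(int(n))],
                    member_inserts=[],
                    consensus_insert=cons,
                )
            )
    return groups
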