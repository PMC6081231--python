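"""Simulate smMIP capture: diploid haplotypes with planted variants, tagged
paired-end reads with PCR duplicates and base errors, and a ground-truth ledger.

The simulator emulates the read structure of an smMIP library sequenced with
paired 100 bp reads:

* read 1 starts with the extension-arm sequence (probe-derived) followed by
  the gap-fill insert copied from one haplotype;
* read 2 starts with the molecular tag, then the reverse complement of the
  ligation arm and of the insert.

Each captured molecule receives an i.i.d. random tag and a PCR duplicate
count drawn from a geometric distribution; every emitted copy is subject to
independent per-base substitution errors.  A molecule ledger records the
ground truth (probe, tag, haplotype, duplicate count) for every molecule so
that downstream deduplication and calling can be validated exactly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import ReferenceSequence, TargetRegion, revcomp
from .panel_design import MipProbe

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


class SimulationError(ValueError):
    """Raised for invalid variant specs or simulation configs."""


@dataclass(frozen=True)
class VariantSpec:
    """A variant to plant, in VCF-style representation (0-based ``pos``).

    For indels ``ref_allele`` and ``alt_allele`` share their first (anchor)
    base; either allele is at most 11 nt (1 anchor + <=10 inserted/deleted).
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    zygosity: str  # "het" | "hom"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise SimulationError(f"alleles identical at {self.contig}:{self.pos}")
        if self.zygosity not in ("het", "hom"):
            raise SimulationError(f"zygosity must be het|hom, got {self.zygosity!r}")
        if max(len(self.ref_allele), len(self.alt_allele)) > 11:
            raise SimulationError("indels longer than 10 nt are not supported")


@dataclass(frozen=True)
class SimConfig:
    molecules_per_probe: int = 100
    duplication_mean: float = 2.0
    base_error_rate: float = 0.0
    read_len: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_error_rate < 0.5):
            raise SimulationError("base_error_rate must be in [0, 0.5)")
        if self.duplication_mean < 1.0:
            raise SimulationError("duplication_mean must be >= 1")
        if self.molecules_per_probe < 1:
            raise SimulationError("molecules_per_probe must be >= 1")


@dataclass(frozen=True)
class LedgerRow:
    molecule_id: str
    probe_id: str
    tag: str
    haplotype_index: int
    duplicate_count: int


@dataclass(frozen=True)
class TruthRecord:
    """A planted variant in VCF terms (1-based POS)."""

    contig: str
    pos1: int
    ref: str
    alt: str
    genotype: str  # "0/1" | "1/1"


class Haplotype:
    """One haplotype of a contig: reference sequence plus applied variants.

    Provides ``slice_ref(start, end)``, the haplotype sequence corresponding
    to a reference interval; variants only partially inside the interval are
    left unapplied (planted variants are kept clear of interval edges by the
    site chooser).
    """

    def __init__(self, reference: ReferenceSequence, variants: Sequence[VariantSpec]):
        self.reference = reference
        self.variants = sorted(variants, key=lambda v: v.pos)
        self._starts = [v.pos for v in self.variants]
        prev_end = -1
        for v in self.variants:
            ref = reference.sequence[v.pos : v.pos + len(v.ref_allele)]
            if ref != v.ref_allele:
                raise SimulationError(
                    f"ref mismatch at {v.contig}:{v.pos}: expected "
                    f"{v.ref_allele!r}, reference has {ref!r}"
                )
            if v.pos < prev_end:
                raise SimulationError(f"overlapping variants near {v.contig}:{v.pos}")
            prev_end = v.pos + len(v.ref_allele)

    def slice_ref(self, start: int, end: int) -> str:
        seq = self.reference.sequence
        parts: list[str] = []
        cur = start
        i = bisect.bisect_left(self._starts, start)
        # step back once in case a variant starting before `start` reaches in
        if i > 0 and self._starts[i - 1] + len(self.variants[i - 1].ref_allele) > start:
            i -= 1
        for v in self.variants[i:]:
            if v.pos >= end:
                break
            if v.pos < cur or v.pos + len(v.ref_allele) > end:
                continue  # partially outside: apply reference
            parts.append(seq[cur : v.pos])
            parts.append(v.alt_allele)
            cur = v.pos + len(v.ref_allele)
        parts.append(seq[cur:end])
        return "".join(parts)

    @property
    def sequence(self) -> str:
        return self.slice_ref(0, len(self.reference))


def left_normalize(
    reference: ReferenceSequence, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Left-align and trim an allele pair against the reference (VCF style).

    Repeatedly truncates a shared terminal base (extending to the left with
    reference sequence when an allele would empty), then strips shared
    leading bases while both alleles keep at least one base.
    """
    seq = reference.sequence
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            continue
        if not ref or not alt:
            if pos == 0:
                raise SimulationError("cannot left-normalize at contig start")
            pos -= 1
            ref = seq[pos] + ref
            alt = seq[pos] + alt
            continue
        break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    return pos, ref, alt


def plant_variants(
    reference: Mapping[str, ReferenceSequence],
    specs: Sequence[VariantSpec],
) -> tuple[dict[str, tuple[Haplotype, Haplotype]], list[TruthRecord]]:
    """Apply variants to a diploid genome and return haplotypes plus truth.

    Homozygous variants go on both haplotypes, heterozygous on the first
    haplotype only.
    """
    by_contig: dict[str, list[VariantSpec]] = {c: [] for c in reference}
    for v in specs:
        if v.contig not in reference:
            raise SimulationError(f"variant on unknown contig {v.contig!r}")
        by_contig[v.contig].append(v)
    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = {}
    truth: list[TruthRecord] = []
    for contig, ref in reference.items():
        vs = sorted(by_contig[contig], key=lambda v: v.pos)
        hap0 = Haplotype(ref, vs)  # het + hom
        hap1 = Haplotype(ref, [v for v in vs if v.zygosity == "hom"])
        haplotypes[contig] = (hap0, hap1)
        for v in vs:
            truth.append(
                TruthRecord(
                    contig=contig,
                    pos1=v.pos + 1,
                    ref=v.ref_allele,
                    alt=v.alt_allele,
                    genotype="1/1" if v.zygosity == "hom" else "0/1",
                )
            )
    return haplotypes, truth


@dataclass(frozen=True)
class FastqRecord:
    name: str
    sequence: str
    quality: str


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    chars = list(seq)
    for i in hits:
        base = chars[i]
        if base not in _BASE_IDX:
            continue
        alt = _BASES[(_BASE_IDX[base] + rng.integers(1, 4)) % 4]
        chars[i] = alt
    return "".join(chars)


def _fit(seq: str, read_len: int) -> str:
    if len(seq) >= read_len:
        return seq[:read_len]
    return seq + "N" * (read_len - len(seq))


def simulate_capture(
    panel: Sequence[MipProbe],
    haplotypes: Mapping[str, tuple[Haplotype, Haplotype]],
    config: SimConfig = SimConfig(),
) -> tuple[list[FastqRecord], list[FastqRecord], list[LedgerRow]]:
    """Simulate tagged, duplicated, error-bearing read pairs for a panel.

    Molecules alternate between the two haplotypes (even molecule index ->
    haplotype 0, which carries the het variants), giving balanced allele
    sampling at heterozygous sites.
    """
    if not panel:
        raise SimulationError("empty panel")
    tag_len = panel[0].tag_len
    max_ext = max(p.ext_arm_end - p.ext_arm_start for p in panel)
    max_lig = max(p.lig_arm_end - p.lig_arm_start for p in panel)
    if config.read_len < max(max_ext, tag_len + max_lig) + 1:
        raise SimulationError(
            f"read_len {config.read_len} too short for arm+tag structure "
            f"(need >= {max(max_ext, tag_len + max_lig) + 1})"
        )
    rng = np.random.default_rng(config.seed)
    qual = "?" * config.read_len  # constant Phred 30
    r1_out: list[FastqRecord] = []
    r2_out: list[FastqRecord] = []
    ledger: list[LedgerRow] = []
    mol_counter = 0
    for probe in panel:
        if probe.contig not in haplotypes:
            raise SimulationError(f"probe {probe.probe_id} on unknown contig")
        haps = haplotypes[probe.contig]
        for m in range(config.molecules_per_probe):
            hap_idx = m % 2
            insert = haps[hap_idx].slice_ref(probe.gap_start, probe.gap_end)
            tag = "".join(_BASES[i] for i in rng.integers(0, 4, size=tag_len))
            n_copies = int(rng.geometric(1.0 / config.duplication_mean))
            mol_id = f"M{mol_counter:07d}"
            mol_counter += 1
            ledger.append(
                LedgerRow(mol_id, probe.probe_id, tag, hap_idx, n_copies)
            )
            r1_template = _fit(probe.ext_arm_seq + insert, config.read_len)
            r2_template = _fit(
                tag + revcomp(insert + probe.lig_arm_seq), config.read_len
            )
            for c in range(n_copies):
                name = f"{mol_id}.{c}"
                r1_out.append(
                    FastqRecord(
                        name,
                        _apply_errors(r1_template, rng, config.base_error_rate),
                        qual,
                    )
                )
                r2_out.append(
                    FastqRecord(
                        name,
                        _apply_errors(r2_template, rng, config.base_error_rate),
                        qual,
                    )
                )
    return r1_out, r2_out, ledger


# ---------------------------------------------------------------------------
# fixture generation


def random_reference(
    name: str, length: int, seed: int, gc: float = 0.5
) -> ReferenceSequence:
    """A random synthetic contig with independent bases at the given GC."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return ReferenceSequence(name, "".join(_BASES[i] for i in idx))


def make_exon_targets(
    contig: str,
    contig_len: int,
    n_exons: int,
    exon_len: int = 240,
    spacing: int = 360,
    first_start: int = 100,
    gene: str = "GENE1",
) -> list[TargetRegion]:
    """Evenly spaced synthetic exon targets along one contig."""
    targets: list[TargetRegion] = []
    start = first_start
    for i in range(n_exons):
        end = start + exon_len
        if end + 100 > contig_len:
            raise SimulationError(
                f"contig length {contig_len} too short for {n_exons} exons"
            )
        targets.append(TargetRegion(contig, start, end, gene, f"e{i + 1}"))
        start = end + spacing
    return targets


def choose_variant_sites(
    panel: Sequence[MipProbe],
    reference: Mapping[str, ReferenceSequence],
    n_snv: int,
    n_indel: int,
    seed: int,
    min_edge_dist: int = 12,
    min_spacing: int = 25,
    het_fraction: float = 0.5,
) -> list[VariantSpec]:
    """Draw non-conflicting variant positions safely interior to gap fills.

    A position is eligible only if it lies at least ``min_edge_dist`` bases
    from both ends of every gap fill covering it, so indels are always fully
    contained in each observing insert.  Indel sites are additionally kept
    more than one gap-fill window apart from each other, so no single insert
    carries two indels and its length stays within the read-merging and
    alignment bands.  Indel alleles are left-normalized against the
    reference at generation time.
    """
    rng = np.random.default_rng(seed)
    eligible: dict[str, np.ndarray] = {}
    for contig, ref in reference.items():
        inside = np.zeros(len(ref), dtype=bool)
        near_edge = np.zeros(len(ref), dtype=bool)
        for p in panel:
            if p.contig != contig:
                continue
            inside[p.gap_start : p.gap_end] = True
            near_edge[p.gap_start : min(p.gap_start + min_edge_dist, len(ref))] = True
            near_edge[max(0, p.gap_end - min_edge_dist) : p.gap_end] = True
        ok = inside & ~near_edge
        # avoid N stretches
        seq_arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        ok &= seq_arr != ord("N")
        eligible[contig] = np.nonzero(ok)[0]
    all_sites = [
        (contig, int(pos)) for contig, arr in eligible.items() for pos in arr
    ]
    rng.shuffle(all_sites)
    max_gap = max(p.gap_end - p.gap_start for p in panel)
    indel_spacing = max_gap + min_spacing
    chosen: list[tuple[str, int, bool]] = []  # (contig, pos, is_indel)
    taken: dict[str, list[int]] = {c: [] for c in reference}
    indel_taken: dict[str, list[int]] = {c: [] for c in reference}
    n_snv_left, n_indel_left = n_snv, n_indel
    for contig, pos in all_sites:
        if n_snv_left == 0 and n_indel_left == 0:
            break
        if any(abs(pos - q) < min_spacing for q in taken[contig]):
            continue
        if n_indel_left and not any(
            abs(pos - q) < indel_spacing for q in indel_taken[contig]
        ):
            chosen.append((contig, pos, True))
            indel_taken[contig].append(pos)
            n_indel_left -= 1
        elif n_snv_left:
            chosen.append((contig, pos, False))
            n_snv_left -= 1
        else:
            continue
        taken[contig].append(pos)
    if n_snv_left or n_indel_left:
        raise SimulationError(
            f"only {len(chosen)} eligible sites for {n_snv + n_indel} variants"
        )
    specs: list[VariantSpec] = []
    for contig, pos, is_indel in chosen:
        seq = reference[contig].sequence
        zyg = "het" if rng.random() < het_fraction else "hom"
        if not is_indel:
            ref_allele = seq[pos]
            alt_allele = _BASES[(_BASE_IDX[ref_allele] + int(rng.integers(1, 4))) % 4]
        else:
            indel_len = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # deletion
                ref_allele = seq[pos : pos + 1 + indel_len]
                alt_allele = seq[pos]
            else:  # insertion
                ref_allele = seq[pos]
                ins = "".join(_BASES[j] for j in rng.integers(0, 4, size=indel_len))
                alt_allele = seq[pos] + ins
            pos, ref_allele, alt_allele = left_normalize(
                reference[contig], pos, ref_allele, alt_allele
            )
        specs.append(VariantSpec(contig, pos, ref_allele, alt_allele, zyg))
    # left-normalization can shift indels; re-check spacing and drop clashes
    specs.sort(key=lambda v: (v.contig, v.pos))
    kept: list[VariantSpec] = []
    prev_end: dict[str, int] = {}
    for v in specs:
        if v.pos < prev_end.get(v.contig, -1):
            continue
        kept.append(v)
        prev_end[v.contig] = v.pos + len(v.ref_allele) + 1
    return kept


# ---------------------------------------------------------------------------
# file output


def write_fastq(path: str | Path, records: Iterable[FastqRecord], mate: int) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.name}/{mate}\n{rec.sequence}\n+\n{rec.quality}\n")


def read_fastq(path: str | Path) -> list[FastqRecord]:
    records: list[FastqRecord] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            name = header.rstrip("\n")[1:].rsplit("/", 1)[0]
            records.append(FastqRecord(name, seq, qual))
    return records


def write_ledger(path: str | Path, ledger: Iterable[LedgerRow]) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tprobe_id\ttag\thaplotype_index\tduplicate_count\n")
        for row in ledger:
            fh.write(
                f"{row.molecule_id}\t{row.probe_id}\t{row.tag}\t"
                f"{row.haplotype_index}\t{row.duplicate_count}\n"
            )


def read_ledger(path: str | Path) -> list[LedgerRow]:
    rows: list[LedgerRow] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            mol, probe, tag, hap, dup = line.rstrip("\n").split("\t")
            rows.append(LedgerRow(mol, probe, tag, int(hap), int(dup)))
    return rows


def write_truth_vcf(
    path: str | Path,
    truth: Sequence[TruthRecord],
    reference: Mapping[str, ReferenceSequence],
    sample_id: str = "truth",
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, ref in reference.items():
            fh.write(f"##contig=<ID={contig},length={len(ref)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for t in sorted(truth, key=lambda t: (t.contig, t.pos1)):
            fh.write(
                f"{t.contig}\t{t.pos1}\t.\t{t.ref}\t{t.alt}\t.\tPASS\t.\tGT\t"
                f"{t.genotype}\n"
            )
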