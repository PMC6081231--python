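"""Readers, writers, and the coordinate model shared by all pipeline stages.

All internal coordinates are 0-based, half-open.  Conversion to 1-based
coordinates happens only where an external format demands it (VCF, HGVS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class LookupError_(KeyError):
    """Raised when a record refers to an unknown contig."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction of a sequence; 0.0 for the empty string."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class ReferenceSequence:
    """A single reference contig: upper-case DNA over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"reference record {self.name!r} has empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"reference record {self.name!r} contains non-IUPAC "
                f"characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetRegion:
    """A targeted interval (typically one padded coding exon), 0-based half-open."""

    contig: str
    start: int
    end: int
    gene: str = ""
    exon_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return f"{self.gene}|{self.exon_id}" if self.gene or self.exon_id else ""


@dataclass(frozen=True)
class TranscriptModel:
    """A coding transcript: CDS sequence plus the signal-peptide length used
    for mature-peptide renumbering (e.g. 26 residues for the GH1 preprotein).
    """

    gene: str
    cds_sequence: str
    signal_peptide_len: int = 0
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if len(self.cds_sequence) % 3 != 0:
            raise FormatError(
                f"CDS length {len(self.cds_sequence)} for {self.gene} is not a "
                "multiple of 3"
            )
        n_residues = len(self.cds_sequence) // 3
        if not (0 <= self.signal_peptide_len < n_residues):
            raise FormatError(
                f"signal peptide length {self.signal_peptide_len} out of range "
                f"for a {n_residues}-residue preprotein"
            )


def read_fasta(path: str | Path) -> dict[str, ReferenceSequence]:
    """Read a multi-record FASTA into an ordered mapping name -> contig.

    Sequences are upper-cased.  Empty records or records with characters
    outside {A,C,G,T,N} raise :class:`FormatError`.
    """
    records: dict[str, ReferenceSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in records:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        records[rec.id] = ReferenceSequence(rec.id, seq)
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, refs: Mapping[str, ReferenceSequence] | Iterable[ReferenceSequence], width: int = 70) -> None:
    if isinstance(refs, Mapping):
        refs = refs.values()
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n")
            for i in range(0, len(ref.sequence), width):
                fh.write(ref.sequence[i : i + width] + "\n")


def merge_regions(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Union overlapping or book-ended intervals per contig.

    Labels of merged regions are the comma-joined distinct labels of their
    members, preserving first-seen order.
    """
    by_contig: dict[str, list[TargetRegion]] = {}
    order: list[str] = []
    for r in regions:
        if r.contig not in by_contig:
            order.append(r.contig)
        by_contig.setdefault(r.contig, []).append(r)
    merged: list[TargetRegion] = []
    for contig in order:
        rs = sorted(by_contig[contig], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        genes: list[str] = [rs[0].gene]
        exons: list[str] = [rs[0].exon_id]
        for r in rs[1:]:
            if r.start <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, r.end)
                if r.gene not in genes:
                    genes.append(r.gene)
                if r.exon_id not in exons:
                    exons.append(r.exon_id)
            else:
                merged.append(
                    TargetRegion(contig, cur_start, cur_end, ",".join(genes), ",".join(exons))
                )
                cur_start, cur_end = r.start, r.end
                genes, exons = [r.gene], [r.exon_id]
        merged.append(
            TargetRegion(contig, cur_start, cur_end, ",".join(genes), ",".join(exons))
        )
    return merged


def read_targets(
    path: str | Path,
    merge_overlaps: bool = False,
    reference: Mapping[str, ReferenceSequence] | None = None,
) -> list[TargetRegion]:
    """Read BED4 target regions (contig, start, end, "gene|exon").

    Coordinates are 0-based half-open as in BED.  A missing or empty name
    column yields an auto-generated ``region<N>`` label.  With
    ``merge_overlaps`` the per-contig interval union is returned.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            if reference is not None:
                if contig not in reference:
                    raise LookupError_(
                        f"{path}:{lineno}: unknown contig {contig!r}"
                    )
                if end > len(reference[contig]):
                    raise FormatError(
                        f"{path}:{lineno}: interval end {end} beyond contig "
                        f"length {len(reference[contig])}"
                    )
            name = fields[3] if len(fields) >= 4 and fields[3] else f"region{lineno}"
            gene, _, exon_id = name.partition("|")
            regions.append(TargetRegion(contig, start, end, gene, exon_id or name))
    if merge_overlaps:
        regions = merge_regions(regions)
    return regions


def write_targets(path: str | Path, regions: Iterable[TargetRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.gene}|{r.exon_id}\n")
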