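"""Clinical-style interpretation utilities.

Covers the arithmetic and bookkeeping that turn a filtered VCF into a
reportable finding: HGVS coding-position/codon mapping and protein change,
mature-peptide renumbering after signal-peptide cleavage (GH1's p.R209H in
preprotein numbering is the p.R183H of the mature-hormone literature),
autosomal-dominant pedigree segregation checks, population allele-frequency
filtering, and cohort phenotype summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genomic_io import TranscriptModel


class AnnotationError(ValueError):
    pass


def cds_codon(c_pos: int, cds_len: int | None = None) -> tuple[int, int]:
    """Map a 1-based CDS position to (codon_number, offset in {1,2,3})."""
    if c_pos < 1 or (cds_len is not None and c_pos > cds_len):
        raise AnnotationError(f"CDS position {c_pos} out of range")
    return (c_pos - 1) // 3 + 1, (c_pos - 1) % 3 + 1


def codon_to_c_pos(codon_number: int, offset: int) -> int:
    """Inverse of :func:`cds_codon`."""
    if offset not in (1, 2, 3) or codon_number < 1:
        raise AnnotationError("invalid codon/offset")
    return (codon_number - 1) * 3 + offset


def mature_numbering(preprotein_residue: int, signal_peptide_len: int) -> int:
    """Renumber a preprotein residue to mature-peptide coordinates.

    The mature peptide starts at residue 1 immediately after cleavage of the
    signal peptide, so the mature number is the preprotein number minus the
    signal-peptide length.
    """
    if signal_peptide_len < 0:
        raise AnnotationError("signal_peptide_len must be >= 0")
    if preprotein_residue <= signal_peptide_len:
        raise AnnotationError(
            f"residue {preprotein_residue} lies within the "
            f"{signal_peptide_len}-residue signal peptide"
        )
    return preprotein_residue - signal_peptide_len


@dataclass(frozen=True)
class HgvsChange:
    transcript_id: str
    c_pos: int
    ref_nt: str
    alt_nt: str
    codon_number: int
    codon_offset: int
    aa_ref: str
    aa_alt: str
    synonymous: bool
    preprotein_residue: int
    mature_residue: int | None

    @property
    def c_hgvs(self) -> str:
        return f"c.{self.c_pos}{self.ref_nt}>{self.alt_nt}"

    @property
    def p_hgvs(self) -> str:
        if self.synonymous:
            return f"p.{self.aa_ref}{self.codon_number}="
        return f"p.{self.aa_ref}{self.codon_number}{self.aa_alt}"


def protein_change(
    transcript: TranscriptModel, c_pos: int, ref_nt: str, alt_nt: str
) -> HgvsChange:
    """Predict the protein-level consequence of a coding SNV.

    Translates the affected codon before and after the substitution with the
    standard genetic code; stop codons are reported as '*'.  The mature
    residue number is given when the change lies beyond the signal peptide.
    """
    cds = transcript.cds_sequence
    codon_number, offset = cds_codon(c_pos, len(cds))
    observed = cds[c_pos - 1]
    if observed != ref_nt:
        raise AnnotationError(
            f"CDS base at position {c_pos} is {observed!r}, not {ref_nt!r}"
        )
    codon_start = (codon_number - 1) * 3
    codon = cds[codon_start : codon_start + 3]
    mutated = codon[: offset - 1] + alt_nt + codon[offset:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    synonymous = aa_ref == aa_alt
    mature: int | None = None
    if transcript.signal_peptide_len and codon_number > transcript.signal_peptide_len:
        mature = mature_numbering(codon_number, transcript.signal_peptide_len)
    elif transcript.signal_peptide_len == 0:
        mature = codon_number
    return HgvsChange(
        transcript_id=transcript.transcript_id,
        c_pos=c_pos,
        ref_nt=ref_nt,
        alt_nt=alt_nt,
        codon_number=codon_number,
        codon_offset=offset,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        synonymous=synonymous,
        preprotein_residue=codon_number,
        mature_residue=mature,
    )


# ---------------------------------------------------------------------------
# pedigree segregation


@dataclass(frozen=True)
class PedigreeMember:
    member_id: str
    affected: str  # "affected" | "unaffected" | "unknown"
    carrier: str  # "yes" | "no" | "untested"

    def __post_init__(self) -> None:
        if self.affected not in ("affected", "unaffected", "unknown"):
            raise AnnotationError(f"bad affected status {self.affected!r}")
        if self.carrier not in ("yes", "no", "untested"):
            raise AnnotationError(f"bad carrier status {self.carrier!r}")


@dataclass(frozen=True)
class SegregationResult:
    consistent: bool
    violations: tuple[str, ...]  # affected non-carriers
    penetrance_notes: tuple[str, ...]  # unaffected carriers


def check_segregation(
    members: Sequence[PedigreeMember], model: str = "autosomal_dominant"
) -> SegregationResult:
    """Check dominant segregation: every affected member must carry the variant.

    An unaffected carrier is not a violation but is noted as possible
    incomplete penetrance (precedent: apparently unaffected carrier parents).
    """
    if model != "autosomal_dominant":
        raise AnnotationError(f"unsupported segregation model {model!r}")
    informative = [
        m for m in members if m.affected != "unknown" and m.carrier != "untested"
    ]
    if not informative:
        raise AnnotationError("no member with known status and carrier state")
    violations = tuple(
        m.member_id
        for m in informative
        if m.affected == "affected" and m.carrier == "no"
    )
    notes = tuple(
        m.member_id
        for m in informative
        if m.affected == "unaffected" and m.carrier == "yes"
    )
    return SegregationResult(len(violations) == 0, violations, notes)


def read_pedigree(path: str | Path) -> list[PedigreeMember]:
    """PED-like TSV: member_id, affected, carrier (with optional header)."""
    members: list[PedigreeMember] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "member_id":
                continue
            members.append(PedigreeMember(fields[0], fields[1], fields[2]))
    return members


# ---------------------------------------------------------------------------
# allele-frequency filtering


def frequency_filter(
    variants: Sequence,
    af_table: Mapping,
    max_af: float = 0.001,
) -> list:
    """Retain variants that are absent from the population table or rarer
    than ``max_af`` (strict).  Keys of ``af_table`` must match the variant
    objects (or their keys) passed in."""
    for key, af in af_table.items():
        if not (0.0 <= af <= 1.0):
            raise AnnotationError(f"allele frequency {af} for {key} outside [0, 1]")
    retained = []
    for v in variants:
        af = af_table.get(v)
        if af is None or af < max_af:
            retained.append(v)
    return retained


def read_af_table(path: str | Path) -> dict[tuple[str, int, str, str], float]:
    """AF TSV: contig, pos (1-based), ref, alt, af."""
    table: dict[tuple[str, int, str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "contig")):
                continue
            contig, pos, ref, alt, af = line.split("\t")
            table[(contig, int(pos), ref, alt)] = float(af)
    return table


# ---------------------------------------------------------------------------
# cohort summary

HORMONE_COLUMNS = ["gh", "acth", "tsh", "gonadotropin", "prl", "adh"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def validate_cohort(sheet: pd.DataFrame) -> None:
    """Diagnosis must be CPHD iff at least two hormone axes are deficient."""
    flags = [c for c in HORMONE_COLUMNS if c in sheet.columns]
    if not flags:
        raise AnnotationError("cohort sheet has no hormone-deficiency columns")
    n_def = sheet[flags].astype(bool).sum(axis=1)
    expected = n_def.map(lambda n: "CPHD" if n >= 2 else "IGHD")
    bad = sheet.loc[sheet["diagnosis"] != expected, "patient_id"].tolist()
    if bad:
        raise AnnotationError(
            f"diagnosis inconsistent with deficiency flags for patients: {bad}"
        )


def summarize_cohort(sheet: pd.DataFrame) -> pd.DataFrame:
    """Counts and integer percentages (half away from zero) per category.

    Categories: each diagnosis value and each hormone-deficiency column.
    """
    if len(sheet) == 0:
        raise AnnotationError("empty cohort sheet")
    validate_cohort(sheet)
    total = len(sheet)
    rows: list[dict] = []
    for dx in ("IGHD", "CPHD"):
        n = int((sheet["diagnosis"] == dx).sum())
        rows.append(
            {"category": dx, "count": n, "percent": _round_half_away(100 * n / total)}
        )
    for col in HORMONE_COLUMNS:
        if col not in sheet.columns:
            continue
        n = int(sheet[col].astype(bool).sum())
        rows.append(
            {
                "category": f"{col}_deficiency",
                "count": n,
                "percent": _round_half_away(100 * n / total),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["total"] = total
    return out


def read_cohort_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"patient_id", "diagnosis"}
    missing = required - set(sheet.columns)
    if missing:
        raise AnnotationError(f"cohort sheet missing columns {sorted(missing)}")
    return sheet
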