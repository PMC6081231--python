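"""Truth-set comparison: variant sensitivity and genotype concordance.

Truth variants are assessable only where unique-molecule depth reaches the
minimum (default 8); sensitivity is the fraction of assessable truth
variants recovered (site and alternate allele both matching after
left-normalization), genotype concordance the fraction of recovered sites
whose genotype agrees as an unordered allele multiset.  False positives are
called variants inside the target domain that are absent from the truth set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

from cyvcf2 import VCF

from .capture_sim import TruthRecord, left_normalize
from .coverage_qc import DepthProfile
from .genomic_io import ReferenceSequence, TargetRegion
from .varcall import GenotypeCall


@dataclass(frozen=True)
class VariantKey:
    contig: str
    pos: int  # 0-based anchor
    ref: str
    alt: str


@dataclass(frozen=True)
class ConcordanceReport:
    n_truth_total: int
    n_truth_assessable: int
    n_detected: int
    sensitivity: float | None
    n_genotype_match: int
    n_compared: int
    genotype_concordance: float | None
    n_false_positive: int

    def to_dict(self) -> dict:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _normalize(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, ReferenceSequence] | None,
) -> VariantKey:
    if reference is not None and contig in reference:
        pos, ref, alt = left_normalize(reference[contig], pos, ref, alt)
    return VariantKey(contig, pos, ref, alt)


def _genotype_multiset(gt: str) -> frozenset[tuple[str, int]]:
    alleles = gt.replace("|", "/").split("/")
    counts: dict[str, int] = {}
    for a in alleles:
        counts[a] = counts.get(a, 0) + 1
    return frozenset(counts.items())


def compare_to_truth(
    calls: Sequence[GenotypeCall],
    truth: Sequence[TruthRecord],
    depth_profile: DepthProfile,
    targets: Sequence[TargetRegion],
    min_depth: int = 8,
    reference: Mapping[str, ReferenceSequence] | None = None,
) -> ConcordanceReport:
    """Score a call set against planted or external truth variants."""
    call_map: dict[VariantKey, str] = {}
    for c in calls:
        if c.genotype == "0/0" or c.alt is None:
            continue
        key = _normalize(c.contig, c.pos, c.ref, c.alt, reference)
        call_map[key] = c.genotype

    domain: dict[str, set[int]] = {}
    for t in targets:
        domain.setdefault(t.contig, set()).update(range(t.start, t.end))

    n_assessable = 0
    n_detected = 0
    n_gt_match = 0
    truth_keys: set[VariantKey] = set()
    for t in truth:
        key = _normalize(t.contig, t.pos1 - 1, t.ref, t.alt, reference)
        truth_keys.add(key)
        if depth_profile.depth_at(key.contig, key.pos) < min_depth:
            continue
        n_assessable += 1
        gt = call_map.get(key)
        if gt is None:
            continue
        n_detected += 1
        if _genotype_multiset(gt) == _genotype_multiset(t.genotype):
            n_gt_match += 1

    n_fp = sum(
        1
        for key in call_map
        if key not in truth_keys and key.pos in domain.get(key.contig, set())
    )

    return ConcordanceReport(
        n_truth_total=len(truth),
        n_truth_assessable=n_assessable,
        n_detected=n_detected,
        sensitivity=(n_detected / n_assessable) if n_assessable else None,
        n_genotype_match=n_gt_match,
        n_compared=n_detected,
        genotype_concordance=(n_gt_match / n_detected) if n_detected else None,
        n_false_positive=n_fp,
    )


def read_calls_vcf(path: str | Path) -> list[GenotypeCall]:
    """Read a single-sample VCF back into genotype calls (first ALT only)."""
    calls: list[GenotypeCall] = []
    for rec in VCF(str(path)):
        gts = rec.genotypes[0]
        alleles = sorted(int(a) for a in gts[:-1])
        gt = "/".join(str(a) for a in alleles)
        depth = int(rec.format("DP")[0][0]) if rec.format("DP") is not None else 0
        ad = rec.format("AD")
        ref_d, alt_d = (int(ad[0][0]), int(ad[0][1])) if ad is not None else (0, 0)
        gq = float(rec.format("GQ")[0][0]) if rec.format("GQ") is not None else 0.0
        calls.append(
            GenotypeCall(
                contig=rec.CHROM,
                pos=rec.POS - 1,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else None,
                genotype=gt,
                depth=depth,
                ref_depth=ref_d,
                alt_depth=alt_d,
                gq=gq,
            )
        )
    return calls


def read_truth_vcf(path: str | Path) -> list[TruthRecord]:
    truth: list[TruthRecord] = []
    for rec in VCF(str(path)):
        gts = rec.genotypes[0]
        alleles = sorted(int(a) for a in gts[:-1])
        gt = "/".join(str(a) for a in alleles)
        truth.append(
            TruthRecord(
                contig=rec.CHROM,
                pos1=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else "",
                genotype=gt,
            )
        )
    return truth
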