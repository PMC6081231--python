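"""Unique-molecule depth of coverage and sample/exon QC rules.

Depth is counted per targeted base as the number of unique molecules (one
per probe/tag group) whose gap fill covers the base — PCR duplicates never
inflate coverage.  A sample passes QC when at least 80% of targeted bases
reach >=8x unique-molecule depth; exons averaging below 10x (or with no
coverage at all) are flagged for follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import TargetRegion
from .panel_design import MipProbe
from .readproc import MoleculeGroup


class QCError(ValueError):
    pass


class DepthProfile:
    """Per-base unique-molecule depth over the targeted (padded) bases."""

    def __init__(self, contig_lengths: Mapping[str, int], targets: Sequence[TargetRegion]):
        self.depth: dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()
        }
        self.mask: dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()
        }
        for t in targets:
            if t.contig not in self.mask:
                raise QCError(f"target on unknown contig {t.contig!r}")
            self.mask[t.contig][t.start : t.end] = True

    def add_interval(self, contig: str, start: int, end: int) -> None:
        self.depth[contig][start:end] += 1

    def depth_at(self, contig: str, pos: int) -> int:
        return int(self.depth[contig][pos])

    def targeted_depths(self) -> np.ndarray:
        parts = [self.depth[c][self.mask[c]] for c in sorted(self.depth)]
        return np.concatenate(parts) if parts else np.array([], dtype=np.int64)

    @property
    def n_targeted_bases(self) -> int:
        return int(sum(m.sum() for m in self.mask.values()))


def compute_depth(
    groups: Iterable[MoleculeGroup],
    panel: Sequence[MipProbe],
    targets: Sequence[TargetRegion],
    contig_lengths: Mapping[str, int],
) -> DepthProfile:
    """Each unique molecule adds 1 to every base its probe's gap fill covers."""
    by_id = {p.probe_id: p for p in panel}
    profile = DepthProfile(contig_lengths, targets)
    for g in groups:
        p = by_id[g.probe_id]
        profile.add_interval(p.contig, p.gap_start, p.gap_end)
    return profile


@dataclass(frozen=True)
class SampleQC:
    fraction_ge8: float
    fraction_ge40: float
    median_depth: int
    passed: bool
    min_frac: float = 0.80
    min_depth: int = 8


def sample_pass(
    profile: DepthProfile, min_frac: float = 0.80, min_depth: int = 8
) -> SampleQC:
    """Apply the sample pass rule: >= min_frac of targeted bases at >= min_depth.

    Both thresholds are inclusive.  The median is the lower median over
    targeted bases.  Also reports the fraction of bases at >=40x.
    """
    depths = profile.targeted_depths()
    if depths.size == 0:
        raise QCError("empty target domain")
    frac8 = float(np.mean(depths >= min_depth))
    frac40 = float(np.mean(depths >= 40))
    sorted_d = np.sort(depths)
    median = int(sorted_d[(depths.size - 1) // 2])  # lower median
    return SampleQC(
        fraction_ge8=frac8,
        fraction_ge40=frac40,
        median_depth=median,
        passed=frac8 >= min_frac,
        min_frac=min_frac,
        min_depth=min_depth,
    )


@dataclass(frozen=True)
class ExonCoverage:
    exon_id: str
    gene: str
    mean_depth: float
    flagged: bool


def exon_mean_coverage(
    profile: DepthProfile,
    exons: Sequence[TargetRegion],
    flag_below: float = 10.0,
) -> list[ExonCoverage]:
    """Mean unique-molecule depth per exon; flag exons with mean strictly
    below ``flag_below`` or with no coverage at all."""
    out: list[ExonCoverage] = []
    for exon in exons:
        if len(exon) == 0:
            raise QCError(f"zero-length exon {exon.exon_id}")
        d = profile.depth[exon.contig][exon.start : exon.end]
        mean = float(d.mean())
        flagged = mean < flag_below or bool((d == 0).all())
        out.append(ExonCoverage(exon.exon_id, exon.gene, mean, flagged))
    return out


def write_depth_table(path: str | Path, profile: DepthProfile) -> None:
    """Targeted-base depths as TSV (contig, pos 0-based, depth)."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tdepth\n")
        for contig in sorted(profile.depth):
            positions = np.nonzero(profile.mask[contig])[0]
            depths = profile.depth[contig][positions]
            for pos, d in zip(positions, depths):
                fh.write(f"{contig}\t{pos}\t{d}\n")


def read_depth_table(
    path: str | Path, contig_lengths: Mapping[str, int]
) -> DepthProfile:
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            contig, pos, depth = line.rstrip("\n").split("\t")
            rows.append((contig, int(pos), int(depth)))
    targets = [TargetRegion(c, p, p + 1) for c, p, _ in rows]
    profile = DepthProfile(contig_lengths, targets)
    for contig, pos, depth in rows:
        profile.depth[contig][pos] = depth
    return profile


def qc_report(
    profile: DepthProfile,
    exons: Sequence[TargetRegion],
    min_frac: float = 0.80,
    min_depth: int = 8,
    flag_below: float = 10.0,
) -> dict:
    qc = sample_pass(profile, min_frac=min_frac, min_depth=min_depth)
    exon_cov = exon_mean_coverage(profile, exons, flag_below=flag_below)
    return {
        "fraction_ge8": qc.fraction_ge8,
        "fraction_ge40": qc.fraction_ge40,
        "median_depth": qc.median_depth,
        "passed": qc.passed,
        "n_targeted_bases": profile.n_targeted_bases,
        "flagged_exons": [
            {"exon_id": e.exon_id, "gene": e.gene, "mean_depth": e.mean_depth}
            for e in exon_cov
            if e.flagged
        ],
    }
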