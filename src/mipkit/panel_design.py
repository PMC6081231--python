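"""smMIP panel design: tile padded targets with probes and assemble synthesis oligos.

A molecular inversion probe carries two genome-complementary targeting arms
(extension and ligation arm) flanking a backbone with a degenerate molecular
tag.  Hybridisation, gap-fill polymerisation, and ligation circularise the
probe around its genomic target; the interval between the arms (the gap fill)
becomes the sequenced insert.  For array synthesis the probe body is embedded
between two amplification-primer flanks which are later released by EarI
digestion, so each flank must carry the EarI recognition site CTCTTC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genomic_io import (
    ReferenceSequence,
    TargetRegion,
    gc_fraction,
    revcomp,
)

# Amplification primer flanks used to PCR the synthesised oligo pool.  Both
# end in the EarI recognition site CTCTTC so that digestion releases the
# probe body.
MIPPREP1F = "GGTAGCAAAGTGCAGATGTGCTCTTC"
MIPPREP1R = "TGAACTCACACTGCTCTGAACTCTTC"

# Backbone linker split around the molecular-tag block.  Both halves are
# chosen so that no junction with an arm, tag, or spacer can complete an
# EarI site: the left half starts, and the right half ends, with bases that
# extend no suffix/prefix of CTCTTC or GAAGAG.
DEFAULT_BACKBONE_LEFT = "ATCAGGCTTGGACGT"
DEFAULT_BACKBONE_RIGHT = "AGCACCGTTCGGTTA"

EAR1_SITE = "CTCTTC"
EAR1_SITE_RC = "GAAGAG"
# EarI is a type IIS enzyme cutting downstream of its recognition site:
# 1 nt beyond the site on the recognition strand, 4 nt on the other strand.
EAR1_TOP_OFFSET = 1
EAR1_BOTTOM_OFFSET = 4


class DesignError(ValueError):
    """Raised when a probe set satisfying the design constraints cannot be built."""


@dataclass(frozen=True)
class DesignParams:
    """Tunable parameters of the probe design.

    Defaults: 25 bp target padding to include exon-intron boundaries, a
    112 nt gap fill sized to be reconstructable from paired 100 bp reads,
    an 8 nt molecular tag, and a 150 nt synthesis length cap.
    """

    pad_bp: int = 25
    ext_arm_len_range: tuple[int, int] = (16, 20)
    lig_arm_len_range: tuple[int, int] = (20, 24)
    gap_fill_len: int = 112
    tag_len: int = 8
    backbone_left: str = DEFAULT_BACKBONE_LEFT
    backbone_right: str = DEFAULT_BACKBONE_RIGHT
    arm_gc_bounds: tuple[float, float] = (0.15, 0.80)
    prep_primer_f: str = MIPPREP1F
    prep_primer_r: str = MIPPREP1R
    max_oligo_len: int = 150

    def __post_init__(self) -> None:
        if self.gap_fill_len <= 0:
            raise DesignError("gap_fill_len must be positive")
        if self.tag_len < 4:
            raise DesignError("tag_len must be >= 4")
        for name, primer in (("prep_primer_f", self.prep_primer_f),
                             ("prep_primer_r", self.prep_primer_r)):
            if EAR1_SITE not in primer:
                raise DesignError(
                    f"{name} lacks the EarI recognition site {EAR1_SITE}"
                )


@dataclass(frozen=True)
class MipProbe:
    """One designed probe: two targeting arms flanking a gap-fill interval.

    Arm sequences are stored as plus-strand reference slices; the extension
    arm abuts the gap fill on its left, the ligation arm on its right.
    """

    probe_id: str
    contig: str
    scan_strand: str
    ext_arm_seq: str
    ext_arm_start: int
    ext_arm_end: int
    lig_arm_seq: str
    lig_arm_start: int
    lig_arm_end: int
    gap_start: int
    gap_end: int
    tag_len: int
    backbone: str

    def __post_init__(self) -> None:
        if not (self.ext_arm_end == self.gap_start and self.lig_arm_start == self.gap_end):
            raise DesignError(f"probe {self.probe_id}: arms must flank the gap fill")
        if "N" in self.ext_arm_seq or "N" in self.lig_arm_seq:
            raise DesignError(f"probe {self.probe_id}: arm contains N")

    @property
    def gap_len(self) -> int:
        return self.gap_end - self.gap_start


@dataclass(frozen=True)
class OligoRecord:
    """A full-length synthesis oligo for one probe."""

    probe_id: str
    full_sequence: str

    @property
    def length(self) -> int:
        return len(self.full_sequence)


def pad_region(region: TargetRegion, pad_bp: int, contig_len: int) -> TargetRegion:
    """Extend a target region by ``pad_bp`` on both sides, clipped to the contig."""
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    return TargetRegion(
        region.contig,
        max(0, region.start - pad_bp),
        min(contig_len, region.end + pad_bp),
        region.gene,
        region.exon_id,
    )


def _best_arms(
    seq: str,
    gap_start: int,
    gap_end: int,
    params: DesignParams,
) -> tuple[str, int, str, int] | None:
    """Pick the arm-length pair whose combined GC distance from 0.5 is minimal.

    Returns (ext_seq, ext_len, lig_seq, lig_len) or None if no candidate is
    valid: an arm must fit in the contig, contain no N and no EarI
    recognition site (digestion would destroy the probe body), and sit
    within the GC bounds.
    """
    lo_gc, hi_gc = params.arm_gc_bounds

    def arm_ok(arm: str) -> bool:
        return (
            "N" not in arm
            and EAR1_SITE not in arm
            and EAR1_SITE_RC not in arm
            and lo_gc <= gc_fraction(arm) <= hi_gc
        )

    best: tuple[float, int, int, str, str] | None = None
    for ext_len in range(params.ext_arm_len_range[0], params.ext_arm_len_range[1] + 1):
        if gap_start - ext_len < 0:
            continue
        ext = seq[gap_start - ext_len : gap_start]
        if not arm_ok(ext):
            continue
        gc_e = gc_fraction(ext)
        for lig_len in range(params.lig_arm_len_range[0], params.lig_arm_len_range[1] + 1):
            if gap_end + lig_len > len(seq):
                continue
            lig = seq[gap_end : gap_end + lig_len]
            if not arm_ok(lig):
                continue
            gc_l = gc_fraction(lig)
            score = abs(gc_e - 0.5) + abs(gc_l - 0.5)
            key = (score, ext_len, lig_len, ext, lig)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    _, ext_len, lig_len, ext, lig = best
    return ext, ext_len, lig, lig_len


def tile_probes(
    padded_regions: Sequence[TargetRegion],
    reference: Mapping[str, ReferenceSequence],
    params: DesignParams = DesignParams(),
) -> list[MipProbe]:
    """Tile every padded region with gap fills of fixed length, left to right.

    The last tile of a region longer than one gap fill is right-aligned to
    the region end (overlap with the previous tile is allowed), so the union
    of gap fills covers every padded base.  Regions shorter than the gap-fill
    length get a single probe whose gap fill contains the whole region.
    """
    probes: list[MipProbe] = []
    failures: list[str] = []
    for region in padded_regions:
        if region.contig not in reference:
            raise DesignError(f"region on unknown contig {region.contig!r}")
        seq = reference[region.contig].sequence
        g = params.gap_fill_len
        starts: list[int] = []
        if len(region) <= g:
            starts.append(region.start)
        else:
            s = region.start
            while s + g < region.end:
                starts.append(s)
                s += g
            starts.append(region.end - g)  # right-aligned closing tile
        for idx, tile_start in enumerate(starts):
            tile_end = min(tile_start + g, len(seq))
            if tile_end - tile_start < min(g, len(region)):
                failures.append(f"{region.label or region.contig}: gap fill off contig end")
                continue
            # If no arm pair is valid at the nominal window (an EarI site or
            # N or extreme GC under every candidate length), grow the gap
            # fill outward a few bases to slide the arm windows off the
            # offending sequence; coverage only increases.
            arms = None
            gap_start = gap_end = 0
            for total in range(0, 17):
                for d_left in range(total + 1):
                    d_right = total - d_left
                    s0 = tile_start - d_left
                    e0 = tile_end + d_right
                    if s0 < 0 or e0 > len(seq):
                        continue
                    arms = _best_arms(seq, s0, e0, params)
                    if arms is not None:
                        gap_start, gap_end = s0, e0
                        break
                if arms is not None:
                    break
            if arms is None:
                failures.append(
                    f"{region.label or region.contig} [{tile_start},{tile_end}): "
                    "no valid arm pair (N, EarI site, or GC bounds)"
                )
                continue
            ext, ext_len, lig, lig_len = arms
            pid = f"{region.gene or region.contig}_{region.exon_id or region.start}_{idx:02d}"
            probes.append(
                MipProbe(
                    probe_id=pid,
                    contig=region.contig,
                    scan_strand="+",
                    ext_arm_seq=ext,
                    ext_arm_start=gap_start - ext_len,
                    ext_arm_end=gap_start,
                    lig_arm_seq=lig,
                    lig_arm_start=gap_end,
                    lig_arm_end=gap_end + lig_len,
                    gap_start=gap_start,
                    gap_end=gap_end,
                    tag_len=params.tag_len,
                    backbone=params.backbone_left + params.backbone_right,
                )
            )
    if failures:
        raise DesignError("design failed for regions: " + "; ".join(failures))
    return probes


# Spacer bases between the primer flanks and the probe body sized so that the
# EarI cuts (1 nt and 4 nt beyond the recognition sites) fall exactly at the
# probe-body boundaries and the released fragment retains both arms intact.
_LEFT_SPACER = "A"
_RIGHT_SPACER = "ATAT"


def assemble_oligo(probe: MipProbe, params: DesignParams = DesignParams()) -> OligoRecord:
    """Assemble the full synthesis oligo for one probe.

    Layout (5'->3'): forward prep primer, 1 nt spacer, ligation arm,
    backbone-left, tag placeholder (N x tag_len), backbone-right, extension
    arm, 4 nt spacer, reverse complement of the reverse prep primer.  The
    spacers absorb the EarI cut offsets so digestion releases the probe body
    exactly.
    """
    full = (
        params.prep_primer_f
        + _LEFT_SPACER
        + probe.lig_arm_seq
        + params.backbone_left
        + "N" * probe.tag_len
        + params.backbone_right
        + probe.ext_arm_seq
        + _RIGHT_SPACER
        + revcomp(params.prep_primer_r)
    )
    if len(full) > params.max_oligo_len:
        raise DesignError(
            f"probe {probe.probe_id}: assembled oligo length {len(full)} exceeds "
            f"{params.max_oligo_len} by {len(full) - params.max_oligo_len} nt"
        )
    return OligoRecord(probe.probe_id, full)


def digest_ear1(oligo: str) -> list[str]:
    """Cut a sequence at every EarI site and return the top-strand fragments.

    Top-strand cuts are placed 1 nt 3' of each CTCTTC occurrence; for
    bottom-strand recognition (GAAGAG on the top strand) the cut on the top
    strand falls 4 nt 5' of the occurrence.  Fragments partition the input.
    """
    cuts: set[int] = set()
    pos = oligo.find(EAR1_SITE)
    while pos != -1:
        c = pos + len(EAR1_SITE) + EAR1_TOP_OFFSET
        if 0 < c < len(oligo):
            cuts.add(c)
        pos = oligo.find(EAR1_SITE, pos + 1)
    pos = oligo.find(EAR1_SITE_RC)
    while pos != -1:
        c = pos - EAR1_BOTTOM_OFFSET
        if 0 < c < len(oligo):
            cuts.add(c)
        pos = oligo.find(EAR1_SITE_RC, pos + 1)
    bounds = [0] + sorted(cuts) + [len(oligo)]
    return [oligo[a:b] for a, b in itertools.pairwise(bounds)]


PROBE_TSV_COLUMNS = [
    "probe_id", "contig", "scan_strand",
    "ext_arm_seq", "ext_arm_start", "ext_arm_end",
    "lig_arm_seq", "lig_arm_start", "lig_arm_end",
    "gap_start", "gap_end", "tag_len", "backbone",
]


def write_probe_table(path: str | Path, probes: Iterable[MipProbe]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PROBE_TSV_COLUMNS) + "\n")
        for p in probes:
            fh.write(
                "\t".join(
                    str(getattr(p, col)) for col in PROBE_TSV_COLUMNS
                )
                + "\n"
            )


def read_probe_table(path: str | Path) -> list[MipProbe]:
    probes: list[MipProbe] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PROBE_TSV_COLUMNS:
            raise DesignError(f"unexpected probe table header in {path}")
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            probes.append(
                MipProbe(
                    probe_id=vals["probe_id"],
                    contig=vals["contig"],
                    scan_strand=vals["scan_strand"],
                    ext_arm_seq=vals["ext_arm_seq"],
                    ext_arm_start=int(vals["ext_arm_start"]),
                    ext_arm_end=int(vals["ext_arm_end"]),
                    lig_arm_seq=vals["lig_arm_seq"],
                    lig_arm_start=int(vals["lig_arm_start"]),
                    lig_arm_end=int(vals["lig_arm_end"]),
                    gap_start=int(vals["gap_start"]),
                    gap_end=int(vals["gap_end"]),
                    tag_len=int(vals["tag_len"]),
                    backbone=vals["backbone"],
                )
            )
    return probes


def write_oligo_table(path: str | Path, oligos: Iterable[OligoRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tsequence\tlength\n")
        for o in oligos:
            fh.write(f"{o.probe_id}\t{o.full_sequence}\t{o.length}\n")


def design_panel(
    targets: Sequence[TargetRegion],
    reference: Mapping[str, ReferenceSequence],
    params: DesignParams = DesignParams(),
) -> tuple[list[MipProbe], list[OligoRecord]]:
    """Pad targets, tile probes, and assemble oligos in one call."""
    padded = [
        pad_region(r, params.pad_bp, len(reference[r.contig])) for r in targets
    ]
    probes = tile_probes(padded, reference, params)
    oligos = [assemble_oligo(p, params) for p in probes]
    return probes, oligos


def padded_targets(
    targets: Sequence[TargetRegion],
    reference: Mapping[str, ReferenceSequence],
    pad_bp: int = 25,
) -> list[TargetRegion]:
    return [pad_region(r, pad_bp, len(reference[r.contig])) for r in targets]
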