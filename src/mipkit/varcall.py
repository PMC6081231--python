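"""Per-probe alignment, pileup, and diploid genotype calling.

Each molecule's consensus insert is globally aligned to its probe's
reference gap-fill window under unit costs (match 0, mismatch 1, gap 1),
with deterministic tie-breaking: mismatch is preferred over a gap, and gaps
are pushed as far left as possible.  Pileup columns count one observation
per molecule per reference position; indel observations are anchored on the
reference base preceding the event, VCF style.  Genotypes are the maximum
a posteriori of {0/0, 0/1, 1/1} under a symmetric per-observation error
model with uniform prior, gated on unique-molecule depth and genotype
quality.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genomic_io import ReferenceSequence, TargetRegion
from .panel_design import MipProbe
from .readproc import MoleculeGroup


class CallerError(ValueError):
    pass


@dataclass(frozen=True)
class CallerParams:
    error_rate: float = 0.01
    min_depth: int = 8
    min_gq: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.error_rate < 0.5):
            raise CallerError("error_rate must be in (0, 0.5)")


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment as CIGAR-style runs over ops {'=', 'X', 'I', 'D'}.

    'I' consumes insert only, 'D' reference only.  ``ref_start`` is the
    window start on the reference; runs always consume the whole window.
    """

    cigar: tuple[tuple[str, int], ...]
    ref_start: int
    score: int

    def __post_init__(self) -> None:
        pass

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def _runs(ops: Sequence[str]) -> tuple[tuple[str, int], ...]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return tuple(out)


def align_insert(
    insert: str, ref_window: str, ref_start: int = 0, band: int = 12
) -> AlignmentResult:
    """Optimal global alignment of an insert to its reference window.

    Cost: match 0, mismatch 1, gap 1 per base.  Among equal-cost alignments
    the one with the fewest gap openings wins (a contiguous indel is never
    split into equal-cost pieces), then mismatch is preferred over gap, and
    gaps are placed leftmost.  Raises on an empty insert or when the length
    difference exceeds the band.
    """
    if not insert:
        raise CallerError("empty insert")
    if not ref_window:
        raise CallerError("empty reference window")
    n, m = len(insert), len(ref_window)
    if abs(n - m) > band:
        raise CallerError(
            f"insert/window length difference {abs(n - m)} exceeds band {band}"
        )

    # fast path: few substitutions, no gapped alignment can beat or tie
    # with fewer openings
    if n == m:
        mism = [i for i in range(n) if insert[i] != ref_window[i]]
        if len(mism) <= 2:
            ops = ["=" if insert[i] == ref_window[i] else "X" for i in range(n)]
            return AlignmentResult(_runs(ops), ref_start, len(mism))

    # three-state banded dynamic program (Gotoh).  Cell values pack
    # (cost, openings) as cost*K + openings so unit edit cost stays the
    # primary objective and gap openings only break ties; the band keeps
    # the work linear in the insert length.
    K = 1 << 10  # openings never reach this
    GAP = K + 1  # one gap base opening a new run
    EXT = K      # one gap base extending a run
    INF = (n + m + 2) * K
    width = min(band, max(n, m)) + abs(n - m) + 1
    M = [[INF] * (m + 1) for _ in range(n + 1)]  # ends in match/mismatch
    D = [[INF] * (m + 1) for _ in range(n + 1)]  # ends in gap-in-insert (ref consumed)
    I = [[INF] * (m + 1) for _ in range(n + 1)]  # ends in gap-in-ref (insert consumed)
    M[0][0] = 0
    for j in range(1, min(width, m) + 1):
        D[0][j] = j * K + 1
    for i in range(1, min(width, n) + 1):
        I[i][0] = i * K + 1
    for i in range(1, n + 1):
        ci = insert[i - 1]
        Mi, Di, Ii = M[i], D[i], I[i]
        Mp, Dp, Ip = M[i - 1], D[i - 1], I[i - 1]
        jlo = max(1, i - width)
        jhi = min(m, i + width)
        for j in range(jlo, jhi + 1):
            sub = K if ci != ref_window[j - 1] else 0
            best_prev = min(Mp[j - 1], Dp[j - 1], Ip[j - 1])
            if best_prev < INF:
                Mi[j] = best_prev + sub
            open_d = min(Mi[j - 1], Ii[j - 1]) + GAP
            ext_d = Di[j - 1] + EXT
            Di[j] = min(open_d, ext_d, INF)
            open_i = min(Mp[j], Dp[j]) + GAP
            ext_i = Ip[j] + EXT
            Ii[j] = min(open_i, ext_i, INF)
    final = min(M[n][m], D[n][m], I[n][m])
    score = final // K

    # traceback; preference at ties: diagonal, then deletion, then insertion
    # (taking gaps as late as possible while walking backwards places them
    # leftmost in the alignment)
    ops: list[str] = []
    i, j = n, m
    if M[n][m] == final:
        state = "M"
    elif D[n][m] == final:
        state = "D"
    else:
        state = "I"
    while i > 0 or j > 0:
        if state == "M":
            sub = 0 if insert[i - 1] == ref_window[j - 1] else K
            ops.append("=" if sub == 0 else "X")
            target = M[i][j] - sub
            i, j = i - 1, j - 1
            if M[i][j] == target:
                state = "M"
            elif D[i][j] == target:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            ops.append("D")
            val = D[i][j]
            j -= 1
            if M[i][j] == val - GAP:
                state = "M"
            elif D[i][j] == val - EXT:
                state = "D"
            else:
                state = "I"
        else:
            ops.append("I")
            val = I[i][j]
            i -= 1
            if M[i][j] == val - GAP:
                state = "M"
            elif D[i][j] == val - EXT:
                state = "D"
            else:
                state = "I"
    ops.reverse()
    return AlignmentResult(_runs(ops), ref_start, score)


# ---------------------------------------------------------------------------
# pileup


@dataclass(frozen=True)
class PileupColumn:
    contig: str
    pos: int  # 0-based
    ref_base: str
    counts: Mapping[str, int]  # allele key -> molecule count

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def _molecule_observations(
    insert: str,
    alignment: AlignmentResult,
    contig_seq: str,
) -> dict[int, str]:
    """Map reference position -> allele key for one aligned molecule.

    Allele keys: a base for a match/mismatch, ``+SEQ`` for an insertion
    anchored at the preceding reference base, ``-SEQ`` for a deletion
    anchored likewise.  Indel observations replace the anchor-base
    observation so each molecule contributes at most one observation per
    position.  N consensus bases are skipped (no observation).
    """
    obs: dict[int, str] = {}
    rpos = alignment.ref_start
    qpos = 0
    for op, length in alignment.cigar:
        if op in ("=", "X"):
            for k in range(length):
                base = insert[qpos + k]
                if base != "N":
                    obs[rpos + k] = base
            rpos += length
            qpos += length
        elif op == "D":
            deleted = contig_seq[rpos : rpos + length]
            if rpos > alignment.ref_start:
                obs[rpos - 1] = f"-{deleted}"
            rpos += length
        elif op == "I":
            inserted = insert[qpos : qpos + length]
            if rpos > alignment.ref_start and "N" not in inserted:
                obs[rpos - 1] = f"+{inserted}"
            qpos += length
    return obs


def pileup(
    groups: Sequence[MoleculeGroup],
    panel: Sequence[MipProbe],
    reference: Mapping[str, ReferenceSequence],
    targets: Sequence[TargetRegion],
    band: int = 12,
) -> list[PileupColumn]:
    """Align every consensus insert and tally per-position allele counts.

    Only positions inside the (padded) target regions are reported; each
    unique molecule contributes at most one observation per position.
    """
    by_id = {p.probe_id: p for p in panel}
    domain: dict[str, set[int]] = defaultdict(set)
    for t in targets:
        domain[t.contig].update(range(t.start, t.end))
    counts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for g in groups:
        probe = by_id[g.probe_id]
        contig_seq = reference[probe.contig].sequence
        window = contig_seq[probe.gap_start : probe.gap_end]
        insert = g.consensus_insert
        if not insert or set(insert) == {"N"}:
            continue
        aln = align_insert(insert, window, ref_start=probe.gap_start, band=band)
        for pos, allele in _molecule_observations(insert, aln, contig_seq).items():
            if pos in domain[probe.contig]:
                counts[(probe.contig, pos)][allele] += 1
    columns = [
        PileupColumn(contig, pos, reference[contig].sequence[pos], dict(c))
        for (contig, pos), c in sorted(counts.items())
    ]
    return columns


# ---------------------------------------------------------------------------
# genotyping


@dataclass(frozen=True)
class GenotypeCall:
    contig: str
    pos: int  # 0-based anchor position
    ref: str  # VCF REF string
    alt: str | None  # VCF ALT string, None for homozygous reference
    genotype: str  # "0/0" | "0/1" | "1/1"
    depth: int
    ref_depth: int
    alt_depth: int
    gq: float


def _vcf_alleles(
    contig_seq: str, pos: int, ref_base: str, allele: str
) -> tuple[str, str]:
    """Convert an internal allele key at an anchor position to VCF REF/ALT."""
    if allele.startswith("-"):
        return ref_base + allele[1:], ref_base
    if allele.startswith("+"):
        return ref_base, ref_base + allele[1:]
    return ref_base, allele


def genotype(
    column: PileupColumn, params: CallerParams = CallerParams()
) -> GenotypeCall | None:
    """MAP diploid genotype for one pileup column, or None below the gates.

    Per-observation likelihoods with error rate e: an observation matches a
    carried allele with probability 1-e, and is any specific other allele
    with probability e/3.  Uniform prior over {RR, RA, AA}; GQ is
    -10*log10(1 - posterior of the winning genotype), capped at 99.
    """
    e = params.error_rate
    depth = column.depth
    if depth < params.min_depth:
        return None
    ref_allele = column.ref_base
    non_ref = [(n, a) for a, n in column.counts.items() if a != ref_allele]
    if non_ref:
        alt_count, alt_allele = max(non_ref, key=lambda t: (t[0], t[1]))
    else:
        alt_count, alt_allele = 0, None

    p_match = 1.0 - e
    p_err = e / 3.0
    p_het = 0.5 * p_match + 0.5 * p_err

    log_rr = log_ra = log_aa = 0.0
    for allele, n in column.counts.items():
        is_ref = allele == ref_allele
        is_alt = alt_allele is not None and allele == alt_allele
        log_rr += n * math.log(p_match if is_ref else p_err)
        log_ra += n * math.log(p_het if (is_ref or is_alt) else p_err)
        log_aa += n * math.log(p_match if is_alt else p_err)
    if alt_allele is None:
        log_ra = log_aa = float("-inf")
    logs = {"0/0": log_rr, "0/1": log_ra, "1/1": log_aa}
    best_gt = max(logs, key=lambda k: (logs[k], k))
    mx = logs[best_gt]
    total = sum(math.exp(v - mx) for v in logs.values() if v > float("-inf"))
    posterior = 1.0 / total
    gq = 99.0 if posterior >= 1.0 else min(99.0, -10.0 * math.log10(1.0 - posterior))
    if gq < params.min_gq:
        return None

    ref_count = column.counts.get(ref_allele, 0)
    if best_gt == "0/0" or alt_allele is None:
        return GenotypeCall(
            column.contig, column.pos, ref_allele, None, "0/0",
            depth, ref_count, 0, gq,
        )
    vcf_ref, vcf_alt = _vcf_alleles("", column.pos, column.ref_base, alt_allele)
    return GenotypeCall(
        column.contig, column.pos, vcf_ref, vcf_alt, best_gt,
        depth, ref_count, alt_count, gq,
    )


def call_variants(
    groups: Sequence[MoleculeGroup],
    panel: Sequence[MipProbe],
    reference: Mapping[str, ReferenceSequence],
    targets: Sequence[TargetRegion],
    params: CallerParams = CallerParams(),
    band: int = 12,
) -> list[GenotypeCall]:
    """Pileup plus genotyping over the target domain; returns emitted calls
    (homozygous-reference included) sorted by position."""
    columns = pileup(groups, panel, reference, targets, band=band)
    calls: list[GenotypeCall] = []
    for col in columns:
        call = genotype(col, params)
        if call is not None:
            calls.append(call)
    return calls


def variant_calls(calls: Iterable[GenotypeCall]) -> list[GenotypeCall]:
    """Filter to non-reference genotypes (the VCF-worthy subset)."""
    return [c for c in calls if c.genotype != "0/0"]


def write_vcf(
    path: str | Path,
    calls: Sequence[GenotypeCall],
    reference: Mapping[str, ReferenceSequence],
    sample_id: str = "sample",
) -> None:
    """Write non-reference calls as VCF 4.2 with GT:DP:AD:GQ."""
    ordered = [c for c in calls if c.genotype != "0/0"]
    for a, b in zip(ordered, ordered[1:]):
        if (a.contig, a.pos) > (b.contig, b.pos):
            raise CallerError("calls must be sorted by (contig, pos)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mipkit\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Unique-molecule depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for contig, ref in reference.items():
            fh.write(f"##contig=<ID={contig},length={len(ref)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for c in ordered:
            gq = int(round(c.gq))
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t{gq}\tPASS\t.\t"
                f"GT:DP:AD:GQ\t{c.genotype}:{c.depth}:{c.ref_depth},{c.alt_depth}:{gq}\n"
            )
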