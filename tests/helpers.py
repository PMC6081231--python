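"""Shared fixtures-by-code for the test suite: small panels and full runs."""

from __future__ import annotations

from dataclasses import dataclass

from mipkit.capture_sim import (
    SimConfig,
    choose_variant_sites,
    make_exon_targets,
    plant_variants,
    random_reference,
    simulate_capture,
)
from mipkit.concordance import ConcordanceReport, compare_to_truth
from mipkit.coverage_qc import compute_depth
from mipkit.genomic_io import TargetRegion
from mipkit.panel_design import design_panel, padded_targets
from mipkit.readproc import process_read_pairs
from mipkit.varcall import CallerParams, call_variants, variant_calls


@dataclass
class StudyRun:
    reference: dict
    targets: list
    padded: list
    probes: list
    specs: list
    truth: list
    ledger: list
    r1: list
    r2: list
    groups: list
    unassigned: list
    profile: object
    calls: list
    variants: list
    report: ConcordanceReport


def run_capture_study(
    seed: int,
    contig_len: int = 42000,
    n_exons: int = 64,
    n_snv: int = 300,
    n_indel: int = 20,
    molecules_per_probe: int = 24,
    duplication_mean: float = 2.0,
    base_error_rate: float = 0.0,
) -> StudyRun:
    """Design, simulate, process, and call one synthetic capture study."""
    ref = random_reference("chrS", contig_len, seed=seed)
    reference = {ref.name: ref}
    targets = make_exon_targets(ref.name, contig_len, n_exons, exon_len=240, spacing=400)
    probes, _ = design_panel(targets, reference)
    specs = choose_variant_sites(
        probes, reference, n_snv=n_snv, n_indel=n_indel, seed=seed + 1
    )
    haplotypes, truth = plant_variants(reference, specs)
    sim = SimConfig(
        molecules_per_probe=molecules_per_probe,
        duplication_mean=duplication_mean,
        base_error_rate=base_error_rate,
        seed=seed + 2,
    )
    r1, r2, ledger = simulate_capture(probes, haplotypes, sim)
    groups, unassigned = process_read_pairs(r1, r2, probes)
    padded = padded_targets(targets, reference)
    contig_lengths = {ref.name: len(ref)}
    profile = compute_depth(groups, probes, padded, contig_lengths)
    calls = call_variants(groups, probes, reference, padded, CallerParams())
    variants = variant_calls(calls)
    report = compare_to_truth(
        variants, truth, profile, padded, reference=reference
    )
    return StudyRun(
        reference=reference,
        targets=targets,
        padded=padded,
        probes=probes,
        specs=specs,
        truth=truth,
        ledger=ledger,
        r1=r1,
        r2=r2,
        groups=groups,
        unassigned=unassigned,
        profile=profile,
        calls=calls,
        variants=variants,
        report=report,
    )
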