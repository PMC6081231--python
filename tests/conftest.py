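from __future__ import annotations

import pytest

from mipkit.capture_sim import (
    SimConfig,
    choose_variant_sites,
    plant_variants,
    random_reference,
    simulate_capture,
)
from mipkit.genomic_io import TargetRegion
from mipkit.panel_design import DesignParams, design_panel


@pytest.fixture(scope="session")
def small_reference():
    """The 2 kb synthetic fixture contig (seed 7)."""
    ref = random_reference("chrS", 2000, seed=7)
    return {ref.name: ref}


@pytest.fixture(scope="session")
def small_targets():
    return [TargetRegion("chrS", 200, 1800, "G1", "e1")]


@pytest.fixture(scope="session")
def small_panel(small_reference, small_targets):
    probes, oligos = design_panel(small_targets, small_reference, DesignParams())
    return probes, oligos


@pytest.fixture(scope="session")
def small_simulation(small_reference, small_targets, small_panel):
    """A seeded simulation over the 2 kb fixture with planted variants."""
    probes, _ = small_panel
    specs = choose_variant_sites(probes, small_reference, n_snv=10, n_indel=3, seed=5)
    haplotypes, truth = plant_variants(small_reference, specs)
    config = SimConfig(
        molecules_per_probe=30, duplication_mean=2.0, base_error_rate=0.0, seed=11
    )
    r1, r2, ledger = simulate_capture(probes, haplotypes, config)
    return {
        "probes": probes,
        "specs": specs,
        "haplotypes": haplotypes,
        "truth": truth,
        "config": config,
        "r1": r1,
        "r2": r2,
        "ledger": ledger,
    }
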