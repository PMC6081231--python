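"""End-to-end orchestration: design -> simulate -> process -> QC -> call ->
concordance, as one reproducible run with a manifest.

A single run seed fans out to per-stage derived seeds (seed + stage index)
so each stage is independently reproducible; every stage output file is
checksummed into the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .capture_sim import (
    SimConfig,
    choose_variant_sites,
    make_exon_targets,
    plant_variants,
    random_reference,
    simulate_capture,
    write_fastq,
    write_ledger,
    write_truth_vcf,
)
from .concordance import compare_to_truth
from .coverage_qc import compute_depth, qc_report, write_depth_table
from .genomic_io import read_fasta, read_targets, write_fasta, write_targets
from .panel_design import (
    DesignParams,
    design_panel,
    padded_targets,
    write_oligo_table,
    write_probe_table,
)
from .readproc import process_read_pairs, write_molecule_table
from .varcall import CallerParams, call_variants, variant_calls, write_vcf


class ConfigError(ValueError):
    pass


_KNOWN_SECTIONS = {
    "seed", "outdir", "sample_id", "fixture", "variants",
    "design", "sim", "caller", "qc",
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 1
    outdir: str = "mipkit_run"
    sample_id: str = "sample"
    # synthetic fixture (used when no external reference/targets are given)
    reference_fasta: str | None = None
    targets_bed: str | None = None
    contig_name: str = "chrS"
    contig_len: int = 8000
    n_exons: int = 8
    exon_len: int = 240
    exon_spacing: int = 360
    n_snv: int = 20
    n_indel: int = 0
    het_fraction: float = 0.5
    design: DesignParams = field(default_factory=DesignParams)
    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    qc_min_frac: float = 0.80
    qc_min_depth: int = 8
    qc_flag_below: float = 10.0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.outdir = str(raw.get("outdir", cfg.outdir))
        cfg.sample_id = str(raw.get("sample_id", cfg.sample_id))
        fixture = raw.get("fixture", {}) or {}
        for key in ("reference_fasta", "targets_bed", "contig_name"):
            if key in fixture:
                setattr(cfg, key, fixture[key])
        for key in ("contig_len", "n_exons", "exon_len", "exon_spacing"):
            if key in fixture:
                setattr(cfg, key, int(fixture[key]))
        variants = raw.get("variants", {}) or {}
        cfg.n_snv = int(variants.get("n_snv", cfg.n_snv))
        cfg.n_indel = int(variants.get("n_indel", cfg.n_indel))
        cfg.het_fraction = float(variants.get("het_fraction", cfg.het_fraction))
        try:
            design_kwargs = dict(raw.get("design", {}) or {})
            for key in ("ext_arm_len_range", "lig_arm_len_range", "arm_gc_bounds"):
                if key in design_kwargs:
                    design_kwargs[key] = tuple(design_kwargs[key])
            cfg.design = DesignParams(**design_kwargs)
            sim_kwargs = dict(raw.get("sim", {}) or {})
            sim_kwargs.setdefault("seed", cfg.seed + 2)
            cfg.sim = SimConfig(**sim_kwargs)
            cfg.caller = CallerParams(**(raw.get("caller", {}) or {}))
        except TypeError as exc:
            raise ConfigError(f"bad parameter name: {exc}") from exc
        qc = raw.get("qc", {}) or {}
        cfg.qc_min_frac = float(qc.get("min_frac", cfg.qc_min_frac))
        cfg.qc_min_depth = int(qc.get("min_depth", cfg.qc_min_depth))
        cfg.qc_flag_below = float(qc.get("flag_below", cfg.qc_flag_below))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def validate(self) -> None:
        max_ext = self.design.ext_arm_len_range[1]
        max_lig = self.design.lig_arm_len_range[1]
        needed = max(max_ext, self.design.tag_len + max_lig) + 1
        if self.sim.read_len < needed:
            raise ConfigError(
                f"read_len {self.sim.read_len} shorter than arm+tag structure "
                f"(need >= {needed})"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "mipkit",
        "version": __version__,
        "seed": config.seed,
        "sample_id": config.sample_id,
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stage_files: dict[str, list[Path]] = {}

    def finish(stage: str, files: list[Path], **metrics: Any) -> None:
        stage_files[stage] = files
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            **metrics,
        }

    try:
        # stage 0: fixture / inputs
        if config.reference_fasta:
            reference = read_fasta(config.reference_fasta)
            targets = read_targets(config.targets_bed, reference=reference)
        else:
            ref = random_reference(
                config.contig_name, config.contig_len, seed=config.seed + 0
            )
            reference = {ref.name: ref}
            targets = make_exon_targets(
                ref.name,
                len(ref),
                config.n_exons,
                exon_len=config.exon_len,
                spacing=config.exon_spacing,
            )
        fasta_path = out / "reference.fa"
        bed_path = out / "targets.bed"
        write_fasta(fasta_path, reference)
        write_targets(bed_path, targets)
        finish("fixture", [fasta_path, bed_path], n_targets=len(targets))

        # stage 1: panel design
        probes, oligos = design_panel(targets, reference, config.design)
        padded = padded_targets(targets, reference, config.design.pad_bp)
        probe_path = out / "panel.tsv"
        oligo_path = out / "oligos.tsv"
        write_probe_table(probe_path, probes)
        write_oligo_table(oligo_path, oligos)
        finish(
            "design",
            [probe_path, oligo_path],
            n_probes=len(probes),
            max_oligo_len=max(o.length for o in oligos),
        )

        # stage 2: variants + simulation
        specs = choose_variant_sites(
            probes,
            reference,
            config.n_snv,
            config.n_indel,
            seed=config.seed + 1,
            het_fraction=config.het_fraction,
        )
        haplotypes, truth = plant_variants(reference, specs)
        r1, r2, ledger = simulate_capture(probes, haplotypes, config.sim)
        r1_path, r2_path = out / "reads_1.fq", out / "reads_2.fq"
        ledger_path = out / "ledger.tsv"
        truth_path = out / "truth.vcf"
        write_fastq(r1_path, r1, mate=1)
        write_fastq(r2_path, r2, mate=2)
        write_ledger(ledger_path, ledger)
        write_truth_vcf(truth_path, truth, reference)
        finish(
            "simulate",
            [r1_path, r2_path, ledger_path, truth_path],
            n_molecules=len(ledger),
            n_read_pairs=len(r1),
            n_truth_variants=len(truth),
        )

        # stage 3: read processing
        groups, unassigned = process_read_pairs(r1, r2, probes)
        mol_path = out / "molecules.tsv"
        write_molecule_table(mol_path, groups)
        finish(
            "process",
            [mol_path],
            n_molecule_groups=len(groups),
            n_unassigned=len(unassigned),
        )

        # stage 4: coverage QC
        contig_lengths = {name: len(r) for name, r in reference.items()}
        profile = compute_depth(groups, probes, padded, contig_lengths)
        qc = qc_report(
            profile,
            targets,
            min_frac=config.qc_min_frac,
            min_depth=config.qc_min_depth,
            flag_below=config.qc_flag_below,
        )
        depth_path = out / "depth.tsv"
        qc_path = out / "qc.json"
        write_depth_table(depth_path, profile)
        qc_path.write_text(json.dumps(qc, indent=2) + "\n")
        finish("qc", [depth_path, qc_path], **{k: qc[k] for k in ("fraction_ge8", "median_depth", "passed")})

        # stage 5: variant calling
        calls = call_variants(groups, probes, reference, padded, config.caller)
        variants = variant_calls(calls)
        vcf_path = out / f"{config.sample_id}.vcf"
        write_vcf(vcf_path, variants, reference, sample_id=config.sample_id)
        finish("call", [vcf_path], n_variant_calls=len(variants))

        # stage 6: concordance against planted truth
        report = compare_to_truth(
            variants, truth, profile, padded,
            min_depth=config.caller.min_depth, reference=reference,
        )
        conc_path = out / "concordance.json"
        report.write_json(conc_path)
        finish(
            "concord",
            [conc_path],
            sensitivity=report.sensitivity,
            genotype_concordance=report.genotype_concordance,
            n_false_positive=report.n_false_positive,
        )
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"] and list(manifest["stages"])[-1]
        manifest["error"] = str(exc)
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
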