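# Methods

This note documents the models and procedures implemented in `mipkit`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make results
reproducible byte for byte.

## Coordinate conventions

All internal coordinates are 0-based, half-open. Conversion to 1-based
coordinates happens exactly twice: in the VCF writer (POS) and in HGVS
coding-position arithmetic. BED input/output is 0-based half-open as usual.

## Panel design

**Padding.** Each target exon is padded by `pad_bp` (default 25) on both
sides, clipped at contig edges, so that splice-site positions at exon–intron
boundaries are captured.

**Tiling.** Gap fills of fixed nominal length `gap_fill_len` (default
112 nt) are laid left to right across each padded region; the last tile is
right-aligned to the region end, so overlap between the final two tiles is
allowed and the union of gap fills covers every padded base (this coverage
completeness is enforced by an oracle test against a per-base mask). A
region shorter than one gap fill gets a single probe whose gap fill contains
it. 112 nt was chosen so that a paired 100 bp read run always determines the
full insert: read 1 carries the first ~80–84 insert bases after the
extension arm, read 2 the last ~68–72 after the tag and ligation arm, so the
fragments overlap for any insert up to ~130 nt.

**Arm selection.** For each tile, every combination of extension-arm length
16–20 nt and ligation-arm length 20–24 nt is scored by
`|GC(ext) − 0.5| + |GC(lig) − 0.5|`; the lowest score wins (ties: shorter
arms). An arm candidate is rejected if it contains N, has GC outside
[0.15, 0.80], or contains an EarI recognition site on either strand —
a probe whose arm carries the release site would be destroyed during
digestion. If no candidate passes at the nominal tile, the gap fill is
grown outward up to 16 nt total to slide the arm windows off the offending
sequence (coverage only increases; every downstream stage uses the
per-probe gap length, so nothing else changes). If growth does not help,
the design fails loudly, naming the region — extreme-GC or site-dense
windows are a genuine design failure, not something to paper over.

**Oligo assembly.** A synthesis oligo is

```
mipPrep1F · s1 · lig_arm · backbone_L · N×tag_len · backbone_R · ext_arm · s4 · revcomp(mipPrep1R)
```

with a 1-nt spacer `s1` and a 4-nt spacer `s4`. EarI cuts 1 nt beyond its
recognition site on the recognition strand and 4 nt on the other; both prep
primers end in the recognition site, so with these spacers the two cuts land
exactly at the probe-body boundaries and digestion releases the body with
both arms intact. The default backbone halves were chosen so that no
junction with an arm, tag, or spacer can complete a recognition site across
a boundary. Worst-case assembled length with default parameters is 139 nt,
under the 150-mer synthesis cap, which is enforced per oligo.

**EarI digestion model.** `digest_ear1` returns top-strand fragment strings
only: cuts at `i+7` for every `CTCTTC` at `i`, and at `j−4` for every
`GAAGAG` at `j`. Fragments always partition the input (property-tested).

## Capture simulation

The simulator is the package's fixture generator and defines the study
conditions under which the pipeline is validated.

* **Diploid haplotypes.** Variants (SNVs and indels ≤10 nt, VCF-style
  anchored alleles) are planted on a reference; homozygous variants go on
  both haplotypes, heterozygous on the first. Indel specs are left-normalized
  at generation time so truth and calls share one representation.
* **Molecules.** Each probe captures `molecules_per_probe` molecules,
  alternating deterministically between the haplotypes, so het sites have
  balanced allele sampling at any depth. Each molecule gets an i.i.d. random
  tag of `tag_len` (default 8) and a PCR duplicate count drawn as
  Geometric with mean `duplication_mean` (support ≥1) — a one-parameter,
  heavy-tailed duplicate model.
* **Reads.** Read 1 = extension arm + insert; read 2 = tag + reverse
  complement of (insert + ligation arm); both truncated/padded to
  `read_len` = 100. Per-base substitution errors are applied i.i.d. at
  `base_error_rate` to every copy, including arm and tag bases. Qualities
  are constant Phred 30 — the caller consumes a scalar error rate, so
  per-base quality modelling is out of scope.
* **Ledger.** Every molecule's (id, probe, tag, haplotype, duplicate count)
  is recorded, making deduplication exactly checkable, tag collisions
  included.
* **Variant placement.** The site chooser only uses positions ≥12 bp from
  every gap-fill boundary that covers them (so indels are always wholly
  inside each observing insert), keeps sites ≥25 bp apart, and keeps indel
  sites more than one gap-fill window apart so no insert carries two indels
  — otherwise an insert could leave the read-merge band. These are generator
  conditions, not caller capabilities: the caller itself simply sees inserts
  and windows.

**What the simulator does not emulate:** capture-efficiency differences
between probes (uniform capture), GC bias, indel sequencing errors, quality
score variation, strand-specific artifacts, off-target capture, and
contamination. Passing tests therefore demonstrate the correctness of the
algorithms under idealised error and sampling models, not performance on
real libraries, where arm mismatches, probe dropout, and context-dependent
error would lower sensitivity.

## Read processing

**Assignment.** Read 1's prefix is compared against every probe's extension
arm, and read 2's prefix (after removing the tag) against the reverse
complement of every ligation arm, by Hamming distance. A pair is assigned
iff exactly one probe matches both arms within `max_mismatch` (default 1)
substitutions; several candidates → "ambiguous", none → "no_match", reads
shorter than arm+tag → "short". An exact-match dictionary accelerates the
common case and defers to the full scan whenever the panel contains
near-identical arm pairs, keeping the fast path equivalent to the exhaustive
definition. Arm-anchored assignment replaces genome-wide alignment: for a
known panel the two are equivalent for on-target reads, and off-panel reads
become "unassigned" rather than unmapped.

**Insert reconstruction.** The two trimmed fragments are a prefix and a
suffix of the molecule insert. The insert length is searched within ±12 of
the probe's reference gap length; each candidate length implies an overlap,
scored by mismatches (N is a wildcard). The best-supported length wins (ties
toward the expected length, then the shorter). Overlap disagreements become
N, which downstream stages treat as missing data.

**Deduplication.** Molecules are groups keyed by (probe, tag). With
`cluster_hamming1` enabled, a directional rule merges a tag into a Hamming-1
neighbour when its read count is at most half the neighbour's — absorbing
tag sequencing errors into the true molecule. Clustering is off by default:
exact duplicate-tag removal is the baseline behaviour, and both modes are
exposed. Groups are emitted sorted, so results are independent of read
order.

**Consensus.** Per-position majority vote over members of the modal insert
length; N votes are ignored; exact ties yield N. A single member is its own
consensus. Tag collisions between haplotypes therefore produce N at het
positions rather than a phantom allele.

## Coverage QC

Depth is unique-molecule depth: each molecule group adds 1 to every padded
target base its probe's gap fill covers, so PCR duplicates never inflate
coverage. The sample rule is `fraction(depth ≥ 8) ≥ 0.80`, both thresholds
inclusive; the ≥40× fraction and the median (lower median over targeted
bases — a deterministic integer) are reported alongside. Exons are flagged
when their mean depth is strictly below 10 or no base is covered. Fractions
are computed over padded target bases (the sequenced gap-fill domain), a
configurable choice.

## Variant calling

**Alignment.** Each consensus insert is globally aligned to its probe's
reference gap window under unit costs (match 0, mismatch 1, gap 1 per base)
with a banded three-state (Gotoh) dynamic program. Tie-breaking is fixed and
deliberate: among equal-cost alignments, (1) fewest gap openings — a
contiguous multi-base indel is never split into equal-cost pieces, which a
plain unit-cost DP will otherwise happily do; (2) mismatch preferred over
gap; (3) gaps leftmost, matching VCF left-normalization. The band (±12)
covers the maximum supported indel length (10) with margin. Equal-length
inserts with ≤2 mismatches take a direct substitution-only fast path that
provably agrees with the DP under these tie-breaks.

**Pileup.** Each molecule contributes at most one observation per reference
position. Deletions contribute a `-SEQ` allele and insertions a `+SEQ`
allele anchored on the preceding reference base (replacing that molecule's
anchor-base observation), mirroring VCF anchoring. N consensus bases
contribute nothing. Only padded-target positions are reported.

**Genotyping.** For the reference allele R and the most frequent non-ref
allele A, per-observation likelihoods with error rate `e` (default 0.01)
are: `P(obs|RR) = 1−e` if obs = R else `e/3`;
`P(obs|RA) = (1−e)/2 + e/6` for obs ∈ {R, A}, else `e/3`; `P(obs|AA)`
symmetric. With a uniform prior the genotype is the posterior argmax; GQ is
`−10·log10(1 − posterior)`, capped at 99. Calls are emitted only at depth ≥8
(the reporting gate used for concordance throughout) and GQ ≥20. A
consequence worth knowing: at depth exactly 8 with one discordant
observation the posterior is flat and the column becomes a no-call rather
than either genotype — the GQ gate, not the argmax, is what prevents false
hets at marginal depth.

**VCF.** Output is VCF 4.2 with GT:DP:AD:GQ, 1-based positions, and
anchor-base indel representation; the writer is cross-checked in tests by
re-reading with cyvcf2.

## Concordance

Truth variants are *assessable* where unique-molecule depth ≥8. Sensitivity
is the fraction of assessable truth variants present in the calls (site and
alternate allele matching after left-normalizing both sides against the
reference); genotype concordance is unordered allele-multiset equality over
the detected sites (the variant-position denominator; raw counts are
reported so other denominators can be recomputed). False positives are
called variants inside the padded target domain absent from truth. An empty
assessable set yields explicit `None` rates, not a crash.

## Annotation

HGVS arithmetic is pure integer math: codon = ⌊(c−1)/3⌋+1, offset =
((c−1) mod 3)+1; protein consequences translate the affected codon with the
standard genetic code ('*' for stop, '=' flag for synonymous). Mature-peptide
renumbering subtracts the signal-peptide length (a transcript-model input,
never inferred from sequence; 26 for the GH1 preprotein), erroring for
residues inside the signal peptide. Segregation checking implements the
autosomal-dominant model only: an affected non-carrier is a violation; an
unaffected carrier is recorded as a reduced-penetrance note, not a
violation. Other inheritance models error as unsupported rather than guess.
The frequency filter retains variants absent from the population table or
with AF strictly below `max_af` (default 0.001). Cohort summaries report
counts and integer percentages rounded half away from zero (58.8 → 59), and
validate that a CPHD diagnosis corresponds to ≥2 deficient hormone axes.
ACMG-style classification is deliberately out of scope; the module stops at
frequency filtering and segregation.

## Pipeline and reproducibility

`run_pipeline` executes fixture → design → simulate → process → qc → call →
concord, writing every stage's outputs and SHA-256 checksums into a
manifest. One run seed fans out to per-stage derived seeds (seed + stage
index) so stages are independently reproducible; identical config and
inputs give identical checksums (tested). Config validation happens before
any stage runs — e.g. a read length shorter than arm+tag structure is
rejected at startup.

## Problem sizes used in validation

The test suite exercises two scales, chosen to give ≥20 and ≥40 unique
molecules per site respectively while keeping the whole suite fast:

* a 2 kb single-region fixture (seed 7): 15 probes, used for design,
  digestion, read-processing, and dedup-oracle tests;
* a 42 kb, 64-exon fixture: 192 probes, ~15 k targeted bases; 300 SNVs + 20
  indels at 24 molecules/probe with zero error for the noise-free recovery
  check (sensitivity, concordance, and false-positive count must be perfect),
  and 300 SNVs at 48 molecules/probe with 0.5% per-base error for the noisy
  sensitivity check (≥0.99).

## Known limitations

* Arms are screened only against exact duplication within the panel;
  cross-reactivity with paralogous loci (the classic *GH1*/*GH2*/*CSH*
  problem) is not modelled — a real panel needs genome-wide arm uniqueness
  screening and downstream confirmation assays.
* The caller is single-sample and biallelic per site; indels longer than
  10 nt, multi-allelic sites, and haplotype-assembly-based calling are out
  of scope.
* The simulator's uniform capture model means coverage QC failure modes
  (probe dropout, GC-poor exons) only arise in real data; the QC rules are
  implemented and boundary-tested, but their discriminative value is not
  demonstrated in silico.
* Arm melting temperature is approximated by GC distance from 0.5; no
  thermodynamic model is used.
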