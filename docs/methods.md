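# Methods

## Scope and model

`strainloh` is a simulator-plus-analysis package for one specific failure mode
of tumor/germline genome comparison in engineered mouse models: a germline
deletion private to one founder strain, genetically linked to a driver allele
whose wild-type counterpart is lost somatically, surfaces as a recurrent focal
"somatic" homozygous deletion. The package contains no read-level simulation
and no alignment: observables are generated directly at the level a CNV/LOH
caller consumes (binned read counts; per-SNP REF/ALT counts).

## Synthetic genome

Two chromosomes stand in for the relevant mouse geometry:

| parameter | default | meaning |
|---|---|---|
| chr11-like length | 122 Mb | carries the driver and the linked variant |
| chr4-like length | 156 Mb | carries a tumor-suppressor locus and a second variant |
| driver position | 69,580,000 | engineered allele of donor-strain origin |
| chr11 variant | [70,980,000, 71,180,000) | 200 kb donor-private deletion, midpoint 1.5 Mb from the driver |
| suppressor position | 89,280,000 (chr4) | locus for two-step somatic loss |
| chr4 variant | [112,000,000, 112,600,000) | 600 kb donor-private deletion |
| SNP spacing | 10 kb grid with ±2.5 kb seeded jitter | strain-diagnostic SNP map |
| map rate | 0.5 cM/Mb, uniform | recombination |

Founders are fully inbred: `REFSTRAIN` defines the reference genome (carries
REF at every diagnostic SNP), `DONOR` carries ALT at every diagnostic SNP and
carries the registry deletions. The coordinates are synthetic stand-ins chosen
at the physical scale of the real loci, not real assembly coordinates; the
data model also admits reference-strain-private variants, though none are in
the defaults. All coordinates are 0-based half-open (BED convention).

## Inheritance

Meiosis follows the Haldane model: crossover count Poisson with mean equal to
the map length in Morgans (`L_bp × map_rate / 100 / 1e6`; 0.61 for the
chr11-like), crossover positions uniform, no interference, no obligate
chiasma, starting copy a fair coin. This is sufficient for the block-scale and
expectation-level claims the package tests; interference would change the
variance of block lengths, not the means. Sex chromosomes, mutation and
genotyping error are not modeled.

Backcross schemes select offspring genotypes by rejection sampling (as real
breeding does by genotyping), capped at 10,000 attempts per generation.
Generations count backcross matings: the F1 is generation 0, so the expected
donor fraction on a non-selected chromosome after n generations is
2^−(n+1) (0.25 after one backcross). This is validated against an independent
grid-based Monte-Carlo meiosis oracle rather than assumed. The default cohort
scheme is an F1 intercross (F2 animals) with configurable genotype selection
at the driver (`carrier`/`het`/`hom`); the real cohorts' pedigrees are mixed
and unknown, so the scheme is a modeling choice exposed in config.

## Somatic events and observables

A tumor genome is the germline plus an ordered event list. Copy-neutral LOH on
target copy X zeroes X and doubles the other haplotype; a focal deletion
zeroes X inside its interval. Later events read the state left by earlier
events, so deletion-then-CN-LOH retaining the deleted copy yields (0,0).
Driver CN-LOH is emitted only for driver-heterozygous germlines (nothing to
select against in homozygotes), targets the copy not carrying the engineered
allele, and by default runs from a uniform start within 30 Mb upstream of the
driver to the chromosome end (telomeric CN-LOH; the real segment extents are
not known, and interstitial events are configurable).

What sequencing reports is *physical copies*: per-haplotype copy number,
zeroed wherever that haplotype's strain carries a registry deletion. Coverage
is negative-binomial per 20 kb bin with mean `depth × copies/2` and
`var = μ + 0.05 μ²`; SNP depth is Poisson with the same mean rule and the ALT
count binomial with success probability equal to the donor-derived fraction of
surviving copies. Defaults (depth 100 per bin and per SNP, dispersion 0.05)
are WES-like; tumor purity defaults to 1.0 (primary cell cultures) and a
purity parameter mixes germline expectations in at fraction 1 − purity.
aCGH-like probe ratios add Gaussian noise (sd 0.15) to
`log2((test+ε)/(ref+ε))` with ε = 0.5 pseudo-copies; probe spacing is a free
parameter since the real array spacing at the locus is not numerically
specified.

## Calling

**Haplotype states.** Windows of 25 SNPs (depth ≥ 10) classified by mean VAF:
HOM_REF below 0.15 (or no ALT reads), HOM_ALT above 0.85, HET between.
Thresholds separate Binomial(100, 0.5) from Binomial(100, ~1) with negligible
error; the paper-style rule is a direct three-way frequency classification, so
a window-threshold segmentation was chosen over an HMM (an HMM is a natural
extension, not needed at these depths). Boundaries fall midway between
flanking SNPs of different-state windows, ties toward the lower coordinate.
The min-depth filter stands in for read-level mapping-quality filtering, which
has no analog here. A caveat documented deliberately: inside a
germline-*heterozygous* donor deletion the surviving copy is pure reference,
so the observable there is genuinely HOM_REF-like (VAF 0 at ~20 SNPs) — the
caller labels it as such, and downstream logic must not assume a single
uninterrupted HET segment across the variant.

**LOH.** Within germline-HET segments, tumor windows with VAF outside
[0.15, 0.85] are LOH; contiguous windows merge, and calls with the same
retained haplotype separated by < 1 Mb are bridged into one call — precisely
because of the caveat above, a sub-window germline feature must not cut one
somatic event in two. Mechanism from the median depth-normalized
tumor/germline bin ratio over the call: CN_LOH in [0.8, 1.2], DELETION_LOH
below 0.7, otherwise (or with missing coverage) UNKNOWN.

**CNV.** Per-bin `log2((t·s + 0.5)/(g + 0.5))` with s the ratio of genome-wide
medians, median-centered; median normalization is robust to the small altered
fraction. Segmentation is deterministic recursive binary segmentation with a
penalty expressed in units of `σ² log n` per chromosome, σ² estimated robustly
from successive differences (signal-insensitive). A single split is accepted
above 3 units. Because a short focal event inside a long chromosome never pays
for a *single* split (its best single-split gain is O(Δ²m²/n), ≈ 1 unit for a
10-bin homozygous dip in 6,100 bins), each rejected step also evaluates the
best interval carve-out — the circular-scan statistic that introduces two
breakpoints at once — accepted above 6 units, reflecting its O(n²) candidate
space. Measured on pure noise these thresholds produce no false splits in 100
seeds at either 200 bins or genome scale, while homozygous-loss signals
(Δ ≈ −6.6) exceed the interval threshold by ~50×. Zero-variance segments
(fewer than 3 bins) accept any non-zero contrast. Calls: HOM_LOSS ≤ −2.0,
HET_LOSS ≤ −0.35, GAIN ≥ +0.3 — a homozygous loss at germline-het depth
(1 → 0 copies) sits near −6.6, far below threshold, while CN-LOH territory
stays at ratio ≈ 0.

**Classification.** Deterministic conjunction of three evidence flags
(registry reciprocal overlap ≥ 0.9; breakpoint concordance ≥ 0.9 across ≥ 3
cluster members at 1-bin tolerance; containment in a driver-spanning LOH
call), not a probabilistic score: the underlying argument is categorical, and
a score would be invention. Thresholds are config-exposed defaults; recurrence
beyond the ≥ 3-member rule is reported, not thresholded.

## What the simulator does and does not establish

The generator emulates: dense strain-diagnostic SNPs, discrete strain-private
deletions, Mendelian inheritance with recombination, driver-selected CN-LOH,
stepped two-hit suppressor loss, and overdispersed WES-like counts. It does
not emulate GC/capture bias, mappability artifacts, subclonality, segmental
duplications or genotyping error. Passing tests therefore demonstrate the
*mechanism* — that linked germline variants provably masquerade as recurrent
focal somatic deletions and that the three-evidence rule separates them — not
that the caller is robust to every real-data artifact class.

## Problem sizes and determinism

Default analyses run a 278 Mb two-chromosome genome (≈ 27,800 SNPs, ≈ 13,900
bins per sample). Cohort runs derive per-animal, per-stage generators from the
master seed by fixed arithmetic (`SeedSequence([seed, animal, stream])`), and
all writers use fixed float formatting, so identical config plus seed
reproduce output trees byte for byte. Monte-Carlo checks in the test suite use
hundreds to thousands of replicates with 3-standard-error tolerances; the
backcross oracle uses an independent grid-based meiosis implementation at
10 kb resolution.

## Known limitations

- Telomeric-only default CN-LOH geometry; interstitial events require config.
- Breakpoint resolution is one bin (20 kb) for CNV and one SNP window
  (~250 kb) for haplotype/LOH boundaries.
- The classifier assumes matched germline; unmatched designs (e.g.
  germline-vs-founder) produce AMBIGUOUS calls by design.
- No purity/ploidy fitting; allele-specific copy number beyond the
  per-haplotype bookkeeping of the simulator is out of scope.
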