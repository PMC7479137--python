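# strainloh

Strain-specific germline deletions masquerading as somatic CNVs in mouse
tumor/normal genomics — a simulator plus the detection stack that unmasks them.

## The problem

Genetically engineered mouse models of cancer are usually built on one inbred
background (e.g. a 129S-related ES-cell line) and then crossed onto another
(e.g. C57BL/6J, the reference genome strain). Inbred strains differ not only at
millions of SNPs but also at discrete structural variants: whole loci that are
homozygously deleted in one strain relative to the reference.

When an engineered driver allele sits in tight genetic linkage with such a
strain-private deletion (in the motivating case, ~1.5 Mb apart), every carrier
animal inherits the deletion on the same haplotype as the driver. If tumors are
under selective pressure to lose the wild-type driver haplotype — which they
do, typically through copy-neutral loss of heterozygosity (CN-LOH) — then a
single somatic event makes the tumor homozygous for the strain deletion. A
tumor-vs-germline CNV comparison then reports a *focal homozygous deletion*
at the variant locus, with these unmistakable (and misleading) features:

1. it looks somatically acquired, although the breakpoints are germline;
2. it has *identical* coordinates in every affected tumor — unlike the
   "stepped" breakpoint pattern of genuine somatic losses at tumor-suppressor
   loci;
3. it is invisible in animals bred to homozygosity for the driver haplotype,
   because the deletion is then already homozygous in the germline.

`strainloh` simulates this mechanism end to end — founder strains, meioses and
backcross schemes, somatic CN-LOH and two-step deletion/CN-LOH events, and
WES-like binned coverage plus per-SNP allele counts — and implements the
analysis that separates such artifacts from real somatic drivers.

## The model and the calling rules

**Haplotype state from SNP frequencies.** At strain-diagnostic SNPs the donor
haplotype carries ALT with probability 1. Windowed variant-allele frequencies
(VAF; 25 SNPs per window, minimum depth 10) classify the genome three ways:
VAF ≈ 0.5 → heterozygous (two haplotypes), VAF ≈ 1.0 → pure donor, no ALT
evidence → homozygous reference.

**LOH mechanism.** Within germline-heterozygous territory, tumor windows whose
VAF leaves [0.15, 0.85] are LOH. The tumor/germline coverage ratio over the
call separates copy-neutral LOH (ratio ≈ 1, total copies conserved) from
deletion LOH (ratio ≈ 0.5).

**CNV from binned coverage.** Per-bin log2 ratios of median-normalized
tumor over germline counts (20 kb bins) are segmented by deterministic
recursive binary segmentation with a CBS-style interval carve-out, and segment
means are thresholded (homozygous loss ≤ −2, het loss ≤ −0.35, gain ≥ +0.3).

**Confounder classification.** Each homozygous-loss call is scored on three
lines of evidence: reciprocal overlap ≥ 0.9 with a strain-variant registry;
identical breakpoints across ≥ 3 tumors (pairwise concordance ≥ 0.9 at 1-bin
tolerance); and location inside an LOH call whose interval contains a driver
under selection. `(registry OR identical breakpoints) AND driver LOH` →
germline-variant artifact; no evidence → somatic candidate; otherwise
ambiguous.

## Worked example

Simulate a four-animal cohort of heterozygous driver carriers (driver on the
donor haplotype, second haplotype from the reference strain) and run the full
pipeline:

```python
import json
import strainloh as sl
from strainloh.config import default_config

cfg = default_config()
cfg["cohort"]["n_animals"] = 4
report = sl.run_cohort_pipeline(cfg, seed=11)
print(json.dumps(report["summary"], indent=2, sort_keys=True))
```

prints

```json
{
  "animals_with_variant_locus_hom_loss": {
    "nlrp1_like_del": 4,
    "skint_like_del": 0
  },
  "classification_counts": {
    "GERMLINE_VARIANT_ARTIFACT": 4
  },
  "n_animals": 4,
  "n_hom_loss_calls": 4
}
```

All four tumors underwent driver CN-LOH, and all four show a homozygous-loss
call at the linked chr11-like variant locus — at exactly the registry
coordinates, e.g. the first verdict:

```
animal_000  chr11  70980000  71180000  GERMLINE_VARIANT_ARTIFACT  distance_to_driver=1500000
```

Every call matches the registry, shares breakpoints with every other tumor,
and lies inside a CN-LOH call spanning the driver — so each is classified as a
germline-variant artifact rather than a somatic candidate. Re-running with
`cfg["breeding"]["selection"] = "hom"` (animals homozygous for the driver
haplotype) yields zero variant-locus calls: the same variant becomes invisible
to tumor/germline comparison.

The same pipeline is exposed on the command line:

```bash
strainloh run-cohort --seed 11 --outdir cohort_out
strainloh report --outdir cohort_out
```

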