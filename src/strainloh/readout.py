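"""WES-like observables: binned coverage, per-SNP allele counts, aCGH ratios.

The quantity sequencing actually reports is the number of *physical* DNA
copies at a position: per-haplotype copy numbers, zeroing any haplotype whose
founder strain carries a registry deletion spanning the position.  A deletion
on a haplotype removes both its sequence coverage and every diagnostic SNP it
would otherwise report — which is why a germline-homozygous strain variant is
invisible to tumor/germline comparison, while the same variant heterozygous in
the germline surfaces as an apparent focal homozygous loss the moment CN-LOH
removes the intact haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breeding import DiploidGenome, HaplotypeMosaic
from .layout import DONOR, GenomeLayout, StrainVariantRegistry
from .tumor import TumorGenome


@dataclass
class CoverageProfile:
    """Binned read counts for one sample; bins tile each chromosome."""

    sample_id: str
    bins: pd.DataFrame  # columns: chrom, start, end, count

    def counts_on(self, chrom: str) -> pd.DataFrame:
        return self.bins[self.bins["chrom"] == chrom].reset_index(drop=True)


@dataclass
class AlleleCountTable:
    """REF/ALT read counts at diagnostic SNP positions; ALT is the donor allele."""

    sample_id: str
    rows: pd.DataFrame  # columns: chrom, pos, ref_count, alt_count

    def on(self, chrom: str) -> pd.DataFrame:
        return self.rows[self.rows["chrom"] == chrom].reset_index(drop=True)


@dataclass
class ProbeSet:
    """aCGH-like probe positions, optionally with per-probe log2 ratios."""

    probes: pd.DataFrame  # columns: chrom, pos [, log2_ratio]

    @classmethod
    def regular(cls, layout: GenomeLayout, spacing: int) -> "ProbeSet":
        frames = []
        for chrom, length in layout.chromosomes.items():
            pos = np.arange(spacing // 2, length, spacing, dtype=np.int64)
            frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        return cls(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# physical-copy step functions


def _germline_steps(genome: DiploidGenome, chrom: str):
    a, b = genome.copies[chrom]
    breaks = np.unique(np.concatenate([a.boundaries(), b.boundaries()]))
    ones = np.ones(breaks.size - 1, dtype=np.int64)
    return breaks, ones, ones.copy(), a, b


def _tumor_steps(tumor: TumorGenome, chrom: str):
    a, b = tumor.germline.copies[chrom]
    ebreaks, n_a, n_b = tumor.copy_number_steps(chrom)
    breaks = np.unique(np.concatenate([ebreaks, a.boundaries(), b.boundaries()]))
    idx = np.searchsorted(ebreaks, breaks[:-1], side="right") - 1
    return breaks, n_a[idx], n_b[idx], a, b


def _strain_codes(mosaic: HaplotypeMosaic, mids: np.ndarray) -> np.ndarray:
    starts = np.array([blk[0] for blk in mosaic.blocks], dtype=np.int64)
    strains = np.array([blk[2] for blk in mosaic.blocks])
    return strains[np.searchsorted(starts, mids, side="right") - 1]


def physical_steps(
    genome: DiploidGenome | TumorGenome,
    registry: StrainVariantRegistry,
    chrom: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step function (breaks, total physical copies, donor-origin physical copies).

    Haplotypes whose strain carries a registry deletion over an interval
    contribute zero physical copies there; ``donor`` counts the surviving
    copies of donor-strain origin (the copies reporting the ALT allele).
    """
    if isinstance(genome, TumorGenome):
        breaks, n_a, n_b, mos_a, mos_b = _tumor_steps(genome, chrom)
    else:
        breaks, n_a, n_b, mos_a, mos_b = _germline_steps(genome, chrom)

    vbounds = [p for v in registry.on(chrom) for p in (v.start, v.end)]
    if vbounds:
        allb = np.unique(np.concatenate([breaks, np.array(vbounds, dtype=np.int64)]))
        allb = allb[(allb >= 0) & (allb <= breaks[-1])]
        idx = np.searchsorted(breaks, allb[:-1], side="right") - 1
        n_a, n_b = n_a[idx], n_b[idx]
        breaks = allb

    mids = (breaks[:-1] + breaks[1:]) // 2
    strain_a = _strain_codes(mos_a, mids)
    strain_b = _strain_codes(mos_b, mids)

    alive_a = np.ones(mids.size, dtype=bool)
    alive_b = np.ones(mids.size, dtype=bool)
    for v in registry.on(chrom):
        inside = (mids >= v.start) & (mids < v.end)
        alive_a &= ~(inside & (strain_a == v.carrier_strain))
        alive_b &= ~(inside & (strain_b == v.carrier_strain))

    phys_a = np.where(alive_a, n_a, 0)
    phys_b = np.where(alive_b, n_b, 0)
    total = phys_a + phys_b
    donor = phys_a * (strain_a == DONOR) + phys_b * (strain_b == DONOR)
    return breaks, total, donor


def physical_copies(
    genome: DiploidGenome | TumorGenome,
    registry: StrainVariantRegistry,
    chrom: str,
    pos: int,
) -> int:
    """Physical DNA copies at one position — what sequencing depth reports."""
    breaks, total, _ = physical_steps(genome, registry, chrom)
    i = int(np.searchsorted(breaks, pos, side="right")) - 1
    if i < 0 or pos >= breaks[-1]:
        raise ValueError(f"position {pos} out of range on {chrom}")
    return int(total[i])


def _step_integral(breaks: np.ndarray, values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Exact integral of a step function between consecutive ``edges``."""
    cum = np.concatenate(([0.0], np.cumsum(values.astype(float) * np.diff(breaks))))
    at_edges = np.interp(edges, breaks, cum)
    return np.diff(at_edges)


def _mixed_profiles(genome, registry, chrom, purity):
    """Tumor/germline expectation mixture for impure samples, on shared breaks."""
    breaks, total, donor = physical_steps(genome, registry, chrom)
    if purity >= 1.0 or not isinstance(genome, TumorGenome):
        return breaks, total.astype(float), donor.astype(float)
    gbreaks, gtotal, gdonor = physical_steps(genome.germline, registry, chrom)
    allb = np.unique(np.concatenate([breaks, gbreaks]))
    ti = np.searchsorted(breaks, allb[:-1], side="right") - 1
    gi = np.searchsorted(gbreaks, allb[:-1], side="right") - 1
    mixed_total = purity * total[ti] + (1 - purity) * gtotal[gi]
    mixed_donor = purity * donor[ti] + (1 - purity) * gdonor[gi]
    return allb, mixed_total, mixed_donor


# ---------------------------------------------------------------------------
# simulators


def simulate_coverage(
    genome: DiploidGenome | TumorGenome,
    registry: StrainVariantRegistry,
    layout: GenomeLayout,
    bin_size: int = 20_000,
    mean_depth: float = 100.0,
    dispersion: float = 0.05,
    seed=0,
    purity: float = 1.0,
    sample_id: str = "sample",
) -> CoverageProfile:
    """Draw binned read counts.

    Expected count per full bin is ``mean_depth * mean_physical_copies / 2``
    (a trailing short bin scales with its width); counts are negative binomial
    with ``var = mu + dispersion * mu**2``, Poisson when dispersion is 0.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    frames = []
    for chrom, length in layout.chromosomes.items():
        edges = np.arange(0, length, bin_size, dtype=np.int64)
        edges = np.concatenate([edges, [length]])
        breaks, total, _ = _mixed_profiles(genome, registry, chrom, purity)
        mass = _step_integral(breaks, total, edges)  # copies * bp per bin
        mu = mean_depth * mass / (2.0 * bin_size)
        if dispersion > 0:
            n = 1.0 / dispersion
            counts = np.where(
                mu > 0, rng.negative_binomial(n, np.minimum(1.0, n / (n + mu))), 0
            )
        else:
            counts = rng.poisson(mu)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": edges[:-1], "end": edges[1:], "count": counts}
            )
        )
    return CoverageProfile(sample_id, pd.concat(frames, ignore_index=True))


def simulate_allele_counts(
    genome: DiploidGenome | TumorGenome,
    registry: StrainVariantRegistry,
    layout: GenomeLayout,
    mean_depth: float = 100.0,
    seed=0,
    purity: float = 1.0,
    sample_id: str = "sample",
) -> AlleleCountTable:
    """Draw REF/ALT read counts at every diagnostic SNP.

    Total depth per SNP is Poisson(mean_depth * physical_copies / 2); the ALT
    count is binomial with success probability equal to the fraction of
    surviving copies that are donor-derived.  SNPs with zero surviving copies
    (inside a homozygous deletion) receive depth 0.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    frames = []
    for chrom in layout.chromosomes:
        snps = layout.snp_positions.get(chrom, np.empty(0, np.int64))
        if snps.size == 0:
            continue
        breaks, total, donor = _mixed_profiles(genome, registry, chrom, purity)
        idx = np.searchsorted(breaks, snps, side="right") - 1
        phys = total[idx]
        don = donor[idx]
        depth = rng.poisson(mean_depth * phys / 2.0)
        p_alt = np.divide(don, phys, out=np.zeros_like(don, dtype=float), where=phys > 0)
        alt = rng.binomial(depth, p_alt)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": snps, "ref_count": depth - alt, "alt_count": alt}
            )
        )
    rows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "ref_count", "alt_count"])
    )
    return AlleleCountTable(sample_id, rows)


def simulate_acgh(
    tumor: DiploidGenome | TumorGenome,
    registry: StrainVariantRegistry,
    layout: GenomeLayout,
    probes: ProbeSet,
    noise_sd: float = 0.15,
    seed=0,
    reference: DiploidGenome | TumorGenome | None = None,
    pseudo_copy: float = 0.5,
) -> ProbeSet:
    """Per-probe log2 ratio of test vs reference physical copies plus noise.

    The reference defaults to the germline of the test sample (tumor/germline
    design); passing a pure reference-strain founder emulates inter-strain
    germline hybridization.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if reference is None:
        reference = tumor.germline if isinstance(tumor, TumorGenome) else tumor
    out = probes.probes.copy()
    ratios = np.empty(len(out))
    for chrom in layout.chromosomes:
        mask = (out["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = out.loc[mask, "pos"].to_numpy()
        tb, tt, _ = physical_steps(tumor, registry, chrom)
        rb, rt, _ = physical_steps(reference, registry, chrom)
        t = tt[np.searchsorted(tb, pos, side="right") - 1]
        r = rt[np.searchsorted(rb, pos, side="right") - 1]
        ratios[mask] = np.log2((t + pseudo_copy) / (r + pseudo_copy))
    ratios += rng.normal(0.0, noise_sd, size=ratios.size)
    out["log2_ratio"] = ratios
    return ProbeSet(out)
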