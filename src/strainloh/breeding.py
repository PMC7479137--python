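"""Meiosis, crosses and backcross schemes over haplotype-mosaic genomes.

Inheritance is modeled at the level of founder-strain haplotype blocks: each
chromosome copy is an ordered tiling of intervals labeled by the founder they
descend from.  Meiosis follows the Haldane model — crossover count Poisson with
mean equal to the map length in Morgans, crossover positions uniform, no
interference and no obligate chiasma — which is sufficient for block-scale and
expectation-level behavior of inbred crosses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import DONOR, EngineeredAllele, GenomeLayout

Block = tuple[int, int, str]


def _merge_blocks(blocks: list[Block]) -> list[Block]:
    merged: list[Block] = []
    for start, end, strain in blocks:
        if start >= end:
            continue
        if merged and merged[-1][2] == strain and merged[-1][1] == start:
            merged[-1] = (merged[-1][0], end, strain)
        else:
            merged.append((start, end, strain))
    return merged


@dataclass
class HaplotypeMosaic:
    """One chromosome copy as an ordered tiling of founder-strain blocks."""

    chrom: str
    blocks: list[Block]

    def __post_init__(self) -> None:
        self.blocks = _merge_blocks([tuple(b) for b in self.blocks])
        if not self.blocks:
            raise ValueError("mosaic must contain at least one block")
        if self.blocks[0][0] != 0:
            raise ValueError("first block must start at 0")
        for (s0, e0, _), (s1, _, _) in zip(self.blocks, self.blocks[1:]):
            if s1 != e0:
                raise ValueError("blocks must be contiguous")

    @classmethod
    def single(cls, chrom: str, length: int, strain: str) -> "HaplotypeMosaic":
        return cls(chrom, [(0, length, strain)])

    @property
    def length(self) -> int:
        return self.blocks[-1][1]

    def boundaries(self) -> np.ndarray:
        return np.array([b[0] for b in self.blocks] + [self.length], dtype=np.int64)

    def strain_at(self, pos: int) -> str:
        if not (0 <= pos < self.length):
            raise ValueError(f"position {pos} outside [0, {self.length})")
        starts = [b[0] for b in self.blocks]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return self.blocks[i][2]

    def restricted(self, start: int, end: int) -> list[Block]:
        """Blocks clipped to [start, end)."""
        out = []
        for s, e, strain in self.blocks:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out.append((lo, hi, strain))
        return out

    def strain_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s, e, strain in self.blocks:
            out[strain] = out.get(strain, 0) + (e - s)
        return out


@dataclass
class DiploidGenome:
    """A germline genome: per chromosome, a pair of haplotype mosaics (A, B)."""

    layout: GenomeLayout
    copies: dict[str, tuple[HaplotypeMosaic, HaplotypeMosaic]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.layout.chromosomes.items():
            if chrom not in self.copies:
                raise ValueError(f"missing chromosome {chrom!r}")
            for m in self.copies[chrom]:
                if m.length != length:
                    raise ValueError(f"mosaic on {chrom!r} does not tile the chromosome")

    @classmethod
    def founder(cls, layout: GenomeLayout, strain: str) -> "DiploidGenome":
        return cls(
            layout,
            {
                c: (
                    HaplotypeMosaic.single(c, L, strain),
                    HaplotypeMosaic.single(c, L, strain),
                )
                for c, L in layout.chromosomes.items()
            },
        )

    def strain_at(self, chrom: str, pos: int, copy: str) -> str:
        idx = {"A": 0, "B": 1}[copy]
        return self.copies[chrom][idx].strain_at(pos)

    def carries_allele(self, allele: EngineeredAllele) -> bool:
        return any(
            self.strain_at(allele.chrom, allele.position, c) == allele.origin_strain
            for c in ("A", "B")
        )

    def allele_dosage(self, allele: EngineeredAllele) -> int:
        """0, 1 or 2 copies of the engineered-allele haplotype at its position."""
        return sum(
            self.strain_at(allele.chrom, allele.position, c) == allele.origin_strain
            for c in ("A", "B")
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def meiosis(parent: DiploidGenome, chrom: str, seed) -> HaplotypeMosaic:
    """Generate one gamete mosaic for ``chrom`` under the Haldane model.

    Crossover count ~ Poisson(L_bp * map_rate / 100 / 1e6), positions uniform,
    starting parental copy a fair coin; the gamete is the alternating splice of
    the two parental copies at the crossover points.
    """
    if chrom not in parent.layout.chromosomes:
        raise ValueError(f"unknown chromosome {chrom!r}")
    rng = _as_rng(seed)
    length = parent.layout.length(chrom)
    morgans = length * parent.layout.map_rate / 100.0 / 1e6
    n_xo = rng.poisson(morgans)
    xovers = np.sort(rng.integers(1, length, size=n_xo)) if n_xo else np.empty(0, np.int64)
    current = int(rng.integers(2))

    edges = np.concatenate(([0], np.unique(xovers), [length]))
    blocks: list[Block] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == hi:
            continue
        blocks.extend(parent.copies[chrom][current].restricted(int(lo), int(hi)))
        current = 1 - current
    return HaplotypeMosaic(chrom, blocks)


def cross(p1: DiploidGenome, p2: DiploidGenome, seed) -> DiploidGenome:
    """Mate two genomes: one independent gamete from each parent per chromosome."""
    if p1.layout.chromosomes != p2.layout.chromosomes:
        raise ValueError("parents have mismatched genome layouts")
    rng = _as_rng(seed)
    copies = {
        chrom: (meiosis(p1, chrom, rng), meiosis(p2, chrom, rng))
        for chrom in p1.layout.chromosomes
    }
    return DiploidGenome(p1.layout, copies)


def backcross_scheme(
    donor_founder: DiploidGenome,
    recurrent_founder: DiploidGenome,
    n_generations: int,
    select_for: EngineeredAllele,
    seed,
    max_attempts: int = 10_000,
) -> DiploidGenome:
    """Repeated backcrossing to the recurrent strain with genotype selection.

    Starting from the F1 of the two founders, each generation mates the current
    carrier to the recurrent founder and keeps the first offspring genotyped as
    carrying the engineered allele (rejection sampling, as in real breeding).
    The returned generation-n carrier always has a donor-origin block spanning
    the allele position on exactly one copy — the mechanism by which donor SNPs
    persist indefinitely near selected alleles.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = _as_rng(seed)
    carrier = cross(donor_founder, recurrent_founder, rng)
    for _ in range(n_generations):
        for attempt in range(max_attempts):
            child = cross(carrier, recurrent_founder, rng)
            if child.carries_allele(select_for):
                carrier = child
                break
        else:
            raise RuntimeError(
                f"no carrier offspring in {max_attempts} attempts; selection failed"
            )
    return carrier


def donor_fraction(
    g: DiploidGenome,
    exclude: tuple[str, int, int] | None = None,
    donor: str = DONOR,
) -> float:
    """Genome-wide fraction of haploid length descending from the donor strain.

    ``exclude`` is an optional (chrom, start, end) interval removed from both
    numerator and denominator — e.g. the selected region around an engineered
    allele when measuring background introgression.
    """
    donor_len = 0
    total_len = 0
    for chrom, (a, b) in g.copies.items():
        for mosaic in (a, b):
            for s, e, strain in mosaic.blocks:
                lo, hi = s, e
                if exclude is not None and exclude[0] == chrom:
                    # subtract overlap with the excluded interval
                    ov = max(0, min(hi, exclude[2]) - max(lo, exclude[1]))
                else:
                    ov = 0
                seg = (hi - lo) - ov
                total_len += seg
                if strain == donor:
                    donor_len += seg
    return donor_len / total_len if total_len else 0.0
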