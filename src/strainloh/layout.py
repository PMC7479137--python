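"""Synthetic genome layout, founder strains, diagnostic SNP map and strain-variant registry.

The model genome is shared by two fully inbred founder strains that differ at a
dense map of diagnostic SNPs (the reference strain carries REF at every such
site, the donor strain carries ALT) and at a small set of discrete deletion
variants private to one strain.  A genetically engineered driver allele sits on
the donor-strain haplotype in tight linkage with one of those deletions.

Coordinates are 0-based, half-open (BED convention) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Founder strain that defines the reference genome (C57BL/6J analog).
REFSTRAIN = "REFSTRAIN"
#: Donor founder strain carrying the engineered allele (129S analog).
DONOR = "DONOR"

FOUNDERS = (REFSTRAIN, DONOR)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class RegistryParseError(ValueError):
    """Malformed strain-variant registry file."""


@dataclass(frozen=True)
class StrainVariant:
    """A deletion fixed in one founder strain relative to the reference genome."""

    id: str
    chrom: str
    start: int
    end: int
    carrier_strain: str
    kind: str = "deletion"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"variant {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.carrier_strain not in FOUNDERS:
            raise ValueError(
                f"variant {self.id!r}: unknown carrier strain {self.carrier_strain!r}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class EngineeredAllele:
    """A targeted allele created on one founder background (e.g. a driver mutation).

    ``loh_selected`` marks alleles whose wild-type counterpart is under negative
    selection in tumors, so that loss of the wild-type haplotype (typically by
    copy-neutral LOH) is near-obligate during tumor progression.
    """

    id: str
    chrom: str
    position: int
    origin_strain: str
    loh_selected: bool = True

    def __post_init__(self) -> None:
        if self.origin_strain not in FOUNDERS:
            raise ValueError(f"allele {self.id!r}: unknown origin strain")


@dataclass
class GenomeLayout:
    """Chromosome sizes, recombination rate and the diagnostic SNP map.

    Parameters
    ----------
    chromosomes
        Ordered mapping of chromosome name to length in bp.
    map_rate
        Uniform recombination rate in cM/Mb.
    snp_positions
        Per chromosome, strictly increasing bp positions where the founders
        differ.  The donor haplotype carries ALT at every such position with
        probability 1, which is what makes SNP allele frequency a direct
        haplotype readout.
    """

    chromosomes: dict[str, int]
    map_rate: float
    snp_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.map_rate <= 0:
            raise ConfigError(f"map_rate must be > 0, got {self.map_rate}")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length")
        for name, pos in self.snp_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.snp_positions[name] = pos
            if name not in self.chromosomes:
                raise ConfigError(f"SNPs given for unknown chromosome {name!r}")
            if pos.size:
                if np.any(np.diff(pos) <= 0):
                    raise ConfigError(f"SNP positions on {name!r} not strictly increasing")
                if pos[0] < 0 or pos[-1] >= self.chromosomes[name]:
                    raise ConfigError(f"SNP positions on {name!r} outside [0, length)")

    def length(self, chrom: str) -> int:
        return self.chromosomes[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())


@dataclass
class StrainVariantRegistry:
    """Catalog of strain-private deletion variants with exact coordinates."""

    variants: list[StrainVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variants = sorted(self.variants, key=lambda v: (v.chrom, v.start))
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in registry")
        # same-strain variants on one chromosome must not overlap
        by_key: dict[tuple[str, str], StrainVariant] = {}
        for v in self.variants:
            key = (v.chrom, v.carrier_strain)
            prev = by_key.get(key)
            if prev is not None and v.start < prev.end:
                raise ValueError(
                    f"overlapping variants {prev.id!r} and {v.id!r} on {v.chrom} "
                    f"for strain {v.carrier_strain}"
                )
            by_key[key] = v

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def on(self, chrom: str) -> list[StrainVariant]:
        return [v for v in self.variants if v.chrom == chrom]

    def deletion_covers(self, chrom: str, pos: int, strain: str) -> bool:
        """True if ``strain`` carries a deletion spanning ``pos`` on ``chrom``."""
        return any(
            v.start <= pos < v.end
            for v in self.variants
            if v.chrom == chrom and v.carrier_strain == strain
        )

    def validate_against(self, layout: GenomeLayout) -> None:
        for v in self.variants:
            if v.chrom not in layout.chromosomes:
                raise ValueError(f"variant {v.id!r} on unknown chromosome {v.chrom!r}")
            if v.end > layout.length(v.chrom):
                raise ValueError(f"variant {v.id!r} extends past end of {v.chrom}")


def _snp_grid(length: int, spacing: int, rng: np.random.Generator) -> np.ndarray:
    """Regular SNP grid with seeded jitter; spacing/4 jitter keeps strict order."""
    n = length // spacing
    base = np.arange(n, dtype=np.int64) * spacing + spacing // 2
    jitter = rng.integers(-(spacing // 4), spacing // 4 + 1, size=n)
    return base + jitter


def build_default_layout(
    config: dict | None = None,
) -> tuple[GenomeLayout, StrainVariantRegistry, list[EngineeredAllele]]:
    """Build the two-chromosome model genome from a ``genome`` config section.

    The default geometry places, on a chr11-like chromosome, an engineered
    driver allele of donor-strain origin 1.5 Mb from the midpoint of a
    donor-private 200 kb deletion, and on a chr4-like chromosome a
    tumor-suppressor locus plus a second donor-private deletion ~23 Mb away.
    """
    from .config import default_config, validate_config

    if config is None:
        config = default_config()
    validate_config(config)
    g = config["genome"]

    chromosomes = {c["name"]: int(c["length"]) for c in g["chromosomes"]}
    spacing = int(g["snp_spacing"])
    if spacing <= 0:
        raise ConfigError("genome.snp_spacing must be > 0")
    rng = np.random.default_rng(int(g.get("seed", 0)))
    snp_positions = {name: _snp_grid(length, spacing, rng) for name, length in chromosomes.items()}

    layout = GenomeLayout(
        chromosomes=chromosomes,
        map_rate=float(g["map_rate"]),
        snp_positions=snp_positions,
    )

    registry = StrainVariantRegistry(
        [
            StrainVariant(
                id=v["id"],
                chrom=v["chrom"],
                start=int(v["start"]),
                end=int(v["end"]),
                carrier_strain=v["carrier_strain"],
                kind=v.get("kind", "deletion"),
            )
            for v in g.get("variants", [])
        ]
    )
    registry.validate_against(layout)

    alleles = [
        EngineeredAllele(
            id=a["id"],
            chrom=a["chrom"],
            position=int(a["position"]),
            origin_strain=a["origin_strain"],
            loh_selected=bool(a.get("loh_selected", True)),
        )
        for a in g.get("engineered_alleles", [])
    ]
    for a in alleles:
        if a.chrom not in chromosomes or not (0 <= a.position < chromosomes[a.chrom]):
            raise ConfigError(f"engineered allele {a.id!r} outside chromosome bounds")
    return layout, registry, alleles


_REGISTRY_HEADER = "#chrom\tstart\tend\tid\tcarrier_strain\tkind"


def write_registry(registry: StrainVariantRegistry, path) -> None:
    """Write a registry as tab-separated BED6+ (chrom, start, end, id, carrier, kind)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_REGISTRY_HEADER + "\n")
        for v in registry:
            fh.write(f"{v.chrom}\t{v.start}\t{v.end}\t{v.id}\t{v.carrier_strain}\t{v.kind}\n")


def read_registry(path) -> StrainVariantRegistry:
    """Read a BED-dialect registry written by :func:`write_registry`.

    Raises
    ------
    RegistryParseError
        On malformed coordinates, naming the offending line number.
    """
    variants = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise RegistryParseError(
                    f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, vid, carrier, kind = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise RegistryParseError(f"line {lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise RegistryParseError(
                    f"line {lineno}: invalid interval [{start}, {end}) for {vid!r}"
                )
            try:
                variants.append(
                    StrainVariant(id=vid, chrom=chrom, start=start, end=end,
                                  carrier_strain=carrier, kind=kind)
                )
            except ValueError as exc:
                raise RegistryParseError(f"line {lineno}: {exc}") from exc
    try:
        return StrainVariantRegistry(variants)
    except ValueError as exc:
        raise RegistryParseError(str(exc)) from exc
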