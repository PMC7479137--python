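"""Somatic events on a germline genome: CN-LOH, focal deletions, composition.

A tumor genome is the germline diploid genome plus an ordered list of somatic
events.  Copy numbers are tracked per germline haplotype: ``(nA, nB)`` counts
how many copies of haplotype A's and haplotype B's sequence are present at a
position.  Copy-neutral LOH on target copy X zeroes X and doubles the other
haplotype (total stays the same where the other copy is intact); a focal
deletion zeroes the target copy inside its interval.  Later events read the
copy state produced by earlier events, which is what lets a focal deletion
followed by CN-LOH retaining the deleted copy produce a homozygous loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breeding import DiploidGenome
from .layout import DONOR, EngineeredAllele

CN_LOH = "CN_LOH"
FOCAL_DEL = "FOCAL_DEL"


@dataclass(frozen=True)
class SomaticEvent:
    type: str  # CN_LOH | FOCAL_DEL
    chrom: str
    start: int
    end: int
    target_copy: str  # "A" | "B"

    def __post_init__(self) -> None:
        if self.type not in (CN_LOH, FOCAL_DEL):
            raise ValueError(f"unknown event type {self.type!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid event interval [{self.start}, {self.end})")
        if self.target_copy not in ("A", "B"):
            raise ValueError("target_copy must be 'A' or 'B'")


@dataclass
class TumorGenome:
    """Germline genome plus ordered somatic events."""

    germline: DiploidGenome
    events: list[SomaticEvent] = field(default_factory=list)

    @property
    def layout(self):
        return self.germline.layout

    def copy_number_steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-haplotype copy number as a step function over ``chrom``.

        Returns (breaks, nA, nB): breaks has k+1 positions starting at 0 and
        ending at the chromosome length; nA[i], nB[i] are the copy counts of
        each germline haplotype's sequence on [breaks[i], breaks[i+1]).
        """
        length = self.layout.length(chrom)
        events = [e for e in self.events if e.chrom == chrom]
        pts = {0, length}
        for e in events:
            if e.end > length:
                raise ValueError(f"event extends past end of {chrom}")
            pts.update((e.start, e.end))
        breaks = np.array(sorted(pts), dtype=np.int64)
        starts = breaks[:-1]
        n_a = np.ones(starts.size, dtype=np.int64)
        n_b = np.ones(starts.size, dtype=np.int64)
        for e in events:
            mask = (starts >= e.start) & (starts < e.end)
            tgt, oth = (n_a, n_b) if e.target_copy == "A" else (n_b, n_a)
            if e.type == FOCAL_DEL:
                tgt[mask] = 0
            else:  # CN_LOH: target replaced by a duplicate of the other haplotype
                oth[mask] *= 2
                tgt[mask] = 0
        return breaks, n_a, n_b

    def copy_state(self, chrom: str, pos: int) -> tuple[int, int]:
        """(copies of haplotype A, copies of haplotype B) at one position."""
        if not (0 <= pos < self.layout.length(chrom)):
            raise ValueError(f"position {pos} out of range on {chrom}")
        breaks, n_a, n_b = self.copy_number_steps(chrom)
        i = int(np.searchsorted(breaks, pos, side="right")) - 1
        return int(n_a[i]), int(n_b[i])


def simulate_kpc_tumor(
    germline: DiploidGenome,
    driver: EngineeredAllele,
    seed,
    scenario: dict | None = None,
    suppressor: dict | None = None,
) -> TumorGenome:
    """Draw the somatic events of a driver-selected tumor.

    If the germline is heterozygous at the driver (the engineered-origin
    haplotype on exactly one copy), selection against the wild-type driver is
    modeled as a CN-LOH event targeting the copy NOT carrying the engineered
    allele, spanning from a uniform start upstream of the driver to the
    chromosome end (telomeric CN-LOH).  A germline homozygous for the
    engineered haplotype has nothing to select against and receives no driver
    event.

    An optional two-step tumor-suppressor scenario on another chromosome first
    deletes a focal interval around the suppressor position on one copy
    (breakpoints uniform within configured windows — the "stepped" geometry of
    genuine somatic losses), then applies CN-LOH retaining the deleted copy.

    ``scenario`` keys (defaults in parentheses): driver_cnloh_prob (1.0),
    cnloh_upstream_window (30 Mb).  ``suppressor`` keys: chrom, position,
    prob (1.0), del_window (2 Mb), del_core (100 kb), link_pos (optional bp
    whose donor-carrying copy is chosen for the deletion).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scenario = dict(scenario or {})
    if not germline.carries_allele(driver):
        raise ValueError(f"germline does not carry engineered allele {driver.id!r}")

    events: list[SomaticEvent] = []
    dosage = germline.allele_dosage(driver)
    p_cnloh = float(scenario.get("driver_cnloh_prob", 1.0))
    if driver.loh_selected and dosage == 1 and rng.random() < p_cnloh:
        carrier_copy = (
            "A"
            if germline.strain_at(driver.chrom, driver.position, "A") == driver.origin_strain
            else "B"
        )
        target = "B" if carrier_copy == "A" else "A"
        window = int(scenario.get("cnloh_upstream_window", 30_000_000))
        lo = max(0, driver.position - window)
        start = int(rng.integers(lo, driver.position))
        events.append(
            SomaticEvent(CN_LOH, driver.chrom, start,
                         germline.layout.length(driver.chrom), target)
        )

    if suppressor is not None and rng.random() < float(suppressor.get("prob", 1.0)):
        chrom = suppressor["chrom"]
        pos = int(suppressor["position"])
        window = int(suppressor.get("del_window", 2_000_000))
        core = int(suppressor.get("del_core", 100_000))
        length = germline.layout.length(chrom)
        del_start = int(rng.integers(max(0, pos - window), pos - core))
        del_end = int(rng.integers(pos + core, min(length, pos + window)))
        link_pos = suppressor.get("link_pos")
        if link_pos is not None and (
            germline.strain_at(chrom, int(link_pos), "A")
            != germline.strain_at(chrom, int(link_pos), "B")
        ):
            del_copy = (
                "A" if germline.strain_at(chrom, int(link_pos), "A") == DONOR else "B"
            )
        else:
            del_copy = "A" if rng.integers(2) == 0 else "B"
        retained_target = "B" if del_copy == "A" else "A"
        events.append(SomaticEvent(FOCAL_DEL, chrom, del_start, del_end, del_copy))
        loh_start = int(rng.integers(max(0, del_start - 30_000_000), del_start))
        events.append(SomaticEvent(CN_LOH, chrom, loh_start, length, retained_target))

    return TumorGenome(germline, events)
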