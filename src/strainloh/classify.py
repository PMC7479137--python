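"""Cohort overlay, breakpoint concordance and confounder classification.

Genuine somatic losses at a tumor-suppressor locus show a "stepped" overlay:
breakpoints vary tumor to tumor around a common core.  A strain-private
germline deletion surfacing through linked driver LOH instead shows the exact
same coordinates in every affected tumor, because the breakpoints are fixed in
the germline of the strain.  Classification combines three lines of evidence:
reciprocal overlap with the strain-variant registry, breakpoint identity
across the cohort, and genetic linkage to a driver locus under LOH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .haplotypes import LOHCall
from .layout import EngineeredAllele, StrainVariantRegistry

GERMLINE_VARIANT_ARTIFACT = "GERMLINE_VARIANT_ARTIFACT"
SOMATIC_CANDIDATE = "SOMATIC_CANDIDATE"
AMBIGUOUS = "AMBIGUOUS"

DEFAULT_CLASSIFY_PARAMS = {
    "reciprocal_overlap": 0.9,
    "concordance_min": 0.9,
    "min_members": 3,
    "tolerance_bins": 1,
    "bin_size": 20_000,
}


@dataclass(frozen=True)
class CohortCall:
    """One homozygous-loss call from one tumor, in cohort context."""

    tumor_id: str
    chrom: str
    start: int
    end: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class CohortOverlay:
    """A cluster of mutually overlapping calls across tumors."""

    cluster_id: int
    members: list[CohortCall]
    breakpoint_concordance: float | None  # None when < 2 members
    recurrence: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, n)

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    def contains(self, call: CohortCall) -> bool:
        return call in self.members


def _pairwise_concordance(members: list[CohortCall], tol: int) -> float | None:
    n = len(members)
    if n < 2:
        return None
    agree = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            if (
                abs(members[i].start - members[j].start) <= tol
                and abs(members[i].end - members[j].end) <= tol
            ):
                agree += 1
    return agree / pairs


def _recurrence_profile(members: list[CohortCall]) -> list[tuple[int, int, int]]:
    pts = sorted({p for m in members for p in (m.start, m.end)})
    out = []
    for lo, hi in zip(pts[:-1], pts[1:]):
        n = sum(1 for m in members if m.start <= lo and m.end >= hi)
        if n > 0:
            out.append((lo, hi, n))
    return out


def overlay_cohort(
    calls: list[CohortCall],
    tolerance_bins: int = 1,
    bin_size: int = 20_000,
) -> list[CohortOverlay]:
    """Single-linkage clustering of overlapping calls, with concordance.

    Breakpoint concordance is the fraction of member pairs whose start AND end
    each agree within ``tolerance_bins * bin_size``; it is recorded as None
    for single-member clusters, where pairwise identity is undefined.
    """
    tol = tolerance_bins * bin_size
    overlays: list[CohortOverlay] = []
    by_chrom: dict[str, list[CohortCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    cid = 0
    for chrom in sorted(by_chrom):
        members: list[CohortCall] = []
        reach = -1
        for c in sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.tumor_id)):
            if members and c.start >= reach:  # >= : half-open intervals touching don't overlap
                overlays.append(
                    CohortOverlay(cid, members, _pairwise_concordance(members, tol),
                                  _recurrence_profile(members))
                )
                cid += 1
                members = []
                reach = -1
            members.append(c)
            reach = max(reach, c.end)
        if members:
            overlays.append(
                CohortOverlay(cid, members, _pairwise_concordance(members, tol),
                              _recurrence_profile(members))
            )
            cid += 1
    return overlays


@dataclass(frozen=True)
class ConfoundVerdict:
    call: CohortCall
    classification: str
    matches_registry: bool
    identical_breakpoints: bool
    linked_driver_loh: bool
    distance_to_driver: int | None


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    ov = max(0, min(a_end, b_end) - max(a_start, b_start))
    if ov == 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def classify_cnv(
    call: CohortCall,
    overlays: list[CohortOverlay],
    registry: StrainVariantRegistry,
    loh_calls: list[LOHCall],
    drivers: list[EngineeredAllele],
    params: dict | None = None,
) -> ConfoundVerdict:
    """Classify one homozygous-loss call as artifact, somatic or ambiguous.

    Evidence:
      matches_registry      — reciprocal overlap >= threshold with a registry variant
      identical_breakpoints — cluster of >= min_members with concordance >= threshold
      linked_driver_loh     — call lies within an LOH call (same tumor) whose
                              interval contains a driver position

    Rule: GERMLINE_VARIANT_ARTIFACT iff (matches_registry OR identical_breakpoints)
    AND linked_driver_loh; SOMATIC_CANDIDATE iff no evidence flag; else AMBIGUOUS.
    """
    p = dict(DEFAULT_CLASSIFY_PARAMS)
    if params:
        p.update({k: v for k, v in params.items() if k in p})

    matches_registry = any(
        v.chrom == call.chrom
        and _reciprocal_overlap(call.start, call.end, v.start, v.end)
        >= p["reciprocal_overlap"]
        for v in registry
    )

    identical = False
    for ov in overlays:
        if ov.contains(call):
            identical = (
                len(ov.members) >= p["min_members"]
                and ov.breakpoint_concordance is not None
                and ov.breakpoint_concordance >= p["concordance_min"]
            )
            break

    linked = False
    distance: int | None = None
    for loh in loh_calls:
        if loh.chrom != call.chrom:
            continue
        if loh.start <= call.start and call.end <= loh.end:
            for d in drivers:
                if d.chrom == loh.chrom and loh.start <= d.position < loh.end:
                    linked = True
                    distance = abs(call.midpoint - d.position)
                    break
        if linked:
            break

    if (matches_registry or identical) and linked:
        cls = GERMLINE_VARIANT_ARTIFACT
    elif not (matches_registry or identical or linked):
        cls = SOMATIC_CANDIDATE
    else:
        cls = AMBIGUOUS
    return ConfoundVerdict(call, cls, matches_registry, identical, linked, distance)
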