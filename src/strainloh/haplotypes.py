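"""Haplotype reconstruction from SNP allele frequencies and LOH calling.

Germline haplotype state follows a direct three-way classification of windowed
variant-allele frequencies at strain-diagnostic SNPs: ~0.5 means two distinct
haplotypes (heterozygous), ~1.0 means pure donor strain on both copies, and
absence of ALT evidence means both copies match the reference strain.  LOH is
then only defined over germline-heterozygous territory: tumor windows whose
VAF escapes the heterozygous band are LOH, and the tumor/germline coverage
ratio over the call separates copy-neutral LOH (ratio ~1) from deletion LOH
(ratio ~0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breeding import DiploidGenome
from .layout import DONOR, GenomeLayout
from .readout import AlleleCountTable, CoverageProfile

HOM_REF = "HOM_REF"
HET = "HET"
HOM_ALT = "HOM_ALT"

MECH_CN_LOH = "CN_LOH"
MECH_DELETION = "DELETION_LOH"
MECH_UNKNOWN = "UNKNOWN"

DEFAULT_PARAMS = {
    "window_snps": 25,
    "min_depth": 10,
    "vaf_lo": 0.15,
    "vaf_hi": 0.85,
    "cnloh_ratio_range": (0.8, 1.2),
    "deletion_ratio_max": 0.7,
    # LOH calls with the same retained haplotype separated by less than this
    # are bridged into one event: a sub-window germline feature (e.g. a short
    # homozygous stretch created by a het strain deletion) must not cut a
    # single somatic LOH event in two.
    "loh_merge_gap": 1_000_000,
}


@dataclass(frozen=True)
class HaplotypeSegment:
    chrom: str
    start: int
    end: int
    state: str  # HOM_REF | HET | HOM_ALT
    n_snps: int
    mean_vaf: float


@dataclass(frozen=True)
class LOHCall:
    chrom: str
    start: int
    end: int
    mechanism: str  # CN_LOH | DELETION_LOH | UNKNOWN
    retained: str  # "ALT" (donor-like) | "REF"
    coverage_ratio: float
    n_snps: int
    mean_vaf: float


def _params(params: dict | None) -> dict:
    out = dict(DEFAULT_PARAMS)
    if params:
        out.update({k: v for k, v in params.items() if k in DEFAULT_PARAMS})
    return out


def _window_stats(pos, vaf, alt, window: int):
    """Chunk consecutive SNPs into windows of ``window``; last partial kept."""
    n = pos.size
    starts = np.arange(0, n, window)
    wins = []
    for s in starts:
        e = min(s + window, n)
        wins.append(
            {
                "first": int(pos[s]),
                "last": int(pos[e - 1]),
                "mean_vaf": float(vaf[s:e].mean()),
                "has_alt": bool(alt[s:e].any()),
                "n": int(e - s),
                "lo": s,
                "hi": e,
            }
        )
    return wins


def _window_state(w, p) -> str:
    v = w["mean_vaf"]
    if not w["has_alt"] or v < p["vaf_lo"]:
        return HOM_REF
    if v > p["vaf_hi"]:
        return HOM_ALT
    return HET


def call_haplotype_segments(
    counts: AlleleCountTable,
    params: dict | None = None,
    layout: GenomeLayout | None = None,
) -> list[HaplotypeSegment]:
    """Segment each chromosome into HOM_REF / HET / HOM_ALT haplotype states.

    SNPs with depth >= min_depth are grouped into consecutive windows; each
    window is classified by its mean VAF, adjacent same-state windows are
    merged, and state boundaries fall midway between the flanking SNPs of
    neighboring different-state windows (ties toward the lower coordinate).
    With a ``layout`` the outer segments extend to the chromosome ends so the
    segmentation tiles the genome.
    """
    p = _params(params)
    segments: list[HaplotypeSegment] = []
    if counts.rows.empty:
        return segments
    for chrom, df in counts.rows.groupby("chrom", sort=False):
        df = df.sort_values("pos")
        depth = (df["ref_count"] + df["alt_count"]).to_numpy()
        keep = depth >= p["min_depth"]
        if not keep.any():
            continue
        pos = df["pos"].to_numpy()[keep]
        alt = df["alt_count"].to_numpy()[keep]
        vaf = alt / depth[keep]
        wins = _window_stats(pos, vaf, alt, p["window_snps"])
        states = [_window_state(w, p) for w in wins]

        chrom_start = 0 if layout is not None else int(pos[0])
        chrom_end = layout.length(chrom) if layout is not None else int(pos[-1]) + 1

        run_start = 0
        for i in range(1, len(wins) + 1):
            if i < len(wins) and states[i] == states[run_start]:
                continue
            seg_start = (
                chrom_start
                if run_start == 0
                else (wins[run_start - 1]["last"] + wins[run_start]["first"]) // 2
            )
            seg_end = (
                chrom_end
                if i == len(wins)
                else (wins[i - 1]["last"] + wins[i]["first"]) // 2
            )
            lo, hi = wins[run_start]["lo"], wins[i - 1]["hi"]
            segments.append(
                HaplotypeSegment(
                    chrom=chrom,
                    start=int(seg_start),
                    end=int(seg_end),
                    state=states[run_start],
                    n_snps=int(hi - lo),
                    mean_vaf=float(vaf[lo:hi].mean()),
                )
            )
            run_start = i
    return segments


def _normalized_ratio(
    tumor_cov: CoverageProfile, germ_cov: CoverageProfile, chrom: str, start: int, end: int
) -> float:
    """Median depth-normalized tumor/germline coverage ratio over an interval."""
    t_med = float(np.median(tumor_cov.bins["count"]))
    g_med = float(np.median(germ_cov.bins["count"]))
    if t_med <= 0 or g_med <= 0:
        return float("nan")
    tb = tumor_cov.counts_on(chrom)
    gb = germ_cov.counts_on(chrom)
    if len(tb) != len(gb) or tb.empty:
        return float("nan")
    sel = (tb["end"] > start) & (tb["start"] < end)
    t = tb.loc[sel, "count"].to_numpy() / t_med
    g = gb.loc[sel.to_numpy(), "count"].to_numpy() / g_med
    ok = g > 0
    if not ok.any():
        return float("nan")
    return float(np.median(t[ok] / g[ok]))


def call_loh(
    germ_segments: list[HaplotypeSegment],
    tumor_counts: AlleleCountTable,
    tumor_cov: CoverageProfile | None = None,
    germ_cov: CoverageProfile | None = None,
    params: dict | None = None,
) -> list[LOHCall]:
    """Call LOH within germline-heterozygous segments of a matched tumor.

    Tumor SNP windows whose mean VAF leaves [vaf_lo, vaf_hi] are LOH;
    contiguous LOH windows merge into one call.  The retained haplotype is
    donor-like ("ALT") when the call's VAF sits above the band, reference-like
    otherwise.  Mechanism: CN_LOH when the median normalized coverage ratio
    lies in cnloh_ratio_range, DELETION_LOH below deletion_ratio_max, else
    UNKNOWN (including when coverage is missing).
    """
    p = _params(params)
    raw: list[dict] = []
    for seg in germ_segments:
        if seg.state != HET:
            continue
        df = tumor_counts.on(seg.chrom)
        df = df[(df["pos"] >= seg.start) & (df["pos"] < seg.end)].sort_values("pos")
        depth = (df["ref_count"] + df["alt_count"]).to_numpy()
        keep = depth >= p["min_depth"]
        if not keep.any():
            continue
        pos = df["pos"].to_numpy()[keep]
        alt = df["alt_count"].to_numpy()[keep]
        vaf = alt / depth[keep]
        wins = _window_stats(pos, vaf, alt, p["window_snps"])
        is_loh = [not (p["vaf_lo"] <= w["mean_vaf"] <= p["vaf_hi"]) for w in wins]

        i = 0
        while i < len(wins):
            if not is_loh[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(wins) and is_loh[j + 1]:
                j += 1
            start = (
                seg.start if i == 0 else (wins[i - 1]["last"] + wins[i]["first"]) // 2
            )
            end = (
                seg.end
                if j == len(wins) - 1
                else (wins[j]["last"] + wins[j + 1]["first"]) // 2
            )
            lo, hi = wins[i]["lo"], wins[j]["hi"]
            call_vaf = float(vaf[lo:hi].mean())
            raw.append(
                {
                    "chrom": seg.chrom,
                    "start": int(start),
                    "end": int(end),
                    "retained": "ALT" if call_vaf > p["vaf_hi"] else "REF",
                    "n_snps": int(hi - lo),
                    "vaf_sum": float(vaf[lo:hi].sum()),
                }
            )
            i = j + 1

    merged = _merge_raw_calls(raw, int(p["loh_merge_gap"]))
    calls: list[LOHCall] = []
    r_lo, r_hi = p["cnloh_ratio_range"]
    for c in merged:
        if tumor_cov is not None and germ_cov is not None:
            ratio = _normalized_ratio(tumor_cov, germ_cov, c["chrom"], c["start"], c["end"])
        else:
            ratio = float("nan")
        if np.isnan(ratio):
            mech = MECH_UNKNOWN
        elif r_lo <= ratio <= r_hi:
            mech = MECH_CN_LOH
        elif ratio < p["deletion_ratio_max"]:
            mech = MECH_DELETION
        else:
            mech = MECH_UNKNOWN
        calls.append(
            LOHCall(
                chrom=c["chrom"],
                start=c["start"],
                end=c["end"],
                mechanism=mech,
                retained=c["retained"],
                coverage_ratio=ratio,
                n_snps=c["n_snps"],
                mean_vaf=c["vaf_sum"] / c["n_snps"],
            )
        )
    return calls


def _merge_raw_calls(raw: list[dict], merge_gap: int) -> list[dict]:
    """Bridge same-haplotype LOH calls separated by short uninformative gaps."""
    out: list[dict] = []
    for c in sorted(raw, key=lambda c: (c["chrom"], c["start"])):
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev["chrom"] == c["chrom"]
            and prev["retained"] == c["retained"]
            and c["start"] - prev["end"] <= merge_gap
        ):
            prev["end"] = max(prev["end"], c["end"])
            prev["n_snps"] += c["n_snps"]
            prev["vaf_sum"] += c["vaf_sum"]
        else:
            out.append(dict(c))
    return out


def _truth_state_steps(truth: DiploidGenome, chrom: str):
    a, b = truth.copies[chrom]
    breaks = np.unique(np.concatenate([a.boundaries(), b.boundaries()]))
    mids = (breaks[:-1] + breaks[1:]) // 2
    states = []
    for m in mids:
        sa, sb = a.strain_at(int(m)), b.strain_at(int(m))
        if sa != sb:
            states.append(HET)
        elif sa == DONOR:
            states.append(HOM_ALT)
        else:
            states.append(HOM_REF)
    return breaks, states


def haplotype_concordance(
    called: list[HaplotypeSegment], truth: DiploidGenome, layout: GenomeLayout | None = None
) -> float:
    """Length-weighted fraction of the genome with correctly called state.

    Genome not covered by any called segment counts as incorrect, so a perfect
    score requires calls that tile the genome.
    """
    layout = layout or truth.layout
    total = layout.total_length
    correct = 0
    by_chrom: dict[str, list[HaplotypeSegment]] = {}
    for seg in called:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom in layout.chromosomes:
        breaks, states = _truth_state_steps(truth, chrom)
        for seg in by_chrom.get(chrom, []):
            for k in range(len(states)):
                lo = max(int(breaks[k]), seg.start)
                hi = min(int(breaks[k + 1]), seg.end)
                if lo < hi and states[k] == seg.state:
                    correct += hi - lo
    return correct / total if total else 0.0
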