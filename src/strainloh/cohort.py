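"""End-to-end cohort orchestration: breeding → tumors → readouts → calls → verdicts.

``run_cohort_pipeline`` simulates a cohort of animals from a single config and
master seed, runs the full analysis stack on each tumor/germline pair, overlays
homozygous-loss calls across the cohort and classifies each one.  Per-animal
seeds are derived from the master seed by fixed arithmetic
(``SeedSequence([master, animal_index, stream])``), so identical config plus
master seed reproduce the cohort byte for byte.
"""

from __future__ import annotations

import json
import os

import numpy as np

from . import io as sio
from .breeding import DiploidGenome, backcross_scheme, cross
from .classify import (
    CohortCall,
    ConfoundVerdict,
    classify_cnv,
    overlay_cohort,
)
from .cnv import HOM_LOSS, call_segments, compute_log_ratios, segment_log_ratios
from .config import default_config, validate_config
from .haplotypes import call_haplotype_segments, call_loh
from .layout import DONOR, REFSTRAIN, ConfigError, build_default_layout, write_registry
from .readout import physical_copies, simulate_allele_counts, simulate_coverage
from .tumor import simulate_kpc_tumor


def _stream(master_seed: int, animal: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), animal, stream]))


def breed_animal(layout, driver, breeding_cfg: dict, rng) -> DiploidGenome:
    """Produce one germline genome under the configured breeding scheme."""
    donor = DiploidGenome.founder(layout, DONOR)
    ref = DiploidGenome.founder(layout, REFSTRAIN)
    scheme = breeding_cfg["scheme"]
    selection = breeding_cfg["selection"]
    max_attempts = int(breeding_cfg.get("max_attempts", 10_000))

    if scheme == "f1":
        return cross(donor, ref, rng)
    if scheme == "backcross":
        return backcross_scheme(
            donor, ref, int(breeding_cfg["backcross_generations"]), driver, rng,
            max_attempts=max_attempts,
        )
    # intercross: F2 from two independent F1s, with genotype selection at the driver
    want = {"carrier": (1, 2), "het": (1,), "hom": (2,)}[selection]
    f1a = cross(donor, ref, rng)
    f1b = cross(donor, ref, rng)
    for _ in range(max_attempts):
        child = cross(f1a, f1b, rng)
        if child.allele_dosage(driver) in want:
            return child
    raise RuntimeError(f"no {selection} offspring in {max_attempts} intercross attempts")


def analyze_pair(germ_counts, tumor_counts, germ_cov, tumor_cov, layout, calling_cfg):
    """Run haplotype, LOH and CNV calling for one tumor/germline pair."""
    params = {
        "window_snps": int(calling_cfg["window_snps"]),
        "min_depth": int(calling_cfg["min_depth"]),
        "vaf_lo": float(calling_cfg["vaf_lo"]),
        "vaf_hi": float(calling_cfg["vaf_hi"]),
        "cnloh_ratio_range": tuple(calling_cfg["cnloh_ratio_range"]),
        "deletion_ratio_max": float(calling_cfg["deletion_ratio_max"]),
    }
    segments = call_haplotype_segments(germ_counts, params, layout)
    loh = call_loh(segments, tumor_counts, tumor_cov, germ_cov, params)
    ratios = compute_log_ratios(tumor_cov, germ_cov, float(calling_cfg["pseudocount"]))
    cnv = call_segments(
        segment_log_ratios(ratios, float(calling_cfg["seg_penalty"])),
        {
            "hom_loss_max": float(calling_cfg["hom_loss_max"]),
            "het_loss_max": float(calling_cfg["het_loss_max"]),
            "gain_min": float(calling_cfg["gain_min"]),
        },
    )
    return segments, loh, cnv


def run_cohort_pipeline(config: dict | None = None, seed: int = 0, outdir=None) -> dict:
    """Simulate and analyze a full cohort; optionally write an output tree.

    Returns a report dict with per-animal records, all confounder verdicts and
    a cohort summary (counts per classification; per registry variant, the
    number of animals with a homozygous-loss call at the variant locus).
    """
    config = config or default_config()
    validate_config(config)
    layout, registry, alleles = build_default_layout(config)
    if not alleles:
        raise ConfigError("genome.engineered_alleles: at least one driver required")
    driver = alleles[0]

    t_cfg = config["tumor"]
    r_cfg = config["readout"]
    c_cfg = config["calling"]
    n_animals = int(config["cohort"]["n_animals"])

    sup_cfg = None
    sc = t_cfg.get("suppressor_scenario", {})
    if sc.get("enabled"):
        sup = config["genome"].get("suppressor")
        if sup is None:
            raise ConfigError("tumor.suppressor_scenario.enabled but genome.suppressor missing")
        link = next(
            (v.midpoint for v in registry if v.chrom == sup["chrom"]), None
        )
        sup_cfg = {
            "chrom": sup["chrom"],
            "position": int(sup["position"]),
            "prob": float(sc.get("prob", 1.0)),
            "del_window": int(sc.get("del_window", 2_000_000)),
            "del_core": int(sc.get("del_core", 100_000)),
            "link_pos": link,
        }

    animals = []
    all_calls: list[CohortCall] = []
    loh_by_tumor: dict[str, list] = {}
    per_animal_files = []

    for i in range(n_animals):
        aid = f"animal_{i:03d}"
        germline = breed_animal(layout, driver, config["breeding"], _stream(seed, i, 0))
        tumor = simulate_kpc_tumor(
            germline, driver, _stream(seed, i, 1),
            scenario={
                "driver_cnloh_prob": float(t_cfg["driver_cnloh_prob"]),
                "cnloh_upstream_window": int(t_cfg["cnloh_upstream_window"]),
            },
            suppressor=sup_cfg,
        )
        purity = float(t_cfg.get("purity", 1.0))
        germ_cov = simulate_coverage(
            germline, registry, layout, int(r_cfg["bin_size"]), float(r_cfg["mean_depth"]),
            float(r_cfg["dispersion"]), _stream(seed, i, 2), sample_id=f"{aid}_germline",
        )
        tumor_cov = simulate_coverage(
            tumor, registry, layout, int(r_cfg["bin_size"]), float(r_cfg["mean_depth"]),
            float(r_cfg["dispersion"]), _stream(seed, i, 3), purity=purity,
            sample_id=f"{aid}_tumor",
        )
        germ_counts = simulate_allele_counts(
            germline, registry, layout, float(r_cfg["snp_depth"]),
            _stream(seed, i, 4), sample_id=f"{aid}_germline",
        )
        tumor_counts = simulate_allele_counts(
            tumor, registry, layout, float(r_cfg["snp_depth"]),
            _stream(seed, i, 5), purity=purity, sample_id=f"{aid}_tumor",
        )

        segments, loh, cnv = analyze_pair(
            germ_counts, tumor_counts, germ_cov, tumor_cov, layout, c_cfg
        )
        loh_by_tumor[aid] = loh
        hom_calls = [
            CohortCall(aid, s.chrom, s.start, s.end) for s in cnv if s.call == HOM_LOSS
        ]
        all_calls.extend(hom_calls)

        variant_hits = {}
        truth_artifact = {}
        for v in registry:
            mid = v.midpoint
            hit = any(
                c.chrom == v.chrom and c.start < v.end and c.end > v.start
                for c in hom_calls
            )
            variant_hits[v.id] = hit
            truth_artifact[v.id] = bool(
                physical_copies(germline, registry, v.chrom, mid) == 1
                and physical_copies(tumor, registry, v.chrom, mid) == 0
            )
        animals.append(
            {
                "id": aid,
                "driver_dosage": germline.allele_dosage(driver),
                "n_events": len(tumor.events),
                "n_hom_loss_calls": len(hom_calls),
                "variant_locus_hom_loss": variant_hits,
                "truth_variant_artifact": truth_artifact,
                "n_loh_calls": len(loh),
            }
        )
        per_animal_files.append(
            (aid, germline, segments, loh, cnv, germ_cov, tumor_cov, germ_counts,
             tumor_counts)
        )

    overlays = overlay_cohort(
        all_calls,
        int(config["classify"]["tolerance_bins"]),
        int(r_cfg["bin_size"]),
    )
    classify_params = dict(config["classify"])
    classify_params["bin_size"] = int(r_cfg["bin_size"])
    verdicts: list[ConfoundVerdict] = [
        classify_cnv(call, overlays, registry, loh_by_tumor[call.tumor_id], alleles,
                     classify_params)
        for call in all_calls
    ]

    cls_counts: dict[str, int] = {}
    for v in verdicts:
        cls_counts[v.classification] = cls_counts.get(v.classification, 0) + 1
    summary = {
        "n_animals": n_animals,
        "n_hom_loss_calls": len(all_calls),
        "classification_counts": cls_counts,
        "animals_with_variant_locus_hom_loss": {
            v.id: sum(1 for a in animals if a["variant_locus_hom_loss"][v.id])
            for v in registry
        },
    }
    report = {
        "seed": int(seed),
        "summary": summary,
        "animals": animals,
        "verdicts": verdicts,
        "overlays": overlays,
    }

    if outdir is not None:
        _write_outputs(outdir, config, seed, registry, report, per_animal_files, verdicts)
    return report


def _write_outputs(outdir, config, seed, registry, report, per_animal_files, verdicts):
    os.makedirs(outdir, exist_ok=True)
    write_registry(registry, os.path.join(outdir, "registry.bed"))
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump({"seed": int(seed), "config": config}, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(os.path.join(outdir, "summary.tsv"), "w", encoding="utf-8") as fh:
        fh.write("#animal\tdriver_dosage\tn_events\tn_loh_calls\tn_hom_loss_calls\t"
                 "variant_locus_hits\n")
        for a in report["animals"]:
            hits = ",".join(k for k, v in a["variant_locus_hom_loss"].items() if v) or "none"
            fh.write(
                f"{a['id']}\t{a['driver_dosage']}\t{a['n_events']}\t{a['n_loh_calls']}\t"
                f"{a['n_hom_loss_calls']}\t{hits}\n"
            )
        counts = report["summary"]["classification_counts"]
        fh.write("#classification_counts\t" + json.dumps(counts, sort_keys=True) + "\n")

    sio.write_verdicts(verdicts, os.path.join(outdir, "verdicts.tsv"))

    for (aid, germline, segments, loh, cnv, germ_cov, tumor_cov, germ_counts,
         tumor_counts) in per_animal_files:
        adir = os.path.join(outdir, aid)
        os.makedirs(adir, exist_ok=True)
        sio.write_mosaics(germline, os.path.join(adir, "germline_mosaics.bed"))
        sio.write_haplotype_segments(segments, os.path.join(adir, "haplotype_segments.tsv"))
        sio.write_loh_calls(loh, os.path.join(adir, "loh_calls.tsv"))
        sio.write_cnv_seg(cnv, os.path.join(adir, "cnv_segments.seg"), sample_id=aid)
        sio.write_coverage(germ_cov, os.path.join(adir, "germline_coverage.tsv"))
        sio.write_coverage(tumor_cov, os.path.join(adir, "tumor_coverage.tsv"))
        sio.write_allele_counts(germ_counts, os.path.join(adir, "germline_snv.tsv"))
        sio.write_allele_counts(tumor_counts, os.path.join(adir, "tumor_snv.tsv"))
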