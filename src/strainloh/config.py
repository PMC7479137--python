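"""Simulation and calling configuration: defaults, YAML loading, validation.

A single nested mapping drives the whole pipeline, with sections ``genome``,
``breeding``, ``tumor``, ``readout``, ``calling``, ``classify`` and ``cohort``.
Every stochastic operation takes an explicit integer seed; the config itself
holds no randomness beyond the genome-layout jitter seed.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

from .layout import DONOR, ConfigError


def default_config() -> dict:
    """Return the default configuration as a fresh nested dict.

    The genome geometry mirrors the real mouse situation at the scale that
    matters — a driver allele 1.5 Mb from a linked 200 kb donor-private
    deletion on a 122 Mb chr11-like chromosome, and an unlinked
    tumor-suppressor locus ~23 Mb from a 600 kb donor-private deletion on a
    156 Mb chr4-like chromosome — while remaining fully synthetic.
    """
    return {
        "genome": {
            "seed": 0,
            "chromosomes": [
                {"name": "chr11", "length": 122_000_000},
                {"name": "chr4", "length": 156_000_000},
            ],
            "snp_spacing": 10_000,  # 1 diagnostic SNP per 10 kb
            "map_rate": 0.5,  # cM/Mb
            "engineered_alleles": [
                {
                    "id": "driver_eng",
                    "chrom": "chr11",
                    "position": 69_580_000,
                    "origin_strain": DONOR,
                    "loh_selected": True,
                }
            ],
            "suppressor": {"id": "suppressor", "chrom": "chr4", "position": 89_280_000},
            "variants": [
                {
                    "id": "nlrp1_like_del",
                    "chrom": "chr11",
                    "start": 70_980_000,
                    "end": 71_180_000,
                    "carrier_strain": DONOR,
                },
                {
                    "id": "skint_like_del",
                    "chrom": "chr4",
                    "start": 112_000_000,
                    "end": 112_600_000,
                    "carrier_strain": DONOR,
                },
            ],
        },
        "breeding": {
            # scheme: "f1" | "intercross" (F2 from two F1s) | "backcross"
            "scheme": "intercross",
            "backcross_generations": 1,
            # genotype selection at the driver: "carrier" | "het" | "hom"
            "selection": "het",
            "max_attempts": 10_000,
        },
        "tumor": {
            "driver_cnloh_prob": 1.0,
            "cnloh_upstream_window": 30_000_000,  # uniform CN-LOH start in [driver-w, driver)
            "purity": 1.0,
            "suppressor_scenario": {
                "enabled": False,
                "prob": 1.0,
                "del_window": 2_000_000,  # breakpoints uniform within +/- window
                "del_core": 100_000,  # minimal half-width always deleted
            },
        },
        "readout": {
            "bin_size": 20_000,
            "mean_depth": 100.0,  # expected reads per bin at 2 copies
            "snp_depth": 100.0,  # expected reads per SNP at 2 copies
            "dispersion": 0.05,  # negative-binomial overdispersion (var = mu + a*mu^2)
            "acgh_noise_sd": 0.15,
            "pseudo_copy": 0.5,  # epsilon copies added inside aCGH log ratios
        },
        "calling": {
            "window_snps": 25,
            "min_depth": 10,
            "vaf_lo": 0.15,
            "vaf_hi": 0.85,
            "cnloh_ratio_range": [0.8, 1.2],
            "deletion_ratio_max": 0.7,
            "seg_penalty": 1.0,
            "pseudocount": 0.5,
            "hom_loss_max": -2.0,
            "het_loss_max": -0.35,
            "gain_min": 0.3,
        },
        "classify": {
            "reciprocal_overlap": 0.9,
            "concordance_min": 0.9,
            "min_members": 3,
            "tolerance_bins": 1,
        },
        "cohort": {
            "n_animals": 12,
        },
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML config file on top of the defaults; then apply ``overrides``."""
    cfg = default_config()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {msg}")


def validate_config(cfg: dict) -> None:
    """Validate ranges and cross-references; errors carry dotted field paths."""
    _require(isinstance(cfg, dict), "", "config must be a mapping")
    for section in ("genome", "breeding", "tumor", "readout", "calling"):
        _require(section in cfg, section, "missing section")

    g = cfg["genome"]
    chroms: dict[str, int] = {}
    _require(bool(g.get("chromosomes")), "genome.chromosomes", "must be non-empty")
    for i, c in enumerate(g["chromosomes"]):
        p = f"genome.chromosomes[{i}]"
        _require(int(c.get("length", 0)) > 0, p + ".length", "must be > 0")
        chroms[c["name"]] = int(c["length"])
    _require(int(g["snp_spacing"]) > 0, "genome.snp_spacing", "must be > 0")
    _require(float(g["map_rate"]) > 0, "genome.map_rate", "must be > 0")
    for i, v in enumerate(g.get("variants", [])):
        p = f"genome.variants[{i}]"
        _require(v["chrom"] in chroms, p + ".chrom", "unknown chromosome")
        _require(
            0 <= int(v["start"]) < int(v["end"]) <= chroms[v["chrom"]],
            p, "invalid interval",
        )
    for i, a in enumerate(g.get("engineered_alleles", [])):
        p = f"genome.engineered_alleles[{i}]"
        _require(a["chrom"] in chroms, p + ".chrom", "unknown chromosome")
        _require(0 <= int(a["position"]) < chroms[a["chrom"]], p + ".position", "out of range")

    b = cfg["breeding"]
    _require(
        b.get("scheme") in ("f1", "intercross", "backcross"),
        "breeding.scheme", "must be one of f1|intercross|backcross",
    )
    _require(
        b.get("selection") in ("carrier", "het", "hom"),
        "breeding.selection", "must be one of carrier|het|hom",
    )
    _require(int(b.get("backcross_generations", 1)) >= 1,
             "breeding.backcross_generations", "must be >= 1")

    t = cfg["tumor"]
    _require(0 <= float(t["driver_cnloh_prob"]) <= 1, "tumor.driver_cnloh_prob", "must be in [0,1]")
    _require(0 < float(t.get("purity", 1.0)) <= 1, "tumor.purity", "must be in (0,1]")

    r = cfg["readout"]
    _require(int(r["bin_size"]) > 0, "readout.bin_size", "must be > 0")
    _require(float(r["mean_depth"]) > 0, "readout.mean_depth", "must be > 0")
    _require(float(r["snp_depth"]) > 0, "readout.snp_depth", "must be > 0")
    _require(float(r["dispersion"]) >= 0, "readout.dispersion", "must be >= 0")

    c = cfg["calling"]
    _require(0 < float(c["vaf_lo"]) < float(c["vaf_hi"]) < 1, "calling.vaf_lo/vaf_hi",
             "need 0 < lo < hi < 1")
    _require(int(c["window_snps"]) >= 1, "calling.window_snps", "must be >= 1")
    _require(
        float(c["hom_loss_max"]) <= float(c["het_loss_max"]) < 0 < float(c["gain_min"]),
        "calling.hom_loss_max/het_loss_max/gain_min", "need hom <= het < 0 < gain",
    )
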