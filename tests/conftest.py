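"""Shared fixtures: default model genome, founder genomes, per-animal pipeline."""

from __future__ import annotations

import numpy as np
import pytest

import strainloh as sl
from strainloh.cohort import analyze_pair
from strainloh.config import default_config


@pytest.fixture(scope="session")
def ctx():
    """Default genome layout, strain-variant registry and engineered alleles."""
    layout, registry, alleles = sl.build_default_layout()
    return {"layout": layout, "registry": registry, "alleles": alleles}


@pytest.fixture(scope="session")
def founders(ctx):
    layout = ctx["layout"]
    return {
        sl.DONOR: sl.DiploidGenome.founder(layout, sl.DONOR),
        sl.REFSTRAIN: sl.DiploidGenome.founder(layout, sl.REFSTRAIN),
    }


@pytest.fixture(scope="session")
def f1(ctx, founders):
    return sl.cross(founders[sl.DONOR], founders[sl.REFSTRAIN], 11)


@pytest.fixture(scope="session")
def calling_cfg():
    return default_config()["calling"]


def simulate_readouts(genome, ctx, seed, depth=100.0, dispersion=0.05):
    """Coverage + allele counts for one genome under default readout settings."""
    layout, registry = ctx["layout"], ctx["registry"]
    rng = np.random.default_rng(seed)
    cov = sl.simulate_coverage(
        genome, registry, layout, 20_000, depth, dispersion, rng, sample_id="s"
    )
    counts = sl.simulate_allele_counts(genome, registry, layout, depth, rng, sample_id="s")
    return cov, counts


def run_pair(germline, tumor, ctx, calling_cfg, seed, depth=100.0):
    """Simulate germline+tumor readouts and run the full calling stack."""
    germ_cov, germ_counts = simulate_readouts(germline, ctx, seed)
    tumor_cov, tumor_counts = simulate_readouts(tumor, ctx, seed + 1)
    segs, loh, cnv = analyze_pair(
        germ_counts, tumor_counts, germ_cov, tumor_cov, ctx["layout"], calling_cfg
    )
    return {
        "segments": segs,
        "loh": loh,
        "cnv": cnv,
        "germ_cov": germ_cov,
        "tumor_cov": tumor_cov,
        "germ_counts": germ_counts,
        "tumor_counts": tumor_counts,
    }


@pytest.fixture(scope="session")
def kpc_het_animal(ctx, f1, calling_cfg):
    """The heterozygous-carrier scenario: F1 germline, driver CN-LOH tumor."""
    driver = ctx["alleles"][0]
    tumor = sl.simulate_kpc_tumor(f1, driver, 2)
    result = run_pair(f1, tumor, ctx, calling_cfg, seed=21)
    result["germline"] = f1
    result["tumor"] = tumor
    return result
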