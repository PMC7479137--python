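"""Haplotype-state segmentation, concordance metric and LOH mechanism calls."""

import numpy as np
import pytest

import strainloh as sl
from strainloh.config import default_config
from strainloh.haplotypes import _truth_state_steps
from strainloh.tumor import FOCAL_DEL, SomaticEvent

from conftest import run_pair, simulate_readouts


@pytest.fixture(scope="module")
def empty_registry():
    return sl.StrainVariantRegistry([])


class TestHaplotypeSegments:
    def test_f1_without_variants_is_single_het_per_chromosome(self, ctx, f1, empty_registry):
        no_var_ctx = dict(ctx, registry=empty_registry)
        _, counts = simulate_readouts(f1, no_var_ctx, seed=31)
        segs = sl.call_haplotype_segments(counts, layout=ctx["layout"])
        by_chrom = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, chrom_segs in by_chrom.items():
            assert len(chrom_segs) == 1
            assert chrom_segs[0].state == sl.HET
            assert chrom_segs[0].start == 0
            assert chrom_segs[0].end == ctx["layout"].length(chrom)

    def test_donor_founder_is_single_hom_alt_per_chromosome(self, ctx, founders):
        _, counts = simulate_readouts(founders[sl.DONOR], ctx, seed=32)
        segs = sl.call_haplotype_segments(counts, layout=ctx["layout"])
        assert {s.chrom for s in segs} == {"chr11", "chr4"}
        assert all(s.state == sl.HOM_ALT for s in segs)

    def test_empty_table_yields_empty_segmentation(self):
        import pandas as pd

        table = sl.AlleleCountTable(
            "e", pd.DataFrame(columns=["chrom", "pos", "ref_count", "alt_count"])
        )
        assert sl.call_haplotype_segments(table) == []

    def test_het_carrier_germline_brackets_driver_and_variant(self, kpc_het_animal, ctx):
        """Heterozygosity spans the driver; the variant region reads reference."""
        driver = ctx["alleles"][0]
        segs = [s for s in kpc_het_animal["segments"] if s.chrom == "chr11"]
        at_driver = [s for s in segs if s.start <= driver.position < s.end]
        assert len(at_driver) == 1 and at_driver[0].state == sl.HET


class TestConcordance:
    def _truth_segments(self, genome, layout):
        segs = []
        for chrom in layout.chromosomes:
            breaks, states = _truth_state_steps(genome, chrom)
            for k, state in enumerate(states):
                segs.append(
                    sl.HaplotypeSegment(chrom, int(breaks[k]), int(breaks[k + 1]), state, 1, 0.5)
                )
        return segs

    def test_perfect_call_scores_one(self, ctx, f1):
        segs = self._truth_segments(f1, ctx["layout"])
        assert sl.haplotype_concordance(segs, f1, ctx["layout"]) == 1.0

    def test_all_hom_ref_on_f1_scores_zero(self, ctx, f1):
        wrong = [
            sl.HaplotypeSegment(c, 0, ctx["layout"].length(c), sl.HOM_REF, 1, 0.0)
            for c in ctx["layout"].chromosomes
        ]
        assert sl.haplotype_concordance(wrong, f1, ctx["layout"]) == 0.0

    def test_concordance_improves_with_depth(self, ctx, founders):
        """Mean concordance over seeded F2 animals is non-decreasing in depth."""
        rng = np.random.default_rng(55)
        animals = [
            sl.cross(
                sl.cross(founders[sl.DONOR], founders[sl.REFSTRAIN], rng),
                sl.cross(founders[sl.DONOR], founders[sl.REFSTRAIN], rng),
                rng,
            )
            for _ in range(4)
        ]
        means = []
        for depth in (20, 100):
            scores = []
            for i, g in enumerate(animals):
                counts = sl.simulate_allele_counts(
                    g, ctx["registry"], ctx["layout"], mean_depth=depth, seed=600 + i
                )
                segs = sl.call_haplotype_segments(counts, layout=ctx["layout"])
                scores.append(sl.haplotype_concordance(segs, g, ctx["layout"]))
            means.append(np.mean(scores))
        assert means[1] >= means[0] - 0.01


class TestLOH:
    def test_tumor_identical_to_germline_has_no_loh(self, ctx, f1, calling_cfg):
        t = sl.TumorGenome(f1, [])
        result = run_pair(f1, t, ctx, calling_cfg, seed=41)
        assert result["loh"] == []

    def test_driver_cnloh_called_with_alt_retained(self, kpc_het_animal, ctx):
        """The wild-type-driver haplotype loss is called CN-LOH, donor retained."""
        driver = ctx["alleles"][0]
        calls = [c for c in kpc_het_animal["loh"] if c.chrom == "chr11"]
        assert len(calls) == 1
        (call,) = calls
        assert call.start <= driver.position < call.end
        assert call.retained == "ALT"
        assert call.mechanism == "CN_LOH"
        assert 0.9 <= call.coverage_ratio <= 1.1

    def test_het_focal_deletion_called_deletion_loh(self, ctx, f1, calling_cfg):
        """A one-copy loss over het territory shows VAF shift at half coverage."""
        ref_copy = "A" if f1.strain_at("chr11", 30_000_000, "A") == sl.REFSTRAIN else "B"
        t = sl.TumorGenome(
            f1, [SomaticEvent(FOCAL_DEL, "chr11", 20_000_000, 40_000_000, ref_copy)]
        )
        result = run_pair(f1, t, ctx, calling_cfg, seed=43)
        dels = [c for c in result["loh"] if c.mechanism == "DELETION_LOH"]
        assert len(dels) == 1
        assert dels[0].retained == "ALT"
        assert abs(dels[0].coverage_ratio - 0.5) < 0.1

    def test_no_loh_inside_germline_homozygous_territory(self, ctx, founders, calling_cfg):
        """LOH is undefined over germline homozygosity: the homozygous-carrier
        tumor yields no LOH calls at all."""
        g = founders[sl.DONOR]
        t = sl.simulate_kpc_tumor(g, ctx["alleles"][0], 3)
        result = run_pair(g, t, ctx, calling_cfg, seed=44)
        assert result["loh"] == []

    def test_loh_calls_overlap_germline_het_segments(self, kpc_het_animal):
        het = [s for s in kpc_het_animal["segments"] if s.state == sl.HET]
        for call in kpc_het_animal["loh"]:
            assert any(
                s.chrom == call.chrom and s.start < call.end and call.start < s.end
                for s in het
            )
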