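"""Coverage, allele-count and aCGH simulators: expectations and conservation."""

import numpy as np
import pytest

import strainloh as sl
from strainloh.tumor import CN_LOH, SomaticEvent


def _bins_in(cov, chrom, start, end):
    df = cov.counts_on(chrom)
    return df[(df["start"] >= start) & (df["end"] <= end)]


class TestCoverage:
    def test_neutral_diploid_mean_matches_depth(self, ctx, f1):
        no_variants = sl.StrainVariantRegistry([])
        cov = sl.simulate_coverage(f1, no_variants, ctx["layout"], seed=1)
        counts = cov.bins["count"].to_numpy()
        assert counts.size >= 1000
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 100.0) < 3 * se

    def test_homozygous_deleted_bins_are_zero(self, ctx, founders):
        v = ctx["registry"].on("chr11")[0]
        cov = sl.simulate_coverage(founders[sl.DONOR], ctx["registry"], ctx["layout"], seed=2)
        inside = _bins_in(cov, "chr11", v.start, v.end)
        assert len(inside) == 10
        assert (inside["count"] == 0).all()

    def test_het_variant_bins_at_half_depth(self, ctx, f1):
        v = ctx["registry"].on("chr11")[0]
        rng = np.random.default_rng(3)
        means = [
            _bins_in(
                sl.simulate_coverage(f1, ctx["registry"], ctx["layout"], seed=rng),
                "chr11", v.start, v.end,
            )["count"].mean()
            for _ in range(30)
        ]
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 50.0) < 3 * se

    def test_germline_cancels_germline(self, ctx, f1):
        """An eventless tumor has bin-by-bin identical expectation to its germline."""
        t = sl.TumorGenome(f1, [])
        g_cov = sl.simulate_coverage(f1, ctx["registry"], ctx["layout"], dispersion=0.0, seed=9)
        t_cov = sl.simulate_coverage(t, ctx["registry"], ctx["layout"], dispersion=0.0, seed=9)
        assert (g_cov.bins["count"] == t_cov.bins["count"]).all()

    def test_cnloh_leaves_total_coverage_flat(self, ctx, f1):
        t = sl.TumorGenome(f1, [SomaticEvent(CN_LOH, "chr11", 40_000_000, 122_000_000, "B")])
        cov = sl.simulate_coverage(t, ctx["registry"], ctx["layout"], seed=4)
        outside_variant = _bins_in(cov, "chr11", 45_000_000, 70_000_000)["count"].to_numpy()
        se = outside_variant.std(ddof=1) / np.sqrt(outside_variant.size)
        assert abs(outside_variant.mean() - 100.0) < 3 * se


class TestAlleleCounts:
    def test_vaf_by_genotype(self, ctx, f1, founders):
        reg, layout = ctx["registry"], ctx["layout"]
        het = sl.simulate_allele_counts(f1, reg, layout, seed=5)
        df = het.on("chr11")
        v = reg.on("chr11")[0]
        outside = df[(df["pos"] < v.start) | (df["pos"] >= v.end)]
        depth = outside["ref_count"] + outside["alt_count"]
        vaf = (outside["alt_count"] / depth).to_numpy()
        se = vaf.std(ddof=1) / np.sqrt(vaf.size)
        assert abs(vaf.mean() - 0.5) < 3 * se

        hom = sl.simulate_allele_counts(founders[sl.DONOR], reg, layout, seed=6)
        dfh = hom.on("chr11")
        covered = dfh[(dfh["ref_count"] + dfh["alt_count"]) > 0]
        assert (covered["ref_count"] == 0).all()  # VAF exactly 1.0

        ref = sl.simulate_allele_counts(founders[sl.REFSTRAIN], reg, layout, seed=7)
        assert (ref.rows["alt_count"] == 0).all()

    def test_het_deletion_snps_report_pure_reference(self, ctx, f1):
        """SNPs inside a het donor deletion lose the donor (ALT) haplotype."""
        v = ctx["registry"].on("chr11")[0]
        counts = sl.simulate_allele_counts(f1, ctx["registry"], ctx["layout"], seed=8)
        df = counts.on("chr11")
        inside = df[(df["pos"] >= v.start) & (df["pos"] < v.end)]
        assert len(inside) > 0
        assert (inside["alt_count"] == 0).all()
        # roughly half depth: only one surviving copy
        assert 30 < inside["ref_count"].mean() < 70

    def test_homozygous_deletion_snps_have_zero_depth(self, ctx, founders):
        v = ctx["registry"].on("chr11")[0]
        counts = sl.simulate_allele_counts(founders[sl.DONOR], ctx["registry"], ctx["layout"], seed=9)
        df = counts.on("chr11")
        inside = df[(df["pos"] >= v.start) & (df["pos"] < v.end)]
        assert ((inside["ref_count"] + inside["alt_count"]) == 0).all()

    def test_cnloh_shifts_vaf_to_one(self, ctx, f1):
        donor_copy = "A" if f1.strain_at("chr11", 69_580_000, "A") == sl.DONOR else "B"
        target = "B" if donor_copy == "A" else "A"
        t = sl.TumorGenome(f1, [SomaticEvent(CN_LOH, "chr11", 40_000_000, 122_000_000, target)])
        counts = sl.simulate_allele_counts(t, ctx["registry"], ctx["layout"], seed=10)
        df = counts.on("chr11")
        loh = df[(df["pos"] >= 45_000_000) & (df["pos"] < 70_000_000)]
        vaf = loh["alt_count"] / (loh["ref_count"] + loh["alt_count"])
        assert vaf.mean() > 0.99


class TestACGH:
    def test_self_comparison_centers_at_zero(self, ctx, f1):
        probes = sl.ProbeSet.regular(ctx["layout"], 1_000_000)
        out = sl.simulate_acgh(f1, ctx["registry"], ctx["layout"], probes, seed=11)
        r = out.probes["log2_ratio"].to_numpy()
        assert abs(r.mean()) < 4 * 0.15 / np.sqrt(r.size)

    def test_interstrain_hybridization_reveals_germline_deletion(self, ctx, founders):
        """Donor DNA against reference DNA drops hard at the donor deletion."""
        v = ctx["registry"].on("chr11")[0]
        probes = sl.ProbeSet.regular(ctx["layout"], 50_000)
        out = sl.simulate_acgh(
            founders[sl.DONOR], ctx["registry"], ctx["layout"], probes,
            seed=12, reference=founders[sl.REFSTRAIN],
        )
        df = out.probes[out.probes["chrom"] == "chr11"]
        inside = df[(df["pos"] >= v.start) & (df["pos"] < v.end)]["log2_ratio"]
        outside = df[(df["pos"] < v.start) | (df["pos"] >= v.end)]["log2_ratio"]
        assert len(inside) > 0
        assert inside.mean() < -1.5
        assert abs(outside.mean()) < 0.1

    def test_probe_free_regions_yield_no_ratios(self, ctx, f1):
        probes = sl.ProbeSet(
            sl.ProbeSet.regular(ctx["layout"], 1_000_000).probes.query("chrom == 'chr11'")
        )
        out = sl.simulate_acgh(f1, ctx["registry"], ctx["layout"], probes, seed=13)
        assert (out.probes["chrom"] == "chr11").all()
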