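"""Meiosis, crosses and backcross introgression dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strainloh as sl


class TestMeiosis:
    def test_homozygous_parent_yields_single_block(self, ctx, founders):
        gam = sl.meiosis(founders[sl.REFSTRAIN], "chr11", 5)
        assert gam.blocks == [(0, 122_000_000, sl.REFSTRAIN)]

    def test_unknown_chromosome_raises(self, founders):
        with pytest.raises(ValueError):
            sl.meiosis(founders[sl.DONOR], "chrX", 0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_f1_gamete_blocks_are_pure_and_tile(self, ctx, f1, seed):
        """Every F1 gamete block is purely one founder; blocks tile the chromosome."""
        gam = sl.meiosis(f1, "chr11", seed)
        assert gam.blocks[0][0] == 0
        assert gam.blocks[-1][1] == 122_000_000
        for (s0, e0, st0), (s1, _, st1) in zip(gam.blocks, gam.blocks[1:]):
            assert s1 == e0
            assert st0 != st1  # merged representation
        assert {b[2] for b in gam.blocks} <= {sl.DONOR, sl.REFSTRAIN}

    def test_crossover_rate_matches_map_length(self, f1):
        """Mean observed crossovers on a 61 cM chromosome ~ Poisson mean 0.61.

        On an F1 every crossover changes the founder label, so crossovers are
        the block-boundary count of the gamete.
        """
        rng = np.random.default_rng(42)
        n = 10_000
        counts = np.array([len(sl.meiosis(f1, "chr11", rng).blocks) - 1 for i in range(n)])
        expected = 0.61
        se = np.sqrt(expected / n)
        assert abs(counts.mean() - expected) < 3 * se


class TestCross:
    def test_f1_is_heterozygous_everywhere(self, f1):
        for chrom in ("chr11", "chr4"):
            a, b = f1.copies[chrom]
            assert len(a.blocks) == 1 and len(b.blocks) == 1
            assert {a.blocks[0][2], b.blocks[0][2]} == {sl.DONOR, sl.REFSTRAIN}

    def test_self_cross_of_homozygote_is_identical(self, founders):
        child = sl.cross(founders[sl.DONOR], founders[sl.DONOR], 3)
        assert sl.donor_fraction(child) == 1.0

    def test_layout_mismatch_rejected(self, founders):
        other_layout = sl.GenomeLayout({"chrZ": 1000}, 0.5, {"chrZ": np.array([5])})
        other = sl.DiploidGenome.founder(other_layout, sl.DONOR)
        with pytest.raises(ValueError):
            sl.cross(founders[sl.DONOR], other, 0)

    def test_f1_backcross_offspring_donor_fraction(self, f1, founders):
        """F1 x REFSTRAIN offspring carry ~25% donor genome on average."""
        rng = np.random.default_rng(7)
        fracs = np.array(
            [sl.donor_fraction(sl.cross(f1, founders[sl.REFSTRAIN], rng)) for _ in range(1000)]
        )
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.25) < 3 * se


class TestDonorFraction:
    def test_founder_and_f1_fractions_exact(self, founders, f1):
        assert sl.donor_fraction(founders[sl.DONOR]) == 1.0
        assert sl.donor_fraction(founders[sl.REFSTRAIN]) == 0.0
        assert sl.donor_fraction(f1) == 0.5

    def test_exclusion_interval_removes_both_sides(self, f1):
        # excluding any interval of an exactly half-donor genome keeps 0.5
        assert sl.donor_fraction(f1, exclude=("chr11", 0, 60_000_000)) == 0.5


def _oracle_backcross_donor_fraction(n_gen, length, map_rate, n_rep, seed, grid=4_000):
    """Independent Monte-Carlo oracle for background (non-selected) introgression.

    Tracks one non-carrier chromosome as a boolean donor mask on a coordinate
    grid; each backcross generation splices the carrier's two copies at
    Poisson/uniform crossovers and pairs the gamete with a pure-reference copy.
    Selection on the other chromosome does not touch this one, so it is
    simulated without selection.
    """
    rng = np.random.default_rng(seed)
    morgans = length * map_rate / 100.0 / 1e6
    fracs = np.empty(n_rep)
    for r in range(n_rep):
        hap_a = np.ones(grid, dtype=bool)  # F1: donor copy + reference copy
        hap_b = np.zeros(grid, dtype=bool)
        for _ in range(n_gen):
            k = rng.poisson(morgans)
            cuts = np.sort(rng.integers(0, grid, size=k))
            phase = np.zeros(grid, dtype=bool)
            for c in cuts:
                phase[c:] = ~phase[c:]
            if rng.integers(2):
                phase = ~phase
            gamete = np.where(phase, hap_a, hap_b)
            hap_a, hap_b = gamete, np.zeros(grid, dtype=bool)
        fracs[r] = (hap_a.sum() + hap_b.sum()) / (2 * grid)
    return fracs


class TestBackcross:
    def test_selected_allele_always_on_donor_block(self, ctx, founders):
        """Selection keeps the engineered allele on a donor block at every n."""
        driver = ctx["alleles"][0]
        for seed in range(5):
            g = sl.backcross_scheme(
                founders[sl.DONOR], founders[sl.REFSTRAIN], 3, driver, seed
            )
            strains = {
                g.strain_at(driver.chrom, driver.position, c) for c in ("A", "B")
            }
            assert strains == {sl.DONOR, sl.REFSTRAIN}

    def test_one_generation_background_fraction(self, ctx, founders):
        """After one backcross the non-carrier chromosome is ~25% donor."""
        driver = ctx["alleles"][0]
        rng = np.random.default_rng(17)
        fracs = []
        for _ in range(300):
            g = sl.backcross_scheme(founders[sl.DONOR], founders[sl.REFSTRAIN], 1, driver, rng)
            a, b = g.copies["chr4"]
            donor_len = sum(
                e - s for m in (a, b) for s, e, strain in m.blocks if strain == sl.DONOR
            )
            fracs.append(donor_len / (2 * g.layout.length("chr4")))
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.25) < 3 * se

    def test_background_introgression_halves_per_generation(self, ctx, founders):
        """Mean donor fraction on the non-carrier chromosome decreases with n
        and matches an independent Monte-Carlo oracle at n=5."""
        driver = ctx["alleles"][0]
        layout = ctx["layout"]
        means = {}
        for n_gen, n_rep in ((1, 150), (3, 150), (5, 400)):
            rng = np.random.default_rng(100 + n_gen)
            fr = []
            for _ in range(n_rep):
                g = sl.backcross_scheme(
                    founders[sl.DONOR], founders[sl.REFSTRAIN], n_gen, driver, rng
                )
                a, b = g.copies["chr4"]
                donor_len = sum(
                    e - s for m in (a, b) for s, e, strain in m.blocks if strain == sl.DONOR
                )
                fr.append(donor_len / (2 * layout.length("chr4")))
            means[n_gen] = (np.mean(fr), np.std(fr, ddof=1) / np.sqrt(len(fr)))
        assert means[1][0] > means[3][0] > means[5][0]

        oracle = _oracle_backcross_donor_fraction(
            5, layout.length("chr4"), layout.map_rate, 2000, seed=999
        )
        o_mean = oracle.mean()
        o_se = oracle.std(ddof=1) / np.sqrt(oracle.size)
        diff_se = np.sqrt(o_se**2 + means[5][1] ** 2)
        assert abs(means[5][0] - o_mean) < 3 * diff_se
        # analytic halving: d_n = 2^-(n+1)
        assert abs(o_mean - 2 ** (-6)) < 3 * o_se
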