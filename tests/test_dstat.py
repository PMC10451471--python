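"""Site-pattern statistics: polarization, weights, D, Dp, jackknife."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introgscan import dstat, treeops
from introgscan.dstat import (
    PatternCounts,
    TripletSpec,
    block_jackknife,
    compute_d,
    compute_dp,
    derived_allele_frequencies,
    enumerate_triplets,
    pattern_counts,
    site_pattern_weights,
)

from conftest import make_genotype_matrix

SAMPLES = ["P1", "P2", "P3", "O"]
TRIP = TripletSpec(("P1",), ("P2",), ("P3",), ("O",))


class TestPolarization:
    def test_fixed_abba_site(self):
        gm = make_genotype_matrix(
            [[(0, 0), (1, 1), (1, 1), (0, 0)]], SAMPLES
        )
        freqs, valid = derived_allele_frequencies(gm, TRIP)
        assert valid[0]
        assert freqs[0].tolist() == [0.0, 1.0, 1.0, 0.0]

    def test_heterozygote_gives_half(self):
        gm = make_genotype_matrix(
            [[(0, 0), (0, 1), (1, 1), (0, 0)]], SAMPLES
        )
        freqs, valid = derived_allele_frequencies(gm, TRIP)
        assert freqs[0].tolist() == [0.0, 0.5, 1.0, 0.0]

    def test_tied_outgroup_skipped(self):
        gm = make_genotype_matrix(
            [[(0, 0), (1, 1), (1, 1), (0, 1)]], SAMPLES
        )
        _, valid = derived_allele_frequencies(gm, TRIP)
        assert not valid[0]

    def test_alt_major_outgroup_flips_polarization(self):
        # outgroup homozygous ALT: the ALT allele is ancestral, so a
        # REF-carrying P2/P3 is the derived state
        gm = make_genotype_matrix(
            [[(1, 1), (0, 0), (0, 0), (1, 1)]], SAMPLES
        )
        freqs, valid = derived_allele_frequencies(gm, TRIP)
        assert valid[0]
        assert freqs[0].tolist() == [0.0, 1.0, 1.0, 0.0]

    def test_population_with_no_calls_skipped(self):
        gm = make_genotype_matrix(
            [[(-1, -1), (1, 1), (1, 1), (0, 0)]], SAMPLES
        )
        _, valid = derived_allele_frequencies(gm, TRIP)
        assert not valid[0]


class TestPatternWeights:
    @pytest.mark.parametrize("freqs,expected", [
        ((0, 1, 1, 0), (0.0, 1.0, 0.0)),     # fixed ABBA
        ((1, 0, 1, 0), (0.0, 0.0, 1.0)),     # fixed BABA
        ((1, 1, 0, 0), (1.0, 0.0, 0.0)),     # fixed BBAA
        ((0, 0.5, 1, 0), (0.0, 0.5, 0.0)),   # heterozygous P2
    ])
    def test_weight_formula(self, freqs, expected):
        bbaa, abba, baba = site_pattern_weights(*freqs)
        assert (float(bbaa), float(abba), float(baba)) == \
            pytest.approx(expected)

    @given(
        st.tuples(*[st.floats(0, 1) for _ in range(4)]),
    )
    @settings(deadline=None, max_examples=50)
    def test_weights_are_probability_products(self, freqs):
        bbaa, abba, baba = site_pattern_weights(*freqs)
        for w in (bbaa, abba, baba):
            assert 0.0 <= float(w) <= 1.0


class TestDandDp:
    def test_equal_counts_give_zero(self):
        c = PatternCounts(bbaa=10, abba=7, baba=7)
        assert compute_d(c) == 0.0
        assert compute_dp(c) == 0.0

    def test_maximal_imbalance(self):
        c = PatternCounts(bbaa=0, abba=5, baba=0)
        assert compute_d(c) == 1.0

    def test_undefined_when_no_discordant_patterns(self):
        c = PatternCounts(bbaa=10, abba=0, baba=0)
        assert math.isnan(compute_d(c))
        assert compute_dp(c) == 0.0
        assert math.isnan(compute_dp(PatternCounts(0, 0, 0)))

    @given(
        st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0, 1e6),
    )
    @settings(deadline=None, max_examples=100)
    def test_dp_magnitude_never_exceeds_d(self, bbaa, abba, baba):
        c = PatternCounts(bbaa=bbaa, abba=abba, baba=baba)
        d, dp = compute_d(c), compute_dp(c)
        if not (math.isnan(d) or math.isnan(dp)):
            assert abs(d) <= 1.0 and abs(dp) <= 1.0
            assert abs(dp) <= abs(d) + 1e-12


class TestBlockJackknife:
    def _brute_force(self, blocks):
        """Independent delete-one implementation of the jackknife SE."""
        tot = np.sum(blocks, axis=0)
        d_full = (tot[1] - tot[2]) / (tot[1] + tot[2])
        loo = []
        for j in range(len(blocks)):
            rest = np.sum(np.delete(blocks, j, axis=0), axis=0)
            loo.append((rest[1] - rest[2]) / (rest[1] + rest[2]))
        loo = np.array(loo)
        n = len(blocks)
        se = math.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
        return d_full, se

    def test_matches_brute_force_on_hand_built_blocks(self):
        blocks = np.array([
            [10.0, 8.0, 5.0],
            [12.0, 6.0, 7.0],
            [9.0, 10.0, 4.0],
        ])
        counts = PatternCounts(
            bbaa=blocks[:, 0].sum(), abba=blocks[:, 1].sum(),
            baba=blocks[:, 2].sum(),
            per_block={f"chr1:{j}": tuple(b) for j, b in enumerate(blocks)},
        )
        d_full, se_expected = self._brute_force(blocks)
        se, z, p = block_jackknife(counts)
        assert se == pytest.approx(se_expected, rel=1e-12)
        assert z == pytest.approx(d_full / se_expected, rel=1e-12)
        assert 0.0 <= p <= 1.0

    def test_identical_blocks_give_zero_se_infinite_z(self):
        block = (5.0, 4.0, 2.0)
        counts = PatternCounts(
            bbaa=15, abba=12, baba=6,
            per_block={f"chr1:{j}": block for j in range(3)},
        )
        se, z, _ = block_jackknife(counts)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert math.isinf(z)

    def test_single_block_undefined(self):
        counts = PatternCounts(
            bbaa=5, abba=4, baba=2, per_block={"chr1:0": (5, 4, 2)}
        )
        se, z, p = block_jackknife(counts)
        assert math.isnan(se) and math.isnan(z) and math.isnan(p)


class TestPatternCounts:
    def test_blocks_sum_to_genome_wide(self):
        rng = np.random.default_rng(5)
        rows = []
        for _ in range(200):
            rows.append([
                tuple(rng.integers(0, 2, size=2)) for _ in range(4)
            ])
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), 200,
                                 replace=False))
        gm = make_genotype_matrix(rows, SAMPLES, pos=pos)
        counts = pattern_counts(gm, TRIP, block_size=1_000_000)
        per = np.array(list(counts.per_block.values()))
        assert per[:, 0].sum() == pytest.approx(counts.bbaa)
        assert per[:, 1].sum() == pytest.approx(counts.abba)
        assert per[:, 2].sum() == pytest.approx(counts.baba)
        assert counts.n_sites_used + counts.n_sites_skipped == 200

    def test_swapping_p1_p2_flips_d_sign(self):
        rng = np.random.default_rng(6)
        rows = [[tuple(rng.integers(0, 2, size=2)) for _ in range(4)]
                for _ in range(300)]
        gm = make_genotype_matrix(rows, SAMPLES)
        d1 = compute_d(pattern_counts(gm, TRIP))
        d2 = compute_d(pattern_counts(gm, TRIP.swap_p1_p2()))
        assert d1 == pytest.approx(-d2)


class TestTripletEnumeration:
    def _brute_force_triplets(self, tree, ingroup):
        """Every 3-subset resolved by restricting the species tree."""
        out = set()
        for trio in itertools.combinations(ingroup, 3):
            for pair in itertools.combinations(trio, 2):
                p3 = next(t for t in trio if t not in pair)
                q = treeops.QuartetSpec(pair[0], pair[1], p3, "__none__")
                # pair is sister iff some clade's restriction equals it
                for side in treeops.restricted_bipartitions(
                        tree, frozenset(trio)):
                    if side == frozenset(pair):
                        out.add((frozenset(pair), p3))
        return out

    @pytest.mark.parametrize("newick,n_ingroup", [
        ("((((A,B),C),D),Out);", 4),
        ("(((((A,B),C),D),E),Out);", 5),
        ("(((A,B),(C,D)),Out);", 4),
    ])
    def test_matches_brute_force(self, newick, n_ingroup):
        (tree,) = treeops.read_trees(newick, rooted=True)
        ingroup = sorted(treeops.leaf_labels(tree) - {"Out"})
        got = enumerate_triplets(tree, ingroup)
        expected = self._brute_force_triplets(tree, ingroup)
        assert len(got) == math.comb(n_ingroup, 3)
        assert {(frozenset((p1, p2)), p3) for p1, p2, p3 in got} == expected

    def test_missing_species_raises(self):
        (tree,) = treeops.read_trees("((A,B),C);", rooted=True)
        with pytest.raises(KeyError):
            enumerate_triplets(tree, ["A", "B", "Z"])


class TestRunDtrios:
    def test_orientation_makes_d_nonnegative(self):
        rng = np.random.default_rng(9)
        samples = ["a1", "b1", "c1", "o1"]
        rows = [[tuple(rng.integers(0, 2, size=2)) for _ in range(4)]
                for _ in range(400)]
        pos = np.sort(rng.choice(np.arange(1, 20_000_000), 400,
                                 replace=False))
        gm = make_genotype_matrix(rows, samples, pos=pos)
        species_map = {"a1": "A", "b1": "B", "c1": "C", "o1": "Out"}
        table = dstat.run_dtrios(
            gm, species_map, "(((A,B),C),Out);", outgroup=["Out"],
            block_size=1_000_000,
        )
        assert len(table) == 1
        assert table.loc[0, "D"] >= 0
        assert set(table.columns) == {
            "P1", "P2", "P3", "D", "Z", "p", "Dp", "BBAA", "ABBA", "BABA"
        }

    def test_unknown_sample_species_raises(self):
        gm = make_genotype_matrix(
            [[(0, 0), (0, 0), (0, 0), (0, 0)]], ["a", "b", "c", "o"]
        )
        species_map = {"a": "A", "b": "B", "c": "C", "zz": "Out"}
        with pytest.raises(KeyError):
            dstat.run_dtrios(gm, species_map, "(((A,B),C),Out);", ["Out"])


def test_p_value_formatting():
    assert dstat.format_p(0.735) == ".735"
    assert dstat.format_p(0.0004) == ".000"
    assert dstat.format_p(0.013) == ".013"
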