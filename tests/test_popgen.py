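"""Microsatellite statistics against a from-first-principles oracle.

The oracle below recomputes every statistic with explicit Python loops
and exact rational arithmetic, independently of the vectorized
implementation under test.
"""

import math
from fractions import Fraction as Fr
from math import comb

import numpy as np
import pytest

from locustload.genepop import read_genepop, write_genepop
from locustload.popgen import (
    GenotypeTable,
    allele_counts,
    allelic_richness,
    expected_heterozygosity,
    inbreeding_coefficient,
    observed_heterozygosity,
    pairwise_fst,
    summarize,
)
from locustload.synthetic_data import GenotypeSimConfig, simulate_genotypes

from conftest import make_table


# ---------------------------------------------------------------------------
# oracle: exact rational statistics from genotype lists
# ---------------------------------------------------------------------------


def oracle_he(genos):
    copies = [a for g in genos if g is not None for a in g]
    tot = len(copies)
    if tot < 2:
        return None
    sum_p2 = sum(Fr(copies.count(a), tot) ** 2 for a in set(copies))
    return Fr(tot, tot - 1) * (1 - sum_p2)


def oracle_ho(genos):
    typed = [g for g in genos if g is not None]
    if not typed:
        return None
    return Fr(sum(1 for a, b in typed if a != b), len(typed))


def oracle_ar(genos, g):
    copies = [a for gg in genos if gg is not None for a in gg]
    N = len(copies)
    return sum(
        1 - Fr(comb(N - copies.count(a), g), comb(N, g)) for a in set(copies)
    )


def oracle_theta(pop_a, pop_b):
    """Weir & Cockerham theta for two populations over all loci,
    multilocus ratio of sums, exact rationals."""
    n_loci = len(pop_a[0])
    num = Fr(0)
    den = Fr(0)
    for j in range(n_loci):
        ga = [ind[j] for ind in pop_a if ind[j] is not None]
        gb = [ind[j] for ind in pop_b if ind[j] is not None]
        n1, n2 = len(ga), len(gb)
        if n1 < 1 or n2 < 1 or n1 + n2 < 2:
            continue
        r = 2
        nbar = Fr(n1 + n2, 2)
        if nbar <= 1:
            continue
        nc = (r * nbar - Fr(n1 * n1 + n2 * n2, 1) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        alleles = {a for g in ga + gb for a in g}
        for allele in alleles:
            p1 = Fr(sum(g.count(allele) for g in ga), 2 * n1)
            p2 = Fr(sum(g.count(allele) for g in gb), 2 * n2)
            h1 = Fr(sum(1 for g in ga if g.count(allele) == 1), n1)
            h2 = Fr(sum(1 for g in gb if g.count(allele) == 1), n2)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - Fr(r - 1, r) * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - Fr(r - 1, r) * s2
                - Fr(2 * nbar - 1, 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    if den == 0:
        return None
    return num / den


# ---------------------------------------------------------------------------
# hand-checkable examples
# ---------------------------------------------------------------------------


class TestExpectedHeterozygosity:
    def test_monomorphic_is_zero(self):
        assert expected_heterozygosity({1: 10}) == 0.0

    def test_biallelic_five_individuals(self):
        # 10 copies split 5/5: (10/9) * (1 - 0.5) = 0.5556
        assert expected_heterozygosity({1: 5, 2: 5}) == pytest.approx(10 / 9 * 0.5)

    def test_large_sample_equifrequent_limit(self):
        k = 4
        counts = {i: 250_000 for i in range(k)}
        assert expected_heterozygosity(counts) == pytest.approx(1 - 1 / k, abs=1e-5)

    def test_too_few_copies_missing(self):
        assert math.isnan(expected_heterozygosity({1: 1}))


class TestObservedHeterozygosity:
    def test_counts_distinct_pairs(self):
        g = np.array([[1, 2], [1, 1], [2, 2], [1, 2]])
        assert observed_heterozygosity(g) == 0.5

    def test_all_missing_is_nan(self):
        assert math.isnan(observed_heterozygosity(np.zeros((3, 2), dtype=int)))


class TestInbreedingCoefficient:
    def test_zero_when_ho_equals_he(self):
        assert inbreeding_coefficient([0.5, 0.3], [0.5, 0.3]) == 0.0

    def test_one_when_no_heterozygotes(self):
        assert inbreeding_coefficient([0.0, 0.0], [0.4, 0.6]) == 1.0

    def test_monomorphic_loci_excluded(self):
        # second locus H_E=0 must not contribute
        assert inbreeding_coefficient([0.25, 0.0], [0.5, 0.0]) == 0.5
        assert math.isnan(inbreeding_coefficient([0.0], [0.0]))


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        assert allelic_richness({1: 10}, 4) == pytest.approx(1.0)

    def test_no_rarefaction_gives_allele_count(self):
        assert allelic_richness({1: 4, 2: 3, 3: 3}, 10) == pytest.approx(3.0)

    def test_rare_allele_hand_value(self):
        # counts 9/1, g=2: 1 + (1 - C(9,2)/C(10,2)) = 1.2
        assert allelic_richness({1: 9, 2: 1}, 2) == pytest.approx(1.2)

    def test_monotone_in_g(self):
        counts = {1: 10, 2: 6, 3: 2, 4: 2}
        vals = [allelic_richness(counts, g) for g in range(2, 21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_g_too_large_errors(self):
        with pytest.raises(ValueError):
            allelic_richness({1: 4}, 5)


class TestPairwiseFst:
    def test_fixed_difference_is_one(self):
        table = make_table(
            {
                "A": [[(1, 1)]] * 6,
                "B": [[(2, 2)]] * 6,
            }
        )
        assert pairwise_fst(table, "A", "B") == pytest.approx(1.0)

    def test_identical_frequency_pools_near_zero(self):
        rng = np.random.default_rng(5)
        cfg = dict(n_loci=4, alleles_per_locus=4, F_is=0.0, n_individuals=800)
        a = simulate_genotypes(GenotypeSimConfig(name="A", **cfg), seed=10)
        b = simulate_genotypes(GenotypeSimConfig(name="B", **cfg), seed=11)
        table = GenotypeTable(
            loci=a.loci, populations={"A": a.populations["A"], "B": b.populations["B"]}
        )
        assert abs(pairwise_fst(table, "A", "B")) < 0.01

    def test_uninformative_table_missing(self):
        table = make_table({"A": [[(1, 1)]] * 3, "B": [[(1, 1)]] * 3})
        assert math.isnan(pairwise_fst(table, "A", "B"))


# ---------------------------------------------------------------------------
# oracle agreement and structural invariants
# ---------------------------------------------------------------------------

TOY_A = [
    [(1, 2), (1, 1)],
    [(1, 1), (1, 2)],
    [(2, 3), (2, 2)],
    [(1, 3), None],
    [(2, 2), (1, 1)],
]
TOY_B = [
    [(2, 2), (2, 2)],
    [(2, 3), (1, 2)],
    [(3, 3), (2, 2)],
    [(1, 2), (2, 2)],
]


def test_statistics_match_exact_enumeration_oracle():
    table = make_table({"A": TOY_A, "B": TOY_B})
    for pop, inds in [("A", TOY_A), ("B", TOY_B)]:
        for j, locus in enumerate(table.loci):
            genos = [ind[j] for ind in inds]
            counts = allele_counts(table.genotypes(pop, locus))
            assert expected_heterozygosity(counts) == pytest.approx(
                float(oracle_he(genos)), abs=1e-12
            )
            assert observed_heterozygosity(table.genotypes(pop, locus)) == pytest.approx(
                float(oracle_ho(genos)), abs=1e-12
            )
            g = 2 * min(
                sum(x is not None for x in [ind[j] for ind in TOY_A]),
                sum(x is not None for x in [ind[j] for ind in TOY_B]),
            )
            assert allelic_richness(counts, g) == pytest.approx(
                float(oracle_ar(genos, g)), abs=1e-12
            )
    assert pairwise_fst(table, "A", "B") == pytest.approx(
        float(oracle_theta(TOY_A, TOY_B)), abs=1e-12
    )


def test_permuting_individuals_changes_nothing():
    table = make_table({"A": TOY_A, "B": TOY_B})
    perm = make_table({"A": TOY_A[::-1], "B": TOY_B[::-1]})
    s1, s2 = summarize(table), summarize(perm)
    assert np.allclose(
        s1.per_population[["A_R", "H_E", "H_O", "F_IS"]],
        s2.per_population[["A_R", "H_E", "H_O", "F_IS"]],
        equal_nan=True,
    )
    assert np.allclose(s1.fst.to_numpy(), s2.fst.to_numpy(), equal_nan=True)


def test_duplicating_individuals_only_rescales_he_bias_factor():
    genos = [g[0] for g in TOY_A]
    counts1 = allele_counts(make_table({"A": TOY_A}).genotypes("A", "L1"))
    doubled = make_table({"A": TOY_A + TOY_A})
    counts2 = allele_counts(doubled.genotypes("A", "L1"))
    n1 = sum(counts1.values())
    n2 = sum(counts2.values())
    raw1 = expected_heterozygosity(counts1) * (n1 - 1) / n1
    raw2 = expected_heterozygosity(counts2) * (n2 - 1) / n2
    assert raw1 == pytest.approx(raw2, abs=1e-12)  # freqs unchanged


def test_fis_recovered_from_simulated_genotypes():
    cfg = GenotypeSimConfig(
        name="X", n_individuals=10_000, n_loci=6, alleles_per_locus=4, F_is=0.3
    )
    table = simulate_genotypes(cfg, seed=17)
    s = summarize(table)
    fis = s.per_population["F_IS"].iloc[0]
    # per-locus SE of 1 - Ho/He, averaged over 6 loci
    he = 0.75
    ho = (1 - 0.3) * he
    se = math.sqrt(ho * (1 - ho) / cfg.n_individuals) / he / math.sqrt(cfg.n_loci)
    assert abs(fis - 0.3) < 4 * se


def test_summarize_reports_rarefaction_and_bounds():
    table = make_table({"A": TOY_A, "B": TOY_B})
    s = summarize(table)
    assert set(s.per_locus.columns) >= {"population", "locus", "H_E", "H_O", "F_IS", "A_R"}
    assert (s.per_locus["A_R"].dropna() >= 1).all()
    with pytest.raises(ValueError, match="rarefaction"):
        summarize(table, rarefaction_g=50)


# ---------------------------------------------------------------------------
# GENEPOP io
# ---------------------------------------------------------------------------


class TestGenepop:
    def test_round_trip(self, tmp_path):
        table = make_table({"Alpha": TOY_A, "Beta": TOY_B})
        path = tmp_path / "toy.gen"
        write_genepop(table, path)
        back = read_genepop(path)
        assert back.loci == table.loci
        for pop in table.populations:
            assert np.array_equal(back.populations[pop], table.populations[pop])

    def test_two_digit_dialect(self, tmp_path):
        text = "toy data\nlocA, locB\nPop\nind1 , 0102 0101\nind2 , 0202 0000\n"
        path = tmp_path / "two.gen"
        path.write_text(text)
        table = read_genepop(path)
        assert table.loci == ["locA", "locB"]
        arr = table.populations[table.population_names[0]]
        assert arr.shape == (2, 2, 2)
        assert arr[0, 0].tolist() == [1, 2]
        assert arr[1, 1].tolist() == [0, 0]  # missing

    def test_malformed_token_rejected(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("t\nloc1\nPop\nind1 , 01x02\n")
        with pytest.raises(ValueError, match="malformed"):
            read_genepop(path)
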