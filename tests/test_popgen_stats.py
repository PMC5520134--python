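"""Diversity and differentiation statistics against closed forms and
independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from fallowpop.core_io import MISSING
from fallowpop.popgen_stats import (
    build_summary_vector,
    founder_fst_expectation,
    hwe_exact_test,
    ld_test,
    mantel_test,
    msat_diversity,
    mtdna_diversity,
    pairwise_fst,
    sequential_bonferroni,
    unbiased_he,
    rarefied_richness,
)

from .conftest import make_alignment, make_dataset


# ---------------------------------------------------------------------------
# diversity


def test_monomorphic_population_diversity_conventions():
    ds = make_dataset({"p": [[(92, 92)]] * 6})
    div = msat_diversity(ds, hwe=False)
    row = div.per_locus.iloc[0]
    assert row["A"] == 1 and row["AR"] == pytest.approx(1.0)
    assert row["He"] == 0.0 and row["Ho"] == 0.0
    assert np.isnan(row["fis"])


def test_rarefaction_exhaustive_hypergeometric_value():
    # counts {a:3, b:1}, rarefy to g=2:
    # [1 - C(1,2)/C(4,2)] + [1 - C(3,2)/C(4,2)] = 1 + 1/2
    assert rarefied_richness(np.array([3, 1]), 2) == pytest.approx(1.5)


def test_rarefaction_matches_enumeration_over_draws():
    # independent oracle: enumerate all g-subsets of the gene copies
    counts = np.array([4, 2, 1])
    copies = [0] * 4 + [1] * 2 + [2]
    g = 3
    subsets = list(itertools.combinations(range(len(copies)), g))
    expected = np.mean([
        len({copies[i] for i in s}) for s in subsets
    ])
    assert rarefied_richness(counts, g) == pytest.approx(expected)


def test_unbiased_he_closed_form():
    copies = np.array([1] * 10 + [2] * 10)
    assert unbiased_he(copies) == pytest.approx(20 / 19 * 0.5)


def test_rarefaction_size_exceeding_sample_errors():
    ds = make_dataset({"p": [[(92, 94)]] * 3})
    with pytest.raises(ValueError, match="rarefaction"):
        msat_diversity(ds, rarefaction_size=10, hwe=False)


def test_he_invariant_to_allele_relabelling_and_order(rng):
    copies = rng.integers(90, 96, size=40)
    relabel = {v: 200 - v for v in np.unique(copies)}
    relabelled = np.array([relabel[v] for v in copies])
    assert unbiased_he(copies) == pytest.approx(
        unbiased_he(rng.permutation(relabelled)))


# ---------------------------------------------------------------------------
# Weir-Cockerham theta: independent oracle


def _wc_oracle_pair(geno1, geno2):
    """Naive transliteration of the two-population diploid variance
    components, explicit sums over alleles (independent of the package's
    vectorised path)."""
    g1 = [g for g in geno1 if g[0] != MISSING]
    g2 = [g for g in geno2 if g[0] != MISSING]
    n1, n2 = len(g1), len(g2)
    r = 2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    alleles = sorted({a for g in g1 + g2 for a in g})
    num = den = 0.0
    for al in alleles:
        p1 = sum(g.count(al) for g in g1) / (2 * n1)
        p2 = sum(g.count(al) for g in g2) / (2 * n2)
        h1 = sum(1 for g in g1 if g.count(al) == 1) / n1
        h2 = sum(1 for g in g2 if g.count(al) == 1) / n2
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        a = (nbar / nc) * (s2 - 1 / (nbar - 1)
                           * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else float("nan")


def _theta_multilocus_oracle(pop_genos):
    """Ratio-of-sums over loci using the per-locus oracle components."""
    num = den = 0.0
    n_loci = len(pop_genos[0][0])
    for l in range(n_loci):
        g1 = [ind[l] for ind in pop_genos[0]]
        g2 = [ind[l] for ind in pop_genos[1]]
        g1t = [g for g in g1 if g[0] != MISSING]
        g2t = [g for g in g2 if g[0] != MISSING]
        if len(g1t) < 1 or len(g2t) < 1 or len(g1t) + len(g2t) < 3:
            continue
        # recompute a, b, c sums (not the ratio) for ratio-of-sums
        n1, n2 = len(g1t), len(g2t)
        r, nbar = 2, (n1 + n2) / 2
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        for al in sorted({a for g in g1t + g2t for a in g}):
            p1 = sum(g.count(al) for g in g1t) / (2 * n1)
            p2 = sum(g.count(al) for g in g2t) / (2 * n2)
            h1 = sum(1 for g in g1t if g.count(al) == 1) / n1
            h2 = sum(1 for g in g2t if g.count(al) == 1) / n2
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                     - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            num += a
            den += a + b + hbar / 2
    return num / den if den else float("nan")


@pytest.mark.parametrize("seed", range(25))
def test_theta_matches_brute_force_oracle_on_random_small_datasets(seed):
    rng = np.random.default_rng(seed)
    n_loci = int(rng.integers(1, 3))
    pops = {}
    genos_by_pop = []
    for k in range(2):
        n = int(rng.integers(2, 10))
        genos = [
            [tuple(sorted(rng.integers(1, 4, size=2))) for _ in range(n_loci)]
            for _ in range(n)
        ]
        pops[f"p{k}"] = genos
        genos_by_pop.append(genos)
    ds = make_dataset(pops)
    theta = pairwise_fst(ds).values[0, 1]
    oracle = _theta_multilocus_oracle(genos_by_pop)
    if math.isnan(oracle):
        assert math.isnan(theta)
    else:
        assert theta == pytest.approx(oracle, abs=1e-12)


def test_theta_toy_example_against_oracle():
    g1 = [[(1, 1)]] * 8 + [[(1, 2)]] * 2
    g2 = [[(1, 1)]] * 2 + [[(2, 2)]] * 8
    ds = make_dataset({"p1": g1, "p2": g2})
    theta = pairwise_fst(ds).values[0, 1]
    assert theta == pytest.approx(
        _wc_oracle_pair([g[0] for g in g1], [g[0] for g in g2]), abs=1e-12)


def test_theta_complete_fixation_is_one():
    ds = make_dataset({"p1": [[(1, 1), (5, 5)]] * 6,
                       "p2": [[(2, 2), (7, 7)]] * 6})
    assert pairwise_fst(ds).values[0, 1] == pytest.approx(1.0)


def test_theta_identical_counts_nonpositive_with_large_p(rng):
    g = [[(1, 1)]] * 5 + [[(2, 2)]] * 5
    ds = make_dataset({"p1": g, "p2": g})
    m = pairwise_fst(ds, n_perm=200, rng=rng)
    assert m.values[0, 1] <= 0
    assert m.p_values[0, 1] > 0.5


def test_theta_small_population_gives_nan_cell():
    ds = make_dataset({"p1": [[(1, 2)]], "p2": [[(1, 1)]] * 4})
    assert np.isnan(pairwise_fst(ds).values[0, 1])


def test_theta_invariant_to_individual_order_and_relabelling(rng):
    genos = [
        [tuple(sorted(rng.integers(1, 5, size=2)))] for _ in range(8)
    ]
    genos2 = [
        [tuple(sorted(rng.integers(1, 5, size=2)))] for _ in range(6)
    ]
    ds = make_dataset({"a": genos, "b": genos2})
    relabelled = make_dataset({
        "a": [[(10 - g[0][0], 10 - g[0][1])] for g in reversed(genos)],
        "b": [[(10 - g[0][0], 10 - g[0][1])] for g in reversed(genos2)],
    })
    assert pairwise_fst(ds).values[0, 1] == pytest.approx(
        pairwise_fst(relabelled).values[0, 1], abs=1e-12)


def test_haploid_theta_fixed_difference():
    aln = make_alignment({"p1": ["AAAA"] * 6, "p2": ["TTTT"] * 6})
    assert pairwise_fst(aln).values[0, 1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# HWE exact test


def _hwe_enumeration_oracle(genotypes):
    """Brute-force: enumerate heterozygote counts for 2 alleles directly."""
    n = len(genotypes)
    na = sum(g.count(1) for g in genotypes)
    nb = 2 * n - na
    obs_het = sum(1 for g in genotypes if g[0] != g[1])

    def log_prob(nab):
        naa = (na - nab) // 2
        nbb = (nb - nab) // 2
        return (nab * math.log(2) + math.lgamma(n + 1)
                - math.lgamma(naa + 1) - math.lgamma(nab + 1)
                - math.lgamma(nbb + 1)
                + math.lgamma(na + 1) + math.lgamma(nb + 1)
                - math.lgamma(2 * n + 1))

    states = [h for h in range(min(na, nb) + 1)
              if (na - h) % 2 == 0 and (nb - h) % 2 == 0]
    lps = {h: log_prob(h) for h in states}
    total = sum(math.exp(v) for v in lps.values())
    p_obs = lps[obs_het]
    return sum(math.exp(v) for v in lps.values() if v <= p_obs + 1e-9) / total


def test_hwe_all_heterozygotes_matches_enumeration_oracle():
    genos = [(1, 2)] * 5
    ds = make_dataset({"p": [[g] for g in genos]})
    res = hwe_exact_test(ds, "p")
    assert res.method["L1"] == "enumeration"
    assert res.per_locus["L1"] == pytest.approx(
        _hwe_enumeration_oracle(genos), abs=1e-12)


def test_hwe_monomorphic_p_is_one_and_fisher_boundary():
    ds = make_dataset({"p": [[(1, 1), (3, 3)]] * 5})
    res = hwe_exact_test(ds, "p")
    assert res.per_locus == {"L1": 1.0, "L2": 1.0}
    assert res.combined_p == pytest.approx(1.0)


def test_hwe_monte_carlo_matches_enumeration():
    rng = np.random.default_rng(0)
    genos = [(1, 2)] * 6 + [(1, 1)] * 3 + [(2, 2)] * 2 + [(2, 3)] * 2
    ds = make_dataset({"p": [[g] for g in genos]})
    exact = hwe_exact_test(ds, "p").per_locus["L1"]
    mc_reps = 8000
    mc = hwe_exact_test(ds, "p", mc_reps=mc_reps, rng=rng,
                        max_tables=1).per_locus["L1"]
    se = math.sqrt(exact * (1 - exact) / mc_reps)
    assert abs(mc - exact) < 3 * se + 2 / mc_reps


# ---------------------------------------------------------------------------
# linkage disequilibrium


def test_ld_self_copy_is_maximally_significant(rng):
    genos = [[tuple(sorted(rng.integers(1, 4, size=2)))] * 2
             for _ in range(12)]
    ds = make_dataset({"p": genos})
    p = ld_test(ds, ("L1", "L2"), n_perm=200, rng=rng)
    assert p <= 2 / 201


def test_ld_monomorphic_pair_p_one(rng):
    ds = make_dataset({"p": [[(1, 1), (2, 3)]] * 8})
    assert ld_test(ds, ("L1", "L2"), n_perm=50, rng=rng) == 1.0


def test_ld_null_p_values_approximately_uniform(rng):
    """Independently simulated biallelic loci (well-populated genotype
    tables): the permutation p is uniform under the null (KS at 0.01)."""
    pvals = []
    for _ in range(200):
        genos = [
            [tuple(sorted(rng.integers(1, 3, size=2))),
             tuple(sorted(rng.integers(1, 3, size=2)))]
            for _ in range(40)
        ]
        ds = make_dataset({"p": genos})
        pvals.append(ld_test(ds, ("L1", "L2"), n_perm=99, rng=rng))
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# mtDNA diversity


def test_mtdna_identical_sequences():
    aln = make_alignment({"bulgaria": ["ACGT" * 20] * 11})
    row = mtdna_diversity(aln).per_population.iloc[0]
    assert row["k"] == 1 and row["hd"] == 0.0 and row["pi"] == 0.0


def test_mtdna_hd_19_to_1_split_is_exactly_point_one():
    seqs = ["A" * 683] * 19 + ["C" + "A" * 682]
    aln = make_alignment({"turkey": seqs})
    row = mtdna_diversity(aln).per_population.iloc[0]
    assert row["hd"] == pytest.approx(0.1)
    assert row["k"] == 2


def test_mtdna_pi_single_difference():
    seqs = ["A" * 683, "C" + "A" * 682] * 6
    aln = make_alignment({"p": seqs})
    row = mtdna_diversity(aln).per_population.iloc[0]
    assert row["pi"] == pytest.approx((36 / 66) / 683)


def test_mtdna_small_samples_suppressed():
    aln = make_alignment({"small": ["ACGT"] * 5})
    row = mtdna_diversity(aln).per_population.iloc[0]
    assert row["k"] == 1 and np.isnan(row["hd"])


def test_mtdna_hd_invariant_to_sequence_order(rng):
    seqs = ["A" * 50] * 12 + ["C" + "A" * 49] * 4
    shuffled = list(seqs)
    rng.shuffle(shuffled)
    a1 = make_alignment({"p": seqs})
    a2 = make_alignment({"p": shuffled})
    assert (mtdna_diversity(a1).per_population["hd"].iloc[0]
            == pytest.approx(mtdna_diversity(a2).per_population["hd"].iloc[0]))


# ---------------------------------------------------------------------------
# Mantel, Holm, founder expectation


def _random_distance_matrix(rng, n=6):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


def test_mantel_affine_relation_r_one(rng):
    m1 = _random_distance_matrix(rng)
    m2 = 2 * m1 + 3
    np.fill_diagonal(m2, 0)
    r, p = mantel_test(m1, m2, n_perm=199, rng=rng)
    assert r == pytest.approx(1.0)
    assert p < 0.05


def test_mantel_negative_relation(rng):
    m1 = _random_distance_matrix(rng)
    m2 = m1.max() + 1 - m1
    np.fill_diagonal(m2, 0)
    r, _ = mantel_test(m1, m2, n_perm=99, rng=rng)
    assert r == pytest.approx(-1.0)


def test_mantel_constant_matrix_undefined(rng):
    m1 = _random_distance_matrix(rng)
    m2 = np.ones_like(m1)
    np.fill_diagonal(m2, 0)
    r, p = mantel_test(m1, m2, n_perm=99, rng=rng)
    assert np.isnan(r) and np.isnan(p)


def test_mantel_null_p_approximately_uniform(rng):
    pvals = [
        mantel_test(_random_distance_matrix(rng, 8),
                    _random_distance_matrix(rng, 8),
                    n_perm=199, rng=rng)[1]
        for _ in range(200)
    ]
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_holm_worked_example():
    assert sequential_bonferroni([0.01, 0.04, 0.03], 0.05) == {0}


def test_holm_edge_cases():
    assert sequential_bonferroni([], 0.05) == set()
    assert sequential_bonferroni([1.0, 1.0, 1.0], 0.05) == set()


@given(st.lists(st.floats(0, 1), max_size=12), st.floats(0.01, 0.2))
def test_holm_rejects_superset_of_plain_bonferroni(pvals, alpha):
    holm = sequential_bonferroni(pvals, alpha)
    bonf = {i for i, p in enumerate(pvals) if p <= alpha / max(len(pvals), 1)}
    assert bonf <= holm


def test_founder_expectation_drift_and_limits():
    assert founder_fst_expectation(7, 1, None) == pytest.approx(1 / 14)
    assert founder_fst_expectation(10**9, 1, None) == pytest.approx(0, abs=1e-8)
    # with sampling only the sampling terms remain at large N
    assert founder_fst_expectation(10**9, 1, (150, 150)) == pytest.approx(
        1 / 150, abs=1e-6)
    assert (founder_fst_expectation(20, 1) < founder_fst_expectation(20, 2)
            < founder_fst_expectation(20, 5))
    with pytest.raises(ValueError):
        founder_fst_expectation(0, 1)


# ---------------------------------------------------------------------------
# summary vector


def test_summary_vector_deterministic_and_named(rng):
    from fallowpop import (PriorSet, SampleConfig, draw_parameters,
                           scenario_catalog, simulate_dataset)

    cat = scenario_catalog()
    params = draw_parameters(PriorSet(), cat[0], rng)
    ds, aln = simulate_dataset(cat[0], params, SampleConfig(), rng)
    v1 = build_summary_vector(ds, aln)
    v2 = build_summary_vector(ds, aln)
    assert v1.names == v2.names
    assert np.array_equal(v1.values, v2.values)
    assert np.isfinite(v1.values).all()


def test_summary_vector_monomorphic_conventions():
    ds = make_dataset({"a": [[(92, 92)]] * 4, "b": [[(92, 92)]] * 4})
    v = build_summary_vector(ds).as_series()
    assert v["msat.a.mean_A"] == 1.0
    assert v["msat.a.mean_He"] == 0.0
    assert v["msat.a-b.fst"] == 0.0


def test_summary_vector_missing_population_errors():
    ds = make_dataset({"a": [[(92, 92)]] * 4})
    with pytest.raises(ValueError, match="ghost"):
        build_summary_vector(ds, pops=["ghost"])


def test_summary_vector_consistent_with_msat_diversity(rng):
    from fallowpop import (PriorSet, SampleConfig, draw_parameters,
                           scenario_catalog, simulate_dataset)

    cat = scenario_catalog()
    params = draw_parameters(PriorSet(), cat[0], rng)
    ds, _ = simulate_dataset(cat[0], params, SampleConfig(), rng)
    v = build_summary_vector(ds).as_series()
    div = msat_diversity(ds, hwe=False).per_population.set_index("population")
    for pop in ds.populations:
        assert v[f"msat.{pop}.mean_A"] == pytest.approx(
            div.loc[pop, "mean_A"])
        assert v[f"msat.{pop}.mean_He"] == pytest.approx(div.loc[pop, "He"])
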