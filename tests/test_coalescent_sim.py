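"""Scenario catalogue, prior draws, and coalescent moment checks."""

import numpy as np
import pytest

from fallowpop.coalescent_sim import (
    LEAVES,
    ParameterDraw,
    PriorSet,
    SampleConfig,
    draw_parameters,
    scenario_catalog,
    simulate_genealogies,
    simulate_dataset,
    apply_msat_mutations,
    apply_sequence_mutations,
)
from fallowpop.popgen_stats import pairwise_fst


def _params(sizes, tb, t=None, msat_rate=5e-4, mt_rate=1e-6, scenario_id=1):
    return ParameterDraw(
        scenario_id=scenario_id,
        sizes=dict(sizes),
        t=t,
        tb=tb,
        msat_locus_rates=np.full(10, msat_rate),
        mtdna_rate=mt_rate,
    )


EQ_SIZES = {"iberia": 500.0, "italia": 500.0, "anatolia": 500.0,
            "ancestral": 500.0}


# ---------------------------------------------------------------------------
# catalogue and priors


def test_catalog_has_seven_scenarios_with_expected_shapes():
    cat = scenario_catalog()
    assert len(cat) == 7
    assert [s.scenario_id for s in cat] == list(range(1, 8))
    assert cat[0].is_trifurcation
    assert cat[0].recent_split is None
    for s in cat[1:]:
        assert not s.is_trifurcation
        assert s.recent_split is not None
    # the six nested scenarios cover all ordered (derived, source) pairs
    pairs = {s.recent_split for s in cat[1:]}
    assert len(pairs) == 6


def test_draws_respect_bounds_and_constraint(rng):
    priors = PriorSet()
    cat = scenario_catalog()
    for _ in range(300):
        s = cat[rng.integers(7)]
        d = draw_parameters(priors, s, rng)
        for v in d.sizes.values():
            assert priors.ne_bounds[0] <= v <= priors.ne_bounds[1]
        assert priors.tb_bounds[0] <= d.tb <= priors.tb_bounds[1]
        if s.is_trifurcation:
            assert d.t is None
        else:
            assert d.t < d.tb
        assert (d.msat_locus_rates > 0).all()


def test_draw_coverage_spans_prior_box():
    priors = PriorSet()
    rng = np.random.default_rng(0)
    spec = scenario_catalog()[0]
    tbs = np.array([draw_parameters(priors, spec, rng).tb
                    for _ in range(10_000)])
    lo, hi = priors.tb_bounds
    assert tbs.min() < lo + 0.05 * (hi - lo)
    assert tbs.max() > hi - 0.05 * (hi - lo)


def test_same_seed_same_draws():
    priors = PriorSet()
    spec = scenario_catalog()[3]
    d1 = draw_parameters(priors, spec, np.random.default_rng(9))
    d2 = draw_parameters(priors, spec, np.random.default_rng(9))
    assert d1.sizes == d2.sizes and d1.t == d2.t and d1.tb == d2.tb


def test_generation_time_converts_years_to_generations():
    priors = PriorSet(generation_time_years=5.9)
    spec = scenario_catalog()[0]
    rng1, rng2 = np.random.default_rng(4), np.random.default_rng(4)
    d59 = draw_parameters(priors, spec, rng1)
    d1 = draw_parameters(PriorSet(), spec, rng2)
    assert d59.tb == pytest.approx(d1.tb / 5.9)


def test_impossible_prior_constraint_errors(rng):
    priors = PriorSet(t_bounds=(60_000.0, 70_000.0))
    with pytest.raises(ValueError):
        draw_parameters(priors, scenario_catalog()[1], rng)


# ---------------------------------------------------------------------------
# genealogy moments


def test_pairwise_tmrca_matches_kingman_expectation(rng):
    """E[T2] = 2 Ne generations for two lineages in one population."""
    ne = 200.0
    params = _params({**EQ_SIZES, "iberia": ne}, tb=10**7)
    spec = scenario_catalog()[0]
    samples = SampleConfig(msat_samples={"iberia": 1, "italia": 0,
                                         "anatolia": 0},
                           mtdna_samples={"iberia": 0, "italia": 0,
                                          "anatolia": 0},
                           n_loci=1)
    tmrcas = []
    for _ in range(4000):
        gen = simulate_genealogies(spec, params, samples, rng)
        t = gen["msat"][0].first()
        tmrcas.append(t.time(t.root))
    tmrcas = np.asarray(tmrcas)
    se = tmrcas.std() / np.sqrt(len(tmrcas))
    assert abs(tmrcas.mean() - 2 * ne) < 3 * se


def test_mtdna_tmrca_matches_quarter_scaling(rng):
    """Haploid mtDNA with the default Ne/4 scaling: E[T2] = Ne/2."""
    ne = 400.0
    params = _params({**EQ_SIZES, "italia": ne}, tb=10**7)
    spec = scenario_catalog()[0]
    samples = SampleConfig(msat_samples={"iberia": 1, "italia": 0,
                                         "anatolia": 0},
                           mtdna_samples={"iberia": 0, "italia": 2,
                                          "anatolia": 0},
                           n_loci=1, seq_length=10)
    tmrcas = []
    for _ in range(3000):
        gen = simulate_genealogies(spec, params, samples, rng)
        t = gen["mtdna"].first()
        tmrcas.append(t.time(t.root))
    tmrcas = np.asarray(tmrcas)
    se = tmrcas.std() / np.sqrt(len(tmrcas))
    assert abs(tmrcas.mean() - ne / 2) < 3 * se


def test_no_cross_population_coalescence_before_split(rng):
    params = _params(EQ_SIZES, tb=5000.0)
    spec = scenario_catalog()[0]
    samples = SampleConfig(msat_samples={"iberia": 2, "italia": 2,
                                         "anatolia": 2},
                           mtdna_samples={"iberia": 0, "italia": 0,
                                          "anatolia": 0},
                           n_loci=2)
    for _ in range(40):
        gen = simulate_genealogies(spec, params, samples, rng)
        for ts in gen["msat"]:
            tree = ts.first()
            pops = ts.tables.nodes.population
            for u in tree.nodes():
                if tree.is_internal(u) and tree.time(u) < params.tb:
                    leaf_pops = {pops[v] for v in tree.leaves(u)}
                    assert len(leaf_pops) == 1


# ---------------------------------------------------------------------------
# mutation overlays


def test_zero_rate_leaves_everything_monomorphic(rng):
    params = _params(EQ_SIZES, tb=1000.0, msat_rate=0.0, mt_rate=0.0)
    spec = scenario_catalog()[0]
    samples = SampleConfig()
    ds, aln = simulate_dataset(spec, params, samples, rng)
    assert (ds.alleles == samples.ancestral_allele).all()
    assert len(set(aln.sequences)) == 1


def test_smm_steps_are_plus_minus_one(rng):
    params = _params(EQ_SIZES, tb=1000.0, msat_rate=5e-3)
    spec = scenario_catalog()[0]
    samples = SampleConfig(n_loci=1)
    gen = simulate_genealogies(spec, params, samples, rng)
    ts = gen["msat"][0]
    vals = apply_msat_mutations(ts, 0.005, model="SMM", rng=rng)
    # allele sizes are integers around the ancestral state
    assert vals.dtype.kind == "i"
    assert np.abs(vals - 200).max() < 200


def test_negative_rate_rejected(rng):
    params = _params(EQ_SIZES, tb=1000.0)
    spec = scenario_catalog()[0]
    gen = simulate_genealogies(spec, params, SampleConfig(n_loci=1), rng)
    with pytest.raises(ValueError):
        apply_msat_mutations(gen["msat"][0], -1.0, rng=rng)
    with pytest.raises(ValueError):
        apply_sequence_mutations(gen["mtdna"], -1.0, rng=rng)


def test_delta_mu_squared_grows_as_2_mu_t(rng):
    """Mean (δμ)² between two populations split T generations ago is 2μT."""
    mu, T = 1e-3, 3000.0
    params = _params(EQ_SIZES, tb=T, msat_rate=mu)
    spec = scenario_catalog()[0]
    samples = SampleConfig(msat_samples={"iberia": 25, "italia": 25,
                                         "anatolia": 0},
                           mtdna_samples={"iberia": 0, "italia": 0,
                                          "anatolia": 0},
                           n_loci=10)
    vals = []
    for _ in range(400):
        gen = simulate_genealogies(spec, params, samples, rng)
        for ts in gen["msat"]:
            sizes = apply_msat_mutations(ts, mu, rng=rng)
            pops = ts.tables.nodes.population[ts.samples()]
            m0 = sizes[pops == pops[0]].mean()
            m1 = sizes[pops != pops[0]].mean()
            vals.append((m0 - m1) ** 2)
    vals = np.asarray(vals)
    # with large samples the finite-sample term is negligible: E = 2μT
    se = vals.std() / np.sqrt(len(vals))
    assert abs(vals.mean() - 2 * mu * T) < 3 * se + 0.02 * 2 * mu * T


def test_watterson_segregating_sites(rng):
    """E[S] = θ_locus Σ 1/i with θ from the haploid mtDNA scaling."""
    ne, mu, L, n = 800.0, 5e-6, 500, 8
    params = _params({**EQ_SIZES, "anatolia": ne}, tb=10**7, mt_rate=mu)
    spec = scenario_catalog()[0]
    samples = SampleConfig(msat_samples={"iberia": 1, "italia": 0,
                                         "anatolia": 0},
                           mtdna_samples={"iberia": 0, "italia": 0,
                                          "anatolia": n},
                           n_loci=1, seq_length=L)
    counts = []
    for _ in range(600):
        gen = simulate_genealogies(spec, params, samples, rng)
        seqs = apply_sequence_mutations(gen["mtdna"], mu, L, rng)
        arr = np.array([list(s) for s in seqs])
        counts.append(int((~(arr == arr[0]).all(axis=0)).sum()))
    counts = np.asarray(counts)
    # haploid effective copies = Ne/2, so per-site θ = 2 (Ne/2) μ ... E[S]
    theta_locus = 2 * (ne / 2) * mu * L
    expected = theta_locus * sum(1 / i for i in range(1, n))
    se = counts.std() / np.sqrt(len(counts))
    assert abs(counts.mean() - expected) < 3 * se + 0.05 * expected


def test_jc_saturation_stays_below_three_quarters(rng):
    params = _params(EQ_SIZES, tb=50_000.0, mt_rate=5e-3)
    spec = scenario_catalog()[0]
    samples = SampleConfig(mtdna_samples={"iberia": 5, "italia": 5,
                                          "anatolia": 5}, seq_length=683)
    _, aln = simulate_dataset(spec, params, samples, rng)
    arr = np.array([list(s) for s in aln.sequences])
    d01 = (arr[0] != arr[10]).mean()
    assert 0.3 < d01 < 0.78


# ---------------------------------------------------------------------------
# full datasets


def test_simulated_dataset_shapes_match_config(rng):
    params = _params(EQ_SIZES, tb=2000.0)
    spec = scenario_catalog()[0]
    samples = SampleConfig()
    ds, aln = simulate_dataset(spec, params, samples, rng)
    assert ds.n_individuals == sum(samples.msat_samples.values())
    assert ds.n_loci == samples.n_loci
    assert {len(ds.members(p)) for p in LEAVES} == {26, 21, 24}
    assert aln.n_sequences == sum(samples.mtdna_samples.values())
    assert aln.length == samples.seq_length


def test_same_seed_bit_identical_dataset():
    params = _params(EQ_SIZES, tb=2000.0, scenario_id=3)
    spec = scenario_catalog()[2]
    params2 = _params(EQ_SIZES, tb=2000.0, scenario_id=3)
    params2.t = params.t = 500.0
    d1, a1 = simulate_dataset(spec, params, SampleConfig(),
                              np.random.default_rng(77))
    d2, a2 = simulate_dataset(spec, params2, SampleConfig(),
                              np.random.default_rng(77))
    assert d1 == d2
    assert a1.sequences == a2.sequences


def test_panmixia_limit_mean_fst_near_zero(rng):
    """With the split at its lower bound and equal sizes, pairwise θ
    averages to ~0 across replicates."""
    params = _params(EQ_SIZES, tb=10.0, msat_rate=1e-3)
    spec = scenario_catalog()[0]
    samples = SampleConfig(mtdna_samples={"iberia": 0, "italia": 0,
                                          "anatolia": 0})
    thetas = []
    for _ in range(100):
        ds, _ = simulate_dataset(spec, params, samples, rng)
        m = pairwise_fst(ds)
        thetas.append(np.nanmean(m.values[np.triu_indices(3, 1)]))
    assert abs(np.nanmean(thetas)) < 0.02


def test_fst_increases_with_split_time(rng):
    spec = scenario_catalog()[0]
    samples = SampleConfig(mtdna_samples={"iberia": 0, "italia": 0,
                                          "anatolia": 0})
    means = []
    for tb in (50.0, 500.0, 5000.0):
        params = _params(EQ_SIZES, tb=tb, msat_rate=1e-3)
        vals = []
        for _ in range(30):
            ds, _ = simulate_dataset(spec, params, samples, rng)
            vals.append(np.nanmean(pairwise_fst(ds).values[
                np.triu_indices(3, 1)]))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
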