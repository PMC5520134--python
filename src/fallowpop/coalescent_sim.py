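"""Backward-in-time simulation of three-refugium divergence scenarios.

Seven scenarios relate the refugial populations of Iberia, Italy and
Anatolia: one trifurcation at time Tb, and six nested topologies in which
one population derives from another at a recent time t inside an older
split at Tb.  Genealogies are simulated with msprime (Kingman coalescent
with population splits); microsatellite mutations (stepwise or generalized
stepwise) are overlaid on the returned trees in this module, and mtDNA
sequences use msprime's finite-sites Jukes–Cantor model.

Times are handled in generations internally; priors are expressed in years
and converted with the configured generation time (default 1 year, the
published alternative being 5.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .core_io import GenotypeDataset, HaplotypeAlignment, detect_indel_blocks

LEAVES = ("iberia", "italia", "anatolia")

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class ScenarioSpec:
    """One divergence topology.

    ``events`` lists ``(time_symbol, derived, source)`` merges viewed
    backwards in time; ``time_symbol`` is ``"t"`` (recent split) or ``"Tb"``
    (old split).  Scenario 1 is the trifurcation: all three leaves merge
    into the ancestral population at Tb.
    """

    scenario_id: int
    events: tuple[tuple[str, str, str], ...]
    description: str = ""

    @property
    def leaves(self) -> tuple[str, ...]:
        return LEAVES

    @property
    def is_trifurcation(self) -> bool:
        return all(sym == "Tb" for sym, _, _ in self.events)

    @property
    def recent_split(self) -> tuple[str, str] | None:
        for sym, derived, source in self.events:
            if sym == "t":
                return (derived, source)
        return None


def scenario_catalog() -> list[ScenarioSpec]:
    """The seven candidate scenarios (trifurcation + six nested splits)."""
    def nested(sid: int, derived: str, source: str, desc: str) -> ScenarioSpec:
        other = next(l for l in LEAVES if l not in (derived, source))
        return ScenarioSpec(
            sid,
            (
                ("t", derived, source),
                ("Tb", source, "ancestral"),
                ("Tb", other, "ancestral"),
            ),
            desc,
        )

    return [
        ScenarioSpec(
            1,
            tuple(("Tb", leaf, "ancestral") for leaf in LEAVES),
            "all three populations diverged at the same time",
        ),
        nested(2, "iberia", "italia",
               "Iberia derived from Italy after Italy diverged from Anatolia"),
        nested(3, "iberia", "anatolia",
               "Iberia derived from Anatolia after Anatolia diverged from Italy"),
        nested(4, "anatolia", "italia",
               "Anatolia derived from Italy after Italy diverged from Iberia"),
        nested(5, "anatolia", "iberia",
               "Anatolia derived from Iberia after Iberia diverged from Italy"),
        nested(6, "italia", "anatolia",
               "Italy derived from Anatolia after Anatolia diverged from Iberia"),
        nested(7, "italia", "iberia",
               "Italy derived from Iberia after Iberia diverged from Anatolia"),
    ]


@dataclass
class PriorSet:
    """Flat priors on effective sizes and split times (years), plus mutation
    rate priors.  The microsatellite prior is uniform on the stated bounds;
    per-locus rates scatter around the drawn mean as Gamma(shape)."""

    ne_bounds: tuple[float, float] = (10.0, 10_000.0)
    t_bounds: tuple[float, float] = (10.0, 10_000.0)
    tb_bounds: tuple[float, float] = (10.0, 50_000.0)
    msat_rate_bounds: tuple[float, float] = (1e-5, 1e-2)
    mtdna_rate_bounds: tuple[float, float] = (1e-8, 1e-5)
    msat_rate_shape: float = 2.0
    generation_time_years: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi in (self.ne_bounds, self.t_bounds, self.tb_bounds,
                       self.msat_rate_bounds, self.mtdna_rate_bounds):
            if not lo < hi:
                raise ValueError("prior bounds must satisfy lower < upper")
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be positive")


@dataclass
class ParameterDraw:
    """One sampled parameter vector.  Sizes are diploid effective sizes;
    times are in generations (already converted from the year-based prior)."""

    scenario_id: int
    sizes: dict[str, float]          # leaf name -> Ne, plus "ancestral"
    t: float | None                  # recent split, generations
    tb: float                        # old split, generations
    msat_locus_rates: np.ndarray     # per-locus, per-generation
    mtdna_rate: float                # per-site per-generation
    generation_time_years: float = 1.0

    def as_record(self) -> dict[str, float]:
        rec = {
            "scenario_id": self.scenario_id,
            "n_iberia": self.sizes["iberia"],
            "n_italia": self.sizes["italia"],
            "n_anatolia": self.sizes["anatolia"],
            "n_ancestral": self.sizes["ancestral"],
            "t": np.nan if self.t is None else self.t,
            "tb": self.tb,
            "mean_msat_rate": float(np.mean(self.msat_locus_rates)),
            "mtdna_rate": self.mtdna_rate,
        }
        return rec


@dataclass
class SampleConfig:
    """Sampling design: diploids per population for microsatellites, haploid
    sequences for mtDNA.  Defaults follow the southern-refugium design
    (Iberia 26, Italy 21, Anatolia 24 diploids; 19/30/20 sequences)."""

    msat_samples: dict[str, int] = field(
        default_factory=lambda: {"iberia": 26, "italia": 21, "anatolia": 24})
    mtdna_samples: dict[str, int] = field(
        default_factory=lambda: {"iberia": 19, "italia": 30, "anatolia": 20})
    n_loci: int = 10
    seq_length: int = 683
    ancestral_allele: int = 200
    mtdna_scale: float = 0.25        # mtDNA effective size as fraction of Ne
    msat_model: str = "SMM"
    gsm_p: float = 0.5               # geometric step parameter for GSM

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.msat_samples.values()):
            raise ValueError("sample sizes must be non-negative")
        if all(v == 0 for v in self.msat_samples.values()):
            raise ValueError("at least one population must be sampled")
        if self.n_loci < 1 or self.seq_length < 1:
            raise ValueError("need at least one locus and one site")


def draw_parameters(priors: PriorSet, scenario: ScenarioSpec,
                    rng: np.random.Generator,
                    n_loci: int = 10) -> ParameterDraw:
    """Sample one parameter vector from the priors.

    For nested scenarios the (t, Tb) pair is redrawn jointly until t < Tb;
    per-locus microsatellite rates are Gamma-distributed around the drawn
    mean rate.
    """
    g = priors.generation_time_years
    sizes = {name: rng.uniform(*priors.ne_bounds)
             for name in (*LEAVES, "ancestral")}
    if scenario.is_trifurcation:
        t = None
        tb = rng.uniform(*priors.tb_bounds)
    else:
        if priors.t_bounds[0] >= priors.tb_bounds[1]:
            raise ValueError("t prior cannot lie below the Tb prior")
        while True:
            t = rng.uniform(*priors.t_bounds)
            tb = rng.uniform(*priors.tb_bounds)
            if t < tb:
                break
    mean_rate = rng.uniform(*priors.msat_rate_bounds)
    shape = priors.msat_rate_shape
    locus_rates = rng.gamma(shape, mean_rate / shape, size=n_loci)
    mt_lo, mt_hi = priors.mtdna_rate_bounds
    mt_rate = np.exp(rng.uniform(np.log(mt_lo), np.log(mt_hi)))
    return ParameterDraw(
        scenario_id=scenario.scenario_id,
        sizes=sizes,
        t=None if t is None else t / g,
        tb=tb / g,
        msat_locus_rates=locus_rates * g,
        mtdna_rate=mt_rate * g,
        generation_time_years=g,
    )


# ---------------------------------------------------------------------------
# demography and genealogies


def _demography(scenario: ScenarioSpec, params: ParameterDraw,
                size_factor: float = 1.0) -> msprime.Demography:
    dem = msprime.Demography()
    for name in LEAVES:
        dem.add_population(name=name,
                           initial_size=params.sizes[name] * size_factor)
    dem.add_population(name="ancestral",
                       initial_size=params.sizes["ancestral"] * size_factor)
    if scenario.is_trifurcation:
        dem.add_population_split(time=params.tb, derived=list(LEAVES),
                                 ancestral="ancestral")
    else:
        derived, source = scenario.recent_split
        other = next(l for l in LEAVES if l not in (derived, source))
        if params.t is None or not params.t < params.tb:
            raise ValueError("nested scenario requires t < Tb")
        dem.add_population_split(time=params.t, derived=[derived],
                                 ancestral=source)
        dem.add_population_split(time=params.tb, derived=[source, other],
                                 ancestral="ancestral")
    dem.sort_events()
    return dem


def _seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_genealogies(scenario: ScenarioSpec, params: ParameterDraw,
                         samples: SampleConfig,
                         rng: np.random.Generator) -> dict:
    """Simulate per-locus genealogies: one single-tree replicate per
    microsatellite locus (diploid) and one mtDNA tree sequence (haploid,
    effective size ``2 * mtdna_scale * Ne`` gene copies, i.e. E[T2] = Ne/2
    at the default scale)."""
    dem = _demography(scenario, params)
    msat_samples = {k: v for k, v in samples.msat_samples.items() if v > 0}
    mt_samples = {k: v for k, v in samples.mtdna_samples.items() if v > 0}
    msat = list(msprime.sim_ancestry(
        samples=msat_samples, demography=dem, ploidy=2,
        sequence_length=1, discrete_genome=True,
        num_replicates=samples.n_loci, random_seed=_seed(rng),
    ))
    if mt_samples:
        dem_mt = _demography(scenario, params,
                             size_factor=2.0 * samples.mtdna_scale)
        mtdna = msprime.sim_ancestry(
            samples=mt_samples, demography=dem_mt, ploidy=1,
            sequence_length=samples.seq_length, discrete_genome=True,
            random_seed=_seed(rng),
        )
    else:
        mtdna = None
    return {"msat": msat, "mtdna": mtdna}


# ---------------------------------------------------------------------------
# mutation overlays


def apply_msat_mutations(ts, rate: float, model: str = "SMM",
                         rng: np.random.Generator | None = None,
                         ancestral: int = 200,
                         gsm_p: float = 0.5) -> np.ndarray:
    """Drop stepwise mutations on a single-tree genealogy.

    Mutation counts are Poisson(rate x branch length) per branch; under SMM
    each mutation steps the repeat size by ±1 with equal probability, under
    GSM by a geometric(p) number of repeats.  Returns allele sizes for the
    tree's sample nodes, in sample order.
    """
    if rate < 0:
        raise ValueError("mutation rate must be non-negative")
    rng = np.random.default_rng(0) if rng is None else rng
    if model not in ("SMM", "GSM"):
        raise ValueError(f"unknown microsatellite model {model!r}")
    tables = ts.tables
    parent = tables.edges.parent
    child = tables.edges.child
    blen = tables.nodes.time[parent] - tables.nodes.time[child]
    k = rng.poisson(rate * blen)
    if model == "SMM":
        up = rng.binomial(k, 0.5)
        delta = 2 * up - k
    else:
        delta = np.zeros(k.size, dtype=np.int64)
        hot = np.flatnonzero(k)
        for e in hot:
            steps = rng.geometric(gsm_p, size=k[e])
            signs = rng.choice((-1, 1), size=k[e])
            delta[e] = int(np.sum(steps * signs))
    disp = np.zeros(ts.num_nodes, dtype=np.int64)
    order = np.argsort(-tables.nodes.time[child], kind="stable")
    for e in order:
        disp[child[e]] = disp[parent[e]] + delta[e]
    return ancestral + disp[ts.samples()]


def apply_sequence_mutations(ts, rate: float, length: int | None = None,
                             rng: np.random.Generator | None = None
                             ) -> list[str]:
    """Finite-sites Jukes–Cantor mutations over the tree sequence; returns
    one sequence string per sample.  Invariant sites take a random uniform
    ancestral base."""
    if rate < 0:
        raise ValueError("mutation rate must be non-negative")
    rng = np.random.default_rng(0) if rng is None else rng
    L = int(ts.sequence_length if length is None else length)
    mts = msprime.sim_mutations(ts, rate=rate, model=msprime.JC69(),
                                random_seed=_seed(rng))
    n = mts.num_samples
    seqs = _BASES[rng.integers(0, 4, size=L)]
    out = np.tile(seqs, (n, 1))
    for var in mts.variants():
        pos = int(var.site.position)
        alleles = np.array(var.alleles)
        out[:, pos] = alleles[var.genotypes]
    return ["".join(row) for row in out]


# ---------------------------------------------------------------------------
# full dataset simulation


def simulate_dataset(scenario: ScenarioSpec, params: ParameterDraw,
                     samples: SampleConfig,
                     rng: np.random.Generator
                     ) -> tuple[GenotypeDataset, HaplotypeAlignment]:
    """Simulate one complete dataset (microsatellite genotypes + mtDNA
    alignment) under a scenario and parameter draw; bit-reproducible for a
    given generator state."""
    gen = simulate_genealogies(scenario, params, samples, rng)

    pop_order = [p for p in LEAVES if samples.msat_samples.get(p, 0) > 0]
    first = gen["msat"][0]
    pop_names = {p.id: p.metadata.get("name", str(p.id))
                 for p in first.populations()}
    snodes = first.samples()
    node_ind = first.tables.nodes.individual[snodes]
    node_pop = first.tables.nodes.population[snodes]
    # sample nodes come in consecutive pairs per diploid individual
    assert (node_ind.reshape(-1, 2)[:, 0] == node_ind.reshape(-1, 2)[:, 1]).all()
    ind_pops = [pop_names[p] for p in node_pop.reshape(-1, 2)[:, 0]]

    n_ind = first.num_individuals
    alleles = np.empty((n_ind, samples.n_loci, 2), dtype=np.int32)
    for l, ts in enumerate(gen["msat"]):
        vals = apply_msat_mutations(
            ts, params.msat_locus_rates[l % len(params.msat_locus_rates)],
            model=samples.msat_model, rng=rng,
            ancestral=samples.ancestral_allele, gsm_p=samples.gsm_p)
        alleles[node_ind.reshape(-1, 2)[:, 0], l, :] = vals.reshape(-1, 2)

    counters: dict[str, int] = {}
    ids = []
    for pop in ind_pops:
        counters[pop] = counters.get(pop, 0) + 1
        ids.append(f"{pop}_{counters[pop]}")
    dataset = GenotypeDataset(
        individual_ids=ids,
        population_of=dict(zip(ids, ind_pops)),
        loci=[f"L{l + 1}" for l in range(samples.n_loci)],
        alleles=alleles,
    )
    # keep stated population order stable regardless of msprime internals
    dataset = dataset.subset([p for p in pop_order if p in set(ind_pops)])

    mts = gen["mtdna"]
    if mts is None:
        return dataset, None
    seqs = apply_sequence_mutations(mts, params.mtdna_rate,
                                    samples.seq_length, rng)
    mt_popnames = {p.id: p.metadata.get("name", str(p.id))
                   for p in mts.populations()}
    records = []
    counters = {}
    for node, seq in zip(mts.samples(), seqs):
        pop = mt_popnames[mts.node(node).population]
        counters[pop] = counters.get(pop, 0) + 1
        records.append((f"{pop}_mt{counters[pop]}", pop, seq))
    records.sort(key=lambda r: pop_order.index(r[1])
                 if r[1] in pop_order else len(pop_order))
    sids = [r[0] for r in records]
    spops = {r[0]: r[1] for r in records}
    seq_list = [r[2] for r in records]
    alignment = HaplotypeAlignment(
        sequence_ids=sids, population_of=spops, sequences=seq_list,
        indel_blocks=detect_indel_blocks(seq_list),
    )
    return dataset, alignment
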