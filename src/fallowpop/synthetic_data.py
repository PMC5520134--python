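"""Study-shaped synthetic datasets: refugial sources plus founder events.

The generator emulates the shape of the European fallow deer survey: 24
sampling sites totalling 364 diploids typed at 10 microsatellites, with an
mtDNA alignment, very low within-site diversity and extreme differentiation.
Three refugial source populations (Iberia, Italy, Anatolia) are simulated
backwards in time under one of the divergence scenarios; each sampling site
is then derived forwards by one or more founder events — a small draw of
diploids followed by Wright–Fisher drift at that size — reproducing the
drift signature of translocated, park-founded populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .coalescent_sim import (
    ParameterDraw,
    PriorSet,
    SampleConfig,
    ScenarioSpec,
    draw_parameters,
    scenario_catalog,
    simulate_dataset,
)
from .core_io import (
    GenotypeDataset,
    HaplotypeAlignment,
    PopulationTable,
    detect_indel_blocks,
)

#: default founder schedules by site class: (n_founders, n_generations)
#: applied in sequence.  Southern refugial sites sit close to their source;
#: northern translocated sites went through harder, repeated founding.
DEFAULT_SCHEDULES = {
    "iberia": [(15, 12)],
    "italia": [(18, 12)],
    "anatolia": [(12, 12)],
    "northern": [(10, 8), (8, 10)],
}


def default_parameters(scenario: ScenarioSpec) -> ParameterDraw:
    """Realistic base parameters for the three-refugium history: effective
    sizes of order 10^3 (Italy largest, the ancestral population smallest),
    a late-Pleistocene/early-Holocene split, and a mean microsatellite rate
    of 2.1e-4 with an mtDNA control-region rate of 2.9e-7 per site."""
    rates = np.full(10, 2.1e-4)
    return ParameterDraw(
        scenario_id=scenario.scenario_id,
        sizes={"iberia": 1060.0, "italia": 4190.0, "anatolia": 1800.0,
               "ancestral": 987.0},
        t=None if scenario.is_trifurcation else 5720.0,
        tb=12_700.0,
        msat_locus_rates=rates,
        mtdna_rate=2.93e-7,
        generation_time_years=1.0,
    )


@dataclass
class FixtureConfig:
    """Layout and demography of a study-shaped fixture.

    The default layout is the 24-site survey table shipped with the package
    (sums to 364 diploids); ``schedules`` maps a site region class to its
    founder-event sequence.
    """

    layout: PopulationTable = field(default_factory=PopulationTable.study_sites)
    n_loci: int = 10
    mtdna_length: int = 683
    scenario_id: int = 1
    parameters: ParameterDraw | None = None
    schedules: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {k: list(v) for k, v in
                                 DEFAULT_SCHEDULES.items()})
    source_pool: int = 150           # diploids sampled per refugial source
    mtdna_fraction: float = 1.0      # fraction of individuals sequenced
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.layout.table["sample_size"]
        if (sizes <= 0).any():
            raise ValueError("site sample sizes must be positive")
        regions = set(self.layout.table["region"])
        missing = regions - set(self.schedules)
        if missing:
            raise ValueError(f"no founder schedule for regions {missing}")


@dataclass
class GroundTruth:
    """Everything needed to regenerate a fixture or pseudo-observed dataset
    bit-for-bit."""

    scenario_id: int
    parameters: ParameterDraw
    founder_history: dict[str, list[tuple[int, int]]]
    seed: int


# ---------------------------------------------------------------------------
# forward founder events


def forward_founder_event(genotypes: np.ndarray, n_founders: int,
                          n_generations: int,
                          rng: np.random.Generator,
                          out_size: int | None = None) -> np.ndarray:
    """Push a population of diploid genotypes through a founder event.

    ``n_founders`` diploids are sampled without replacement — that draw is
    the first generation spent at the bottleneck size — followed by
    ``n_generations - 1`` further Wright–Fisher resamplings of
    2 x n_founders gene copies per locus; the output population of
    ``out_size`` diploids is then drawn from the final allele frequencies
    under random mating (instant expansion).  With ``n_generations=0`` the
    draw is a pure subsample.  Loci are independent (no linkage).
    """
    if n_founders < 1:
        raise ValueError("n_founders must be at least 1")
    n_src, n_loci, _ = genotypes.shape
    if n_founders > n_src:
        raise ValueError(
            f"founder draw of {n_founders} exceeds source pool of {n_src}"
        )
    out_size = n_src if out_size is None else int(out_size)
    founders = genotypes[rng.choice(n_src, size=n_founders, replace=False)]
    out = np.empty((out_size, n_loci, 2), dtype=genotypes.dtype)
    m = 2 * n_founders
    for l in range(n_loci):
        copies = founders[:, l, :].ravel()
        if n_generations == 0 and out_size == n_src and n_founders == n_src:
            out[:, l, :] = founders[:, l, :]
            continue
        vals, counts = np.unique(copies, return_counts=True)
        freqs = counts / m
        for _ in range(max(0, n_generations - 1)):
            counts = rng.multinomial(m, freqs)
            keep = counts > 0
            vals, counts = vals[keep], counts[keep]
            freqs = counts / counts.sum()
        draw = rng.choice(vals, size=(out_size, 2), p=freqs)
        out[:, l, :] = draw
    return out


def forward_founder_event_haploid(seq_indices: np.ndarray, n_founders: int,
                                  n_generations: int,
                                  rng: np.random.Generator,
                                  out_size: int) -> np.ndarray:
    """Maternal-lineage analogue on haplotype class indices; the founder
    count is the number of female lineages."""
    if n_founders < 1:
        raise ValueError("n_founders must be at least 1")
    if n_founders > seq_indices.size:
        raise ValueError("founder draw exceeds source pool")
    lineages = rng.choice(seq_indices, size=n_founders, replace=False)
    vals, counts = np.unique(lineages, return_counts=True)
    freqs = counts / counts.sum()
    for _ in range(max(0, n_generations - 1)):
        counts = rng.multinomial(n_founders, freqs)
        keep = counts > 0
        vals, counts = vals[keep], counts[keep]
        freqs = counts / counts.sum()
    return rng.choice(vals, size=out_size, p=freqs)


# ---------------------------------------------------------------------------
# fixtures


def generate_study_fixture(config: FixtureConfig | None = None
                           ) -> tuple[GenotypeDataset, HaplotypeAlignment,
                                      GroundTruth]:
    """Generate a full study-shaped fixture.

    Source populations are simulated under the configured scenario; each
    site in the layout is founded from its source region's sample pool
    according to its founder schedule and expanded to the tabulated sample
    size.  Deterministic in ``config.seed``.
    """
    config = FixtureConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    scenario = scenario_catalog()[config.scenario_id - 1]
    params = (default_parameters(scenario) if config.parameters is None
              else config.parameters)
    params = replace(params, msat_locus_rates=np.resize(
        np.asarray(params.msat_locus_rates, dtype=float), config.n_loci))

    pool = config.source_pool
    samples = SampleConfig(
        msat_samples={"iberia": pool, "italia": pool, "anatolia": pool},
        mtdna_samples={"iberia": pool, "italia": pool, "anatolia": pool},
        n_loci=config.n_loci,
        seq_length=config.mtdna_length,
    )
    src_geno, src_aln = simulate_dataset(scenario, params, samples, rng)

    src_alleles = {r: src_geno.alleles[src_geno.members(r)]
                   for r in ("iberia", "italia", "anatolia")}
    seq_arr = np.array(src_aln.sequences)
    src_seq_idx = {r: np.array(src_aln.members(r), dtype=np.intp)
                   for r in ("iberia", "italia", "anatolia")}

    ids: list[str] = []
    pops: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    sids: list[str] = []
    spops: dict[str, str] = {}
    site_seqs: list[str] = []
    history: dict[str, list[tuple[int, int]]] = {}

    for row in config.layout.table.itertuples():
        site, region, source = row.name, row.region, row.source
        n_site = int(row.sample_size)
        schedule = config.schedules[region]
        history[site] = list(schedule)

        geno = src_alleles[source]
        for step, (nf, ng) in enumerate(schedule):
            last = step == len(schedule) - 1
            geno = forward_founder_event(
                geno, nf, ng, rng, out_size=n_site if last else max(nf, 60))
        blocks.append(geno)
        for i in range(n_site):
            iid = f"{site}_{i + 1}"
            ids.append(iid)
            pops[iid] = site

        n_mt = max(1, int(round(config.mtdna_fraction * n_site)))
        lineage_idx = src_seq_idx[source]
        for nf, ng in schedule:
            nf_mat = max(1, math.ceil(nf / 2))
            lineage_idx = forward_founder_event_haploid(
                lineage_idx, min(nf_mat, lineage_idx.size), ng, rng,
                out_size=max(nf_mat, 40))
        final = forward_founder_event_haploid(
            lineage_idx, min(lineage_idx.size, lineage_idx.size), 0, rng,
            out_size=n_mt)
        for j, src_i in enumerate(final):
            sid = f"{site}_mt{j + 1}"
            sids.append(sid)
            spops[sid] = site
            site_seqs.append(str(seq_arr[src_i]))

    dataset = GenotypeDataset(
        individual_ids=ids,
        population_of=pops,
        loci=[f"L{l + 1}" for l in range(config.n_loci)],
        alleles=np.concatenate(blocks, axis=0),
    )
    alignment = HaplotypeAlignment(
        sequence_ids=sids, population_of=spops, sequences=site_seqs,
        indel_blocks=detect_indel_blocks(site_seqs),
    )
    truth = GroundTruth(
        scenario_id=config.scenario_id,
        parameters=params,
        founder_history=history,
        seed=config.seed,
    )
    return dataset, alignment, truth


# ---------------------------------------------------------------------------
# pseudo-observed datasets for ABC calibration


def generate_abc_truth_set(scenario: ScenarioSpec,
                           params: ParameterDraw | PriorSet,
                           n_datasets: int,
                           samples: SampleConfig,
                           seed: int) -> tuple[list, list[GroundTruth]]:
    """Generate pseudo-observed datasets with recorded ground truths.

    ``params`` may be a fixed :class:`ParameterDraw` or a :class:`PriorSet`
    (a fresh truth is drawn per dataset).  Each dataset gets its own derived
    seed so any single one can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(seed)
    datasets, truths = [], []
    for child in ss.spawn(n_datasets):
        draw_seed, sim_seed = (int(v % (2**31 - 1)) + 1
                               for v in child.generate_state(2))
        if isinstance(params, PriorSet):
            draw = draw_parameters(params, scenario,
                                   np.random.default_rng(draw_seed),
                                   n_loci=samples.n_loci)
        else:
            draw = params
        data = simulate_dataset(scenario, draw, samples,
                                np.random.default_rng(sim_seed))
        datasets.append(data)
        truths.append(GroundTruth(scenario.scenario_id, draw, {}, sim_seed))
    return datasets, truths


def regenerate(truth: GroundTruth, samples: SampleConfig):
    """Rebuild the dataset recorded by a pseudo-observed ground truth
    (fixtures regenerate via :func:`generate_study_fixture` instead)."""
    if truth.founder_history:
        raise ValueError("fixture truths regenerate via generate_study_fixture")
    scenario = scenario_catalog()[truth.scenario_id - 1]
    return simulate_dataset(scenario, truth.parameters, samples,
                            np.random.default_rng(truth.seed))
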