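import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fallowpop.core_io import GenotypeDataset, HaplotypeAlignment

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


def make_dataset(pop_genotypes: dict[str, list[list[tuple[int, int]]]],
                 loci: list[str] | None = None) -> GenotypeDataset:
    """Build a GenotypeDataset from {pop: [per-individual locus pairs]}."""
    ids, pops, rows = [], {}, []
    for pop, genos in pop_genotypes.items():
        for i, g in enumerate(genos):
            iid = f"{pop}_{i + 1}"
            ids.append(iid)
            pops[iid] = pop
            rows.append(g)
    n_loci = len(rows[0])
    return GenotypeDataset(
        individual_ids=ids,
        population_of=pops,
        loci=loci or [f"L{k + 1}" for k in range(n_loci)],
        alleles=np.array(rows, dtype=np.int32),
    )


def make_alignment(pop_seqs: dict[str, list[str]],
                   indel_blocks=None) -> HaplotypeAlignment:
    ids, pops, seqs = [], {}, []
    for pop, ss in pop_seqs.items():
        for i, s in enumerate(ss):
            sid = f"{pop}_{i + 1}"
            ids.append(sid)
            pops[sid] = pop
            seqs.append(s)
    from fallowpop.core_io import detect_indel_blocks

    blocks = detect_indel_blocks(seqs) if indel_blocks is None else indel_blocks
    return HaplotypeAlignment(ids, pops, seqs, blocks)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
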