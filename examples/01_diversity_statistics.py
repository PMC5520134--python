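"""Per-population diversity statistics on a study-shaped dataset.

Generates the default 24-site fixture (364 diploids, 10 microsatellites)
and prints the survey-style table: mean allele count (A), rarefaction
allelic richness (AR), observed/expected heterozygosity and Weir-Cockerham
F_IS per site, plus an exact multilocus Hardy-Weinberg p-value.  Low He and
small allele counts are the signature of founder-effect drift.
"""

import numpy as np

from fallowpop import FixtureConfig, generate_study_fixture, msat_diversity

dataset, alignment, truth = generate_study_fixture(FixtureConfig(seed=1))
summary = msat_diversity(dataset, rng=np.random.default_rng(1))

print(summary.per_population.round(3).to_string(index=False))
print(f"\nrarefaction size: {summary.rarefaction_size} gene copies")
print("Low He (~0.1-0.5) and A below ~3 alleles/locus mirror a strongly "
      "drifted, translocated species; hwe_p is the Fisher-combined exact "
      "test per site.")
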