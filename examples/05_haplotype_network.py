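"""Median-joining haplotype network from an mtDNA alignment.

Collapses the fixture's control-region sequences into haplotypes (indel
blocks count as single presence/absence characters), builds the network,
and prints nodes and edges.  Star-like clusters around a frequent central
haplotype are the classic signature of founder expansion.
"""

from fallowpop import (
    FixtureConfig,
    build_network,
    collapse_haplotypes,
    generate_study_fixture,
)

_, alignment, _ = generate_study_fixture(FixtureConfig(seed=5))
haps = collapse_haplotypes(alignment)
print(f"{alignment.n_sequences} sequences collapse to "
      f"{haps.n_haplotypes} haplotypes")
for lab, freq, pops in zip(haps.labels, haps.frequencies, haps.populations):
    top = sorted(pops.items(), key=lambda kv: -kv[1])[:3]
    print(f"  {lab}: n={freq:3d}  " +
          ", ".join(f"{p}={c}" for p, c in top))

net = build_network(haps, method="mjn")
print("\nnetwork edges (mutational steps):")
for u, v, w in net.edges:
    print(f"  {u} -- {v}  ({w})")
n_med = sum(net.is_median)
print(f"{n_med} inferred median vector(s); node frequencies sum to "
      f"{int(net.frequencies.sum())} (= sample size).")
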