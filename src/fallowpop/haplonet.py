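"""Haplotype collapsing and network construction for mtDNA alignments.

Sequences are reduced to character vectors in which every annotated indel
block counts as a single presence/absence character — the biological reading
under which an 80-bp or 21-bp insertion is one mutational event, however many
columns it spans.  Networks come in two flavours: the minimum-spanning
network (union of all minimum spanning trees) and a median-joining network
that inserts consensus (median) vectors while doing so shortens the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core_io import HaplotypeAlignment

#: block-presence characters
_PRESENT, _ABSENT = "+", "-"


def haplotype_key(sequence: str, indel_blocks) -> tuple[str, ...]:
    """Reduce an aligned sequence to its haplotype character vector:
    one character per column outside indel blocks, one presence/absence
    character per block."""
    blocked = np.zeros(len(sequence), dtype=bool)
    flags = []
    for s, e, _ in sorted(indel_blocks):
        blocked[s:e] = True
        seg = sequence[s:e]
        flags.append(_ABSENT if set(seg) == {"-"} else _PRESENT)
    body = [c for c, b in zip(sequence, blocked) if not b]
    return tuple(body + flags)


def _hamming(u: tuple[str, ...], v: tuple[str, ...]) -> int:
    """Mutational steps between two character vectors; positions where
    either carries an N (missing base) are skipped."""
    return sum(
        1 for a, b in zip(u, v) if a != b and a != "N" and b != "N"
    )


@dataclass
class HaplotypeSet:
    """Collapsed haplotypes with frequencies and population composition."""

    labels: list[str]
    vectors: list[tuple[str, ...]]
    frequencies: np.ndarray
    populations: list[dict[str, int]]
    representatives: list[str]       # one full-length aligned sequence each
    indel_blocks: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.labels)

    @property
    def total_count(self) -> int:
        return int(self.frequencies.sum())


def collapse_haplotypes(alignment: HaplotypeAlignment) -> HaplotypeSet:
    """Merge identical sequences (indel blocks compared as one character).

    Haplotypes are labelled H1, H2, ... in order of first appearance.
    """
    seen: dict[tuple[str, ...], int] = {}
    labels: list[str] = []
    vectors: list[tuple[str, ...]] = []
    freqs: list[int] = []
    pops: list[dict[str, int]] = []
    reps: list[str] = []
    for sid, seq in zip(alignment.sequence_ids, alignment.sequences):
        key = haplotype_key(seq, alignment.indel_blocks)
        pop = alignment.population_of[sid]
        if key not in seen:
            seen[key] = len(labels)
            labels.append(f"H{len(labels) + 1}")
            vectors.append(key)
            freqs.append(0)
            pops.append({})
            reps.append(seq)
        i = seen[key]
        freqs[i] += 1
        pops[i][pop] = pops[i].get(pop, 0) + 1
    return HaplotypeSet(labels, vectors, np.array(freqs), pops, reps,
                        list(alignment.indel_blocks))


def pairwise_hap_distance(haps: HaplotypeSet) -> np.ndarray:
    """Integer mutational-step matrix: substitutions per differing site,
    plus one step per indel block differing in presence."""
    k = haps.n_haplotypes
    d = np.zeros((k, k), dtype=int)
    for i, j in combinations(range(k), 2):
        d[i, j] = d[j, i] = _hamming(haps.vectors[i], haps.vectors[j])
    return d


# ---------------------------------------------------------------------------
# networks


@dataclass
class HaplotypeNetwork:
    labels: list[str]
    vectors: list[tuple[str, ...]]
    frequencies: np.ndarray          # median vectors carry frequency 0
    is_median: list[bool]
    edges: list[tuple[str, str, int]]

    def degree(self, label: str) -> int:
        return sum(1 for u, v, _ in self.edges if label in (u, v))

    @property
    def total_edge_weight(self) -> int:
        return sum(w for _, _, w in self.edges)

    def to_tables(self):
        """(nodes, edges) DataFrames for CSV export."""
        import pandas as pd

        nodes = pd.DataFrame({
            "label": self.labels,
            "frequency": self.frequencies,
            "is_median": self.is_median,
        })
        edges = pd.DataFrame(self.edges, columns=["from", "to", "steps"])
        return nodes, edges

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for lab, freq, med in zip(self.labels, self.frequencies,
                                  self.is_median):
            g.add_node(lab, frequency=int(freq), is_median=med)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g

    def to_dot(self) -> str:
        lines = ["graph haplotypes {"]
        for lab, freq, med in zip(self.labels, self.frequencies,
                                  self.is_median):
            shape = "point" if med else "circle"
            lines.append(f'  "{lab}" [shape={shape}, label="{lab} ({freq})"];')
        for u, v, w in self.edges:
            lines.append(f'  "{u}" -- "{v}" [label="{w}"];')
        lines.append("}")
        return "\n".join(lines)


def _msn_edges(dist: np.ndarray, epsilon: int = 0
               ) -> list[tuple[int, int, int]]:
    """Minimum-spanning-network edges over a complete distance graph.

    An edge belongs to some minimum spanning tree exactly when its weight
    equals the minimax (bottleneck) path weight between its endpoints, so
    the union of all MSTs is ``{(i, j): d(i, j) <= B(i, j)}`` with ``B`` the
    minimax distance; ``epsilon`` relaxes the threshold by that many extra
    steps."""
    n = dist.shape[0]
    B = dist.astype(float).copy()
    for k in range(n):
        np.minimum(B, np.maximum(B[:, k][:, None], B[k, :][None, :]), out=B)
    return [
        (i, j, int(dist[i, j]))
        for i, j in combinations(range(n), 2)
        if dist[i, j] <= B[i, j] + epsilon
    ]


def _mst_weight(dist: np.ndarray) -> int:
    """Minimum-spanning-tree weight (zero distances carry zero cost)."""
    from scipy.sparse.csgraph import minimum_spanning_tree

    n = dist.shape[0]
    if n < 2:
        return 0
    # offset so that zero-weight edges survive the sparse representation
    mst = minimum_spanning_tree(dist.astype(float) + 1.0)
    return int(round(mst.sum())) - (n - 1)


def _median_vector(u, v, w) -> tuple[str, ...]:
    """Per-position majority consensus of three character vectors; ties
    resolve to the lexicographically smallest modal character."""
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(min(a, b, c))
    return tuple(out)


def build_network(haps: HaplotypeSet, method: str = "mjn",
                  epsilon: int = 0) -> HaplotypeNetwork:
    """Build a haplotype network.

    ``msn`` is the union of all minimum spanning trees over the mutational
    step distances.  ``mjn`` additionally proposes median (consensus)
    vectors from triples of connected nodes and inserts any that strictly
    shortens the minimum-spanning-tree length, repeating until no candidate
    helps; median vectors that end up with degree ≤ 2 are pruned.
    Construction is deterministic: ties break on lexicographic labels.
    """
    if haps.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if method not in ("msn", "mjn"):
        raise ValueError(f"unknown method {method!r}")

    vectors: list[tuple[str, ...]] = list(haps.vectors)
    labels: list[str] = list(haps.labels)
    freqs: list[int] = [int(f) for f in haps.frequencies]
    is_median: list[bool] = [False] * len(labels)

    def dist_matrix() -> np.ndarray:
        n = len(vectors)
        d = np.zeros((n, n), dtype=int)
        for i, j in combinations(range(n), 2):
            d[i, j] = d[j, i] = _hamming(vectors[i], vectors[j])
        return d

    if method == "mjn":
        while True:
            d = dist_matrix()
            base = _mst_weight(d)
            edges = _msn_edges(d, epsilon)
            adj: dict[int, set[int]] = {i: set() for i in range(len(vectors))}
            for i, j, _ in edges:
                adj[i].add(j)
                adj[j].add(i)
            seen = set(vectors)
            candidates: list[tuple[str, ...]] = []
            for v in range(len(vectors)):
                for u, w in combinations(sorted(adj[v]), 2):
                    m = _median_vector(vectors[u], vectors[v], vectors[w])
                    if m not in seen:
                        seen.add(m)
                        candidates.append(m)
            best_gain, best_m = 0, None
            for m in sorted(candidates):
                ext = np.zeros((len(vectors) + 1, len(vectors) + 1), dtype=int)
                ext[:-1, :-1] = d
                row = [_hamming(m, x) for x in vectors]
                ext[-1, :-1] = row
                ext[:-1, -1] = row
                gain = base - _mst_weight(ext)
                if gain > best_gain:
                    best_gain, best_m = gain, m
            if best_m is None:
                break
            vectors.append(best_m)
            labels.append(f"mv{sum(is_median) + 1}")
            freqs.append(0)
            is_median.append(True)

        # prune median vectors that do not branch
        while True:
            d = dist_matrix()
            edges = _msn_edges(d, epsilon)
            deg = [0] * len(vectors)
            for i, j, _ in edges:
                deg[i] += 1
                deg[j] += 1
            drop = [i for i in range(len(vectors))
                    if is_median[i] and deg[i] <= 2]
            if not drop:
                break
            for i in reversed(drop):
                del vectors[i], labels[i], freqs[i], is_median[i]

    d = dist_matrix()
    edges = _msn_edges(d, epsilon)
    named = sorted(
        (labels[i], labels[j], int(w)) if labels[i] < labels[j]
        else (labels[j], labels[i], int(w))
        for i, j, w in edges
    )
    return HaplotypeNetwork(labels, vectors, np.array(freqs), is_median,
                            named)
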