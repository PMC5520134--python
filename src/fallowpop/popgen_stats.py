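"""Diversity, differentiation and hypothesis-test statistics.

Implements the classical microsatellite and mtDNA survey statistics for
strongly structured populations: per-population allele counts, rarefaction
allelic richness, unbiased expected heterozygosity, Weir–Cockerham f (F_IS)
and θ (F_ST) with permutation significance, exact Hardy–Weinberg tests,
genotypic linkage-disequilibrium tests, haplotype/nucleotide diversity,
Mantel isolation-by-distance, Holm's sequential Bonferroni, the
Allendorf–Phelps founder-event F_ST expectation, and the named summary-vector
builder used by the ABC machinery.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import MISSING, GenotypeDataset, HaplotypeAlignment

__all__ = [
    "DiversitySummary",
    "MtdnaSummary",
    "PairwiseMatrix",
    "SummaryVector",
    "msat_diversity",
    "pairwise_fst",
    "hwe_exact_test",
    "ld_test",
    "mtdna_diversity",
    "mantel_test",
    "sequential_bonferroni",
    "founder_fst_expectation",
    "build_summary_vector",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class DiversitySummary:
    """Per-locus and per-population microsatellite diversity table."""

    per_locus: pd.DataFrame      # population, locus, n, A, AR, Ho, He, fis
    per_population: pd.DataFrame  # population, mean_A, mean_AR, fis, Ho, He, hwe_p
    rarefaction_size: int


@dataclass
class MtdnaSummary:
    per_population: pd.DataFrame  # population, n, k, hd, pi, mean_pairwise, k_per_n
    sites_used: int


@dataclass
class PairwiseMatrix:
    populations: list[str]
    values: np.ndarray
    p_values: np.ndarray | None
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations,
                            columns=self.populations)


@dataclass
class SummaryVector:
    """Named, ordered statistic vector comparing datasets for ABC."""

    names: tuple[str, ...]
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __len__(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# basic per-population quantities


def _gene_copies(dataset: GenotypeDataset, idx: np.ndarray, locus: int
                 ) -> np.ndarray:
    a = dataset.alleles[idx, locus, :].ravel()
    return a[a != MISSING]


def unbiased_he(copies: np.ndarray) -> float:
    """Nei's unbiased expected heterozygosity from a vector of gene copies."""
    m = copies.size
    if m < 2:
        return np.nan
    _, counts = np.unique(copies, return_counts=True)
    p = counts / m
    return (m / (m - 1)) * (1.0 - float(np.sum(p * p)))


def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected number of alleles in a hypergeometric draw of ``g`` gene
    copies from the observed multiset (El Mousadik & Petit rarefaction)."""
    m = int(counts.sum())
    if g > m:
        raise ValueError(f"rarefaction size {g} exceeds sample of {m} copies")
    # 1 - C(m - n_a, g) / C(m, g) summed over alleles, in log space
    total = 0.0
    for na in counts:
        if m - na < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(
                math.lgamma(m - na + 1) - math.lgamma(m - na - g + 1)
                - math.lgamma(m + 1) + math.lgamma(m - g + 1)
            )
    return total


def _single_pop_f_components(dataset: GenotypeDataset, idx: np.ndarray,
                             locus: int) -> tuple[float, float]:
    """Weir–Cockerham within-population variance components (b, c) summed
    over alleles; f = 1 - Σc / Σ(b + c)."""
    geno = dataset.alleles[idx, locus, :]
    typed = geno[:, 0] != MISSING
    geno = geno[typed]
    n = geno.shape[0]
    if n < 2:
        return (np.nan, np.nan)
    alleles = np.unique(geno)
    b_sum = c_sum = 0.0
    for al in alleles:
        carry = geno == al
        p = carry.mean()
        h = float((carry.sum(axis=1) == 1).mean())
        b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
        b_sum += b
        c_sum += h / 2.0
    return (b_sum, c_sum)


def msat_diversity(dataset: GenotypeDataset,
                   rarefaction_size: int | None = None,
                   hwe: bool = True,
                   mc_reps: int = 5000,
                   rng: np.random.Generator | None = None) -> DiversitySummary:
    """Per-population, per-locus A, AR, Ho, He and F_IS, with multilocus
    means and an exact multilocus Hardy–Weinberg p per population.

    ``rarefaction_size`` is a gene-copy count; by default the smallest
    gene-copy count over population x locus cells with data.  F_IS follows
    Weir–Cockerham f, multilocus by ratio of summed variance components.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    pops = dataset.populations
    copies = {
        (pop, l): _gene_copies(dataset, dataset.members(pop), l)
        for pop in pops for l in range(dataset.n_loci)
    }
    sizes = [c.size for c in copies.values() if c.size > 0]
    if not sizes:
        raise ValueError("dataset has no typed genotypes")
    g = min(sizes) if rarefaction_size is None else int(rarefaction_size)
    if g > min(sizes):
        raise ValueError(
            f"rarefaction size {g} exceeds the smallest sample ({min(sizes)})"
        )

    rows = []
    pop_rows = []
    for pop in pops:
        idx = dataset.members(pop)
        b_tot = c_tot = 0.0
        a_vals, ar_vals, ho_vals, he_vals = [], [], [], []
        for l, locus in enumerate(dataset.loci):
            cop = copies[(pop, l)]
            geno = dataset.alleles[idx, l, :]
            typed = geno[:, 0] != MISSING
            n = int(typed.sum())
            if cop.size == 0:
                rows.append({"population": pop, "locus": locus, "n": 0,
                             "A": np.nan, "AR": np.nan, "Ho": np.nan,
                             "He": np.nan, "fis": np.nan})
                continue
            _, counts = np.unique(cop, return_counts=True)
            A = counts.size
            ar = rarefied_richness(counts, g)
            ho = float((geno[typed, 0] != geno[typed, 1]).mean())
            he = unbiased_he(cop)
            b, c = _single_pop_f_components(dataset, idx, l)
            if A > 1 and not np.isnan(b) and (b + c) > 0:
                fis = 1.0 - c / (b + c)
                b_tot += b
                c_tot += c
            else:
                fis = np.nan
            rows.append({"population": pop, "locus": locus, "n": n,
                         "A": A, "AR": ar, "Ho": ho, "He": he, "fis": fis})
            a_vals.append(A)
            ar_vals.append(ar)
            ho_vals.append(ho)
            he_vals.append(he)
        multi_fis = 1.0 - c_tot / (b_tot + c_tot) if (b_tot + c_tot) > 0 else np.nan
        hwe_p = np.nan
        if hwe:
            hwe_p = hwe_exact_test(dataset, pop, mc_reps=mc_reps,
                                   rng=rng).combined_p
        pop_rows.append({
            "population": pop,
            "mean_A": float(np.mean(a_vals)) if a_vals else np.nan,
            "mean_AR": float(np.mean(ar_vals)) if ar_vals else np.nan,
            "fis": multi_fis,
            "Ho": float(np.mean(ho_vals)) if ho_vals else np.nan,
            "He": float(np.mean(he_vals)) if he_vals else np.nan,
            "hwe_p": hwe_p,
        })
    return DiversitySummary(pd.DataFrame(rows), pd.DataFrame(pop_rows), g)


# ---------------------------------------------------------------------------
# Weir–Cockerham theta


def _wc_components_diploid(geno1: np.ndarray, geno2: np.ndarray
                           ) -> tuple[float, float, float]:
    """Summed WC84 variance components (a, b, c) over alleles for one locus
    and two populations of diploid genotypes (rows, 2 columns)."""
    g1 = geno1[geno1[:, 0] != MISSING]
    g2 = geno2[geno2[:, 0] != MISSING]
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        return (np.nan, np.nan, np.nan)
    r = 2
    nbar = (n1 + n2) / 2.0
    nsum = n1 + n2
    nc = (nsum - (n1 * n1 + n2 * n2) / nsum) / (r - 1)
    if nc <= 0:
        return (np.nan, np.nan, np.nan)
    both = np.concatenate([g1, g2], axis=0)
    alleles, inv = np.unique(both, return_inverse=True)
    k = alleles.size
    inv = inv.reshape(-1, 2)
    het = inv[:, 0] != inv[:, 1]
    # per-allele gene-copy counts and heterozygote-carrier counts, per pop
    def counts(sub_inv, sub_het):
        pc = np.bincount(sub_inv.ravel(), minlength=k).astype(float)
        hc = np.bincount(
            np.concatenate([sub_inv[sub_het, 0], sub_inv[sub_het, 1]]),
            minlength=k).astype(float)
        return pc, hc

    pc1, hc1 = counts(inv[:n1], het[:n1])
    pc2, hc2 = counts(inv[n1:], het[n1:])
    p1, p2 = pc1 / (2 * n1), pc2 / (2 * n2)
    h1, h2 = hc1 / n1, hc2 / n2
    pbar = (n1 * p1 + n2 * p2) / nsum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / nsum
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return (float(a.sum()), float(b.sum()), float(c.sum()))


def _wc_components_haploid(h1: np.ndarray, h2: np.ndarray
                           ) -> tuple[float, float]:
    """Haploid analogue: components (a, b) over haplotype classes."""
    n1, n2 = h1.size, h2.size
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        return (np.nan, np.nan)
    r = 2
    nbar = (n1 + n2) / 2.0
    nsum = n1 + n2
    nc = (nsum - (n1 * n1 + n2 * n2) / nsum) / (r - 1)
    if nc <= 0:
        return (np.nan, np.nan)
    alleles = np.unique(np.concatenate([h1, h2]))
    a_sum = b_sum = 0.0
    for al in alleles:
        p1, p2 = (h1 == al).mean(), (h2 == al).mean()
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        a_sum, b_sum = a_sum + a, b_sum + b
    return (a_sum, b_sum)


def wc_theta_pair_diploid(alleles: np.ndarray, is_pop2: np.ndarray) -> float:
    """Multilocus WC θ for two populations given an ``(n, L, 2)`` allele
    array and a boolean membership vector (ratio of summed components)."""
    num = den = 0.0
    for l in range(alleles.shape[1]):
        a, b, c = _wc_components_diploid(alleles[~is_pop2, l, :],
                                         alleles[is_pop2, l, :])
        if np.isnan(a):
            continue
        num += a
        den += a + b + c
    return num / den if den != 0 else np.nan


def wc_theta_pair_haploid(haps: np.ndarray, is_pop2: np.ndarray) -> float:
    a, b = _wc_components_haploid(haps[~is_pop2], haps[is_pop2])
    if np.isnan(a):
        return np.nan
    den = a + b
    return a / den if den != 0 else np.nan


def _haplotype_codes(alignment: HaplotypeAlignment) -> np.ndarray:
    """Integer haplotype class per sequence (indel blocks as one character)."""
    from .haplonet import haplotype_key

    keys = [haplotype_key(s, alignment.indel_blocks)
            for s in alignment.sequences]
    mapping = {k: i for i, k in enumerate(dict.fromkeys(keys))}
    return np.array([mapping[k] for k in keys], dtype=np.int64)


def pairwise_fst(data: GenotypeDataset | HaplotypeAlignment,
                 n_perm: int = 0,
                 rng: np.random.Generator | None = None) -> PairwiseMatrix:
    """Pairwise Weir–Cockerham θ with optional permutation p-values.

    Microsatellites use the diploid variance components; mtDNA uses the
    haploid haplotype-frequency analogue.  Permutations shuffle individuals
    between the two populations of each pair; the p-value is the fraction of
    permuted θ at least as large as observed (with the +1 convention).
    Negative estimates are reported as computed.  Populations with fewer than
    2 members give undefined (NaN) cells.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    pops = data.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    k = len(pops)
    theta = np.zeros((k, k))
    pmat = np.full((k, k), np.nan) if n_perm else None

    diploid = isinstance(data, GenotypeDataset)
    if diploid:
        member_idx = {p: data.members(p) for p in pops}
        payload = data.alleles
    else:
        codes = _haplotype_codes(data)
        member_idx = {p: np.array(data.members(p), dtype=np.intp)
                      for p in pops}
        payload = codes

    for i, j in combinations(range(k), 2):
        idx = np.concatenate([member_idx[pops[i]], member_idx[pops[j]]])
        lab = np.zeros(idx.size, dtype=bool)
        lab[len(member_idx[pops[i]]):] = True
        if len(member_idx[pops[i]]) < 2 or len(member_idx[pops[j]]) < 2:
            theta[i, j] = theta[j, i] = np.nan
            continue
        sub = payload[idx]
        est = (wc_theta_pair_diploid if diploid else wc_theta_pair_haploid)
        obs = est(sub, lab)
        theta[i, j] = theta[j, i] = obs
        if n_perm and not np.isnan(obs):
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(lab)
                t = est(sub, perm)
                if not np.isnan(t) and t >= obs:
                    count += 1
            p = (count + 1) / (n_perm + 1)
            pmat[i, j] = pmat[j, i] = p
    if pmat is not None:
        np.fill_diagonal(pmat, np.nan)
    return PairwiseMatrix(pops, theta, pmat, n_perm)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test


def _table_log_prob(het: dict[tuple[int, int], int],
                    hom: dict[int, int],
                    allele_counts: dict[int, int],
                    n: int) -> float:
    """Log conditional probability of a genotype table given allele counts
    (Levene's distribution)."""
    H = sum(het.values())
    lp = (H * math.log(2.0) + math.lgamma(n + 1)
          - math.lgamma(2 * n + 1))
    for m in allele_counts.values():
        lp += math.lgamma(m + 1)
    for v in het.values():
        lp -= math.lgamma(v + 1)
    for v in hom.values():
        lp -= math.lgamma(v + 1)
    return lp


def _enumerate_tables(allele_counts: dict[int, int], n: int,
                      max_tables: int):
    """Yield all genotype tables consistent with the allele-count margins,
    or None if more than ``max_tables`` would be generated."""
    alleles = sorted(allele_counts)
    pairs = list(combinations(alleles, 2))
    tables: list[tuple[dict, dict]] = []

    def rec(p_idx: int, het: dict, used: dict) -> bool:
        if len(tables) > max_tables:
            return False
        if p_idx == len(pairs):
            hom = {}
            for al in alleles:
                rem = allele_counts[al] - used.get(al, 0)
                if rem < 0 or rem % 2:
                    return True
                hom[al] = rem // 2
            tables.append((dict(het), hom))
            return True
        a, b = pairs[p_idx]
        cap = min(allele_counts[a] - used.get(a, 0),
                  allele_counts[b] - used.get(b, 0))
        for nab in range(cap + 1):
            het[(a, b)] = nab
            used[a] = used.get(a, 0) + nab
            used[b] = used.get(b, 0) + nab
            ok = rec(p_idx + 1, het, used)
            used[a] -= nab
            used[b] -= nab
            del het[(a, b)]
            if not ok:
                return False
        return True

    complete = rec(0, {}, {})
    return tables if complete else None


@dataclass
class HweResult:
    per_locus: dict[str, float]
    combined_p: float
    method: dict[str, str]


def hwe_exact_test(dataset: GenotypeDataset, population: str,
                   mc_reps: int = 10000,
                   rng: np.random.Generator | None = None,
                   max_tables: int = 100_000) -> HweResult:
    """Exact test of Hardy–Weinberg proportions per locus, conditional on
    allele counts; full enumeration when the table space is small, Monte
    Carlo (random re-pairing of gene copies) otherwise.  Monomorphic loci
    give p = 1 by convention; per-population p combines loci by Fisher's
    method."""
    rng = np.random.default_rng(0) if rng is None else rng
    idx = dataset.members(population)
    pvals: dict[str, float] = {}
    methods: dict[str, str] = {}
    for l, locus in enumerate(dataset.loci):
        geno = dataset.alleles[idx, l, :]
        geno = geno[geno[:, 0] != MISSING]
        n = geno.shape[0]
        if n < 2 or np.unique(geno).size < 2:
            pvals[locus] = 1.0
            methods[locus] = "trivial"
            continue
        copies = np.sort(geno, axis=1)
        vals, counts = np.unique(copies.ravel(), return_counts=True)
        allele_counts = dict(zip(vals.tolist(), counts.tolist()))
        het_obs: dict[tuple[int, int], int] = {}
        hom_obs: dict[int, int] = {}
        for a, b in copies:
            a, b = int(a), int(b)
            if a == b:
                hom_obs[a] = hom_obs.get(a, 0) + 1
            else:
                het_obs[(a, b)] = het_obs.get((a, b), 0) + 1
        lp_obs = _table_log_prob(het_obs, hom_obs, allele_counts, n)

        tables = _enumerate_tables(allele_counts, n, max_tables)
        if tables is not None:
            lps = np.array([
                _table_log_prob(het, hom, allele_counts, n)
                for het, hom in tables
            ])
            probs = np.exp(lps - lps.max())
            probs /= probs.sum()
            pvals[locus] = float(probs[lps <= lp_obs + 1e-9].sum())
            methods[locus] = "enumeration"
        else:
            pool = copies.ravel().copy()
            count = 0
            for _ in range(mc_reps):
                rng.shuffle(pool)
                pairs = np.sort(pool.reshape(-1, 2), axis=1)
                het: dict[tuple[int, int], int] = {}
                hom: dict[int, int] = {}
                for a, b in pairs:
                    a, b = int(a), int(b)
                    if a == b:
                        hom[a] = hom.get(a, 0) + 1
                    else:
                        het[(a, b)] = het.get((a, b), 0) + 1
                if _table_log_prob(het, hom, allele_counts, n) <= lp_obs + 1e-9:
                    count += 1
            pvals[locus] = (count + 1) / (mc_reps + 1)
            methods[locus] = "monte-carlo"
    x = -2.0 * sum(math.log(max(p, 1e-300)) for p in pvals.values())
    combined = float(sps.chi2.sf(x, 2 * len(pvals))) if pvals else np.nan
    return HweResult(pvals, combined, methods)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _two_locus_g(g1: np.ndarray, g2: np.ndarray) -> float:
    """Log-likelihood-ratio (G) statistic of the two-locus genotype table."""
    cats1, inv1 = np.unique(g1, axis=0, return_inverse=True)
    cats2, inv2 = np.unique(g2, axis=0, return_inverse=True)
    table = np.zeros((cats1.shape[0], cats2.shape[0]))
    np.add.at(table, (inv1, inv2), 1.0)
    tot = table.sum()
    if tot == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / tot
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / exp[mask])).sum())


def ld_test(dataset: GenotypeDataset, locus_pair: tuple[str, str],
            n_perm: int = 1000,
            rng: np.random.Generator | None = None) -> float:
    """Genotypic linkage-disequilibrium test for one locus pair.

    The statistic sums, over populations, the G statistic of the two-locus
    genotype contingency table; the null distribution permutes one locus's
    genotypes among individuals within each population.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    l1 = dataset.loci.index(locus_pair[0])
    l2 = dataset.loci.index(locus_pair[1])
    per_pop = []
    for pop in dataset.populations:
        idx = dataset.members(pop)
        g1 = dataset.alleles[idx, l1, :]
        g2 = dataset.alleles[idx, l2, :]
        typed = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
        per_pop.append((g1[typed], g2[typed]))
    obs = sum(_two_locus_g(g1, g2) for g1, g2 in per_pop)
    if obs == 0.0:
        return 1.0
    count = 0
    for _ in range(n_perm):
        stat = 0.0
        for g1, g2 in per_pop:
            stat += _two_locus_g(g1, g2[rng.permutation(g2.shape[0])])
        if stat >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# mtDNA diversity


def _comparable_columns(alignment: HaplotypeAlignment) -> np.ndarray:
    mask = np.ones(alignment.length, dtype=bool)
    for s, e, _ in alignment.indel_blocks:
        mask[s:e] = False
    return mask


def mtdna_diversity(alignment: HaplotypeAlignment,
                    min_n: int = 11) -> MtdnaSummary:
    """Per-population haplotype and nucleotide diversity.

    hd = (n/(n-1))(1 - Σ f_i²); π = mean pairwise proportion of differing
    sites over the columns outside indel blocks; the mean pairwise divergence
    is the same quantity in absolute site counts.  hd, π and the divergence
    are reported only for samples of at least ``min_n`` sequences (the
    survey convention N > 10); k and k/N are always reported.
    """
    from .haplonet import haplotype_key

    cols = _comparable_columns(alignment)
    n_sites = int(cols.sum())
    arr = np.array([list(s) for s in alignment.sequences])[:, cols]
    rows = []
    for pop in alignment.populations:
        idx = alignment.members(pop)
        n = len(idx)
        keys = [haplotype_key(alignment.sequences[i], alignment.indel_blocks)
                for i in idx]
        counts = np.array(list(Counter(keys).values()))
        k = counts.size
        hd = pi = mpd = np.nan
        if n >= min_n:
            f = counts / n
            hd = (n / (n - 1.0)) * (1.0 - float(np.sum(f * f))) if n > 1 else np.nan
            sub = arr[idx]
            dmat = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
            iu = np.triu_indices(n, k=1)
            mpd = float(dmat[iu].mean()) if iu[0].size else 0.0
            pi = mpd / n_sites
        rows.append({"population": pop, "n": n, "k": k, "hd": hd, "pi": pi,
                     "mean_pairwise": mpd, "k_per_n": k / n})
    return MtdnaSummary(pd.DataFrame(rows), n_sites)


# ---------------------------------------------------------------------------
# Mantel, Holm, founder expectation


def mantel_test(m1: np.ndarray, m2: np.ndarray, n_perm: int = 10000,
                rng: np.random.Generator | None = None
                ) -> tuple[float, float]:
    """One-tailed Mantel test of matrix correlation (isolation by distance).

    Thin wrapper over scikit-bio's implementation; returns (r, p).  A
    constant matrix has no defined correlation and returns (nan, nan).
    """
    from skbio import DistanceMatrix
    from skbio.stats.distance import mantel as _skbio_mantel

    rng = np.random.default_rng(0) if rng is None else rng
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    iu = np.triu_indices_from(m1, k=1)
    if np.allclose(m1[iu], m1[iu][0]) or np.allclose(m2[iu], m2[iu][0]):
        return (np.nan, np.nan)
    # scikit-bio draws permutations from the global numpy RNG
    state = np.random.get_state()
    np.random.seed(int(rng.integers(0, 2**31 - 1)))
    try:
        r, p, _ = _skbio_mantel(DistanceMatrix(m1), DistanceMatrix(m2),
                                method="pearson", permutations=n_perm,
                                alternative="greater")
    finally:
        np.random.set_state(state)
    return (float(r), float(p))


def sequential_bonferroni(pvalues, alpha: float = 0.05) -> set[int]:
    """Holm's step-down correction; returns indices of rejected tests."""
    p = np.asarray(list(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return set()
    order = np.argsort(p, kind="stable")
    rejected: set[int] = set()
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            rejected.add(int(idx))
        else:
            break
    return rejected


def founder_fst_expectation(n_founders: int, n_generations: int = 1,
                            sample_sizes: tuple[int, int] | None = (150, 150)
                            ) -> float:
    """Expected F_ST between a source population and a population founded
    from it by ``n_founders`` diploids, after ``n_generations`` at that size
    (Allendorf–Phelps founder-event expectation).

    Drift accumulates as ``1 - (1 - 1/(2N))^t``.  The expectation of the
    standardized-variance F_ST computed from finite samples adds one further
    episode of binomial gene-copy sampling per sample (the temporal-method
    convention), ``1/(2S)`` for each of the two samples.  The default sample
    pair (150, 150) is the herd-survey scale at which this expectation is
    conventionally quoted for bottlenecked ungulate populations; pass
    ``sample_sizes=None`` for the pure drift expectation.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be at least 1")
    if n_generations < 0:
        raise ValueError("n_generations must be non-negative")
    drift = 1.0 - (1.0 - 1.0 / (2.0 * n_founders)) ** n_generations
    if sample_sizes is None:
        return drift
    s1, s2 = sample_sizes
    if s1 < 1 or s2 < 1:
        raise ValueError("sample sizes must be positive")
    return drift + 1.0 / (2.0 * s1) + 1.0 / (2.0 * s2)


# ---------------------------------------------------------------------------
# ABC summary vector


def _shared_allele_distance(a1: np.ndarray, a2: np.ndarray) -> float:
    """Mean 1 - ps over cross-population individual pairs, where ps is the
    proportion of shared alleles per locus (0, 1/2 or 1), averaged over
    typed loci."""
    x1 = a1[:, None, :, 0]
    x2 = a1[:, None, :, 1]
    y1 = a2[None, :, :, 0]
    y2 = a2[None, :, :, 1]
    typed = (x1 != MISSING) & (y1 != MISSING)
    # multiset intersection of sorted pairs {x1,x2} and {y1,y2}
    two = ((x1 == y1) & (x2 == y2)) | ((x1 == y2) & (x2 == y1))
    one = (x1 == y1) | (x1 == y2) | (x2 == y1) | (x2 == y2)
    shared = np.where(two, 1.0, np.where(one, 0.5, 0.0))
    n_typed = typed.sum(axis=2)
    with np.errstate(invalid="ignore"):
        per_pair = 1.0 - np.where(typed, shared, 0.0).sum(axis=2) / n_typed
    ok = n_typed > 0
    return float(per_pair[ok].mean()) if ok.any() else 0.0


def build_summary_vector(dataset: GenotypeDataset,
                         alignment: HaplotypeAlignment | None = None,
                         pops: list[str] | None = None) -> SummaryVector:
    """Deterministic named statistic vector for ABC comparisons.

    Microsatellite one-sample statistics per population (mean A, mean
    unbiased He, mean allele-size variance, Garza–Williamson M), pairwise
    statistics per population pair (WC θ clamped to [0, 1], shared-allele
    distance, (δμ)²), and, when an alignment is given, mtDNA per-population
    (k, segregating sites, mean pairwise differences) and pairwise haploid
    θ.  Undefined entries are set to 0 by convention so vectors stay finite.
    """
    pops = dataset.populations if pops is None else list(pops)
    for p in pops:
        if p not in dataset.populations:
            raise ValueError(f"population {p!r} not in dataset")
    names: list[str] = []
    values: list[float] = []

    member = {p: dataset.members(p) for p in pops}
    for pop in pops:
        idx = member[pop]
        a_vals, he_vals, var_vals, gw_vals = [], [], [], []
        for l in range(dataset.n_loci):
            cop = _gene_copies(dataset, idx, l)
            if cop.size == 0:
                continue
            vals, counts = np.unique(cop, return_counts=True)
            a_vals.append(vals.size)
            he = unbiased_he(cop)
            he_vals.append(0.0 if np.isnan(he) else he)
            var_vals.append(float(np.var(cop, ddof=1)) if cop.size > 1 else 0.0)
            gw_vals.append(vals.size / (vals.max() - vals.min() + 1.0))
        names += [f"msat.{pop}.mean_A", f"msat.{pop}.mean_He",
                  f"msat.{pop}.mean_size_var", f"msat.{pop}.gw_M"]
        values += [float(np.mean(x)) if x else 0.0
                   for x in (a_vals, he_vals, var_vals, gw_vals)]

    for p1, p2 in combinations(pops, 2):
        i1, i2 = member[p1], member[p2]
        idx = np.concatenate([i1, i2])
        lab = np.zeros(idx.size, dtype=bool)
        lab[i1.size:] = True
        theta = wc_theta_pair_diploid(dataset.alleles[idx], lab)
        theta = 0.0 if np.isnan(theta) else min(max(theta, 0.0), 1.0)
        das = _shared_allele_distance(dataset.alleles[i1], dataset.alleles[i2])
        dmu2 = []
        for l in range(dataset.n_loci):
            c1 = _gene_copies(dataset, i1, l)
            c2 = _gene_copies(dataset, i2, l)
            if c1.size and c2.size:
                dmu2.append((c1.mean() - c2.mean()) ** 2)
        dmu2 = float(np.mean(dmu2)) if dmu2 else 0.0
        names += [f"msat.{p1}-{p2}.fst", f"msat.{p1}-{p2}.das",
                  f"msat.{p1}-{p2}.dmu2"]
        values += [theta, das, dmu2]

    if alignment is not None:
        from .haplonet import haplotype_key

        cols = _comparable_columns(alignment)
        arr = np.array([list(s) for s in alignment.sequences])[:, cols]
        codes = _haplotype_codes(alignment)
        amember = {p: np.array(alignment.members(p), dtype=np.intp)
                   for p in alignment.populations}
        for pop in pops:
            idx = amember.get(pop, np.array([], dtype=np.intp))
            if idx.size == 0:
                k = s = mpd = 0.0
            else:
                sub = arr[idx]
                k = float(np.unique(codes[idx]).size)
                s = float((~(sub == sub[0]).all(axis=0)).sum())
                if idx.size > 1:
                    dmat = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
                    iu = np.triu_indices(idx.size, k=1)
                    mpd = float(dmat[iu].mean())
                else:
                    mpd = 0.0
            names += [f"mt.{pop}.k", f"mt.{pop}.seg_sites",
                      f"mt.{pop}.mean_pairwise"]
            values += [k, s, mpd]
        for p1, p2 in combinations(pops, 2):
            i1 = amember.get(p1, np.array([], dtype=np.intp))
            i2 = amember.get(p2, np.array([], dtype=np.intp))
            if i1.size < 2 or i2.size < 2:
                theta = 0.0
            else:
                idx = np.concatenate([i1, i2])
                lab = np.zeros(idx.size, dtype=bool)
                lab[i1.size:] = True
                theta = wc_theta_pair_haploid(codes[idx], lab)
                theta = 0.0 if np.isnan(theta) else min(max(theta, 0.0), 1.0)
            names.append(f"mt.{p1}-{p2}.fst")
            values.append(theta)

    return SummaryVector(tuple(names), np.array(values, dtype=float))
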