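"""Domain containers and file I/O for microsatellite and mtDNA datasets.

The package works with two primary containers: :class:`GenotypeDataset`
(diploid allele-size matrices with population labels) and
:class:`HaplotypeAlignment` (equal-length haploid sequences with population
labels and annotated indel blocks).  Readers and writers cover the two text
dialects that dominate microsatellite work — Genepop (2- and 3-digit allele
codes) and the two-row STRUCTURE layout — plus FASTA alignments via Biopython.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Sentinel for a missing allele / genotype.  Distinguishable from any valid
#: allele size, which must be a positive integer.
MISSING = -1


class ParseError(ValueError):
    """Raised when an input file violates its format; names the line."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes with population labels.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)`` and holds integer
    allele sizes, with :data:`MISSING` marking an untyped genotype.  Allele
    pairs are unordered; the constructor canonicalises each pair (ascending)
    so that datasets compare equal regardless of input phase.
    """

    individual_ids: list[str]
    population_of: dict[str, str]
    loci: list[str]
    alleles: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        n, L = len(self.individual_ids), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        missing_pops = [i for i in self.individual_ids if i not in self.population_of]
        if missing_pops:
            raise ValueError(f"no population for individuals {missing_pops[:5]}")
        # one allele missing implies the genotype is missing
        half = (self.alleles == MISSING).any(axis=2)
        self.alleles[half] = MISSING
        self.alleles = np.sort(self.alleles, axis=2)

    # -- structure helpers ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population names, ordered by first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)

    def members(self, population: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``population``."""
        return np.array(
            [
                i
                for i, ind in enumerate(self.individual_ids)
                if self.population_of[ind] == population
            ],
            dtype=np.intp,
        )

    def subset(self, populations: list[str]) -> "GenotypeDataset":
        idx = np.concatenate([self.members(p) for p in populations])
        ids = [self.individual_ids[i] for i in idx]
        return GenotypeDataset(
            individual_ids=ids,
            population_of={i: self.population_of[i] for i in ids},
            loci=list(self.loci),
            alleles=self.alleles[idx].copy(),
        )

    def allele_counts(self, population: str, locus: int) -> dict[int, int]:
        """Multiset of observed gene copies at one population x locus cell."""
        a = self.alleles[self.members(population), locus, :].ravel()
        a = a[a != MISSING]
        vals, counts = np.unique(a, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.population_of == other.population_of
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class HaplotypeAlignment:
    """Aligned haploid sequences over ``{A, C, G, T, -, N}``.

    ``indel_blocks`` lists maximal runs of gap columns with a constant
    gapped-sequence pattern, as ``(start, end, label)`` with ``end``
    exclusive.  Such a block is treated downstream as a single
    presence/absence character (one mutational step).
    """

    sequence_ids: list[str]
    population_of: dict[str, str]
    sequences: list[str]
    indel_blocks: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("sequences are not all the same length")
        for s, e, _ in self.indel_blocks:
            if not (0 <= s < e <= L):
                raise ValueError(f"indel block ({s},{e}) out of bounds")
        spans = sorted((s, e) for s, e, _ in self.indel_blocks)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("overlapping indel blocks")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid in self.sequence_ids:
            seen.setdefault(self.population_of[sid], None)
        return list(seen)

    def members(self, population: str) -> list[int]:
        return [
            i
            for i, sid in enumerate(self.sequence_ids)
            if self.population_of[sid] == population
        ]


@dataclass
class PopulationTable:
    """Per-population metadata: map number, expected N, coordinates, park flag."""

    table: pd.DataFrame

    REQUIRED = ("name", "sample_size")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"population table lacks column {col!r}")
        if self.table["name"].duplicated().any():
            raise ValueError("population names are not unique")

    @classmethod
    def from_csv(cls, path) -> "PopulationTable":
        return cls(pd.read_csv(path))

    @classmethod
    def study_sites(cls) -> "PopulationTable":
        """The 24-site European fallow deer survey layout shipped with the
        package (sample sizes, map numbers, refugial source region, park flag
        and the published per-site diversity values)."""
        ref = importlib.resources.files("fallowpop.data") / "site_survey.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
        df = df.rename(columns={"n": "sample_size"})
        return cls(df)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def sample_size(self, name: str) -> int:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise KeyError(name)
        return int(row["sample_size"].iloc[0])


def mtdna_survey_table() -> pd.DataFrame:
    """Published per-country mtDNA diversity metrics (haplotype counts,
    haplotype diversity, nucleotide diversity) for the study regions."""
    ref = importlib.resources.files("fallowpop.data") / "mtdna_survey.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


@dataclass
class StudyConfig:
    """Run-level configuration: the master seed fully determines any
    stochastic computation; times are converted with ``generation_time_years``
    (1 year by default, 5.9 the published alternative)."""

    seed: int = 0
    generation_time_years: float = 1.0
    paths: dict[str, str] = field(default_factory=dict)
    toggles: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be positive")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Flat ``key = value`` text config; unknown keys go to ``paths``."""
        kwargs: dict = {"paths": {}, "toggles": {}}
        with open(path) as fh:
            for ln, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParseError(f"{path}:{ln}: expected key = value")
                key, val = (t.strip() for t in line.split("=", 1))
                if key == "seed":
                    kwargs["seed"] = int(val)
                elif key == "generation_time_years":
                    kwargs["generation_time_years"] = float(val)
                elif val.lower() in ("true", "false"):
                    kwargs["toggles"][key] = val.lower() == "true"
                else:
                    kwargs["paths"][key] = val
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Genepop


def _decode_genotype(tok: str, digits: int, path: str, ln: int) -> tuple[int, int]:
    if len(tok) != 2 * digits or not tok.isdigit():
        raise ParseError(
            f"{path}:{ln}: genotype {tok!r} does not match the "
            f"{digits}-digit dialect"
        )
    a, b = int(tok[:digits]), int(tok[digits:])
    if a == 0 or b == 0:
        if a != b:
            raise ParseError(f"{path}:{ln}: half-missing genotype {tok!r}")
        return (MISSING, MISSING)
    return (a, b)


def read_genepop(path, dialect: str = "3-digit") -> GenotypeDataset:
    """Read a Genepop file.

    Populations are delimited by ``POP`` records.  Individual labels of the
    form ``population:individual`` (the convention :func:`write_genepop`
    emits) assign the population name; otherwise populations are named
    ``pop_1``, ``pop_2``, ...  The all-zero code decodes to missing.
    """
    digits = {"2-digit": 2, "3-digit": 3}.get(dialect)
    if digits is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}:1: empty file")

    loci: list[str] = []
    i = 1  # line 0 is the title
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = lines[i].strip()
        if not chunk:
            raise ParseError(f"{path}:{i + 1}: blank line in locus header")
        loci.extend(t.strip() for t in chunk.split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no POP record found")
    if not loci:
        raise ParseError(f"{path}: no locus names before first POP")

    ids: list[str] = []
    pops: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    pop_name = None
    for ln in range(i, len(lines)):
        line = lines[ln].strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_idx += 1
            pop_name = None
            continue
        if "," not in line:
            raise ParseError(f"{path}:{ln + 1}: expected 'id , genotypes'")
        label, geno = line.split(",", 1)
        label = label.strip()
        if ":" in label:
            pname, iid = label.split(":", 1)
        else:
            pname, iid = f"pop_{pop_idx}", label
        if pop_name is None:
            pop_name = pname
        toks = geno.split()
        if len(toks) != len(loci):
            raise ParseError(
                f"{path}:{ln + 1}: {len(toks)} genotypes for {len(loci)} loci"
            )
        uid = iid
        k = 1
        while uid in pops:
            k += 1
            uid = f"{iid}.{k}"
        ids.append(uid)
        pops[uid] = pop_name
        rows.append([_decode_genotype(t, digits, str(path), ln + 1) for t in toks])

    if not ids:
        raise ParseError(f"{path}: no individuals")
    return GenotypeDataset(ids, pops, loci, np.array(rows, dtype=np.int32))


def write_genepop(dataset: GenotypeDataset, path, dialect: str = "3-digit",
                  title: str = "fallowpop export") -> None:
    """Write Genepop; inverse of :func:`read_genepop` on valid datasets."""
    digits = {"2-digit": 2, "3-digit": 3}.get(dialect)
    if digits is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    limit = 10 ** digits
    valid = dataset.alleles[dataset.alleles != MISSING]
    if valid.size and (valid.min() < 1 or valid.max() >= limit):
        raise ValueError(
            f"allele sizes outside [1, {limit - 1}] cannot be written in the "
            f"{dialect} dialect"
        )
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in dataset.loci:
            fh.write(locus + "\n")
        for pop in dataset.populations:
            fh.write("POP\n")
            for i in dataset.members(pop):
                iid = dataset.individual_ids[i]
                toks = []
                for pair in dataset.alleles[i]:
                    a, b = (0, 0) if pair[0] == MISSING else (pair[0], pair[1])
                    toks.append(f"{a:0{digits}d}{b:0{digits}d}")
                fh.write(f"{pop}:{iid} , " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE two-row text


def read_structure(path) -> GenotypeDataset:
    """Two-rows-per-individual STRUCTURE text; column 2 is the population
    label, -9 is missing.  The first line lists locus names."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}:1: empty file")
    loci = lines[0].split()
    body = lines[1:]
    if len(body) % 2:
        raise ParseError(f"{path}: odd number of genotype rows")
    ids, pops, rows = [], {}, []
    for r in range(0, len(body), 2):
        t1, t2 = body[r].split(), body[r + 1].split()
        if len(t1) != len(loci) + 2 or len(t2) != len(loci) + 2:
            raise ParseError(f"{path}: row {r + 2}: wrong field count")
        if t1[0] != t2[0] or t1[1] != t2[1]:
            raise ParseError(f"{path}: row {r + 2}: mismatched individual rows")
        iid, pop = t1[0], t1[1]
        ids.append(iid)
        pops[iid] = pop
        pair_rows = []
        for a, b in zip(t1[2:], t2[2:]):
            a, b = int(a), int(b)
            pair_rows.append(
                (MISSING, MISSING) if a == -9 or b == -9 else (a, b)
            )
        rows.append(pair_rows)
    return GenotypeDataset(ids, pops, loci, np.array(rows, dtype=np.int32))


def write_structure(dataset: GenotypeDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(dataset.loci) + "\n")
        for pop in dataset.populations:
            for i in dataset.members(pop):
                iid = dataset.individual_ids[i]
                for k in (0, 1):
                    row = [
                        str(-9 if a == MISSING else int(a))
                        for a in dataset.alleles[i, :, k]
                    ]
                    fh.write(f"{iid} {pop} " + " ".join(row) + "\n")


# ---------------------------------------------------------------------------
# FASTA alignments


def detect_indel_blocks(sequences: list[str]) -> list[tuple[int, int, str]]:
    """Maximal runs of gap-containing columns whose gapped-sequence pattern is
    constant across the run.  Each run is one presence/absence character."""
    if not sequences or not any("-" in s for s in sequences):
        return []
    arr = np.array([list(s) for s in sequences])
    gap = arr == "-"
    anygap = gap.any(axis=0)
    blocks = []
    start = None
    for j in range(arr.shape[1] + 1):
        boundary = (
            j == arr.shape[1]
            or not anygap[j]
            or (start is not None and not np.array_equal(gap[:, j], gap[:, start]))
        )
        if start is not None and boundary:
            blocks.append((start, j, f"indel_{start}_{j - start}"))
            start = None
        if j < arr.shape[1] and anygap[j] and start is None:
            start = j
    return blocks


def read_fasta_alignment(path, populations: dict[str, str] | None = None
                         ) -> HaplotypeAlignment:
    """Read an aligned FASTA.  Population labels come either from the
    ``populations`` map or from record ids of the form ``id|population``;
    unlabelled records go to population ``"all"``.  Indel blocks are
    auto-detected (see :func:`detect_indel_blocks`)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty FASTA")
    ids, seqs, pops = [], [], {}
    for rec in records:
        rid = rec.id
        if populations is not None:
            pop = populations.get(rid, "all")
        elif "|" in rid:
            rid, pop = rid.rsplit("|", 1)
        else:
            pop = "all"
        ids.append(rid)
        pops[rid] = pop
        seqs.append(str(rec.seq).upper())
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ParseError(f"{path}: records are not all the same length")
    return HaplotypeAlignment(ids, pops, seqs, detect_indel_blocks(seqs))


def write_fasta_alignment(alignment: HaplotypeAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.sequence_ids, alignment.sequences):
            fh.write(f">{sid}|{alignment.population_of[sid]}\n{seq}\n")


# ---------------------------------------------------------------------------
# pooling and validation


def pool_populations(data, groups: dict[str, list[str]]):
    """Merge populations according to ``groups`` (new name -> member names).

    Works on either container (both carry ``population_of``).  Populations not
    mentioned are kept unchanged; members must exist and be disjoint.
    """
    seen: set[str] = set()
    existing = set(data.populations)
    for new, members in groups.items():
        for m in members:
            if m not in existing:
                raise ValueError(f"unknown population {m!r} in group {new!r}")
            if m in seen:
                raise ValueError(f"population {m!r} appears in two groups")
            seen.add(m)
    relabel = {m: new for new, members in groups.items() for m in members}
    new_map = {
        ind: relabel.get(pop, pop) for ind, pop in data.population_of.items()
    }
    return replace(data, population_of=new_map)


@dataclass
class ValidationReport:
    per_population: pd.DataFrame
    failures: list[str]
    total_individuals: int
    n_populations: int

    @property
    def passed(self) -> bool:
        return not self.failures


def validate_dataset(dataset: GenotypeDataset, table: PopulationTable
                     ) -> ValidationReport:
    """Check a dataset against a population table: per-population sample
    sizes, missing-data rates and duplicate ids.  Failures are reported, not
    raised."""
    failures: list[str] = []
    recs = []
    pops = dataset.populations
    for pop in pops:
        idx = dataset.members(pop)
        n = len(idx)
        miss = float((dataset.alleles[idx, :, 0] == MISSING).mean()) if n else 0.0
        try:
            expected = table.sample_size(pop)
        except KeyError:
            expected = None
            failures.append(f"population {pop!r} missing from table")
        if expected is not None and expected != n:
            failures.append(f"population {pop!r}: N={n}, table says {expected}")
        recs.append(
            {"population": pop, "n": n, "missing_rate": miss,
             "expected_n": expected}
        )
    for name in table.names:
        if name not in pops:
            failures.append(f"table population {name!r} absent from dataset")
    return ValidationReport(
        per_population=pd.DataFrame(recs),
        failures=failures,
        total_individuals=dataset.n_individuals,
        n_populations=len(pops),
    )
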