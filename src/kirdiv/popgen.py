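"""Population statistics: allele frequencies, heterozygosity, rarefaction.

Heterozygosity (gene diversity) follows Nei & Tajima: the uncorrected form
is ``1 - sum(p_i^2)``; the unbiased small-sample form multiplies by
``n/(n-1)`` with ``n`` the number of gene copies (2N for diploids).
Rarefaction resamples gene copies without replacement to estimate the
expected number of distinct alleles at each sample size, with Monte-Carlo
quantile envelopes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from kirdiv.sequence_io import parse_allele_name


@dataclass
class PopulationFrequencyTable:
    population: str
    n_individuals: int
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("N must be >= 1")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("negative frequency")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")

    def collapse_to_allotype(self) -> "PopulationFrequencyTable":
        """Sum frequencies over alleles sharing the first-three-digit group."""
        out: dict[str, float] = {}
        for allele, f in self.frequencies.items():
            gene, allotype, _ = parse_allele_name(allele)
            out[f"{gene}*{allotype}"] = out.get(f"{gene}*{allotype}", 0.0) + f
        return PopulationFrequencyTable(self.population, self.n_individuals, out)


@dataclass
class GenotypeTable:
    """Two allele calls per diploid individual."""

    population: str
    genotypes: list[tuple[str, str]]
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.individuals:
            self.individuals = [f"ind{i + 1}" for i in range(len(self.genotypes))]
        if len(self.individuals) != len(self.genotypes):
            raise ValueError("individuals and genotypes differ in length")
        for ind, g in zip(self.individuals, self.genotypes):
            if len(g) != 2:
                raise ValueError(f"individual {ind}: expected exactly 2 allele calls, got {len(g)}")

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    def gene_copies(self, drop_missing: bool = True) -> list[str]:
        """Flat list of allele calls; missing calls ('') dropped copy-wise."""
        copies = [a for g in self.genotypes for a in g]
        if drop_missing:
            copies = [a for a in copies if a]
        return copies

    @classmethod
    def from_tsv(cls, path: str | Path, population: str | None = None) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        pops = df["population"].unique()
        if population is None:
            if len(pops) != 1:
                raise ValueError(f"file holds populations {list(pops)}; specify one")
            population = pops[0]
        sub = df[df["population"] == population]
        return cls(
            population=population,
            genotypes=[(r.allele1, r.allele2) for r in sub.itertuples()],
            individuals=list(sub["individual"]),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("population\tindividual\tallele1\tallele2\n")
            for ind, (a1, a2) in zip(self.individuals, self.genotypes):
                fh.write(f"{self.population}\t{ind}\t{a1}\t{a2}\n")


def frequencies_from_genotypes(
    g: GenotypeTable, collapse: bool = False
) -> PopulationFrequencyTable:
    """Allele (or allotype) frequencies as copy count / total copies."""
    copies = g.gene_copies()
    if not copies:
        raise ValueError(f"population {g.population}: no non-missing allele calls")
    counts = Counter(copies)
    total = sum(counts.values())
    table = PopulationFrequencyTable(
        g.population, g.n_individuals, {a: c / total for a, c in counts.items()}
    )
    return table.collapse_to_allotype() if collapse else table


def heterozygosity(f: PopulationFrequencyTable, unbiased: bool = True) -> float:
    """Nei-Tajima gene diversity; unbiased form uses n/(n-1), n = 2N copies."""
    h = 1.0 - sum(p * p for p in f.frequencies.values())
    if unbiased:
        n = 2 * f.n_individuals
        if n < 2:
            raise ValueError("unbiased correction needs >= 2 gene copies")
        h *= n / (n - 1)
    return h


@dataclass
class RarefactionCurve:
    locus: str
    n: np.ndarray  # gene copies sampled, 1..total
    mean: np.ndarray
    q05: np.ndarray
    q95: np.ndarray
    permutations: int
    seed: int

    @property
    def individuals_axis(self) -> np.ndarray:
        """Fig-style x-axis in individuals (gene copies / 2)."""
        return self.n / 2.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("locus\tn_copies\tn_individuals\tmean\tq05\tq95\n")
            for i in range(len(self.n)):
                fh.write(
                    f"{self.locus}\t{self.n[i]}\t{self.n[i] / 2:g}\t"
                    f"{self.mean[i]:.6g}\t{self.q05[i]:.6g}\t{self.q95[i]:.6g}\n"
                )


def rarefaction_curve(
    g: GenotypeTable,
    locus: str = "",
    permutations: int = 200,
    seed: int = 1,
) -> RarefactionCurve:
    """Distinct-allele rarefaction by resampling gene copies.

    For each n from 1 to the total number of genotyped copies, n copies are
    drawn without replacement and the distinct alleles counted; the mean
    and the 0.05/0.95 quantiles over the permutations are reported.  Each
    permutation is one shuffle of the copy list, so all n share draws.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    copies = np.array(g.gene_copies())
    total = len(copies)
    if total == 0:
        raise ValueError("no gene copies")
    _, codes = np.unique(copies, return_inverse=True)
    rng = np.random.default_rng(seed)
    counts = np.empty((permutations, total), dtype=np.int64)
    for p in range(permutations):
        perm = rng.permutation(codes)
        seen = np.zeros(codes.max() + 1, dtype=bool)
        new = np.empty(total, dtype=np.int64)
        for i, c in enumerate(perm):
            new[i] = 0 if seen[c] else 1
            seen[c] = True
        counts[p] = np.cumsum(new)
    return RarefactionCurve(
        locus=locus or g.population,
        n=np.arange(1, total + 1),
        mean=counts.mean(axis=0),
        q05=np.quantile(counts, 0.05, axis=0),
        q95=np.quantile(counts, 0.95, axis=0),
        permutations=permutations,
        seed=seed,
    )


@dataclass
class SharedAllotypeSummary:
    presence: pd.DataFrame  # allotypes x populations, bool
    shared_in_all: list[str]
    population_counts: dict[str, int]
    modal: dict[str, list[str]]  # population -> modal allotype(s), >1 on tie


def shared_allotype_summary(
    tables: Sequence[PopulationFrequencyTable],
) -> SharedAllotypeSummary:
    """Cross-population allele-sharing summary.

    Reports, per allotype, the number of populations where it occurs; the
    set present in every population; and each population's most frequent
    allotype (all of them when tied, flagged by length > 1).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 populations")
    pops = [t.population for t in tables]
    alleles = sorted({a for t in tables for a in t.frequencies})
    presence = pd.DataFrame(
        {t.population: [t.frequencies.get(a, 0.0) > 0 for a in alleles] for t in tables},
        index=alleles,
    )
    counts = presence.sum(axis=1).to_dict()
    shared = [a for a in alleles if counts[a] == len(pops)]
    modal: dict[str, list[str]] = {}
    for t in tables:
        top = max(t.frequencies.values())
        modal[t.population] = sorted(a for a, f in t.frequencies.items() if f == top)
    return SharedAllotypeSummary(
        presence=presence, shared_in_all=shared, population_counts=counts, modal=modal
    )


@dataclass
class DimorphismResult:
    population: str
    ancestral: str
    derived: str
    freq_ancestral: float
    freq_derived: float
    n_copies: int
    missing_rate: float
    monomorphic: bool


def site_dimorphism(
    calls: Mapping[str, Sequence[str]],
    ancestral: str,
    derived: str,
    missing: str = "",
) -> list[DimorphismResult]:
    """Per-population frequencies of a two-state residue dimorphism.

    ``calls`` maps population -> one residue call per gene copy.  Any state
    other than the two declared ones (or missing) raises, listing the
    offending copies.
    """
    out = []
    for pop, states in calls.items():
        bad = [i for i, s in enumerate(states) if s not in (ancestral, derived, missing)]
        if bad:
            raise ValueError(
                f"population {pop}: unexpected third state at copy indices {bad[:10]}"
            )
        observed = [s for s in states if s != missing]
        n = len(observed)
        n_anc = sum(1 for s in observed if s == ancestral)
        fa = n_anc / n if n else float("nan")
        out.append(
            DimorphismResult(
                population=pop,
                ancestral=ancestral,
                derived=derived,
                freq_ancestral=fa,
                freq_derived=1.0 - fa if n else float("nan"),
                n_copies=n,
                missing_rate=1.0 - n / len(states) if states else 0.0,
                monomorphic=n_anc in (0, n) if n else True,
            )
        )
    return out


def heterozygosity_report(
    tables: Mapping[str, Mapping[str, PopulationFrequencyTable]], path: str | Path
) -> None:
    """TSV of heterozygosity per locus x population, both variants."""
    with open(path, "w") as fh:
        fh.write("locus\tpopulation\tN\theterozygosity_unbiased\theterozygosity\n")
        for locus, pops in tables.items():
            for pop, t in pops.items():
                fh.write(
                    f"{locus}\t{pop}\t{t.n_individuals}\t"
                    f"{heterozygosity(t, True):.6g}\t{heterozygosity(t, False):.6g}\n"
                )
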