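"""Synthetic allele cohorts with recoverable evolutionary ground truth.

The generator emulates the three input kinds the analysis pipeline
consumes: (1) codon-aligned allele CDS sets evolved along a random
coalescent tree under a kappa/omega codon substitution process with
per-domain or per-site rate classes (stop codons are disallowed states, so
every simulated allele translates cleanly unless a null allele is planted
explicitly); (2) per-population allele frequencies drawn from a symmetric
Dirichlet; (3) diploid genotype tables sampled under Hardy-Weinberg
equilibrium.  All randomness flows from one seed and the same seed and
config reproduce every output byte-identically.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import yaml
from Bio.Data.CodonTable import standard_dna_table

from kirdiv.phylo import PhyloTree
from kirdiv.popgen import GenotypeTable, PopulationFrequencyTable
from kirdiv.sequence_io import AlleleRecord, DomainMap, default_domain_map

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
SENSE_CODONS = sorted(standard_dna_table.forward_table)
_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are desk-fast: 20 alleles, 3 populations of 50 diploid
    individuals, kappa 2.5, and a coalescent tree rescaled to a total
    length of 2.0 expected neutral substitutions per codon — deep enough
    divergence that per-domain rate regimes leave a measurable footprint,
    in the spirit of the multi-species comparisons the pipeline targets.
    """

    seed: int = 1
    n_alleles: int = 20
    gene: str = "KIR3DL3S"  # synthetic gene tag used in allele names
    kappa: float = 2.5
    tree_length: float = 2.0  # expected neutral substitutions/codon, tree total
    per_domain_omega: dict[str, float] | None = None
    default_omega: float = 0.5
    planted_sites: dict[int, tuple[float, float]] = field(default_factory=dict)
    # ^ 1-based CDS codon -> (alpha, beta) overriding the domain class
    domain_map: DomainMap | None = None
    n_codons: int | None = None  # used when domain_map is None: single domain
    n_populations: int = 3
    dirichlet_concentration: float = 0.5
    n_individuals: int = 50
    root_cds: str | None = None
    dimorphic_codon: int | None = None  # force both states present everywhere
    itim_positions: tuple[int, int] = (341, 367)  # mature starts of the two slots

    def resolved_domain_map(self) -> DomainMap:
        if self.domain_map is not None:
            return self.domain_map
        if self.n_codons is not None:
            return DomainMap(segments=[("D", 1, self.n_codons)], leader_length_codons=0)
        return default_domain_map()


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    records: list[AlleleRecord]
    tree: PhyloTree
    truth: dict
    frequency_tables: list[PopulationFrequencyTable]
    genotype_tables: list[GenotypeTable]

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Emit FASTA, newick, truth TSV, frequency and genotype TSVs."""
        from kirdiv.sequence_io import write_allele_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_allele_fasta(self.records, outdir / "alleles.fasta")
        paths["fasta"] = str(outdir / "alleles.fasta")
        with open(outdir / "true_tree.nwk", "w") as fh:
            fh.write(self.tree.newick())
        paths["tree"] = str(outdir / "true_tree.nwk")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("codon\tdomain\talpha\tbeta\tplanted\n")
            for row in self.truth["sites"]:
                fh.write(
                    f"{row['codon']}\t{row['domain']}\t{row['alpha']:g}\t"
                    f"{row['beta']:g}\t{int(row['planted'])}\n"
                )
        paths["truth"] = str(outdir / "truth.tsv")
        with open(outdir / "frequencies.tsv", "w") as fh:
            fh.write("population\tN\tallele\tfrequency\n")
            for t in self.frequency_tables:
                for a, f in sorted(t.frequencies.items()):
                    fh.write(f"{t.population}\t{t.n_individuals}\t{a}\t{f:.8g}\n")
        paths["frequencies"] = str(outdir / "frequencies.tsv")
        with open(outdir / "genotypes.tsv", "w") as fh:
            fh.write("population\tindividual\tallele1\tallele2\n")
            for g in self.genotype_tables:
                for ind, (a1, a2) in zip(g.individuals, g.genotypes):
                    fh.write(f"{g.population}\t{ind}\t{a1}\t{a2}\n")
        paths["genotypes"] = str(outdir / "genotypes.tsv")
        return paths


# ---------------------------------------------------------------------------
# Tree and sequence evolution


def _coalescent_tree(n: int, rng: np.random.Generator) -> dendropy.Tree:
    """Kingman coalescent topology with exponential coalescence times."""
    ns = dendropy.TaxonNamespace([dendropy.Taxon(label=f"t{i}") for i in range(n)])
    nodes = [dendropy.Node(taxon=t) for t in ns]
    heights = [0.0] * n
    active = list(range(n))
    all_nodes = list(nodes)
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = dendropy.Node()
        all_nodes[a].edge.length = t - heights[a]
        all_nodes[b].edge.length = t - heights[b]
        parent.add_child(all_nodes[a])
        parent.add_child(all_nodes[b])
        all_nodes.append(parent)
        heights.append(t)
        active = [x for x in active if x not in (a, b)] + [len(all_nodes) - 1]
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=all_nodes[active[0]])
    tree.is_rooted = True
    return tree


def _codon_generator(kappa: float, alpha: float, beta: float) -> np.ndarray:
    """Uniform-frequency codon generator; stop codons are absent states.

    Scaled so alpha = beta = 1 gives one expected substitution per codon
    per unit branch length.
    """
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if c1[p] != c2[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            w = kappa if (c1[p], c2[p]) in _TRANSITIONS else 1.0
            w *= alpha if _AA[c1] == _AA[c2] else beta
            q[i, j] = w
    # neutral-scale normalisation shared by all (alpha, beta) classes
    qn = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if c1[p] != c2[p]]
            if len(diffs) == 1:
                qn[i, j] = kappa if (c1[diffs[0]], c2[diffs[0]]) in _TRANSITIONS else 1.0
    mu = qn.sum() / n
    q /= mu
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _transition_matrices(
    q: np.ndarray, lengths: Sequence[float]
) -> list[np.ndarray]:
    lam, vec = np.linalg.eigh(q)
    out = []
    for t in lengths:
        p = (vec * np.exp(lam * t)) @ vec.T
        p = np.clip(p, 0.0, None)
        p /= p.sum(axis=1, keepdims=True)
        out.append(p)
    return out


def _evolve_sites(
    tree: dendropy.Tree,
    root_states: np.ndarray,
    site_class: np.ndarray,
    classes: list[tuple[float, float]],
    kappa: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve codon states site-independently down the tree.

    ``site_class[s]`` indexes into ``classes`` (alpha, beta) per site.
    Returns leaf-label -> codon index array.
    """
    nodes = list(tree.preorder_node_iter())
    lengths = [max(n.edge.length or 0.0, 0.0) for n in nodes]
    pmats: dict[int, list[np.ndarray]] = {}
    for k, (a, b) in enumerate(classes):
        q = _codon_generator(kappa, a, b)
        pmats[k] = _transition_matrices(q, lengths)

    states: dict[int, np.ndarray] = {id(nodes[0]): root_states.copy()}
    leaf_states: dict[str, np.ndarray] = {}
    for ni, node in enumerate(nodes):
        if node is nodes[0]:
            cur = states[id(node)]
        else:
            parent_states = states[id(node.parent_node)]
            cur = parent_states.copy()
            for k in range(len(classes)):
                mask = site_class == k
                if not mask.any():
                    continue
                p = pmats[k][ni]
                u = rng.random(mask.sum())
                cdf = np.cumsum(p[parent_states[mask]], axis=1)
                cur[mask] = (u[:, None] > cdf).sum(axis=1)
            states[id(node)] = cur
        if node.is_leaf():
            leaf_states[node.taxon.label] = cur
    return leaf_states


def _random_root(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    states = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    states[0] = SENSE_CODONS.index("ATG")
    return states


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Simulate a full cohort: tree, alleles, frequencies, genotypes, truth."""
    dm = cfg.resolved_domain_map()
    n_codons = dm.n_codons
    for codon in cfg.planted_sites:
        if not 1 <= codon <= n_codons:
            raise ValueError(f"planted site codon {codon} outside CDS (1..{n_codons})")
    if cfg.dimorphic_codon is not None and not 1 <= cfg.dimorphic_codon <= n_codons:
        raise ValueError(f"dimorphic codon {cfg.dimorphic_codon} outside CDS")
    rng = np.random.default_rng(cfg.seed)

    # per-site (alpha, beta) classes
    per_dom = cfg.per_domain_omega or {}
    site_ab: list[tuple[float, float]] = []
    planted_flags = []
    for codon in range(1, n_codons + 1):
        dom = dm.domain_of_codon(codon)
        omega = per_dom.get(dom, cfg.default_omega)
        ab = (1.0, omega)
        planted = codon in cfg.planted_sites
        if planted:
            ab = cfg.planted_sites[codon]
        site_ab.append(ab)
        planted_flags.append(planted)
    classes = sorted(set(site_ab))
    site_class = np.array([classes.index(ab) for ab in site_ab])

    # root sequence
    if cfg.root_cds is not None:
        if len(cfg.root_cds) != 3 * n_codons:
            raise ValueError("root CDS length does not match domain map")
        root = np.array([SENSE_CODONS.index(cfg.root_cds[i : i + 3]) for i in range(0, 3 * n_codons, 3)])
    else:
        root = _random_root(n_codons, rng)

    # tree, rescaled to the configured total length (subs/codon, neutral)
    if cfg.n_alleles == 1:
        leaf_states = {"t0": root.copy()}
        tree = dendropy.Tree()
        tree.seed_node.taxon = tree.taxon_namespace.new_taxon(label="t0")
        sim_tree = PhyloTree(tree=tree)
    else:
        tree = _coalescent_tree(cfg.n_alleles, rng)
        total = sum(max(e.length or 0.0, 0.0) for e in tree.preorder_edge_iter())
        scale = cfg.tree_length / total
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= scale
        leaf_states = _evolve_sites(tree, root, site_class, classes, cfg.kappa, rng)
        sim_tree = PhyloTree(tree=tree)

    # planted dimorphism: overwrite the column with exactly two states
    # (ancestral = root codon, derived = a one-step nonsynonymous neighbour)
    if cfg.dimorphic_codon is not None:
        s = cfg.dimorphic_codon - 1
        labels = sorted(leaf_states)
        base = SENSE_CODONS[root[s]]
        alts = [
            c for c in SENSE_CODONS
            if sum(a != b for a, b in zip(c, base)) == 1 and _AA[c] != _AA[base]
        ]
        alt = SENSE_CODONS.index(alts[int(rng.integers(len(alts)))])
        flip = set(rng.choice(len(labels), size=max(1, len(labels) // 2), replace=False).tolist())
        for i, l in enumerate(labels):
            leaf_states[l][s] = alt if i in flip else root[s]

    # population frequencies over leaves (Dirichlet), then IPD-style names
    labels = sorted(leaf_states)
    n = len(labels)
    pop_freqs = rng.dirichlet([cfg.dirichlet_concentration] * n, size=cfg.n_populations)
    mean_freq = pop_freqs.mean(axis=0)

    proteins: dict[str, str] = {}
    for l in labels:
        cds = "".join(SENSE_CODONS[i] for i in leaf_states[l])
        proteins[l] = cds
    # group by protein (allotype), order groups and members by mean frequency
    by_protein: dict[str, list[str]] = {}
    for l in labels:
        aa = "".join(_AA[proteins[l][i : i + 3]] for i in range(0, 3 * n_codons, 3))
        by_protein.setdefault(aa, []).append(l)
    freq_of = dict(zip(labels, mean_freq))
    groups = sorted(
        by_protein.values(), key=lambda g: -sum(freq_of[l] for l in g)
    )
    name_of: dict[str, str] = {}
    for gi, group in enumerate(groups, start=1):
        for vi, l in enumerate(sorted(group, key=lambda x: -freq_of[x]), start=1):
            name_of[l] = f"{cfg.gene}*{gi:03d}{vi:02d}"

    records = [
        AlleleRecord(name=name_of[l], cds=proteins[l], species="Homo")
        for l in sorted(labels, key=lambda x: name_of[x])
    ]
    # rename tree leaves to allele names
    if cfg.n_alleles > 1:
        for lf in sim_tree.tree.leaf_node_iter():
            lf.taxon.label = name_of[lf.taxon.label]
    else:
        sim_tree.tree.seed_node.taxon.label = name_of["t0"]

    freq_tables = []
    geno_tables = []
    allele_names = [name_of[l] for l in labels]
    for p in range(cfg.n_populations):
        f = pop_freqs[p]
        table = PopulationFrequencyTable(
            population=f"pop{p + 1}",
            n_individuals=cfg.n_individuals,
            frequencies={a: float(x) for a, x in zip(allele_names, f) if x > 0},
        )
        freq_tables.append(table)
        # HWE genotypes; when a dimorphism is planted, resample until both
        # residue states occur among the population's gene copies, then
        # force one copy if the minor state has negligible mass
        if cfg.dimorphic_codon is not None:
            s = cfg.dimorphic_codon - 1
            aa_of_allele = {
                name_of[l]: _AA[proteins[l][3 * s : 3 * s + 3]] for l in labels
            }
        for _ in range(100):
            draws = rng.choice(allele_names, size=(cfg.n_individuals, 2), p=f)
            if cfg.dimorphic_codon is None:
                break
            if len({aa_of_allele[nm] for nm in draws.ravel()}) > 1:
                break
        else:
            present = {aa_of_allele[nm] for nm in draws.ravel()}
            missing_carriers = [a for a in allele_names if aa_of_allele[a] not in present]
            if missing_carriers:
                i = int(rng.integers(cfg.n_individuals))
                draws[i, 1] = missing_carriers[int(rng.integers(len(missing_carriers)))]
        geno_tables.append(
            GenotypeTable(
                population=f"pop{p + 1}",
                genotypes=[tuple(row) for row in draws],
            )
        )

    truth = {
        "sites": [
            {
                "codon": i + 1,
                "domain": dm.domain_of_codon(i + 1),
                "alpha": site_ab[i][0],
                "beta": site_ab[i][1],
                "planted": planted_flags[i],
            }
            for i in range(n_codons)
        ],
        "name_of_leaf": name_of,
        "planted_nulls": [],
    }
    return SyntheticCohort(
        config=cfg,
        records=records,
        tree=sim_tree,
        truth=truth,
        frequency_tables=freq_tables,
        genotype_tables=geno_tables,
    )


def simulate_lineage_panel(
    seed: int = 1,
    n_lineages: int = 5,
    refs_per_lineage: int = 4,
    queries_per_lineage: int = 1,
    n_codons: int = 150,
    divergence: float = 0.6,
    within: float = 0.08,
    kappa: float = 2.5,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], dict[str, str]]:
    """Labeled reference clades plus within-clade query sequences.

    Emulates the deep-lineage structure of a receptor family: one founder
    per lineage evolved ``divergence`` expected neutral substitutions per
    codon from a common root, then a shallow coalescent of references and
    queries (total length ``within``) inside each clade.

    Returns ``(queries, references, lineage_of_reference, truth)`` where
    truth maps each query to its source lineage.
    """
    rng = np.random.default_rng(seed)
    lineage_names = ["I", "II", "III", "IV", "V"][:n_lineages]
    root = _random_root(n_codons, rng)
    site_class = np.zeros(n_codons, dtype=int)
    classes = [(1.0, 1.0)]
    queries: dict[str, str] = {}
    references: dict[str, str] = {}
    labels: dict[str, str] = {}
    truth: dict[str, str] = {}
    for lin in lineage_names:
        # founder: evolve root along one branch of the given length
        chain = dendropy.Tree()
        child = dendropy.Node(taxon=chain.taxon_namespace.new_taxon(label="f"))
        child.edge.length = divergence
        chain.seed_node.add_child(child)
        founder = _evolve_sites(chain, root, site_class, classes, kappa, rng)["f"]
        k = refs_per_lineage + queries_per_lineage
        clade = _coalescent_tree(k, rng)
        total = sum(max(e.length or 0.0, 0.0) for e in clade.preorder_edge_iter())
        for e in clade.preorder_edge_iter():
            if e.length is not None:
                e.length *= within / total
        leaves = _evolve_sites(clade, founder, site_class, classes, kappa, rng)
        tips = sorted(leaves)
        for i, tip in enumerate(tips):
            cds = "".join(SENSE_CODONS[x] for x in leaves[tip])
            if i < refs_per_lineage:
                name = f"ref_{lin}_{i + 1}"
                references[name] = cds
                labels[name] = lin
            else:
                name = f"query_{lin}_{i - refs_per_lineage + 1}"
                queries[name] = cds
                truth[name] = lin
    return queries, references, labels, truth


def plant_null_allele(
    cohort: SyntheticCohort, domain: str, seed: int = 1
) -> SyntheticCohort:
    """Return a copy of the cohort with one premature stop planted.

    One allele is chosen at random and one codon within the named domain is
    replaced by a stop codon (the codon-aligned realisation of a truncating
    single-base insertion).  The truth table records the change so it can
    be reverted exactly.
    """
    dm = cohort.config.resolved_domain_map()
    segs = {l: (s, e) for l, s, e in dm.segments}
    if domain not in segs:
        raise ValueError(f"domain {domain!r} not in map (have {list(segs)})")
    start, end = segs[domain]
    end = min(end, dm.n_codons - 1)  # never the final codon
    rng = np.random.default_rng(seed)
    new = copy.deepcopy(cohort)
    rec = new.records[int(rng.integers(len(new.records)))]
    codon = int(rng.integers(start, end + 1))
    old = rec.cds[(codon - 1) * 3 : codon * 3]
    cds = rec.cds[: (codon - 1) * 3] + "TGA" + rec.cds[codon * 3 :]
    idx = new.records.index(rec)
    new.records[idx] = AlleleRecord(name=rec.name, cds=cds, species=rec.species)
    new.truth["planted_nulls"] = list(cohort.truth.get("planted_nulls", [])) + [
        {"allele": rec.name, "codon": codon, "original": old, "domain": domain}
    ]
    return new


def revert_null_alleles(cohort: SyntheticCohort) -> SyntheticCohort:
    """Undo every planted stop using the truth table (inverse of planting)."""
    new = copy.deepcopy(cohort)
    for entry in reversed(new.truth.get("planted_nulls", [])):
        for i, rec in enumerate(new.records):
            if rec.name == entry["allele"]:
                c = entry["codon"]
                cds = rec.cds[: (c - 1) * 3] + entry["original"] + rec.cds[c * 3 :]
                new.records[i] = AlleleRecord(name=rec.name, cds=cds, species=rec.species)
    new.truth["planted_nulls"] = []
    return new


def plant_itim_stop(cohort: SyntheticCohort, ordinal: int = 2, seed: int = 1) -> SyntheticCohort:
    """Plant a stop in the third codon of an ITIM slot of one allele,
    mirroring the truncating insertion that removed the second ITIM of
    human KIR3DL3."""
    cfg = cohort.config
    dm = cfg.resolved_domain_map()
    mature_start = cfg.itim_positions[ordinal - 1]
    codon = dm.mature_to_codon(mature_start) + 2  # third codon of the 6-mer
    rng = np.random.default_rng(seed)
    new = copy.deepcopy(cohort)
    rec = new.records[int(rng.integers(len(new.records)))]
    old = rec.cds[(codon - 1) * 3 : codon * 3]
    cds = rec.cds[: (codon - 1) * 3] + "TGA" + rec.cds[codon * 3 :]
    idx = new.records.index(rec)
    new.records[idx] = AlleleRecord(name=rec.name, cds=cds, species=rec.species)
    new.truth["planted_nulls"] = list(cohort.truth.get("planted_nulls", [])) + [
        {"allele": rec.name, "codon": codon, "original": old, "domain": dm.domain_of_codon(codon)}
    ]
    return new
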