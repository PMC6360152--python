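"""Pairwise dN/dS, the codon-based Z-test of neutrality, and site scans.

Pairwise rates follow Nei & Gojobori (1986): synonymous and nonsynonymous
site counts from codon degeneracy (optionally transition/transversion
weighted, the "modified" variant), substitution counts averaged over all
minimal mutational pathways that avoid stop codons, and Jukes-Cantor
correction of the proportions.  Domain-level selection is tested with the
codon-bootstrap Z-test on the difference of pairwise-averaged dN and dS.

The codon-by-codon scan offers two routes: a grid empirical-Bayes method
(per-site synonymous rate alpha and nonsynonymous rate beta on a fixed
grid, site likelihoods by Felsenstein pruning under a symmetric codon
model, grid weights by EM with a Dirichlet prior, per-site posterior
P(beta > alpha)) and a parsimony counting method with an extended binomial
test, used as a mutual cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.special import betainc
from scipy.stats import norm
from Bio.Data.CodonTable import standard_dna_table

from kirdiv.phylo import PhyloTree

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

SENSE_CODONS: list[str] = sorted(standard_dna_table.forward_table)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61
_AA = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}
_STOPS = set(standard_dna_table.stop_codons)


def _is_transition(x: str, y: str) -> bool:
    return (x, y) in _TRANSITIONS


@lru_cache(maxsize=4)
def synonymous_site_counts(kappa: float | None = None) -> np.ndarray:
    """Per-codon synonymous site counts s_c (nonsynonymous = 3 - s_c).

    Each codon position contributes the (weighted) fraction of its possible
    single-nucleotide changes that are synonymous; changes to stop codons
    are excluded from the opportunity set.  ``kappa`` weights transitions
    (the modified-NG variant); ``None`` gives plain NG86 equal weighting.
    """
    s = np.zeros(N_CODONS)
    for c in SENSE_CODONS:
        total = 0.0
        for p in range(3):
            wsyn = 0.0
            wall = 0.0
            for b in _BASES:
                if b == c[p]:
                    continue
                mut = c[:p] + b + c[p + 1 :]
                if mut in _STOPS:
                    continue
                w = (kappa if _is_transition(c[p], b) else 1.0) if kappa else 1.0
                wall += w
                if _AA[mut] == _AA[c]:
                    wsyn += w
            if wall > 0:
                total += wsyn / wall
        s[CODON_INDEX[c]] = total
    return s


@lru_cache(maxsize=1)
def pathway_difference_counts() -> tuple[np.ndarray, np.ndarray]:
    """(Sd, Nd) tables: per codon pair, synonymous and nonsynonymous
    difference counts averaged over all minimal mutational pathways that
    avoid stop codons (all pathways if every one passes through a stop)."""
    sd = np.zeros((N_CODONS, N_CODONS))
    nd = np.zeros((N_CODONS, N_CODONS))
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            if c1 == c2:
                continue
            positions = [p for p in range(3) if c1[p] != c2[p]]
            paths = []
            for order in itertools.permutations(positions):
                cur = c1
                steps = []
                via_stop = False
                for p in order:
                    nxt = cur[:p] + c2[p] + cur[p + 1 :]
                    if nxt in _STOPS:
                        via_stop = True
                    else:
                        steps.append(1.0 if _AA.get(nxt) == _AA.get(cur, object()) else 0.0)
                    cur = nxt
                if not via_stop:
                    paths.append(steps)
            if not paths:  # every pathway blocked by a stop: count through them
                for order in itertools.permutations(positions):
                    cur = c1
                    steps = []
                    for p in order:
                        nxt = cur[:p] + c2[p] + cur[p + 1 :]
                        syn = (
                            nxt not in _STOPS
                            and cur not in _STOPS
                            and _AA.get(nxt) == _AA.get(cur)
                        )
                        steps.append(1.0 if syn else 0.0)
                        cur = nxt
                    paths.append(steps)
            arr = np.array(paths)
            i, j = CODON_INDEX[c1], CODON_INDEX[c2]
            sd[i, j] = arr.sum(axis=1).mean()
            nd[i, j] = len(positions) - sd[i, j]
    return sd, nd


def encode_codons(cds: str) -> np.ndarray:
    """Codon index array; -1 for codons with gaps, N, or stops."""
    if len(cds) % 3:
        raise ValueError("length not multiple of 3")
    out = np.empty(len(cds) // 3, dtype=np.int64)
    for k in range(0, len(cds), 3):
        out[k // 3] = CODON_INDEX.get(cds[k : k + 3].upper(), -1)
    return out


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p <= 0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class PairwiseDnDs:
    pair: tuple[str, str]
    dn: float
    ds: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    codons_compared: int
    method: str = "NG86"

    @property
    def applicable(self) -> bool:
        return not (math.isnan(self.dn) or math.isnan(self.ds))


def ng86_pairwise(
    a: str,
    b: str,
    names: tuple[str, str] = ("a", "b"),
    method: str = "NG86",
    kappa: float = 2.0,
) -> PairwiseDnDs:
    """Nei-Gojobori pairwise dN and dS with codon-level pairwise deletion.

    ``method`` is ``"NG86"`` (unweighted sites) or ``"modified-NG"``
    (transition/transversion-weighted sites with the given kappa).
    Codons with a gap, N, or stop in either sequence are skipped.
    """
    ca, cb = encode_codons(a), encode_codons(b)
    if len(ca) != len(cb):
        raise ValueError("unequal codon lengths")
    mask = (ca >= 0) & (cb >= 0)
    ca, cb = ca[mask], cb[mask]
    kap = kappa if method == "modified-NG" else None
    ssites = synonymous_site_counts(kap)
    sd_t, nd_t = pathway_difference_counts()
    s = 0.5 * (ssites[ca].sum() + ssites[cb].sum())
    n = 3.0 * len(ca) - s
    sd = sd_t[ca, cb].sum()
    nd = nd_t[ca, cb].sum()
    ps = sd / s if s > 0 else 0.0
    pn = nd / n if n > 0 else 0.0
    return PairwiseDnDs(
        pair=names,
        dn=_jc_correct(pn),
        ds=_jc_correct(ps),
        n_sites=n,
        s_sites=s,
        nd=nd,
        sd=sd,
        codons_compared=int(len(ca)),
        method=method,
    )


@dataclass
class SelectionTest:
    scope: str
    mean_dn: float
    mean_ds: float
    ratio: float  # inf when mean_ds == 0; nan when undefined
    z: float
    p: float
    direction: str  # positive | negative | neutral
    reps: int
    method: str = "NG86"
    diagnostic: str = ""


def _pair_arrays(
    codons: np.ndarray, method: str, kappa: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-(pair, codon-column) site and difference contributions.

    Returns (Ssites, Nsites, Sd, Nd), each of shape (n_pairs, n_columns),
    zero where a column is deleted pairwise.
    """
    kap = kappa if method == "modified-NG" else None
    ssites = synonymous_site_counts(kap)
    sd_t, nd_t = pathway_difference_counts()
    nseq, ncol = codons.shape
    pairs = [(i, j) for i in range(nseq) for j in range(i + 1, nseq)]
    S = np.zeros((len(pairs), ncol))
    N = np.zeros((len(pairs), ncol))
    Sd = np.zeros((len(pairs), ncol))
    Nd = np.zeros((len(pairs), ncol))
    for k, (i, j) in enumerate(pairs):
        ci, cj = codons[i], codons[j]
        m = (ci >= 0) & (cj >= 0)
        S[k, m] = 0.5 * (ssites[ci[m]] + ssites[cj[m]])
        N[k, m] = 3.0 - S[k, m]
        Sd[k, m] = sd_t[ci[m], cj[m]]
        Nd[k, m] = nd_t[ci[m], cj[m]]
    return S, N, Sd, Nd


def _mean_rates(S, N, Sd, Nd, cols) -> tuple[float, float]:
    """Pairwise-averaged dN and dS over the selected codon columns."""
    s = S[:, cols].sum(axis=1)
    n = N[:, cols].sum(axis=1)
    sd = Sd[:, cols].sum(axis=1)
    nd = Nd[:, cols].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(s > 0, sd / np.maximum(s, 1e-300), 0.0)
        pn = np.where(n > 0, nd / np.maximum(n, 1e-300), 0.0)
        ds = np.where(ps < 0.75, -0.75 * np.log1p(-4 * ps / 3), np.nan)
        dn = np.where(pn < 0.75, -0.75 * np.log1p(-4 * pn / 3), np.nan)
    return float(np.nanmean(dn)), float(np.nanmean(ds))


def codon_z_test(
    block: Mapping[str, str],
    scope: str = "CDS",
    reps: int = 1000,
    seed: int = 1,
    method: str = "NG86",
    kappa: float = 2.0,
    alpha: float = 0.05,
) -> SelectionTest:
    """Codon-based Z-test of neutral evolution on an aligned codon block.

    dN and dS are each averaged over all pairs of unique sequences;
    Z = (mean dN - mean dS) / SE with SE the bootstrap (codon-column
    resampling) standard error of the difference.  The one-tailed p-value
    is for the alternative matching the sign of Z, and ``direction`` is
    set when p < alpha.  The reported ratio is the ratio of the averages.
    """
    uniq: dict[str, str] = {}
    for name, seq in block.items():
        if seq not in uniq.values():
            uniq[name] = seq
    if len(uniq) < 2:
        return SelectionTest(
            scope, 0.0, 0.0, math.nan, math.nan, 1.0, "neutral", reps, method,
            diagnostic="fewer than 2 unique sequences",
        )
    codons = np.stack([encode_codons(s) for s in uniq.values()])
    S, N, Sd, Nd = _pair_arrays(codons, method, kappa)
    ncol = codons.shape[1]
    all_cols = np.arange(ncol)
    mean_dn, mean_ds = _mean_rates(S, N, Sd, Nd, all_cols)
    if math.isnan(mean_dn) and math.isnan(mean_ds):
        raise ValueError("all sequence pairs inapplicable (saturated)")
    diff = mean_dn - mean_ds
    if diff == 0 and float(np.sum(Sd) + np.sum(Nd)) == 0:
        return SelectionTest(
            scope, 0.0, 0.0, math.nan, math.nan, 1.0, "neutral", reps, method,
            diagnostic="no substitutions observed; Z undefined",
        )
    rng = np.random.default_rng(seed)
    boot = np.empty(reps)
    for r in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        bdn, bds = _mean_rates(S, N, Sd, Nd, cols)
        boot[r] = bdn - bds
    se = float(np.nanstd(boot, ddof=1))
    if se == 0 or math.isnan(se):
        z = math.nan
        p = 1.0
        direction = "neutral"
        diag = "bootstrap SE zero; Z undefined"
    else:
        z = diff / se
        p = float(norm.sf(abs(z)))
        direction = "neutral"
        diag = ""
        if p < alpha:
            direction = "positive" if z > 0 else "negative"
    ratio = math.inf if mean_ds == 0 else mean_dn / mean_ds
    return SelectionTest(scope, mean_dn, mean_ds, ratio, z, p, direction, reps, method, diag)


# ---------------------------------------------------------------------------
# Codon-by-codon site selection scan


@dataclass
class SiteSelectionResult:
    mature_residue: int
    method: str  # grid-eb | counting
    posterior: float  # P(beta > alpha) for grid-eb; 1 - p(positive) for counting
    mean_alpha: float = math.nan
    mean_beta: float = math.nan
    flagged_90: bool = False
    flagged_95: bool = False

    def __post_init__(self) -> None:
        self.flagged_90 = self.posterior > 0.90
        self.flagged_95 = self.posterior > 0.95


def estimate_kappa(codons: np.ndarray) -> float:
    """Transition/transversion rate ratio by pairwise difference counting.

    Counts single-position differences between all sequence pairs; the
    rate ratio doubles the count ratio to correct for the two-fold
    transversion opportunity.  Falls back to 2.0 when no transversions
    are observed.
    """
    ts = tv = 0
    nseq = codons.shape[0]
    codon_str = np.array(SENSE_CODONS)
    for i in range(nseq):
        for j in range(i + 1, nseq):
            m = (codons[i] >= 0) & (codons[j] >= 0)
            for ci, cj in zip(codons[i][m], codons[j][m]):
                if ci == cj:
                    continue
                c1, c2 = codon_str[ci], codon_str[cj]
                for p in range(3):
                    if c1[p] != c2[p]:
                        if _is_transition(c1[p], c2[p]):
                            ts += 1
                        else:
                            tv += 1
    if tv == 0:
        return 2.0
    return max(2.0 * ts / tv, 0.1)


@lru_cache(maxsize=8)
def _codon_generators(kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric synonymous and nonsynonymous generator components.

    Uniform codon frequencies; single-nucleotide exchanges weighted kappa
    for transitions.  Scaled so the total rate at alpha = beta = 1 is one
    expected substitution per codon per unit branch length.
    """
    qs = np.zeros((N_CODONS, N_CODONS))
    qn = np.zeros((N_CODONS, N_CODONS))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if c1[p] != c2[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            w = kappa if _is_transition(c1[p], c2[p]) else 1.0
            if _AA[c1] == _AA[c2]:
                qs[i, j] = w
            else:
                qn[i, j] = w
    mu = (qs.sum() + qn.sum()) / N_CODONS  # mean leaving rate at alpha=beta=1
    qs /= mu
    qn /= mu
    np.fill_diagonal(qs, -qs.sum(axis=1))
    np.fill_diagonal(qn, -qn.sum(axis=1))
    return qs, qn


def default_rate_grid(k: int = 20, max_rate: float = 10.0) -> np.ndarray:
    """K rate values spanning (0, max], linear below 1, geometric above."""
    n_high = k // 2 - 2
    low = np.linspace(0.05, 1.0, k - n_high)
    high = np.geomspace(1.25, max_rate, n_high)
    return np.concatenate([low, high])


def _site_likelihoods_grid(
    codons: np.ndarray,
    names: Sequence[str],
    tree: PhyloTree,
    grid: np.ndarray,
    kappa: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Log site likelihoods on the (alpha, beta) grid by pruning.

    Returns (cells, loglik) where cells is (n_cells, 2) of (alpha, beta)
    and loglik is (n_sites, n_cells).
    """
    qs, qn = _codon_generators(round(kappa, 3))
    t = tree.tree.clone(depth=1)
    t.resolve_polytomies()
    leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    if leaves != set(names):
        raise ValueError("tree leaves do not match alignment sequences")
    name_row = {n: i for i, n in enumerate(names)}
    nsites = codons.shape[1]

    nodes = list(t.postorder_node_iter())
    # leaf partials: one-hot; missing data -> all ones
    partials0 = {}
    for node in nodes:
        if node.is_leaf():
            arr = np.ones((nsites, N_CODONS))
            row = codons[name_row[node.taxon.label]]
            obs = row >= 0
            arr[obs] = 0.0
            arr[np.arange(nsites)[obs], row[obs]] = 1.0
            partials0[id(node)] = arr

    cells = np.array([(a, b) for a in grid for b in grid])
    loglik = np.empty((nsites, len(cells)))
    # branch lengths rescaled: NJ distances are per nucleotide site -> per codon
    blens = {}
    for node in nodes:
        if node.parent_node is not None:
            bl = node.edge.length or 0.0
            blens[id(node)] = max(bl, 0.0) * 3.0

    for ci, (a, b) in enumerate(cells):
        q = a * qs + b * qn
        lam, vec = np.linalg.eigh(q)
        logscale = np.zeros(nsites)
        partial = {}
        for node in nodes:
            if node.is_leaf():
                partial[id(node)] = partials0[id(node)]
                continue
            acc = np.ones((nsites, N_CODONS))
            for child in node.child_nodes():
                p_mat = (vec * np.exp(lam * blens[id(child)])) @ vec.T
                acc *= partial[id(child)] @ p_mat.T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            logscale += np.log(mx)
            partial[id(node)] = acc / mx[:, None]
        root = partial[id(nodes[-1])]
        loglik[:, ci] = np.log(np.maximum(root.mean(axis=1), 1e-300)) + logscale
    return cells, loglik


def _em_grid_weights(
    loglik: np.ndarray, concentration: float = 0.5, tol: float = 1e-6, max_iter: int = 2000
) -> np.ndarray:
    """EM for grid mixture weights, smoothed by a symmetric Dirichlet prior.

    The M-step uses the Dirichlet posterior mean (expected counts plus the
    concentration), which keeps every grid cell alive and shrinks weights
    toward uniform rather than pruning the grid.
    """
    nsites, ncells = loglik.shape
    lik = np.exp(loglik - loglik.max(axis=1, keepdims=True))
    w = np.full(ncells, 1.0 / ncells)
    for _ in range(max_iter):
        resp = lik * w
        resp /= resp.sum(axis=1, keepdims=True)
        new = resp.sum(axis=0) + concentration
        new /= new.sum()
        if np.abs(new - w).max() < tol:
            w = new
            break
        w = new
    return w


def _grid_eb_scan(
    codons: np.ndarray,
    names: Sequence[str],
    tree: PhyloTree,
    first_mature_residue: int,
    grid_size: int,
) -> list[SiteSelectionResult]:
    kappa = estimate_kappa(codons)
    grid = default_rate_grid(grid_size)
    # Nucleotide-model branch lengths under-estimate codon-model depth, which
    # shifts the whole (alpha, beta) surface off-grid.  A second pass rescales
    # branch lengths by the posterior-mean synonymous rate so alpha centres
    # near 1 and the beta grid retains headroom for selected sites.
    scale = 1.0
    for _ in range(2):
        scaled = tree
        if scale != 1.0:
            scaled = PhyloTree(tree=tree.tree.clone(depth=1))
            for e in scaled.tree.preorder_edge_iter():
                if e.length is not None:
                    e.length *= scale
        cells, loglik = _site_likelihoods_grid(codons, names, scaled, grid, kappa)
        w = _em_grid_weights(loglik)
        lik0 = np.exp(loglik - loglik.max(axis=1, keepdims=True))
        post0 = lik0 * w
        post0 /= post0.sum(axis=1, keepdims=True)
        mean_alpha = float((post0 @ cells[:, 0]).mean())
        if 0.8 <= mean_alpha <= 1.25:
            break
        scale *= mean_alpha
    lik = np.exp(loglik - loglik.max(axis=1, keepdims=True))
    post = lik * w
    post /= post.sum(axis=1, keepdims=True)
    positive = cells[:, 1] > cells[:, 0]
    results = []
    for s in range(codons.shape[1]):
        if np.all(codons[:, s] < 0):
            continue  # entirely gapped site omitted
        pp = float(post[s, positive].sum())
        results.append(
            SiteSelectionResult(
                mature_residue=first_mature_residue + s,
                method="grid-eb",
                posterior=pp,
                mean_alpha=float(post[s] @ cells[:, 0]),
                mean_beta=float(post[s] @ cells[:, 1]),
            )
        )
    return results


def _fitch_counts(codons: np.ndarray, names: Sequence[str], tree: PhyloTree):
    """Parsimony substitution counts per site, decomposed syn/nonsyn."""
    sd_t, nd_t = pathway_difference_counts()
    t = tree.tree.clone(depth=1)
    t.resolve_polytomies()
    name_row = {n: i for i, n in enumerate(names)}
    nsites = codons.shape[1]
    nd = np.zeros(nsites)
    sd = np.zeros(nsites)
    for s in range(nsites):
        sets: dict[int, frozenset[int]] = {}
        for node in t.postorder_node_iter():
            if node.is_leaf():
                state = codons[name_row[node.taxon.label], s]
                sets[id(node)] = frozenset([int(state)]) if state >= 0 else frozenset()
            else:
                child_sets = [sets[id(c)] for c in node.child_nodes() if sets[id(c)]]
                if not child_sets:
                    sets[id(node)] = frozenset()
                    continue
                inter = frozenset.intersection(*child_sets)
                sets[id(node)] = inter if inter else frozenset.union(*child_sets)
        # top-down resolution, deterministic min-state tie break
        assign: dict[int, int] = {}
        for node in t.preorder_node_iter():
            st = sets[id(node)]
            if not st:
                parent = node.parent_node
                assign[id(node)] = assign.get(id(parent), -1) if parent else -1
                continue
            parent = node.parent_node
            if parent is not None and assign.get(id(parent), -1) in st:
                assign[id(node)] = assign[id(parent)]
            else:
                assign[id(node)] = min(st)
        for node in t.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            x, y = assign[id(parent)], assign[id(node)]
            if x >= 0 and y >= 0 and x != y:
                sd[s] += sd_t[x, y]
                nd[s] += nd_t[x, y]
    return sd, nd


def _extended_binomial_sf(k: float, n: float, p: float) -> float:
    """P(X >= k) for Binomial(n, p) extended to fractional counts via the
    regularized incomplete beta function; 1 when k <= 0."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(betainc(k, n - k + 1.0, p))


def _counting_scan(
    codons: np.ndarray,
    names: Sequence[str],
    tree: PhyloTree,
    first_mature_residue: int,
) -> list[SiteSelectionResult]:
    ssites = synonymous_site_counts(None)
    sd, nd = _fitch_counts(codons, names, tree)
    results = []
    for s in range(codons.shape[1]):
        obs = codons[:, s][codons[:, s] >= 0]
        if obs.size == 0:
            continue
        s_frac = float(ssites[obs].mean()) / 3.0
        p_nonsyn = 1.0 - s_frac
        total = sd[s] + nd[s]
        p_pos = _extended_binomial_sf(nd[s], total, p_nonsyn) if total > 0 else 1.0
        results.append(
            SiteSelectionResult(
                mature_residue=first_mature_residue + s,
                method="counting",
                posterior=1.0 - p_pos,
            )
        )
    return results


def site_selection_scan(
    block: Mapping[str, str],
    tree: PhyloTree | None = None,
    method: str = "grid-eb",
    seed: int = 1,
    first_mature_residue: int = 1,
    grid_size: int = 20,
) -> list[SiteSelectionResult]:
    """Codon-by-codon selection scan over an aligned block.

    Sequences are deduplicated within the block before analysis.  If no
    tree is given, an NJ tree with TN93 distances is built from the
    deduplicated block.  ``method`` selects the grid empirical-Bayes
    route or the parsimony counting route.
    """
    from kirdiv.phylo import distance_matrix, nj_build

    uniq: dict[str, str] = {}
    for name, seq in block.items():
        if seq not in uniq.values():
            uniq[name] = seq
    if len(uniq) < 3:
        raise ValueError("need at least 3 unique sequences for the site scan")
    names = list(uniq)
    codons = np.stack([encode_codons(uniq[n]) for n in names])
    if tree is None:
        tree = nj_build(distance_matrix(uniq))
    else:
        if {lf.taxon.label for lf in tree.tree.leaf_node_iter()} != set(names):
            raise ValueError("tree leaves do not match (deduplicated) alignment")
    if method == "grid-eb":
        return _grid_eb_scan(codons, names, tree, first_mature_residue, grid_size)
    if method == "counting":
        return _counting_scan(codons, names, tree, first_mature_residue)
    raise ValueError(f"unknown method {method!r}")


def selection_report(tests: Sequence[SelectionTest], path) -> None:
    with open(path, "w") as fh:
        fh.write("scope\tmethod\tmean_dN\tmean_dS\tratio\tZ\tp\tdirection\treps\n")
        for t in tests:
            fh.write(
                f"{t.scope}\t{t.method}\t{t.mean_dn:.6g}\t{t.mean_ds:.6g}\t"
                f"{t.ratio:.6g}\t{t.z:.6g}\t{t.p:.6g}\t{t.direction}\t{t.reps}\n"
            )


def site_report(results: Sequence[SiteSelectionResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("mature_residue\tmethod\tposterior\tmean_alpha\tmean_beta\tPP90\tPP95\n")
        for r in results:
            fh.write(
                f"{r.mature_residue}\t{r.method}\t{r.posterior:.6g}\t"
                f"{r.mean_alpha:.6g}\t{r.mean_beta:.6g}\t"
                f"{int(r.flagged_90)}\t{int(r.flagged_95)}\n"
            )
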