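# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `kirdiv`.

## Sequence handling and coordinates

A CDS is codon-aligned: length divisible by three, gaps (`-`) only in
whole-codon triples. Gap codons translate to `-`; codons containing `N`
translate to `X` and are excluded from codon statistics. An allele is
flagged null when a stop codon occurs before the final codon.

All codon and nucleotide coordinates are 1-based inclusive. The domain map
partitions the CDS into Leader / D0 / D1 / D2 / TM-Cyt; mature-protein
residue *r* sits at CDS codon *r* + leader length. The shipped default map
uses a 21-codon leader, which places mature residue 147 at CDS nucleotides
502–504 — the coordinate convention used when anchoring SNP calls to the
full-length CDS. The Ig-domain boundaries in the default map follow the
~100-codon exon organisation of three-domain KIR; they are a documented,
editable convention (no authoritative per-codon table exists), as is the
45-position binding-loop configuration, which ships as YAML and should be
validated against a structural reference before cross-gene work.

Novel-allele classification minimises the nucleotide-difference count to
the known set, breaking ties toward the lexicographically smallest known
name. A premature stop makes `null_allele`; an identical protein makes
`synonymous_variant`; anything else is `new_allotype`.

## Distances and trees

TN93 distances are computed from the transition-type proportions (A↔G,
C↔T, transversions) and base composition of the retained columns, with
pairwise deletion of any column carrying a gap or ambiguity in either
sequence. Base frequencies are pooled over both sequences. A non-positive
logarithm argument (saturation) or an empty column set yields an
*inapplicable* flag (`nan` plus the site count), never silent propagation.
The implementation agrees with `ape::dist.dna(model="TN93")` to ~1e-11.

Neighbor joining is the standard Saitou–Nei agglomeration. Ties in the Q
criterion resolve to the lowest (i, j) pair in row-major order over the
current node list, so runs are bit-reproducible. Negative branch-length
estimates are kept internally and clamped to zero only at newick
serialization. For an additive matrix the reconstructed tree reproduces
the input path lengths exactly (tested over random 4–12-taxon trees).

Bootstrap support resamples alignment columns with replacement and counts
the fraction of replicate NJ trees containing each internal bipartition of
the point-estimate tree. Taxa are canonically sorted internally, so
support values do not depend on input order. Saturated replicates are
skipped (they count against support). The conventional 1,000 replicates is
the default in the pipeline configuration; tests use fewer.

Lineage assignment builds one joint bootstrapped tree over queries plus
labeled references and gives each query the lineage of the smallest
supported (default ≥ 70%) monophyletic reference group containing it,
falling back to a zero-distance nearest reference for singleton lineages,
else `unresolved`. The 70% default encodes "strong support" where no
numeric threshold is standard.

## Pairwise dN/dS and the Z-test

NG86 site counting enumerates, per codon position, the fraction of the
three possible changes that are synonymous, excluding changes to stop
codons from the opportunity set; per-pair sites average the two sequences.
The modified-NG variant weights each change by κ for transitions before
taking the fraction. Substitution counts for codons differing at 2–3
positions average over all minimal mutational pathways that avoid stops
(over all pathways when every one is blocked — a rare corner retained for
completeness). Proportions are Jukes–Cantor corrected; a proportion
≥ 0.75 flags that class inapplicable. Which variant produced a number is
recorded in the output (`NG86` / `modified-NG`), and the domain-level
statistic is the *ratio of pairwise-averaged* dN and dS, not the average
of ratios.

The Z-test deduplicates sequences, computes d̄N − d̄S over all pairs, and
estimates its standard error by bootstrap over codon columns
(per-pair per-column contributions are precomputed, so resampling is a
vectorised sum). The p-value is one-tailed on the side matching the sign
of Z; `direction` is set at α = 0.05. Degenerate inputs (fewer than two
unique sequences, no substitutions, zero SE) return a neutral result with
a diagnostic rather than raising.

## Codon-by-codon selection scan

The grid empirical-Bayes route assigns each site synonymous rate α and
nonsynonymous rate β on a 20 × 20 grid (linear 0.05–1, geometric 1.25–10;
geometric spacing above 1 avoids a resolution gap where moderately
selected sites would otherwise fall between cells). Site likelihoods come
from Felsenstein pruning under a codon model with uniform codon
frequencies and a single κ estimated by transition/transversion counting
(rate ratio = 2 × count ratio, correcting the two-fold transversion
opportunity). Uniform frequencies make the generator symmetric, so each
grid cell needs one eigendecomposition and per-branch transition matrices
are cheap; this is a deliberate simplification relative to FUBAR's
empirical codon frequencies and MCMC. Grid weights are fitted by EM with a
symmetric Dirichlet(0.5) prior, using the Dirichlet *posterior-mean*
M-step (expected counts + concentration): the MAP form (counts +
concentration − 1) prunes the 400-cell grid to a single cell whenever
sites-per-cell < 0.5, which collapses every per-site posterior — the
posterior-mean update keeps the full grid alive and shrinks toward
uniform instead. Per-site P(β > α) averages the posterior over cells.

Because NJ branch lengths come from a nucleotide model, deep codon-model
divergence is systematically underestimated, which pushes the whole
(α, β) surface toward the grid ceiling; the scan therefore runs a second
pass with branch lengths rescaled by the posterior-mean α so that the
synonymous rate centres near 1. Tree branch lengths are converted from
substitutions per nucleotide site to per codon (× 3); entirely gapped
sites are omitted from the output.

The counting route reconstructs ancestral codons by Fitch parsimony
(deterministic minimum-state tie break), decomposes each inferred change
via the NG86 pathway table, and tests the nonsynonymous count against the
site's nonsynonymous opportunity fraction with an extended binomial tail
(regularised incomplete beta, valid for fractional counts). It reports
`1 − p(positive)` on the same 0–1 scale so the two routes rank sites
comparably; in simulations they agree on the top selected site.

Flag tiers are fixed at PP > 0.90 and PP > 0.95 and are nested by
construction.

## Population statistics

Heterozygosity is Nei–Tajima gene diversity; the unbiased form multiplies
1 − Σp² by n/(n−1) with n = 2N gene copies and is the default, with the
uncorrected variant always emitted alongside (reports include both so
either convention can be compared). Rarefaction samples *gene copies*
without replacement — for each n from 1 to the total, via one shuffle per
permutation and a cumulative first-occurrence count, so all n share draws —
and reports the mean and the 0.05/0.95 quantiles over permutations
(default 200). An individuals-based x-axis (copies/2) is also emitted,
flagged as an interpretation of per-individual plotting conventions.
Missing genotype calls are dropped copy-wise, never individual-wise.
Dimorphism summaries insist on exactly the two declared states and report
missingness; read-depth filtering is the caller's concern.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume: a
Kingman coalescent topology rescaled to a configured total tree length
(expected neutral substitutions per codon); site-independent codon
evolution with uniform-frequency, κ-weighted, stop-avoiding substitution
(stops are absent from the state space, so planted stops are the only
route to null alleles); per-domain ω or per-site (α, β) overrides;
IPD-style names assigned by grouping identical proteins into allotypes
ordered by simulated mean frequency; symmetric Dirichlet population
frequencies; and Hardy–Weinberg diploid genotypes. One
`numpy.random.default_rng(seed)` drives everything, and identical
config + seed reproduces every output byte-identically.

Desk defaults are 20 alleles, 3 populations of 50 individuals, κ = 2.5,
ω = 0.5, tree length 2.0 — divergence deep enough that domain-level rate
regimes are measurable while runs stay in seconds. What the generator does
*not* emulate: recombination and domain shuffling, site-rate
autocorrelation, codon-usage bias, sequencing error, and linkage between
sites — so passing recovery tests demonstrates the estimators work under
their own model assumptions, not that real data meet those assumptions.

Recovery-test conditions were fixed by power analysis before freezing:
the domain Z-test regime recovery uses 20 alleles × 100 codons (ω = 3
vs 0.3), where recovery exceeds 90% of seeds; the planted-site scan uses
60 alleles, 150 codons, background ω = 0.2, ten sites at β/α = 5, total
tree length 24 — an information depth comparable to multi-species
receptor alignments — with the true simulated tree supplied, isolating
scan power from tree estimation. Under these conditions the scan recovers
≥ 8/10 planted sites at PP > 0.90 with no false positives in almost all
seeds; residual misses are sites whose realised synonymous histories
mimic α ≈ 2–4, an intrinsic limitation of P(β > α)-style inference.

## Orchestration

The CLI derives per-stage seeds from one master seed
(`stage_seed = (master × 10007 + stage_index) mod 2³¹`), so toggling one
stage never changes another's stream. Each run logs per-stage timing and
writes a manifest listing every artifact with its SHA-256 checksum and
seed; reruns with the same config are byte-identical. Exit codes: 0 ok,
1 input error, 2 runtime failure.

## Known limitations

- The grid-EB scan is approximate relative to full FUBAR (uniform codon
  frequencies, EM instead of MCMC, no rate-grid marginalisation over
  branch lengths); site lists on real data should be read qualitatively.
- The "Kumar method" family of Z-tests is represented by both NG86 and
  modified-NG; results under both are emitted because published analyses
  rarely state which variant was used.
- TN93 distances saturate near 75% raw divergence; saturated pairs are
  flagged, and trees over such sets require taxon removal or a
  codon-model distance outside this package's scope.
- No recombination detection, no ML/Bayesian tree inference, no structural
  modeling.
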