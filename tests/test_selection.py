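"""Nei-Gojobori dN/dS, the codon Z-test, and the site-selection scans.

The NG86 expectations below are hand-worked: synonymous site fractions per
codon come from enumerating the nine single-nucleotide changes against the
standard genetic code (stop-codon changes excluded from the opportunity
set), and multi-step codon differences enumerate both substitution orders
explicitly.
"""

import itertools
import math

import numpy as np
import pytest

from kirdiv.selection import (
    SENSE_CODONS,
    codon_z_test,
    ng86_pairwise,
    pathway_difference_counts,
    site_selection_scan,
    synonymous_site_counts,
)
from kirdiv.synthetic_data import SimulationConfig, simulate_cohort


class TestNG86Pairwise:
    def test_identity(self):
        a = "ATGGTGACG" * 10
        r = ng86_pairwise(a, a)
        assert r.dn == 0 and r.ds == 0
        assert r.n_sites + r.s_sites == pytest.approx(3 * 30)

    def test_single_synonymous_change_hand_worked(self):
        # TTT vs TTC (both Phe): s(TTT) = s(TTC) = 1/3 (only position 3 offers
        # a synonymous change); GGG contributes 1 synonymous site (3/3 at
        # position 3).  With 9 GGG filler codons: S = 1/3 + 9, N = 30 - S,
        # Sd = 1, Nd = 0, pS = 1/S, dS = -3/4 ln(1 - 4 pS / 3).
        a = "TTT" + "GGG" * 9
        b = "TTC" + "GGG" * 9
        r = ng86_pairwise(a, b)
        S = 1 / 3 + 9
        assert r.s_sites == pytest.approx(S)
        assert r.n_sites == pytest.approx(30 - S)
        assert r.nd == 0 and r.sd == 1
        assert r.dn == 0
        assert r.ds == pytest.approx(-0.75 * math.log(1 - 4 / (3 * S)), abs=1e-12)

    def test_two_position_pathways_averaged(self):
        # GTT (Val) vs GCA (Ala): order 2->3 gives N then S, order 3->2 gives
        # S then N; both pathways valid, so Sd = Nd = 1.
        sd, nd = pathway_difference_counts()
        i, j = SENSE_CODONS.index("GTT"), SENSE_CODONS.index("GCA")
        assert sd[i, j] == pytest.approx(1.0)
        assert nd[i, j] == pytest.approx(1.0)

    def test_stop_blocked_pathway_excluded(self):
        # TCA (Ser) vs TAT (Tyr): the position-2-first path visits TAA (stop)
        # and is excluded, leaving TCA->TCT (S) ->TAT (N).
        sd, nd = pathway_difference_counts()
        i, j = SENSE_CODONS.index("TCA"), SENSE_CODONS.index("TAT")
        assert sd[i, j] == pytest.approx(1.0)
        assert nd[i, j] == pytest.approx(1.0)

    def test_pathways_match_brute_force_enumeration(self):
        from Bio.Data.CodonTable import standard_dna_table

        aa = dict(standard_dna_table.forward_table)
        stops = set(standard_dna_table.stop_codons)
        sd_t, nd_t = pathway_difference_counts()
        rng = np.random.default_rng(0)
        pairs = rng.integers(0, len(SENSE_CODONS), size=(200, 2))
        for i, j in pairs:
            c1, c2 = SENSE_CODONS[i], SENSE_CODONS[j]
            positions = [p for p in range(3) if c1[p] != c2[p]]
            if not positions:
                continue
            path_counts = []
            for order in itertools.permutations(positions):
                cur, s = c1, 0
                blocked = False
                for p in order:
                    nxt = cur[:p] + c2[p] + cur[p + 1:]
                    if nxt in stops:
                        blocked = True
                        break
                    s += aa[nxt] == aa[cur]
                    cur = nxt
                if not blocked:
                    path_counts.append(s)
            if path_counts:
                assert sd_t[i, j] == pytest.approx(np.mean(path_counts))

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        codons = rng.choice(SENSE_CODONS, size=30)
        a = "".join(codons)
        b = "".join(rng.choice(SENSE_CODONS, size=30))
        ra = ng86_pairwise(a, b)
        rb = ng86_pairwise(b, a)
        assert (ra.dn, ra.ds, ra.n_sites, ra.s_sites) == (rb.dn, rb.ds, rb.n_sites, rb.s_sites)

    def test_codon_pairwise_deletion(self):
        a = "TTT" + "GGG" * 9
        b = "---" + "GGG" * 9
        r = ng86_pairwise(a, b)
        assert r.codons_compared == 9

    def test_modified_ng_weights_sites(self):
        s_plain = synonymous_site_counts(None)
        s_k5 = synonymous_site_counts(5.0)
        i = SENSE_CODONS.index("TTT")
        # TTT's one synonymous change (T->C at pos 3) is a transition, so
        # weighting transitions up raises its synonymous site fraction
        assert s_k5[i] > s_plain[i]

    def test_saturated_class_inapplicable(self):
        # every codon differs at all three positions, pushing the
        # nonsynonymous proportion past the 0.75 correction limit
        a = "ATG" * 20
        b = "CGT" * 20
        r = ng86_pairwise(a, b)
        assert math.isnan(r.dn)


class TestCodonZTest:
    def test_identical_sequences_neutral_with_diagnostic(self):
        block = {f"s{i}": "ATGGTGACG" * 5 for i in range(4)}
        t = codon_z_test(block, reps=50, seed=1)
        assert t.direction == "neutral"
        assert t.diagnostic

    def test_positive_regime_recovered(self):
        cfg = SimulationConfig(seed=5, n_alleles=20, n_codons=100, default_omega=3.0,
                               n_populations=1, n_individuals=5)
        block = {r.name: r.cds for r in simulate_cohort(cfg).records}
        t = codon_z_test(block, reps=300, seed=5)
        assert t.direction == "positive"
        assert t.ratio > 1

    def test_negative_regime_recovered(self):
        cfg = SimulationConfig(seed=5, n_alleles=20, n_codons=100, default_omega=0.3,
                               n_populations=1, n_individuals=5)
        block = {r.name: r.cds for r in simulate_cohort(cfg).records}
        t = codon_z_test(block, reps=300, seed=5)
        assert t.direction == "negative"
        assert t.ratio < 1

    def test_sequence_order_invariance(self):
        cfg = SimulationConfig(seed=3, n_alleles=8, n_codons=60, default_omega=1.0,
                               n_populations=1, n_individuals=5)
        block = {r.name: r.cds for r in simulate_cohort(cfg).records}
        t1 = codon_z_test(block, reps=100, seed=7)
        t2 = codon_z_test(dict(reversed(list(block.items()))), reps=100, seed=7)
        assert t1.z == pytest.approx(t2.z)
        assert t1.p == pytest.approx(t2.p)

    def test_both_method_variants_run(self):
        cfg = SimulationConfig(seed=2, n_alleles=10, n_codons=60, default_omega=1.0,
                               n_populations=1, n_individuals=5)
        block = {r.name: r.cds for r in simulate_cohort(cfg).records}
        for method in ("NG86", "modified-NG"):
            t = codon_z_test(block, reps=50, seed=2, method=method)
            assert t.method == method
            assert np.isfinite(t.z)


class TestSiteScan:
    @pytest.fixture(scope="module")
    def planted_cohort(self):
        planted = {c: (1.0, 5.0) for c in (10, 30, 50)}
        cfg = SimulationConfig(seed=8, n_alleles=30, n_codons=80, default_omega=0.2,
                               planted_sites=planted, n_populations=1, n_individuals=5,
                               tree_length=12.0)
        coh = simulate_cohort(cfg)
        return coh, set(planted)

    def test_grid_eb_prefers_planted_sites(self, planted_cohort):
        coh, planted = planted_cohort
        block = {r.name: r.cds for r in coh.records}
        res = site_selection_scan(block, method="grid-eb", seed=8)
        pp = {r.mature_residue: r.posterior for r in res}
        top3 = sorted(pp, key=pp.get, reverse=True)[:3]
        assert set(top3) == planted

    def test_grid_eb_posteriors_are_probabilities(self, planted_cohort):
        coh, _ = planted_cohort
        block = {r.name: r.cds for r in coh.records}
        res = site_selection_scan(block, method="grid-eb", seed=8)
        for r in res:
            assert 0.0 <= r.posterior <= 1.0
            assert r.flagged_95 <= r.flagged_90  # tiers nested

    def test_counting_ranks_top_planted_site_like_grid_eb(self, planted_cohort):
        coh, planted = planted_cohort
        block = {r.name: r.cds for r in coh.records}
        eb = site_selection_scan(block, method="grid-eb", seed=8)
        ct = site_selection_scan(block, method="counting", seed=8)
        top_eb = max(eb, key=lambda r: r.posterior).mature_residue
        top_ct = max(ct, key=lambda r: r.posterior).mature_residue
        assert top_eb in planted and top_ct in planted

    def test_zero_variation_scan_has_no_signal(self):
        block = {f"s{i}": "ATGGTGACGCATGGGTTC" * 3 for i in range(4)}
        with pytest.raises(ValueError, match="unique"):
            site_selection_scan(block, method="grid-eb", seed=1)

    def test_low_variation_sites_not_flagged(self):
        # nearly invariant alignment: no site should reach PP > 0.9
        base = "ATGGTGACGCATGGGTTC" * 5
        block = {"a": base, "b": base[:3] + "GTC" + base[6:],
                 "c": base[:9] + "CAC" + base[12:],
                 "d": base[:15] + "GGC" + base[18:]}
        res = site_selection_scan(block, method="grid-eb", seed=1)
        assert all(not r.flagged_90 for r in res)

    def test_counting_all_synonymous_site(self):
        # single variable site where every change is synonymous:
        # no evidence for positive selection (p = 1, posterior score 0)
        base = "ATGGTGACGCAT" * 5
        block = {
            "a": base,
            "b": base[:5] + "C" + base[6:],  # GTG->GTC Val synonymous
            "c": base[:5] + "A" + base[6:],
            "d": base[:5] + "T" + base[6:],
        }
        res = site_selection_scan(block, method="counting", seed=1)
        site2 = next(r for r in res if r.mature_residue == 2)
        assert site2.posterior == pytest.approx(0.0)

    def test_tree_alignment_mismatch_rejected(self, planted_cohort):
        coh, _ = planted_cohort
        block = {r.name: r.cds for r in coh.records}
        wrong = dict(list(block.items())[:5])
        from kirdiv.phylo import distance_matrix, nj_build

        tree = nj_build(distance_matrix(wrong))
        with pytest.raises(ValueError, match="match"):
            site_selection_scan(block, tree=tree, method="grid-eb", seed=1)
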