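import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from dupsel.codonml import (CodonModelSpec, CodonSpace, LikTree, SiteClass,
                            _Engine, build_rate_matrix, f3x4_frequencies,
                            fit_model, kh_sh_tests, lrt, ng86_counts,
                            site_log_likelihoods, site_posteriors)
from dupsel.seqio import Alignment, parse_newick, to_codon_alignment
from dupsel.synthetic_data import simulate_codon_alignment


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _oracle_ng86_pair(ca, cb, code):
    """Independent pathway-enumeration recount for one codon pair."""
    from Bio.Seq import Seq

    def tr(c):
        return str(Seq(c).translate())

    def syn_sites(c):
        s = 0.0
        for k in range(3):
            for nt in "ACGT":
                if nt == c[k]:
                    continue
                alt = c[:k] + nt + c[k + 1:]
                if tr(alt) == "*":
                    continue
                if tr(alt) == tr(c):
                    s += 1 / 3
        return s

    pos = [k for k in range(3) if ca[k] != cb[k]]
    paths = []
    for order in itertools.permutations(pos):
        cur, sd, nd, blocked = ca, 0, 0, False
        for k in order:
            nxt = cur[:k] + cb[k] + cur[k + 1:]
            if tr(nxt) == "*":
                blocked = True
            if tr(nxt) == tr(cur) and tr(nxt) != "*" and tr(cur) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_p = [(s, n) for s, n, b in paths if not b] or \
        [(s, n) for s, n, _ in paths]
    return (syn_sites(ca) + syn_sites(cb)) / 2, \
        np.mean([s for s, _ in open_p]), np.mean([n for _, n in open_p])


class TestNG86:
    def test_identical(self, code):
        c = ng86_counts("ATGAAA", "ATGAAA", code)
        assert c.Sd == 0 and c.Nd == 0 and c.pS == 0 and c.pN == 0

    def test_synonymous_phe(self, code):
        c = ng86_counts("TTT", "TTC", code)
        assert c.Sd == 1 and c.Nd == 0

    def test_sites_sum_to_three_per_codon(self, code):
        rng = np.random.default_rng(0)
        space = CodonSpace(code)
        a = [space.codons[i] for i in rng.integers(0, 61, 50)]
        b = [space.codons[i] for i in rng.integers(0, 61, 50)]
        c = ng86_counts(a, b, code)
        assert c.S_sites + c.N_sites == pytest.approx(3 * c.n_codons)

    def test_matches_pathway_enumeration_oracle(self, code):
        rng = np.random.default_rng(1)
        space = CodonSpace(code)
        for _ in range(200):
            ca = space.codons[rng.integers(0, 61)]
            cb = space.codons[rng.integers(0, 61)]
            sites, sd, nd = _oracle_ng86_pair(ca, cb, code)
            c = ng86_counts([ca], [cb], code)
            assert c.S_sites == pytest.approx(sites)
            assert c.Sd == pytest.approx(sd)
            assert c.Nd == pytest.approx(nd)

    def test_gapped_codons_masked(self, code):
        c = ng86_counts(["ATG", "A-G", "TTT"], ["ATG", "AAG", "TTC"], code)
        assert c.n_codons == 2

    def test_omega_infinite_flag(self, code):
        c = ng86_counts("AAA", "AGA", code)  # K->R nonsynonymous only
        assert c.pS == 0 and c.pN > 0
        assert np.isinf(c.omega)


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class TestSiteLikelihoods:
    def test_two_sequence_oracle(self, code):
        """Single branch: pruning equals the direct pairwise formula
        sum_s log( pi_a * expm(Q t)[a, b] ) with an independent expm."""
        rng = np.random.default_rng(2)
        space = CodonSpace(code)
        a = [space.codons[i] for i in rng.integers(0, 61, 40)]
        b = [space.codons[i] if rng.random() < 0.3 else a[k]
             for k, i in enumerate(rng.integers(0, 61, 40))]
        aln = Alignment(["x", "y"], ["".join(a), "".join(b)])
        caln = to_codon_alignment(aln, code)
        t1, t2 = 0.07, 0.05
        tree = parse_newick(f"(x:{t1},y:{t2});")
        spec = CodonModelSpec(kappa=2.5, codon_freqs="equal",
                              classes=(SiteClass(1.0, 0.4),))
        mine = site_log_likelihoods(caln, tree, spec).sum()
        pi = np.full(61, 1 / 61)
        Q = build_rate_matrix(2.5, 0.4, pi, code)
        P = expm(Q * (t1 + t2))
        idx = space.index
        direct = sum(np.log(pi[idx[ca]] * P[idx[ca], idx[cb]])
                     for ca, cb in zip(a, b))
        assert mine == pytest.approx(direct, abs=1e-6)

    def test_zero_branch_limit(self, code):
        space = CodonSpace(code)
        seq = "".join(space.codons[i] for i in range(10))
        aln = Alignment(["x", "y"], [seq, seq])
        caln = to_codon_alignment(aln, code)
        tree = parse_newick("(x:0.0000001,y:0.0000001);")
        spec = CodonModelSpec(kappa=2.0, codon_freqs="equal",
                              classes=(SiteClass(1.0, 0.5),))
        total = site_log_likelihoods(caln, tree, spec).sum()
        assert total == pytest.approx(10 * np.log(1 / 61), abs=1e-3)

    def test_class_probability_renormalization_invariance(
            self, m0_data, six_taxon_tree):
        caln, _, _ = m0_data
        c1 = (SiteClass(0.5, 0.2), SiteClass(0.5, 1.0))
        c2 = (SiteClass(1.0, 0.2), SiteClass(1.0, 1.0))  # doubled, renorm
        s1 = CodonModelSpec(kappa=2.0, codon_freqs="equal", classes=c1)
        s2 = CodonModelSpec(kappa=2.0, codon_freqs="equal", classes=c2)
        l1 = site_log_likelihoods(caln, six_taxon_tree, s1)
        l2 = site_log_likelihoods(caln, six_taxon_tree, s2)
        assert np.allclose(l1, l2)

    def test_rerooting_invariance(self, code):
        """The reversible codon model gives the same likelihood for two
        rootings of the same unrooted tree."""
        rng = np.random.default_rng(4)
        tree1 = parse_newick("((A:0.1,B:0.2):0.15,(C:0.05,D:0.3):0.0);")
        tree2 = parse_newick("((C:0.05,D:0.3):0.15,(A:0.1,B:0.2):0.0);")
        spec = CodonModelSpec(kappa=2.0, codon_freqs="equal",
                              classes=(SiteClass(1.0, 0.5),))
        caln, _ = simulate_codon_alignment(tree1, spec, 60, seed=8)
        l1 = site_log_likelihoods(caln, tree1, spec).sum()
        l2 = site_log_likelihoods(caln, tree2, spec).sum()
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_rate_matrix_properties(self, code):
        pi = np.full(61, 1 / 61)
        Q = build_rate_matrix(3.0, 0.7, pi, code)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert np.allclose(pi @ Q, 0, atol=1e-12)  # stationarity
        assert -pi @ np.diag(Q) == pytest.approx(1.0)  # unit mean rate

    def test_tip_mismatch_rejected(self, m0_data):
        caln, _, _ = m0_data
        with pytest.raises(ValueError):
            site_log_likelihoods(
                caln, parse_newick("((A:1,B:1):1,Z:1);"),
                CodonModelSpec(codon_freqs="equal"))


class TestForegroundSelection:
    def test_stem_vs_all(self, six_taxon_tree, m0_data):
        caln, _, _ = m0_data
        eng = _Engine(caln, six_taxon_tree)
        stem = eng.ltree.foreground_edges(["A", "B", "C"], "stem")
        alle = eng.ltree.foreground_edges(["A", "B", "C"], "all")
        assert len(stem) == 1
        assert len(alle) == 5  # A, B, AB, C, ABC
        assert stem <= alle

    def test_nonexistent_clade(self, six_taxon_tree, m0_data):
        caln, _, _ = m0_data
        eng = _Engine(caln, six_taxon_tree)
        with pytest.raises(ValueError):
            eng.ltree.foreground_edges(["A", "D"], "stem")


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

class TestFitting:
    def test_m0_recovery(self, m0_data, six_taxon_tree):
        caln, _, _ = m0_data  # simulated at omega 0.3, kappa 2
        fit = fit_model(caln, six_taxon_tree, "M0", n_restarts=1,
                        codon_freqs="equal")
        w = fit.mles["class_omegas_background"][0]
        assert 0.2 < w < 0.4
        assert 1.2 < fit.mles["kappa"] < 3.2
        assert fit.lnL < 0 and np.isfinite(fit.lnL)

    def test_nesting_chain(self, m0_data, six_taxon_tree):
        caln, _, _ = m0_data
        m0 = fit_model(caln, six_taxon_tree, "M0", n_restarts=1,
                       codon_freqs="equal")
        kw = dict(branch_lengths=m0.branch_lengths, n_restarts=1,
                  codon_freqs="equal")
        m1a = fit_model(caln, six_taxon_tree, "M1a", **kw)
        m2a = fit_model(caln, six_taxon_tree, "M2a", start_from=m1a, **kw)
        m7 = fit_model(caln, six_taxon_tree, "M7", **kw)
        m8a = fit_model(caln, six_taxon_tree, "M8a", start_from=m7, **kw)
        m8 = fit_model(caln, six_taxon_tree, "M8", start_from=m8a, **kw)
        tol = 1e-3
        assert m2a.lnL >= m1a.lnL - tol
        assert m8a.lnL >= m7.lnL - tol
        assert m8.lnL >= m8a.lnL - tol

    def test_free_ratio_nests_m0(self, code):
        tree = parse_newick("((A:0.15,B:0.2):0.1,C:0.25);")
        spec = CodonModelSpec(kappa=2.0, codon_freqs="equal",
                              classes=(SiteClass(1.0, 0.3),))
        caln, _ = simulate_codon_alignment(tree, spec, 150, seed=21)
        m0 = fit_model(caln, tree, "M0", n_restarts=1, codon_freqs="equal")
        fr = fit_model(caln, tree, "free-ratio", codon_freqs="equal")
        assert fr.lnL >= m0.lnL - 1e-3
        assert len(fr.per_branch_omega) == 4

    def test_bsa_requires_foreground(self, m0_data, six_taxon_tree):
        caln, _, _ = m0_data
        with pytest.raises(ValueError):
            fit_model(caln, six_taxon_tree, "bsA")

    def test_unknown_template(self, m0_data, six_taxon_tree):
        caln, _, _ = m0_data
        with pytest.raises(ValueError):
            fit_model(caln, six_taxon_tree, "M99")


# ---------------------------------------------------------------------------
# LRT arithmetic
# ---------------------------------------------------------------------------

class TestLRT:
    def test_branch_site_pair_one(self):
        two_dl, p = lrt(-2629.741, -2629.503, 1, boundary_mixture=True)
        assert two_dl == pytest.approx(0.476, abs=1e-3)
        assert p > 0.05

    def test_branch_site_pair_two(self):
        two_dl, p = lrt(-2629.786, -2625.364, 1, boundary_mixture=True)
        assert two_dl == pytest.approx(8.844, abs=1e-3)
        assert p < 0.005

    def test_equal_lnls(self):
        two_dl, p = lrt(-100.0, -100.0, 1, boundary_mixture=True)
        assert two_dl == 0.0 and p == 1.0

    def test_negative_statistic_warns(self):
        with pytest.warns(RuntimeWarning):
            two_dl, p = lrt(-100.0, -100.5, 1)
        assert np.isnan(p)

    def test_mixture_halves_chi2_tail(self):
        from scipy.stats import chi2
        _, p_mix = lrt(-100.0, -98.0, 1, boundary_mixture=True)
        _, p_chi = lrt(-100.0, -98.0, 1)
        assert p_mix == pytest.approx(0.5 * chi2.sf(4.0, 1))
        assert p_chi == pytest.approx(chi2.sf(4.0, 1))


# ---------------------------------------------------------------------------
# Site posteriors
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def m2a_fit(six_taxon_tree):
    classes = (SiteClass(0.6, 0.1), SiteClass(0.3, 1.0),
               SiteClass(0.1, 8.0))
    spec = CodonModelSpec(kappa=2.0, codon_freqs="equal", classes=classes)
    caln, rec = simulate_codon_alignment(six_taxon_tree, spec, 300, seed=31)
    m0 = fit_model(caln, six_taxon_tree, "M0", n_restarts=1,
                   codon_freqs="equal")
    m1a = fit_model(caln, six_taxon_tree, "M1a", n_restarts=1,
                    branch_lengths=m0.branch_lengths, codon_freqs="equal")
    m2a = fit_model(caln, six_taxon_tree, "M2a", n_restarts=2,
                    branch_lengths=m0.branch_lengths, start_from=m1a,
                    codon_freqs="equal")
    return caln, rec, m2a


class TestPosteriors:

    def test_posteriors_sum_to_one(self, m2a_fit, six_taxon_tree):
        caln, _, fit = m2a_fit
        sp = site_posteriors(fit, caln, six_taxon_tree)
        assert np.allclose(sp.class_posteriors.sum(axis=0), 1.0)

    def test_flagged_sites_enriched_in_truth(self, m2a_fit, six_taxon_tree):
        caln, rec, fit = m2a_fit
        sp = site_posteriors(fit, caln, six_taxon_tree)
        truth = set(np.nonzero(rec.site_class == 2)[0])
        flagged = set(sp.flagged_sites)
        if flagged:
            precision = len(flagged & truth) / len(flagged)
            assert precision >= 0.7

    def test_no_positive_class_rejected(self, m0_data, six_taxon_tree):
        caln, _, _ = m0_data
        m0 = fit_model(caln, six_taxon_tree, "M0", n_restarts=1,
                       codon_freqs="equal")
        with pytest.raises(ValueError):
            site_posteriors(m0, caln, six_taxon_tree)


# ---------------------------------------------------------------------------
# KH / SH
# ---------------------------------------------------------------------------

class TestTopologyTests:
    def test_duplicate_topology_p_near_one(self, m0_data, six_taxon_tree):
        caln, _, _ = m0_data
        res = kh_sh_tests(caln, [six_taxon_tree, six_taxon_tree],
                          n_boot=2000, seed=1)
        assert all(r["p_kh"] > 0.9 for r in res)

    def test_sh_at_least_kh_for_competitor(self, m0_data, six_taxon_tree):
        caln, _, _ = m0_data
        wrong = parse_newick(
            "(((A:0.1,D:0.1):0.1,C:0.2):0.2,((B:0.1,E:0.1):0.1,F:0.2):0.2);")
        res = kh_sh_tests(caln, [six_taxon_tree, wrong], n_boot=2000, seed=2)
        loser = [r for r in res if not r["best"]][0]
        assert loser["p_sh"] >= loser["p_kh"] - 1e-12

    def test_single_topology_rejected(self, m0_data, six_taxon_tree):
        caln, _, _ = m0_data
        with pytest.raises(ValueError):
            kh_sh_tests(caln, [six_taxon_tree])


def test_f3x4_frequencies_sum_to_one(m0_data):
    caln, _, _ = m0_data
    pi = f3x4_frequencies(caln)
    assert pi.shape == (61,)
    assert pi.sum() == pytest.approx(1.0)
    assert np.all(pi > 0)
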