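import numpy as np
import pytest

from dupsel.codonml import CodonModelSpec, SiteClass, ng86_counts
from dupsel.seqio import write_newick
from dupsel.synthetic_data import (DuplicationScenario, SimulationError,
                                   simulate_codon_alignment,
                                   simulate_duplication_gene_tree,
                                   simulate_radical_bias, simulate_rate_shift,
                                   simulate_tree)


class TestSimulateTree:
    def test_exact_tip_count(self):
        for n in (3, 7, 20):
            assert len(simulate_tree("yule", n, seed=1).leaf_nodes()) == n

    def test_same_seed_identical_newick(self):
        a = write_newick(simulate_tree("yule", 9, seed=5))
        b = write_newick(simulate_tree("yule", 9, seed=5))
        assert a == b

    def test_ultrametric(self):
        t = simulate_tree("yule", 12, seed=2)
        depths = [lf.distance_from_root() for lf in t.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_yule_internode_means(self):
        # while k lineages exist the wait is Exp(k * birth): compare the
        # mean of the k=2 and k=3 intervals over replicates
        g2, g3 = [], []
        for s in range(2000):
            t = simulate_tree("yule", 3, seed=s, birth=1.0)
            node_depths = sorted(
                nd.distance_from_root() for nd in t.preorder_node_iter()
                if not nd.is_leaf())
            tip = max(lf.distance_from_root() for lf in t.leaf_node_iter())
            g2.append(node_depths[1] - node_depths[0])
            g3.append(tip - node_depths[1])
        assert np.mean(g2) == pytest.approx(1 / 2, abs=0.05)
        assert np.mean(g3) == pytest.approx(1 / 3, abs=0.04)

    def test_birth_death_prunes_extinct(self):
        t = simulate_tree("birth-death", 8, birth=1.0, death=0.4, seed=3)
        assert len(t.leaf_nodes()) == 8
        depths = [lf.distance_from_root() for lf in t.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_impossible_conditioning_raises(self):
        with pytest.raises(SimulationError):
            simulate_tree("birth-death", 40, birth=0.1, death=2.0, seed=1,
                          max_retries=5)


class TestDuplicationGeneTree:
    def test_before_speciation_mirrored_clades(self):
        sc = DuplicationScenario(n_species=4, duplication="before-speciation")
        t = simulate_duplication_gene_tree(sc, seed=1)
        tips = {lf.taxon.label for lf in t.leaf_node_iter()}
        assert tips == {f"t{i}_{d}" for i in range(1, 5)
                        for d in ("dup1", "dup2")}
        for ch in t.seed_node.child_nodes():
            suffixes = {lf.taxon.label.rsplit("_", 1)[1]
                        for lf in ch.leaf_iter()}
            assert len(suffixes) == 1  # each root clade is one paralog

    def test_after_speciation_cherries(self):
        sc = DuplicationScenario(n_species=4, duplication="after-speciation")
        t = simulate_duplication_gene_tree(sc, seed=1)
        for i in range(1, 5):
            mrca = t.mrca(taxon_labels=[f"t{i}_dup1", f"t{i}_dup2"])
            assert {lf.taxon.label for lf in mrca.leaf_iter()} == \
                {f"t{i}_dup1", f"t{i}_dup2"}

    def test_lost_tips_removed(self):
        sc = DuplicationScenario(n_species=4,
                                 lost_tips=frozenset({"t1_dup2"}))
        t = simulate_duplication_gene_tree(sc, seed=1)
        assert "t1_dup2" not in {lf.taxon.label for lf in t.leaf_node_iter()}


class TestCodonAlignmentSimulation:
    def test_omega_zero_no_nonsynonymous(self, six_taxon_tree):
        spec = CodonModelSpec(kappa=2.0, codon_freqs="equal",
                              classes=(SiteClass(1.0, 0.0),))
        caln, rec = simulate_codon_alignment(six_taxon_tree, spec, 100, seed=1)
        assert rec.total_nonsynonymous == 0
        assert rec.total_synonymous > 0

    def test_zero_branch_lengths_identical(self):
        from dupsel.seqio import parse_newick

        t = parse_newick("((A:0.0,B:0.0):0.0,C:0.0);")
        spec = CodonModelSpec(codon_freqs="equal")
        caln, rec = simulate_codon_alignment(t, spec, 50, seed=2)
        assert len(set(caln.alignment.seqs)) == 1
        assert rec.total_synonymous == rec.total_nonsynonymous == 0

    def test_same_seed_bit_identical(self, six_taxon_tree):
        spec = CodonModelSpec(codon_freqs="equal",
                              classes=(SiteClass(1.0, 0.5),))
        a, _ = simulate_codon_alignment(six_taxon_tree, spec, 80, seed=9)
        b, _ = simulate_codon_alignment(six_taxon_tree, spec, 80, seed=9)
        assert a.alignment.seqs == b.alignment.seqs

    def test_neutral_omega_gives_unit_pn_ps(self, six_taxon_tree):
        # omega = 1: NG86 counting on the simulated data should give
        # pN/pS near 1 (median over replicates)
        spec = CodonModelSpec(kappa=2.0, codon_freqs="equal",
                              classes=(SiteClass(1.0, 1.0),))
        ratios = []
        for s in range(12):
            caln, _ = simulate_codon_alignment(six_taxon_tree, spec, 500,
                                               seed=100 + s)
            cods = caln.codon_matrix()
            c = ng86_counts(cods[0], cods[-1], caln.code)
            if c.pS > 0:
                ratios.append(c.pN / c.pS)
        assert 0.85 < float(np.median(ratios)) < 1.15

    def test_counts_reconcile_with_hamming(self):
        # at low rates realized event counts match observed differences
        from dupsel.seqio import parse_newick

        t = parse_newick("(A:0.02,B:0.02);")
        spec = CodonModelSpec(codon_freqs="equal",
                              classes=(SiteClass(1.0, 0.5),))
        caln, rec = simulate_codon_alignment(t, spec, 2000, seed=3)
        diffs = sum(a != b for a, b in zip(*caln.alignment.seqs))
        events = rec.total_synonymous + rec.total_nonsynonymous
        assert events >= diffs  # hidden events only add
        assert events - diffs <= 0.2 * max(events, 1)

    def test_manifest_regenerates(self, six_taxon_tree):
        spec = CodonModelSpec(codon_freqs="equal",
                              classes=(SiteClass(1.0, 0.3),))
        caln, rec = simulate_codon_alignment(six_taxon_tree, spec, 60, seed=7)
        again, rec2 = simulate_codon_alignment(
            six_taxon_tree, spec, rec.manifest["n_codons"],
            seed=rec.manifest["seed"])
        assert caln.alignment.seqs == again.alignment.seqs
        assert rec.branch_counts == rec2.branch_counts


class TestRadicalBias:
    def test_truth_partitions_sites(self):
        d = simulate_radical_bias(255, 0.1, seed=1)
        assert d.truth.sum() == round(0.1 * 255)
        assert len(d.truth) == 255

    def test_divergent_sites_cross_charge_classes(self):
        from dupsel.divergence import charge_class

        d = simulate_radical_bias(100, 0.2, within_rate=0.0, seed=2)
        for s in np.nonzero(d.truth)[0]:
            a = d.aln1.seqs[0][s]
            b = d.aln2.seqs[0][s]
            assert charge_class(a) != charge_class(b)

    def test_fraction_zero_shares_all_sites(self):
        d = simulate_radical_bias(100, 0.0, within_rate=0.0, seed=3)
        assert d.aln1.seqs[0] == d.aln2.seqs[0]

    def test_rate_shift_truth_labels(self):
        d = simulate_rate_shift(200, 0.25, seed=4)
        assert d.truth.sum() == round(0.25 * 200)
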