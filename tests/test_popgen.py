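import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dupsel import popgen
from dupsel.popgen import (SegSites, UndefinedResult, four_gamete_Rm,
                           hudson_R, incompatible_pairs,
                           nucleotide_diversity, pairwise_r2,
                           segregating_sites, tajima_constants, tajimas_d,
                           watterson_theta, zz_statistic)
from dupsel.seqio import Alignment

from .conftest import random_nt_alignment


# ---------------------------------------------------------------------------
# segregating sites
# ---------------------------------------------------------------------------

class TestSegSites:
    def test_identical_sequences(self):
        aln = Alignment(list("abcd"), ["ACGT"] * 4)
        assert segregating_sites(aln).total_segregating == 0

    def test_single_site(self):
        seg = segregating_sites(Alignment(list("abc"), ["AAT", "AAA", "AAT"]))
        assert seg.S == 1 and seg.positions.tolist() == [2]

    def test_multiallelic_excluded_from_binary(self):
        seg = segregating_sites(Alignment(list("abc"), ["AC", "AG", "AT"]))
        assert seg.S == 0
        assert seg.multiallelic_positions.tolist() == [1]
        assert seg.total_segregating == 1

    def test_missing_masked(self):
        seg = segregating_sites(Alignment(list("abc"), ["AN", "AT", "AA"]))
        assert seg.S == 1
        assert seg.states[0].tolist() == [-1, 1, 0]


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_pi_one_difference(self):
        assert nucleotide_diversity(Alignment(["a", "b"], ["AAAA", "AAAT"])) == 1.0

    def test_watterson_closed_form(self):
        aln = Alignment(list("abcd"), ["AAA", "AAT", "ATA", "TAA"])
        seg = segregating_sites(aln)
        assert seg.total_segregating == 3
        assert watterson_theta(seg) == pytest.approx(3 / (1 + 1 / 2 + 1 / 3))

    def test_pi_matches_columnwise_oracle(self):
        # independent route: per-column heterozygosity count
        rng = np.random.default_rng(1)
        for _ in range(10):
            aln = random_nt_alignment(rng, n=6, L=100)
            m = aln.matrix
            npairs = 6 * 5 / 2
            col_pi = 0.0
            for j in range(aln.length):
                col = m[:, j]
                for x, y in itertools.combinations(range(6), 2):
                    col_pi += col[x] != col[y]
            assert nucleotide_diversity(aln) == pytest.approx(col_pi / npairs)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_pi_invariant_under_row_and_site_permutation(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_nt_alignment(rng, n=5, L=40)
        rows = rng.permutation(5)
        cols = rng.permutation(40)
        perm = Alignment([aln.ids[i] for i in rows],
                         ["".join(aln.seqs[i][j] for j in cols) for i in rows])
        assert nucleotide_diversity(perm) == pytest.approx(
            nucleotide_diversity(aln))
        assert watterson_theta(segregating_sites(perm)) == pytest.approx(
            watterson_theta(segregating_sites(aln)))


class TestTajimasD:
    def test_undefined_at_s_zero(self):
        with pytest.raises(UndefinedResult):
            tajimas_d(Alignment(list("abcd"), ["ACGT"] * 4))

    def test_fixed_toy_against_constant_recomputation(self):
        # 4 haplotypes over 4 segregating sites: 0000, 0011, 1100, 1111
        aln = Alignment(list("abcd"), ["AAAA", "AATT", "TTAA", "TTTT"])
        n, S = 4, 4
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        pi = (2 + 2 + 4 + 4 + 2 + 2) / 6
        expected = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_d(aln) == pytest.approx(expected)
        assert tajimas_d(aln) == pytest.approx(2.08033, abs=1e-4)

    def test_agrees_with_dendropy(self):
        import dendropy
        from dendropy.calculate import popgenstat

        rng = np.random.default_rng(3)
        aln = random_nt_alignment(rng, n=8, L=60)
        mat = dendropy.DnaCharacterMatrix.get(
            data="".join(f">{i}\n{s}\n" for i, s in zip(aln.ids, aln.seqs)),
            schema="fasta")
        assert tajimas_d(aln) == pytest.approx(
            popgenstat.tajimas_d(mat), abs=1e-6)


# ---------------------------------------------------------------------------
# four-gamete test
# ---------------------------------------------------------------------------

def _brute_force_rm(seg: SegSites) -> int:
    """Minimum number of gap positions covering all incompatible
    intervals, by exhaustive subset search."""
    pairs = incompatible_pairs(seg)
    if not pairs:
        return 0
    gaps = range(seg.S - 1)  # gap g sits between sites g and g+1
    for k in range(1, seg.S):
        for chosen in itertools.combinations(gaps, k):
            if all(any(i <= g < j for g in chosen) for i, j in pairs):
                return k
    return seg.S - 1


class TestRm:
    def test_single_site_zero(self):
        aln = Alignment(list("ab"), ["AT", "AA"])
        assert four_gamete_Rm(segregating_sites(aln)) == 0

    def test_four_gametes_give_one(self):
        aln = Alignment(list("abcd"), ["AA", "AT", "TA", "TT"])
        assert four_gamete_Rm(segregating_sites(aln)) == 1

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(4, 9))
            S = int(rng.integers(2, 9))
            states = rng.integers(0, 2, size=(S, n)).astype(np.int8)
            # guarantee biallelic sites
            states[:, 0] = 0
            states[:, 1] = 1
            seg = SegSites(np.arange(S), states, n)
            assert four_gamete_Rm(seg) == _brute_force_rm(seg)


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

def _oracle_r2(a, b):
    ok = (a >= 0) & (b >= 0)
    x, y = a[ok], b[ok]
    pa, pb = x.mean(), y.mean()
    pab = np.mean(x * y)
    D = pab - pa * pb
    den = pa * (1 - pa) * pb * (1 - pb)
    return np.nan if den == 0 else D * D / den


class TestZZ:
    def test_two_sites_zero(self):
        aln = Alignment(list("abcd"), ["AA", "AT", "TA", "TT"])
        za, zns, zz = zz_statistic(segregating_sites(aln))
        assert za == zns and zz == 0.0

    def test_perfect_ld_zero(self):
        aln = Alignment(list("abcd"), ["AAA", "AAA", "TTT", "TTT"])
        za, zns, zz = zz_statistic(segregating_sites(aln))
        assert za == pytest.approx(1.0) and zz == pytest.approx(0.0)

    def test_undefined_below_two_sites(self):
        aln = Alignment(list("abcd"), ["AAAT", "AAAT", "AAAA", "AAAA"])
        with pytest.raises(UndefinedResult):
            zz_statistic(segregating_sites(aln))

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            aln = random_nt_alignment(rng, n=20, L=50)
            seg = segregating_sites(aln)
            if seg.S < 2:
                continue
            st_ = seg.states
            allv, adjv = [], []
            for i in range(seg.S):
                for j in range(i + 1, seg.S):
                    allv.append(_oracle_r2(st_[i].astype(float),
                                           st_[j].astype(float)))
            for k in range(seg.S - 1):
                adjv.append(_oracle_r2(st_[k].astype(float),
                                       st_[k + 1].astype(float)))
            za, zns, zz = zz_statistic(seg)
            assert zns == pytest.approx(np.nanmean(allv))
            assert za == pytest.approx(np.nanmean(adjv))
            assert zz == pytest.approx(za - zns)
            assert -1.0 <= zz <= 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_r2_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=12).astype(np.int8)
        b = rng.integers(0, 2, size=12).astype(np.int8)
        r2 = pairwise_r2(a, b)
        assert np.isnan(r2) or 0.0 <= r2 <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# Hudson's R
# ---------------------------------------------------------------------------

class TestHudsonR:
    def test_identical_sequences_undefined(self):
        aln = Alignment(list("abcd"), ["ACGT"] * 4)
        with pytest.raises(UndefinedResult):
            hudson_R(aln)

    def test_adjacent_identity(self):
        rng = np.random.default_rng(2)
        aln = random_nt_alignment(rng, n=8, L=40)
        rg, ra, flag = hudson_R(aln, reps=10, seed=1)
        assert ra * aln.length == pytest.approx(rg)

    def test_median_recovers_simulated_rho(self):
        # coalescent data at rho=10, n=30, 1000 sites; noisy estimator,
        # so only the median over replicates is banded
        import msprime

        grid = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)
        ests = []
        for s in range(24):
            ts = msprime.sim_ancestry(
                samples=30, ploidy=1, population_size=1.0,
                sequence_length=1000, recombination_rate=10.0 / 2000,
                random_seed=5000 + s)
            mts = msprime.sim_mutations(
                ts, rate=5.0 / 2000, random_seed=6000 + s,
                model=msprime.BinaryMutationModel())
            G = mts.genotype_matrix()
            if G.shape[0] < 2:
                continue
            seqs = ["".join("A" if g == 0 else "T" for g in G[:, i])
                    for i in range(30)]
            aln = Alignment([f"s{i}" for i in range(30)], seqs)
            rg, _, _ = hudson_R(aln, reps=40, seed=s, grid=grid)
            ests.append(rg)
        assert 5.0 <= float(np.median(ests)) <= 20.0


def test_summary_row(toy_alignment):
    s = popgen.summarize(toy_alignment)
    assert s.n == 4 and s.S == 2
    assert s.pi_gene > 0 and s.Rm in (0, 1)
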