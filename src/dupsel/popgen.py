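"""Diversity, neutrality and recombination statistics on an alignment.

Implements the classical sample statistics used to characterise a
gene-family alignment: nucleotide diversity (pi), Watterson's theta,
Tajima's D, Hudson's recombination-parameter estimator R, the
Hudson-Kaplan minimum number of recombination events (Rm) from the
four-gamete test, and the linkage-disequilibrium statistics ZnS, Za and
ZZ = Za - ZnS.

Missing-data policy: gaps, N and IUPAC ambiguity codes are masked
pairwise (a site contributes to a pairwise comparison only when both
sequences carry an unambiguous base there).  S for Watterson/Tajima
counts every variable site including multiallelic ones; LD statistics
and the four-gamete test use biallelic sites only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Alignment

__all__ = [
    "SegSites",
    "PopgenSummary",
    "UndefinedResult",
    "segregating_sites",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "tajima_constants",
    "hudson_R",
    "four_gamete_Rm",
    "incompatible_pairs",
    "zz_statistic",
    "pairwise_r2",
    "summarize",
]


class UndefinedResult(ArithmeticError):
    """A statistic is undefined on this input (e.g. S = 0)."""


@dataclass
class SegSites:
    """Biallelic segregating sites in 0/1 coding.

    Attributes
    ----------
    positions : (S,) int array
        Strictly increasing 0-based site indices of biallelic sites.
    states : (S, n) int8 array
        0 = first observed allele, 1 = second, -1 = missing.
    n : int
        Sample size.
    multiallelic_positions : int array
        Variable sites with >2 observed states, excluded from ``states``.
    """

    positions: np.ndarray
    states: np.ndarray
    n: int
    multiallelic_positions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    @property
    def S(self) -> int:
        """Number of biallelic segregating sites."""
        return len(self.positions)

    @property
    def total_segregating(self) -> int:
        """All variable sites, biallelic plus multiallelic (Watterson's S)."""
        return self.S + len(self.multiallelic_positions)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.positions), self.n):
            raise ValueError("states must have shape (S, n)")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


def segregating_sites(aln: Alignment) -> SegSites:
    """Extract biallelic segregating sites; record multiallelic ones."""
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    m = aln.matrix
    miss = aln.missing_mask()
    positions, rows, multi = [], [], []
    for j in range(aln.length):
        col = m[:, j]
        ok = ~miss[:, j]
        alleles = sorted(set(col[ok]))
        if len(alleles) <= 1:
            continue
        if len(alleles) > 2:
            multi.append(j)
            continue
        a0 = alleles[0]
        row = np.full(n, -1, dtype=np.int8)
        row[ok] = (col[ok] != a0).astype(np.int8)
        positions.append(j)
        rows.append(row)
    states = (
        np.array(rows, dtype=np.int8) if rows else np.empty((0, n), dtype=np.int8)
    )
    return SegSites(np.array(positions, dtype=int), states, n,
                    np.array(multi, dtype=int))


def nucleotide_diversity(aln: Alignment, *, per_site: bool = False) -> float:
    """Mean number of pairwise differences (pi).

    Differences are counted over mutually non-missing sites for each pair.
    With ``per_site`` the per-gene value is divided by the alignment
    length.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    m = aln.matrix
    miss = aln.missing_mask()
    total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            total += np.count_nonzero(m[i, ok] != m[j, ok])
            npairs += 1
    pi = total / npairs
    return pi / aln.length if per_site else pi


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


def watterson_theta(seg: SegSites) -> float:
    """Watterson's per-gene estimator theta_W = S / a1."""
    return seg.total_segregating / _harmonic(seg.n)


def tajima_constants(n: int) -> dict:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants of Tajima's D."""
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(aln: Alignment) -> float:
    """Tajima's D = (pi - S/a1) / sqrt(e1 S + e2 S(S-1)).

    Raises :class:`UndefinedResult` when S = 0 (D is reported missing,
    never as zero).
    """
    n = len(aln)
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    seg = segregating_sites(aln)
    S = seg.total_segregating
    if S == 0:
        raise UndefinedResult("Tajima's D undefined for S = 0")
    c = tajima_constants(n)
    pi = nucleotide_diversity(aln)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi - S / c["a1"]) / np.sqrt(var)


def tajimas_d_from_segsites(seg: SegSites) -> float:
    """Tajima's D from 0/1 segregating-site data (coalescent replicates)."""
    n, S = seg.n, seg.total_segregating
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S == 0:
        raise UndefinedResult("Tajima's D undefined for S = 0")
    c = tajima_constants(n)
    st = seg.states
    # pi from allele frequencies (no missing data in simulated samples)
    if np.any(st < 0):
        pi = 0.0
        npairs = n * (n - 1) / 2
        for k in range(seg.S):
            row = st[k]
            ok = row >= 0
            n1 = int(np.sum(row[ok] == 1))
            n0 = int(np.sum(row[ok] == 0))
            pi += n0 * n1 / npairs
    else:
        ones = st.sum(axis=1)
        pi = float(np.sum(ones * (n - ones))) / (n * (n - 1) / 2)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi - S / c["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Hudson's recombination-parameter estimator
# ---------------------------------------------------------------------------

_HUDSON_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0,
                256.0, 512.0)


def _expected_sk2(C: float, n: int, pi: float, L: int, reps: int,
                  seed: int) -> float:
    """Monte-Carlo evaluation of E[S_k^2 | C, n, theta = pi]: the expected
    within-sample variance of pairwise difference counts under the
    neutral coalescent with per-gene recombination parameter C."""
    import msprime

    vals = np.empty(reps)
    for r in range(reps):
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1.0, sequence_length=L,
            recombination_rate=C / (2.0 * L),
            random_seed=seed + 7919 * r + 1,
        )
        mts = msprime.sim_mutations(
            ts, rate=pi / (2.0 * L), random_seed=seed + 7919 * r + 2,
            model=msprime.BinaryMutationModel(), discrete_genome=False,
        )
        G = mts.genotype_matrix()  # (S, n), 0/1
        if G.shape[0] == 0:
            vals[r] = 0.0
            continue
        G = (G > 0).astype(np.int32)
        s = G.sum(axis=0)
        K = s[:, None] + s[None, :] - 2 * (G.T @ G)
        iu = np.triu_indices(n, 1)
        vals[r] = K[iu].astype(float).var(ddof=1)
    return float(vals.mean())


def hudson_R(
    aln: Alignment,
    *,
    reps: int = 80,
    seed: int = 0,
    l_divisor: int | None = None,
    grid: tuple = _HUDSON_GRID,
):
    """Hudson's (1987) recombination-parameter estimate per gene.

    The variance-of-pairwise-differences method: the observed sample
    variance S_k^2 of the pairwise difference counts is matched to its
    neutral-coalescent expectation given the sample size and theta
    estimated by pi, and the per-gene C = 4Nc solving the expectation
    equation is returned.  The expectation (which must account for the
    shared genealogy of overlapping sequence pairs) is evaluated by
    seeded coalescent Monte Carlo on a recombination grid and inverted
    by monotone interpolation in log(1 + C); larger excess variance
    yields smaller C.

    Returns
    -------
    (R_gene, R_adjacent, flag)
        ``R_adjacent = R_gene / L`` (mean adjacent-site rate over the
        analyzed length).  ``flag`` is "at_upper_bound" /
        "at_lower_bound" when the observed variance falls outside the
        attainable range, else "".
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    seg = segregating_sites(aln)
    if seg.total_segregating < 2:
        raise UndefinedResult("Hudson's R undefined for S < 2")
    m = aln.matrix
    miss = aln.missing_mask()
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            diffs.append(int(np.count_nonzero(m[i, ok] != m[j, ok])))
    diffs = np.asarray(diffs, dtype=float)
    pi = float(diffs.mean())
    sk2 = float(diffs.var(ddof=1))
    if pi <= 0:
        raise UndefinedResult("no pairwise differences")
    L = l_divisor if l_divisor is not None else aln.length

    expect = np.array([
        _expected_sk2(C, n, pi, aln.length, reps, seed + 104729 * k)
        for k, C in enumerate(grid)
    ])
    # enforce monotone decrease (isotonic in reverse) before inversion
    expect = np.minimum.accumulate(expect)
    if sk2 >= expect[0]:
        return float(grid[0]), float(grid[0]) / L, "at_lower_bound"
    if sk2 <= expect[-1]:
        return float(grid[-1]), float(grid[-1]) / L, "at_upper_bound"
    x = np.log1p(np.asarray(grid))
    C = float(np.expm1(np.interp(-sk2, -expect, x)))
    return C, C / L, ""


# ---------------------------------------------------------------------------
# Four-gamete test / Hudson-Kaplan Rm
# ---------------------------------------------------------------------------

def _four_gametes(a: np.ndarray, b: np.ndarray) -> bool:
    ok = (a >= 0) & (b >= 0)
    if np.count_nonzero(ok) < 4:
        return False
    g = set(zip(a[ok].tolist(), b[ok].tolist()))
    return len(g) == 4


def incompatible_pairs(seg: SegSites) -> list:
    """All index pairs (i, j), i < j, showing all four gametes."""
    out = []
    S = seg.S
    for i in range(S):
        for j in range(i + 1, S):
            if _four_gametes(seg.states[i], seg.states[j]):
                out.append((i, j))
    return out


def four_gamete_Rm(seg: SegSites) -> int:
    """Hudson-Kaplan minimum number of recombination events.

    Every four-gamete-incompatible site pair requires a crossover in the
    open interval between the two sites; Rm is the size of the largest
    set of pairwise non-overlapping incompatible intervals, found by the
    standard greedy sweep after removing non-minimal intervals.
    """
    pairs = incompatible_pairs(seg)
    if not pairs:
        return 0
    # keep minimal intervals only
    minimal = [
        (i, j)
        for (i, j) in pairs
        if not any((i <= a and b <= j and (a, b) != (i, j)) for (a, b) in pairs)
    ]
    minimal.sort(key=lambda p: p[1])
    rm, last_end = 0, -1
    for a, b in minimal:
        if a >= last_end:
            rm += 1
            last_end = b
    return rm


# ---------------------------------------------------------------------------
# Linkage-disequilibrium statistics
# ---------------------------------------------------------------------------

def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared correlation of the 0/1 allele indicators at two sites,
    over haplotypes non-missing at both.  NaN when either site is
    monomorphic on the shared rows."""
    ok = (a >= 0) & (b >= 0)
    x, y = a[ok].astype(float), b[ok].astype(float)
    if len(x) < 2:
        return np.nan
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return np.nan
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def zz_statistic(seg: SegSites):
    """(Za, ZnS, ZZ): mean adjacent-pair r^2, mean all-pair r^2, and their
    difference.  Undefined for S < 2."""
    S = seg.S
    if S < 2:
        raise UndefinedResult("ZZ undefined for S < 2")
    st = seg.states
    if not np.any(st < 0):
        # fast path: vectorised correlation matrix
        x = st.astype(float)
        xc = x - x.mean(axis=1, keepdims=True)
        sd = xc.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (xc @ xc.T) / len(x[0]) / np.outer(sd, sd)
        r2 = corr * corr
        iu = np.triu_indices(S, k=1)
        all_vals = r2[iu]
        adj_vals = np.array([r2[k, k + 1] for k in range(S - 1)])
    else:
        all_vals = np.array(
            [pairwise_r2(st[i], st[j]) for i in range(S) for j in range(i + 1, S)]
        )
        adj_vals = np.array([pairwise_r2(st[k], st[k + 1]) for k in range(S - 1)])
    zns = float(np.nanmean(all_vals))
    za = float(np.nanmean(adj_vals))
    return za, zns, za - zns


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

@dataclass
class PopgenSummary:
    """Observed per-alignment statistics (one row of a diversity table)."""

    n: int
    L: int
    S: int
    pi_gene: float
    pi_site: float
    theta_w: float
    tajima_d: float | None
    R_gene: float | None
    R_adjacent: float | None
    R_flag: str
    Rm: int
    Za: float | None
    ZnS: float | None
    ZZ: float | None


def summarize(aln: Alignment) -> PopgenSummary:
    """Compute the full observed statistic set for one alignment."""
    seg = segregating_sites(aln)
    pi = nucleotide_diversity(aln)
    theta = watterson_theta(seg)
    try:
        d = tajimas_d(aln)
    except (UndefinedResult, ValueError):
        d = None
    try:
        rg, ra, flag = hudson_R(aln)
    except UndefinedResult:
        rg, ra, flag = None, None, "undefined"
    rm = four_gamete_Rm(seg)
    try:
        za, zns, zz = zz_statistic(seg)
    except UndefinedResult:
        za = zns = zz = None
    return PopgenSummary(
        n=len(aln), L=aln.length, S=seg.total_segregating,
        pi_gene=pi, pi_site=pi / aln.length, theta_w=theta, tajima_d=d,
        R_gene=rg, R_adjacent=ra, R_flag=flag, Rm=rm, Za=za, ZnS=zns, ZZ=zz,
    )
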