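"""Coalescent simulation under fixed-S conditioning.

Produces the null distributions, percentile confidence intervals and
empirical p-values against which the observed recombination and
neutrality statistics are judged.  Three recombination regimes:

``none``
    a single Kingman genealogy per replicate; all S sites share it
    (complete linkage).
``free``
    every site draws an independent genealogy (complete linkage
    equilibrium) — the classic "free recombination" null.
``rho:<value>``
    an ancestral-recombination-graph simulation with per-gene scaled
    rate rho = 4Nc over L sites (delegated to msprime), with mutations
    then placed on the marginal trees.

All regimes condition on the observed number of segregating sites S:
each replicate carries exactly S biallelic sites, each created by a
single mutation placed on a branch with probability proportional to
branch length.  Time is in standard coalescent units (pairwise
coalescence rate 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .popgen import SegSites, UndefinedResult

__all__ = [
    "CoalescentConfig",
    "NullDistribution",
    "simulate_sample",
    "null_distribution",
    "kingman_branches",
]


@dataclass(frozen=True)
class CoalescentConfig:
    """Parameters of one simulation run.

    recomb_mode is "none", "free" or "rho"; rho > 0 requires L (the
    number of sites over which recombination can act).
    """

    n: int
    S: int
    recomb_mode: str = "none"
    rho: float = 0.0
    L: int = 1000
    reps: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        if self.S < 0:
            raise ValueError("S must be >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.recomb_mode not in ("none", "free", "rho"):
            raise ValueError(f"unknown recomb_mode {self.recomb_mode!r}")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


def kingman_branches(n: int, rng: np.random.Generator):
    """One standard n-coalescent genealogy.

    Returns (lengths, leafsets): per non-root branch its length and the
    frozenset of 0-based sample indices below it.
    """
    active = [(frozenset([i]), 0.0) for i in range(n)]  # (leafset, node time)
    t = 0.0
    lengths, leafsets = [], []
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (i, j) if i < j else (j, i)
        (si, ti) = active[i]
        (sj, tj) = active[j]
        lengths.extend([t - ti, t - tj])
        leafsets.extend([si, sj])
        merged = (si | sj, t)
        active[i] = merged
        del active[j]
        k -= 1
    return np.asarray(lengths), leafsets


def _states_from_branches(n, S, lengths, leafsets, rng):
    """Place S mutations on branches with probability prop. to length."""
    p = lengths / lengths.sum()
    picks = rng.choice(len(lengths), size=S, p=p)
    states = np.zeros((S, n), dtype=np.int8)
    for s, b in enumerate(picks):
        states[s, list(leafsets[b])] = 1
    return states


def simulate_sample(cfg: CoalescentConfig, rng: np.random.Generator | None = None) -> SegSites:
    """One fixed-S replicate under the configured recombination regime."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, S = cfg.n, cfg.S
    if S == 0:
        return SegSites(np.empty(0, dtype=int), np.empty((0, n), dtype=np.int8), n)
    if cfg.recomb_mode == "none" or (cfg.recomb_mode == "rho" and cfg.rho == 0):
        lengths, leafsets = kingman_branches(n, rng)
        states = _states_from_branches(n, S, lengths, leafsets, rng)
    elif cfg.recomb_mode == "free":
        states = np.zeros((S, n), dtype=np.int8)
        for s in range(S):
            lengths, leafsets = kingman_branches(n, rng)
            p = lengths / lengths.sum()
            b = rng.choice(len(lengths), p=p)
            states[s, list(leafsets[b])] = 1
    else:  # rho mode: ancestral recombination graph via msprime
        states = _arg_states(cfg, rng)
    positions = np.sort(rng.choice(cfg.L, size=S, replace=False)) if cfg.L >= S \
        else np.arange(S)
    return SegSites(positions, states, n)


def _arg_states(cfg: CoalescentConfig, rng: np.random.Generator) -> np.ndarray:
    import msprime

    # population_size=1, ploidy=1 gives pairwise coalescence rate 1
    # (standard coalescent time units); per-lineage recombination rate
    # over the gene must then be rho/2, i.e. rho/(2L) per unit length.
    ts = msprime.sim_ancestry(
        samples=cfg.n,
        ploidy=1,
        population_size=1.0,
        sequence_length=cfg.L,
        recombination_rate=cfg.rho / (2.0 * cfg.L),
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    # site positions uniform over the gene; mutation branch chosen with
    # probability proportional to branch length on that site's marginal tree
    pos = np.sort(rng.uniform(0, cfg.L, size=cfg.S))
    states = np.zeros((cfg.S, cfg.n), dtype=np.int8)
    tree = ts.first()
    for s, x in enumerate(pos):
        while tree.interval.right <= x:
            tree.next()
        nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
        bl = np.array([tree.branch_length(u) for u in nodes])
        u = nodes[rng.choice(len(nodes), p=bl / bl.sum())]
        for leaf in tree.samples(u):
            states[s, leaf] = 1
    return states


@dataclass
class NullDistribution:
    """Simulated null of a statistic plus its comparison to an observation."""

    statistic: str
    observed: float
    samples: np.ndarray
    n_dropped: int = 0
    ci: tuple = (0.025, 0.975)

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def ci_low(self) -> float:
        return float(np.quantile(self.samples, self.ci[0]))

    @property
    def ci_high(self) -> float:
        return float(np.quantile(self.samples, self.ci[1]))

    @property
    def p_ge_raw(self) -> float:
        """Raw proportion Pr(sim >= observed)."""
        return float(np.mean(self.samples >= self.observed))

    @property
    def p_ge(self) -> float:
        """Add-one (Davison-Hinkley) corrected Pr(sim >= observed)."""
        r = len(self.samples)
        return (np.count_nonzero(self.samples >= self.observed) + 1) / (r + 1)

    @property
    def p_le(self) -> float:
        r = len(self.samples)
        return (np.count_nonzero(self.samples <= self.observed) + 1) / (r + 1)

    def table_row(self) -> dict:
        """Observed / mean / CI / p in the shape of a recombination table."""
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_ge": self.p_ge,
            "p_ge_raw": self.p_ge_raw,
            "n_dropped": self.n_dropped,
        }


def null_distribution(
    cfg: CoalescentConfig,
    statistic,
    observed: float,
    *,
    name: str = "statistic",
) -> NullDistribution:
    """Simulate ``cfg.reps`` replicates and evaluate ``statistic`` on each.

    Replicates on which the statistic is undefined are dropped and
    counted; a warning is emitted when more than 10% drop.  Bit-identical
    under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    vals = []
    dropped = 0
    for _ in range(cfg.reps):
        seg = simulate_sample(cfg, rng)
        try:
            v = statistic(seg)
        except (UndefinedResult, ZeroDivisionError, FloatingPointError):
            dropped += 1
            continue
        if v is None or (isinstance(v, float) and np.isnan(v)):
            dropped += 1
            continue
        vals.append(float(v))
    if dropped > 0.1 * cfg.reps:
        warnings.warn(
            f"{dropped}/{cfg.reps} replicates dropped (statistic undefined)",
            RuntimeWarning,
        )
    if not vals:
        raise UndefinedResult("statistic undefined on every replicate")
    return NullDistribution(name, float(observed), np.asarray(vals), dropped)
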