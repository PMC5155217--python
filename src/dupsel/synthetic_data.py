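"""Synthetic-data generators with recorded ground truth.

Every generator is a pure function of (parameters, seed) and emits a
manifest sufficient to regenerate its output bit-identically:

* ultrametric Yule / birth-death trees (diversification-rate nulls);
* duplicate-gene trees for the two rival scenarios — duplication before
  speciation (two mirrored species clades) or after speciation (within-
  species paralog cherries);
* codon alignments evolved along a tree by exact Gillespie simulation of
  the 61-state codon process, honouring per-site-class and per-branch
  (foreground) omega regimes, with realized synonymous/nonsynonymous
  substitution counts recorded per branch;
* two-clade protein datasets with a controlled fraction of radically
  divergent sites (opposite charge classes between the clade ancestors)
  for exercising type-II divergence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codonml import CodonModelSpec, CodonSpace, build_rate_matrix
from .divergence import AMINO_ACIDS, ClusterPair, charge_class
from .seqio import Alignment, CodonAlignment, GeneticCode, parse_newick

__all__ = [
    "SimulationError",
    "simulate_tree",
    "DuplicationScenario",
    "simulate_duplication_gene_tree",
    "SimRecord",
    "simulate_codon_alignment",
    "RadicalBiasData",
    "simulate_radical_bias",
]


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("label", "start", "children", "end")

    def __init__(self, label, start):
        self.label = label
        self.start = start
        self.children = None
        self.end = None

    def newick(self):
        if self.children is None:
            return f"{self.label}:{self.end - self.start:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.end - self.start:.10g}"


def simulate_tree(kind: str, n: int, *, birth: float = 1.0, death: float = 0.0,
                  seed: int = 0, max_retries: int = 1000) -> dendropy.Tree:
    """An ultrametric tree with exactly ``n`` extant tips.

    ``yule``: pure birth.  ``birth-death``: constant rates with complete
    extinct-lineage pruning; impossible conditionings (death >= birth
    failing repeatedly) raise :class:`SimulationError`.
    Tips are labeled t1..tn in attachment order.
    """
    if n < 3:
        raise ValueError("need n >= 3 tips")
    if birth <= 0 or death < 0:
        raise ValueError("birth must be > 0 and death >= 0")
    rng = np.random.default_rng(seed)
    if kind not in ("yule", "birth-death"):
        raise ValueError(f"unknown tree kind {kind!r}")
    mu = 0.0 if kind == "yule" else death

    for _ in range(max_retries):
        t = 0.0
        counter = [0]

        def leaf():
            counter[0] += 1
            return _Lineage(f"t{counter[0]}", t)

        root = _Lineage("", 0.0)
        a, b = leaf(), leaf()
        root.children = [a, b]
        root.end = 0.0
        active = [a, b]
        dead_happened = False
        while 0 < len(active) < n:
            k = len(active)
            t += rng.exponential(1.0 / (k * (birth + mu)))
            lin = active[int(rng.integers(k))]
            if rng.random() < birth / (birth + mu):
                lin.children = []
                lin.end = t
                c1, c2 = leaf(), leaf()
                c1.start = c2.start = t
                lin.children = [c1, c2]
                active.remove(lin)
                active.extend([c1, c2])
            else:
                lin.end = t
                lin.label = f"__dead_{lin.label}"  # extinct
                active.remove(lin)
                dead_happened = True
        if not active:
            continue
        # survive to the present: one more memoryless holding time
        t += rng.exponential(1.0 / (len(active) * (birth + mu)))
        for lin in active:
            lin.end = t
        nwk = f"({root.children[0].newick()},{root.children[1].newick()});"
        tree = parse_newick(nwk)
        if dead_happened:
            keep = [lf.taxon for lf in tree.leaf_node_iter()
                    if not lf.taxon.label.startswith("__dead_")]
            tree.retain_taxa(keep)
            tree.purge_taxon_namespace()
        if len(tree.leaf_nodes()) == n:
            for k, lf in enumerate(tree.leaf_node_iter()):
                lf.taxon.label = f"t{k + 1}"
            return tree
    raise SimulationError(f"failed to draw an {kind} tree with {n} tips")


@dataclass(frozen=True)
class DuplicationScenario:
    """A duplicate-gene simulation design.

    ``duplication`` is "before-speciation" (the duplication node precedes
    the species radiation: two mirrored species clades) or
    "after-speciation" (each species carries a local paralog cherry).
    """

    n_species: int = 6
    duplication: str = "before-speciation"
    species_depth: float = 0.3
    dup_stem_length: float = 0.15
    cherry_length: float = 0.05
    lost_tips: frozenset = frozenset()

    def __post_init__(self):
        if self.duplication not in ("before-speciation", "after-speciation"):
            raise ValueError(f"unknown duplication mode {self.duplication!r}")


def _scale_depth(tree: dendropy.Tree, depth: float) -> dendropy.Tree:
    cur = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    for e in tree.preorder_edge_iter():
        if e.length:
            e.length *= depth / cur
    return tree


def simulate_duplication_gene_tree(scenario: DuplicationScenario,
                                   seed: int = 0) -> dendropy.Tree:
    """Gene tree for a duplication scenario; tips named <species>_<dupN>."""
    sp = simulate_tree("yule", scenario.n_species, seed=seed)
    _scale_depth(sp, scenario.species_depth)
    sp_newick = sp.as_string(schema="newick", suppress_rooting=True).strip()
    sp_newick = sp_newick.rstrip(";")

    def relabel(nwk: str, suffix: str) -> str:
        import re
        return re.sub(r"t(\d+):", lambda m: f"t{m.group(1)}_{suffix}:", nwk)

    if scenario.duplication == "before-speciation":
        c1 = relabel(sp_newick, "dup1")
        c2 = relabel(sp_newick, "dup2")
        s = scenario.dup_stem_length
        nwk = f"({c1}:{s},{c2}:{s});"
    else:
        import re
        cl = scenario.cherry_length
        nwk = re.sub(
            r"t(\d+):(\d+\.?\d*(?:[eE][+-]?\d+)?)",
            lambda m: (f"(t{m.group(1)}_dup1:{cl},t{m.group(1)}_dup2:{cl})"
                       f":{max(float(m.group(2)) - cl, 0.0):.10g}"),
            sp_newick,
        ) + ";"
    tree = parse_newick(nwk)
    if scenario.lost_tips:
        keep = [lf.taxon for lf in tree.leaf_node_iter()
                if lf.taxon.label not in scenario.lost_tips]
        tree.retain_taxa(keep)
    return tree


# ---------------------------------------------------------------------------
# Codon alignments (Gillespie)
# ---------------------------------------------------------------------------

@dataclass
class SimRecord:
    """Ground truth of one codon-alignment simulation."""

    seed: int
    n_codons: int
    manifest: dict
    site_class: np.ndarray
    branch_counts: dict = field(default_factory=dict)  # key -> (syn, nonsyn)

    @property
    def total_synonymous(self) -> int:
        return sum(s for s, _ in self.branch_counts.values())

    @property
    def total_nonsynonymous(self) -> int:
        return sum(n for _, n in self.branch_counts.values())


def _sim_pi(spec: CodonModelSpec, code: GeneticCode) -> np.ndarray:
    if isinstance(spec.codon_freqs, str):
        n = CodonSpace(code).n
        return np.full(n, 1.0 / n)  # simulation default: equal sense-codon freqs
    pi = np.asarray(spec.codon_freqs, dtype=float)
    return pi / pi.sum()


def simulate_codon_alignment(
    tree: dendropy.Tree,
    spec: CodonModelSpec,
    n_codons: int,
    seed: int = 0,
    *,
    code: GeneticCode | None = None,
):
    """Evolve a codon alignment along ``tree`` under ``spec``.

    Exact Gillespie simulation per branch and site, so the realized
    substitution counts in the returned :class:`SimRecord` are event-level
    ground truth.  Branch lengths are expected substitutions per codon at
    equilibrium within each site class; ``spec.foreground`` branch keys
    (frozensets of tip labels) switch those branches to the classes'
    foreground omega.
    """
    code = code or GeneticCode.standard()
    space = CodonSpace(code)
    rng = np.random.default_rng(seed)
    pi = _sim_pi(spec, code)
    probs = spec.normalized_probs()
    if np.all(probs <= 0):
        raise SimulationError("all class proportions zero")
    site_class = rng.choice(len(probs), size=n_codons, p=probs)

    # per (class, regime) jump structure; a single scale factor from the
    # background mixture (matching the likelihood convention) so branch
    # lengths mean expected substitutions per codon under the background
    # regime and omega > 1 classes genuinely evolve faster
    aa = space.amino_acids
    mu_mix = 0.0
    for p, cls in zip(probs, spec.classes):
        Q = build_rate_matrix(spec.kappa, cls.omega_background, pi, code,
                              scale=False)
        mu_mix += p * (-float(pi @ np.diag(Q)))
    mu_mix = max(mu_mix, 1e-12)
    jump = {}
    for ci, cls in enumerate(spec.classes):
        for regime, om in (("bg", cls.omega_background), ("fg", cls.omega_fg)):
            key = (ci, regime)
            if key in jump:
                continue
            Q = build_rate_matrix(spec.kappa, om, pi, code, scale=False) / mu_mix
            exit_rate = -np.diag(Q).copy()
            P = Q.copy()
            np.fill_diagonal(P, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                P = np.where(exit_rate[:, None] > 0, P / exit_rate[:, None], 0.0)
            jump[key] = (exit_rate, P)

    nodes = list(tree.preorder_node_iter())
    states = {}
    root = nodes[0]
    states[id(root)] = rng.choice(space.n, size=n_codons, p=pi)
    branch_counts = {}
    tipset = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            tipset[id(nd)] = frozenset([nd.taxon.label])
        else:
            s = frozenset()
            for ch in nd.child_nodes():
                s |= tipset[id(ch)]
            tipset[id(nd)] = s

    for nd in nodes[1:]:
        parent_state = states[id(nd.parent_node)]
        t_branch = nd.edge.length or 0.0
        key = tipset[id(nd)]
        regime = "fg" if key in spec.foreground else "bg"
        cur = parent_state.copy()
        syn = nonsyn = 0
        if t_branch > 0:
            for s in range(n_codons):
                er, P = jump[(site_class[s], regime)]
                st = cur[s]
                t = 0.0
                while True:
                    r = er[st]
                    if r <= 0:
                        break
                    t += rng.exponential(1.0 / r)
                    if t >= t_branch:
                        break
                    new = rng.choice(space.n, p=P[st])
                    if aa[new] == aa[st]:
                        syn += 1
                    else:
                        nonsyn += 1
                    st = new
                cur[s] = st
        states[id(nd)] = cur
        branch_counts[key] = (syn, nonsyn)

    ids, seqs = [], []
    for lf in tree.leaf_node_iter():
        ids.append(lf.taxon.label)
        seqs.append("".join(space.codons[i] for i in states[id(lf)]))
    aln = Alignment(ids, seqs)
    caln = CodonAlignment(aln, code)
    manifest = {
        "kappa": spec.kappa,
        "classes": [(c.prop, c.omega_background, c.omega_fg)
                    for c in spec.classes],
        "foreground": sorted(sorted(k) for k in spec.foreground),
        "n_codons": n_codons,
        "seed": seed,
    }
    rec = SimRecord(seed=seed, n_codons=n_codons, manifest=manifest,
                    site_class=site_class, branch_counts=branch_counts)
    return caln, rec


# ---------------------------------------------------------------------------
# Rate-shift protein data (type-I divergence exercise)
# ---------------------------------------------------------------------------

def simulate_rate_shift(
    n_sites: int = 255,
    switched_fraction: float = 0.3,
    *,
    n_per_clade: int = 6,
    tip_depth: float = 0.5,
    gamma_shape: float = 0.5,
    seed: int = 0,
) -> "RadicalBiasData":
    """Two clades with gamma-distributed site rates; a ``switched_fraction``
    of sites draws independent rates in the two clades (type-I divergent),
    the rest share one rate.  Tips evolve on star trees with Poisson
    substitution counts (uniform replacement), giving sequence-level data
    for the rate-correlation statistics.
    """
    if not 0.0 <= switched_fraction <= 1.0:
        raise ValueError("switched_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    anc = rng.choice(20, size=n_sites)
    lam1 = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_sites)
    lam2 = lam1.copy()
    truth = np.zeros(n_sites, dtype=bool)
    n_sw = int(round(switched_fraction * n_sites))
    sw = rng.choice(n_sites, size=n_sw, replace=False)
    truth[sw] = True
    lam2[sw] = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_sw)

    def clade(lam, prefix, tree_seed):
        # resolved topology with many short branches keeps per-site
        # substitution counts Poisson-like (rate-correlation statistics
        # assume Poisson sampling of the site rates)
        tree = simulate_tree("yule", n_per_clade, seed=tree_seed)
        depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
        for e in tree.preorder_edge_iter():
            if e.length:
                e.length *= tip_depth / depth
        for i, lf in enumerate(tree.leaf_node_iter()):
            lf.taxon.label = f"{prefix}{i + 1}"
        ids, seqs = [], []
        states = {id(tree.seed_node): anc.copy()}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            row = states[id(nd.parent_node)].copy()
            nhits = rng.poisson(lam * (nd.edge.length or 0.0))
            for s in np.nonzero(nhits > 0)[0]:
                for _ in range(nhits[s]):
                    choices = [i for i in range(20) if i != row[s]]
                    row[s] = choices[int(rng.integers(19))]
            states[id(nd)] = row
        for lf in tree.leaf_node_iter():
            ids.append(lf.taxon.label)
            seqs.append("".join(aas[states[id(lf)]]))
        return Alignment(ids, seqs, alphabet="aa"), tree

    aln1, tree1 = clade(lam1, "A", seed * 2 + 1)
    aln2, tree2 = clade(lam2, "B", seed * 2 + 2)
    manifest = {
        "n_sites": n_sites, "switched_fraction": switched_fraction,
        "n_per_clade": n_per_clade, "tip_depth": tip_depth,
        "gamma_shape": gamma_shape, "seed": seed,
    }
    return RadicalBiasData(aln1, aln2, tree1, tree2, truth, manifest)


# ---------------------------------------------------------------------------
# Radical-bias protein data (type-II divergence exercise)
# ---------------------------------------------------------------------------

@dataclass
class RadicalBiasData:
    """Two-clade protein alignments with known divergent-site labels."""

    aln1: Alignment
    aln2: Alignment
    tree1: dendropy.Tree
    tree2: dendropy.Tree
    truth: np.ndarray  # True at type-II divergent sites
    manifest: dict

    def pair(self) -> ClusterPair:
        return ClusterPair(self.aln1, self.aln2, self.tree1, self.tree2)


def simulate_radical_bias(
    n_sites: int = 255,
    divergent_fraction: float = 0.1,
    *,
    n_per_clade: int = 5,
    within_rate: float = 0.05,
    seed: int = 0,
) -> RadicalBiasData:
    """Two clades whose ancestors differ radically at a chosen site fraction.

    At divergent sites the two clade-ancestral residues are forced into
    different charge classes (hence radical); elsewhere the ancestors are
    identical.  Tips carry independent within-clade noise at
    ``within_rate`` expected replacements per site on star trees.
    """
    if not 0.0 <= divergent_fraction <= 1.0:
        raise ValueError("divergent_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    anc1 = rng.choice(20, size=n_sites)
    anc2 = anc1.copy()
    truth = np.zeros(n_sites, dtype=bool)
    n_div = int(round(divergent_fraction * n_sites))
    div_sites = rng.choice(n_sites, size=n_div, replace=False)
    truth[div_sites] = True
    for s in div_sites:
        c1 = charge_class(aas[anc1[s]])
        alt = [i for i in range(20) if charge_class(aas[i]) != c1]
        anc2[s] = rng.choice(alt)

    p_change = 1.0 - np.exp(-within_rate)

    def clade(anc, prefix, ntips):
        ids, seqs = [], []
        for k in range(ntips):
            row = anc.copy()
            hits = rng.random(n_sites) < p_change
            for s in np.nonzero(hits)[0]:
                choices = [i for i in range(20) if i != row[s]]
                row[s] = choices[int(rng.integers(19))]
            ids.append(f"{prefix}{k + 1}")
            seqs.append("".join(aas[row]))
        nwk = "(" + ",".join(f"{i}:{within_rate:.6g}" for i in ids) + ");"
        return Alignment(ids, seqs, alphabet="aa"), parse_newick(nwk)

    aln1, tree1 = clade(anc1, "A", n_per_clade)
    aln2, tree2 = clade(anc2, "B", n_per_clade)
    manifest = {
        "n_sites": n_sites, "divergent_fraction": divergent_fraction,
        "n_per_clade": n_per_clade, "within_rate": within_rate, "seed": seed,
    }
    return RadicalBiasData(aln1, aln2, tree1, tree2, truth, manifest)
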