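"""Codon-substitution counting and likelihood machinery.

Two layers:

* **Counting** — Nei-Gojobori (1986) synonymous/nonsynonymous site and
  difference counts with exact minimal-pathway averaging
  (:func:`ng86_counts`), reported as proportions (pS, pN) without
  multiple-hit correction.

* **Likelihood** — a Goldman-Yang-style Markov model on the 61 sense
  codons.  Instantaneous rates for single-nucleotide changes are
  ``pi_j``, ``kappa*pi_j``, ``omega*pi_j`` or ``omega*kappa*pi_j``
  according to transition/transversion and synonymous/nonsynonymous
  status; multi-nucleotide changes have rate 0; the generator is scaled
  to one expected substitution per codon site at equilibrium.  Site-class
  mixtures implement the standard model templates (M0, free-ratio, M1a,
  M2a, M7, M8, M8a, branch-site model A and its fixed-omega2 null), with
  likelihood-ratio tests, naive-empirical-Bayes site posteriors, and
  RELL-based KH/SH topology tests.

Fitting strategy: branch lengths are estimated once under M0 (quasi-
Newton, initialised from the input tree or NG86/NJ distances) and shared
by the site-class models, whose alternative fits start from the fitted
null so the nesting inequalities hold numerically.  Multi-restart is
used for the class-model parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .seqio import CodonAlignment, GeneticCode

__all__ = [
    "NGCounts",
    "ng86_counts",
    "SiteClass",
    "CodonModelSpec",
    "FitResult",
    "SitePosterior",
    "CodonSpace",
    "build_rate_matrix",
    "f3x4_frequencies",
    "site_log_likelihoods",
    "fit_model",
    "lrt",
    "site_posteriors",
    "kh_sh_tests",
    "MODEL_TEMPLATES",
]

_NT = "ACGT"
_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


# ===========================================================================
# Nei-Gojobori 1986 counting
# ===========================================================================

@dataclass
class NGCounts:
    """Synonymous/nonsynonymous site and difference counts (proportions).

    ``omega`` is pN/pS; when pS = 0 it is reported as inf with
    ``omega_infinite`` set rather than a sentinel value.
    """

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    n_codons: int

    @property
    def pS(self) -> float:
        return self.Sd / self.S_sites if self.S_sites > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N_sites if self.N_sites > 0 else 0.0

    # proportion method: no multiple-hit correction
    dS = pS
    dN = pN

    @property
    def omega_infinite(self) -> bool:
        return self.pS == 0 and self.pN > 0

    @property
    def omega(self) -> float:
        if self.pS == 0:
            return np.inf if self.pN > 0 else np.nan
        return self.pN / self.pS


def _codon_ok(c: str) -> bool:
    return len(c) == 3 and all(ch in _NT for ch in c)


def _syn_sites_one(codon: str, code: GeneticCode) -> float:
    """Fraction of the codon's 3 positions that are synonymous sites.

    Each position contributes (#synonymous one-step changes)/3; changes
    into stop codons are disregarded (they count neither as synonymous
    nor reduce the denominator, i.e. they fall to the nonsynonymous
    side), so S + N = 3 per codon.
    """
    aa = code.translate_codon(codon)
    s = 0.0
    for k in range(3):
        for nt in _NT:
            if nt == codon[k]:
                continue
            alt = codon[:k] + nt + codon[k + 1:]
            if alt in code.stops:
                continue
            if code.translate_codon(alt) == aa:
                s += 1.0 / 3.0
    return s


def _pathway_diffs(ca: str, cb: str, code: GeneticCode):
    """Average synonymous/nonsynonymous step counts over all minimal
    mutational pathways between two codons; pathways through stop codons
    are excluded (unless every pathway is blocked)."""
    pos = [k for k in range(3) if ca[k] != cb[k]]
    results = []
    for order in itertools.permutations(pos):
        cur = ca
        sd = nd = 0.0
        blocked = False
        for k in order:
            nxt = cur[:k] + cb[k] + cur[k + 1:]
            if nxt in code.stops:
                blocked = True
            if code.translate_codon(cur) == code.translate_codon(nxt) and \
                    nxt not in code.stops and cur not in code.stops:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in results if not b]
    use = open_paths if open_paths else [(s, n) for s, n, _ in results]
    sd = float(np.mean([s for s, _ in use]))
    nd = float(np.mean([n for _, n in use]))
    return sd, nd


def ng86_counts(codons_a, codons_b, code: GeneticCode | None = None) -> NGCounts:
    """NG86 counts between two equal-length codon sequences.

    ``codons_a``/``codons_b`` are lists of 3-mers (or plain nucleotide
    strings of length divisible by 3).  Codons with gaps or ambiguity in
    either sequence are masked pairwise.
    """
    code = code or GeneticCode.standard()
    if isinstance(codons_a, str):
        codons_a = [codons_a[i:i + 3] for i in range(0, len(codons_a), 3)]
    if isinstance(codons_b, str):
        codons_b = [codons_b[i:i + 3] for i in range(0, len(codons_b), 3)]
    if len(codons_a) != len(codons_b):
        raise ValueError("codon sequences must have equal length")
    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb in zip(codons_a, codons_b):
        if not (_codon_ok(ca) and _codon_ok(cb)):
            continue
        if ca in code.stops or cb in code.stops:
            continue
        used += 1
        sa, sb = _syn_sites_one(ca, code), _syn_sites_one(cb, code)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        if ca != cb:
            sd, nd = _pathway_diffs(ca, cb, code)
            Sd += sd
            Nd += nd
    if used == 0:
        raise ArithmeticError("no comparable codons")
    return NGCounts(S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, n_codons=used)


# ===========================================================================
# Codon state space and rate matrices
# ===========================================================================

class CodonSpace:
    """The sense-codon state space of a genetic code, with precomputed
    single-nucleotide-change structure."""

    _cache: dict = {}

    def __new__(cls, code: GeneticCode):
        if code.table_id in cls._cache:
            return cls._cache[code.table_id]
        self = super().__new__(cls)
        self.code = code
        self.codons = code.sense_codons
        self.index = {c: i for i, c in enumerate(self.codons)}
        n = len(self.codons)
        self.n = n
        aa = [code.translate_codon(c) for c in self.codons]
        self.amino_acids = aa
        pairs_i, pairs_j, is_ts, is_syn = [], [], [], []
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diff = [k for k in range(3) if ci[k] != cj[k]]
                if len(diff) != 1:
                    continue
                k = diff[0]
                pairs_i.append(i)
                pairs_j.append(j)
                is_ts.append(_is_transition(ci[k], cj[k]))
                is_syn.append(aa[i] == aa[j])
        self.pair_i = np.asarray(pairs_i)
        self.pair_j = np.asarray(pairs_j)
        self.pair_ts = np.asarray(is_ts, dtype=bool)
        self.pair_syn = np.asarray(is_syn, dtype=bool)
        cls._cache[code.table_id] = self
        return self


def f3x4_frequencies(codon_aln: CodonAlignment, *, floor: float = 1e-4) -> np.ndarray:
    """Equilibrium codon frequencies from position-specific nucleotide
    frequencies (the F3x4 convention), restricted to sense codons."""
    space = CodonSpace(codon_aln.code)
    counts = np.zeros((3, 4))
    for cods in codon_aln.codon_matrix():
        for c in cods:
            if _codon_ok(c):
                for k in range(3):
                    counts[k, _NT.index(c[k])] += 1
    counts += floor * counts.sum()
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, _NT.index(c[0])] * freqs[1, _NT.index(c[1])]
         * freqs[2, _NT.index(c[2])] for c in space.codons]
    )
    return pi / pi.sum()


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                      code: GeneticCode | None = None,
                      *, scale: bool = True) -> np.ndarray:
    """Scaled generator Q of the codon model (mean rate 1 at equilibrium
    when ``scale``)."""
    code = code or GeneticCode.standard()
    space = CodonSpace(code)
    n = space.n
    Q = np.zeros((n, n))
    rate = pi[space.pair_j].copy()
    rate[space.pair_ts] *= kappa
    rate[~space.pair_syn] *= omega
    Q[space.pair_i, space.pair_j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -float(pi @ np.diag(Q))
        if mu > 0:
            Q /= mu
    return Q


def _eig_reversible(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible generator; returns (A, lam, B)
    with P(t) = A @ diag(exp(lam t)) @ B."""
    d = np.sqrt(pi)
    Sym = (Q * d[:, None]) / d[None, :]
    Sym = (Sym + Sym.T) / 2.0
    lam, V = np.linalg.eigh(Sym)
    A = V / d[:, None]
    B = V.T * d[None, :]
    return A, lam, B


def _pmat(A, lam, B, t: float) -> np.ndarray:
    P = (A * np.exp(lam * t)) @ B
    np.clip(P, 0.0, None, out=P)
    rs = P.sum(axis=1, keepdims=True)
    return P / rs


# ===========================================================================
# Model specification
# ===========================================================================

@dataclass(frozen=True)
class SiteClass:
    """One mixture class: proportion plus background/foreground omega."""

    prop: float
    omega_background: float
    omega_foreground: float | None = None  # None = same as background

    @property
    def omega_fg(self) -> float:
        return self.omega_background if self.omega_foreground is None \
            else self.omega_foreground


@dataclass(frozen=True)
class CodonModelSpec:
    """Parameterisation of a (possibly branch-heterogeneous) codon model.

    ``foreground`` is a frozenset of branch keys; a branch is keyed by
    the frozenset of tip labels on its child side.  Class proportions
    are renormalised when they do not sum to one.
    """

    kappa: float = 2.0
    codon_freqs: object = "f3x4"  # "f3x4" | "equal" | explicit array
    classes: tuple = (SiteClass(1.0, 1.0),)
    foreground: frozenset = frozenset()

    def normalized_probs(self) -> np.ndarray:
        p = np.array([c.prop for c in self.classes], dtype=float)
        if np.any(p < 0):
            raise ValueError("class proportions must be >= 0")
        tot = p.sum()
        if tot <= 0:
            raise ValueError("class proportions sum to zero")
        return p / tot

    def frequencies(self, codon_aln: CodonAlignment) -> np.ndarray:
        if isinstance(self.codon_freqs, str):
            if self.codon_freqs == "f3x4":
                return f3x4_frequencies(codon_aln)
            if self.codon_freqs == "equal":
                n = CodonSpace(codon_aln.code).n
                return np.full(n, 1.0 / n)
            raise ValueError(f"unknown codon_freqs {self.codon_freqs!r}")
        pi = np.asarray(self.codon_freqs, dtype=float)
        return pi / pi.sum()


# ===========================================================================
# Internal tree / pruning machinery
# ===========================================================================

class LikTree:
    """Array-form rooted (possibly multifurcating) tree for pruning.

    Nodes are in postorder; the last node is the root.  The branch above
    node ``i`` has index ``i``.  Branch keys (frozensets of tip labels
    below the branch) support foreground selection.
    """

    def __init__(self, tree: dendropy.Tree, tip_order):
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.node_index = {id(nd): i for i, nd in enumerate(nodes)}
        self.children = [
            [self.node_index[id(ch)] for ch in nd.child_nodes()] for nd in nodes
        ]
        self.lengths = np.array(
            [nd.edge.length if nd.edge.length else 0.0 for nd in nodes]
        )
        self.is_leaf = np.array([nd.is_leaf() for nd in nodes])
        self.leaf_label = {
            i: nodes[i].taxon.label for i in range(self.n_nodes)
            if self.is_leaf[i] and nodes[i].taxon is not None
        }
        tips = set(tip_order)
        missing = tips - set(self.leaf_label.values())
        extra = set(self.leaf_label.values()) - tips
        if extra:
            raise ValueError(f"tree tips not in alignment: {sorted(extra)}")
        if missing:
            raise ValueError(f"alignment ids not in tree: {sorted(missing)}")
        self.root = self.n_nodes - 1
        # branch keys: tip labels below each node
        self.branch_key = {}
        below = [set() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_leaf[i]:
                below[i] = {self.leaf_label[i]}
            else:
                for ch in self.children[i]:
                    below[i] |= below[ch]
            self.branch_key[i] = frozenset(below[i])
        self.n_edges = self.n_nodes - 1

    def edges(self):
        return [i for i in range(self.n_nodes) if i != self.root]

    def foreground_edges(self, clade_tips, mode: str = "all"):
        """Edge indices for a foreground clade.

        ``stem`` selects only the branch subtending the clade (the
        whole-clade lineage); ``all`` selects the stem plus every branch
        inside the clade.
        """
        clade = frozenset(clade_tips)
        stem = [i for i in self.edges() if self.branch_key[i] == clade]
        if not stem:
            raise ValueError("no branch subtends exactly the requested clade")
        if mode == "stem":
            return set(stem)
        if mode == "all":
            return {i for i in self.edges() if self.branch_key[i] <= clade}
        raise ValueError(f"unknown foreground mode {mode!r}")


def _patterns(codon_aln: CodonAlignment, ids):
    """Compress alignment columns into unique patterns.

    Returns (pattern_matrix[tax, pat] of codon indices, -1 = missing;
    weights; site_to_pattern)."""
    space = CodonSpace(codon_aln.code)
    rows = []
    for sid in ids:
        cods = codon_aln.codons(sid)
        rows.append([space.index.get(c, -1) for c in cods])
    arr = np.asarray(rows, dtype=int)  # (ntax, nsites)
    cols = [tuple(arr[:, s]) for s in range(arr.shape[1])]
    uniq = {}
    site_to_pat = np.empty(len(cols), dtype=int)
    for s, c in enumerate(cols):
        if c not in uniq:
            uniq[c] = len(uniq)
        site_to_pat[s] = uniq[c]
    pats = np.asarray(list(uniq), dtype=int).T  # (ntax, npat)
    weights = np.bincount(site_to_pat, minlength=pats.shape[1]).astype(float)
    return pats, weights, site_to_pat


class _Engine:
    """Bound (alignment, tree) likelihood evaluator."""

    def __init__(self, codon_aln: CodonAlignment, tree: dendropy.Tree,
                 *, ids=None):
        self.code = codon_aln.code
        self.space = CodonSpace(self.code)
        self.ids = list(ids) if ids is not None else codon_aln.coding_ids()
        self.aln = codon_aln
        self.ltree = LikTree(tree, self.ids)
        self.pats, self.weights, self.site_to_pat = _patterns(codon_aln, self.ids)
        n = self.space.n
        npat = self.pats.shape[1]
        # leaf partials
        self.leaf_partial = {}
        for row, sid in enumerate(self.ids):
            M = np.zeros((n, npat))
            for p in range(npat):
                c = self.pats[row, p]
                if c < 0:
                    M[:, p] = 1.0
                else:
                    M[c, p] = 1.0
            for i, lbl in self.ltree.leaf_label.items():
                if lbl == sid:
                    self.leaf_partial[i] = M
        self.n_sites = len(self.site_to_pat)

    # -- pruning (batched over site classes) -----------------------------
    def _class_pattern_loglik(self, pmats) -> np.ndarray:
        """log-likelihood per pattern for one site class; ``pmats`` maps
        edge index -> P matrix."""
        out = self._batched_pattern_loglik(
            {e: P[None] for e, P in pmats.items()}, 1)
        return out[0]

    def _batched_pattern_loglik(self, pmats, C: int) -> np.ndarray:
        """(C, n_patterns) log-likelihoods; ``pmats`` maps edge index to a
        (C, 61, 61) stack of per-class transition matrices."""
        lt = self.ltree
        npat = self.pats.shape[1]
        partial = [None] * lt.n_nodes
        logscale = np.zeros((C, npat))
        for i in range(lt.n_nodes):
            if lt.is_leaf[i]:
                partial[i] = np.broadcast_to(
                    self.leaf_partial[i], (C, self.space.n, npat))
                continue
            M = np.ones((C, self.space.n, npat))
            for ch in lt.children[i]:
                M = M * (pmats[ch] @ partial[ch])
            mx = M.max(axis=1)
            mx[mx == 0] = 1.0
            M /= mx[:, None, :]
            logscale += np.log(mx)
            partial[i] = M
        root = partial[lt.root]
        like = np.einsum("j,cjp->cp", self._pi, root)
        like[like <= 0] = np.finfo(float).tiny
        return np.log(like) + logscale

    def class_pattern_logliks(self, spec: CodonModelSpec,
                              branch_lengths: np.ndarray | None = None,
                              pi: np.ndarray | None = None) -> np.ndarray:
        """(n_classes, n_patterns) per-class log-likelihoods."""
        lt = self.ltree
        bl = self.ltree.lengths if branch_lengths is None else branch_lengths
        self._pi = pi if pi is not None else spec.frequencies(self.aln)
        fg = set()
        if spec.foreground:
            fg = {i for i in lt.edges() if lt.branch_key[i] in spec.foreground}
            if len(fg) != len(spec.foreground):
                raise ValueError("foreground branch keys not found in tree")
        eig_cache = {}

        def eig_for(omega):
            key = round(float(omega), 12)
            if key not in eig_cache:
                Q = build_rate_matrix(spec.kappa, omega, self._pi, self.code,
                                      scale=False)
                mu = -float(self._pi @ np.diag(Q))
                eig_cache[key] = (*_eig_reversible(Q, self._pi), mu)
            return eig_cache[key]

        # one scale factor from the background mixture: branch lengths are
        # expected substitutions per codon under the background regime, so
        # foreground classes with omega > 1 genuinely accelerate
        probs = spec.normalized_probs()
        mu_mix = sum(
            p * eig_for(cls.omega_background)[3]
            for p, cls in zip(probs, spec.classes)
        )
        mu_mix = max(mu_mix, 1e-12)

        C = len(spec.classes)
        pmats = {}
        for e in lt.edges():
            stack = np.empty((C, self.space.n, self.space.n))
            t_eff = max(bl[e], 1e-9) / mu_mix
            seen = {}
            for ci, cls in enumerate(spec.classes):
                om = cls.omega_fg if e in fg else cls.omega_background
                key = round(float(om), 12)
                if key not in seen:
                    A, lam, B, _ = eig_for(om)
                    seen[key] = _pmat(A, lam, B, t_eff)
                stack[ci] = seen[key]
            pmats[e] = stack
        return self._batched_pattern_loglik(pmats, C)

    def site_logliks(self, spec, branch_lengths=None, pi=None) -> np.ndarray:
        """Per-site mixture log-likelihoods (expanded to sites)."""
        cls_ll = self.class_pattern_logliks(spec, branch_lengths, pi)
        p = spec.normalized_probs()
        pat_ll = logsumexp(cls_ll + np.log(p)[:, None], axis=0)
        return pat_ll[self.site_to_pat]

    def lnL(self, spec, branch_lengths=None, pi=None) -> float:
        cls_ll = self.class_pattern_logliks(spec, branch_lengths, pi)
        p = spec.normalized_probs()
        pat_ll = logsumexp(cls_ll + np.log(p)[:, None], axis=0)
        return float(pat_ll @ self.weights)


def site_log_likelihoods(codon_aln: CodonAlignment, tree: dendropy.Tree,
                         spec: CodonModelSpec,
                         branch_lengths: np.ndarray | None = None) -> np.ndarray:
    """Per-codon-site log-likelihood under a (mixture) codon model, using
    the tree's branch lengths unless an explicit vector is given."""
    eng = _Engine(codon_aln, tree)
    return eng.site_logliks(spec, branch_lengths)


# ===========================================================================
# Model templates and fitting
# ===========================================================================

def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def _beta_cats(p, q, K):
    mids = (2 * np.arange(K) + 1) / (2.0 * K)
    return beta_dist.ppf(mids, p, q)


class _Template:
    """Transform between optimizer vector and a CodonModelSpec."""

    def __init__(self, name, n_beta_cats=10):
        self.name = name
        self.K = n_beta_cats

    def x0(self, rng=None):
        base = {
            "M0": [np.log(2.0), np.log(0.3)],
            "M1a": [np.log(2.0), 0.5, 0.0],
            "M2a": [np.log(2.0), 0.5, 0.5, 0.0, np.log(2.0)],
            "M7": [np.log(2.0), 0.0, 0.0],
            "M8": [np.log(2.0), 0.0, 0.0, 2.0, np.log(1.0)],
            "M8a": [np.log(2.0), 0.0, 0.0, 2.0],
            "bsA": [np.log(2.0), 1.0, -0.5, 0.0, np.log(2.0)],
            "bsA-null": [np.log(2.0), 1.0, -0.5, 0.0],
        }[self.name]
        x = np.array(base, dtype=float)
        if rng is not None:
            x = x + rng.normal(0, 0.8, size=len(x))
        return x

    def bounds(self):
        LK = (np.log(0.2), np.log(30.0))
        LOGIT = (-12.0, 12.0)
        W0 = (-12.0, 0.0)          # log omega0 in (~0, 1]
        W2 = (-14.0, np.log(400.0))  # omega_pos = 1 + exp(x)
        LBETA = (np.log(0.05), np.log(50.0))
        return {
            "M0": [LK, (np.log(1e-4), np.log(50.0))],
            "M1a": [LK, LOGIT, W0],
            "M2a": [LK, LOGIT, LOGIT, W0, W2],
            "M7": [LK, LBETA, LBETA],
            "M8": [LK, LBETA, LBETA, LOGIT, W2],
            "M8a": [LK, LBETA, LBETA, LOGIT],
            "bsA": [LK, LOGIT, LOGIT, W0, W2],
            "bsA-null": [LK, LOGIT, LOGIT, W0],
        }[self.name]

    def n_free(self):
        return len(self.bounds())

    def spec(self, x, foreground=frozenset(), codon_freqs="f3x4") -> CodonModelSpec:
        name = self.name
        kappa = float(np.exp(x[0]))
        if name == "M0":
            classes = (SiteClass(1.0, float(np.exp(x[1]))),)
        elif name == "M1a":
            p0 = _sig(x[1])
            w0 = float(np.exp(x[2]))
            classes = (SiteClass(p0, w0), SiteClass(1 - p0, 1.0))
        elif name == "M2a":
            p0 = _sig(x[1])
            p1 = (1 - p0) * _sig(x[2])
            w0, w2 = float(np.exp(x[3])), 1.0 + float(np.exp(x[4]))
            classes = (SiteClass(p0, w0), SiteClass(p1, 1.0),
                       SiteClass(1 - p0 - p1, w2))
        elif name in ("M7", "M8", "M8a"):
            p, q = float(np.exp(x[1])), float(np.exp(x[2]))
            cats = _beta_cats(p, q, self.K)
            if name == "M7":
                classes = tuple(SiteClass(1.0 / self.K, float(w)) for w in cats)
            else:
                p0 = _sig(x[3])
                ws = 1.0 + float(np.exp(x[4])) if name == "M8" else 1.0
                classes = tuple(
                    SiteClass(p0 / self.K, float(w)) for w in cats
                ) + (SiteClass(1 - p0, ws),)
        elif name in ("bsA", "bsA-null"):
            p0 = _sig(x[1])
            p1 = (1 - p0) * _sig(x[2])
            w0 = float(np.exp(x[3]))
            w2 = 1.0 + float(np.exp(x[4])) if name == "bsA" else 1.0
            rest = max(1.0 - p0 - p1, 0.0)
            tot01 = max(p0 + p1, 1e-12)
            p2a = rest * p0 / tot01
            p2b = rest * p1 / tot01
            classes = (
                SiteClass(p0, w0, w0),
                SiteClass(p1, 1.0, 1.0),
                SiteClass(p2a, w0, w2),
                SiteClass(p2b, 1.0, w2),
            )
        else:
            raise ValueError(f"unknown template {name!r}")
        return CodonModelSpec(kappa=kappa, codon_freqs=codon_freqs,
                              classes=classes, foreground=frozenset(foreground))


MODEL_TEMPLATES = ("M0", "free-ratio", "M1a", "M2a", "M7", "M8", "M8a",
                   "bsA", "bsA-null")


@dataclass
class FitResult:
    """Maximum-likelihood fit of one codon model."""

    template: str
    lnL: float
    n_params: int
    mles: dict
    spec: CodonModelSpec
    branch_lengths: np.ndarray
    converged: bool
    n_restarts_used: int
    per_branch_omega: dict | None = None
    x: np.ndarray | None = field(default=None, repr=False)


def _nj_branch_init(codon_aln: CodonAlignment, tree: dendropy.Tree,
                    eng: _Engine) -> np.ndarray:
    """Initial branch lengths: tree lengths if present, else scaled NG86
    p-distance based values."""
    bl = eng.ltree.lengths.copy()
    if np.all(bl <= 0):
        bl[:] = 0.05
    bl[bl < 1e-4] = 1e-4
    return bl


def fit_model(
    codon_aln: CodonAlignment,
    tree: dendropy.Tree,
    template: str,
    *,
    foreground=None,
    foreground_mode: str = "all",
    n_restarts: int = 3,
    branch_lengths: np.ndarray | None = None,
    optimize_branch_lengths: bool | None = None,
    codon_freqs: object = "f3x4",
    start_from: FitResult | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    maxfun: int = 400,
) -> FitResult:
    """Fit a codon model template by bounded quasi-Newton with restarts.

    Branch lengths: M0 and free-ratio optimize them jointly; site-class
    templates reuse a supplied ``branch_lengths`` vector (typically from
    a preliminary M0 fit — computed automatically when absent) unless
    ``optimize_branch_lengths=True``.  ``start_from`` seeds the class
    parameters from a previously fitted (nested null) model.
    """
    if template not in MODEL_TEMPLATES:
        raise ValueError(f"unknown model template {template!r}")
    eng = _Engine(codon_aln, tree)
    rng = np.random.default_rng(seed)

    fg_keys = frozenset()
    if template in ("bsA", "bsA-null"):
        if not foreground:
            raise ValueError("branch-site model A requires a foreground clade")
        edges = eng.ltree.foreground_edges(foreground, foreground_mode)
        fg_keys = frozenset(eng.ltree.branch_key[e] for e in edges)

    pi = CodonModelSpec(codon_freqs=codon_freqs).frequencies(codon_aln) \
        if isinstance(codon_freqs, str) else np.asarray(codon_freqs)
    n_edges_vec = eng.ltree.n_nodes  # lengths vector indexed by node

    if template == "free-ratio":
        return _fit_free_ratio(eng, codon_aln, pi, rng, tol, maxfun)

    tmpl = _Template(template)
    if optimize_branch_lengths is None:
        optimize_branch_lengths = template == "M0"

    if branch_lengths is None:
        if template == "M0" or optimize_branch_lengths:
            bl0 = _nj_branch_init(codon_aln, tree, eng)
        else:
            m0 = fit_model(codon_aln, tree, "M0", n_restarts=1,
                           codon_freqs=codon_freqs, seed=seed,
                           tol=tol, maxfun=maxfun)
            bl0 = m0.branch_lengths
    else:
        bl0 = np.asarray(branch_lengths, dtype=float).copy()

    edges = eng.ltree.edges()
    bl_bounds = [(np.log(1e-6), np.log(30.0))] * len(edges)

    def make_bl(xb):
        bl = np.zeros(n_edges_vec)
        bl[edges] = np.exp(xb)
        return bl

    if optimize_branch_lengths:
        def neg(x):
            spec = tmpl.spec(x[:tmpl.n_free()], fg_keys, codon_freqs)
            bl = make_bl(x[tmpl.n_free():])
            try:
                return -eng.lnL(spec, bl, pi)
            except FloatingPointError:
                return 1e12
        bounds = tmpl.bounds() + bl_bounds
        def pack(xc):
            return np.concatenate([xc, np.log(np.maximum(bl0[edges], 1e-6))])
    else:
        fixed_bl = bl0
        def neg(x):
            spec = tmpl.spec(x, fg_keys, codon_freqs)
            try:
                return -eng.lnL(spec, fixed_bl, pi)
            except FloatingPointError:
                return 1e12
        bounds = tmpl.bounds()
        def pack(xc):
            return xc

    starts = [pack(tmpl.x0())]
    if start_from is not None and start_from.x is not None:
        xs = np.array(start_from.x[:tmpl.n_free()], dtype=float)
        if len(xs) < tmpl.n_free():  # null has fewer params: pad
            # (a) extra params at their lower bound: reproduces the null
            # point, so the alternative can only improve on it
            lo = np.array([b[0] for b in tmpl.bounds()[len(xs):]])
            starts.insert(0, pack(np.concatenate([xs, lo])))
            # (b) exploratory pad with template defaults
            starts.insert(1, pack(np.concatenate([xs, tmpl.x0()[len(xs):]])))
        else:
            starts.insert(0, pack(xs))
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(pack(tmpl.x0(rng)))

    best = None
    used = 0
    converged = False
    for x0 in starts:
        used += 1
        res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxfun": maxfun, "ftol": tol * 1e-3,
                                "gtol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or converged
        if best.fun < np.inf and used >= len(starts):
            break
    if not converged:
        warnings.warn(f"{template} fit did not fully converge "
                      f"(best lnL = {-best.fun:.4f})", RuntimeWarning)

    xbest = best.x
    if optimize_branch_lengths:
        xc = xbest[:tmpl.n_free()]
        bl = make_bl(xbest[tmpl.n_free():])
        n_params = tmpl.n_free() + len(edges)
    else:
        xc = xbest
        bl = bl0
        n_params = tmpl.n_free() + len(edges)  # branch lengths count as in codeml

    spec = tmpl.spec(xc, fg_keys, codon_freqs)
    mles = {"kappa": spec.kappa,
            "class_props": spec.normalized_probs().tolist(),
            "class_omegas_background":
                [c.omega_background for c in spec.classes],
            "class_omegas_foreground": [c.omega_fg for c in spec.classes]}
    return FitResult(template=template, lnL=-best.fun, n_params=n_params,
                     mles=mles, spec=spec, branch_lengths=bl,
                     converged=converged, n_restarts_used=used, x=xc)


def _fit_free_ratio(eng, codon_aln, pi, rng, tol, maxfun):
    """Per-branch-omega model: every branch gets its own dN/dS.

    Implemented as branch-specific single-class models stitched by
    per-branch P matrices."""
    lt = eng.ltree
    edges = lt.edges()
    E = len(edges)

    def neg(x):
        kappa = np.exp(x[0])
        omegas = np.exp(x[1:1 + E])
        bl = np.zeros(lt.n_nodes)
        bl[edges] = np.exp(x[1 + E:])
        eng._pi = pi
        pmats = {}
        for k, e in enumerate(edges):
            Q = build_rate_matrix(kappa, omegas[k], pi, eng.code)
            A, lam, B = _eig_reversible(Q, pi)
            pmats[e] = _pmat(A, lam, B, max(bl[e], 1e-9))
        ll = eng._class_pattern_loglik(pmats)
        return -float(ll @ eng.weights)

    bl0 = _nj_branch_init(codon_aln, None, eng)
    x0 = np.concatenate([[np.log(2.0)], np.full(E, np.log(0.3)),
                         np.log(np.maximum(bl0[edges], 1e-6))])
    bounds = ([(np.log(0.2), np.log(30.0))]
              + [(np.log(1e-4), np.log(999.0))] * E
              + [(np.log(1e-6), np.log(30.0))] * E)
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxfun": max(maxfun, 200 + 40 * E),
                            "ftol": tol * 1e-3})
    kappa = float(np.exp(res.x[0]))
    omegas = np.exp(res.x[1:1 + E])
    bl = np.zeros(lt.n_nodes)
    bl[edges] = np.exp(res.x[1 + E:])
    per_branch = {lt.branch_key[e]: float(omegas[k]) for k, e in enumerate(edges)}
    spec = CodonModelSpec(kappa=kappa, classes=(SiteClass(1.0, 1.0),))
    return FitResult(template="free-ratio", lnL=-res.fun,
                     n_params=1 + 2 * E, mles={"kappa": kappa},
                     spec=spec, branch_lengths=bl,
                     converged=bool(res.success), n_restarts_used=1,
                     per_branch_omega=per_branch, x=res.x)


# ===========================================================================
# Likelihood-ratio test
# ===========================================================================

def lrt(lnL_null: float, lnL_alt: float, df: int,
        *, boundary_mixture: bool = False, tol: float = 1e-3):
    """(2*deltaL, p) for nested models.

    ``boundary_mixture`` uses the 50:50 mixture of chi2_0 and chi2_df
    appropriate when the null pins a parameter at the boundary (the
    branch-site test with foreground omega fixed at 1).  A negative
    statistic beyond tolerance triggers an optimizer-failure warning and
    p is reported as NaN.
    """
    two_dl = 2.0 * (lnL_alt - lnL_null)
    if two_dl < -tol:
        warnings.warn(
            f"negative LRT statistic {two_dl:.4f}: optimizer failure suspected",
            RuntimeWarning,
        )
        return two_dl, float("nan")
    x = max(two_dl, 0.0)
    if boundary_mixture:
        p = 1.0 if x == 0 else 0.5 * float(chi2.sf(x, df))
    else:
        p = float(chi2.sf(x, df))
    return two_dl, p


# ===========================================================================
# Site posteriors (naive empirical Bayes)
# ===========================================================================

@dataclass
class SitePosterior:
    """Per-site posterior probability of the positive-selection class."""

    prob_positive: np.ndarray          # (n_sites,)
    class_posteriors: np.ndarray       # (n_classes, n_sites)
    positive_classes: list
    threshold: float = 0.95

    @property
    def flagged_sites(self) -> np.ndarray:
        """0-based site indices with posterior above the threshold."""
        return np.nonzero(self.prob_positive > self.threshold)[0]


def site_posteriors(fit: FitResult, codon_aln: CodonAlignment,
                    tree: dendropy.Tree, *, threshold: float = 0.95) -> SitePosterior:
    """NEB posteriors under a fitted mixture model with an omega>1 class."""
    spec = fit.spec
    pos = [i for i, c in enumerate(spec.classes)
           if max(c.omega_background, c.omega_fg) > 1.0]
    if not pos:
        raise ValueError("fitted model has no positive-selection class")
    eng = _Engine(codon_aln, tree)
    cls_ll = eng.class_pattern_logliks(spec, fit.branch_lengths)
    logp = np.log(spec.normalized_probs())[:, None]
    joint = cls_ll + logp
    post = np.exp(joint - logsumexp(joint, axis=0, keepdims=True))
    post_sites = post[:, eng.site_to_pat]
    prob_pos = post_sites[pos].sum(axis=0)
    return SitePosterior(prob_positive=prob_pos, class_posteriors=post_sites,
                         positive_classes=pos, threshold=threshold)


# ===========================================================================
# KH / SH topology tests (RELL)
# ===========================================================================

def kh_sh_tests(
    codon_aln: CodonAlignment,
    trees,
    spec: CodonModelSpec | None = None,
    *,
    n_boot: int = 10_000,
    optimize: bool = True,
    seed: int = 0,
):
    """KH and SH tests over candidate topologies by RELL bootstrap.

    Per topology, branch lengths (and kappa/omega when no ``spec`` is
    supplied) are optimized under M0; per-site log-likelihood vectors
    are then resampled (n_boot replicates) to form the KH centered
    pairwise-difference test against the best topology and the
    max-corrected SH test.

    Returns a list of dicts (one per tree) with lnL, delta_lnL, p_kh,
    p_sh; the best topology has delta_lnL = 0.
    """
    trees = list(trees)
    if len(trees) < 2:
        raise ValueError("need at least 2 candidate topologies")
    rng = np.random.default_rng(seed)
    site_ll = []
    for t in trees:
        eng = _Engine(codon_aln, t)
        if optimize or spec is None:
            fit = fit_model(codon_aln, t, "M0", n_restarts=1, seed=seed)
            use_spec = fit.spec if spec is None else replace(
                spec, foreground=frozenset())
            bl = fit.branch_lengths
            if spec is not None:
                bl = _optimize_bl_only(eng, use_spec, bl)
            site_ll.append(eng.site_logliks(use_spec, bl))
        else:
            site_ll.append(eng.site_logliks(spec))
    site_ll = np.asarray(site_ll)  # (T, L)
    T, L = site_ll.shape
    totals = site_ll.sum(axis=1)
    best = int(np.argmax(totals))

    counts = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot)  # (B, L)
    R = counts @ site_ll.T  # (B, T) resampled totals
    Rc = R - R.mean(axis=0, keepdims=True)  # per-topology centering

    out = []
    for t in range(T):
        d_obs = totals[best] - totals[t]
        if t == best:
            p_kh = 1.0
        else:
            diff = Rc[:, best] - Rc[:, t]
            p_kh = float(np.mean(np.abs(diff) >= d_obs))
        s = Rc.max(axis=1) - Rc[:, t]
        p_sh = float(np.mean(s >= d_obs))
        out.append({"tree_index": t, "lnL": float(totals[t]),
                    "delta_lnL": float(d_obs), "p_kh": p_kh, "p_sh": p_sh,
                    "best": t == best})
    return out


def _optimize_bl_only(eng: _Engine, spec: CodonModelSpec,
                      bl0: np.ndarray, maxfun: int = 200) -> np.ndarray:
    edges = eng.ltree.edges()
    pi = spec.frequencies(eng.aln)

    def neg(xb):
        bl = np.zeros(eng.ltree.n_nodes)
        bl[edges] = np.exp(xb)
        return -eng.lnL(spec, bl, pi)

    x0 = np.log(np.maximum(bl0[edges], 1e-6))
    res = minimize(neg, x0, method="L-BFGS-B",
                   bounds=[(np.log(1e-6), np.log(30.0))] * len(edges),
                   options={"maxfun": maxfun})
    bl = np.zeros(eng.ltree.n_nodes)
    bl[edges] = np.exp(res.x)
    return bl
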