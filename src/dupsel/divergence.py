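"""Functional-divergence statistics between two duplicate clades.

Type-I divergence (rate shift): after duplication, a fraction theta_I of
sites switches its evolutionary rate between the two paralog clades.
Estimated (i) model-free, from the attenuation-corrected correlation of
per-site substitution counts (theta_I = 1 - r_lambda, counts by
parsimony within each clade), and (ii) by maximum likelihood under a
two-state site-class model with gamma-distributed rates (correlated
versus independent rates across clades; Poisson counts give closed-form
negative-binomial marginals), with an LRT against theta_I = 0.

Type-II divergence (property shift): a fraction theta_II of sites was
driven into a different amino-acid property class between the two clade
ancestors.  Sites are classified against the reconstructed clade
ancestors as N (no change), C (conserved change) or R (radical change),
where radical means a change of charge class (positive {K,R,H} /
negative {D,E} / neutral) or of hydropathy class (Kyte-Doolittle sign).
Restricting to F00 sites (no within-clade change), the estimator reads
the radical excess over the neutral expectation:

    theta_II = f_R - f_C * pi_R / (1 - pi_R)

with pi_R the stationary radical fraction of the replacement model
(type-II divergent sites are property-altering by definition, so all of
their between-ancestor changes are radical).  Standard errors by site
bootstrap; Z = theta / SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import norm

from .seqio import Alignment

__all__ = [
    "AMINO_ACIDS",
    "charge_class",
    "hydropathy_class",
    "classify_change",
    "ClusterPair",
    "AncestralResult",
    "ancestral_states",
    "TypeIResult",
    "gu_type1",
    "TypeIIResult",
    "gu_type2",
    "site_posterior_profile",
    "radical_fraction_neutral",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_POSITIVE = frozenset("KRH")
_NEGATIVE = frozenset("DE")
# Kyte-Doolittle hydropathy > 0
_HYDROPHOBIC = frozenset("ACFILMV")


def charge_class(aa: str) -> str:
    if aa in _POSITIVE:
        return "positive"
    if aa in _NEGATIVE:
        return "negative"
    return "neutral"


def hydropathy_class(aa: str) -> str:
    return "hydrophobic" if aa in _HYDROPHOBIC else "hydrophilic"


def classify_change(aa_from: str, aa_to: str) -> str:
    """'conserved' or 'radical'; a change is radical iff it alters the
    charge class or the hydropathy class.  Symmetric by construction;
    nonstandard residues return 'masked'."""
    a, b = aa_from.upper(), aa_to.upper()
    if a not in _AA_INDEX or b not in _AA_INDEX:
        return "masked"
    if charge_class(a) != charge_class(b) or \
            hydropathy_class(a) != hydropathy_class(b):
        return "radical"
    return "conserved"


def radical_fraction_neutral(freqs: np.ndarray) -> float:
    """Stationary fraction of radical substitutions under an
    equal-exchangeability replacement model with the given amino-acid
    frequencies."""
    tot = rad = 0.0
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i == j:
                continue
            w = freqs[i] * freqs[j]
            tot += w
            if classify_change(a, b) == "radical":
                rad += w
    return rad / tot


# ===========================================================================
# Ancestral reconstruction (20-state, equal exchangeabilities)
# ===========================================================================

@dataclass
class AncestralResult:
    """Clade-root marginal ML states plus per-site parsimony change counts."""

    states: np.ndarray        # (L,) ancestral aa indices, -1 masked
    posteriors: np.ndarray    # (L, 20) marginal root posteriors
    change_counts: np.ndarray  # (L,) parsimony substitution counts in clade


def _aa_matrix(aln: Alignment) -> np.ndarray:
    """(n, L) amino-acid indices, -1 for gaps/unknowns."""
    out = np.full((len(aln), aln.length), -1, dtype=int)
    for i, s in enumerate(aln.seqs):
        for j, ch in enumerate(s):
            out[i, j] = _AA_INDEX.get(ch, -1)
    return out


def _aa_frequencies(mats) -> np.ndarray:
    counts = np.zeros(20)
    for m in mats:
        idx, c = np.unique(m[m >= 0], return_counts=True)
        counts[idx] += c
    counts += 1.0  # pseudocount keeps every state reachable
    return counts / counts.sum()


def _f81_pmat(pi: np.ndarray, t: float) -> np.ndarray:
    """Transition probabilities of the equal-exchangeability model,
    scaled to one expected replacement per site at equilibrium."""
    beta = 1.0 / (1.0 - float(pi @ pi))
    e = np.exp(-beta * t)
    P = (1.0 - e) * np.tile(pi, (len(pi), 1))
    P[np.diag_indices_from(P)] += e
    return P


def ancestral_states(clade_aln: Alignment, clade_tree: dendropy.Tree,
                     *, freqs: np.ndarray | None = None,
                     method: str = "ml") -> AncestralResult:
    """Per-site clade-ancestor reconstruction and substitution counts.

    ``ml`` (default): marginal maximum-likelihood root state under the
    equal-exchangeability replacement model; ``parsimony``: Fitch
    root-set majority.  Change counts are Fitch parsimony counts either
    way.  All-gap sites are masked.
    """
    mat = _aa_matrix(clade_aln)
    n, L = mat.shape
    if n < 3:
        raise ValueError("a clade needs >= 3 sequences")
    pi = _aa_frequencies([mat]) if freqs is None else freqs

    nodes = list(clade_tree.postorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    children = [[idx[id(c)] for c in nd.child_nodes()] for nd in nodes]
    lengths = [nd.edge.length or 0.0 for nd in nodes]
    leaf_row = {}
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            lbl = nd.taxon.label
            if lbl not in clade_aln.ids:
                raise ValueError(f"tree tip {lbl!r} not in clade alignment")
            leaf_row[i] = clade_aln.ids.index(lbl)

    # Fitch sets and counts
    counts = np.zeros(L, dtype=int)
    fitch = [None] * len(nodes)
    FULL = (1 << 20) - 1
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            row = mat[leaf_row[i]]
            fitch[i] = np.where(row >= 0, 1 << np.maximum(row, 0), FULL)
        else:
            acc = None
            for c in children[i]:
                if acc is None:
                    acc = fitch[c].copy()
                    continue
                inter = acc & fitch[c]
                empty = inter == 0
                counts += empty
                acc = np.where(empty, acc | fitch[c], inter)
            fitch[i] = acc

    # masked sites: all rows missing
    masked = np.all(mat < 0, axis=0)

    if method == "parsimony":
        root_set = fitch[len(nodes) - 1]
        states = np.array([
            -1 if masked[s] else int(np.argmax(
                [(root_set[s] >> k) & 1 for k in range(20)]))
            for s in range(L)
        ])
        post = np.zeros((L, 20))
        post[np.arange(L)[states >= 0], states[states >= 0]] = 1.0
        return AncestralResult(states, post, counts)

    # marginal ML at the root
    partial = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            row = mat[leaf_row[i]]
            M = np.ones((20, L))
            known = row >= 0
            M[:, known] = 0.0
            M[row[known], np.nonzero(known)[0]] = 1.0
            partial[i] = M
        else:
            M = np.ones((20, L))
            for c in children[i]:
                P = _f81_pmat(pi, max(lengths[c], 1e-6))
                M = M * (P @ partial[c])
            mx = M.max(axis=0)
            mx[mx == 0] = 1.0
            partial[i] = M / mx
    root = partial[len(nodes) - 1] * pi[:, None]
    tot = root.sum(axis=0)
    tot[tot == 0] = 1.0
    post = (root / tot).T
    states = np.argmax(post, axis=1)
    states[masked] = -1
    return AncestralResult(states, post, counts)


# ===========================================================================
# Cluster pair
# ===========================================================================

@dataclass
class ClusterPair:
    """Two disjoint duplicate clades of one protein alignment."""

    aln1: Alignment
    aln2: Alignment
    tree1: dendropy.Tree
    tree2: dendropy.Tree

    def __post_init__(self):
        if self.aln1.length != self.aln2.length:
            raise ValueError("clade alignments must have equal length")
        if set(self.aln1.ids) & set(self.aln2.ids):
            raise ValueError("clades must be disjoint")
        if len(self.aln1) < 3 or len(self.aln2) < 3:
            raise ValueError("each clade needs >= 3 sequences")

    @property
    def length(self) -> int:
        return self.aln1.length


# ===========================================================================
# Type I
# ===========================================================================

@dataclass
class TypeIResult:
    theta: float
    se: float
    z: float
    p: float
    theta_ml: float
    se_ml: float
    lrt: float
    p_ml: float
    alpha_ml: float
    counts1: np.ndarray = field(repr=False, default=None)
    counts2: np.ndarray = field(repr=False, default=None)
    out_of_range: bool = False


def _theta_free(x1: np.ndarray, x2: np.ndarray) -> float:
    """Model-free theta = 1 - r_lambda with Poisson attenuation
    correction: the sampling noise of counts is removed from the
    variances before correlating."""
    v1 = x1.var() - x1.mean()
    v2 = x2.var() - x2.mean()
    if v1 <= 0 or v2 <= 0:
        raise ArithmeticError("no substitution-rate variance in a clade")
    cov = np.cov(x1, x2, ddof=0)[0, 1]
    return 1.0 - cov / np.sqrt(v1 * v2)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise ArithmeticError("no substitution-rate variance in a half-clade")
    return float(np.corrcoef(a, b)[0, 1])


def _theta_split_half(h1a, h1b, h2a, h2b) -> float:
    """Split-half count-correlation estimator of theta.

    Each clade's per-site counts are measured on two disjoint subtrees.
    With multiplicative attenuation c of each half's counts, the
    geometric mean of the four cross-clade correlations equals
    sqrt(c1a c1b c2a c2b) * rho while the within-clade split-half
    correlations supply sqrt(c1a c1b c2a c2b); their ratio is the rate
    correlation rho and theta = 1 - rho.  Robust to non-Poisson
    (parsimony-compressed) counts because the calibration is empirical.
    """
    within = _corr(h1a, h1b) * _corr(h2a, h2b)
    cross = [_corr(h1a, h2a), _corr(h1a, h2b),
             _corr(h1b, h2a), _corr(h1b, h2b)]
    if within <= 0 or any(c <= 0 for c in cross):
        # no usable shared-rate signal: fall back to the Poisson form
        raise ArithmeticError("non-positive count correlations")
    rho = float(np.exp(np.mean(np.log(cross)))) / np.sqrt(within)
    return 1.0 - rho


def _nb_logpmf(x, d, alpha):
    """log P(X = x) for X ~ Poisson(lambda d), lambda ~ Gamma(alpha, 1/alpha)."""
    return (gammaln(alpha + x) - gammaln(alpha) - gammaln(x + 1)
            + alpha * np.log(alpha) + x * np.log(d)
            - (alpha + x) * np.log(alpha + d))


def _corr_logpmf(x1, x2, d1, d2, alpha):
    """Joint log-pmf when both clades share one gamma rate."""
    return (gammaln(alpha + x1 + x2) - gammaln(alpha)
            - gammaln(x1 + 1) - gammaln(x2 + 1)
            + alpha * np.log(alpha) + x1 * np.log(d1) + x2 * np.log(d2)
            - (alpha + x1 + x2) * np.log(alpha + d1 + d2))


def _type1_ml(x1, x2, *, fix_theta=None):
    """ML fit of (theta, alpha, d1, d2); returns (lnL, theta, alpha)."""
    def nll(v):
        la, ld1, ld2 = v[0], v[1], v[2]
        theta = fix_theta if fix_theta is not None else 1 / (1 + np.exp(-v[3]))
        alpha, d1, d2 = np.exp(la), np.exp(ld1), np.exp(ld2)
        lc = _corr_logpmf(x1, x2, d1, d2, alpha)
        li = _nb_logpmf(x1, d1, alpha) + _nb_logpmf(x2, d2, alpha)
        m = np.maximum(lc, li)
        ll = m + np.log((1 - theta) * np.exp(lc - m) + theta * np.exp(li - m)
                        + 1e-300)
        return -ll.sum()

    x0 = [0.0, np.log(max(x1.mean(), 0.05)), np.log(max(x2.mean(), 0.05))]
    if fix_theta is None:
        x0 = x0 + [0.0]
    bounds = [(-4, 5), (-6, 4), (-6, 4)] + ([(-12, 12)] if fix_theta is None else [])
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxfun": 500})
    theta = fix_theta if fix_theta is not None else \
        float(1 / (1 + np.exp(-res.x[3])))
    return -float(res.fun), theta, float(np.exp(res.x[0]))


def _fitch_counts(aln: Alignment, tree: dendropy.Tree) -> np.ndarray:
    """Per-site Fitch parsimony substitution counts (works from 2 tips)."""
    mat = _aa_matrix(aln)
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 sequences for substitution counts")
    nodes = list(tree.postorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    children = [[idx[id(c)] for c in nd.child_nodes()] for nd in nodes]
    counts = np.zeros(mat.shape[1], dtype=int)
    FULL = (1 << 20) - 1
    fitch = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            row = mat[aln.ids.index(nd.taxon.label)]
            fitch[i] = np.where(row >= 0, 1 << np.maximum(row, 0), FULL)
        else:
            acc = None
            for c in children[i]:
                if acc is None:
                    acc = fitch[c].copy()
                    continue
                inter = acc & fitch[c]
                empty = inter == 0
                counts += empty
                acc = np.where(empty, acc | fitch[c], inter)
            fitch[i] = acc
    return counts


def _root_split(tree: dendropy.Tree):
    """Split the tips at the internal edge whose clade is closest to half
    the sample.  The two sides induce edge-disjoint subtrees, so their
    substitution counts carry independent reconstruction noise; both
    sides need >= 2 tips."""
    all_tips = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(all_tips)
    best = None
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        clade = sorted(lf.taxon.label for lf in nd.leaf_iter())
        if len(clade) < 2 or n - len(clade) < 2:
            continue
        key = (abs(len(clade) - n / 2), clade)
        if best is None or key < best[0]:
            best = (key, clade)
    if best is None:
        raise ArithmeticError("clade too small for split-half calibration")
    clade = best[1]
    rest = [t for t in all_tips if t not in set(clade)]
    return clade, rest


def _split_half_counts(aln: Alignment, tree: dendropy.Tree):
    la, lb = _root_split(tree)
    ha = _fitch_counts(aln.subset(la), tree.extract_tree_with_taxa_labels(la))
    hb = _fitch_counts(aln.subset(lb), tree.extract_tree_with_taxa_labels(lb))
    return ha.astype(float), hb.astype(float)


def gu_type1(pair: ClusterPair, *, n_boot: int = 500, seed: int = 0) -> TypeIResult:
    """Type-I (rate-shift) divergence between two clades.

    Substitution counts per site come from Fitch parsimony within each
    clade.  The model-free coefficient uses the split-half correlation
    construction (falling back to the Poisson-corrected form when a
    clade is too small to split); its SE comes from a site bootstrap.
    The ML coefficient comes from the gamma-rates two-state mixture.
    """
    a1 = ancestral_states(pair.aln1, pair.tree1)
    a2 = ancestral_states(pair.aln2, pair.tree2)
    x1 = a1.change_counts.astype(float)
    x2 = a2.change_counts.astype(float)

    rng = np.random.default_rng(seed)
    L = len(x1)
    try:
        h1a, h1b = _split_half_counts(pair.aln1, pair.tree1)
        h2a, h2b = _split_half_counts(pair.aln2, pair.tree2)
        halves = (h1a, h1b, h2a, h2b)
        theta = _theta_split_half(*halves)

        def boot_stat(idx):
            return _theta_split_half(*(h[idx] for h in halves))
    except ArithmeticError:
        halves = None
        theta = _theta_free(x1, x2)

        def boot_stat(idx):
            return _theta_free(x1[idx], x2[idx])

    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        try:
            boots.append(boot_stat(idx))
        except ArithmeticError:
            continue
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan
    z = theta / se if se and se > 0 else np.nan
    p = float(norm.sf(abs(z))) if np.isfinite(z) else np.nan

    lnL1, theta_ml, alpha = _type1_ml(x1, x2)
    lnL0, _, _ = _type1_ml(x1, x2, fix_theta=0.0)
    lrt_stat = 2.0 * (lnL1 - lnL0)
    from scipy.stats import chi2
    p_ml = 0.5 * float(chi2.sf(max(lrt_stat, 0.0), 1))  # boundary mixture
    # SE of theta_ml from a profile-curvature approximation
    se_ml = _ml_se(x1, x2, theta_ml)
    return TypeIResult(
        theta=float(theta), se=se, z=float(z), p=p,
        theta_ml=float(theta_ml), se_ml=se_ml,
        lrt=float(lrt_stat), p_ml=p_ml, alpha_ml=alpha,
        counts1=x1, counts2=x2,
        out_of_range=not (0.0 <= theta <= 1.0),
    )


def _ml_se(x1, x2, theta_hat, h=0.02):
    """Numerical curvature of the theta profile likelihood."""
    def prof(th):
        th = min(max(th, 1e-4), 1 - 1e-4)
        return _type1_ml(x1, x2, fix_theta=th)[0]
    t0 = min(max(theta_hat, h), 1 - h)
    f0, fp, fm = prof(t0), prof(t0 + h), prof(t0 - h)
    d2 = (fp - 2 * f0 + fm) / h**2
    return float(1.0 / np.sqrt(-d2)) if d2 < 0 else np.nan


# ===========================================================================
# Type II
# ===========================================================================

@dataclass
class TypeIIResult:
    theta: float
    se: float
    z: float | None
    p: float | None
    pi_r: float
    a_r: float            # radical fraction among between-ancestor changes
    a_r_over_pi_r: float
    g_r_over_g_c: float
    counts_ncr: tuple     # all-site (N, C, R)
    f00: tuple            # (F00_N, F00_C, F00_R) proportions of all sites
    site_class: np.ndarray = field(repr=False, default=None)  # 'N','C','R','M'
    f00_mask: np.ndarray = field(repr=False, default=None)
    posterior_ratio: np.ndarray = field(repr=False, default=None)
    out_of_range: bool = False


def _classify_sites(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    out = np.full(len(s1), "M", dtype="<U1")
    for i, (a, b) in enumerate(zip(s1, s2)):
        if a < 0 or b < 0:
            continue
        if a == b:
            out[i] = "N"
        else:
            c = classify_change(AMINO_ACIDS[a], AMINO_ACIDS[b])
            out[i] = "R" if c == "radical" else "C"
    return out


def _theta2_from_f(f_n, f_c, f_r, pi_r) -> float:
    return f_r - f_c * pi_r / (1.0 - pi_r)


def gu_type2(pair: ClusterPair, *, n_boot: int = 1000, seed: int = 0) -> TypeIIResult:
    """Type-II (radical property shift) divergence between two clades.

    Reconstructs both clade ancestors, classifies every comparable site
    as N/C/R, and estimates theta_II from the radical excess on the F00
    subset (no within-clade change), with a site-bootstrap SE.
    """
    freqs = _aa_frequencies([_aa_matrix(pair.aln1), _aa_matrix(pair.aln2)])
    a1 = ancestral_states(pair.aln1, pair.tree1, freqs=freqs)
    a2 = ancestral_states(pair.aln2, pair.tree2, freqs=freqs)
    pi_r = radical_fraction_neutral(freqs)

    cls = _classify_sites(a1.states, a2.states)
    usable = cls != "M"
    f00_mask = usable & (a1.change_counts == 0) & (a2.change_counts == 0)

    n_all = int(np.count_nonzero(cls == "N"))
    c_all = int(np.count_nonzero(cls == "C"))
    r_all = int(np.count_nonzero(cls == "R"))
    L_use = max(int(np.count_nonzero(usable)), 1)

    sub = cls[f00_mask]
    m = max(len(sub), 1)
    f_n, f_c, f_r = (np.count_nonzero(sub == k) / m for k in "NCR")
    theta = _theta2_from_f(f_n, f_c, f_r, pi_r)

    changed = (sub == "C") | (sub == "R")
    if not np.any(changed):
        theta, se, z, p = 0.0, 0.0, None, None
    else:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        codes = np.select([sub == "N", sub == "C", sub == "R"], [0, 1, 2])
        for b in range(n_boot):
            r = codes[rng.integers(0, len(codes), size=len(codes))]
            bn = np.count_nonzero(r == 0) / len(r)
            bc = np.count_nonzero(r == 1) / len(r)
            br = np.count_nonzero(r == 2) / len(r)
            boots[b] = _theta2_from_f(bn, bc, br, pi_r)
        se = float(np.std(boots, ddof=1))
        z = theta / se if se > 0 else None
        p = float(2 * norm.sf(abs(z))) if z is not None else None

    a_r = r_all / (r_all + c_all) if (r_all + c_all) else np.nan
    f00_props = tuple(
        float(np.count_nonzero((cls == k) & f00_mask)) / L_use for k in "NCR"
    )
    ratio = site_posterior_profile_from_parts(cls, f00_mask, theta, f_n, pi_r)
    return TypeIIResult(
        theta=float(theta), se=se, z=z, p=p, pi_r=float(pi_r),
        a_r=float(a_r), a_r_over_pi_r=float(a_r / pi_r) if np.isfinite(a_r) else np.nan,
        g_r_over_g_c=(r_all / c_all) if c_all else np.inf,
        counts_ncr=(n_all, c_all, r_all), f00=f00_props,
        site_class=cls, f00_mask=f00_mask, posterior_ratio=ratio,
        out_of_range=not (0.0 <= theta <= 1.0),
    )


def site_posterior_profile_from_parts(cls, f00_mask, theta, f_n, pi_r,
                                      eps: float = 1e-6) -> np.ndarray:
    """Per-site posterior odds of the type-II divergent class.

    Divergent sites necessarily differ between the ancestors and do so
    radically; neutral sites change with the background rate and are
    radical with probability pi_r.  The odds r convert to probabilities
    as r/(1+r).
    """
    th = min(max(theta, eps), 1 - eps)
    p_nochange = min(max(f_n / (1 - th), eps), 1 - eps)
    ratio = np.zeros(len(cls))
    for i, k in enumerate(cls):
        if k == "R":
            l_div, l_neut = 1.0, (1 - p_nochange) * pi_r
        elif k == "C":
            l_div, l_neut = eps, (1 - p_nochange) * (1 - pi_r)
        elif k == "N":
            l_div, l_neut = eps, p_nochange
        else:
            ratio[i] = np.nan
            continue
        ratio[i] = th * l_div / ((1 - th) * l_neut)
    return ratio


def site_posterior_profile(result: TypeIIResult) -> np.ndarray:
    """Posterior odds profile of a fitted type-II analysis."""
    return result.posterior_ratio
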