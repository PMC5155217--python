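"""Codon-usage bias indices: effective number of codons and codon bias index.

ENC follows Wright (1990): per amino-acid family homozygosity
F = (n * sum p_i^2 - 1)/(n - 1), averaged within each degeneracy class,
then ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 (standard-code family counts;
a missing F3 is imputed as the mean of F2 and F4; values above 61 are
clamped).  CBI measures usage of a designated optimal codon per
degenerate amino acid, scaled so 0 is uniform synonymous usage and 1 is
exclusive optimal-codon usage.  Met, Trp and stop codons are excluded
from both indices (non-degenerate).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqio import CodonAlignment, GeneticCode

__all__ = [
    "enc",
    "enc_expected",
    "gc3",
    "cbi",
    "infer_optimal_codons",
    "compare_groups",
    "CodonUsageSummary",
    "codon_usage_summary",
]


def _codon_counts(codon_seq, code: GeneticCode) -> dict:
    """Per-amino-acid codon usage counts, skipping stops/gaps/ambiguity."""
    if isinstance(codon_seq, str):
        codon_seq = [codon_seq[i:i + 3] for i in range(0, len(codon_seq), 3)]
    fams = defaultdict(Counter)
    for c in codon_seq:
        if len(c) != 3 or any(ch not in "ACGT" for ch in c):
            continue
        aa = code.translate_codon(c)
        if aa == "*":
            continue
        fams[aa][c] += 1
    return fams


def _family_degeneracy(code: GeneticCode) -> dict:
    deg = Counter()
    for codon, aa in code.forward.items():
        deg[aa] += 1
    return dict(deg)


def enc(codon_seq, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons for one coding sequence.

    Families observed fewer than 2 times, or with non-positive
    homozygosity estimates, are excluded from their degeneracy-class
    mean (Wright's rules).
    """
    code = code or GeneticCode.standard()
    deg = _family_degeneracy(code)
    fams = _codon_counts(codon_seq, code)
    fhat_by_k = defaultdict(list)
    for aa, counts in fams.items():
        k = deg.get(aa, 1)
        if k < 2:
            continue  # Met, Trp
        n = sum(counts.values())
        if n < 2:
            continue
        p2 = sum((c / n) ** 2 for c in counts.values())
        f = (n * p2 - 1.0) / (n - 1.0)
        if f > 0:
            fhat_by_k[k].append(f)
    fbar = {k: float(np.mean(v)) for k, v in fhat_by_k.items() if v}
    if 2 not in fbar or 4 not in fbar or 6 not in fbar:
        raise ArithmeticError("too few observed codon families for ENC")
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    val = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return min(val, 61.0)


def enc_expected(gc3_value: float) -> float:
    """Wright's null ENC at third-position GC content s:
    2 + s + 29/(s^2 + (1-s)^2); boundary values by limit."""
    s = min(max(float(gc3_value), 0.0), 1.0)
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def gc3(codon_seq, code: GeneticCode | None = None) -> float:
    """GC content at third codon positions (sense codons only)."""
    code = code or GeneticCode.standard()
    if isinstance(codon_seq, str):
        codon_seq = [codon_seq[i:i + 3] for i in range(0, len(codon_seq), 3)]
    third = [c[2] for c in codon_seq
             if len(c) == 3 and all(ch in "ACGT" for ch in c)
             and code.translate_codon(c) != "*"]
    if not third:
        raise ArithmeticError("no sense codons")
    return sum(ch in "GC" for ch in third) / len(third)


def infer_optimal_codons(codon_seqs, code: GeneticCode | None = None) -> frozenset:
    """Modal codon per degenerate amino acid over a pooled sequence set
    (deterministic: ties broken alphabetically)."""
    code = code or GeneticCode.standard()
    deg = _family_degeneracy(code)
    pooled = defaultdict(Counter)
    for s in codon_seqs:
        for aa, counts in _codon_counts(s, code).items():
            pooled[aa].update(counts)
    out = set()
    for aa, counts in pooled.items():
        if deg.get(aa, 1) < 2:
            continue
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.add(best)
    return frozenset(out)


def cbi(codon_seq, optimal_codons, code: GeneticCode | None = None) -> float:
    """Codon bias index toward an optimal-codon set.

    CBI = (N_opt - N_ran) / (N_tot - N_ran) over degenerate amino acids,
    with N_ran the optimal-codon count expected under uniform synonymous
    usage.
    """
    code = code or GeneticCode.standard()
    deg = _family_degeneracy(code)
    fams = _codon_counts(codon_seq, code)
    n_opt = n_tot = n_ran = 0.0
    for aa, counts in fams.items():
        k = deg.get(aa, 1)
        if k < 2:
            continue
        n = sum(counts.values())
        n_tot += n
        n_ran += n / k
        n_opt += sum(c for codon, c in counts.items() if codon in optimal_codons)
    if n_tot - n_ran == 0:
        raise ArithmeticError("degenerate CBI denominator")
    return (n_opt - n_ran) / (n_tot - n_ran)


def compare_groups(values_a, values_b, *, equal_var: bool = False):
    """Two-sample comparison of an index between paralog groups.

    Welch's t by default (classic Student variant behind ``equal_var``).
    Returns (mean_a, sd_a, mean_b, sd_b, t, p); both-groups-constant
    inputs with equal means give t = 0, p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    stats_a = (float(a.mean()), float(a.std(ddof=1)))
    stats_b = (float(b.mean()), float(b.std(ddof=1)))
    if stats_a[1] == 0 and stats_b[1] == 0:
        if stats_a[0] == stats_b[0]:
            return (*stats_a, *stats_b, 0.0, 1.0)
        return (*stats_a, *stats_b, np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return (*stats_a, *stats_b, float(t), float(p))


@dataclass
class CodonUsageSummary:
    """Per-sequence indices plus a two-group comparison for one index."""

    ids: list
    enc: dict
    cbi: dict
    gc3: dict
    enc_expected: dict
    optimal_codons: frozenset
    group_of: dict | None = None
    comparisons: dict | None = None


def codon_usage_summary(
    codon_aln: CodonAlignment,
    groups: dict | None = None,
    optimal_codons=None,
) -> CodonUsageSummary:
    """ENC/CBI/GC3 per sequence; Welch comparisons per index when a
    two-group labelling is supplied.  The optimal-codon set defaults to
    the modal codon per amino acid over the pooled input."""
    seqs = {sid: codon_aln.codons(sid) for sid in codon_aln.ids}
    opt = frozenset(optimal_codons) if optimal_codons is not None else \
        infer_optimal_codons(seqs.values(), codon_aln.code)
    enc_v, cbi_v, gc3_v, exp_v = {}, {}, {}, {}
    for sid, cods in seqs.items():
        enc_v[sid] = enc(cods, codon_aln.code)
        cbi_v[sid] = cbi(cods, opt, codon_aln.code)
        gc3_v[sid] = gc3(cods, codon_aln.code)
        exp_v[sid] = enc_expected(gc3_v[sid])
    comparisons = None
    if groups is not None:
        labels = sorted(set(groups.values()))
        if len(labels) == 2:
            ga = [sid for sid in codon_aln.ids if groups.get(sid) == labels[0]]
            gb = [sid for sid in codon_aln.ids if groups.get(sid) == labels[1]]
            comparisons = {}
            for name, vals in (("enc", enc_v), ("cbi", cbi_v)):
                ma, sa, mb, sb, t, p = compare_groups(
                    [vals[i] for i in ga], [vals[i] for i in gb]
                )
                comparisons[name] = {
                    labels[0]: {"mean": ma, "sd": sa, "n": len(ga)},
                    labels[1]: {"mean": mb, "sd": sb, "n": len(gb)},
                    "t": t, "p": p,
                }
    return CodonUsageSummary(
        ids=list(codon_aln.ids), enc=enc_v, cbi=cbi_v, gc3=gc3_v,
        enc_expected=exp_v, optimal_codons=opt, group_of=groups,
        comparisons=comparisons,
    )
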