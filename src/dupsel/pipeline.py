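"""Staged orchestration of a duplicate-gene analysis.

Runs the analysis stages in dependency order over one dataset —
diversity/recombination statistics with coalescent nulls, trees and the
gamma diversification statistic, branch-site selection tests, codon
usage and functional divergence — and emits a consolidated report whose
tables mirror the four standard summaries (recombination/neutrality,
branch-site likelihoods, divergence coefficients, gamma per clade).
Identical config + seeds reproduce the report byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import codonml, codonusage, coalsim, divergence, phylo, popgen
from .seqio import (Alignment, CodonAlignment, GeneticCode, read_fasta,
                    read_newick, to_codon_alignment)

__all__ = ["RunConfig", "Report", "run", "clade_assign"]

logger = logging.getLogger("dupsel.pipeline")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    ``clades`` maps the two paralog labels to tip lists, or is the
    string "suffix" to split tips on a trailing ``_<label>`` token.
    Stage toggles default to everything the inputs allow.
    """

    codon_fasta: str | Path | None = None
    codon_alignment: CodonAlignment | None = None
    tree_newick: str | Path | None = None
    tree: object | None = None
    clades: object = "suffix"
    outgroup: str | None = None
    stages: tuple = ("popgen", "coalnull", "trees", "selection",
                     "codonusage", "divergence")
    foreground_modes: tuple = ("stem", "all")
    coal_reps: int = 1000
    boot_type2: int = 1000
    seed: int = 1
    out_dir: str | Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class Report:
    """Per-stage result tables plus a provenance block."""

    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)
        return json.dumps(
            {"tables": self.tables, "failures": self.failures,
             "provenance": self.provenance},
            indent=2, default=default, sort_keys=True,
        )

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "report.json"
        path.write_text(self.to_json())
        return path


def clade_assign(tree, rule="suffix"):
    """Partition tree tips into the two duplicate clades.

    ``rule`` may be a mapping {label: [tips...]}, the string "suffix"
    (split on the trailing _token of each tip name), or "bipartition"
    (the deepest branch splitting the tips into two species-complete
    sets, species = tip-name prefix).
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if isinstance(rule, dict):
        known = set()
        for label, members in rule.items():
            for t in members:
                if t not in tips:
                    raise ValueError(f"clade tip {t!r} not in tree")
                known.add(t)
        return {k: list(v) for k, v in rule.items()}
    if rule == "suffix":
        groups = {}
        for t in tips:
            if "_" not in t:
                raise ValueError(f"tip {t!r} has no _<paralog> suffix")
            groups.setdefault(t.rsplit("_", 1)[1], []).append(t)
        if len(groups) != 2:
            raise ValueError(f"expected 2 paralog suffixes, found {sorted(groups)}")
        return groups
    if rule == "bipartition":
        root_children = tree.seed_node.child_nodes()
        if len(root_children) != 2:
            raise ValueError("bipartition rule needs a rooted binary root; "
                             "supply an outgroup or explicit clades")
        species = lambda t: t.rsplit("_", 1)[0]
        sides = []
        for ch in root_children:
            side = [lf.taxon.label for lf in ch.leaf_iter()]
            sides.append(side)
        sp_sets = [sorted(species(t) for t in s) for s in sides]
        if sp_sets[0] != sp_sets[1]:
            raise ValueError("root bipartition is not species-complete on "
                             "both sides")
        return {"dup1": sides[0], "dup2": sides[1]}
    raise ValueError(f"unknown clade rule {rule!r}")


def _load_inputs(cfg: RunConfig):
    if cfg.codon_alignment is not None:
        caln = cfg.codon_alignment
    elif cfg.codon_fasta is not None:
        caln = to_codon_alignment(read_fasta(cfg.codon_fasta),
                                  GeneticCode.standard(), allow_stops=True)
    else:
        raise ValueError("config must supply a codon alignment")
    tree = cfg.tree
    if tree is None and cfg.tree_newick is not None:
        tree = read_newick(cfg.tree_newick)
    return caln, tree


def run(cfg: RunConfig) -> Report:
    """Execute the enabled stages in dependency order.

    A failing stage is recorded in ``report.failures`` and its
    dependents are skipped; the report is still returned (callers decide
    the exit status).
    """
    caln, tree = _load_inputs(cfg)
    aln = caln.alignment
    rng = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(
                 ("coalnull", "selection", "divergence"), rng.spawn(3))}
    report = Report()
    cfg_text = json.dumps(
        {k: str(v) for k, v in vars(cfg).items() if k not in
         ("codon_alignment", "tree")}, sort_keys=True)
    report.provenance = {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "seed": cfg.seed, "stage_seeds": seeds,
        "n_sequences": len(aln), "n_codons": caln.n_codons,
    }

    clades = None
    if tree is not None:
        try:
            clades = clade_assign(tree, cfg.clades)
        except ValueError as exc:
            report.failures["clade_assign"] = str(exc)

    def stage(name, dependencies=()):
        if name not in cfg.stages:
            return False
        for d in dependencies:
            if d in report.failures:
                report.failures[name] = f"skipped: dependency {d} failed"
                return False
        logger.info("stage %s: starting", name)
        return True

    if stage("popgen"):
        try:
            s = popgen.summarize(aln)
            report.tables["popgen"] = vars(s)
        except Exception as exc:
            report.failures["popgen"] = str(exc)

    if stage("coalnull", ("popgen",)):
        try:
            seg = popgen.segregating_sites(aln)
            obs_rm = popgen.four_gamete_Rm(seg)
            obs_zz = popgen.zz_statistic(seg)[2] if seg.S >= 2 else None
            rows = []
            cfg_rm = coalsim.CoalescentConfig(
                n=len(aln), S=seg.total_segregating, recomb_mode="free",
                reps=cfg.coal_reps, seed=seeds["coalnull"])
            rows.append(coalsim.null_distribution(
                cfg_rm, popgen.four_gamete_Rm, obs_rm, name="Rm").table_row())
            if obs_zz is not None:
                cfg_zz = coalsim.CoalescentConfig(
                    n=len(aln), S=seg.total_segregating, recomb_mode="none",
                    reps=cfg.coal_reps, seed=seeds["coalnull"] + 1)
                rows.append(coalsim.null_distribution(
                    cfg_zz, lambda s: popgen.zz_statistic(s)[2], obs_zz,
                    name="ZZ").table_row())
            report.tables["coalnull"] = rows
        except Exception as exc:
            report.failures["coalnull"] = str(exc)

    if stage("trees"):
        try:
            table = {}
            for method in ("ng-nonsyn", "ng-syn"):
                dm = phylo.distance_matrix(caln, method)
                nj = phylo.neighbor_joining(dm)
                g = phylo.gamma_statistic(nj, outgroup=cfg.outgroup)
                row = {"gamma": g, "p": phylo.gamma_p_value(g),
                       "newick": nj.as_string(schema="newick").strip()}
                if clades:
                    for label, members in clades.items():
                        sub = nj.extract_tree_with_taxa_labels(members)
                        try:
                            gc = phylo.gamma_statistic(sub)
                            row[f"gamma_{label}"] = gc
                            row[f"p_{label}"] = phylo.gamma_p_value(gc)
                        except (ValueError, ArithmeticError) as exc:
                            row[f"gamma_{label}"] = f"undefined: {exc}"
                table[method] = row
            report.tables["gamma"] = table
        except Exception as exc:
            report.failures["trees"] = str(exc)

    if stage("selection"):
        if tree is None or not clades:
            report.failures.setdefault(
                "selection", "needs a tree with assignable clades")
        else:
            try:
                rows = []
                m0 = codonml.fit_model(caln, tree, "M0", n_restarts=1,
                                       seed=seeds["selection"])
                for label, members in sorted(clades.items()):
                    for mode in cfg.foreground_modes:
                        null = codonml.fit_model(
                            caln, tree, "bsA-null", foreground=members,
                            foreground_mode=mode,
                            branch_lengths=m0.branch_lengths,
                            n_restarts=2, seed=seeds["selection"])
                        alt = codonml.fit_model(
                            caln, tree, "bsA", foreground=members,
                            foreground_mode=mode,
                            branch_lengths=m0.branch_lengths,
                            n_restarts=2, start_from=null,
                            seed=seeds["selection"])
                        two_dl, p = codonml.lrt(null.lnL, alt.lnL, 1,
                                                boundary_mixture=True)
                        rows.append({
                            "clade": label, "foreground_mode": mode,
                            "lnL_null": null.lnL, "lnL_alt": alt.lnL,
                            "np_null": null.n_params, "np_alt": alt.n_params,
                            "two_delta_L": two_dl, "p": p,
                            "mles_alt": alt.mles,
                        })
                report.tables["selection"] = rows
            except Exception as exc:
                report.failures["selection"] = str(exc)

    if stage("codonusage"):
        try:
            groups = None
            if clades:
                groups = {t: label for label, members in clades.items()
                          for t in members}
            cu = codonusage.codon_usage_summary(caln, groups)
            report.tables["codonusage"] = {
                "enc": cu.enc, "cbi": cu.cbi, "gc3": cu.gc3,
                "enc_expected": cu.enc_expected,
                "optimal_codons": sorted(cu.optimal_codons),
                "comparisons": cu.comparisons,
            }
        except Exception as exc:
            report.failures["codonusage"] = str(exc)

    if stage("divergence"):
        if tree is None or not clades:
            report.failures.setdefault(
                "divergence", "needs a tree with assignable clades")
        else:
            try:
                labels = sorted(clades)
                prot = caln.translate()
                sub1 = prot.subset(clades[labels[0]])
                sub2 = prot.subset(clades[labels[1]])
                t1 = tree.extract_tree_with_taxa_labels(clades[labels[0]])
                t2 = tree.extract_tree_with_taxa_labels(clades[labels[1]])
                pair = divergence.ClusterPair(sub1, sub2, t1, t2)
                t2r = divergence.gu_type2(pair, n_boot=cfg.boot_type2,
                                          seed=seeds["divergence"])
                table = {
                    "theta_II": t2r.theta, "theta_II_se": t2r.se,
                    "theta_II_z": t2r.z,
                    "a_r_over_pi_r": t2r.a_r_over_pi_r,
                    "g_r_over_g_c": t2r.g_r_over_g_c,
                    "counts_NCR": t2r.counts_ncr, "F00_NCR": t2r.f00,
                }
                try:
                    t1r = divergence.gu_type1(pair, seed=seeds["divergence"])
                    table.update({
                        "theta_I": t1r.theta, "theta_I_se": t1r.se,
                        "theta_I_z": t1r.z, "theta_I_ml": t1r.theta_ml,
                        "theta_I_ml_se": t1r.se_ml, "lrt_theta_I": t1r.lrt,
                    })
                except ArithmeticError as exc:
                    table["theta_I"] = f"undefined: {exc}"
                report.tables["divergence"] = table
            except Exception as exc:
                report.failures["divergence"] = str(exc)

    if cfg.out_dir is not None:
        report.write(cfg.out_dir)
    return report
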