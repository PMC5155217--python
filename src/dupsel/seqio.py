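"""Sequence and tree input/output with validation.

Containers and readers shared by every analysis stage: aligned nucleotide
matrices (:class:`Alignment`), frame-checked codon views
(:class:`CodonAlignment`), genetic-code tables and Newick trees.

Conventions
-----------
* Coordinates are 0-based, half-open internally; only user-facing reports
  are 1-based.
* Symbols are upper-cased on input; ``-`` is the gap character.
* IUPAC ambiguity codes and ``N`` are treated as missing data by all
  downstream statistics (masked pairwise).
* A terminal stop codon shared by the alignment is stripped before codon
  analyses (the usual codeml convention); internal stops are rejected
  unless the sequence is explicitly allowed to be a pseudogene.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "AlignmentError",
    "FormatError",
    "FrameError",
    "Alignment",
    "CodonAlignment",
    "GeneticCode",
    "read_fasta",
    "parse_fasta",
    "write_fasta",
    "to_codon_alignment",
    "read_newick",
    "parse_newick",
    "write_newick",
    "validate_tree",
]

#: unambiguous nucleotide symbols; everything else except '-' is missing
_NUCS = frozenset("ACGT")
#: full accepted symbol set (IUPAC + gap)
_VALID = frozenset("ACGTURYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised when sequences violate alignment invariants (ragged lengths)."""


class FormatError(ValueError):
    """Raised for malformed input files (duplicate ids, empty files)."""


class FrameError(ValueError):
    """Raised when a nucleotide alignment cannot be interpreted as codons."""


@dataclass(frozen=True)
class GeneticCode:
    """A genetic-code table: codon -> amino acid map plus stop codons."""

    table_id: int
    forward: dict
    stops: frozenset

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi_id(1)

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        tab = CodonTable.unambiguous_dna_by_id[table_id]
        fwd = dict(tab.forward_table)
        stops = frozenset(tab.stop_codons)
        if len(fwd) + len(stops) != 64:
            raise ValueError(f"genetic code table {table_id} does not map 64 codons")
        return cls(table_id=table_id, forward=fwd, stops=stops)

    def translate_codon(self, codon: str) -> str:
        """Amino acid for a codon; '*' for stops, 'X' for ambiguous/gapped."""
        if codon in self.stops:
            return "*"
        return self.forward.get(codon, "X")

    @property
    def sense_codons(self) -> list:
        return sorted(self.forward)


class Alignment:
    """An equal-length matrix of nucleotide (or amino acid) sequences.

    Parameters
    ----------
    ids : sequence of str
        Unique sequence identifiers.
    seqs : sequence of str
        Aligned sequences, all of equal length >= 1.
    """

    def __init__(self, ids, seqs, *, alphabet: str = "nt"):
        ids = list(ids)
        seqs = [str(s).upper() for s in seqs]
        if len(ids) != len(seqs):
            raise AlignmentError("ids and seqs must have equal length")
        if not seqs:
            raise FormatError("empty alignment")
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dup}")
        L = len(seqs[0])
        if L < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid, s in zip(ids, seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"ragged alignment: {sid!r} has length {len(s)}, expected {L}"
                )
        self.ids = ids
        self.seqs = seqs
        self.length = L
        self.alphabet = alphabet
        self._matrix = None

    def __len__(self) -> int:
        return len(self.ids)

    def __repr__(self) -> str:
        return f"Alignment({len(self)} sequences x {self.length} sites)"

    @property
    def matrix(self) -> np.ndarray:
        """(n, L) array of single characters."""
        if self._matrix is None:
            self._matrix = np.array([list(s) for s in self.seqs], dtype="<U1")
        return self._matrix

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean array: True where the symbol is gap/ambiguous/N."""
        m = self.matrix
        return ~np.isin(m, list(_NUCS)) if self.alphabet == "nt" else (m == "-") | (m == "X")

    def subset(self, keep_ids) -> "Alignment":
        keep = [i for i in self.ids if i in set(keep_ids)]
        idx = {i: k for k, i in enumerate(self.ids)}
        return Alignment(keep, [self.seqs[idx[i]] for i in keep], alphabet=self.alphabet)


@dataclass
class CodonAlignment:
    """A frame-checked codon view of a nucleotide alignment.

    ``pseudogene_ids`` lists sequences with internal stop codons; they are
    excluded from codon-model fitting but retained for reporting.
    """

    alignment: Alignment
    code: GeneticCode
    pseudogene_ids: frozenset = field(default_factory=frozenset)

    @property
    def n_codons(self) -> int:
        return self.alignment.length // 3

    @property
    def ids(self):
        return self.alignment.ids

    def codons(self, sid: str) -> list:
        s = self.alignment.seqs[self.alignment.ids.index(sid)]
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def codon_matrix(self) -> list:
        """List (per sequence) of codon lists, in id order."""
        return [
            [s[i : i + 3] for i in range(0, len(s), 3)] for s in self.alignment.seqs
        ]

    def coding_ids(self) -> list:
        """Ids that are not flagged pseudogene (usable for model fitting)."""
        return [i for i in self.ids if i not in self.pseudogene_ids]

    def translate(self) -> Alignment:
        """Amino-acid alignment ('X' at gapped/ambiguous codons, '*' at stops)."""
        rows = []
        for cods in self.codon_matrix():
            rows.append("".join(self.code.translate_codon(c) for c in cods))
        return Alignment(list(self.ids), rows, alphabet="aa")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(text: str, *, alphabet: str = "nt") -> Alignment:
    """Parse FASTA text into a validated :class:`Alignment`."""
    recs = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not recs:
        raise FormatError("no FASTA records found")
    ids = [r.id for r in recs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate sequence ids: {dup}")
    return Alignment(ids, [str(r.seq) for r in recs], alphabet=alphabet)


def read_fasta(path, *, alphabet: str = "nt") -> Alignment:
    """Read an aligned FASTA file."""
    with open(path) as fh:
        return parse_fasta(fh.read(), alphabet=alphabet)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, s in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{s}\n")


# ---------------------------------------------------------------------------
# Codon framing
# ---------------------------------------------------------------------------

def _internal_stop_positions(seq: str, code: GeneticCode) -> list:
    """0-based codon indices of internal (non-terminal) stop codons."""
    ncod = len(seq) // 3
    out = []
    for k in range(ncod - 1):  # terminal codon exempt
        if seq[3 * k : 3 * k + 3] in code.stops:
            out.append(k)
    return out


def to_codon_alignment(
    aln: Alignment, code: GeneticCode | None = None, *, allow_stops: bool = False
) -> CodonAlignment:
    """Frame-check an alignment as codons.

    Terminal stop codons are stripped when every sequence ends in a stop,
    a gap codon, or an ambiguous codon.  Sequences with internal stops
    raise :class:`FrameError` unless ``allow_stops``, in which case they
    are flagged as pseudogenes.
    """
    code = code or GeneticCode.standard()
    if aln.length % 3 != 0:
        raise FrameError(f"alignment length {aln.length} is not divisible by 3")
    # strip a shared terminal stop column block
    last = [s[-3:] for s in aln.seqs]
    def _stoppish(c):
        return c in code.stops or any(ch not in _NUCS for ch in c)
    if aln.length >= 6 and any(c in code.stops for c in last) and all(_stoppish(c) for c in last):
        aln = Alignment(aln.ids, [s[:-3] for s in aln.seqs], alphabet=aln.alphabet)
    pseudo = []
    for sid, s in zip(aln.ids, aln.seqs):
        if _internal_stop_positions(s, code):
            if not allow_stops:
                pos = _internal_stop_positions(s, code)[0]
                raise FrameError(
                    f"internal stop codon in {sid!r} at codon {pos + 1} "
                    "(pass allow_stops=True to flag as pseudogene)"
                )
            pseudo.append(sid)
    return CodonAlignment(aln, code, frozenset(pseudo))


# ---------------------------------------------------------------------------
# Newick trees (dendropy containers)
# ---------------------------------------------------------------------------

class TreeParseError(ValueError):
    pass


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Check tip-label uniqueness and non-negative finite branch lengths."""
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeParseError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        if not np.isfinite(edge.length) or edge.length < 0:
            raise TreeParseError(f"invalid branch length {edge.length!r}")
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"could not parse Newick: {exc}") from exc
    return validate_tree(tree)


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s
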