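"""Core alignment containers and matrix-modifying operations.

The :class:`Alignment` is the universal substrate of the package: a taxa x
columns character matrix over the nucleotide alphabet (plus gap and IUPAC
ambiguity codes) or, after translation, the amino-acid alphabet.  A
:class:`PartitionMap` carries the gene structure of a concatenated
supermatrix as named, non-overlapping column intervals (0-based half-open
internally; the RAxML partition-file dialect uses 1-based inclusive
coordinates, handled in :mod:`lbalens.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

#: unambiguous nucleotide states
NT_STATES = "ACGT"
#: IUPAC ambiguity codes (everything observed that is not ACGT, gap, or N)
NT_AMBIGUOUS = set("RYSWKMBDHVN")
GAP = "-"


class AlignmentError(ValueError):
    """Malformed alignment (ragged rows, empty input, bad characters)."""


class DuplicateLabelError(AlignmentError):
    """Two rows share one taxon label."""


class FrameError(AlignmentError):
    """Alignment (or gene) width is not divisible by 3."""


class PartitionError(ValueError):
    """Invalid partition map (overlap, bad range, unknown gene)."""


@dataclass
class Alignment:
    """Character matrix with unique taxon labels.

    Parameters
    ----------
    taxa
        Ordered unique sequence labels.
    matrix
        ``(n_taxa, n_columns)`` array of single characters (dtype ``<U1``).
    molecule
        ``"nt"`` for nucleotide, ``"aa"`` for amino acid.
    """

    taxa: list[str]
    matrix: np.ndarray
    molecule: str = "nt"

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-D (taxa x columns)")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} labels for {self.matrix.shape[0]} rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateLabelError("duplicate taxon labels")
        if self.molecule not in ("nt", "aa"):
            raise AlignmentError(f"unknown molecule type {self.molecule!r}")

    # -- basic protocol ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.molecule == other.molecule
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )

    @classmethod
    def from_dict(cls, seqs: dict[str, str], molecule: str = "nt") -> "Alignment":
        """Build from a label -> sequence mapping (order preserved)."""
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        width = lengths.pop() if lengths else 0
        mat = np.empty((len(taxa), width), dtype="<U1")
        for i, t in enumerate(taxa):
            mat[i] = list(seqs[t])
        return cls(taxa, mat, molecule)

    def take_columns(self, idx) -> "Alignment":
        """New alignment restricted to columns ``idx`` (order given)."""
        return Alignment(self.taxa, self.matrix[:, np.asarray(idx, dtype=int)],
                         self.molecule)

    def encoded(self) -> np.ndarray:
        """Integer codes: A,C,G,T -> 0..3; everything else (gap, ambiguity,
        amino acids' non-applicability) -> -1.  Nucleotide only."""
        codes = np.full(self.matrix.shape, -1, dtype=np.int8)
        for k, s in enumerate(NT_STATES):
            codes[self.matrix == s] = k
        return codes

    def state_codes(self) -> np.ndarray:
        """Generic integer codes for any molecule: unambiguous residues get
        consecutive codes, gap/ambiguity/missing get -1."""
        if self.molecule == "nt":
            return self.encoded()
        codes = np.full(self.matrix.shape, -1, dtype=np.int8)
        aa = "ACDEFGHIKLMNPQRSTVWY*"
        for k, s in enumerate(aa):
            codes[self.matrix == s] = k
        return codes


@dataclass
class PartitionMap:
    """Named gene -> column-interval map over a supermatrix.

    Intervals are 0-based half-open, non-overlapping, and stored sorted by
    start; gene names are unique.
    """

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise PartitionError("duplicate gene names")
        for name, start, end in self.entries:
            if end < start or start < 0:
                raise PartitionError(f"bad interval for {name}: {start}-{end}")
        ordered = sorted(self.entries, key=lambda e: e[1])
        for (n1, _, e1), (n2, s2, _) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise PartitionError(f"intervals overlap: {n1} and {n2}")
        self.entries = ordered

    @property
    def genes(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def width(self) -> int:
        return max((e[2] for e in self.entries), default=0)

    def interval(self, gene: str) -> tuple[int, int]:
        for name, start, end in self.entries:
            if name == gene:
                return start, end
        raise PartitionError(f"unknown gene {gene!r}")

    def columns(self, gene: str) -> np.ndarray:
        s, e = self.interval(gene)
        return np.arange(s, e)


# ---------------------------------------------------------------------------
# matrix-modifying operations
# ---------------------------------------------------------------------------

def concatenate(alignments: list[Alignment],
                names: list[str]) -> tuple[Alignment, PartitionMap]:
    """Concatenate gene alignments sharing one taxon set into a supermatrix.

    Columns are appended in the given order and the returned
    :class:`PartitionMap` records each gene's interval.
    """
    if len(alignments) != len(names):
        raise ValueError("one name per alignment required")
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    ref = alignments[0]
    for a in alignments[1:]:
        if a.taxa != ref.taxa:
            raise AlignmentError("taxon sets (or their order) differ")
        if a.molecule != ref.molecule:
            raise AlignmentError("molecule types differ")
    mat = np.concatenate([a.matrix for a in alignments], axis=1)
    entries, pos = [], 0
    for name, a in zip(names, alignments):
        entries.append((name, pos, pos + a.n_columns))
        pos += a.n_columns
    return Alignment(ref.taxa, mat, ref.molecule), PartitionMap(entries)


def _codon_check(width: int, gene: str = "<alignment>") -> None:
    if width % 3 != 0:
        raise FrameError(f"{gene}: width {width} not divisible by 3")


def extract_codon_positions(aln: Alignment, keep: set[int],
                            pm: PartitionMap | None = None) -> Alignment:
    """Retain the requested within-codon positions (1, 2 and/or 3).

    When a partition map is supplied the reading frame restarts at each
    gene's first column and divisibility by 3 is enforced per gene.
    """
    keep = set(keep)
    if not keep <= {1, 2, 3} or not keep:
        raise ValueError("keep must be a nonempty subset of {1,2,3}")
    if aln.molecule != "nt":
        raise AlignmentError("codon positions only defined for nucleotides")
    if pm is not None:
        idx_parts = []
        for gene, start, end in pm.entries:
            _codon_check(end - start, gene)
            offs = np.arange(start, end)
            idx_parts.append(offs[np.isin((offs - start) % 3 + 1, list(keep))])
        idx = np.concatenate(idx_parts) if idx_parts else np.array([], dtype=int)
    else:
        _codon_check(aln.n_columns)
        offs = np.arange(aln.n_columns)
        idx = offs[np.isin(offs % 3 + 1, list(keep))]
    return aln.take_columns(np.sort(idx))


def translate_codon_alignment(aln: Alignment, table_id: int = 11,
                              pm: PartitionMap | None = None) -> Alignment:
    """Translate a codon-aligned nucleotide matrix to amino acids.

    Policy: a codon containing any gap translates to a gap (so amino-acid
    gap structure mirrors nucleotide indels); a codon containing an
    ambiguity code translates to ``X``; internal stops are kept as ``*``
    with a logged warning.  Default genetic code is NCBI table 11
    (bacterial/plastid), overridable.
    """
    if aln.molecule != "nt":
        raise AlignmentError("can only translate nucleotide alignments")
    if pm is not None:
        for gene, start, end in pm.entries:
            _codon_check(end - start, gene)
    _codon_check(aln.n_columns)
    table = CodonTable.unambiguous_dna_by_id[table_id]
    n_codons = aln.n_columns // 3
    out = np.empty((aln.n_taxa, n_codons), dtype="<U1")
    n_stops = 0
    for i in range(aln.n_taxa):
        row = aln.matrix[i]
        for j in range(n_codons):
            codon = "".join(row[3 * j:3 * j + 3])
            if GAP in codon:
                out[i, j] = GAP
            elif any(c not in NT_STATES for c in codon):
                out[i, j] = "X"
            elif codon in table.stop_codons:
                out[i, j] = "*"
                n_stops += 1
            else:
                out[i, j] = table.forward_table[codon]
    if n_stops:
        logger.warning("%d internal stop codon(s) translated to '*'", n_stops)
    return Alignment(aln.taxa, out, "aa")


def subset_genes(aln: Alignment, pm: PartitionMap, genes,
                 mode: str = "keep") -> tuple[Alignment, PartitionMap]:
    """Keep or drop named genes, rebuilding the supermatrix and its map."""
    genes = set(genes)
    known = set(pm.genes)
    unknown = genes - known
    if unknown:
        raise PartitionError(f"unknown gene(s): {sorted(unknown)}")
    if mode not in ("keep", "drop"):
        raise ValueError("mode must be 'keep' or 'drop'")
    selected = [e for e in pm.entries
                if (e[0] in genes) == (mode == "keep")]
    if not selected:
        return (Alignment(aln.taxa, np.empty((aln.n_taxa, 0), dtype="<U1"),
                          aln.molecule), PartitionMap([]))
    cols = np.concatenate([np.arange(s, e) for _, s, e in selected])
    entries, pos = [], 0
    for name, s, e in selected:
        entries.append((name, pos, pos + (e - s)))
        pos += e - s
    return aln.take_columns(cols), PartitionMap(entries)
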