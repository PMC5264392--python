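"""File I/O: FASTA / relaxed-PHYLIP alignments, RAxML-style partition
files, and Newick trees (one per line).

Reading normalises characters: everything is uppercased, ``U`` is mapped to
``T`` (RNA input), and any character outside the declared alphabet is
mapped to ``N`` with a logged count.  Ambiguity codes other than ``N`` are
retained so I/O is lossless; individual analyses decide how to treat them.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import (
    GAP,
    NT_AMBIGUOUS,
    NT_STATES,
    Alignment,
    AlignmentError,
    DuplicateLabelError,
    PartitionError,
    PartitionMap,
)

logger = logging.getLogger(__name__)

_NT_ALPHABET = set(NT_STATES) | NT_AMBIGUOUS | {GAP}
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*") | {GAP, "?"}


def _normalise(seqs: dict[str, str], molecule: str) -> dict[str, str]:
    alphabet = _NT_ALPHABET if molecule == "nt" else _AA_ALPHABET
    out, n_unknown = {}, 0
    for name, s in seqs.items():
        s = s.upper()
        if molecule == "nt":
            s = s.replace("U", "T").replace("?", "N")
        cleaned = []
        for c in s:
            if c in alphabet:
                cleaned.append(c)
            else:
                cleaned.append("N" if molecule == "nt" else "X")
                n_unknown += 1
        out[name] = "".join(cleaned)
    if n_unknown:
        logger.warning("%d unknown character(s) mapped to %s", n_unknown,
                       "N" if molecule == "nt" else "X")
    return out


def read_alignment(path, format: str = "fasta",
                   molecule: str = "nt") -> Alignment:
    """Read an alignment from ``fasta`` or ``phylip-relaxed``."""
    path = Path(path)
    if format not in ("fasta", "phylip-relaxed"):
        raise ValueError(f"unsupported format {format!r}")
    try:
        if format == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(AlignIO.read(str(path), "phylip-relaxed"))
    except (ValueError, IndexError) as exc:
        raise AlignmentError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise AlignmentError(f"{path}: no sequences found")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise DuplicateLabelError(f"{path}: duplicate taxon labels")
    seqs = {r.id: str(r.seq) for r in records}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise AlignmentError(f"{path}: unequal row lengths {sorted(lengths)}")
    return Alignment.from_dict(_normalise(seqs, molecule), molecule)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    path = Path(path)
    records = [SeqRecord(Seq("".join(aln.matrix[i])), id=t, description="")
               for i, t in enumerate(aln.taxa)]
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "phylip-relaxed":
        from Bio.Align import MultipleSeqAlignment
        AlignIO.write(MultipleSeqAlignment(records), str(path),
                      "phylip-relaxed")
    else:
        raise ValueError(f"unsupported format {format!r}")


_PARTITION_RE = re.compile(
    r"^\s*(\w+)\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$")


def read_partition_map(path) -> PartitionMap:
    """Parse a RAxML-style partition file (``DNA, rbcL = 1-1428``).

    File coordinates are 1-based inclusive; the returned map is 0-based
    half-open.
    """
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.strip().startswith("#"):
            continue
        m = _PARTITION_RE.match(line)
        if m is None:
            raise PartitionError(f"cannot parse partition line: {line!r}")
        _, name, start, end = m.groups()
        start, end = int(start), int(end)
        if end < start:
            raise PartitionError(f"{name}: end {end} < start {start}")
        entries.append((name, start - 1, end))
    return PartitionMap(entries)


def write_partition_map(pm: PartitionMap, path,
                        datatype: str = "DNA") -> None:
    lines = [f"{datatype}, {name} = {start + 1}-{end}"
             for name, start, end in pm.entries]
    Path(path).write_text("\n".join(lines) + "\n")


# -- trees ------------------------------------------------------------------

def read_trees(path, rooting: str = "default-unrooted") -> list[dendropy.Tree]:
    """Read Newick trees, one per line, into a shared taxon namespace."""
    text = Path(path).read_text()
    tns = dendropy.TaxonNamespace()
    trees = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(dendropy.Tree.get(
                data=line, schema="newick", taxon_namespace=tns,
                rooting=rooting))
        except Exception as exc:  # dendropy raises various error types
            raise ValueError(f"cannot parse Newick: {line[:60]!r}: {exc}")
    return trees


def write_tree(tree: dendropy.Tree, path) -> None:
    write_trees([tree], path)


def write_trees(trees: list[dendropy.Tree], path) -> None:
    lines = [t.as_string(schema="newick", suppress_rooting=True).strip()
             for t in trees]
    Path(path).write_text("\n".join(lines) + "\n")


def parse_tree(newick: str, rooting: str = "default-unrooted") -> dendropy.Tree:
    """Parse one Newick string."""
    return dendropy.Tree.get(data=newick, schema="newick", rooting=rooting)
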