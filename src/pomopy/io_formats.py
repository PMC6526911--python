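"""Readers and writers: counts files, Newick trees, FASTA-to-counts.

The counts-file dialect is the one used by the pomo-dev tooling::

    COUNTSFILE NPOP 2 NSITES 3
    CHROM POS pop_a pop_b
    chr1  1   10,0,0,0  9,1,0,0

Cells are comma-separated allele counts in alphabet (A,C,G,T) order; an
all-zero cell means the site was not observed in that population.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np

from .alignment import CountsAlignment
from .phylotree import Node, PhyloTree
from .statespace import DNA, Alphabet

__all__ = [
    "read_counts",
    "write_counts",
    "fasta_to_counts",
    "parse_newick",
    "read_newick",
    "write_newick",
    "CountsParseError",
]

_UNAMBIGUOUS = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class CountsParseError(ValueError):
    pass


def read_counts(path: str | Path, alphabet: Alphabet = DNA) -> CountsAlignment:
    """Parse a counts file into a :class:`CountsAlignment`."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise CountsParseError(f"{path}: empty counts file")
    header = lines[0].split()
    if len(header) != 5 or header[0] != "COUNTSFILE" or header[1] != "NPOP" or header[3] != "NSITES":
        raise CountsParseError(f"{path}:1: malformed header {lines[0]!r}")
    try:
        npop, nsites = int(header[2]), int(header[4])
    except ValueError as exc:
        raise CountsParseError(f"{path}:1: non-integer NPOP/NSITES") from exc
    cols = lines[1].split()
    if len(cols) != 2 + npop or cols[0].upper() != "CHROM" or cols[1].upper() != "POS":
        raise CountsParseError(f"{path}:2: malformed column header {lines[1]!r}")
    populations = cols[2:]
    n_sym = alphabet.size
    chrom: list[str] = []
    pos: list[int] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[2:], start=3):
        parts = ln.split()
        if len(parts) != 2 + npop:
            raise CountsParseError(
                f"{path}:{lineno}: expected {2 + npop} columns, got {len(parts)}"
            )
        chrom.append(parts[0])
        try:
            pos.append(int(parts[1]))
        except ValueError:
            pos.append(-1)
        row: list[int] = []
        for cell in parts[2:]:
            vals = cell.split(",")
            if len(vals) != n_sym:
                raise CountsParseError(
                    f"{path}:{lineno}: cell {cell!r} needs {n_sym} comma-separated counts"
                )
            try:
                row.extend(int(v) for v in vals)
            except ValueError as exc:
                raise CountsParseError(
                    f"{path}:{lineno}: non-integer count in cell {cell!r}"
                ) from exc
        rows.append(row)
    if len(rows) != nsites:
        warnings.warn(
            f"{path}: header claims NSITES={nsites} but {len(rows)} rows parsed; "
            "trusting parsed data",
            stacklevel=2,
        )
    counts = np.asarray(rows, dtype=np.int64).reshape(len(rows), npop, n_sym)
    return CountsAlignment(populations, counts, alphabet, chrom=chrom, pos=np.asarray(pos))


def write_counts(aln: CountsAlignment, path: str | Path) -> None:
    """Write a :class:`CountsAlignment` in the canonical counts dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"COUNTSFILE NPOP {aln.n_populations} NSITES {aln.n_sites}\n")
        fh.write("CHROM\tPOS\t" + "\t".join(aln.populations) + "\n")
        chrom = aln.chrom if aln.chrom is not None else ["NA"] * aln.n_sites
        pos = aln.pos if aln.pos is not None else np.arange(1, aln.n_sites + 1)
        for s in range(aln.n_sites):
            cells = [
                ",".join(str(int(v)) for v in aln.counts[s, p])
                for p in range(aln.n_populations)
            ]
            fh.write(f"{chrom[s]}\t{int(pos[s])}\t" + "\t".join(cells) + "\n")


def fasta_to_counts(population_fastas: dict[str, str | Path]) -> CountsAlignment:
    """Convert per-population FASTA alignments to allele counts.

    ``population_fastas`` maps population name -> FASTA path containing the
    aligned sequences of that population's individuals.  Sequences must all
    have equal length.  Gaps and ambiguity codes contribute no counts (an
    all-ambiguous column becomes a missing observation).
    """
    from Bio import SeqIO

    pops = list(population_fastas)
    per_pop: list[np.ndarray] = []
    length: int | None = None
    for pop in pops:
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(population_fastas[pop]), "fasta")]
        if not seqs:
            raise ValueError(f"population {pop!r}: no sequences in FASTA")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError(f"population {pop!r}: sequences differ in length")
        if length is None:
            length = len(seqs[0])
        elif len(seqs[0]) != length:
            raise ValueError("populations have different alignment lengths")
        counts = np.zeros((length, 4), dtype=np.int64)
        for s in seqs:
            for site, ch in enumerate(s):
                k = _UNAMBIGUOUS.get(ch)
                if k is not None:
                    counts[site, k] += 1
        per_pop.append(counts)
    return CountsAlignment(pops, np.stack(per_pop, axis=1))


# -- Newick ------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    missing = [False]

    def convert(dnode, is_root: bool) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if not is_root:
                missing[0] = True
            length = 0.0
        node = Node(label, length)
        for child in dnode.child_nodes():
            node.add_child(convert(child, False))
        return node

    root = convert(dtree.seed_node, True)
    root.length = 0.0
    if missing[0]:
        warnings.warn("branch length missing in Newick; defaulting to 0.0", stacklevel=3)
    return PhyloTree(root)


def parse_newick(newick: str) -> PhyloTree:
    """Parse a Newick string (quoted labels and comments tolerated)."""
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path, digits: int = 12) -> None:
    Path(path).write_text(tree.newick(digits=digits) + "\n")
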