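"""Mapping clones to cells via long-read molecular bridges.

A molecular bridge is a cDNA molecule that carries both the droplet cell
barcode (the cellular cDNA index) and the transcribed clonal tracking
barcode.  Circular-consensus long reads of these molecules link each cell in
a 10x channel to the clone it belongs to.

Mapping rules:

* a read counts toward a (cell, clone) pair only if it contains, as exact
  substrings, exactly one whitelisted cellular index and exactly one
  whitelisted clone barcode — no misreads are tolerated;
* one supporting molecule suffices to assign a cell (minimum support is
  configurable);
* cells whose reads name more than one distinct clone are excluded from all
  downstream analyses;
* whitelisted cells with no informative read remain unmapped.

Reads are scanned in both orientations (consensus reads have arbitrary
strand); hits from the two strands are pooled, so a strand disagreement shows
up as multiple distinct hits and discards the read.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .barcode_quant import reverse_complement

__all__ = ["BridgeRead", "CellCloneMap", "scan_bridge_reads", "assign_cells"]


@dataclass(frozen=True)
class BridgeRead:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("bridge read sequence must be non-empty")


@dataclass
class CellCloneMap:
    """Partition of a cell whitelist into assigned / multimapped / unmapped."""

    assignments: dict[str, str] = field(default_factory=dict)
    excluded_multimapped: set[str] = field(default_factory=set)
    unmapped_cells: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        a = set(self.assignments)
        if a & self.excluded_multimapped or a & self.unmapped_cells \
                or self.excluded_multimapped & self.unmapped_cells:
            raise ValueError("assigned/excluded/unmapped sets must be disjoint")

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)

    def mapped_fraction(self) -> float:
        n = len(self.assignments) + len(self.excluded_multimapped) + len(self.unmapped_cells)
        return len(self.assignments) / n if n else 0.0


def _window_hits(seq: str, whitelist: frozenset[str], lengths: tuple[int, ...]) -> set[str]:
    hits: set[str] = set()
    for L in lengths:
        for i in range(len(seq) - L + 1):
            w = seq[i:i + L]
            if w in whitelist:
                hits.add(w)
    return hits


def scan_bridge_reads(
    reads: Iterable,
    cell_whitelist: Iterable[str],
    clone_whitelist: Iterable[str],
) -> dict[tuple[str, str], int]:
    """Scan bridge reads for exact whitelist matches.

    Returns (cell index, clone barcode) -> supporting read count.  A read is
    informative iff it contains exactly one distinct whitelisted cell index
    and exactly one distinct whitelisted clone barcode across both
    orientations; all other reads are discarded.
    """
    cells = frozenset(cell_whitelist)
    clones = frozenset(clone_whitelist)
    if not cells or not clones:
        raise ValueError("cell and clone whitelists must be non-empty")
    cell_lens = tuple(sorted({len(c) for c in cells}))
    clone_lens = tuple(sorted({len(c) for c in clones}))

    support: dict[tuple[str, str], int] = defaultdict(int)
    for r in reads:
        if isinstance(r, str):
            seq = r.upper()
        elif isinstance(r, BridgeRead):
            seq = r.sequence.upper()
        else:  # SeqRecord
            seq = str(r.seq).upper()
        rc = reverse_complement(seq)
        cell_hits = _window_hits(seq, cells, cell_lens) | _window_hits(rc, cells, cell_lens)
        if len(cell_hits) != 1:
            continue
        clone_hits = _window_hits(seq, clones, clone_lens) | _window_hits(rc, clones, clone_lens)
        if len(clone_hits) != 1:
            continue
        support[(next(iter(cell_hits)), next(iter(clone_hits)))] += 1
    return dict(support)


def assign_cells(
    pairs: Mapping[tuple[str, str], int],
    cell_whitelist: Iterable[str],
    min_support: int = 1,
) -> CellCloneMap:
    """Resolve (cell, clone) pair support into a cell -> clone map.

    A cell is assigned iff its pairs (with support >= ``min_support``) name
    exactly one distinct clone; cells naming two or more distinct clones are
    excluded as multimapped; whitelisted cells with no qualifying pair are
    unmapped.  The three sets partition the whitelist.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    cells = set(cell_whitelist)
    by_cell: dict[str, set[str]] = defaultdict(set)
    for (cell, clone), n in pairs.items():
        if n >= min_support and cell in cells:
            by_cell[cell].add(clone)
    out = CellCloneMap()
    for cell in cells:
        clones = by_cell.get(cell)
        if not clones:
            out.unmapped_cells.add(cell)
        elif len(clones) == 1:
            out.assignments[cell] = next(iter(clones))
        else:
            out.excluded_multimapped.add(cell)
    return out
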