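"""Clonal tracking barcode quantification from amplicon sequencing reads.

Clones are marked by synthetic DNA barcodes carried in the 3'UTR of a GFP
transgene delivered by a lentiviral vector; every descendant of a transduced
cell inherits the barcode.  Sorted GFP+ cells are PCR-amplified around the
barcode locus and sequenced.  This module extracts barcodes from those reads,
counts them, and converts read shares into clonal abundances expressed as a
percentage of mononuclear cells (MNC) using the FACS fractions measured for
each sample:

    abundance(b) = 100 * (reads_b / total_reads)
                       * (human cells / total MNC)
                       * (GFP+ cells / human cells)

Clones must exceed a detection threshold (default 0.01% of MNC, strict
inequality) to be considered detected; the threshold is applied per sample, so
a clone may be detected in one tissue and not another.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeLibrarySpec",
    "SampleMeta",
    "BarcodeCountTable",
    "extract_barcodes",
    "collapse_barcodes",
    "compute_clonal_abundance",
    "abundance_matrix",
    "filter_clones",
]

_ACGT = re.compile(r"^[ACGT]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BarcodeLibrarySpec:
    """Architecture of the barcode amplicon: flank5 + barcode + flank3.

    The exact flank sequences and barcode length are properties of the
    lentiviral construct and must be supplied as configuration.
    """

    upstream_flank: str
    downstream_flank: str
    barcode_length: int

    def __post_init__(self) -> None:
        for name, flank in (("upstream_flank", self.upstream_flank),
                            ("downstream_flank", self.downstream_flank)):
            if not flank or not _ACGT.match(flank):
                raise ValueError(f"{name} must be a non-empty uppercase ACGT string")
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")


@dataclass
class SampleMeta:
    """Per-sample metadata: cohort position and the FACS scaling fractions."""

    sample_id: str
    mouse_id: str = ""
    tissue: str = ""
    timepoint_days: float = 0.0
    treatment_arm: str = "none"
    passage: int = 1
    frac_human_of_mnc: float | None = None
    frac_gfp_of_human: float | None = None

    def __post_init__(self) -> None:
        for name, frac in (("frac_human_of_mnc", self.frac_human_of_mnc),
                           ("frac_gfp_of_human", self.frac_gfp_of_human)):
            if frac is not None and not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.passage < 1:
            raise ValueError("passage must be >= 1")


@dataclass
class BarcodeCountTable:
    """Read counts per barcode for one sorted sample, plus an unparsed tally."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    unparsed: int = 0

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))


def _read_sequences(reads: Iterable) -> Iterator[str]:
    """Accept plain strings or Bio.SeqRecord-like objects."""
    for r in reads:
        if isinstance(r, str):
            yield r.upper()
        else:  # SeqRecord or Seq
            yield str(getattr(r, "seq", r)).upper()


def _find_barcode(seq: str, spec: BarcodeLibrarySpec) -> str | None:
    """First position where flank5 + barcode + flank3 matches exactly."""
    up, down, blen = spec.upstream_flank, spec.downstream_flank, spec.barcode_length
    start = 0
    while True:
        i = seq.find(up, start)
        if i < 0:
            return None
        bpos = i + len(up)
        bc = seq[bpos:bpos + blen]
        if len(bc) == blen and seq.startswith(down, bpos + blen) and _ACGT.match(bc):
            return bc
        start = i + 1


def extract_barcodes(
    reads: Iterable,
    spec: BarcodeLibrarySpec,
    sample_id: str = "sample",
    scan_reverse_complement: bool = False,
) -> BarcodeCountTable:
    """Extract and count barcodes from a read stream.

    Each read contributes at most one barcode: the ``barcode_length``
    substring between exact matches of both flanks.  Reads without both
    flanks in the expected architecture are tallied as unparsed.  Matching is
    forward-strand by default (amplicon sequencing is directional); set
    ``scan_reverse_complement`` to also try the reverse complement of reads
    that fail on the forward strand.

    Raises
    ------
    ValueError
        If the read stream is empty.
    """
    table = BarcodeCountTable(sample_id=sample_id)
    n = 0
    min_len = len(spec.upstream_flank) + spec.barcode_length + len(spec.downstream_flank)
    short_warned = False
    for seq in _read_sequences(reads):
        n += 1
        if len(seq) < min_len and not short_warned:
            warnings.warn(
                "reads shorter than flank5+barcode+flank3 can never parse",
                stacklevel=2,
            )
            short_warned = True
        bc = _find_barcode(seq, spec)
        if bc is None and scan_reverse_complement:
            bc = _find_barcode(reverse_complement(seq), spec)
        if bc is None:
            table.unparsed += 1
        else:
            table.counts[bc] = table.counts.get(bc, 0) + 1
    if n == 0:
        raise ValueError("no reads")
    return table


def collapse_barcodes(table: BarcodeCountTable, max_hamming: int = 0) -> BarcodeCountTable:
    """Optionally absorb likely sequencing-error barcodes into neighbours.

    Barcodes within Hamming distance <= ``max_hamming`` of a higher-count
    barcode are merged into it (greedy, largest counts first).  The default
    ``max_hamming=0`` disables collapsing, reproducing exact counting.
    """
    if max_hamming < 0:
        raise ValueError("max_hamming must be >= 0")
    if max_hamming == 0 or len(table.counts) < 2:
        return table
    # largest first; ties broken lexicographically for determinism
    ordered = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept: dict[str, int] = {}
    for bc, cnt in ordered:
        target = None
        for parent in kept:
            if len(parent) == len(bc):
                d = sum(a != b for a, b in zip(parent, bc))
                if d <= max_hamming:
                    target = parent
                    break
        if target is None:
            kept[bc] = cnt
        else:
            kept[target] += cnt
    return BarcodeCountTable(sample_id=table.sample_id, counts=kept, unparsed=table.unparsed)


def compute_clonal_abundance(counts: BarcodeCountTable, meta: SampleMeta) -> pd.Series:
    """Convert barcode read counts to clonal abundance in % of MNC.

    abundance(b) = 100 * count(b)/total_reads * frac_human_of_mnc * frac_gfp_of_human

    The per-sample sum equals 100 * frac_human * frac_gfp exactly (before any
    detection filtering).
    """
    if counts.total_reads == 0:
        raise ValueError("no barcode reads")
    if meta.frac_human_of_mnc is None or meta.frac_gfp_of_human is None:
        raise ValueError(f"sample {meta.sample_id}: missing FACS fraction")
    scale = 100.0 * meta.frac_human_of_mnc * meta.frac_gfp_of_human
    total = counts.total_reads
    items = sorted(counts.counts.items())
    ser = pd.Series(
        {bc: scale * c / total for bc, c in items},
        name=meta.sample_id,
        dtype=float,
    )
    return ser


def abundance_matrix(
    tables: Sequence[BarcodeCountTable],
    metas: Mapping[str, SampleMeta] | Sequence[SampleMeta],
) -> pd.DataFrame:
    """Stack per-sample abundances into a samples x clones matrix (% of MNC).

    Clones absent from a sample get abundance 0.
    """
    if not isinstance(metas, Mapping):
        metas = {m.sample_id: m for m in metas}
    rows = []
    for t in tables:
        if t.sample_id not in metas:
            raise ValueError(f"no metadata for sample {t.sample_id}")
        rows.append(compute_clonal_abundance(t, metas[t.sample_id]))
    df = pd.DataFrame(rows).fillna(0.0)
    df.index.name = "sample_id"
    return df.reindex(columns=sorted(df.columns))


def filter_clones(matrix: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Apply the detection threshold (default 0.01% of MNC, strict >).

    Entries at or below the threshold are zeroed per sample; clones that end
    up zero in every sample are dropped.  Idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if (matrix.values < 0).any():
        raise ValueError("abundance matrix contains negative values")
    out = matrix.where(matrix > threshold, 0.0)
    keep = out.columns[(out > 0).any(axis=0)]
    return out[keep]
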