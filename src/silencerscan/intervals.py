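"""Genomic-interval data model, set operations and BED-dialect I/O.

All coordinates are 0-based half-open (BED convention): an interval covers
bases ``start .. end-1``. This single convention is used by every module in
the package; readers and writers below do no coordinate shifting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "TssRecord",
    "merge",
    "subtract_any_overlap",
    "overlap_counts",
    "overlapping_mask",
    "promoter_windows",
    "read_bed",
    "write_bed",
    "read_tss_table",
    "write_tss_table",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site. Strand must be + or - (promoter windows
    are strand-aware, so an unstranded TSS is rejected at window time)."""

    gene_id: str
    chrom: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"TSS {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )


class IntervalSet:
    """A named, sorted, deduplicated collection of :class:`GenomicInterval`.

    Sorted by (chrom, start, end) after any construction or operation;
    identical records are collapsed to one.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
        cell_type: Optional[str] = None,
    ) -> None:
        seen = dict.fromkeys(intervals)  # dedupe, order-stable
        self.intervals: list[GenomicInterval] = sorted(seen, key=GenomicInterval.sort_key)
        self.label = label
        self.cell_type = cell_type
        self._by_chrom: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({self.label!r}, n={len(self)})"

    @property
    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def total_bp(self) -> int:
        """Number of distinct covered bases (overlaps counted once)."""
        return sum(len(iv) for iv in merge(self))

    def arrays_by_chrom(self) -> Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, indices) arrays, cached.

        ``indices`` point back into :attr:`intervals`; starts are sorted.
        """
        if self._by_chrom is None:
            by: dict[str, list[list[int]]] = {}
            for i, iv in enumerate(self.intervals):
                by.setdefault(iv.chrom, [[], [], []])
                by[iv.chrom][0].append(iv.start)
                by[iv.chrom][1].append(iv.end)
                by[iv.chrom][2].append(i)
            self._by_chrom = {
                c: (np.asarray(s), np.asarray(e), np.asarray(ix))
                for c, (s, e, ix) in by.items()
            }
        return self._by_chrom

    def with_label(self, label: str, cell_type: Optional[str] = None) -> "IntervalSet":
        return IntervalSet(self.intervals, label=label, cell_type=cell_type)


def _warn_if_no_shared_chroms(a: IntervalSet, b: IntervalSet) -> None:
    if len(a) and len(b) and not (a.chroms & b.chroms):
        warnings.warn(
            "interval sets share no chromosome names "
            f"({sorted(a.chroms)[:3]} vs {sorted(b.chroms)[:3]}); "
            "possible 'chr' prefix mismatch",
            stacklevel=3,
        )


def merge(a: IntervalSet, merge_bookended: bool = True) -> IntervalSet:
    """Collapse overlapping intervals into their union.

    With ``merge_bookended`` (default), touching intervals (end == start)
    are also joined, mirroring common peak-merging behaviour. Name/score/
    strand metadata is dropped on merged records.
    """
    out: list[GenomicInterval] = []
    cur = None
    for iv in a:
        if cur is None or iv.chrom != cur[0] or iv.start > cur[2] or (
            iv.start == cur[2] and not merge_bookended
        ):
            if cur is not None:
                out.append(GenomicInterval(*cur))
            cur = [iv.chrom, iv.start, iv.end]
        else:
            cur[2] = max(cur[2], iv.end)
    if cur is not None:
        out.append(GenomicInterval(*cur))
    return IntervalSet(out, label=a.label, cell_type=a.cell_type)


def overlapping_mask(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> np.ndarray:
    """Boolean array over records of ``a``: True where the record shares
    >= min_bp bases with at least one record of ``b``."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    _warn_if_no_shared_chroms(a, b)
    mask = np.zeros(len(a), dtype=bool)
    b_by = b.arrays_by_chrom()
    for chrom, (a_starts, a_ends, a_idx) in a.arrays_by_chrom().items():
        if chrom not in b_by:
            continue
        b_starts, b_ends, _ = b_by[chrom]
        for s, e, i in zip(a_starts, a_ends, a_idx):
            hi = np.searchsorted(b_starts, e - min_bp, side="right")
            if hi == 0:
                continue
            ov = np.minimum(b_ends[:hi], e) - np.maximum(b_starts[:hi], s)
            if (ov >= min_bp).any():
                mask[i] = True
    return mask


def subtract_any_overlap(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> IntervalSet:
    """Whole-record subtraction: return the records of ``a`` having fewer
    than ``min_bp`` overlapping bases with every record of ``b``.

    Records are returned whole, never clipped: a single shared base (at the
    default min_bp=1) removes the entire record.
    """
    keep = ~overlapping_mask(a, b, min_bp=min_bp)
    return IntervalSet(
        [iv for iv, k in zip(a.intervals, keep) if k],
        label=a.label,
        cell_type=a.cell_type,
    )


def overlap_counts(a: IntervalSet, b: IntervalSet) -> pd.DataFrame:
    """Per-record overlap summary of ``a`` against ``b``.

    Returns a DataFrame with one row per record of ``a``:
    chrom, start, end, name, n_overlaps (count of b records sharing >= 1 bp)
    and overlap_bp (total shared bases, summed over those b records).
    """
    _warn_if_no_shared_chroms(a, b)
    n = np.zeros(len(a), dtype=int)
    bp = np.zeros(len(a), dtype=int)
    b_by = b.arrays_by_chrom()
    for chrom, (a_starts, a_ends, a_idx) in a.arrays_by_chrom().items():
        if chrom not in b_by:
            continue
        b_starts, b_ends, _ = b_by[chrom]
        for s, e, i in zip(a_starts, a_ends, a_idx):
            hi = np.searchsorted(b_starts, e, side="left")
            if hi == 0:
                continue
            ov = np.minimum(b_ends[:hi], e) - np.maximum(b_starts[:hi], s)
            ov = ov[ov > 0]
            n[i] = ov.size
            bp[i] = int(ov.sum())
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in a],
            "start": [iv.start for iv in a],
            "end": [iv.end for iv in a],
            "name": [iv.name for iv in a],
            "n_overlaps": n,
            "overlap_bp": bp,
        }
    )


def promoter_windows(
    tss: Sequence[TssRecord], upstream: int = 2000, downstream: int = 500
) -> IntervalSet:
    """Strand-aware promoter windows around TSS, clipped at the origin.

    + strand TSS at p -> [p-upstream, p+downstream); - strand mirrored.
    The default -2000/+500 window treats the region just downstream of the
    TSS as part of the promoter.
    """
    out = []
    for t in tss:
        if t.strand == "+":
            s, e = t.position - upstream, t.position + downstream
        else:
            s, e = t.position - downstream, t.position + upstream
        out.append(GenomicInterval(t.chrom, max(0, s), e, strand=t.strand, name=t.gene_id))
    return IntervalSet(out, label="promoter_windows")


# ---------------------------------------------------------------------------
# I/O: BED3/BED6 (narrowPeak/broadPeak accepted via their leading columns),
# TSS tables as tab-separated (gene_id, chrom, position, strand).

def read_bed(path, label: str = "", cell_type: Optional[str] = None) -> IntervalSet:
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}, skip_blank_lines=True
    )
    ivs = []
    ncol = df.shape[1]
    for row in df.itertuples(index=False):
        name = None
        if ncol > 3 and not pd.isna(row[3]) and str(row[3]) != ".":
            name = str(row[3])
        score = None
        if ncol > 4 and not pd.isna(row[4]) and str(row[4]) != ".":
            score = float(row[4])
        strand = str(row[5]) if ncol > 5 and str(row[5]) in _STRANDS else "."
        ivs.append(
            GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand, name, score)
        )
    return IntervalSet(ivs, label=label or path.stem, cell_type=cell_type)


def write_bed(a: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in a:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [
                    iv.name if iv.name is not None else ".",
                    f"{iv.score:g}" if iv.score is not None else ".",
                    iv.strand,
                ]
            fh.write("\t".join(fields) + "\n")


def read_tss_table(path) -> list[TssRecord]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["gene_id", "chrom", "position", "strand"],
        dtype={"gene_id": str, "chrom": str},
    )
    return [
        TssRecord(r.gene_id, r.chrom, int(r.position), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def write_tss_table(tss: Sequence[TssRecord], path) -> None:
    with open(path, "w") as fh:
        for t in tss:
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.position}\t{t.strand}\n")
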