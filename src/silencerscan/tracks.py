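"""Base-resolution value tracks and track-based element characterization.

Per-element averaging over methylation (per-cytosine fractions from WGBS)
and conservation (phastCons-style per-base probabilities) tracks, active
enhancer calling (DHS + H3K4me1 + H3K27ac), silencer-to-enhancer
switching across cell types, digital-footprint density, and a simplified
priority-based genomic-context annotator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chic import compare_expression_wilcoxon
from .intervals import (
    GenomicInterval,
    IntervalSet,
    TssRecord,
    merge,
    overlap_counts,
    overlapping_mask,
    promoter_windows,
)

__all__ = [
    "ValueTrack",
    "GeneModel",
    "mean_track_value",
    "call_active_enhancers",
    "enhancer_switch_matrix",
    "footprints_per_element",
    "compare_footprint_groups",
    "annotate_genomic_context",
    "read_bedgraph",
    "write_bedgraph",
]

log = logging.getLogger(__name__)


class ValueTrack:
    """A per-base value track stored as (chrom, start, end, value) runs.

    ``dense`` tracks (phastCons convention) treat positions absent from
    the track as 0, so element means divide by element length; ``sparse``
    tracks (per-cytosine methylation) divide by covered bases only, and an
    element covering no track position has an undefined mean.
    """

    def __init__(self, df: pd.DataFrame, dense: bool = False, label: str = "") -> None:
        required = {"chrom", "start", "end", "value"}
        if not required <= set(df.columns):
            raise ValueError(f"value track needs columns {sorted(required)}")
        df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        if (df["end"] <= df["start"]).any():
            raise ValueError("track runs must have end > start")
        self.df = df
        self.dense = dense
        self.label = label
        self._by_chrom = {
            str(c): (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
            for c, g in df.groupby("chrom")
        }

    def __len__(self) -> int:
        return len(self.df)


def mean_track_value(elements: IntervalSet, track: ValueTrack) -> pd.Series:
    """Unweighted per-base mean of the track inside each element.

    Every covered base counts once with its run's value. Sparse tracks:
    elements with zero covered positions get NaN (count logged). Dense
    tracks: uncovered bases count as 0 and the divisor is element length.
    """
    names = [iv.name if iv.name is not None else f"el{i}" for i, iv in enumerate(elements)]
    out = np.full(len(elements), np.nan)
    for i, iv in enumerate(elements):
        if iv.chrom not in track._by_chrom:
            if track.dense:
                out[i] = 0.0
            continue
        s_arr, e_arr, v_arr = track._by_chrom[iv.chrom]
        hi = np.searchsorted(s_arr, iv.end, side="left")
        ov = np.minimum(e_arr[:hi], iv.end) - np.maximum(s_arr[:hi], iv.start)
        m = ov > 0
        covered = int(ov[m].sum())
        weighted = float((ov[m] * v_arr[:hi][m]).sum())
        if track.dense:
            out[i] = weighted / len(iv)
        elif covered > 0:
            out[i] = weighted / covered
    n_undef = int(np.isnan(out).sum())
    if n_undef:
        log.info("mean_track_value: %d elements with undefined mean", n_undef)
    return pd.Series(out, index=names)


def call_active_enhancers(
    dhs: IntervalSet, h3k4me1: IntervalSet, h3k27ac: IntervalSet
) -> IntervalSet:
    """Active enhancers: DHS records overlapping (>= 1 bp) both H3K4me1
    and H3K27ac, returned whole."""
    for nm, trk in (("dhs", dhs), ("h3k4me1", h3k4me1), ("h3k27ac", h3k27ac)):
        if trk is None:
            raise ValueError(f"missing track: {nm}")
    keep = overlapping_mask(dhs, h3k4me1) & overlapping_mask(dhs, h3k27ac)
    return IntervalSet(
        [iv for iv, k in zip(dhs.intervals, keep) if k],
        label=f"active_enhancers_{dhs.cell_type or ''}".rstrip("_"),
        cell_type=dhs.cell_type,
    )


def enhancer_switch_matrix(
    silencers_by_cell: Mapping[str, IntervalSet],
    enhancers_by_cell: Mapping[str, IntervalSet],
) -> tuple[pd.Series, float]:
    """Fraction of each cell type's silencers that act as active enhancers
    in at least one *other* cell type, plus the aggregate fraction over
    all distinct silencer records.
    """
    cells = list(silencers_by_cell)
    if len(cells) < 2:
        raise ValueError("need >= 2 cell types")
    per_cell = {}
    switching: set[tuple] = set()
    all_sil: set[tuple] = set()
    for c in cells:
        sil = silencers_by_cell[c]
        others = [
            iv for c2, enh in enhancers_by_cell.items() if c2 != c for iv in enh
        ]
        union = merge(IntervalSet(others))
        mask = overlapping_mask(sil, union) if len(sil) and len(union) else np.zeros(len(sil), bool)
        per_cell[c] = float(mask.sum()) / len(sil) if len(sil) else np.nan
        for iv, m in zip(sil, mask):
            key = (iv.chrom, iv.start, iv.end)
            all_sil.add(key)
            if m:
                switching.add(key)
    aggregate = len(switching) / len(all_sil) if all_sil else float("nan")
    return pd.Series(per_cell), aggregate


def footprints_per_element(elements: IntervalSet, dgf: IntervalSet) -> pd.Series:
    """Number of digital genomic footprints overlapping each element."""
    counts = overlap_counts(elements, dgf)["n_overlaps"]
    names = [iv.name if iv.name is not None else f"el{i}" for i, iv in enumerate(elements)]
    return pd.Series(counts.values, index=names)


def compare_footprint_groups(
    elements_a: IntervalSet, elements_b: IntervalSet, dgf: IntervalSet
) -> dict:
    """One-tailed comparison of footprint density (alternative: group a
    carries fewer footprints per element than group b)."""
    ca = footprints_per_element(elements_a, dgf)
    cb = footprints_per_element(elements_b, dgf)
    p = compare_expression_wilcoxon(ca.values, cb.values)
    return {
        "counts_a": ca, "counts_b": cb,
        "mean_a": float(ca.mean()), "mean_b": float(cb.mean()),
        "p_value": p,
    }


@dataclass
class GeneModel:
    """Gene annotation for the simplified genomic-context annotator."""

    tss: Sequence[TssRecord]
    exons: IntervalSet
    gene_bodies: IntervalSet


def annotate_genomic_context(
    elements: IntervalSet,
    gene_model: GeneModel,
    repeats: Optional[IntervalSet] = None,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> pd.Series:
    """One category per element by highest-priority >= 1 bp overlap:
    promoter (-2000/+500 TSS window) > exon > intron (gene body that is
    not exon) > repeat (if provided) > intergenic.

    This is a deliberately simplified priority annotator; it does not
    replicate any particular annotation suite's precedence bit-for-bit.
    """
    prom = promoter_windows(gene_model.tss, promoter_upstream, promoter_downstream)
    layers = [
        ("promoter", overlapping_mask(elements, prom) if len(prom) else None),
        ("exon", overlapping_mask(elements, gene_model.exons) if len(gene_model.exons) else None),
        ("intron", overlapping_mask(elements, gene_model.gene_bodies) if len(gene_model.gene_bodies) else None),
    ]
    if repeats is not None and len(repeats):
        layers.append(("repeat", overlapping_mask(elements, repeats)))
    cats = np.array(["intergenic"] * len(elements), dtype=object)
    unassigned = np.ones(len(elements), dtype=bool)
    for name, mask in layers:
        if mask is None:
            continue
        hit = unassigned & mask
        cats[hit] = name
        unassigned &= ~mask
    names = [iv.name if iv.name is not None else f"el{i}" for i, iv in enumerate(elements)]
    return pd.Series(cats, index=names)


# ---------------------------------------------------------------------------
# bedGraph I/O (chrom, start, end, value)

def read_bedgraph(path, dense: bool = False, label: str = "") -> ValueTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    return ValueTrack(df, dense=dense, label=label)


def write_bedgraph(track: ValueTrack, path) -> None:
    track.df.to_csv(path, sep="\t", header=False, index=False,
                    columns=["chrom", "start", "end", "value"])
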