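"""Simple subtractive analysis (SSA): uncharacterized-CRE calling.

Open chromatin (DHS peaks) is filtered against tracks with known regulatory
identity — enhancers (H3K4me1 peaks), promoters (H3K4me3 peaks plus
strand-aware -2000/+500 TSS windows) and candidate insulators (CTCF sites,
pooled across cell types) — in a cell-type-specific manner. DHS records
left untouched by every subtraction track are "uncharacterized CREs", the
candidate pool expected to contain silencer elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .intervals import (
    IntervalSet,
    TssRecord,
    merge,
    overlapping_mask,
    promoter_windows,
    subtract_any_overlap,
)

__all__ = ["CellTypeTracks", "call_uncharacterized_cres", "repressor_overlap_fraction"]


@dataclass
class CellTypeTracks:
    """Input tracks for one cell type. ``ctcf_pooled`` is shared across cell
    types (insulator sites are largely cell-type invariant)."""

    cell_type: str
    dhs: IntervalSet
    h3k4me1: IntervalSet
    h3k4me3: IntervalSet
    ctcf_pooled: IntervalSet
    tss: Sequence[TssRecord]


def call_uncharacterized_cres(
    tracks: CellTypeTracks,
    min_bp: int = 1,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> IntervalSet:
    """DHS records with zero (< min_bp) overlap with every subtraction track.

    Subtraction is whole-record: any overlapping DHS peak is discarded in
    full. The output is order-invariant in the subtraction tracks and is
    labeled with the cell type.
    """
    for attr in ("dhs", "h3k4me1", "h3k4me3", "ctcf_pooled"):
        if getattr(tracks, attr) is None:
            raise ValueError(f"missing required track: {attr}")
    if tracks.tss is None:
        raise ValueError("missing required track: tss")
    if len(tracks.dhs) == 0:
        raise ValueError("dhs track is empty")
    if len(tracks.tss) == 0:
        warnings.warn("tss table is empty; no TSS promoter windows subtracted")

    out = tracks.dhs
    subtraction = [
        tracks.h3k4me1,
        tracks.h3k4me3,
        promoter_windows(tracks.tss, promoter_upstream, promoter_downstream),
        tracks.ctcf_pooled,
    ]
    for trk in subtraction:
        out = subtract_any_overlap(out, trk, min_bp=min_bp)
    return out.with_label(f"ucre_{tracks.cell_type}", cell_type=tracks.cell_type)


def repressor_overlap_fraction(
    ucres: IntervalSet, tfbs_tracks: Mapping[str, IntervalSet]
) -> tuple[float, dict[str, int]]:
    """Fraction of uncharacterized CREs overlapping >= 1 known repressor
    binding site, with per-factor overlap counts.

    The fraction is computed against the union of all provided TFBS tracks
    (an element bound by any of the factors counts once).
    """
    if len(ucres) == 0:
        raise ValueError("ucres is empty")
    if not tfbs_tracks:
        raise ValueError("tfbs_tracks mapping is empty")
    per_factor = {
        factor: int(overlapping_mask(ucres, trk).sum())
        for factor, trk in tfbs_tracks.items()
    }
    union = merge(
        IntervalSet([iv for trk in tfbs_tracks.values() for iv in trk], label="tfbs_union")
    )
    frac = float(overlapping_mask(ucres, union).sum()) / len(ucres)
    return frac, per_factor
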