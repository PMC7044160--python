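"""Promoter-capture Hi-C target assignment and expression analysis.

Candidate silencer elements are linked to genes by overlapping them with
the "other end" (promoter-interacting) fragments of significant bait/
other-end interactions, keeping only interactions separated by >= 10 kb
(removing close-proximity ligation noise). Target-gene expression is then
binned (RPKM 0, (0,2], (2,10], >10) and compared between silencer- and
enhancer-contacted genes with a one-tailed Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations as _combinations
from math import comb, erf, sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .intervals import GenomicInterval, IntervalSet, TssRecord
from .enrich import Segmentation, _assign_states

__all__ = [
    "ChicInteraction",
    "DEFAULT_BINS",
    "assign_targets",
    "bin_by_expression",
    "compare_expression_wilcoxon",
    "tss_state_by_expression",
    "read_interactions",
    "read_expression_table",
]

log = logging.getLogger(__name__)

#: Right edges of the expression bins above the dedicated RPKM=0 bin.
DEFAULT_BINS = (2.0, 10.0, float("inf"))


@dataclass(frozen=True)
class ChicInteraction:
    """A bait (captured promoter fragment) / other-end fragment pair."""

    bait: GenomicInterval
    bait_genes: tuple[str, ...]
    other_end: GenomicInterval
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.bait_genes:
            raise ValueError("bait_genes must be non-empty")

    def gap(self) -> float:
        """Edge-to-edge distance between bait and other end; 0 when the
        fragments overlap or touch, +inf for trans (inter-chromosomal)."""
        if self.bait.chrom != self.other_end.chrom:
            return float("inf")
        if self.other_end.start >= self.bait.end:
            return self.other_end.start - self.bait.end
        if self.bait.start >= self.other_end.end:
            return self.bait.start - self.other_end.end
        return 0.0


def assign_targets(
    elements: IntervalSet,
    interactions: Sequence[ChicInteraction],
    min_dist: int = 10_000,
) -> pd.DataFrame:
    """Pair elements with the genes whose promoter interactions they sit in.

    Interactions with bait/other-end edge-to-edge gap < min_dist are
    dropped; each element overlapping (>= 1 bp) a retained interaction's
    other end is paired with every bait gene of that interaction.
    Many-to-many pairs are preserved.

    Returns a DataFrame (element_name, element_chrom, element_start,
    element_end, gene_id, gap); lowering min_dist only adds rows.
    """
    retained = [ia for ia in interactions if ia.gap() >= min_dist]
    log.info(
        "assign_targets: %d of %d interactions pass the %d bp distance filter",
        len(retained), len(interactions), min_dist,
    )
    rows = []
    if retained:
        oe_set = IntervalSet(
            [ia.other_end for ia in retained], label="other_ends"
        )
        # map coordinates back to interactions (dedupe in IntervalSet may
        # collapse identical fragments shared by several interactions)
        by_coord: dict[tuple, list[ChicInteraction]] = {}
        for ia in retained:
            by_coord.setdefault(
                (ia.other_end.chrom, ia.other_end.start, ia.other_end.end), []
            ).append(ia)
        for el in elements:
            for oe_key, ias in by_coord.items():
                chrom, s, e = oe_key
                if chrom == el.chrom and s < el.end and e > el.start:
                    for ia in ias:
                        for gene in ia.bait_genes:
                            rows.append(
                                (el.name, el.chrom, el.start, el.end, gene, ia.gap())
                            )
    return pd.DataFrame(
        rows,
        columns=["element_name", "element_chrom", "element_start", "element_end",
                 "gene_id", "gap"],
    )


def _bin_label(rpkm: float, bins: Sequence[float]) -> str:
    if np.isnan(rpkm):
        return "NA"
    if rpkm == 0:
        return "0"
    lo = 0.0
    for hi in bins:
        if rpkm <= hi:
            return f"({lo:g},{hi:g}]" if np.isfinite(hi) else f"({lo:g},inf)"
        lo = hi
    return "NA"


def bin_by_expression(
    pairs: pd.DataFrame, expr: pd.Series, bins: Sequence[float] = DEFAULT_BINS
) -> pd.DataFrame:
    """Count distinct genes and distinct elements per expression bin.

    The first bin is the point mass RPKM = 0 (transcriptionally inactive
    genes); the remaining bins are right-closed intervals with the given
    upper edges, default (0,2], (2,10], (10,inf). Genes absent from the
    expression table fall into an "NA" bin (logged).
    """
    bins = list(bins)
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])) or any(b <= 0 for b in bins):
        raise ValueError("bin edges must be positive and strictly increasing")
    df = pairs.copy()
    df["rpkm"] = expr.reindex(df["gene_id"]).values
    n_missing = df["rpkm"].isna().sum()
    if n_missing:
        log.info("bin_by_expression: %d pairs with genes missing from expression", n_missing)
    df["bin"] = [_bin_label(v, bins) for v in df["rpkm"]]
    labels = ["0"]
    lo = 0.0
    for hi in bins:
        labels.append(f"({lo:g},{hi:g}]" if np.isfinite(hi) else f"({lo:g},inf)")
        lo = hi
    if n_missing:
        labels.append("NA")
    out = []
    for lab in labels:
        sub = df[df["bin"] == lab]
        out.append((lab, sub["gene_id"].nunique(), sub["element_name"].nunique()))
    return pd.DataFrame(out, columns=["bin", "n_genes", "n_elements"]).set_index("bin")


def compare_expression_wilcoxon(group_a, group_b) -> float:
    """One-tailed Wilcoxon rank-sum P for the alternative "a < b".

    Uses midranks for ties; exact enumeration of all C(n, n_a) rank
    assignments when n_a + n_b <= 12, otherwise the normal approximation
    with tie-corrected variance and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na, nb = pooled.size, a.size, b.size
    ranks = rankdata(pooled)
    r_a = float(ranks[:na].sum())

    if n <= 12:
        count = 0
        total = comb(n, na)
        for idx in _combinations(range(n), na):
            if ranks[list(idx)].sum() <= r_a + 1e-9:
                count += 1
        return count / total

    mu = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 0.5
    z = (r_a + 0.5 - mu) / sqrt(var)
    return 0.5 * (1 + erf(z / sqrt(2)))


def tss_state_by_expression(
    pairs: pd.DataFrame,
    expr: pd.Series,
    tss: Sequence[TssRecord],
    seg: Segmentation,
    bins: Sequence[float] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Chromatin state of target-gene TSS per expression bin.

    Each paired gene's TSS (a 1-bp point) is assigned the segmentation
    state whose half-open interval contains it; per-bin fractions sum to 1
    over genes with an assigned state. Genes lacking a TSS record are
    assigned "NA" (logged).
    """
    tss_by_gene = {t.gene_id: t for t in tss}
    genes = pairs["gene_id"].drop_duplicates()
    records, kept_genes = [], []
    n_missing = 0
    for g in genes:
        t = tss_by_gene.get(g)
        if t is None:
            n_missing += 1
            continue
        records.append(GenomicInterval(t.chrom, t.position, t.position + 1, name=g))
        kept_genes.append(g)
    if n_missing:
        log.info("tss_state_by_expression: %d genes lack a TSS record", n_missing)
    # IntervalSet sorts records; recover gene order via names
    ivset = IntervalSet(records)
    name_to_state = {
        iv.name: st for iv, st in zip(ivset, _assign_states(ivset, seg))
    }
    df = pd.DataFrame({"gene_id": kept_genes})
    df["state"] = [name_to_state[g] for g in kept_genes]
    df["rpkm"] = expr.reindex(df["gene_id"]).values
    df["bin"] = [_bin_label(v, list(bins)) for v in df["rpkm"]]
    df = df[df["state"] != "NA"]
    out = (
        df.groupby(["bin", "state"]).size().unstack(fill_value=0)
    )
    return out.div(out.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# I/O: interactions as tab-separated (bait_chrom, bait_start, bait_end,
# bait_genes semicolon-joined, oe_chrom, oe_start, oe_end, score);
# expression as (gene_id, RPKM).

def read_interactions(path) -> list[ChicInteraction]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["bait_chrom", "bait_start", "bait_end", "bait_genes",
               "oe_chrom", "oe_start", "oe_end", "score"],
        dtype={"bait_chrom": str, "oe_chrom": str, "bait_genes": str},
    )
    out = []
    for r in df.itertuples(index=False):
        out.append(
            ChicInteraction(
                bait=GenomicInterval(r.bait_chrom, int(r.bait_start), int(r.bait_end)),
                bait_genes=tuple(str(r.bait_genes).split(";")),
                other_end=GenomicInterval(r.oe_chrom, int(r.oe_start), int(r.oe_end)),
                score=None if pd.isna(r.score) else float(r.score),
            )
        )
    return out


def write_interactions(interactions: Sequence[ChicInteraction], path) -> None:
    with open(path, "w") as fh:
        for ia in interactions:
            fh.write(
                "\t".join(
                    [
                        ia.bait.chrom, str(ia.bait.start), str(ia.bait.end),
                        ";".join(ia.bait_genes),
                        ia.other_end.chrom, str(ia.other_end.start), str(ia.other_end.end),
                        "" if ia.score is None else f"{ia.score:g}",
                    ]
                )
                + "\n"
            )


def read_expression_table(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "rpkm"],
                     dtype={"gene_id": str})
    if (df["rpkm"] < 0).any():
        raise ValueError("RPKM values must be non-negative")
    return df.set_index("gene_id")["rpkm"]
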