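"""Enrichment statistics for candidate silencer elements.

Covers the permutation overlap test (empirical P = (sum_n + 1)/(N + 1)
with N random draws of matched element counts from a universe),
hypergeometric GWAS-trait enrichment with LD-proxy expansion, binomial
motif-hit enrichment, and chromHMM state distributions with a permuted
random baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, overlapping_mask
from .mpra import bh_adjust

__all__ = [
    "CORE15_STATES",
    "PermutationResult",
    "Segmentation",
    "permutation_overlap_test",
    "expand_ld",
    "hypergeom_trait_enrichment",
    "binomial_overlap_enrichment",
    "chromhmm_distribution",
    "snps_to_intervals",
    "read_snp_catalog",
    "read_proxy_table",
    "read_segmentation",
]

log = logging.getLogger(__name__)

#: Canonical ordering of the core 15-state chromatin model mnemonics.
#: Used for deterministic tie-breaking in per-element state assignment.
CORE15_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)


@dataclass
class PermutationResult:
    """Outcome of the permutation overlap test.

    p = (sum_n + 1) / (N + 1), where sum_n counts permutations whose null
    overlap strictly exceeds the observed overlap; the +1 terms make the
    estimate valid and floor it at 1/(N+1).
    """

    observed_overlap: int
    null_overlaps: np.ndarray
    N: int

    @property
    def sum_n(self) -> int:
        return int((self.null_overlaps > self.observed_overlap).sum())

    @property
    def p(self) -> float:
        return (self.sum_n + 1) / (self.N + 1)


def permutation_overlap_test(
    target: IntervalSet,
    universe: IntervalSet,
    features: IntervalSet,
    N: int = 10_000,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Is the overlap of ``target`` with ``features`` higher than expected
    for |target| records drawn at random from ``universe``?

    observed = number of target records overlapping >= 1 feature record;
    each permutation draws |target| universe records without replacement
    and recounts. No length or GC matching is applied to the null draws.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if len(universe) < len(target):
        raise ValueError(
            f"universe ({len(universe)}) smaller than target ({len(target)})"
        )
    observed = int(overlapping_mask(target, features).sum())
    flags = overlapping_mask(universe, features)  # per-universe-record overlap
    rng = np.random.default_rng(seed)
    k = len(target)
    null = np.empty(N, dtype=int)
    for i in range(N):
        null[i] = int(flags[rng.choice(flags.size, size=k, replace=False)].sum())
    return PermutationResult(observed_overlap=observed, null_overlaps=null, N=N)


# ---------------------------------------------------------------------------
# GWAS SNPs: LD expansion and hypergeometric trait enrichment

def expand_ld(
    leads: pd.DataFrame, proxy_table: Optional[pd.DataFrame], r2_min: float = 0.8
) -> pd.DataFrame:
    """Expand lead SNPs with their LD proxies at r^2 >= r2_min.

    ``leads`` columns: snp_id, chrom, pos, trait. ``proxy_table`` columns:
    lead_id, proxy_id, proxy_chrom, proxy_pos, r2. Proxies inherit their
    lead's trait; a proxy referencing an unknown lead is skipped with a
    warning; the result is deduplicated by (snp_id, trait). Leads carry
    r2 = 1.0 and is_lead = True.
    """
    out = leads.copy()
    out["is_lead"] = True
    out["r2"] = 1.0
    if proxy_table is not None and len(proxy_table):
        known = set(leads["snp_id"])
        unknown = set(proxy_table["lead_id"]) - known
        if unknown:
            warnings.warn(f"{len(unknown)} proxies reference unknown leads; skipped")
        pt = proxy_table[
            proxy_table["lead_id"].isin(known) & (proxy_table["r2"] >= r2_min)
        ]
        traits = leads[["snp_id", "trait"]].rename(columns={"snp_id": "lead_id"})
        px = pt.merge(traits, on="lead_id")
        px = pd.DataFrame(
            {
                "snp_id": px["proxy_id"],
                "chrom": px["proxy_chrom"],
                "pos": px["proxy_pos"],
                "trait": px["trait"],
                "is_lead": False,
                "r2": px["r2"],
            }
        )
        out = pd.concat([out, px], ignore_index=True)
    out = out.drop_duplicates(subset=["snp_id", "trait"]).reset_index(drop=True)
    return out


def snps_to_intervals(snps: pd.DataFrame, label: str = "snps") -> IntervalSet:
    """1-bp half-open records, one per distinct SNP position."""
    ivs = [
        GenomicInterval(str(r.chrom), int(r.pos), int(r.pos) + 1, name=str(r.snp_id))
        for r in snps.drop_duplicates("snp_id").itertuples(index=False)
    ]
    return IntervalSet(ivs, label=label)


def _snp_membership(snps: pd.DataFrame, elements: IntervalSet) -> pd.Series:
    """Boolean per distinct snp_id: position inside >= 1 element (point in
    half-open interval)."""
    uniq = snps.drop_duplicates("snp_id")
    pts = snps_to_intervals(uniq)
    mask = overlapping_mask(pts, elements)
    ids = [iv.name for iv in pts]
    return pd.Series(mask, index=pd.Index(ids, name="snp_id"))


def hypergeom_trait_enrichment(
    snps: pd.DataFrame,
    silencers_by_cell: Mapping[str, IntervalSet],
    alpha: float = 0.01,
    scope: str = "global",
) -> pd.DataFrame:
    """Per (cell type, trait) hypergeometric enrichment of trait SNPs
    inside that cell's silencer elements.

    With M = distinct SNPs in the catalog, K = distinct SNPs of the trait,
    n = distinct SNPs inside the cell's silencers and k = trait SNPs
    inside, p = P[X >= k] for X ~ Hypergeom(M, K, n) (the trait's SNPs
    against the rest of the catalog). BH adjustment runs across the full
    cell x trait matrix by default (scope="global") or within each cell
    (scope="per_cell"). enriched = q < alpha.
    """
    if scope not in {"global", "per_cell"}:
        raise ValueError("scope must be 'global' or 'per_cell'")
    uniq = snps.drop_duplicates("snp_id")
    M = len(uniq)
    trait_ids = snps.drop_duplicates(["snp_id", "trait"])
    rows = []
    for cell, sil in silencers_by_cell.items():
        inside = _snp_membership(snps, sil)
        n = int(inside.sum())
        for trait, grp in trait_ids.groupby("trait"):
            K = len(grp)
            if K == 0:
                warnings.warn(f"trait {trait!r} has no SNPs; skipped")
                continue
            k = int(inside.reindex(grp["snp_id"]).fillna(False).sum())
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
            rows.append((cell, trait, k, n, K, M, p))
    out = pd.DataFrame(rows, columns=["cell", "trait", "k", "n", "K", "M", "p"])
    if out.empty:
        out["q"] = out["enriched"] = []
        return out
    if scope == "global":
        out["q"] = bh_adjust(out["p"].values)
    else:
        out["q"] = np.nan
        for cell, grp in out.groupby("cell"):
            out.loc[grp.index, "q"] = bh_adjust(grp["p"].values)
    out["enriched"] = out["q"] < alpha
    return out


def binomial_overlap_enrichment(k_target: int, n_target: int, background_rate: float) -> float:
    """Upper-tail binomial P[X >= k] for X ~ Binomial(n, rate); the motif
    hit-count enrichment arithmetic."""
    if not (0 <= k_target <= n_target):
        raise ValueError("need 0 <= k <= n")
    if background_rate < 0 or background_rate > 1:
        raise ValueError("background_rate must be in [0, 1]")
    if background_rate == 0:
        return 0.0 if k_target > 0 else 1.0
    if k_target == 0:
        return 1.0
    return float(stats.binom.sf(k_target - 1, n_target, background_rate))


# ---------------------------------------------------------------------------
# chromHMM state distributions

class Segmentation(IntervalSet):
    """A chromatin-state segmentation: intervals carrying a state label in
    their ``name`` field, non-overlapping within a chromosome. The state
    ordering controls tie-breaking in per-element state assignment."""

    def __init__(self, intervals, state_order: Sequence[str] = CORE15_STATES, label="chromhmm"):
        super().__init__(intervals, label=label)
        self.state_order = list(state_order)
        for iv in self.intervals:
            if iv.name is None:
                raise ValueError("segmentation records must carry a state name")
        by = self.arrays_by_chrom()
        for chrom, (s, e, _) in by.items():
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"segmentation states overlap on {chrom}")

    def state_rank(self, state: str) -> int:
        try:
            return self.state_order.index(state)
        except ValueError:
            return len(self.state_order)


@dataclass
class ChromhmmDistribution:
    fractions: pd.Series          # per-state fraction over assigned elements
    assignments: pd.Series        # per-element state ("NA" when uncovered)
    n_na: int
    baseline_fractions: Optional[pd.Series] = None  # mean over B random draws


def _assign_states(elements: IntervalSet, seg: Segmentation) -> list[str]:
    """Per element, the state with maximal overlapping bp (ties -> state
    earlier in the canonical ordering); "NA" when no state covers it."""
    seg_by = seg.arrays_by_chrom()
    out = []
    for iv in elements:
        if iv.chrom not in seg_by:
            out.append("NA")
            continue
        s_arr, e_arr, idx = seg_by[iv.chrom]
        hi = np.searchsorted(s_arr, iv.end, side="left")
        best_state, best_bp = "NA", 0
        for j in range(hi):
            ov = min(e_arr[j], iv.end) - max(s_arr[j], iv.start)
            if ov <= 0:
                continue
            state = seg.intervals[idx[j]].name
            if ov > best_bp or (
                ov == best_bp and seg.state_rank(state) < seg.state_rank(best_state)
            ):
                best_state, best_bp = state, ov
        out.append(best_state)
    return out


def chromhmm_distribution(
    elements: IntervalSet,
    seg: Segmentation,
    baseline_universe: Optional[IntervalSet] = None,
    B: int = 1000,
    seed: Optional[int] = None,
) -> ChromhmmDistribution:
    """Chromatin-state composition of a set of elements.

    Each element is assigned the state covering most of its bases;
    fractions are over assigned elements and sum to 1 (elements with no
    covering state are reported separately as "NA"). If a baseline
    universe is given, B random draws of |elements| records yield mean
    baseline fractions for comparison.
    """
    if len(seg) == 0:
        raise ValueError("segmentation is empty")
    states = _assign_states(elements, seg)
    ser = pd.Series(states, index=[iv.name or i for i, iv in enumerate(elements)])
    n_na = int((ser == "NA").sum())
    if n_na:
        log.info("chromhmm_distribution: %d elements uncovered (NA)", n_na)
    assigned = ser[ser != "NA"]
    fractions = assigned.value_counts(normalize=True).sort_index()

    baseline = None
    if baseline_universe is not None:
        if len(baseline_universe) < len(elements):
            raise ValueError("baseline universe smaller than element set")
        uni_states = np.array(_assign_states(baseline_universe, seg))
        rng = np.random.default_rng(seed)
        acc: dict[str, float] = {}
        k = len(elements)
        for _ in range(B):
            draw = uni_states[rng.choice(uni_states.size, size=k, replace=False)]
            sub = pd.Series(draw)
            sub = sub[sub != "NA"]
            fr = sub.value_counts(normalize=True)
            for st, v in fr.items():
                acc[st] = acc.get(st, 0.0) + v / B
        baseline = pd.Series(acc).sort_index()
    return ChromhmmDistribution(
        fractions=fractions, assignments=ser, n_na=n_na, baseline_fractions=baseline
    )


# ---------------------------------------------------------------------------
# I/O

def read_snp_catalog(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["snp_id", "chrom", "pos", "trait"],
        dtype={"snp_id": str, "chrom": str, "trait": str},
    )


def read_proxy_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["lead_id", "proxy_id", "proxy_chrom", "proxy_pos", "r2"],
        dtype={"lead_id": str, "proxy_id": str, "proxy_chrom": str},
    )


def read_segmentation(path, state_order: Sequence[str] = CORE15_STATES) -> Segmentation:
    from .intervals import read_bed

    bed = read_bed(path)
    return Segmentation(bed.intervals, state_order=state_order)
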