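"""MPRA/STARR-seq activity quantification, silencer calling and qPCR utilities.

Activity of a tested element is its library-size-normalized RNA/plasmid
ratio, averaged over biological replicates and divided by the mean ratio of
the control-random regions, so that control-random activity is 1 by
construction. Elements with activity (fold change) < 1 and one-tailed
Benjamini-Hochberg-adjusted P < 0.05 against the pooled control ratios are
called silencers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "MpraCountTable",
    "CtTable",
    "filter_by_replicates",
    "compute_activity",
    "bh_adjust",
    "call_silencers",
    "delta_delta_ct",
    "read_count_table",
    "write_activity_table",
]

log = logging.getLogger(__name__)

CATEGORIES = ("tested", "control_random", "control_enhancer", "control_silencer")


@dataclass
class MpraCountTable:
    """Per-element, per-replicate RNA and plasmid counts.

    ``rna`` and ``plasmid`` are element x replicate DataFrames with identical
    index (element ids) and columns (replicate labels); ``categories`` maps
    each element to one of :data:`CATEGORIES`. Library sizes default to the
    column sums of the full table and are carried through filtering
    unchanged (normalization is by the sequencing library totals, not by
    the totals of whatever subset survives a filter).
    """

    rna: pd.DataFrame
    plasmid: pd.DataFrame
    categories: pd.Series
    rna_lib_sizes: Optional[pd.Series] = None
    plasmid_lib_sizes: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not self.rna.index.equals(self.plasmid.index):
            raise ValueError("RNA and plasmid tables must share element index")
        if not self.rna.columns.equals(self.plasmid.columns):
            raise ValueError("RNA and plasmid tables must share replicate columns")
        if (self.rna.values < 0).any() or (self.plasmid.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.categories = self.categories.reindex(self.rna.index)
        bad = set(self.categories.dropna()) - set(CATEGORIES)
        if bad or self.categories.isna().any():
            raise ValueError(f"invalid or missing element categories: {sorted(bad)}")
        if (self.categories == "control_random").sum() < 1:
            raise ValueError("at least one control_random element is required")
        if self.rna_lib_sizes is None:
            self.rna_lib_sizes = self.rna.sum(axis=0).astype(float)
        if self.plasmid_lib_sizes is None:
            self.plasmid_lib_sizes = self.plasmid.sum(axis=0).astype(float)

    @property
    def n_replicates(self) -> int:
        return self.rna.shape[1]

    @property
    def element_ids(self) -> pd.Index:
        return self.rna.index

    def subset(self, ids) -> "MpraCountTable":
        return MpraCountTable(
            rna=self.rna.loc[ids],
            plasmid=self.plasmid.loc[ids],
            categories=self.categories.loc[ids],
            rna_lib_sizes=self.rna_lib_sizes,
            plasmid_lib_sizes=self.plasmid_lib_sizes,
        )


def filter_by_replicates(t: MpraCountTable, min_reps: int = 3) -> MpraCountTable:
    """Keep elements detected (count > 0) in >= min_reps replicates in both
    the RNA and the plasmid library."""
    if min_reps > t.n_replicates:
        raise ValueError(
            f"min_reps={min_reps} exceeds replicate dimension {t.n_replicates}"
        )
    ok = ((t.rna > 0).sum(axis=1) >= min_reps) & ((t.plasmid > 0).sum(axis=1) >= min_reps)
    dropped = int((~ok).sum())
    if dropped:
        log.info("filter_by_replicates: dropped %d of %d elements", dropped, len(ok))
    return t.subset(t.element_ids[ok])


def _normalized_ratios(t: MpraCountTable) -> pd.DataFrame:
    """Per-replicate library-normalized RNA/plasmid ratios; NaN where the
    plasmid count is 0 (ratio undefined). Zero RNA gives ratio 0 (valid)."""
    rna_n = t.rna / t.rna_lib_sizes
    pla_n = t.plasmid / t.plasmid_lib_sizes
    ratios = rna_n / pla_n
    return ratios.where(t.plasmid > 0)


def compute_activity(t: MpraCountTable) -> pd.DataFrame:
    """Control-normalized activity (fold change) per element.

    Per replicate r with plasmid > 0:
    ratio_er = (RNA_er / rna_lib_r) / (plasmid_er / plasmid_lib_r);
    raw_e = mean of valid ratios; activity_e = raw_e / mean(raw over
    control_random). The control-random mean activity is exactly 1.

    Returns a DataFrame indexed by element id with columns
    category, n_valid_replicates, raw_ratio, activity.
    """
    ratios = _normalized_ratios(t)
    raw = ratios.mean(axis=1)
    n_valid = ratios.notna().sum(axis=1)
    ctrl = raw[t.categories == "control_random"].dropna()
    if ctrl.empty:
        raise ValueError("no control_random element with a defined ratio")
    activity = raw / ctrl.mean()
    return pd.DataFrame(
        {
            "category": t.categories,
            "n_valid_replicates": n_valid,
            "raw_ratio": raw,
            "activity": activity,
        }
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, returned in the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_silencers(
    t: MpraCountTable,
    alpha: float = 0.05,
    log_scale: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Statistical silencer calling for tested elements.

    Each tested element's per-replicate normalized ratios are compared with
    the pooled per-replicate ratios of all control_random elements by a
    two-sample one-tailed t test (alternative: element < controls), on the
    log2 scale by default (variance stabilization for ratio data; zero
    ratios, which have no log, are excluded from the test sample but still
    count toward the activity mean). The pooled-variance form is the
    default: on the log scale both groups share the count-model variance,
    and pooling borrows the large control sample's degrees of freedom,
    which a Welch test (``equal_var=False``) forfeits when an element has
    only a handful of replicates. P-values are BH-adjusted across tested
    elements; is_silencer = (activity < 1) and (q < alpha).

    Returns the :func:`compute_activity` frame with added columns
    p_value, q_value, is_silencer (non-tested elements carry NaN p/q).
    """
    act = compute_activity(t)
    ratios = _normalized_ratios(t)
    ctrl_pool = ratios.loc[t.categories == "control_random"].values.ravel()
    ctrl_pool = ctrl_pool[~np.isnan(ctrl_pool)]
    if log_scale:
        n_zero = int((ctrl_pool == 0).sum())
        if n_zero:
            log.info("call_silencers: %d zero control ratios excluded from log2 test", n_zero)
        ctrl_sample = np.log2(ctrl_pool[ctrl_pool > 0])
    else:
        ctrl_sample = ctrl_pool
    if ctrl_sample.size < 2:
        raise ValueError("need >= 2 pooled control ratios for testing")

    tested = t.element_ids[t.categories == "tested"]
    pvals = pd.Series(np.nan, index=t.element_ids)
    for eid in tested:
        vals = ratios.loc[eid].dropna().values
        if log_scale:
            vals = vals[vals > 0]
            sample = np.log2(vals)
        else:
            sample = vals
        if sample.size < 2:
            log.info("call_silencers: %s has <2 usable ratios; p set to 1", eid)
            pvals[eid] = 1.0
            continue
        res = stats.ttest_ind(
            sample, ctrl_sample, equal_var=equal_var, alternative="less"
        )
        p = float(res.pvalue)
        if np.isnan(p):  # zero variance in both groups with equal means
            log.info("call_silencers: degenerate t test for %s; p set to 1", eid)
            p = 1.0
        pvals[eid] = p

    act["p_value"] = pvals
    qvals = pd.Series(np.nan, index=t.element_ids)
    if len(tested):
        qvals[tested] = bh_adjust(pvals[tested].values)
    act["q_value"] = qvals
    act["is_silencer"] = (act["activity"] < 1) & (act["q_value"] < alpha)
    act["is_silencer"] = act["is_silencer"].fillna(False)
    return act


# ---------------------------------------------------------------------------
# qPCR: delta-delta-Ct fold changes for reporter assays and CRISPR editing.

@dataclass
class CtTable:
    """qPCR cycle-threshold values.

    ``data`` columns: sample, group ("experimental" or "control"),
    ct_target, ct_ref1 and optionally ct_ref2 (second internal reference).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "group", "ct_target", "ct_ref1"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        cts = self.data[[c for c in self.data.columns if c.startswith("ct_")]]
        if cts.isna().any().any() or (cts <= 0).any().any():
            raise ValueError("Ct values must be finite and positive")
        if not set(self.data["group"]) >= {"control"}:
            raise ValueError("CtTable needs a 'control' group")


def delta_delta_ct(
    t: CtTable, reference_mode: str = "single", alternative: str = "greater"
) -> dict:
    """Per-sample fold changes 2^(-ddCt) relative to the control group.

    dCt = Ct_target - Ct_ref, with Ct_ref either the single reference or
    the mean of two references; ddCt = dCt_sample - mean dCt of controls;
    fold = 2^(-ddCt). A one-tailed Welch t test compares experimental vs
    control dCt values (default alternative "greater": the experimental
    target is expressed lower, i.e. its dCt is larger).
    """
    df = t.data.copy()
    if reference_mode == "single":
        ref = df["ct_ref1"]
    elif reference_mode == "mean_of_two":
        if "ct_ref2" not in df.columns:
            raise ValueError("reference_mode='mean_of_two' requires a ct_ref2 column")
        ref = (df["ct_ref1"] + df["ct_ref2"]) / 2.0
    else:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    df["delta_ct"] = df["ct_target"] - ref
    ctrl_mean = df.loc[df["group"] == "control", "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - ctrl_mean
    df["fold_change"] = 2.0 ** (-df["delta_delta_ct"])

    exp = df.loc[df["group"] == "experimental", "delta_ct"].values
    ctl = df.loc[df["group"] == "control", "delta_ct"].values
    if exp.size >= 2 and ctl.size >= 2:
        p = float(
            stats.ttest_ind(exp, ctl, equal_var=False, alternative=alternative).pvalue
        )
    else:
        p = float("nan")
    group_means = df.groupby("group")["fold_change"].mean().to_dict()
    return {"table": df, "group_mean_fold": group_means, "p_value": p}


# ---------------------------------------------------------------------------
# I/O: tab-separated count matrices (rows = elements with a category column,
# columns = replicates), one file per library.

def read_count_table(rna_path, plasmid_path) -> MpraCountTable:
    rna = pd.read_csv(rna_path, sep="\t", index_col=0)
    plasmid = pd.read_csv(plasmid_path, sep="\t", index_col=0)
    if "category" not in rna.columns:
        raise ValueError("RNA count table needs a 'category' column")
    categories = rna.pop("category")
    plasmid = plasmid.drop(columns=["category"], errors="ignore")
    return MpraCountTable(
        rna=rna.astype(int), plasmid=plasmid.astype(int), categories=categories
    )


def write_activity_table(records: pd.DataFrame, path) -> None:
    out = records.reset_index(names="element_id")
    out.to_csv(path, sep="\t", index=False)
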