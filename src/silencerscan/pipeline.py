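"""End-to-end silencer-discovery run on a synthetic dataset.

Chains every stage: SSA uncharacterized-CRE calling per cell type, MPRA
replicate filtering / activity computation / silencer calling, gapped
k-mer SVM training on the activity extremes and genome-wide candidate
prediction, then the characterization analyses (methylation and
conservation averages, chromHMM composition, p-CHiC target expression,
GWAS-trait enrichment, enhancer switching, footprint density) — and
scores everything against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import chic, enrich, gkm, mpra, ssa, tracks
from .synth import SynthBundle, SynthConfig, generate_dataset

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    """Everything the end-to-end run computed, with truth-recovery scores."""

    n_ucres_by_cell: dict
    activity: pd.DataFrame            # per-element activity + silencer calls
    n_silencers: int
    silencer_fraction: float          # of tested elements
    realized_fdr: float               # against planted truth
    realized_power: float
    model: gkm.GkmModel
    auroc: float
    auprc: float
    predicted_fraction: float         # candidate fraction among scored elements
    methylation_means: dict           # class -> mean fraction
    conservation_means: dict
    chromhmm_fractions: pd.Series
    chic_bins: pd.DataFrame
    chic_low_expr_fraction: float     # silencer-contacted genes with RPKM <= 2
    chic_wilcoxon_p: float
    trait_enrichment: pd.DataFrame
    recovered_trait_pairs: list
    switch_per_cell: pd.Series
    switch_aggregate: float
    footprint_comparison: dict

    def summary(self) -> str:
        lines = [
            "silencerscan end-to-end report",
            "-" * 34,
            "uncharacterized CREs: "
            + ", ".join(f"{c}: {n}" for c, n in self.n_ucres_by_cell.items()),
            f"MPRA silencers: {self.n_silencers} "
            f"({100 * self.silencer_fraction:.1f}% of tested)",
            f"  realized FDR {self.realized_fdr:.3f}, power {self.realized_power:.3f}",
            f"classifier held-out AUROC {self.auroc:.3f}, AUPRC {self.auprc:.3f}",
            f"  candidate fraction among scored elements {100 * self.predicted_fraction:.1f}%",
            "methylation means: "
            + ", ".join(f"{k} {v:.3f}" for k, v in self.methylation_means.items()),
            "conservation means: "
            + ", ".join(f"{k} {v:.3f}" for k, v in self.conservation_means.items()),
            "top chromHMM states: "
            + ", ".join(
                f"{s} {f:.2f}"
                for s, f in self.chromhmm_fractions.sort_values(ascending=False)
                .head(3)
                .items()
            ),
            f"p-CHiC: {100 * self.chic_low_expr_fraction:.1f}% of silencer-contacted "
            f"genes at RPKM <= 2 (silencer-vs-enhancer Wilcoxon p = "
            f"{self.chic_wilcoxon_p:.2e})",
            f"enriched trait/cell pairs (q < 0.01): {self.recovered_trait_pairs}",
            f"silencer-to-enhancer switching: aggregate "
            f"{100 * self.switch_aggregate:.1f}%",
            f"footprints per element: silencers {self.footprint_comparison['mean_a']:.2f} "
            f"vs enhancers {self.footprint_comparison['mean_b']:.2f} "
            f"(p = {self.footprint_comparison['p_value']:.2e})",
        ]
        return "\n".join(lines)


def run_pipeline(
    cfg: Optional[SynthConfig] = None,
    bundle: Optional[SynthBundle] = None,
    n_per_class: int = 500,
    gkm_l: int = 6,
    gkm_k: int = 4,
    fdr_alpha: float = 0.05,
) -> PipelineReport:
    """Run the full analysis on a synthetic bundle (generated from ``cfg``
    if not supplied). Classifier preset l=6, k=4 and n_per_class=500 keep
    the default problem desk-scale; both are exposed."""
    if bundle is None:
        bundle = generate_dataset(cfg or SynthConfig())
    cfg = bundle.config
    seed = cfg.seed

    # --- SSA per cell type
    ucres_by_cell = {
        cell: ssa.call_uncharacterized_cres(tr)
        for cell, tr in bundle.tracks_by_cell.items()
    }
    n_ucres = {c: len(u) for c, u in ucres_by_cell.items()}

    # --- MPRA silencer calling
    table = mpra.filter_by_replicates(bundle.counts, min_reps=3)
    act = mpra.call_silencers(table, alpha=fdr_alpha)
    tested = act[act["category"] == "tested"]
    called = tested.index[tested["is_silencer"]]
    truth = bundle.truth["is_true_silencer"]
    n_called = len(called)
    fp = int((~truth.reindex(called)).sum())
    realized_fdr = fp / n_called if n_called else 0.0
    true_ids = truth[truth & (bundle.truth["category"] == "tested")].index
    testable = true_ids.intersection(tested.index)
    power = float(tested.loc[testable, "is_silencer"].mean()) if len(testable) else 0.0

    # --- classifier on activity extremes
    pos, neg = gkm.build_training_sets(act, n_per_class=min(n_per_class, len(tested) // 2))
    seq_by_id = {s.id: s for s in bundle.sequences}
    train_seqs = [seq_by_id[i] for i in pos + neg]
    labels = np.r_[np.ones(len(pos), bool), np.zeros(len(neg), bool)]
    X, fz = gkm.gapped_kmer_features(train_seqs, l=gkm_l, k=gkm_k)
    model = gkm.train_and_evaluate(X, labels, featurizer=fz, seed=seed)
    tested_seqs = [seq_by_id[i] for i in tested.index if i in seq_by_id]
    preds = gkm.predict_candidates(model, tested_seqs)
    predicted_fraction = float(preds["call"].mean())

    # --- methylation / conservation contrasts (designated cell)
    cell0 = "cell_0"
    sil_ivs = tracks.IntervalSet(
        [iv for iv in bundle.ucres_by_cell[cell0] if truth.get(iv.name, False)],
        label="true_silencers",
    )
    enh_ivs = tracks.call_active_enhancers(
        bundle.tracks_by_cell[cell0].dhs,
        bundle.tracks_by_cell[cell0].h3k4me1,
        bundle.h3k27ac_by_cell[cell0],
    )
    meth_sil = tracks.mean_track_value(sil_ivs, bundle.methylation)
    meth_enh = tracks.mean_track_value(enh_ivs, bundle.methylation)
    cons_sil = tracks.mean_track_value(sil_ivs, bundle.conservation)
    cons_enh = tracks.mean_track_value(enh_ivs, bundle.conservation)
    methylation_means = {
        "silencers": float(meth_sil.mean()), "enhancers": float(meth_enh.mean())
    }
    conservation_means = {
        "silencers": float(cons_sil.mean()), "enhancers": float(cons_enh.mean())
    }

    # --- chromHMM composition of true silencers
    chmm = enrich.chromhmm_distribution(sil_ivs, bundle.segmentation_by_cell[cell0])

    # --- p-CHiC
    pairs_sil = chic.assign_targets(sil_ivs, bundle.interactions)
    pairs_enh = chic.assign_targets(enh_ivs, bundle.interactions)
    bins = chic.bin_by_expression(pairs_sil, bundle.expression)
    sil_expr = bundle.expression.reindex(pairs_sil["gene_id"].drop_duplicates()).dropna()
    enh_expr = bundle.expression.reindex(pairs_enh["gene_id"].drop_duplicates()).dropna()
    low_frac = float((sil_expr <= 2).mean()) if len(sil_expr) else float("nan")
    wilc_p = (
        chic.compare_expression_wilcoxon(sil_expr.values, enh_expr.values)
        if len(sil_expr) and len(enh_expr)
        else float("nan")
    )

    # --- GWAS trait enrichment over true-silencer sets per cell
    snps = enrich.expand_ld(bundle.snps, bundle.proxy_table, r2_min=0.8)
    sil_by_cell = {}
    for cell, ucres in bundle.ucres_by_cell.items():
        members = [iv for iv in ucres if truth.get(iv.name, False)]
        if not members:
            # cells without MPRA truth: deterministic subset at the planted rate
            step = max(1, int(round(1 / max(cfg.silencer_fraction, 1e-9))))
            members = list(ucres)[::step]
        sil_by_cell[cell] = tracks.IntervalSet(members, label=f"silencers_{cell}")
    trait_tab = enrich.hypergeom_trait_enrichment(snps, sil_by_cell, alpha=0.01)
    recovered = [
        (r.cell, r.trait) for r in trait_tab.itertuples(index=False) if r.enriched
    ]

    # --- switching + footprints
    enh_by_cell = {
        cell: tracks.call_active_enhancers(
            tr.dhs, tr.h3k4me1, bundle.h3k27ac_by_cell[cell]
        )
        for cell, tr in bundle.tracks_by_cell.items()
    }
    switch_per_cell, switch_agg = tracks.enhancer_switch_matrix(
        {c: ucres for c, ucres in bundle.ucres_by_cell.items()}, enh_by_cell
    )
    fp_cmp = tracks.compare_footprint_groups(sil_ivs, enh_ivs, bundle.dgf_by_cell[cell0])

    return PipelineReport(
        n_ucres_by_cell=n_ucres,
        activity=act,
        n_silencers=n_called,
        silencer_fraction=n_called / max(1, len(tested)),
        realized_fdr=realized_fdr,
        realized_power=power,
        model=model,
        auroc=model.training_meta["auroc"],
        auprc=model.training_meta["auprc"],
        predicted_fraction=predicted_fraction,
        methylation_means=methylation_means,
        conservation_means=conservation_means,
        chromhmm_fractions=chmm.fractions,
        chic_bins=bins,
        chic_low_expr_fraction=low_frac,
        chic_wilcoxon_p=wilc_p,
        trait_enrichment=trait_tab,
        recovered_trait_pairs=recovered,
        switch_per_cell=switch_per_cell,
        switch_aggregate=switch_agg,
        footprint_comparison=fp_cmp,
    )
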