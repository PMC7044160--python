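"""Synthetic-data generator with planted ground truth.

Emulates every input class the pipeline consumes — per-cell-type peak
tracks, element sequences, MPRA count tables, promoter-capture Hi-C
interactions with expression, GWAS SNPs with LD proxies, methylation and
conservation value tracks, and a chromatin-state segmentation — on a
scaled-down genome, with machine-readable truth tables (which elements
are true silencers, which interactions are decoys, which trait/cell pair
is enriched). All randomness flows from one master seed through named
substreams, so the bundle and each of its parts are bit-reproducible.

The defaults define the study conditions the rest of the package is
tested against: a 2 Mb single-chromosome genome, 3 cell types, 2000
tested elements with 67/20/20 control-random/-enhancer/-silencer
elements, 5 replicates of negative-binomial counts (dispersion 0.1),
true silencer activity 0.3 for the 40% of tested elements planted as
silencers, a consensus word planted at rate 0.9 in silencer sequences
versus 0.1 elsewhere, and a 10x SNP-density boost for one designated
(trait, cell type) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .chic import ChicInteraction
from .gkm import SequenceRecord
from .intervals import GenomicInterval, IntervalSet, TssRecord, merge, promoter_windows
from .enrich import Segmentation
from .mpra import MpraCountTable
from .ssa import CellTypeTracks
from .tracks import ValueTrack

__all__ = ["SynthConfig", "SynthBundle", "generate_dataset", "generate_mpra_counts",
           "generate_sequences_with_motifs", "generate_chic_interactions",
           "generate_snp_catalog", "write_dataset"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic study. See the module docstring for the
    rationale behind the defaults."""

    seed: int = 0
    genome: dict = field(default_factory=lambda: {"chr1": 2_000_000})
    n_cell_types: int = 3
    # per-cell track structure
    n_genes: int = 60
    n_enhancers: int = 150
    frac_active_enhancers: float = 0.6     # of enhancers, carry H3K27ac too
    n_ctcf: int = 100
    n_ucres: int = 2000                    # planted uncharacterized DHS per cell
    peak_len_median: float = 300.0         # lognormal peak lengths
    peak_len_sigma: float = 0.35
    element_len: int = 200                 # tested-oligo length
    # MPRA
    silencer_fraction: float = 0.4         # of tested ucres planted as silencers
    silencer_activity: float = 0.3         # true activity delta of a silencer
    n_tested: int = 2000
    n_control_random: int = 67
    n_control_enhancer: int = 20
    n_control_silencer: int = 20
    control_enhancer_activity: float = 3.0
    control_silencer_activity: float = 0.3
    n_replicates: int = 5
    nb_mean: float = 200.0
    nb_dispersion: float = 0.1
    # sequences
    consensus: str = "TCAGCACCACGG"
    plant_rate_pos: float = 0.9
    plant_rate_neg: float = 0.1
    # p-CHiC
    n_interactions: int = 400
    decoy_fraction: float = 0.0            # sub-10kb interactions for filter tests
    low_rpkm_zero_mass: float = 0.5
    high_rpkm_mean_log: float = 3.0        # lognormal log-mean for enhancer targets
    # SNPs
    n_traits: int = 8
    snps_per_trait: int = 60
    proxies_per_lead: int = 2
    snp_enrichment_factor: float = 10.0
    enriched_trait: str = "trait_0"
    enriched_cell: str = "cell_0"
    # value tracks
    meth_beta_silencer: tuple = (7.0, 3.0)   # mean 0.7
    meth_beta_enhancer: tuple = (4.0, 6.0)   # mean 0.4
    meth_beta_background: tuple = (5.0, 5.0)
    cons_beta_silencer: tuple = (2.0, 8.0)
    cons_beta_enhancer: tuple = (2.0, 8.5)
    cons_beta_background: tuple = (1.0, 9.0)

    def validate(self) -> None:
        for name in ("silencer_fraction", "frac_active_enhancers",
                     "plant_rate_pos", "plant_rate_neg", "decoy_fraction",
                     "low_rpkm_zero_mass"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.silencer_activity <= 0:
            raise ValueError("silencer_activity must be > 0")
        if self.n_tested > self.n_ucres:
            raise ValueError("cannot test more elements than planted ucres")
        if self.n_control_random < 1:
            raise ValueError("need >= 1 control_random element")
        if len(self.consensus) > self.element_len:
            raise ValueError("consensus longer than element sequence")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(abs(hash_stream(stream)),))
        )


def hash_stream(name: str) -> int:
    """Stable (non-salted) small hash of a stream name."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


@dataclass
class SynthBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SynthConfig
    tracks_by_cell: dict            # cell -> CellTypeTracks
    h3k27ac_by_cell: dict           # cell -> IntervalSet
    dgf_by_cell: dict               # cell -> IntervalSet
    ucres_by_cell: dict             # cell -> IntervalSet (planted truth)
    counts: MpraCountTable
    true_activity: pd.Series        # element id -> planted activity
    sequences: list                 # SequenceRecord per tested/control element
    motif_positions: pd.Series      # element id -> insert position (-1 if none)
    interactions: list              # ChicInteraction
    interaction_truth: pd.DataFrame # kind (silencer/enhancer/decoy) per interaction
    expression: pd.Series           # gene_id -> RPKM
    target_tss: list                # TssRecord per synthetic target gene
    snps: pd.DataFrame              # lead SNPs (snp_id, chrom, pos, trait)
    proxy_table: pd.DataFrame
    methylation: ValueTrack
    conservation: ValueTrack
    segmentation_by_cell: dict      # cell -> Segmentation
    truth: pd.DataFrame             # per tested element: is_silencer etc.


# ---------------------------------------------------------------------------
# helpers

def _sample_positions(rng, n, lo, hi, min_sep, forbidden=None):
    """Sample n positions in [lo, hi), pairwise >= min_sep apart and
    outside forbidden spans (expanded by min_sep), by greedy left-to-right
    selection from a sorted pool of uniform candidates. O(candidates)."""
    forb: list[tuple[int, int]] = []
    if forbidden is not None:
        spans = sorted((iv.start - min_sep, iv.end + min_sep) for iv in forbidden)
        for s, e in spans:  # merge expanded spans
            if forb and s <= forb[-1][1]:
                forb[-1] = (forb[-1][0], max(forb[-1][1], e))
            else:
                forb.append((s, e))
    for factor in (4, 16, 64):
        cand = np.sort(rng.integers(lo, hi, size=factor * n))
        out: list[int] = []
        last = -(10**12)
        fi = 0
        for p in cand:
            p = int(p)
            if p - last < min_sep:
                continue
            while fi < len(forb) and forb[fi][1] <= p:
                fi += 1
            if fi < len(forb) and forb[fi][0] <= p:
                continue
            out.append(p)
            last = p
            if len(out) == n:
                return out
    raise ValueError(f"could not place {n} intervals; genome too crowded")


def _peak(rng, cfg, chrom, center, name=None):
    length = int(np.clip(rng.lognormal(np.log(cfg.peak_len_median), cfg.peak_len_sigma),
                         50, 5000))
    start = max(0, center - length // 2)
    return GenomicInterval(chrom, start, start + length, name=name)


# ---------------------------------------------------------------------------
# generators

def generate_tracks(cfg: SynthConfig) -> tuple[dict, dict, dict, dict, dict]:
    """Per-cell peak tracks with planted uncharacterized CREs.

    Subtraction tracks (H3K4me1/H3K4me3, TSS windows, pooled CTCF) are laid
    down first; ucres are then placed in the uncovered complement with a
    safety margin, so SSA recovers exactly the planted set by construction.
    """
    cfg.validate()
    chrom = next(iter(cfg.genome))
    glen = cfg.genome[chrom]
    rng = cfg.rng("tracks")

    # pooled CTCF shared by all cells
    ctcf_pos = _sample_positions(rng, cfg.n_ctcf, 1000, glen - 1000, 400)
    ctcf = IntervalSet(
        [GenomicInterval(chrom, p, p + 200, name=f"ctcf_{i}") for i, p in enumerate(ctcf_pos)],
        label="ctcf_pooled",
    )

    tracks_by_cell, h3k27ac_by_cell, dgf_by_cell, ucres_by_cell, seg_by_cell = {}, {}, {}, {}, {}
    for ci in range(cfg.n_cell_types):
        cell = f"cell_{ci}"
        crng = cfg.rng(f"tracks/{cell}")
        tss_pos = _sample_positions(crng, cfg.n_genes, 3000, glen - 3000, 6000)
        strands = crng.choice(["+", "-"], size=cfg.n_genes)
        tss = [
            TssRecord(f"{cell}_gene_{i}", chrom, p, s)
            for i, (p, s) in enumerate(zip(tss_pos, strands))
        ]
        h3k4me3 = IntervalSet(
            [_peak(crng, cfg, chrom, p, name=f"k4me3_{i}") for i, p in enumerate(tss_pos)],
            label="h3k4me3", cell_type=cell,
        )
        enh_pos = _sample_positions(
            crng, cfg.n_enhancers, 1000, glen - 1000, 1200,
            forbidden=promoter_windows(tss),
        )
        enh_peaks = [_peak(crng, cfg, chrom, p, name=f"enh_{i}") for i, p in enumerate(enh_pos)]
        h3k4me1 = IntervalSet(enh_peaks, label="h3k4me1", cell_type=cell)
        n_active = int(round(cfg.frac_active_enhancers * cfg.n_enhancers))
        active_idx = crng.choice(cfg.n_enhancers, size=n_active, replace=False)
        h3k27ac = IntervalSet(
            [enh_peaks[i] for i in sorted(active_idx)], label="h3k27ac", cell_type=cell
        )

        forbidden = merge(IntervalSet(
            list(h3k4me1) + list(h3k4me3) + list(promoter_windows(tss)) + list(ctcf)
        ))
        ucre_pos = _sample_positions(
            crng, cfg.n_ucres, 500, glen - cfg.element_len - 500,
            cfg.element_len + 50, forbidden=forbidden,
        )
        ucres = IntervalSet(
            [GenomicInterval(chrom, p, p + cfg.element_len, name=f"{cell}_ucre_{i}")
             for i, p in enumerate(ucre_pos)],
            label="planted_ucres", cell_type=cell,
        )
        # DHS = every enhancer + promoter peak (these overlap marks) + ucres
        dhs = IntervalSet(
            list(ucres) + enh_peaks + list(h3k4me3), label="dhs", cell_type=cell
        )
        tracks_by_cell[cell] = CellTypeTracks(
            cell_type=cell, dhs=dhs, h3k4me1=h3k4me1, h3k4me3=h3k4me3,
            ctcf_pooled=ctcf, tss=tss,
        )
        h3k27ac_by_cell[cell] = h3k27ac
        ucres_by_cell[cell] = ucres

        # footprints: denser at active enhancers than at ucres
        fps = []
        for iv in h3k27ac:
            for j in range(int(crng.poisson(4))):
                p = int(crng.integers(iv.start, max(iv.start + 1, iv.end - 20)))
                fps.append(GenomicInterval(chrom, p, p + 20, name=f"dgf_e{len(fps)}"))
        for iv in ucres:
            for j in range(int(crng.poisson(1.2))):
                p = int(crng.integers(iv.start, max(iv.start + 1, iv.end - 20)))
                fps.append(GenomicInterval(chrom, p, p + 20, name=f"dgf_u{len(fps)}"))
        dgf_by_cell[cell] = IntervalSet(fps, label="dgf", cell_type=cell)
    return tracks_by_cell, h3k27ac_by_cell, dgf_by_cell, ucres_by_cell, ctcf


def generate_mpra_counts(cfg: SynthConfig) -> tuple[MpraCountTable, pd.Series, pd.DataFrame]:
    """MPRA count table with planted activities.

    Plasmid counts are negative-binomial around a per-element lognormal
    abundance scaled by a per-replicate library factor; RNA means are the
    plasmid means times the element's true activity (delta for silencers,
    1 for nulls and control-random, >1 / <1 for control enhancers and
    silencers). Returns (table, true_activity, truth).
    """
    cfg.validate()
    rng = cfg.rng("mpra")
    cell = "cell_0"
    ids = [f"{cell}_ucre_{i}" for i in range(cfg.n_tested)]
    cats = ["tested"] * cfg.n_tested
    truth_sil = np.zeros(cfg.n_tested, dtype=bool)
    n_sil = int(round(cfg.silencer_fraction * cfg.n_tested))
    sil_idx = rng.choice(cfg.n_tested, size=n_sil, replace=False)
    truth_sil[sil_idx] = True
    activity = np.where(truth_sil, cfg.silencer_activity, 1.0).tolist()

    for i in range(cfg.n_control_random):
        ids.append(f"ctrl_rand_{i}"); cats.append("control_random"); activity.append(1.0)
    for i in range(cfg.n_control_enhancer):
        ids.append(f"ctrl_enh_{i}"); cats.append("control_enhancer")
        activity.append(cfg.control_enhancer_activity)
    for i in range(cfg.n_control_silencer):
        ids.append(f"ctrl_sil_{i}"); cats.append("control_silencer")
        activity.append(cfg.control_silencer_activity)

    n_el = len(ids)
    activity = np.asarray(activity)
    abundance = rng.lognormal(np.log(cfg.nb_mean), 0.3, size=n_el)
    pla_factor = rng.uniform(0.7, 1.3, size=cfg.n_replicates)
    rna_factor = rng.uniform(0.7, 1.3, size=cfg.n_replicates)

    def nb(mean):
        r = 1.0 / cfg.nb_dispersion
        return rng.negative_binomial(r, r / (r + mean))

    pla_mean = abundance[:, None] * pla_factor[None, :]
    rna_mean = abundance[:, None] * activity[:, None] * rna_factor[None, :]
    plasmid = nb(pla_mean)
    rna = nb(rna_mean)
    reps = [f"rep{r+1}" for r in range(cfg.n_replicates)]
    table = MpraCountTable(
        rna=pd.DataFrame(rna, index=ids, columns=reps),
        plasmid=pd.DataFrame(plasmid, index=ids, columns=reps),
        categories=pd.Series(cats, index=ids),
    )
    true_activity = pd.Series(activity, index=ids, name="true_activity")
    truth = pd.DataFrame(
        {
            "element_id": ids,
            "category": cats,
            "true_activity": activity,
            "is_true_silencer": [
                c == "tested" and a < 1 for c, a in zip(cats, activity)
            ],
        }
    ).set_index("element_id")
    return table, true_activity, truth


def generate_sequences_with_motifs(
    cfg: SynthConfig, truth: pd.DataFrame
) -> tuple[list, pd.Series]:
    """Uniform-random background sequences with the consensus word planted
    at configured rates (positives = true silencers). Returns
    (sequences, insert positions; -1 where nothing was planted)."""
    cfg.validate()
    rng = cfg.rng("sequences")
    bases = np.array(list("ACGT"))
    seqs, positions = [], {}
    L, w = cfg.element_len, len(cfg.consensus)
    for eid, row in truth.iterrows():
        seq = "".join(rng.choice(bases, size=L))
        rate = cfg.plant_rate_pos if row["is_true_silencer"] else cfg.plant_rate_neg
        pos = -1
        if rng.random() < rate:
            pos = int(rng.integers(0, L - w + 1))
            seq = seq[:pos] + cfg.consensus + seq[pos + w:]
        seqs.append(SequenceRecord(str(eid), seq))
        positions[str(eid)] = pos
    return seqs, pd.Series(positions, name="motif_pos")


def generate_chic_interactions(
    cfg: SynthConfig,
    ucres_by_cell: dict,
    h3k27ac_by_cell: dict,
    tracks_by_cell: dict,
    truth: pd.DataFrame,
) -> tuple[list, pd.DataFrame, pd.Series]:
    """Promoter-capture interactions with planted expression bias.

    Silencer-contacting genes draw RPKM from a low distribution (point
    mass at 0 plus Uniform(0, 2]); enhancer-contacting genes from a high
    lognormal. Bait/other-end gaps are >= 10 kb except for a configured
    fraction of sub-10 kb decoys (for testing the distance filter).
    Returns (interactions, per-interaction truth, expression, target TSS
    records for the synthetic target genes).
    """
    cfg.validate()
    rng = cfg.rng("chic")
    cell = "cell_0"
    tracks = tracks_by_cell[cell]
    chrom = next(iter(cfg.genome))
    glen = cfg.genome[chrom]
    tss_list = list(tracks.tss)
    sil_ids = set(truth.index[truth["is_true_silencer"]])
    sil_ivs = [iv for iv in ucres_by_cell[cell] if iv.name in sil_ids]
    enh_ivs = list(h3k27ac_by_cell[cell])

    interactions, kinds, expr = [], [], {}
    target_tss = []
    n_decoy = int(round(cfg.decoy_fraction * cfg.n_interactions))
    half = (cfg.n_interactions - n_decoy) // 2
    plan = (["silencer"] * half + ["enhancer"] * (cfg.n_interactions - n_decoy - half)
            + ["decoy"] * n_decoy)
    gene_counter = 0
    for kind in plan:
        t = tss_list[int(rng.integers(0, len(tss_list)))]
        gene_counter += 1
        gene = f"{cell}_tgt_{gene_counter}"
        if kind == "silencer":
            anchor = sil_ivs[int(rng.integers(0, len(sil_ivs)))]
            rpkm = 0.0 if rng.random() < cfg.low_rpkm_zero_mass else float(rng.uniform(0.01, 2.0))
        elif kind == "enhancer":
            anchor = enh_ivs[int(rng.integers(0, len(enh_ivs)))]
            rpkm = float(rng.lognormal(cfg.high_rpkm_mean_log, 0.6))
        else:  # decoy: other end too close to the bait
            off = int(rng.integers(1500, 8000))
            s = min(max(0, t.position + 1000 + off), glen - 2000)
            anchor = GenomicInterval(chrom, s, s + 1500)
            rpkm = float(rng.uniform(0, 5))
        oe = GenomicInterval(
            chrom, max(0, anchor.start - 200), min(glen, anchor.end + 200)
        )
        bait = GenomicInterval(chrom, max(0, t.position - 1000), t.position + 1000)
        if kind != "decoy" and ChicInteraction(bait, (gene,), oe).gap() < 10_000:
            # re-anchor the bait to a distant TSS to guarantee the gap
            t = max(tss_list, key=lambda x: abs(x.position - anchor.start))
            bait = GenomicInterval(chrom, max(0, t.position - 1000), t.position + 1000)
        interactions.append(ChicInteraction(bait, (gene,), oe, score=float(rng.uniform(5, 15))))
        kinds.append(kind)
        expr[gene] = rpkm
        target_tss.append(TssRecord(gene, chrom, t.position, t.strand))
    itruth = pd.DataFrame({"kind": kinds})
    itruth["gap"] = [ia.gap() for ia in interactions]
    return interactions, itruth, pd.Series(expr, name="rpkm"), target_tss


def generate_snp_catalog(
    cfg: SynthConfig, ucres_by_cell: dict, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """GWAS-like lead SNPs plus LD proxies.

    One designated (trait, cell) pair has its SNP density inside that
    cell's true silencer elements multiplied by the enrichment factor;
    all other trait SNPs are uniform over the genome. Proxies lie within
    +/- 50 kb of their lead with r^2 ~ Uniform(0.5, 1).
    """
    cfg.validate()
    rng = cfg.rng("snps")
    chrom = next(iter(cfg.genome))
    glen = cfg.genome[chrom]
    sil_ids = set(truth.index[truth["is_true_silencer"]])
    sil_ivs = [iv for iv in ucres_by_cell[cfg.enriched_cell] if iv.name in sil_ids]

    rows = []
    for ti in range(cfg.n_traits):
        trait = f"trait_{ti}"
        enriched = trait == cfg.enriched_trait
        # probability a SNP of this trait falls inside a silencer element
        sil_bp = sum(len(iv) for iv in sil_ivs)
        base_rate = sil_bp / glen
        rate = min(1.0, base_rate * (cfg.snp_enrichment_factor if enriched else 1.0))
        for si in range(cfg.snps_per_trait):
            if rng.random() < rate:
                iv = sil_ivs[int(rng.integers(0, len(sil_ivs)))]
                pos = int(rng.integers(iv.start, iv.end))
            else:
                pos = int(rng.integers(0, glen))
            rows.append((f"rs_{trait}_{si}", chrom, pos, trait))
    leads = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "trait"])

    prows = []
    for r in leads.itertuples(index=False):
        for pi in range(cfg.proxies_per_lead):
            ppos = int(np.clip(r.pos + rng.integers(-50_000, 50_001), 0, glen - 1))
            prows.append(
                (r.snp_id, f"{r.snp_id}_px{pi}", chrom, ppos, float(rng.uniform(0.5, 1.0)))
            )
    proxies = pd.DataFrame(
        prows, columns=["lead_id", "proxy_id", "proxy_chrom", "proxy_pos", "r2"]
    )
    truth_info = {"enriched_trait": cfg.enriched_trait, "enriched_cell": cfg.enriched_cell}
    return leads, proxies, truth_info


def generate_value_tracks(
    cfg: SynthConfig, ucres_by_cell: dict, h3k27ac_by_cell: dict, truth: pd.DataFrame
) -> tuple[ValueTrack, ValueTrack]:
    """Methylation (sparse, per-cytosine) and conservation (dense, 50 bp
    runs) tracks whose element-class means follow the configured Beta
    distributions (hypermethylated silencers, hypomethylated enhancers)."""
    rng = cfg.rng("value_tracks")
    chrom = next(iter(cfg.genome))
    glen = cfg.genome[chrom]
    cell = "cell_0"
    sil_ids = set(truth.index[truth["is_true_silencer"]])

    rows = []
    def add_cytosines(iv, ab):
        n_c = max(3, len(iv) // 10)
        pos = np.sort(rng.choice(np.arange(iv.start, iv.end), size=n_c, replace=False))
        vals = rng.beta(*ab, size=n_c)
        for p, v in zip(pos, vals):
            rows.append((chrom, int(p), int(p) + 1, float(v)))

    for iv in ucres_by_cell[cell]:
        ab = cfg.meth_beta_silencer if iv.name in sil_ids else cfg.meth_beta_background
        add_cytosines(iv, ab)
    for iv in h3k27ac_by_cell[cell]:
        add_cytosines(iv, cfg.meth_beta_enhancer)
    meth_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    meth_df = meth_df.drop_duplicates(subset=["chrom", "start"])
    methylation = ValueTrack(meth_df, dense=False, label="methylation")

    # conservation: dense 50-bp runs over the genome, element-aware means
    step = 50
    starts = np.arange(0, glen, step)
    vals = rng.beta(*cfg.cons_beta_background, size=starts.size)
    def paint(iv, ab):
        i0, i1 = iv.start // step, (iv.end - 1) // step + 1
        vals[i0:i1] = rng.beta(*ab, size=i1 - i0)
    for iv in ucres_by_cell[cell]:
        if iv.name in sil_ids:
            paint(iv, cfg.cons_beta_silencer)
    for iv in h3k27ac_by_cell[cell]:
        paint(iv, cfg.cons_beta_enhancer)
    cons_df = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": np.minimum(starts + step, glen),
         "value": vals}
    )
    conservation = ValueTrack(cons_df, dense=True, label="conservation")
    return methylation, conservation


def generate_segmentations(
    cfg: SynthConfig, tracks_by_cell: dict, h3k27ac_by_cell: dict,
    ucres_by_cell: dict, truth: pd.DataFrame
) -> dict:
    """Per-cell 15-state segmentations tiling the genome: TssA at
    promoters, Enh at active enhancers, Quies-dominated mixture over true
    silencers, background mixture elsewhere."""
    chrom = next(iter(cfg.genome))
    glen = cfg.genome[chrom]
    sil_ids = set(truth.index[truth["is_true_silencer"]])
    seg_by_cell = {}
    for cell, tracks in tracks_by_cell.items():
        rng = cfg.rng(f"segmentation/{cell}")
        # paint per 200-bp tile
        step = 200
        n_tiles = (glen + step - 1) // step
        states = rng.choice(
            ["Quies", "TxWk", "Tx", "Het", "ReprPCWk"], size=n_tiles,
            p=[0.45, 0.2, 0.15, 0.1, 0.1],
        )
        def paint(iv, choices, probs):
            i0, i1 = iv.start // step, (iv.end - 1) // step + 1
            states[i0:i1] = rng.choice(choices, size=i1 - i0, p=probs)
        for t in tracks.tss:
            iv = GenomicInterval(chrom, max(0, t.position - 400), min(glen, t.position + 400))
            paint(iv, ["TssA", "TssAFlnk"], [0.8, 0.2])
        for iv in h3k27ac_by_cell[cell]:
            paint(iv, ["Enh", "EnhG"], [0.85, 0.15])
        for iv in ucres_by_cell[cell]:
            if iv.name in sil_ids:
                paint(iv, ["Quies", "ReprPCWk", "Het", "TxWk"], [0.6, 0.2, 0.1, 0.1])
        # run-length encode tiles into intervals
        ivs = []
        run_start = 0
        for i in range(1, n_tiles + 1):
            if i == n_tiles or states[i] != states[run_start]:
                ivs.append(
                    GenomicInterval(
                        chrom, run_start * step, min(glen, i * step),
                        name=str(states[run_start]),
                    )
                )
                run_start = i
        seg_by_cell[cell] = Segmentation(ivs, label=f"chromhmm_{cell}")
    return seg_by_cell


def generate_dataset(cfg: Optional[SynthConfig] = None) -> SynthBundle:
    """Generate the full fixture bundle; deterministic under the seed."""
    cfg = cfg or SynthConfig()
    cfg.validate()
    tracks_by_cell, h3k27ac_by_cell, dgf_by_cell, ucres_by_cell, _ctcf = generate_tracks(cfg)
    counts, true_activity, truth = generate_mpra_counts(cfg)
    sequences, motif_positions = generate_sequences_with_motifs(cfg, truth)
    interactions, itruth, expression, target_tss = generate_chic_interactions(
        cfg, ucres_by_cell, h3k27ac_by_cell, tracks_by_cell, truth
    )
    snps, proxies, snp_truth = generate_snp_catalog(cfg, ucres_by_cell, truth)
    methylation, conservation = generate_value_tracks(
        cfg, ucres_by_cell, h3k27ac_by_cell, truth
    )
    seg_by_cell = generate_segmentations(
        cfg, tracks_by_cell, h3k27ac_by_cell, ucres_by_cell, truth
    )
    truth = truth.copy()
    truth["enriched_trait"] = snp_truth["enriched_trait"]
    truth["enriched_cell"] = snp_truth["enriched_cell"]
    return SynthBundle(
        config=cfg,
        tracks_by_cell=tracks_by_cell,
        h3k27ac_by_cell=h3k27ac_by_cell,
        dgf_by_cell=dgf_by_cell,
        ucres_by_cell=ucres_by_cell,
        counts=counts,
        true_activity=true_activity,
        sequences=sequences,
        motif_positions=motif_positions,
        interactions=interactions,
        interaction_truth=itruth,
        expression=expression,
        target_tss=target_tss,
        snps=snps,
        proxy_table=proxies,
        methylation=methylation,
        conservation=conservation,
        segmentation_by_cell=seg_by_cell,
        truth=truth,
    )


def write_dataset(bundle: SynthBundle, outdir) -> None:
    """Write the bundle as a directory tree of plain-text files
    (BED/FASTA/TSV/bedGraph) plus truth.tsv and the exact config used."""
    from .intervals import write_bed, write_tss_table
    from .gkm import write_fasta
    from .chic import write_interactions
    from .tracks import write_bedgraph

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for cell, tr in bundle.tracks_by_cell.items():
        d = out / cell
        d.mkdir(exist_ok=True)
        write_bed(tr.dhs, d / "dhs.bed")
        write_bed(tr.h3k4me1, d / "h3k4me1.bed")
        write_bed(tr.h3k4me3, d / "h3k4me3.bed")
        write_bed(bundle.h3k27ac_by_cell[cell], d / "h3k27ac.bed")
        write_bed(bundle.dgf_by_cell[cell], d / "dgf.bed")
        write_bed(bundle.ucres_by_cell[cell], d / "planted_ucres.bed")
        write_tss_table(tr.tss, d / "tss.tsv")
        write_bed(bundle.segmentation_by_cell[cell], d / "chromhmm.bed")
    write_bed(next(iter(bundle.tracks_by_cell.values())).ctcf_pooled, out / "ctcf_pooled.bed")

    rna = bundle.counts.rna.copy()
    rna.insert(0, "category", bundle.counts.categories)
    rna.to_csv(out / "mpra_rna.tsv", sep="\t")
    pla = bundle.counts.plasmid.copy()
    pla.insert(0, "category", bundle.counts.categories)
    pla.to_csv(out / "mpra_plasmid.tsv", sep="\t")

    write_fasta(bundle.sequences, out / "elements.fa")
    write_interactions(bundle.interactions, out / "chic_interactions.tsv")
    write_tss_table(bundle.target_tss, out / "target_tss.tsv")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t", header=False)
    bundle.snps.to_csv(out / "gwas_leads.tsv", sep="\t", header=False, index=False)
    bundle.proxy_table.to_csv(out / "ld_proxies.tsv", sep="\t", header=False, index=False)
    write_bedgraph(bundle.methylation, out / "methylation.bedgraph")
    write_bedgraph(bundle.conservation, out / "conservation.bedgraph")
    bundle.truth.to_csv(out / "truth.tsv", sep="\t")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(bundle.config), fh, sort_keys=True)
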