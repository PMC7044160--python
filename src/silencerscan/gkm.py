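"""Gapped k-mer featurization, SVM training and candidate-silencer prediction.

A gapped k-mer is a length-``l`` DNA word with ``k`` informative positions
and ``l-k`` wildcards. Every length-``l`` window of a sequence contributes
one count to C(l, k) gapped words (one per choice of informative
positions). The resulting sparse count vectors, L2-normalized per
sequence, feed a linear SVM trained on the activity extremes of the MPRA
screen (lowest-activity elements as positives, highest as negatives). This
explicit featurization is a transparent, directly testable formulation of
the gapped k-mer kernel idea: defaults l=10, k=6 follow the published
tool lineage, while small-l presets keep test problems fast.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import normalize as l2_normalize
from sklearn.svm import LinearSVC

__all__ = [
    "SequenceRecord",
    "GkmFeaturizer",
    "GkmModel",
    "gapped_kmer_features",
    "build_training_sets",
    "train_and_evaluate",
    "compute_auc",
    "select_threshold",
    "predict_candidates",
    "read_fasta",
    "write_fasta",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_BASE = "ACGTN"


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence keyed by element id. Uppercased on construction;
    characters outside {A,C,G,T,N} are rejected."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if set(self.seq) - set("ACGTN"):
            raise ValueError(f"sequence {self.id}: invalid characters")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class GkmFeaturizer:
    """Maps sequences to sparse gapped k-mer count vectors.

    Feature columns are indexed as combo_index * 4**k + word_code where
    ``combo_index`` enumerates the C(l,k) choices of informative positions
    (lexicographic) and ``word_code`` is the base-4 encoding of the k
    informative bases. With ``rc_collapse`` a feature and its reverse
    complement share the numerically smaller of the two codes.
    """

    def __init__(self, l: int = 10, k: int = 6, rc_collapse: bool = True) -> None:
        if not (1 <= k <= l):
            raise ValueError("need 1 <= k <= l")
        self.l = l
        self.k = k
        self.rc_collapse = rc_collapse
        self.combos = list(combinations(range(l), k))
        self.n_features = len(self.combos) * 4**k
        self._pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        self._canon: Optional[np.ndarray] = None

    def _canonical_map(self) -> np.ndarray:
        """code -> canonical code under reverse complementation."""
        if self._canon is not None:
            return self._canon
        k, l = self.k, self.l
        combo_index = {c: i for i, c in enumerate(self.combos)}
        fourk = 4**k
        canon = np.empty(self.n_features, dtype=np.int64)
        words = np.arange(fourk, dtype=np.int64)
        # digits of every word, most-significant (first informative position) first
        digits = (words[:, None] // self._pow4[None, :]) % 4
        rc_digits = 3 - digits[:, ::-1]
        rc_words = rc_digits @ self._pow4
        for ci, combo in enumerate(self.combos):
            rc_combo = tuple(sorted(l - 1 - p for p in combo))
            rci = combo_index[rc_combo]
            codes = ci * fourk + words
            rc_codes = rci * fourk + rc_words
            canon[codes] = np.minimum(codes, rc_codes)
        self._canon = canon
        return canon

    def feature_name(self, code: int) -> str:
        """Human-readable gapped word for a feature column, e.g. 'AC..G.T'."""
        fourk = 4**self.k
        combo = self.combos[code // fourk]
        word_code = code % fourk
        out = ["."] * self.l
        for pos, p4 in zip(combo, self._pow4):
            out[pos] = _CODE_BASE[(word_code // int(p4)) % 4]
        return "".join(out)

    def transform(self, seqs: Sequence[SequenceRecord]) -> sparse.csr_matrix:
        """Sparse (n_sequences x n_features) gapped k-mer count matrix.

        Windows containing N contribute only the patterns whose informative
        positions avoid the N. Sequences shorter than l yield a zero row
        (with a warning).
        """
        rows, cols, data = [], [], []
        canon = self._canonical_map() if self.rc_collapse else None
        fourk = 4**self.k
        for si, rec in enumerate(seqs):
            codes = np.frombuffer(
                rec.seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
                dtype=np.uint8,
            ).astype(np.int64)
            if codes.size < self.l:
                warnings.warn(f"sequence {rec.id} shorter than l={self.l}; zero vector")
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, self.l)
            feats = []
            for ci, combo in enumerate(self.combos):
                sub = windows[:, combo]
                valid = (sub < 4).all(axis=1)
                if not valid.any():
                    continue
                word_codes = sub[valid] @ self._pow4
                feats.append(ci * fourk + word_codes)
            if not feats:
                continue
            feats = np.concatenate(feats)
            if canon is not None:
                feats = canon[feats]
            uniq, counts = np.unique(feats, return_counts=True)
            rows.append(np.full(uniq.size, si, dtype=np.int64))
            cols.append(uniq)
            data.append(counts)
        if rows:
            mat = sparse.coo_matrix(
                (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
                shape=(len(seqs), self.n_features),
                dtype=np.float64,
            ).tocsr()
        else:
            mat = sparse.csr_matrix((len(seqs), self.n_features), dtype=np.float64)
        return mat


def gapped_kmer_features(
    seqs: Sequence[SequenceRecord], l: int = 10, k: int = 6, rc_collapse: bool = True
) -> tuple[sparse.csr_matrix, GkmFeaturizer]:
    """Convenience wrapper: featurize ``seqs`` and return (matrix, featurizer)."""
    fz = GkmFeaturizer(l=l, k=k, rc_collapse=rc_collapse)
    return fz.transform(seqs), fz


def build_training_sets(
    activity: pd.DataFrame, n_per_class: int = 2000
) -> tuple[list[str], list[str]]:
    """Training extremes from the MPRA screen: the n_per_class
    lowest-activity tested elements as positives (silencer-like) and the
    n_per_class highest-activity as negatives. Boundary ties are broken by
    element id (stable, deterministic)."""
    tested = activity[activity["category"] == "tested"].dropna(subset=["activity"])
    if len(tested) < 2 * n_per_class:
        raise ValueError(
            f"need >= {2 * n_per_class} tested elements with defined activity, "
            f"have {len(tested)}"
        )
    ranked = tested.reset_index(names="element_id").sort_values(
        ["activity", "element_id"], kind="stable"
    )
    pos = ranked["element_id"].head(n_per_class).tolist()
    neg = ranked["element_id"].tail(n_per_class).tolist()[::-1]
    return pos, neg


def compute_auc(scores, labels) -> tuple[float, float]:
    """(AUROC, AUPRC) from decision scores and binary labels.

    AUROC is the trapezoidal area over all score thresholds, equivalent to
    the Mann-Whitney pair statistic with half credit for ties. AUPRC is the
    step-wise precision-recall integral sum_i (R_i - R_{i-1}) * P_i over
    distinct thresholds in descending score order.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group ties: boundaries where the score changes
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp = np.cumsum(y)[distinct].astype(float)
    fp = np.cumsum(~y)[distinct].astype(float)
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    precision = tp / (tp + fp)
    recall = tp / n_pos
    auprc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return auroc, auprc


def select_threshold(scores, labels) -> tuple[float, float]:
    """Max-accuracy score cutoff under the rule "positive if score >= t".

    Candidate cutpoints are the observed score values plus +inf (classify
    nothing positive); among accuracy ties the lowest qualifying threshold
    is returned. Returns (threshold, accuracy_at_threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n = scores.size
    best_t, best_acc = np.inf, float((~labels).sum()) / n
    for t in np.unique(scores):  # ascending: first max hit is the lowest threshold
        pred = scores >= t
        acc = float((pred == labels).sum()) / n
        if acc > best_acc or (acc == best_acc and t < best_t):
            best_t, best_acc = float(t), acc
    return best_t, best_acc


@dataclass
class GkmModel:
    """A trained gapped k-mer linear classifier.

    Holds the featurization parameters, the linear decision function
    (sparse-aware weight vector + bias), the classification cutoff chosen
    at maximum held-out accuracy, and training metadata (split fraction,
    seed, AUROC, AUPRC, accuracy at threshold).
    """

    featurizer: GkmFeaturizer
    weights: np.ndarray
    bias: float
    score_threshold: Optional[float] = None
    training_meta: dict = field(default_factory=dict)

    @property
    def is_trained(self) -> bool:
        return self.weights is not None

    def decision_scores(self, seqs: Sequence[SequenceRecord]) -> np.ndarray:
        X = l2_normalize(self.featurizer.transform(seqs))
        return np.asarray(X @ self.weights).ravel() + self.bias

    def save(self, path) -> None:
        meta = {
            "l": self.featurizer.l,
            "k": self.featurizer.k,
            "rc_collapse": self.featurizer.rc_collapse,
            "bias": self.bias,
            "score_threshold": self.score_threshold,
            "training_meta": self.training_meta,
            "format_version": 1,
        }
        w = sparse.csr_matrix(self.weights.reshape(1, -1))
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            w_data=w.data,
            w_indices=w.indices,
            w_shape=np.array(w.shape),
        )

    @classmethod
    def load(cls, path) -> "GkmModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            w = np.zeros(int(z["w_shape"][1]))
            w[z["w_indices"]] = z["w_data"]
        fz = GkmFeaturizer(meta["l"], meta["k"], meta["rc_collapse"])
        return cls(
            featurizer=fz,
            weights=w,
            bias=meta["bias"],
            score_threshold=meta["score_threshold"],
            training_meta=meta["training_meta"],
        )


def train_and_evaluate(
    features: sparse.csr_matrix,
    labels,
    featurizer: GkmFeaturizer,
    train_fraction: float = 0.8,
    seed: int = 0,
    C: float = 1.0,
) -> GkmModel:
    """Fit a linear SVM on a stratified train split and evaluate held out.

    Features are L2-normalized per sequence (length invariance) before the
    fit. AUROC/AUPRC are computed on the held-out decision scores, and the
    classification threshold is chosen there at maximum accuracy. The fixed
    seed makes the split (and hence the model) reproducible.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for training")
    X = l2_normalize(features)
    idx = np.arange(labels.size)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed
    )
    clf = LinearSVC(C=C, random_state=seed)
    clf.fit(X[train_idx], labels[train_idx])
    test_scores = clf.decision_function(X[test_idx])
    auroc, auprc = compute_auc(test_scores, labels[test_idx])
    thr, acc = select_threshold(test_scores, labels[test_idx])
    return GkmModel(
        featurizer=featurizer,
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        score_threshold=thr,
        training_meta={
            "train_fraction": train_fraction,
            "seed": seed,
            "C": C,
            "auroc": auroc,
            "auprc": auprc,
            "max_accuracy": acc,
            "n_train": int(train_idx.size),
            "n_test": int(test_idx.size),
        },
    )


def predict_candidates(model: GkmModel, seqs: Sequence[SequenceRecord]) -> pd.DataFrame:
    """Score sequences and call candidates at the model's threshold.

    Returns a DataFrame (element_id, score, call); an all-N sequence has a
    zero feature vector, so its score is exactly the bias.
    """
    if not model.is_trained:
        raise ValueError("model is not trained")
    if model.score_threshold is None:
        raise ValueError("model has no score threshold; run train_and_evaluate first")
    scores = model.decision_scores(seqs)
    return pd.DataFrame(
        {
            "element_id": [s.id for s in seqs],
            "score": scores,
            "call": scores >= model.score_threshold,
        }
    )


# ---------------------------------------------------------------------------
# FASTA I/O (ids must match the BED names of the corresponding elements)

def read_fasta(path) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), 80):
                fh.write(s.seq[i : i + 80] + "\n")
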