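"""Cross-validation protocols and classification metrics.

Scores are evaluated in grouped 10-fold cross-validation.  Two grouping
protocols are supported: per-protein (all variants of one protein share a
fold) and per-cluster (all variants of proteins in one >=50%-identity
cluster share a fold).  Per-cluster evaluation estimates performance on
proteins dissimilar to the training set; per-protein evaluation permits
close homologs and alternative isoforms across folds and therefore yields
optimistic estimates when such homologs exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .classifier import ClassifierConfig, fit_preprocessor, predict_scores, \
    train_ensemble
from .features import FeatureConfig, assemble_feature_matrix
from .variants import IndelVariant, ProteinRecord


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity between two sequences.

    Computed from the Needleman-Wunsch edit distance ``d`` as
    ``100 * (1 - d / max(len_a, len_b))``: substitutions and gaps both
    count against identity, and equal-length point-substituted homologs
    score exactly their fraction of conserved positions.
    """
    if not seq_a or not seq_b:
        return 0.0
    d = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(seq_a), len(seq_b)))


def cluster_by_identity(proteins: Sequence[ProteinRecord],
                        threshold: float = 50.0) -> Dict[str, int]:
    """Single-linkage clusters of proteins at >= *threshold* % identity.

    Transitive closure: if A~B and B~C meet the threshold, A, B and C share
    a cluster even when A~C does not.  Returns protein_id -> cluster index.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("need at least one protein")
    parent = list(range(len(proteins)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if percent_identity(proteins[i].sequence,
                                proteins[j].sequence) >= threshold:
                parent[find(i)] = find(j)
    roots = {}
    out = {}
    for i, p in enumerate(proteins):
        r = find(i)
        out[p.protein_id] = roots.setdefault(r, len(roots))
    return out


@dataclass
class FoldAssignment:
    """Variant -> fold mapping under a grouping protocol."""

    folds: Dict[int, int]            # variant index -> fold
    grouping: str                    # "per_protein" | "per_cluster"
    k: int
    cluster_map: Optional[Dict[str, int]] = None

    def fold_of(self, i: int) -> int:
        return self.folds[i]

    def test_indices(self, fold: int) -> np.ndarray:
        return np.array([i for i, f in self.folds.items() if f == fold])

    def train_indices(self, fold: int) -> np.ndarray:
        return np.array([i for i, f in self.folds.items() if f != fold])


def make_folds(variants: Sequence[IndelVariant], k: int = 10,
               grouping: str = "per_protein",
               cluster_map: Optional[Dict[str, int]] = None,
               seed: int = 0) -> FoldAssignment:
    """Assign variants to *k* folds keeping their groups intact.

    Groups (proteins, or identity clusters via *cluster_map*) are shuffled
    with the seed, ordered by variant count descending, and dealt greedily
    to the currently lightest fold so fold sizes balance.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if grouping == "per_protein":
        group_of = {v.protein_id for v in variants}
        key = lambda v: v.protein_id
    elif grouping == "per_cluster":
        if cluster_map is None:
            raise ValueError("per_cluster grouping needs a cluster_map")
        key = lambda v: cluster_map[v.protein_id]
        group_of = {key(v) for v in variants}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    groups: Dict[object, list] = {}
    for i, v in enumerate(variants):
        groups.setdefault(key(v), []).append(i)
    if len(groups) < k:
        raise ValueError(f"{len(groups)} groups < {k} folds")

    rng = np.random.default_rng(seed)
    items = list(groups.items())
    rng.shuffle(items)
    items.sort(key=lambda kv: -len(kv[1]))  # stable: ties keep shuffled order
    loads = np.zeros(k, dtype=int)
    folds = {}
    for _, idxs in items:
        f = int(np.argmin(loads))
        for i in idxs:
            folds[i] = f
        loads[f] += len(idxs)
    fa = FoldAssignment(folds=folds, grouping=grouping, k=k,
                        cluster_map=cluster_map)
    labels = np.array([v.label for v in variants])
    for f in range(k):
        tr = fa.train_indices(f)
        if len(set(labels[tr])) < 2 and len(set(labels)) >= 2:
            raise ValueError(f"training partition of fold {f} is single-class")
    return fa


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic; ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes required")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def threshold_at_fpr(neutral_scores, fpr: float) -> float:
    """Least cutoff whose empirical FPR on *neutral_scores* is <= *fpr*.

    A variant is called pathogenic when its score is >= the cutoff, so the
    empirical FPR of cutoff ``c`` is ``mean(neutral >= c)``.  With all
    neutral scores equal and ``fpr < 1`` the cutoff lands just above the
    constant (zero neutral variants called).
    """
    s = np.sort(np.asarray(neutral_scores, dtype=float))
    if s.size == 0:
        raise ValueError("neutral scores must be nonempty")
    if not 0.0 < fpr <= 1.0:
        raise ValueError("fpr must be in (0, 1]")
    candidates = np.unique(np.concatenate([s, np.nextafter(s, np.inf)]))
    n = s.size
    for c in candidates:
        if (s >= c).sum() / n <= fpr:
            return float(c)
    return float(candidates[-1])  # unreachable: last candidate has FPR 0


def score_percentile(scores, percentile: float = 95.0) -> float:
    """Percentile cutoff of a score distribution (e.g. the 95th percentile
    of the neutral cohort, used to flag 'predicted' variants)."""
    return float(np.percentile(np.asarray(scores, dtype=float), percentile))


def confusion_metrics(scores, labels, cutoff: float) -> dict:
    """Accuracy, balanced accuracy, sensitivity and specificity at a cutoff.

    Balanced accuracy is the mean of sensitivity and specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes required")
    pred = (scores >= cutoff).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "accuracy": (tp + tn) / labels.size,
        "balanced_accuracy": 0.5 * (sens + spec),
        "sensitivity": sens,
        "specificity": spec,
    }


def roc_points(scores, labels) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int),
                              np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


#: Named experiment presets mirroring the published training ablations.
#: ``variant_filter`` acts on (variant) and ``protein_filter`` on (protein);
#: ``drop_groups`` removes feature groups before training.
EXPERIMENT_PRESETS = {
    "default": {},
    "include_singletons": {"keep_ac1": True},
    "canonical_only": {"protein_filter": lambda p: p.canonical},
    "insertions_only": {"variant_filter": lambda v: v.kind == "insertion"},
    "deletions_only": {"variant_filter": lambda v: v.kind == "deletion"},
    "complex_only": {"variant_filter": lambda v: v.kind == "complex"},
    "no_conservation": {"drop_groups": ("conservation",)},
    "no_gene": {"drop_groups": ("gene",)},
    "no_composition": {"drop_groups": ("composition",)},
    "no_functional_w4": {"drop_groups": ("functional_w4",)},
    "no_functional_w20": {"drop_groups": ("functional_w20",)},
    "no_functional_whole": {"drop_groups": ("functional_whole",)},
    "no_homolog": {"drop_groups": ("homolog",)},
}


@dataclass
class CVResult:
    """Cross-validated scores plus per-fold and pooled metrics."""

    scores: np.ndarray
    labels: np.ndarray
    fold_of: np.ndarray
    per_fold_auc: list
    auc: float

    def summary(self) -> dict:
        return {"auc": self.auc,
                "per_fold_auc": self.per_fold_auc,
                "n": int(self.labels.size)}


def cross_validate(variants: Sequence[IndelVariant], proteins: dict,
                   feature_config: FeatureConfig,
                   classifier_config: Optional[ClassifierConfig] = None,
                   k: int = 10, grouping: str = "per_protein",
                   cluster_map: Optional[Dict[str, int]] = None,
                   seed: int = 0,
                   drop_groups: Sequence[str] = ()) -> CVResult:
    """Grouped k-fold cross-validation of the full pipeline.

    Features are assembled once; for each fold the preprocessor and the
    ensemble are fitted on the training partition only and scores are
    produced for the held-out partition, so no per-fold leakage occurs.
    """
    classifier_config = classifier_config or ClassifierConfig()
    X = assemble_feature_matrix(variants, proteins, feature_config)
    if drop_groups:
        from .features import feature_groups
        gmap = feature_groups(feature_config)
        keep = [c for c in X.columns if gmap[c] not in set(drop_groups)]
        X = X[keep]
    y = np.array([1.0 if v.label == "pathogenic" else 0.0 for v in variants])
    fa = make_folds(variants, k=k, grouping=grouping,
                    cluster_map=cluster_map, seed=seed)
    scores = np.full(len(variants), np.nan)
    fold_of = np.array([fa.fold_of(i) for i in range(len(variants))])
    per_fold = []
    for f in range(k):
        tr, te = fa.train_indices(f), fa.test_indices(f)
        cfg = ClassifierConfig(**{**classifier_config.__dict__,
                                  "seed": classifier_config.seed + f})
        pp = fit_preprocessor(X.iloc[tr], y[tr],
                              cfg.t_test_p, cfg.retained_variance)
        model = train_ensemble(X.iloc[tr], y[tr], cfg, preprocessor=pp)
        scores[te] = predict_scores(model, X.iloc[te])
        if len(np.unique(y[te])) == 2:
            per_fold.append(roc_auc(scores[te], y[te]))
    return CVResult(scores=scores, labels=y, fold_of=fold_of,
                    per_fold_auc=per_fold, auc=roc_auc(scores, y))
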