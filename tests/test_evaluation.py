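"""Cross-validation protocols, ROC/AUC, thresholds and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from indelfx.evaluation import (cluster_by_identity, confusion_metrics,
                                make_folds, percent_identity, roc_auc,
                                threshold_at_fpr)
from indelfx.synthetic import _substitute
from indelfx.variants import AA_ALPHABET, IndelVariant, ProteinRecord


def random_protein(pid, L=200, seed=0):
    rng = np.random.default_rng(seed)
    return ProteinRecord(pid, "".join(rng.choice(list(AA_ALPHABET), L)))


def mutated_copy(base, fraction, pid, seed):
    rng = np.random.default_rng(seed)
    return ProteinRecord(pid, _substitute(rng, base.sequence, fraction))


def test_identical_sequences_cluster_together():
    a = random_protein("A")
    b = ProteinRecord("B", a.sequence)
    assert len(set(cluster_by_identity([a, b]).values())) == 1


def test_single_linkage_transitivity():
    # A~B at ~60%, B~C at ~55%, A~C well below threshold
    a = random_protein("A", seed=1)
    b = mutated_copy(a, 0.40, "B", seed=2)
    c = mutated_copy(b, 0.45, "C", seed=3)
    assert percent_identity(a.sequence, b.sequence) >= 55
    assert percent_identity(b.sequence, c.sequence) >= 50
    assert percent_identity(a.sequence, c.sequence) < 50
    clusters = cluster_by_identity([a, b, c])
    assert len(set(clusters.values())) == 1


def test_random_proteins_are_singletons():
    proteins = [random_protein(f"P{i}", seed=100 + i) for i in range(10)]
    clusters = cluster_by_identity(proteins)
    assert len(set(clusters.values())) == 10
    # brute-force check: every pair really is below threshold
    for i in range(10):
        for j in range(i + 1, 10):
            assert percent_identity(proteins[i].sequence,
                                    proteins[j].sequence) < 50


def variants_on(proteins, per_protein=2):
    out = []
    for k, p in enumerate(proteins):
        for j in range(per_protein):
            pos = 5 + j
            label = "pathogenic" if k % 2 == 0 else "neutral"
            out.append(IndelVariant(p.protein_id, pos, pos,
                                    p.sequence[pos - 1], "", label=label))
    return out


def test_per_protein_folds_do_not_split_proteins():
    proteins = [random_protein(f"P{i}", seed=i) for i in range(20)]
    variants = variants_on(proteins)
    fa = make_folds(variants, k=10, grouping="per_protein", seed=0)
    fold_by_protein = {}
    for i, v in enumerate(variants):
        fold_by_protein.setdefault(v.protein_id, set()).add(fa.fold_of(i))
    assert all(len(folds) == 1 for folds in fold_by_protein.values())
    assert all(len(fa.test_indices(f)) >= 1 for f in range(10))


def test_per_cluster_folds_keep_chain_together():
    a = random_protein("A", seed=1)
    b = mutated_copy(a, 0.40, "B", seed=2)
    c = mutated_copy(b, 0.45, "C", seed=3)
    others = [random_protein(f"P{i}", seed=50 + i) for i in range(12)]
    proteins = [a, b, c] + others
    variants = variants_on(proteins)
    cmap = cluster_by_identity(proteins)
    fa = make_folds(variants, k=5, grouping="per_cluster",
                    cluster_map=cmap, seed=0)
    chain_folds = {fa.fold_of(i) for i, v in enumerate(variants)
                   if v.protein_id in ("A", "B", "C")}
    assert len(chain_folds) == 1


def test_folds_deterministic_and_reject_too_few_groups():
    proteins = [random_protein(f"P{i}", seed=i) for i in range(20)]
    variants = variants_on(proteins)
    f1 = make_folds(variants, k=10, seed=3)
    f2 = make_folds(variants, k=10, seed=3)
    assert f1.folds == f2.folds
    with pytest.raises(ValueError):
        make_folds(variants[:4], k=10)


def auc_bruteforce(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0
                for p in pos for n in neg)
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize("scores,labels,expected", [
    ([0, 0, 1, 1], [0, 0, 1, 1], 1.0),
    ([0.5] * 6, [0, 1, 0, 1, 0, 1], 0.5),
    # brute-force pairwise concordance: all 4 pos/neg pairs concordant
    ([0.1, 0.4, 0.35, 0.8], [0, 1, 0, 1], 1.0),
    # 6 pos/neg pairs: 4 concordant, 1 tie (counts 1/2), 1 discordant
    ([0.1, 0.4, 0.4, 0.8, 0.2], [0, 1, 0, 1, 1], 4.5 / 6),
])
def test_roc_auc_examples(scores, labels, expected):
    assert roc_auc(scores, labels) == pytest.approx(expected)


def test_roc_auc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 2**31 - 1))
def test_roc_auc_matches_pairwise_concordance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 200))
    scores = np.round(rng.uniform(size=n), 2)  # coarse grid forces ties
    labels = rng.integers(0, 2, size=n)
    if len(np.unique(labels)) < 2:
        labels[0], labels[1] = 0, 1
    assert roc_auc(scores, labels) == pytest.approx(
        auc_bruteforce(scores, labels))


def test_threshold_at_fpr_equally_spaced():
    # 10 equally spaced neutral scores at fpr=0.10: the least valid cutoff
    # leaves exactly the top value at or above it
    scores = np.linspace(0.0, 0.9, 10)
    cut = threshold_at_fpr(scores, 0.10)
    assert (scores >= cut).sum() == 1
    assert sorted(scores)[-2] < cut <= scores.max()


def test_threshold_at_fpr_limit_and_constant():
    scores = np.linspace(0.1, 0.9, 9)
    assert threshold_at_fpr(scores, 1.0) <= scores.min()
    const = np.full(20, 0.3)
    cut = threshold_at_fpr(const, 0.10)
    assert cut > 0.3
    assert (const >= cut).sum() == 0


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 2**31 - 1))
def test_threshold_at_fpr_is_least_valid_cutoff(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.uniform(size=int(rng.integers(1, 50))), 2)
    fpr = float(rng.uniform(0.01, 0.5))
    cut = threshold_at_fpr(scores, fpr)
    n = scores.size
    assert (scores >= cut).sum() / n <= fpr
    # enumeration oracle: no smaller candidate cutoff satisfies the bound
    candidates = np.unique(np.concatenate(
        [scores, np.nextafter(scores, np.inf)]))
    valid = [c for c in candidates if (scores >= c).sum() / n <= fpr]
    assert cut == pytest.approx(min(valid))


@pytest.mark.parametrize("tp,fn,tn,fp,acc,bacc", [
    (50, 0, 50, 0, 1.0, 1.0),
    (50, 0, 0, 50, 0.5, 0.5),     # all-pathogenic calls on a balanced set
    (80, 20, 90, 10, 0.85, 0.85),
])
def test_confusion_metrics(tp, fn, tn, fp, acc, bacc):
    scores = np.concatenate([np.ones(tp), np.zeros(fn),
                             np.zeros(tn), np.ones(fp)])
    labels = np.concatenate([np.ones(tp + fn), np.zeros(tn + fp)])
    m = confusion_metrics(scores, labels, cutoff=0.5)
    assert m["accuracy"] == pytest.approx(acc)
    assert m["balanced_accuracy"] == pytest.approx(bacc)
    assert m["balanced_accuracy"] == pytest.approx(
        0.5 * (m["sensitivity"] + m["specificity"]))
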