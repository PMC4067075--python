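"""SVM classification protocols.

Binary protocol: linear SVMs per descriptor block, trained on
mirror-augmented 4:1 splits, decision threshold tuned on the training
set for equal false-positive and false-negative counts; at test time
each instance is scored on both its original and mirrored version and
the decision values are summed, with shape+appearance fusion by adding
the two block scores.  Forced choice: all pairwise classifiers vote
probabilistically (Platt-calibrated decision values); an instance takes
the label with the highest summed vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC


@dataclass
class FeatureSet:
    """Instances of one group: ids, features and mirrored-image features."""

    ids: list[str]
    x: np.ndarray
    x_mirror: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        if self.x_mirror is None:
            self.x_mirror = self.x
        self.x_mirror = np.asarray(self.x_mirror, float)
        if len(self.ids) != len(self.x) or self.x.shape != self.x_mirror.shape:
            raise ValueError("ids/features/mirror features disagree")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "FeatureSet":
        return FeatureSet([self.ids[i] for i in idx], self.x[idx],
                          self.x_mirror[idx])


def _split(n: int, test_fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    return idx[n_test:], idx[:n_test]


def _equal_error_threshold(dec_pos: np.ndarray, dec_neg: np.ndarray) -> float:
    """Threshold with #false positives == #false negatives on training.

    Sweeps midpoints of the sorted decision values and returns the
    threshold minimizing |FP - FN| (ties resolved to the midpoint of
    the optimal interval).
    """
    values = np.sort(np.concatenate([dec_pos, dec_neg]))
    cuts = np.concatenate([
        [values[0] - 1.0],
        (values[:-1] + values[1:]) / 2.0,
        [values[-1] + 1.0],
    ])
    fp = np.array([(dec_neg >= c).sum() for c in cuts])
    fn = np.array([(dec_pos < c).sum() for c in cuts])
    gap = np.abs(fp - fn)
    best = np.where(gap == gap.min())[0]
    return float(cuts[best].mean())


@dataclass
class PairClassifier:
    svm: SVC
    threshold: float
    train_ids: set
    test_pos: FeatureSet
    test_neg: FeatureSet


@dataclass
class BinaryProtocolResult:
    pair: tuple[str, str]
    block_accuracy: dict
    fused_accuracy: float
    thresholds: dict


def train_binary_pair(
    g1: FeatureSet,
    g2: FeatureSet,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> PairClassifier:
    """Linear SVM distinguishing g1 (positive) from g2 on a 4:1 split.

    Training uses each instance and its mirror; the decision threshold
    is tuned on training summed (original + mirror) decision values for
    equal error counts.
    """
    if len(g1) < 5 or len(g2) < 5:
        raise ValueError("each group needs at least 5 instances")
    rng = np.random.default_rng(seed)
    tr1, te1 = _split(len(g1), test_fraction, rng)
    tr2, te2 = _split(len(g2), test_fraction, rng)
    g1_tr, g1_te = g1.subset(tr1), g1.subset(te1)
    g2_tr, g2_te = g2.subset(tr2), g2.subset(te2)

    x_train = np.vstack([g1_tr.x, g1_tr.x_mirror, g2_tr.x, g2_tr.x_mirror])
    y_train = np.concatenate([np.ones(2 * len(g1_tr)),
                              np.zeros(2 * len(g2_tr))])
    svm = SVC(kernel="linear", C=1.0)
    svm.fit(x_train, y_train)

    dec_pos = (svm.decision_function(g1_tr.x)
               + svm.decision_function(g1_tr.x_mirror))
    dec_neg = (svm.decision_function(g2_tr.x)
               + svm.decision_function(g2_tr.x_mirror))
    thr = _equal_error_threshold(dec_pos, dec_neg)
    train_ids = set(g1_tr.ids) | set(g2_tr.ids)
    return PairClassifier(svm, thr, train_ids, g1_te, g2_te)


def _summed_scores(clf: PairClassifier, fs: FeatureSet) -> np.ndarray:
    return (clf.svm.decision_function(fs.x)
            + clf.svm.decision_function(fs.x_mirror))


def evaluate_binary_mirrored(
    classifiers: dict[str, PairClassifier],
    pair: tuple[str, str] = ("G1", "G2"),
) -> BinaryProtocolResult:
    """Evaluate per-block classifiers and their fusion on the test split.

    ``classifiers`` maps block names (e.g. "shape", "appearance") to
    classifiers trained on the *same* split.  Per block, an instance's
    score is the sum of the decision values of its original and mirror
    versions; fusion adds the threshold-centred block scores.
    """
    blocks = list(classifiers)
    ref = classifiers[blocks[0]]
    test_ids = set(ref.test_pos.ids) | set(ref.test_neg.ids)
    for name in blocks:
        clf = classifiers[name]
        if set(clf.test_pos.ids) | set(clf.test_neg.ids) != test_ids:
            raise ValueError("blocks evaluated on different test splits")
        if clf.train_ids & test_ids:
            raise ValueError("leakage: test instance present in training")

    block_acc = {}
    fused_pos = np.zeros(len(ref.test_pos))
    fused_neg = np.zeros(len(ref.test_neg))
    for name in blocks:
        clf = classifiers[name]
        sp = _summed_scores(clf, clf.test_pos) - clf.threshold
        sn = _summed_scores(clf, clf.test_neg) - clf.threshold
        block_acc[name] = float(((sp >= 0).sum() + (sn < 0).sum())
                                / (len(sp) + len(sn)))
        fused_pos += sp
        fused_neg += sn
    fused_acc = float(((fused_pos >= 0).sum() + (fused_neg < 0).sum())
                      / (len(fused_pos) + len(fused_neg)))
    return BinaryProtocolResult(pair, block_acc, fused_acc,
                                {n: classifiers[n].threshold for n in blocks})


def repeat_binary_protocol(
    g1_blocks: dict[str, FeatureSet],
    g2_blocks: dict[str, FeatureSet],
    repeats: int = 10,
    seed: int = 0,
    pair: tuple[str, str] = ("G1", "G2"),
) -> list[BinaryProtocolResult]:
    """The 10-repeat binary protocol with fresh random splits."""
    out = []
    for r in range(repeats):
        classifiers = {
            name: train_binary_pair(g1_blocks[name], g2_blocks[name],
                                    seed=seed + r)
            for name in g1_blocks
        }
        out.append(evaluate_binary_mirrored(classifiers, pair))
    return out


@dataclass
class ConfusionMatrix:
    labels: list
    counts: np.ndarray   # rows true class, columns predicted (avg of repeats)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


def forced_choice_classify(
    groups: dict[object, FeatureSet],
    seed: int = 0,
    repeats: int = 10,
    test_fraction: float = 0.2,
) -> ConfusionMatrix:
    """Multi-way assignment by probabilistic pairwise voting.

    Per repeat each group is split 4:1; a linear SVM is trained for
    every pair (28 classifiers for 8 groups).  Decision values are
    mapped to probabilities by a logistic (Platt) fit on the training
    decisions; presenting instance i to the (j vs k) classifier casts a
    vote of weight P for j and 1-P for k.  The instance takes the label
    with the highest vote total; the confusion matrix is averaged over
    repeats.
    """
    labels = list(groups)
    n_cls = len(labels)
    if n_cls != 8:
        warnings.warn(f"forced choice designed for 8 groups, got {n_cls}; "
                      f"using C({n_cls},2) pairwise classifiers")
    if any(len(g) < 5 for g in groups.values()):
        raise ValueError("each group needs at least 5 instances")

    acc_counts = np.zeros((n_cls, n_cls))
    for r in range(repeats):
        rng = np.random.default_rng(seed + 1000 * r)
        splits = {}
        for lab in labels:
            tr, te = _split(len(groups[lab]), test_fraction, rng)
            splits[lab] = (groups[lab].subset(tr), groups[lab].subset(te))

        votes = {lab: np.zeros((len(splits[lab][1]), n_cls))
                 for lab in labels}
        for a in range(n_cls):
            for b in range(a + 1, n_cls):
                ga_tr, gb_tr = splits[labels[a]][0], splits[labels[b]][0]
                x = np.vstack([ga_tr.x, ga_tr.x_mirror,
                               gb_tr.x, gb_tr.x_mirror])
                y = np.concatenate([np.ones(2 * len(ga_tr)),
                                    np.zeros(2 * len(gb_tr))])
                svm = SVC(kernel="linear", C=1.0).fit(x, y)
                platt = LogisticRegression(max_iter=1000).fit(
                    svm.decision_function(x).reshape(-1, 1), y)
                for lab in labels:
                    te = splits[lab][1]
                    dec = 0.5 * (svm.decision_function(te.x)
                                 + svm.decision_function(te.x_mirror))
                    p = platt.predict_proba(dec.reshape(-1, 1))[:, 1]
                    votes[lab][:, a] += p
                    votes[lab][:, b] += 1.0 - p
        for ti, lab in enumerate(labels):
            pred = np.argmax(votes[lab], axis=1)
            for p in pred:
                acc_counts[ti, p] += 1
    return ConfusionMatrix(labels, acc_counts / repeats)
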