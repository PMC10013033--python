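"""Epoch-ensemble psychosis-risk score.

Each corrected epoch is summarised by the covariance matrix of the DNMnet
channels; bagged classification trees are trained on PD epochs (label 1)
versus HC epochs (label 0).  A subject's risk is the mean hard label the
ensemble assigns to their epochs, R_k = (1/n_k) sum_i O_i, which lies in
[0, 1].  UHR epochs are never used for training; they are only scored.

Cross-validated accuracy is computed with all epochs of a subject kept in
the same fold, so a subject can never appear on both sides of a split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import GroupKFold
from sklearn.tree import DecisionTreeClassifier

from dnmcrit.dnmnet import DNMnet
from dnmcrit.epochs_io import CorrectedEpochs

__all__ = [
    "RiskResult",
    "epoch_features",
    "train_ensemble",
    "subject_risk",
    "risk_accuracy",
    "estimate_risk",
]


@dataclass(frozen=True)
class RiskResult:
    """Per-subject risks plus cohort-level summaries."""

    subject_ids: tuple[str, ...]
    groups: tuple[str, ...]
    risks: np.ndarray
    training_accuracy: float
    cv_accuracy: float
    risk_accuracy: dict[str, float]


def epoch_features(corrected: CorrectedEpochs, net: DNMnet) -> np.ndarray:
    """Per-epoch covariance features over the DNMnet channels.

    For each epoch the sample covariance (over time, ddof=1) of the
    node-index-sorted DNMnet channels is computed; the feature vector is its
    upper triangle including the diagonal in row-major order, so m nodes
    give m(m+1)/2 features.
    """
    nodes = sorted(net.nodes)
    if len(nodes) < 2:
        raise ValueError("epoch_features: the network needs at least two nodes")
    d = corrected.data[:, nodes, :]  # epoch x m x T
    mean = d.mean(axis=2, keepdims=True)
    c = d - mean
    n_t = d.shape[2]
    cov = np.einsum("eit,ejt->eij", c, c) / (n_t - 1)
    iu = np.triu_indices(len(nodes))
    return cov[:, iu[0], iu[1]]


def train_ensemble(
    features: np.ndarray,
    labels: np.ndarray,
    subject_ids,
    n_trees: int = 100,
    cv_folds: int = 5,
    seed: int = 0,
):
    """Bagged classification trees on epoch features.

    Returns ``(classifier, training_accuracy, cv_accuracy)`` where training
    accuracy is resubstitution accuracy (1 − loss) and CV accuracy is
    subject-grouped k-fold accuracy (all epochs of a subject share a fold).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    if np.unique(labels).size < 2:
        raise ValueError("train_ensemble: both classes must be present")

    def _make(rs):
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=rs),
            n_estimators=n_trees,
            random_state=rs,
        )

    clf = _make(seed)
    clf.fit(features, labels)
    training_accuracy = float(np.mean(clf.predict(features) == labels))

    n_groups = np.unique(subject_ids).size
    folds = min(cv_folds, n_groups)
    correct = 0
    for k, (tr, te) in enumerate(
        GroupKFold(n_splits=folds).split(features, labels, groups=subject_ids)
    ):
        assert not set(subject_ids[tr]) & set(subject_ids[te])
        if np.unique(labels[tr]).size < 2:
            continue
        fold_clf = _make(seed + k + 1)
        fold_clf.fit(features[tr], labels[tr])
        correct += int(np.sum(fold_clf.predict(features[te]) == labels[te]))
    cv_accuracy = correct / features.shape[0]
    return clf, training_accuracy, cv_accuracy


def subject_risk(classifier, features: np.ndarray) -> float:
    """Mean hard predicted label over a subject's epochs (R_k in [0, 1])."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 1:
        raise ValueError("subject_risk: no epochs")
    return float(np.mean(classifier.predict(features)))


def risk_accuracy(risks, group_labels, subject_ids=None) -> dict[str, float]:
    """The four cohort risk-accuracy indices.

    Risks are sorted ascending (ties broken by a stable sort on subject id);
    with group sizes n_HC, n_UHR, n_PD the indices are the fraction of HC
    subjects among the n_HC smallest risks, of UHR among the middle n_UHR,
    of PD among the n_PD largest, and of UHR+PD ("disease") among the
    n_UHR + n_PD largest.
    """
    risks = np.asarray(risks, dtype=float)
    groups = np.asarray(group_labels)
    if subject_ids is None:
        subject_ids = np.arange(risks.size)
    subject_ids = np.asarray(subject_ids)
    order = np.lexsort((subject_ids, risks))  # stable: risk, then subject id
    g = groups[order]
    n_hc = int(np.sum(groups == "HC"))
    n_uhr = int(np.sum(groups == "UHR"))
    n_pd = int(np.sum(groups == "PD"))
    out = {}
    if n_hc:
        out["HC"] = float(np.mean(g[:n_hc] == "HC"))
    if n_uhr:
        out["UHR"] = float(np.mean(g[n_hc:n_hc + n_uhr] == "UHR"))
    if n_pd:
        out["PD"] = float(np.mean(g[-n_pd:] == "PD"))
    if n_uhr + n_pd:
        tail = g[-(n_uhr + n_pd):]
        out["disease"] = float(np.mean(np.isin(tail, ("UHR", "PD"))))
    return out


def estimate_risk(
    study: list[CorrectedEpochs],
    net: DNMnet,
    n_trees: int = 100,
    cv_folds: int = 5,
    seed: int = 0,
) -> RiskResult:
    """End-to-end risk scoring of a cohort of corrected-epoch sets.

    Trains on HC (0) and PD (1) epochs only, scores every subject including
    UHR, and reports the cohort risk-accuracy indices.
    """
    feats = {s.subject_id: epoch_features(s, net) for s in study}
    train_x, train_y, train_sid = [], [], []
    for s in study:
        if s.group not in ("HC", "PD"):
            continue
        f = feats[s.subject_id]
        train_x.append(f)
        train_y.append(np.full(f.shape[0], 1 if s.group == "PD" else 0))
        train_sid.append(np.full(f.shape[0], s.subject_id, dtype=object))
    if not train_x:
        raise ValueError("estimate_risk: no HC/PD training subjects")
    clf, train_acc, cv_acc = train_ensemble(
        np.vstack(train_x),
        np.concatenate(train_y),
        np.concatenate(train_sid),
        n_trees=n_trees,
        cv_folds=cv_folds,
        seed=seed,
    )
    sids = tuple(s.subject_id for s in study)
    groups = tuple(s.group for s in study)
    risks = np.array([subject_risk(clf, feats[sid]) for sid in sids])
    return RiskResult(
        subject_ids=sids,
        groups=groups,
        risks=risks,
        training_accuracy=train_acc,
        cv_accuracy=cv_acc,
        risk_accuracy=risk_accuracy(risks, groups, sids),
    )
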