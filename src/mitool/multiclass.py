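"""Multi-class classifier topologies over CSP features and binary SVMs.

Four structures for a K-class (typically four-class) motor-imagery task:

* **OVR** — K one-vs-rest SVMs, each on its own OVR-CSP features; exactly
  one +1 decides the class, otherwise the maximal decision value does (with
  an ambiguity flag).
* **OVO** — K(K−1)/2 pairwise SVMs on OVO-CSP features; majority vote, ties
  broken by summed signed decision values toward each tied class, then by
  smallest class id.
* **DAG** — the same pairwise nodes arranged as Platt's decision DAG: start
  with the smallest-vs-largest class pair and eliminate the loser until one
  class survives (K−1 evaluations; a root error cannot be recovered).
* **two-layer** — a two-level tree for K=4: one SVM separates two class
  groups (default {1,2} vs {3,4}) on group-pooled CSP features, then one
  pairwise SVM inside the chosen group (2 evaluations).

Every node owns its own CSP model (features are pairing-specific) and its
(C, g) is chosen by cross-validated grid search on that node's training
subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import CspModel, csp_features, features_for, fit_csp
from .signal_io import EpochSet
from .svm import BinarySvmModel, SvmParams, decision_value, grid_search_cv, train_binary

SCHEMES = ("ovr", "ovo", "dag", "two_layer")


@dataclass
class _Node:
    """One binary decision unit: CSP features → standardization → SVM."""

    csp: CspModel
    svm: BinarySvmModel
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    role: str
    pair: tuple  # what +1 / -1 mean: (pos, neg); entries are class ids or tuples of ids

    def decision(self, epoch: np.ndarray) -> float:
        f = csp_features(self.csp, epoch)
        f = (f - self.scaler_mean) / self.scaler_std
        return decision_value(self.svm, f)


@dataclass
class MulticlassModel:
    scheme: str
    classes: list[int]
    nodes: list[_Node]
    grouping: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    config: dict = field(default_factory=dict)

    @property
    def n_svms(self) -> int:
        return len(self.nodes)


def _fit_node(
    epochs_A: EpochSet,
    epochs_B: EpochSet,
    pair: tuple,
    role: str,
    csp_m: int,
    csp_reg: float,
    svm_cfg: dict,
) -> _Node:
    model = fit_csp(epochs_A, epochs_B, m=csp_m, reg=csp_reg)
    model.class_pair = pair
    X = np.vstack([features_for(model, epochs_A), features_for(model, epochs_B)])
    y = np.concatenate([np.ones(epochs_A.n_epochs, dtype=int), -np.ones(epochs_B.n_epochs, dtype=int)])

    result = grid_search_cv(
        X,
        y,
        C_grid=svm_cfg.get("C_grid"),
        g_grid=svm_cfg.get("g_grid"),
        K=svm_cfg.get("K", 5),
        seed=svm_cfg.get("seed", 0),
        standardize=svm_cfg.get("standardize", True),
    )
    C, g = result.best
    if svm_cfg.get("standardize", True):
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        mu, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
    svm = train_binary((X - mu) / sd, y, SvmParams(C=C, kernel="rbf", g=g))
    return _Node(csp=model, svm=svm, scaler_mean=mu, scaler_std=sd, role=role, pair=pair)


def train_multiclass(
    epochs: EpochSet,
    scheme: str = "ovo",
    csp_m: int = 2,
    csp_reg: float = 0.0,
    svm_config: dict | None = None,
    grouping: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
) -> MulticlassModel:
    """Train one of the four topologies on labeled epochs."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    svm_cfg = dict(svm_config or {})
    classes = [int(k) for k in epochs.classes]
    K = len(classes)
    if K < 2:
        raise ValueError("at least 2 classes required")
    for k in classes:
        if not np.any(epochs.labels == k):
            raise ValueError(f"class {k} has no epochs")

    nodes: list[_Node] = []
    if scheme == "ovr":
        for k in classes:
            A = epochs.select(epochs.labels == k)
            B = epochs.select(epochs.labels != k)
            nodes.append(_fit_node(A, B, (k, "rest"), f"ovr:{k}", csp_m, csp_reg, svm_cfg))
    elif scheme in ("ovo", "dag"):
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                A = epochs.select(epochs.labels == a)
                B = epochs.select(epochs.labels == b)
                nodes.append(_fit_node(A, B, (a, b), f"pair:{a}-{b}", csp_m, csp_reg, svm_cfg))
    else:  # two_layer
        if grouping is None:
            if K != 4:
                raise ValueError("two_layer requires K = 4 or an explicit grouping")
            grouping = (tuple(classes[:2]), tuple(classes[2:]))
        ga, gb = tuple(grouping[0]), tuple(grouping[1])
        if sorted(ga + gb) != sorted(classes):
            raise ValueError("grouping must partition the class set")
        A = epochs.select(np.isin(epochs.labels, ga))
        B = epochs.select(np.isin(epochs.labels, gb))
        nodes.append(_fit_node(A, B, (ga, gb), "layer1", csp_m, csp_reg, svm_cfg))
        for grp in (ga, gb):
            if len(grp) == 1:
                continue
            if len(grp) != 2:
                raise ValueError("two_layer groups must hold 1 or 2 classes")
            A = epochs.select(epochs.labels == grp[0])
            B = epochs.select(epochs.labels == grp[1])
            nodes.append(_fit_node(A, B, (grp[0], grp[1]), f"layer2:{grp[0]}-{grp[1]}", csp_m, csp_reg, svm_cfg))
        grouping = (ga, gb)

    return MulticlassModel(
        scheme=scheme,
        classes=classes,
        nodes=nodes,
        grouping=grouping,
        config={"csp_m": csp_m, "csp_reg": csp_reg, "svm": svm_cfg},
    )


def predict_ovr(model: MulticlassModel, epoch: np.ndarray) -> tuple[int, dict]:
    """OVR rule: a single +1 wins outright; otherwise argmax decision value."""
    if model.scheme != "ovr":
        raise ValueError("model is not an OVR model")
    values = np.array([node.decision(epoch) for node in model.nodes])
    positive = np.flatnonzero(values > 0)
    if positive.size == 1:
        k = model.classes[positive[0]]
        ambiguous = False
    else:
        k = model.classes[int(np.argmax(values))]
        ambiguous = True
    return k, {"decision_values": dict(zip(model.classes, values)), "ambiguous": ambiguous}


def predict_ovo(model: MulticlassModel, epoch: np.ndarray) -> tuple[int, dict]:
    """Pairwise voting; ties → summed signed decisions, then smallest id."""
    if model.scheme not in ("ovo", "dag"):
        raise ValueError("model is not a pairwise model")
    votes = {k: 0 for k in model.classes}
    margin = {k: 0.0 for k in model.classes}
    for node in model.nodes:
        a, b = node.pair
        d = node.decision(epoch)
        votes[a if d >= 0 else b] += 1
        margin[a] += d
        margin[b] -= d
    top = max(votes.values())
    tied = [k for k in model.classes if votes[k] == top]
    if len(tied) > 1:
        best_margin = max(margin[k] for k in tied)
        tied = [k for k in tied if margin[k] == best_margin]
    winner = min(tied)
    return winner, {"votes": votes, "margins": margin}


def predict_dag(model: MulticlassModel, epoch: np.ndarray) -> tuple[int, dict]:
    """Platt's DAG: test smallest-vs-largest surviving class, drop the loser."""
    if model.scheme != "dag":
        raise ValueError("model is not a DAG model")
    node_by_pair = {node.pair: node for node in model.nodes}
    alive = list(model.classes)
    path = []
    while len(alive) > 1:
        a, b = alive[0], alive[-1]
        node = node_by_pair[(a, b)]
        d = node.decision(epoch)
        loser = b if d >= 0 else a
        path.append({"pair": (a, b), "decision": d, "eliminated": loser})
        alive.remove(loser)
    return alive[0], {"path": path}


def predict_two_layer(model: MulticlassModel, epoch: np.ndarray) -> tuple[int, dict]:
    """Layer 1 picks the class group, layer 2 the class within it."""
    if model.scheme != "two_layer":
        raise ValueError("model is not a two-layer model")
    root = model.nodes[0]
    d1 = root.decision(epoch)
    group = root.pair[0] if d1 >= 0 else root.pair[1]
    decisions = {"layer1": d1, "group": group}
    if len(group) == 1:
        return group[0], decisions
    node = next(n for n in model.nodes[1:] if set(n.pair) == set(group))
    d2 = node.decision(epoch)
    decisions["layer2"] = d2
    return (node.pair[0] if d2 >= 0 else node.pair[1]), decisions


_PREDICTORS = {
    "ovr": predict_ovr,
    "ovo": predict_ovo,
    "dag": predict_dag,
    "two_layer": predict_two_layer,
}


def predict_epoch(model: MulticlassModel, epoch: np.ndarray) -> int:
    """Predicted class id for one channels × samples epoch."""
    return _PREDICTORS[model.scheme](model, epoch)[0]


def predict_all(model: MulticlassModel, epochs: EpochSet) -> np.ndarray:
    return np.array([predict_epoch(model, ep) for ep in epochs.data])


def evaluate(model: MulticlassModel, test: EpochSet) -> tuple[float, np.ndarray]:
    """Accuracy in percent and a K × K confusion matrix (rows = true)."""
    if test.n_epochs == 0:
        raise ValueError("empty test set")
    pred = predict_all(model, test)
    classes = model.classes
    index = {k: i for i, k in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(test.labels, pred):
        confusion[index[int(t)], index[int(p)]] += 1
    accuracy = 100.0 * np.trace(confusion) / test.n_epochs
    return accuracy, confusion
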