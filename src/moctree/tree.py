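"""Recursive-partitioning model for heterogeneous treatment effects.

Trees are grown best-first: every expandable node is scored by its best
candidate split under the configured criterion, and the node with the highest
such score is expanded next, until ``max_splits`` internal nodes exist or no
valid candidate remains.  Best-first growth makes "compare methods at the
same number of splits" well-defined across criteria.  Rows with feature value
``<= threshold`` are routed left; this convention is fixed and recorded in the
serialized model.

With ``honest=True`` the training rows are split 50/50 (seeded): one half
selects the splits, the other re-estimates every leaf effect, removing the
selection bias of estimating on the same data that chose the partition.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .criteria import Criterion, SplitCandidate, scan_feature_splits
from .data_model import (
    DatasetError,
    InestimableNodeError,
    ObservationalDataset,
    as_node_index,
    estimate_node_cate,
    estimate_propensity,
    transformed_outcome,
)
from .pareto import EmptyArchiveError, EpsilonArchive, EpsilonParams

__all__ = [
    "TreeConfig",
    "TreeNode",
    "TreeModel",
    "enumerate_candidate_splits",
    "grow_tree",
    "predict_cate",
    "serialize",
    "deserialize",
]

SERIAL_FORMAT = "moctree-tree"
SERIAL_VERSION = 1


@dataclass(frozen=True)
class TreeConfig:
    """Growth configuration; the snapshot suffices to regrow the tree.

    ``min_leaf`` is the minimum child size and ``min_arm`` the minimum number
    of treated and of control samples per child (at least 1 is always
    enforced so every node's effect stays estimable).
    """

    criterion: Criterion = Criterion.MO
    eps1: float = 0.1
    eps2: float = 0.1
    selection_rule: str = "max_hete"
    max_splits: int = 10
    min_leaf: int = 50
    min_arm: int = 2
    honest: bool = False
    seed: int | None = None
    propensity_method: str = "auto"
    propensity_clip: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "criterion", Criterion(self.criterion))
        if self.max_splits < 0:
            raise ValueError(f"max_splits must be >= 0, got {self.max_splits}")
        if self.min_leaf < 1 or self.min_arm < 1:
            raise ValueError("min_leaf and min_arm must be >= 1")
        EpsilonParams(self.eps1, self.eps2)
        if self.selection_rule not in ("max_hete", "max_fit"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")


@dataclass
class TreeNode:
    """Internal node (with children and split) or leaf (tau_hat only)."""

    tau_hat: float
    n: int
    n_treated: int
    n_control: int
    feature_index: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    fit: float | None = None
    hete: float | None = None
    archive_size: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class TreeModel:
    """A grown tree plus the configuration that produced it."""

    root: TreeNode
    config: TreeConfig
    n_splits: int
    n_features: int
    feature_names: tuple[str, ...] | None = None

    def predict(self, X) -> np.ndarray:
        return predict_cate(self, X)


# ---------------------------------------------------------------------------
# candidate enumeration


def enumerate_candidate_splits(
    dataset: ObservationalDataset,
    node,
    config: TreeConfig = TreeConfig(),
) -> list[SplitCandidate]:
    """All valid candidate splits of a node, ordered by (feature, threshold).

    Thresholds are midpoints between consecutive distinct sorted values of
    the node members; candidates whose children would violate the minimum
    size or single-arm rules are excluded.
    """
    rows = as_node_index(node, dataset.n)
    y = dataset.outcome[rows]
    w = np.asarray(dataset.treatment, dtype=np.float64)[rows]
    e = np.full(rows.size, 0.5)  # validity masks do not depend on e
    out: list[SplitCandidate] = []
    for f in range(dataset.p):
        xv = dataset.covariates[rows, f]
        res = scan_feature_splits(xv, y, w, e, config.min_leaf, config.min_arm)
        if res is None:
            continue
        for thr in res["threshold"]:
            mask = xv <= thr
            out.append(
                SplitCandidate(
                    feature_index=f,
                    threshold=float(thr),
                    left_rows=rows[mask],
                    right_rows=rows[~mask],
                )
            )
    return out


# ---------------------------------------------------------------------------
# growth


@dataclass
class _Chosen:
    feature: int
    threshold: float
    fit: float
    hete: float
    priority: float
    archive_size: int | None = None


def _best_split(
    dataset: ObservationalDataset,
    rows: np.ndarray,
    propensity: np.ndarray,
    config: TreeConfig,
    tot_y: np.ndarray | None,
) -> _Chosen | None:
    crit = config.criterion
    y = dataset.outcome[rows]
    w = np.asarray(dataset.treatment, dtype=np.float64)[rows]
    e = propensity[rows]
    need_ts = crit is Criterion.TS
    sse_target = None
    if crit is Criterion.RT:
        sse_target = dataset.outcome
    elif crit is Criterion.TOT:
        sse_target = tot_y
    if crit is Criterion.MO:
        archive = EpsilonArchive(EpsilonParams(config.eps1, config.eps2))
        blocks: list[tuple[int, dict]] = []  # (start_id, per-feature arrays)
        offsets: list[int] = []
        total = 0
        for f in range(dataset.p):
            res = scan_feature_splits(
                dataset.covariates[rows, f], y, w, e, config.min_leaf, config.min_arm
            )
            if res is None:
                continue
            archive.bulk_insert(res["fit"], res["hete"], start_id=total)
            blocks.append((f, res))
            offsets.append(total)
            total += res["threshold"].size
        if total == 0:
            return None
        pair = archive.select(config.selection_rule)
        cid = int(pair.candidate_id)
        block = bisect_right(offsets, cid) - 1
        f, res = blocks[block]
        local = cid - offsets[block]
        return _Chosen(
            feature=f,
            threshold=float(res["threshold"][local]),
            fit=float(res["fit"][local]),
            hete=float(res["hete"][local]),
            priority=pair.hete if config.selection_rule == "max_hete" else pair.fit,
            archive_size=len(archive),
        )
    key = {
        Criterion.MH: "hete",
        Criterion.CT: "fit",
        Criterion.TS: "ts",
        Criterion.RT: "vr",
        Criterion.TOT: "vr",
    }[crit]
    best: _Chosen | None = None
    for f in range(dataset.p):
        res = scan_feature_splits(
            dataset.covariates[rows, f],
            y,
            w,
            e,
            config.min_leaf,
            config.min_arm,
            need_ts=need_ts,
            sse_target=sse_target,
        )
        if res is None:
            continue
        scores = res[key]
        k = int(np.argmax(scores))  # first max -> lowest threshold on ties
        score = float(scores[k])
        if best is None or score > best.priority:
            best = _Chosen(
                feature=f,
                threshold=float(res["threshold"][k]),
                fit=float(res["fit"][k]),
                hete=float(res["hete"][k]),
                priority=score,
            )
    return best


def _node_stats(
    dataset: ObservationalDataset, rows: np.ndarray, propensity: np.ndarray
) -> tuple[float, int, int]:
    tau = estimate_node_cate(dataset, rows, propensity)
    n_t = int(np.sum(dataset.treatment[rows]))
    return tau, n_t, rows.size - n_t


def grow_tree(dataset: ObservationalDataset, config: TreeConfig = TreeConfig()) -> TreeModel:
    """Grow a treatment-effect tree under the configured splitting criterion."""
    propensity = estimate_propensity(
        dataset, config.propensity_method, config.propensity_clip
    )
    all_rows = np.arange(dataset.n, dtype=np.intp)
    if config.honest:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(dataset.n)
        split_rows = np.sort(perm[: dataset.n // 2]).astype(np.intp)
        est_rows = np.sort(perm[dataset.n // 2 :]).astype(np.intp)
        if split_rows.size == 0 or est_rows.size == 0:
            raise DatasetError("honest mode requires at least two samples")
    else:
        split_rows, est_rows = all_rows, None

    tot_y = None
    if config.criterion is Criterion.TOT:
        tot_y = transformed_outcome(dataset, float(np.mean(propensity)))

    tau, n_t, n_c = _node_stats(dataset, split_rows, propensity)  # root estimable
    root = TreeNode(tau_hat=tau, n=split_rows.size, n_treated=n_t, n_control=n_c)

    # best-first frontier: (priority, insertion seq) -> expand highest priority
    frontier: list[tuple[float, int, TreeNode, np.ndarray, _Chosen]] = []
    seq = 0

    def consider(node: TreeNode, rows: np.ndarray) -> None:
        nonlocal seq
        chosen = _best_split(dataset, rows, propensity, config, tot_y)
        if chosen is not None:
            frontier.append((chosen.priority, seq, node, rows, chosen))
            seq += 1

    if config.max_splits > 0:
        consider(root, split_rows)
    n_splits = 0
    while frontier and n_splits < config.max_splits:
        best_i = 0
        for i in range(1, len(frontier)):
            if frontier[i][0] > frontier[best_i][0]:
                best_i = i
        _, _, node, rows, chosen = frontier.pop(best_i)
        mask = dataset.covariates[rows, chosen.feature] <= chosen.threshold
        left_rows, right_rows = rows[mask], rows[~mask]
        tau_l, t_l, c_l = _node_stats(dataset, left_rows, propensity)
        tau_r, t_r, c_r = _node_stats(dataset, right_rows, propensity)
        node.feature_index = chosen.feature
        node.threshold = chosen.threshold
        node.fit = chosen.fit
        node.hete = chosen.hete
        node.archive_size = chosen.archive_size
        node.left = TreeNode(tau_hat=tau_l, n=left_rows.size, n_treated=t_l, n_control=c_l)
        node.right = TreeNode(tau_hat=tau_r, n=right_rows.size, n_treated=t_r, n_control=c_r)
        n_splits += 1
        if n_splits < config.max_splits:
            consider(node.left, left_rows)
            consider(node.right, right_rows)

    if est_rows is not None:
        _reestimate_leaves(root, dataset, est_rows, propensity)

    return TreeModel(
        root=root,
        config=config,
        n_splits=n_splits,
        n_features=dataset.p,
        feature_names=dataset.feature_names,
    )


def _reestimate_leaves(
    node: TreeNode,
    dataset: ObservationalDataset,
    rows: np.ndarray,
    propensity: np.ndarray,
) -> None:
    """Honest mode: recompute leaf effects on the estimation half.

    A leaf whose estimation-half rows lack a treatment arm keeps its
    split-half estimate (documented fallback).
    """
    if node.is_leaf:
        n_t = int(np.sum(dataset.treatment[rows])) if rows.size else 0
        n_c = rows.size - n_t
        node.n, node.n_treated, node.n_control = rows.size, n_t, n_c
        if n_t >= 1 and n_c >= 1:
            node.tau_hat = estimate_node_cate(dataset, rows, propensity)
        return
    mask = dataset.covariates[rows, node.feature_index] <= node.threshold
    _reestimate_leaves(node.left, dataset, rows[mask], propensity)
    _reestimate_leaves(node.right, dataset, rows[~mask], propensity)


# ---------------------------------------------------------------------------
# prediction


def predict_cate(model: TreeModel, X) -> np.ndarray:
    """Route rows to leaves (``value <= threshold`` -> left) and return τ̂."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise DatasetError(
            f"input has {X.shape[1]} features, model expects {model.n_features}"
        )
    out = np.empty(X.shape[0])

    def walk(node: TreeNode, idx: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.tau_hat
            return
        mask = X[idx, node.feature_index] <= node.threshold
        walk(node.left, idx[mask])
        walk(node.right, idx[~mask])

    walk(model.root, np.arange(X.shape[0]))
    return out


# ---------------------------------------------------------------------------
# serialization


def _node_to_dict(node: TreeNode) -> dict:
    d = {
        "tau_hat": node.tau_hat,
        "n": node.n,
        "n_treated": node.n_treated,
        "n_control": node.n_control,
    }
    if not node.is_leaf:
        d.update(
            kind="split",
            feature_index=node.feature_index,
            threshold=node.threshold,
            fit=node.fit,
            hete=node.hete,
            archive_size=node.archive_size,
            left=_node_to_dict(node.left),
            right=_node_to_dict(node.right),
        )
    else:
        d["kind"] = "leaf"
    return d


def _node_from_dict(d: dict) -> TreeNode:
    try:
        kind = d["kind"]
        node = TreeNode(
            tau_hat=float(d["tau_hat"]),
            n=int(d["n"]),
            n_treated=int(d["n_treated"]),
            n_control=int(d["n_control"]),
        )
        if kind == "split":
            node.feature_index = int(d["feature_index"])
            node.threshold = float(d["threshold"])
            node.fit = d.get("fit")
            node.hete = d.get("hete")
            node.archive_size = d.get("archive_size")
            node.left = _node_from_dict(d["left"])
            node.right = _node_from_dict(d["right"])
        elif kind != "leaf":
            raise ValueError(f"unknown node kind {kind!r}")
    except KeyError as exc:
        raise ValueError(f"malformed tree document: missing field {exc}") from exc
    return node


def serialize(model: TreeModel) -> str:
    """Versioned JSON document; byte-identical for identical models."""
    cfg = dataclasses.asdict(model.config)
    cfg["criterion"] = model.config.criterion.value
    doc = {
        "format": SERIAL_FORMAT,
        "version": SERIAL_VERSION,
        "split_rule": "le_goes_left",
        "config": cfg,
        "n_splits": model.n_splits,
        "n_features": model.n_features,
        "feature_names": list(model.feature_names) if model.feature_names else None,
        "root": _node_to_dict(model.root),
    }
    return json.dumps(doc, sort_keys=True, indent=1)


def deserialize(text: str) -> TreeModel:
    """Parse a serialized tree; malformed documents raise ``ValueError``."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed tree document: {exc}") from exc
    if doc.get("format") != SERIAL_FORMAT:
        raise ValueError("not a moctree tree document")
    if doc.get("version") != SERIAL_VERSION:
        raise ValueError(f"unsupported tree document version {doc.get('version')!r}")
    try:
        cfg = TreeConfig(**doc["config"])
        names = doc.get("feature_names")
        return TreeModel(
            root=_node_from_dict(doc["root"]),
            config=cfg,
            n_splits=int(doc["n_splits"]),
            n_features=int(doc["n_features"]),
            feature_names=tuple(names) if names else None,
        )
    except KeyError as exc:
        raise ValueError(f"malformed tree document: missing field {exc}") from exc
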