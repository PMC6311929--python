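"""Splitting criteria for treatment-effect trees.

Every criterion scores a candidate split of a node into a left child (feature
value ≤ threshold) and a right child:

* ``ct`` — fitness: ``C_fit = n_L·τ̂_L² + n_R·τ̂_R²``, the causal-tree
  maximization surrogate for the (unobservable) MSE of the effect estimates.
* ``mh`` — heterogeneity: ``C_hete = (τ̂_L − τ̂_R)²``, rewarding splits whose
  children differ most in estimated effect.
* ``mo`` — multi-objective: keeps the ``(C_fit, C_hete)`` pair of every
  candidate and lets the ε-dominance archive pick a balanced winner.
* ``ts`` — squared t-statistic for equal child effects.
* ``rt`` / ``tot`` — CART variance reduction on the raw / transformed outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .data_model import (
    InestimableNodeError,
    ObservationalDataset,
    as_node_index,
    estimate_node_cate,
)

__all__ = [
    "Criterion",
    "SplitCandidate",
    "ScorePair",
    "InvalidCandidateError",
    "fit_score",
    "hete_score",
    "ts_score",
    "variance_reduction_score",
    "score_split",
    "scan_feature_splits",
]

TS_VARIANCE_FLOOR = 1e-12


class Criterion(str, Enum):
    """Closed set of split-selection criteria."""

    MH = "mh"
    MO = "mo"
    CT = "ct"
    TS = "ts"
    TOT = "tot"
    RT = "rt"


class InvalidCandidateError(ValueError):
    """A candidate split violates the child-node requirements."""


@dataclass(frozen=True)
class SplitCandidate:
    """One candidate split: rows with ``x[feature] <= threshold`` go left."""

    feature_index: int
    threshold: float
    left_rows: np.ndarray
    right_rows: np.ndarray


@dataclass(frozen=True, slots=True)
class ScorePair:
    """The ``(C_fit, C_hete)`` score pair attached to one candidate split."""

    fit: float
    hete: float
    candidate_id: object = None

    def __post_init__(self) -> None:
        if not (self.fit >= 0.0 and self.hete >= 0.0):
            raise ValueError("score components must be finite and >= 0")
        if math.isinf(self.fit) or math.isinf(self.hete):
            raise ValueError("score components must be finite and >= 0")


def fit_score(tau_l: float, tau_r: float, n_l: int, n_r: int) -> float:
    """Fitness score ``n_L·τ̂_L² + n_R·τ̂_R²`` (higher is better)."""
    if n_l < 1 or n_r < 1:
        raise InvalidCandidateError("child nodes must be non-empty")
    return float(n_l * tau_l**2 + n_r * tau_r**2)


def hete_score(tau_l: float, tau_r: float) -> float:
    """Heterogeneity score ``(τ̂_L − τ̂_R)²``."""
    return float((tau_l - tau_r) ** 2)


def ts_score(
    tau_l: float,
    tau_r: float,
    var_l: float,
    var_r: float,
    n_l: int,
    n_r: int,
    n: int,
) -> float:
    """Squared t-statistic ``n·(τ̂_L − τ̂_R)² / (σ²_L/n_L + σ²_R/n_R)``."""
    denom = var_l / n_l + var_r / n_r
    if denom <= 0.0:
        raise InvalidCandidateError("zero variance denominator in t-statistic")
    return float(n * (tau_l - tau_r) ** 2 / denom)


def variance_reduction_score(parent_y, left_y, right_y) -> float:
    """CART impurity decrease: ``SSE(parent) − SSE(left) − SSE(right)``."""
    parent_y = np.asarray(parent_y, dtype=np.float64)
    left_y = np.asarray(left_y, dtype=np.float64)
    right_y = np.asarray(right_y, dtype=np.float64)
    if left_y.size + right_y.size != parent_y.size:
        raise InvalidCandidateError("children must partition the parent")

    def sse(v: np.ndarray) -> float:
        return float(np.sum((v - v.mean()) ** 2)) if v.size else 0.0

    return sse(parent_y) - sse(left_y) - sse(right_y)


def score_split(
    dataset: ObservationalDataset,
    propensity: np.ndarray,
    candidate: SplitCandidate,
) -> ScorePair:
    """Score one candidate split: both children estimated, both scores emitted.

    Raises :class:`InvalidCandidateError` when either child lacks a treatment
    arm (such candidates are rejected during enumeration).
    """
    left = as_node_index(candidate.left_rows, dataset.n)
    right = as_node_index(candidate.right_rows, dataset.n)
    if np.intersect1d(left, right).size:
        raise InvalidCandidateError("child nodes overlap")
    try:
        tau_l = estimate_node_cate(dataset, left, propensity)
        tau_r = estimate_node_cate(dataset, right, propensity)
    except InestimableNodeError as exc:
        raise InvalidCandidateError(str(exc)) from exc
    return ScorePair(
        fit=fit_score(tau_l, tau_r, left.size, right.size),
        hete=hete_score(tau_l, tau_r),
        candidate_id=candidate,
    )


def scan_feature_splits(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    e: np.ndarray,
    min_leaf: int,
    min_arm: int,
    *,
    need_ts: bool = False,
    sse_target: np.ndarray | None = None,
) -> dict | None:
    """Score every valid threshold of one feature for a node, vectorized.

    ``x, y, w, e`` are already restricted to the node's member rows.  Valid
    thresholds are midpoints between consecutive distinct sorted values whose
    children each hold ``min_leaf`` samples and ``min_arm`` samples per
    treatment arm (at least one per arm always).  Returns ``None`` if no valid
    candidate exists, otherwise a dict of equal-length arrays: ``threshold``,
    ``n_l``, ``n_r``, ``tau_l``, ``tau_r``, ``fit``, ``hete`` and, on request,
    ``ts`` (pooled per-arm child variances, sample variance with a floor) and
    ``vr`` (variance reduction on ``sse_target``).
    """
    min_arm = max(int(min_arm), 1)
    min_leaf = max(int(min_leaf), 1)
    n = x.size
    if n < 2 * min_leaf or n < 2 * 2 * min_arm:
        return None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    cut = np.nonzero(xs[:-1] < xs[1:])[0]
    if cut.size == 0:
        return None
    ws = np.asarray(w, dtype=np.float64)[order]
    n_l = cut + 1
    n_r = n - n_l
    nt = np.cumsum(ws)
    nt_total = nt[-1]
    nt_l = nt[cut]
    nc_l = n_l - nt_l
    nt_r = nt_total - nt_l
    nc_r = n_r - nt_r
    valid = (
        (n_l >= min_leaf)
        & (n_r >= min_leaf)
        & (nt_l >= min_arm)
        & (nc_l >= min_arm)
        & (nt_r >= min_arm)
        & (nc_r >= min_arm)
    )
    if not valid.any():
        return None
    cut = cut[valid]
    n_l, n_r = n_l[valid], n_r[valid]
    nt_l, nc_l, nt_r, nc_r = nt_l[valid], nc_l[valid], nt_r[valid], nc_r[valid]
    ys = y[order]
    es = e[order]

    def left(v: np.ndarray) -> np.ndarray:
        return np.cumsum(v)[cut]

    a = left(ws * ys / es)
    b = left(ws / es)
    c = left((1.0 - ws) * ys / (1.0 - es))
    d = left((1.0 - ws) / (1.0 - es))
    a_tot, b_tot = np.sum(ws * ys / es), np.sum(ws / es)
    c_tot = np.sum((1.0 - ws) * ys / (1.0 - es))
    d_tot = np.sum((1.0 - ws) / (1.0 - es))
    tau_l = a / b - c / d
    tau_r = (a_tot - a) / (b_tot - b) - (c_tot - c) / (d_tot - d)
    out = {
        "threshold": (xs[cut] + xs[cut + 1]) / 2.0,
        "n_l": n_l,
        "n_r": n_r,
        "tau_l": tau_l,
        "tau_r": tau_r,
        "fit": n_l * tau_l**2 + n_r * tau_r**2,
        "hete": (tau_l - tau_r) ** 2,
    }
    if need_ts:
        st = left(ws * ys)
        stt = left(ws * ys**2)
        sc = left((1.0 - ws) * ys)
        scc = left((1.0 - ws) * ys**2)
        st_tot, stt_tot = np.sum(ws * ys), np.sum(ws * ys**2)
        sc_tot = np.sum((1.0 - ws) * ys)
        scc_tot = np.sum((1.0 - ws) * ys**2)

        def samp_var(sy, syy, m):
            with np.errstate(invalid="ignore", divide="ignore"):
                v = (syy - sy**2 / m) / (m - 1)
            return np.where(m >= 2, np.maximum(v, 0.0), 0.0)

        var_l = samp_var(st, stt, nt_l) + samp_var(sc, scc, nc_l)
        var_r = samp_var(st_tot - st, stt_tot - stt, nt_r) + samp_var(
            sc_tot - sc, scc_tot - scc, nc_r
        )
        denom = np.maximum(var_l / n_l + var_r / n_r, TS_VARIANCE_FLOOR)
        out["ts"] = n * (tau_l - tau_r) ** 2 / denom
    if sse_target is not None:
        z = np.asarray(sse_target, dtype=np.float64)[order]
        sz, szz = left(z), left(z**2)
        sz_tot, szz_tot = float(np.sum(z)), float(np.sum(z**2))
        sse_parent = szz_tot - sz_tot**2 / n
        sse_l = szz - sz**2 / n_l
        sse_r = (szz_tot - szz) - (sz_tot - sz) ** 2 / n_r
        out["vr"] = sse_parent - sse_l - sse_r
    return out
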