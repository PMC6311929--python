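"""Synthetic benchmark designs, error metrics, and the criterion comparison.

Each design draws i.i.d. standard-normal covariates, a randomized treatment
``W ~ Bernoulli(P)`` with ``P = 0.5``, Gaussian noise, and the outcome

    Y = m(x) + α·(2W − 1)·τ(x) + σ,

so the actual conditional average treatment effect of the generated data is
``E[Y(1) − Y(0) | x] = 2·α·τ(x)``.  ``SimulatedDataset.true_tau`` carries the
design's τ(x) formula values and ``SimulatedDataset.cate`` the effect on the
outcome scale (``2·α·true_tau``), which is what estimators are evaluated
against.

Designs (active covariates / total p / α):

1. ``m = x₁/2 + x₂``, ``τ = x₁/2`` — p=2, α=0.5.
2. ``m = ½Σ₁⁴xₖ + Σ₅⁸xₖ``, ``τ = Σ₁⁴ 1{xₖ>0}·xₖ`` — 12 noise covariates
   (p=20), α=1.
3. Same functions as design 2 with 50 noise covariates (p=58), α=1.
4. ``m`` as design 2, ``τ = Σ₁⁴ sin(xₖ) + Σ₅⁸ xₖ^{k−3}`` — nonlinear effect,
   p=20, α=1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .criteria import Criterion
from .data_model import ObservationalDataset
from .tree import TreeConfig, grow_tree, predict_cate

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "DESIGNS",
    "get_design",
    "mean_outcome",
    "true_tau",
    "generate_design",
    "rmse",
    "wrmse",
    "run_benchmark",
]


@dataclass(frozen=True)
class SimulationDesign:
    """One data-generating process: design id, dimension, α, noise, P."""

    design_id: int
    p: int
    alpha: float
    noise_sd: float = 1.0
    propensity: float = 0.5

    _ACTIVE = {1: 2, 2: 8, 3: 8, 4: 8}

    def __post_init__(self) -> None:
        if self.design_id not in self._ACTIVE:
            raise ValueError(f"unknown design id {self.design_id}")
        if self.p < self._ACTIVE[self.design_id]:
            raise ValueError(
                f"design {self.design_id} needs p >= {self._ACTIVE[self.design_id]}"
            )
        if self.alpha <= 0.0:
            raise ValueError("alpha must be positive")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.propensity < 1.0:
            raise ValueError("propensity must lie strictly in (0, 1)")


DESIGNS: dict[int, SimulationDesign] = {
    1: SimulationDesign(1, p=2, alpha=0.5),
    2: SimulationDesign(2, p=20, alpha=1.0),
    3: SimulationDesign(3, p=58, alpha=1.0),
    4: SimulationDesign(4, p=20, alpha=1.0),
}


def get_design(design, **overrides) -> SimulationDesign:
    """Resolve an id or design object, optionally overriding fields."""
    if isinstance(design, SimulationDesign):
        return replace(design, **overrides) if overrides else design
    return replace(DESIGNS[int(design)], **overrides) if overrides else DESIGNS[int(design)]


def _as_matrix(design: SimulationDesign, x) -> tuple[np.ndarray, bool]:
    X = np.asarray(x, dtype=np.float64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != design.p:
        raise ValueError(f"expected {design.p} covariates, got {X.shape[1]}")
    return X, single


def mean_outcome(design, x):
    """Treatment-independent mean component m(x)."""
    design = get_design(design)
    X, single = _as_matrix(design, x)
    if design.design_id == 1:
        m = 0.5 * X[:, 0] + X[:, 1]
    else:
        m = 0.5 * X[:, :4].sum(axis=1) + X[:, 4:8].sum(axis=1)
    return float(m[0]) if single else m


def true_tau(design, x):
    """Design τ(x) formula evaluated exactly at each row."""
    design = get_design(design)
    X, single = _as_matrix(design, x)
    if design.design_id == 1:
        t = 0.5 * X[:, 0]
    elif design.design_id in (2, 3):
        head = X[:, :4]
        t = np.where(head > 0.0, head, 0.0).sum(axis=1)
    else:
        powers = np.arange(5, 9) - 3  # exponents 2..5 for x5..x8
        t = np.sin(X[:, :4]).sum(axis=1) + (X[:, 4:8] ** powers).sum(axis=1)
    return float(t[0]) if single else t


@dataclass(frozen=True)
class SimulatedDataset:
    """Generated study data plus its ground truth."""

    dataset: ObservationalDataset
    true_tau: np.ndarray
    design: SimulationDesign

    @property
    def cate(self) -> np.ndarray:
        """Actual treatment effect of the DGP, ``2·α·τ(x)``."""
        return 2.0 * self.design.alpha * self.true_tau


def generate_design(design, n: int, seed=None, **overrides) -> SimulatedDataset:
    """Draw ``n`` samples from a design; fully reproducible given ``seed``."""
    design = get_design(design, **overrides)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, design.p))
    w = (rng.random(n) < design.propensity).astype(np.int8)
    noise = (
        rng.normal(0.0, design.noise_sd, n) if design.noise_sd > 0 else np.zeros(n)
    )
    tau = true_tau(design, X)
    y = mean_outcome(design, X) + design.alpha * (2.0 * w - 1.0) * tau + noise
    ds = ObservationalDataset(
        covariates=X,
        outcome=y,
        treatment=w,
        propensity=np.full(n, design.propensity),
        feature_names=tuple(f"x{k + 1}" for k in range(design.p)),
    )
    return SimulatedDataset(dataset=ds, true_tau=tau, design=design)


def rmse(tau_hat, tau_true) -> float:
    """Root mean squared error between estimated and true effects."""
    tau_hat = np.asarray(tau_hat, dtype=np.float64).ravel()
    tau_true = np.asarray(tau_true, dtype=np.float64).ravel()
    if tau_hat.size != tau_true.size or tau_hat.size == 0:
        raise ValueError("vectors must have equal, nonzero length")
    return float(np.sqrt(np.mean((tau_hat - tau_true) ** 2)))


def wrmse(tau_hat, tau_true) -> float:
    """Sign-weighted RMSE: weight 1 on sign disagreements, 0.1 otherwise.

    Squared errors get weight 1 when ``τ·τ̂ < 0`` (the estimate points the
    wrong way) and 0.1 when ``τ·τ̂ > 0``; a zero product also takes 0.1 since
    no sign disagreement is demonstrated.
    """
    tau_hat = np.asarray(tau_hat, dtype=np.float64).ravel()
    tau_true = np.asarray(tau_true, dtype=np.float64).ravel()
    if tau_hat.size != tau_true.size or tau_hat.size == 0:
        raise ValueError("vectors must have equal, nonzero length")
    weights = np.where(tau_hat * tau_true < 0.0, 1.0, 0.1)
    return float(np.sqrt(np.mean(weights * (tau_hat - tau_true) ** 2)))


def _cell_seed(seed: int, design_id: int, n: int, rep: int, role: int):
    return np.random.SeedSequence(entropy=seed, spawn_key=(design_id, n, rep, role))


def run_benchmark(
    designs,
    criteria,
    sample_sizes,
    max_splits_grid,
    n_reps: int,
    seed: int = 0,
    *,
    n_test: int | None = None,
    min_leaf: int = 50,
    min_arm: int = 2,
    eps1: float = 0.1,
    eps2: float = 0.1,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Compare splitting criteria at equal split counts on fresh draws.

    For each (design, n, rep) an independent training and test set is drawn
    (test size defaults to ``n``); each criterion is fitted at every split
    count of ``max_splits_grid`` and scored by test-set RMSE/wRMSE against
    the DGP's actual CATE.  Per-rep seeds are a pure function of
    ``(seed, design, n, rep)``, so adding reps never perturbs earlier rows.
    Fit errors are recorded per cell in the ``error`` column, not raised.
    """
    records = []
    for design in designs:
        d = get_design(design, **({"noise_sd": noise_sd} if noise_sd is not None else {}))
        for n in sample_sizes:
            for rep in range(n_reps):
                train = generate_design(d, n, _cell_seed(seed, d.design_id, n, rep, 0))
                test = generate_design(
                    d, n_test or n, _cell_seed(seed, d.design_id, n, rep, 1)
                )
                for crit in criteria:
                    for splits in max_splits_grid:
                        row = {
                            "design": d.design_id,
                            "n": n,
                            "criterion": Criterion(crit).value,
                            "splits": splits,
                            "rep": rep,
                            "rmse": np.nan,
                            "wrmse": np.nan,
                            "error": None,
                        }
                        try:
                            cfg = TreeConfig(
                                criterion=crit,
                                max_splits=splits,
                                min_leaf=min_leaf,
                                min_arm=min_arm,
                                eps1=eps1,
                                eps2=eps2,
                                seed=seed,
                            )
                            model = grow_tree(train.dataset, cfg)
                            pred = predict_cate(model, test.dataset.covariates)
                            row["rmse"] = rmse(pred, test.cate)
                            row["wrmse"] = wrmse(pred, test.cate)
                        except Exception as exc:  # recorded, not fatal
                            row["error"] = f"{type(exc).__name__}: {exc}"
                        records.append(row)
    return pd.DataFrame.from_records(
        records,
        columns=["design", "n", "criterion", "splits", "rep", "rmse", "wrmse", "error"],
    )
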