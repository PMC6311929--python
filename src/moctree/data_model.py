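"""Observational-study data container and treatment-effect primitives.

The package works on tabular study data: one row per sample carrying numeric
covariates ``x``, a binary treatment indicator ``W``, an observed outcome ``Y``
and optionally a known propensity score ``e(x) = Pr(W = 1 | x)``.  Under the
potential-outcomes model each sample has two outcomes ``Y(0)``/``Y(1)`` of
which only ``Y = W·Y(1) + (1−W)·Y(0)`` is observed; assuming unconfoundedness
(treatment independent of the potential outcomes given ``x``) the conditional
average treatment effect (CATE) within a subgroup can be estimated by inverse
propensity weighting, which :func:`estimate_node_cate` implements as a
ratio-of-sums difference between the weighted treated and control means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "InestimableNodeError",
    "ObservationalDataset",
    "validate_dataset",
    "read_csv",
    "estimate_propensity",
    "estimate_node_cate",
    "transformed_outcome",
    "as_node_index",
]


class DatasetError(ValueError):
    """Input data violate the observational-study contract."""


class InestimableNodeError(ValueError):
    """A node lacks treated or control samples, so its CATE is undefined."""


@dataclass(frozen=True)
class ObservationalDataset:
    """Validated study data.

    Parameters
    ----------
    covariates
        ``(n, p)`` float matrix of pre-treatment covariates.
    outcome
        Length-``n`` observed outcome vector ``Y``.
    treatment
        Length-``n`` binary treatment assignment ``W`` (0 = control,
        1 = treated).
    propensity
        Optional length-``n`` vector of known treatment propensities, each
        strictly inside ``(0, 1)``.
    feature_names
        Optional covariate labels, length ``p``.
    """

    covariates: np.ndarray
    outcome: np.ndarray
    treatment: np.ndarray
    propensity: np.ndarray | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
        y = np.asarray(self.outcome, dtype=np.float64).ravel()
        w_raw = np.asarray(self.treatment).ravel()
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "outcome", y)
        n = X.shape[0]
        if n < 1:
            raise DatasetError("dataset must contain at least one sample")
        if y.shape[0] != n:
            raise DatasetError(
                f"outcome length {y.shape[0]} != number of rows {n}"
            )
        if w_raw.shape[0] != n:
            raise DatasetError(
                f"treatment length {w_raw.shape[0]} != number of rows {n}"
            )
        if not np.all(np.isfinite(X)):
            raise DatasetError("covariates contain missing/non-finite values")
        if not np.all(np.isfinite(y)):
            raise DatasetError("outcome contains missing/non-finite values")
        w_float = np.asarray(w_raw, dtype=np.float64)
        if not np.all(np.isfinite(w_float)):
            raise DatasetError("treatment contains missing/non-finite values")
        bad = np.nonzero(~np.isin(w_float, (0.0, 1.0)))[0]
        if bad.size:
            raise DatasetError(
                f"treatment must be binary (0/1); offending row(s): {bad[:5].tolist()}"
            )
        object.__setattr__(self, "treatment", w_float.astype(np.int8))
        if self.propensity is not None:
            e = np.asarray(self.propensity, dtype=np.float64).ravel()
            if e.shape[0] != n:
                raise DatasetError(
                    f"propensity length {e.shape[0]} != number of rows {n}"
                )
            bad = np.nonzero(~((e > 0.0) & (e < 1.0)))[0]
            if bad.size:
                raise DatasetError(
                    "propensity must lie strictly in (0, 1); "
                    f"offending row(s): {bad[:5].tolist()}"
                )
            object.__setattr__(self, "propensity", e)
        if self.feature_names is not None:
            names = tuple(str(f) for f in self.feature_names)
            if len(names) != X.shape[1]:
                raise DatasetError(
                    f"{len(names)} feature names for {X.shape[1]} covariates"
                )
            object.__setattr__(self, "feature_names", names)

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]


def validate_dataset(
    table: pd.DataFrame,
    outcome_col: str = "Y",
    treatment_col: str = "W",
    propensity_col: str | None = None,
) -> ObservationalDataset:
    """Build an :class:`ObservationalDataset` from a labelled table.

    All numeric columns other than the designated outcome / treatment /
    propensity columns become covariates, in their original order.  Missing
    values anywhere in the used columns are rejected (no imputation).
    """
    table = pd.DataFrame(table)
    for col in (outcome_col, treatment_col) + (
        (propensity_col,) if propensity_col else ()
    ):
        if col not in table.columns:
            raise DatasetError(f"required column {col!r} not found in table")
        na = table.index[table[col].isna()]
        if len(na):
            raise DatasetError(
                f"column {col!r} has missing values at row(s) {list(na[:5])}"
            )
    special = {outcome_col, treatment_col}
    if propensity_col:
        special.add(propensity_col)
    cov_cols = [
        c
        for c in table.columns
        if c not in special and pd.api.types.is_numeric_dtype(table[c])
    ]
    if not cov_cols:
        raise DatasetError("no numeric covariate columns found")
    for c in cov_cols:
        na = table.index[table[c].isna()]
        if len(na):
            raise DatasetError(
                f"covariate column {c!r} has missing values at row(s) {list(na[:5])}"
            )
    return ObservationalDataset(
        covariates=table[cov_cols].to_numpy(dtype=np.float64),
        outcome=table[outcome_col].to_numpy(dtype=np.float64),
        treatment=table[treatment_col].to_numpy(),
        propensity=(
            table[propensity_col].to_numpy(dtype=np.float64)
            if propensity_col
            else None
        ),
        feature_names=tuple(map(str, cov_cols)),
    )


def read_csv(
    path,
    outcome_col: str = "Y",
    treatment_col: str = "W",
    propensity_col: str | None = None,
) -> ObservationalDataset:
    """Read a header-ed CSV (``#`` comment lines allowed) into a dataset."""
    return validate_dataset(
        pd.read_csv(path, comment="#"),
        outcome_col=outcome_col,
        treatment_col=treatment_col,
        propensity_col=propensity_col,
    )


def estimate_propensity(
    dataset: ObservationalDataset,
    method: str = "auto",
    clip: float = 0.01,
) -> np.ndarray:
    """Return a length-``n`` propensity vector strictly inside ``(0, 1)``.

    ``known`` returns the dataset's propensity column unchanged; ``constant``
    returns the empirical treated fraction everywhere (the right choice for
    completely randomized designs); ``logistic`` fits an unpenalized logistic
    regression of ``W`` on the covariates by maximum likelihood and clips the
    fitted probabilities to ``[clip, 1−clip]``.  ``auto`` resolves to ``known``
    when a propensity column exists, else ``constant``.
    """
    if not 0.0 < clip < 0.5:
        raise DatasetError(f"clip must be in (0, 0.5), got {clip}")
    if method == "auto":
        method = "known" if dataset.propensity is not None else "constant"
    if method == "known":
        if dataset.propensity is None:
            raise DatasetError("method='known' requires a propensity column")
        return dataset.propensity
    frac = float(np.mean(dataset.treatment))
    if frac in (0.0, 1.0):
        raise DatasetError(
            "propensity degenerate: all samples are "
            + ("treated" if frac == 1.0 else "control")
        )
    if method == "constant":
        return np.full(dataset.n, frac)
    if method == "logistic":
        from sklearn.linear_model import LogisticRegression

        # C=inf disables regularization: plain maximum likelihood
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        model.fit(dataset.covariates, np.asarray(dataset.treatment))
        proba = model.predict_proba(dataset.covariates)[:, 1]
        return np.clip(proba, clip, 1.0 - clip)
    raise DatasetError(f"unknown propensity method {method!r}")


def as_node_index(rows, n: int) -> np.ndarray:
    """Validate a collection of row indices against a dataset of size ``n``."""
    idx = np.asarray(sorted(rows) if isinstance(rows, (set, frozenset)) else rows)
    idx = idx.astype(np.intp).ravel()
    if idx.size == 0:
        raise DatasetError("node index must be non-empty")
    if idx.min() < 0 or idx.max() >= n:
        raise DatasetError("node index contains out-of-range rows")
    if np.unique(idx).size != idx.size:
        raise DatasetError("node index contains duplicate rows")
    return idx


def estimate_node_cate(
    dataset: ObservationalDataset,
    node,
    propensity: np.ndarray | None = None,
) -> float:
    """Inverse-propensity-weighted CATE over the samples of one node.

    Computes the ratio-of-sums estimator

    .. math::

        \\hat\\tau = \\frac{\\sum_i W_i Y_i / e_i}{\\sum_i W_i / e_i}
                 - \\frac{\\sum_i (1-W_i) Y_i / (1-e_i)}{\\sum_i (1-W_i)/(1-e_i)}

    over the node members.  With a constant propensity this reduces exactly to
    the difference of treated and control sample means.
    """
    if propensity is None:
        propensity = estimate_propensity(dataset)
    rows = as_node_index(node, dataset.n)
    w = np.asarray(dataset.treatment, dtype=np.float64)[rows]
    y = dataset.outcome[rows]
    e = np.asarray(propensity, dtype=np.float64).ravel()
    if e.shape[0] != dataset.n:
        raise DatasetError("propensity vector length mismatch")
    e = e[rows]
    n_t = int(w.sum())
    n_c = int(rows.size - n_t)
    if n_t == 0 or n_c == 0:
        raise InestimableNodeError(
            f"node has {n_t} treated and {n_c} control samples; "
            "both treatment arms are required"
        )
    treated = np.sum(w * y / e) / np.sum(w / e)
    control = np.sum((1.0 - w) * y / (1.0 - e)) / np.sum((1.0 - w) / (1.0 - e))
    return float(treated - control)


def transformed_outcome(dataset: ObservationalDataset, pi: float) -> np.ndarray:
    """Per-sample transformed outcome ``Y·(W − π) / (π·(1 − π))``.

    For a randomized study with constant propensity ``π`` the transformed
    outcome is an unbiased signal of the CATE: ``E[Y^TOT | x] = τ(x)``, so an
    ordinary regression tree on it estimates treatment effects.
    """
    if not 0.0 < pi < 1.0:
        raise DatasetError(f"pi must lie strictly in (0, 1), got {pi}")
    w = np.asarray(dataset.treatment, dtype=np.float64)
    return dataset.outcome * (w - pi) / (pi * (1.0 - pi))
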