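"""Test-set prediction-accuracy metrics for continuous traits.

When a polygenic prediction model trained on one cohort is evaluated on a
held-out test set, "the R-squared" is ambiguous.  Three common definitions are
implemented here, all written directly as the sums they are defined by (so
population- vs sample-variance conventions can never change a result):

``r2`` (squared correlation)
    ``r^2 = [sum (y_i - ybar)(yhat_i - yhatbar)]^2 /
    [sum (y_i - ybar)^2 * sum (yhat_i - yhatbar)^2]``.
    Pure discrimination: invariant to any affine recalibration of the
    predictions, always in ``[0, 1]``.

``R2_1A`` (MSPE relative to the *training*-mean intercept model)
    ``1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar_train)^2``.
    Requires the training-phenotype mean; unbounded below.

``R2_1B`` (MSPE relative to the *test*-mean intercept model)
    ``1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar_test)^2``.
    Computable from the test pairs alone; unbounded below.

The MSPE-based definitions penalise miscalibration: a systematically shifted
prediction can drive them negative while ``r2`` stays high.  Negative values
mean the model predicts worse (in mean squared error) than the corresponding
intercept-only model — an important signal, not a bug.

Degenerate inputs (zero variance in either vector, missing training mean)
raise explicit errors rather than returning NaN or 0, because silent zeros
corrupt method rankings, the central use case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "UndefinedMetricError",
    "TrainMeanUnavailableError",
    "EvalVectors",
    "ReferenceMeans",
    "MetricSet",
    "MetricCI",
    "correlation",
    "squared_correlation",
    "r2_mspe_train_ref",
    "r2_mspe_test_ref",
    "mspe",
    "mae",
    "evaluate",
    "bootstrap_ci",
]

METRIC_NAMES = ("r", "r_squared", "r2_1a", "r2_1b", "mspe", "mae")


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined on the supplied vectors."""


class TrainMeanUnavailableError(UndefinedMetricError):
    """R2_1A requested but the training-phenotype mean is not available.

    The training-referenced definition explicitly depends on the training
    data, so it cannot be computed from test pairs alone.
    """


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(
            f"{name} contains missing or non-finite values; "
            "resolve missingness upstream before evaluation"
        )
    return arr


@dataclass(frozen=True)
class EvalVectors:
    """Paired observed and predicted phenotype values on a test set.

    Both vectors are in trait units, same length ``n >= 2``, no missing
    values (missingness is an upstream concern).
    """

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self):
        obs = _as_vector(self.observed, "observed")
        pred = _as_vector(self.predicted, "predicted")
        if obs.shape != pred.shape:
            raise ValueError(
                f"observed and predicted differ in length: {obs.size} vs {pred.size}"
            )
        if obs.size < 2:
            raise ValueError("at least two test observations are required")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "predicted", pred)

    @property
    def n(self) -> int:
        return int(self.observed.size)

    @property
    def residuals(self) -> np.ndarray:
        """observed - predicted (the sign convention used throughout)."""
        return self.observed - self.predicted


@dataclass(frozen=True)
class ReferenceMeans:
    """Phenotype means of the intercept reference models.

    ``train_mean`` is the phenotype mean on the training data (``None`` when
    unavailable, in which case R2_1A cannot be computed).  ``test_mean`` is
    always the arithmetic mean of the observed test phenotypes.
    """

    test_mean: float
    train_mean: float | None = None

    @classmethod
    def for_test_data(cls, ev: EvalVectors, train_mean: float | None = None
                      ) -> "ReferenceMeans":
        return cls(test_mean=float(ev.observed.mean()), train_mean=train_mean)

    def check_consistent(self, ev: EvalVectors) -> None:
        actual = float(ev.observed.mean())
        scale = max(1.0, abs(actual))
        if abs(self.test_mean - actual) > 1e-8 * scale:
            raise ValueError(
                f"test_mean {self.test_mean} does not match the mean of the "
                f"observed vector ({actual})"
            )


def correlation(ev: EvalVectors) -> float:
    """Signed Pearson correlation r between observed and predicted values.

    Raises :class:`UndefinedMetricError` when either vector has zero variance.
    """
    y = ev.observed
    p = ev.predicted
    yc = y - y.mean()
    pc = p - p.mean()
    syy = float(yc @ yc)
    spp = float(pc @ pc)
    if syy <= 0.0:
        raise UndefinedMetricError(
            "correlation undefined: observed phenotypes have zero variance"
        )
    if spp <= 0.0:
        raise UndefinedMetricError(
            "correlation undefined: predictions have zero variance"
        )
    r = float(yc @ pc) / math.sqrt(syy * spp)
    return min(1.0, max(-1.0, r))


def squared_correlation(ev: EvalVectors) -> float:
    """Squared correlation r^2 between observed and predicted phenotypes.

    Measures discrimination only: invariant to affine transforms of the
    predictions, bounded in [0, 1].  Examine ``correlation`` (and
    scatterplots) alongside it — the underlying association could even be
    negative.
    """
    r = correlation(ev)
    return r * r


def _sse(ev: EvalVectors) -> float:
    resid = ev.observed - ev.predicted
    return float(resid @ resid)


def r2_mspe_train_ref(ev: EvalVectors, ref: ReferenceMeans) -> float:
    """R2_1A: one minus SSE relative to the training-mean intercept model.

    ``1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar_train)^2``.  May be negative
    for miscalibrated models; negative means a constant prediction at the
    training mean would beat the model on this test set.
    """
    if ref.train_mean is None:
        raise TrainMeanUnavailableError(
            "R2_1A not computable: training-phenotype mean unavailable"
        )
    dev = ev.observed - float(ref.train_mean)
    denom = float(dev @ dev)
    if denom <= 0.0:
        raise UndefinedMetricError(
            "R2_1A undefined: observed values all equal the training mean"
        )
    return 1.0 - _sse(ev) / denom


def r2_mspe_test_ref(ev: EvalVectors) -> float:
    """R2_1B: one minus SSE relative to the test-mean intercept model.

    ``1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar_test)^2``.  Equals the
    classical in-sample coefficient of determination when the predictions come
    from an intercept-containing least-squares fit evaluated on its own
    fitting data.  May be negative for miscalibrated models.
    """
    dev = ev.observed - ev.observed.mean()
    denom = float(dev @ dev)
    if denom <= 0.0:
        raise UndefinedMetricError(
            "R2_1B undefined: observed phenotypes are constant on the test set"
        )
    return 1.0 - _sse(ev) / denom


def mspe(ev: EvalVectors) -> float:
    """Mean squared prediction error, ``mean (y_i - yhat_i)^2``."""
    return _sse(ev) / ev.n


def mae(ev: EvalVectors) -> float:
    """Median absolute prediction error (robust companion to the MSPE)."""
    return float(np.median(np.abs(ev.observed - ev.predicted)))


@dataclass(frozen=True)
class MetricSet:
    """All metrics computed on one (population, model) test set.

    Fields that are mathematically undefined on the input are ``None``, with a
    human-readable reason in ``absent`` keyed by metric name; a missing
    training mean likewise leaves ``r2_1a`` absent rather than zero.
    """

    r: float | None
    r_squared: float | None
    r2_1a: float | None
    r2_1b: float | None
    mspe: float
    mae: float
    n_test: int
    absent: Mapping[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "r_squared": self.r_squared,
            "r2_1a": self.r2_1a,
            "r2_1b": self.r2_1b,
            "mspe": self.mspe,
            "mae": self.mae,
            "n_test": self.n_test,
        }


def evaluate(ev: EvalVectors, ref: ReferenceMeans | None = None) -> MetricSet:
    """Compute the full metric set in one pass.

    ``ref`` defaults to test-data-only references (no training mean, so
    ``r2_1a`` is reported absent).  Per-metric degeneracies are recorded as
    absent-with-reason entries instead of failing the whole set.
    """
    if ref is None:
        ref = ReferenceMeans.for_test_data(ev)
    else:
        ref.check_consistent(ev)

    absent: dict[str, str] = {}
    r = r_squared = r2_1a = r2_1b = None
    try:
        r = correlation(ev)
        r_squared = r * r
    except UndefinedMetricError as exc:
        absent["r"] = absent["r_squared"] = str(exc)
    try:
        r2_1a = r2_mspe_train_ref(ev, ref)
    except UndefinedMetricError as exc:
        absent["r2_1a"] = str(exc)
    try:
        r2_1b = r2_mspe_test_ref(ev)
    except UndefinedMetricError as exc:
        absent["r2_1b"] = str(exc)

    return MetricSet(
        r=r,
        r_squared=r_squared,
        r2_1a=r2_1a,
        r2_1b=r2_1b,
        mspe=mspe(ev),
        mae=mae(ev),
        n_test=ev.n,
        absent=absent,
    )


_METRIC_FUNCS = {
    "r": lambda ev, ref: correlation(ev),
    "r_squared": lambda ev, ref: squared_correlation(ev),
    "r2_1a": r2_mspe_train_ref,
    "r2_1b": lambda ev, ref: r2_mspe_test_ref(ev),
    "mspe": lambda ev, ref: mspe(ev),
    "mae": lambda ev, ref: mae(ev),
}


@dataclass(frozen=True)
class MetricCI:
    """Percentile-bootstrap confidence interval for one metric."""

    metric_name: str
    point: float
    lower: float
    upper: float
    level: float
    n_boot: int
    seed: int


def bootstrap_ci(
    ev: EvalVectors,
    ref: ReferenceMeans | None = None,
    metric_name: str = "r2_1b",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> MetricCI:
    """Paired case-resampling percentile bootstrap CI for one metric.

    Individuals (observed, predicted) pairs are resampled with replacement;
    replicates on which the metric is undefined are dropped.  Deterministic
    given ``seed``.  Raises :class:`UndefinedMetricError` if the metric is
    undefined on more than half of the replicates (or on the full data).
    """
    if metric_name not in _METRIC_FUNCS:
        raise ValueError(
            f"unknown metric {metric_name!r}; choose from {sorted(_METRIC_FUNCS)}"
        )
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if ref is None:
        ref = ReferenceMeans.for_test_data(ev)
    func = _METRIC_FUNCS[metric_name]

    # ReferenceMeans.test_mean must track each resample's observed mean.
    point = func(ev, ref)

    rng = np.random.default_rng(seed)
    n = ev.n
    values = []
    failures: dict[str, int] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bev = EvalVectors(ev.observed[idx], ev.predicted[idx])
        bref = ReferenceMeans.for_test_data(bev, train_mean=ref.train_mean)
        try:
            values.append(func(bev, bref))
        except UndefinedMetricError as exc:
            key = str(exc)
            failures[key] = failures.get(key, 0) + 1
    if len(values) < n_boot / 2:
        detail = "; ".join(f"{v}x {k}" for k, v in failures.items())
        raise UndefinedMetricError(
            f"{metric_name} undefined on {n_boot - len(values)}/{n_boot} "
            f"bootstrap replicates ({detail})"
        )
    alpha = 1.0 - level
    lower, upper = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return MetricCI(
        metric_name=metric_name,
        point=float(point),
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_boot=n_boot,
        seed=seed,
    )
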