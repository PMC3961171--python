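"""Single-property likelihood models P(property | substrate class).

Two families are supported, matching the two kinds of input property:

* :class:`CategoricalModel` — a pseudocounted frequency table for categorical
  properties (fold group, localization class, expression cluster, and their
  binary indicator expansions).

* :class:`SteppedModel` — a step function over a continuous domain (pI and
  its windowed extrema) or over a circle (expression onset within the
  300-minute metabolic cycle), with one or two free thresholds fitted by
  maximum likelihood and logistic smoothing between adjacent levels.

The smoothed step blends the two adjacent interval probabilities through a
logistic sigmoid of steepness ``k``: with a single threshold ``t`` and levels
``p1``, ``p2`` the likelihood is ``p1 + (p2 - p1) * sigmoid(k * (x - t))``,
which converges pointwise (off the threshold) to the hard step as k grows.
On a circular domain the blend is applied to the periodic extension of the
step function, so the likelihood is continuous across the wrap point up to
terms of order exp(-k * period) — far below double precision at the default
steepness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .data_model import PosteriorVector, TrainingTable
from .features import property_value

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class SmoothingSpec:
    """Logistic smoothing of the step function.

    ``k`` is the steepness per unit of the property (pH units for pI,
    minutes for onset); ``enabled=False`` gives the hard step.
    """

    enabled: bool = True
    k: float = 0.99

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("smoothing steepness k must be > 0")


@dataclass(frozen=True)
class CategoricalModel:
    """P(value | class) table for one categorical property."""

    property_name: str
    classes: tuple[str, ...]
    values: tuple
    table: np.ndarray  # (n_classes, n_values)
    alpha: float = 0.5

    def __post_init__(self) -> None:
        table = np.asarray(self.table, float)
        object.__setattr__(self, "table", table)
        if table.shape != (len(self.classes), len(self.values)):
            raise ValueError("table shape must be (n_classes, n_values)")
        if np.any(table < 0):
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(table.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each class row must sum to 1")

    def likelihood(self, value) -> np.ndarray:
        """P(value | class) for every class, shape (n_classes,)."""
        try:
            j = self.values.index(value)
        except ValueError:
            raise KeyError(
                f"value {value!r} not in the fitted value set of "
                f"{self.property_name!r}: {self.values}"
            ) from None
        return self.table[:, j].copy()

    def likelihood_array(self, values: Sequence) -> np.ndarray:
        """Stacked likelihoods for a sequence of (non-missing) values."""
        idx = np.array([self.values.index(v) for v in values], int)
        return self.table[:, idx].T  # (N, n_classes)

    @property
    def n_parameters_free(self) -> int:
        return (len(self.values) - 1) * len(self.classes)

    def to_dict(self) -> dict:
        return {
            "kind": "categorical",
            "property_name": self.property_name,
            "classes": list(self.classes),
            "values": list(self.values),
            "table": [[round(float(p), 12) for p in row] for row in self.table],
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoricalModel":
        values = tuple(bool(v) if isinstance(v, bool) else v for v in d["values"])
        return cls(
            property_name=d["property_name"],
            classes=tuple(d["classes"]),
            values=values,
            table=np.array(d["table"], float),
            alpha=float(d["alpha"]),
        )


@dataclass(frozen=True)
class SteppedModel:
    """Smoothed step-function likelihood for a continuous/circular property.

    ``levels[c, j]`` is the probability that a class-``c`` enzyme's property
    value falls in interval ``j``; per class the levels sum to 1.  On a
    bounded domain m thresholds delimit m+1 intervals; on a circle of period
    ``period`` m thresholds delimit m intervals (interval ``j`` starts at
    ``thresholds[j]`` and wraps after the last threshold).
    """

    property_name: str
    classes: tuple[str, ...]
    thresholds: tuple[float, ...]
    levels: np.ndarray  # (n_classes, n_intervals)
    domain: tuple[float, float] = (0.0, 14.0)
    periodic: bool = False
    period: float = 300.0
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, float)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        t = np.asarray(self.thresholds)
        if len(t) == 0:
            raise ValueError("at least one threshold required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        n_int = len(t) if self.periodic else len(t) + 1
        if levels.shape != (len(self.classes), n_int):
            raise ValueError(
                f"levels shape {levels.shape} incompatible with "
                f"{len(t)} thresholds ({'circular' if self.periodic else 'linear'})"
            )
        if np.any(levels < 0) or not np.allclose(levels.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("per-class interval probabilities must sum to 1")
        if self.periodic:
            if np.any((t < 0) | (t >= self.period)):
                raise ValueError("circular thresholds must lie in [0, period)")
        else:
            lo, hi = self.domain
            if np.any((t <= lo) | (t >= hi)):
                raise ValueError("thresholds must lie strictly inside the domain")

    @property
    def n_intervals(self) -> int:
        return self.levels.shape[1]

    def _check_domain(self, x: np.ndarray) -> np.ndarray:
        if self.periodic:
            return np.mod(x, self.period)
        lo, hi = self.domain
        if np.any((x < lo) | (x > hi)):
            raise ValueError(
                f"value outside domain [{lo}, {hi}] of {self.property_name!r}"
            )
        return x

    def interval_index(self, x) -> np.ndarray:
        """Hard (unsmoothed) interval membership; values exactly at a
        threshold belong to the upper interval."""
        xa = self._check_domain(np.atleast_1d(np.asarray(x, float)))
        t = np.asarray(self.thresholds)
        idx = np.searchsorted(t, xa, side="right")
        if self.periodic:
            return np.mod(idx - 1, self.n_intervals)
        return idx

    def likelihood_array(self, x) -> np.ndarray:
        """P(x | class) for an array of values, shape (N, n_classes)."""
        xa = self._check_domain(np.atleast_1d(np.asarray(x, float)))
        t = np.asarray(self.thresholds)
        L = self.levels  # (C, I)
        if not self.smoothing.enabled:
            if self.periodic:
                idx = np.mod(np.searchsorted(t, xa, side="right") - 1, self.n_intervals)
            else:
                idx = np.searchsorted(t, xa, side="right")
            return L[:, idx].T
        k = self.smoothing.k
        if not self.periodic:
            # base level + telescoping logistic blends at each threshold
            diff = L[:, 1:] - L[:, :-1]           # (C, m)
            sig = expit(k * (xa[:, None] - t[None, :]))  # (N, m)
            return L[:, 0][None, :] + sig @ diff.T
        # circular: blend the periodic extension; ΔL at threshold j is the
        # level jump entering interval j, replicated one period either side
        dL = L - np.roll(L, 1, axis=1)            # (C, m)
        base = L[:, -1]                           # wrap interval level
        reps = np.concatenate([t - self.period, t, t + self.period])
        drep = np.concatenate([dL, dL, dL], axis=1)  # (C, 3m)
        sig = expit(k * (xa[:, None] - reps[None, :]))
        return base[None, :] + sig @ drep.T

    def likelihood(self, x: float) -> np.ndarray:
        return self.likelihood_array([x])[0]

    def to_dict(self) -> dict:
        return {
            "kind": "stepped",
            "property_name": self.property_name,
            "classes": list(self.classes),
            "thresholds": [round(float(t), 12) for t in self.thresholds],
            "levels": [[round(float(p), 12) for p in row] for row in self.levels],
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "periodic": self.periodic,
            "period": self.period,
            "smoothing": {"enabled": self.smoothing.enabled, "k": self.smoothing.k},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SteppedModel":
        return cls(
            property_name=d["property_name"],
            classes=tuple(d["classes"]),
            thresholds=tuple(d["thresholds"]),
            levels=np.array(d["levels"], float),
            domain=tuple(d["domain"]),
            periodic=bool(d["periodic"]),
            period=float(d["period"]),
            smoothing=SmoothingSpec(**d["smoothing"]),
        )


def model_from_dict(d: dict):
    if d["kind"] == "categorical":
        return CategoricalModel.from_dict(d)
    if d["kind"] == "stepped":
        return SteppedModel.from_dict(d)
    raise ValueError(f"unknown model kind {d['kind']!r}")


def step_prob(x: float, model: SteppedModel, cls: str) -> float:
    """P(x | cls) under a stepped model (scalar convenience wrapper)."""
    return float(model.likelihood(x)[model.classes.index(cls)])


# ---------------------------------------------------------------------------
# Fitting

def _labeled_values(training: TrainingTable, property_name: str):
    xs, labels = [], []
    for rec in training.labeled:
        v = property_value(rec, property_name)
        if v is not None:
            xs.append(v)
            labels.append(training.classes.index(rec.label))
    return xs, np.array(labels, int)


def fit_categorical(
    training: TrainingTable,
    property_name: str,
    alpha: float = 0.5,
    value_set: Sequence | None = None,
) -> CategoricalModel:
    """Estimate P(value | class) from labeled records with pseudocount alpha.

    P(v | c) = (count(v, c) + alpha) / (n_c + alpha * |V|).  Records missing
    the property are excluded from the counts.  With alpha > 0 every
    value-class combination keeps nonzero probability, so the predictor can
    propose class assignments never observed in training.
    """
    xs, labels = _labeled_values(training, property_name)
    if not xs:
        raise ValueError(f"property {property_name!r} absent from every labeled record")
    if value_set is None:
        if all(isinstance(v, (bool, np.bool_)) for v in xs):
            values: tuple = (False, True)
        else:
            values = tuple(sorted(set(xs)))
    else:
        values = tuple(value_set)
        for v in xs:
            if v not in values:
                raise ValueError(f"observed value {v!r} outside value_set {values}")
    n_classes = len(training.classes)
    counts = np.zeros((n_classes, len(values)))
    for v, c in zip(xs, labels):
        counts[c, values.index(bool(v) if isinstance(v, np.bool_) else v)] += 1
    if alpha == 0 and np.any(counts.sum(axis=1) == 0):
        # a class with no observations and no pseudocount has no distribution
        raise ValueError(
            f"alpha=0 with a class lacking any observation of {property_name!r}"
        )
    table = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + alpha * len(values))
    return CategoricalModel(property_name, tuple(training.classes), values, table, alpha)


@dataclass(frozen=True)
class OptimizerConfig:
    """Powell-search settings for threshold fitting.

    Multi-start from fixed data quantiles keeps the fit deterministic; ties
    between starts resolve to the first-found optimum.
    """

    maxiter: int = 200
    xtol: float = 1e-4
    ftol: float = 1e-8
    start_quantiles: tuple[float, ...] = (0.2, 0.5, 0.8)


def _interval_levels(
    xs: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray,
    n_classes: int,
    n_intervals: int,
    periodic: bool,
    alpha: float,
) -> np.ndarray:
    """Pseudocounted per-class interval frequencies under hard thresholds."""
    idx = np.searchsorted(thresholds, xs, side="right")
    if periodic:
        idx = np.mod(idx - 1, n_intervals)
    counts = np.zeros((n_classes, n_intervals))
    np.add.at(counts, (labels, idx), 1.0)
    return (counts + alpha) / (
        counts.sum(axis=1, keepdims=True) + alpha * n_intervals
    )


def fit_stepped(
    training: TrainingTable,
    property_name: str,
    m: int = 1,
    smoothing: SmoothingSpec | None = None,
    optimizer_cfg: OptimizerConfig | None = None,
    alpha: float = 0.5,
    periodic: bool | None = None,
    domain: tuple[float, float] | None = None,
    period: float = 300.0,
) -> SteppedModel:
    """Maximum-likelihood step model for a continuous or circular property.

    The m thresholds are optimized by Powell's direction-set method to
    maximize the classification log-likelihood sum over records of
    log P(label | x) (Bayes posterior under the training priors) — the same
    quantity the model search scores families by.  At any thresholds the
    interval levels are profiled out as the pseudocounted per-class interval
    frequencies.  The levels are interval probabilities; the class-independent
    interval-width factor cancels in the posterior, so maximizing the
    posterior likelihood sidesteps the degeneracy where a probability-valued
    conditional likelihood always prefers a single all-covering interval.
    ``periodic`` defaults to True for ``onset_min`` (the expression-onset
    circle) and False otherwise; ``domain`` defaults to the pH scale (0, 14)
    for pI-derived properties, else the observed data range.
    """
    if m not in (1, 2):
        raise ValueError("threshold count m must be 1 or 2")
    smoothing = smoothing if smoothing is not None else SmoothingSpec()
    cfg = optimizer_cfg if optimizer_cfg is not None else OptimizerConfig()
    if periodic is None:
        periodic = property_name == "onset_min"
    xs_list, labels = _labeled_values(training, property_name)
    xs = np.asarray(xs_list, float)
    if xs.size == 0:
        raise ValueError(f"property {property_name!r} absent from every labeled record")
    n_intervals = m if periodic else m + 1
    if periodic and m < 2:
        raise ValueError("a circular domain needs at least 2 thresholds")
    if len(np.unique(xs)) < m + 1:
        raise ValueError(
            f"need at least {m + 1} distinct values of {property_name!r} "
            f"to fit {m} threshold(s); got {len(np.unique(xs))}"
        )
    n_classes = len(training.classes)
    if periodic:
        xs = np.mod(xs, period)
        lo, hi = 0.0, period
    elif domain is not None:
        lo, hi = domain
    elif property_name.startswith("pi"):
        lo, hi = 0.0, 14.0
    else:
        span = xs.max() - xs.min()
        pad = 0.05 * span if span > 0 else 1.0
        lo, hi = xs.min() - pad, xs.max() + pad
    eps = 1e-3 * (hi - lo)
    priors = training.priors

    def build(thresholds: np.ndarray) -> SteppedModel:
        levels = _interval_levels(xs, labels, thresholds, n_classes,
                                  n_intervals, periodic, alpha)
        return SteppedModel(
            property_name=property_name,
            classes=tuple(training.classes),
            thresholds=tuple(thresholds),
            levels=levels,
            domain=(lo, hi),
            periodic=periodic,
            period=period,
            smoothing=smoothing,
        )

    def negloglik(raw: np.ndarray) -> float:
        t = np.sort(np.clip(raw, lo + eps, hi - eps))
        # collapsed thresholds would make an interval empty: penalize
        if len(t) > 1 and np.any(np.diff(t) < eps):
            return 1e12
        model = build(t)
        like = model.likelihood_array(xs)            # (N, C)
        joint = like * priors[None, :]
        post = joint / np.maximum(joint.sum(axis=1, keepdims=True), _LOG_FLOOR)
        p_true = post[np.arange(len(xs)), labels]
        return -float(np.log(np.maximum(p_true, _LOG_FLOOR)).sum())

    qs = np.quantile(xs, cfg.start_quantiles)
    if m == 1:
        starts = [np.array([q]) for q in qs]
    else:
        starts = [np.array(sorted((qs[i], qs[j])))
                  for i in range(len(qs)) for j in range(i + 1, len(qs))]
    best: tuple[float, np.ndarray] | None = None
    for x0 in starts:
        res = minimize(
            negloglik, x0, method="Powell",
            options={"maxiter": cfg.maxiter, "xtol": cfg.xtol, "ftol": cfg.ftol},
        )
        if not (res.status in (0, 1) or res.success):
            raise RuntimeError(
                f"Powell optimization failed for {property_name!r}: {res.message}"
            )
        val = float(res.fun)
        if best is None or val < best[0] - 1e-12:
            t = np.sort(np.clip(np.atleast_1d(res.x), lo + eps, hi - eps))
            if len(t) == 1 or np.all(np.diff(t) >= eps):
                best = (val, t)
    if best is None:
        raise RuntimeError(f"no admissible threshold fit for {property_name!r}")
    return build(best[1])


def single_property_posterior(
    x, model, priors: Sequence[float]
) -> PosteriorVector:
    """Bayes posterior over classes from one property value.

    P(class | x) = P(x | class) P(class) / sum_m P(x | class_m) P(class_m);
    the denominator realizes the marginal P(property).
    """
    priors_a = np.asarray(priors, float)
    if abs(priors_a.sum() - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    like = np.asarray(model.likelihood(x), float)
    numer = like * priors_a
    total = numer.sum()
    if total <= 0:
        raise ValueError(
            f"all class likelihoods are zero at {x!r} for {model.property_name!r}"
        )
    return PosteriorVector(
        classes=tuple(model.classes),
        probs=numer / total,
        used_properties=(model.property_name,),
    )
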