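"""Naive-Bayes combination of single-property likelihoods.

Properties are assumed conditionally independent given the substrate class,
so the posterior is

    P(class | x_1..x_p)  ∝  P(class) * prod_j P(x_j | class)

normalized over the n classes.  Missing properties simply contribute no
factor — a record with no properties at all falls back to the priors — which
is what makes the method applicable to every protein even with patchy
annotation.  All products are computed in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.special import logsumexp

from .data_model import PosteriorVector, ProteinRecord, TrainingTable
from .features import property_value
from .property_models import (
    CategoricalModel,
    SteppedModel,
    model_from_dict,
)

_LOG_FLOOR = 1e-300


@dataclass
class FittedModel:
    """A fitted multi-property model: priors plus per-property submodels.

    ``k`` counts the free parameters and ``aic = 2k - 2 logL``; both are
    filled in by the model-search layer, as is the training log-likelihood.
    """

    classes: tuple[str, ...]
    priors: np.ndarray
    submodels: dict[str, CategoricalModel | SteppedModel]
    family: Any = None
    logL: float | None = None
    k: int | None = None
    aic: float | None = None
    failed: bool = False
    error: str | None = None

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, float)
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        names = list(self.submodels)
        if len(set(names)) != len(names):
            raise ValueError("submodel property names must be distinct")
        for name, sub in self.submodels.items():
            if tuple(sub.classes) != tuple(self.classes):
                raise ValueError(f"class order mismatch in submodel {name!r}")

    # -- posterior computation ------------------------------------------------

    def posterior_matrix(
        self, records: Sequence[ProteinRecord]
    ) -> tuple[np.ndarray, list[tuple[str, ...]]]:
        """Posterior probabilities for many records at once.

        Returns (probs of shape (N, n_classes), per-record tuple of the
        property names that actually contributed).
        """
        n = len(records)
        logpost = np.tile(np.log(self.priors)[None, :], (n, 1))
        used: list[list[str]] = [[] for _ in range(n)]
        for name, sub in self.submodels.items():
            values = [property_value(rec, name) for rec in records]
            present = [i for i, v in enumerate(values) if v is not None]
            if not present:
                continue
            if isinstance(sub, SteppedModel):
                like = sub.likelihood_array(
                    np.array([values[i] for i in present], float)
                )
            else:
                like = sub.likelihood_array([values[i] for i in present])
            logpost[present] += np.log(np.maximum(like, _LOG_FLOOR))
            for i in present:
                used[i].append(name)
        lse = logsumexp(logpost, axis=1, keepdims=True)
        if np.any(~np.isfinite(lse)):
            raise ValueError("posterior numerators all zero for some record")
        probs = np.exp(logpost - lse)
        probs /= probs.sum(axis=1, keepdims=True)
        return probs, [tuple(u) for u in used]

    def posterior(self, record: ProteinRecord) -> PosteriorVector:
        probs, used = self.posterior_matrix([record])
        return PosteriorVector(tuple(self.classes), probs[0], used[0])

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "priors": [round(float(p), 12) for p in self.priors],
            "submodels": {name: sub.to_dict() for name, sub in self.submodels.items()},
            "family": (self.family.to_dict()
                       if hasattr(self.family, "to_dict") else self.family),
            "logL": self.logL,
            "k": self.k,
            "aic": self.aic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        family = d.get("family")
        if isinstance(family, dict):
            from .model_search import ModelFamily

            family = ModelFamily.from_dict(family)
        return cls(
            classes=tuple(d["classes"]),
            priors=np.array(d["priors"], float),
            submodels={name: model_from_dict(sd)
                       for name, sd in d["submodels"].items()},
            family=family,
            logL=d.get("logL"),
            k=d.get("k"),
            aic=d.get("aic"),
        )


def posterior(record: ProteinRecord, model: FittedModel) -> PosteriorVector:
    """P(class | record's present properties), normalized."""
    return model.posterior(record)


def predict(
    record: ProteinRecord, model: FittedModel
) -> tuple[str, PosteriorVector]:
    """Highest-posterior class; exact ties break to the earlier class in the
    fixed class order (RNA, PROTEIN, OTHER by default)."""
    post = model.posterior(record)
    return post.argmax_class, post


def training_log_likelihood(
    training: TrainingTable, model: FittedModel
) -> float:
    """Sum over labeled records of log P(true class | record's properties).

    Records with partially (or wholly) missing properties still contribute,
    through whatever evidence they do carry.  A record whose true class gets
    zero posterior drives the result to -inf (reported with a warning).
    """
    labeled = training.labeled
    if not labeled:
        raise ValueError("training table has no labeled records")
    probs, _ = model.posterior_matrix(labeled)
    idx = np.array([training.classes.index(r.label) for r in labeled], int)
    p_true = probs[np.arange(len(labeled)), idx]
    if np.any(p_true <= 0):
        warnings.warn(
            "zero posterior for the true class of some record(s); "
            "log-likelihood is -inf",
            stacklevel=2,
        )
        return float("-inf")
    return float(np.log(p_true).sum())
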