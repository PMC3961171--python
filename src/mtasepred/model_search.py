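"""Enumeration and AIC ranking of multi-property model families.

A *family* is a subset of properties together with their parameterization
(threshold count and smoothing for continuous properties).  Each family is
fitted by maximum likelihood — thresholds through Powell's direction-set
method, categorical tables by pseudocounted frequencies — scored by the
training log-likelihood of the resulting posteriors, and ranked by

    AIC = 2 k - 2 ln(L)

which trades goodness of fit against parameter count and so discourages
stacking correlated properties.  When the full cross-product of subsets and
parameterizations exceeds the configured budget, the enumerator keeps every
family of at most two properties and draws a seeded uniform sample of the
rest, and the result is flagged as sampled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .data_model import TrainingTable
from .predictor import FittedModel, training_log_likelihood
from .property_models import (
    CategoricalModel,
    OptimizerConfig,
    SmoothingSpec,
    fit_categorical,
    fit_stepped,
)


@dataclass(frozen=True)
class PropertySpec:
    """One property with its parameterization.

    ``kind`` is "categorical" or "continuous"; ``m`` (threshold count,
    1 or 2) and ``smoothing`` apply only to continuous properties.
    """

    name: str
    kind: str
    m: int | None = None
    smoothing: bool = True
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown property kind {self.kind!r}")
        if self.kind == "continuous" and self.m not in (1, 2):
            raise ValueError("continuous properties need m in {1, 2}")

    @property
    def spec_id(self) -> str:
        if self.kind == "categorical":
            return self.name
        tag = "s" if self.smoothing else "h"
        return f"{self.name}[m={self.m}{tag}]"

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "m": self.m,
                "smoothing": self.smoothing, "periodic": self.periodic}

    @classmethod
    def from_dict(cls, d: dict) -> "PropertySpec":
        return cls(**d)


@dataclass(frozen=True)
class ModelFamily:
    """A concrete candidate model: a tuple of property specs (possibly empty,
    which is the priors-only model)."""

    specs: tuple[PropertySpec, ...] = ()

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("family property names must be distinct")

    @property
    def family_id(self) -> str:
        if not self.specs:
            return "priors-only"
        return "+".join(sorted(s.spec_id for s in self.specs))

    def __len__(self) -> int:
        return len(self.specs)

    def to_dict(self) -> dict:
        return {"specs": [s.to_dict() for s in self.specs]}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFamily":
        return cls(tuple(PropertySpec.from_dict(s) for s in d["specs"]))


#: Default candidate pool: the binary indicator expansions of fold and
#: expression cluster, the two most class-specific localization indicators,
#: the global isoelectric point with a single threshold, and the circular
#: expression onset with two thresholds.
DEFAULT_POOL: tuple[PropertySpec, ...] = (
    PropertySpec("Rossmann-like", "categorical"),
    PropertySpec("SET", "categorical"),
    PropertySpec("SPOUT", "categorical"),
    PropertySpec("other fold", "categorical"),
    PropertySpec("Ox", "categorical"),
    PropertySpec("R/B", "categorical"),
    PropertySpec("R/C", "categorical"),
    PropertySpec("No cluster", "categorical"),
    PropertySpec("nucleolus", "categorical"),
    PropertySpec("mitochondrion", "categorical"),
    PropertySpec("pi_global", "continuous", m=1),
    PropertySpec("onset_min", "continuous", m=2, periodic=True),
)


@dataclass
class SearchConfig:
    """Everything that determines a model search, for reproducibility."""

    pool: tuple[PropertySpec, ...] = DEFAULT_POOL
    alpha: float = 0.5
    smoothing_k: float = 0.99
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    max_properties: int = 14
    top_n: int = 22
    family_budget: int = 2000
    seed: int = 0
    scheme: str = "default"
    free_priors: bool = False

    def __post_init__(self) -> None:
        if not self.pool:
            raise ValueError("property pool must be nonempty")
        if self.scheme not in PARAMETER_SCHEMES:
            raise ValueError(
                f"unknown parameter-counting scheme {self.scheme!r}; "
                f"registered: {sorted(PARAMETER_SCHEMES)}"
            )


# ---------------------------------------------------------------------------
# Parameter counting

def _default_scheme(model: FittedModel) -> int:
    """(|V|-1)*n free conditionals per categorical property; m thresholds
    plus (intervals-1)*n free levels per stepped property; priors fixed."""
    n = len(model.classes)
    k = 0
    for sub in model.submodels.values():
        if isinstance(sub, CategoricalModel):
            k += (len(sub.values) - 1) * n
        else:
            k += len(sub.thresholds) + (sub.n_intervals - 1) * n
    return k


def _table_s4_scheme(model: FittedModel) -> int:
    """Fidelity scheme in which a binary categorical property costs 5
    parameters; everything else follows the default rule."""
    n = len(model.classes)
    k = 0
    for sub in model.submodels.values():
        if isinstance(sub, CategoricalModel):
            k += 5 if len(sub.values) == 2 else (len(sub.values) - 1) * n
        else:
            k += len(sub.thresholds) + (sub.n_intervals - 1) * n
    return k


PARAMETER_SCHEMES: dict[str, Callable[[FittedModel], int]] = {
    "default": _default_scheme,
    "table-s4": _table_s4_scheme,
}


def count_parameters(
    model: FittedModel, scheme: str = "default", free_priors: bool = False
) -> int:
    """Free-parameter count k of a fitted model under a registered scheme.

    ``free_priors`` adds n-1 when the class priors are treated as optimized
    rather than fixed at the training frequencies.
    """
    if scheme not in PARAMETER_SCHEMES:
        raise ValueError(f"unknown parameter-counting scheme {scheme!r}")
    k = PARAMETER_SCHEMES[scheme](model)
    if free_priors:
        k += len(model.classes) - 1
    return k


# ---------------------------------------------------------------------------
# Fitting one family

def _fit_submodel(
    training: TrainingTable, spec: PropertySpec, cfg: SearchConfig
):
    if spec.kind == "categorical":
        return fit_categorical(training, spec.name, alpha=cfg.alpha)
    return fit_stepped(
        training,
        spec.name,
        m=spec.m,
        smoothing=SmoothingSpec(k=cfg.smoothing_k) if spec.smoothing
        else SmoothingSpec(enabled=False, k=cfg.smoothing_k),
        optimizer_cfg=cfg.optimizer,
        alpha=cfg.alpha,
        periodic=True if spec.periodic else None,
    )


def fit_family(
    training: TrainingTable,
    family: ModelFamily,
    cfg: SearchConfig | None = None,
    _cache: dict | None = None,
) -> FittedModel:
    """ML-fit one family and score it: logL (posterior log-likelihood of the
    training labels), k (per ``cfg.scheme``) and AIC = 2k - 2 logL.

    A submodel fit failure yields a FittedModel flagged ``failed`` rather
    than an exception, so one pathological family cannot abort a search.
    Single-property conditionals do not depend on the other family members,
    so an optional cache shares fitted submodels across families.
    """
    cfg = cfg if cfg is not None else SearchConfig()
    priors = training.priors
    submodels = {}
    try:
        for spec in family.specs:
            if _cache is not None and spec.spec_id in _cache:
                submodels[spec.name] = _cache[spec.spec_id]
            else:
                sub = _fit_submodel(training, spec, cfg)
                if _cache is not None:
                    _cache[spec.spec_id] = sub
                submodels[spec.name] = sub
    except (ValueError, RuntimeError) as exc:
        return FittedModel(
            classes=tuple(training.classes), priors=priors, submodels={},
            family=family, failed=True, error=str(exc),
        )
    model = FittedModel(
        classes=tuple(training.classes), priors=priors,
        submodels=submodels, family=family,
    )
    model.logL = training_log_likelihood(training, model)
    model.k = count_parameters(model, cfg.scheme, cfg.free_priors)
    model.aic = 2.0 * model.k - 2.0 * model.logL
    if not np.isfinite(model.aic):
        model.failed = True
        model.error = "non-finite log-likelihood"
    return model


# ---------------------------------------------------------------------------
# Screening and enumeration

def screen_single_properties(
    training: TrainingTable,
    pool: Sequence[PropertySpec] | None = None,
    cfg: SearchConfig | None = None,
) -> list[PropertySpec]:
    """Rank pool properties by their single-property AIC and keep the top N.

    Continuous properties appearing with several parameterizations compete
    within their name first (best m/smoothing wins), then across names.
    Unfittable properties are dropped with their diagnostic retained in the
    returned specs' absence, never fatally.
    """
    cfg = cfg if cfg is not None else SearchConfig()
    pool = tuple(pool) if pool is not None else cfg.pool
    cache: dict = {}
    best_by_name: dict[str, tuple[float, PropertySpec]] = {}
    for spec in pool:
        fitted = fit_family(training, ModelFamily((spec,)), cfg, _cache=cache)
        if fitted.failed:
            continue
        cur = best_by_name.get(spec.name)
        if cur is None or fitted.aic < cur[0] - 1e-12:
            best_by_name[spec.name] = (fitted.aic, spec)
    ranked = sorted(
        best_by_name.values(), key=lambda pair: (pair[0], pair[1].spec_id)
    )
    return [spec for _aic, spec in ranked[: cfg.top_n]]


@dataclass
class FamilyEnumeration:
    """The families actually produced, with sampling provenance."""

    families: list[ModelFamily]
    total_families: int
    sampled: bool
    seed: int | None = None


def enumerate_families(
    pool: Sequence[PropertySpec],
    cfg: SearchConfig | None = None,
) -> FamilyEnumeration:
    """All subsets of the pool (one parameterization per property name) up to
    ``max_properties``, including the priors-only family.

    When the exact count exceeds ``family_budget``, every family of size
    <= 2 is kept and the remainder is a seeded uniform reservoir sample,
    labeled as sampled.
    """
    cfg = cfg if cfg is not None else SearchConfig()
    pool = tuple(pool)
    if not pool:
        raise ValueError("empty property pool")
    by_name: dict[str, list[PropertySpec]] = {}
    for spec in pool:
        by_name.setdefault(spec.name, []).append(spec)
    names = sorted(by_name)
    options = [[None, *sorted(by_name[n], key=lambda s: s.spec_id)] for n in names]

    def all_families() -> Iterable[ModelFamily]:
        for choice in itertools.product(*options):
            specs = tuple(s for s in choice if s is not None)
            if len(specs) <= cfg.max_properties:
                yield ModelFamily(specs)

    total = sum(1 for _ in all_families())
    if total <= cfg.family_budget:
        return FamilyEnumeration(list(all_families()), total, sampled=False)
    rng = np.random.default_rng(cfg.seed)
    small = [f for f in all_families() if len(f) <= 2]
    n_sample = max(0, cfg.family_budget - len(small))
    # seeded reservoir sample over the large families, order-deterministic
    reservoir: list[ModelFamily] = []
    seen = 0
    for fam in all_families():
        if len(fam) <= 2:
            continue
        seen += 1
        if len(reservoir) < n_sample:
            reservoir.append(fam)
        else:
            j = int(rng.integers(0, seen))
            if j < n_sample:
                reservoir[j] = fam
    families = small + sorted(reservoir, key=lambda f: f.family_id)
    return FamilyEnumeration(families, total, sampled=True, seed=cfg.seed)


# ---------------------------------------------------------------------------
# Search driver

@dataclass
class SearchResult:
    """Ranked outcome of a model search (ascending AIC; ties broken by fewer
    parameters, then lexicographic family id)."""

    ranked: list[FittedModel]
    diagnostics: list[dict]
    total_families: int
    sampled: bool
    config: SearchConfig

    @property
    def best(self) -> FittedModel:
        return select_best(self)


def _rank_key(model: FittedModel) -> tuple:
    return (model.aic, model.k, model.family.family_id)


def select_best(results: "SearchResult | Sequence[FittedModel]") -> FittedModel:
    """Minimum-AIC model among the successful fits."""
    models = results.ranked if isinstance(results, SearchResult) else list(results)
    ok = [m for m in models if not m.failed]
    if not ok:
        raise ValueError("no successfully fitted model to select from")
    return min(ok, key=_rank_key)


def search(
    training: TrainingTable, cfg: SearchConfig | None = None
) -> SearchResult:
    """Screen → enumerate → fit → rank.  Fully deterministic given the
    training table and config (including the enumeration seed)."""
    cfg = cfg if cfg is not None else SearchConfig()
    screened = screen_single_properties(training, cfg.pool, cfg)
    if not screened:
        raise ValueError("no fittable property in the pool")
    enum = enumerate_families(screened, cfg)
    cache: dict = {}
    fitted = [fit_family(training, fam, cfg, _cache=cache) for fam in enum.families]
    ok = sorted((m for m in fitted if not m.failed), key=_rank_key)
    diagnostics = [
        {
            "family": m.family.family_id,
            "status": "failed" if m.failed else "ok",
            "logL": m.logL,
            "k": m.k,
            "aic": m.aic,
            "error": m.error,
        }
        for m in fitted
    ]
    return SearchResult(
        ranked=ok,
        diagnostics=diagnostics,
        total_families=enum.total_families,
        sampled=enum.sampled,
        config=cfg,
    )
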