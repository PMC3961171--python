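"""Seeded generators of synthetic enzyme property tables and sequences.

The default :class:`GeneratorSpec` emulates the published yeast MTase
training set: 61 labeled enzymes (26 RNA / 24 protein / 11 other-substrate)
plus 25 unlabeled candidates, with class-conditional property distributions
that reproduce the documented associations — every SET-fold enzyme
methylates protein, every SPOUT-fold enzyme methylates RNA, every nucleolar
enzyme methylates RNA, the reductive/charging expression cluster is enriched
for other-substrate enzymes, and RNA MTases sit at high pI with protein
MTases low and other-substrate enzymes in between.  Properties are sampled
class-conditionally independent, matching the predictor's independence
assumption, and all generation is a pure function of the spec (including its
seed).

The generators are first-class library code: the same machinery drives the
test suite, the parameter-recovery harness and the ``simulate`` CLI
subcommand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .data_model import (
    DEFAULT_CLASSES,
    FOLD_GROUPS,
    LOCALIZATION_CLASSES,
    YMC_CLUSTERS,
    ProteinRecord,
    TrainingTable,
)
from .features import INDICATOR_SOURCES
from .predictor import FittedModel
from .property_models import CategoricalModel, SteppedModel

#: Hard property-class associations that the default spec must respect:
#: (record attribute, value) -> the only class allowed to carry it.
HARD_ASSOCIATIONS: dict[tuple[str, str], str] = {
    ("fold_group", "SET"): "PROTEIN",
    ("fold_group", "SPOUT"): "RNA",
    ("localization_class", "NUCLEOLUS"): "RNA",
}

_ATTR_VALUES = {
    "fold_group": FOLD_GROUPS,
    "localization_class": LOCALIZATION_CLASSES,
    "ymc_cluster": YMC_CLUSTERS,
}


def _default_fold_tables() -> dict[str, dict[str, float]]:
    return {
        "RNA": {"ROSSMANN": 20 / 26, "SET": 0.0, "SPOUT": 4 / 26, "OTHER_FOLD": 2 / 26},
        "PROTEIN": {"ROSSMANN": 14 / 24, "SET": 8 / 24, "SPOUT": 0.0, "OTHER_FOLD": 2 / 24},
        "OTHER": {"ROSSMANN": 4 / 11, "SET": 0.0, "SPOUT": 0.0, "OTHER_FOLD": 7 / 11},
    }


def _default_loc_tables() -> dict[str, dict[str, float]]:
    return {
        "RNA": {"NUCLEOLUS": 8 / 26, "NUCLEUS_NOT_NUCLEOLUS": 9 / 26,
                "MITO_NOT_NUCLEUS": 3 / 26, "OTHER_LOC": 6 / 26},
        "PROTEIN": {"NUCLEOLUS": 0.0, "NUCLEUS_NOT_NUCLEOLUS": 11 / 24,
                    "MITO_NOT_NUCLEUS": 1 / 24, "OTHER_LOC": 12 / 24},
        "OTHER": {"NUCLEOLUS": 0.0, "NUCLEUS_NOT_NUCLEOLUS": 2 / 11,
                  "MITO_NOT_NUCLEUS": 4 / 11, "OTHER_LOC": 5 / 11},
    }


def _default_cluster_tables() -> dict[str, dict[str, float]]:
    return {
        "RNA": {"Ox": 10 / 26, "R/B": 2 / 26, "R/C": 1 / 26, "none": 13 / 26},
        "PROTEIN": {"Ox": 7 / 24, "R/B": 5 / 24, "R/C": 1 / 24, "none": 11 / 24},
        "OTHER": {"Ox": 2 / 11, "R/B": 1 / 11, "R/C": 4 / 11, "none": 4 / 11},
    }


@dataclass
class GeneratorSpec:
    """Full description of the synthetic training-table distribution.

    pI is per-class Gaussian truncated to (3, 12), placing RNA enzymes high,
    protein enzymes low and other-substrate enzymes mid-range so that a
    single fitted pI threshold lands near 6.95-7.  Expression onset is a
    wrapped normal on the 300-minute cycle: the RNA and protein components
    sit in the wrap region around the cycle start while the other-substrate
    component sits mid-cycle.  Onset is missing for a fraction of records,
    as only periodically expressed genes have one.
    """

    seed: int = 0
    classes: tuple[str, ...] = DEFAULT_CLASSES
    n_labeled: int = 61
    n_unlabeled: int = 25
    class_counts: tuple[int, ...] = (26, 24, 11)
    fold_given_class: dict[str, dict[str, float]] = field(
        default_factory=_default_fold_tables)
    loc_given_class: dict[str, dict[str, float]] = field(
        default_factory=_default_loc_tables)
    cluster_given_class: dict[str, dict[str, float]] = field(
        default_factory=_default_cluster_tables)
    #: class -> (mean, sd) of the truncated-Gaussian pI component, pH units
    pi_given_class: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "RNA": (8.5, 1.0), "PROTEIN": (5.8, 0.8), "OTHER": (6.7, 0.5)})
    pi_bounds: tuple[float, float] = (3.0, 12.0)
    #: class -> (mean, sd) of the wrapped-normal onset component, minutes
    onset_given_class: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "RNA": (355.0, 25.0), "PROTEIN": (5.0, 25.0), "OTHER": (150.0, 60.0)})
    onset_period: float = 300.0
    #: per-property probability that the value is missing from a record
    missingness: dict[str, float] = field(default_factory=lambda: {
        "onset_min": 0.15})
    enforce_associations: bool = True

    def __post_init__(self) -> None:
        if len(self.class_counts) != len(self.classes):
            raise ValueError("class_counts must have one entry per class")
        if sum(self.class_counts) != self.n_labeled:
            raise ValueError(
                f"class_counts {self.class_counts} must sum to n_labeled "
                f"{self.n_labeled}"
            )
        for attr, tables in (("fold_given_class", self.fold_given_class),
                             ("loc_given_class", self.loc_given_class),
                             ("cluster_given_class", self.cluster_given_class)):
            for cls, row in tables.items():
                total = sum(row.values())
                if abs(total - 1.0) > 1e-9 or any(p < 0 for p in row.values()):
                    raise ValueError(f"{attr}[{cls!r}] is not a distribution")
        for cls, (_mu, sd) in {**self.pi_given_class}.items():
            if sd <= 0:
                raise ValueError(f"pI sd for {cls!r} must be > 0")
        for cls, (_mu, sd) in {**self.onset_given_class}.items():
            if sd <= 0:
                raise ValueError(f"onset sd for {cls!r} must be > 0")
        if self.enforce_associations:
            attr_table = {"fold_group": self.fold_given_class,
                          "localization_class": self.loc_given_class}
            for (attr, value), only_cls in HARD_ASSOCIATIONS.items():
                for cls, row in attr_table[attr].items():
                    if cls != only_cls and row.get(value, 0.0) > 0:
                        raise ValueError(
                            f"infeasible spec: {attr}={value} has probability "
                            f"{row[value]} under class {cls}, but is reserved "
                            f"for {only_cls}"
                        )

    @property
    def priors(self) -> np.ndarray:
        counts = np.asarray(self.class_counts, float)
        return counts / counts.sum()


def _sample_categorical(rng: np.random.Generator, row: Mapping[str, float]) -> str:
    values = list(row)
    probs = np.array([row[v] for v in values], float)
    return values[int(rng.choice(len(values), p=probs / probs.sum()))]


def _sample_truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling did not converge")


def generate_training_table(spec: GeneratorSpec | None = None) -> TrainingTable:
    """Sample a property table with exact per-class label counts.

    Labeled records come first in a seeded permutation of the exact class
    composition; unlabeled records draw a latent class from the priors and
    then their properties, but carry no label.  Identical seeds give
    byte-identical tables.
    """
    spec = spec if spec is not None else GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    label_pool = [c for c, n in zip(spec.classes, spec.class_counts) for _ in range(n)]
    order = rng.permutation(spec.n_labeled)
    labeled_classes = [label_pool[i] for i in order]
    latent_unlabeled = [
        spec.classes[int(rng.choice(len(spec.classes), p=spec.priors))]
        for _ in range(spec.n_unlabeled)
    ]
    records = []
    for i, (cls, labeled) in enumerate(
        [(c, True) for c in labeled_classes] + [(c, False) for c in latent_unlabeled]
    ):
        rid = f"SYN{i + 1:04d}" if labeled else f"PUT{i + 1 - spec.n_labeled:04d}"
        mu, sd = spec.pi_given_class[cls]
        pi = _sample_truncated_normal(rng, mu, sd, *spec.pi_bounds)
        omu, osd = spec.onset_given_class[cls]
        onset: float | None = float(np.mod(rng.normal(omu, osd), spec.onset_period))
        if rng.random() < spec.missingness.get("onset_min", 0.0):
            onset = None
        fold = _sample_categorical(rng, spec.fold_given_class[cls])
        loc = _sample_categorical(rng, spec.loc_given_class[cls])
        cluster = _sample_categorical(rng, spec.cluster_given_class[cls])
        records.append(ProteinRecord(
            id=rid,
            fold_group=None if rng.random() < spec.missingness.get("fold_group", 0.0) else fold,
            localization_class=None if rng.random() < spec.missingness.get(
                "localization_class", 0.0) else loc,
            ymc_cluster=None if rng.random() < spec.missingness.get(
                "ymc_cluster", 0.0) else cluster,
            onset_min=onset,
            pi_global=None if rng.random() < spec.missingness.get(
                "pi_global", 0.0) else pi,
            label=cls if labeled else None,
        ))
    return TrainingTable(records, classes=spec.classes)


# ---------------------------------------------------------------------------
# Sequence generation

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def generate_sequences(
    seed: int,
    n: int,
    length_range: tuple[int, int] = (120, 400),
    composition: Mapping[str, float] | None = None,
    planted_blocks: Sequence[tuple[int, int, str]] = (),
) -> dict[str, str]:
    """Random amino-acid sequences, optionally with planted charge blocks.

    ``planted_blocks`` is a sequence of (start, length, residue) segments
    (0-based start) overwritten into every sequence — e.g. a poly-K block to
    plant a known basic pI-maximum window.  Deterministic per seed.
    """
    lo, hi = length_range
    if lo < 15:
        raise ValueError("minimum sequence length is 15 (the smallest window)")
    if lo > hi:
        raise ValueError("invalid length range")
    residues = list(composition) if composition else list(STANDARD_RESIDUES)
    probs = (np.array([composition[r] for r in residues], float)
             if composition else np.ones(len(residues)))
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(residues, size=length, p=probs))
        for start, blen, res in planted_blocks:
            if start + blen > length:
                raise ValueError(
                    f"planted block [{start}, {start + blen}) exceeds sequence "
                    f"length {length}"
                )
            seq[start:start + blen] = [res] * blen
        out[f"SEQ{i + 1:04d}"] = "".join(seq)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences as FASTA, ids verbatim."""
    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Sampling from a fitted model (parameter-recovery harness)

def _sample_stepped(rng: np.random.Generator, sub: SteppedModel, cls_idx: int) -> float:
    """Draw from the piecewise-uniform density implied by the (unsmoothed)
    interval probabilities."""
    levels = sub.levels[cls_idx]
    j = int(rng.choice(len(levels), p=levels / levels.sum()))
    t = list(sub.thresholds)
    if sub.periodic:
        starts = t
        ends = t[1:] + [t[0] + sub.period]
        x = rng.uniform(starts[j], ends[j])
        return float(np.mod(x, sub.period))
    edges = [sub.domain[0], *t, sub.domain[1]]
    return float(rng.uniform(edges[j], edges[j + 1]))


def generate_from_fitted(
    model: FittedModel, n: int, seed: int
) -> TrainingTable:
    """Sample labels from the model's priors and properties from its own
    class-conditional submodels — the exact generative match to the
    predictor's independence assumption.

    Binary indicator properties are written back into the underlying
    categorical record field; the supported configurations use at most one
    indicator per source field (two independently sampled true indicators of
    the same field cannot be represented in one record and raise).
    """
    rng = np.random.default_rng(seed)
    classes = tuple(model.classes)
    records = []
    for i in range(n):
        cls_idx = int(rng.choice(len(classes), p=model.priors))
        attrs: dict[str, object] = {}
        # (attr -> list of (indicated value, sampled bool)) for indicators
        demands: dict[str, list[tuple[str, bool]]] = {}
        for name, sub in model.submodels.items():
            if isinstance(sub, SteppedModel):
                x = _sample_stepped(rng, sub, cls_idx)
                if name == "pi_global":
                    attrs["pi_global"] = min(max(x, 1e-6), 14 - 1e-6)
                elif name == "onset_min":
                    attrs["onset_min"] = x
                elif name.startswith(("pi_max_", "pi_min_")):
                    attrs.setdefault(
                        "pi_max_by_window" if name.startswith("pi_max_")
                        else "pi_min_by_window", {})[
                        int(name.rsplit("_", 1)[1])] = min(max(x, 1e-6), 14 - 1e-6)
                else:
                    raise ValueError(f"cannot place continuous property {name!r}")
            else:
                value = sub.values[int(rng.choice(
                    len(sub.values), p=sub.table[cls_idx] / sub.table[cls_idx].sum()))]
                if name in _ATTR_VALUES:          # base categorical property
                    attrs[name] = value
                elif name in INDICATOR_SOURCES:   # binary indicator
                    attr, indicated = INDICATOR_SOURCES[name]
                    demands.setdefault(attr, []).append((indicated, bool(value)))
                else:
                    raise ValueError(f"cannot place categorical property {name!r}")
        for attr, dem in demands.items():
            trues = [v for v, b in dem if b]
            falses = {v for v, b in dem if not b}
            if len(trues) > 1:
                raise ValueError(
                    f"inconsistent indicator sample for {attr!r}: {trues}"
                )
            if trues:
                attrs[attr] = trues[0]
            else:
                filler = [v for v in _ATTR_VALUES[attr] if v not in falses]
                if not filler:
                    raise ValueError(f"no admissible filler value for {attr!r}")
                attrs[attr] = filler[0]
        records.append(ProteinRecord(
            id=f"GEN{i + 1:05d}", label=classes[cls_idx], **attrs))
    return TrainingTable(records, classes=classes)
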