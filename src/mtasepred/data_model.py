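"""Core domain types and file I/O for the substrate-specificity predictor.

The canonical on-disk formats are plain text: a UTF-8 tab-separated property
table (one row per enzyme), FASTA for sequences, TSV for predictions and a
JSON document for fitted models.  Empty cells and the literal string ``NA``
denote missing values; missing data is legal everywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Fixed, documented class order.  The order matters: exact posterior ties
#: are broken in favour of the earlier class.
DEFAULT_CLASSES: tuple[str, ...] = ("RNA", "PROTEIN", "OTHER")

FOLD_GROUPS = ("ROSSMANN", "SET", "SPOUT", "OTHER_FOLD")
LOCALIZATION_CLASSES = (
    "NUCLEOLUS",
    "NUCLEUS_NOT_NUCLEOLUS",
    "MITO_NOT_NUCLEUS",
    "OTHER_LOC",
)
YMC_CLUSTERS = ("Ox", "R/B", "R/C", "none")

#: Residues whose ionization behaviour is undefined in the standard pKa
#: tables; they are retained in sequences but flagged on input.
NONSTANDARD_RESIDUES = frozenset("BZXU*")

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "None"}

#: Fixed column order of the property table.  Windowed pI columns
#: (``pi_max_<w>`` / ``pi_min_<w>``) are appended after these.
TABLE_COLUMNS = (
    "id",
    "fold_group",
    "localization_class",
    "ymc_cluster",
    "onset_min",
    "pi_global",
    "label",
)


class TableFormatError(ValueError):
    """Raised when a property table violates the documented dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """One enzyme with its derived property values and optional label.

    Every property is optional: the predictor treats an absent property as
    contributing no evidence.  ``onset_min`` lives on a 300-minute circle.
    """

    id: str
    sequence: str | None = None
    fold_group: str | None = None
    localization_class: str | None = None
    ymc_cluster: str | None = None
    onset_min: float | None = None
    pi_global: float | None = None
    pi_max_by_window: Mapping[int, float] = field(default_factory=dict)
    pi_min_by_window: Mapping[int, float] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if self.onset_min is not None and not (0 <= self.onset_min < 300):
            raise ValueError(
                f"onset_min must lie in [0, 300): got {self.onset_min!r} for {self.id}"
            )
        for pi in (self.pi_global, *self.pi_max_by_window.values(),
                   *self.pi_min_by_window.values()):
            if pi is not None and not (0 < pi < 14):
                raise ValueError(f"pI value {pi!r} outside (0, 14) for {self.id}")
        if self.fold_group is not None and self.fold_group not in FOLD_GROUPS:
            raise ValueError(f"unknown fold group {self.fold_group!r}")
        if (self.localization_class is not None
                and self.localization_class not in LOCALIZATION_CLASSES):
            raise ValueError(f"unknown localization class {self.localization_class!r}")
        if self.ymc_cluster is not None and self.ymc_cluster not in YMC_CLUSTERS:
            raise ValueError(f"unknown YMC cluster {self.ymc_cluster!r}")


@dataclass
class TrainingTable:
    """An ordered collection of records plus the substrate class set.

    ``classes`` defaults to (RNA, PROTEIN, OTHER) but is configurable so the
    same machinery extends to other class systems (more substrate categories,
    methylated-atom classes, enzyme families with n != 3 functions).
    """

    records: list[ProteinRecord]
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TableFormatError(f"duplicate record id(s): {dupes}")
        for r in self.records:
            if r.label is not None and r.label not in self.classes:
                raise TableFormatError(
                    f"label {r.label!r} of record {r.id!r} not in class set {self.classes}"
                )

    @property
    def labeled(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.label is not None]

    @property
    def unlabeled(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.label is None]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for r in self.labeled:
            counts[r.label] += 1
        return counts

    @property
    def priors(self) -> np.ndarray:
        """Empirical class frequencies among labeled records."""
        counts = np.array([self.class_counts[c] for c in self.classes], float)
        total = counts.sum()
        if total == 0:
            raise ValueError("no labeled records: priors undefined")
        return counts / total


def _window_columns(records: Iterable[ProteinRecord]) -> tuple[list[int], list[int]]:
    max_ws: set[int] = set()
    min_ws: set[int] = set()
    for r in records:
        max_ws.update(r.pi_max_by_window)
        min_ws.update(r.pi_min_by_window)
    return sorted(max_ws), sorted(min_ws)


def write_property_table(table: TrainingTable, path: str | Path) -> None:
    """Write a TrainingTable to the canonical TSV dialect.

    Floats are printed with 12 decimal digits so a write/read cycle is the
    identity on every value.
    """
    max_ws, min_ws = _window_columns(table.records)
    cols = list(TABLE_COLUMNS)
    cols += [f"pi_max_{w}" for w in max_ws] + [f"pi_min_{w}" for w in min_ws]
    if any(r.sequence is not None for r in table.records):
        cols.append("sequence")
    rows = []
    for r in table.records:
        row: dict[str, object] = {
            "id": r.id,
            "fold_group": r.fold_group,
            "localization_class": r.localization_class,
            "ymc_cluster": r.ymc_cluster,
            "onset_min": r.onset_min,
            "pi_global": r.pi_global,
            "label": r.label,
            "sequence": r.sequence,
        }
        for w in max_ws:
            row[f"pi_max_{w}"] = r.pi_max_by_window.get(w)
        for w in min_ws:
            row[f"pi_min_{w}"] = r.pi_min_by_window.get(w)
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12f")


def _parse_float(cell: object, *, row: int, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if text in _MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise TableFormatError(
            f"row {row}: column {column!r} is not numeric: {text!r}"
        ) from exc


def _parse_str(cell: object) -> str | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    return None if text in _MISSING_TOKENS else text


def read_property_table(
    path: str | Path, classes: tuple[str, ...] = DEFAULT_CLASSES
) -> TrainingTable:
    """Read a property table from the canonical TSV dialect.

    Unknown columns are ignored with a warning; empty cells and ``NA`` become
    absent properties; labels are validated against the class set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"property table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    if "id" not in df.columns:
        raise TableFormatError(f"{path}: header must contain an 'id' column")
    known = set(TABLE_COLUMNS) | {"sequence"}
    unknown = [c for c in df.columns
               if c not in known and not c.startswith(("pi_max_", "pi_min_"))]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown column(s) {unknown}", stacklevel=2)
    max_ws = sorted(int(c.removeprefix("pi_max_")) for c in df.columns
                    if c.startswith("pi_max_"))
    min_ws = sorted(int(c.removeprefix("pi_min_")) for c in df.columns
                    if c.startswith("pi_min_"))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row_d = dict(zip(df.columns, row))
        rid = _parse_str(row_d.get("id"))
        if rid is None:
            raise TableFormatError(f"row {i}: missing id")
        try:
            rec = ProteinRecord(
                id=rid,
                sequence=_parse_str(row_d.get("sequence")),
                fold_group=_parse_str(row_d.get("fold_group")),
                localization_class=_parse_str(row_d.get("localization_class")),
                ymc_cluster=_parse_str(row_d.get("ymc_cluster")),
                onset_min=_parse_float(row_d.get("onset_min"), row=i, column="onset_min"),
                pi_global=_parse_float(row_d.get("pi_global"), row=i, column="pi_global"),
                pi_max_by_window={
                    w: v for w in max_ws
                    if (v := _parse_float(row_d.get(f"pi_max_{w}"), row=i,
                                          column=f"pi_max_{w}")) is not None
                },
                pi_min_by_window={
                    w: v for w in min_ws
                    if (v := _parse_float(row_d.get(f"pi_min_{w}"), row=i,
                                          column=f"pi_min_{w}")) is not None
                },
                label=_parse_str(row_d.get("label")),
            )
        except ValueError as exc:
            raise TableFormatError(f"row {i}: {exc}") from exc
        records.append(rec)
    return TrainingTable(records, classes=classes)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from FASTA, keyed by the first header token.

    Sequences are upper-cased.  Non-standard residues (B, Z, X, U, ``*``) are
    retained but reported via a warning so downstream pI code can treat them
    as non-ionizable.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    flagged: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if set(seq) & NONSTANDARD_RESIDUES:
            flagged.append(rec.id)
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    if flagged:
        warnings.warn(
            f"{path}: non-standard residues (B/Z/X/U/*) in {flagged}; "
            "they contribute no charge to pI calculations",
            stacklevel=2,
        )
    return sequences


@dataclass(frozen=True)
class PosteriorVector:
    """Normalized posterior P(class | properties) over the substrate classes."""

    classes: tuple[str, ...]
    probs: np.ndarray
    used_properties: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (len(self.classes),):
            raise ValueError("probs must have one entry per class")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("posterior must be nonnegative and sum to 1")

    @property
    def argmax_class(self) -> str:
        # np.argmax returns the first maximum: ties go to the earlier class.
        return self.classes[int(np.argmax(self.probs))]

    def prob(self, cls: str) -> float:
        return float(self.probs[self.classes.index(cls)])


def write_predictions(
    records: Sequence[ProteinRecord],
    posteriors: Sequence[PosteriorVector],
    path: str | Path,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
) -> None:
    """Write predictions as TSV: id, predicted class, per-class probabilities,
    and the properties that contributed."""
    if len(records) != len(posteriors):
        raise ValueError(
            f"records ({len(records)}) and posteriors ({len(posteriors)}) "
            "must be aligned"
        )
    cols = ["id", "predicted"] + [f"p_{c}" for c in classes] + ["used_properties"]
    rows = []
    for rec, post in zip(records, posteriors):
        if tuple(post.classes) != tuple(classes):
            raise ValueError(f"posterior class order mismatch for {rec.id}")
        row = {"id": rec.id, "predicted": post.argmax_class,
               "used_properties": ",".join(post.used_properties)}
        row.update({f"p_{c}": p for c, p in zip(classes, post.probs)})
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.12f")


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions TSV back into a DataFrame (floats re-parsed)."""
    return pd.read_csv(path, sep="\t", comment="#")


# --- model JSON serialization -------------------------------------------------
# The fitted-model document is deliberately plain JSON so that models are
# diffable and testable; (de)serializers for the concrete model classes live
# here to keep every on-disk format in one module.

def save_model_json(model, path: str | Path) -> None:
    """Serialize a fitted multi-property model (predictor.FittedModel)."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))


def load_model_json(path: str | Path):
    """Load a fitted model saved by :func:`save_model_json`."""
    from .predictor import FittedModel

    return FittedModel.from_dict(json.loads(Path(path).read_text()))
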