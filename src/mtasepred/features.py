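"""Derivation of model input properties from raw annotations and sequence.

Continuous properties are all isoelectric-point (pI) based: the global pI of
the chain and the extrema of locally computed pI over sliding windows of a
given length (``pI max`` / ``pI min``), which flag strongly charged regions
that plausibly correspond to substrate-binding surfaces.  Categorical
properties (structural fold, cellular localization, metabolic-cycle
expression cluster) are collapsed into small supergroups and additionally
expanded into binary indicator properties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import ProteinRecord

# ---------------------------------------------------------------------------
# pKa tables

@dataclass(frozen=True)
class PkaSet:
    """Ionizable-group pKa values: ``basic`` groups carry +1 when protonated,
    ``acidic`` groups carry -1 when deprotonated.

    Keys are one-letter residue codes plus the pseudo-residues ``Nterm`` and
    ``Cterm``.  Custom (even partial) sets are allowed; the shipped tables
    cover both termini and the ionizable residues D, E, C, Y, H, K, R.
    """

    name: str
    acidic: Mapping[str, float]
    basic: Mapping[str, float]


#: EMBOSS iep default table (the package default).
EMBOSS = PkaSet(
    name="emboss",
    acidic={"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    basic={"Nterm": 8.6, "H": 6.5, "K": 10.8, "R": 12.5},
)

#: Free-amino-acid pKa values as tabulated in Lehninger.
LEHNINGER = PkaSet(
    name="lehninger",
    acidic={"Cterm": 2.34, "D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07},
    basic={"Nterm": 9.69, "H": 6.00, "K": 10.53, "R": 12.48},
)

PKA_SETS: dict[str, PkaSet] = {"emboss": EMBOSS, "lehninger": LEHNINGER}


@dataclass(frozen=True)
class PIProfile:
    """Sliding-window pI extrema for one sequence.

    ``pi_max[w]`` / ``pi_min[w]`` are the extreme pI values over every
    contiguous window of length ``w``; window sizes longer than the sequence
    are omitted and listed in ``omitted_window_sizes``.
    """

    window_sizes: tuple[int, ...]
    pi_max: Mapping[int, float]
    pi_min: Mapping[int, float]
    global_pi: float
    omitted_window_sizes: tuple[int, ...] = ()


#: Window-size grid used by default: 15..185 aa in steps of 5.
DEFAULT_WINDOW_SIZES: tuple[int, ...] = tuple(range(15, 186, 5))


def _group_counts(
    sequence: str, pka_set: PkaSet, include_termini: bool
) -> tuple[list[float], list[float], np.ndarray]:
    """Return (pKas, signs, counts) for one whole sequence."""
    pkas: list[float] = []
    signs: list[float] = []
    counts: list[float] = []
    for table, sign in ((pka_set.basic, +1.0), (pka_set.acidic, -1.0)):
        for group, pka in table.items():
            if group in ("Nterm", "Cterm"):
                n = 1.0 if include_termini else 0.0
            else:
                n = float(sequence.count(group))
            pkas.append(pka)
            signs.append(sign)
            counts.append(n)
    return pkas, signs, np.array(counts, float)[None, :]


def _charge_matrix(
    counts: np.ndarray, pkas: Sequence[float], signs: Sequence[float], ph: np.ndarray
) -> np.ndarray:
    """Henderson-Hasselbalch net charge for each row of ``counts`` at the
    matching entry of ``ph`` (both shaped (n,) / (n, groups))."""
    pkas_a = np.asarray(pkas, float)[None, :]
    signs_a = np.asarray(signs, float)[None, :]
    ph_a = np.asarray(ph, float)[:, None]
    # basic: +1/(1+10^(pH-pKa));  acidic: -1/(1+10^(pKa-pH))
    frac = 1.0 / (1.0 + 10.0 ** (signs_a * (ph_a - pkas_a)))
    return (counts * signs_a * frac).sum(axis=1)


def net_charge(
    sequence: str,
    ph: float,
    pka_set: PkaSet = EMBOSS,
    include_termini: bool = True,
) -> float:
    """Net charge (elementary-charge units) of ``sequence`` at ``ph``.

    Strictly decreasing in pH.  Residues with undefined ionization
    (B, Z, X, U, ``*``) contribute zero charge.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not (0 < ph < 14):
        raise ValueError(f"pH must lie in (0, 14): got {ph}")
    pkas, signs, counts = _group_counts(sequence.upper(), pka_set, include_termini)
    return float(_charge_matrix(counts, pkas, signs, np.array([ph]))[0])


def _bisect_pi(
    counts: np.ndarray,
    pkas: Sequence[float],
    signs: Sequence[float],
    tol: float,
) -> np.ndarray:
    """Vectorized bisection for the zero-charge pH of each counts row."""
    n = counts.shape[0]
    lo = np.full(n, 1e-9)
    hi = np.full(n, 14.0 - 1e-9)
    c_lo = _charge_matrix(counts, pkas, signs, lo)
    c_hi = _charge_matrix(counts, pkas, signs, hi)
    bad = (c_lo <= 0) | (c_hi >= 0)
    if np.any(bad):
        raise ValueError(
            "net charge does not cross zero in (0, 14) for some window(s); "
            "the pKa set lacks an acidic or basic group"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c_mid = _charge_matrix(counts, pkas, signs, mid)
        pos = c_mid > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
        if np.all((np.abs(c_mid) < tol) | (hi - lo < 1e-6)):
            break
    return 0.5 * (lo + hi)


def isoelectric_point(
    sequence: str,
    pka_set: PkaSet = EMBOSS,
    tol: float = 1e-9,
    include_termini: bool = True,
) -> float:
    """pH at which the net charge of ``sequence`` is zero.

    Found by bisection on (0, 14) until |charge| < ``tol`` or the bracketing
    interval is narrower than 1e-6 pH units; deterministic, and a pure
    function of amino-acid composition.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pkas, signs, counts = _group_counts(sequence.upper(), pka_set, include_termini)
    if counts.sum() == 0:
        raise ValueError("sequence has no ionizable group under this pKa set")
    return float(_bisect_pi(counts, pkas, signs, tol)[0])


def sliding_window_pi_extrema(
    sequence: str,
    window_sizes: Iterable[int] = DEFAULT_WINDOW_SIZES,
    pka_set: PkaSet = EMBOSS,
    tol: float = 1e-9,
    include_termini: bool = True,
) -> PIProfile:
    """Extreme local pI over every contiguous window of each requested size.

    Windows are 1-based, inclusive, stride 1, and never padded: window sizes
    exceeding the sequence length are omitted from the profile and reported
    in ``omitted_window_sizes``.  Each window is treated as a peptide (both
    termini ionizable) when ``include_termini`` is set, mirroring the global
    pI convention.
    """
    seq = sequence.upper()
    sizes = sorted(set(int(w) for w in window_sizes))
    if not sizes:
        raise ValueError("no window sizes given")
    for w in sizes:
        if not (15 <= w <= 185):
            raise ValueError(f"window size {w} outside [15, 185]")
    usable = [w for w in sizes if w <= len(seq)]
    omitted = tuple(w for w in sizes if w > len(seq))
    if not usable:
        raise ValueError(
            f"all window sizes exceed sequence length {len(seq)}"
        )
    pkas, signs, _ = _group_counts(seq, pka_set, include_termini)
    groups = list(pka_set.basic) + list(pka_set.acidic)
    # cumulative residue counts: occ[g][i] = count of g in seq[:i]
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    cum = {
        g: np.concatenate(([0], np.cumsum(arr == ord(g))))
        for g in groups if g not in ("Nterm", "Cterm")
    }
    pi_max: dict[int, float] = {}
    pi_min: dict[int, float] = {}
    for w in usable:
        n_win = len(seq) - w + 1
        cols = []
        for table, _sign in ((pka_set.basic, +1.0), (pka_set.acidic, -1.0)):
            for g in table:
                if g in ("Nterm", "Cterm"):
                    cols.append(np.full(n_win, 1.0 if include_termini else 0.0))
                else:
                    c = cum[g]
                    cols.append((c[w:] - c[:-w]).astype(float))
        counts = np.stack(cols, axis=1)
        pis = _bisect_pi(counts, pkas, signs, tol)
        pi_max[w] = float(pis.max())
        pi_min[w] = float(pis.min())
    global_pi = isoelectric_point(seq, pka_set, tol, include_termini)
    return PIProfile(
        window_sizes=tuple(usable),
        pi_max=pi_max,
        pi_min=pi_min,
        global_pi=global_pi,
        omitted_window_sizes=omitted,
    )


# ---------------------------------------------------------------------------
# Categorical property grouping

#: The nine catalytic-domain folds observed among yeast MTases, collapsed
#: into four groups; only Rossmann-like, SET and SPOUT are frequent enough
#: (and specific enough) to stand alone.
DEFAULT_FOLD_MAP: dict[str, str] = {
    "rossmann-like": "ROSSMANN",
    "spout": "SPOUT",
    "set domain": "SET",
    "tim beta/alpha-barrel": "OTHER_FOLD",
    "transmembrane": "OTHER_FOLD",
    "tetrapyrrole methylase": "OTHER_FOLD",
    "dna/rna-binding 3-helical bundle": "OTHER_FOLD",
    "sso0622-like": "OTHER_FOLD",
    "thymidylate synthetase": "OTHER_FOLD",
}


def group_fold(raw_fold_name: str, fold_map: Mapping[str, str] | None = None) -> str:
    """Collapse a raw fold name into one of ROSSMANN / SET / SPOUT / OTHER_FOLD."""
    mapping = DEFAULT_FOLD_MAP if fold_map is None else {
        k.lower(): v for k, v in fold_map.items()
    }
    key = raw_fold_name.strip().lower()
    if key not in mapping:
        raise ValueError(
            f"unknown fold name {raw_fold_name!r}; known: {sorted(mapping)}"
        )
    return mapping[key]


def collapse_localization(term_list: Iterable[str]) -> str:
    """Collapse a set of localization terms into one of four mutually
    exclusive classes.

    The classes are defined by negation — "nucleus and not nucleolus",
    "mitochondrion and not nucleus" — which forces the precedence
    nucleolus > nucleus > mitochondrion > other.  The empty set maps to
    OTHER_LOC.  Idempotent on any input.
    """
    terms = {t.strip().lower() for t in term_list}
    if "nucleolus" in terms:
        return "NUCLEOLUS"
    if "nucleus" in terms:
        return "NUCLEUS_NOT_NUCLEOLUS"
    if "mitochondrion" in terms:
        return "MITO_NOT_NUCLEUS"
    return "OTHER_LOC"


# ---------------------------------------------------------------------------
# Binary indicator expansion

#: indicator name -> (record attribute, attribute value it indicates)
INDICATOR_SOURCES: dict[str, tuple[str, str]] = {
    "Rossmann-like": ("fold_group", "ROSSMANN"),
    "SET": ("fold_group", "SET"),
    "SPOUT": ("fold_group", "SPOUT"),
    "other fold": ("fold_group", "OTHER_FOLD"),
    "Ox": ("ymc_cluster", "Ox"),
    "R/B": ("ymc_cluster", "R/B"),
    "R/C": ("ymc_cluster", "R/C"),
    "No cluster": ("ymc_cluster", "none"),
    "nucleolus": ("localization_class", "NUCLEOLUS"),
    "nucleus": ("localization_class", "NUCLEUS_NOT_NUCLEOLUS"),
    "mitochondrion": ("localization_class", "MITO_NOT_NUCLEUS"),
    "other localization": ("localization_class", "OTHER_LOC"),
}


def expand_binary_indicators(record: ProteinRecord) -> dict[str, bool]:
    """One-hot expansion of the categorical properties into true/false
    indicator properties; indicators whose source property is absent are
    themselves absent (not emitted)."""
    out: dict[str, bool] = {}
    for name, (attr, value) in INDICATOR_SOURCES.items():
        source = getattr(record, attr)
        if source is not None:
            out[name] = source == value
    return out


# ---------------------------------------------------------------------------
# Uniform property access

CATEGORICAL_BASE_PROPERTIES = ("fold_group", "localization_class", "ymc_cluster")
CONTINUOUS_PROPERTIES = ("pi_global", "onset_min")


def property_value(record: ProteinRecord, name: str):
    """Resolve a property by name on a record; returns None when absent.

    Recognized names: the categorical base properties, the binary indicators
    of :data:`INDICATOR_SOURCES`, ``pi_global``, ``onset_min``, and windowed
    pI extrema as ``pi_max_<w>`` / ``pi_min_<w>``.
    """
    if name in CATEGORICAL_BASE_PROPERTIES or name in CONTINUOUS_PROPERTIES:
        return getattr(record, name)
    if name in INDICATOR_SOURCES:
        return expand_binary_indicators(record).get(name)
    if name.startswith("pi_max_"):
        return record.pi_max_by_window.get(int(name.removeprefix("pi_max_")))
    if name.startswith("pi_min_"):
        return record.pi_min_by_window.get(int(name.removeprefix("pi_min_")))
    raise KeyError(f"unknown property {name!r}")


def derive_record(
    rid: str,
    sequence: str | None = None,
    raw_fold: str | None = None,
    localization_terms: Iterable[str] | None = None,
    ymc_cluster: str | None = None,
    onset_min: float | None = None,
    window_sizes: Iterable[int] = DEFAULT_WINDOW_SIZES,
    pka_set: PkaSet = EMBOSS,
    label: str | None = None,
) -> ProteinRecord:
    """Build a fully derived ProteinRecord from raw inputs: computes global
    and windowed pI from the sequence (when present) and collapses fold and
    localization annotations."""
    pi_global = None
    pi_max: dict[int, float] = {}
    pi_min: dict[int, float] = {}
    if sequence:
        profile = sliding_window_pi_extrema(sequence, window_sizes, pka_set)
        pi_global = profile.global_pi
        pi_max = dict(profile.pi_max)
        pi_min = dict(profile.pi_min)
    return ProteinRecord(
        id=rid,
        sequence=sequence.upper() if sequence else None,
        fold_group=group_fold(raw_fold) if raw_fold is not None else None,
        localization_class=(
            collapse_localization(localization_terms)
            if localization_terms is not None else None
        ),
        ymc_cluster=ymc_cluster,
        onset_min=onset_min,
        pi_global=pi_global,
        pi_max_by_window=pi_max,
        pi_min_by_window=pi_min,
        label=label,
    )
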