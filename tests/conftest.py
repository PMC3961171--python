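import numpy as np
import pytest
from hypothesis import settings

from mtasepred.data_model import ProteinRecord, TrainingTable
from mtasepred.synthetic_data import GeneratorSpec, generate_training_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

CLASSES = ("RNA", "PROTEIN", "OTHER")


def _records_with_folds(spec: list[tuple[str, str, int]]) -> list[ProteinRecord]:
    records = []
    i = 0
    for label, fold, count in spec:
        for _ in range(count):
            i += 1
            records.append(ProteinRecord(id=f"P{i:03d}", fold_group=fold, label=label))
    return records


@pytest.fixture(scope="session")
def composition_table() -> TrainingTable:
    """Deterministic 61-record table with the canonical class composition
    (26 RNA / 24 protein / 11 other) and the hard fold-class associations:
    all 8 SET-fold enzymes methylate protein, all 4 SPOUT-fold enzymes
    methylate RNA."""
    records = _records_with_folds([
        ("RNA", "SPOUT", 4), ("RNA", "ROSSMANN", 20), ("RNA", "OTHER_FOLD", 2),
        ("PROTEIN", "SET", 8), ("PROTEIN", "ROSSMANN", 14), ("PROTEIN", "OTHER_FOLD", 2),
        ("OTHER", "ROSSMANN", 4), ("OTHER", "OTHER_FOLD", 7),
    ])
    return TrainingTable(records, classes=CLASSES)


@pytest.fixture(scope="session")
def default_table() -> TrainingTable:
    """Default synthetic fixture emulating the training set (seeded)."""
    return generate_training_table(GeneratorSpec(seed=11))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)
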