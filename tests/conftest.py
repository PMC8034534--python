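import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from soluprot.features import compute_feature_matrix
from soluprot.synthetic import PlantedModel, gen_sequences


@pytest.fixture
def write_fasta_text(tmp_path):
    def _write(text: str, name: str = "in.fa") -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def planted_2000():
    """The planted-signal study dataset: n=2000, seed 1, default weights.

    Session-scoped: feature extraction over 2000 sequences is shared by the
    recovery tests. Returns (records, feature matrix, excluded features,
    label array)."""
    records = gen_sequences(PlantedModel(n=2000, seed=1))
    matrix, excluded = compute_feature_matrix(records)
    labels = np.array([1 if r.label == "soluble" else 0 for r in records])
    return records, matrix, excluded, labels
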