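import numpy as np
import pytest

from molpool import (
    CompoundRecord,
    DatasetTable,
    EnumerationConfig,
    FixtureSpec,
    build_frequency_table,
    enumerate_dataset,
    generate_library,
)


@pytest.fixture(scope="session")
def config_d4() -> EnumerationConfig:
    return EnumerationConfig(max_diameter=4, invariants="standard", use_chirality=True)


@pytest.fixture(scope="session")
def config_d2() -> EnumerationConfig:
    return EnumerationConfig(max_diameter=2, invariants="standard", use_chirality=False)


@pytest.fixture(scope="session")
def library100(config_d4):
    """A heavy-tailed synthetic library with its enumeration and vocabulary."""
    table = generate_library(FixtureSpec(n_compounds=100, seed=11))
    sets = enumerate_dataset(table, config_d4)
    freq = build_frequency_table(sets, config_d4)
    return table, sets, freq


def marker_table(presence: np.ndarray, markers: list[str], labels=None) -> DatasetTable:
    """Build compounds from a compound x marker presence matrix.

    Every compound gets a CC backbone plus the marker fragments its row
    selects, so each marker's substructures appear in exactly the compounds
    of its column.
    """
    records = []
    for i, row in enumerate(np.asarray(presence)):
        smi = "CC" + "".join(m for m, on in zip(markers, row) if on)
        label = None if labels is None else float(labels[i])
        records.append(CompoundRecord(id=f"m{i}", smiles=smi, label=label))
    return DatasetTable(records)
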