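from pathlib import Path

import numpy as np
import pytest

from colonykin import Pedigree, SimConfig, simulate

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def toy_csv() -> Path:
    """20-row breeding-record fixture with known duplicates, a weaned>born
    row, an invalid date and assorted incomplete rows."""
    return DATA_DIR / "toy_records.csv"


@pytest.fixture
def classical_ped() -> Pedigree:
    """Founders F1-F3; C and D are full sibs, H a half sib of C (shared
    sire F1), X an offspring of the full-sib mating C x D."""
    return Pedigree(
        {
            "C": ("F1", "F2"),
            "D": ("F1", "F2"),
            "H": ("F1", "F3"),
            "X": ("C", "D"),
        }
    )


@pytest.fixture(scope="session")
def small_colony():
    """One deterministic null colony shared by consistency tests."""
    return simulate(SimConfig(n_pairs=12, n_years=10, rng_seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
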