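import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from pairlens.simulate import SimulationConfig, build_germline_db, simulate_paired_repertoire


@pytest.fixture(scope="session")
def db():
    return build_germline_db(seed=1)


@pytest.fixture(scope="session")
def small_pairs(db):
    cfg = SimulationConfig(n_pairs=200, seed=11)
    return simulate_paired_repertoire(cfg, db)
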