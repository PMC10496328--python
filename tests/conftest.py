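import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from rinkit import BondParams, PrepOptions, annotate_chemistry, prepare_model
from rinkit.detectors import DETECTORS


@pytest.fixture
def params():
    return BondParams()


@pytest.fixture
def prep():
    return PrepOptions()


@pytest.fixture
def run_detector(params, prep):
    """Run one named detector on model 1 of a structure with default settings."""

    def _run(structure, bond_type, use_params=None):
        prepared = prepare_model(structure.models[0], prep)
        chem = annotate_chemistry(prepared)
        return DETECTORS[bond_type](prepared, chem, use_params or params)

    return _run


@pytest.fixture
def prepared_and_chem(prep):
    def _make(structure):
        prepared = prepare_model(structure.models[0], prep)
        return prepared, annotate_chemistry(prepared)

    return _make
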