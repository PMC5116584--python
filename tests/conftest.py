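"""Shared fixtures: the published truth tables and a default registry."""

import pytest

from rcalogic import default_registry

# Output columns of the reference designs, rows in canonical binary order
# (first input is the most significant bit): the basic modules (metabolite,
# repressor) behave as ORN / NAND; then the 12 two-input gates and the
# three-input gate.
PRINTED_TABLES = {
    "ORN1": (1, 0, 1, 1),
    "ORN2": (1, 0, 1, 1),
    "NAND1": (1, 1, 1, 0),
    "NAND2": (1, 1, 1, 0),
    "AND": (0, 0, 0, 1),
    "OR": (0, 1, 1, 1),
    "NOR": (1, 0, 0, 0),
    "NAND": (1, 1, 1, 0),
    "ANDN": (0, 0, 1, 0),
    "ORN": (1, 0, 1, 1),
    "XNOR": (1, 0, 0, 1),
    "XOR": (0, 1, 1, 0),
    "YES": (0, 1, 0, 1),
    "NOT": (1, 0, 1, 0),
    "ALL": (1, 1, 1, 1),
    "NONE": (0, 0, 0, 0),
    "THREE_INPUT": (0, 0, 0, 0, 0, 0, 1, 0),
}

# The gate name each design classifies to (catalogue key -> printed name).
PRINTED_NAMES = {
    "ORN1": "ORN",
    "ORN2": "ORN",
    "NAND1": "NAND",
    "NAND2": "NAND",
    "AND": "AND",
    "OR": "OR",
    "NOR": "NOR",
    "NAND": "NAND",
    "ANDN": "ANDN",
    "ORN": "ORN",
    "XNOR": "XNOR",
    "XOR": "XOR",
    "YES": "YES",
    "NOT": "NOT",
    "ALL": "ALL",
    "NONE": "NONE",
    "THREE_INPUT": "THREE_INPUT_CUSTOM",
}


@pytest.fixture(scope="session")
def registry():
    return default_registry()
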