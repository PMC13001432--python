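import numpy as np
import pandas as pd
import pytest

from chemprofiler.store import (
    BioactivityRecord,
    CompoundRegistry,
    Outcome,
    merge_with_registry,
)


@pytest.fixture
def small_registry():
    reg = CompoundRegistry()
    reg.add("C1", "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3", "LFQSCWFLJHTTHZ-UHFFFAOYSA-N", "CCO")
    reg.add("C2", "InChI=1S/C6H6/c1-2-4-6-5-3-1/h1-6H", "UHOVQNZJYSORNB-UHFFFAOYSA-N", "c1ccccc1")
    reg.add("C3", "InChI=1S/CH4/h1H4", "VNWKTOKETHGBQD-UHFFFAOYSA-N", "C")
    reg.add("C4", "InChI=1S/C3H8/c1-3-2/h3H2,1-2H3", "ATUOYWHBWRKTHZ-UHFFFAOYSA-N", "CCC")
    return reg


@pytest.fixture
def small_db(small_registry):
    records = [
        BioactivityRecord("C1", "A1", Outcome.ACTIVE),
        BioactivityRecord("C2", "A1", Outcome.INACTIVE),
        BioactivityRecord("C3", "A1", Outcome.INCONCLUSIVE),
        BioactivityRecord("C1", "A2", Outcome.INACTIVE),
        BioactivityRecord("C2", "A2", Outcome.ACTIVE),
        BioactivityRecord("C3", "A2", Outcome.PROBE),
        BioactivityRecord("C4", "A3", Outcome.INACTIVE),
        BioactivityRecord("C2", "A3", Outcome.INACTIVE),
    ]
    db, _ = merge_with_registry(records, small_registry)
    return db


@pytest.fixture(scope="session")
def structure_library():
    from chemprofiler.synthetic import generate_chemical_library

    return generate_chemical_library(200, seed=42)
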