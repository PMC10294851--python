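import numpy as np
import pytest

from mitocompare.datasets import PTEROMALID_IDS, load_all_records
from mitocompare.gene_order import order_from_record


@pytest.fixture(scope="session")
def records():
    """The four bundled pteromalid records, keyed by short species key."""
    return load_all_records()


@pytest.fixture(scope="session")
def orders(records):
    """Signed circular gene orders (CR included) of the four records."""
    return {k: order_from_record(r) for k, r in records.items()}


@pytest.fixture(scope="session")
def species_keys():
    return list(PTEROMALID_IDS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230614)
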