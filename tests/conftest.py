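import logging

import pytest

from sideroforge.assembly import enumerate_ent_series, enumerate_products
from sideroforge.chemcore import default_registry
from sideroforge.io_cli import (
    load_known_unmatched,
    load_reference_fragments,
    load_reference_products,
    reference_spectra,
)

logging.getLogger("sideroforge").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def registry_by_id(registry):
    return {p.ref_no: p for p in registry}


@pytest.fixture(scope="session")
def candidates(registry):
    return enumerate_products(registry) + enumerate_ent_series()


@pytest.fixture(scope="session")
def candidates_by_id(candidates):
    return {p.id: p for p in candidates}


@pytest.fixture(scope="session")
def reference_products():
    return load_reference_products()


@pytest.fixture(scope="session")
def reference_fragments():
    return load_reference_fragments()


@pytest.fixture(scope="session")
def known_unmatched():
    return load_known_unmatched()


@pytest.fixture(scope="session")
def labeled_spectra():
    return reference_spectra(labels=True)


@pytest.fixture(scope="session")
def unlabeled_spectra():
    return reference_spectra(labels=False)
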