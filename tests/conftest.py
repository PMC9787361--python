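import pytest

from plastcmp import plastome_io
from plastcmp.synthetic_data import default_demo_config, generate_dataset


@pytest.fixture(scope="session")
def demo():
    """The default demo dataset (seed 1) shared across the suite."""
    return generate_dataset(default_demo_config(seed=1))


@pytest.fixture(scope="session")
def demo_records(demo):
    """Demo plastomes parsed back from their flat files, regions inferred."""
    records = {}
    for taxon, text in demo.genbank.items():
        rec = plastome_io.parse_plastome(text)
        rec.regions = plastome_io.infer_regions(rec)
        records[taxon] = rec
    return records


@pytest.fixture(scope="session")
def demo_taxonomy(demo):
    return demo.taxonomy
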