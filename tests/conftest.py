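import dataclasses

import pytest

from mmcurate.pipeline import run_pipeline
from mmcurate.schema import builtin_catalog, catalog_by_id
from mmcurate.simulate import ScenarioConfig


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def by_id(catalog):
    return catalog_by_id(catalog)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default 250-patient scenario, seed 7."""
    return run_pipeline(ScenarioConfig(), seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    """A fast scenario for tests that only need structure, not precision."""
    return dataclasses.replace(ScenarioConfig(), n_patients=60,
                               n_timeline_patients=30)
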