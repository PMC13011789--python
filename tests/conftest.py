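"""Shared fixtures: a coarse (4 mm) test grid keeps image-level tests fast;
the physical head geometry is identical to the canonical 2 mm grid."""

import pytest

from centamine.atlas import GridSpec, build_synthetic_atlas
from centamine.phantom import DEFAULT_HC_VALUES, build_template_bank


@pytest.fixture(scope="session")
def grid_small():
    return GridSpec((46, 55, 46), (4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def atlas_small(grid_small):
    return build_synthetic_atlas(grid_small)


@pytest.fixture(scope="session")
def bank_small(atlas_small):
    return build_template_bank(atlas_small)


@pytest.fixture(scope="session")
def hc_values():
    return dict(DEFAULT_HC_VALUES)


@pytest.fixture(scope="session")
def report_regions():
    return [
        "striatum",
        "putamen",
        "caudate",
        "pre_commissural_putamen",
        "post_commissural_putamen",
    ]
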