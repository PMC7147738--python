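import numpy as np
import pytest

import flexmarine as fm


@pytest.fixture(scope="session")
def hex_mesh():
    """7 regular hexagons (one ring), 100 m center spacing, 10 m deep."""
    return fm.generate_fixture_mesh("hex", rings=1, dx=100.0, depth=10.0)


@pytest.fixture(scope="session")
def rect_mesh():
    """10 x 10 rect mesh, 100 m cells, 10 m deep, 5 layers."""
    return fm.generate_fixture_mesh(
        "rect", nx=10, ny=10, dx=100.0, depth=10.0,
        layer_interfaces=np.linspace(0.0, 10.0, 6))


@pytest.fixture()
def column_mesh():
    """Single 10 m x 10 m column, 100 layers of 1 m."""
    return fm.generate_fixture_mesh(
        "rect", nx=1, ny=1, dx=10.0, depth=100.0,
        layer_interfaces=np.linspace(0.0, 100.0, 101))


@pytest.fixture(scope="session")
def seiche_mesh():
    """Closed 50 x 1 basin, 100 m cells, 10 m deep, one layer."""
    return fm.generate_fixture_mesh("rect", nx=50, ny=1, dx=100.0, depth=10.0)
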