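import pytest

from celldose.geometry import CellModel, DegraderSlab, DegraderStack


@pytest.fixture(scope="session")
def cell() -> CellModel:
    """Default MIRD cell: 12.5/5 µm radii, 1.5 µm boron sphere, 10×10 nm shells."""
    return CellModel()


@pytest.fixture(scope="session")
def degrader_template() -> DegraderStack:
    """One fixed 25 µm Mylar foil plus a free air path."""
    return DegraderStack((DegraderSlab("mylar", 25.0),
                          DegraderSlab("air", None)))
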