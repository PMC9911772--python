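import numpy as np
import pandas as pd
import pytest

from neodrs import (
    BloodPanel,
    PairedTable,
    RawSpectrum,
    WavelengthGrid,
    default_grid,
    ground_truth_models,
)


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    """The working 450-650 nm grid at 0.47 nm (426 points)."""
    return default_grid()


@pytest.fixture(scope="session")
def models():
    return ground_truth_models()


@pytest.fixture()
def flat_triple(grid):
    """Sample == reference triple (zero absorbance everywhere)."""
    n = len(grid)
    dark = RawSpectrum(grid, np.full(n, 100.0), role="dark")
    reference = RawSpectrum(grid, np.full(n, 40100.0), role="reference")
    sample = RawSpectrum(grid, np.full(n, 40100.0), role="sample")
    return sample, dark, reference


def make_table(device, reference) -> PairedTable:
    device = np.asarray(device, dtype=float)
    return PairedTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(device.size)],
                "device": device,
                "reference": np.asarray(reference, dtype=float),
            }
        )
    )


@pytest.fixture()
def toy_table() -> PairedTable:
    """5-row table with hand-checkable regression/agreement statistics."""
    return make_table([2.1, 3.9, 6.2, 7.8, 10.1], [2.0, 4.0, 6.0, 8.0, 10.0])


@pytest.fixture()
def mid_panel() -> BloodPanel:
    return BloodPanel(tsb=10.0, hb=13.0, spo2=90.0)
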