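import numpy as np
import pytest

from vemmorph.synthetic_data import (
    OrganellePopulation,
    PhantomSpec,
    generate_phantom_cell,
    generate_phase_series,
)


def digital_ball(radius: int, pad: int = 3) -> np.ndarray:
    """Exhaustively rasterised digital ball (the brute-force oracle shape)."""
    n = 2 * radius + 2 * pad + 1
    c = n // 2
    zz, yy, xx = np.mgrid[:n, :n, :n]
    return ((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) <= radius * radius


@pytest.fixture(scope="session")
def phase_series():
    """One phantom cell per mitotic phase at the 90 nm test resolution."""
    return generate_phase_series(seed=20)


@pytest.fixture(scope="session")
def metaphase_phantom(phase_series):
    return phase_series["metaphase"][0]


@pytest.fixture(scope="session")
def small_phantom():
    """A quick-to-generate cell for I/O and pipeline tests."""
    spec = PhantomSpec(
        seed=77,
        voxel_size=(90.0, 90.0, 90.0),
        phase="metaphase",
        cell_semi_axes_um=(3.6, 3.2, 2.8),
        chromosome_volumes_um3=(1.2, 1.0, 0.8),
        chromosome_displacement_um=1.2,
        organelles={
            "mitochondrion": OrganellePopulation(count=12, mean_volume_um3=0.15),
            "vesicle": OrganellePopulation(count=8, mean_volume_um3=0.02),
        },
    )
    return generate_phantom_cell(spec)
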