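import numpy as np
import pytest

from myotract.io import DWIVolume, GradientTable, LabelMask
from myotract.phantom import PhantomSpec, default_gradient_table


@pytest.fixture(scope="session")
def gtab() -> GradientTable:
    """The default acquisition: 1 b0 + 32 directions at b = 400 s/mm^2."""
    return default_gradient_table()


@pytest.fixture(scope="session")
def small_straight_spec() -> PhantomSpec:
    """A compact straight-bundle phantom for fast unit tests."""
    return PhantomSpec(
        geometry_kind="straight",
        grid_shape=(20, 20, 8),
        geometry_params={"half_span": 10.0, "bundle_radius": 2.0},
        seed=1,
    )


def single_voxel_dwi(gtab, sticks, s0=1000.0, iso_fraction=0.1,
                     d_stick=1.5e-3, d_iso=2.0e-3, voxel=1.5):
    """1x1x1 DWIVolume with an exact stick-mixture signal (no noise).

    ``sticks``: list of (unit direction, volume fraction).
    """
    b, g = gtab.bvals, gtab.bvecs
    total = sum(f for _, f in sticks)
    signal = (1.0 - total) * np.exp(-b * d_iso)
    for n, f in sticks:
        n = np.asarray(n, float)
        n = n / np.linalg.norm(n)
        signal = signal + f * np.exp(-b * d_stick * (g @ n) ** 2)
    aff = np.eye(4)
    aff[:3, :3] *= voxel
    return DWIVolume(data=(s0 * signal).reshape(1, 1, 1, -1), affine=aff, gtab=gtab)


def full_mask(dwi) -> LabelMask:
    return LabelMask(data=np.ones(dwi.shape, dtype=int), affine=dwi.affine)
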