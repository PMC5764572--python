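import numpy as np
import pytest

from coloc3d import StackGeometry, SpotTruth, fit_spot_3d, render_stack

#: Bright-spot fixture: 100,000 photons (shot-noise-limited regime) on a
#: background of 100 counts/voxel, default PSF, 64 nm pixels / 200 nm steps.
FIXTURE_TRUTH = SpotTruth(
    channel="green", x=10.3 * 64, y=10.6 * 64, z=7.45 * 200, photons=100_000
)
FIXTURE_SEED_VOXEL = (10, 10, 7)
FIXTURE_BACKGROUND = 100.0
N_REPEATS = 200


@pytest.fixture(scope="session")
def small_geom() -> StackGeometry:
    return StackGeometry(nx=21, ny=21, nz=15)


@pytest.fixture(scope="session")
def repeat_fits(small_geom):
    """Centroids fitted to 200 independent Poisson renders of the bright spot."""
    out = []
    for seed in range(N_REPEATS):
        stack = render_stack(
            [FIXTURE_TRUTH],
            small_geom,
            background=FIXTURE_BACKGROUND,
            noise="poisson",
            seed=seed,
        )
        fit = fit_spot_3d(stack, FIXTURE_SEED_VOXEL)
        if fit.converged:
            out.append((fit.x, fit.y, fit.z))
    return np.array(out)
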