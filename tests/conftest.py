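import numpy as np
import pytest

from dystromorph import fibers, synth


@pytest.fixture(scope="session")
def fiber_field_small():
    """25-fiber field, 30% planted central nucleation, seeded."""
    mem, nuc, truth = synth.generate_fiber_field(
        25, size_px=(320, 320), border_width_px=3.0, pct_central=0.28,
        noise_sd=4.0, seed=11)
    return mem, nuc, truth


@pytest.fixture(scope="session")
def fiber_field_small_run(fiber_field_small):
    mem, nuc, truth = fiber_field_small
    cfg = fibers.MorphometryConfig(um_per_px=1.0)
    fiber_map, records, summary = fibers.run_morphometry(mem, nuc, cfg)
    return truth, fiber_map, records, summary


@pytest.fixture(scope="session")
def plate_volume_small():
    """Noiseless parallel-plate phantom: t=40 um, s=160 um at 8 um/voxel."""
    vol, truth = synth.generate_trabecular_volume(
        "parallel_plates", 40.0, 160.0, size_vox=(75, 64, 64),
        um_per_vox=8.0, noise_sd=0.0, seed=0)
    return vol, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20231005)
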