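import numpy as np
import pytest

from actincap.synthgen import SynthCellSpec, SynthFieldSpec, make_field_spec, render_field


@pytest.fixture(scope="session")
def small_field():
    """A 5-cell disjoint field with its images and ground truth."""
    spec = make_field_spec(5, image_size=(512, 512), seed=11)
    nuc, actin, truth = render_field(spec)
    return spec, nuc, actin, truth


@pytest.fixture()
def single_cell_spec():
    """One round nucleus with parallel fibers, centered in a small frame."""
    def _make(**overrides):
        seed = overrides.pop("seed", 5)
        defaults = dict(
            nucleus_center=(100.0, 100.0),
            nucleus_semi_axes=(20.0, 20.0),
            n_fibers=10,
            fiber_angle_mean=30.0,
            fiber_angle_sd=0.0,
            fiber_length_range=(60.0, 60.0),
        )
        defaults.update(overrides)
        return SynthFieldSpec(
            image_size=(200, 200),
            cell_specs=[SynthCellSpec(**defaults)],
            noise_sd=3.0,
            seed=seed,
        )
    return _make
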