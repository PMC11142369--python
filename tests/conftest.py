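import numpy as np
import pytest

import phagehab as ph
from phagehab.geometry import build_hex_array
from phagehab.transport import ConcentrationField


@pytest.fixture(scope="session")
def device_preset():
    return ph.reference_layout()


@pytest.fixture(scope="session")
def preset_gradient(device_preset):
    """20 h pre-run plus 30 h of continued evolution of the virion field."""
    params = ph.TransportParams()
    return ph.simulate_gradient(device_preset, params, duration_h=50.0, store_every=60)


@pytest.fixture(scope="session")
def preset_experiment(device_preset, preset_gradient):
    """Seeded 30 h spatial run on the device preset under the gradient.

    Shared by the hot-spot, refuge and colonization checks; seed 11 is the
    documented reference run.
    """
    field = preset_gradient.after(20 * 3600.0)
    record = ph.run_experiment(
        device_preset,
        field,
        ph.EcoParams(),
        ph.MutationParams(theta_L=1e-5),
        duration_h=30.0,
        seed=11,
        dt_h=0.001,
        record_every=100,
    )
    return record, field


@pytest.fixture()
def single_chamber():
    """Minimal 1-chamber layout plus a constant-exposure field factory."""
    layout = build_hex_array(1, 1, target_area_mm2=0.09)

    def field_at(c):
        return ConcentrationField(
            times_s=np.array([0.0]),
            values=np.array([[float(c)]]),
            chamber_ids=[layout.chambers[0].id],
        )

    return layout, field_at
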