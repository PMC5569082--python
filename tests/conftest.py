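import numpy as np
import pytest

from ptoct import AcquisitionConfig
from ptoct.simulate import make_phantom, simulate_mscan


@pytest.fixture(scope="session")
def small_config():
    """Reduced spectrometer sampling, full temporal record."""
    return AcquisitionConfig(n_spectrometer_pixels=256)


@pytest.fixture(scope="session")
def mirror_truth():
    """Single non-absorbing mirror at 200 µm."""
    return make_phantom("single_reflector", depth_um=200.0, phase_model="local")


@pytest.fixture(scope="session")
def sine_5nm_profile(small_config):
    """End-to-end noiseless pure-sine recovery of a 5 nm drive."""
    from ptoct.signal import process_mscan

    cfg = AcquisitionConfig(n_spectrometer_pixels=512, pt_power_mw=1.0)
    truth = make_phantom(
        "single_reflector", depth_um=200.0, absorber_units=5.0 / 1.56,
        thermal_mode="pure_sine", phase_model="local",
    )
    raw = simulate_mscan(truth, cfg, power_mw=1.0, noiseless=True)
    return process_mscan(raw, window_um=(150.0, 250.0), n_out=101)


@pytest.fixture(scope="session")
def power_series_df():
    """Pigmented-phantom power series: 6 eyes × P ∈ {1, 2, 4, 8} mW.

    Shared across the axial-profile acceptance checks because each B-scan
    is simulated column by column.
    """
    from ptoct.experiments import run_power_series

    return run_power_series(powers_mw=(1.0, 2.0, 4.0, 8.0), n_replicates=6, seed=0)
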