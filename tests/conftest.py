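import numpy as np
import pytest

from cardiomea import build_config, generate_recording, radial_spec
from cardiomea.beats import find_beats
from cardiomea.geometry import ElectrodeConfig


@pytest.fixture(scope="session")
def cfg120():
    return build_config("mcs_120")


@pytest.fixture(scope="session")
def cfg60():
    return build_config("mcs_60")


@pytest.fixture(scope="session")
def toy_cfg():
    """A 2x2 toy array with 200 um pitch for hand-checkable fixtures."""
    labels = ("A1", "B1", "A2", "B2")
    coords = {"A1": (0.0, 0.0), "B1": (200.0, 0.0), "A2": (0.0, 200.0), "B2": (200.0, 200.0)}
    return ElectrodeConfig(name="toy_4", pitch=200.0, diameter=30.0, labels=labels, coords=coords)


@pytest.fixture(scope="session")
def radial_clean(cfg120):
    """Noise-free radial wave from electrode F7 at 300 um/ms, 40 bpm, 6 beats."""
    spec = radial_spec(cfg120, cfg120.coords["F7"], speed=300.0, bpm=40.0, n_beats=6, seed=11)
    rec, gt = generate_recording(spec)
    return rec, gt


@pytest.fixture(scope="session")
def radial_clean_table(radial_clean):
    rec, gt = radial_clean
    return find_beats(rec)


def spike_train_recording(toy_cfg, times_ms, amp=300.0, width_ms=3.0, dt=1.0,
                          total_ms=None, noise=0.0, seed=0, sign=-1.0):
    """Simple per-electrode Gaussian spike train on the toy array."""
    from cardiomea.io import Recording

    total_ms = total_ms or (max(times_ms) + 500.0)
    t = np.arange(0.0, total_ms, dt)
    v = np.zeros_like(t)
    for t0 in times_ms:
        v += sign * amp * np.exp(-0.5 * ((t - t0) / width_ms) ** 2)
    rng = np.random.default_rng(seed)
    volts = np.tile(v, (toy_cfg.n_electrodes, 1))
    if noise:
        volts = volts + rng.normal(0, noise, volts.shape)
    return Recording(time=t, voltages=volts, cfg=toy_cfg)
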