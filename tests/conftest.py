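import numpy as np
import pytest

from hyperlink.epochs_io import EpochArray
from hyperlink.spectral import BandSpec, compute_freq_bands
from hyperlink.synthgen import DyadSimConfig, simulate_coupled_dyad

ALPHA_LOW = BandSpec("Alpha_Low", 7.5, 11.0)


def make_epochs(
    n_epochs=2,
    n_channels=3,
    n_samples=100,
    sfreq=100.0,
    seed=0,
    with_positions=True,
    bads=(),
    participant_id="p1",
):
    rng = np.random.default_rng(seed)
    names = [f"CH{i}" for i in range(n_channels)]
    pos = None
    if with_positions:
        angles = 2 * np.pi * np.arange(n_channels) / max(n_channels, 1)
        pos = {
            n: np.array([0.08 * np.cos(a), 0.08 * np.sin(a), 0.04])
            for n, a in zip(names, angles)
        }
    return EpochArray(
        data=rng.normal(0, 1e-5, (n_epochs, n_channels, n_samples)),
        sfreq=sfreq,
        ch_names=names,
        ch_pos=pos,
        bads=set(bads),
        participant_id=participant_id,
    )


@pytest.fixture
def epochs_factory():
    return make_epochs


@pytest.fixture(scope="session")
def coupled_dyad():
    """A strongly phase-coupled dyad with matched envelopes, no sensor noise."""
    cfg = DyadSimConfig(
        n_epochs=8,
        n_channels=3,
        kappa=1.0,
        phase_lag=np.pi / 2,
        noise_sd=0.0,
        rho_env=1.0,
        seed=11,
    )
    return simulate_coupled_dyad(cfg)


@pytest.fixture(scope="session")
def coupled_analytic(coupled_dyad):
    return compute_freq_bands(coupled_dyad, [ALPHA_LOW])
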