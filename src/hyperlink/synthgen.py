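"""Deterministic generator of coupled and null dyads with known ground truth.

Each participant's channels carry narrow-band oscillations built from a
wrapped Gaussian random-walk phase around a carrier frequency — a simple
model of the inherently non-stationary phase dynamics of real EEG — with
log-normal amplitude envelopes and additive Gaussian sensor noise.  On the
designated coupled channel pair, participant 2's phase interpolates
circularly between an independent walk (weight 1 - kappa) and participant
1's phase plus a fixed lag (weight kappa), so kappa = 0 is an exact null
and kappa = 1 a constant phase offset (inter-brain PLV -> 1).  Each
independent oscillator also carries a small random carrier detuning, as
two individuals' rhythms are never at exactly the same frequency.

Seeding uses one master seed that spawns per-participant, per-epoch
substreams, so changing the epoch count never reshuffles earlier epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs_io import EpochArray


@dataclass
class DyadSimConfig:
    """Ground-truth configuration of a simulated dyad.

    Defaults describe a small, realistic resting-style recording: 20 epochs
    of 2 s at 256 Hz, 8 channels per participant, a 10 Hz (alpha) carrier,
    and sensor noise at 0.2 of the oscillation RMS.
    """

    n_epochs: int = 20
    n_channels: int = 8
    sfreq: float = 256.0
    epoch_duration: float = 2.0
    carrier: float = 10.0
    kappa: float = 0.0
    phase_lag: float = np.pi / 4
    coupled_pairs: list[tuple[int, int]] = field(default_factory=lambda: [(0, 0)])
    rho_env: float = 0.0
    noise_sd: float = 0.2
    phase_walk_sd: float = 0.05
    carrier_jitter: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if not -1.0 <= self.rho_env <= 1.0:
            raise ValueError(f"rho_env must be in [-1, 1], got {self.rho_env}")
        if self.carrier >= self.sfreq / 2:
            raise ValueError(
                f"carrier {self.carrier} Hz at or above Nyquist ({self.sfreq / 2} Hz)"
            )
        for c1, c2 in self.coupled_pairs:
            if not (0 <= c1 < self.n_channels and 0 <= c2 < self.n_channels):
                raise ValueError(f"coupled pair ({c1}, {c2}) references invalid channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.sfreq))


def _rng(seed: int, participant: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(participant, epoch)))


def _phase_walk(
    rng: np.random.Generator,
    n: int,
    carrier: float,
    sfreq: float,
    sd: float,
    jitter: float = 0.0,
) -> np.ndarray:
    # per-draw carrier detuning: independent oscillators are never exactly
    # at the same frequency, which keeps the uncoupled case a genuine null
    f = carrier + rng.uniform(-jitter, jitter)
    base = 2 * np.pi * f * np.arange(n) / sfreq
    walk = np.cumsum(rng.normal(0.0, sd, n))
    return base + rng.uniform(-np.pi, np.pi) + walk


def _smooth_envelope(z: np.ndarray, sfreq: float) -> np.ndarray:
    """Log-normal envelope from a Gaussian series, smoothed to ~0.5 s scale."""
    n = len(z)
    width = max(int(0.5 * sfreq), 3)
    kernel = np.hanning(width)
    kernel /= kernel.sum()
    smooth = np.convolve(np.pad(z, width, mode="reflect"), kernel, mode="same")[width:-width]
    if smooth.std() > 0:
        smooth = (smooth - smooth.mean()) / smooth.std()
    return np.exp(0.3 * smooth)


def circular_montage(n_channels: int, radius: float = 0.09) -> dict[str, np.ndarray]:
    """Sensor positions on a circular ring of the upper head (head frame, m)."""
    names = [f"CH{i}" for i in range(n_channels)]
    angles = 2 * np.pi * np.arange(n_channels) / n_channels
    elev = np.pi / 4  # 45 degrees above the equator
    pos = {
        name: np.array(
            [
                radius * np.cos(elev) * np.cos(a),
                radius * np.cos(elev) * np.sin(a),
                radius * np.sin(elev),
            ]
        )
        for name, a in zip(names, angles)
    }
    return pos


def simulate_coupled_dyad(cfg: DyadSimConfig) -> tuple[EpochArray, EpochArray]:
    """Simulate a dyad with controllable inter-participant phase coupling.

    Returns two :class:`EpochArray` containers (participants 1 and 2) with
    a shared circular montage.  Reproducible bit-exactly from ``cfg.seed``.
    """
    n_s = cfg.n_samples
    amp = 1e-5  # ~10 microvolt oscillations
    coupled_src = {c1 for c1, _ in cfg.coupled_pairs}
    coupled_dst = {c2 for _, c2 in cfg.coupled_pairs}
    src_of = {c2: c1 for c1, c2 in cfg.coupled_pairs}

    data = [
        np.empty((cfg.n_epochs, cfg.n_channels, n_s)),
        np.empty((cfg.n_epochs, cfg.n_channels, n_s)),
    ]
    for ep in range(cfg.n_epochs):
        rng1 = _rng(cfg.seed, 1, ep)
        rng2 = _rng(cfg.seed, 2, ep)
        rng_dyad = _rng(cfg.seed, 0, ep)

        phases1 = {
            ch: _phase_walk(
                rng1, n_s, cfg.carrier, cfg.sfreq, cfg.phase_walk_sd, cfg.carrier_jitter
            )
            for ch in range(cfg.n_channels)
        }
        # correlated log-normal envelopes for the coupled pair
        cov = np.array([[1.0, cfg.rho_env], [cfg.rho_env, 1.0]])
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
        z = chol @ rng_dyad.normal(size=(2, n_s))
        env_pair = (_smooth_envelope(z[0], cfg.sfreq), _smooth_envelope(z[1], cfg.sfreq))

        for ch in range(cfg.n_channels):
            env = env_pair[0] if ch in coupled_src else _smooth_envelope(
                rng1.normal(size=n_s), cfg.sfreq
            )
            sig = amp * env * np.cos(phases1[ch])
            noise = rng1.normal(0.0, cfg.noise_sd * amp * np.sqrt(0.5), n_s)
            data[0][ep, ch] = sig + noise

        for ch in range(cfg.n_channels):
            indep = _phase_walk(
                rng2, n_s, cfg.carrier, cfg.sfreq, cfg.phase_walk_sd, cfg.carrier_jitter
            )
            if ch in coupled_dst and cfg.kappa > 0:
                # circular interpolation between the independent walk and the
                # lagged source phase: exact lock at kappa=1, exact null at 0
                target = phases1[src_of[ch]] + cfg.phase_lag
                phase = indep + cfg.kappa * np.angle(np.exp(1j * (target - indep)))
            else:
                phase = indep
            env = env_pair[1] if ch in coupled_dst else _smooth_envelope(
                rng2.normal(size=n_s), cfg.sfreq
            )
            sig = amp * env * np.cos(phase)
            noise = rng2.normal(0.0, cfg.noise_sd * amp * np.sqrt(0.5), n_s)
            data[1][ep, ch] = sig + noise

    pos = circular_montage(cfg.n_channels)
    names = list(pos)
    out = []
    for pi in (0, 1):
        out.append(
            EpochArray(
                data=data[pi],
                sfreq=cfg.sfreq,
                ch_names=names,
                ch_pos=dict(pos),
                participant_id=f"sim{pi + 1}",
            )
        )
    return out[0], out[1]


def simulate_directed_dyad(
    cfg: DyadSimConfig,
    direction: tuple[int, int] = (0, 0),
    ar_coeff: float = 0.5,
) -> tuple[EpochArray, EpochArray]:
    """Simulate a dyad with a known directed (lagged linear) influence.

    Participant 2's target channel is ``ar_coeff`` times participant 1's
    source channel one sample earlier, plus white noise; all other channels
    are independent noise.  Ground truth: information flows source -> target
    only, so PDC and transfer entropy should be asymmetric in that
    direction.  ``ar_coeff = 0`` is an exact null.
    """
    if not abs(ar_coeff) < 1:
        raise ValueError(f"|ar_coeff| must be < 1, got {ar_coeff}")
    src, dst = direction
    if not (0 <= src < cfg.n_channels and 0 <= dst < cfg.n_channels):
        raise ValueError(f"direction ({src}, {dst}) references invalid channels")
    n_s = cfg.n_samples
    amp = 1e-5
    data = [
        np.empty((cfg.n_epochs, cfg.n_channels, n_s)),
        np.empty((cfg.n_epochs, cfg.n_channels, n_s)),
    ]
    for ep in range(cfg.n_epochs):
        rng1 = _rng(cfg.seed, 1, ep)
        rng2 = _rng(cfg.seed, 2, ep)
        x1 = rng1.normal(0.0, amp, (cfg.n_channels, n_s))
        x2 = rng2.normal(0.0, amp, (cfg.n_channels, n_s))
        x2[dst, 1:] += ar_coeff * x1[src, :-1]
        data[0][ep] = x1
        data[1][ep] = x2
    pos = circular_montage(cfg.n_channels)
    names = list(pos)
    return (
        EpochArray(data=data[0], sfreq=cfg.sfreq, ch_names=names, ch_pos=dict(pos), participant_id="sim1"),
        EpochArray(data=data[1], sfreq=cfg.sfreq, ch_names=names, ch_pos=dict(pos), participant_id="sim2"),
    )
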