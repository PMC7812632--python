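"""Welch power spectral density and analytic-signal band decomposition.

Connectivity metrics downstream are computed from the analytic signal
(Hilbert transform of a narrow-band-filtered signal) rather than from
cross-spectral densities: the analytic signal yields an *instantaneous*
phase and envelope and therefore does not assume stationarity, which suits
naturalistic hyperscanning data.  Each named frequency band is decomposed
into integer-Hz bins at a fixed 1 Hz spectral resolution: for a band
(fmin, fmax) the bins are every integer f with fmin <= f <= fmax, each
obtained by a zero-phase FIR band-pass 1 Hz wide centered on f followed by
an epoch-wise Hilbert transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .epochs_io import EpochArray

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz (0 < fmin < fmax)."""

    name: str
    fmin: float
    fmax: float

    def __post_init__(self) -> None:
        if not 0 < self.fmin < self.fmax:
            raise ValueError(f"need 0 < fmin < fmax, got ({self.fmin}, {self.fmax})")

    def integer_bins(self) -> np.ndarray:
        """Every integer frequency f with fmin <= f <= fmax."""
        lo = math.ceil(self.fmin)
        hi = math.floor(self.fmax)
        if hi < lo:
            raise ValueError(
                f"band {self.name} ({self.fmin}-{self.fmax} Hz) contains no integer frequency"
            )
        return np.arange(lo, hi + 1)


#: Conventional EEG band table; only configurable defaults, not a constraint.
DEFAULT_BANDS = [
    BandSpec("Theta", 4.0, 7.0),
    BandSpec("Alpha_Low", 7.5, 11.0),
    BandSpec("Alpha_High", 11.5, 13.0),
    BandSpec("Beta", 13.5, 29.5),
    BandSpec("Gamma", 30.0, 48.0),
]


@dataclass
class PsdResult:
    """Welch PSD values (V^2/Hz) with the exact frequency bins used."""

    psd: np.ndarray  # (channels, bins) or (epochs, channels, bins)
    freq_list: np.ndarray
    fmin: float
    fmax: float
    n_fft: int | None
    n_per_seg: int
    epochs_average: bool


@dataclass
class AnalyticSignal:
    """Complex analytic decomposition: (epochs, channels, freq-bins, samples).

    ``freqs`` are the integer-Hz bin centers (consecutive bins of one band
    differ by exactly 1 Hz); ``band_index`` maps band name -> slice into the
    bin axis.  Envelope is the modulus, phase the argument.
    """

    values: np.ndarray
    freqs: np.ndarray
    band_index: dict[str, slice]
    sfreq: float
    ch_names: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def envelope(self) -> np.ndarray:
        return np.abs(self.values)

    def phase(self) -> np.ndarray:
        return np.angle(self.values)


def min_segment_length(fmin: float, sfreq: float) -> int:
    """Minimum Welch segment length: four periods of the lowest frequency.

    To estimate power at ``fmin`` the segment must span at least four times
    its period, i.e. ``ceil(4 * sfreq / fmin)`` samples (4 Hz at 1000 Hz
    sampling -> 1000 samples, one second).
    """
    if fmin <= 0 or sfreq <= 0:
        raise ValueError(f"fmin and sfreq must be positive, got ({fmin}, {sfreq})")
    return math.ceil(4.0 * sfreq / fmin)


def welch_psd(
    e: EpochArray,
    fmin: float,
    fmax: float,
    n_per_seg: int,
    n_fft: int | None = None,
    epochs_average: bool = True,
) -> PsdResult:
    """Welch PSD of epoched data restricted to [fmin, fmax].

    Hann windows, 50% overlap, constant detrend per segment.  Frequency
    spacing is ``sfreq / (n_fft or n_per_seg)``; ``n_fft`` zero-pads the FFT
    and must be >= ``n_per_seg``.  With ``epochs_average`` the per-epoch
    Welch estimates are averaged, otherwise the epoch axis is preserved.
    """
    if n_per_seg > e.n_samples:
        raise ValueError(
            f"n_per_seg={n_per_seg} exceeds samples per epoch ({e.n_samples})"
        )
    if n_fft is not None and n_fft < n_per_seg:
        raise ValueError(
            f"n_fft={n_fft} < n_per_seg={n_per_seg}: n_fft has to be bigger or equal to n_per_seg"
        )
    min_len = min_segment_length(fmin, e.sfreq) if fmin > 0 else 0
    if n_per_seg < min_len:
        logger.warning(
            "n_per_seg=%d is below the four-period rule for fmin=%g Hz "
            "(recommended >= %d samples)",
            n_per_seg,
            fmin,
            min_len,
        )
    freqs, psd = signal.welch(
        e.data,
        fs=e.sfreq,
        window="hann",
        nperseg=n_per_seg,
        noverlap=n_per_seg // 2,
        nfft=n_fft,
        detrend="constant",
        axis=-1,
    )
    mask = (freqs >= fmin) & (freqs <= fmax)
    freqs = freqs[mask]
    psd = psd[..., mask]
    if epochs_average:
        psd = psd.mean(axis=0)
    return PsdResult(
        psd=psd,
        freq_list=freqs,
        fmin=fmin,
        fmax=fmax,
        n_fft=n_fft,
        n_per_seg=n_per_seg,
        epochs_average=epochs_average,
    )


def _fir_bandpass(center: float, sfreq: float, n_samples: int) -> np.ndarray:
    """Hamming-window FIR band-pass 1 Hz wide centered on ``center``.

    Target transition width 0.5 Hz; the tap count is capped near a third of
    the epoch length so zero-phase filtering with reflection padding stays
    well-posed on short epochs (the effective transition then widens).
    """
    transition = 0.5
    ideal = int(math.ceil(3.3 * sfreq / transition))
    numtaps = min(ideal, max(9, n_samples // 3))
    if numtaps % 2 == 0:
        numtaps -= 1
    lo = max(center - 0.5, 0.1)
    hi = min(center + 0.5, sfreq / 2 - 0.1)
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=sfreq)


def analytic_signal(
    e: EpochArray,
    bands: list[BandSpec] | None = None,
) -> AnalyticSignal:
    """Per-band integer-bin analytic signal of one participant's epochs."""
    bands = DEFAULT_BANDS if bands is None else bands
    nyq = e.sfreq / 2
    all_freqs: list[int] = []
    band_index: dict[str, slice] = {}
    for band in bands:
        bins = band.integer_bins()
        if bins[-1] >= nyq:
            raise ValueError(
                f"band {band.name} reaches {bins[-1]} Hz, at or above Nyquist ({nyq} Hz)"
            )
        band_index[band.name] = slice(len(all_freqs), len(all_freqs) + len(bins))
        all_freqs.extend(int(b) for b in bins)
    freqs = np.array(all_freqs)
    out = np.empty((e.n_epochs, e.n_channels, len(freqs), e.n_samples), dtype=complex)
    for k, f in enumerate(freqs):
        taps = _fir_bandpass(float(f), e.sfreq, e.n_samples)
        padlen = min(e.n_samples - 1, 3 * len(taps))
        filtered = signal.filtfilt(taps, [1.0], e.data, axis=-1, padlen=padlen)
        out[:, :, k, :] = signal.hilbert(filtered, axis=-1)
    return AnalyticSignal(
        values=out,
        freqs=freqs,
        band_index=band_index,
        sfreq=e.sfreq,
        ch_names=list(e.ch_names),
    )


def compute_freq_bands(
    pair: tuple[EpochArray, EpochArray],
    bands: list[BandSpec] | None = None,
) -> tuple[AnalyticSignal, AnalyticSignal]:
    """Analytic-signal decomposition of both participants on shared bins.

    Both containers must share sampling rate, epoch count and samples per
    epoch; the returned decompositions share ``freqs`` exactly, enabling
    element-wise metric computation across the dyad.
    """
    e1, e2 = pair
    if e1.sfreq != e2.sfreq:
        raise ValueError(f"sampling rates differ: {e1.sfreq} vs {e2.sfreq}")
    if e1.n_epochs != e2.n_epochs or e1.n_samples != e2.n_samples:
        raise ValueError(
            "participants must share epoch count and samples per epoch: "
            f"({e1.n_epochs},{e1.n_samples}) vs ({e2.n_epochs},{e2.n_samples})"
        )
    a1 = analytic_signal(e1, bands)
    a2 = analytic_signal(e2, bands)
    assert np.array_equal(a1.freqs, a2.freqs)
    return a1, a2
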