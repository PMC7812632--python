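"""Artifact marking and the cross-participant intersection rule.

In a hyperscanning analysis the two participants' recordings must stay
aligned epoch-for-epoch, so rejection is matched across participants: only
channels and epochs that are good for *every* participant are preserved.
Epoch rejection here uses a single global peak-to-peak amplitude threshold
(default 150 microvolts) — a deliberately simple, fully documented rule;
the scientific content of this module is the matching, not the detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .epochs_io import EpochArray

DEFAULT_PTP_THRESHOLD = 150e-6  # volts


class EmptyDataError(ValueError):
    """Every epoch (or channel) was rejected; downstream stages need data."""


@dataclass
class RejectionReport:
    """Record of what was rejected, per participant and in common.

    ``kept_epochs`` is the intersection of per-participant kept epochs;
    ``dropped_channels`` is the union (de-suffixed) of per-participant bad
    channels, removed from every participant.
    """

    bad_epochs: list[set[int]] = field(default_factory=list)
    bad_channels: list[set[str]] = field(default_factory=list)
    kept_epochs: list[int] = field(default_factory=list)
    dropped_channels: set[str] = field(default_factory=set)
    threshold: float = DEFAULT_PTP_THRESHOLD

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "bad_epochs": [sorted(s) for s in self.bad_epochs],
            "bad_channels": [sorted(s) for s in self.bad_channels],
            "kept_epochs": list(self.kept_epochs),
            "dropped_channels": sorted(self.dropped_channels),
            "threshold_volts": self.threshold,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def mark_bad_epochs_ptp(e: EpochArray, threshold: float = DEFAULT_PTP_THRESHOLD) -> set[int]:
    """Indices of epochs whose peak-to-peak amplitude exceeds ``threshold``.

    An epoch is flagged when *any* channel not already marked bad has
    ``max - min > threshold`` (volts) within the epoch.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    good_idx = [i for i, ch in enumerate(e.ch_names) if ch not in e.bads]
    if not good_idx:
        return set()
    d = e.data[:, good_idx]
    ptp = d.max(axis=2) - d.min(axis=2)  # (epochs, channels)
    return set(np.nonzero((ptp > threshold).any(axis=1))[0].tolist())


def intersect_good(
    es: list[EpochArray],
    bad_epochs: list[set[int]] | None = None,
    bad_channels: list[set[str]] | None = None,
    ptp_threshold: float = DEFAULT_PTP_THRESHOLD,
) -> tuple[list[EpochArray], RejectionReport]:
    """Keep only epochs and channels good for every participant.

    Parameters
    ----------
    es : list of EpochArray
        Participants' containers with equal epoch counts.
    bad_epochs, bad_channels : optional per-participant rejections
        When omitted, bad epochs come from :func:`mark_bad_epochs_ptp` at
        ``ptp_threshold`` and bad channels from each container's ``bads``.

    Returns
    -------
    (containers, report)
        Every returned container has the same kept-epoch index list and the
        same dropped channels (channel labels compared de-suffixed when
        participants use suffixed montages is the caller's concern; labels
        are compared literally here, matching same-montage recordings).
    """
    if not es:
        raise ValueError("need at least one participant")
    counts = {e.n_epochs for e in es}
    if len(counts) != 1:
        raise ValueError(f"unequal epoch counts before rejection: {sorted(counts)}")
    n_epochs = counts.pop()
    if bad_epochs is None:
        bad_epochs = [mark_bad_epochs_ptp(e, ptp_threshold) for e in es]
    if bad_channels is None:
        bad_channels = [set(e.bads) for e in es]
    if len(bad_epochs) != len(es) or len(bad_channels) != len(es):
        raise ValueError("per-participant rejection lists must match participant count")

    all_bad_epochs: set[int] = set().union(*bad_epochs)
    kept = [i for i in range(n_epochs) if i not in all_bad_epochs]
    if not kept:
        raise EmptyDataError("all epochs rejected across participants")
    dropped: set[str] = set().union(*bad_channels)
    out = []
    for e in es:
        if dropped >= set(e.ch_names):
            raise EmptyDataError("all channels rejected across participants")
        out.append(e.select(epochs=kept, drop_channels=dropped))
    report = RejectionReport(
        bad_epochs=[set(b) for b in bad_epochs],
        bad_channels=[set(b) for b in bad_channels],
        kept_epochs=kept,
        dropped_channels=dropped,
        threshold=ptp_threshold,
    )
    return out, report


def highpass(
    data: np.ndarray, sfreq: float, cutoff: float = 1.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth high-pass along the last axis (drift removal)."""
    sos = signal.butter(order, cutoff, btype="highpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)
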