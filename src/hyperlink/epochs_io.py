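"""Epoch containers, readers/writers, and two-participant merge/split.

The unit of analysis is the *epoch*: a fixed-length segment of a continuous
recording.  :class:`EpochArray` holds one participant's epoched signal as an
``(epochs, channels, samples)`` array in volts, together with the sampling
rate, channel labels, 3-D sensor positions (head-centered RAS, meters) and
bad-channel metadata.  :func:`merge` concatenates two participants' channels
into a single "hyper-epoch" container whose labels carry ``"_1"``/``"_2"``
suffixes; :func:`split` is its exact inverse.

Supported on-disk formats: FIF epoch files and EDF (through MNE), and a
plain columnar text dialect used for small fixtures and demos.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_SUFFIXES = ("_1", "_2")


class FormatError(ValueError):
    """A file does not parse in the named format."""


class IncompatibleEpochsError(ValueError):
    """Two containers cannot be merged or split as requested."""


@dataclass
class EpochArray:
    """One participant's epoched multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Signal in volts.
    sfreq : float
        Sampling rate in Hz; must be positive.
    ch_names : list of str
        Ordered, unique channel labels; length must match ``data.shape[1]``.
    ch_pos : dict or None
        Mapping channel label -> 3-vector position (head-centered RAS,
        meters).  ``None`` marks the container position-free; visualization
        and spatial adjacency refuse position-free containers.
    bads : set of str
        Labels of channels marked bad; must be a subset of ``ch_names``.
    drop_log : list of bool
        Per-original-epoch kept flag (True = kept).  Defaults to all-kept.
    participant_id : str
        Free-form participant label.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    ch_pos: dict[str, np.ndarray] | None = None
    bads: set[str] = field(default_factory=set)
    drop_log: list[bool] = field(default_factory=list)
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (epochs, channels, samples); got ndim={self.data.ndim}"
            )
        if self.sfreq <= 0:
            raise ValueError(f"sfreq must be positive, got {self.sfreq}")
        self.ch_names = list(self.ch_names)
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for data with "
                f"{self.data.shape[1]} channels"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        self.bads = set(self.bads)
        if not self.bads <= set(self.ch_names):
            raise ValueError(f"bads not a subset of ch_names: {self.bads - set(self.ch_names)}")
        if self.ch_pos is not None:
            self.ch_pos = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.ch_pos.items()}
            missing = set(self.ch_names) - set(self.ch_pos)
            if missing:
                raise ValueError(f"channels without positions: {sorted(missing)}")
        if not self.drop_log:
            self.drop_log = [True] * self.data.shape[0]

    # -- convenience -----------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def has_positions(self) -> bool:
        return self.ch_pos is not None

    def positions_array(self) -> np.ndarray:
        """Positions stacked in channel order, shape (n_channels, 3)."""
        if self.ch_pos is None:
            raise ValueError("container is position-free")
        return np.stack([self.ch_pos[ch] for ch in self.ch_names])

    def copy(self) -> "EpochArray":
        return replace(
            self,
            data=self.data.copy(),
            ch_names=list(self.ch_names),
            ch_pos=None if self.ch_pos is None else {k: v.copy() for k, v in self.ch_pos.items()},
            bads=set(self.bads),
            drop_log=list(self.drop_log),
        )

    def select(self, epochs: list[int] | None = None, drop_channels: set[str] | None = None) -> "EpochArray":
        """Return a copy restricted to the given epochs, without the given channels."""
        out = self.copy()
        if epochs is not None:
            epochs = sorted(epochs)
            out.data = out.data[epochs]
            kept = set(epochs)
            # drop_log tracks original epoch indices of this container
            orig = [i for i, k in enumerate(out.drop_log) if k]
            dlog = list(out.drop_log)
            for j, oi in enumerate(orig):
                if j not in kept:
                    dlog[oi] = False
            out.drop_log = dlog
        if drop_channels:
            keep_idx = [i for i, ch in enumerate(out.ch_names) if ch not in drop_channels]
            out.data = out.data[:, keep_idx]
            out.ch_names = [out.ch_names[i] for i in keep_idx]
            out.bads = out.bads - drop_channels
            if out.ch_pos is not None:
                out.ch_pos = {ch: out.ch_pos[ch] for ch in out.ch_names}
        return out


@dataclass
class HyperEpochArray(EpochArray):
    """Merged two-participant container; channel labels carry participant suffixes."""

    source_ids: tuple[str, str] = ("", "")
    suffixes: tuple[str, str] = DEFAULT_SUFFIXES

    def __post_init__(self) -> None:
        super().__post_init__()
        n = len(self.ch_names)
        if n % 2:
            raise IncompatibleEpochsError(f"hyper-epoch channel count must be even, got {n}")
        half = n // 2
        s1, s2 = self.suffixes
        first, second = self.ch_names[:half], self.ch_names[half:]
        if not all(c.endswith(s1) for c in first) or not all(c.endswith(s2) for c in second):
            raise IncompatibleEpochsError(
                f"expected first {half} labels suffixed {s1!r} and last {half} suffixed {s2!r}"
            )
        base1 = [c[: -len(s1)] for c in first]
        base2 = [c[: -len(s2)] for c in second]
        if base1 != base2:
            raise IncompatibleEpochsError(
                "de-suffixed channel sequences of the two halves differ"
            )


def merge(
    e1: EpochArray,
    e2: EpochArray,
    suffixes: tuple[str, str] = DEFAULT_SUFFIXES,
) -> HyperEpochArray:
    """Merge two participants' epochs into one hyper-epoch container.

    Channels are concatenated as ``[e1 channels + suffixes[0],
    e2 channels + suffixes[1]]``; epochs are aligned strictly index-wise.
    Bad-channel labels are carried over with their participant's suffix.
    """
    if e1.sfreq != e2.sfreq:
        raise IncompatibleEpochsError(f"sampling rates differ: {e1.sfreq} vs {e2.sfreq}")
    if e1.n_samples != e2.n_samples:
        raise IncompatibleEpochsError(
            f"samples per epoch differ: {e1.n_samples} vs {e2.n_samples}"
        )
    if e1.n_epochs != e2.n_epochs:
        raise IncompatibleEpochsError(
            f"epoch counts differ: {e1.n_epochs} vs {e2.n_epochs}; "
            "align epochs before merging"
        )
    if e1.ch_names != e2.ch_names:
        logger.warning("merging containers with different channel sets/orders")
    s1, s2 = suffixes
    names = [c + s1 for c in e1.ch_names] + [c + s2 for c in e2.ch_names]
    pos = None
    if e1.ch_pos is not None and e2.ch_pos is not None:
        pos = {c + s1: e1.ch_pos[c] for c in e1.ch_names}
        pos.update({c + s2: e2.ch_pos[c] for c in e2.ch_names})
    return HyperEpochArray(
        data=np.concatenate([e1.data, e2.data], axis=1),
        sfreq=e1.sfreq,
        ch_names=names,
        ch_pos=pos,
        bads={c + s1 for c in e1.bads} | {c + s2 for c in e2.bads},
        participant_id=f"{e1.participant_id}+{e2.participant_id}",
        source_ids=(e1.participant_id, e2.participant_id),
        suffixes=suffixes,
    )


def split(h: HyperEpochArray) -> tuple[EpochArray, EpochArray]:
    """Split a hyper-epoch container back into the two participants.

    Exact inverse of :func:`merge`: suffixes are stripped (trailing match
    only) and ``split(merge(a, b))`` reproduces ``(a, b)`` data bit-exactly.
    """
    half = h.n_channels // 2
    s1, s2 = h.suffixes
    out = []
    for idx, (sl, suf, pid) in enumerate(
        [(slice(0, half), s1, h.source_ids[0]), (slice(half, None), s2, h.source_ids[1])]
    ):
        names = [c[: -len(suf)] for c in h.ch_names[sl]]
        pos = None
        if h.ch_pos is not None:
            pos = {c[: -len(suf)]: h.ch_pos[c] for c in h.ch_names[sl]}
        bads = {c[: -len(suf)] for c in h.bads if c in h.ch_names[sl]}
        out.append(
            EpochArray(
                data=h.data[:, sl].copy(),
                sfreq=h.sfreq,
                ch_names=names,
                ch_pos=pos,
                bads=bads,
                participant_id=pid,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Columnar text dialect
#
# Header lines:  # sfreq=<Hz>
#                # participant=<id>
#                # unit=V
#                # ch=<name>:<x>,<y>,<z>     (or "# ch=<name>" when position-free)
#                # bads=<comma list>
# Data lines: <epoch index> TAB <value per channel ...>, one line per
# (epoch, sample).  Values are float32 printed with %.9g, which round-trips
# float32 bit-exactly.
# ---------------------------------------------------------------------------


def _write_columnar(e: EpochArray, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sfreq={float(e.sfreq)!r}\n")
        if e.participant_id:
            fh.write(f"# participant={e.participant_id}\n")
        fh.write("# unit=V\n")
        for ch in e.ch_names:
            if e.ch_pos is None:
                fh.write(f"# ch={ch}\n")
            else:
                x, y, z = (float(v) for v in e.ch_pos[ch])
                fh.write(f"# ch={ch}:{x!r},{y!r},{z!r}\n")
        if e.bads:
            fh.write("# bads=" + ",".join(sorted(e.bads)) + "\n")
        data32 = e.data.astype(np.float32)
        for ep in range(e.n_epochs):
            for s in range(e.n_samples):
                vals = "\t".join("%.9g" % v for v in data32[ep, :, s])
                fh.write(f"{ep}\t{vals}\n")


def _read_columnar(path: Path) -> EpochArray:
    sfreq = None
    participant = ""
    ch_names: list[str] = []
    ch_pos: dict[str, np.ndarray] = {}
    position_free = False
    bads: set[str] = set()
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sfreq="):
                    sfreq = float(body[6:])
                elif body.startswith("participant="):
                    participant = body[12:]
                elif body.startswith("ch="):
                    spec = body[3:]
                    if ":" in spec:
                        name, coords = spec.split(":", 1)
                        ch_names.append(name)
                        ch_pos[name] = np.array([float(c) for c in coords.split(",")])
                    else:
                        ch_names.append(spec)
                        position_free = True
                elif body.startswith("bads="):
                    bads = {b for b in body[5:].split(",") if b}
                continue
            parts = line.split("\t")
            rows.append((int(parts[0]), parts[1:]))
    if sfreq is None or not ch_names:
        raise FormatError(f"{path}: missing sfreq or channel headers")
    n_ch = len(ch_names)
    epochs = sorted({r[0] for r in rows})
    if epochs != list(range(len(epochs))):
        raise FormatError(f"{path}: epoch indices not contiguous from 0")
    per_epoch: dict[int, list[list[str]]] = {ep: [] for ep in epochs}
    for ep, vals in rows:
        if len(vals) != n_ch:
            raise FormatError(
                f"{path}: row with {len(vals)} values for {n_ch} channels"
            )
        per_epoch[ep].append(vals)
    lens = {len(v) for v in per_epoch.values()}
    if len(lens) != 1:
        raise FormatError(f"{path}: inconsistent samples per epoch: {sorted(lens)}")
    data = np.array(
        [np.array(per_epoch[ep], dtype=np.float32).T for ep in epochs], dtype=np.float32
    )
    return EpochArray(
        data=data.astype(float),
        sfreq=sfreq,
        ch_names=ch_names,
        ch_pos=None if position_free else ch_pos,
        bads=bads,
        participant_id=participant,
    )


# ---------------------------------------------------------------------------
# FIF via MNE
# ---------------------------------------------------------------------------


def _to_mne(e: EpochArray):
    import mne

    info = mne.create_info(e.ch_names, e.sfreq, ch_types="eeg")
    epochs = mne.EpochsArray(e.data, info, verbose="error")
    if e.ch_pos is not None:
        montage = mne.channels.make_dig_montage(
            ch_pos={ch: e.ch_pos[ch] for ch in e.ch_names}, coord_frame="head"
        )
        epochs.set_montage(montage, verbose="error")
    epochs.info["bads"] = sorted(e.bads)
    epochs.info["subject_info"] = {"his_id": e.participant_id or "unknown"}
    return epochs


def from_mne(epochs) -> EpochArray:
    """Build an :class:`EpochArray` from an ``mne.Epochs``-like object."""
    montage = epochs.get_montage()
    ch_pos = None
    if montage is not None:
        pos = montage.get_positions()["ch_pos"]
        if pos and all(ch in pos and np.isfinite(pos[ch]).all() for ch in epochs.ch_names):
            ch_pos = {ch: np.asarray(pos[ch]) for ch in epochs.ch_names}
    sub = epochs.info.get("subject_info") or {}
    return EpochArray(
        data=epochs.get_data(copy=True),
        sfreq=float(epochs.info["sfreq"]),
        ch_names=list(epochs.ch_names),
        ch_pos=ch_pos,
        bads=set(epochs.info["bads"]),
        participant_id=sub.get("his_id", "") if sub.get("his_id") != "unknown" else "",
    )


# ---------------------------------------------------------------------------
# Minimal EDF writer + MNE-backed reader
#
# One EDF data record per epoch; signals stored as int16 with per-channel
# physical min/max spanning the data range.  EDF cannot represent epoch
# boundaries natively, so the record duration encodes the epoch length.
# ---------------------------------------------------------------------------


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _edf_number(v: float) -> str:
    """Densest decimal for an 8-char EDF physical min/max field."""
    for prec in range(7, -1, -1):
        s = f"{v:.{prec}f}"
        if len(s) <= 8:
            return s
    return f"{v:.1g}"[:8]


def _write_edf(e: EpochArray, path: Path) -> None:
    n_sig = e.n_channels
    n_rec = e.n_epochs
    spr = e.n_samples
    rec_dur = spr / e.sfreq
    # physical scaling per channel (microvolts to keep numbers readable)
    data_uv = e.data * 1e6
    pmin = data_uv.min(axis=(0, 2))
    pmax = data_uv.max(axis=(0, 2))
    span = pmax - pmin
    pmax = np.where(span <= 0, pmin + 1.0, pmax)
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(e.participant_id or "X", 80))
        fh.write(_edf_field("Startdate 01-JAN-2000", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(256 + 256 * n_sig), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_rec), 8))
        fh.write(_edf_field(("%.6f" % rec_dur).rstrip("0").rstrip("."), 8))
        fh.write(_edf_field(str(n_sig), 4))
        for ch in e.ch_names:
            fh.write(_edf_field(ch, 16))
        for _ in range(n_sig):
            fh.write(_edf_field("", 80))  # transducer
        for _ in range(n_sig):
            fh.write(_edf_field("uV", 8))
        for v in pmin:
            fh.write(_edf_field(_edf_number(v), 8))
        for v in pmax:
            fh.write(_edf_field(_edf_number(v), 8))
        for _ in range(n_sig):
            fh.write(_edf_field("-32768", 8))
        for _ in range(n_sig):
            fh.write(_edf_field("32767", 8))
        for _ in range(n_sig):
            fh.write(_edf_field("", 80))  # prefiltering
        for _ in range(n_sig):
            fh.write(_edf_field(str(spr), 8))
        for _ in range(n_sig):
            fh.write(_edf_field("", 32))  # reserved
        dmin, dmax = -32768.0, 32767.0
        for rec in range(n_rec):
            for ci in range(n_sig):
                phys = data_uv[rec, ci]
                dig = (phys - pmin[ci]) / (pmax[ci] - pmin[ci]) * (dmax - dmin) + dmin
                fh.write(np.round(dig).astype("<i2").tobytes())


def _edf_record_info(path: Path) -> tuple[int, float]:
    """Read (n_records, record_duration_s) from an EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
    if len(header) < 256:
        raise FormatError(f"{path}: truncated EDF header")
    n_rec = int(header[236:244].decode("ascii").strip())
    rec_dur = float(header[244:252].decode("ascii").strip())
    return n_rec, rec_dur


def _read_edf(path: Path) -> EpochArray:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    n_rec, rec_dur = _edf_record_info(path)
    sfreq = float(raw.info["sfreq"])
    spr = int(round(rec_dur * sfreq))
    data = raw.get_data()
    total = data.shape[1]
    if spr * n_rec != total:
        raise FormatError(
            f"{path}: {total} samples do not tile into {n_rec} records of {spr}"
        )
    data = data.reshape(data.shape[0], n_rec, spr).transpose(1, 0, 2)
    return EpochArray(
        data=data,
        sfreq=sfreq,
        ch_names=list(raw.ch_names),
        ch_pos=None,
        bads=set(raw.info["bads"]),
    )


# ---------------------------------------------------------------------------
# Public readers/writers
# ---------------------------------------------------------------------------

_FORMATS = ("fif", "edf", "columnar")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".fif":
        return "fif"
    if suffix == ".edf":
        return "edf"
    return "columnar"


def read_epochs(path: str | Path, format: str | None = None) -> EpochArray:
    """Read an epoch container from ``path`` in the named (or inferred) format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "columnar":
        return _read_columnar(path)
    if fmt == "edf":
        return _read_edf(path)
    import mne

    return from_mne(mne.read_epochs(path, preload=True, verbose="error"))


def write_epochs(e: EpochArray, path: str | Path, format: str | None = None) -> Path:
    """Write ``e`` to ``path``; returns the path written."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "columnar":
        _write_columnar(e, path)
    elif fmt == "edf":
        _write_edf(e, path)
    else:
        _to_mne(e).save(path, overwrite=True, verbose="error")
    return path
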