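"""Connectivity metrics and the joint two-participant connectivity matrix.

Ten metrics are computed channel-pair-wise from the analytic signal of the
two participants stacked into 2N channels, yielding per frequency band a
(2N x 2N) matrix that tiles into four N x N blocks: intra-brain for each
participant on the diagonal blocks, inter-brain A->B and B->A off the
diagonal.  Non-directional metrics give an exactly symmetric matrix (the
two inter-brain blocks are transposes of each other); the causality
measures — partial directed coherence and transfer entropy — do not.

Phase metrics (plv, pli, ccorr) are computed over time within each epoch
and then averaged across epochs; the coherence family averages its
expectations over both samples and epochs.  The per-band value is the
unweighted mean of per-integer-bin values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .spectral import AnalyticSignal

logger = logging.getLogger(__name__)

EPS = 1e-12

NONDIRECTIONAL_MODES = (
    "coh",
    "imaginary_coh",
    "plv",
    "pli",
    "ccorr",
    "envelope_corr",
    "pow_corr",
    "proj_pow_corr",
)
DIRECTIONAL_MODES = ("pdc", "transfer_entropy")
ALL_MODES = NONDIRECTIONAL_MODES + DIRECTIONAL_MODES


class DegenerateInputError(ValueError):
    """Input is too short or has zero variance for the requested metric."""


# ---------------------------------------------------------------------------
# Scalar kernels (single channel pair, one epoch)
# ---------------------------------------------------------------------------


def plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase-locking value: modulus of the mean unit phasor of the phase
    difference.  1 for a perfectly constant phase relation (any offset),
    ~1/sqrt(n) for independent phases."""
    phase_x, phase_y = _check_pair(phase_x, phase_y, min_len=2)
    return float(np.abs(np.mean(np.exp(1j * (phase_x - phase_y)))))


def pli(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase lag index: modulus of the mean sign of sin(phase difference).

    Insensitive to zero-lag coupling (sign(0) contributes 0); 1 when the
    phase difference keeps a constant sign.
    """
    phase_x, phase_y = _check_pair(phase_x, phase_y, min_len=2)
    return float(np.abs(np.mean(np.sign(np.sin(phase_x - phase_y)))))


def ccorr(
    phase_x: np.ndarray, phase_y: np.ndarray, angle_pearson: bool = False
) -> float:
    """Circular correlation coefficient of two phase series.

    Uses the circular-statistics sine-deviation form
    ``sum sin(x - mx) sin(y - my) / sqrt(sum sin^2(x - mx) sum sin^2(y - my))``
    with circular means mx, my.  ``angle_pearson=True`` switches to a
    literal Pearson correlation of the wrapped angle values (a
    compatibility mode; discontinuous at +-pi).
    """
    phase_x, phase_y = _check_pair(phase_x, phase_y, min_len=3)
    if angle_pearson:
        if np.std(phase_x) < EPS or np.std(phase_y) < EPS:
            raise DegenerateInputError("zero angular variance")
        return float(np.corrcoef(phase_x, phase_y)[0, 1])
    sx = np.sin(phase_x - _circ_mean(phase_x))
    sy = np.sin(phase_y - _circ_mean(phase_y))
    den = np.sqrt(np.sum(sx**2) * np.sum(sy**2))
    if den < EPS:
        raise DegenerateInputError("zero angular dispersion in an input")
    return float(np.sum(sx * sy) / den)


def coherence(x: np.ndarray, y: np.ndarray) -> float:
    """Magnitude-squared coherence of two complex analytic series.

    ``|<x conj(y)>|^2 / (<|x|^2><|y|^2>)`` with the expectation over all
    supplied elements (samples, and epochs when a 2-D stack is given).
    A single complex value has no averaging support and is refused, since
    its coherence is identically 1.
    """
    x, y = _check_pair(x, y, min_len=2, dtype=complex)
    sxy = np.mean(x * np.conj(y))
    sxx = np.mean(np.abs(x) ** 2)
    syy = np.mean(np.abs(y) ** 2)
    den = sxx * syy
    if den <= 0:
        raise DegenerateInputError("zero autospectral power")
    return float(np.abs(sxy) ** 2 / den)


def imaginary_coherence(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute imaginary part of the coherency; discards zero-lag dependence."""
    x, y = _check_pair(x, y, min_len=2, dtype=complex)
    sxy = np.mean(x * np.conj(y))
    sxx = np.mean(np.abs(x) ** 2)
    syy = np.mean(np.abs(y) ** 2)
    den = np.sqrt(sxx * syy)
    if den <= 0:
        raise DegenerateInputError("zero autospectral power")
    return float(np.abs(np.imag(sxy / den)))


def envelope_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of the envelopes |x| and |y| over time."""
    return _amp_corr(x, y, power=False)


def pow_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of the powers |x|^2 and |y|^2 over time."""
    return _amp_corr(x, y, power=True)


def proj_pow_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Projected (orthogonalized) power correlation.

    Removes the component of y parallel to x in the complex plane per
    sample (``y_orth = Im(y conj(x) / |x|)``), correlates ``|x|`` with
    ``|y_orth|``, and symmetrizes by averaging both orthogonalization
    directions.  When y is proportional to x the orthogonalized signal
    vanishes and the correlation is reported as 0 (degenerate case).
    """
    x, y = _check_pair(x, y, min_len=3, dtype=complex)
    return float(0.5 * (_ppc_oneside(x, y) + _ppc_oneside(y, x)))


def transfer_entropy(x: np.ndarray, y: np.ndarray, k: int = 1) -> float:
    """Gaussian-estimator transfer entropy TE(x -> y) in nats.

    ``0.5 * ln( Var(y_t | y_past) / Var(y_t | y_past, x_past) )`` with k
    lags of past; equals half the linear Granger-causality log statistic,
    the Gaussian-process equivalence of GC and TE.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if k < 1:
        raise ValueError(f"lag k must be >= 1, got {k}")
    if x.shape[-1] <= 10 * k:
        raise DegenerateInputError(f"series length must exceed 10*k = {10 * k}")
    tgt, own, src = [], [], []
    for xe, ye in zip(x, y):
        n = len(ye)
        tgt.append(ye[k:])
        own.append(np.column_stack([ye[k - m - 1 : n - m - 1] for m in range(k)]))
        src.append(np.column_stack([xe[k - m - 1 : n - m - 1] for m in range(k)]))
    t = np.concatenate(tgt)
    own_m = np.vstack(own)
    src_m = np.vstack(src)
    v_red = _resid_var(own_m, t)
    v_full = _resid_var(np.hstack([own_m, src_m]), t)
    floor = 1e-12 * max(np.var(t), EPS)
    if v_full < floor or v_red < floor:
        raise DegenerateInputError("singular conditioning covariance")
    return float(max(0.0, 0.5 * np.log(v_red / v_full)))


# ---------------------------------------------------------------------------
# MVAR / partial directed coherence
# ---------------------------------------------------------------------------


@dataclass
class MvarModel:
    """Multivariate autoregression of order p over C channels.

    ``coeffs`` has shape (p, C, C) with ``coeffs[m][i, j]`` the influence of
    channel j at lag m+1 on channel i; ``resid_cov`` is the residual
    covariance; ``stable`` flags a companion-matrix spectral radius < 1.
    """

    coeffs: np.ndarray
    resid_cov: np.ndarray
    order: int
    stable: bool


def fit_mvar(data: np.ndarray, order: int = 5) -> MvarModel:
    """Least-squares MVAR fit; per-epoch coefficients averaged across epochs.

    ``data`` is (channels, samples) or (epochs, channels, samples); each
    epoch must provide more samples than ``order * channels`` for
    identifiability.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    n_ch, n_samp = data.shape[1], data.shape[2]
    if n_samp <= order * n_ch:
        raise DegenerateInputError(
            f"samples per epoch ({n_samp}) must exceed order*channels ({order * n_ch})"
        )
    coeffs = np.zeros((order, n_ch, n_ch))
    resid_cov = np.zeros((n_ch, n_ch))
    for ep in data:
        Z = np.hstack([ep[:, order - m - 1 : n_samp - m - 1].T for m in range(order)])
        Y = ep[:, order:].T
        B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
        if rank < Z.shape[1]:
            raise DegenerateInputError(
                f"rank-deficient MVAR design (rank {rank} < {Z.shape[1]}); try a lower order"
            )
        resid = Y - Z @ B
        resid_cov += resid.T @ resid / max(len(Y) - Z.shape[1], 1)
        coeffs += B.T.reshape(n_ch, order, n_ch).transpose(1, 0, 2)
    coeffs /= len(data)
    resid_cov /= len(data)
    return MvarModel(coeffs, resid_cov, order, stable=_mvar_stable(coeffs))


def _mvar_stable(coeffs: np.ndarray) -> bool:
    p, c, _ = coeffs.shape
    companion = np.zeros((p * c, p * c))
    companion[:c] = coeffs.transpose(1, 0, 2).reshape(c, p * c)
    if p > 1:
        companion[c:, : (p - 1) * c] = np.eye((p - 1) * c)
    return bool(np.max(np.abs(np.linalg.eigvals(companion))) < 1.0)


def pdc(model: MvarModel, freqs: np.ndarray, sfreq: float) -> np.ndarray:
    """Classic (Baccala-Sameshima) partial directed coherence.

    Returns (n_freqs, C, C) with entry ``[f, i, j]`` the directed influence
    of channel j on channel i at frequency f:
    ``|Abar_ij(f)| / sqrt(sum_k |Abar_kj(f)|^2)`` with
    ``Abar(f) = I - sum_m A_m exp(-i 2 pi f (m+1) / sfreq)``.  Squared
    entries of each column sum to 1 at every frequency by construction.
    """
    if not model.stable:
        logger.warning("PDC computed from an unstable MVAR model")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    p, c, _ = model.coeffs.shape
    out = np.empty((len(freqs), c, c))
    for fi, f in enumerate(freqs):
        phase = np.exp(-2j * np.pi * f * (np.arange(1, p + 1)) / sfreq)
        a_bar = np.eye(c, dtype=complex) - np.tensordot(phase, model.coeffs, axes=(0, 0))
        mag = np.abs(a_bar)
        out[fi] = mag / np.maximum(np.sqrt((mag**2).sum(axis=0, keepdims=True)), EPS)
    return out


# ---------------------------------------------------------------------------
# Joint connectivity matrix
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """Per-band (2N x 2N) connectivity values for a dyad.

    ``values`` is (bands, 2N, 2N), or (epochs, bands, 2N, 2N) when
    per-epoch values are preserved.  Rows/columns 0..N-1 are participant 1,
    N..2N-1 participant 2; entry [i, j] of a directional metric is the
    influence of channel i on channel j.
    """

    values: np.ndarray
    metric: str
    directional: bool
    n_ch: int
    band_names: list[str]
    ch_names: list[str] | None = None

    @property
    def per_epoch(self) -> bool:
        return self.values.ndim == 4

    def band(self, name: str) -> np.ndarray:
        idx = self.band_names.index(name)
        return self.values[..., idx, :, :]


@dataclass
class BlockView:
    """The four N x N tiles of a joint matrix."""

    intra_1: np.ndarray
    intra_2: np.ndarray
    inter_12: np.ndarray
    inter_21: np.ndarray


def slice_blocks(values: np.ndarray | ConnectivityMatrix) -> BlockView:
    """Tile a (..., 2N, 2N) matrix into intra/inter blocks.

    ``intra_1 = C[:N,:N]``, ``intra_2 = C[N:,N:]``, ``inter_12 = C[:N,N:]``,
    ``inter_21 = C[N:,:N]``.  For non-directional metrics ``inter_12`` equals
    ``inter_21`` transposed; for causality measures it does not.
    """
    if isinstance(values, ConnectivityMatrix):
        values = values.values
    n = values.shape[-1] // 2
    return BlockView(
        intra_1=values[..., :n, :n],
        intra_2=values[..., n:, n:],
        inter_12=values[..., :n, n:],
        inter_21=values[..., n:, :n],
    )


def standardize(block: np.ndarray) -> np.ndarray:
    """Zero the diagonal, then grand z-score the whole block.

    ``C = (V - mean(V)) / std(V)`` after ``V -= diag(diag(V))``, with mean
    and std taken over every cell including the zeroed diagonal.  The
    output has grand mean 0 and grand std 1 by construction.  Exactly
    invariant to positive rescaling of the input; an additive offset is
    *not* removed exactly because it interacts with the zeroed diagonal.
    """
    block = np.asarray(block, dtype=float)
    v = block - np.diag(np.diag(block))
    off = v[~np.eye(len(v), dtype=bool)]
    if off.std() < EPS * max(1.0, np.abs(off).max()):
        raise DegenerateInputError(
            "off-diagonal values are constant; standardization is undefined"
        )
    s = v.std()
    if s < EPS:
        raise DegenerateInputError("zero variance after diagonal zeroing")
    return (v - v.mean()) / s


def compute_sync(
    a: tuple[AnalyticSignal, AnalyticSignal],
    mode: str,
    epochs_average: bool = True,
    mvar_order: int = 5,
    te_lag: int = 1,
) -> ConnectivityMatrix:
    """Joint (2N x 2N) connectivity matrix per band from analytic signals.

    Dispatches to the per-metric kernel channel-pair-wise on the stacked
    2N channels; the per-band value is the unweighted mean over the band's
    integer bins.  ``epochs_average`` controls whether the epoch axis is
    averaged out (the coherence family always pools epochs into its
    expectation when averaging; per-epoch values use within-epoch samples
    as the averaging support).
    """
    if mode not in ALL_MODES:
        raise ValueError(f"mode must be one of {ALL_MODES}, got {mode!r}")
    a1, a2 = a
    if a1.values.shape != a2.values.shape or not np.array_equal(a1.freqs, a2.freqs):
        raise ValueError("the two analytic signals must share shape and freqs")
    X = np.concatenate([a1.values, a2.values], axis=1)  # (E, 2N, B, S)
    n_e, n2, _, _ = X.shape
    band_names = list(a1.band_index)
    directional = mode in DIRECTIONAL_MODES
    ch_names = None
    if a1.ch_names and a2.ch_names:
        ch_names = [c + "_1" for c in a1.ch_names] + [c + "_2" for c in a2.ch_names]

    if mode in ("pdc", "transfer_entropy"):
        values = _directional_sync(X, a1, mode, epochs_average, mvar_order, te_lag)
    elif epochs_average and mode in ("coh", "imaginary_coh"):
        # pool epochs and samples into one expectation per bin
        values = np.empty((len(band_names), n2, n2))
        for bi, name in enumerate(band_names):
            sl = a1.band_index[name]
            acc = np.zeros((n2, n2))
            for k in range(sl.start, sl.stop):
                flat = X[:, :, k, :].transpose(1, 0, 2).reshape(n2, -1)
                acc += _pair_matrix(flat, mode)
            values[bi] = acc / (sl.stop - sl.start)
    else:
        per_epoch = np.empty((n_e, len(band_names), n2, n2))
        for bi, name in enumerate(band_names):
            sl = a1.band_index[name]
            n_bins = sl.stop - sl.start
            for ep in range(n_e):
                acc = np.zeros((n2, n2))
                for k in range(sl.start, sl.stop):
                    acc += _pair_matrix(X[ep, :, k, :], mode)
                per_epoch[ep, bi] = acc / n_bins
        values = per_epoch.mean(axis=0) if epochs_average else per_epoch

    return ConnectivityMatrix(
        values=values,
        metric=mode,
        directional=directional,
        n_ch=n2 // 2,
        band_names=band_names,
        ch_names=ch_names,
    )


# ---------------------------------------------------------------------------
# Vectorized pair-matrix kernels
# ---------------------------------------------------------------------------


def _pair_matrix(z: np.ndarray, mode: str) -> np.ndarray:
    """(C x C) metric matrix from one (C, samples) complex slab."""
    if mode == "plv":
        u = np.exp(1j * np.angle(z))
        return np.abs(u @ u.conj().T) / z.shape[1]
    if mode == "pli":
        ph = np.angle(z)
        d = np.sin(ph[:, None, :] - ph[None, :, :])
        return np.abs(np.mean(np.sign(d), axis=-1))
    if mode == "ccorr":
        ph = np.angle(z)
        mu = np.angle(np.mean(np.exp(1j * ph), axis=-1))
        s = np.sin(ph - mu[:, None])
        ss = np.sum(s**2, axis=-1)
        den = np.sqrt(np.maximum(np.outer(ss, ss), EPS))
        return (s @ s.T) / den
    if mode in ("coh", "imaginary_coh"):
        n = z.shape[1]
        g = z @ z.conj().T / n
        auto = np.real(np.diag(g))
        outer = np.outer(auto, auto)
        dead = outer <= 0  # silent channels: define their coherence as 0
        outer = np.where(dead, 1.0, outer)
        if mode == "coh":
            out = np.abs(g) ** 2 / outer
        else:
            out = np.abs(np.imag(g / np.sqrt(outer)))
        out[dead] = 0.0
        return out
    if mode in ("envelope_corr", "pow_corr"):
        env = np.abs(z)
        if mode == "pow_corr":
            env = env**2
        zc = env - env.mean(axis=-1, keepdims=True)
        norm = np.sqrt(np.sum(zc**2, axis=-1))
        dead = norm <= 0
        norm[dead] = 1.0
        out = (zc @ zc.T) / np.outer(norm, norm)
        out[dead, :] = 0.0
        out[:, dead] = 0.0
        return out
    if mode == "proj_pow_corr":
        return _ppc_matrix(z)
    raise ValueError(mode)


def _ppc_matrix(z: np.ndarray) -> np.ndarray:
    """Symmetrized projected power correlation for one (C, S) slab."""
    re, im = np.real(z), np.imag(z)
    env = np.abs(z)
    scale = env.max()
    if scale <= 0:
        return np.zeros((z.shape[0], z.shape[0]))
    env = np.maximum(env, 1e-12 * scale)
    # cross[i, j, s] = Im(z_j conj(z_i)) : component of j orthogonal to i
    cross = im[None, :, :] * re[:, None, :] - re[None, :, :] * im[:, None, :]
    env_orth = np.abs(cross) / env[:, None, :]
    zc = env - env.mean(axis=-1, keepdims=True)
    znorm = np.sqrt(np.sum(zc**2, axis=-1, keepdims=True))
    zdead = znorm[..., 0] <= 0
    zc = zc / np.where(znorm > 0, znorm, 1.0)
    oc = env_orth - env_orth.mean(axis=-1, keepdims=True)
    onorm = np.sqrt(np.sum(oc**2, axis=-1, keepdims=True))
    degenerate = onorm[..., 0] <= 1e-8 * scale
    oc = oc / np.where(onorm > 0, onorm, 1.0)
    r = np.einsum("is,ijs->ij", zc, oc)
    r[degenerate] = 0.0
    r[zdead, :] = 0.0
    return 0.5 * (r + r.T)


def _directional_sync(
    X: np.ndarray,
    a1: AnalyticSignal,
    mode: str,
    epochs_average: bool,
    mvar_order: int,
    te_lag: int,
) -> np.ndarray:
    """PDC / transfer entropy per band on band-limited real signals.

    The band signal is reconstructed as the mean of per-bin real parts of
    the analytic signal (an average of adjacent 1 Hz-wide band-passes).
    Entry [i, j] is the influence of channel i on channel j.
    """
    n_e, n2 = X.shape[0], X.shape[1]
    band_names = list(a1.band_index)

    def one(band_real: np.ndarray, sl: slice) -> np.ndarray:
        # band_real: (epochs, 2N, samples)
        if mode == "pdc":
            model = fit_mvar(band_real, order=mvar_order)
            bins = a1.freqs[sl].astype(float)
            m = pdc(model, bins, a1.sfreq).mean(axis=0)  # [i,j] = j -> i
            out = m.T.copy()
        else:
            out = np.empty((n2, n2))
            for i in range(n2):
                for j in range(n2):
                    if i == j:
                        out[i, j] = 0.0
                        continue
                    out[i, j] = transfer_entropy(
                        band_real[:, i, :], band_real[:, j, :], k=te_lag
                    )
        return out

    if epochs_average:
        values = np.empty((len(band_names), n2, n2))
        for bi, name in enumerate(band_names):
            sl = a1.band_index[name]
            band_real = np.real(X[:, :, sl, :]).mean(axis=2)
            values[bi] = one(band_real, sl)
    else:
        values = np.empty((n_e, len(band_names), n2, n2))
        for bi, name in enumerate(band_names):
            sl = a1.band_index[name]
            band_real = np.real(X[:, :, sl, :]).mean(axis=2)
            for ep in range(n_e):
                values[ep, bi] = one(band_real[ep : ep + 1], sl)
    return values


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _check_pair(x, y, min_len: int, dtype=float):
    x = np.asarray(x, dtype=dtype).ravel()
    y = np.asarray(y, dtype=dtype).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < min_len:
        raise DegenerateInputError(f"need at least {min_len} samples, got {x.size}")
    return x, y


def _circ_mean(ph: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * ph))))


def _amp_corr(x, y, power: bool) -> float:
    x = np.atleast_2d(np.asarray(x, dtype=complex))
    y = np.atleast_2d(np.asarray(y, dtype=complex))
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.shape[-1] < 3:
        raise DegenerateInputError("need at least 3 samples")
    rs = []
    for xe, ye in zip(x, y):
        a, b = np.abs(xe), np.abs(ye)
        if power:
            a, b = a**2, b**2
        if a.std() < EPS or b.std() < EPS:
            raise DegenerateInputError("zero envelope variance")
        rs.append(sp_stats.pearsonr(a, b)[0])
    return float(np.mean(rs))


def _ppc_oneside(x: np.ndarray, y: np.ndarray) -> float:
    env_x = np.maximum(np.abs(x), EPS)
    y_orth = np.abs(np.imag(y * np.conj(x) / env_x))
    if y_orth.std() < 1e-8 * max(y_orth.mean(), EPS) or y_orth.std() < EPS:
        logger.debug("orthogonalized signal degenerate; returning 0")
        return 0.0
    if env_x.std() < EPS:
        return 0.0
    return float(sp_stats.pearsonr(env_x, y_orth)[0])


def _resid_var(design: np.ndarray, target: np.ndarray) -> float:
    d = np.column_stack([np.ones(len(design)), design])
    beta, _, _, _ = np.linalg.lstsq(d, target, rcond=None)
    resid = target - d @ beta
    return float(np.var(resid))
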