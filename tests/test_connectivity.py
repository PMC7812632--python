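"""Metric kernels, MVAR/PDC, transfer entropy and the joint matrix."""

import numpy as np
import pytest

from hyperlink.connectivity import (
    ALL_MODES,
    DIRECTIONAL_MODES,
    NONDIRECTIONAL_MODES,
    DegenerateInputError,
    ccorr,
    coherence,
    compute_sync,
    envelope_corr,
    fit_mvar,
    imaginary_coherence,
    pdc,
    pli,
    plv,
    pow_corr,
    proj_pow_corr,
    slice_blocks,
    standardize,
    transfer_entropy,
)
from hyperlink.spectral import BandSpec, compute_freq_bands
from hyperlink.synthgen import DyadSimConfig, simulate_directed_dyad

from conftest import ALPHA_LOW, make_epochs


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# Phase metrics
# ---------------------------------------------------------------------------


class TestPhaseMetrics:
    def test_plv_identity_and_offset_invariance(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert plv(ph, ph) == pytest.approx(1.0)
        assert plv(ph, ph - np.pi / 2) == pytest.approx(1.0)

    def test_plv_null_level_closed_form(self, rng):
        """E[PLV] of independent uniform phases is sqrt(pi/4)/sqrt(n)."""
        n = 100
        vals = [
            plv(rng.uniform(-np.pi, np.pi, n), rng.uniform(-np.pi, np.pi, n))
            for _ in range(200)
        ]
        assert 0.06 <= np.mean(vals) <= 0.12  # 0.886/sqrt(100) = 0.0886
        big = [
            plv(rng.uniform(-np.pi, np.pi, 10_000), rng.uniform(-np.pi, np.pi, 10_000))
            for _ in range(50)
        ]
        assert np.mean(big) < 0.02  # 0.886/sqrt(1e4) = 0.0089

    def test_pli_zero_lag_blind_and_quarter_lag_saturated(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert pli(ph, ph) == pytest.approx(0.0)
        assert pli(ph + np.pi / 2, ph) == pytest.approx(1.0)

    def test_pli_alternating_offsets_cancel(self):
        ph = np.zeros(400)
        offs = np.tile([np.pi / 4, -np.pi / 4], 200)
        assert pli(ph + offs, ph) == pytest.approx(0.0)

    def test_ccorr_reflection_antisymmetry(self, rng):
        ph = rng.normal(0.0, 0.8, 500)  # dispersed but not uniform
        assert ccorr(ph, ph) == pytest.approx(1.0)
        assert ccorr(ph, -ph) == pytest.approx(-1.0)

    def test_ccorr_null_small(self, rng):
        hits = 0
        for _ in range(200):
            a = rng.uniform(-np.pi, np.pi, 10_000)
            b = rng.uniform(-np.pi, np.pi, 10_000)
            hits += abs(ccorr(a, b)) < 0.05
        assert hits >= 190  # 95% of replicates

    def test_ccorr_zero_dispersion_rejected(self):
        with pytest.raises(DegenerateInputError):
            ccorr(np.zeros(10), np.linspace(-1, 1, 10))

    def test_too_short_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            plv([0.1], [0.2])


# ---------------------------------------------------------------------------
# Coherence family
# ---------------------------------------------------------------------------


class TestCoherenceFamily:
    def test_self_and_scale_invariance(self, rng):
        x = rng.normal(size=(5, 64)) + 1j * rng.normal(size=(5, 64))
        assert coherence(x, x) == pytest.approx(1.0)
        assert coherence(x, 3.0 * x) == pytest.approx(1.0)

    def test_null_level(self, rng):
        vals = []
        for _ in range(100):
            x = rng.normal(size=(50, 8)) + 1j * rng.normal(size=(50, 8))
            y = rng.normal(size=(50, 8)) + 1j * rng.normal(size=(50, 8))
            vals.append(coherence(x, y))
        assert np.mean(vals) < 0.1

    def test_single_value_refused(self):
        with pytest.raises(DegenerateInputError):
            coherence(np.array([1 + 1j]), np.array([1 - 1j]))

    def test_imaginary_coherence_zero_at_zero_lag(self, rng):
        x = rng.normal(size=(5, 64)) + 1j * rng.normal(size=(5, 64))
        assert imaginary_coherence(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_rotation_moves_real_coherency_into_imaginary_part(self, rng):
        """icoh(x, i*y) == |Re coherency(x, y)|: for y = x (real coherency 1)
        the rotation yields icoh exactly 1, the full coherency magnitude."""
        x = rng.normal(size=(5, 64)) + 1j * rng.normal(size=(5, 64))
        noise = 0.5 * (rng.normal(size=x.shape) + 1j * rng.normal(size=x.shape))
        y = x + noise
        # real part of the coherency of (x, y), computed independently
        creal = np.abs(
            np.real(
                np.mean(x * np.conj(y))
                / np.sqrt(np.mean(np.abs(x) ** 2) * np.mean(np.abs(y) ** 2))
            )
        )
        assert imaginary_coherence(x, 1j * y) == pytest.approx(creal, rel=1e-10)
        assert imaginary_coherence(x, 1j * x) == pytest.approx(1.0, rel=1e-10)


# ---------------------------------------------------------------------------
# Envelope / power correlations
# ---------------------------------------------------------------------------


class TestEnvelopeCorrelations:
    def test_identity(self, rng):
        x = rng.normal(size=200) + 1j * rng.normal(size=200)
        assert envelope_corr(x, x) == pytest.approx(1.0)
        assert pow_corr(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        env = 1.0 + 0.5 * rng.random(500)
        x = env * np.exp(1j * ph)
        y = (2.5 - env) * np.exp(1j * ph)
        assert envelope_corr(x, y) == pytest.approx(-1.0)

    def test_null_level(self, rng):
        x = rng.normal(size=10_000) + 1j * rng.normal(size=10_000)
        y = rng.normal(size=10_000) + 1j * rng.normal(size=10_000)
        assert abs(envelope_corr(x, y)) < 0.1
        assert abs(pow_corr(x, y)) < 0.1

    def test_zero_variance_rejected(self):
        x = np.exp(1j * np.linspace(0, 6, 100))  # unit envelope
        with pytest.raises(DegenerateInputError):
            envelope_corr(x, x)


class TestProjectedPowerCorrelation:
    def test_proportional_signals_are_degenerate_zero(self, rng):
        x = (1 + rng.random(300)) * np.exp(1j * rng.uniform(-np.pi, np.pi, 300))
        assert proj_pow_corr(x, 2.0 * x) == 0.0

    def test_recovers_known_envelope_correlation(self, rng):
        """x and a quarter-rotated y with envelope correlation 0.8."""
        n = 20_000
        u, v = rng.normal(size=n), rng.normal(size=n)
        a = 1.5 + 0.3 * u
        b = 1.5 + 0.3 * (0.8 * u + 0.6 * v)
        ph = rng.uniform(-np.pi, np.pi, n)
        x = a * np.exp(1j * ph)
        y = b * np.exp(1j * (ph + np.pi / 2))
        target = np.corrcoef(np.abs(a), np.abs(b))[0, 1]
        assert proj_pow_corr(x, y) == pytest.approx(target, abs=0.1)

    def test_null_level(self, rng):
        n = 10_000
        x = rng.normal(size=n) + 1j * rng.normal(size=n)
        y = rng.normal(size=n) + 1j * rng.normal(size=n)
        assert abs(proj_pow_corr(x, y)) < 0.1


# ---------------------------------------------------------------------------
# MVAR / PDC / transfer entropy
# ---------------------------------------------------------------------------


def simulate_var(coeffs, n, rng, sd=1.0):
    p, c, _ = coeffs.shape
    z = np.zeros((c, n))
    for t in range(p, n):
        z[:, t] = sum(coeffs[m] @ z[:, t - m - 1] for m in range(p)) + rng.normal(
            0, sd, c
        )
    return z


class TestMvar:
    A_TRUE = np.array(
        [[[0.5, 0.1], [0.0, 0.4]], [[-0.2, 0.0], [0.1, -0.3]]]
    )  # stable VAR(2)

    def test_simulate_and_recover(self, rng):
        z = simulate_var(self.A_TRUE, 10_000, rng)
        m = fit_mvar(z, order=2)
        assert np.sqrt(np.mean((m.coeffs - self.A_TRUE) ** 2)) < 0.05
        assert m.stable

    def test_white_noise_coefficients_near_zero(self, rng):
        z = rng.normal(size=(2, 10_000))
        m = fit_mvar(z, order=2)
        assert np.abs(m.coeffs).max() < 0.05

    def test_order_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mvar(rng.normal(size=(2, 100)), order=0)

    def test_identifiability_guard(self, rng):
        with pytest.raises(DegenerateInputError):
            fit_mvar(rng.normal(size=(4, 15)), order=5)


class TestPdc:
    def test_uncoupled_var_has_no_cross_pdc(self, rng):
        a = np.zeros((1, 2, 2))
        a[0] = np.diag([0.5, -0.3])
        z = simulate_var(a, 10_000, rng)
        m = fit_mvar(z, order=1)
        p = pdc(m, np.linspace(1.0, 400.0, 9), 1000.0)
        off = p[:, ~np.eye(2, dtype=bool)]
        assert off.max() < 0.05

    def test_unidirectional_coupling_recovered(self, rng):
        a = np.zeros((1, 2, 2))
        a[0] = np.array([[0.5, 0.0], [0.7, 0.2]])  # channel 0 drives channel 1
        z = simulate_var(a, 10_000, rng)
        m = fit_mvar(z, order=1)
        p = pdc(m, np.array([10.0]), 1000.0)[0]
        assert p[1, 0] > 0.5  # 0 -> 1
        assert p[0, 1] < 0.1  # 1 -> 0

    def test_column_normalization_exact(self, rng):
        z = rng.normal(size=(3, 2_000))
        m = fit_mvar(z, order=3)
        p = pdc(m, np.linspace(1, 100, 7), 250.0)
        colsums = (p**2).sum(axis=1)
        np.testing.assert_allclose(colsums, 1.0, atol=1e-10)


class TestTransferEntropy:
    def test_null_bias_tiny(self, rng):
        vals = [
            transfer_entropy(rng.normal(size=10_000), rng.normal(size=10_000))
            for _ in range(100)
        ]
        assert np.mean(vals) < 0.005

    def test_linear_gaussian_closed_form(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        noise = rng.normal(0, 0.5, n)
        y = np.zeros(n)
        y[1:] = 0.8 * x[:-1] + noise[1:]
        te = transfer_entropy(x, y, k=1)
        expected = 0.5 * np.log(1 + 0.64 * np.var(x) / np.var(noise))
        assert te == pytest.approx(expected, rel=0.10)

    def test_directionality(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = np.zeros(n)
        y[1:] = 0.8 * x[:-1] + rng.normal(0, 0.5, n - 1)
        assert transfer_entropy(x, y) > 10 * transfer_entropy(y, x)

    def test_matches_granger_log_ratio(self, rng):
        """TE equals half the Granger variance-ratio log statistic."""
        n = 10_000
        x = rng.normal(size=n)
        y = np.zeros(n)
        y[1:] = 0.5 * y[:-1]
        y[1:] += 0.6 * x[:-1] + rng.normal(0, 1.0, n - 1)
        # independent GC oracle via explicit OLS residual variances
        yt, y1, x1 = y[1:], y[:-1], x[:-1]
        r_red = yt - np.polyval(np.polyfit(y1, yt, 1), y1)
        d = np.column_stack([np.ones(n - 1), y1, x1])
        beta = np.linalg.lstsq(d, yt, rcond=None)[0]
        r_full = yt - d @ beta
        gc = np.log(np.var(r_red) / np.var(r_full))
        assert transfer_entropy(x, y) == pytest.approx(0.5 * gc, rel=0.05)


# ---------------------------------------------------------------------------
# Joint matrix assembly
# ---------------------------------------------------------------------------


RANGES = {
    "plv": (0.0, 1.0),
    "pli": (0.0, 1.0),
    "coh": (0.0, 1.0),
    "imaginary_coh": (0.0, 1.0),
    "pdc": (0.0, 1.0),
    "ccorr": (-1.0, 1.0),
    "envelope_corr": (-1.0, 1.0),
    "pow_corr": (-1.0, 1.0),
    "proj_pow_corr": (-1.0, 1.0),
    "transfer_entropy": (0.0, np.inf),
}


class TestComputeSync:
    @pytest.mark.parametrize("mode", NONDIRECTIONAL_MODES)
    def test_nondirectional_matrix_exactly_symmetric(self, mode, coupled_analytic):
        c = compute_sync(coupled_analytic, mode)
        assert not c.directional
        asym = np.abs(c.values - np.swapaxes(c.values, -1, -2)).max()
        assert asym < 1e-10

    @pytest.mark.parametrize("mode", ALL_MODES)
    def test_range_invariants(self, mode, coupled_analytic):
        c = compute_sync(coupled_analytic, mode)
        lo, hi = RANGES[mode]
        assert c.values.min() >= lo - 1e-9
        assert c.values.max() <= hi + 1e-9

    def test_shape_and_blocks(self, coupled_analytic):
        c = compute_sync(coupled_analytic, "plv")
        n = coupled_analytic[0].n_channels
        assert c.values.shape == (1, 2 * n, 2 * n)
        b = slice_blocks(c)
        reassembled = np.block(
            [[b.intra_1, b.inter_12], [b.inter_21, b.intra_2]]
        )
        np.testing.assert_array_equal(reassembled, c.values)

    def test_identical_participants_have_unit_inter_diagonal(self, coupled_analytic):
        a1, _ = coupled_analytic
        c = compute_sync((a1, a1), "plv")
        b = slice_blocks(c)
        np.testing.assert_allclose(np.diagonal(b.inter_12, axis1=-2, axis2=-1), 1.0)

    def test_epoch_axis_preserved_on_request(self, coupled_analytic):
        c = compute_sync(coupled_analytic, "plv", epochs_average=False)
        assert c.per_epoch
        assert c.values.shape[0] == coupled_analytic[0].n_epochs

    def test_unknown_mode_rejected(self, coupled_analytic):
        with pytest.raises(ValueError, match="mode must be one of"):
            compute_sync(coupled_analytic, "wavelet_coh")

    @pytest.mark.parametrize("mode", DIRECTIONAL_MODES)
    def test_directed_fixture_breaks_inter_block_symmetry(self, mode):
        cfg = DyadSimConfig(n_epochs=6, n_channels=2, seed=5)
        pair = simulate_directed_dyad(cfg, direction=(0, 0), ar_coeff=0.6)
        analytic = compute_freq_bands(pair, [ALPHA_LOW])
        c = compute_sync(analytic, mode)
        assert c.directional
        b = slice_blocks(c)
        asym = np.abs(b.inter_12 - np.swapaxes(b.inter_21, -1, -2)).max()
        assert asym > 1e-6


class TestStandardize:
    def test_grand_mean_zero_std_one(self, rng):
        out = standardize(rng.normal(2.0, 3.0, (6, 6)))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std() - 1.0) < 1e-12

    def test_positive_scale_invariance_exact(self, rng):
        x = rng.normal(size=(5, 5))
        np.testing.assert_allclose(standardize(3.7 * x), standardize(x), atol=1e-12)

    def test_constant_off_diagonal_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize(np.ones((4, 4)))
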