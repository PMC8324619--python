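"""Reconstruction: SCF/k conversion, DEW, OSEM, Butterworth, quantitation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qspect import (
    ConfigurationError,
    PhantomRealization,
    PhysicsModel,
    ReconParams,
    ScatterParams,
    UnitsError,
    VoxelGrid,
    AcquisitionProtocol,
    ac_to_counts,
    butterworth3d,
    counts_to_ac,
    dew_scatter_estimate,
    k_to_scf,
    osem,
    scf_to_k,
    simulate_acquisition,
    voi_stats,
)
from qspect.analysis import noise_pct, snr
from qspect.phantom import BACKGROUND_LABEL, SPHERE_LABELS
from qspect.projector import Projector
from qspect.recon import ReconVolume


class TestScatterFactorConversion:
    def test_study_factors(self):
        """SCF 1.10 and 0.41 map to the Jaszczak multipliers 0.470 / 0.175."""
        assert scf_to_k(1.10, 28.1, 12.0) == 0.470
        assert scf_to_k(0.41, 28.1, 12.0) == 0.175
        assert scf_to_k(0.0, 28.1, 12.0) == 0.0

    def test_inverse(self):
        assert k_to_scf(0.175) == pytest.approx(0.41)

    @given(st.floats(0.0, 5.0))
    @settings(derandomize=True, max_examples=25)
    def test_scatterparams_consistent(self, scf):
        p = ScatterParams(scf=scf)
        assert ScatterParams.from_k(p.k).scf == pytest.approx(scf, abs=1e-12)

    def test_invalid_windows(self):
        with pytest.raises(ValueError):
            scf_to_k(1.0, 0.0, 12.0)


class TestDewEstimate:
    def test_zero_k(self):
        assert np.all(dew_scatter_estimate(np.ones((2, 3)), 0.0) == 0.0)

    def test_linear_in_k(self):
        s = np.arange(12.0).reshape(3, 4)
        assert np.allclose(dew_scatter_estimate(s, 0.4), 2 * dew_scatter_estimate(s, 0.2))

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            dew_scatter_estimate(np.ones(3), -0.1)

    def test_recovers_simulated_scatter_with_true_k(self, mini_acq_noisefree):
        """With k = k_true the DEW estimate equals the simulator's
        photopeak scatter component bin for bin (the pipeline anchor)."""
        k = mini_acq_noisefree.physics.k_true
        est = dew_scatter_estimate(mini_acq_noisefree.scatter_window, k)
        assert np.allclose(est, mini_acq_noisefree.scatter_in_peak, rtol=1e-12)


class TestOsem:
    def _tiny_problem(self, seed=1):
        g = VoxelGrid(shape=(16, 16, 1), voxel_size=4.0)
        rng = np.random.default_rng(seed)
        mu = np.zeros(g.shape)
        mu[4:12, 4:12, :] = 0.15
        act = np.zeros(g.shape)
        act[5:10, 6:11, 0] = rng.random((5, 5)) * 30
        real = PhantomRealization(act, mu, np.zeros(g.shape, np.int16), g, None)
        prot = AcquisitionProtocol(12, 10.0)
        ps = simulate_acquisition(real, prot, PhysicsModel(scatter_fraction=0.0), seed=3)
        return g, mu, prot, ps

    def test_single_subset_matches_mlem_oracle(self):
        """OSEM with one subset reproduces an independently coded
        matrix-based MLEM to 1e-10 relative on a 16x16 slice."""
        g, mu, prot, ps = self._tiny_problem()
        vol = osem(ps, mu, ReconParams(iterations=5, subsets=1, scatter=ScatterParams(scf=0.0)))

        op = Projector(g, prot.angles_deg, mu, psf=True)
        n = 16 * 16
        A = np.zeros((12 * 16, n))
        for j in range(n):
            e = np.zeros((16, 16, 1))
            e.flat[j] = 1.0
            A[:, j] = op.forward(e).ravel()
        A *= prot.dwell / prot.total_time
        y = ps.photopeak.reshape(-1).astype(float)
        x = (mu.ravel() > 0).astype(float)
        At1 = A.T @ np.ones_like(y)
        for _ in range(5):
            ratio = y / np.maximum(A @ x, 1e-12)
            x *= np.where(At1 > 1e-12, (A.T @ ratio) / np.maximum(At1, 1e-12), 0.0)
        ref = x.reshape(16, 16, 1)
        scale = np.abs(ref).max()
        assert np.max(np.abs(vol.values - ref)) / scale < 1e-10

    def test_nonnegativity(self):
        g, mu, prot, ps = self._tiny_problem(seed=2)
        vol = osem(ps, mu, ReconParams(iterations=3, subsets=3))
        assert vol.values.min() >= 0.0

    def test_subset_mismatch_rejected(self):
        g, mu, prot, ps = self._tiny_problem()
        with pytest.raises(ConfigurationError):
            osem(ps, mu, ReconParams(iterations=1, subsets=5))  # 12 angles, 6/head

    def test_all_zero_data_returns_zero_volume(self):
        g, mu, prot, ps = self._tiny_problem()
        ps.photopeak = np.zeros_like(ps.photopeak)
        ps.scatter_window = np.zeros_like(ps.scatter_window)
        with pytest.warns(UserWarning):
            vol = osem(ps, mu, ReconParams(iterations=2, subsets=2))
        assert np.all(vol.values == 0.0)
        assert vol.provenance["warning"] == "all-zero data"

    def test_subtraction_mode_runs(self):
        g, mu, prot, ps = self._tiny_problem()
        vol = osem(ps, mu, ReconParams(iterations=2, subsets=2, scatter_mode="subtract"))
        assert vol.values.min() >= 0.0


@pytest.fixture(scope="module")
def mini_qf(mini_physics, mini_grid):
    return 1.0 / (mini_physics.sensitivity * 1200.0 * mini_grid.v_voxel)


@pytest.fixture(scope="module")
def recons_by_scf(mini_acq_noisefree, mini_real):
    """Noise-free 2i/10s reconstructions over SCF in {0, 0.41, 1.10}."""
    out = {}
    for scf in (0.0, 0.41, 1.10):
        out[scf] = osem(
            mini_acq_noisefree,
            mini_real.mu,
            ReconParams(iterations=2, subsets=10, scatter=ScatterParams(scf=scf)),
        )
    return out


@pytest.fixture(scope="module")
def recons_by_updates(mini_acq, mini_real):
    """Noisy reconstructions over the study's update ladder (SCF 0.41)."""
    out = {}
    for it, sub in ((2, 10), (4, 10), (5, 15), (24, 10)):
        out[it * sub] = osem(
            mini_acq,
            mini_real.mu,
            ReconParams(iterations=it, subsets=sub, scatter=ScatterParams(scf=0.41)),
            dtype=np.float32,
        )
    return out


class TestReconstructionBehaviour:
    def test_sphere_ac_nonincreasing_in_scf(self, recons_by_scf, mini_real, mini_qf):
        """More scatter weighting removes more counts from the spheres."""
        means = [
            voi_stats(counts_to_ac(recons_by_scf[s], mini_qf), mini_real.voi_labels, SPHERE_LABELS[-1]).mean_ac
            for s in (0.0, 0.41, 1.10)
        ]
        assert means[0] >= means[1] >= means[2]

    def test_true_k_gives_best_recovery(self, recons_by_scf, mini_real, mini_qf):
        """SCF 0.41 (the simulator's ground truth) beats the default 1.10."""
        h = {}
        for s in (0.41, 1.10):
            ac = counts_to_ac(recons_by_scf[s], mini_qf)
            h[s] = voi_stats(ac, mini_real.voi_labels, SPHERE_LABELS[-1]).mean_ac / 85.1
        assert abs(1.0 - h[0.41]) < abs(1.0 - h[1.10])

    def test_updates_raise_sphere_ac_and_noise(self, recons_by_updates, mini_real, mini_qf):
        sphere, noise = [], []
        for upd in (20, 40, 75, 240):
            ac = counts_to_ac(recons_by_updates[upd], mini_qf)
            sphere.append(voi_stats(ac, mini_real.voi_labels, SPHERE_LABELS[-1]).mean_ac)
            bg = voi_stats(ac, mini_real.voi_labels, BACKGROUND_LABEL)
            noise.append(noise_pct(bg.sd, bg.mean_ac))
        assert all(b > a for a, b in zip(sphere, sphere[1:]))
        assert all(b > a for a, b in zip(noise, noise[1:]))

    def test_postfilter_trades_noise_for_snr(self, recons_by_updates, mini_real, mini_qf):
        """Butterworth lowers background noise and raises sphere SNR."""
        ac = counts_to_ac(recons_by_updates[20], mini_qf)
        filtered = butterworth3d(ac.values, 0.5, 10, mini_real.grid.voxel_size)
        lab = mini_real.voi_labels

        def _metrics(values):
            bg_m = values[lab == BACKGROUND_LABEL].mean()
            bg_sd = values[lab == BACKGROUND_LABEL].std()
            sp = values[lab == SPHERE_LABELS[-1]].mean()
            return noise_pct(bg_sd, bg_m), snr(sp, bg_m, bg_sd)

        n0, snr0 = _metrics(ac.values)
        n1, snr1 = _metrics(filtered)
        assert n1 < n0
        assert snr1 > snr0


class TestButterworth:
    def test_constant_volume_unchanged(self):
        v = np.full((16, 16, 8), 3.7)
        out = butterworth3d(v, 0.5, 10, 2.21)
        assert np.allclose(out, v, atol=1e-12)

    def test_half_gain_at_cutoff(self):
        """H(f_c) = 0.5 under the chosen exponent convention."""
        n, voxel = 64, 2.5
        fc = 0.5  # cycles/cm
        # pure cosine at the cutoff frequency along x
        cycles = fc * (voxel / 10.0) * n  # per grid length
        assert cycles == round(cycles)  # chosen to land on a DFT bin
        x = np.cos(2 * np.pi * cycles * np.arange(n) / n)
        v = np.tile(x[:, None, None], (1, 4, 4))
        out = butterworth3d(v, fc, 10, voxel)
        assert out.max() == pytest.approx(0.5, rel=1e-3)

    def test_variance_reduction_matches_dft_oracle(self):
        """White-noise variance shrink equals Parseval's sum of |H|^2."""
        rng = np.random.default_rng(0)
        v = rng.standard_normal((24, 24, 16))
        voxel = 2.21
        out = butterworth3d(v, 0.5, 10, voxel)
        # oracle: full-FFT Parseval accounting, independent of rfft path
        freqs = [np.fft.fftfreq(n, d=voxel / 10.0) for n in v.shape]
        f = np.sqrt(
            freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2 + freqs[2][None, None, :] ** 2
        )
        h = 1.0 / (1.0 + (f / 0.5) ** 20)
        spec = np.fft.fftn(v)
        expected_var = float(np.sum(np.abs(spec * h) ** 2) / v.size**2) - float(
            np.abs(spec.flat[0] * h.flat[0]) / v.size
        ) ** 2
        assert out.var() == pytest.approx(expected_var, rel=0.01)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            butterworth3d(np.zeros((4, 4, 4)), 0.0, 10, 2.21)


class TestQuantitation:
    def _vol(self, values):
        return ReconVolume(
            values=values, units="counts", params=ReconParams(1, 1), grid=VoxelGrid(shape=(2, 2, 2))
        )

    def test_identity_scaling(self):
        v = self._vol(np.full((2, 2, 2), 5.0))
        out = counts_to_ac(v, 1.0)  # S*T*V = 1
        assert np.allclose(out.values, 5000.0)  # MBq/ml -> kBq/ml
        assert out.units == "kBq/ml"

    def test_zero_counts(self):
        out = counts_to_ac(self._vol(np.zeros((2, 2, 2))), 1e-3)
        assert np.all(out.values == 0.0)

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        v = self._vol(rng.random((2, 2, 2)))
        back = ac_to_counts(counts_to_ac(v, 1.068e-3), 1.068e-3)
        assert np.allclose(back.values, v.values, rtol=1e-12)

    def test_double_conversion_rejected(self):
        v = counts_to_ac(self._vol(np.ones((2, 2, 2))), 1e-3)
        with pytest.raises(UnitsError):
            counts_to_ac(v, 1e-3)

    def test_invalid_qf(self):
        with pytest.raises(ValueError):
            counts_to_ac(self._vol(np.ones((2, 2, 2))), 0.0)
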