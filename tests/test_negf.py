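"""Green's-function machinery: blocks, surface GFs, self-energies,
device GF and the Caroli transmission trace."""

import math

import numpy as np
import pytest

from aquaphonon import (
    DeviceModel,
    DisorderRecipe,
    UnitCell,
    band_structure,
    complex_wavevector,
    dispersion_coskl,
    disordered_device,
    table1_device,
    transmission,
    transmission_spectrum,
)
from aquaphonon.errors import DecimationError
from aquaphonon.negf import (
    build_dynamical_blocks,
    device_gf,
    device_gf_corner,
    green_function_set,
    self_energies,
    surface_gf,
    transmission_n1_closed_form,
)


def monatomic_cell(M=2e-26, K=50.0):
    return UnitCell(M1=M, M2=M, K1=K, K2=K, l=3e-10)


def monatomic_surface_gf(eps, eta, M, K):
    """Closed-form retarded surface GF of the semi-infinite monatomic chain:
    g = [E - e0 - sqrt((E - e0)^2 - 4 t^2)] / (2 t^2), branch with Im g <= 0,
    with e0 = 2K/M and t = K/M."""
    e0, t = 2 * K / M, K / M
    E = eps + 1j * eta
    root = np.sqrt((E - e0) ** 2 - 4 * t * t)
    g = (E - e0 - root) / (2 * t * t)
    if g.imag > 0:
        g = (E - e0 + root) / (2 * t * t)
    return g


class TestDynamicalBlocks:
    def test_homogeneous_bloch_reduction_gives_band_edges(self, cell, bands):
        """At kl = pi the 2x2 Bloch matrix eigenvalues are (wr^2, wq^2)."""
        dev = DeviceModel(left=cell, right=cell, cells=(cell,))
        blocks = build_dynamical_blocks(dev, 1e13)
        s = math.sqrt(cell.M1 * cell.M2)
        # assemble the Bloch matrix at kl = pi from the block values
        off = blocks.hopping[0] + (-cell.K2 / s) * np.exp(-1j * math.pi)
        m = np.array([[blocks.onsite[0], off], [np.conj(off), blocks.onsite[1]]])
        eigs = np.linalg.eigvalsh(m)
        assert math.sqrt(eigs[0]) == pytest.approx(bands.omega_r, rel=1e-12)
        assert math.sqrt(eigs[1]) == pytest.approx(bands.omega_q, rel=1e-12)

    def test_monatomic_limit(self):
        c = monatomic_cell()
        dev = DeviceModel(left=c, right=c, cells=(c,) * 3)
        blocks = build_dynamical_blocks(dev, 1e13)
        np.testing.assert_allclose(blocks.onsite, 2 * c.K1 / c.M1)
        np.testing.assert_allclose(blocks.hopping, -c.K1 / c.M1)

    def test_heterogeneous_operator_is_hermitian(self, rng):
        from conftest import random_cells

        cells = tuple(random_cells(rng, 4))
        dev = DeviceModel(left=cells[0], right=cells[-1], cells=cells)
        h = build_dynamical_blocks(dev, 2e13).dense_hamiltonian()
        np.testing.assert_allclose(h, h.conj().T, atol=1e-20)


class TestSurfaceGF:
    def test_matches_monatomic_closed_form(self):
        """Decimation vs the closed-form monatomic surface GF across the band."""
        M, K = 2e-26, 50.0
        c = monatomic_cell(M, K)
        wmax = 2 * math.sqrt(K / M)
        eta = 1e-8 * wmax**2
        for w in np.linspace(0.05, 1.3, 15) * wmax:
            eps = w * w
            expected = monatomic_surface_gf(eps, eta, M, K)
            for side, idx in (("left", (1, 1)), ("right", (0, 0))):
                g = surface_gf(w, eta, c, side)[idx]
                assert g == pytest.approx(expected, rel=1e-8)

    def test_in_band_open_channel(self, cell, bands):
        eta = 1e-8 * bands.omega_p**2
        g = surface_gf(bands.omega_r / 2, eta, cell, "left")
        assert g[1, 1].imag < 0

    def test_gap_imaginary_part_vanishes_with_eta(self, cell, bands):
        w = 0.5 * (bands.omega_r + bands.omega_q)
        eta = 1e-8 * bands.omega_p**2
        g = surface_gf(w, eta, cell, "left")[1, 1]
        assert abs(g.imag) < 1e-4 * abs(g.real)

    def test_retarded_convention(self, cell, bands):
        eta = 1e-8 * bands.omega_p**2
        for w in (0.2 * bands.omega_r, 0.99 * bands.omega_r, 1.2 * bands.omega_p):
            for side in ("left", "right"):
                g = surface_gf(w, eta, cell, side)
                assert np.all(np.diag(g).imag <= 1e-30)

    def test_nonconvergence_raises(self, cell, bands):
        with pytest.raises(DecimationError):
            surface_gf(bands.omega_r / 2, 1e-8 * bands.omega_p**2, cell,
                       "left", max_iter=2)


class TestSelfEnergies:
    def test_in_band_broadening_positive(self, device, bands):
        eta = 1e-8 * bands.omega_p**2
        w = bands.omega_r / 2
        blocks = build_dynamical_blocks(device, w)
        gL = surface_gf(w, eta, device.left, "left")
        gR = surface_gf(w, eta, device.right, "right")
        _, _, gamma_L, gamma_R = self_energies(blocks, gL, gR)
        assert gamma_L > 0 and gamma_R > 0

    def test_gap_broadening_vanishes_with_eta(self, device, bands):
        w = 0.5 * (bands.omega_r + bands.omega_q)
        gammas = []
        for eta_scale in (1e-6, 1e-8, 1e-10):
            eta = eta_scale * bands.omega_p**2
            blocks = build_dynamical_blocks(device, w)
            gL = surface_gf(w, eta, device.left, "left")
            gR = surface_gf(w, eta, device.right, "right")
            _, _, gamma_L, _ = self_energies(blocks, gL, gR)
            gammas.append(gamma_L)
        assert gammas[0] > gammas[1] > gammas[2] >= 0

    def test_matrix_identity_matches_scalar_formula(self, device, bands):
        """Gamma = i(Sigma - Sigma^dagger) equals -2 v^2 Im(g) exactly."""
        eta = 1e-8 * bands.omega_p**2
        w = 0.7 * bands.omega_r
        blocks = build_dynamical_blocks(device, w)
        gL = surface_gf(w, eta, device.left, "left")
        gR = surface_gf(w, eta, device.right, "right")
        sL, sR, gamma_L, gamma_R = self_energies(blocks, gL, gR)
        assert 1j * (sL - np.conj(sL)) == pytest.approx(gamma_L, rel=1e-12)
        assert 1j * (sR - np.conj(sR)) == pytest.approx(gamma_R, rel=1e-12)


class TestDeviceGF:
    def test_n1_closed_form_vs_matrix_inversion(self, device, bands):
        """Scalar N = 1 formula vs 2x2 inversion on a 200-point grid."""
        grid = np.linspace(0.01, 1.1, 200) * bands.omega_p
        for w in grid:
            a = transmission(device, float(w), method="dense")
            b = transmission_n1_closed_form(device, float(w))
            assert b == pytest.approx(a, rel=1e-10, abs=1e-300)

    def test_recursive_vs_dense_n3(self, bands):
        dev = table1_device(n_cells=3)
        eta = dev.eta_value()
        for w in (0.4 * bands.omega_r, 0.9 * bands.omega_r,
                  0.5 * (bands.omega_q + bands.omega_p)):
            blocks = build_dynamical_blocks(dev, w)
            gL = surface_gf(w, eta, dev.left, "left")
            gR = surface_gf(w, eta, dev.right, "right")
            sL, sR, _, _ = self_energies(blocks, gL, gR)
            dense = device_gf(blocks, sL, sR, eta)[0, -1]
            rec = device_gf_corner(blocks, sL, sR, eta)
            assert rec == pytest.approx(dense, rel=1e-10)

    def test_decoupled_limit_poles_at_molecular_modes(self, cell):
        """Interface springs -> 0: the isolated cell resonates at
        omega^2 = 0 and omega^2 = K1 (1/M1 + 1/M2)."""
        weak = UnitCell(M1=cell.M1, M2=cell.M2, K1=cell.K1, K2=cell.K2 * 1e-9,
                        l=cell.l)
        dev = DeviceModel(left=weak, right=weak, cells=(weak,),
                          interface_spring="device")
        w_mol = math.sqrt(weak.K1 * (1 / weak.M1 + 1 / weak.M2))
        eta = 1e-8 * w_mol**2
        blocks = build_dynamical_blocks(dev, w_mol)
        h = blocks.dense_hamiltonian()
        eigs = np.linalg.eigvalsh(h.real)
        assert math.sqrt(max(eigs)) == pytest.approx(w_mol, rel=1e-6)

    def test_device_gf_is_complex_symmetric(self, device, bands):
        """Reciprocity of the retarded GF: G_D = G_D^T (advanced counterpart
        is its conjugate transpose)."""
        gfs = green_function_set(device, 0.6 * bands.omega_r)
        np.testing.assert_allclose(
            gfs.GD, gfs.GD.T, rtol=1e-12, atol=1e-12 * np.abs(gfs.GD).max()
        )


class TestTransmission:
    def test_acoustic_band_ballistic(self, device, bands):
        assert transmission(device, bands.omega_r / 2) == pytest.approx(1.0, abs=1e-3)

    def test_gap_attenuated(self, device, bands):
        w = 0.5 * (bands.omega_r + bands.omega_q)
        assert transmission(device, w) < 1e-3

    def test_above_band_vanishes(self, device, bands):
        assert transmission(device, 1.5 * bands.omega_p) < 1e-6

    def test_gap_decay_slope_matches_complex_band_structure(self, cell, bands):
        """log tr(T) vs N is linear with slope -2 Im(kl) in the gap."""
        w = 40e12  # just above the acoustic band, moderate attenuation
        logs = [math.log(transmission(table1_device(n_cells=n), w))
                for n in range(1, 7)]
        slopes = np.diff(logs)
        expected = -2.0 * complex_wavevector(w, cell).kl_plus.imag
        np.testing.assert_allclose(slopes, expected, rtol=0.05)

    def test_reciprocity(self, bands, rng):
        """Swapping reservoirs and reversing the device leaves tr(T) unchanged."""
        dev = disordered_device(
            DisorderRecipe(n_cells=4, mass_rel_sd=0.1, spring_rel_sd=0.1, seed=7)
        )
        rev = dev.reversed()
        for w in np.linspace(0.1, 1.02, 12) * bands.omega_p:
            a = transmission(dev, float(w))
            b = transmission(rev, float(w))
            assert b == pytest.approx(a, rel=1e-10, abs=1e-280)

    def test_eta_convergence_in_band(self, device, bands):
        """In-band tr(T) deviates from 1 linearly in eta; halving eta at or
        below 1e-7 * omega_p^2 moves it by less than 1e-4."""
        for w in (0.4 * bands.omega_r, 0.5 * (bands.omega_q + bands.omega_p)):
            for scale in (1e-7, 1e-8):
                t1 = transmission(device, w, eta=scale * bands.omega_p**2)
                t2 = transmission(device, w, eta=0.5 * scale * bands.omega_p**2)
                assert abs(t2 - t1) < 1e-4

    def test_unitarity_bound(self, bands, rng):
        dev = disordered_device(
            DisorderRecipe(n_cells=6, mass_rel_sd=0.15, spring_rel_sd=0.1, seed=3)
        )
        for w in np.linspace(0.05, 1.04, 25) * bands.omega_p:
            assert transmission(dev, float(w)) <= 1.0 + 1e-6

    def test_negative_omega_rejected(self, device):
        with pytest.raises(ValueError):
            transmission(device, -1.0)


class TestTransmissionSpectrum:
    def test_homogeneous_bands_ballistic_gap_closed(self, device, bands):
        """Normalized probability ~1 over the central 80% of both bands and
        ~0 over the central 80% of the gap."""
        spec = transmission_spectrum(device, npoints=300)
        prob = spec.probability
        w = spec.omega

        def central(lo, hi):
            width = hi - lo
            return (w >= lo + 0.1 * width) & (w <= hi - 0.1 * width)

        assert np.all(prob[central(0.0, bands.omega_r)] >= 0.99)
        assert np.all(prob[central(bands.omega_q, bands.omega_p)] >= 0.99)
        assert np.all(prob[central(bands.omega_r, bands.omega_q)] <= 0.01)

    def test_invariants_on_random_disordered_devices(self):
        for seed in range(20):
            dev = disordered_device(
                DisorderRecipe(n_cells=3, mass_rel_sd=0.08, spring_rel_sd=0.08,
                               seed=seed)
            )
            spec = transmission_spectrum(dev, npoints=40)
            assert np.all(spec.trace >= 0.0)
            assert np.all(spec.probability >= 0.0)
            assert np.all(spec.probability <= 1.0)

    def test_disorder_suppresses_band_average(self, bands):
        """10% mass disorder, N = 8: band-average normalized transmission is
        strictly below the homogeneous value from the same engine."""
        grid = np.linspace(0.05, 0.95, 40) * bands.omega_r
        clean = table1_device(n_cells=8)
        noisy = disordered_device(DisorderRecipe(n_cells=8, mass_rel_sd=0.1, seed=1))
        t_clean = np.mean([transmission(clean, float(w)) for w in grid])
        t_noisy = np.mean([transmission(noisy, float(w)) for w in grid])
        assert t_noisy < t_clean

    def test_npoints_validated(self, device):
        with pytest.raises(ValueError):
            transmission_spectrum(device, npoints=5)


class TestDeviceModelSerialization:
    def test_json_round_trip(self):
        dev = disordered_device(DisorderRecipe(n_cells=3, mass_rel_sd=0.1, seed=2))
        assert DeviceModel.from_json(dev.to_json()) == dev
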