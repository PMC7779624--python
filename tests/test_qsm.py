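"""Susceptibility chain: frequency conversion, SMV/SHARP background removal,
dipole forward model, LSQR inversion and ROI quantification."""

import numpy as np
import pytest

from glymphiron.errors import ComputeError, ValidationError
from glymphiron.grids import AcquisitionParams, VolumeGrid
from glymphiron.qsm import (
    InversionParams,
    NucleusLabelMap,
    SharpParams,
    dipole_kernel,
    forward_field,
    frequency_to_ppm,
    lsqr_invert,
    phase_to_frequency,
    reference_to_mask_mean,
    roi_means,
    sharp_remove_background,
    smv_kernel,
)


def make_grid(data, voxel=(1.0, 1.0, 1.0), units="dimensionless"):
    return VolumeGrid(np.asarray(data, dtype=float), np.asarray(voxel), units=units)


class TestFrequencyConversion:
    def test_constant_phase_gives_inverse_te(self):
        phase = make_grid(np.full((8, 8, 8), 2 * np.pi), units="radians")
        acq = AcquisitionParams(te_s=11.5e-3)
        freq = phase_to_frequency(phase, acq)
        assert freq.units == "Hz"
        assert np.allclose(freq.data, 1.0 / 11.5e-3)

    def test_zero_phase_zero_frequency(self):
        phase = make_grid(np.zeros((4, 4, 4)), units="radians")
        freq = phase_to_frequency(phase, AcquisitionParams(te_s=0.01))
        assert np.all(freq.data == 0)

    def test_single_voxel_pi_at_te_10ms(self):
        data = np.zeros((6, 6, 6))
        data[3, 3, 3] = np.pi
        freq = phase_to_frequency(
            make_grid(data, units="radians"), AcquisitionParams(te_s=0.010),
            check_wraps=False,
        )
        assert freq.data[3, 3, 3] == pytest.approx(50.0)

    def test_non_finite_voxels_rejected_with_count(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = np.nan
        data[1, 1, 1] = np.inf
        with pytest.raises(ValidationError, match="2 non-finite"):
            phase_to_frequency(make_grid(data, units="radians"), AcquisitionParams())

    def test_wrapped_phase_detected(self):
        data = np.zeros((4, 4, 4))
        data[2:, :, :] = 2 * np.pi  # > pi jump between neighbours
        with pytest.raises(ValidationError, match="wrap"):
            phase_to_frequency(make_grid(data, units="radians"), AcquisitionParams())

    def test_wrong_units_rejected(self):
        with pytest.raises(ValidationError, match="radians"):
            phase_to_frequency(make_grid(np.zeros((4, 4, 4))), AcquisitionParams())

    @pytest.mark.parametrize(
        "hz,expected_ppm",
        [(127.728, 1.0), (0.0, 0.0), (0.127728, 1.0e-3)],
    )
    def test_ppm_normalisation(self, hz, expected_ppm):
        freq = make_grid(np.full((4, 4, 4), hz), units="Hz")
        acq = AcquisitionParams(b0_tesla=3.0, gamma_hz_per_tesla=42.576e6)
        ppm = frequency_to_ppm(freq, acq)
        assert ppm.units == "ppm"
        assert np.allclose(ppm.data, expected_ppm, rtol=1e-12, atol=1e-15)


class TestSmvKernel:
    def test_sums_to_one(self, unit_grid):
        for r in (1.0, 2.5, 5.0):
            k = smv_kernel(r, unit_grid)
            assert abs(k.sum() - 1.0) < 1e-9
            assert np.all(k >= 0)

    def test_unit_radius_support_is_centre_plus_six_neighbours(self, unit_grid):
        k = smv_kernel(1.0, unit_grid)
        support = np.argwhere(k > 0)
        assert len(support) == 7
        centre = np.array(unit_grid.shape) // 2
        offsets = np.abs(support - centre).sum(axis=1)
        assert offsets.max() == 1  # 6-connected neighbourhood plus centre

    def test_constant_field_preserved_under_convolution(self, unit_grid):
        from scipy import fft as sfft

        k = smv_kernel(3.0, unit_grid)
        wrapped = np.fft.ifftshift(k)
        const = np.full(unit_grid.shape, 2.5)
        out = sfft.irfftn(
            sfft.rfftn(wrapped) * sfft.rfftn(const), s=unit_grid.shape
        )
        assert np.allclose(out, 2.5, atol=1e-10)

    def test_subvoxel_radius_rejected(self, unit_grid):
        with pytest.raises(ValidationError, match="smaller than one voxel"):
            smv_kernel(0.5, unit_grid)


class TestDipoleKernel:
    def test_axis_values(self, unit_grid):
        d = dipole_kernel(unit_grid)
        assert d[0, 0, 1] == pytest.approx(-2.0 / 3.0)  # k along B0
        assert d[1, 0, 0] == pytest.approx(1.0 / 3.0)   # k orthogonal to B0
        assert d[1, 1, 1] == pytest.approx(0.0, abs=1e-15)  # magic angle
        assert d[0, 0, 0] == 0.0

    def test_d_at_zero_honoured(self, unit_grid):
        assert dipole_kernel(unit_grid, d_at_zero=0.3)[0, 0, 0] == 0.3


class TestForwardField:
    def test_zero_chi_zero_field(self, unit_grid):
        f = forward_field(unit_grid.with_data(np.zeros(unit_grid.shape), "ppm"))
        assert np.all(f.data == 0)

    def test_linearity(self, unit_grid):
        rng = np.random.default_rng(7)
        c1 = unit_grid.with_data(rng.standard_normal(unit_grid.shape), "ppm")
        c2 = unit_grid.with_data(rng.standard_normal(unit_grid.shape), "ppm")
        lhs = forward_field(c1.with_data(2.0 * c1.data - 3.0 * c2.data)).data
        rhs = 2.0 * forward_field(c1).data - 3.0 * forward_field(c2).data
        scale = np.abs(rhs).max()
        assert np.abs(lhs - rhs).max() < 1e-10 * scale

    def test_uniform_sphere_interior_field_vanishes(self):
        n = 64
        x, y, z = np.ogrid[:n, :n, :n]
        grid = VolumeGrid(np.zeros((n, n, n)))
        centre_fields = []
        for r in (4, 8, 16):
            chi = ((x - n // 2) ** 2 + (y - n // 2) ** 2 + (z - n // 2) ** 2
                   <= r * r).astype(float) * 0.1
            f = forward_field(grid.with_data(chi, "ppm"))
            centre_fields.append(abs(f.data[n // 2, n // 2, n // 2]))
        # Lorentz-corrected interior field of a uniform sphere is zero
        assert all(v < 0.02 * 0.1 for v in centre_fields)
        assert all(b <= a + 1e-12 for a, b in zip(centre_fields, centre_fields[1:]))

    def test_single_voxel_matches_independent_spectral_oracle(self):
        # brute-force oracle: full complex FFT with an independently built kernel
        n = 16
        chi = np.zeros((n, n, n))
        chi[n // 2, n // 2, n // 2] = 1.0
        ks = np.fft.fftfreq(n)
        kx, ky, kz = np.meshgrid(ks, ks, ks, indexing="ij")
        k2 = kx**2 + ky**2 + kz**2
        with np.errstate(invalid="ignore"):
            d_oracle = 1.0 / 3.0 - kz**2 / k2
        d_oracle[0, 0, 0] = 0.0
        expected = np.real(np.fft.ifftn(d_oracle * np.fft.fftn(chi)))
        f = forward_field(VolumeGrid(chi).with_data(chi, "ppm"))
        assert np.abs(f.data - expected).max() < 1e-12


def _harmonic_field(shape, coeffs):
    a, b, c, d = coeffs
    x, y, z = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    return a + b * x + c * y + d * z


class TestSharp:
    @pytest.mark.parametrize("coeffs", [(1.0, 0.02, 0.0, 0.0), (0.5, 0.01, -0.03, 0.02)])
    def test_annihilates_harmonic_fields(self, coeffs):
        n = 48
        x, y, z = np.ogrid[:n, :n, :n]
        mask = ((x - n / 2) ** 2 + (y - n / 2) ** 2 + (z - n / 2) ** 2
                <= (n / 2 - 2) ** 2)
        field = _harmonic_field((n, n, n), coeffs)
        span = np.ptp(field[mask])
        grid = VolumeGrid(field)
        local, eroded = sharp_remove_background(
            grid, VolumeGrid(mask.astype(np.uint8), units="mask")
        )
        erb = eroded.data.astype(bool)
        assert erb.any()
        assert np.abs(local.data[erb]).max() < 1e-6 * span
        assert np.all(local.data[~erb] == 0)

    def test_removes_field_of_outside_source(self, full_phantom, nucleus_phantom):
        # background-only field = full phantom minus its nuclei contribution
        bg_chi = full_phantom.chi.with_data(
            np.where(full_phantom.mask.data > 0, 0.0, full_phantom.chi.data)
        )
        bg_field = forward_field(bg_chi)
        mask = full_phantom.mask
        span = np.ptp(bg_field.data[mask.data.astype(bool)])
        local, eroded = sharp_remove_background(bg_field, mask)
        erb = eroded.data.astype(bool)
        # tolerance frozen from the measured oracle (max residual ~2.7% of span)
        assert np.abs(local.data[erb]).max() < 0.05 * span

    def test_preserves_internal_source_energy(self, nucleus_phantom):
        field = forward_field(nucleus_phantom.chi)
        local, eroded = sharp_remove_background(field, nucleus_phantom.mask)
        erb = eroded.data.astype(bool)
        retained = np.sum(local.data[erb] ** 2) / np.sum(field.data[erb] ** 2)
        assert retained >= 0.90

    def test_empty_erosion_is_reported(self):
        mask = np.zeros((16, 16, 16), dtype=np.uint8)
        mask[7:9, 7:9, 7:9] = 1
        with pytest.raises(ComputeError, match="erod"):
            sharp_remove_background(
                VolumeGrid(np.zeros((16, 16, 16))),
                VolumeGrid(mask, units="mask"),
                SharpParams(radii_mm=(5.0,), erosion=4),
            )

    def test_param_validation(self):
        with pytest.raises(ValidationError):
            SharpParams(radii_mm=())
        with pytest.raises(ValidationError):
            SharpParams(radii_mm=(1.0, 2.0))  # ascending
        with pytest.raises(ValidationError):
            SharpParams(svd_threshold=1.5)


class TestLsqrInversion:
    def test_zero_field_gives_zero_chi(self, unit_grid):
        mask = VolumeGrid(np.ones(unit_grid.shape, dtype=np.uint8), units="mask")
        chi = lsqr_invert(unit_grid.with_data(np.zeros(unit_grid.shape), "ppm"), mask)
        assert np.all(chi.data == 0)

    def test_nucleus_phantom_round_trip(self, nucleus_phantom):
        from scipy import ndimage

        ph = nucleus_phantom
        field = forward_field(ph.chi)
        er = ndimage.binary_erosion(ph.mask.data.astype(bool), iterations=1)
        erg = VolumeGrid(er.astype(np.uint8), ph.mask.voxel_size, units="mask")
        chi = lsqr_invert(field, erg, InversionParams(), support=ph.mask)
        chi = reference_to_mask_mean(chi, ph.mask)
        means = roi_means(chi, ph.labels)
        truth = np.array([ph.truth_chi_e3[n] for n in means])
        meas = np.array([m * 1e3 for m, _ in means.values()])
        assert np.corrcoef(truth, meas)[0, 1] >= 0.99
        assert np.all(np.abs(meas - truth) / truth <= 0.10)

    def test_noisy_sphere_recovered_within_ten_percent(self):
        n = 48
        x, y, z = np.ogrid[:n, :n, :n]
        sphere = ((x - 24) ** 2 + (y - 24) ** 2 + (z - 24) ** 2) <= 36
        chi_true = sphere.astype(float) * 0.09
        grid = VolumeGrid(np.zeros((n, n, n)))
        field = forward_field(grid.with_data(chi_true, "ppm"))
        rng = np.random.default_rng(11)
        noisy = field.data + rng.standard_normal(field.shape) * 0.01 * np.ptp(field.data)
        brain = ((x - 24) ** 2 + (y - 24) ** 2 + (z - 24) ** 2) <= 20**2
        maskg = VolumeGrid(brain.astype(np.uint8), units="mask")
        chi = lsqr_invert(field.with_data(noisy), maskg)
        chi = reference_to_mask_mean(chi, maskg)
        recovered = chi.data[sphere].mean()
        assert recovered == pytest.approx(0.09, rel=0.10)


class TestRoiMeans:
    def _labels(self):
        lab = np.zeros((8, 8, 8), dtype=np.int16)
        lab[1:3, 1:3, 1:3] = 1
        lab[5:7, 5:7, 5:7] = 2
        return NucleusLabelMap(lab, {1: "putamen", 2: "thalamus"})

    def test_constant_map_gives_constant_means(self):
        labels = self._labels()
        chi = VolumeGrid(np.full((8, 8, 8), 0.042), units="ppm")
        means = roi_means(chi, labels)
        assert means["putamen"] == (pytest.approx(0.042), 8)
        assert means["thalamus"] == (pytest.approx(0.042), 8)

    def test_prescribed_regions_recovered_exactly(self):
        labels = self._labels()
        chi = np.zeros((8, 8, 8))
        chi[labels.labels == 1] = 0.088
        chi[labels.labels == 2] = 0.045
        means = roi_means(VolumeGrid(chi, units="ppm"), labels)
        assert means["putamen"][0] == 0.088
        assert means["thalamus"][0] == 0.045

    def test_invariant_to_label_permutation(self):
        labels = self._labels()
        swapped = NucleusLabelMap(
            np.where(labels.labels == 1, 9, np.where(labels.labels == 2, 4, 0)).astype(np.int16),
            {9: "putamen", 4: "thalamus"},
        )
        rng = np.random.default_rng(3)
        chi = VolumeGrid(rng.standard_normal((8, 8, 8)), units="ppm")
        assert roi_means(chi, labels) == roi_means(chi, swapped)

    def test_empty_nucleus_named_in_error(self):
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        lab[0, 0, 0] = 1
        labels = NucleusLabelMap(lab, {1: "putamen", 2: "red nucleus"})
        with pytest.raises(ValidationError, match="red nucleus"):
            roi_means(VolumeGrid(np.zeros((4, 4, 4)), units="ppm"), labels)

    def test_legend_validation(self):
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        lab[0, 0, 0] = 3
        with pytest.raises(ValidationError, match="absent from the legend"):
            NucleusLabelMap(lab, {1: "putamen"})
        with pytest.raises(ValidationError, match="unknown"):
            NucleusLabelMap(np.zeros((4, 4, 4), dtype=np.int16), {1: "hippocampus"})


class TestFullChain:
    def test_phantom_through_whole_chain(self, full_phantom):
        from glymphiron.pipeline import reconstruct_susceptibility

        ph = full_phantom
        chi, eroded = reconstruct_susceptibility(ph.phase, ph.mask, ph.acq)
        means = roi_means(chi, ph.labels)
        for name, (mean, _) in means.items():
            truth = ph.truth_chi_e3[name]
            # reconstruction tolerance frozen from the measured noiseless chain
            assert abs(mean * 1e3 - truth) / truth <= 0.15, name
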