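"""Co-processing, region extraction and peak heights."""

import numpy as np
import pytest

from nosco.binding import BindingParameters, TitrationScheme
from nosco.schedules import make_complementary_schedules
from nosco.simulate import (
    AcquisitionParams,
    PeakGroundTruth,
    PseudoThreeDData,
    simulate_nosco_dataset,
    simulate_reference_fid,
)
from nosco.spectral import (
    assemble_fid,
    coprocess,
    extract_peak_region,
    isolated_fid,
    peak_height,
    process_fid,
)


def small_dataset(dnu=(0.0, 0.0), kd=9.0, dilution=None, n1=32, n2=32):
    acq = AcquisitionParams(
        n1=n1, n2=n2, sw1=400.0, sw2=400.0,
        dilution_factors=dilution, seed=5,
    )
    scheme = TitrationScheme(x_values=[1.0, 2.0, 4.0, 8.0], c_p=0.5)
    ss = make_complementary_schedules(n1, 4, seed=5, x_values=scheme.x_values)
    peak = PeakGroundTruth("p", 50.0, -60.0, dnu[0], dnu[1])
    binding = {"p": BindingParameters(kd, dnu[0], dnu[1])}
    data = simulate_nosco_dataset([peak], acq, scheme, ss, binding)
    ref = simulate_reference_fid([peak], acq)
    return peak, acq, data, ref


class TestCoprocess:
    def test_stationary_peak_matches_reference_height(self):
        peak, acq, data, ref = small_dataset()
        spec = coprocess(data, zero_fill=4, window=None)
        ref_spec = process_fid(ref, acq.sw1, acq.sw2, zero_fill=4, window=None)
        assert peak_height(spec) == pytest.approx(
            peak_height(ref_spec), rel=1e-9
        )

    def test_dilution_compensation_restores_reference(self):
        dil = np.linspace(1.0, 0.6, 4)
        peak, acq, data, ref = small_dataset(dilution=dil)
        fid = assemble_fid(data, compensate_dilution=True)
        assert np.allclose(fid, ref, atol=1e-12)

    def test_smeared_peak_is_lower_than_reference(self):
        peak, acq, data, ref = small_dataset(dnu=(30.0, -40.0))
        spec = coprocess(data, zero_fill=4, window=None)
        ref_spec = process_fid(ref, acq.sw1, acq.sw2, zero_fill=4, window=None)
        assert peak_height(spec) < 0.95 * peak_height(ref_spec)

    def test_smearing_monotone_in_csp_amplitude(self):
        heights = []
        for a in (0.0, 10.0, 20.0, 40.0):
            _, acq, data, _ = small_dataset(dnu=(a, a))
            heights.append(peak_height(coprocess(data, window=None)))
        assert all(h1 >= h2 - 1e-9 for h1, h2 in zip(heights, heights[1:]))

    def test_linearity(self):
        peak, acq, data, ref = small_dataset(dnu=(20.0, 10.0))
        spec1 = coprocess(data, zero_fill=2, window=None)
        data.values = 3.0 * data.values
        spec3 = coprocess(data, zero_fill=2, window=None)
        assert np.allclose(spec3.values, 3.0 * spec1.values, atol=1e-9)

    def test_all_zero_input(self):
        peak, acq, data, ref = small_dataset()
        data.values[:] = 0
        spec = coprocess(data, window=None)
        assert np.all(spec.values == 0)

    def test_undersampled_data_rejected(self):
        peak, acq, data, _ = small_dataset()
        ss = make_complementary_schedules(
            32, 4, seed=5, mode="undersampled", level=0.15,
            x_values=[1.0, 2.0, 4.0, 8.0],
        )
        scheme = TitrationScheme(x_values=[1.0, 2.0, 4.0, 8.0], c_p=0.5)
        under = simulate_nosco_dataset(
            [peak], acq, scheme, ss,
            {"p": BindingParameters(9.0, 0.0, 0.0)},
        )
        with pytest.raises(ValueError, match="partition"):
            coprocess(under)

    def test_axis_convention_peak_at_synthesis_frequency(self):
        peak, acq, data, ref = small_dataset()
        spec = process_fid(ref, acq.sw1, acq.sw2, zero_fill=4, window=None)
        i, j = np.unravel_index(np.argmax(spec.values.real), spec.values.shape)
        assert spec.axis1[i] == pytest.approx(peak.nu_n0, abs=spec.df1)
        assert spec.axis2[j] == pytest.approx(peak.nu_h0, abs=spec.df2)


class TestPeakRegion:
    def test_whole_spectrum_round_trip(self):
        peak, acq, data, ref = small_dataset(dnu=(20.0, -15.0))
        spec = coprocess(data, zero_fill=2, window=None)
        # an even FFT grid spans [-SW/2, SW/2 - df]: center the window on
        # -df/2 so it covers every bin exactly
        full = extract_peak_region(
            spec, (-spec.df1 / 2, -spec.df2 / 2),
            ((acq.sw1 - spec.df1) / 2, (acq.sw2 - spec.df2) / 2),
        )
        fid = assemble_fid(data)
        assert np.allclose(full.time_domain[: acq.n1, : acq.n2], fid, atol=1e-9)
        # zero-fill padding region is empty
        assert np.abs(full.time_domain[acq.n1 :, :]).max() < 1e-9

    def test_region_excluding_peak_has_little_energy(self):
        peak, acq, data, ref = small_dataset()
        spec = coprocess(data, zero_fill=2, window=None)
        off = extract_peak_region(spec, (-100.0, 100.0), (40.0, 40.0))
        fid = assemble_fid(data)
        # band energy via Parseval: sum |sub|^2 / (Nz1 Nz2)
        nz1, nz2 = spec.values.shape
        e_off = np.sum(np.abs(off.region_values) ** 2) / (nz1 * nz2)
        e_fid = np.sum(np.abs(fid) ** 2)
        assert e_off < 1e-3 * e_fid

    def test_window_shift_applies_linear_phase(self):
        # shifting the window by whole bins multiplies the time-domain
        # signal by the Fourier shift phase, up to the small content
        # difference at the window edges (sinc tails)
        peak, acq, data, ref = small_dataset()
        # cos2 apodization keeps the peak's energy inside the window, so
        # the two windows hold essentially identical content
        spec = coprocess(data, zero_fill=2, window="cos2")
        hw = 20 * spec.df1  # peak well inside, edge bins negligible
        r1 = extract_peak_region(spec, (peak.nu_n0, peak.nu_h0), (hw, hw))
        shift_bins = 3
        c2 = (peak.nu_n0 + shift_bins * spec.df1, peak.nu_h0)
        r2 = extract_peak_region(spec, c2, (hw, hw))
        m = r1.time_domain.shape[0]
        phase = np.exp(-2j * np.pi * shift_bins * np.arange(m) / m)
        err = np.linalg.norm(
            r2.time_domain - r1.time_domain * phase[:, None]
        ) / np.linalg.norm(r1.time_domain)
        assert err < 0.05

    def test_clipping_window_rejected(self):
        peak, acq, data, ref = small_dataset()
        spec = coprocess(data, zero_fill=2, window=None)
        with pytest.raises(ValueError, match="clips"):
            extract_peak_region(spec, (150.0, 0.0), (100.0, 50.0))

    def test_two_peak_region_flagged(self):
        acq = AcquisitionParams(n1=32, n2=32, sw1=400.0, sw2=400.0)
        peaks = [
            PeakGroundTruth("a", 30.0, 0.0),
            PeakGroundTruth("b", -30.0, 0.0),
        ]
        ref = simulate_reference_fid(peaks, acq)
        spec = process_fid(ref, acq.sw1, acq.sw2, zero_fill=2, window="cos2")
        with pytest.warns(RuntimeWarning, match="local maxima"):
            region = extract_peak_region(spec, (0.0, 0.0), (80.0, 60.0))
        assert region.multiple_maxima

    def test_band_isolation_recovers_single_peak_fid(self):
        acq = AcquisitionParams(n1=32, n2=32, sw1=400.0, sw2=400.0)
        peaks = [
            PeakGroundTruth("a", 80.0, 90.0, r2_n=8.0, r2_h=8.0),
            PeakGroundTruth("b", -90.0, -100.0, r2_n=8.0, r2_h=8.0),
        ]
        ref = simulate_reference_fid(peaks, acq)
        spec = process_fid(ref, acq.sw1, acq.sw2, zero_fill=4, window=None)
        region = extract_peak_region(spec, (80.0, 90.0), (115.0, 105.0))
        only_a = simulate_reference_fid([peaks[0]], acq)
        iso = isolated_fid(spec, region, (acq.n1, acq.n2))
        # band-limited isolation: close to the lone-peak FID up to the
        # truncated out-of-band sinc tails
        err = np.linalg.norm(iso - only_a) / np.linalg.norm(only_a)
        assert err < 0.15


class TestPeakHeight:
    def test_zero_matrix(self):
        assert peak_height(np.zeros((4, 4), dtype=complex)) == 0.0

    def test_height_linear_in_amplitude(self):
        acq = AcquisitionParams(n1=32, n2=32, sw1=400.0, sw2=400.0)
        h = []
        for a in (1.0, 2.0):
            peak = PeakGroundTruth("p", 50.0, -60.0, amplitude=a)
            fid = simulate_reference_fid([peak], acq)
            h.append(peak_height(process_fid(fid, 400.0, 400.0, window=None)))
        assert h[1] == pytest.approx(2 * h[0], rel=1e-12)

    def test_height_stable_under_extra_zero_fill(self):
        # on-grid peak: factor 4 and 8 agree within 1%
        acq = AcquisitionParams(n1=32, n2=32, sw1=400.0, sw2=400.0)
        peak = PeakGroundTruth("p", 50.0, -62.5, amplitude=1.0)
        fid = simulate_reference_fid([peak], acq)
        h4 = peak_height(process_fid(fid, 400, 400, zero_fill=4, window=None))
        h8 = peak_height(process_fid(fid, 400, 400, zero_fill=8, window=None))
        assert h8 == pytest.approx(h4, rel=0.01)

    def test_magnitude_mode_geq_real(self):
        acq = AcquisitionParams(n1=16, n2=16, sw1=400.0, sw2=400.0)
        fid = simulate_reference_fid([PeakGroundTruth("p", 33.0, -47.0)], acq)
        spec = process_fid(fid, 400, 400, window=None)
        assert peak_height(spec, "magnitude") >= peak_height(spec, "real")

    def test_parseval_region_energy_bounded(self):
        peak, acq, data, ref = small_dataset()
        spec = coprocess(data, zero_fill=2, window=None)
        region = extract_peak_region(spec, (peak.nu_n0, peak.nu_h0), (50.0, 50.0))
        fid = assemble_fid(data)
        # energy in the region band cannot exceed the total signal energy
        e_region = np.sum(np.abs(region.region_values) ** 2) / region.parent_shape[0] / region.parent_shape[1]
        e_total = np.sum(np.abs(np.fft.fft2(np.pad(fid, ((0, acq.n1), (0, acq.n2))))) ** 2) / (2 * acq.n1) / (2 * acq.n2)
        assert e_region <= e_total * (1 + 1e-12)
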