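"""Calibration-curve I/O, single-date calibration, and interval queries."""

import io
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calphase import (
    CalendarPDF,
    CalibrationError,
    CurveFormatError,
    Determination,
    apply_reservoir_offset,
    calibrate,
    curve_lookup,
    gen_calibration_curve,
    hpd_interval,
    mix_calibration,
    read_calibration_curve,
    read_pdf_csv,
    round_interval,
    write_calibration_curve,
    write_pdf_csv,
)


class TestCurveIO:
    def test_two_knot_comma_stream_interpolates_midpoint(self):
        curve = read_calibration_curve("0,100,5\n10,110,5")
        assert curve.theta.size == 2
        mu, sig = curve_lookup(curve, 5.0)
        assert mu == pytest.approx(105.0)
        assert sig == pytest.approx(5.0)

    def test_comment_and_blank_lines_ignored(self):
        with_comments = read_calibration_curve("# header\n\n0,100,5\n10,110,5\n")
        plain = read_calibration_curve("0,100,5\n10,110,5")
        assert np.array_equal(with_comments.theta, plain.theta)
        assert np.array_equal(with_comments.mu, plain.mu)

    def test_tab_dialect_and_unsorted_input(self):
        curve = read_calibration_curve("10\t110\t5\n0\t100\t5", dialect="tab")
        assert list(curve.theta) == [0.0, 10.0]

    @pytest.mark.parametrize(
        "text,err",
        [
            ("0,100,5", CurveFormatError),  # single knot
            ("0,100\n10,110,5", CurveFormatError),  # short line
            ("0,abc,5\n10,110,5", CurveFormatError),  # non-numeric
            ("0,100,5\n0,110,5", CurveFormatError),  # duplicate theta
        ],
    )
    def test_malformed_input_raises(self, text, err):
        with pytest.raises(err):
            read_calibration_curve(text)

    def test_parse_error_reports_line_number(self):
        with pytest.raises(CurveFormatError, match="line 2"):
            read_calibration_curve("0,100,5\nbroken\n10,110,5")

    @pytest.mark.parametrize("dialect", ["comma", "tab"])
    def test_fifty_knot_round_trip_lossless(self, dialect):
        curve = gen_calibration_curve((6000, 5000), knot_step=20, wiggle_sd=30,
                                      error_level=10, seed=7)
        assert curve.theta.size >= 50
        buf = io.StringIO()
        write_calibration_curve(curve, buf, dialect=dialect)
        back = read_calibration_curve(io.StringIO(buf.getvalue()), dialect=dialect)
        assert np.allclose(back.theta, curve.theta, atol=1e-9)
        assert np.allclose(back.mu, curve.mu, atol=1e-9)
        assert np.allclose(back.sigma, curve.sigma, atol=1e-9)


class TestCurveLookup:
    def test_midpoint_interpolation(self):
        curve = read_calibration_curve("1000,900,10\n1100,1000,20")
        assert curve_lookup(curve, 1050.0) == pytest.approx((950.0, 15.0))

    def test_knot_values_exact(self):
        curve = read_calibration_curve("1000,900,10\n1100,1000,20")
        assert curve_lookup(curve, 1100.0) == (1000.0, 20.0)

    def test_out_of_range_raises(self, identity_curve):
        with pytest.raises(CalibrationError):
            curve_lookup(identity_curve, 4000.0)

    def test_matches_two_point_formula_on_random_draws(self, wiggly_curve):
        rng = np.random.default_rng(3)
        thetas = rng.uniform(wiggly_curve.theta_min, wiggly_curve.theta_max, 1000)
        kn_t, kn_mu, kn_sig = wiggly_curve.theta, wiggly_curve.mu, wiggly_curve.sigma
        for theta in thetas:
            j = np.searchsorted(kn_t, theta)
            j = max(j, 1)
            w = (theta - kn_t[j - 1]) / (kn_t[j] - kn_t[j - 1])
            mu_ref = kn_mu[j - 1] + w * (kn_mu[j] - kn_mu[j - 1])
            sig_ref = kn_sig[j - 1] + w * (kn_sig[j] - kn_sig[j - 1])
            mu, sig = curve_lookup(wiggly_curve, theta)
            assert abs(mu - mu_ref) < 1e-9
            assert abs(sig - sig_ref) < 1e-9
            # scalar fast path agrees with the vector path
            mu_s, sig_s = wiggly_curve.lookup_scalar(theta)
            assert abs(mu_s - mu) < 1e-9
            assert abs(sig_s - sig) < 1e-9


class TestReservoirOffset:
    def test_positive_offset_subtracted_and_error_propagated(self):
        det = Determination("S", 5000, 40, reservoir="marine", delta_r=(100, 30))
        out = apply_reservoir_offset(det)
        assert out.cra == 4900
        assert out.sigma == pytest.approx(50.0)
        assert det.cra == 5000  # original unchanged

    def test_zero_offset_identity(self):
        det = Determination("S", 5000, 40, reservoir="marine", delta_r=(0, 0))
        out = apply_reservoir_offset(det)
        assert (out.cra, out.sigma) == (5000, 40)

    def test_negative_offset(self):
        det = Determination("S", 5000, 40, reservoir="marine", delta_r=(-150, 25))
        out = apply_reservoir_offset(det)
        assert out.cra == 5150
        assert out.sigma == pytest.approx(math.hypot(40, 25))

    def test_atmospheric_determination_rejected(self):
        with pytest.raises(ValueError):
            apply_reservoir_offset(Determination("S", 5000, 40), (100, 30))

    def test_delta_r_required_iff_marine(self):
        with pytest.raises(ValueError):
            Determination("S", 5000, 40, reservoir="marine")
        with pytest.raises(ValueError):
            Determination("S", 5000, 40, delta_r=(100, 30))


def _brute_force_calibration(det, curve, grid, fine_step=0.1):
    """0.1-yr Riemann normalisation reference, re-binned to the grid cells."""
    res = grid[1] - grid[0]
    dens = np.zeros_like(grid)
    for i, centre in enumerate(grid):
        fine = np.arange(centre - res / 2, centre + res / 2, fine_step) + fine_step / 2
        fine = fine[(fine >= curve.theta_min) & (fine <= curve.theta_max)]
        if fine.size == 0:
            continue
        mu = np.interp(fine, curve.theta, curve.mu)
        sig = np.interp(fine, curve.theta, curve.sigma)
        var = det.sigma**2 + sig**2
        dens[i] = (np.exp(-0.5 * (det.cra - mu) ** 2 / var) / np.sqrt(var)).sum()
    return dens / dens.sum()


class TestCalibrate:
    def test_flat_curve_gives_uniform_pdf(self):
        theta = np.arange(9000.0, 11000.0, 50.0)
        curve = read_calibration_curve(
            "\n".join(f"{t},10000,0.01" for t in theta)
        )
        pdf = calibrate(Determination("X", 10000, 50), curve)
        ratio = pdf.mass.max() / pdf.mass.min()
        assert ratio < 1 + 1e-6

    def test_identity_curve_reproduces_measurement_error(self, identity_curve):
        pdf = calibrate(Determination("X", 10000, 50), identity_curve, grid_resolution=1.0)
        inside = pdf.mass[(pdf.grid >= 9900) & (pdf.grid <= 10100)].sum()
        assert inside == pytest.approx(0.954, abs=0.002)
        assert pdf.mean() == pytest.approx(10000, abs=1)

    def test_mass_normalised(self, wiggly_curve):
        pdf = calibrate(Determination("X", 12000, 60), wiggly_curve)
        assert pdf.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_date_outside_curve_raises(self, identity_curve):
        with pytest.raises(CalibrationError):
            calibrate(Determination("X", 60000, 50), identity_curve)

    def test_matches_fine_grid_oracle_on_wiggly_curve(self):
        curve = gen_calibration_curve((13000, 11000), 20, 25, 10, seed=9)
        det = Determination("X", 12000, 45)
        pdf = calibrate(det, curve)
        ref = _brute_force_calibration(det, curve, pdf.grid)
        assert 0.5 * np.abs(pdf.mass - ref).sum() < 1e-6

    def test_widening_sigma_never_narrows_hpd(self, identity_curve):
        widths = []
        for sigma in (30, 60, 120, 240):
            pdf = calibrate(Determination("X", 12000, sigma), identity_curve)
            spans = hpd_interval(pdf, 0.954)
            widths.append(sum(o - y for o, y in spans))
        assert all(b >= a for a, b in itertools.pairwise(widths))


class TestMixCalibration:
    def test_identical_curves_equal_plain_calibration(self, wiggly_curve, det):
        d = det(12000)
        mixed = mix_calibration(d, wiggly_curve, wiggly_curve)
        plain = calibrate(d, wiggly_curve)
        # align supports before comparing
        common = np.intersect1d(mixed.grid, plain.grid)
        ma = mixed.mass[np.isin(mixed.grid, common)]
        pa = plain.mass[np.isin(plain.grid, common)]
        assert 0.5 * np.abs(ma - pa).sum() < 1e-9

    def test_offset_curves_match_dense_quadrature(self, det):
        north = gen_calibration_curve((14000, 10000), 20, 15, 10, seed=5)
        south = gen_calibration_curve((14000, 10000), 20, 15, 10, seed=5, offset=40)
        d = det(12000)
        pdf = mix_calibration(d, north, south)
        # 1001-point Riemann quadrature over the mixing fraction, with cell
        # masses integrated on an independent 0.2-yr sub-grid
        grid = pdf.grid
        res = pdf.resolution
        k = 25
        offsets = (np.arange(k) + 0.5) / k * res - 0.5 * res
        fine = (grid[:, None] + offsets[None, :]).ravel()
        mu_n = np.interp(fine, north.theta, north.mu)
        mu_s = np.interp(fine, south.theta, south.mu)
        s_n = np.interp(fine, north.theta, north.sigma)
        s_s = np.interp(fine, south.theta, south.sigma)
        dens = np.zeros_like(fine)
        for m in (np.arange(1001) + 0.5) / 1001:
            mu = m * mu_n + (1 - m) * mu_s
            sig = m * s_n + (1 - m) * s_s
            var = d.sigma**2 + sig**2
            dens += np.exp(-0.5 * (d.cra - mu) ** 2 / var) / np.sqrt(var)
        dens = dens.reshape(grid.size, k).mean(axis=1)
        dens /= dens.sum()
        assert 0.5 * np.abs(pdf.mass - dens).sum() < 1e-4


class TestHPD:
    def test_normal_pdf_954_interval(self, normal_pdf):
        pdf = normal_pdf(10000, 50, resolution=1.0)
        (old, young), = hpd_interval(pdf, 0.954)
        assert old == pytest.approx(10098, abs=2)
        assert young == pytest.approx(9902, abs=2)

    def test_equal_point_masses_both_included(self):
        pdf = CalendarPDF(np.array([100.0, 200.0]), np.array([0.5, 0.5]),
                          resolution=100.0)
        spans = hpd_interval(pdf, 0.954)
        included = {g for old, young in spans for g in (old, young)}
        assert included == {100.0, 200.0}

    def test_level_validation(self, normal_pdf):
        with pytest.raises(ValueError):
            hpd_interval(normal_pdf(10000), 1.2)

    def test_bimodal_matches_exhaustive_cell_search(self):
        rng = np.random.default_rng(8)
        grid = np.arange(0.0, 250.0, 5.0)  # 50 cells
        mass = np.exp(-0.5 * ((grid - 60) / 20) ** 2) + 0.7 * np.exp(
            -0.5 * ((grid - 180) / 15) ** 2
        )
        mass += 0.01 * rng.random(grid.size)
        mass /= mass.sum()
        pdf = CalendarPDF(grid, mass, resolution=5.0)
        for level in (0.682, 0.954):
            spans = hpd_interval(pdf, level)
            chosen = {
                g for old, young in spans
                for g in grid[(grid >= young) & (grid <= old)]
            }
            # oracle: smallest cell count reaching the level (greedy on sorted
            # masses is optimal for the minimal-cardinality cover)
            order = np.argsort(mass)[::-1]
            k = int(np.searchsorted(np.cumsum(mass[order]), level)) + 1
            assert len(chosen) == k
            assert mass[np.isin(grid, sorted(chosen))].sum() >= level


class TestRoundInterval:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((16663, 15907), (16660, 15910)),
            ((13750, 12830), (13750, 12830)),
            ((12345, 12335), (12350, 12330)),  # half-way rounds outward
        ],
    )
    def test_examples(self, interval, expected):
        assert round_interval(interval) == expected

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            round_interval((12000, 13000))

    @given(
        older=st.floats(0, 50000, allow_nan=False),
        width=st.floats(0, 5000, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_rounded_endpoints_are_multiples_and_close(self, older, width):
        old_r, young_r = round_interval((older, older - width))
        assert old_r % 10 == pytest.approx(0, abs=1e-6)
        assert young_r % 10 == pytest.approx(0, abs=1e-6)
        assert abs(old_r - older) <= 5 + 1e-6
        assert abs(young_r - (older - width)) <= 5 + 1e-6
        assert old_r >= young_r


class TestPdfCsv:
    def test_round_trip(self, normal_pdf):
        pdf = normal_pdf(12345, 60)
        buf = io.StringIO()
        write_pdf_csv(pdf, buf)
        back = read_pdf_csv(io.StringIO(buf.getvalue()))
        assert np.allclose(back.grid, pdf.grid)
        assert np.allclose(back.mass, pdf.mass, atol=1e-10)
        assert back.resolution == pdf.resolution
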