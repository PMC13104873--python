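"""Curvature correction, profile-model fitting, integration, concentrations."""

import numpy as np
import pytest
from scipy.integrate import quad

from memquant import profiles as pr
from memquant.simulate import CellGroundTruth


def gauss(x, A, mu, sigma):
    return A * np.exp(-((mu - x) ** 2) / (2.0 * sigma**2))


def sigmoid(x, L, U, B, C):
    return L + (U - L) / (1.0 + (x / C) ** B)


def make_region(truth: CellGroundTruth, t_min=-10.0, noise=None, seed=0):
    """Receptor and arrestin cross-section regions straight from the model."""
    h, w = truth.shape
    shifts = truth.row_shifts()
    x0 = np.arange(1, w + 1, dtype=float)
    rec = np.empty((h, w))
    arr = np.empty((h, w))
    for r in range(h):
        xe = np.clip(x0 - shifts[r], 0.5, None)
        rec[r] = truth.receptor_profile(xe)
        arr[r] = truth.arrestin_profile(xe, t_min)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        rec, arr = rng.poisson(rec).astype(float), rng.poisson(arr).astype(float)
    return rec, arr


@pytest.fixture(scope="module")
def cell():
    return CellGroundTruth.default(n_timepoints=6, shape=(64, 128))


class TestAlignment:
    def test_straight_membrane_zero_shifts(self, cell):
        straight = CellGroundTruth.default(n_timepoints=6, shape=(32, 128), curvature=0.0)
        rec, _ = make_region(straight)
        al = pr.build_alignment(rec)
        assert np.all(al.shifts == 0)
        assert al.mu == straight.mu

    def test_curved_membrane_aligned_to_single_column(self, cell):
        rec, _ = make_region(cell)
        al = pr.build_alignment(rec)
        aligned = pr.apply_alignment(rec, al)
        peaks = np.nanargmax(np.where(np.isfinite(aligned), aligned, -1), axis=1)
        assert np.all(peaks[al.included] == al.mu - 1)  # mu is 1-based

    def test_vesicle_row_excluded(self):
        truth = CellGroundTruth.default(
            n_timepoints=6, shape=(64, 128),
            vesicle={"row": 20, "col_offset": -8, "amplitude": 5000.0},
        )
        from memquant.simulate import _cross_section_maps
        rec = _cross_section_maps(truth, -10.0)["mEGFP"]
        al = pr.build_alignment(rec)
        assert 20 in al.excluded_rows

    def test_manual_exclusion_carried(self, cell):
        rec, _ = make_region(cell)
        al = pr.build_alignment(rec, manual_exclude=[3, 5])
        assert al.excluded_rows[3] == "manual"
        assert not al.included[5]

    def test_narrow_roi_rejected(self):
        with pytest.raises(ValueError):
            pr.build_alignment(np.ones((10, 8)))

    def test_alignment_is_row_permutation(self, cell):
        """Shifting preserves each row's pixel multiset up to dropped
        boundary pixels."""
        rec, _ = make_region(cell)
        al = pr.build_alignment(rec)
        aligned = pr.apply_alignment(rec, al)
        for r in range(rec.shape[0]):
            s = al.shifts[r]
            kept = aligned[r][np.isfinite(aligned[r])]
            src = rec[r, :rec.shape[1] - s] if s >= 0 else rec[r, -s:]
            np.testing.assert_array_equal(np.sort(kept), np.sort(src))

    def test_apply_alignment_consistency_and_identity(self, cell):
        rec, arr = make_region(cell)
        al = pr.build_alignment(rec)
        zero = pr.AlignmentMatrix(
            shifts=np.zeros(rec.shape[0], dtype=int), mu=al.mu,
            peak_columns=al.peak_columns)
        np.testing.assert_array_equal(pr.apply_alignment(rec, zero), rec)
        # arrestin membrane lands at the same aligned column (+/- 1 px)
        arr_al = pr.apply_alignment(arr, al)
        # subtract the cytoplasm ramp before locating the membrane bump
        prof = pr.column_profile(arr_al, al.included)
        bump = prof.mean_intensity - sigmoid(prof.x, cell.L, cell.U0, cell.B, cell.C)
        assert abs(int(np.nanargmax(bump)) + 1 - al.mu) <= 1

    def test_shape_mismatch_rejected(self, cell):
        rec, _ = make_region(cell)
        al = pr.build_alignment(rec)
        with pytest.raises(ValueError):
            pr.apply_alignment(rec[:-3], al)


class TestColumnProfile:
    def test_identical_rows_give_that_row(self):
        row = np.linspace(1, 12, 12)
        prof = pr.column_profile(np.tile(row, (5, 1)))
        np.testing.assert_allclose(prof.mean_intensity, row)
        assert np.all(prof.n_rows == 5)

    def test_all_missing_column_marked(self):
        region = np.ones((4, 10))
        region[:, 3] = np.nan
        prof = pr.column_profile(region)
        assert np.isnan(prof.mean_intensity[3])
        assert prof.n_rows[3] == 0

    def test_noiseless_profile_matches_model(self, cell):
        rec, _ = make_region(cell)
        al = pr.build_alignment(rec)
        prof = pr.column_profile(pr.apply_alignment(rec, al), al.included)
        offset = al.mu - cell.mu
        expect = gauss(prof.x, cell.receptor_amplitude, cell.mu + offset,
                       cell.sigma_receptor)
        ok = np.isfinite(prof.mean_intensity)
        np.testing.assert_allclose(prof.mean_intensity[ok], expect[ok], rtol=1e-3,
                                   atol=1e-3 * cell.receptor_amplitude)

    def test_no_rows_rejected(self):
        with pytest.raises(ValueError):
            pr.column_profile(np.ones((3, 10)), np.zeros(3, dtype=bool))


class TestReceptorFit:
    def test_exact_gaussian_recovered(self):
        x = np.arange(1, 41, dtype=float)
        prof = pr.Profile(x, gauss(x, 10.0, 20.0, 3.0), np.ones(40))
        fit = pr.fit_receptor_profile(prof, mu=20.0)
        assert fit.A == pytest.approx(10.0, abs=1e-6)
        assert fit.sigma == pytest.approx(3.0, abs=1e-6)

    def test_flat_profile_flagged(self):
        x = np.arange(1, 41, dtype=float)
        prof = pr.Profile(x, np.full(40, 2.0), np.ones(40))
        fit = pr.fit_receptor_profile(prof, mu=20.0)
        assert fit.A < 0.05 or "A~0" in fit.flags or "degenerate" in fit.flags

    def test_too_few_points_rejected(self):
        prof = pr.Profile(np.arange(1, 5.0), np.ones(4), np.ones(4))
        with pytest.raises(ValueError):
            pr.fit_receptor_profile(prof, mu=2.0)


class TestArrestinFit:
    TRUTH = dict(A=5.0, sigma=2.0, L=1.0, U=9.0, B=8.0, C=20.0)

    def _profile(self, mu=20.0, n=40):
        x = np.arange(1, n + 1, dtype=float)
        t = self.TRUTH
        y = gauss(x, t["A"], mu, t["sigma"]) + sigmoid(x, t["L"], t["U"], t["B"], t["C"])
        return pr.Profile(x, y, np.ones(n))

    def test_noiseless_all_parameters_recovered(self):
        fit = pr.fit_arrestin_profile(self._profile(), mu=20.0)
        for key, val in self.TRUTH.items():
            got = getattr(fit, "sigma" if key == "sigma" else key)
            assert got == pytest.approx(val, rel=1e-4), key

    def test_zero_membrane_component_limit(self):
        x = np.arange(1, 41, dtype=float)
        t = self.TRUTH
        y = sigmoid(x, t["L"], t["U"], t["B"], t["C"])
        fit = pr.fit_arrestin_profile(pr.Profile(x, y, np.ones(40)), mu=20.0)
        assert fit.A == pytest.approx(0.0, abs=1e-6)
        assert fit.U == pytest.approx(9.0, rel=1e-4)

    def test_fixed_c_at_truth_matches_free_fit(self):
        free = pr.fit_arrestin_profile(self._profile(), mu=20.0)
        fixed = pr.fit_arrestin_profile(self._profile(), mu=20.0, C=20.0)
        for key in ("A", "sigma", "L", "U", "B"):
            assert getattr(fixed, key) == pytest.approx(getattr(free, key), rel=1e-4)

    def test_poisson_recovery_within_5pct_median(self):
        """A, sigma, L, U bias under Poisson noise at the generator-default
        SNR: median over 10 seeds below 5%."""
        cell = CellGroundTruth.default(n_timepoints=6, shape=(180, 128))
        t_min = 20.0
        p = cell.arrestin_params(t_min)
        x = np.arange(1, 129, dtype=float)
        model = cell.arrestin_profile(x, t_min)
        results = {k: [] for k in ("A", "sigma", "L", "U")}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            data = rng.poisson(np.tile(model, (180, 1))).mean(axis=0)
            fit = pr.fit_arrestin_profile(
                pr.Profile(x, data, np.full(128, 180)), mu=cell.mu)
            results["A"].append(fit.A / p["A"] - 1)
            results["sigma"].append(fit.sigma / p["sigma"] - 1)
            results["L"].append((fit.L - p["L"]) / p["U"])  # L ~ 0: scale by U
            results["U"].append(fit.U / p["U"] - 1)
        for key, rel in results.items():
            assert abs(np.median(rel)) < 0.05, key


class TestFixC:
    def test_mean_of_two(self):
        fits = [pr.ProfileFit(1, 10, 2, C=19.8, model="gaussian+sigmoid"),
                pr.ProfileFit(1, 10, 2, C=20.2, model="gaussian+sigmoid")]
        assert pr.fix_C_from_untreated(fits) == pytest.approx(20.0)

    def test_single_fit_passthrough(self):
        fits = [pr.ProfileFit(1, 10, 2, C=21.5, model="gaussian+sigmoid")]
        assert pr.fix_C_from_untreated(fits) == 21.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pr.fix_C_from_untreated([])


class TestIntegration:
    def test_unit_gaussian_closed_form(self):
        fit = pr.ProfileFit(A=1.0, mu=0.0, sigma=1.0)
        assert pr.integrate_gaussian(fit) == pytest.approx(np.sqrt(2 * np.pi), abs=1e-9)

    def test_matches_quadrature_oracle(self):
        fit = pr.ProfileFit(A=10.0, mu=25.0, sigma=3.0)
        oracle, _ = quad(lambda x: gauss(x, 10.0, 25.0, 3.0), -np.inf, np.inf)
        assert pr.integrate_gaussian(fit) == pytest.approx(oracle, rel=1e-6)
        assert oracle == pytest.approx(75.19884, rel=1e-6)

    def test_linearity_in_amplitude(self):
        one = pr.integrate_gaussian(pr.ProfileFit(A=3.0, mu=0.0, sigma=2.0))
        two = pr.integrate_gaussian(pr.ProfileFit(A=6.0, mu=0.0, sigma=2.0))
        assert two == pytest.approx(2 * one)


class TestConcentration:
    def test_identity_case(self):
        assert pr.membrane_concentration(6.0, 2.0, 3.0) == pytest.approx(1.0)

    def test_inverse_in_brightness(self):
        c1 = pr.membrane_concentration(10.0, 1.0, 1.0)
        c2 = pr.membrane_concentration(10.0, 2.0, 1.0)
        assert c1 == pytest.approx(2 * c2)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            pr.membrane_concentration(10.0, 0.0, 1.0)


class TestConcentrationSeries:
    def _fits(self, times, As, model="gaussian", **kw):
        return [(t, pr.ProfileFit(A=a, mu=20.0, sigma=2.0, model=model, **kw))
                for t, a in zip(times, As)]

    def test_14_point_series_full_output(self):
        times = (np.arange(14) - 2) * 5.0
        fits = {
            "mEGFP": self._fits(times, np.full(14, 10.0)),
            "mCitrine": self._fits(times, np.linspace(1, 8, 14)),
        }
        points, trends = pr.concentration_series(
            fits, {"mEGFP": 2.0, "mCitrine": 2.0}, 1.0,
            receptor_label="mEGFP", arrestin_label="mCitrine")
        assert sum(p.protein_label == "mEGFP" for p in points) == 14
        assert sum(p.protein_label == "mCitrine" for p in points) == 14
        assert trends["mEGFP"]["model"] == "linear"
        assert trends["mCitrine"]["model"] == "cubic"
        assert len(trends["mCitrine"]["coefficients"]) == 4

    def test_constant_receptor_zero_slope(self):
        times = np.arange(10) * 5.0
        fits = {"mEGFP": self._fits(times, np.full(10, 10.0))}
        _, trends = pr.concentration_series(fits, {"mEGFP": 1.0}, 1.0,
                                            receptor_label="mEGFP")
        assert trends["mEGFP"]["coefficients"][0] == pytest.approx(0.0, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pr.concentration_series({"x": self._fits([0.0], [1.0])}, {"x": 1.0}, 1.0)


class TestArrestinTotal:
    def test_conserved_under_transfer(self):
        """Moving amplitude from the sigmoid pool into the Gaussian with the
        generator's exchange rule leaves the diagnostic unchanged."""
        base = dict(mu=20.0, sigma=2.0, L=1.0, B=8.0, C=20.0,
                    model="gaussian+sigmoid")
        f0 = pr.ProfileFit(A=0.0, U=9.0, **base)
        moved = 4.0 * 20.0  # (U drop) x C
        f1 = pr.ProfileFit(A=moved / (2.0 * np.sqrt(2 * np.pi)), U=5.0, **base)
        assert pr.arrestin_total_signal(f1) == pytest.approx(
            pr.arrestin_total_signal(f0))

    def test_requires_composite_model(self):
        with pytest.raises(ValueError):
            pr.arrestin_total_signal(pr.ProfileFit(1.0, 10.0, 2.0, model="gaussian"))
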