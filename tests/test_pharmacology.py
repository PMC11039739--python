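"""4PL fitting, Loewe expectation and synergy scoring."""

import numpy as np
import pandas as pd
import pytest

from crisprmod import pharmacology
from crisprmod.pharmacology import FourPL

LADDER = np.array([0.0, 1.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0])


def bisection_loewe(fit_a, fit_b, da, db, tol=1e-10):
    """Independent bisection solver for the Loewe response."""
    lo = max(fit_a.bottom, fit_b.bottom) + 1e-9
    hi = min(fit_a.top, fit_b.top) - 1e-9

    def g(y):
        return da / fit_a.inverse(y) + db / fit_b.inverse(y) - 1.0

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


class TestNormalizeViability:
    def test_fraction_of_vehicle_mean(self):
        raw = pd.DataFrame({"r1": [10000.0, 5000.0], "r2": [10000.0, 5000.0]},
                           index=[0.0, 100.0])
        series = pharmacology.normalize_viability(raw)
        assert series.viability.loc[100.0, "r1"] == pytest.approx(0.5)
        assert series.mean_viability().loc[0.0] == pytest.approx(1.0)

    def test_all_equal_plate(self):
        raw = pd.DataFrame({"r1": [7.0, 7.0, 7.0]}, index=[0.0, 10.0, 100.0])
        series = pharmacology.normalize_viability(raw)
        np.testing.assert_allclose(series.viability, 1.0)

    def test_zero_vehicle_rejected(self):
        raw = pd.DataFrame({"r1": [0.0, 5.0]}, index=[0.0, 10.0])
        with pytest.raises(ValueError):
            pharmacology.normalize_viability(raw)


class TestFitDoseResponse:
    def test_noiseless_recovery_on_dose_ladder(self):
        truth = FourPL(1.0, 0.0, 100.0, 1.5)
        fit = pharmacology.fit_dose_response(doses=LADDER, viability=truth(LADDER))
        assert fit.converged
        assert fit.ed50 == pytest.approx(100.0, rel=0.01)
        assert fit.hill == pytest.approx(1.5, rel=0.05)

    def test_fitted_midpoint_is_definitional_ed50(self):
        truth = FourPL(0.95, 0.1, 40.0, 2.0)
        fit = pharmacology.fit_dose_response(doses=LADDER, viability=truth(LADDER))
        midpoint = (fit.top + fit.bottom) / 2.0
        assert fit.curve(fit.ed50) == pytest.approx(midpoint, abs=1e-6)

    def test_flat_response_flagged(self):
        fit = pharmacology.fit_dose_response(doses=LADDER,
                                             viability=np.ones_like(LADDER))
        assert not fit.converged
        assert np.isnan(fit.ed50)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            pharmacology.fit_dose_response(doses=np.array([0.0, 1.0, 10.0]),
                                           viability=np.array([1.0, 0.8, 0.3]))


class TestLoeweExpected:
    fit_a = FourPL(1.0, 0.0, 100.0, 1.5)
    fit_b = FourPL(1.0, 0.0, 50.0, 1.2)

    def test_zero_dose_reduces_to_monotherapy(self):
        assert pharmacology.loewe_expected(self.fit_a, self.fit_b, 70.0, 0.0) == \
            pytest.approx(float(self.fit_a(70.0)))
        assert pharmacology.loewe_expected(self.fit_a, self.fit_b, 0.0, 35.0) == \
            pytest.approx(float(self.fit_b(35.0)))

    def test_sham_combination_axiom(self):
        for da, db in [(10.0, 20.0), (100.0, 100.0), (3.0, 300.0)]:
            expected = pharmacology.loewe_expected(self.fit_a, self.fit_a, da, db)
            assert expected == pytest.approx(float(self.fit_a(da + db)), abs=1e-7)

    def test_matches_independent_bisection_oracle(self):
        for da in (5.0, 50.0, 500.0):
            for db in (5.0, 50.0, 500.0):
                ours = pharmacology.loewe_expected(self.fit_a, self.fit_b, da, db)
                oracle = bisection_loewe(self.fit_a, self.fit_b, da, db)
                assert ours == pytest.approx(oracle, abs=1e-6)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            pharmacology.loewe_expected(self.fit_a, self.fit_b, -1.0, 1.0)


def additive_matrix(fit_a, fit_b, doses):
    grid = np.empty((len(doses), len(doses)))
    for i, da in enumerate(doses):
        for j, db in enumerate(doses):
            grid[i, j] = 100.0 * pharmacology.loewe_expected(fit_a, fit_b, da, db)
    return pd.DataFrame(grid, index=doses, columns=doses)


class TestSynergyMap:
    fit_a = FourPL(1.0, 0.2, 100.0, 1.5)
    fit_b = FourPL(1.0, 0.2, 50.0, 1.2)
    doses = np.array([0.0, 30.0, 60.0, 120.0, 250.0, 500.0, 1000.0])

    def test_exact_additivity_scores_zero(self):
        matrix = additive_matrix(self.fit_a, self.fit_b, self.doses)
        smap = pharmacology.synergy_map(matrix, self.fit_a, self.fit_b)
        assert abs(smap.overall) < 0.5
        assert smap.classification == "additive"
        assert smap.n_cells == 36

    @pytest.mark.parametrize("shift,expected_class,expected_score", [
        (15.0, "synergistic", 15.0), (-15.0, "antagonistic", -15.0),
    ])
    def test_forced_offset_recovered(self, shift, expected_class, expected_score):
        matrix = additive_matrix(self.fit_a, self.fit_b, self.doses)
        comb = (matrix.index.to_numpy()[:, None] > 0) & (matrix.columns.to_numpy() > 0)
        matrix = matrix.where(~comb, matrix - shift)
        smap = pharmacology.synergy_map(matrix, self.fit_a, self.fit_b)
        assert smap.overall == pytest.approx(expected_score, abs=0.5)
        assert smap.classification == expected_class

    def test_sham_self_combination_scores_zero(self):
        matrix = additive_matrix(self.fit_a, self.fit_a, self.doses)
        smap = pharmacology.synergy_map(matrix, self.fit_a, self.fit_a)
        assert abs(smap.overall) < 0.5

    def test_dose_unit_relabelling_invariance(self):
        matrix = additive_matrix(self.fit_a, self.fit_b, self.doses)
        comb_shifted = matrix - 8.0
        comb_shifted.loc[0.0, :] = matrix.loc[0.0, :]
        comb_shifted.loc[:, 0.0] = matrix.loc[:, 0.0]
        smap_nm = pharmacology.synergy_map(comb_shifted, self.fit_a, self.fit_b)
        # relabel nM -> uM with matched fits
        um = comb_shifted.copy()
        um.index = um.index / 1000.0
        um.columns = um.columns / 1000.0
        fit_a_um = FourPL(self.fit_a.top, self.fit_a.bottom, self.fit_a.ed50 / 1000.0,
                          self.fit_a.hill)
        fit_b_um = FourPL(self.fit_b.top, self.fit_b.bottom, self.fit_b.ed50 / 1000.0,
                          self.fit_b.hill)
        smap_um = pharmacology.synergy_map(um, fit_a_um, fit_b_um)
        assert smap_um.overall == pytest.approx(smap_nm.overall, abs=1e-8)

    def test_missing_cells_excluded_and_reported(self):
        matrix = additive_matrix(self.fit_a, self.fit_b, self.doses)
        matrix.iloc[3, 3] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            smap = pharmacology.synergy_map(matrix, self.fit_a, self.fit_b)
        assert smap.n_cells == 35
        assert len(smap.flagged_cells) == 1
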