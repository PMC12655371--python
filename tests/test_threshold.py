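import numpy as np
import pytest

from effluxlim import (
    EffluxClass,
    InfeasibleObservationError,
    classify,
    pm_at_energy_limit,
    sensitivity_table,
    threshold_curve,
)

JMAX = 1.6e-4  # umol/cm2/s


class TestPmAtEnergyLimit:
    def test_doubling_concentration_halves_pm(self, geometry):
        """Pm*Cext is the invariant of the energy limit: doubling Cext halves
        the limiting Pm, exactly in the strong-pump limit (the residual comes
        from aqueous-side resistances and decays as 1/p_pgp)."""
        deviations = []
        for p_pgp in (1e3, 1e4):
            pm1 = pm_at_energy_limit(p_pgp, JMAX, geometry, cext_um=1.0)
            pm2 = pm_at_energy_limit(p_pgp, JMAX, geometry, cext_um=2.0)
            deviations.append(abs(pm2 / (pm1 / 2.0) - 1.0))
        assert deviations[1] < 1e-4
        # asymptotic: one decade more pump strength, one decade less residual
        assert deviations[1] < 0.2 * deviations[0]

    def test_jmax_proportionality_deep_in_plateau(self, geometry):
        """With a strong pump the limiting Pm scales linearly with Jmax."""
        p_pgp = 1e4
        pm1 = pm_at_energy_limit(p_pgp, JMAX, geometry, cext_um=1.0)
        pm3 = pm_at_energy_limit(p_pgp, 3.0 * JMAX, geometry, cext_um=1.0)
        assert pm3 / pm1 == pytest.approx(3.0, rel=1e-3)

    def test_zero_pump_is_infeasible(self, geometry):
        with pytest.raises(InfeasibleObservationError):
            pm_at_energy_limit(0.0, JMAX, geometry, cext_um=1.0)

    def test_too_weak_pump_is_infeasible(self, geometry):
        # a vanishing pump cannot reach the energy limit at any permeability
        with pytest.raises(InfeasibleObservationError):
            pm_at_energy_limit(1e-9, JMAX, geometry, cext_um=1.0)


class TestThresholdCurve:
    def test_default_geometry_plateau(self, geometry):
        """Jmax = 1.6e-4 umol/cm2/s with the MDCKII geometry (SA 7.5) puts
        the high-ER plateau close to log10(Pm*Cext) = -1.7."""
        curve = threshold_curve(JMAX, geometry)
        assert curve.plateau_log_pmc == pytest.approx(-1.7, abs=0.15)

    def test_curve_rises_sharply_at_low_er(self, geometry):
        curve = threshold_curve(JMAX, geometry)
        er = np.asarray(curve.er)
        lpmc = np.asarray(curve.log_pmc)
        low = lpmc[er < 3.0]
        assert low.size and np.max(low) > curve.plateau_log_pmc + 0.5

    def test_plateau_concentration_normalisation(self, geometry):
        """log10(Pm*Cext) plateau barely moves when Cext changes 100-fold:
        the residual (aqueous resistances that do not scale with Pm) stays
        below 1e-4 log units."""
        p1 = threshold_curve(JMAX, geometry, cext_um=1.0).plateau_log_pmc
        p100 = threshold_curve(JMAX, geometry, cext_um=100.0).plateau_log_pmc
        assert abs(p100 - p1) < 1e-4

    def test_plateau_linear_in_log_jmax_with_unit_slope(self, geometry):
        jmaxes = np.array([1e-6, 1e-5, 1e-4, 1e-3])
        plateaus = [threshold_curve(j, geometry).plateau_log_pmc for j in jmaxes]
        slope = np.polyfit(np.log10(jmaxes), plateaus, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_er_grid_interpolation(self, geometry):
        grid = [2.0, 10.0, 50.0]
        curve = threshold_curve(JMAX, geometry, er_grid=grid)
        assert len(curve.log_pmc_on_grid) == 3
        # interpolated values follow the monotone decline of the curve
        assert curve.log_pmc_on_grid[0] > curve.log_pmc_on_grid[2]


class TestSensitivity:
    def test_joint_sa_jmax_scaling_leaves_plateau_unchanged(self, geometry):
        """Raising the apical surface-area factor by 3.2x while the
        extracted Jmax rises by the same factor leaves the threshold put."""
        table = sensitivity_table(
            JMAX, geometry, axes={"sa_factor": [24.0]}, sa_jmax_paired=True
        )
        base = table.loc[table["axis"] == "base", "plateau_log_pmc"].iloc[0]
        scaled = table.loc[table["axis"] == "sa_factor", "plateau_log_pmc"].iloc[0]
        assert scaled == pytest.approx(base, abs=1e-4)

    def test_unpaired_sa_shifts_plateau(self, geometry):
        table = sensitivity_table(JMAX, geometry, axes={"sa_factor": [24.0]})
        base = table.loc[table["axis"] == "base", "plateau_log_pmc"].iloc[0]
        scaled = table.loc[table["axis"] == "sa_factor", "plateau_log_pmc"].iloc[0]
        # fixed Jmax: bigger apical area means lower tolerable Pm
        assert scaled < base - 0.3

    def test_paracellular_permeability_is_inconsequential(self, geometry):
        table = sensitivity_table(JMAX, geometry, axes={"p_para": [1e-7, 1e-5]})
        base = table.loc[table["axis"] == "base", "plateau_log_pmc"].iloc[0]
        for value in table.loc[table["axis"] == "p_para", "plateau_log_pmc"]:
            assert abs(value - base) < 0.05

    def test_jmax_axis_spans_reported_range(self, geometry):
        table = sensitivity_table(JMAX, geometry, axes={"jmax": [8.7e-6, 4.4e-4]})
        lo, hi = table.loc[table["axis"] == "jmax", "plateau_log_pmc"]
        assert lo == pytest.approx(-2.94, abs=0.1)
        assert hi == pytest.approx(-1.23, abs=0.1)


class TestClassify:
    def test_below_borderline_above(self):
        assert classify(-2.72).label is EffluxClass.BELOW
        assert classify(-1.5).label is EffluxClass.BORDERLINE
        assert classify(0.08).label is EffluxClass.ABOVE

    def test_outlier_flag_requires_significant_er_above_threshold(self):
        assert classify(0.08, er=2.8).outlier_flag
        assert not classify(0.08, er=2.0).outlier_flag
        assert not classify(-2.72, er=5.0).outlier_flag

    def test_classification_is_monotone(self):
        order = {EffluxClass.BELOW: 0, EffluxClass.BORDERLINE: 1, EffluxClass.ABOVE: 2}
        values = np.linspace(-4.0, 1.0, 41)
        ranks = [order[classify(v).label] for v in values]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))
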