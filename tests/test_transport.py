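import math
from dataclasses import replace

import numpy as np
import pytest

from effluxlim import (
    AssayGeometry,
    Compound,
    Direction,
    InvalidInputError,
    MichaelisMentenEfflux,
    PermeabilityNetwork,
    ProtolyticProfile,
    build_network,
    efflux_ratio,
    steady_state,
)
from oracles import finite_difference_series_papp


def passive_network(**overrides) -> PermeabilityNetwork:
    """A symmetric, fully neutral network with no pumps and no paracellular leak."""
    defaults = dict(
        p_abl_a=5e-4, p_abl_b=5e-4, p_filter=5.5e-4, p_para=0.0,
        p0=1e-4, fn_apical=1.0, fn_basolateral=1.0, fn_cytosol=1.0,
        p_cyt=5e-3, sa_factor=1.0,
    )
    defaults.update(overrides)
    return PermeabilityNetwork(**defaults)


def series_permeabilities(net: PermeabilityNetwork) -> list[float]:
    p_exit = 1.0 / (1.0 / net.p_filter + 1.0 / net.p_abl_b)
    return [net.p_abl_a, net.sa_factor * net.p0, net.p_cyt, net.p0, p_exit]


class TestBuildNetwork:
    def test_filter_permeability_from_manufacturer_specs(self, geometry, neutral_compound):
        """Pore area fraction pi*r^2*rho ~ 0.126 for 0.2 um pores at 1e8/cm2."""
        assert geometry.filter_area_fraction == pytest.approx(0.1257, abs=2e-4)
        net = build_network(neutral_compound, geometry)
        from effluxlim import aqueous_diffusivity

        dw = aqueous_diffusivity(400.0, 37.0)
        expected = geometry.filter_area_fraction * dw / 11.5e-4
        assert net.p_filter == pytest.approx(expected, rel=1e-12)

    def test_symmetric_membranes_at_unit_sa(self, neutral_compound):
        geometry = AssayGeometry(sa_factor=1.0)
        net = build_network(neutral_compound, geometry)
        assert net.p_m_apical == pytest.approx(net.p_m_basolateral, rel=1e-12)

    def test_halving_abl_doubles_its_permeability(self, neutral_compound):
        thin = build_network(neutral_compound, AssayGeometry(abl_apical_um=50.0))
        thick = build_network(neutral_compound, AssayGeometry(abl_apical_um=100.0))
        assert thin.p_abl_a == pytest.approx(2.0 * thick.p_abl_a, rel=1e-12)


class TestSteadyState:
    def test_passive_stack_matches_harmonic_sum_and_fd_oracle(self):
        net = passive_network()
        result = steady_state(net, 10.0)
        harmonic = 1.0 / sum(1.0 / p for p in series_permeabilities(net))
        assert result.papp_ab == pytest.approx(harmonic, rel=1e-10)
        oracle = finite_difference_series_papp(series_permeabilities(net))
        assert result.papp_ab == pytest.approx(oracle, rel=5e-3)

    def test_fd_oracle_agreement_on_random_networks(self):
        """Closed form vs an independent finite-difference diffusion solve,
        20 random passive parameter draws, <= 0.5% relative."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            p = 10.0 ** rng.uniform(-5.0, -2.0, size=5)
            net = passive_network(
                p_abl_a=p[0], p_abl_b=p[1], p_filter=p[2], p0=p[3], p_cyt=p[4]
            )
            result = steady_state(net, 5.0)
            oracle = finite_difference_series_papp(series_permeabilities(net))
            assert result.papp_ab == pytest.approx(oracle, rel=5e-3)

    def test_no_transporters_gives_unit_efflux_ratio(self):
        result = steady_state(passive_network(p_para=1e-6), 10.0)
        assert result.er == pytest.approx(1.0, rel=1e-9)

    def test_flux_conservation_through_cytosol(self):
        """Flux entering the cytosol equals flux leaving it to 1e-10 relative."""
        net = passive_network(p_pgp_active=3e-4, p_para=1e-6, fn_cytosol=0.8)
        from effluxlim.transport import _barrier_coefficients, _solve_chain

        coeffs = _barrier_coefficients(net, Direction.AB, net.p_pgp_active)
        conc, flux = _solve_chain(coeffs, 10.0)
        nodes = [10.0, *conc, 0.0]
        into_cyt = coeffs[1][0] * nodes[1] - coeffs[1][1] * nodes[2]
        out_of_cyt = coeffs[3][0] * nodes[3] - coeffs[3][1] * nodes[4]
        assert into_cyt == pytest.approx(out_of_cyt, rel=1e-10)

    def test_pump_monotonicity_and_paracellular_floor(self):
        """Papp(A->B) falls and Papp(B->A) rises with pump strength; the
        apparent permeability never drops below the paracellular route."""
        base = passive_network(p_para=1e-6)
        prev_ab, prev_ba = math.inf, 0.0
        for p_pgp in [0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1.0]:
            r = steady_state(replace(base, p_pgp_active=p_pgp), 10.0)
            assert r.papp_ab <= prev_ab * (1 + 1e-12)
            assert r.papp_ba >= prev_ba * (1 - 1e-12)
            assert r.papp_ab >= base.p_para
            prev_ab, prev_ba = r.papp_ab, r.papp_ba
        # overwhelming efflux: Papp(A->B) approaches the paracellular floor
        huge = steady_state(replace(base, p_pgp_active=1e6 * base.p0), 10.0)
        assert huge.papp_ab == pytest.approx(base.p_para, rel=0.02)

    def test_michaelis_menten_linear_limit(self):
        """Km -> inf at fixed Jmax/Km reduces MM mode to fixed-pump mode."""
        net = passive_network(p_para=1e-6)
        p_fixed = 2.5e-4
        km = 1e7
        mm = MichaelisMentenEfflux(jmax=p_fixed * km * 1e-3, km=km)
        fixed = steady_state(replace(net, p_pgp_active=p_fixed), 10.0)
        saturable = steady_state(net, 10.0, mm)
        assert saturable.papp_ab == pytest.approx(fixed.papp_ab, rel=1e-5)
        assert saturable.papp_ba == pytest.approx(fixed.papp_ba, rel=1e-5)

    def test_active_flux_consistency_in_mm_mode(self):
        """In saturable mode the reported flux equals Jmax*C/(Km+C)."""
        net = passive_network(p_para=1e-6)
        mm = MichaelisMentenEfflux(jmax=1.6e-4, km=5.0)
        r = steady_state(net, 10.0, mm)
        assert r.j_active == pytest.approx(
            mm.jmax * r.c_cyt_a / (mm.km + r.c_cyt_a), rel=1e-9
        )

    def test_ion_trapping_asymmetry(self):
        """A base trapped in the (more acidic) cytosol still yields ER = 1
        without pumps, but raises the cytosolic concentration."""
        trapped = passive_network(fn_cytosol=0.2, p_para=0.0)
        r = steady_state(trapped, 10.0)
        assert r.er == pytest.approx(1.0, rel=1e-9)
        free = steady_state(passive_network(p_para=0.0), 10.0)
        assert r.c_cyt_a > free.c_cyt_a

    def test_invalid_donor_concentration(self):
        with pytest.raises(InvalidInputError):
            steady_state(passive_network(), 0.0)


class TestEffluxRatio:
    def test_ratio_increases_with_pump_strength(self, neutral_compound, geometry):
        ers = [
            efflux_ratio(neutral_compound, geometry, 10.0, p_pgp_active=p)
            for p in [0.0, 1e-5, 1e-4, 1e-3, 1e-2]
        ]
        assert all(b > a for a, b in zip(ers, ers[1:]))
        assert ers[0] == pytest.approx(1.0, rel=1e-9)

    def test_saturable_er_declines_with_concentration(self, geometry):
        """Borderline-compound signature: transporter saturation pulls the
        efflux ratio down as the applied concentration rises."""
        compound = Compound(name="borderline", mw=400.0, log_p0_experimental=-3.3)
        mm = MichaelisMentenEfflux(jmax=1.6e-4, km=5.0)
        ers = [efflux_ratio(compound, geometry, c, efflux=mm) for c in [1.0, 10.0, 100.0]]
        assert ers[0] > ers[1] > ers[2]

    def test_er_for_charged_compound(self, geometry):
        base = Compound(
            name="weakbase", mw=450.0,
            profile=ProtolyticProfile(sites=((8.4, "base"),)),
            log_p0_experimental=-2.0,
        )
        assert efflux_ratio(base, geometry, 10.0) == pytest.approx(1.0, rel=1e-6)
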