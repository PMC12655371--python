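"""Steady-state transwell transport model with unidirectional active efflux.

A compound crossing an epithelial monolayer in a transwell insert passes a
chain of resistances in series: the donor-side aqueous boundary layer (ABL),
the donor-side membrane, the cytosol, the acceptor-side membrane, and — on
the basolateral side — the supporting filter plus the basolateral ABL.
Tight-junction (paracellular) transport runs in parallel and puts a floor
under the apparent permeability.  An ATP-driven efflux pump in the apical
membrane moves compound unidirectionally from the cytosol to the apical
exterior; an optional basolateral uptake transporter moves compound from
the basolateral exterior into the cytosol.

Membranes pass only the neutral fraction of the compound, so each membrane
flux is ``P0 * (fn_out * C_out - fn_in * C_in)`` with compartment-specific
neutral fractions (ion trapping falls out of this naturally).  The folded
apical membrane carries a surface-area multiplier ``sa_factor``; active
fluxes are always reported per nominal insert area.

Steady state means equal net flux through every series element.  With a
fixed pump permeability the node concentrations solve a small linear
system; with Michaelis–Menten saturation the apparent pump permeability is
``Jmax / (Km + C_cyt,a)`` and the sub-apical cytosolic concentration is
found by a bracketed scalar root solve (the flux balance is monotone in
``C_cyt,a``, so the bracket is guaranteed).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import brentq

from .errors import ConvergenceError, InvalidInputError
from .permeability import (
    DEFAULT_TEMPERATURE_C,
    Compound,
    aqueous_diffusivity,
    resolve_p0,
)
from .speciation import cytosolic_pH, neutral_fraction

#: micromolar -> umol/cm^3, so that P (cm/s) * C (uM) * UM_TO_UMOL_PER_CM3
#: is a flux in umol/cm^2/s.
UM_TO_UMOL_PER_CM3 = 1.0e-3

#: Relative tolerance on the steady-state flux balance.
FLUX_BALANCE_RTOL = 1.0e-9


class Direction(str, enum.Enum):
    AB = "a_to_b"
    BA = "b_to_a"


@dataclass(frozen=True)
class AssayGeometry:
    """Transwell geometry and assay conditions (MDCKII defaults).

    Filter specs follow 12-well inserts (0.4 um pores, 11.5 um thick,
    1e8 pores/cm^2).  ABL thicknesses of 100 um per side correspond to
    orbital shaking; the paracellular permeability is a configurable
    constant standing in for a full size/charge tight-junction model.
    """

    abl_apical_um: float = 100.0
    abl_basolateral_um: float = 100.0
    filter_pore_radius_um: float = 0.2
    filter_thickness_um: float = 11.5
    filter_pore_density_per_cm2: float = 1.0e8
    sa_factor: float = 7.5
    p_para_cm_s: float = 1.0e-6
    cytosol_path_um: float = 5.0
    cytosol_diffusivity_factor: float = 0.5
    pH_apical: float = 7.4
    pH_basolateral: float = 7.4
    temperature_c: float = DEFAULT_TEMPERATURE_C

    def __post_init__(self) -> None:
        positive = {
            "abl_apical_um": self.abl_apical_um,
            "abl_basolateral_um": self.abl_basolateral_um,
            "filter_pore_radius_um": self.filter_pore_radius_um,
            "filter_thickness_um": self.filter_thickness_um,
            "filter_pore_density_per_cm2": self.filter_pore_density_per_cm2,
            "sa_factor": self.sa_factor,
            "cytosol_path_um": self.cytosol_path_um,
            "cytosol_diffusivity_factor": self.cytosol_diffusivity_factor,
        }
        for name, value in positive.items():
            if not (value > 0 and math.isfinite(value)):
                raise InvalidInputError(f"geometry field {name} must be positive, got {value!r}")
        if not self.p_para_cm_s >= 0:
            raise InvalidInputError(f"p_para_cm_s must be >= 0, got {self.p_para_cm_s!r}")

    @property
    def filter_area_fraction(self) -> float:
        """Open (porous) fraction of the filter surface."""
        r_cm = self.filter_pore_radius_um * 1.0e-4
        return math.pi * r_cm**2 * self.filter_pore_density_per_cm2

    @classmethod
    def from_dict(cls, data: dict) -> "AssayGeometry":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AssayGeometry":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass(frozen=True)
class PermeabilityNetwork:
    """All resistances of the transwell stack, resolved for one compound.

    Aqueous elements (ABLs, filter, cytosol) act on total dissolved
    concentration; membranes act on the neutral fraction of it.  Pump
    permeabilities are apparent values per nominal insert area.
    """

    p_abl_a: float
    p_abl_b: float
    p_filter: float
    p_para: float
    p0: float
    fn_apical: float
    fn_basolateral: float
    fn_cytosol: float
    p_cyt: float
    sa_factor: float
    p_pgp_active: float = 0.0
    p_b_active: float = 0.0
    direction: Optional[Direction] = None

    def __post_init__(self) -> None:
        for name in ("p_abl_a", "p_abl_b", "p_filter", "p0", "p_cyt"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"network field {name} must be positive")
        for name in ("p_para", "p_pgp_active", "p_b_active"):
            if not getattr(self, name) >= 0:
                raise InvalidInputError(f"network field {name} must be >= 0")
        for name in ("fn_apical", "fn_basolateral", "fn_cytosol"):
            fn = getattr(self, name)
            if not 0.0 < fn <= 1.0:
                raise InvalidInputError(f"network field {name} must be in (0, 1], got {fn!r}")

    @property
    def p_m_apical(self) -> float:
        """Passive permeability of the apical membrane at apical pH."""
        return self.sa_factor * self.p0 * self.fn_apical

    @property
    def p_m_basolateral(self) -> float:
        """Passive permeability of the basolateral membrane at basolateral pH."""
        return self.p0 * self.fn_basolateral


@dataclass(frozen=True)
class MichaelisMentenEfflux:
    """Saturable efflux: apparent pump permeability Jmax / (Km + C_cyt,a).

    ``jmax`` in umol/cm^2/s (per nominal insert area), ``km`` in uM on the
    cytosolic (intracellular) concentration axis.
    """

    jmax: float
    km: float

    def __post_init__(self) -> None:
        if not self.jmax > 0 or not self.km > 0:
            raise InvalidInputError("Michaelis-Menten efflux needs jmax > 0 and km > 0")


@dataclass(frozen=True)
class SteadyStateResult:
    """Directional apparent permeabilities plus the apical-cytosol state.

    ``c_cyt_a`` and ``j_active`` refer to the A->B experiment, the direction
    in which pump activity is fitted from assay data.
    """

    papp_ab: float
    papp_ba: float
    er: float
    c_cyt_a: float
    j_active: float


def build_network(
    compound: Compound,
    geometry: AssayGeometry,
    direction: Direction = Direction.AB,
) -> PermeabilityNetwork:
    """Resolve every barrier permeability of the transwell stack for one compound."""
    dw = aqueous_diffusivity(compound.mw, geometry.temperature_c)
    log_p0, _ = resolve_p0(compound, geometry.temperature_c)
    fn_a = neutral_fraction(compound.profile, geometry.pH_apical)
    fn_b = neutral_fraction(compound.profile, geometry.pH_basolateral)
    fn_c = neutral_fraction(compound.profile, cytosolic_pH(geometry.pH_apical))
    return PermeabilityNetwork(
        p_abl_a=dw / (geometry.abl_apical_um * 1.0e-4),
        p_abl_b=dw / (geometry.abl_basolateral_um * 1.0e-4),
        p_filter=geometry.filter_area_fraction * dw / (geometry.filter_thickness_um * 1.0e-4),
        p_para=geometry.p_para_cm_s,
        p0=10.0 ** log_p0,
        fn_apical=fn_a,
        fn_basolateral=fn_b,
        fn_cytosol=fn_c,
        p_cyt=geometry.cytosol_diffusivity_factor * dw / (geometry.cytosol_path_um * 1.0e-4),
        sa_factor=geometry.sa_factor,
        direction=direction,
    )


def _series(*perms: float) -> float:
    return 1.0 / sum(1.0 / p for p in perms)


def _barrier_coefficients(net: PermeabilityNetwork, direction: Direction, p_pgp: float):
    """Linear flux coefficients (a_i, b_i) with J_i = a_i*C_i - b_i*C_{i+1}.

    Node order follows the permeation path of the chosen direction; the
    cytosol contributes two nodes so that the sub-apical concentration that
    the pump sees is explicit.
    """
    pm_a_out = net.sa_factor * net.p0 * net.fn_apical      # apical face
    pm_a_in = net.sa_factor * net.p0 * net.fn_cytosol      # cytosolic face, apical membrane
    pm_b_out = net.p0 * net.fn_basolateral
    pm_b_in = net.p0 * net.fn_cytosol
    p_exit_b = _series(net.p_filter, net.p_abl_b)          # filter + basolateral ABL

    if direction is Direction.AB:
        # donor(apical) | ABL | apical membrane | cytosol | basolateral
        # membrane | filter+ABL | acceptor.  The pump (cytosol -> apical)
        # and basolateral uptake (basolateral -> cytosol) both oppose A->B.
        return [
            (net.p_abl_a, net.p_abl_a),
            (pm_a_out, pm_a_in + p_pgp),
            (net.p_cyt, net.p_cyt),
            (pm_b_in, pm_b_out + net.p_b_active),
            (p_exit_b, p_exit_b),
        ]
    # B->A: donor(basolateral) | ABL+filter | basolateral membrane |
    # cytosol | apical membrane | apical ABL | acceptor.  Pump and uptake
    # both aid B->A.
    return [
        (p_exit_b, p_exit_b),
        (pm_b_out + net.p_b_active, pm_b_in),
        (net.p_cyt, net.p_cyt),
        (pm_a_in + p_pgp, pm_a_out),
        (net.p_abl_a, net.p_abl_a),
    ]


def _solve_chain(coeffs, c_donor: float):
    """Solve the steady-state node concentrations of a 5-barrier chain.

    Returns ``(concentrations c1..c4, flux)`` with the acceptor a perfect
    sink (C=0).  Conservation: a_{i-1} c_{i-1} - b_{i-1} c_i = a_i c_i -
    b_i c_{i+1} at every internal node.
    """
    n = len(coeffs) - 1  # internal nodes
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for i in range(n):
        a_prev, b_prev = coeffs[i]
        a_next, b_next = coeffs[i + 1]
        A[i, i] = b_prev + a_next
        if i > 0:
            A[i, i - 1] = -a_prev
        else:
            rhs[i] = a_prev * c_donor
        if i < n - 1:
            A[i, i + 1] = -b_next
        # acceptor node is the sink: b_next * 0 contributes nothing
    conc = np.linalg.solve(A, rhs)
    if np.any(conc < -1e-12 * max(c_donor, 1.0)):
        raise ConvergenceError(f"negative steady-state concentration: {conc}")
    conc = np.clip(conc, 0.0, None)
    flux = coeffs[-1][0] * conc[-1]
    _check_flux_balance(coeffs, c_donor, conc, flux)
    return conc, flux


def _check_flux_balance(coeffs, c_donor, conc, flux) -> None:
    # Backward-error style check: each barrier flux is a difference of two
    # potentially huge terms, so imbalances are measured against the largest
    # term anywhere in the chain (the system's natural scale).
    nodes = [c_donor, *conc, 0.0]
    terms = [(a * nodes[i], b * nodes[i + 1]) for i, (a, b) in enumerate(coeffs)]
    scale = max(max(abs(t1), abs(t2)) for t1, t2 in terms)
    scale = max(scale, abs(flux), 1e-300)
    for i, (t1, t2) in enumerate(terms):
        if abs((t1 - t2) - flux) > FLUX_BALANCE_RTOL * scale:
            raise ConvergenceError(
                f"steady-state flux imbalance at barrier {i}: "
                f"{t1 - t2:.6e} vs {flux:.6e}"
            )


def _cytosol_apical_index(direction: Direction) -> int:
    # internal nodes are [surface_in, cyt_near_in, cyt_near_out, surface_out]
    return 1 if direction is Direction.AB else 2


def _solve_direction(
    net: PermeabilityNetwork,
    direction: Direction,
    c_donor: float,
    efflux: Optional[MichaelisMentenEfflux],
):
    """One directional steady state; returns (papp_trans, c_cyt_a, p_pgp)."""
    icyt = _cytosol_apical_index(direction)

    def solve_with(p_pgp: float):
        coeffs = _barrier_coefficients(net, direction, p_pgp)
        conc, flux = _solve_chain(coeffs, c_donor)
        return conc, flux

    if efflux is None:
        p_pgp = net.p_pgp_active
        conc, flux = solve_with(p_pgp)
        return flux / c_donor, conc[icyt], p_pgp

    jmax_u = efflux.jmax / UM_TO_UMOL_PER_CM3  # cm/s * uM flux units

    def pump_perm(c_cyt: float) -> float:
        return jmax_u / (efflux.km + c_cyt)

    # Pump removal only lowers the cytosolic concentration, so the passive
    # solution bounds the bracket from above and g crosses zero inside it.
    c_passive = solve_with(0.0)[0][icyt]

    def g(c_guess: float) -> float:
        conc, _ = solve_with(pump_perm(c_guess))
        return conc[icyt] - c_guess

    hi = c_passive * (1.0 + 1e-9) + 1e-30
    if g(hi) > 0:  # numerical guard; should not occur
        raise ConvergenceError(
            f"Michaelis-Menten bracket failed: g({hi:.3e}) > 0 in {direction}"
        )
    c_star = brentq(g, 0.0, hi, xtol=1e-18, rtol=1e-14)
    p_pgp = pump_perm(c_star)
    conc, flux = solve_with(p_pgp)
    return flux / c_donor, conc[icyt], p_pgp


def steady_state(
    network: PermeabilityNetwork,
    c_donor_um: float,
    efflux: Optional[MichaelisMentenEfflux] = None,
) -> SteadyStateResult:
    """Solve both directional steady states of the transwell stack.

    Parameters
    ----------
    network:
        Resolved barrier permeabilities.  In fixed mode the pump strength is
        ``network.p_pgp_active``; passing ``efflux`` switches to saturable
        Michaelis–Menten mode and ignores that field.
    c_donor_um:
        Applied donor concentration (uM); the acceptor is a perfect sink.

    Returns the apparent permeabilities of both directions (paracellular
    route included), the efflux ratio, and the A->B sub-apical cytosolic
    concentration together with the active flux ``p_pgp * C_cyt,a`` in
    umol/cm^2/s.
    """
    if not c_donor_um > 0:
        raise InvalidInputError(f"donor concentration must be positive, got {c_donor_um!r}")
    papp_ab_t, c_cyt_a, p_pgp_ab = _solve_direction(network, Direction.AB, c_donor_um, efflux)
    papp_ba_t, _, _ = _solve_direction(network, Direction.BA, c_donor_um, efflux)
    papp_ab = papp_ab_t + network.p_para
    papp_ba = papp_ba_t + network.p_para
    return SteadyStateResult(
        papp_ab=papp_ab,
        papp_ba=papp_ba,
        er=papp_ba / papp_ab,
        c_cyt_a=c_cyt_a,
        j_active=p_pgp_ab * c_cyt_a * UM_TO_UMOL_PER_CM3,
    )


def efflux_ratio(
    compound: Compound,
    geometry: AssayGeometry,
    cext_um: float,
    efflux: Optional[MichaelisMentenEfflux] = None,
    p_pgp_active: float = 0.0,
) -> float:
    """Efflux ratio Papp(B->A)/Papp(A->B) for a compound in a given geometry."""
    net = build_network(compound, geometry)
    if p_pgp_active:
        net = replace(net, p_pgp_active=p_pgp_active)
    return steady_state(net, cext_um, efflux).er
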