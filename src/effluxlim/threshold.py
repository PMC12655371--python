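"""Energy-limited permeability threshold: from maximal flux to Pm*Cext.

A cell can spend only a bounded amount of ATP on efflux, which caps the
areal active flux at some ``Jmax`` (umol/cm^2/s).  For a compound to show a
given efflux ratio, its pump must move ``p_pgp * C_cyt,a`` of material per
unit time; demanding that this equals ``Jmax`` singles out, for every pump
strength, the largest passive membrane permeability the cell can still
fight.  Sweeping the pump strength traces a curve of (ER, Pm) pairs; after
normalising to the applied concentration, ``log10(Pm * Cext)`` plateaus for
large ER — that plateau is the screening threshold.  Compounds above it are
too permeable to efflux sustainably; a borderline window below it holds
compounds whose ER collapses with concentration as the pump saturates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InfeasibleObservationError, InvalidInputError
from .permeability import Compound
from .speciation import ProtolyticProfile
from .transport import (
    UM_TO_UMOL_PER_CM3,
    AssayGeometry,
    PermeabilityNetwork,
    build_network,
    steady_state,
)

#: Final single threshold on log10(Pm*Cext) for the MDCKII-MDR1 system.
DEFAULT_LOG_PMC_THRESHOLD = -1.7
#: Transitional (borderline) window on log10(Pm*Cext).
DEFAULT_BORDERLINE_BAND = (-2.0, -1.0)
#: Efflux ratios at or above this value count as significant active efflux.
ER_SIGNIFICANCE_CUTOFF = 2.5
#: Plateau statistic: median of log10(Pm*Cext) over samples with ER >= this.
PLATEAU_ER_MIN = 10.0

#: Default pump-permeability sweep, as multiples of Jmax/(Cext*1e-3): the
#: natural pump scale at which the energy limit is reachable.  The sweep
#: extends far past the curve's knee so the plateau statistic samples the
#: asymptote.
_PPGP_SWEEP_RELATIVE = np.logspace(-1.0, 6.0, 71)

#: Bracket for the permeability root solve, log10 cm/s.
_PM_SOLVE_BRACKET = (-9.0, 3.0)


def default_compound_template() -> Compound:
    """Neutral, drug-like template (MW 400) used to build threshold curves."""
    return Compound(
        name="template",
        mw=400.0,
        profile=ProtolyticProfile.neutral(),
        log_p0_experimental=0.0,  # placeholder; the sweep overrides P0
    )


class EffluxClass(str, enum.Enum):
    BELOW = "below_threshold_effluxable"
    BORDERLINE = "borderline"
    ABOVE = "above_threshold_non_effluxable"


@dataclass(frozen=True)
class Classification:
    label: EffluxClass
    log_pmc: float
    outlier_flag: bool = False


@dataclass(frozen=True)
class ThresholdCurve:
    """Sampled (ER, Pm, log Pm*Cext) curve and its high-ER plateau."""

    er: tuple[float, ...]
    pm: tuple[float, ...]
    log_pmc: tuple[float, ...]
    plateau_log_pmc: float
    jmax: float
    cext_um: float
    geometry: AssayGeometry
    er_grid: tuple[float, ...] = ()
    log_pmc_on_grid: tuple[float, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"er": self.er, "pm_cm_s": self.pm, "log_pmc": self.log_pmc})


# --- Pm at the energy limit -------------------------------------------------


def _flux_at(network: PermeabilityNetwork, p0: float, p_pgp: float, cext_um: float) -> float:
    net = replace(network, p0=p0, p_pgp_active=p_pgp)
    return steady_state(net, cext_um).j_active


def pm_at_energy_limit(
    p_pgp_active: float,
    jmax: float,
    geometry: AssayGeometry,
    compound_template: Optional[Compound] = None,
    cext_um: float = 1.0,
) -> float:
    """Membrane permeability at which a given pump strength hits the energy limit.

    Solves for the P0 (hence Pm at apical pH) such that the steady-state
    active flux ``p_pgp_active * C_cyt,a`` equals ``jmax``.  The flux grows
    monotonically with P0 (more influx, higher cytosolic concentration), so
    a bracketed solve on log10 P0 over [1e-9, 1e3] cm/s is used; when even
    the bracket edge cannot supply the flux, the configuration is infeasible
    (e.g. pump too weak for the requested limit at this concentration).
    """
    if not (p_pgp_active > 0 and jmax > 0 and cext_um > 0):
        raise InfeasibleObservationError(
            f"pm_at_energy_limit needs p_pgp_active > 0, jmax > 0, Cext > 0 "
            f"(got {p_pgp_active!r}, {jmax!r}, {cext_um!r})"
        )
    template = compound_template or default_compound_template()
    network = build_network(template, geometry)

    def f(log_p0: float) -> float:
        return _flux_at(network, 10.0**log_p0, p_pgp_active, cext_um) - jmax

    lo, hi = _PM_SOLVE_BRACKET
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise InfeasibleObservationError(
            f"no membrane permeability in [1e{lo:.0f}, 1e{hi:.0f}] cm/s lets a pump of "
            f"{p_pgp_active:.3e} cm/s reach Jmax={jmax:.3e} umol/cm2/s at "
            f"Cext={cext_um:.3g} uM (flux range [{f_lo + jmax:.3e}, {f_hi + jmax:.3e}])"
        )
    log_p0 = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return 10.0**log_p0 * network.fn_apical


# --- threshold curve --------------------------------------------------------


def threshold_curve(
    jmax: float,
    geometry: Optional[AssayGeometry] = None,
    compound_template: Optional[Compound] = None,
    cext_um: float = 1.0,
    er_grid: Optional[Sequence[float]] = None,
    p_pgp_grid: Optional[Sequence[float]] = None,
) -> ThresholdCurve:
    """Sweep the pump strength and trace the Pm*Cext limit as a function of ER.

    For each pump permeability the energy-limited Pm is solved and the
    efflux ratio of the resulting (Pm, pump) pair computed.  Samples whose
    pump is too weak to ever reach ``jmax`` are skipped.  The plateau is the
    median ``log10(Pm*Cext)`` over samples with ER >= 10; optionally the
    curve is also interpolated onto a user ER grid.
    """
    geometry = geometry or AssayGeometry()
    template = compound_template or default_compound_template()
    if er_grid is not None:
        er_grid = np.asarray(er_grid, dtype=float)
        if np.any(er_grid < 1.1) or np.any(er_grid > 1.0e4):
            raise InvalidInputError("er_grid values must lie within [1.1, 1e4]")
    if p_pgp_grid is None:
        scale = jmax / UM_TO_UMOL_PER_CM3 / cext_um
        p_pgp_grid = scale * _PPGP_SWEEP_RELATIVE
    network = build_network(template, geometry)

    ers, pms = [], []
    for p_pgp in np.asarray(p_pgp_grid, dtype=float):
        try:
            pm = pm_at_energy_limit(p_pgp, jmax, geometry, template, cext_um)
        except InfeasibleObservationError:
            continue
        net = replace(network, p0=pm / network.fn_apical, p_pgp_active=p_pgp)
        ers.append(steady_state(net, cext_um).er)
        pms.append(pm)
    if not ers:
        raise InfeasibleObservationError(
            f"no pump strength in the sweep reaches Jmax={jmax:.3e} at Cext={cext_um:.3g} uM"
        )
    er_arr = np.asarray(ers)
    pm_arr = np.asarray(pms)
    order = np.argsort(er_arr)
    er_arr, pm_arr = er_arr[order], pm_arr[order]
    log_pmc = np.log10(pm_arr * cext_um)

    high = er_arr >= PLATEAU_ER_MIN
    if not np.any(high):
        raise InfeasibleObservationError(
            "sweep produced no samples with ER >= 10; cannot extract a plateau"
        )
    plateau = float(np.median(log_pmc[high]))

    grid_vals: tuple[float, ...] = ()
    grid: tuple[float, ...] = ()
    if er_grid is not None:
        grid_vals = tuple(np.interp(np.log10(er_grid), np.log10(er_arr), log_pmc))
        grid = tuple(er_grid)
    return ThresholdCurve(
        er=tuple(er_arr),
        pm=tuple(pm_arr),
        log_pmc=tuple(log_pmc),
        plateau_log_pmc=plateau,
        jmax=jmax,
        cext_um=cext_um,
        geometry=geometry,
        er_grid=grid,
        log_pmc_on_grid=grid_vals,
    )


# --- sensitivity analysis ---------------------------------------------------

_SENSITIVITY_AXES = {"sa_factor", "cext", "p_para", "p_b_active", "jmax"}


def sensitivity_table(
    jmax: float,
    geometry: Optional[AssayGeometry] = None,
    axes: Optional[Mapping[str, Sequence[float]]] = None,
    cext_um: float = 1.0,
    sa_jmax_paired: bool = False,
    compound_template: Optional[Compound] = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity of the plateau to assay and model settings.

    ``axes`` maps axis names (``sa_factor``, ``cext``, ``p_para``,
    ``p_b_active``, ``jmax``) to value lists; each value is evaluated with
    everything else at its base setting.  With ``sa_jmax_paired`` the
    surface-area axis rescales the maximal flux proportionally — the
    empirical pairing in which the extracted threshold should be invariant.
    """
    geometry = geometry or AssayGeometry()
    axes = dict(axes or {})
    unknown = set(axes) - _SENSITIVITY_AXES
    if unknown:
        raise InvalidInputError(f"unknown sensitivity axes: {sorted(unknown)}")

    rows = []

    def plateau_for(geom: AssayGeometry, jm: float, cext: float, p_b: float = 0.0) -> float:
        template = compound_template or default_compound_template()
        if p_b > 0.0:
            net = build_network(template, geom)
            net = replace(net, p_b_active=p_b)
            # re-run the sweep with the uptake transporter in place
            scale = jm / UM_TO_UMOL_PER_CM3 / cext
            ers, lpmc = [], []
            for p_pgp in scale * _PPGP_SWEEP_RELATIVE:
                try:
                    pm = _pm_at_limit_for_network(net, p_pgp, jm, cext)
                except InfeasibleObservationError:
                    continue
                n2 = replace(net, p0=pm / net.fn_apical, p_pgp_active=p_pgp)
                ers.append(steady_state(n2, cext).er)
                lpmc.append(math.log10(pm * cext))
            sel = [v for e, v in zip(ers, lpmc) if e >= PLATEAU_ER_MIN]
            if not sel:
                raise InfeasibleObservationError("no ER >= 10 samples on sensitivity axis")
            return float(np.median(sel))
        return threshold_curve(jm, geom, template, cext).plateau_log_pmc

    rows.append(
        {"axis": "base", "value": float("nan"), "plateau_log_pmc": plateau_for(geometry, jmax, cext_um)}
    )
    for axis, values in axes.items():
        for value in values:
            if axis == "sa_factor":
                geom = replace(geometry, sa_factor=value)
                jm = jmax * (value / geometry.sa_factor) if sa_jmax_paired else jmax
                plateau = plateau_for(geom, jm, cext_um)
            elif axis == "cext":
                plateau = plateau_for(geometry, jmax, value)
            elif axis == "p_para":
                plateau = plateau_for(replace(geometry, p_para_cm_s=value), jmax, cext_um)
            elif axis == "p_b_active":
                plateau = plateau_for(geometry, jmax, cext_um, p_b=value)
            else:  # jmax
                plateau = plateau_for(geometry, value, cext_um)
            rows.append({"axis": axis, "value": float(value), "plateau_log_pmc": plateau})
    return pd.DataFrame(rows)


def _pm_at_limit_for_network(
    network: PermeabilityNetwork, p_pgp: float, jmax: float, cext_um: float
) -> float:
    """pm_at_energy_limit on a pre-built (possibly modified) network."""

    def f(log_p0: float) -> float:
        return _flux_at(network, 10.0**log_p0, p_pgp, cext_um) - jmax

    lo, hi = _PM_SOLVE_BRACKET
    if f(lo) > 0 or f(hi) < 0:
        raise InfeasibleObservationError("no root in permeability bracket")
    log_p0 = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return 10.0**log_p0 * network.fn_apical


# --- classification ---------------------------------------------------------


def classify(
    log_pmc: float,
    er: Optional[float] = None,
    threshold: float = DEFAULT_LOG_PMC_THRESHOLD,
    band: tuple[float, float] = DEFAULT_BORDERLINE_BAND,
) -> Classification:
    """Place a compound relative to the energy-limited permeability threshold.

    Below the borderline band the compound is effluxable; inside it efflux
    is concentration-dependent; above it sustained efflux exceeds the
    cell's energy budget.  A compound with a significant efflux ratio
    (ER >= 2.5) *and* log10(Pm*Cext) above the single threshold contradicts
    the energy limit and is flagged as an outlier for re-examination.
    """
    if not math.isfinite(log_pmc):
        raise InvalidInputError(f"non-finite log Pm*Cext: {log_pmc!r}")
    lo, hi = band
    if not lo < hi:
        raise InvalidInputError(f"borderline band must be ordered, got {band!r}")
    if log_pmc < lo:
        label = EffluxClass.BELOW
    elif log_pmc <= hi:
        label = EffluxClass.BORDERLINE
    else:
        label = EffluxClass.ABOVE
    outlier = er is not None and er >= ER_SIGNIFICANCE_CUTOFF and log_pmc > threshold
    return Classification(label=label, log_pmc=log_pmc, outlier_flag=outlier)
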