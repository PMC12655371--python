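"""Inversion of assay data: Papp, apparent pump permeability, maximal flux.

The analysis chain mirrors how saturation experiments are evaluated:

1. apparent permeability from acceptor-compartment time courses, with a
   recovery correction and lag-time handling;
2. per-concentration fit of the apparent active efflux permeability
   ``p_pgp_active`` so that the steady-state model reproduces the observed
   A->B permeability (the pump is treated as constant at each
   concentration);
3. the active flux ``J = p_pgp_active * C_cyt,a`` at each concentration;
4. a Michaelis–Menten fit of ``J`` against the cytosolic concentration
   across the series, whose plateau ``Jmax`` is the cell's energy limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

from .errors import (
    ConvergenceError,
    InfeasibleObservationError,
    InsufficientDataError,
    InvalidInputError,
)
from .transport import (
    UM_TO_UMOL_PER_CM3,
    AssayGeometry,
    Direction,
    PermeabilityNetwork,
    build_network,
    steady_state,
)

#: Monolayer-integrity cutoff for the paracellular marker Lucifer yellow;
#: inserts with a higher marker permeability are leaky and rejected.
LY_QC_THRESHOLD_CM_S = 1.5e-6

#: Km multi-start grid (log-spaced factors of the median concentration).
_KM_START_FACTORS = (0.05, 0.25, 1.0, 4.0, 20.0)

#: A fitted Km beyond this multiple of the largest concentration means the
#: data never left the linear regime: Jmax is only bounded from below.
_KM_IDENTIFIABILITY_FACTOR = 3.0


@dataclass(frozen=True)
class TimeCourse:
    """Acceptor-compartment accumulation of one insert.

    ``times_s`` strictly increasing sampling times; ``acceptor_amounts_nmol``
    cumulative amounts; ``recovery`` the mass-balance fraction used to
    correct for losses (binding, evaporation, degradation).
    """

    times_s: tuple[float, ...]
    acceptor_amounts_nmol: tuple[float, ...]
    donor_initial_um: float
    insert_area_cm2: float
    recovery: float = 1.0
    direction: Direction = Direction.AB

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times_s)
        amounts = tuple(float(q) for q in self.acceptor_amounts_nmol)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "acceptor_amounts_nmol", amounts)
        if len(times) != len(amounts):
            raise InvalidInputError("times and acceptor amounts must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidInputError("sampling times must be strictly increasing")
        if any(q < 0 for q in amounts):
            raise InvalidInputError("acceptor amounts must be >= 0")
        if not self.donor_initial_um > 0 or not self.insert_area_cm2 > 0:
            raise InvalidInputError("donor concentration and insert area must be positive")
        if not 0.0 < self.recovery <= 1.5:
            raise InvalidInputError(f"recovery must be in (0, 1.5], got {self.recovery!r}")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Bidirectional Papp of one compound over applied concentrations."""

    cext_um: tuple[float, ...]
    papp_ab: tuple[float, ...]
    papp_ba: tuple[float, ...]
    sd_ab: tuple[float, ...] = ()
    sd_ba: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.cext_um)
        object.__setattr__(self, "cext_um", c)
        object.__setattr__(self, "papp_ab", tuple(float(x) for x in self.papp_ab))
        object.__setattr__(self, "papp_ba", tuple(float(x) for x in self.papp_ba))
        object.__setattr__(self, "sd_ab", tuple(float(x) for x in self.sd_ab))
        object.__setattr__(self, "sd_ba", tuple(float(x) for x in self.sd_ba))
        if any(x <= 0 for x in c):
            raise InvalidInputError("concentrations must be positive")
        if len(set(c)) != len(c):
            raise InvalidInputError("concentrations must be unique")
        if not len(c) == len(self.papp_ab) == len(self.papp_ba):
            raise InvalidInputError("concentration series columns must align")

    @property
    def er(self) -> tuple[float, ...]:
        return tuple(ba / ab for ab, ba in zip(self.papp_ab, self.papp_ba))


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten parameters of the extracted active flux.

    ``jmax`` in umol/cm^2/s, ``km`` in uM on the cytosolic axis.  When the
    sampled concentrations never approach saturation the fit is flagged
    non-identifiable and ``jmax`` is only a lower bound.
    """

    jmax: float
    km: float
    jmax_se: float
    km_se: float
    n_points: int
    converged: bool
    identifiable: bool = True


# --- Papp from time courses -------------------------------------------------


def papp_from_timecourse(tc: TimeCourse) -> float:
    """Apparent permeability (cm/s) from an acceptor accumulation time course.

    Per-timepoint permeabilities are interval slopes ``dQ/dt / (A * C0)``
    (with Q(0) = 0 prepended), each divided by the recovery fraction; the
    mean is returned.  In the A->B direction the first interval is dropped
    because it absorbs the lag time before quasi-steady transport.
    """
    times = np.concatenate([[0.0], np.asarray(tc.times_s)])
    amounts = np.concatenate([[0.0], np.asarray(tc.acceptor_amounts_nmol)])
    slopes = np.diff(amounts) / np.diff(times)  # nmol/s
    papps = slopes / (tc.insert_area_cm2 * tc.donor_initial_um)  # uM == nmol/cm^3
    if tc.direction is Direction.AB:
        papps = papps[1:]
    if len(papps) < 2:
        raise InsufficientDataError(
            "need at least 2 usable time points after lag-time exclusion"
        )
    return float(np.mean(papps) / tc.recovery)


def apply_ly_qc(
    ly_papp_cm_s: Sequence[float], threshold: float = LY_QC_THRESHOLD_CM_S
) -> np.ndarray:
    """Boolean mask of inserts whose Lucifer-yellow permeability passes QC."""
    return np.asarray(ly_papp_cm_s, dtype=float) <= threshold


# --- pump-permeability fit --------------------------------------------------


def _papp_ab_model(network: PermeabilityNetwork, p_pgp: float, cext_um: float) -> float:
    net = replace(network, p_pgp_active=p_pgp)
    return steady_state(net, cext_um).papp_ab


def fit_ppgp(
    papp_ab_observed: float,
    network: PermeabilityNetwork,
    cext_um: float = 1.0,
) -> float:
    """Apparent active efflux permeability reproducing an observed A->B Papp.

    The steady-state A->B permeability decreases monotonically with the
    pump strength, from the passive-only value down to the paracellular
    floor, so a bracketed root solve on log10(p_pgp) is exact.  Observations
    at or above the passive prediction return 0 (no efflux needed);
    observations below the paracellular floor are unreachable and raise.
    """
    if not papp_ab_observed > 0:
        raise InvalidInputError("observed Papp must be positive")
    passive = _papp_ab_model(network, 0.0, cext_um)
    if papp_ab_observed >= passive:
        return 0.0
    if papp_ab_observed <= network.p_para:
        raise InfeasibleObservationError(
            f"observed Papp {papp_ab_observed:.3e} cm/s is at or below the "
            f"paracellular floor {network.p_para:.3e} cm/s; no pump strength "
            "can reproduce it"
        )

    def f(log_p: float) -> float:
        return _papp_ab_model(network, 10.0**log_p, cext_um) - papp_ab_observed

    lo, hi = -12.0, 4.0
    f_lo, f_hi = f(lo), f(hi)
    while f_hi > 0 and hi < 12.0:  # floor not yet approached; extend
        hi += 2.0
        f_hi = f(hi)
    if f_lo < 0 or f_hi > 0:
        raise ConvergenceError(
            f"pump fit bracket failed on log10 p_pgp in [{lo}, {hi}]: "
            f"f(lo)={f_lo:.3e}, f(hi)={f_hi:.3e}"
        )
    log_p = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return 10.0**log_p


def active_flux(p_pgp_active: float, c_cyt_a_um: float) -> float:
    """Active efflux flux J = p_pgp * C_cyt,a in umol/cm^2/s."""
    if p_pgp_active < 0 or c_cyt_a_um < 0:
        raise InvalidInputError("pump permeability and concentration must be >= 0")
    return p_pgp_active * c_cyt_a_um * UM_TO_UMOL_PER_CM3


def extract_flux_series(
    series: ConcentrationSeries,
    network: PermeabilityNetwork,
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Per-concentration (C_cyt,a, J_active, sigma_J) from an observed series.

    For each applied concentration the pump permeability is fitted from the
    A->B permeability, the steady state re-solved to obtain the sub-apical
    cytosolic concentration, and the active flux formed as their product.
    When the series carries replicate standard deviations, flux
    uncertainties are propagated through the (nonlinear) inversion by
    finite differences.  Assay noise is multiplicative, so a single pooled
    relative error (median sd/Papp over the series) is used rather than the
    per-point replicate SDs, which are themselves very noisy with few
    replicates; the resulting sigmas capture the inversion sensitivity —
    near saturation the observed Papp approaches the passive value and the
    extracted flux becomes very noisy, which a downstream weighted fit must
    know about.
    """

    def flux_of(papp: float, cext: float) -> tuple[float, float]:
        p_pgp = fit_ppgp(papp, network, cext)
        result = steady_state(replace(network, p_pgp_active=p_pgp), cext)
        return result.c_cyt_a, active_flux(p_pgp, result.c_cyt_a)

    n = len(series.cext_um)
    c_cyt = np.empty(n)
    j = np.empty(n)
    have_sd = len(series.sd_ab) == n and any(s > 0 for s in series.sd_ab)
    sigma = np.empty(n) if have_sd else None
    pooled_cv = 0.0
    if have_sd:
        pooled_cv = float(
            np.median(np.asarray(series.sd_ab) / np.asarray(series.papp_ab))
        )
    for i, (cext, papp_ab) in enumerate(zip(series.cext_um, series.papp_ab)):
        c_cyt[i], j[i] = flux_of(papp_ab, cext)
        if sigma is not None:
            lo = max(papp_ab * (1.0 - pooled_cv), network.p_para * (1.0 + 1e-9))
            hi = papp_ab * (1.0 + pooled_cv)
            _, j_lo = flux_of(lo, cext)
            _, j_hi = flux_of(hi, cext)
            sigma[i] = max(abs(j_hi - j_lo) / 2.0, 1e-12 * max(j[i], 1e-30))
    return c_cyt, j, sigma


# --- Michaelis-Menten fit ---------------------------------------------------


def _mm(c: np.ndarray, jmax: float, km: float) -> np.ndarray:
    return jmax * c / (km + c)


def fit_michaelis_menten(
    c_cyt_a_um: Sequence[float],
    j_active: Sequence[float],
    sigma: Optional[Sequence[float]] = None,
) -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit of active flux vs C_cyt,a.

    Multi-start over log-spaced Km guesses; the best converged start by
    (weighted) residual sum of squares wins.  ``sigma`` supplies per-point
    flux uncertainties for a weighted fit; only relative weights matter.
    Standard errors come from the local covariance.  If the fitted Km lies
    far beyond the sampled concentration range the data were effectively
    linear and ``jmax`` is reported as a lower bound with
    ``identifiable=False``.
    """
    c = np.asarray(c_cyt_a_um, dtype=float)
    j = np.asarray(j_active, dtype=float)
    if c.ndim != 1 or c.shape != j.shape:
        raise InvalidInputError("concentration and flux arrays must be 1-D and aligned")
    if len(np.unique(c)) < 3:
        raise InsufficientDataError("Michaelis-Menten fit needs >= 3 distinct concentrations")
    if np.any(c < 0) or np.any(~np.isfinite(c)) or np.any(~np.isfinite(j)):
        raise InvalidInputError("concentrations and fluxes must be finite, C >= 0")

    # Fit on flux normalised to its maximum so the optimiser's tolerances
    # act on O(1) residuals regardless of the absolute flux scale.
    j_scale = float(np.max(np.abs(j)))
    if not j_scale > 0:
        raise InvalidInputError("all fluxes are zero; nothing to fit")
    jn = j / j_scale
    sig = None
    if sigma is not None:
        sig = np.asarray(sigma, dtype=float) / j_scale
        if sig.shape != jn.shape or np.any(sig <= 0) or np.any(~np.isfinite(sig)):
            raise InvalidInputError("sigma must be positive, finite and aligned with the data")
    c_med = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    weights = 1.0 / sig**2 if sig is not None else np.ones_like(jn)
    best = None
    for factor in _KM_START_FACTORS:
        try:
            popt, pcov = curve_fit(
                _mm,
                c,
                jn,
                p0=(1.2, factor * c_med),
                sigma=sig,
                bounds=((0.0, 0.0), (np.inf, np.inf)),
                maxfev=20000,
                xtol=1e-13,
                ftol=1e-14,
                gtol=1e-14,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum(weights * (_mm(c, *popt) - jn) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        return MMFit(
            jmax=float(np.max(j)),
            km=float("nan"),
            jmax_se=float("nan"),
            km_se=float("nan"),
            n_points=len(c),
            converged=False,
            identifiable=False,
        )
    _, (jmax_n, km), pcov = best
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    identifiable = bool(km <= _KM_IDENTIFIABILITY_FACTOR * float(np.max(c)))
    return MMFit(
        jmax=float(jmax_n * j_scale),
        km=float(km),
        jmax_se=float(se[0] * j_scale),
        km_se=float(se[1]),
        n_points=len(c),
        converged=True,
        identifiable=identifiable,
    )


def fit_jmax_from_series(
    series: ConcentrationSeries,
    compound,
    geometry: AssayGeometry,
) -> MMFit:
    """Full inversion of one concentration series to the maximal flux.

    Convenience wrapper chaining :func:`extract_flux_series` (pump fit and
    cytosolic concentration per concentration) and
    :func:`fit_michaelis_menten`.
    """
    network = build_network(compound, geometry)
    c_cyt, j, sigma = extract_flux_series(series, network)
    return fit_michaelis_menten(c_cyt, j, sigma)
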