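"""Passive membrane permeability: solubility–diffusion prediction and resolution.

The intrinsic permeability P0 (cm/s) of the neutral species is either taken
from experiment or predicted with the solubility–diffusion model (SDM),

    P0_SDM = D_hex * K_hex/w / x_m,

where K_hex/w is the hexadecane–water partition coefficient standing in for
the hydrocarbon core of the bilayer, D_hex the diffusivity in that core
(taken as one tenth of the aqueous diffusivity), and x_m the core thickness.
SDM values are mapped onto the MDCK cell-membrane scale by the empirical
linear calibration

    log10 P0_MDCK = 0.84 * log10 P0_SDM - 1.85.

The permeability at assay pH is then Pm = P0 * f_n with f_n the neutral
fraction from :mod:`effluxlim.speciation`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import InvalidInputError, UnresolvableP0Error
from .speciation import ProtolyticProfile, neutral_fraction

# --- constants --------------------------------------------------------------

#: Membrane hydrocarbon-core thickness (cm); 3 nm, configurable per call.
DEFAULT_XM_CM = 3.0e-7
#: Assay temperature (deg C).
DEFAULT_TEMPERATURE_C = 37.0

#: Aqueous-diffusivity correlation for drug-like solutes at 25 deg C
#: (Avdeef-type molecular-weight power law): log10 Dw = A + B log10 MW.
_DW_CORRELATION_25C = (-4.113, -0.4609)

#: Vogel equation parameters for the dynamic viscosity of water:
#: eta(T) = A * 10^(B / (T - C)) with T in kelvin, eta in Pa s.
_WATER_VISCOSITY_VOGEL = (2.414e-5, 247.8, 140.0)

_T0_K = 298.15  # correlation reference temperature


class P0Provenance(enum.Enum):
    """Origin of an intrinsic-permeability value, in decreasing reliability."""

    MDCK_EXPERIMENTAL = "MDCK_experimental"
    PAMPA_SDM = "PAMPA_SDM"
    SDM_EXPERIMENTAL_DESCRIPTORS = "SDM_experimental_descriptors"
    SDM_CALCULATED_DESCRIPTORS = "SDM_calculated_descriptors"
    COSMO = "COSMO"


#: Khex/w source tags that route through the SDM + MDCK calibration.
_SDM_SOURCES = {
    P0Provenance.PAMPA_SDM,
    P0Provenance.SDM_EXPERIMENTAL_DESCRIPTORS,
    P0Provenance.SDM_CALCULATED_DESCRIPTORS,
    P0Provenance.COSMO,
}


@dataclass(frozen=True)
class Compound:
    """A screening-table row: identity, speciation, permeability sources.

    ``log_khexw`` requires a ``khexw_source`` tag so that the reliability
    hierarchy of the resolution step can be applied.  ``cext_um`` is the
    applied freely dissolved donor concentration in micromolar.
    """

    name: str
    mw: float
    profile: ProtolyticProfile = field(default_factory=ProtolyticProfile.neutral)
    log_khexw: Optional[float] = None
    khexw_source: Optional[P0Provenance] = None
    log_p0_experimental: Optional[float] = None
    cext_um: Optional[float] = None
    er_literature: Optional[float] = None
    permanent_charge: bool = False

    def __post_init__(self) -> None:
        if not (self.mw > 0 and math.isfinite(self.mw)):
            raise InvalidInputError(f"{self.name}: MW must be positive, got {self.mw!r}")
        if self.cext_um is not None and not self.cext_um > 0:
            raise InvalidInputError(f"{self.name}: Cext must be positive, got {self.cext_um!r}")
        if self.log_khexw is not None and self.khexw_source is None:
            raise InvalidInputError(f"{self.name}: log Khex/w given without a provenance tag")


# --- aqueous diffusivity ----------------------------------------------------


def water_viscosity(temperature_c: float) -> float:
    """Dynamic viscosity of water (Pa s) from the Vogel equation."""
    a, b, c = _WATER_VISCOSITY_VOGEL
    t_k = temperature_c + 273.15
    return a * 10.0 ** (b / (t_k - c))


def aqueous_diffusivity(mw: float, temperature_c: float = DEFAULT_TEMPERATURE_C) -> float:
    """Aqueous diffusion coefficient Dw (cm^2/s) of a solute of mass ``mw``.

    Molecular-weight power law at 25 deg C, rescaled to the requested
    temperature with the Stokes–Einstein factor ``(T/T0) * (eta0/eta(T))``.
    """
    if not mw > 0:
        raise InvalidInputError(f"MW must be positive, got {mw!r}")
    if not 0.0 <= temperature_c <= 50.0:
        raise InvalidInputError(f"temperature {temperature_c} outside supported range [0, 50]")
    a, b = _DW_CORRELATION_25C
    d25 = 10.0 ** (a + b * math.log10(mw))
    t_k = temperature_c + 273.15
    scale = (t_k / _T0_K) * (water_viscosity(25.0) / water_viscosity(temperature_c))
    return d25 * scale


def hexadecane_diffusivity(mw: float, temperature_c: float = DEFAULT_TEMPERATURE_C) -> float:
    """Diffusivity in the membrane hydrocarbon core, one tenth of Dw."""
    return aqueous_diffusivity(mw, temperature_c) / 10.0


# --- solubility-diffusion model and MDCK calibration ------------------------


def log_p0_sdm(
    log_khexw: float,
    mw: float,
    temperature_c: float = DEFAULT_TEMPERATURE_C,
    xm_cm: float = DEFAULT_XM_CM,
) -> float:
    """log10 of the SDM intrinsic permeability, P0 = Dhex * Khexw / xm (cm/s)."""
    if not xm_cm > 0:
        raise InvalidInputError(f"membrane core thickness must be positive, got {xm_cm!r}")
    if not math.isfinite(log_khexw):
        raise InvalidInputError(f"non-finite log Khex/w: {log_khexw!r}")
    dhex = hexadecane_diffusivity(mw, temperature_c)
    return math.log10(dhex) + log_khexw - math.log10(xm_cm)


def log_p0_mdck(log_p0_sdm_value: float) -> float:
    """MDCK-calibrated intrinsic permeability from the SDM one (both log10 cm/s)."""
    if not math.isfinite(log_p0_sdm_value):
        raise InvalidInputError(f"non-finite log P0,SDM: {log_p0_sdm_value!r}")
    return 0.84 * log_p0_sdm_value - 1.85


def resolve_p0(
    compound: Compound,
    temperature_c: float = DEFAULT_TEMPERATURE_C,
    xm_cm: float = DEFAULT_XM_CM,
) -> tuple[float, P0Provenance]:
    """Pick the most reliable intrinsic permeability for ``compound``.

    Priority: experimental MDCK-extracted P0 first; otherwise the Khex/w
    route (PAMPA > experimental descriptors > calculated descriptors)
    through the SDM and the MDCK calibration.  COSMO-derived Khex/w is
    accepted only for zwitterions or compounds above 1000 g/mol, where
    descriptor-based estimates are unreliable.

    Returns ``(log10 P0 in cm/s, provenance)``.
    """
    if compound.log_p0_experimental is not None:
        return float(compound.log_p0_experimental), P0Provenance.MDCK_EXPERIMENTAL
    if compound.log_khexw is not None:
        source = compound.khexw_source
        if source not in _SDM_SOURCES:
            raise UnresolvableP0Error(
                f"{compound.name}: unknown Khex/w source {source!r}"
            )
        if source is P0Provenance.COSMO and not (
            compound.profile.zwitterion or compound.mw > 1000.0
        ):
            raise UnresolvableP0Error(
                f"{compound.name}: COSMO-derived Khex/w is only accepted for "
                "zwitterions or MW > 1000 g/mol; provide a descriptor-based or "
                "experimental value instead"
            )
        lp_sdm = log_p0_sdm(compound.log_khexw, compound.mw, temperature_c, xm_cm)
        return log_p0_mdck(lp_sdm), source
    raise UnresolvableP0Error(
        f"{compound.name}: no P0 source available (need log_p0_experimental "
        "or log_khexw with a provenance tag)"
    )


def pm_at_pH(log_p0: float, profile: ProtolyticProfile, pH: float) -> float:
    """Membrane permeability at ``pH``: Pm = P0 * f_n (cm/s)."""
    if not math.isfinite(log_p0):
        raise InvalidInputError(f"non-finite log P0: {log_p0!r}")
    return 10.0 ** log_p0 * neutral_fraction(profile, pH)
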