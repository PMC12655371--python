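"""Acid/base speciation: the neutral, membrane-permeant fraction of a compound.

Only the fully uncharged microspecies of an ionizable compound crosses the
hydrophobic membrane core at an appreciable rate (pH-partition hypothesis),
so every membrane permeability in the transport model is weighted by the
neutral fraction ``f_n`` at the pH of the adjacent aqueous compartment.

Sites are treated as independent Henderson–Hasselbalch equilibria: the
protonation state of one group does not shift the pKa of another.  For a
zwitterion the uncharged microspecies (all acids protonated, all bases
deprotonated) is distinguished from the net-neutral zwitterionic one; only
the former counts toward ``f_n``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

ACID = "acid"
BASE = "base"

#: pKa values outside this window are physically implausible for drug-like
#: compounds and usually indicate a parsing or transcription error; they are
#: accepted but logged.
PLAUSIBLE_PKA_RANGE = (-2.0, 16.0)


@dataclass(frozen=True)
class ProtolyticProfile:
    """Ionizable sites of a compound.

    Parameters
    ----------
    sites:
        Tuple of ``(pKa, kind)`` pairs with ``kind`` either ``"acid"`` or
        ``"base"``.
    zwitterion:
        Whether the compound carries at least one acid and one base and can
        populate a net-neutral but doubly charged microspecies.
    """

    sites: tuple[tuple[float, str], ...] = field(default_factory=tuple)
    zwitterion: bool = False

    def __post_init__(self) -> None:
        sites = tuple((float(pka), kind) for pka, kind in self.sites)
        object.__setattr__(self, "sites", sites)
        for pka, kind in sites:
            if not math.isfinite(pka):
                raise InvalidInputError(f"non-finite pKa: {pka!r}")
            if kind not in (ACID, BASE):
                raise InvalidInputError(f"site kind must be 'acid' or 'base', got {kind!r}")
            if not PLAUSIBLE_PKA_RANGE[0] <= pka <= PLAUSIBLE_PKA_RANGE[1]:
                logger.warning("suspicious pKa %.2f outside %s", pka, PLAUSIBLE_PKA_RANGE)
        if self.zwitterion:
            kinds = {kind for _, kind in sites}
            if not {ACID, BASE} <= kinds:
                raise InvalidInputError(
                    "zwitterion flag requires at least one acid and one base site"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @classmethod
    def neutral(cls) -> "ProtolyticProfile":
        """Profile of a compound with no ionizable groups."""
        return cls(sites=(), zwitterion=False)

    @classmethod
    def parse(cls, token: str | None, zwitterion: bool = False) -> "ProtolyticProfile":
        """Parse the table encoding ``"3.4:acid;9.4:base"`` into a profile.

        An empty or missing token yields the neutral profile.
        """
        if token is None or (isinstance(token, float) and math.isnan(token)) or not str(token).strip():
            return cls(sites=(), zwitterion=zwitterion)
        sites = []
        for part in str(token).split(";"):
            part = part.strip()
            if not part:
                continue
            try:
                value, kind = part.split(":")
                sites.append((float(value), kind.strip().lower()))
            except ValueError as exc:
                raise InvalidInputError(f"cannot parse pKa token {part!r}") from exc
        return cls(sites=tuple(sites), zwitterion=zwitterion)


def _site_neutral_probability(pka: float, kind: str, pH: float) -> float:
    """Probability that one site is in its uncharged form at ``pH``."""
    if kind == ACID:
        # neutral = protonated HA; deprotonated fraction grows with pH
        return 1.0 / (1.0 + 10.0 ** (pH - pka))
    # base: neutral = deprotonated B; protonated BH+ grows as pH drops
    return 1.0 / (1.0 + 10.0 ** (pka - pH))


def _enumerate_microspecies(profile: ProtolyticProfile, pH: float) -> float:
    """Uncharged fraction via the explicit protonation-state partition function.

    Each of the 2^n microspecies gets a Boltzmann-like weight that is the
    product of per-site Henderson–Hasselbalch factors; the uncharged species
    is the single state with every acid protonated and every base
    deprotonated.  Log-space accumulation keeps extreme pKa values stable.
    """
    log_weights: list[float] = []
    neutral_log_weight: float | None = None
    for states in itertools.product((0, 1), repeat=profile.n_sites):
        # state 1 = protonated
        lw = 0.0
        is_neutral = True
        for (pka, kind), protonated in zip(profile.sites, states):
            if protonated:
                lw += 0.0  # protonated form is the weight reference
                if kind == BASE:
                    is_neutral = False
            else:
                lw += (pH - pka) * math.log(10.0)
                if kind == ACID:
                    is_neutral = False
        log_weights.append(lw)
        if is_neutral:
            neutral_log_weight = lw
    assert neutral_log_weight is not None
    m = max(log_weights)
    z = sum(math.exp(lw - m) for lw in log_weights)
    return math.exp(neutral_log_weight - m) / z


def neutral_fraction(profile: ProtolyticProfile, pH: float) -> float:
    """Fraction of molecules in the fully uncharged state at ``pH``.

    For independent sites this is the product of per-site neutral
    probabilities; for zwitterions the full microspecies enumeration is used
    so that the zwitterionic (net-neutral, doubly charged) state is counted
    as charged.  Both routes agree analytically under site independence; the
    enumeration makes the zwitterion semantics explicit.

    Returns a value in ``(0, 1]``; exactly 1 for a profile with no sites.
    """
    if not math.isfinite(pH):
        raise InvalidInputError(f"non-finite pH: {pH!r}")
    if profile.n_sites == 0:
        return 1.0
    if profile.zwitterion:
        return _enumerate_microspecies(profile, pH)
    f = 1.0
    for pka, kind in profile.sites:
        f *= _site_neutral_probability(pka, kind, pH)
    return f


# --- cytosolic pH -----------------------------------------------------------

#: Cytosolic pH observed at the reference external pH of 7.4.
CYTOSOL_PH_AT_REFERENCE = 7.2
#: Damping of cytosolic pH against external swings: cells buffer their
#: interior, so the cytosol tracks the bath with a slope well below 1.
CYTOSOL_PH_SLOPE = 0.3
_REFERENCE_EXTERNAL_PH = 7.4

EXTERNAL_PH_RANGE = (4.0, 10.0)


def cytosolic_pH(pH_external: float, mapping=None) -> float:
    """Cytosolic pH as a function of the external (assay buffer) pH.

    The default map is a damped linear homeostasis model anchored at
    7.2 for an external pH of 7.4, with slope 0.3 (the cytosol follows the
    bath only weakly).  Any callable ``pH_ext -> pH_cyt`` can be supplied
    instead, e.g. ``lambda p: p`` for an identity (unbuffered) mapping.
    """
    if not math.isfinite(pH_external):
        raise InvalidInputError(f"non-finite external pH: {pH_external!r}")
    if not EXTERNAL_PH_RANGE[0] <= pH_external <= EXTERNAL_PH_RANGE[1]:
        raise InvalidInputError(
            f"external pH {pH_external} outside supported range {EXTERNAL_PH_RANGE}"
        )
    if mapping is not None:
        return float(mapping(pH_external))
    return CYTOSOL_PH_AT_REFERENCE + CYTOSOL_PH_SLOPE * (pH_external - _REFERENCE_EXTERNAL_PH)
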