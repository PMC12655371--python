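"""Synthetic assay data with known ground truth.

Every pipeline stage can be exercised without laboratory data: compound
panels spanning the log(Pm*Cext) axis, concentration-series bidirectional
assays produced by the forward steady-state model with Michaelis–Menten
efflux and multiplicative measurement noise, and raw acceptor time courses
with recovery losses.  All generators are pure functions of their
configuration and a seed.

Noise is multiplicative lognormal on Papp (assay scatter scales with the
measured value), default CV 5%.  The default borderline truth —
Jmax = 1.6e-4 umol/cm^2/s, Km = 5 uM — parameterises a compound whose ER
visibly collapses with concentration over the practical assay range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .permeability import Compound
from .speciation import ProtolyticProfile, neutral_fraction
from .transport import (
    AssayGeometry,
    Direction,
    MichaelisMentenEfflux,
    build_network,
    steady_state,
)
from .fitting import ConcentrationSeries, TimeCourse

DEFAULT_NOISE_CV = 0.05
DEFAULT_JMAX = 1.6e-4  # umol/cm^2/s
DEFAULT_KM_UM = 5.0
DEFAULT_REPLICATES = 3
DEFAULT_INSERT_AREA_CM2 = 1.12  # 12-well transwell insert


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters behind one simulated compound."""

    compound: Compound
    jmax: float = DEFAULT_JMAX
    km_um: float = DEFAULT_KM_UM
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = 0
    geometry: AssayGeometry = field(default_factory=AssayGeometry)

    def __post_init__(self) -> None:
        if not self.jmax > 0 or not self.km_um > 0:
            raise InvalidInputError("truth needs jmax > 0 and km > 0")
        if not 0.0 <= self.noise_cv < 1.0:
            raise InvalidInputError(f"noise CV must be in [0, 1), got {self.noise_cv!r}")

    @property
    def efflux(self) -> MichaelisMentenEfflux:
        return MichaelisMentenEfflux(jmax=self.jmax, km=self.km_um)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-median multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0.0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


# --- compound panels --------------------------------------------------------


def make_compound_panel(
    n: int,
    log_pmc_range: tuple[float, float] = (-5.0, 1.0),
    seed: int = 0,
    pH: float = 7.4,
) -> pd.DataFrame:
    """Panel of ``n`` compounds whose log10(Pm*Cext) is uniform over a range.

    Molecular weights, ionisation profiles (neutral / weak acid / weak
    base) and applied concentrations are drawn independently; the intrinsic
    permeability is then back-computed so the target log(Pm*Cext) is met
    exactly, and emitted as an experimental log P0 column.  The truth value
    is included as ``log_pmc_true``.
    """
    if n < 1:
        raise InvalidInputError("panel size must be >= 1")
    lo, hi = log_pmc_range
    if not lo < hi:
        raise InvalidInputError(f"empty log_pmc range: {log_pmc_range!r}")
    rng = np.random.default_rng(seed)
    targets = rng.uniform(lo, hi, size=n)
    mw = rng.uniform(200.0, 600.0, size=n)
    cext = 10.0 ** rng.uniform(0.0, 2.0, size=n)  # 1-100 uM
    kinds = rng.integers(0, 3, size=n)  # 0 neutral, 1 acid, 2 base
    rows = []
    for i in range(n):
        if kinds[i] == 0:
            pka_token, profile = "", ProtolyticProfile.neutral()
        elif kinds[i] == 1:
            pka = round(float(rng.uniform(3.0, 6.0)), 2)  # rounded once: table and truth agree
            pka_token = f"{pka:.2f}:acid"
            profile = ProtolyticProfile(sites=((pka, "acid"),))
        else:
            pka = round(float(rng.uniform(7.0, 10.0)), 2)
            pka_token = f"{pka:.2f}:base"
            profile = ProtolyticProfile(sites=((pka, "base"),))
        fn = neutral_fraction(profile, pH)
        log_p0 = targets[i] - np.log10(cext[i]) - np.log10(fn)
        rows.append(
            {
                "name": f"synthetic_{i:03d}",
                "mw": round(float(mw[i]), 1),
                "pka_sites": pka_token,
                "zwitterion": False,
                "log_khexw": np.nan,
                "khexw_source": "",
                "log_p0_exp": float(log_p0),
                "cext_um": float(cext[i]),
                "er": np.nan,
                "permanent_charge": False,
                "log_pmc_true": float(targets[i]),
            }
        )
    return pd.DataFrame(rows)


# --- forward assay simulation ----------------------------------------------


def simulate_assay(
    truth: SyntheticTruth,
    concentrations_um: Sequence[float],
    replicates: int = DEFAULT_REPLICATES,
) -> ConcentrationSeries:
    """Bidirectional Papp series from the forward model with saturable efflux.

    Each concentration is solved in Michaelis–Menten mode in both
    directions; ``replicates`` noisy realisations are averaged and their
    standard deviation reported, emulating replicate inserts.
    """
    conc = np.asarray(list(concentrations_um), dtype=float)
    if conc.size < 3 or np.any(conc <= 0):
        raise InvalidInputError("need >= 3 positive concentrations")
    rng = np.random.default_rng(truth.seed)
    network = build_network(truth.compound, truth.geometry)
    papp_ab, papp_ba, sd_ab, sd_ba = [], [], [], []
    for c in conc:
        result = steady_state(network, c, truth.efflux)
        reps_ab = result.papp_ab * _lognormal_factor(rng, truth.noise_cv, replicates)
        reps_ba = result.papp_ba * _lognormal_factor(rng, truth.noise_cv, replicates)
        papp_ab.append(float(np.mean(reps_ab)))
        papp_ba.append(float(np.mean(reps_ba)))
        sd_ab.append(float(np.std(reps_ab, ddof=1)) if replicates > 1 else 0.0)
        sd_ba.append(float(np.std(reps_ba, ddof=1)) if replicates > 1 else 0.0)
    return ConcentrationSeries(
        cext_um=tuple(conc),
        papp_ab=tuple(papp_ab),
        papp_ba=tuple(papp_ba),
        sd_ab=tuple(sd_ab),
        sd_ba=tuple(sd_ba),
    )


def simulate_timecourse(
    truth: SyntheticTruth,
    direction: Direction = Direction.AB,
    sample_times_s: Sequence[float] = (900.0, 1800.0, 2700.0, 3600.0),
    loss_fraction: float = 0.0,
    cext_um: float = 10.0,
    insert_area_cm2: float = DEFAULT_INSERT_AREA_CM2,
    lag_s: float = 0.0,
    seed: Optional[int] = None,
) -> TimeCourse:
    """Acceptor time course at the model's true Papp, with losses and noise.

    Accumulation is linear at the true directional Papp (sink conditions),
    scaled by ``1 - loss_fraction`` to emulate incomplete recovery; an
    optional lag delays the onset of transport.  The recovery field is set
    to the true ``1 - loss_fraction``, as a mass balance would measure.
    """
    times = np.asarray(list(sample_times_s), dtype=float)
    if np.any(np.diff(times) <= 0) or np.any(times <= 0):
        raise InvalidInputError("sample times must be positive and strictly increasing")
    if not 0.0 <= loss_fraction <= 0.5:
        raise InvalidInputError(f"loss fraction must be in [0, 0.5], got {loss_fraction!r}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    network = build_network(truth.compound, truth.geometry)
    result = steady_state(network, cext_um, truth.efflux)
    papp = result.papp_ab if direction is Direction.AB else result.papp_ba
    rate = papp * insert_area_cm2 * cext_um  # nmol/s (uM == nmol/cm^3)
    effective = np.clip(times - lag_s, 0.0, None)
    amounts = rate * effective * (1.0 - loss_fraction)
    amounts = amounts * _lognormal_factor(rng, truth.noise_cv, size=len(times))
    amounts = np.maximum.accumulate(amounts)  # physical: cumulative never decreases
    return TimeCourse(
        times_s=tuple(times),
        acceptor_amounts_nmol=tuple(amounts),
        donor_initial_um=cext_um,
        insert_area_cm2=insert_area_cm2,
        recovery=1.0 - loss_fraction,
        direction=direction,
    )


# --- canonical borderline panel ---------------------------------------------


def borderline_truth_panel(
    seed: int = 0,
    geometry: Optional[AssayGeometry] = None,
    jmax: float = DEFAULT_JMAX,
    km_um: float = DEFAULT_KM_UM,
    noise_cv: float = DEFAULT_NOISE_CV,
) -> list[SyntheticTruth]:
    """Four borderline compounds showing concentration-dependent efflux.

    Membrane permeabilities at assay pH are spread over log10 Pm in
    [-3.5, -3.05] cm/s — the window in which, with the default energy limit,
    the efflux ratio declines markedly with concentration (from roughly 12
    down to 2 over 1.5-150 uM) while efflux stays clearly measurable at
    every tested concentration.  Two compounds are neutral, one is a weak
    base and one a weak acid; intrinsic permeabilities are back-computed
    from the target Pm so ionisation is compensated.
    """
    geometry = geometry or AssayGeometry()
    specs = [
        ("borderline_a", -3.50, ProtolyticProfile.neutral()),
        ("borderline_b", -3.35, ProtolyticProfile(sites=((8.0, "base"),))),
        ("borderline_c", -3.20, ProtolyticProfile(sites=((5.0, "acid"),))),
        ("borderline_d", -3.05, ProtolyticProfile.neutral()),
    ]
    panel = []
    for i, (name, log_pm, profile) in enumerate(specs):
        fn = neutral_fraction(profile, geometry.pH_apical)
        log_p0 = log_pm - np.log10(fn)
        compound = Compound(
            name=name, mw=400.0 + 25.0 * i, profile=profile, log_p0_experimental=float(log_p0)
        )
        panel.append(
            SyntheticTruth(
                compound=compound,
                jmax=jmax,
                km_um=km_um,
                noise_cv=noise_cv,
                seed=seed + i,
                geometry=geometry,
            )
        )
    return panel
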