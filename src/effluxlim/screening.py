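"""Batch screening of compound tables against the Pm*Cext threshold.

Input is a delimited table with one row per compound (or per literature
datapoint; conflicting efflux ratios for one compound stay separate rows).
Each row is resolved to an intrinsic permeability, speciated at assay pH,
normalised to the applied concentration and classified.  Permanently
charged compounds have no membrane-permeant species and are excluded with
a machine-readable reason code, as are rows whose permeability cannot be
resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UnresolvableP0Error
from .permeability import Compound, P0Provenance, resolve_p0
from .speciation import ProtolyticProfile, neutral_fraction
from .threshold import (
    DEFAULT_BORDERLINE_BAND,
    DEFAULT_LOG_PMC_THRESHOLD,
    ER_SIGNIFICANCE_CUTOFF,
    EffluxClass,
    classify,
)

REQUIRED_COLUMNS = ("name", "mw", "cext_um")
OPTIONAL_COLUMNS = (
    "pka_sites",
    "zwitterion",
    "log_khexw",
    "khexw_source",
    "log_p0_exp",
    "er",
    "permanent_charge",
)

#: Machine-readable exclusion reason codes.
EXCLUDED_PERMANENT_CHARGE = "permanent_charge"
EXCLUDED_UNRESOLVABLE_P0 = "unresolvable_p0"

_SOURCE_ALIASES = {
    "pampa": P0Provenance.PAMPA_SDM,
    "pampa_sdm": P0Provenance.PAMPA_SDM,
    "experimental_descriptors": P0Provenance.SDM_EXPERIMENTAL_DESCRIPTORS,
    "sdm_experimental_descriptors": P0Provenance.SDM_EXPERIMENTAL_DESCRIPTORS,
    "calculated_descriptors": P0Provenance.SDM_CALCULATED_DESCRIPTORS,
    "sdm_calculated_descriptors": P0Provenance.SDM_CALCULATED_DESCRIPTORS,
    "cosmo": P0Provenance.COSMO,
    "mdck_experimental": P0Provenance.MDCK_EXPERIMENTAL,
}


@dataclass(frozen=True)
class ScreenSummary:
    """Dataset-level counts of a screening run."""

    n_compounds: int
    n_datapoints: int
    n_excluded: int
    n_below: int
    n_borderline: int
    n_above: int
    n_outliers: int
    fraction_above_among_nonsubstrates: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and not value.strip():
        return True
    return False


def parse_khexw_source(token) -> Optional[P0Provenance]:
    if _is_missing(token):
        return None
    key = str(token).strip().lower()
    if key not in _SOURCE_ALIASES:
        raise InvalidInputError(f"unknown Khex/w source tag {token!r}")
    return _SOURCE_ALIASES[key]


def compound_from_row(row: pd.Series) -> Compound:
    """Build a :class:`Compound` from one screening-table row."""
    zwit = bool(row.get("zwitterion", False)) if not _is_missing(row.get("zwitterion")) else False
    profile = ProtolyticProfile.parse(row.get("pka_sites"), zwitterion=zwit)
    perm = bool(row.get("permanent_charge", False)) if not _is_missing(row.get("permanent_charge")) else False
    return Compound(
        name=str(row["name"]),
        mw=float(row["mw"]),
        profile=profile,
        log_khexw=None if _is_missing(row.get("log_khexw")) else float(row["log_khexw"]),
        khexw_source=parse_khexw_source(row.get("khexw_source")),
        log_p0_experimental=None if _is_missing(row.get("log_p0_exp")) else float(row["log_p0_exp"]),
        cext_um=float(row["cext_um"]),
        er_literature=None if _is_missing(row.get("er")) else float(row["er"]),
        permanent_charge=perm,
    )


def screen(
    table: pd.DataFrame,
    threshold: float = DEFAULT_LOG_PMC_THRESHOLD,
    band: tuple[float, float] = DEFAULT_BORDERLINE_BAND,
    pH: float = 7.4,
) -> tuple[pd.DataFrame, ScreenSummary]:
    """Classify every row of a compound table against the threshold.

    Returns the annotated table (log P0 with provenance, neutral fraction,
    ``log_pmc``, class label, outlier flag, exclusion reason) and a
    :class:`ScreenSummary`.  Row order does not affect the summary.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"screening table is missing required columns: {missing}")

    out = table.copy()
    n = len(out)
    log_p0 = np.full(n, np.nan)
    provenance = np.array([""] * n, dtype=object)
    fn = np.full(n, np.nan)
    log_pmc = np.full(n, np.nan)
    label = np.array([""] * n, dtype=object)
    outlier = np.zeros(n, dtype=bool)
    excluded = np.array([""] * n, dtype=object)

    for i, (_, row) in enumerate(out.iterrows()):
        compound = compound_from_row(row)
        if compound.permanent_charge:
            excluded[i] = EXCLUDED_PERMANENT_CHARGE
            continue
        try:
            lp0, prov = resolve_p0(compound)
        except UnresolvableP0Error:
            excluded[i] = EXCLUDED_UNRESOLVABLE_P0
            continue
        f = neutral_fraction(compound.profile, pH)
        lpmc = lp0 + math.log10(f) + math.log10(compound.cext_um)
        cls = classify(lpmc, er=compound.er_literature, threshold=threshold, band=band)
        log_p0[i] = lp0
        provenance[i] = prov.value
        fn[i] = f
        log_pmc[i] = lpmc
        label[i] = cls.label.value
        outlier[i] = cls.outlier_flag

    out["log_p0"] = log_p0
    out["p0_provenance"] = provenance
    out["fn"] = fn
    out["log_pmc"] = log_pmc
    out["efflux_class"] = label
    out["outlier_flag"] = outlier
    out["excluded_reason"] = excluded

    kept = out[out["excluded_reason"] == ""]
    er = pd.to_numeric(kept.get("er"), errors="coerce") if "er" in kept else pd.Series(dtype=float)
    nonsub = kept[(er.notna()) & (er < ER_SIGNIFICANCE_CUTOFF)] if len(er) else kept.iloc[0:0]
    frac_above = (
        float(np.mean(nonsub["log_pmc"] > threshold)) if len(nonsub) else float("nan")
    )
    summary = ScreenSummary(
        n_compounds=int(out["name"].nunique()),
        n_datapoints=n,
        n_excluded=int((out["excluded_reason"] != "").sum()),
        n_below=int((kept["efflux_class"] == EffluxClass.BELOW.value).sum()),
        n_borderline=int((kept["efflux_class"] == EffluxClass.BORDERLINE.value).sum()),
        n_above=int((kept["efflux_class"] == EffluxClass.ABOVE.value).sum()),
        n_outliers=int(kept["outlier_flag"].sum()),
        fraction_above_among_nonsubstrates=frac_above,
    )
    return out, summary


def read_compound_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited compound table (TSV by default)."""
    return pd.read_csv(path, sep=sep)


def write_table(frame: pd.DataFrame, path, sep: str = "\t") -> None:
    frame.to_csv(path, sep=sep, index=False)
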