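"""Model for End-Stage Liver Disease (MELD) score, the comparator system.

MELD = 9.57*ln(creatinine) + 3.78*ln(total bilirubin) + 11.2*ln(INR) + 6.43

with creatinine and bilirubin in mg/dL.  Laboratories reporting umol/L are
converted with the standard molar-mass factors (creatinine / 88.4,
bilirubin / 17.1).  By the usual convention each input is floored at 1.0
before taking logs — a sub-unity lab would otherwise subtract points —
which makes 6.43 the minimum attainable score; the floor is switchable.
Higher scores indicate higher short-term mortality risk.  No creatinine
cap or dialysis override is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ConfigurationError, DomainError

__all__ = ["MELDInput", "UMOL_PER_MG_DL", "normalize_units", "meld_score"]

#: umol/L per mg/dL conversion divisors by analyte.
UMOL_PER_MG_DL: dict[str, float] = {"creatinine": 88.4, "bilirubin": 17.1}


@dataclass(frozen=True)
class MELDInput:
    """The three MELD inputs in mg/dL (creatinine, bilirubin) and ratio (INR).

    ``source_units`` records the units the values were converted from, so
    the conversion path stays auditable.
    """

    creatinine: float
    total_bilirubin: float
    inr: float
    source_units: tuple[str, str, str] = ("mg_per_dL", "mg_per_dL", "ratio")


def normalize_units(value: float, analyte: str, unit: str) -> float:
    """Convert a concentration to mg/dL.

    analyte: 'creatinine' or 'bilirubin'; unit: 'umol_per_L' or 'mg_per_dL'
    (mg/dL passes through unchanged).
    """
    if analyte not in UMOL_PER_MG_DL:
        raise ConfigurationError(
            f"unknown analyte {analyte!r}; expected one of {sorted(UMOL_PER_MG_DL)}"
        )
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise DomainError(f"{analyte} concentration must be positive and finite, got {value!r}")
    if unit == "mg_per_dL":
        return float(value)
    if unit == "umol_per_L":
        return float(value) / UMOL_PER_MG_DL[analyte]
    raise ConfigurationError(f"unknown unit {unit!r}; expected 'umol_per_L' or 'mg_per_dL'")


def meld_score(
    creatinine: float | MELDInput,
    total_bilirubin: float | None = None,
    inr: float | None = None,
    *,
    clamp: bool = True,
    floor: float = 1.0,
) -> float:
    """MELD points from creatinine (mg/dL), total bilirubin (mg/dL) and INR.

    With ``clamp`` (default) each input is floored at ``floor`` before the
    logarithm; with clamping off, any non-positive input is a domain error.
    """
    if isinstance(creatinine, MELDInput):
        inp = creatinine
        creatinine, total_bilirubin, inr = inp.creatinine, inp.total_bilirubin, inp.inr
    values = {"creatinine": creatinine, "total_bilirubin": total_bilirubin, "inr": inr}
    for name, v in values.items():
        if v is None or not math.isfinite(v):
            raise DomainError(f"MELD input {name} must be finite, got {v!r}")
        if not clamp and v <= 0:
            raise DomainError(
                f"MELD input {name} must be positive when clamping is disabled, got {v!r}"
            )
    if clamp:
        values = {k: max(v, floor) for k, v in values.items()}
    return (
        9.57 * math.log(values["creatinine"])
        + 3.78 * math.log(values["total_bilirubin"])
        + 11.2 * math.log(values["inr"])
        + 6.43
    )
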