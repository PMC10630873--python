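"""Ratio-response mathematics: the golden logarithm and its elementary scores.

The quantitative-difference (QD) algorithm rests on the Weber-Fechner
observation that perceived (and, empirically, biological) response scales
with the logarithm of a stimulus *ratio*, not its absolute difference.  The
natural unit chosen for that ratio response is the golden section: a paired
measurement (pre, post) is summarised by its golden logarithm

    L_tau = ln(max(pre, post) / min(pre, post)) / ln(phi),

with phi = (1 + sqrt(5)) / 2.  L_tau is dimensionless, symmetric in its two
arguments, invariant under a common rescaling (so unit changes cancel), and
zero exactly when nothing changed.  Note ln(phi) = -ln(tau) for the golden
section tau = (sqrt(5) - 1) / 2, so a base-phi and an inverse-base-tau
reading of the logarithm coincide.

Two elementary scores are derived per indicator:

* the direction score A in {-1, 0, +1}: +1 when the value fell after
  treatment, -1 when it rose, 0 on an exact tie;
* the magnitude score B in {0..3}: L_tau bucketed against a threshold
  scheme.  The default molecular-level scheme uses cuts 0.80 (health),
  1.22 (subhealth) and 1.69 (disease); coarser two-cut schemes exist for
  the organ/tissue (0.47, 0.80) and whole-body (0.27, 0.47) scales.

Bucket boundaries are lower-inclusive: L_tau equal to a cut stays in the
lower bucket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "PHI",
    "LN_PHI",
    "ThresholdScheme",
    "SCHEMES",
    "DEFAULT_SCHEME",
    "golden_log",
    "direction_score",
    "magnitude_score",
]

#: The golden ratio, base of the golden logarithm.
PHI: float = (1.0 + math.sqrt(5.0)) / 2.0

#: Natural log of the golden ratio (== -ln(tau) for tau = (sqrt(5)-1)/2).
LN_PHI: float = math.log(PHI)


@dataclass(frozen=True)
class ThresholdScheme:
    """A named set of strictly increasing L_tau cuts defining score buckets.

    A scheme with k cuts maps L_tau to an integer in {0..k}; the built-in
    schemes carry two cuts (scores 0-2) except ``molecular_beta`` which
    carries three (scores 0-3) and is the default for the scoring workflow.
    """

    level: str
    cuts: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.cuts) not in (2, 3):
            raise ConfigurationError(
                f"threshold scheme {self.level!r} needs 2 or 3 cuts, got {len(self.cuts)}"
            )
        if any(not (c > 0 and math.isfinite(c)) for c in self.cuts):
            raise ConfigurationError(
                f"threshold scheme {self.level!r} has non-positive or non-finite cuts: {self.cuts}"
            )
        if any(a >= b for a, b in zip(self.cuts, self.cuts[1:])):
            raise ConfigurationError(
                f"threshold scheme {self.level!r} cuts must be strictly increasing: {self.cuts}"
            )

    @property
    def cut_low(self) -> float:
        return self.cuts[0]

    @property
    def cut_mid(self) -> float:
        return self.cuts[1]

    @property
    def cut_high(self) -> float | None:
        return self.cuts[2] if len(self.cuts) == 3 else None

    @property
    def max_score(self) -> int:
        return len(self.cuts)


#: Built-in threshold schemes, keyed by level name.
SCHEMES: dict[str, ThresholdScheme] = {
    "cellular_molecular": ThresholdScheme("cellular_molecular", (0.80, 1.22)),
    "organ_tissue": ThresholdScheme("organ_tissue", (0.47, 0.80)),
    "body": ThresholdScheme("body", (0.27, 0.47)),
    "molecular_beta": ThresholdScheme("molecular_beta", (0.80, 1.22, 1.69)),
}

#: Default scheme for the scoring workflow (health / subhealth / disease cuts).
DEFAULT_SCHEME: ThresholdScheme = SCHEMES["molecular_beta"]


def resolve_scheme(scheme: ThresholdScheme | str | None) -> ThresholdScheme:
    """Accept a scheme object, a built-in level name, or None (default)."""
    if scheme is None:
        return DEFAULT_SCHEME
    if isinstance(scheme, ThresholdScheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise ConfigurationError(
            f"unknown threshold scheme {scheme!r}; built-ins: {sorted(SCHEMES)}"
        ) from None


def _check_pair(pre: float, post: float, indicator: str | None) -> None:
    label = f" for indicator {indicator!r}" if indicator else ""
    for name, v in (("pre", pre), ("post", post)):
        if not math.isfinite(v):
            raise DomainError(f"non-finite {name} value {v!r}{label}")
        if v <= 0:
            raise DomainError(
                f"non-positive {name} value {v!r}{label}: the golden logarithm "
                "is undefined for values <= 0"
            )


def golden_log(pre: float, post: float, *, indicator: str | None = None) -> float:
    """Golden logarithm L_tau of a paired measurement.

    Parameters
    ----------
    pre, post
        Strictly positive measurement values in the same units.
    indicator
        Optional name attached to error messages.

    Returns
    -------
    float
        ln(max/min) / ln(phi), always >= 0.
    """
    _check_pair(pre, post, indicator)
    hi, lo = (pre, post) if pre >= post else (post, pre)
    return math.log(hi / lo) / LN_PHI


def direction_score(pre: float, post: float, *, indicator: str | None = None) -> int:
    """Direction of change A: +1 if the value fell, -1 if it rose, 0 on a tie."""
    _check_pair(pre, post, indicator)
    if post < pre:
        return 1
    if post > pre:
        return -1
    return 0


def magnitude_score(
    l_tau: float, scheme: ThresholdScheme | str | None = None
) -> int:
    """Bucketed magnitude B of a golden-logarithm value.

    With the default ``molecular_beta`` scheme: L_tau <= 0.80 -> 0,
    0.80 < L_tau <= 1.22 -> 1, 1.22 < L_tau <= 1.69 -> 2, L_tau > 1.69 -> 3.
    Boundaries are lower-inclusive; the function is non-decreasing in l_tau.
    """
    if not math.isfinite(l_tau) or l_tau < 0:
        raise DomainError(f"golden logarithm must be finite and >= 0, got {l_tau!r}")
    scheme = resolve_scheme(scheme)
    return sum(l_tau > cut for cut in scheme.cuts)
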