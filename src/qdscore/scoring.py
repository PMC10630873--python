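"""Per-indicator and per-patient QD scoring.

Each indicator of a paired pre/post panel is reduced to three signed
integers and their product:

* A — direction of change: +1 fell, -1 rose, 0 tie;
* B — bucketed magnitude of the golden logarithm L_tau (0-3 under the
  default molecular-level thresholds);
* C — normal-range correction: whether the value moved toward (+1) or away
  from (-1) its reference interval, measured as relative distance to the
  nearer bound (0 inside the interval).

The per-indicator score is the literal product A*B*C.  Note the algebra is
taken at face value: an indicator that *worsens* while moving away from its
reference interval has A = -1 and C = -1 and therefore contributes a
*positive* product.  This double-negative behaviour is deliberate — it is
the stated composition rule — and the full breakdown is retained per
indicator so it can be audited.

The composite patient score sums the products of all non-liver indicators
and adds a liver contribution gated by two binary conditions on the
four-indicator liver panel (ALT, AST, total and conjugated bilirubin):

* D gate — all four decreased (sum of A == 4);
* E gate — summed B >= 9, i.e. at least three of the four decreased by more
  than the disease-level threshold.

Under the default rule the liver contribution is D*E*sum(A*B*C) over the
panel, so a panel in which any liver indicator rose contributes nothing.
Alternative combination rules (a flat gated bonus, or the ungated sum plus
a gated bonus) are selectable via :class:`LiverRule`.

Higher composite scores indicate better therapeutic efficacy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .exceptions import ContractError, InputError
from .golden import (
    ThresholdScheme,
    direction_score,
    golden_log,
    magnitude_score,
    resolve_scheme,
)
from .registry import LIVER_PANEL, IndicatorSpec

__all__ = [
    "PairedMeasurement",
    "IndicatorScore",
    "QDBreakdown",
    "PatientPanel",
    "LiverRule",
    "normal_range_score",
    "score_indicator",
    "liver_modification",
    "score_patient",
]


@dataclass(frozen=True)
class PairedMeasurement:
    """One patient's pre- and post-treatment values for one indicator."""

    indicator: str
    pre: float
    post: float


@dataclass(frozen=True)
class IndicatorScore:
    """The A/B/C decomposition and product for one scored indicator."""

    indicator: str
    a: int
    b: int
    c: int
    l_tau: float
    is_liver_panel: bool = False

    @property
    def product(self) -> int:
        return self.a * self.b * self.c


@dataclass(frozen=True)
class QDBreakdown:
    """A patient's full scoring breakdown.

    ``d_gate``/``e_gate`` are None when the liver panel was incomplete and
    the gates therefore undefined (the liver contribution is then 0).
    """

    per_indicator: tuple[IndicatorScore, ...]
    skipped: tuple[str, ...]
    d_gate: int | None
    e_gate: int | None
    liver_contribution: int
    non_liver_sum: int
    total: int

    @property
    def gates_defined(self) -> bool:
        return self.d_gate is not None


@dataclass(frozen=True)
class PatientPanel:
    """A patient's paired measurements plus cohort annotations."""

    patient_id: str
    measurements: tuple[PairedMeasurement, ...]
    arm: str | None = None
    outcome: str | None = None
    status_flags: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class LiverRule:
    """How the gated liver panel enters the composite score.

    kind:
      * ``gated_sum`` (default) — D*E*sum(A*B*C) over the four indicators;
      * ``flat_bonus`` — D*E*bonus;
      * ``ungated_plus_bonus`` — sum(A*B*C) + D*E*bonus.
    """

    kind: str = "gated_sum"
    bonus: int = 12

    _KINDS = ("gated_sum", "flat_bonus", "ungated_plus_bonus")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ContractError(
                f"unknown liver combination rule {self.kind!r}; choose from {self._KINDS}"
            )

    def contribution(self, d_gate: int, e_gate: int, panel_sum: int) -> int:
        gate = d_gate * e_gate
        if self.kind == "gated_sum":
            return gate * panel_sum
        if self.kind == "flat_bonus":
            return gate * self.bonus
        return panel_sum + gate * self.bonus


def _relative_distance(value: float, spec: IndicatorSpec) -> float:
    """Relative distance from a value to the reference interval (0 inside)."""
    low, high = spec.ref_low, spec.ref_high
    if low is not None and value < low:
        return (low - value) / low
    if high is not None and value > high:
        return (value - high) / high
    return 0.0


def normal_range_score(pre: float, post: float, spec: IndicatorSpec) -> int:
    """Normal-range correction C.

    Distances to the reference interval are relative (scaled by the nearer
    bound) so open-ended intervals and disparate units behave comparably.
    Returns +1 when the post value is strictly closer to (or both values
    are inside) the interval, -1 when it is strictly farther, 0 when both
    are equally far outside.
    """
    d_pre = _relative_distance(pre, spec)
    d_post = _relative_distance(post, spec)
    if d_post < d_pre or (d_pre == 0.0 and d_post == 0.0):
        return 1
    if d_post > d_pre:
        return -1
    return 0


def score_indicator(
    m: PairedMeasurement,
    spec: IndicatorSpec,
    scheme: ThresholdScheme | str | None = None,
) -> IndicatorScore:
    """Score one paired measurement against its registry spec.

    The magnitude threshold scheme resolves, in order: the ``scheme``
    argument, the spec's per-indicator override, then the molecular-level
    default.
    """
    if scheme is None and spec.scheme is not None:
        scheme = spec.scheme
    scheme = resolve_scheme(scheme)
    a = direction_score(m.pre, m.post, indicator=m.indicator)
    l_tau = golden_log(m.pre, m.post, indicator=m.indicator)
    b = magnitude_score(l_tau, scheme)
    c = normal_range_score(m.pre, m.post, spec)
    return IndicatorScore(
        indicator=m.indicator,
        a=a,
        b=b,
        c=c,
        l_tau=l_tau,
        is_liver_panel=spec.is_liver_panel,
    )


def liver_modification(
    scores: Iterable[IndicatorScore],
    rule: LiverRule | None = None,
) -> tuple[int, int, int]:
    """Apply the four-liver-indicator modification.

    Returns ``(d_gate, e_gate, liver_contribution)``.  Requires exactly the
    four liver-panel indicators, each scored once.
    """
    rule = rule or LiverRule()
    scores = list(scores)
    names = sorted(s.indicator for s in scores)
    if names != sorted(LIVER_PANEL):
        raise ContractError(
            f"liver modification requires exactly the indicators {sorted(LIVER_PANEL)}, "
            f"got {names}"
        )
    sum_a = sum(s.a for s in scores)
    sum_b = sum(s.b for s in scores)
    d_gate = int(sum_a == len(LIVER_PANEL))
    e_gate = int(sum_b >= 9)
    panel_sum = sum(s.product for s in scores)
    return d_gate, e_gate, rule.contribution(d_gate, e_gate, panel_sum)


def _iter_measurements(
    panel: PatientPanel | Mapping[str, tuple[float, float]] | Iterable[PairedMeasurement],
) -> list[PairedMeasurement]:
    if isinstance(panel, PatientPanel):
        return list(panel.measurements)
    if isinstance(panel, Mapping):
        return [PairedMeasurement(k, *v) for k, v in panel.items()]
    return list(panel)


def score_patient(
    panel: PatientPanel | Mapping[str, tuple[float, float]] | Iterable[PairedMeasurement],
    registry: Mapping[str, IndicatorSpec],
    scheme: ThresholdScheme | str | None = None,
    liver_rule: LiverRule | None = None,
) -> QDBreakdown:
    """Compute a patient's composite QD score with its full breakdown.

    Indicators missing either value (NaN/None) or absent from the registry
    are skipped, contribute 0, and are listed in ``skipped``.  The liver
    modification applies only when all four liver-panel indicators were
    scored; otherwise the gates are undefined and the liver contribution
    is 0 (a warning is emitted).
    """
    measurements = _iter_measurements(panel)
    if not measurements:
        raise InputError("empty panel: nothing to score")

    scored: list[IndicatorScore] = []
    skipped: list[str] = []
    for m in measurements:
        spec = registry.get(m.indicator)
        missing = any(
            v is None or (isinstance(v, float) and not math.isfinite(v))
            for v in (m.pre, m.post)
        )
        if spec is None or missing:
            skipped.append(m.indicator)
            continue
        scored.append(score_indicator(m, spec, scheme))
    if not scored:
        raise InputError("panel has no scoreable indicator")

    liver = [s for s in scored if s.is_liver_panel]
    non_liver_sum = sum(s.product for s in scored if not s.is_liver_panel)
    if len(liver) == len(LIVER_PANEL):
        d_gate, e_gate, contribution = liver_modification(liver, liver_rule)
    else:
        warnings.warn(
            "liver panel incomplete: gates undefined, liver contribution set to 0",
            stacklevel=2,
        )
        d_gate = e_gate = None
        contribution = 0

    return QDBreakdown(
        per_indicator=tuple(scored),
        skipped=tuple(skipped),
        d_gate=d_gate,
        e_gate=e_gate,
        liver_contribution=contribution,
        non_liver_sum=non_liver_sum,
        total=non_liver_sum + contribution,
    )
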