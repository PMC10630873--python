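"""Indicator registry: names, units, reference intervals, liver-panel flags.

The registry is plain editable data (YAML); the packaged default covers the
21-indicator ACLF panel with standard adult reference intervals and marks
the four liver-panel indicators whose joint behaviour gates the D/E
modification: alanine aminotransferase, aspartate aminotransferase, total
bilirubin and conjugated bilirubin.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .golden import SCHEMES

__all__ = ["IndicatorSpec", "LIVER_PANEL", "load_registry", "default_registry"]

#: The four liver-function indicators subject to the D/E gate modification.
LIVER_PANEL: tuple[str, ...] = (
    "alanine_aminotransferase",
    "aspartate_aminotransferase",
    "total_bilirubin",
    "conjugated_bilirubin",
)


@dataclass(frozen=True)
class IndicatorSpec:
    """One laboratory indicator: identity, units, reference interval, flags.

    At least one of ``ref_low`` / ``ref_high`` must be present; an absent
    bound is treated as an open end (-inf / +inf) by the normal-range
    correction.  ``scheme`` optionally names a per-indicator threshold
    scheme overriding the workflow default.
    """

    name: str
    units: str = ""
    ref_low: float | None = None
    ref_high: float | None = None
    is_liver_panel: bool = False
    scheme: str | None = None

    def __post_init__(self) -> None:
        if self.ref_low is None and self.ref_high is None:
            raise ConfigurationError(
                f"indicator {self.name!r} has no reference interval: at least one "
                "of ref_low/ref_high is required for the normal-range correction"
            )
        for label, v in (("ref_low", self.ref_low), ("ref_high", self.ref_high)):
            if v is not None and not v > 0:
                raise ConfigurationError(
                    f"indicator {self.name!r}: {label} must be a positive real, got {v!r}"
                )
        if (
            self.ref_low is not None
            and self.ref_high is not None
            and not self.ref_low < self.ref_high
        ):
            raise ConfigurationError(
                f"indicator {self.name!r}: ref_low ({self.ref_low}) must be < "
                f"ref_high ({self.ref_high})"
            )
        if self.scheme is not None and self.scheme not in SCHEMES:
            raise ConfigurationError(
                f"indicator {self.name!r}: unknown threshold scheme {self.scheme!r}"
            )


def _build(entries: list[dict]) -> dict[str, IndicatorSpec]:
    registry: dict[str, IndicatorSpec] = {}
    for entry in entries:
        try:
            spec = IndicatorSpec(**entry)
        except TypeError as exc:
            raise ConfigurationError(f"bad registry entry {entry!r}: {exc}") from None
        if spec.name in registry:
            raise ConfigurationError(f"duplicate registry entry {spec.name!r}")
        registry[spec.name] = spec
    if not registry:
        raise ConfigurationError("registry contains no indicators")
    return registry


def load_registry(path: str | Path) -> dict[str, IndicatorSpec]:
    """Load an indicator registry from a YAML file.

    The file must contain a top-level ``indicators:`` list of mappings with
    keys name, units, ref_low, ref_high, is_liver_panel, scheme (the last
    four optional).  Validation happens here, at load time, so per-call
    scoring never sees an unusable spec.
    """
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "indicators" not in payload:
        raise ConfigurationError(f"{path}: expected a top-level 'indicators' list")
    return _build(payload["indicators"])


def default_registry() -> dict[str, IndicatorSpec]:
    """The packaged 21-indicator ACLF registry."""
    source = resources.files("qdscore.data").joinpath("registry.yaml")
    payload = yaml.safe_load(source.read_text(encoding="utf-8"))
    return _build(payload["indicators"])
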