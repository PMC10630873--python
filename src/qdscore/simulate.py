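"""Seeded synthetic ACLF cohort generator.

No patient-level data exist for this kind of study, so the pipeline is
exercised on synthetic cohorts with the statistical structure the analysis
assumes:

* pre-treatment values per indicator are drawn from a log-normal
  moment-matched to a configured natural-scale mean/SD (lab values are
  positive and right-skewed — several panel SDs exceed their means — so a
  normal marginal would produce negatives);
* post-treatment values follow the multiplicative treatment-effect model
  ``post = pre * multiplier * exp(eps)``, ``eps ~ N(0, dispersion^2)``,
  where the multiplier is the expected post/pre ratio and the dispersion
  the log-scale SD of the patient-level response;
* outcome labels and clinical-status flags (fatigue, abdominal distension,
  anorexia, jaundice, lower-limb oedema) are attached per patient.

Indicators are generated independently (no inter-lab correlation) — a
``correlation`` hook exists on :class:`CohortConfig` but ships off.  The
seed governs a named stream with one sub-stream per patient index, so
enlarging a cohort never reshuffles the patients already drawn.

Built-in effect profiles parameterise the expected post/pre ratios from the
packaged two-arm cohort summary (``dpmas_responder`` and ``conventional``
use each arm's post/pre mean ratios, e.g. ALT 50.58/689.29 ~ 0.073 for the
responder), plus a ``non_responder`` profile whose bilirubins rise, which
closes the liver D gate by construction.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InputError

__all__ = [
    "EffectProfile",
    "CohortConfig",
    "STATUS_FLAGS",
    "load_baselines",
    "builtin_profile",
    "default_config",
    "generate_cohort",
    "generate_study",
    "effect_recovery_check",
]

#: Clinical-status flags carried per patient; values are
#: 'improved', 'deteriorated_or_unchanged' or 'absent'.
STATUS_FLAGS: tuple[str, ...] = (
    "fatigue",
    "abdominal_distension",
    "anorexia",
    "jaundice",
    "lower_limb_oedema",
)

#: Default log-scale SD of the patient-level post/pre response.
DEFAULT_DISPERSION: float = 0.3


@dataclass(frozen=True)
class EffectProfile:
    """A treatment-effect profile: expected post/pre ratio per indicator.

    ``flag_improved_prob`` / ``flag_absent_prob`` drive the clinical-status
    flag draw (remaining mass is 'deteriorated_or_unchanged').
    """

    name: str
    outcome_label: str
    multipliers: Mapping[str, float]
    dispersions: Mapping[str, float] = field(default_factory=dict)
    default_dispersion: float = DEFAULT_DISPERSION
    flag_improved_prob: float = 0.5
    flag_absent_prob: float = 0.15

    def __post_init__(self) -> None:
        if self.outcome_label not in ("recovered", "dropped_out", "died"):
            raise ConfigurationError(f"unknown outcome label {self.outcome_label!r}")
        bad = {k: v for k, v in self.multipliers.items() if not v > 0}
        bad.update({k: v for k, v in self.dispersions.items() if not v > 0})
        if bad or not self.default_dispersion > 0:
            raise ConfigurationError(
                f"profile {self.name!r}: multipliers and dispersions must be "
                f"strictly positive (offending: {bad or self.default_dispersion})"
            )

    def multiplier(self, indicator: str) -> float:
        return float(self.multipliers.get(indicator, 1.0))

    def dispersion(self, indicator: str) -> float:
        return float(self.dispersions.get(indicator, self.default_dispersion))


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration: arm label, size, seed and baselines.

    ``baselines`` maps indicator -> (natural-scale mean, SD) of the
    pre-treatment distribution.  The same seed and config always produce a
    byte-identical cohort.
    """

    arm: str
    n: int
    seed: int
    baselines: Mapping[str, tuple[float, float]]
    correlation: np.ndarray | None = None  # hook; off by default

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError(f"cohort size must be positive, got {self.n}")
        if not self.baselines:
            raise ConfigurationError("baselines mapping is empty")
        for name, (mean, sd) in self.baselines.items():
            if not (mean > 0 and sd > 0):
                raise ConfigurationError(
                    f"baseline for {name!r} must have positive mean and SD, got {(mean, sd)}"
                )
        if self.correlation is not None:
            raise ConfigurationError(
                "inter-indicator correlation is a hook only; no covariance "
                "structure is configured in this release"
            )


def load_baselines() -> dict:
    """The packaged two-arm cohort summary (means/SDs per indicator)."""
    source = resources.files("qdscore.data").joinpath("cohort_baselines.yaml")
    return yaml.safe_load(source.read_text(encoding="utf-8"))["arms"]


def _arm_ratio_multipliers(arm: dict) -> dict[str, float]:
    return {
        name: row["post_mean"] / row["pre_mean"]
        for name, row in arm["indicators"].items()
    }


def builtin_profile(name: str) -> EffectProfile:
    """One of the named built-in effect profiles.

    * ``dpmas_responder`` — the artificial-liver-support arm's post/pre mean
      ratios; strong liver-panel clearance; outcome 'recovered'.
    * ``conventional`` — the conventional arm's ratios; outcome 'dropped_out'.
    * ``non_responder`` — transaminases fall but both bilirubins rise (the
      pattern of patients who dropped out or died); outcome 'died'.
    """
    arms = load_baselines()
    if name == "dpmas_responder":
        return EffectProfile(
            name=name,
            outcome_label="recovered",
            multipliers=_arm_ratio_multipliers(arms["dpmas"]),
            flag_improved_prob=0.70,
        )
    if name == "conventional":
        return EffectProfile(
            name=name,
            outcome_label="dropped_out",
            multipliers=_arm_ratio_multipliers(arms["conventional"]),
            flag_improved_prob=0.35,
        )
    if name == "non_responder":
        multipliers = {k: 1.0 for k in arms["dpmas"]["indicators"]}
        multipliers.update(
            {
                "alanine_aminotransferase": 0.45,
                "aspartate_aminotransferase": 0.60,
                "total_bilirubin": 1.25,
                "conjugated_bilirubin": 1.20,
            }
        )
        return EffectProfile(
            name=name,
            outcome_label="died",
            multipliers=multipliers,
            flag_improved_prob=0.15,
        )
    raise ConfigurationError(
        f"unknown built-in profile {name!r}; choose from "
        "'dpmas_responder', 'conventional', 'non_responder'"
    )


def default_config(arm: str, seed: int, n: int | None = None) -> CohortConfig:
    """A CohortConfig for one of the packaged arms ('dpmas' or 'conventional')."""
    arms = load_baselines()
    if arm not in arms:
        raise ConfigurationError(f"unknown arm {arm!r}; choose from {sorted(arms)}")
    baselines = {
        name: (row["pre_mean"], row["pre_sd"])
        for name, row in arms[arm]["indicators"].items()
    }
    return CohortConfig(arm=arm, n=n or arms[arm]["n"], seed=seed, baselines=baselines)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given natural-scale mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _patient_rng(seed: int, arm: str, index: int) -> np.random.Generator:
    # sub-stream per patient index: adding patients never reshuffles others
    arm_key = zlib.crc32(arm.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(arm_key, int(index)))
    )


def generate_cohort(config: CohortConfig, profile: EffectProfile) -> pd.DataFrame:
    """Generate one synthetic treatment arm as a long-format cohort table.

    Columns: patient_id, arm, outcome, the five clinical-status flags,
    indicator, pre, post.  Every generated lab value is strictly positive.
    """
    indicators = list(config.baselines)
    rows = []
    flag_levels = np.array(["improved", "deteriorated_or_unchanged", "absent"])
    flag_p = np.array(
        [
            profile.flag_improved_prob,
            1.0 - profile.flag_improved_prob - profile.flag_absent_prob,
            profile.flag_absent_prob,
        ]
    )
    if flag_p.min() < 0:
        raise ConfigurationError("flag probabilities exceed 1")
    for i in range(config.n):
        rng = _patient_rng(config.seed, config.arm, i)
        patient_id = f"{config.arm}-{i + 1:03d}"
        flags = {name: rng.choice(flag_levels, p=flag_p) for name in STATUS_FLAGS}
        for name in indicators:
            mu, sigma = _lognormal_params(*config.baselines[name])
            pre = float(np.exp(rng.normal(mu, sigma)))
            eps = rng.normal(0.0, profile.dispersion(name))
            post = float(pre * profile.multiplier(name) * np.exp(eps))
            rows.append(
                {
                    "patient_id": patient_id,
                    "arm": config.arm,
                    "outcome": profile.outcome_label,
                    **flags,
                    "indicator": name,
                    "pre": pre,
                    "post": post,
                }
            )
    return pd.DataFrame(rows)


def generate_study(seed: int, n_dpmas: int | None = None, n_conventional: int | None = None) -> pd.DataFrame:
    """A two-arm study: a responder-profiled dpmas arm and a conventional arm.

    Within each arm a minority of patients follow the non-responder profile
    (roughly the observed 2:1 / 5:7 recovered-vs-not split of a 15 + 12
    cohort), so outcome groups are mixed as a real study's are.
    """
    arms = load_baselines()
    n_dpmas = n_dpmas or arms["dpmas"]["n"]
    n_conventional = n_conventional or arms["conventional"]["n"]
    responder = builtin_profile("dpmas_responder")
    conventional = builtin_profile("conventional")
    non_responder = builtin_profile("non_responder")

    parts = []
    # dpmas arm: ~2/3 responders, remainder non-responders
    n_resp = max(1, round(n_dpmas * 2 / 3))
    cfg = default_config("dpmas", seed=seed, n=n_resp)
    parts.append(generate_cohort(cfg, responder))
    if n_dpmas - n_resp > 0:
        cfg = CohortConfig(
            arm="dpmas_nr", n=n_dpmas - n_resp, seed=seed, baselines=cfg.baselines
        )
        part = generate_cohort(cfg, non_responder)
        part["arm"] = "dpmas"
        parts.append(part)
    # conventional arm: mostly drop-outs, a few deaths
    n_conv_main = max(1, round(n_conventional * 3 / 4))
    cfg = default_config("conventional", seed=seed, n=n_conv_main)
    parts.append(generate_cohort(cfg, conventional))
    if n_conventional - n_conv_main > 0:
        cfg2 = CohortConfig(
            arm="conv_nr",
            n=n_conventional - n_conv_main,
            seed=seed,
            baselines=cfg.baselines,
        )
        part = generate_cohort(cfg2, non_responder)
        part["arm"] = "conventional"
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def effect_recovery_check(
    cohort: pd.DataFrame, profile: EffectProfile, z: float = 3.0
) -> pd.DataFrame:
    """Parameter-recovery harness: geometric-mean post/pre ratio per indicator.

    Under the generative model the patient-level log ratio is
    N(ln multiplier, dispersion^2), so the geometric-mean ratio should lie
    within multiplier * exp(+/- z * dispersion / sqrt(n)).  Returns a frame
    with the estimate, the tolerance band (which widens naturally at small
    n) and a pass/fail verdict per indicator.
    """
    if cohort.empty:
        raise InputError("empty cohort: nothing to check")
    out = []
    for name, grp in cohort.groupby("indicator", sort=True):
        log_ratio = np.log(grp["post"].to_numpy() / grp["pre"].to_numpy())
        n = len(log_ratio)
        estimate = float(np.exp(log_ratio.mean()))
        mult = profile.multiplier(name)
        half_width = z * profile.dispersion(name) / math.sqrt(n)
        lo, hi = mult * math.exp(-half_width), mult * math.exp(half_width)
        out.append(
            {
                "indicator": name,
                "n": n,
                "multiplier": mult,
                "estimate": estimate,
                "tol_low": lo,
                "tol_high": hi,
                "ok": bool(lo <= estimate <= hi),
            }
        )
    return pd.DataFrame(out)
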