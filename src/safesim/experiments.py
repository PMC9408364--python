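"""Scenario runner and gain calibration.

Reproduces the two experimental designs: single-variable scenarios that set
one context field (IGII, GKS, or GI) to a low (2) or high (8) site mean
while holding the others at their defaults, and a multi-variable design of
four combined scenarios (IGII, GI, GKS) = (2,2,2), (8,2,2), (8,8,2),
(8,8,8). Scenarios share a deterministic seed schedule (base_seed +
replicate index) so that cross-scenario comparisons are coupled draw for
draw.

The cultivation gain — the one free parameter the model needs to bridge
the 0-10 field scale and the 0-100 willingness scale — is set by
``calibrate_gain``: a bisection on the replicate median onset, which is
monotone nonincreasing in the gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .dynamics import run
from .metrics import RunResult, ScenarioSummary, onset_tick, summarize_replicates
from .model_core import ModelConfig, validate_config

__all__ = [
    "CalibrationError",
    "ScenarioSpec",
    "run_scenario",
    "single_variable_specs",
    "single_variable_suite",
    "multi_variable_specs",
    "multi_variable_suite",
    "calibrate_gain",
]


class CalibrationError(RuntimeError):
    """The calibration target is not bracketed by the supplied gain bounds."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One named scenario: config overrides plus a replicate seed schedule.

    Replicate i runs with seed ``base_seed + i``.
    """

    name: str
    overrides: Mapping[str, Any] = field(default_factory=dict)
    replicates: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1 (got {self.replicates})")

    def seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.replicates)]


def run_scenario(
    spec: ScenarioSpec, base: ModelConfig
) -> tuple[list[RunResult], ScenarioSummary]:
    """Run all replicates of one scenario and summarize them."""
    base_dict = base.to_dict()
    results = [
        run(validate_config({**base_dict, **spec.overrides, "seed": seed}))
        for seed in spec.seeds()
    ]
    return results, summarize_replicates(results, spec.name)


def single_variable_specs(replicates: int = 100, base_seed: int = 0) -> list[ScenarioSpec]:
    """Low/high (2 vs 8) scenarios for each context field, others at defaults."""
    specs = []
    for var in ("igii", "gks", "gi"):
        for label, level in (("low", 2), ("high", 8)):
            specs.append(
                ScenarioSpec(
                    name=f"{var}_{label}",
                    overrides={f"initial_{var}": level},
                    replicates=replicates,
                    base_seed=base_seed,
                )
            )
    return specs


def single_variable_suite(
    base: ModelConfig, replicates: int = 100, base_seed: int = 0
) -> list[ScenarioSummary]:
    """Six summaries: igii_low/high, gks_low/high, gi_low/high."""
    return [
        run_scenario(spec, base)[1]
        for spec in single_variable_specs(replicates, base_seed)
    ]


# (IGII, GI, GKS) levels, in the published order.
_MULTI_LEVELS = [(2, 2, 2), (8, 2, 2), (8, 8, 2), (8, 8, 8)]


def multi_variable_specs(replicates: int = 100, base_seed: int = 0) -> list[ScenarioSpec]:
    """The four combined scenarios (IGII, GI, GKS) = (2,2,2)...(8,8,8)."""
    return [
        ScenarioSpec(
            name=f"combo_{igii}_{gi}_{gks}",
            overrides={"initial_igii": igii, "initial_gi": gi, "initial_gks": gks},
            replicates=replicates,
            base_seed=base_seed,
        )
        for igii, gi, gks in _MULTI_LEVELS
    ]


def multi_variable_suite(
    base: ModelConfig, replicates: int = 100, base_seed: int = 0
) -> list[ScenarioSummary]:
    """Four summaries, in increasing-context order (2,2,2) -> (8,8,8)."""
    return [
        run_scenario(spec, base)[1]
        for spec in multi_variable_specs(replicates, base_seed)
    ]


def _median_onset(base: ModelConfig, gain: float, replicates: int, base_seed: int) -> float:
    """Replicate median onset at a given gain; no-onset runs count as +inf."""
    onsets = []
    base_dict = base.to_dict()
    for i in range(replicates):
        cfg = validate_config(
            {**base_dict, "cultivation_gain": gain, "seed": base_seed + i}
        )
        o = onset_tick(run(cfg))
        onsets.append(np.inf if o is None else o)
    return float(np.median(onsets))


def calibrate_gain(
    base: ModelConfig,
    target_onset_median: float,
    replicates: int = 100,
    bounds: tuple[float, float] = (0.05, 5.0),
    base_seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Find the cultivation gain whose baseline median onset hits the target.

    Bisection on the gain, exploiting that the median onset is monotone
    nonincreasing in it. Runs that never onset within the tick budget enter
    the median as +inf (explicit censoring). Returns a gain at which the
    median equals the target, or the bracket midpoint once the bracket
    width drops below ``tol``.

    Raises :class:`CalibrationError` unless the bounds bracket the target
    (median onset at the low bound above the target, at the high bound at
    or below it).
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError(f"bounds must satisfy 0 < low < high (got {bounds})")
    f_lo = _median_onset(base, lo, replicates, base_seed)
    f_hi = _median_onset(base, hi, replicates, base_seed)
    if f_lo <= target_onset_median:
        raise CalibrationError(
            f"median onset at low gain {lo} is {f_lo} <= target "
            f"{target_onset_median}; widen bounds downward"
        )
    if f_hi > target_onset_median:
        raise CalibrationError(
            f"median onset at high gain {hi} is {f_hi} > target "
            f"{target_onset_median}; widen bounds upward"
        )
    if f_hi == target_onset_median:
        return hi
    for _ in range(max_iter):
        if hi - lo < tol:
            break
        mid = 0.5 * (lo + hi)
        f_mid = _median_onset(base, mid, replicates, base_seed)
        if f_mid > target_onset_median:
            lo = mid
        elif f_mid < target_onset_median:
            hi = mid
        else:
            return mid
    return 0.5 * (lo + hi)
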