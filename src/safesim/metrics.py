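"""Summary quantities of run time series: onset, plateau, replicate summaries.

Onset is the first tick at which any worker exhibits safety behavior.
"Stabilization" is operationalized on the latent willing count — the
monotone series — as the first tick reaching a configurable fraction
(default 95%) of its final value; the noisy exhibiting series is unsuitable
for a first-crossing definition. The plateau level is the tail-window mean
of the exhibiting count, which in saturated runs fluctuates binomially
around n x adoption probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RunResult",
    "ScenarioSummary",
    "onset_tick",
    "plateau_tick",
    "plateau_level",
    "summarize_replicates",
]


@dataclass(frozen=True)
class RunResult:
    """Per-tick time series of one seeded run.

    Both series are indexed t = 0..ticks; values lie in [0, n_workers].
    ``config_digest`` identifies the configuration up to the seed, so
    replicates of one scenario share it.
    """

    exhibiting_count: np.ndarray
    willing_count: np.ndarray
    seed: int
    config_digest: str
    n_workers: int

    def __post_init__(self) -> None:
        ex, wi = self.exhibiting_count, self.willing_count
        if len(ex) != len(wi):
            raise ValueError("series lengths must match")
        for arr in (ex, wi):
            if arr.size and (arr.min() < 0 or arr.max() > self.n_workers):
                raise ValueError("counts must lie in [0, n_workers]")

    @property
    def ticks(self) -> int:
        return len(self.exhibiting_count) - 1


@dataclass(frozen=True)
class ScenarioSummary:
    """Replicate-aggregated onset/plateau statistics for one scenario.

    Runs that never reach onset (or plateau) are excluded from the medians
    and counted explicitly in ``n_no_onset`` — never dropped silently.
    """

    scenario_name: str
    replicates: int
    onset_median: Optional[float]
    onset_iqr: Optional[float]
    plateau_tick_median: Optional[float]
    plateau_level_mean: float
    plateau_fraction: float
    n_no_onset: int


def onset_tick(series: RunResult) -> Optional[int]:
    """Smallest t with at least one exhibiting worker; None if never."""
    nz = np.flatnonzero(series.exhibiting_count)
    return int(nz[0]) if nz.size else None


def plateau_tick(series: RunResult, fraction: float = 0.95) -> Optional[int]:
    """Smallest t where the willing count reaches ``fraction`` of its final value.

    Defined on the latent willing series, which is monotone under
    time-constant fields. None if the run ends with no willing worker.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1] (got {fraction})")
    final = series.willing_count[-1]
    if final == 0:
        return None
    hits = np.flatnonzero(series.willing_count >= fraction * final)
    return int(hits[0])


def plateau_level(series: RunResult, tail_window: int = 10) -> float:
    """Mean exhibiting count over the final ``tail_window`` ticks."""
    if not 1 <= tail_window <= len(series.exhibiting_count):
        raise ValueError(
            f"tail_window must lie in 1..{len(series.exhibiting_count)} "
            f"(got {tail_window})"
        )
    return float(series.exhibiting_count[-tail_window:].mean())


def _median_iqr(values: list[int]) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    return float(np.median(arr)), float(q3 - q1)


def summarize_replicates(
    results: Sequence[RunResult],
    name: str,
    plateau_fraction_threshold: float = 0.95,
    tail_window: int = 10,
) -> ScenarioSummary:
    """Aggregate replicate runs of one scenario.

    All results must share a config digest (same scenario up to seed).
    ``tail_window`` is clamped to the series length so short runs still
    summarize.
    """
    if not results:
        raise ValueError("summarize_replicates requires at least one result")
    digests = {r.config_digest for r in results}
    if len(digests) > 1:
        raise ValueError(f"mixed configurations in one summary: {sorted(digests)}")

    onsets = [onset_tick(r) for r in results]
    n_no_onset = sum(o is None for o in onsets)
    onset_median, onset_iqr = _median_iqr([o for o in onsets if o is not None])

    plateaus = [plateau_tick(r, plateau_fraction_threshold) for r in results]
    plateau_median, _ = _median_iqr([p for p in plateaus if p is not None])

    window = min(tail_window, min(len(r.exhibiting_count) for r in results))
    level_mean = float(np.mean([plateau_level(r, window) for r in results]))
    n_workers = results[0].n_workers
    return ScenarioSummary(
        scenario_name=name,
        replicates=len(results),
        onset_median=onset_median,
        onset_iqr=onset_iqr,
        plateau_tick_median=plateau_median,
        plateau_level_mean=level_mean,
        plateau_fraction=level_mean / n_workers if n_workers else 0.0,
        n_no_onset=n_no_onset,
    )
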