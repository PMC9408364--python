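"""Per-tick update rules and the run loop.

Each tick, every worker (in id order): (1) moves to a uniformly chosen
Moore neighbor with torus wrapping; (2) accumulates a willingness increment
from the context fields of its new cell; (3) has its net willingness
evaluated (baseline + cultivated - cost, behavior possible only when
strictly positive); (4) exhibits safety behavior with probability
``adoption_prob`` if willing. Behavior expression is re-evaluated every
tick rather than absorbing, which is what produces the binomial
fluctuation of the exhibiting count around n x p once the population
saturates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import RunResult
from .model_core import (
    ConfigError,
    GridSpec,
    ModelConfig,
    SimulationState,
    Worker,
    config_digest,
    init_world,
)

__all__ = [
    "CultivationWeights",
    "move_worker",
    "cultivation_increment",
    "net_willingness",
    "generate_behavior",
    "step",
    "run",
]

# Moore neighborhood offsets, fixed order: the uniform draw k in [0, 8)
# indexes this table.
_MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@dataclass(frozen=True)
class CultivationWeights:
    """Relative influence of the three context fields plus an overall gain.

    Weights are nonnegative and sum to 1; ``gain`` converts field units
    (0-10 scale) into willingness units (0-100 scale) per tick.
    """

    w_igii: float
    w_gks: float
    w_gi: float
    gain: float

    def __post_init__(self) -> None:
        if min(self.w_igii, self.w_gks, self.w_gi) < 0:
            raise ConfigError("cultivation weights must be nonnegative")
        total = self.w_igii + self.w_gks + self.w_gi
        if abs(total - 1.0) > 1e-12:
            raise ConfigError(f"cultivation weights must sum to 1 (got {total!r})")
        if self.gain <= 0:
            raise ConfigError(f"cultivation gain must be positive (got {self.gain})")

    @classmethod
    def from_config(cls, config: ModelConfig) -> "CultivationWeights":
        w1, w2, w3 = config.cultivation_weights
        return cls(w_igii=w1, w_gks=w2, w_gi=w3, gain=config.cultivation_gain)


def move_worker(
    worker: Worker, grid: GridSpec, rng: np.random.Generator
) -> tuple[int, int]:
    """Return the cell the worker steps to: a uniform Moore neighbor, wrapped.

    On degenerate lattices the wrapped neighbors may coincide with the
    current cell (a 1x1 torus maps all eight back onto itself).
    """
    dr, dc = _MOORE[int(rng.integers(8))]
    return (
        int((worker.row + dr) % grid.height),
        int((worker.col + dc) % grid.width),
    )


def cultivation_increment(
    cell_fields: tuple[float, float, float], weights: CultivationWeights
) -> float:
    """Willingness gained from one tick on a cell: gain x weighted field mean."""
    igii, gks, gi = cell_fields
    return weights.gain * (
        weights.w_igii * igii + weights.w_gks * gks + weights.w_gi * gi
    )


def net_willingness(worker: Worker) -> float:
    """Baseline intention plus accumulated cultivation, minus behavior cost.

    The cost enters negatively: it is the internal barrier that reduces
    willingness. "Willing" means this value is strictly positive.
    """
    return worker.base_intention + worker.cultivated - worker.sb_cost


def generate_behavior(
    willing: bool, adoption_prob: float, rng: np.random.Generator
) -> bool:
    """Bernoulli(adoption_prob) behavior expression, gated on willingness.

    Drawn independently per worker per tick; never true for an unwilling
    worker.
    """
    if not willing:
        return False
    return bool(rng.random() < adoption_prob)


def step(state: SimulationState, config: ModelConfig) -> tuple[int, int]:
    """Advance the world one tick in place; return (exhibiting, willing) counts.

    All workers are processed in id order: move, cultivate, evaluate,
    express. Behavior uniforms are drawn for every worker regardless of
    willingness so that runs with coupled seeds remain aligned draw-for-draw
    when a scenario change shifts the willingness crossing times.
    """
    n = state.n_workers
    w = CultivationWeights.from_config(config)

    k = state.rng_move.integers(0, 8, size=n)
    state.rows = (state.rows + _MOORE[k, 0]) % state.spec.height
    state.cols = (state.cols + _MOORE[k, 1]) % state.spec.width

    state.cultivated += w.gain * (
        w.w_igii * state.patches.igii[state.rows, state.cols]
        + w.w_gks * state.patches.gks[state.rows, state.cols]
        + w.w_gi * state.patches.gi[state.rows, state.cols]
    )

    willing = (state.base_intention + state.cultivated - state.sb_cost) > 0
    u = state.rng_behavior.random(n)
    state.exhibiting = willing & (u < config.adoption_prob)
    state.tick += 1
    return int(state.exhibiting.sum()), int(willing.sum())


def run(config: ModelConfig) -> RunResult:
    """Initialize a world and advance it ``config.ticks`` ticks.

    Returns the per-tick time series of exhibiting and willing counts,
    indexed t = 0..ticks (t = 0 is the freshly initialized world, where no
    one exhibits and willingness is baseline minus cost only).
    """
    state = init_world(config)
    ticks = config.ticks
    exhibiting = np.zeros(ticks + 1, dtype=np.int64)
    willing = np.zeros(ticks + 1, dtype=np.int64)
    willing[0] = int(
        ((state.base_intention + state.cultivated - state.sb_cost) > 0).sum()
    )
    for t in range(1, ticks + 1):
        exhibiting[t], willing[t] = step(state, config)
    return RunResult(
        exhibiting_count=exhibiting,
        willing_count=willing,
        seed=config.seed,
        config_digest=config_digest(config),
        n_workers=state.n_workers,
    )
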