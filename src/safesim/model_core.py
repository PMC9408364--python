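"""Domain types, configuration validation, and seeded world initialization.

The model has no external data: this module *is* the synthetic-data
generator. A construction site is a torus lattice of patches, each carrying
three fixed group-context fields on a 0-10 scale — intra-group informal
interaction (IGII), group knowledge sharing (GKS), and group identification
(GI) — drawn once per run from Normal(site mean, field_sd) and clamped to
the valid range. Workers are mobile agents with a safety-behavior cost and
a baseline willingness (both on a 0-100 scale, Normal(site mean, worker_sd),
clamped), an accumulated cultivated willingness that starts at zero, and a
per-tick binary behavior flag.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "ConfigError",
    "GridSpec",
    "ModelConfig",
    "PatchGrid",
    "Worker",
    "SimulationState",
    "DEFAULT_CULTIVATION_GAIN",
    "validate_config",
    "sample_patch_fields",
    "spawn_workers",
    "init_world",
    "config_digest",
]

#: Default willingness gained per tick per unit of (weighted) context field.
#: Derived by ``experiments.calibrate_gain`` against the baseline scenario
#: (all site means at their defaults) with a target median onset of t = 15
#: over 100 replicates; see docs/methods.md.
DEFAULT_CULTIVATION_GAIN = 0.7074


class ConfigError(ValueError):
    """A configuration value is missing, unknown, or out of range."""


@dataclass(frozen=True)
class GridSpec:
    """Dimensions and topology of the site lattice.

    The lattice wraps on both axes (torus). Simulation configs require at
    least 3x3 (see :func:`validate_config`); the type itself admits any
    positive dimensions so that degenerate kinematics are expressible.
    """

    width: int = 33
    height: int = 33
    topology: str = "torus"

    def __post_init__(self) -> None:
        if not (isinstance(self.width, (int, np.integer)) and self.width >= 1):
            raise ConfigError(f"grid width must be a positive integer (got {self.width})")
        if not (isinstance(self.height, (int, np.integer)) and self.height >= 1):
            raise ConfigError(f"grid height must be a positive integer (got {self.height})")
        if self.topology != "torus":
            raise ConfigError(f"topology must be 'torus' (got {self.topology!r})")

    @property
    def n_cells(self) -> int:
        return self.width * self.height


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterization of one simulation run.

    Site means (``initial_*``) are the directly adjustable scenario knobs;
    per-patch and per-worker values are drawn around them with standard
    deviations ``field_sd`` / ``worker_sd`` (default 1, i.e. variance 1).
    ``cultivation_weights`` and ``cultivation_gain`` govern how context
    fields convert into willingness per tick; ``adoption_prob`` is the
    probability that a positively willing worker exhibits safety behavior
    on a given tick.
    """

    initial_igii: float = 2.0
    initial_gks: float = 2.0
    initial_gi: float = 2.0
    initial_workers_count: int = 50
    initial_sb_cost: float = 45.0
    initial_sb_intention: float = 20.0
    adoption_prob: float = 0.8
    field_sd: float = 1.0
    worker_sd: float = 1.0
    cultivation_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    cultivation_gain: float = DEFAULT_CULTIVATION_GAIN
    ticks: int = 50
    grid: GridSpec = field(default_factory=GridSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("initial_igii", "initial_gks", "initial_gi"):
            v = getattr(self, name)
            _require(0 <= v <= 10, f"{name} must lie in 0–10 (got {v})")
        n = self.initial_workers_count
        _require(
            isinstance(n, (int, np.integer)) and 0 <= n <= 100,
            f"initial_workers_count must be an integer in 0–100 (got {n})",
        )
        for name in ("initial_sb_cost", "initial_sb_intention"):
            v = getattr(self, name)
            _require(0 <= v <= 100, f"{name} must lie in 0–100 (got {v})")
        _require(
            0 < self.adoption_prob <= 1,
            f"adoption_prob must lie in (0, 1] (got {self.adoption_prob})",
        )
        _require(self.field_sd >= 0, f"field_sd must be nonnegative (got {self.field_sd})")
        _require(self.worker_sd >= 0, f"worker_sd must be nonnegative (got {self.worker_sd})")
        w = self.cultivation_weights
        _require(
            len(w) == 3 and all(x >= 0 for x in w),
            f"cultivation_weights must be three nonnegative reals (got {w})",
        )
        _require(
            abs(sum(w) - 1.0) <= 1e-12,
            f"cultivation_weights must sum to 1 within 1e-12 (got sum {sum(w)!r})",
        )
        _require(
            self.cultivation_gain > 0,
            f"cultivation_gain must be positive (got {self.cultivation_gain})",
        )
        _require(
            isinstance(self.ticks, (int, np.integer)) and self.ticks >= 1,
            f"ticks must be a positive integer (got {self.ticks})",
        )
        _require(
            isinstance(self.seed, (int, np.integer)) and self.seed >= 0,
            f"seed must be a nonnegative integer (got {self.seed})",
        )
        _require(
            self.grid.width >= 3 and self.grid.height >= 3,
            f"grid must be at least 3×3 (got {self.grid.width}×{self.grid.height})",
        )

    def to_dict(self) -> dict[str, Any]:
        """Flat, YAML/JSON-friendly mapping; inverse of :func:`validate_config`."""
        return {
            "initial_igii": self.initial_igii,
            "initial_gks": self.initial_gks,
            "initial_gi": self.initial_gi,
            "initial_workers_count": self.initial_workers_count,
            "initial_sb_cost": self.initial_sb_cost,
            "initial_sb_intention": self.initial_sb_intention,
            "adoption_prob": self.adoption_prob,
            "field_sd": self.field_sd,
            "worker_sd": self.worker_sd,
            "cultivation_weights": list(self.cultivation_weights),
            "cultivation_gain": self.cultivation_gain,
            "ticks": self.ticks,
            "grid_width": self.grid.width,
            "grid_height": self.grid.height,
            "seed": self.seed,
        }

    def with_overrides(self, **kwargs: Any) -> "ModelConfig":
        """Return a revalidated copy with the given flat keys replaced."""
        return validate_config({**self.to_dict(), **kwargs})


# Historical key spelling kept for config-file compatibility.
_KEY_ALIASES = {"initial_wokers_count": "initial_workers_count"}

_VALID_KEYS = frozenset(ModelConfig().to_dict()) | frozenset(_KEY_ALIASES)


def validate_config(raw_config: Mapping[str, Any]) -> ModelConfig:
    """Build a fully populated, range-checked :class:`ModelConfig`.

    ``raw_config`` may supply any subset of the flat keys returned by
    :meth:`ModelConfig.to_dict` (plus the alias ``initial_wokers_count``);
    missing keys take the documented defaults. Unknown keys and
    out-of-range values raise :class:`ConfigError`.
    """
    data: dict[str, Any] = {}
    for key, value in raw_config.items():
        key = _KEY_ALIASES.get(key, key)
        if key not in _VALID_KEYS:
            raise ConfigError(
                f"unknown configuration key {key!r}; valid keys: "
                + ", ".join(sorted(_VALID_KEYS - set(_KEY_ALIASES)))
            )
        data[key] = value

    width = int(data.pop("grid_width", 33))
    height = int(data.pop("grid_height", 33))
    if "cultivation_weights" in data:
        data["cultivation_weights"] = tuple(float(x) for x in data["cultivation_weights"])
    for key in ("initial_workers_count", "ticks", "seed"):
        if key in data:
            data[key] = int(data[key])
    return ModelConfig(grid=GridSpec(width=width, height=height), **data)


def config_digest(config: ModelConfig) -> str:
    """Short stable identifier of a config *up to the seed*.

    Replicates of one scenario differ only by seed and therefore share a
    digest; :func:`metrics.summarize_replicates` relies on this.
    """
    d = config.to_dict()
    d.pop("seed")
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


@dataclass(frozen=True)
class PatchGrid:
    """Per-cell context fields, sampled once at initialization, never updated.

    Arrays are indexed ``[row, col]`` with shape ``(height, width)``; every
    stored value lies in [0, 10].
    """

    igii: np.ndarray
    gks: np.ndarray
    gi: np.ndarray

    def __post_init__(self) -> None:
        if not (self.igii.shape == self.gks.shape == self.gi.shape):
            raise ValueError("field arrays must share one shape")
        for arr in (self.igii, self.gks, self.gi):
            if arr.size and (arr.min() < 0 or arr.max() > 10):
                raise ValueError("patch field values must lie in [0, 10]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.igii.shape

    def fields_at(self, row: int, col: int) -> tuple[float, float, float]:
        return (
            float(self.igii[row, col]),
            float(self.gks[row, col]),
            float(self.gi[row, col]),
        )


@dataclass
class Worker:
    """One mobile worker agent.

    ``cultivated`` accumulates willingness from visited patches and is
    monotone nondecreasing over a run; ``exhibiting`` is re-evaluated every
    tick and can be true only while net willingness is positive.
    """

    id: int
    row: int
    col: int
    sb_cost: float
    base_intention: float
    cultivated: float = 0.0
    exhibiting: bool = False

    @property
    def position(self) -> tuple[int, int]:
        return (self.row, self.col)


def sample_patch_fields(
    grid: GridSpec, config: ModelConfig, rng: np.random.Generator
) -> PatchGrid:
    """Draw the three context fields for every cell.

    Each cell's (igii, gks, gi) triple is drawn independently from
    Normal(site mean, ``field_sd``) and clamped to [0, 10]. Draws proceed
    row-major by (row, column), field order (igii, gks, gi) within a cell,
    so results are reproducible from the rng state alone.
    """
    z = rng.standard_normal((grid.height, grid.width, 3))
    means = np.array([config.initial_igii, config.initial_gks, config.initial_gi])
    vals = np.clip(means + config.field_sd * z, 0.0, 10.0)
    return PatchGrid(
        igii=np.ascontiguousarray(vals[:, :, 0]),
        gks=np.ascontiguousarray(vals[:, :, 1]),
        gi=np.ascontiguousarray(vals[:, :, 2]),
    )


def spawn_workers(
    config: ModelConfig, grid: GridSpec, rng: np.random.Generator
) -> list[Worker]:
    """Create ``initial_workers_count`` workers.

    Positions are uniform over cells (several workers may share a cell);
    cost and baseline willingness are Normal(site mean, ``worker_sd``)
    clamped to [0, 100]; cultivated willingness starts at 0 and no worker
    exhibits behavior before the first tick.
    """
    n = config.initial_workers_count
    rows = rng.integers(0, grid.height, size=n)
    cols = rng.integers(0, grid.width, size=n)
    costs = np.clip(
        config.initial_sb_cost + config.worker_sd * rng.standard_normal(n), 0.0, 100.0
    )
    intents = np.clip(
        config.initial_sb_intention + config.worker_sd * rng.standard_normal(n), 0.0, 100.0
    )
    return [
        Worker(
            id=i,
            row=int(rows[i]),
            col=int(cols[i]),
            sb_cost=float(costs[i]),
            base_intention=float(intents[i]),
        )
        for i in range(n)
    ]


@dataclass
class SimulationState:
    """Mutable state of one run, stored as parallel arrays indexed by worker id.

    The worker count is constant for the run; ``tick`` increments by exactly
    1 per step. ``rng_move`` and ``rng_behavior`` are independent substreams
    spawned from the master seed, so changing one rule's draws never shifts
    another's.
    """

    tick: int
    spec: GridSpec
    patches: PatchGrid
    rows: np.ndarray
    cols: np.ndarray
    sb_cost: np.ndarray
    base_intention: np.ndarray
    cultivated: np.ndarray
    exhibiting: np.ndarray
    rng_move: np.random.Generator
    rng_behavior: np.random.Generator

    @property
    def n_workers(self) -> int:
        return len(self.rows)

    @property
    def workers(self) -> list[Worker]:
        """Snapshot of the worker population as :class:`Worker` records."""
        return [
            Worker(
                id=i,
                row=int(self.rows[i]),
                col=int(self.cols[i]),
                sb_cost=float(self.sb_cost[i]),
                base_intention=float(self.base_intention[i]),
                cultivated=float(self.cultivated[i]),
                exhibiting=bool(self.exhibiting[i]),
            )
            for i in range(self.n_workers)
        ]


def init_world(config: ModelConfig) -> SimulationState:
    """Initialize the world at tick 0 from the config's master seed.

    The master seed spawns four independent substreams — patch sampling,
    worker sampling, movement, behavior — so two calls with equal configs
    produce identical states and identical subsequent runs.
    """
    ss = np.random.SeedSequence(config.seed)
    patch_rng, worker_rng, move_rng, behavior_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    patches = sample_patch_fields(config.grid, config, patch_rng)
    workers = spawn_workers(config, config.grid, worker_rng)
    n = len(workers)
    return SimulationState(
        tick=0,
        spec=config.grid,
        patches=patches,
        rows=np.array([w.row for w in workers], dtype=np.int64),
        cols=np.array([w.col for w in workers], dtype=np.int64),
        sb_cost=np.array([w.sb_cost for w in workers], dtype=float),
        base_intention=np.array([w.base_intention for w in workers], dtype=float),
        cultivated=np.zeros(n, dtype=float),
        exhibiting=np.zeros(n, dtype=bool),
        rng_move=move_rng,
        rng_behavior=behavior_rng,
    )
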