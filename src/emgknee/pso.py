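"""Particle swarm search over the four DBN hidden-layer widths.

Standard PSO with a linearly decreasing inertia weight

    w(k) = (w_max - w_min) (k_max - k) / k_max + w_min

and velocity/position updates

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)
    x <- x + v

where r1, r2 are drawn fresh per term and per component.  Positions are
layer-width vectors, kept integral by round-then-clamp into
[pos_min, pos_max] after each continuous update; velocities are clamped to
+-v_max componentwise.

The fitness used for architecture search trains a reduced-budget DBN plus
BPNN head on an internal 80/20 split of the training windows and returns
the validation RMSE in degrees.  Fitness is deterministic per position, so
repeated visits are served from a cache.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .bpnn import BpnnTrainConfig, bpnn_forward, train_bpnn
from .dbn import DbnTrainConfig, fine_tune_autoencoder, pretrain_dbn, transform
from .preprocess import FeatureDataset

__all__ = [
    "SwarmConfig",
    "Particle",
    "FitnessConfig",
    "inertia_weight",
    "init_swarm",
    "step",
    "optimize",
    "architecture_fitness",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters: 20 particles, 10 iterations, c1/c2 = 0.9/0.5,
    inertia decreasing 0.9 -> 0.5, layer widths searched in [1, 50]^4."""

    n_particles: int = 20
    max_iter: int = 10
    c1: float = 0.9
    c2: float = 0.5
    w_max: float = 0.9
    w_min: float = 0.5
    pos_min: int = 1
    pos_max: int = 50
    v_max: Optional[float] = None  # default: half the box width
    dim: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_min <= self.w_max:
            raise ValueError("require 0 <= w_min <= w_max")
        if self.pos_min > self.pos_max:
            raise ValueError("require pos_min <= pos_max")
        if self.n_particles < 2:
            raise ValueError("need at least two particles")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.v_max is None:
            object.__setattr__(self, "v_max", 0.5 * (self.pos_max - self.pos_min))


@dataclass
class Particle:
    position: np.ndarray  # integer layer widths
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


def inertia_weight(k: int, config: SwarmConfig) -> float:
    """Linearly decreasing inertia: w_max at k = 0, w_min at k = max_iter."""
    if not 0 <= k <= config.max_iter:
        raise ValueError("iteration index outside [0, max_iter]")
    return (config.w_max - config.w_min) * (config.max_iter - k) / config.max_iter + config.w_min


def _clamp_position(x: np.ndarray, config: SwarmConfig) -> np.ndarray:
    return np.clip(np.rint(x), config.pos_min, config.pos_max).astype(float)


def init_swarm(
    fitness: Callable[[np.ndarray], float], config: SwarmConfig, rng: np.random.Generator
) -> List[Particle]:
    """Random integer positions and uniform velocities in +-v_max."""
    swarm = []
    for _ in range(config.n_particles):
        pos = rng.integers(config.pos_min, config.pos_max + 1, size=config.dim).astype(float)
        vel = rng.uniform(-config.v_max, config.v_max, size=config.dim)
        fit = float(fitness(pos))
        swarm.append(Particle(pos, vel, pos.copy(), fit))
    return swarm


def step(
    swarm: List[Particle],
    k: int,
    fitness: Callable[[np.ndarray], float],
    config: SwarmConfig,
    rng: np.random.Generator,
) -> None:
    """One synchronous PSO iteration (in place)."""
    gbest = min(swarm, key=lambda p: p.pbest_fitness).pbest_position.copy()
    w = inertia_weight(k, config)
    for i, p in enumerate(swarm):
        r1 = rng.random(config.dim)
        r2 = rng.random(config.dim)
        vel = (
            w * p.velocity
            + config.c1 * r1 * (p.pbest_position - p.position)
            + config.c2 * r2 * (gbest - p.position)
        )
        p.velocity = np.clip(vel, -config.v_max, config.v_max)
        p.position = _clamp_position(p.position + p.velocity, config)
        try:
            fit = float(fitness(p.position))
        except Exception as exc:
            raise RuntimeError(f"fitness evaluation failed for particle {i}") from exc
        if fit < p.pbest_fitness:
            p.pbest_fitness = fit
            p.pbest_position = p.position.copy()


def optimize(
    fitness: Callable[[np.ndarray], float],
    config: SwarmConfig,
    log_path: Optional[str] = None,
) -> Tuple[np.ndarray, float, List[float]]:
    """Run the swarm; returns (best position, best fitness, gbest history).

    The history has one entry per iteration including initialization and is
    monotone non-increasing.  Fitness values are cached by position, which
    is sound because the fitness contract requires determinism.  With
    ``log_path`` given, a per-iteration table (iteration, gbest position,
    gbest fitness) is written as comma-separated text.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 31]))
    cache: dict = {}

    def cached(pos: np.ndarray) -> float:
        key = tuple(int(v) for v in pos)
        if key not in cache:
            cache[key] = float(fitness(np.asarray(pos, dtype=float)))
        return cache[key]

    swarm = init_swarm(cached, config, rng)
    best = min(swarm, key=lambda p: p.pbest_fitness)
    history = [best.pbest_fitness]
    trace = [(0, best.pbest_position.copy(), best.pbest_fitness)]
    for k in range(1, config.max_iter + 1):
        step(swarm, k, cached, config, rng)
        best = min(swarm, key=lambda p: p.pbest_fitness)
        history.append(best.pbest_fitness)
        trace.append((k, best.pbest_position.copy(), best.pbest_fitness))

    if log_path is not None:
        header = ["iteration"] + [f"h{i + 1}" for i in range(config.dim)] + ["gbest_fitness"]
        lines = [",".join(header)]
        for k, pos, fit in trace:
            lines.append(",".join([str(k)] + [str(int(v)) for v in pos] + [repr(fit)]))
        with open(log_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    return best.pbest_position.astype(int), best.pbest_fitness, history


@dataclass(frozen=True)
class FitnessConfig:
    """Reduced training budget for architecture-search fitness evaluations.

    Candidate architectures are ranked with far fewer epochs than the final
    model is trained with; the winner is retrained at full budget.
    """

    dbn_epochs: int = 50
    fine_tune_epochs: int = 40
    bpnn_max_iter: int = 200
    batch_size: int = 64
    train_fraction: float = 0.8
    seed: int = 0


def architecture_fitness(
    dataset: FeatureDataset,
    reduced: FitnessConfig = FitnessConfig(),
    dbn_config: DbnTrainConfig = DbnTrainConfig(),
    bpnn_config: BpnnTrainConfig = BpnnTrainConfig(),
) -> Callable[[np.ndarray], float]:
    """Fitness over layer-width vectors: held-out RMSE of a cheap pipeline.

    The dataset (training windows only) is split 80/20 chronologically;
    each evaluation pretrains a DBN with ``reduced`` budgets, fine-tunes,
    trains the BPNN head, and scores RMSE (deg) on the held-out 20%.
    Internal seeds are fixed, so the fitness is deterministic per position.
    """
    if len(dataset) < 50:
        raise ValueError("need at least 50 windows for architecture search")
    fit_ds, val_ds = dataset.split(reduced.train_fraction)
    dcfg = DbnTrainConfig(
        learning_rate=dbn_config.learning_rate,
        epochs=reduced.dbn_epochs,
        batch_size=reduced.batch_size,
        cd_k=dbn_config.cd_k,
        fine_tune_epochs=reduced.fine_tune_epochs,
        fine_tune_lr=dbn_config.fine_tune_lr,
        seed=reduced.seed,
    )
    bcfg = BpnnTrainConfig(
        max_iter=reduced.bpnn_max_iter,
        learning_rate=bpnn_config.learning_rate,
        hidden_size=bpnn_config.hidden_size,
        seed=reduced.seed,
    )

    def fitness(position: np.ndarray) -> float:
        widths = [int(v) for v in np.asarray(position).ravel()]
        if len(widths) != 4 or any(w < 1 for w in widths):
            raise ValueError(f"invalid architecture {widths}")
        layer_sizes = [fit_ds.features.shape[1]] + widths
        dbn = pretrain_dbn(layer_sizes, fit_ds.features, dcfg)
        dbn = fine_tune_autoencoder(dbn, fit_ds.features, dcfg)
        head = train_bpnn(transform(dbn, fit_ds.features), fit_ds.labels, bcfg)
        pred = bpnn_forward(head, transform(dbn, val_ds.features))
        return float(np.sqrt(np.mean((pred - val_ds.labels) ** 2)))

    return fitness
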