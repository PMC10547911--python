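"""Quantum-bit squirrel search for gene-subset selection (FSQSSA).

Each candidate solution ("squirrel") is a vector of D angles θ ∈ [θL, θU];
the j-th angle encodes a quantum bit q = cos θ|0> + sin θ|1> whose
measurement decides whether gene j enters the subset (bit 1 iff
|cos θ|² ≤ |sin θ|²).  Squirrels are ranked by fitness into a tree
hierarchy — one hickory (global best), three acorn (runners-up) and the
rest normal — and move by gliding steps toward better-ranked squirrels:

    θ' = θ + dg · Gc · (θ_target − θ)        with prob. 1 − Pdp
    θ' = fresh uniform position               with prob. Pdp (predator)

where dg ~ U[0.3, 0.7] is the glide distance and Gc = 1.9 the gliding
constant.  A seasonal monitoring condition compares each acorn's squared
angular distance to the hickory against a threshold decaying over
iterations; when triggered, all normal-tree squirrels are relocated by a
heavy-tailed Lévy flight to restore exploration.  The best-ever solution
is kept elitistically outside the population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "FsqssaConfig",
    "Squirrel",
    "SearchState",
    "TraceRecord",
    "FsqssaResult",
    "binarize",
    "init_population",
    "assign_roles",
    "glide_update",
    "seasonal_constant",
    "s_min",
    "levy_steps",
    "levy_relocate",
    "run_fsqssa",
]

HICKORY, ACORN, NORMAL = "hickory", "acorn", "normal"

# |cos θ|² and |sin θ|² can differ by one ulp at the exact threshold π/4;
# the inclusion test is therefore applied with a small tolerance so that
# the boundary angle selects the gene.
_BINARIZE_TOL = 1e-12


@dataclass(frozen=True)
class FsqssaConfig:
    """Search hyperparameters; defaults follow the published configuration."""

    pop_size: int = 50
    n_acorn: int = 3
    max_iter: int = 100
    w: float = 0.9
    pdp: float = 0.1
    gc: float = 1.9
    dg_low: float = 0.3
    dg_high: float = 0.7
    theta_low: float = 0.0
    theta_high: float = math.pi / 2
    levy_beta: float = 1.5

    def __post_init__(self) -> None:
        if self.pop_size < self.n_acorn + 2:
            raise ValueError("population must hold 1 hickory, the acorns and ≥1 normal")
        if not 0 <= self.dg_low <= self.dg_high:
            raise ValueError("require 0 <= dg_low <= dg_high")
        if not self.theta_low < self.theta_high:
            raise ValueError("require theta_low < theta_high")
        if not 0 <= self.pdp <= 1:
            raise ValueError("pdp must lie in [0, 1]")

    @property
    def n_normal(self) -> int:
        return self.pop_size - 1 - self.n_acorn


@dataclass
class Squirrel:
    """One candidate solution: Q-bit angles, derived mask, cached fitness."""

    theta: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    fitness: float | None = None
    role: str = NORMAL

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.mask is None:
            self.mask = binarize(self.theta)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class TraceRecord:
    iteration: int
    best_fitness: float
    mean_fitness: float
    n_selected_best: int
    role_counts: tuple[int, int, int] = (0, 0, 0)  # hickory, acorn, normal


@dataclass
class SearchState:
    population: list[Squirrel]
    iteration: int = 0
    best: Squirrel | None = None
    trace: list[TraceRecord] = field(default_factory=list)


@dataclass
class FsqssaResult:
    """Best-ever mask, its fitness, and the per-iteration convergence trace."""

    mask: np.ndarray
    fitness: float
    trace: list[TraceRecord]
    state: SearchState


def binarize(theta: np.ndarray) -> np.ndarray:
    """Measure the Q-bits: bit j = 1 iff |cos θj|² ≤ |sin θj|² (inclusive)."""
    theta = np.asarray(theta, dtype=float)
    return (np.sin(theta) ** 2 - np.cos(theta) ** 2 >= -_BINARIZE_TOL).astype(np.int8)


def init_population(
    cfg: FsqssaConfig, D: int, rng: np.random.Generator
) -> SearchState:
    """Uniformly random angle vectors in [θL, θU]^D for every squirrel."""
    if D < 2:
        raise ValueError("need at least 2 features to search over")
    span = cfg.theta_high - cfg.theta_low
    pop = [
        Squirrel(theta=cfg.theta_low + rng.random(D) * span)
        for _ in range(cfg.pop_size)
    ]
    return SearchState(population=pop)


def _rank_key(s: Squirrel, idx: int) -> tuple:
    return (-s.fitness, s.n_selected, idx)


def assign_roles(state: SearchState, cfg: FsqssaConfig) -> SearchState:
    """Rank by fitness: best → hickory, next ``n_acorn`` → acorn, rest normal.

    Ties break by smaller selected-gene count, then by original index.
    """
    for s in state.population:
        if s.fitness is None:
            raise ValueError("cannot assign roles before all fitnesses are evaluated")
    order = sorted(range(len(state.population)),
                   key=lambda i: _rank_key(state.population[i], i))
    for rank, i in enumerate(order):
        if rank == 0:
            state.population[i].role = HICKORY
        elif rank <= cfg.n_acorn:
            state.population[i].role = ACORN
        else:
            state.population[i].role = NORMAL
    return state


def glide_update(
    source: np.ndarray,
    target: np.ndarray,
    cfg: FsqssaConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One foraging move toward a better-ranked squirrel, or predator escape.

    With probability 1 − Pdp the squirrel glides: θ + dg·Gc·(target − θ)
    with a single dg ~ U[dg_low, dg_high] shared across dimensions; with
    probability Pdp it flees to a fresh uniform random location.  Output is
    clipped into [θL, θU].
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have the same dimension")
    r = rng.random()
    if r >= cfg.pdp:
        dg = rng.uniform(cfg.dg_low, cfg.dg_high)
        new = source + dg * cfg.gc * (target - source)
    else:
        new = cfg.theta_low + rng.random(source.size) * (cfg.theta_high - cfg.theta_low)
    return np.clip(new, cfg.theta_low, cfg.theta_high)


def seasonal_constant(acorn_theta: np.ndarray, hickory_theta: np.ndarray) -> float:
    """Squared angular distance Σ (θ_acorn − θ_hickory)² between two squirrels."""
    a = np.asarray(acorn_theta, dtype=float)
    h = np.asarray(hickory_theta, dtype=float)
    if a.shape != h.shape:
        raise ValueError("angle vectors must have the same dimension")
    return float(np.sum((a - h) ** 2))


def s_min(t: int, tm: int) -> float:
    """Seasonal threshold 10⁻⁶ / 365^(t / (tm/2.5)); strictly decreasing in t."""
    if tm <= 0:
        raise ValueError("tm must be positive")
    return 1e-6 / 365.0 ** (t / (tm / 2.5))


def _mantegna_sigma(beta: float) -> float:
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    return (num / den) ** (1 / beta)


def levy_steps(beta: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed Lévy step sample via the Mantegna algorithm."""
    sigma = _mantegna_sigma(beta)
    u = rng.normal(0.0, sigma, size)
    v = rng.normal(0.0, 1.0, size)
    return u / np.abs(v) ** (1 / beta)


def levy_relocate(cfg: FsqssaConfig, D: int, rng: np.random.Generator) -> np.ndarray:
    """Random migration θL + Lévy(D)·(θU − θL), clipped into bounds."""
    steps = levy_steps(cfg.levy_beta, D, rng)
    new = cfg.theta_low + steps * (cfg.theta_high - cfg.theta_low)
    return np.clip(new, cfg.theta_low, cfg.theta_high)


def _evaluate(s: Squirrel, fitness_fn, errors: list) -> None:
    s.mask = binarize(s.theta)
    if s.mask.sum() == 0:
        s.fitness = -np.inf  # inadmissible: empty gene subset
        return
    try:
        s.fitness = float(fitness_fn(s.mask))
    except Exception as exc:  # noqa: BLE001 - caller decides whether to abort
        errors.append(exc)
        s.fitness = -np.inf


def _update_best(state: SearchState) -> None:
    for s in state.population:
        if s.n_selected == 0 or not np.isfinite(s.fitness):
            continue
        if state.best is None or s.fitness > state.best.fitness:
            state.best = Squirrel(
                theta=s.theta.copy(), mask=s.mask.copy(), fitness=s.fitness
            )


def _record(state: SearchState, cfg: FsqssaConfig) -> None:
    fits = np.array([s.fitness for s in state.population], dtype=float)
    finite = fits[np.isfinite(fits)]
    roles = [s.role for s in state.population]
    state.trace.append(
        TraceRecord(
            iteration=state.iteration,
            best_fitness=state.best.fitness if state.best else -np.inf,
            mean_fitness=float(finite.mean()) if finite.size else -np.inf,
            n_selected_best=state.best.n_selected if state.best else 0,
            role_counts=(
                roles.count(HICKORY), roles.count(ACORN), roles.count(NORMAL)
            ),
        )
    )


def run_fsqssa(
    D: int,
    cfg: FsqssaConfig,
    fitness_fn,
    rng: np.random.Generator,
) -> FsqssaResult:
    """Run the full search over D-dimensional gene masks.

    ``fitness_fn(mask) -> float`` scores a binary mask (larger is better);
    empty masks are never passed to it.  Returns the elitist best-ever mask
    (guaranteed non-empty), its fitness, and the convergence trace with one
    record for the initial population and one per iteration.
    """
    state = init_population(cfg, D, rng)
    errors: list = []
    for s in state.population:
        _evaluate(s, fitness_fn, errors)
    if len(errors) >= cfg.pop_size:
        raise RuntimeError(
            f"fitness evaluation failed for the entire population; "
            f"last error: {errors[-1]!r}"
        ) from errors[-1]
    assign_roles(state, cfg)
    _update_best(state)
    if state.best is None:
        raise RuntimeError("no admissible (non-empty) mask in the initial population")
    _record(state, cfg)

    for t in range(1, cfg.max_iter + 1):
        state.iteration = t
        pop = state.population
        hickory = next(s for s in pop if s.role == HICKORY)
        acorns = [s for s in pop if s.role == ACORN]
        normals = [s for s in pop if s.role == NORMAL]
        moved: list[Squirrel] = []
        # moves are synchronous: targets are frozen at the iteration start
        hickory_theta = hickory.theta.copy()
        acorn_thetas = [s.theta.copy() for s in acorns]

        # Case 1: acorn squirrels glide toward the hickory tree.
        for s in acorns:
            s.theta = glide_update(s.theta, hickory_theta, cfg, rng)
            moved.append(s)
        # Cases 2 and 3: each normal squirrel flies either to a random acorn
        # tree or directly to the hickory tree (even split, per iteration).
        for s in normals:
            if rng.random() < 0.5:
                target = acorn_thetas[rng.integers(len(acorn_thetas))]
            else:
                target = hickory_theta
            s.theta = glide_update(s.theta, target, cfg, rng)
            moved.append(s)

        for s in moved:
            _evaluate(s, fitness_fn, errors)

        # Seasonal monitoring: if any acorn has drifted within the decaying
        # threshold of the hickory, exploration has stalled — relocate every
        # normal-tree squirrel by a Lévy flight.
        smin = s_min(t, cfg.max_iter)
        triggered = any(
            seasonal_constant(s.theta, hickory.theta) < smin for s in acorns
        )
        if triggered:
            for s in normals:
                s.theta = levy_relocate(cfg, D, rng)
                _evaluate(s, fitness_fn, errors)

        assign_roles(state, cfg)
        _update_best(state)
        _record(state, cfg)

    if errors:
        warnings.warn(
            f"{len(errors)} fitness evaluations failed during the search; "
            f"affected squirrels were scored -inf",
            RuntimeWarning,
            stacklevel=2,
        )
    return FsqssaResult(
        mask=state.best.mask.copy(),
        fitness=state.best.fitness,
        trace=list(state.trace),
        state=state,
    )
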