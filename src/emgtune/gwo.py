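"""Grey Wolf Optimizer over a box-bounded search space.

Candidate solutions ("wolves") move toward the three best solutions
found so far (alpha, beta, delta). Per iteration t of T the control
scalar a = 2 - t*(2/T) shrinks linearly from 2 to 0; for every wolf,
leader and dimension, stochastic coefficients

    A = 2*a*r1 - a          (in [-a, a], exploration when |A| > 1)
    C = 2*r2                (in [0, 2])

define a perturbed distance D = |C * X_leader - X_i| and an attraction
point X_l = X_leader - A * D. The new position is the average of the
three attraction points, clipped to the box.

Leaders are retained best-so-far (elitist), so the best-cost trace is
monotone non-increasing. Integer dimensions are kept continuous here
and rounded only when the cost function decodes a position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Bounds:
    lower: np.ndarray
    upper: np.ndarray
    integer_mask: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower/upper must be 1-D vectors of equal length")
        if not np.all(self.lower < self.upper):
            raise ValueError("every lower bound must be strictly below its upper")
        if self.integer_mask is not None:
            object.__setattr__(
                self, "integer_mask", np.asarray(self.integer_mask, dtype=bool)
            )

    @property
    def dim(self) -> int:
        return len(self.lower)


@dataclass
class Wolf:
    position: np.ndarray
    fitness: float


@dataclass(frozen=True)
class CoefficientDraw:
    A: np.ndarray
    C: np.ndarray
    r1: np.ndarray
    r2: np.ndarray


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_cost: float
    history: pd.DataFrame
    n_evaluations: int
    population: list[Wolf] = field(default_factory=list)


def control_parameter(t: int, T: int) -> float:
    """a = 2 - t*(2/T), decreasing linearly from near 2 to 0 over 1..T."""
    if T <= 0:
        raise ValueError("T must be positive")
    if not (1 <= t <= T):
        raise ValueError(f"t must be in 1..{T}")
    return 2.0 - t * (2.0 / T)


def draw_coefficients(a: float, rng, d: int) -> CoefficientDraw:
    """Fresh per-dimension uniforms: A = 2a*r1 - a, C = 2*r2."""
    r1 = rng.random(d)
    r2 = rng.random(d)
    return CoefficientDraw(A=2.0 * a * r1 - a, C=2.0 * r2, r1=r1, r2=r2)


def leader_distance(C: np.ndarray, x_leader: np.ndarray, x_i: np.ndarray) -> np.ndarray:
    """D = |C o X_leader - X_i| component-wise."""
    C, x_leader, x_i = (np.asarray(v, dtype=float) for v in (C, x_leader, x_i))
    if not (C.shape == x_leader.shape == x_i.shape):
        raise ValueError("dimension mismatch")
    return np.abs(C * x_leader - x_i)


def clip_to_bounds(x: np.ndarray, bounds: Bounds) -> np.ndarray:
    return np.clip(x, bounds.lower, bounds.upper)


def update_position(
    x_i: np.ndarray,
    leaders: list[np.ndarray],
    draws: list[CoefficientDraw],
    bounds: Bounds | None = None,
) -> np.ndarray:
    """Average of the three leader attraction points, clipped to bounds."""
    if len(leaders) != 3 or len(draws) != 3:
        raise ValueError("exactly three leaders and three coefficient draws required")
    terms = []
    for x_l, d in zip(leaders, draws):
        D = leader_distance(d.C, x_l, x_i)
        terms.append(np.asarray(x_l, dtype=float) - d.A * D)
    x_new = (terms[0] + terms[1] + terms[2]) / 3.0
    if bounds is not None:
        x_new = clip_to_bounds(x_new, bounds)
    return x_new


def _safe_cost(cost_fn, x, i, t, pass_context):
    out = cost_fn(x, i, t) if pass_context else cost_fn(x)
    new_pos = None
    if isinstance(out, tuple):
        out, new_pos = out
    cost = float(out)
    if not math.isfinite(cost):
        logger.warning("non-finite cost at wolf %d iteration %d; treating as +inf", i, t)
        cost = math.inf
    return cost, new_pos


def optimize(
    cost_fn,
    bounds: Bounds,
    n_wolves: int = 20,
    n_iterations: int = 10,
    seed: int = 0,
    callback=None,
    rng=None,
    pass_context: bool = False,
) -> OptimizeResult:
    """Run GWO; deterministic given ``seed``.

    ``cost_fn(x)`` returns a scalar cost (lower is better); it may
    instead return ``(cost, adjusted_position)`` to write feedback back
    into the evaluated wolf's position (clipped to bounds). With
    ``pass_context`` the cost function is called as
    ``cost_fn(x, wolf_index, iteration)`` (iteration 0 = initialization).
    History has one row per iteration: best-so-far cost and population
    mean cost, the standard convergence traces.
    """
    if n_wolves < 3:
        raise ValueError("need at least 3 wolves (three leaders)")
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    if rng is None:
        rng = np.random.default_rng(seed)
    d = bounds.dim

    positions = rng.uniform(bounds.lower, bounds.upper, size=(n_wolves, d))
    wolves = []
    n_eval = 0
    for i in range(n_wolves):
        cost, new_pos = _safe_cost(cost_fn, positions[i].copy(), i, 0, pass_context)
        n_eval += 1
        if new_pos is not None:
            positions[i] = clip_to_bounds(np.asarray(new_pos, dtype=float), bounds)
        wolves.append(Wolf(position=positions[i].copy(), fitness=cost))

    # elitist leader archive: (cost, insertion order, position)
    archive: list[tuple[float, int, np.ndarray]] = []
    counter = 0

    def absorb(w: Wolf):
        nonlocal counter
        archive.append((w.fitness, counter, w.position.copy()))
        counter += 1
        archive.sort(key=lambda e: (e[0], e[1]))
        del archive[3:]

    for w in wolves:
        absorb(w)

    rows = []
    for t in range(1, n_iterations + 1):
        a = control_parameter(t, n_iterations)
        leaders = [archive[min(k, len(archive) - 1)][2] for k in range(3)]
        for i, w in enumerate(wolves):
            draws = [draw_coefficients(a, rng, d) for _ in range(3)]
            x_new = update_position(w.position, leaders, draws, bounds)
            cost, new_pos = _safe_cost(cost_fn, x_new, i, t, pass_context)
            n_eval += 1
            if new_pos is not None:
                x_new = clip_to_bounds(np.asarray(new_pos, dtype=float), bounds)
            w.position = x_new
            w.fitness = cost
            absorb(w)
        best_cost, _, best_pos = archive[0]
        mean_cost = float(np.mean([w.fitness for w in wolves]))
        rows.append(
            {"iteration": t, "a": a, "best_cost": best_cost, "mean_cost": mean_cost}
            | {f"best_x{q}": best_pos[q] for q in range(d)}
        )
        if callback is not None:
            callback(t, best_pos.copy(), best_cost, wolves)

    best_cost, _, best_pos = archive[0]
    return OptimizeResult(
        best_position=best_pos.copy(),
        best_cost=best_cost,
        history=pd.DataFrame(rows),
        n_evaluations=n_eval,
        population=wolves,
    )


def save_history(path, result: OptimizeResult) -> None:
    """Delimited-text export of the per-iteration convergence trace."""
    result.history.to_csv(path, index=False)
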