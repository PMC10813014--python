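"""Wolf-position decoding and validation-error fitness for the search.

A wolf position is a length-5 real vector ordered as
(lr, n1, n2, batch_size, epochs). Integer dimensions stay continuous
inside the optimizer and are rounded half-up only when a position is
decoded into hyperparameters for a training run. Fitness is
1 - validation accuracy of a model trained from scratch with those
hyperparameters; the number of epochs actually run before early
stopping (effective epochs) is fed back into the wolf's epochs
dimension after each evaluation, so the search space reflects realized
training lengths.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import gwo, rnn

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchSpace:
    """Tuned quantities and their bounds (defaults: the study ranges)."""

    lr: tuple[float, float] = (1e-5, 0.1)
    n1: tuple[int, int] = (10, 150)
    n2: tuple[int, int] = (10, 150)
    batch_size: tuple[int, int] = (128, 512)
    epochs: tuple[int, int] = (10, 100)

    _ORDER = ("lr", "n1", "n2", "batch_size", "epochs")
    _INTEGER = (False, True, True, True, True)

    def to_bounds(self) -> gwo.Bounds:
        lo = [getattr(self, k)[0] for k in self._ORDER]
        hi = [getattr(self, k)[1] for k in self._ORDER]
        return gwo.Bounds(lower=lo, upper=hi, integer_mask=np.array(self._INTEGER))


@dataclass(frozen=True)
class Hyperparameters:
    lr: float
    n1: int
    n2: int
    batch_size: int
    epochs: int

    def as_dict(self):
        return {
            "lr": self.lr,
            "n1": self.n1,
            "n2": self.n2,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
        }


@dataclass
class EvaluationRecord:
    iteration: int
    wolf: int
    hyperparameters: Hyperparameters
    cost: float
    effective_epochs: int
    train_seconds: float
    timestamp: float


@dataclass
class SearchResult:
    best_hyperparameters: Hyperparameters
    best_cost: float
    history: object  # per-iteration best/mean cost DataFrame
    evaluations: list[EvaluationRecord] = field(default_factory=list)
    final_population: list = field(default_factory=list)

    def report(self) -> str:
        """Best hyperparameters in the study's table layout."""
        hp = self.best_hyperparameters
        rows = [
            ("Number of neurons in first layer", hp.n1),
            ("Number of neurons in second layer", hp.n2),
            ("Batch size", hp.batch_size),
            ("Training epochs", hp.epochs),
            ("Learning rate", hp.lr),
        ]
        width = max(len(r[0]) for r in rows)
        lines = [f"{name:<{width}}  {value}" for name, value in rows]
        lines.append(f"{'Validation error':<{width}}  {self.best_cost:.4f}")
        return "\n".join(lines)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def decode_position(x, space: SearchSpace = SearchSpace()) -> Hyperparameters:
    """Continuous dims pass through; integer dims round half-up, clamp."""
    x = np.asarray(x, dtype=float)
    if x.shape != (5,):
        raise ValueError(f"expected a length-5 position, got shape {x.shape}")
    vals = {}
    for q, name in enumerate(SearchSpace._ORDER):
        lo, hi = getattr(space, name)
        v = float(np.clip(x[q], lo, hi))
        if SearchSpace._INTEGER[q]:
            v = int(np.clip(_round_half_up(v), int(np.ceil(lo)), int(np.floor(hi))))
        vals[name] = v
    return Hyperparameters(**vals)


def fitness(
    hp: Hyperparameters,
    arch: str,
    train_data,
    val_data,
    seed: int = 0,
    *,
    normalize_input: bool | None = None,
    patience: int = 5,
    input_timesteps: int = 4,
    input_features: int = 375,
    n_classes: int = 5,
):
    """Train one candidate from scratch; cost = 1 - best validation
    accuracy. Returns (cost, TrainingResult); training failures yield
    cost = +inf.
    """
    if normalize_input is None:
        normalize_input = arch != "bidirectional"
    spec = rnn.ModelSpec(
        arch=arch,
        n1=hp.n1,
        n2=hp.n2,
        input_timesteps=input_timesteps,
        input_features=input_features,
        n_classes=n_classes,
        normalize_input=normalize_input,
        lr=hp.lr,
    )
    cfg = rnn.TrainConfig(
        batch_size=hp.batch_size, max_epochs=hp.epochs, patience=patience, seed=seed
    )
    try:
        model = rnn.build_model(spec, seed=seed)
        result = rnn.train(model, spec, train_data, val_data, cfg)
    except (FloatingPointError, ValueError) as exc:
        logger.warning("training failed for %s: %s", hp, exc)
        return float("inf"), None
    return 1.0 - result.best_val_accuracy, result


def _derive_seed(master: int, wolf: int, iteration: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(iteration, wolf))
    return int(ss.generate_state(1)[0] % (2**31))


def run_search(
    arch: str,
    train_data,
    val_data,
    space: SearchSpace = SearchSpace(),
    n_wolves: int = 20,
    n_iterations: int = 10,
    seed: int = 0,
    *,
    epoch_feedback: str = "replace",
    normalize_input: bool | None = None,
    patience: int = 5,
    input_timesteps: int = 4,
    input_features: int = 375,
    n_classes: int = 5,
    cache: bool = False,
    fitness_fn=None,
) -> SearchResult:
    """Grey-wolf search over the 5-dim hyperparameter box.

    ``epoch_feedback='replace'`` writes each candidate's realized epoch
    count back into its epochs dimension; ``'log'`` only records it.
    One master seed drives the optimizer; each training run derives its
    own seed from (seed, wolf, iteration) so evaluations are
    independent yet reproducible.

    ``fitness_fn(hp, seed) -> (cost, effective_epochs | None)`` may
    replace the training-based fitness (e.g. a closed-form objective
    for optimizer diagnostics); ``None`` effective epochs skips the
    feedback substitution for that evaluation.
    """
    if epoch_feedback not in ("replace", "log"):
        raise ValueError("epoch_feedback must be 'replace' or 'log'")
    records: list[EvaluationRecord] = []
    memo: dict = {}

    def cost_fn(x, wolf_index, iteration):
        hp = decode_position(x, space)
        key = (hp, arch)
        if cache and key in memo:
            cost, eff = memo[key]
            records.append(
                EvaluationRecord(iteration, wolf_index, hp, cost, eff, 0.0, time.time())
            )
            return _with_feedback(cost, x, eff)
        t0 = time.perf_counter()
        eval_seed = _derive_seed(seed, wolf_index, iteration)
        if fitness_fn is not None:
            cost, eff = fitness_fn(hp, eval_seed)
        else:
            cost, result = fitness(
                hp,
                arch,
                train_data,
                val_data,
                seed=eval_seed,
                normalize_input=normalize_input,
                patience=patience,
                input_timesteps=input_timesteps,
                input_features=input_features,
                n_classes=n_classes,
            )
            eff = result.effective_epochs if result is not None else hp.epochs
        if cache:
            memo[key] = (cost, eff)
        eff_logged = eff if eff is not None else hp.epochs
        records.append(
            EvaluationRecord(
                iteration, wolf_index, hp, cost, eff_logged,
                time.perf_counter() - t0, time.time(),
            )
        )
        logger.info(
            "eval iter=%d wolf=%d cost=%.4f eff_epochs=%d hp=%s",
            iteration,
            wolf_index,
            cost,
            eff_logged,
            hp.as_dict(),
        )
        return _with_feedback(cost, x, eff)

    def _with_feedback(cost, x, eff):
        if epoch_feedback == "replace" and eff is not None:
            x_new = np.asarray(x, dtype=float).copy()
            x_new[4] = eff
            return cost, x_new
        return cost

    opt = gwo.optimize(
        cost_fn,
        space.to_bounds(),
        n_wolves=n_wolves,
        n_iterations=n_iterations,
        seed=seed,
        pass_context=True,
    )
    best_idx = int(np.argmin([r.cost for r in records]))
    best = records[best_idx]
    return SearchResult(
        best_hyperparameters=best.hyperparameters,
        best_cost=best.cost,
        history=opt.history,
        evaluations=records,
        final_population=opt.population,
    )
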