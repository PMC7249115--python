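"""Training of the refinement network.

Loss is the batch RMSE; optimisation uses AdamW (Adam with decoupled weight
decay and standard bias correction) at a constant learning rate — no
schedules.  The training set is enlarged by ring rotations of the 3x3 patch:
keeping the centre pixel fixed, the eight surrounding cells of both layers
are cyclically rotated, producing up to 7 extra samples per original, all
sharing the same reference value.  A learning-rate range test and a
random-then-grid hyperparameter search are provided for tuning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import RarefyNet, RarefyNetConfig, build_model
from .raster_io import PatchTensor, SamplePair, pairs_to_arrays


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; the model was restored to the last good state."""

    def __init__(self, message: str, history: pd.DataFrame | None = None):
        super().__init__(message)
        self.history = history


@dataclass
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults follow the reference protocol: 300 epochs, mini-batches of 64,
    constant learning rate 5e-4, and all 7 nonzero ring rotations as data
    augmentation on the training partition only.
    """

    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 5e-4
    weight_decay: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    augmentation_rotations: int = 7
    test_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in [0, 1)")
        if not 0 <= self.augmentation_rotations <= 7:
            raise ValueError("augmentation_rotations must be in [0, 7]")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


@dataclass
class OptimizerState:
    """Per-parameter AdamW accumulators: first/second moments and step count."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0


# ring positions of a 3x3 patch in clockwise order starting at the top-left
_RING_ROWS = np.array([0, 0, 0, 1, 2, 2, 2, 1])
_RING_COLS = np.array([0, 1, 2, 2, 2, 1, 0, 0])


def _rotate_ring(grid: np.ndarray, steps: int) -> np.ndarray:
    """Rotate the 8-cell ring of a 3x3 grid clockwise by ``steps`` positions."""
    out = grid.copy()
    src_r = np.roll(_RING_ROWS, steps)
    src_c = np.roll(_RING_COLS, steps)
    out[_RING_ROWS, _RING_COLS] = grid[src_r, src_c]
    return out


def augment_sample(pair: SamplePair, n_rotations: int = 7) -> list[SamplePair]:
    """The original sample plus ``n_rotations`` distinct nonzero ring rotations.

    Both the NDVI and the location layer rotate together; the centre cell and
    the reference value never change.
    """
    if not 0 <= n_rotations <= 7:
        raise ValueError("n_rotations must be in [0, 7]")
    out = [pair]
    for step in range(1, n_rotations + 1):
        out.append(
            SamplePair(
                x=PatchTensor(
                    patch=_rotate_ring(pair.x.patch, step),
                    locations=_rotate_ring(pair.x.locations, step),
                    center_index=pair.x.center_index,
                ),
                y=pair.y,
            )
        )
    return out


def rmse_loss(predictions: np.ndarray, references: np.ndarray) -> float:
    """Root-mean-square error over a batch; zero iff elementwise equal."""
    predictions = np.asarray(predictions, dtype=np.float64)
    references = np.asarray(references, dtype=np.float64)
    if predictions.shape != references.shape:
        raise ValueError("predictions and references must have the same length")
    if predictions.size == 0:
        raise ValueError("rmse_loss of an empty batch is undefined")
    return float(np.sqrt(np.mean((predictions - references) ** 2)))


def _rmse_grad(predictions: np.ndarray, references: np.ndarray,
               loss: float) -> np.ndarray:
    """d(RMSE)/d(predictions); zero at the (non-differentiable) minimum."""
    if loss == 0.0:
        return np.zeros_like(predictions)
    return (predictions - references) / (predictions.size * loss)


def adamw_step(theta: np.ndarray, grad: np.ndarray, state: OptimizerState,
               learning_rate: float, weight_decay: float = 0.0,
               beta1: float = 0.9, beta2: float = 0.999,
               eps: float = 1e-8) -> tuple[np.ndarray, OptimizerState]:
    """One AdamW update: bias-corrected Adam step plus decoupled decay.

    With ``weight_decay == 0`` this is exactly plain Adam; with zero
    gradients from a zero state only the decay term survives and the
    parameters contract by ``(1 - lr * weight_decay)``.
    """
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite gradient passed to adamw_step")
    t = state.t + 1
    m = beta1 * state.m + (1.0 - beta1) * grad
    v = beta2 * state.v + (1.0 - beta2) * grad ** 2
    m_hat = m / (1.0 - beta1 ** t)
    v_hat = v / (1.0 - beta2 ** t)
    theta_new = theta - learning_rate * m_hat / (np.sqrt(v_hat) + eps) \
        - learning_rate * weight_decay * theta
    return theta_new, OptimizerState(m=m, v=v, t=t)


class AdamW:
    """Keeps AdamW state for a dict of live parameter arrays, updated in place."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float,
                 weight_decay: float = 0.0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.state = {k: OptimizerState(np.zeros_like(p), np.zeros_like(p))
                      for k, p in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for key, grad in grads.items():
            if not np.all(np.isfinite(grad)):
                raise FloatingPointError(f"non-finite gradient for parameter {key!r}")
            new_theta, self.state[key] = adamw_step(
                self.params[key], grad, self.state[key],
                self.learning_rate, self.weight_decay,
                self.beta1, self.beta2, self.eps,
            )
            self.params[key][...] = new_theta


class _FlatAdamW:
    """AdamW on one flat parameter vector (same arithmetic as `adamw_step`).

    The training loop uses this vectorised form for speed; equivalence with
    the per-array `adamw_step` is exact and covered by tests.
    """

    def __init__(self, theta: np.ndarray, config: "TrainConfig"):
        self.theta = theta
        self.cfg = config
        self.m = np.zeros_like(theta)
        self.v = np.zeros_like(theta)
        self.t = 0
        self.learning_rate = config.learning_rate

    def step(self, grad: np.ndarray) -> None:
        cfg = self.cfg
        self.t += 1
        self.m *= cfg.beta1
        self.m += (1.0 - cfg.beta1) * grad
        self.v *= cfg.beta2
        self.v += (1.0 - cfg.beta2) * grad ** 2
        m_hat = self.m / (1.0 - cfg.beta1 ** self.t)
        denom = np.sqrt(self.v / (1.0 - cfg.beta2 ** self.t))
        denom += cfg.eps
        self.theta -= self.learning_rate * (m_hat / denom + cfg.weight_decay * self.theta)


def split_train_test(samples: list, test_fraction: float,
                     seed: int) -> tuple[list, list]:
    """Random, reproducible, disjoint and exhaustive train/test partition.

    Augmentation belongs to the training partition only; apply it after
    splitting (``train`` does this internally).
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    n = len(samples)
    n_test = int(round(n * test_fraction))
    perm = np.random.default_rng(seed).permutation(n)
    test = [samples[i] for i in perm[:n_test]]
    train = [samples[i] for i in perm[n_test:]]
    return train, test


def split_train_test_blocked(samples: list[SamplePair], test_fraction: float,
                             seed: int, ncols: int) -> tuple[list, list]:
    """Row-blocked alternative split: whole raster rows go to one partition."""
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    rows = sorted({p.x.center_index // ncols for p in samples})
    n_test_rows = int(round(len(rows) * test_fraction))
    perm = np.random.default_rng(seed).permutation(len(rows))
    test_rows = {rows[i] for i in perm[:n_test_rows]}
    train = [p for p in samples if p.x.center_index // ncols not in test_rows]
    test = [p for p in samples if p.x.center_index // ncols in test_rows]
    return train, test


def _snapshot(model: RarefyNet) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in {**model.parameters(), **model.stats()}.items()}


def _restore(model: RarefyNet, snap: dict[str, np.ndarray]) -> None:
    live = {**model.parameters(), **model.stats()}
    for k, v in snap.items():
        live[k][...] = v


def train(model: RarefyNet, train_pairs: list[SamplePair],
          test_pairs: list[SamplePair] | None, config: TrainConfig,
          keep_best: bool = False) -> tuple[RarefyNet, pd.DataFrame]:
    """Mini-batch training loop; returns the model and a per-epoch history.

    The training partition is augmented once up front with
    ``config.augmentation_rotations`` ring rotations; the test partition is
    never augmented.  ``history`` has columns (epoch, train_loss, test_loss):
    train_loss is the mean of the optimisation batch losses, test_loss a full
    inference-mode pass.  Deterministic for a fixed ``config.seed``.

    With ``keep_best=True`` the parameters from the epoch with the lowest
    test loss are restored at the end (the default keeps the final epoch).
    """
    if not train_pairs:
        raise ValueError("training set is empty")
    rng_shuffle, rng_dropout = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(2)
    )
    augmented = [aug for pair in train_pairs
                 for aug in augment_sample(pair, config.augmentation_rotations)]
    x_train, y_train = pairs_to_arrays(augmented)
    x_test, y_test = pairs_to_arrays(test_pairs or [])

    optimizer = _FlatAdamW(model.flatten_parameters(), config)
    history: list[dict] = []
    best_loss, best_snap = np.inf, None
    snap = _snapshot(model)
    n = len(x_train)
    for epoch in range(config.epochs):
        perm = rng_shuffle.permutation(n)
        batch_losses, batch_sizes = [], []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            with np.errstate(over="ignore", invalid="ignore"):
                pred = model.forward(x_train[idx], training=True, rng=rng_dropout)
                loss = np.sqrt(np.mean((pred - y_train[idx]) ** 2))
                if np.isfinite(loss):
                    model.backward(_rmse_grad(pred, y_train[idx], loss))
                    grad = model.flat_gradients()
            if not np.isfinite(loss) or not np.all(np.isfinite(grad)):
                _restore(model, snap)
                raise TrainingDivergedError(
                    f"loss diverged at epoch {epoch}; restored last good checkpoint",
                    history=pd.DataFrame(history),
                )
            optimizer.step(grad)
            batch_losses.append(loss * len(idx))
            batch_sizes.append(len(idx))
        snap = _snapshot(model)
        record = {"epoch": epoch,
                  "train_loss": float(np.sum(batch_losses) / np.sum(batch_sizes))}
        if len(x_test):
            test_loss = rmse_loss(model.predict(x_test), y_test)
            record["test_loss"] = test_loss
            if test_loss < best_loss:
                best_loss, best_snap = test_loss, snap
        history.append(record)
    if keep_best and best_snap is not None:
        _restore(model, best_snap)
    return model, pd.DataFrame(history)


def suggest_lr_from_curve(lrs: np.ndarray, losses: np.ndarray,
                          smoothing: float = 0.85,
                          blowup: float = 4.0) -> tuple[float, bool]:
    """Pick a learning rate from a range-test sweep.

    The loss curve is exponentially smoothed; the sweep is truncated at the
    divergence point (smoothed loss exceeding ``blowup`` times the running
    minimum, or going non-finite) and the suggestion is the rate at the
    smoothed-loss minimum divided by 10.  Returns ``(suggestion, diverged)``.
    """
    lrs = np.asarray(lrs, dtype=np.float64)
    losses = np.asarray(losses, dtype=np.float64)
    ema = np.empty_like(losses)
    running = losses[0]
    diverged = False
    cut = len(losses)
    best = np.inf
    for i, loss in enumerate(losses):
        if not np.isfinite(loss):
            diverged, cut = True, i
            break
        running = smoothing * running + (1 - smoothing) * loss
        ema[i] = running
        best = min(best, running)
        if running > blowup * best:
            diverged, cut = True, i
            break
    if cut == 0:
        raise ValueError("loss is non-finite at the smallest learning rate")
    idx = int(np.argmin(ema[:cut]))
    return float(lrs[idx] / 10.0), diverged


def lr_range_test(model: RarefyNet, samples: list[SamplePair],
                  lr_min: float = 1e-7, lr_max: float = 1.0,
                  steps: int = 100, batch_size: int = 64,
                  seed: int = 0) -> float:
    """Exponential learning-rate sweep over one pass, on a throwaway model copy.

    Returns the suggested (maximum safe) constant learning rate: one decade
    below the loss-divergence point.  If the loss never diverges across the
    sweep, ``lr_max / 10`` is returned with a warning.
    """
    if steps < 10:
        raise ValueError("lr_range_test needs at least 10 steps")
    if not samples:
        raise ValueError("no samples provided")
    probe = model.copy()
    x, y = pairs_to_arrays(samples)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    lrs = np.geomspace(lr_min, lr_max, steps)
    optimizer = AdamW(probe.parameters(), lrs[0])
    losses = np.empty(steps)
    pos = 0
    for i, lr in enumerate(lrs):
        if pos + batch_size > len(order):
            order = rng.permutation(len(x))
            pos = 0
        idx = order[pos:pos + batch_size]
        pos += batch_size
        pred = probe.forward(x[idx], training=True, rng=rng)
        loss = np.sqrt(np.mean((pred - y[idx]) ** 2))
        if i == 0 and not np.isfinite(loss):
            raise ValueError("loss is non-finite at lr_min")
        losses[i] = loss
        if not np.isfinite(loss):
            losses = losses[:i + 1]
            break
        probe.backward(_rmse_grad(pred, y[idx], loss))
        optimizer.learning_rate = lr
        optimizer.step(probe.gradients())
    suggestion, diverged = suggest_lr_from_curve(lrs[:len(losses)], losses)
    if not diverged:
        warnings.warn("loss never diverged over the sweep; returning lr_max / 10")
        return lr_max / 10.0
    return suggestion


def hyperparameter_search(space: dict[str, list], samples: list[SamplePair],
                          budget_random: int = 8, grid_refinement: int = 1,
                          base_config: TrainConfig | None = None,
                          arch_config: RarefyNetConfig | None = None,
                          search_epochs: int = 10, subset_fraction: float = 0.10,
                          seed: int = 0, full_output: bool = False):
    """Two-stage tuning: uniform random search, then a local grid refinement.

    Each candidate is scored by training briefly (``search_epochs``) on a
    small subset (``subset_fraction`` of the samples, split 70/30 into
    fit/validation) and taking the final validation RMSE.  Stage 2 evaluates
    the grid of neighbouring values (index distance <= ``grid_refinement``)
    around the stage-1 winner.  Returns the best :class:`TrainConfig` with
    the base epoch budget restored (or ``(config, trials)`` with
    ``full_output=True``).
    """
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("search space must map parameter names to non-empty value lists")
    base = base_config or TrainConfig()
    unknown = set(space) - set(vars(base))
    if unknown:
        raise ValueError(f"unknown TrainConfig fields in space: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    n_sub = max(int(round(subset_fraction * len(samples))), 10)
    n_sub = min(n_sub, len(samples))
    sub_idx = rng.choice(len(samples), size=n_sub, replace=False)
    subset = [samples[i] for i in sub_idx]
    fit_set, val_set = split_train_test(subset, 0.30, seed=int(rng.integers(2 ** 31)))

    keys = sorted(space)
    scores: dict[tuple, float] = {}

    def evaluate(combo: tuple) -> float:
        if combo not in scores:
            cfg = replace(base, **dict(zip(keys, combo)),
                          epochs=search_epochs, seed=seed)
            model = build_model(arch_config, seed=seed)
            _, hist = train(model, fit_set, val_set, cfg)
            scores[combo] = float(hist["test_loss"].iloc[-1])
        return scores[combo]

    candidates = {tuple(space[k][int(rng.integers(len(space[k])))] for k in keys)
                  for _ in range(budget_random)}
    best = min(candidates, key=evaluate)

    # stage 2: neighbourhood grid around the stage-1 winner
    axes = []
    for k, value in zip(keys, best):
        i = space[k].index(value)
        lo, hi = max(0, i - grid_refinement), min(len(space[k]), i + grid_refinement + 1)
        axes.append(space[k][lo:hi])
    best = min(itertools.product(*axes), key=evaluate)

    best_config = replace(base, **dict(zip(keys, best)))
    if full_output:
        trials = pd.DataFrame(
            [dict(zip(keys, combo), val_loss=loss) for combo, loss in scores.items()]
        ).sort_values("val_loss", ignore_index=True)
        return best_config, trials
    return best_config
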