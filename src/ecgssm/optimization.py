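"""Training machinery: learning-rate schedules, Adam, stratified splits and
the epoch-aware training loop.

Two schedules are provided.  The Noam schedule

    lr(t) = d_model^{-0.5} * min(t^{-0.5}, t * omega^{-1.5})

rises linearly for ``omega`` warm-up steps (4,000 by default) and decays as
t^{-0.5} afterwards; ``d_model`` defaults to 729, the token-sequence length,
following the reference configuration (which fixes d_model at 729 even though
the embedding width is 384).  The StepLR comparator starts at 1e-3 and decays
by 10x every 20 epochs.

Splits use iterative multilabel stratification: labels are processed from
rarest to most frequent, and each record carrying the current label goes to
the fold with the greatest remaining demand for it.  Batching drops the last
incomplete batch, so steps per epoch = floor(N / batch): 70,602 records at
batch 30 give 2,353 steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import augment as aug
from .autograd import Tensor, bce_with_logits
from .model import ECGSSMClassifier


@dataclass
class NoamConfig:
    d_model: int = 729
    warmup: int = 4000

    def __post_init__(self) -> None:
        if self.d_model <= 0 or self.warmup <= 0:
            raise ValueError("d_model and warmup must be positive")


@dataclass
class StepLRConfig:
    init_lr: float = 1e-3
    gamma: float = 0.1
    step_epochs: int = 20

    def __post_init__(self) -> None:
        if self.init_lr <= 0 or not 0 < self.gamma < 1:
            raise ValueError("init_lr must be > 0 and gamma in (0, 1)")


def noam_lr(t: int, config: NoamConfig) -> float:
    """Warm-up/decay learning rate at optimizer step ``t`` (1-based)."""
    if t < 1:
        raise ValueError("steps are 1-based")
    return config.d_model ** -0.5 * min(t ** -0.5,
                                        t * config.warmup ** -1.5)


def step_lr(epoch: int, config: StepLRConfig) -> float:
    """Staircase decay: init_lr * gamma^floor(epoch / step_epochs)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.init_lr * config.gamma ** (epoch // config.step_epochs)


def steps_per_epoch(n_train: int, batch_size: int) -> int:
    """Drop-last convention: the final incomplete batch is discarded."""
    return n_train // batch_size


def holdout_sizes(n: int, train_frac: float = 0.8) -> tuple[int, int]:
    """Round-half-up train/test sizes for a single stratified holdout."""
    train = int(math.floor(n * train_frac + 0.5))
    return train, n - train


# --------------------------------------------------------------------------
# stratified multilabel splits
# --------------------------------------------------------------------------

@dataclass
class SplitPlan:
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


def _fold_capacities(n: int, k: int) -> np.ndarray:
    """Fold sizes: fold 0 gets n - floor(n*(k-1)/k + 0.5) (so that holding
    out fold 0 reproduces the round-half-up holdout arithmetic); the rest is
    spread over folds 1..k-1 largest-remainder."""
    test0 = n - int(math.floor(n * (k - 1) / k + 0.5))
    rest, base = n - test0, (n - test0) // (k - 1)
    sizes = [test0] + [base] * (k - 1)
    for i in range(1, 1 + rest - base * (k - 1)):
        sizes[i] += 1
    return np.array(sizes)


def make_splits(label_sets: list[set[str]],
                plan: SplitPlan | None = None) -> np.ndarray:
    """Assign each record to one of ``n_folds`` disjoint folds, balancing
    per-class positive counts across folds (iterative stratification).

    Returns an integer fold index per record.  Classes with fewer positives
    than folds are placed best-effort.
    """
    plan = plan or SplitPlan()
    n, k = len(label_sets), plan.n_folds
    if n < k:
        raise ValueError("fewer records than folds")
    rng = np.random.default_rng(plan.seed)
    capacity = _fold_capacities(n, k).astype(float)
    assign = np.full(n, -1, dtype=int)

    codes = sorted({c for s in label_sets for c in s})
    counts = {c: sum(c in s for s in label_sets) for c in codes}
    # per-fold demand for each label, proportional to fold capacity
    demand = {c: counts[c] * capacity / n for c in codes}

    remaining = set(range(n))
    while True:
        active = [c for c in codes
                  if any(c in label_sets[i] for i in remaining)]
        if not active:
            break
        # rarest remaining label first
        label = min(active,
                    key=lambda c: sum(c in label_sets[i] for i in remaining))
        members = [i for i in remaining if label in label_sets[i]]
        rng.shuffle(members)
        for i in members:
            pref = demand[label]
            best = np.flatnonzero(pref == pref.max())
            if len(best) > 1:
                cap = capacity[best]
                best = best[np.flatnonzero(cap == cap.max())]
            fold = int(rng.choice(best))
            assign[i] = fold
            remaining.discard(i)
            capacity[fold] -= 1
            for c in label_sets[i]:
                demand[c][fold] -= 1

    leftovers = list(remaining)
    rng.shuffle(leftovers)
    for i in leftovers:
        fold = int(np.argmax(capacity + rng.random(k) * 1e-9))
        assign[i] = fold
        capacity[fold] -= 1
    return assign


def fold_train_test(assign: np.ndarray,
                    fold: int) -> tuple[np.ndarray, np.ndarray]:
    test = np.flatnonzero(assign == fold)
    train = np.flatnonzero(assign != fold)
    return train, test


# --------------------------------------------------------------------------
# Adam and the training loop
# --------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 30
    schedule: str = "noam"                    # or "steplr"
    noam: NoamConfig = field(default_factory=NoamConfig)
    steplr: StepLRConfig = field(default_factory=StepLRConfig)
    augment_mode: str = "none"                # none | mixup | cutmix
    participation: aug.ParticipationSchedule = field(
        default_factory=aug.ParticipationSchedule)
    mix: aug.MixConfig = field(default_factory=aug.MixConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schedule not in ("noam", "steplr"):
            raise ValueError("schedule must be 'noam' or 'steplr'")
        if self.augment_mode not in ("none", "mixup", "cutmix"):
            raise ValueError("augment_mode must be none/mixup/cutmix")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")


@dataclass
class TrainResult:
    model: ECGSSMClassifier
    log: list[dict]


def train(model: ECGSSMClassifier, signals: np.ndarray, labels: np.ndarray,
          config: TrainConfig | None = None) -> TrainResult:
    """Adam training with epoch-aware non-uniform augmentation.

    ``signals``: [N, 12, input_len] preprocessed records; ``labels``:
    [N, n_classes] multi-hot (soft values allowed).  Each epoch the
    augmentation hook rewrites the scheduled fraction of the dataset, the
    order is reshuffled, and drop-last minibatches are consumed with BCE loss
    on (soft) targets.  Deterministic for a given seed on one device.
    """
    config = config or TrainConfig()
    signals = np.asarray(signals, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(signals) != len(labels):
        raise ValueError("signals and labels disagree on N")
    n = len(signals)
    optimizer = Adam(model.parameters())
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    step = 0

    for epoch in range(1, config.epochs + 1):
        if config.augment_mode == "none":
            dataset = list(zip(signals, labels))
            n_mixed = 0
        else:
            dataset, report = aug.apply_epoch(
                list(zip(signals, labels)), epoch, config.participation,
                config.mix, rng, mode=config.augment_mode)
            n_mixed = report.n_mixed

        order = rng.permutation(n)
        losses = []
        for b in range(steps_per_epoch(n, config.batch_size)):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            x = np.stack([dataset[i][0] for i in idx])
            y = np.stack([dataset[i][1] for i in idx])
            step += 1
            lr = (noam_lr(step, config.noam) if config.schedule == "noam"
                  else step_lr(epoch - 1, config.steplr))
            logits = model.forward(x, training=True)
            loss = bce_with_logits(logits, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: loss={loss.data} at step {step}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step(lr)
            losses.append(float(loss.data))
        log.append({"epoch": epoch, "steps": len(losses),
                    "mean_loss": float(np.mean(losses)) if losses else None,
                    "n_mixed": n_mixed, "lr": lr if losses else None})
    return TrainResult(model=model, log=log)
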