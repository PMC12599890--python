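"""Non-uniform MixUp / CutMix scheduling over training epochs.

Classic MixUp blends every sample every epoch.  The non-uniform variant
implemented here mixes only a per-epoch fraction of the training set: 20% in
epoch 1, growing by 20 points per epoch to an 80% cap where it stays, or a
user-supplied cycling pattern such as (0, 0.6, 0.8, 0).  The blending itself
is the standard convex combination

    X_g = lam * X_c + (1 - lam) * X_r,    L_g = lam * L_c + (1 - lam) * L_r,

with lam ~ Beta(alpha, beta), alpha = beta = 10 by default (draws concentrate
near 1/2).  Participants are chosen uniformly without replacement; each
participant's partner is drawn uniformly from the full dataset (a sample may
serve as both participant and partner in the same epoch).  CutMix swaps a
contiguous time segment, identical across all 12 leads, and mixes labels in
proportion to the swapped fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class MixConfig:
    alpha: float = 10.0
    beta: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")


@dataclass
class ParticipationSchedule:
    """Per-epoch fraction of the dataset that gets mixed.

    ``ramp``: min(ramp_step * epoch, cap) — the default non-uniform schedule.
    ``cycle``: cycle_pattern[epoch - 1], repeating the last entry forever.
    ``constant``: cap at every epoch.
    """

    mode: str = "ramp"
    ramp_step: float = 0.20
    cap: float = 0.80
    cycle_pattern: tuple[float, ...] = (0.0, 0.2, 0.4, 0.0)

    def __post_init__(self) -> None:
        if self.mode not in ("ramp", "cycle", "constant"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        for f in (self.ramp_step, self.cap, *self.cycle_pattern):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.cap < self.ramp_step:
            raise ValueError("cap must be >= ramp_step")


@dataclass
class MixedSample:
    signal: np.ndarray
    label: np.ndarray
    lambda_used: float
    partner_id: int | str | None = None

    def __post_init__(self) -> None:
        if np.any(self.label < 0) or np.any(self.label > 1):
            raise ValueError("soft labels must lie in [0, 1]")
        if not np.isfinite(self.signal).all():
            raise ValueError("mixed signal must be finite")


@dataclass
class EpochMixReport:
    """Instrumentation emitted by :func:`apply_epoch`."""

    epoch: int
    fraction: float
    n_mixed: int
    participants: np.ndarray
    partners: np.ndarray
    lambdas: np.ndarray


def participation_fraction(epoch: int,
                           schedule: ParticipationSchedule) -> float:
    """Fraction of the dataset mixed at ``epoch`` (1-based)."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    if schedule.mode == "ramp":
        return min(schedule.ramp_step * epoch, schedule.cap)
    if schedule.mode == "cycle":
        idx = min(epoch - 1, len(schedule.cycle_pattern) - 1)
        return schedule.cycle_pattern[idx]
    return schedule.cap


def sample_lambda(config: MixConfig, rng: np.random.Generator) -> float:
    return float(rng.beta(config.alpha, config.beta))


def mixup_pair(x_c: np.ndarray, x_r: np.ndarray, l_c: np.ndarray,
               l_r: np.ndarray, lam: float) -> MixedSample:
    """Convex combination of two (signal, label) pairs with coefficient lam."""
    x_c, x_r = np.asarray(x_c, dtype=float), np.asarray(x_r, dtype=float)
    l_c, l_r = np.asarray(l_c, dtype=float), np.asarray(l_r, dtype=float)
    if x_c.shape != x_r.shape or l_c.shape != l_r.shape:
        raise ValueError("signal/label shapes must match")
    if not 0 <= lam <= 1:
        raise ValueError("lam must lie in [0, 1]")
    return MixedSample(signal=lam * x_c + (1 - lam) * x_r,
                       label=lam * l_c + (1 - lam) * l_r,
                       lambda_used=lam)


def cutmix_pair(x_c: np.ndarray, x_r: np.ndarray, l_c: np.ndarray,
                l_r: np.ndarray, cut_fraction: float,
                rng: np.random.Generator | None = None,
                start: int | None = None) -> MixedSample:
    """Replace a contiguous time segment of ``x_c`` by the partner's samples.

    The segment position is shared by all leads; labels mix in proportion to
    the replaced fraction.  ``start`` pins the segment (for tests); otherwise
    it is drawn uniformly from ``rng``.
    """
    x_c, x_r = np.asarray(x_c, dtype=float), np.asarray(x_r, dtype=float)
    l_c, l_r = np.asarray(l_c, dtype=float), np.asarray(l_r, dtype=float)
    if x_c.shape != x_r.shape or l_c.shape != l_r.shape:
        raise ValueError("signal/label shapes must match")
    if not 0 < cut_fraction < 1:
        raise ValueError("cut_fraction must lie in (0, 1)")
    n = x_c.shape[-1]
    seg = int(round(cut_fraction * n))
    if seg < 1 or seg > n - 1:
        warnings.warn("degenerate cut segment clipped to [1, n-1]")
        seg = min(max(seg, 1), n - 1)
    if start is None:
        rng = rng or np.random.default_rng()
        start = int(rng.integers(0, n - seg + 1))
    elif not 0 <= start <= n - seg:
        raise ValueError("segment start out of range")
    mixed = x_c.copy()
    mixed[..., start:start + seg] = x_r[..., start:start + seg]
    frac = seg / n
    return MixedSample(signal=mixed,
                       label=(1 - frac) * l_c + frac * l_r,
                       lambda_used=1 - frac)


def apply_epoch(dataset: list[tuple[np.ndarray, np.ndarray]], epoch: int,
                schedule: ParticipationSchedule, mix_config: MixConfig,
                rng: np.random.Generator, mode: str = "mixup",
                ) -> tuple[list[tuple[np.ndarray, np.ndarray]],
                           EpochMixReport]:
    """Mix exactly round(fraction * N) samples of ``dataset`` for one epoch.

    Participants are drawn uniformly without replacement, partners uniformly
    from the whole dataset; non-participants pass through untouched.  Returns
    the transformed dataset and an :class:`EpochMixReport` with the
    participation bookkeeping.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    if mode not in ("mixup", "cutmix"):
        raise ValueError(f"unknown mix mode {mode!r}")
    n = len(dataset)
    fraction = participation_fraction(epoch, schedule)
    n_mix = int(round(fraction * n))
    participants = rng.choice(n, size=n_mix, replace=False)
    partners = rng.integers(0, n, size=n_mix)
    lambdas = np.empty(n_mix)

    out = list(dataset)
    for k, (i, j) in enumerate(zip(participants, partners)):
        x_c, l_c = dataset[i]
        x_r, l_r = dataset[j]
        if mode == "mixup":
            lam = sample_lambda(mix_config, rng)
            mixed = mixup_pair(x_c, x_r, l_c, l_r, lam)
        else:
            lam = sample_lambda(mix_config, rng)
            # Beta draw reused as the cut fraction, clipped away from {0, 1}
            cut = min(max(lam, 1e-3), 1 - 1e-3)
            mixed = cutmix_pair(x_c, x_r, l_c, l_r, cut, rng=rng)
        lambdas[k] = mixed.lambda_used
        out[i] = (mixed.signal, mixed.label)

    report = EpochMixReport(epoch=epoch, fraction=fraction, n_mixed=n_mix,
                            participants=participants, partners=partners,
                            lambdas=lambdas)
    return out, report
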