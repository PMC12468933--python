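"""Unpaired-probability curves and learning-rate schedules.

The central object is the *unpaired probability curve* ``P(t)``: at normalized
training time ``t = step / total_steps`` it gives the probability that an
example in the current batch is drawn from the unpaired (single-chain) corpus
rather than the natively paired corpus.  Three curve families are supported:

``curriculum``
    A decaying sigmoid ``P(t) = B - A / (1 + exp(-k * (t - shift)))`` that
    starts near its upper bound ``B``, transitions around ``t = shift`` with
    steepness ``k``, and ends near ``B - A``.  The ``shift`` parameter is
    normally *solved* so that the time-average of ``P`` equals a target total
    unpaired fraction (default 62.5%), which keeps total unpaired exposure
    comparable across curve shapes.

``constant``
    ``P(t) = target_mean`` for all ``t`` — a fixed unpaired:paired mixture.

``finetune``
    ``P(t) = 1`` for ``t < switch_fraction`` and ``0`` afterwards — classic
    pretrain-on-unpaired-then-finetune-on-paired, expressed as a schedule so
    that all strategies share one interface.  ``switch_fraction`` equals the
    target mean, so total unpaired exposure again matches.

Learning-rate schedules (linear decay, warmup-stable-decay, cosine annealing
with warm restarts) live here too, since they are configured alongside the
data schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ScheduleSpec",
    "LRScheduleSpec",
    "unpaired_probability",
    "mean_unpaired_fraction",
    "solve_shift",
    "learning_rate",
    "curve_table",
]

#: Total unpaired fraction used when solving curriculum shifts, matching the
#: fixed 62.5% mixture used for all mixed-data strategies.
DEFAULT_TARGET_MEAN = 0.625

_SHIFT_BRACKET = (-5.0, 6.0)


class InfeasibleTargetError(ValueError):
    """Requested mean lies outside the attainable range of the curve family."""


@dataclass
class ScheduleSpec:
    """Parameters of one unpaired-probability curve.

    Parameters
    ----------
    kind:
        ``"curriculum"``, ``"constant"`` or ``"finetune"``.
    A:
        Height of the sigmoid drop (curriculum only), in [0, 1].
    B:
        Upper bound of the curve (curriculum only), in (0, 1]; requires
        ``B - A >= 0`` so probabilities stay non-negative.
    k:
        Sigmoid steepness (> 0).  Larger values give a sharper transition.
    shift:
        Sigmoid midpoint in normalized time.  ``None`` means "solve for
        ``target_mean``" on construction.
    total_steps:
        Number of optimizer steps the schedule spans.
    target_mean:
        Intended time-averaged unpaired fraction in (0, 1).
    switch_fraction:
        For ``kind="finetune"``, the normalized time of the unpaired→paired
        switch.  Defaults to ``target_mean`` so exposure matches.
    """

    kind: str = "curriculum"
    A: float = 0.4
    B: float = 0.7
    k: float = 15.0
    shift: Optional[float] = None
    total_steps: int = 100_000
    target_mean: float = DEFAULT_TARGET_MEAN
    switch_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("curriculum", "constant", "finetune"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        for name in ("A", "B", "k", "target_mean"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.total_steps <= 0:
            raise ValueError("total_steps must be positive")
        # constant admits the closed endpoints so that pure paired-only
        # (P≡0) and unpaired-only (P≡1) strategies share the interface
        if self.kind == "constant":
            if not 0.0 <= self.target_mean <= 1.0:
                raise ValueError("target_mean must lie in [0, 1]")
        elif not 0.0 < self.target_mean < 1.0:
            raise ValueError("target_mean must lie strictly inside (0, 1)")
        if self.kind == "curriculum":
            if not (0.0 <= self.A <= 1.0 and 0.0 < self.B <= 1.0):
                raise ValueError("need 0 <= A <= 1 and 0 < B <= 1")
            if self.B - self.A < 0.0:
                raise ValueError("need B - A >= 0 so that P(t) stays in [0, 1]")
            if self.k <= 0:
                raise ValueError("k must be positive")
            if self.shift is None:
                self.shift = solve_shift(self.A, self.B, self.k, self.target_mean)
        elif self.kind == "finetune":
            if self.switch_fraction is None:
                self.switch_fraction = self.target_mean
            if not 0.0 < self.switch_fraction < 1.0:
                raise ValueError("switch_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScheduleSpec":
        return cls(**d)


@dataclass
class LRScheduleSpec:
    """Learning-rate schedule: linear decay, WSD, or SGDR.

    All kinds share a linear warmup from 0 to ``peak_lr`` over
    ``warmup_steps`` steps.  After warmup:

    - ``linear``: affine decay to 0 at ``total_steps``.
    - ``wsd``: constant at ``peak_lr`` until ``stable_fraction`` of total
      steps, then linear decay to 0 (warmup-stable-decay).
    - ``sgdr``: ``n_restarts`` equal cosine half-periods, each decaying from
      ``peak_lr`` to 0 and restarting at the peak.
    """

    kind: str = "linear"
    peak_lr: float = 4e-4
    warmup_steps: int = 6000
    total_steps: int = 100_000
    stable_fraction: float = 0.8
    n_restarts: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "wsd", "sgdr"):
            raise ValueError(f"unknown LR schedule kind {self.kind!r}")
        if self.warmup_steps < 0 or self.total_steps <= 0:
            raise ValueError("warmup_steps >= 0 and total_steps > 0 required")
        if self.warmup_steps > self.total_steps:
            raise ValueError("warmup_steps cannot exceed total_steps")
        if not (0.0 < self.stable_fraction < 1.0):
            raise ValueError("stable_fraction must lie in (0, 1)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not math.isfinite(self.peak_lr) or self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive and finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LRScheduleSpec":
        return cls(**d)


def _sigmoid(x: float) -> float:
    # numerically stable logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def unpaired_probability(spec: ScheduleSpec, step: int) -> float:
    """Evaluate P(t) at ``t = step / total_steps``, clamped to [0, 1].

    ``step`` is 0-based and evaluated at batch start, so ``P(0)`` is the
    mixture of the very first batch.
    """
    if not 0 <= step <= spec.total_steps:
        raise ValueError(f"step {step} outside [0, {spec.total_steps}]")
    t = step / spec.total_steps
    if spec.kind == "constant":
        p = spec.target_mean
    elif spec.kind == "finetune":
        p = 1.0 if t < spec.switch_fraction else 0.0
    else:
        p = spec.B - spec.A * _sigmoid(spec.k * (t - spec.shift))
    return min(1.0, max(0.0, p))


def _softplus(x: float) -> float:
    # log(1 + e^x) without overflow
    if x > 30:
        return x + math.log1p(math.exp(-x))
    return math.log1p(math.exp(x))


def _curriculum_mean(A: float, B: float, k: float, shift: float) -> float:
    # closed form of ∫₀¹ B − A·σ(k(t−shift)) dt
    return B - (A / k) * (_softplus(k * (1.0 - shift)) - _softplus(-k * shift))


def mean_unpaired_fraction(spec: ScheduleSpec) -> float:
    """Exact time-average of P(t) over t ∈ [0, 1] (closed form, no sampling)."""
    if spec.kind == "constant":
        return spec.target_mean
    if spec.kind == "finetune":
        return spec.switch_fraction
    return _curriculum_mean(spec.A, spec.B, spec.k, spec.shift)


def solve_shift(A: float, B: float, k: float,
                target_mean: float = DEFAULT_TARGET_MEAN) -> float:
    """Solve for the sigmoid midpoint giving a desired time-averaged mixture.

    The mean is strictly increasing in ``shift`` (pushing the drop later keeps
    P near its upper bound longer), so a bracketing root search converges.
    Raises :class:`InfeasibleTargetError` when ``target_mean`` is outside the
    open interval attainable with finite shift.
    """
    if A <= 0:
        raise InfeasibleTargetError(
            "A must be positive for the mean to depend on shift")
    lo_shift, hi_shift = _SHIFT_BRACKET
    lo = _curriculum_mean(A, B, k, lo_shift)
    hi = _curriculum_mean(A, B, k, hi_shift)
    if not lo < target_mean < hi:
        raise InfeasibleTargetError(
            f"target mean {target_mean} not attainable: the curve family "
            f"(A={A}, B={B}, k={k}) reaches means in ({B - A}, {B}) "
            f"(numerically [{lo:.6g}, {hi:.6g}] over the solver bracket)")
    return brentq(
        lambda s: _curriculum_mean(A, B, k, s) - target_mean,
        lo_shift, hi_shift, xtol=1e-12, maxiter=200,
    )


def learning_rate(spec: LRScheduleSpec, step: int) -> float:
    """Learning rate at an optimizer step (0-based, evaluated at batch start)."""
    if not 0 <= step <= spec.total_steps:
        raise ValueError(f"step {step} outside [0, {spec.total_steps}]")
    if spec.warmup_steps > 0 and step < spec.warmup_steps:
        return spec.peak_lr * step / spec.warmup_steps
    if spec.kind == "linear":
        span = spec.total_steps - spec.warmup_steps
        if span == 0:
            return 0.0
        return spec.peak_lr * (spec.total_steps - step) / span
    if spec.kind == "wsd":
        stable_end = spec.warmup_steps + spec.stable_fraction * (
            spec.total_steps - spec.warmup_steps)
        if step <= stable_end:
            return spec.peak_lr
        return spec.peak_lr * (spec.total_steps - step) / (
            spec.total_steps - stable_end)
    # sgdr: n_restarts equal cosine half-periods over the post-warmup span
    span = spec.total_steps - spec.warmup_steps
    if span == 0:
        return 0.0
    period = span / spec.n_restarts
    phase = ((step - spec.warmup_steps) % period) / period
    if step == spec.total_steps:
        phase = 1.0
    return spec.peak_lr * 0.5 * (1.0 + math.cos(math.pi * phase))


def curve_table(spec: ScheduleSpec, lr_spec: Optional[LRScheduleSpec] = None,
                n_points: int = 1001) -> "np.ndarray":
    """Tabulate (step, t, p_unpaired, lr) for plotting/export.

    Returns a structured-friendly float array of shape (n_points, 4); the
    ``lr`` column is NaN when no LR schedule is given.
    """
    steps = np.linspace(0, spec.total_steps, n_points).round().astype(int)
    rows = np.empty((len(steps), 4))
    for i, s in enumerate(steps):
        rows[i, 0] = s
        rows[i, 1] = s / spec.total_steps
        rows[i, 2] = unpaired_probability(spec, int(s))
        if lr_spec is not None:
            lr_step = min(int(round(s / spec.total_steps * lr_spec.total_steps)),
                          lr_spec.total_steps)
            rows[i, 3] = learning_rate(lr_spec, lr_step)
        else:
            rows[i, 3] = np.nan
    return rows
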