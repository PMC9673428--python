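"""Hybrid dilated convolution (HDC) primitives.

A dilated convolution samples the input on a grid spaced ``rate`` pixels
apart: ``(F *_l k)(p) = sum_{s + l t = p} F(s) k(t)`` for a filter ``k``
supported on the square ``[-r, r]^2``.  Stacking dilated convolutions whose
rates share a common factor leaves periodic holes in the receptive field
(the "gridding" / chessboard artefact).  An HDC group avoids this by
choosing a sawtooth rate sequence r_1..r_n such that

* the maximum distance between two nonzero taps, computed by the backward
  recurrence ``M_i = max[M_{i+1} - 2 r_i, M_{i+1} - 2 (M_{i+1} - r_i), r_i]``
  with ``M_n = r_n``, satisfies ``M_2 <= K`` (kernel size), and
* ``gcd(r_1..r_n) <= 1``.

The default schedule is rates (1, 2, 3) with a 3x3 kernel; the alternative
(2, 3, 4) used in width-ablation experiments is available as a preset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.tensor import Tensor

__all__ = [
    "FilterKernel", "HDCSchedule", "ScheduleReport",
    "dilated_conv2d", "validate_schedule", "HDCGroup",
    "DEFAULT_SCHEDULE", "ABLATION_SCHEDULE", "ScheduleInvalidError",
]


class ScheduleInvalidError(ValueError):
    """Raised when an HDC group is built on a schedule that fails validation."""


@dataclass(frozen=True)
class FilterKernel:
    """A square discrete filter supported on [-radius, radius]^2."""

    radius: int
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        k = 2 * self.radius + 1
        if w.shape != (k, k):
            raise ValueError(f"radius {self.radius} requires a {k}x{k} weight "
                             f"grid, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("kernel weights must be finite")
        object.__setattr__(self, "weights", w)


def _default_paddings(kernel_size: int, rates: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(r * (kernel_size - 1) // 2 for r in rates)


@dataclass(frozen=True)
class HDCSchedule:
    """Kernel size plus an ordered dilation-rate sequence.

    Default paddings are ``rate * (K - 1) / 2`` so every unit preserves the
    spatial size.
    """

    kernel_size: int = 3
    rates: tuple[int, ...] = (1, 2, 3)
    paddings: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        rates = tuple(int(r) for r in self.rates)
        object.__setattr__(self, "rates", rates)
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if any(r < 1 for r in rates):
            raise ValueError(f"all dilation rates must be >= 1, got {rates}")
        if self.paddings is None:
            object.__setattr__(self, "paddings",
                               _default_paddings(self.kernel_size, rates))
        else:
            pads = tuple(int(p) for p in self.paddings)
            if len(pads) != len(rates):
                raise ValueError("paddings and rates must have equal length")
            object.__setattr__(self, "paddings", pads)


DEFAULT_SCHEDULE = HDCSchedule(kernel_size=3, rates=(1, 2, 3))
ABLATION_SCHEDULE = HDCSchedule(kernel_size=3, rates=(2, 3, 4))


@dataclass(frozen=True)
class ScheduleReport:
    """Validation outcome: per-stage maximum tap gaps and the gcd rule."""

    m_values: tuple[int, ...]
    gcd_of_rates: int
    valid: bool
    reasons: tuple[str, ...]

    def __str__(self):
        status = "valid" if self.valid else "INVALID"
        lines = [f"schedule {status}",
                 f"  M values (M_1..M_n): {list(self.m_values)}",
                 f"  gcd of rates: {self.gcd_of_rates}"]
        for r in self.reasons:
            lines.append(f"  reason: {r}")
        return "\n".join(lines)


def validate_schedule(schedule: HDCSchedule) -> ScheduleReport:
    """Check the gridding criterion and the coprimality rule.

    ``M_n = r_n``; going downward,
    ``M_i = max[M_{i+1} - 2 r_i, M_{i+1} - 2 (M_{i+1} - r_i), r_i]``.
    The schedule is valid iff ``M_2 <= kernel_size`` and
    ``gcd(rates) <= 1``.
    """
    rates = schedule.rates
    n = len(rates)
    if n < 2:
        raise ValueError("schedule needs >= 2 rates for the M recurrence")
    m = [0] * n
    m[n - 1] = rates[n - 1]
    for i in range(n - 2, -1, -1):
        nxt = m[i + 1]
        r = rates[i]
        m[i] = max(nxt - 2 * r, nxt - 2 * (nxt - r), r)
    g = math.gcd(*rates)
    reasons = []
    if m[1] > schedule.kernel_size:
        reasons.append(f"M_2 = {m[1]} exceeds kernel size {schedule.kernel_size}"
                       " (gridding holes)")
    if g > 1:
        reasons.append(f"gcd of rates is {g} > 1 (common-factor gridding)")
    return ScheduleReport(m_values=tuple(m), gcd_of_rates=g,
                          valid=not reasons, reasons=tuple(reasons))


def dilated_conv2d(inputs, kernel, rate: int, padding: int):
    """Apply one scalar dilated filter to every channel of `inputs`.

    Parameters
    ----------
    inputs : array of shape (H, W) or (C, H, W)
    kernel : FilterKernel or square 2-D weight array
    rate : dilation factor (1 = ordinary convolution)
    padding : zero padding on each border; ``rate * (K - 1) / 2`` preserves
        the spatial size.
    """
    if rate < 1:
        raise ValueError(f"dilation rate must be >= 1, got {rate}")
    if padding < 0:
        raise ValueError(f"padding must be >= 0, got {padding}")
    if isinstance(kernel, FilterKernel):
        w = kernel.weights
    else:
        w = np.asarray(kernel, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0:
            raise ValueError("kernel must be a square odd-sized 2-D array")
    x = np.asarray(inputs, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.ndim != 3:
        raise ValueError(f"inputs must be (H, W) or (C, H, W), got {x.shape}")
    _conv_out_shape(x.shape[1:], w.shape[0], rate, padding)  # shape guard
    # the scalar operator acts channel-wise: run channels as the batch axis
    o = nn.conv2d(Tensor(x[:, None]), Tensor(w[None, None]),
                  padding=padding, dilation=rate)
    out = o.data[:, 0]
    return out[0] if squeeze else out


def _conv_out_shape(hw, k, rate, padding):
    eff = rate * (k - 1) + 1
    oh = hw[0] + 2 * padding - eff + 1
    ow = hw[1] + 2 * padding - eff + 1
    if oh <= 0 or ow <= 0:
        raise ValueError(f"dilated kernel (size {k}, rate {rate}) larger than "
                         f"padded input {hw[0] + 2 * padding}x{hw[1] + 2 * padding}")
    return oh, ow


class HDCGroup(nn.Module):
    """n sequential units of [dilated conv -> batch norm -> ReLU].

    The first unit maps in_channels -> out_channels; later units keep
    out_channels.  Spatial size is preserved by the schedule's paddings.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 schedule: HDCSchedule = DEFAULT_SCHEDULE, *,
                 rng: np.random.Generator, override_invalid: bool = False,
                 dtype=np.float32):
        report = validate_schedule(schedule)
        if not report.valid and not override_invalid:
            raise ScheduleInvalidError(str(report))
        self.schedule = schedule
        self.convs: list[nn.Conv2d] = []
        self.norms: list[nn.BatchNorm2d] = []
        cin = in_channels
        for rate, pad in zip(schedule.rates, schedule.paddings):
            self.convs.append(nn.Conv2d(cin, out_channels, schedule.kernel_size,
                                        padding=pad, dilation=rate, rng=rng,
                                        dtype=dtype))
            self.norms.append(nn.BatchNorm2d(out_channels, dtype=dtype))
            cin = out_channels

    def forward(self, x: Tensor) -> Tensor:
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x)).relu()
        return x
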