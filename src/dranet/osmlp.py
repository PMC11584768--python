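"""Ordered shift MLP block.

The block ranks feature channels by pooled importance, gathers them into
that order, splits them into contiguous groups and displaces each group a
few pixels along one spatial axis (zero-filled), so that subsequent
per-position MLPs mix information from neighbouring locations — an axial,
AS-MLP-style receptive field without convolutionally fixed geometry.  The
full block runs the sequence twice, height first then width, re-ranking
channels in between.

All operations accept channels-last feature maps shaped ``(H, W, C)`` or
``(N, H, W, C)``; the batch axis is added and removed transparently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, InvalidInputError
from .nn import F, Tensor

__all__ = [
    "ChannelOrder",
    "ShiftSpec",
    "ScoreMLP",
    "ChannelMLP",
    "PositionalTokenMLP",
    "OrderedShiftMLP",
    "compute_channel_order",
    "reorder_channels",
    "axial_group_shift",
    "positional_token_mlp",
    "osmlp_forward",
]

_AXES = {"height": 1, "width": 2}


@dataclass
class ChannelOrder:
    """A permutation of channel indices and the scores that produced it.

    ``order`` is ``(C,)`` or per-sample ``(N, C)``; channels are sorted by
    descending score with ties broken by ascending original index.
    """

    order: np.ndarray
    scores: np.ndarray


@dataclass
class ShiftSpec:
    """Grouped axial shift: ``group_count`` contiguous channel groups, group
    ``i`` displaced by ``offsets[i]`` pixels along ``axis`` (zero fill).

    The default offset window is symmetric around zero, ``i - group_count//2``.
    """

    group_count: int = 5
    offsets: tuple[int, ...] | None = None
    axis: str = "height"

    def __post_init__(self):
        if self.group_count < 1:
            raise ConfigurationError("group_count must be positive")
        if self.axis not in _AXES:
            raise ConfigurationError(f"axis must be 'height' or 'width', got {self.axis!r}")
        if self.offsets is None:
            self.offsets = tuple(i - self.group_count // 2 for i in range(self.group_count))
        elif len(self.offsets) != self.group_count:
            raise ConfigurationError("offsets length must equal group_count")


def _ensure_batched(x) -> tuple[Tensor, bool]:
    t = nn.as_tensor(x)
    if t.ndim == 3:
        return F.reshape(t, (1,) + t.shape), False
    if t.ndim == 4:
        return t, True
    raise InvalidInputError(f"expected (H, W, C) or (N, H, W, C), got shape {t.shape}")


def _debatch(t: Tensor, had_batch: bool) -> Tensor:
    return t if had_batch else F.reshape(t, t.shape[1:])


class ScoreMLP(nn.Module):
    """Two-layer bottleneck scoring map, shared across the average- and
    max-pooled channel vectors (reduction 4 by default)."""

    def __init__(self, channels: int, rng: np.random.Generator, hidden: int | None = None):
        hidden = hidden or max(8, channels // 4)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def forward(self, v):
        return self.fc2(F.relu(self.fc1(v)))


class ChannelMLP(nn.Module):
    """Per-position two-layer MLP over channels."""

    def __init__(self, channels: int, rng: np.random.Generator, hidden: int | None = None):
        hidden = hidden or channels
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def forward(self, x):
        return self.fc2(F.gelu(self.fc1(x)))


class PositionalTokenMLP(nn.Module):
    """Channel MLP followed by a depthwise separable 3x3 convolution and GELU;
    the depthwise stage encodes relative position into the tokens."""

    def __init__(self, channels: int, rng: np.random.Generator, hidden: int | None = None):
        self.mlp = ChannelMLP(channels, rng, hidden)
        self.dw = nn.DepthwiseConv2d(channels, 3, rng, bias=True)
        self.pw = nn.Conv2d(channels, channels, 1, rng, bias=True)

    def forward(self, x):
        return F.gelu(self.pw(self.dw(self.mlp(x))))


def compute_channel_order(x, score_mlp) -> ChannelOrder:
    """Rank channels by ``score_mlp(avg_pool(x)) + score_mlp(max_pool(x))``.

    Returns the descending-score permutation; ties keep ascending original
    index (numpy's stable argsort on the negated scores).  The ordering is a
    discrete decision and carries no gradient.
    """
    xb, had_batch = _ensure_batched(x)
    if not np.all(np.isfinite(xb.data)):
        raise InvalidInputError("feature map contains non-finite values")
    avg = F.mean(xb, axis=(1, 2))
    mx = F.maximum_reduce(xb, axis=(1, 2))
    scores = (score_mlp(avg) + score_mlp(mx)).data
    order = np.argsort(-scores, axis=-1, kind="stable")
    if not had_batch:
        order, scores = order[0], scores[0]
    return ChannelOrder(order=order, scores=scores)


def reorder_channels(x, order) -> Tensor:
    """Gather channels so output channel ``j`` is input channel ``order[j]``."""
    xb, had_batch = _ensure_batched(x)
    idx = np.asarray(order.order if isinstance(order, ChannelOrder) else order, dtype=np.intp)
    c = xb.shape[-1]
    check = idx if idx.ndim == 1 else idx[0]
    if sorted(check.tolist()) != list(range(c)):
        raise InvalidInputError("order is not a permutation of the channel indices")
    if idx.ndim == 2 and not all(sorted(row.tolist()) == list(range(c)) for row in idx):
        raise InvalidInputError("order is not a permutation of the channel indices")
    return _debatch(F.take_channels(xb, idx), had_batch)


def inverse_order(order: np.ndarray) -> np.ndarray:
    idx = np.asarray(order, dtype=np.intp)
    inv = np.empty_like(idx)
    if idx.ndim == 1:
        inv[idx] = np.arange(idx.shape[0])
    else:
        rows = np.arange(idx.shape[0])[:, None]
        inv[rows, idx] = np.arange(idx.shape[1])
    return inv


def axial_group_shift(x, spec: ShiftSpec) -> Tensor:
    """Displace contiguous channel groups along one spatial axis, zero-filled.

    ``out[h, w, c] = in[h - offset(group(c)), w, c]`` along the height axis
    (analogously for width) where the source index is in range, else 0.
    """
    xb, had_batch = _ensure_batched(x)
    c = xb.shape[-1]
    g = spec.group_count
    if c % g:
        raise ConfigurationError(f"channel count {c} not divisible by group count {g}")
    pad = max((abs(o) for o in spec.offsets), default=0)
    axis = _AXES[spec.axis]
    if pad == 0:
        return _debatch(xb, had_batch)
    padded = F.pad2d(xb, (pad, pad) if axis == 1 else (0, 0),
                     (pad, pad) if axis == 2 else (0, 0))
    extent = xb.shape[axis]
    width = c // g
    pieces = []
    for i, off in enumerate(spec.offsets):
        grp = F.slice_axis(padded, 3, i * width, (i + 1) * width)
        start = pad - off
        pieces.append(F.slice_axis(grp, axis, start, start + extent))
    return _debatch(F.concat(pieces, axis=-1), had_batch)


def positional_token_mlp(x, weights: PositionalTokenMLP) -> Tensor:
    xb, had_batch = _ensure_batched(x)
    if not np.all(np.isfinite(xb.data)):
        raise InvalidInputError("feature map contains non-finite values")
    return _debatch(weights(xb), had_batch)


class OrderedShiftMLP(nn.Module):
    """The full ordered shift MLP block.

    Pipeline: rank channels (first score MLP) -> gather -> grouped shift
    along height -> positional token MLP -> rank again (second score MLP,
    computed on the intermediate feature by default) -> gather -> grouped
    shift along width -> final channel MLP.  Output shape equals input
    shape.

    ``second_order_from_input=True`` recomputes the second ranking from the
    block input instead of the intermediate feature (the literal reading of
    the published recurrence, kept as a switch).
    """

    def __init__(self, channels: int, rng: np.random.Generator, groups: int = 4,
                 hidden: int | None = None, score_hidden: int | None = None,
                 offsets: tuple[int, ...] | None = None,
                 second_order_from_input: bool = False):
        hidden = hidden or max(8, (204 * channels) // 512)
        self.channels = channels
        self.score1 = ScoreMLP(channels, rng, score_hidden)
        self.score2 = ScoreMLP(channels, rng, score_hidden)
        self.token_mlp = PositionalTokenMLP(channels, rng, hidden)
        self.out_mlp = ChannelMLP(channels, rng, hidden)
        self.shift_h = ShiftSpec(groups, offsets, "height")
        self.shift_w = ShiftSpec(groups, offsets, "width")
        self.second_order_from_input = second_order_from_input

    def forward(self, x):
        xb, had_batch = _ensure_batched(x)
        s1 = compute_channel_order(xb, self.score1)
        xs = reorder_channels(xb, s1)
        th = axial_group_shift(xs, self.shift_h)
        t = positional_token_mlp(th, self.token_mlp)
        s2_src = xb if self.second_order_from_input else t
        s2 = compute_channel_order(s2_src, self.score2)
        ts = reorder_channels(t, s2)
        tw = axial_group_shift(ts, self.shift_w)
        out = self.out_mlp(tw)
        return _debatch(out, had_batch)


def osmlp_forward(x, params: OrderedShiftMLP) -> Tensor:
    """Functional entry point for the block; see :class:`OrderedShiftMLP`."""
    return params(x)
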