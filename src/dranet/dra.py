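"""Dynamic regional attention (DRA).

The block collapses a feature map to a single channel, partitions that map
into ``k`` non-overlapping regions of mutually similar pixels, replaces each
pixel by its region mean, and squashes the result through a sigmoid to form
an ``H x W`` spatial gate.  Two partitioning modes exist:

``local``
    SLIC-style superpixels: joint feature/spatial distance, centers on a
    regular grid, each pixel searched only among centers within a ``2s``
    window where ``s = sqrt(H*W/k)`` is the expected region spacing.
``global``
    Feature distance only, every center searchable — one-dimensional
    k-means on pixel values with grid-sampled initial centers.

Region assignment is a discrete computation and carries no gradient; the
learning signal flows through the projection weights and the region means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, InvalidInputError
from .nn import F, Tensor
from .nn.autodiff import _accumulate, _node

__all__ = [
    "DRAConfig",
    "RegionPartition",
    "DRAGate",
    "project_channels",
    "similarity",
    "partition_regions",
    "fuse_regions",
    "dra_forward",
]


@dataclass
class DRAConfig:
    """Region count ``k``, feature-distance normalizer ``m`` (applied to
    values standardized to unit variance), search ``mode`` and the number of
    center-update ``iterations``.  The spatial normalizer ``s`` is derived:
    ``s = sqrt(H*W/k)``."""

    k: int = 5
    m: float = 10.0
    mode: str = "local"
    iterations: int = 5

    def __post_init__(self):
        if self.k < 1:
            raise ConfigurationError("k must be a positive integer")
        if self.m <= 0:
            raise ConfigurationError("m must be positive")
        if self.mode not in ("local", "global"):
            raise ConfigurationError(f"mode must be 'local' or 'global', got {self.mode!r}")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be positive")


@dataclass
class RegionPartition:
    """Exhaustive, disjoint pixel labeling into ``k`` regions.

    ``labels`` is an ``(H, W)`` integer array with entries in ``[0, k-1]``;
    ``centers`` is ``(k, 3)`` rows of (feature value, h, w).
    """

    labels: np.ndarray
    centers: np.ndarray
    k: int


def similarity(value_i: float, h_i: float, w_i: float,
               value_j: float, h_j: float, w_j: float,
               m: float, s: float) -> float:
    """Joint similarity distance ``sqrt((d_f/m)^2 + (d_s/s)^2)`` with
    ``d_f = |value_i - value_j|`` and ``d_s`` the Euclidean pixel distance."""
    if m <= 0 or s <= 0:
        raise ConfigurationError("normalizers m and s must be positive")
    d_f = abs(value_i - value_j)
    d_s = np.hypot(h_i - h_j, w_i - w_j)
    return float(np.hypot(d_f / m, d_s / s))


def _proj_data(p) -> np.ndarray:
    arr = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError(f"projected map must be 2-D, got shape {arr.shape}")
    return arr


def _grid_sites(h: int, w: int, k: int) -> np.ndarray:
    """Regular ceil(sqrt(k))-spaced grid trimmed to k sites, row-major."""
    rows = int(np.ceil(np.sqrt(k)))
    cols = int(np.ceil(k / rows))
    sites = []
    for i in range(rows):
        for j in range(cols):
            if len(sites) == k:
                break
            sites.append(((i + 0.5) * h / rows, (j + 0.5) * w / cols))
    return np.asarray(sites[:k])


def _standardize(v: np.ndarray) -> np.ndarray:
    std = v.std()
    return (v - v.mean()) / std if std > 0 else np.zeros_like(v)


def _repair_and_finalize(labels, centers, vals, hh, ww, dist_to_center, k):
    """Give every empty region one pixel: steal the pixel farthest from its
    current center (from regions keeping at least one member)."""
    for r in range(k):
        if np.any(labels == r):
            continue
        counts = np.bincount(labels.ravel(), minlength=k)
        eligible = counts[labels] > 1
        if not np.any(eligible):
            break
        d = np.where(eligible, dist_to_center, -np.inf)
        idx = np.unravel_index(np.argmax(d), labels.shape)
        labels[idx] = r
        centers[r] = (vals[idx], hh[idx], ww[idx])
        dist_to_center[idx] = 0.0
    return labels, centers


def partition_regions(p, cfg: DRAConfig) -> RegionPartition:
    """Partition a projected map into ``cfg.k`` regions (see module docs)."""
    v_raw = _proj_data(p)
    h, w = v_raw.shape
    if cfg.k > h * w:
        raise ConfigurationError(f"k={cfg.k} exceeds pixel count {h * w}")
    vals = _standardize(v_raw)
    hh, ww = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    k = cfg.k
    s = float(np.sqrt(h * w / k))
    sites = _grid_sites(h, w, k)
    # initial center values sampled at the nearest pixel to each grid site
    ci = np.clip(np.round(sites[:, 0] - 0.5).astype(int), 0, h - 1)
    cj = np.clip(np.round(sites[:, 1] - 0.5).astype(int), 0, w - 1)
    centers = np.column_stack([vals[ci, cj], sites[:, 0], sites[:, 1]])

    labels = np.zeros((h, w), dtype=np.intp)
    best = np.full((h, w), np.inf)
    for _ in range(cfg.iterations):
        best.fill(np.inf)
        labels.fill(-1)
        if cfg.mode == "global":
            d = np.abs(vals[None] - centers[:, 0, None, None])
            labels = np.argmin(d, axis=0)
            best = np.min(d, axis=0)
        else:
            for r in range(k):
                cv, chh, cww = centers[r]
                h0, h1 = max(0, int(np.floor(chh - 2 * s))), min(h, int(np.ceil(chh + 2 * s)) + 1)
                w0, w1 = max(0, int(np.floor(cww - 2 * s))), min(w, int(np.ceil(cww + 2 * s)) + 1)
                if h0 >= h1 or w0 >= w1:
                    continue
                df = np.abs(vals[h0:h1, w0:w1] - cv) / cfg.m
                ds = np.hypot(hh[h0:h1, w0:w1] - chh, ww[h0:h1, w0:w1] - cww) / s
                dist = np.hypot(df, ds)
                win_best = best[h0:h1, w0:w1]
                better = dist < win_best
                win_best[better] = dist[better]
                labels[h0:h1, w0:w1][better] = r
            uncovered = labels < 0
            if np.any(uncovered):
                df = np.abs(vals[uncovered][None] - centers[:, 0, None]) / cfg.m
                ds = np.hypot(hh[uncovered][None] - centers[:, 1, None],
                              ww[uncovered][None] - centers[:, 2, None]) / s
                dist = np.hypot(df, ds)
                labels[uncovered] = np.argmin(dist, axis=0)
                best[uncovered] = np.min(dist, axis=0)
        # update centers to region means (value and coordinates)
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=k).astype(float)
        nonempty = counts > 0
        sums_v = np.bincount(flat, weights=vals.ravel(), minlength=k)
        sums_h = np.bincount(flat, weights=hh.ravel(), minlength=k)
        sums_w = np.bincount(flat, weights=ww.ravel(), minlength=k)
        centers[nonempty, 0] = sums_v[nonempty] / counts[nonempty]
        centers[nonempty, 1] = sums_h[nonempty] / counts[nonempty]
        centers[nonempty, 2] = sums_w[nonempty] / counts[nonempty]
        labels, centers = _repair_and_finalize(labels, centers, vals, hh, ww, best, k)
    # centers are computed on standardized values; report them in raw units
    out_centers = centers.copy()
    std = v_raw.std()
    out_centers[:, 0] = centers[:, 0] * std + v_raw.mean() if std > 0 else v_raw.mean()
    return RegionPartition(labels=labels, centers=out_centers, k=k)


def fuse_regions(p, part: RegionPartition) -> Tensor:
    """Replace each pixel by the arithmetic mean of its region's values.

    Differentiable in ``p``: the gradient of a region mean distributes
    uniformly (1/n) over the region's members.
    """
    t = nn.as_tensor(p)
    if t.ndim != 2:
        raise InvalidInputError(f"projected map must be 2-D, got shape {t.shape}")
    labels = np.asarray(part.labels, dtype=np.intp)
    if labels.shape != t.shape:
        raise InvalidInputError("partition labels do not cover the projected map")
    if labels.min() < 0 or labels.max() >= part.k:
        raise InvalidInputError(f"labels outside [0, {part.k - 1}]")
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=part.k).astype(float)
    counts[counts == 0] = 1.0
    means = np.bincount(flat, weights=t.data.ravel(), minlength=part.k) / counts
    out_data = means[labels]

    def backward(g):
        gsum = np.bincount(flat, weights=g.ravel(), minlength=part.k) / counts
        _accumulate(t, gsum[labels])

    return _node(out_data, (t,), backward)


class DRAGate(nn.Module):
    """Pointwise projection + region partition + fusion + sigmoid gate.

    The projection is a two-layer per-pixel MLP (``C -> hidden -> 1``); the
    resulting gate broadcasts over all channels of the branch it multiplies.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 cfg: DRAConfig | None = None, hidden: int | None = None):
        hidden = hidden or max(4, (14 * channels) // 512)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)
        self.cfg = cfg or DRAConfig()

    def project(self, x: Tensor) -> Tensor:
        return F.reshape(self.fc2(F.gelu(self.fc1(x))), x.shape[:-1])

    def gate(self, x: Tensor) -> Tensor:
        """Compute the (N, H, W) attention gate for a batched feature map."""
        proj = self.project(x)
        fused = []
        for n in range(proj.shape[0]):
            sample = F.reshape(F.slice_axis(proj, 0, n, n + 1), proj.shape[1:])
            part = partition_regions(sample, self.cfg)
            fused.append(F.reshape(fuse_regions(sample, part), (1,) + proj.shape[1:]))
        return F.sigmoid(F.concat(fused, axis=0))

    def forward(self, x: Tensor, branch: Tensor) -> Tensor:
        if x.shape != branch.shape:
            raise InvalidInputError(f"shape mismatch: x {x.shape} vs branch {branch.shape}")
        g = self.gate(x)
        return branch * F.reshape(g, g.shape + (1,))


def project_channels(x, weights) -> Tensor:
    """Per-pixel linear collapse of ``C`` channels into one value.

    ``weights`` may be an ``nn.Linear(C, 1)`` module or a plain
    ``(C,)`` weight vector (optionally a ``(weight, bias)`` pair).
    """
    t = nn.as_tensor(x)
    single = t.ndim == 3
    c = t.shape[-1]
    if isinstance(weights, nn.Linear):
        if weights.in_features != c or weights.out_features != 1:
            raise ConfigurationError(f"projection must map {c} channels to 1")
        out = weights(t)
    else:
        if isinstance(weights, tuple):
            wvec, bias = weights
        else:
            wvec, bias = weights, None
        wvec = np.asarray(wvec, dtype=np.float64).reshape(-1, 1)
        if wvec.shape[0] != c:
            raise ConfigurationError(f"weight length {wvec.shape[0]} != channel count {c}")
        out = F.linear(t, nn.as_tensor(wvec),
                       None if bias is None else nn.as_tensor(np.atleast_1d(bias)))
    return F.reshape(out, t.shape[:-1])


def dra_forward(x, branch, cfg: DRAConfig, weights) -> Tensor:
    """Full DRA pass: gate = sigmoid(fuse(partition(project(x)))), applied
    multiplicatively (broadcast over channels) to ``branch``."""
    xt, bt = nn.as_tensor(x), nn.as_tensor(branch)
    if xt.shape != bt.shape:
        raise InvalidInputError(f"shape mismatch: x {xt.shape} vs branch {bt.shape}")
    single = xt.ndim == 3
    if single:
        xt = F.reshape(xt, (1,) + xt.shape)
        bt = F.reshape(bt, (1,) + bt.shape)
    proj = project_channels(xt, weights)
    fused = []
    for n in range(proj.shape[0]):
        sample = F.reshape(F.slice_axis(proj, 0, n, n + 1), proj.shape[1:])
        part = partition_regions(sample, cfg)
        fused.append(F.reshape(fuse_regions(sample, part), (1,) + proj.shape[1:]))
    gate = F.sigmoid(F.concat(fused, axis=0))
    out = bt * F.reshape(gate, gate.shape + (1,))
    return F.reshape(out, out.shape[1:]) if single else out
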