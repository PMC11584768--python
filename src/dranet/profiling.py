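"""Parameter and FLOP profiling for the segmentation network.

Conventions: one multiply-accumulate = one FLOP; parameter totals are
reported in millions rounded to two decimals.  The DRA region search is
counted explicitly (generic shape-walking misses it): each iteration of the
local mode evaluates one similarity distance per (center, window pixel)
pair, ``k * (4s)^2 = 16*H*W`` distances per round; the global mode evaluates
``H*W*k`` distances per round.  One distance evaluation is charged as one
MAC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dra import DRAGate
from .model import DRANet, Decoder, Encoder, ModelConfig
from .osmlp import OrderedShiftMLP

__all__ = ["ProfileReport", "count_parameters", "count_flops", "profile_model"]


@dataclass
class ProfileReport:
    parameters_millions: float
    gflops: float
    breakdown: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "parameters_millions": self.parameters_millions,
            "gflops": self.gflops,
            "breakdown": self.breakdown,
        }, indent=2)

    def pretty(self) -> str:
        lines = [f"{'module':<16}{'params (M)':>12}{'GFLOPs':>10}"]
        for name, row in self.breakdown.items():
            lines.append(f"{name:<16}{row['parameters_millions']:>12.4f}{row['gflops']:>10.4f}")
        lines.append(f"{'total':<16}{self.parameters_millions:>12.2f}{self.gflops:>10.2f}")
        return "\n".join(lines)


def _component_params(model: DRANet) -> dict[str, int]:
    parts: dict[str, int] = {"encoder": model.encoder.n_parameters(),
                             "decoder": model.decoder.n_parameters()}
    if model.osmlp_blocks:
        parts["osmlp"] = sum(b.n_parameters() for b in model.osmlp_blocks.values())
    if model.dra_blocks:
        parts["dra"] = sum(b.n_parameters() for b in model.dra_blocks.values())
    return parts


def count_parameters(model: DRANet) -> ProfileReport:
    """Count all trainable scalars, with a per-module breakdown whose
    entries sum exactly to the total."""
    parts = _component_params(model)
    total = sum(parts.values())
    breakdown = {name: {"parameters_millions": n / 1e6, "gflops": 0.0}
                 for name, n in parts.items()}
    return ProfileReport(parameters_millions=round(total / 1e6, 2),
                         gflops=0.0, breakdown=breakdown)


def _encoder_macs(enc: Encoder, cfg: ModelConfig, h: int, w: int):
    widths = cfg.stage_widths
    macs = 0
    h2, w2 = h // 2, w // 2
    macs += 49 * 3 * widths[0] * h2 * w2                     # stem 7x7 s2
    hs, ws = h2 // 2, w2 // 2
    for b in enc.stage2:
        macs += b.macs(hs, ws)
    sizes = [(hs, ws)]
    for stage in (enc.stage3, enc.stage4, enc.stage5):
        macs += stage[0].macs(hs, ws)
        hs, ws = hs // 2, ws // 2
        for b in stage[1:]:
            macs += b.macs(hs, ws)
        sizes.append((hs, ws))
    return macs, sizes


def _osmlp_macs(block: OrderedShiftMLP, h: int, w: int) -> int:
    c = block.channels
    hid_score = block.score1.fc1.out_features
    hid = block.token_mlp.mlp.fc1.out_features
    macs = 2 * 2 * (c * hid_score + hid_score * c)           # two score MLPs, two pools
    macs += h * w * (c * hid + hid * c)                      # Eq-4 channel MLP
    macs += h * w * (9 * c + c * c)                          # depthwise + pointwise conv
    macs += h * w * (c * hid + hid * c)                      # final channel MLP
    return macs


def _dra_macs(block: DRAGate, h: int, w: int) -> int:
    hid = block.fc1.out_features
    c = block.fc1.in_features
    macs = h * w * (c * hid + hid)                           # projection to one channel
    cfg = block.cfg
    if cfg.mode == "global":
        search = h * w * cfg.k
    else:
        search = 16 * h * w                                  # k centers x (4s)^2 window
    macs += search * cfg.iterations
    macs += h * w                                            # region-mean fusion + gate
    return macs


def _decoder_macs(dec: Decoder, cfg: ModelConfig, h: int, w: int) -> int:
    macs = 0
    # each decoder stage works at the resolution of the skip it consumes
    stage_hw = [(h // 16, w // 16), (h // 8, w // 8), (h // 4, w // 4), (h // 2, w // 2)]
    for stage, (sh, sw) in zip(dec.stages, stage_hw):
        macs += stage.macs(sh, sw)
    macs += cfg.decoder_widths[3] * cfg.classes * h * w      # 1x1 head at full res
    return macs


def count_flops(model: DRANet, input_size: tuple[int, int] | None = None) -> ProfileReport:
    """Analytic MAC count at a fixed input size (1 MAC = 1 FLOP)."""
    cfg = model.cfg
    h, w = input_size or cfg.input_size
    enc_macs, _ = _encoder_macs(model.encoder, cfg, h, w)
    parts = {"encoder": enc_macs}
    # spatial size of each encoder stage output
    stage_sizes = {0: (h // 2, w // 2), 1: (h // 4, w // 4), 2: (h // 8, w // 8),
                   3: (h // 16, w // 16), 4: (h // 32, w // 32)}
    if model.osmlp_blocks:
        parts["osmlp"] = sum(_osmlp_macs(b, *stage_sizes[s])
                             for s, b in model.osmlp_blocks.items())
    if model.dra_blocks:
        parts["dra"] = sum(_dra_macs(b, *stage_sizes[s])
                           for s, b in model.dra_blocks.items())
    parts["decoder"] = _decoder_macs(model.decoder, cfg, h, w)
    total = sum(parts.values())
    params = _component_params(model)
    breakdown = {name: {"parameters_millions": params.get(name, 0) / 1e6,
                        "gflops": macs / 1e9} for name, macs in parts.items()}
    return ProfileReport(parameters_millions=round(sum(params.values()) / 1e6, 2),
                         gflops=round(total / 1e9, 2), breakdown=breakdown)


def profile_model(model: DRANet, input_size: tuple[int, int] | None = None) -> ProfileReport:
    """Joint parameter + FLOP report."""
    return count_flops(model, input_size)
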