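"""Deconvnet inversion of the trained segmentation network.

The forward pass of the U-Net is inverted block by block to recover the
baseline-OCT input features that drive each segmentation: every
convolution block is paired with a reverse block that applies the ReLU
first and then the transposed convolutions of the forward block in
reverse order, sharing the forward kernels (biases are not re-applied);
every 2x2 max pooling is inverted by placing values back at the recorded
argmax locations ("switches") and zeroing the rest. No parameters are
trained or modified.

Skip connections are inverted by splitting the reconstruction of a
decoder block's input back into its upsampled half and its encoder half;
the encoder half is routed into the encoder-side reverse path and summed
where the paths merge.

The reverse pass starts from the last decoder block's output features
(pre-softmax), so the reconstruction shows what feeds the segmentation
logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import relu, unpool2x2
from .segnet import UNetModel, positive_probability, normalize_bscan

__all__ = [
    "SwitchStore",
    "ReconstructionStack",
    "forward_with_switches",
    "unpool",
    "invert_block",
    "reconstruct_stack",
    "saliency_image",
]


@dataclass
class SwitchStore:
    """Argmax locations from every pooling layer, in forward order.

    Each entry is an int8 array over the pooled grid holding the flat
    (row-major) index 0..3 of the window position that carried the max.
    """

    switches: list

    def __len__(self):
        return len(self.switches)

    def __getitem__(self, i):
        return self.switches[i]


@dataclass
class ReconstructionStack:
    """Per-block reconstructions in reverse-forward order.

    ``blocks`` lists (name, array) pairs starting from the block applied
    last in the forward pass; the final entry is the input-space
    reconstruction with the B-scan's shape.
    """

    blocks: list

    def __len__(self):
        return len(self.blocks)

    @property
    def input_space(self) -> np.ndarray:
        """Input-space reconstruction (height x width)."""
        return self.blocks[-1][1][0, 0]


def forward_with_switches(model: UNetModel, bscan: np.ndarray):
    """Forward pass that also records per-block activations and pooling
    switches. The probability output is identical to plain prediction.

    Returns ``(prob_map, activations, SwitchStore)`` where ``activations``
    is a list of (name, array) in forward block order.
    """
    b = normalize_bscan(bscan)
    if b.shape != tuple(model.cfg.in_shape):
        raise ValueError(
            f"B-scan shape {b.shape} != configured {tuple(model.cfg.in_shape)}")
    x = b[None, None].astype(model.dtype)
    logits, acts, switches = model.forward(x, capture=True)
    prob = positive_probability(logits)[0].astype(np.float64)
    named = [(f"{kind}{'' if idx is None else idx}", arr)
             for kind, idx, arr in acts]
    return prob, named, SwitchStore(switches=switches)


def unpool(pooled: np.ndarray, switches: np.ndarray, out_shape=None) -> np.ndarray:
    """Inverse of 2x2 max pooling: each pooled value returns to its stored
    argmax location; all other positions are zero."""
    return unpool2x2(pooled, switches, out_shape=out_shape)


class _GateTape:
    """Records (or replays) the ReLU gate masks of a reverse pass, so the
    pass can be re-run as a frozen linear map for superposition checks."""

    def __init__(self, masks=None):
        self.record = masks is None
        self.masks = [] if masks is None else list(masks)
        self._i = 0

    def apply(self, x):
        if self.record:
            m = x > 0
            self.masks.append(m)
        else:
            m = self.masks[self._i]
            self._i += 1
        return np.where(m, x, 0)


def invert_block(signal: np.ndarray, block, gates: _GateTape | None = None) -> np.ndarray:
    """Reverse one convolution block: rectify, then apply the transposed
    convolution of each forward convolution in reverse order (shared
    weights, no biases)."""
    tape = gates if gates is not None else _GateTape()
    s = tape.apply(signal)
    for conv in reversed(block.convs):
        s = conv.transposed_apply(s)
        if conv is not block.convs[0]:
            s = tape.apply(s)
    return s


def reconstruct_stack(model: UNetModel, bscan: np.ndarray,
                      start: np.ndarray | None = None,
                      gates: list | None = None,
                      return_gates: bool = False) -> ReconstructionStack:
    """Invert the trained network from the segmentation features down to
    input space.

    Runs the forward pass (recording switches), then alternately applies
    block inversions and unpooling from the last decoder block back to the
    input. No parameter updates occur. ``start`` optionally replaces the
    starting feature tensor (defaults to the last decoder block's output);
    ``gates`` replays previously recorded ReLU gate masks, making the pass
    a frozen linear map for superposition analysis.
    """
    d = model.cfg.depth
    prob, acts, switches = forward_with_switches(model, bscan)
    act = dict(acts)
    signal = np.array(act["dec0"] if start is None else start,
                      dtype=model.dtype, copy=True)
    tape = _GateTape(masks=gates)
    blocks = []
    skip_parts = [None] * d
    # decoder chain: dec0 is the last forward block, so it is inverted first
    for i in range(d):
        r = invert_block(signal, model.dec[i], gates=tape)
        c = r.shape[1] // 2
        r_up, skip_parts[i] = r[:, :c], r[:, c:]
        blocks.append((f"dec{i}", r))
        signal = model.up[i].transposed_apply(r_up)
    r = invert_block(signal, model.bottleneck, gates=tape)
    blocks.append(("bottleneck", r))
    signal = r
    # encoder chain, deepest level first
    for i in reversed(range(d)):
        signal = unpool(signal, switches[i]) + skip_parts[i]
        r = invert_block(signal, model.enc[i], gates=tape)
        blocks.append((f"enc{i}", r))
        signal = r
    stack = ReconstructionStack(blocks=blocks)
    if return_gates:
        return stack, tape.masks
    return stack


def saliency_image(stack: ReconstructionStack) -> np.ndarray:
    """Display/analysis map from the input-space reconstruction: negative
    values zeroed, then max-normalized to [0, 1] (scale-invariant)."""
    m = relu(stack.input_space.astype(np.float64))
    peak = m.max()
    if peak > 0:
        m = m / peak
    return m
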