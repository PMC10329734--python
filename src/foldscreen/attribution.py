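"""Attribution over model inputs: regional activation maps and attention scores.

The regional activation map (a Grad-CAM generalization to 2D map
outputs) scores layer positions by channel-weighted rectified
activations, with channel weights the spatially averaged gradients of a
selected output region:

    alpha_k = (1/Z) sum_positions d(sum of region r) / dA_k
    map     = sum_k ReLU(alpha_k) * ReLU(A_k)

By default the region is the full output map; bottom encoder layers give
near-nucleotide resolution.  Attention scores average the captured
softmax weight matrices across a layer's heads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .data import WindowSample
from .model import ContactPredictor


@dataclass
class AttributionMap:
    """One attribution result projected onto layer positions."""

    layer: str
    values: np.ndarray                 # 1D per-position (GRAM) or (L, L) (attention)
    channel_weights: Optional[np.ndarray] = None
    stride: int = 1                    # bp per position, for genomic projection

    def to_bedgraph(self, path, chrom: str, start: int = 0):
        with open(path, "w") as fh:
            for i, v in enumerate(np.atleast_1d(self.values)):
                fh.write(f"{chrom}\t{start + i * self.stride}"
                         f"\t{start + (i + 1) * self.stride}\t{v:.6g}\n")

    def save(self, path, name: Optional[str] = None):
        """Write the map (e.g. an attention matrix) to an HDF5 dataset."""
        import h5py
        with h5py.File(path, "a") as f:
            key = name or self.layer
            if key in f:
                del f[key]
            ds = f.create_dataset(key, data=self.values)
            ds.attrs["layer"] = self.layer
            ds.attrs["stride"] = self.stride


def _region_slices(region: Optional[Tuple[int, int, int, int]], n: int):
    if region is None:
        return slice(0, n), slice(0, n)
    r0, r1, c0, c1 = region
    return slice(r0, r1), slice(c0, c1)


def gram(model: ContactPredictor, sample: WindowSample, layer: str,
         region: Optional[Tuple[int, int, int, int]] = None,
         dtype=None) -> AttributionMap:
    """Gradient-weighted regional activation map at a named layer.

    ``layer`` is one of the model's capture points (e.g.
    ``"seq_encoder.block0"``, ``"decoder.block2"``); ``region`` is a
    rectangle (row0, row1, col0, col1) in the output map, defaulting to
    the full output space.  The map is per-position (1D layers are
    summed over channels after weighting; 2D layers are returned as a
    map flattened to the first spatial axis by summing the second).
    """
    model.eval()
    x = sample.model_inputs()[None]
    if dtype is not None:
        # float64 runs the whole pass in double precision (weights promote),
        # used when validating gradients numerically
        x = x.astype(dtype)
    from .autograd import Tensor
    out = model(Tensor(x), capture=True)
    if layer not in model.captures:
        raise KeyError(f"layer {layer!r} exposes no activations; available: "
                       f"{sorted(model.captures)}")
    act = model.captures[layer]
    rs, cs = _region_slices(region, out.shape[-1])
    total = out[:, rs, cs].sum()
    total.backward()
    if act.grad is None:
        raise RuntimeError(f"no differentiable path through layer {layer!r}")
    A = act.data[0]
    G = act.grad[0]
    # Z = number of spatial positions (the double spatial sum collapses to
    # one axis for 1D encoder layers)
    spatial_axes = tuple(range(1, A.ndim))
    Z = int(np.prod([A.shape[ax] for ax in spatial_axes]))
    alpha = G.sum(axis=spatial_axes) / Z
    weighted = np.tensordot(np.maximum(alpha, 0.0), np.maximum(A, 0.0), axes=(0, 0))
    values = weighted if weighted.ndim == 1 else weighted.sum(axis=-1)
    stride = sample.spec.window_length // A.shape[-1] if A.ndim == 2 else \
        sample.spec.bin_size
    return AttributionMap(layer, values.astype(np.float64), alpha, stride)


def attention_scores(model: ContactPredictor, sample: WindowSample
                     ) -> List[AttributionMap]:
    """Per-layer head-averaged attention weight matrices for one sample.

    Runs an evaluation forward pass with weight capture; each returned
    map is the elementwise mean of the layer's head weight matrices and
    remains row-stochastic.
    """
    model.eval()
    model(sample.model_inputs()[None])
    out = []
    for i, w in enumerate(model.attention_weights()):
        out.append(AttributionMap(f"transformer.layer{i}", w.mean(axis=0
                                                                  ).astype(np.float64),
                                  stride=sample.spec.bin_size))
    return out


def attention_received(maps: List[AttributionMap]) -> np.ndarray:
    """Column-marginal attention (summed weight received per bin), averaged
    over layers; highlights bins other positions attend to."""
    cols = [m.values.sum(axis=0) for m in maps]
    return np.mean(cols, axis=0)
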