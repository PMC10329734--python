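"""Inference: window prediction, chromosome stitching, in silico editing,
and custom (translocated) chromosome assembly.

Deletions remove a span from every input channel, shift the downstream
content left and pad the window end (all-N sequence columns, zero
features) so the model input shape never changes.  Chromosome-scale maps
are stitched from sliding-window predictions by overlap averaging; cells
never covered carry an explicit missing mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import autograd as ag
from .containers import ContactMatrix
from .data import ChromData, SignalVector, WindowSample, WindowSpec, extract_window
from .genome import reverse_complement_str
from .model import ContactPredictor


@dataclass
class PerturbationSpec:
    """Non-overlapping sorted deletion intervals on one chromosome."""

    chrom: str
    deletions: List[Tuple[int, int]]
    padding: str = "end"

    def validate(self, chrom_length: Optional[int] = None):
        prev = -1
        for s, e in self.deletions:
            if s < 0 or e < s or s <= prev:
                raise ValueError("deletions must be sorted, non-overlapping, in bounds")
            prev = e
        if chrom_length is not None and self.deletions and self.deletions[-1][1] > chrom_length:
            raise ValueError("deletion outside chromosome")


@dataclass
class ChromAssembly:
    """Ordered segments (chrom, start, end, strand) fused into one coordinate system."""

    segments: List[Tuple[str, int, int, str]]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("assembly needs at least one segment")
        for c, s, e, st in self.segments:
            if e <= s or st not in "+-":
                raise ValueError(f"bad segment {(c, s, e, st)}")

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e, _ in self.segments)

    def breakpoints(self) -> List[int]:
        """Fused coordinates where consecutive segments join."""
        out, pos = [], 0
        for _, s, e, _ in self.segments[:-1]:
            pos += e - s
            out.append(pos)
        return out

    def map_to_source(self, fused_pos: int) -> Tuple[str, int, str]:
        """Round-trip a fused coordinate back to (chrom, position, strand)."""
        pos = fused_pos
        for c, s, e, st in self.segments:
            if pos < e - s:
                return (c, s + pos, st) if st == "+" else (c, e - 1 - pos, st)
            pos -= e - s
        raise ValueError("fused position outside assembly")


def predict_window(model: ContactPredictor, sample: WindowSample,
                   symmetrize: bool = True) -> ContactMatrix:
    """Deterministic evaluation-mode prediction for one window.

    The architecture does not constrain the output to be symmetric; by
    default the map is symmetrized by averaging with its transpose.
    """
    if sample.spec.window_length != model.config.window_length:
        raise ValueError("sample does not match model window length")
    model.eval()
    with ag.no_grad():
        out = model(sample.model_inputs()[None]).data[0].astype(np.float64)
    if symmetrize:
        out = 0.5 * (out + out.T)
    return ContactMatrix(out, sample.spec.bin_size, sample.spec.chrom,
                         sample.spec.start, "ln1p")


def apply_deletion(sample: WindowSample, interval: Tuple[int, int]) -> WindowSample:
    """Delete ``[start, end)`` (window coordinates) from all input channels.

    Downstream content shifts left and the window end is padded with
    (end - start) bp of empty input: all-N sequence columns and zero
    features.  The window length is unchanged; the target is dropped
    (it no longer corresponds to the edited input).
    """
    s, e = interval
    W = sample.spec.window_length
    if not (0 <= s <= e <= W):
        raise ValueError("deletion interval outside window")
    if s == e:
        return WindowSample(sample.spec, sample.sequence.copy(),
                            [SignalVector(f.values.copy(), f.transform)
                             for f in sample.features], sample.target)
    n_pad = e - s
    seq = np.concatenate([sample.sequence[:, :s], sample.sequence[:, e:],
                          np.zeros((5, n_pad), dtype=np.float32)], axis=1)
    seq[4, W - n_pad:] = 1.0  # N channel
    feats = []
    for f in sample.features:
        v = np.concatenate([f.values[:s], f.values[e:],
                            np.zeros(n_pad, dtype=np.float32)])
        feats.append(SignalVector(v, f.transform))
    return WindowSample(sample.spec, seq, feats, None)


def apply_deletions(sample: WindowSample, intervals: List[Tuple[int, int]]) -> WindowSample:
    """Apply multiple disjoint deletions in one pass (right to left)."""
    for s, e in sorted(intervals, reverse=True):
        sample = apply_deletion(sample, (s, e))
    return sample


def apply_perturbation(sample: WindowSample, spec: PerturbationSpec) -> WindowSample:
    """Apply a validated perturbation (window-relative deletions)."""
    spec.validate(sample.spec.window_length)
    return apply_deletions(sample, spec.deletions)


def stitch_chromosome(model: ContactPredictor, chrom: ChromData,
                      step: Optional[int] = None,
                      predict_fn=None) -> ContactMatrix:
    """Chromosome-wide map from overlap-averaged sliding-window predictions.

    Every covered cell is the mean over all windows covering it
    (count-division applied uniformly, including chromosome edges);
    never-covered cells are flagged in the missing mask.  ``predict_fn``
    may replace the model call (used by tests with mock predictors).
    """
    W = model.config.window_length
    bs = model.config.bin_size
    step = step or W // 8
    if chrom.length < W:
        raise ValueError("chromosome shorter than one window")
    n = chrom.length // bs
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=np.int64)
    start = 0
    while start + W <= chrom.length:
        spec = WindowSpec(chrom.name, start, W, bs)
        sample = extract_window(chrom, spec, with_target=False)
        if predict_fn is not None:
            pred = np.asarray(predict_fn(sample), dtype=np.float64)
        else:
            pred = predict_window(model, sample).values
        b0 = start // bs
        nb = W // bs
        acc[b0:b0 + nb, b0:b0 + nb] += pred
        cnt[b0:b0 + nb, b0:b0 + nb] += 1
        start += step
    mask = cnt == 0
    with np.errstate(invalid="ignore"):
        values = np.where(mask, np.nan, acc / np.maximum(cnt, 1))
    return ContactMatrix(values, bs, chrom.name, 0, "ln1p", mask=mask)


def assemble_custom_chromosome(assembly: ChromAssembly,
                               chrom_data: Dict[str, ChromData],
                               name: str = "custom") -> ChromData:
    """Fuse genome segments into one chromosome-like input.

    Minus-strand segments contribute the reverse-complemented sequence and
    reversed feature tracks.  The result is addressable as a single
    coordinate system; :meth:`ChromAssembly.map_to_source` maps back.
    """
    seqs, track_parts = [], {}
    track_names = None
    for c, s, e, strand in assembly.segments:
        if c not in chrom_data:
            raise ValueError(f"unknown chromosome {c!r}")
        src = chrom_data[c]
        if e > src.length:
            raise ValueError(f"segment {(c, s, e)} out of bounds")
        seg_seq = src.sequence[s:e]
        if track_names is None:
            track_names = list(src.track_order)
        if strand == "-":
            seg_seq = reverse_complement_str(seg_seq)
        seqs.append(seg_seq)
        for t in track_names:
            v = src.tracks[t][s:e]
            track_parts.setdefault(t, []).append(v[::-1] if strand == "-" else v)
    tracks = {t: np.concatenate(parts) for t, parts in track_parts.items()}
    return ChromData(name, "".join(seqs), tracks, None, track_names)


def heterozygous_average(pred_fused: ContactMatrix,
                         pred_normal_left: ContactMatrix,
                         pred_normal_right: ContactMatrix,
                         breakpoint_bin: int) -> ContactMatrix:
    """Average a fused-allele map with the normal-allele maps.

    The normal alleles occupy their own sides of the breakpoint on the
    fused coordinate system; their cross-breakpoint (interchromosomal)
    cells are missing, so there the output equals the fused prediction
    alone.  Within each side the output is the elementwise mean of the
    fused and the normal-allele prediction.
    """
    n = pred_fused.n_bins
    b = breakpoint_bin
    if pred_normal_left.n_bins != n or pred_normal_right.n_bins != n:
        raise ValueError("all maps must live on the fused coordinate system")
    normal = np.full((n, n), np.nan)
    normal[:b, :b] = pred_normal_left.values[:b, :b]
    normal[b:, b:] = pred_normal_right.values[b:, b:]
    out = np.where(np.isnan(normal), pred_fused.values,
                   0.5 * (pred_fused.values + normal))
    return ContactMatrix(out, pred_fused.bin_size, pred_fused.chrom,
                         pred_fused.start, pred_fused.transform)
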