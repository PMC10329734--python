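"""Hi-C evaluation computations.

Insulation follows the ratio form
``(max(mean Left, mean Right) + pc) / (mean Center + pc)`` where Left and
Right are the flank x flank intra-domain squares on the diagonal on
either side of bin i, Center is the flank x flank square of contacts
crossing bin i, and the pseudocount guards unmappable regions (by
default the chromosome-wide mean intensity within a 2-Mb diagonal band).
Under this form TAD boundaries are local maxima of the score.

Also provided: distance-stratified means and Pearson correlation,
per-diagonal normalization of a prediction onto a target, observed over
expected, differential/conserved region selection between two cell
types, virtual 4C profiles from valid pairs, and matrix-to-pairs
conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .containers import ContactMatrix


@dataclass
class InsulationConfig:
    flank: int = 10                      # bins per square side
    pseudocount: "float | str" = "auto"  # "auto": chromosome mean within 2 Mb
    band_bp: int = 2_000_000             # diagonal band for the auto pseudocount

    def resolve_pseudocount(self, M: ContactMatrix) -> float:
        if self.pseudocount != "auto":
            return float(self.pseudocount)
        n = M.n_bins
        band = max(1, min(n - 1, self.band_bp // M.bin_size))
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        vals = M.values[d <= band]
        return float(np.nanmean(vals))


def insulation_profile(M: ContactMatrix, cfg: Optional[InsulationConfig] = None
                       ) -> np.ndarray:
    """Per-bin insulation score; edge bins without full flanks are NaN."""
    cfg = cfg or InsulationConfig()
    f = cfg.flank
    if f < 1:
        raise ValueError("flank must be >= 1")
    pc = cfg.resolve_pseudocount(M)
    V = M.values
    n = M.n_bins
    out = np.full(n, np.nan)
    zero_center = False
    for i in range(f, n - f):
        left = V[i - f:i, i - f:i].mean()
        right = V[i + 1:i + f + 1, i + 1:i + f + 1].mean()
        center = V[i - f:i, i + 1:i + f + 1].mean()
        denom = center + pc
        if denom == 0:
            zero_center = True
            continue
        out[i] = (max(left, right) + pc) / denom
    if zero_center:
        warnings.warn("zero center intensity with zero pseudocount; scores left missing")
    return out


@dataclass
class StratifiedStats:
    """Per-distance mean intensities and Pearson correlation."""

    distance: np.ndarray
    mean_pred: np.ndarray
    mean_target: np.ndarray
    correlation: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.distance, "mean_pred": self.mean_pred,
                             "mean_target": self.mean_target,
                             "correlation": self.correlation})

    def mean_correlation(self) -> float:
        return float(np.nanmean(self.correlation))


def _diagonal(M: np.ndarray, d: int) -> np.ndarray:
    return np.diagonal(M, offset=d)


def stratified_stats(P: ContactMatrix, T: ContactMatrix,
                     max_distance: Optional[int] = None,
                     min_pairs: int = 3) -> StratifiedStats:
    """Distance-stratified means and Pearson r between prediction and target.

    Missing cells are excluded pairwise; distances with fewer than
    ``min_pairs`` finite pairs report a missing correlation.
    """
    if P.values.shape != T.values.shape:
        raise ValueError("matrices must share shape")
    n = P.n_bins
    dmax = max_distance if max_distance is not None else n - 1
    dists, mp, mt, corr = [], [], [], []
    for d in range(dmax + 1):
        p, t = _diagonal(P.values, d), _diagonal(T.values, d)
        finite = np.isfinite(p) & np.isfinite(t)
        p, t = p[finite], t[finite]
        dists.append(d)
        mp.append(p.mean() if len(p) else np.nan)
        mt.append(t.mean() if len(t) else np.nan)
        if len(p) >= min_pairs and p.std() > 0 and t.std() > 0:
            corr.append(float(np.corrcoef(p, t)[0, 1]))
        else:
            corr.append(np.nan)
    return StratifiedStats(np.array(dists), np.array(mp), np.array(mt), np.array(corr))


def normalize_to_target(M: ContactMatrix, T: ContactMatrix) -> ContactMatrix:
    """Match every diagonal of ``M`` to the target's per-diagonal moments.

    Each entry becomes ``(sigma_T/sigma_M) (m - mu_M) + mu_T`` computed on
    its own diagonal; a zero-spread diagonal in ``M`` collapses to the
    target's mean with a warning.
    """
    if M.values.shape != T.values.shape:
        raise ValueError("matrices must share shape")
    n = M.n_bins
    out = np.empty_like(M.values)
    degenerate = False
    for d in range(-(n - 1), n):
        m = np.diagonal(M.values, d)
        t = np.diagonal(T.values, d)
        mu_m, sd_m = m.mean(), m.std()
        mu_t, sd_t = t.mean(), t.std()
        idx = np.arange(len(m))
        rows = idx if d >= 0 else idx - d
        cols = idx + d if d >= 0 else idx
        if sd_m == 0:
            degenerate = True
            out[rows, cols] = mu_t
        else:
            out[rows, cols] = (sd_t / sd_m) * (m - mu_m) + mu_t
    if degenerate:
        warnings.warn("zero-s.d. diagonal in source matrix; set to target mean")
    return ContactMatrix(out, M.bin_size, M.chrom, M.start, M.transform)


def observed_over_expected(M: ContactMatrix, relog: bool = False) -> ContactMatrix:
    """Observed/expected in count space from a log-space matrix.

    Counts are recovered by the inverse transform, each cell is divided by
    the mean of its distance stratum (zero-count strata become missing,
    not infinite), and the result is optionally re-logged.
    """
    if M.transform != "ln1p":
        raise ValueError("observed/expected expects a log-space matrix")
    counts = np.expm1(M.values)
    n = M.n_bins
    out = np.full_like(counts, np.nan)
    for d in range(n):
        diag = np.diagonal(counts, d)
        mu = np.nanmean(diag)
        idx = np.arange(len(diag))
        if np.isfinite(mu) and mu > 0:
            out[idx, idx + d] = diag / mu
            out[idx + d, idx] = np.diagonal(counts, -d) / mu
    if relog:
        out = np.log1p(out)
    return ContactMatrix(out, M.bin_size, M.chrom, M.start,
                         "ln1p" if relog else "raw")


def select_regions(insul_a: np.ndarray, insul_b: np.ndarray,
                   intensity_a: np.ndarray, intensity_b: np.ndarray,
                   mode: Literal["differential", "conserved"] = "differential",
                   intensity_quantile: float = 0.10,
                   difference_quantile: float = 0.20,
                   differential_is_top: bool = True) -> np.ndarray:
    """Select structurally differential or conserved windows between two cell types.

    Rows are aligned windows; insulation arrays are (n_windows, n_bins).
    Windows pass the intensity gate when their mean intensity (averaged
    over the two cell types) exceeds the ``intensity_quantile`` of all
    windows; they are then ranked by mean absolute insulation difference,
    with "differential" the top ``difference_quantile`` fraction (or the
    bottom when ``differential_is_top`` is False) and "conserved" the
    complement.  Returns the boolean selection per window.
    """
    intensity = 0.5 * (np.asarray(intensity_a) + np.asarray(intensity_b))
    gate = intensity > np.quantile(intensity, intensity_quantile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        diff = np.nanmean(np.abs(np.asarray(insul_a) - np.asarray(insul_b)), axis=1)
    if not gate.any():
        return np.zeros_like(gate)
    cut = np.quantile(diff[gate], 1 - difference_quantile
                      if differential_is_top else difference_quantile)
    if differential_is_top:
        differential = gate & (diff > cut)
    else:
        differential = gate & (diff < cut)
    if mode == "differential":
        return differential
    return gate & ~differential


def virtual_4c(pairs: pd.DataFrame, chrom: str, viewpoint: int,
               span: int = 2_500_000, bin_size: int = 100,
               window: int = 5_000) -> pd.DataFrame:
    """Viewpoint contact profile from a valid-pairs list.

    For each ``bin_size`` bin within +-``span`` of the viewpoint, counts
    pairs with one end inside the viewpoint's ``window`` (centered) and
    the other end inside the bin's centered ``window``, normalized by the
    total valid pairs of the sample.  ``pairs`` needs columns
    chrom, pos1, pos2 and optionally count.
    """
    if "count" not in pairs.columns:
        pairs = pairs.assign(count=1)
    total = float(pairs["count"].sum())
    sub = pairs[pairs["chrom"] == chrom]
    centers = np.arange(viewpoint - span, viewpoint + span + 1, bin_size)
    profile = np.zeros(len(centers))
    half = window // 2
    p1 = sub["pos1"].to_numpy()
    p2 = sub["pos2"].to_numpy()
    cnt = sub["count"].to_numpy(dtype=float)
    at_vp1 = np.abs(p1 - viewpoint) <= half
    at_vp2 = np.abs(p2 - viewpoint) <= half
    for which, other in ((at_vp1, p2), (at_vp2, p1)):
        pos, c = other[which], cnt[which]
        for p, k in zip(pos, c):
            lo = np.searchsorted(centers, p - half, side="left")
            hi = np.searchsorted(centers, p + half, side="right")
            profile[lo:hi] += k
    if total == 0:
        warnings.warn("empty pairs list; returning zero profile")
        norm = profile
    else:
        norm = profile / total
    return pd.DataFrame({"chrom": chrom, "position": centers, "signal": norm})


def matrix_to_pairs(M: ContactMatrix) -> pd.DataFrame:
    """Convert a log-space matrix to (bin_i, bin_j, count) valid-pairs triples.

    Counts are the inverse transform rounded to non-negative integers;
    only upper-triangle (i <= j) cells with positive counts are emitted.
    """
    if M.transform != "ln1p":
        raise ValueError("matrix_to_pairs expects a log-space matrix")
    counts = np.rint(np.expm1(M.values)).astype(np.int64)
    counts = np.clip(counts, 0, None)
    iu, ju = np.triu_indices(M.n_bins)
    c = counts[iu, ju]
    keep = c > 0
    return pd.DataFrame({"bin_i": iu[keep], "bin_j": ju[keep], "count": c[keep]})


def insulation_correlation(P: ContactMatrix, T: ContactMatrix,
                           cfg: Optional[InsulationConfig] = None) -> float:
    """Pearson correlation of the two matrices' insulation profiles."""
    a = insulation_profile(P, cfg)
    b = insulation_profile(T, cfg)
    finite = np.isfinite(a) & np.isfinite(b)
    if finite.sum() < 3:
        return float("nan")
    return float(np.corrcoef(a[finite], b[finite])[0, 1])
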