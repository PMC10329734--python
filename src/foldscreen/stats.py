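"""Downstream statistics: trans-factor enrichment, odds-ratio clustering,
intra-TAD activity testing, and CRISPR proliferation-screen gene scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .containers import ContactMatrix, GenomicIntervalSet


@dataclass
class TFProfile:
    """One transcription factor's binding intervals."""

    name: str
    intervals: GenomicIntervalSet
    n_experiments: int = 1

    @property
    def n_hits(self) -> int:
        return len(self.intervals)


@dataclass
class EnrichmentRow:
    factor: str
    odds_ratio: float
    p: float
    q: float
    table: tuple                  # (a, b, c, d)
    corrected: bool = False       # continuity correction applied to the OR

    def __post_init__(self):
        if self.odds_ratio < 0:
            raise ValueError("odds ratio must be non-negative")


def _downsample(profile: GenomicIntervalSet, n: int,
                rng: np.random.Generator) -> GenomicIntervalSet:
    idx = np.sort(rng.choice(len(profile), size=n, replace=False))
    return GenomicIntervalSet(profile.df.iloc[idx])


def tf_enrichment(elements: GenomicIntervalSet, profiles: List[TFProfile],
                  universe: GenomicIntervalSet,
                  min_hits: int = 7_000, min_experiments: int = 2,
                  downsample_above: int = 20_000, seed: int = 0
                  ) -> pd.DataFrame:
    """Fisher-exact overlap enrichment of screened elements per TF profile.

    Profiles with fewer than ``min_hits`` intervals or a single experiment
    are dropped; oversized profiles are uniformly downsampled to
    ``downsample_above`` with a fixed seed.  For each surviving profile a
    2x2 table (element vs non-element loci x overlapping vs not) feeds a
    two-sided Fisher exact test; q-values are Benjamini-Hochberg over the
    tested profiles.  Zero cells get a +0.5 continuity-corrected odds
    ratio (flagged); the test itself uses the uncorrected table.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    rng = np.random.default_rng(seed)
    is_element = universe.overlaps(elements)
    rows = []
    for prof in profiles:
        if prof.n_hits < min_hits or prof.n_experiments < min_experiments:
            continue
        iv = prof.intervals
        if prof.n_hits > downsample_above:
            iv = _downsample(iv, downsample_above, rng)
        hit = universe.overlaps(iv)
        a = int(np.sum(is_element & hit))
        b = int(np.sum(is_element & ~hit))
        c = int(np.sum(~is_element & hit))
        d = int(np.sum(~is_element & ~hit))
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        corrected = 0 in (a, b, c, d)
        if corrected:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append(EnrichmentRow(prof.name, float(odds), float(p), float(p),
                                  (a, b, c, d), corrected))
    if not rows:
        return pd.DataFrame(columns=["factor", "odds_ratio", "p", "q",
                                     "a", "b", "c", "d", "corrected"])
    qs = multipletests([r.p for r in rows], method="fdr_bh")[1]
    for r, q in zip(rows, qs):
        r.q = float(q)
    df = pd.DataFrame([{"factor": r.factor, "odds_ratio": r.odds_ratio,
                        "p": r.p, "q": r.q, "a": r.table[0], "b": r.table[1],
                        "c": r.table[2], "d": r.table[3],
                        "corrected": r.corrected} for r in rows])
    return df.sort_values("odds_ratio", ascending=False).reset_index(drop=True)


def cluster_factors(odds: pd.DataFrame, k: int = 6, seed: int = 0,
                    normalize: str = "minmax") -> pd.Series:
    """k-means over factors' per-cell-type odds ratios (six centroids).

    Odds ratios are normalized within each cell type (column) before
    clustering; rows are factors.  Returns the cluster label per factor;
    the fitted inertia is attached as ``result.attrs['inertia']``.
    """
    X = odds.to_numpy(dtype=float)
    if normalize == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        X = (X - lo) / span
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    out = pd.Series(labels, index=odds.index, name="cluster")
    out.attrs["inertia"] = float(km.inertia_)
    return out


def distance_normalize(M: ContactMatrix) -> ContactMatrix:
    """Divide each cell by the total of its distance stratum.

    Expects non-negative count-space input; every diagonal of the output
    sums to one when the stratum total is positive, and zero diagonals
    stay zero (no NaNs).
    """
    V = np.asarray(M.values, dtype=float)
    if not np.isfinite(V).all() or (V < 0).any():
        raise ValueError("expected finite, non-negative count-space matrix")
    n = M.n_bins
    out = np.zeros_like(V)
    for d in range(n):
        diag = np.diagonal(V, d)
        s = diag.sum()
        idx = np.arange(len(diag))
        if s > 0:
            out[idx, idx + d] = diag / s
            if d:
                out[idx + d, idx] = np.diagonal(V, -d) / np.diagonal(V, -d).sum()
    return ContactMatrix(out, M.bin_size, M.chrom, M.start, "raw")


@dataclass
class TADRecord:
    """One reference TAD with its intra-TAD activity statistics."""

    chrom: str
    start: int
    end: int
    mean_s1: float = np.nan
    mean_s2: float = np.nan
    change: float = np.nan
    log2fc: float = np.nan
    p: float = np.nan
    fdr: float = np.nan
    label: str = "Stable"
    flagged: bool = False


def _tad_cells(M: ContactMatrix, start: int, end: int):
    b0 = start // M.bin_size
    b1 = -(-end // M.bin_size)
    iu, ju = np.triu_indices(b1 - b0)
    return M.values[b0 + iu, b0 + ju]


def intra_tad_changes(S1: ContactMatrix, S2: ContactMatrix,
                      tads: GenomicIntervalSet,
                      fdr_threshold: float = 0.01,
                      log2fc_threshold: float = 0.25,
                      change_threshold: float = 0.1) -> List[TADRecord]:
    """Classify intra-TAD activity changes between two samples.

    Inputs are distance-normalized, aligned matrices.  Per TAD: a paired
    two-sided t-test over the within-TAD cells, the change in mean
    intensity, and the log2 fold change of mean intensities; BH-FDR over
    all TADs; Loss/Gain when FDR < 0.01, |log2fc| > 0.25 and |change| >
    0.1 (strict inequalities), signed by the change, otherwise Stable.
    """
    if S1.values.shape != S2.values.shape:
        raise ValueError("matrices must be aligned")
    records, pvals = [], []
    for row in tads.df.itertuples():
        c1 = _tad_cells(S1, int(row.start), int(row.end))
        c2 = _tad_cells(S2, int(row.start), int(row.end))
        rec = TADRecord(row.chrom, int(row.start), int(row.end))
        rec.mean_s1, rec.mean_s2 = float(c1.mean()), float(c2.mean())
        rec.change = rec.mean_s2 - rec.mean_s1
        with np.errstate(divide="ignore", invalid="ignore"):
            rec.log2fc = float(np.log2(rec.mean_s2 / rec.mean_s1)) \
                if rec.mean_s1 > 0 and rec.mean_s2 > 0 else np.nan
        diff = c2 - c1
        if len(diff) >= 2 and diff.std(ddof=1) > 0:
            _, rec.p = sps.ttest_rel(c2, c1)
        else:
            rec.flagged = True          # zero-variance differences: p missing
        records.append(rec)
        pvals.append(rec.p)
    pv = np.asarray(pvals, dtype=float)
    ok = np.isfinite(pv)
    fdr = np.full(len(pv), np.nan)
    if ok.any():
        fdr[ok] = multipletests(pv[ok], method="fdr_bh")[1]
    for rec, q in zip(records, fdr):
        rec.fdr = float(q) if np.isfinite(q) else np.nan
        if (np.isfinite(rec.fdr) and rec.fdr < fdr_threshold
                and np.isfinite(rec.log2fc) and abs(rec.log2fc) > log2fc_threshold
                and abs(rec.change) > change_threshold):
            rec.label = "Gain" if rec.change > 0 else "Loss"
        else:
            rec.label = "Stable"
    return records


def crispr_gene_scores(counts: pd.DataFrame) -> pd.DataFrame:
    """Gene-level proliferation scores from a pooled CRISPR screen.

    ``counts`` needs columns guide, gene, day4, day20.  Per-guide counts
    are normalized to reads-per-100k of their sample; guide fold change
    is normalized Day 4 / Day 20 (a zero Day-20 count adds a pseudocount
    of 1 to both days for that guide, flagged); the gene fold change is
    the mean over its guides, reported with its log2, and p is a
    two-sided one-sample t-test of the guide fold changes against 1.
    """
    df = counts.copy()
    for col in ("day4", "day20"):
        total = df[col].sum()
        if total <= 0:
            raise ValueError(f"total {col} counts must be positive")
    flagged = df["day20"] == 0
    df.loc[flagged, ["day4", "day20"]] += 1
    df["norm4"] = df["day4"] / df["day4"].sum() * 100_000
    df["norm20"] = df["day20"] / df["day20"].sum() * 100_000
    df["fc"] = df["norm4"] / df["norm20"]
    rows = []
    for gene, sub in df.groupby("gene"):
        fc = sub["fc"].to_numpy()
        mean_fc = float(fc.mean())
        if len(fc) >= 2 and fc.std(ddof=1) > 0:
            _, p = sps.ttest_1samp(fc, 1.0)
        else:
            p = np.nan
        rows.append({"gene": gene, "n_guides": len(fc), "mean_fc": mean_fc,
                     "log2fc": float(np.log2(mean_fc)) if mean_fc > 0 else np.nan,
                     "p": float(p) if np.isfinite(p) else np.nan,
                     "flagged": bool(sub.index.isin(df.index[flagged]).any())})
    return pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)
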