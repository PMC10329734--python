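"""Core in-memory containers shared across the package.

Coordinates are 0-based, half-open throughout. Contact matrices carry
their genomic anchoring (chromosome, origin, bin size) and a transform
flag so that the reversible ``ln(1+x)`` count transform is applied
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import h5py
import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass
class ContactMatrix:
    """Square, genomically anchored chromatin interaction matrix.

    ``transform`` is ``"raw"`` for (ICE-normalized) counts or ``"ln1p"``
    for natural-log transformed counts ``ln(1 + x)``.  ``mask`` marks
    cells with no data (e.g. never covered during stitching).
    """

    values: np.ndarray
    bin_size: int
    chrom: str = "chr"
    start: int = 0
    transform: str = "ln1p"
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.transform not in ("raw", "ln1p"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.values.copy(), self.bin_size, self.chrom, self.start,
                             self.transform,
                             None if self.mask is None else self.mask.copy())

    def symmetrized(self) -> "ContactMatrix":
        out = self.copy()
        out.values = 0.5 * (out.values + out.values.T)
        return out

    def to_counts(self) -> "ContactMatrix":
        """Invert the log transform back to count space (``expm1``)."""
        out = self.copy()
        if self.transform == "ln1p":
            out.values = np.expm1(out.values)
            out.transform = "raw"
        return out

    def to_log(self) -> "ContactMatrix":
        """Apply ``ln(1+x)``; raises if the transform was already applied."""
        if self.transform == "ln1p":
            raise ValueError("matrix is already log-transformed; refusing double log")
        out = self.copy()
        out.values = np.log1p(out.values)
        out.transform = "ln1p"
        return out

    def save(self, path, name: str = "matrix"):
        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            ds = f.create_dataset(name, data=self.values.astype(np.float32),
                                  compression="gzip", compression_opts=4)
            ds.attrs["bin_size"] = self.bin_size
            ds.attrs["chrom"] = self.chrom
            ds.attrs["start"] = self.start
            ds.attrs["transform"] = self.transform
            if self.mask is not None:
                f.create_dataset(name + "_mask", data=self.mask)

    @classmethod
    def load(cls, path, name: str = "matrix") -> "ContactMatrix":
        with h5py.File(path, "r") as f:
            ds = f[name]
            mask = f[name + "_mask"][...] if name + "_mask" in f else None
            return cls(ds[...].astype(np.float64), int(ds.attrs["bin_size"]),
                       str(ds.attrs["chrom"]), int(ds.attrs["start"]),
                       str(ds.attrs["transform"]), mask)


@dataclass
class SignalTrack:
    """Per-base coverage for one feature over one chromosome (raw units)."""

    chrom: str
    values: np.ndarray
    name: str = "signal"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)

    def __len__(self) -> int:
        return len(self.values)

    def to_bedgraph(self, path, mode: str = "w"):
        """Write run-length-compressed bedGraph (zero runs skipped)."""
        v = self.values
        change = np.nonzero(np.diff(v) != 0)[0]
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(v)]))
        with open(path, mode) as fh:
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{self.chrom}\t{s}\t{e}\t{v[s]:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path, chrom: str, length: int, name: str = "signal") -> "SignalTrack":
        values = np.zeros(length, dtype=np.float32)
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        for row in df[df["chrom"] == chrom].itertuples():
            values[int(row.start):int(row.end)] = row.value
        return cls(chrom, values, name)


class GenomicIntervalSet:
    """Strand-aware labelled 0-based half-open intervals on a genome."""

    COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

    def __init__(self, df: Optional[pd.DataFrame] = None):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        df = df.copy()
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        self.df = df[self.COLUMNS].reset_index(drop=True)
        if len(self.df) and (self.df["end"] <= self.df["start"]).any():
            raise ValueError("intervals must satisfy start < end")

    @classmethod
    def from_records(cls, records) -> "GenomicIntervalSet":
        return cls(pd.DataFrame(records, columns=["chrom", "start", "end", "name",
                                                  "score", "strand"][:len(records[0])])
                   if records else None)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[tuple]:
        return iter(self.df.itertuples(index=False))

    def sorted(self) -> "GenomicIntervalSet":
        return GenomicIntervalSet(self.df.sort_values(["chrom", "start", "end"]))

    def _trees(self) -> dict:
        trees: dict = {}
        for row in self.df.itertuples():
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.Index)
        return trees

    def overlaps(self, other: "GenomicIntervalSet") -> np.ndarray:
        """Boolean per interval of ``self``: does it intersect any of ``other``."""
        trees = other._trees()
        out = np.zeros(len(self.df), dtype=bool)
        for i, row in enumerate(self.df.itertuples()):
            t = trees.get(row.chrom)
            out[i] = bool(t is not None and t.overlap(row.start, row.end))
        return out

    def expanded(self, min_width: int) -> "GenomicIntervalSet":
        """Center-expand every interval narrower than ``min_width``."""
        df = self.df.copy()
        width = df["end"] - df["start"]
        narrow = width < min_width
        mid = (df["start"] + df["end"]) // 2
        df.loc[narrow, "start"] = np.maximum(0, mid[narrow] - min_width // 2)
        df.loc[narrow, "end"] = df.loc[narrow, "start"] + min_width
        return GenomicIntervalSet(df)

    def to_bed(self, path):
        self.df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "GenomicIntervalSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df.columns = cls.COLUMNS[:df.shape[1]]
        return cls(df)


@dataclass
class GroundTruthManifest:
    """Planted structure of a synthetic genome.

    ``boundary_positions`` maps chromosome name to sorted bp coordinates of
    planted boundary elements; ``tad_intervals`` tile each chromosome
    between consecutive boundaries (plus the chromosome ends).
    """

    boundary_positions: dict
    boundary_strands: dict
    tad_intervals: GenomicIntervalSet
    enhancer_positions: dict = field(default_factory=dict)
    planted_tf_names: list = field(default_factory=lambda: ["causal_factor"])

    def __post_init__(self):
        for chrom, pos in self.boundary_positions.items():
            arr = np.asarray(pos)
            if len(arr) < 2:
                raise ValueError(f"{chrom}: need at least two boundary elements")
            if not (np.all(np.diff(arr) > 0)):
                raise ValueError(f"{chrom}: boundary positions must be sorted and unique")
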