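"""Reading genomic formats and assembling model-ready window samples.

Windows are fixed-length genomic spans (default 2,097,152 bp binned at
8,192 bp into 256 bins).  Sequence is five-channel one-hot over 'ATCGN';
coverage tracks are per-base with missing data as zero and an ``ln(1+x)``
transform; Hi-C targets are resampled to the window bin grid by
area-weighted interpolation and log-transformed exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ContactMatrix, GenomicIntervalSet, SignalTrack

SEQ_CHANNELS = "ATCGN"
_CHANNEL_INDEX = {c: i for i, c in enumerate(SEQ_CHANNELS)}

DEFAULT_WINDOW = 2_097_152
DEFAULT_BIN = 8_192
DEFAULT_STEP = 40_960


@dataclass(frozen=True)
class WindowSpec:
    """One fixed genomic window with its bin grid."""

    chrom: str
    start: int
    window_length: int = DEFAULT_WINDOW
    bin_size: int = DEFAULT_BIN

    def __post_init__(self):
        if self.window_length % self.bin_size:
            raise ValueError("window_length must be a multiple of bin_size")
        n = self.window_length // self.bin_size
        if n & (n - 1):
            raise ValueError("n_bins must be a power of two")

    @property
    def n_bins(self) -> int:
        return self.window_length // self.bin_size

    @property
    def end(self) -> int:
        return self.start + self.window_length


@dataclass
class SignalVector:
    """Per-base feature values for one window (transform tracked)."""

    values: np.ndarray
    transform: str = "ln1p"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)


@dataclass
class WindowSample:
    """One training/inference example."""

    spec: WindowSpec
    sequence: np.ndarray                      # (5, window_length) one-hot
    features: List[SignalVector]              # default [CTCF, ATAC]
    target: Optional[ContactMatrix] = None

    def validate(self):
        W = self.spec.window_length
        if self.sequence.shape != (5, W):
            raise ValueError("sequence shape mismatch")
        for f in self.features:
            if len(f.values) != W:
                raise ValueError("feature length mismatch")
        if self.target is not None and self.target.n_bins != self.spec.n_bins:
            raise ValueError("target side must equal n_bins")

    def model_inputs(self) -> np.ndarray:
        """Stacked (5 + n_features, window_length) input array."""
        feats = np.stack([f.values for f in self.features])
        return np.concatenate([self.sequence, feats], axis=0)


@dataclass
class DatasetSplit:
    """Chromosome-level train/validation/test partition."""

    train_chroms: List[str]
    val_chroms: List[str]
    test_chroms: List[str]

    def validate(self, all_chroms: Sequence[str]):
        groups = [set(self.train_chroms), set(self.val_chroms), set(self.test_chroms)]
        union = set().union(*groups)
        if sum(len(g) for g in groups) != len(union):
            raise ValueError("split groups must be disjoint")
        if union != set(all_chroms):
            raise ValueError("split must cover all chromosomes")


# -- sequence encoding -------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    """One-hot encode a nucleotide string to a (5, L) matrix (A,T,C,G,N)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for c, i in _CHANNEL_INDEX.items():
        lut[ord(c)] = i
    idx = lut[arr]
    bad = np.nonzero(idx == 255)[0]
    if len(bad):
        raise ValueError(f"unknown nucleotide {seq[bad[0]]!r} at position {int(bad[0])}")
    out = np.zeros((5, len(seq)), dtype=np.float32)
    out[idx, np.arange(len(seq))] = 1.0
    return out


def reverse_complement(onehot: np.ndarray) -> np.ndarray:
    """Reverse-complement a one-hot matrix: A<->T, C<->G, N fixed, order reversed."""
    if onehot.shape[0] != 5:
        raise ValueError("expected 5 channels (ATCGN)")
    return onehot[[1, 0, 3, 2, 4], ::-1].copy()


# -- coverage tracks ---------------------------------------------------------

def load_track(path: str, chrom: str, start: int, end: int,
               chrom_length: Optional[int] = None,
               transform: str = "ln1p") -> SignalVector:
    """Load per-base coverage from bigWig or bedGraph; missing data is zero.

    Applies ``ln(x+1)`` unless ``transform="raw"``.
    """
    if start < 0 or end <= start:
        raise ValueError("invalid interval")
    path = str(path)
    if path.endswith((".bw", ".bigwig", ".bigWig")):
        import pyBigWig
        bw = pyBigWig.open(path)
        try:
            if chrom not in bw.chroms():
                raise KeyError(f"chromosome {chrom!r} absent from {path}")
            if end > bw.chroms()[chrom]:
                raise ValueError("interval out of chromosome bounds")
            values = np.nan_to_num(
                np.asarray(bw.values(chrom, start, end), dtype=np.float64))
        finally:
            bw.close()
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        sub = df[df["chrom"] == chrom]
        if sub.empty and chrom not in set(df["chrom"]):
            raise KeyError(f"chromosome {chrom!r} absent from {path}")
        if chrom_length is not None and end > chrom_length:
            raise ValueError("interval out of chromosome bounds")
        values = np.zeros(end - start, dtype=np.float64)
        for row in sub.itertuples():
            lo, hi = max(int(row.start), start), min(int(row.end), end)
            if lo < hi:
                values[lo - start:hi - start] = row.value
    if transform == "ln1p":
        values = np.log1p(values)
    return SignalVector(values, transform)


# -- Hi-C targets ------------------------------------------------------------

def _overlap_weights(n_target: int, target_bin: float, n_source: int,
                     source_bin: float) -> np.ndarray:
    """(n_target, n_source) area-overlap weights, rows normalized by target width."""
    t_edges = np.arange(n_target + 1) * target_bin
    s_edges = np.arange(n_source + 1) * source_bin
    lo = np.maximum(t_edges[:-1, None], s_edges[None, :-1])
    hi = np.minimum(t_edges[1:, None], s_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None) / target_bin


def prepare_hic_target(matrix: ContactMatrix, spec: WindowSpec) -> ContactMatrix:
    """Extract and resample the window submatrix, log-transforming exactly once.

    The source grid is resampled to the window's bin grid with
    area-weighted linear interpolation (separable along both axes); if the
    source is in count space, ``ln(1+x)`` is applied afterwards.  A source
    already in log space is only extracted/resampled, never re-logged.
    """
    src_bin = matrix.bin_size
    extent = matrix.start + matrix.n_bins * src_bin
    if spec.start < matrix.start or spec.end > extent or spec.chrom != matrix.chrom:
        raise ValueError("window exceeds contact-matrix extent")
    offset = spec.start - matrix.start
    if src_bin == spec.bin_size:
        if offset % src_bin:
            raise ValueError("window start must align to the shared bin grid")
        i0 = offset // src_bin
        sub = matrix.values[i0:i0 + spec.n_bins, i0:i0 + spec.n_bins].copy()
    else:
        # source columns covering the window, then area-overlap resampling
        j0 = offset // src_bin
        j1 = -(-(offset + spec.window_length) // src_bin)
        block = matrix.values[j0:j1, j0:j1]
        w = _overlap_weights(spec.n_bins, spec.bin_size,
                             j1 - j0, src_bin)
        # account for the window not starting exactly at a source-bin edge
        shift = offset - j0 * src_bin
        if shift:
            t_edges = np.arange(spec.n_bins + 1) * spec.bin_size + shift
            s_edges = np.arange(j1 - j0 + 1) * src_bin
            lo = np.maximum(t_edges[:-1, None], s_edges[None, :-1])
            hi = np.minimum(t_edges[1:, None], s_edges[None, 1:])
            w = np.clip(hi - lo, 0.0, None) / spec.bin_size
        sub = w @ block @ w.T
    out = ContactMatrix(sub, spec.bin_size, spec.chrom, spec.start, matrix.transform)
    if out.transform == "raw":
        out = out.to_log()
    out.values = 0.5 * (out.values + out.values.T)
    return out


# -- window enumeration ------------------------------------------------------

def enumerate_windows(chrom_sizes: Dict[str, int],
                      exclusion: Optional[GenomicIntervalSet] = None,
                      window_length: int = DEFAULT_WINDOW,
                      bin_size: int = DEFAULT_BIN,
                      step: int = DEFAULT_STEP) -> List[WindowSpec]:
    """Sliding windows at multiples of ``step``, dropping exclusion overlaps.

    Windows extending past the chromosome end are dropped; a chromosome
    shorter than the window yields no windows.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    trees = exclusion._trees() if exclusion is not None and len(exclusion) else {}
    out = []
    for chrom, size in chrom_sizes.items():
        tree = trees.get(chrom)
        start = 0
        while start + window_length <= size:
            if tree is None or not tree.overlap(start, start + window_length):
                out.append(WindowSpec(chrom, start, window_length, bin_size))
            start += step
    return out


def enumerate_benchmark_regions(chrom_sizes: Dict[str, int],
                                window_length: int = 1_000_000,
                                step: int = 500_000,
                                midpoint_margin: int = 1_500_000) -> List[pd.Series]:
    """Genome-wide benchmark regions: 1-Mb windows on a 0.5-Mb grid.

    A window is kept when its midpoint lies at least ``midpoint_margin``
    from both chromosome ends, buffering the larger input context some
    models need around each evaluated region.  Over the hg38 primary
    chromosomes (chr1-22, chrX) this enumerates 5,935 regions.
    """
    margin = midpoint_margin - window_length // 2
    out = []
    for chrom, size in chrom_sizes.items():
        start = margin
        while start + window_length + margin <= size:
            out.append(pd.Series({"chrom": chrom, "start": start,
                                  "end": start + window_length}))
            start += step
    return out


def read_chrom_sizes(path) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     usecols=[0, 1])
    return dict(zip(df["chrom"], df["size"].astype(int)))


# hg38 primary-assembly chromosome sizes (GRCh38, UCSC); packaged so the
# genome-wide benchmark enumeration is reproducible without downloads.
HG38_CHROM_SIZES: Dict[str, int] = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559, "chr4": 190214555,
    "chr5": 181538259, "chr6": 170805979, "chr7": 159345973, "chr8": 145138636,
    "chr9": 138394717, "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189, "chr16": 90338345,
    "chr17": 83257441, "chr18": 80373285, "chr19": 58617616, "chr20": 64444167,
    "chr21": 46709983, "chr22": 50818468, "chrX": 156040895, "chrY": 57227415,
}


# -- in-memory genome access -------------------------------------------------

@dataclass
class ChromData:
    """Per-chromosome raw inputs held in memory for window extraction."""

    name: str
    sequence: str
    tracks: Dict[str, np.ndarray]          # per-base raw coverage
    matrix: Optional[ContactMatrix] = None
    track_order: List[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.track_order:
            self.track_order = list(self.tracks)

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_window(chrom: ChromData, spec: WindowSpec,
                   with_target: bool = True) -> WindowSample:
    """Assemble a model-ready sample for one window of a chromosome."""
    if spec.start < 0 or spec.end > chrom.length:
        raise ValueError("window outside chromosome")
    seq = encode_sequence(chrom.sequence[spec.start:spec.end])
    feats = [SignalVector(np.log1p(chrom.tracks[t][spec.start:spec.end]))
             for t in chrom.track_order]
    target = None
    if with_target and chrom.matrix is not None:
        target = prepare_hic_target(chrom.matrix, spec)
    sample = WindowSample(spec, seq, feats, target)
    sample.validate()
    return sample


def load_genome_dir(path) -> Dict[str, ChromData]:
    """Load a simulated-genome directory (FASTA, bedGraph tracks, HDF5 matrices).

    Expects the layout written by :func:`foldscreen.genome.write_genome`:
    ``genome.fa``, ``chrom.sizes``, ``ctcf.bedgraph``, ``atac.bedgraph``
    and ``contacts.h5`` with one dataset per chromosome.
    """
    import os

    from pyfaidx import Fasta

    from .containers import ContactMatrix, SignalTrack

    sizes = read_chrom_sizes(os.path.join(path, "chrom.sizes"))
    fasta = Fasta(os.path.join(path, "genome.fa"))
    out = {}
    h5 = os.path.join(path, "contacts.h5")
    for chrom, size in sizes.items():
        tracks = {}
        for name in ("ctcf", "atac"):
            bg = os.path.join(path, f"{name}.bedgraph")
            tracks[name] = SignalTrack.from_bedgraph(bg, chrom, size, name).values
        matrix = ContactMatrix.load(h5, chrom) if os.path.exists(h5) else None
        out[chrom] = ChromData(chrom, str(fasta[chrom][:]), tracks, matrix,
                               ["ctcf", "atac"])
    return out


def genome_to_chrom_data(genome) -> Dict[str, ChromData]:
    """Adapt a :class:`~foldscreen.genome.SyntheticGenome` for window extraction."""
    out = {}
    for chrom in genome.chrom_names:
        out[chrom] = ChromData(
            chrom, genome.sequences[chrom],
            {"ctcf": genome.ctcf[chrom].values, "atac": genome.atac[chrom].values},
            genome.matrices[chrom], ["ctcf", "atac"])
    return out
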