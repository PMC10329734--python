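"""Synthetic genomes with planted ground truth.

The generator emulates the statistical structure the contact-map
predictor assumes in real data: CTCF-motif instances planted at TAD
boundary elements (convergently alternating orientation), peak-shaped
CTCF/ATAC coverage over those elements (ATAC additionally at decoy
"enhancer" sites), and contact maps combining exponential distance
decay, TAD blocks delimited by the planted boundaries, loop foci at
boundary-element pairs, and log-normal noise.  A manifest records the
planted structure so downstream recovery can be scored exactly.

It deliberately does not emulate realistic nucleotide composition,
replication timing or A/B compartments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict

import numpy as np

from .containers import ContactMatrix, GenomicIntervalSet, GroundTruthManifest, SignalTrack

# CTCF-like 19-mer core motif planted at boundary elements
DEFAULT_MOTIF = "CCACCAGGTGGCGCTAGAT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement_str(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticGenomeConfig:
    """Study conditions for one synthetic genome.

    Defaults are sized so that three chromosomes support held-out training
    of the desk-scale predictor: 256-kb chromosomes at 1-kb-scale element
    geometry, ~30-kb TADs, exponential contact decay with a 50-kb length
    scale, two-fold within-TAD enrichment and three-fold loop foci.
    """

    n_chromosomes: int = 3
    chrom_length: int = 262_144
    n_boundary_elements: int = 8
    motif: str = DEFAULT_MOTIF
    peak_width: int = 600          # bp, full width of planted coverage peaks
    peak_height: float = 4.0       # coverage units at peak center
    background_rate: float = 0.2   # coverage units
    decay_length: float = 50_000.0  # bp, exponential contact decay scale
    tad_boost: float = 2.0
    loop_boost: float = 3.0
    noise_sd: float = 0.1          # sd of additive Gaussian noise in log space
    contact_scale: float = 20.0    # counts at distance zero before boosts
    bin_size: int = 1024
    n_enhancers: int = 6           # decoy accessible sites per chromosome
    seed: int = 0

    def validate(self, min_window: int = 0):
        if self.chrom_length % self.bin_size:
            raise ValueError("chrom_length must be divisible by bin_size")
        if self.n_boundary_elements < 2:
            raise ValueError("need at least two boundary elements per chromosome")
        if self.tad_boost < 1 or self.loop_boost < 1:
            raise ValueError("boosts must be >= 1")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if min_window and self.chrom_length < 4 * min_window:
            raise ValueError(
                f"chrom_length {self.chrom_length} < 4 x window {min_window}: "
                "cannot form held-out windows")


@dataclass
class SyntheticGenome:
    config: SyntheticGenomeConfig
    sequences: Dict[str, str]
    ctcf: Dict[str, SignalTrack]
    atac: Dict[str, SignalTrack]
    matrices: Dict[str, ContactMatrix]
    manifest: GroundTruthManifest

    @property
    def chrom_names(self):
        return list(self.sequences)

    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _boundary_positions(rng: np.random.Generator, cfg: SyntheticGenomeConfig) -> np.ndarray:
    """Jittered regular grid, kept clear of the chromosome ends."""
    n = cfg.n_boundary_elements
    spacing = cfg.chrom_length / (n + 1)
    jitter = rng.uniform(-0.2, 0.2, size=n) * spacing
    pos = (np.arange(1, n + 1) * spacing + jitter).astype(np.int64)
    pos = np.clip(pos, cfg.peak_width, cfg.chrom_length - cfg.peak_width)
    return np.sort(pos)


def _peak_track(length: int, centers, width: int, height: float,
                background: float) -> np.ndarray:
    values = np.full(length, background, dtype=np.float32)
    sd = width / 4.0
    x = np.arange(length)
    for c in centers:
        lo, hi = max(0, int(c - 3 * sd)), min(length, int(c + 3 * sd) + 1)
        values[lo:hi] += height * np.exp(-0.5 * ((x[lo:hi] - c) / sd) ** 2)
    return values


def _contact_map(cfg: SyntheticGenomeConfig, boundaries: np.ndarray,
                 rng: np.random.Generator, chrom: str) -> ContactMatrix:
    n = cfg.chrom_length // cfg.bin_size
    idx = np.arange(n)
    dist_bp = np.abs(idx[:, None] - idx[None, :]) * float(cfg.bin_size)
    contacts = cfg.contact_scale * np.exp(-dist_bp / cfg.decay_length)

    boundary_bins = boundaries // cfg.bin_size
    tad_id = np.searchsorted(boundaries, idx * cfg.bin_size, side="right")
    same_tad = tad_id[:, None] == tad_id[None, :]
    contacts *= np.where(same_tad, cfg.tad_boost, 1.0)

    is_boundary = np.zeros(n, dtype=bool)
    is_boundary[boundary_bins] = True
    loop = is_boundary[:, None] & is_boundary[None, :] & (idx[:, None] != idx[None, :])
    contacts *= np.where(loop, cfg.loop_boost, 1.0)

    if cfg.noise_sd > 0:
        eps = rng.normal(0.0, cfg.noise_sd, size=(n, n))
        eps = np.triu(eps) + np.triu(eps, 1).T  # symmetric log-normal noise
        contacts = contacts * np.exp(eps)

    contacts = 0.5 * (contacts + contacts.T)
    return ContactMatrix(np.log1p(contacts), cfg.bin_size, chrom, 0, "ln1p")


def generate_genome(config: SyntheticGenomeConfig,
                    min_window: int = 0) -> SyntheticGenome:
    """Generate sequences, tracks, contact maps and the ground-truth manifest.

    Deterministic given ``config.seed``.  Motifs are planted exactly at the
    boundary positions with convergently alternating strand; the returned
    manifest records positions, strands, TAD tiling and enhancer decoys.
    """
    config.validate(min_window)
    rng = np.random.default_rng(config.seed)
    motif = config.motif.upper()
    seqs, ctcf, atac, mats = {}, {}, {}, {}
    boundary_positions, boundary_strands, enhancer_positions = {}, {}, {}
    tad_records = []

    for ci in range(config.n_chromosomes):
        chrom = f"chrS{ci + 1}"
        L = config.chrom_length
        boundaries = _boundary_positions(rng, config)
        strands = np.where(np.arange(len(boundaries)) % 2 == 0, "+", "-")

        seq = rng.choice(list("ACGT"), size=L)
        for b, s in zip(boundaries, strands):
            planted = motif if s == "+" else reverse_complement_str(motif)
            start = int(b) - len(motif) // 2
            seq[start:start + len(motif)] = list(planted)
        seqs[chrom] = "".join(seq)

        # enhancer decoys: accessible but CTCF-free, kept away from boundaries
        enh = []
        while len(enh) < config.n_enhancers:
            p = int(rng.integers(config.peak_width, L - config.peak_width))
            if np.abs(boundaries - p).min() > 4 * config.peak_width:
                enh.append(p)
        enh = np.sort(np.asarray(enh))

        ctcf[chrom] = SignalTrack(chrom, _peak_track(
            L, boundaries, config.peak_width, config.peak_height,
            config.background_rate), "ctcf")
        atac[chrom] = SignalTrack(chrom, _peak_track(
            L, np.concatenate([boundaries, enh]), config.peak_width,
            config.peak_height, config.background_rate), "atac")
        mats[chrom] = _contact_map(config, boundaries, rng, chrom)

        boundary_positions[chrom] = boundaries
        boundary_strands[chrom] = strands
        enhancer_positions[chrom] = enh
        edges = np.concatenate(([0], boundaries, [L]))
        for k in range(len(edges) - 1):
            tad_records.append((chrom, int(edges[k]), int(edges[k + 1]),
                                f"{chrom}_tad{k}", 0.0, "."))

    manifest = GroundTruthManifest(boundary_positions, boundary_strands,
                                   GenomicIntervalSet.from_records(tad_records),
                                   enhancer_positions)
    return SyntheticGenome(config, seqs, ctcf, atac, mats, manifest)


def generate_tf_profiles(manifest: GroundTruthManifest, n_decoy_factors: int,
                         seed: int, chrom_sizes: Dict[str, int],
                         n_intervals_per_chrom: int = 60,
                         interval_width: int = 500,
                         boundary_coverage: float = 0.95
                         ) -> Dict[str, GenomicIntervalSet]:
    """Binding profiles for one causal factor plus uniform decoys.

    The causal factor covers ``boundary_coverage`` of the planted boundary
    elements (>= the 0.9 guarantee) plus random background intervals up to
    ``n_intervals_per_chrom``; each decoy has the same interval count drawn
    uniformly.  Interval counts scale with genome size rather than the
    fixed profile sizes used on real genomes.
    """
    rng = np.random.default_rng(seed)
    half = interval_width // 2

    causal = []
    for chrom, boundaries in manifest.boundary_positions.items():
        L = chrom_sizes[chrom]
        n_cover = max(2, int(round(boundary_coverage * len(boundaries))))
        covered = rng.choice(len(boundaries), size=n_cover, replace=False)
        for b in np.asarray(boundaries)[np.sort(covered)]:
            causal.append((chrom, max(0, int(b) - half), int(b) + half,
                           "causal_factor", 0.0, "."))
        n_bg = max(0, n_intervals_per_chrom - n_cover)
        for p in rng.integers(0, L - interval_width, size=n_bg):
            causal.append((chrom, int(p), int(p) + interval_width,
                           "causal_factor", 0.0, "."))
    profiles = {"causal_factor": GenomicIntervalSet.from_records(causal).sorted()}

    for d in range(n_decoy_factors):
        name = f"decoy_{d + 1:02d}"
        recs = []
        for chrom, L in chrom_sizes.items():
            for p in rng.integers(0, L - interval_width, size=n_intervals_per_chrom):
                recs.append((chrom, int(p), int(p) + interval_width, name, 0.0, "."))
        profiles[name] = GenomicIntervalSet.from_records(recs).sorted()
    return profiles


def write_genome(genome: SyntheticGenome, outdir: str):
    """Write FASTA, bedGraph tracks, BED manifest and HDF5 matrices."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for chrom, size in genome.chrom_sizes().items():
            fh.write(f"{chrom}\t{size}\n")
    for tracks, fname in ((genome.ctcf, "ctcf.bedgraph"), (genome.atac, "atac.bedgraph")):
        path = os.path.join(outdir, fname)
        if os.path.exists(path):
            os.remove(path)
        for chrom in genome.chrom_names:
            tracks[chrom].to_bedgraph(path, mode="a")
    h5 = os.path.join(outdir, "contacts.h5")
    if os.path.exists(h5):
        os.remove(h5)
    for chrom, mat in genome.matrices.items():
        mat.save(h5, name=chrom)
    genome.manifest.tad_intervals.to_bed(os.path.join(outdir, "tads.bed"))
    recs = []
    for chrom, pos in genome.manifest.boundary_positions.items():
        for p, s in zip(pos, genome.manifest.boundary_strands[chrom]):
            recs.append((chrom, int(p) - 1, int(p) + 1, "boundary", 0.0, str(s)))
    GenomicIntervalSet.from_records(recs).to_bed(os.path.join(outdir, "boundaries.bed"))
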