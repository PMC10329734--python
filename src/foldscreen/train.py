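"""Training of the contact-map predictor.

Exposed statsmodels-style: :class:`ContactMapModel` is built from
per-chromosome data and a chromosome-level split; ``fit()`` runs the
optimization (MSE loss, Adam, cosine learning-rate schedule, the three
stochastic augmentations: random window shift, reverse-complement with
target flip, Gaussian input noise) and returns a
:class:`ContactMapResults` carrying the best-validation predictor, the
loss history and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import autograd as ag
from . import nn
from .data import (ChromData, DatasetSplit, WindowSample, WindowSpec,
                   enumerate_windows, extract_window, reverse_complement)
from .model import ContactPredictor, ModelConfig


@dataclass
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 0.002
    scheduler_period: int = 200        # epochs; cosine, no restarts, floor 0
    max_shift: int = 368_640           # bp, uniform window-shift augmentation
    revcomp_prob: float = 0.5
    noise_sd: float = 0.1              # Gaussian noise on input channels
    noise_on_sequence: bool = True     # include one-hot channels in the noise
    n_epochs: int = 40
    step: Optional[int] = None         # window enumeration step; None = window/8
    # plateau restarts: short runs can stall in a decay-only solution that
    # ignores the feature tracks; like k-means n_init, re-initialize with a
    # derived seed when the train loss has not improved enough by the check
    # epoch.  max_restarts=0 disables the mechanism.
    max_restarts: int = 0
    restart_check_epoch: int = 18
    restart_ratio: float = 0.6         # vs the epoch-2 train loss
    seed: int = 0

    def validate(self, window_length: int):
        if not 0 <= self.revcomp_prob <= 1:
            raise ValueError("revcomp_prob must be in [0, 1]")
        if self.max_shift >= window_length:
            raise ValueError("max_shift must be smaller than the window")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Small-batch, densely overlapping windows: more update steps per
        CPU-minute, which the boundary-structure term needs."""
        kw = dict(batch_size=2, max_shift=8_192, n_epochs=32, step=4_096,
                  max_restarts=2, restart_check_epoch=20, restart_ratio=0.65)
        kw.update(overrides)
        return cls(**kw)


def flip_sample(sample: WindowSample) -> WindowSample:
    """Reverse-complement the sequence, reverse features, flip the target."""
    seq = reverse_complement(sample.sequence)
    feats = [type(f)(f.values[::-1].copy(), f.transform) for f in sample.features]
    target = sample.target
    if target is not None:
        target = target.copy()
        target.values = target.values[::-1, ::-1].copy()
    return WindowSample(sample.spec, seq, feats, target)


def augment(sample: WindowSample, cfg: TrainConfig, rng: np.random.Generator,
            chrom: Optional[ChromData] = None) -> WindowSample:
    """Apply the three training augmentations to one sample.

    When ``chrom`` is given the window start is shifted by a uniform
    bin-aligned offset in [-max_shift, +max_shift] (resampled if it would
    leave the chromosome) and all inputs and the target re-extracted.
    Reverse-complement flips every axis; Gaussian noise (sd
    ``noise_sd``) goes on all input channels, never the target.
    """
    spec = sample.spec
    if chrom is not None and cfg.max_shift > 0:
        max_bins = cfg.max_shift // spec.bin_size
        for _ in range(100):
            off = int(rng.integers(-max_bins, max_bins + 1)) * spec.bin_size
            if 0 <= spec.start + off and spec.start + off + spec.window_length <= chrom.length:
                break
        else:
            off = 0
        spec = WindowSpec(spec.chrom, spec.start + off, spec.window_length, spec.bin_size)
        sample = extract_window(chrom, spec)
    if rng.random() < cfg.revcomp_prob:
        sample = flip_sample(sample)
    if cfg.noise_sd > 0:
        seq = sample.sequence
        if cfg.noise_on_sequence:
            seq = seq + rng.normal(0, cfg.noise_sd, seq.shape).astype(np.float32)
        feats = [type(f)(f.values + rng.normal(0, cfg.noise_sd, f.values.shape
                                               ).astype(np.float32), f.transform)
                 for f in sample.features]
        sample = WindowSample(sample.spec, seq, feats, sample.target)
    return sample


def _batch_arrays(samples: List[WindowSample]):
    x = np.stack([s.model_inputs() for s in samples])
    y = np.stack([s.target.values for s in samples]).astype(nn.DTYPE)
    return x, y


@dataclass
class ContactMapResults:
    """Fitted predictor with its training diagnostics."""

    predictor: ContactPredictor
    loss_history: pd.DataFrame
    best_epoch: int
    model_config: ModelConfig
    train_config: TrainConfig
    n_train_windows: int
    n_val_windows: int

    @property
    def best_val_loss(self) -> float:
        return float(self.loss_history["val_loss"].iloc[self.best_epoch])

    def predict(self, sample: WindowSample, symmetrize: bool = True) -> np.ndarray:
        from .engine import predict_window
        return predict_window(self.predictor, sample, symmetrize=symmetrize).values

    def summary(self) -> str:
        lines = [
            "Contact-map predictor fit",
            "=" * 48,
            f"window / bins        {self.model_config.window_length:>12,} bp / "
            f"{self.model_config.n_bins}",
            f"parameters           {self.predictor.n_parameters():>12,}",
            f"train / val windows  {self.n_train_windows:>6} / {self.n_val_windows}",
            f"epochs (best)        {len(self.loss_history):>6} ({self.best_epoch})",
            f"final train MSE      {self.loss_history['train_loss'].iloc[-1]:>12.5f}",
            f"best val MSE         {self.best_val_loss:>12.5f}",
        ]
        return "\n".join(lines)

    def save(self, path):
        self.predictor.save(path)


class ContactMapModel:
    """Contact-map prediction model over a windowed genomic dataset.

    Parameters
    ----------
    chrom_data : dict of ChromData
        Per-chromosome sequence, feature tracks and target matrices.
    split : DatasetSplit
        Chromosome-level train/validation/test partition.
    model_config, train_config : configurations; desk- and full-scale
        presets are available on the config classes.
    """

    def __init__(self, chrom_data: Dict[str, ChromData], split: DatasetSplit,
                 model_config: ModelConfig, train_config: TrainConfig):
        split.validate(list(chrom_data))
        train_config.validate(model_config.window_length)
        if not split.train_chroms or not split.val_chroms:
            raise ValueError("train and validation chromosome lists must be nonempty")
        self.chrom_data = chrom_data
        self.split = split
        self.model_config = model_config
        self.train_config = train_config
        step = train_config.step or model_config.window_length // 8
        sizes = {c: chrom_data[c].length for c in chrom_data}
        self.windows = enumerate_windows(sizes, None, model_config.window_length,
                                         model_config.bin_size, step)
        self.train_windows = [w for w in self.windows if w.chrom in split.train_chroms]
        self.val_windows = [w for w in self.windows if w.chrom in split.val_chroms]
        if not self.train_windows:
            raise ValueError("no training windows fit the chromosomes")

    @classmethod
    def from_genome(cls, genome, split: DatasetSplit, model_config: ModelConfig,
                    train_config: TrainConfig) -> "ContactMapModel":
        from .data import genome_to_chrom_data
        return cls(genome_to_chrom_data(genome), split, model_config, train_config)

    def _val_loss(self, predictor: ContactPredictor) -> float:
        predictor.eval()
        losses = []
        with ag.no_grad():
            for w in self.val_windows:
                s = extract_window(self.chrom_data[w.chrom], w)
                pred = predictor(s.model_inputs()[None]).data[0]
                losses.append(float(np.mean((pred - s.target.values) ** 2)))
        predictor.train()
        return float(np.mean(losses))

    def fit(self, n_epochs: Optional[int] = None, verbose: bool = False,
            callback=None, warm_start: Optional[ContactPredictor] = None
            ) -> ContactMapResults:
        cfg = self.train_config
        n_epochs = n_epochs or cfg.n_epochs
        history = []
        best = (np.inf, -1, None)
        attempt = 0
        while True:
            rng = np.random.default_rng(cfg.seed + 1013 * attempt)
            model_cfg = self.model_config if attempt == 0 else \
                ModelConfig(**{**self.model_config.__dict__,
                               "seed": self.model_config.seed + 1013 * attempt})
            predictor = ContactPredictor(model_cfg)
            if warm_start is not None:
                predictor.load_state_dict(warm_start.state_dict())
            predictor.train()
            opt = nn.Adam(predictor.parameters(), lr=cfg.learning_rate)
            best = (np.inf, -1, None)
            restarted = False
            for epoch in range(n_epochs):
                lr = nn.cosine_lr(cfg.learning_rate, epoch, cfg.scheduler_period)
                opt.lr = lr
                order = rng.permutation(len(self.train_windows))
                epoch_losses = []
                for lo in range(0, len(order), cfg.batch_size):
                    batch = [self.train_windows[i]
                             for i in order[lo:lo + cfg.batch_size]]
                    samples = []
                    for w in batch:
                        chrom = self.chrom_data[w.chrom]
                        samples.append(augment(extract_window(chrom, w), cfg,
                                               rng, chrom))
                    x, y = _batch_arrays(samples)
                    pred = predictor(x)
                    diff = pred - ag.Tensor(y)
                    loss = ag.tmean(diff * diff)
                    if not np.isfinite(loss.data):
                        raise RuntimeError(
                            f"divergent loss at epoch {epoch}: {float(loss.data)!r}")
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    epoch_losses.append(float(loss.data))
                val = self._val_loss(predictor)
                history.append({"attempt": attempt, "epoch": epoch,
                                "train_loss": float(np.mean(epoch_losses)),
                                "val_loss": val, "lr": lr})
                if val < best[0]:
                    best = (val, len(history) - 1, predictor.state_dict())
                if verbose:
                    print(f"epoch {epoch:3d}  train {history[-1]['train_loss']:.5f}  "
                          f"val {val:.5f}  lr {lr:.5f}", flush=True)
                if callback is not None:
                    callback(epoch, history[-1])
                if (attempt < cfg.max_restarts and warm_start is None
                        and epoch == cfg.restart_check_epoch
                        and epoch >= 3):
                    recent = np.mean([h["train_loss"] for h in history[-3:]])
                    baseline = history[len(history) - 1 - epoch + 2]["train_loss"]
                    if recent > cfg.restart_ratio * baseline:
                        if verbose:
                            print(f"plateau at epoch {epoch} "
                                  f"(train {recent:.4f} vs baseline {baseline:.4f}); "
                                  "restarting with a new initialization",
                                  flush=True)
                        restarted = True
                        break
            if not restarted:
                break
            attempt += 1
        if best[2] is not None:
            predictor.load_state_dict(best[2])
        predictor.eval()
        return ContactMapResults(predictor, pd.DataFrame(history), best[1],
                                 self.model_config, cfg,
                                 len(self.train_windows), len(self.val_windows))
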