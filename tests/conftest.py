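"""Shared fixtures: synthetic genomes and a tiny trainable model configuration.

The session-scoped ``trained_desk`` fixture runs the full desk-scale
recovery experiment (train on one chromosome, validate on a second,
hold out a third) once; the acceptance tests share its artifacts.
"""

import numpy as np
import pytest

from foldscreen.data import DatasetSplit, genome_to_chrom_data
from foldscreen.genome import SyntheticGenomeConfig, generate_genome
from foldscreen.model import ModelConfig
from foldscreen.train import ContactMapModel, TrainConfig


@pytest.fixture(scope="session")
def genome7():
    """The three-chromosome synthetic genome used by the recovery experiments."""
    return generate_genome(SyntheticGenomeConfig(seed=7), min_window=65_536)


@pytest.fixture(scope="session")
def chrom_data7(genome7):
    return genome_to_chrom_data(genome7)


@pytest.fixture()
def tiny_model_config():
    """A model small enough for per-test forward/backward passes."""
    return ModelConfig(window_length=16_384, bin_size=512,
                       encoder_hidden_schedule=(4, 4, 4, 4, 8, 8, 8, 8),
                       n_attention_layers=1, n_heads=2, d_model=8,
                       decoder_channels=8, seed=0)


@pytest.fixture(scope="session")
def trained_desk(genome7, chrom_data7):
    """Desk-scale model trained on the seed-7 synthetic genome (shared)."""
    split = DatasetSplit(["chrS1"], ["chrS2"], ["chrS3"])
    model = ContactMapModel(chrom_data7, split,
                            ModelConfig.desk_scale(seed=1),
                            TrainConfig.desk_scale(seed=1))
    return model.fit()
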