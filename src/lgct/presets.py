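"""Desk-scale study preset.

The full published protocol (20 channels, 250 Hz, 800 epochs with patience
100) is GPU-scale. For CPU experiments and the simulation study shipped
with the package we freeze one reduced protocol here:

* channels: the two homologous sensorimotor pairs C3/C4 and CP3/CP4 — the
  electrodes over hand motor cortex where the lateralised ERD contrast
  lives;
* rate: decimated 250 -> 125 Hz (keeps the beta band below Nyquist);
* model: the ``small_config`` architecture (4 temporal filters, kernel 13,
  embedding 8);
* training: Adam at 1e-3 for at most 30 epochs, early stopping patience
  10. The higher learning rate and short schedule match the reduced
  problem size; the published 1e-4 / 800-epoch schedule remains the
  TrainConfig default for full-scale use.
"""

from __future__ import annotations

from .data import EpochSet
from .model import ModelConfig, small_config
from .preprocess import downsample, select_channels
from .training import TrainConfig

__all__ = ["DESK_CHANNELS", "DESK_FS", "desk_preprocess", "desk_model_config",
           "desk_train_config"]

DESK_CHANNELS = ["C3", "C4", "CP3", "CP4"]
DESK_FS = 125.0


def desk_preprocess(epochs: EpochSet) -> EpochSet:
    """Channel-select and decimate a 250 Hz recording to the desk scale."""
    return downsample(select_channels(epochs, DESK_CHANNELS), DESK_FS)


def desk_model_config(n_samples: int, n_classes: int, seed: int = 0) -> ModelConfig:
    return small_config(len(DESK_CHANNELS), n_samples, n_classes, seed=seed)


def desk_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(learning_rate=1e-3, max_epochs=30, batch_size=32,
                       patience_epochs=10, seed=seed)
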