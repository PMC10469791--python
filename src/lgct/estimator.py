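"""Scikit-learn estimator facade.

:class:`LGCTClassifier` wraps the full pipeline — three-band assembly,
network construction, Adam training with early stopping — behind the
standard ``fit`` / ``predict`` / ``predict_proba`` interface, so the model
composes with sklearn model selection and pipelines. ``X`` is an epoched
array of shape (trials, channels, samples).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .data import EpochSet, Montage
from .model import build_model, reference_config, small_config
from .preprocess import make_multiband
from .training import TrainConfig, predict, train
from .utils import derive_seed

__all__ = ["LGCTClassifier"]


def _default_labels(n_channels: int) -> list[str]:
    """Placeholder mirror-pair labels (C1/C2, C3/C4, ...) for unnamed data;
    an odd trailing channel becomes the midline Cz."""
    labels = []
    for i in range(n_channels // 2):
        labels += [f"C{2 * i + 1}", f"C{2 * i + 2}"]
    if n_channels % 2:
        labels.append("Cz")
    return labels


class LGCTClassifier(BaseEstimator, ClassifierMixin):
    """Local-global convolutional transformer classifier for epoched EEG.

    Parameters
    ----------
    preset : {"small", "reference"}
        Base architecture size; "small" is sized for CPU training.
    variant : {"full", "wo_trans", "wo_diff_hemi", "wo_tdense"}
        Full model or one of the ablation variants.
    fs : float
        Sampling rate of ``X`` in Hz (needed for the mu/beta band filters).
    channel_names : list of str or None
        10-20 labels defining the hemisphere partition; None generates
        placeholder mirror pairs.
    validation_fraction : float
        Stratified fraction of the training data held out for early
        stopping.
    model_params : dict or None
        Overrides applied to the preset ModelConfig (e.g. {"dropout_rate": 0}).
    """

    def __init__(self, preset: str = "small", variant: str = "full",
                 fs: float = 250.0, channel_names: list[str] | None = None,
                 learning_rate: float = 1e-4, max_epochs: int = 100,
                 batch_size: int = 32, patience_epochs: int = 20,
                 validation_fraction: float = 0.15,
                 model_params: dict | None = None, random_state: int = 0):
        self.preset = preset
        self.variant = variant
        self.fs = fs
        self.channel_names = channel_names
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience_epochs = patience_epochs
        self.validation_fraction = validation_fraction
        self.model_params = model_params
        self.random_state = random_state

    def _montage(self, n_channels: int) -> Montage:
        labels = self.channel_names or _default_labels(n_channels)
        if len(labels) != n_channels:
            raise ValueError(f"{len(labels)} channel names for "
                             f"{n_channels}-channel data")
        return Montage.from_labels(list(labels))

    def fit(self, X, y):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("X must be (trials, channels, samples)")
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y disagree on the number of trials")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n, C, T = X.shape
        montage = self._montage(C)
        epochs = EpochSet(X, self.fs, y_enc, np.ones(n, dtype=int), montage)
        mb = make_multiband(epochs)

        maker = {"small": small_config, "reference": reference_config}
        if self.preset not in maker:
            raise ValueError(f"unknown preset {self.preset!r}")
        cfg = maker[self.preset](C, T, len(self.classes_),
                                 seed=derive_seed(self.random_state, "model"))
        for k, v in (self.model_params or {}).items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown model parameter {k!r}")
            setattr(cfg, k, v)

        tr, va = train_test_split(
            np.arange(n), test_size=self.validation_fraction, stratify=y_enc,
            random_state=derive_seed(self.random_state, "valsplit") % (2**32))
        model = build_model(cfg, montage=montage, variant=self.variant)
        tcfg = TrainConfig(learning_rate=self.learning_rate,
                           max_epochs=self.max_epochs,
                           batch_size=self.batch_size,
                           patience_epochs=self.patience_epochs,
                           seed=derive_seed(self.random_state, "train"))
        self.model_, self.history_ = train(model, mb.select_trials(tr),
                                           mb.select_trials(va), tcfg)
        self.n_features_in_ = C * T
        return self

    def _transform(self, X) -> list[np.ndarray]:
        X = np.asarray(X)
        n = X.shape[0]
        epochs = EpochSet(X, self.fs, np.zeros(n, dtype=int),
                          np.ones(n, dtype=int), self._montage(X.shape[1]))
        return make_multiband(epochs).arrays()

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        probs, _ = predict(self.model_, self._transform(X))
        return probs

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
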