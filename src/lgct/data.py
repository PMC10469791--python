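"""Core containers: electrode montage, epoched trials, frequency bands.

An :class:`EpochSet` (trials x channels x samples, with sampling rate, labels,
session ids and a montage) is the currency passed between every stage of the
pipeline, from the synthetic generator or EDF reader through preprocessing to
the classifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "EpochSet", "BandSpec", "MultiBandInput", "KU_MOTOR_20"]

#: The 20-electrode motor-cortex subset used for the Korea University
#: recordings: the C, CP and FC rows over sensorimotor cortex.
KU_MOTOR_20 = [
    "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
]

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


@dataclass(frozen=True)
class Montage:
    """Channel labels partitioned into left / right / midline index sets.

    ``left_idx[i]`` and ``right_idx[i]`` are homologous (mirror-pair)
    electrodes, e.g. C3 <-> C4, following the 10-20 convention that odd
    suffixes lie over the left hemisphere, even suffixes over the right and
    ``z`` on the midline.
    """

    channel_names: tuple[str, ...]
    left_idx: tuple[int, ...]
    right_idx: tuple[int, ...]
    midline_idx: tuple[int, ...]

    def __post_init__(self):
        n = len(self.channel_names)
        all_idx = list(self.left_idx) + list(self.right_idx) + list(self.midline_idx)
        if sorted(all_idx) != list(range(n)):
            raise ValueError("left/right/midline sets must partition all channels")
        if len(self.left_idx) != len(self.right_idx):
            raise ValueError(
                f"hemisphere sets must pair up: {len(self.left_idx)} left vs "
                f"{len(self.right_idx)} right"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @classmethod
    def from_labels(cls, labels: list[str]) -> "Montage":
        """Build a montage from 10-20 labels via the mirror-pair rule."""
        left: dict[tuple[str, int], int] = {}
        right: dict[tuple[str, int], int] = {}
        midline = []
        for i, lab in enumerate(labels):
            m = _LABEL_RE.match(lab)
            if not m:
                raise ValueError(f"cannot parse electrode label {lab!r}")
            prefix, suffix = m.group(1), m.group(2)
            if suffix == "z":
                midline.append(i)
            else:
                num = int(suffix)
                if num % 2 == 1:
                    left[(prefix, num)] = i
                else:
                    right[(prefix, num)] = i
        left_idx, right_idx = [], []
        for (prefix, num), i in sorted(left.items(), key=lambda kv: kv[1]):
            mirror = (prefix, num + 1)
            if mirror not in right:
                raise ValueError(f"no right-hemisphere mirror for {prefix}{num}")
            left_idx.append(i)
            right_idx.append(right.pop(mirror))
        if right:
            orphan = next(iter(right))
            raise ValueError(f"no left-hemisphere mirror for {orphan[0]}{orphan[1]}")
        return cls(tuple(labels), tuple(left_idx), tuple(right_idx), tuple(midline))

    def subset(self, keep: list[str]) -> "Montage":
        missing = [k for k in keep if k not in self.channel_names]
        if missing:
            raise KeyError(f"unknown channel label(s): {missing}")
        return Montage.from_labels(list(keep))


def ku_motor_montage() -> Montage:
    return Montage.from_labels(KU_MOTOR_20)


@dataclass
class EpochSet:
    """Epoched trials: data is trials x channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    labels: np.ndarray
    sessions: np.ndarray
    montage: Montage

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64) \
            if self.data.dtype not in (np.float32, np.float64) else np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.sessions = np.asarray(self.sessions, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n, c, _ = self.data.shape
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if len(self.labels) != n or len(self.sessions) != n:
            raise ValueError("labels and sessions must have one entry per trial")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if c != self.montage.n_channels:
            raise ValueError(
                f"data has {c} channels but montage lists {self.montage.n_channels}"
            )
        if n and (self.labels.min() < 0):
            raise ValueError("labels must be nonnegative class integers")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EpochSet":
        return EpochSet(data, fs if fs is not None else self.fs,
                        self.labels.copy(), self.sessions.copy(), self.montage)

    def select_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(self.data[idx], self.fs, self.labels[idx],
                        self.sessions[idx], self.montage)


@dataclass(frozen=True)
class BandSpec:
    """A pass band; low=None and high=None marks the raw passthrough."""

    name: str
    low: float | None
    high: float | None

    @property
    def is_raw(self) -> bool:
        return self.low is None and self.high is None

    def validate(self, fs: float) -> None:
        if self.is_raw:
            return
        if self.low is None or self.high is None:
            raise ValueError(f"band {self.name!r}: both edges or neither must be set")
        if not (0 < self.low < self.high < fs / 2):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high < Nyquist "
                f"({self.low}-{self.high} Hz at fs={fs} Hz)"
            )


RAW_BAND = BandSpec("raw", None, None)
ALPHA_BAND = BandSpec("alpha", 7.0, 12.0)
BETA_BAND = BandSpec("beta", 13.0, 32.0)


@dataclass
class MultiBandInput:
    """The model's three inputs, in fixed order: raw, alpha, beta."""

    bands: list[tuple[BandSpec, EpochSet]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.bands) != 3:
            raise ValueError("expected exactly 3 bands (raw, alpha, beta)")
        shapes = {es.data.shape for _, es in self.bands}
        if len(shapes) != 1:
            raise ValueError(f"band entries differ in dimensions: {shapes}")

    @property
    def n_trials(self) -> int:
        return self.bands[0][1].n_trials

    @property
    def shape(self):
        return self.bands[0][1].data.shape

    def arrays(self) -> list[np.ndarray]:
        return [es.data for _, es in self.bands]

    def select_trials(self, idx) -> "MultiBandInput":
        return MultiBandInput([(b, es.select_trials(idx)) for b, es in self.bands])

    @property
    def labels(self) -> np.ndarray:
        return self.bands[0][1].labels
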