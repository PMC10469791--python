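"""Signal conditioning: channel selection, downsampling, band filtering,
per-trial Z-score normalisation, and assembly of the three-band model input.

The model consumes three views of every trial — the raw broadband signal and
two band-passed copies around the mu (7-12 Hz) and beta (13-32 Hz)
sensorimotor rhythms — each Z-scored per trial and channel.

Filtering uses a zero-phase (forward-backward) 4th-order Butterworth filter
applied within each 4-s epoch; edge transients at the epoch borders are
accepted rather than padded away.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .data import (
    ALPHA_BAND,
    BETA_BAND,
    RAW_BAND,
    BandSpec,
    EpochSet,
    MultiBandInput,
)

__all__ = [
    "select_channels",
    "downsample",
    "bandpass",
    "zscore",
    "make_multiband",
    "read_edf",
]


def select_channels(epochs: EpochSet, keep: list[str]) -> EpochSet:
    """Restrict to the channels in `keep`, in `keep` order."""
    names = list(epochs.montage.channel_names)
    missing = [k for k in keep if k not in names]
    if missing:
        raise KeyError(f"unknown channel label(s): {missing}")
    idx = [names.index(k) for k in keep]
    sub = epochs.montage.subset(keep)
    return EpochSet(epochs.data[:, idx, :], epochs.fs, epochs.labels.copy(),
                    epochs.sessions.copy(), sub)


def downsample(epochs: EpochSet, target_fs: float) -> EpochSet:
    """Anti-alias low-pass then integer decimation to `target_fs`."""
    if target_fs == epochs.fs:
        return epochs.with_data(epochs.data.copy())
    ratio = epochs.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"sampling rate {epochs.fs} Hz is not an integer multiple of "
            f"target {target_fs} Hz (rational resampling not supported)"
        )
    out = signal.decimate(epochs.data, factor, axis=-1, ftype="fir", zero_phase=True)
    return epochs.with_data(np.ascontiguousarray(out), fs=target_fs)


def bandpass(epochs: EpochSet, band: BandSpec, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass; the raw band passes through."""
    if band.is_raw:
        return epochs.with_data(epochs.data.copy())
    band.validate(epochs.fs)
    sos = signal.butter(order, [band.low, band.high], btype="bandpass",
                        fs=epochs.fs, output="sos")
    out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.with_data(np.ascontiguousarray(out))


def zscore(epochs: EpochSet) -> EpochSet:
    """Z = (x - mu) / sigma per trial and channel (population sigma)."""
    mu = epochs.data.mean(axis=-1, keepdims=True)
    sigma = epochs.data.std(axis=-1, keepdims=True)  # population (divide by N)
    bad = np.nonzero(sigma[..., 0] == 0)
    if bad[0].size:
        t, c = bad[0][0], bad[1][0]
        raise ValueError(
            f"zero-variance channel: trial {t}, channel "
            f"{epochs.montage.channel_names[c]!r} (index {c})"
        )
    return epochs.with_data((epochs.data - mu) / sigma)


def make_multiband(epochs: EpochSet,
                   alpha: BandSpec = ALPHA_BAND,
                   beta: BandSpec = BETA_BAND) -> MultiBandInput:
    """Assemble the model input: Z-scored (raw, alpha, beta), in that order."""
    return MultiBandInput([
        (RAW_BAND, zscore(epochs)),
        (alpha, zscore(bandpass(epochs, alpha))),
        (beta, zscore(bandpass(epochs, beta))),
    ])


def read_edf(path, cue_annotations: dict[str, int], duration: float = 4.0,
             channels: list[str] | None = None) -> EpochSet:
    """Cut [cue, cue + duration) epochs from an EDF recording.

    `cue_annotations` maps annotation descriptions to integer class labels;
    annotations not listed are ignored. Session id is set to 1 (merge
    EpochSets from several files to build multi-session datasets).
    """
    import mne  # optional dependency, only needed on the real-data path

    from .data import Montage

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    fs = float(raw.info["sfreq"])
    n_samp = int(round(duration * fs))
    sig = raw.get_data() * 1e6  # volts -> microvolts
    trials, labels = [], []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc not in cue_annotations:
            continue
        start = int(round(onset * fs))
        if start + n_samp > sig.shape[1]:
            continue
        trials.append(sig[:, start : start + n_samp])
        labels.append(cue_annotations[desc])
    if not trials:
        raise ValueError(f"no usable cue annotations found in {path}")
    montage = Montage.from_labels(list(raw.ch_names))
    data = np.stack(trials)
    return EpochSet(data, fs, np.array(labels), np.ones(len(trials), dtype=int),
                    montage)
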