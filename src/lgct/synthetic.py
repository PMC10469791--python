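"""Synthetic motor-imagery EEG with controllable class separability.

Each trial is 1/f ("pink") background noise per channel plus ongoing mu
(~10 Hz) and beta (~20 Hz) oscillations on the motor channels. Imagining a
hand movement desynchronises the rhythm over the contralateral hemisphere:
the oscillation POWER there is multiplied by (1 - erd_depth) — amplitude by
sqrt(1 - erd_depth) — which is the classic ERD signature the classifier has
to pick up. With erd_depth = 0 the classes are statistically exchangeable.

Four-class mode is a toy convention, not physiology: class 2 ("feet")
attenuates beta power on midline channels, class 3 ("tongue") attenuates mu
power everywhere.

Session 2, when generated, is perturbed by per-channel gain jitter and a
shift of the mu centre frequency, emulating the between-day drift of
statistical distributions that makes cross-session evaluation hard.

Everything is drawn from one seeded generator: a config reproduces its
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .data import EpochSet, Montage, ku_motor_montage

__all__ = ["SynthConfig", "SynthDataset", "generate_trial", "generate_dataset",
           "pink_noise"]


@dataclass
class SessionDrift:
    gain_sd: float = 0.2
    freq_jitter_hz: float = 0.5


@dataclass
class SynthConfig:
    n_subjects: int = 1
    n_sessions: int = 2
    trials_per_session: int = 200
    n_classes: int = 2
    fs: float = 250.0
    duration: float = 4.0
    montage: Montage = field(default_factory=ku_motor_montage)
    erd_depth: float = 0.8
    background_amp: float = 10.0  # microvolt RMS of the 1/f background
    mu_amp: float = 10.0  # microvolt peak amplitude of the ~10 Hz rhythm
    beta_amp: float = 5.0  # microvolt peak amplitude of the ~20 Hz rhythm
    pink_exponent: float = 1.0
    subject_gain_sd: float = 0.1
    session_drift: SessionDrift = field(default_factory=SessionDrift)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.erd_depth < 1.0):
            raise ValueError("erd_depth must be in [0, 1)")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        n_samp = self.fs * self.duration
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        if self.trials_per_session % self.n_classes != 0:
            raise ValueError("trials_per_session must divide evenly by classes")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class SynthDataset:
    """One EpochSet per subject (sessions concatenated) plus ground truth."""

    subjects: list[EpochSet]
    truth: dict


def pink_noise(rng: np.random.Generator, n_samples: int, exponent: float = 1.0,
               shape: tuple = ()) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise, via spectral shaping of white noise."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = np.sqrt((x**2).mean(axis=-1, keepdims=True))
    return x / rms


def _erd_factors(cls: int, cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel amplitude multipliers for the mu and beta oscillations."""
    C = cfg.montage.n_channels
    att = np.sqrt(1.0 - cfg.erd_depth)  # power x (1 - d)
    mu = np.ones(C)
    beta = np.ones(C)
    left = list(cfg.montage.left_idx)
    right = list(cfg.montage.right_idx)
    mid = list(cfg.montage.midline_idx)
    if cls == 0:  # left hand -> contralateral (right) hemisphere ERD
        mu[right] = att
        beta[right] = att
    elif cls == 1:  # right hand -> left hemisphere ERD
        mu[left] = att
        beta[left] = att
    elif cls == 2:  # feet -> midline beta ERD (toy convention)
        beta[mid] = att
    elif cls == 3:  # tongue -> broadband mu ERD everywhere (toy convention)
        mu[:] = att
    else:
        raise ValueError(f"invalid class id {cls}")
    return mu, beta


def generate_trial(cls: int, cfg: SynthConfig, rng: np.random.Generator,
                   channel_gain: np.ndarray | None = None,
                   mu_center: float = 10.0,
                   beta_center: float = 20.0) -> np.ndarray:
    """One channels x samples trial in microvolts."""
    cfg.validate()
    C, n = cfg.montage.n_channels, cfg.n_samples
    t = np.arange(n) / cfg.fs
    bg = cfg.background_amp * pink_noise(rng, n, cfg.pink_exponent, (C,))
    mu_f = mu_center + rng.normal(0, 0.3)
    beta_f = beta_center + rng.normal(0, 0.5)
    mu_phase = rng.uniform(0, 2 * np.pi, size=(C, 1))
    beta_phase = rng.uniform(0, 2 * np.pi, size=(C, 1))
    env_f = rng.uniform(0.1, 0.5)
    env = 1.0 + 0.3 * np.sin(2 * np.pi * env_f * t + rng.uniform(0, 2 * np.pi))
    mu_mult, beta_mult = _erd_factors(cls, cfg)
    mu_osc = cfg.mu_amp * mu_mult[:, None] * env \
        * np.sin(2 * np.pi * mu_f * t + mu_phase)
    beta_osc = cfg.beta_amp * beta_mult[:, None] * env \
        * np.sin(2 * np.pi * beta_f * t + beta_phase)
    trial = bg + mu_osc + beta_osc
    if channel_gain is not None:
        trial = trial * channel_gain[:, None]
    return trial


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Balanced, shuffled, per-subject multi-session epoch sets."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    subjects = []
    truth: dict = {"config": _truth_config(cfg), "subjects": []}
    for s in range(cfg.n_subjects):
        gain = 1.0 + rng.normal(0, cfg.subject_gain_sd,
                                size=cfg.montage.n_channels)
        gain = np.clip(gain, 0.2, None)
        sub_truth = {"subject": s, "sessions": []}
        data_parts, label_parts, session_parts = [], [], []
        for sess in range(1, cfg.n_sessions + 1):
            if sess == 1:
                sess_gain = gain
                mu_center = 10.0
            else:
                drift = cfg.session_drift
                sess_gain = gain * np.clip(
                    1.0 + rng.normal(0, drift.gain_sd,
                                     size=cfg.montage.n_channels), 0.2, None)
                mu_center = 10.0 + rng.normal(0, drift.freq_jitter_hz)
            labels = np.repeat(np.arange(cfg.n_classes),
                               cfg.trials_per_session // cfg.n_classes)
            rng.shuffle(labels)
            trials = np.stack([
                generate_trial(int(c), cfg, rng, sess_gain, mu_center)
                for c in labels
            ])
            data_parts.append(trials)
            label_parts.append(labels)
            session_parts.append(np.full(len(labels), sess))
            sub_truth["sessions"].append({
                "session": sess,
                "mu_center_hz": float(mu_center),
                "channel_gain": [float(g) for g in sess_gain],
            })
        subjects.append(EpochSet(
            np.concatenate(data_parts), cfg.fs, np.concatenate(label_parts),
            np.concatenate(session_parts), cfg.montage))
        truth["subjects"].append(sub_truth)
    return SynthDataset(subjects, truth)


def _truth_config(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["montage"] = list(cfg.montage.channel_names)
    return d
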