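"""Session-based evaluation scenarios and cross-subject statistics.

Four within-subject protocols, distinguished by how the two recording
sessions (different days, hence drifted distributions) enter training:

* ``within_session`` — stratified 10-fold CV on a single session; one of
  the non-test folds rotates in as the validation set for early stopping;
* ``cross_session_case1`` — train on all of session 1; session 2 is split
  in recorded order into a validation phase and a test phase;
* ``cross_session_case2`` — train and validate on session 1 only; ALL of
  session 2 is the test set (nothing from day 2 is seen before testing);
* ``two_session`` — both sessions pooled into a stratified 10-fold CV.

In the cross-session scenarios no session-2 trial ever reaches a training
set; `ScenarioSplit.check_no_leakage` asserts this, plus pairwise
disjointness, programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import EpochSet
from .model import ModelConfig, build_model
from .preprocess import make_multiband
from .training import TrainConfig, predict, train
from .utils import derive_seed

__all__ = ["SCENARIOS", "ScenarioSplit", "ScenarioResult", "make_splits",
           "run_scenario", "paired_ttest"]

SCENARIOS = ("within_session", "cross_session_case1", "cross_session_case2",
             "two_session")


@dataclass
class ScenarioSplit:
    scenario: str
    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray]]

    def check_no_leakage(self, sessions: np.ndarray | None = None) -> None:
        """Assert pairwise disjointness and the cross-session rule."""
        for k, (tr, va, te) in enumerate(self.folds):
            for a, b, names in ((tr, va, "train/val"), (tr, te, "train/test"),
                                (va, te, "val/test")):
                if np.intersect1d(a, b).size:
                    raise AssertionError(
                        f"{self.scenario} fold {k}: {names} sets overlap")
            if sessions is not None and self.scenario.startswith("cross_session"):
                if np.any(sessions[tr] == 2):
                    raise AssertionError(
                        f"{self.scenario} fold {k}: session-2 trial in training")


@dataclass
class ScenarioResult:
    scenario: str
    variant: str
    fold_acc: list[float]  # percent
    histories: list = field(default_factory=list)
    subject: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_acc))

    @property
    def sd(self) -> float:
        # sample SD (n-1), the convention of reported fold/subject spreads
        if len(self.fold_acc) < 2:
            return 0.0
        return float(np.std(self.fold_acc, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject if self.subject is not None else 0,
            "scenario": self.scenario,
            "variant": self.variant,
            "fold": np.arange(len(self.fold_acc)),
            "accuracy": self.fold_acc,
        })

    def summary(self) -> dict:
        return {"scenario": self.scenario, "variant": self.variant,
                "mean_accuracy": self.mean, "sd": self.sd,
                "fold_accuracies": self.fold_acc}


def _require_sessions(epochs: EpochSet, needed: set[int], scenario: str):
    present = set(int(s) for s in np.unique(epochs.sessions))
    if not needed <= present:
        raise ValueError(f"{scenario} requires sessions {sorted(needed)}; "
                         f"dataset has {sorted(present)}")


def _stratified_folds(idx: np.ndarray, labels: np.ndarray, k: int, seed: int):
    counts = np.bincount(labels)
    if (counts[counts > 0] < k).any():
        raise ValueError(f"a class has fewer than {k} trials; "
                         "stratified folds would lose a class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [idx[test] for _, test in skf.split(np.zeros(len(idx)), labels)]


def make_splits(dataset: EpochSet, scenario: str, k_folds: int = 10,
                seed: int = 0, session: int | None = None) -> ScenarioSplit:
    """Trial-index folds (train, validation, test) for a scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    sessions = dataset.sessions
    labels = dataset.labels
    all_idx = np.arange(dataset.n_trials)
    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    if scenario in ("within_session", "two_session"):
        if scenario == "within_session":
            if session is None:
                session = int(sessions.min())
            _require_sessions(dataset, {session}, scenario)
            pool = all_idx[sessions == session]
        else:
            pool = all_idx
        test_folds = _stratified_folds(pool, labels[pool], k_folds, seed)
        for i in range(k_folds):
            test = test_folds[i]
            val = test_folds[(i + 1) % k_folds]  # rotating validation fold
            train_idx = np.setdiff1d(pool, np.concatenate([test, val]))
            folds.append((train_idx, val, test))
    elif scenario == "cross_session_case1":
        _require_sessions(dataset, {1, 2}, scenario)
        train_idx = all_idx[sessions == 1]
        s2 = all_idx[sessions == 2]  # recorded order: phase 1 val, phase 2 test
        half = len(s2) // 2
        folds.append((train_idx, s2[:half], s2[half:]))
    elif scenario == "cross_session_case2":
        _require_sessions(dataset, {1, 2}, scenario)
        s1 = all_idx[sessions == 1]
        tr, va = train_test_split(s1, test_size=0.2, stratify=labels[s1],
                                  random_state=seed)
        folds.append((np.sort(tr), np.sort(va), all_idx[sessions == 2]))

    split = ScenarioSplit(scenario, folds)
    split.check_no_leakage(sessions)
    return split


def run_scenario(dataset: EpochSet, scenario: str, model_cfg: ModelConfig,
                 train_cfg: TrainConfig, seed: int = 0, k_folds: int = 10,
                 variant: str = "full", session: int | None = None,
                 subject: int | None = None) -> ScenarioResult:
    """Full protocol: split, per-fold fresh model, train, test accuracy.

    `dataset` must already be preprocessed (channel-selected, downsampled);
    the three-band input is assembled here once.
    """
    split = make_splits(dataset, scenario, k_folds=k_folds, seed=seed,
                        session=session)
    mb = make_multiband(dataset)
    result = ScenarioResult(scenario, variant, [], subject=subject)
    for i, (tr, va, te) in enumerate(split.folds):
        fold_seed = derive_seed(seed, f"{scenario}-fold{i}")
        cfg = replace(model_cfg, seed=fold_seed)
        model = build_model(cfg, montage=dataset.montage, variant=variant)
        fold_train_cfg = replace(train_cfg, seed=fold_seed)
        model, hist = train(model, mb.select_trials(tr), mb.select_trials(va),
                            fold_train_cfg)
        _, pred = predict(model, mb.select_trials(te))
        acc = 100.0 * float((pred == dataset.labels[te]).mean())
        result.fold_acc.append(acc)
        result.histories.append(hist)
    return result


def paired_ttest(acc_a, acc_b) -> tuple[float, float, float]:
    """Two-sided paired t-test plus the Pearson correlation of the pair.

    Returns (t statistic, two-sided p, correlation). Identical vectors give
    (0, 1, corr); constant nonzero differences are degenerate and rejected.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 paired values")
    corr = float(stats.pearsonr(a, b).statistic) if a.std() > 0 and b.std() > 0 \
        else float("nan")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, 1.0, corr
        raise ValueError("degenerate paired test: constant nonzero differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), corr
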