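"""Latent-space separability tasks: SVM classification and KS comparison.

A radial-basis-function SVM is fit directly on 2-D latent points and scored
by resubstitution error (misclassified points / total points) — the aim is
to measure how much class or identity structure a reducer's latent space
preserves, not to maximize generalization.  The SVM settings are fixed once
and reused for every task and every reducer.

Because autoencoder latent spaces vary between trainings, each task is
repeated (default 10 times) with a fresh reducer initialization per
repetition; PCA is deterministic, so its single error is recorded for every
repetition.  Error distributions of two reducers are compared with the
two-sample Kolmogorov-Smirnov test, which is robust to unequal variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

TASKS = ("movement", "individual")


class SingleClassError(ValueError):
    """Classification requested on latent points with fewer than 2 labels."""


class EmptyRunError(ValueError):
    pass


@dataclass(frozen=True)
class SVMParams:
    """Fixed RBF-kernel SVM settings shared by all tasks and reducers."""

    C: float = 1.0
    gamma: str | float = "scale"  # 1 / (n_features * var(X))
    kernel: str = "rbf"


DEFAULT_SVM = SVMParams()


def classify_latent(
    points: np.ndarray,
    labels: Sequence,
    svm_params: SVMParams = DEFAULT_SVM,
) -> float:
    """Resubstitution error of an RBF SVM on latent points."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.shape[0] != labels.shape[0]:
        raise ValueError("one label per point required")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise SingleClassError("need at least 2 distinct labels")
    if counts.min() < 2:
        raise ValueError("need at least 2 points per class")
    clf = SVC(C=svm_params.C, gamma=svm_params.gamma, kernel=svm_params.kernel)
    clf.fit(points, labels)
    predicted = clf.predict(points)
    return float(np.mean(predicted != labels))


@dataclass
class ClassificationRun:
    """Per-repetition latent-space error rates for one reducer and task."""

    task: str
    reducer_id: str
    errors: list[float]

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if any(not 0.0 <= e <= 1.0 for e in self.errors):
            raise ValueError("error rates must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors))

    @property
    def sd(self) -> float:
        return float(np.std(self.errors))

    @property
    def median(self) -> float:
        return float(np.median(self.errors))


@dataclass
class LatentProvider:
    """A reducer wired to one task's data.

    ``fit_encode(seed)`` retrains the reducer from a fresh initialization
    and returns the latent coordinates of every task sample; ``labels`` are
    the matching targets.  ``deterministic`` reducers (PCA) are fit once.
    """

    name: str
    labels: np.ndarray
    fit_encode: Callable[[int], np.ndarray]
    deterministic: bool = False


@dataclass
class KSComparison:
    reducer_a: str
    reducer_b: str
    statistic: float
    p_value: float


def run_task(
    task: str,
    providers: list[LatentProvider],
    repetitions: int = 10,
    seed: int = 0,
    svm_params: SVMParams = DEFAULT_SVM,
) -> list[ClassificationRun]:
    """Repeat (retrain reducer, fit SVM, score) for every provider."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    runs = []
    for pidx, provider in enumerate(providers):
        if provider.deterministic:
            latent = provider.fit_encode(seed)
            err = classify_latent(latent, provider.labels, svm_params)
            errors = [err] * repetitions
        else:
            errors = []
            for rep in range(repetitions):
                rep_seed = int(
                    np.random.SeedSequence([seed, pidx, rep]).generate_state(1)[0]
                    % (2**31)
                )
                latent = provider.fit_encode(rep_seed)
                errors.append(classify_latent(latent, provider.labels, svm_params))
        runs.append(ClassificationRun(task=task, reducer_id=provider.name, errors=errors))
    return runs


def compare_runs(a: ClassificationRun, b: ClassificationRun) -> KSComparison:
    """Two-sample Kolmogorov-Smirnov test between two error distributions."""
    if not a.errors or not b.errors:
        raise EmptyRunError("both runs must contain error values")
    result = stats.ks_2samp(a.errors, b.errors, method="auto")
    return KSComparison(
        reducer_a=a.reducer_id,
        reducer_b=b.reducer_id,
        statistic=float(result.statistic),
        p_value=float(result.pvalue),
    )


def summarize_runs(runs: list[ClassificationRun]) -> dict:
    """JSON-ready summary: per-reducer mean/sd/median error."""
    return {
        run.reducer_id: {
            "task": run.task,
            "errors": run.errors,
            "mean": run.mean,
            "sd": run.sd,
            "median": run.median,
        }
        for run in runs
    }
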