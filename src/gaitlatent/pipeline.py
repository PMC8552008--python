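"""End-to-end orchestration: synthesize, preprocess, reduce, classify.

``prepare_study`` turns a synthetic study into standardized pose samples
and movement windows with provenance labels.  The provider factories wire
each reducer (PCA, pose autoencoder, movement autoencoder) to a task's data
so :func:`gaitlatent.tasks.run_task` can retrain and score them.

The pelvic-velocity filter is applied only to the natural stream;
standardization statistics are pooled over every analysis recording of all
classes.  For classification tasks a single PCA basis is fit on the union
of the task's poses.  Autoencoders are trained on an (optionally
subsampled) training set but always encode *every* task sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import move_ae as mae
from . import pca as _pca
from . import pose_ae as pae
from .preprocess import (
    DEFAULT_STRIDE,
    DEFAULT_WINDOW,
    Standardizer,
    filter_by_pelvic_velocity,
    fit_standardizer,
    sample_poses,
    sample_windows,
    select_channels,
    stack_poses,
    stack_windows,
)
from .synthetic import SyntheticDataset, generate_study
from .tasks import LatentProvider


@dataclass
class PreparedStudy:
    """Standardized samples with provenance for every analysis recording."""

    standardizer: Standardizer
    pose_x: np.ndarray  # (n_poses, 14)
    pose_activity: np.ndarray  # (n_poses,) str
    pose_subject: np.ndarray  # (n_poses,) str
    pose_frame: np.ndarray  # (n_poses,) int
    win_w: np.ndarray  # (n_windows, 60, 14)
    win_activity: np.ndarray
    win_subject: np.ndarray
    win_start: np.ndarray

    def poses_for(self, activities: tuple[str, ...]) -> np.ndarray:
        return np.isin(self.pose_activity, activities)

    def windows_for(self, activities: tuple[str, ...]) -> np.ndarray:
        return np.isin(self.win_activity, activities)


def prepare_study(
    dataset: SyntheticDataset,
    stride: int = DEFAULT_STRIDE,
    window: int = DEFAULT_WINDOW,
    pelvic_threshold: float | None = None,
    min_segment: int = DEFAULT_WINDOW,
) -> PreparedStudy:
    """Channel-select, filter, standardize and sample a whole study."""
    analysis_recs = []
    for rec in dataset.recordings:
        rec = select_channels(rec)
        if rec.activity == "natural":
            analysis_recs.extend(
                filter_by_pelvic_velocity(rec, pelvic_threshold, min_segment)
            )
        else:
            analysis_recs.append(rec)
    standardizer = fit_standardizer(analysis_recs)
    poses, windows = [], []
    for rec in analysis_recs:
        poses.extend(sample_poses(rec, standardizer, stride))
        windows.extend(sample_windows(rec, standardizer, window, stride))
    return PreparedStudy(
        standardizer=standardizer,
        pose_x=stack_poses(poses),
        pose_activity=np.array([p.activity for p in poses]),
        pose_subject=np.array([p.subject_id for p in poses]),
        pose_frame=np.array([p.frame for p in poses]),
        win_w=stack_windows(windows),
        win_activity=np.array([w.activity for w in windows]),
        win_subject=np.array([w.subject_id for w in windows]),
        win_start=np.array([w.start_frame for w in windows]),
    )


def prepare_synthetic_study(
    n_flat: int = 8,
    n_stair: int = 11,
    n_natural: int = 0,
    duration: float = 60.0,
    seed: int = 0,
    **kwargs,
) -> PreparedStudy:
    return prepare_study(
        generate_study(n_flat, n_stair, n_natural, duration=duration, seed=seed),
        **kwargs,
    )


# --------------------------------------------------------------------------
# providers


def _subsample(n: int, max_n: int | None, seed: int) -> np.ndarray:
    if max_n is None or n <= max_n:
        return np.arange(n)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]))
    return np.sort(rng.choice(n, size=max_n, replace=False))


def pca_provider(
    pose_x: np.ndarray, labels: np.ndarray, k: int = 2, name: str = "pca"
) -> LatentProvider:
    def fit_encode(seed: int) -> np.ndarray:
        model = _pca.fit_pca(pose_x)
        return _pca.encode_pca(model, pose_x, k=k)

    return LatentProvider(
        name=name, labels=labels, fit_encode=fit_encode, deterministic=True
    )


def pose_ae_provider(
    pose_x: np.ndarray,
    labels: np.ndarray,
    config: pae.PoseAEConfig | None = None,
    max_train: int | None = 2000,
    name: str = "pose_ae",
) -> LatentProvider:
    base = config or pae.PoseAEConfig()

    def fit_encode(seed: int) -> np.ndarray:
        cfg = pae.PoseAEConfig(
            input_width=base.input_width,
            latent_width=base.latent_width,
            hidden_widths=base.hidden_widths,
            learning_rate=base.learning_rate,
            iterations=base.iterations,
            seed=seed,
            log_every=base.log_every,
        )
        idx = _subsample(pose_x.shape[0], max_train, seed)
        model = pae.train_pose_ae(pose_x[idx], cfg)
        return pae.encode_pose(model, pose_x)

    return LatentProvider(name=name, labels=labels, fit_encode=fit_encode)


def move_ae_provider(
    win_w: np.ndarray,
    labels: np.ndarray,
    config: mae.MoveAEConfig | None = None,
    max_train: int | None = None,
    name: str = "move_ae",
) -> LatentProvider:
    base = config or mae.MoveAEConfig()

    def fit_encode(seed: int) -> np.ndarray:
        cfg = mae.MoveAEConfig(
            window=base.window,
            channels=base.channels,
            latent_width=base.latent_width,
            td_width=base.td_width,
            hidden_size=base.hidden_size,
            intermediate_width=base.intermediate_width,
            learning_rate=base.learning_rate,
            iterations=base.iterations,
            batch_size=base.batch_size,
            seed=seed,
            grad_clip=base.grad_clip,
            log_every=base.log_every,
        )
        idx = _subsample(win_w.shape[0], max_train, seed)
        model = mae.train_move_ae(win_w[idx], cfg)
        return mae.encode_move(model, win_w)

    return LatentProvider(name=name, labels=labels, fit_encode=fit_encode)


def movement_task_providers(
    study: PreparedStudy,
    pose_config: pae.PoseAEConfig | None = None,
    move_config: mae.MoveAEConfig | None = None,
    max_train_poses: int | None = 2000,
    max_train_windows: int | None = None,
) -> list[LatentProvider]:
    """Flat vs stair classification; the natural stream is excluded."""
    pm = study.poses_for(("flat", "stair"))
    wm = study.windows_for(("flat", "stair"))
    return [
        pca_provider(study.pose_x[pm], study.pose_activity[pm]),
        pose_ae_provider(
            study.pose_x[pm], study.pose_activity[pm], pose_config, max_train_poses
        ),
        move_ae_provider(
            study.win_w[wm], study.win_activity[wm], move_config, max_train_windows
        ),
    ]


def individual_task_providers(
    study: PreparedStudy,
    pose_config: pae.PoseAEConfig | None = None,
    move_config: mae.MoveAEConfig | None = None,
    max_train_poses: int | None = 2000,
    max_train_windows: int | None = None,
) -> list[LatentProvider]:
    """Subject identification within the flat-ground dataset only."""
    pm = study.poses_for(("flat",))
    wm = study.windows_for(("flat",))
    return [
        pca_provider(study.pose_x[pm], study.pose_subject[pm]),
        pose_ae_provider(
            study.pose_x[pm], study.pose_subject[pm], pose_config, max_train_poses
        ),
        move_ae_provider(
            study.win_w[wm], study.win_subject[wm], move_config, max_train_windows
        ),
    ]
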