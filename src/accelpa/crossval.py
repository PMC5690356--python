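"""Leave-one-subject-out cross-validation (LOSO-CV) orchestration.

Each subject's windows are predicted exactly once, by a network trained on
all other subjects' non-transition windows.  Each wear site is modeled
independently (no parameter sharing), mirroring the four distinct
site-specific networks of the study design.  Fold seeds are derived from a
stable hash of (global seed, subject id), so results are reproducible
regardless of subject iteration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream_seed
from .ann import IntensityNet
from .annotation import IntensityCategory, WindowLabel
from .errors import DegenerateTrainingError, DesignError

logger = logging.getLogger(__name__)

_TRANS = int(IntensityCategory.TRANSITION)


@dataclass
class SubjectData:
    """One subject's aligned features and DO window labels at one site.

    ``y`` uses integer IntensityCategory values and may contain TRANSITION
    (3); transition windows are stripped for training and intensity
    evaluation but retained here so break counting can see the full
    timeline.
    """

    subject_id: str
    window_index: np.ndarray
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.window_index = np.asarray(self.window_index, dtype=int)
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.window_index) == len(self.X) == len(self.y)):
            raise ValueError("window_index, X and y must be aligned")

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.y != _TRANS

    @classmethod
    def from_labels(cls, subject_id, window_index, X,
                    labels: Sequence[WindowLabel]) -> "SubjectData":
        y = np.asarray([int(lab.intensity) for lab in labels])
        return cls(subject_id, window_index, X, y)


@dataclass
class LabeledDataset:
    """Per-site collection of SubjectData, keyed by subject id."""

    site: str
    subjects: dict[str, SubjectData]

    def usable_subjects(self) -> list[str]:
        """Subjects with ≥1 non-transition window; others are dropped with a
        warning (they carry no trainable or evaluable windows)."""
        out = []
        for sid, sd in self.subjects.items():
            if sd.labeled_mask.any():
                out.append(sid)
            else:
                logger.warning(
                    "subject %s has no non-transition windows at site %s; dropped",
                    sid, self.site,
                )
        return out


@dataclass
class FoldResult:
    """Out-of-sample predictions for one held-out subject."""

    subject_id: str
    window_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: np.ndarray
    fold_seed: int
    train_loss: float
    model: IntensityNet | None = field(default=None, repr=False)


@dataclass
class CVResult:
    """LOSO result for one site: every labeled window of every subject is
    predicted exactly once, never by a model that saw that subject."""

    site: str
    folds: list[FoldResult]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV form: site,subject,window_index,true,pred,p_sb,p_lpa,p_mvpa."""
        frames = []
        for f in self.folds:
            frames.append(pd.DataFrame({
                "site": self.site,
                "subject": f.subject_id,
                "window_index": f.window_index,
                "true": [IntensityCategory(v).name for v in f.y_true],
                "pred": [IntensityCategory(v).name for v in f.y_pred],
                "p_sb": f.proba[:, 0],
                "p_lpa": f.proba[:, 1],
                "p_mvpa": f.proba[:, 2],
            }))
        return pd.concat(frames, ignore_index=True)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def cv_result_from_frame(df: pd.DataFrame, site: str | None = None) -> CVResult:
    """Rebuild a CVResult (without models) from the persisted CSV form."""
    required = {"site", "subject", "window_index", "true", "pred",
                "p_sb", "p_lpa", "p_mvpa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing columns {sorted(missing)}")
    if site is None:
        sites = df["site"].unique()
        if len(sites) != 1:
            raise ValueError("multiple sites in table; pass site explicitly")
        site = sites[0]
    sub = df[df["site"] == site]
    folds = []
    for sid, g in sub.groupby("subject", sort=True):
        folds.append(FoldResult(
            subject_id=str(sid),
            window_index=g["window_index"].to_numpy(),
            y_true=np.asarray([int(IntensityCategory[v]) for v in g["true"]]),
            y_pred=np.asarray([int(IntensityCategory[v]) for v in g["pred"]]),
            proba=g[["p_sb", "p_lpa", "p_mvpa"]].to_numpy(),
            fold_seed=-1,
            train_loss=float("nan"),
        ))
    return CVResult(site=site, folds=folds, seed=-1)


def loso_cv(
    data: LabeledDataset,
    hyper: Mapping | None = None,
    seed: int = 0,
    keep_models: bool = True,
) -> CVResult:
    """Leave-one-subject-out CV over a per-site dataset.

    For each of the n subjects, a network is trained on the other n−1
    subjects' non-transition windows and predicts *all* windows of the
    held-out subject (intensity metrics later ignore the transition ones;
    break counting uses them).  Fold seeds derive from (seed, subject_id).
    """
    hyper = dict(hyper or {})
    subjects = data.usable_subjects()
    if len(subjects) < 2:
        raise DesignError(
            f"LOSO requires >= 2 usable subjects, got {len(subjects)} at site "
            f"{data.site}"
        )
    folds = []
    for sid in subjects:
        train_X, train_y = [], []
        for other in subjects:
            if other == sid:
                continue
            sd = data.subjects[other]
            m = sd.labeled_mask
            train_X.append(sd.X[m])
            train_y.append(sd.y[m])
        Xtr = np.vstack(train_X)
        ytr = np.concatenate(train_y)
        fold_seed = substream_seed(seed, "fold", sid)
        try:
            model = IntensityNet(random_state=fold_seed, **hyper).fit(Xtr, ytr)
        except DegenerateTrainingError as exc:
            raise DegenerateTrainingError(
                f"fold holding out {sid!r} at site {data.site}: {exc}"
            ) from exc
        held = data.subjects[sid]
        proba = model.predict_proba(held.X)
        y_pred = model.classes_[np.argmax(proba, axis=1)]
        folds.append(FoldResult(
            subject_id=sid,
            window_index=held.window_index.copy(),
            y_true=held.y.copy(),
            y_pred=y_pred,
            proba=proba,
            fold_seed=fold_seed,
            train_loss=model.loss_,
            model=model if keep_models else None,
        ))
    return CVResult(site=data.site, folds=folds, seed=seed)


def run_site_models(
    datasets: Mapping[str, LabeledDataset],
    hyper: Mapping | None = None,
    seed: int = 0,
    keep_models: bool = False,
) -> dict[str, CVResult]:
    """Independent LOSO-CV per wear site; no parameter sharing across sites."""
    if not 1 <= len(datasets) <= 4:
        raise DesignError(f"expected 1-4 sites, got {len(datasets)}")
    out = {}
    for site, data in datasets.items():
        if site != data.site:
            raise DesignError(f"dataset site {data.site!r} filed under {site!r}")
        try:
            out[site] = loso_cv(data, hyper=hyper, seed=seed,
                                keep_models=keep_models)
        except (DesignError, DegenerateTrainingError) as exc:
            raise type(exc)(f"site {site}: {exc}") from exc
    return out
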