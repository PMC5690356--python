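"""Evaluation statistics: confusion matrices, sensitivity/specificity,
quadratic-weighted kappa, time in category, and breaks in sedentary behavior.

Sensitivity of class c is the proportion of windows truly in c classified as
c; specificity is the proportion of windows truly not in c classified as not
c.  Agreement is summarized by Cohen's kappa with quadratic weights
w_ij = 1 − (i−j)²/(k−1)², which penalizes misclassification by squared
ordinal distance between the intensity categories SB < LPA < MVPA.  A break
in SB is a non-sedentary 30-s window immediately following a sedentary one.

Undefined metrics (e.g. sensitivity of a class absent from the truth) are
reported as NaN ("missing"), never silently as 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import IntensityCategory

K = 3  # intensity classes
CLASS_NAMES = ("SB", "LPA", "MVPA")

#: Quadratic agreement weights, w_ij = 1 - (i-j)^2 / (K-1)^2.
QUADRATIC_WEIGHTS = 1.0 - (
    (np.arange(K)[:, None] - np.arange(K)[None, :]) ** 2 / (K - 1) ** 2
)


def _as_int_array(seq: Sequence, allow_transition: bool = False) -> np.ndarray:
    arr = np.asarray([int(v) for v in seq], dtype=int)
    if arr.size and (arr.min() < 0 or arr.max() > 3):
        raise ValueError("labels must be IntensityCategory values")
    if not allow_transition and np.any(arr == int(IntensityCategory.TRANSITION)):
        raise ValueError("TRANSITION labels are not allowed here")
    return arr


@dataclass(frozen=True)
class ConfusionMatrix:
    """3×3 window counts; rows = true category, columns = predicted;
    class order (SB, LPA, MVPA)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (K, K):
            raise ValueError(f"confusion matrix must be {K}x{K}, got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"true_{c}" for c in CLASS_NAMES],
            columns=[f"pred_{c}" for c in CLASS_NAMES],
        )


def confusion(true: Sequence, pred: Sequence) -> ConfusionMatrix:
    """Tally a confusion matrix; entry (i, j) counts windows with true class
    i predicted as j.  TRANSITION entries are a domain error."""
    t = _as_int_array(true)
    p = _as_int_array(pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    cm = np.zeros((K, K), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return ConfusionMatrix(cm)


def sensitivity(cm: ConfusionMatrix, cls: IntensityCategory | int) -> float:
    """100 × (correctly classified windows of cls) / (windows truly cls);
    NaN when the class never occurs in the truth."""
    i = int(cls)
    row = cm.counts[i].sum()
    if row == 0:
        return float("nan")
    return 100.0 * cm.counts[i, i] / row


def specificity(cm: ConfusionMatrix, cls: IntensityCategory | int) -> float:
    """100 × (windows truly not cls predicted not cls) / (windows truly not
    cls); NaN when every window is truly cls."""
    i = int(cls)
    mask = np.ones(K, dtype=bool)
    mask[i] = False
    off = cm.counts[mask]
    denom = off.sum()
    if denom == 0:
        return float("nan")
    return 100.0 * off[:, mask].sum() / denom


def weighted_kappa(
    cm: ConfusionMatrix,
    conf_level: float = 0.95,
    method: str = "asymptotic",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Quadratic-weighted Cohen's kappa with a confidence interval.

    κ = (p_o − p_e) / (1 − p_e) with p_o = Σ w_ij n_ij / N and
    p_e = Σ w_ij r_i c_j / N², using agreement weights
    w_ij = 1 − (i−j)²/(K−1)².  The default CI uses the large-sample
    (Fleiss–Cohen–Everitt) standard error; ``method="bootstrap"`` resamples
    windows instead.

    Returns ``(kappa, ci_low, ci_high)``; raises if chance agreement is 1
    (all mass in one marginal cell on both axes), where κ is undefined.
    """
    n = cm.counts.astype(float)
    N = n.sum()
    if N == 0:
        raise ValueError("empty confusion matrix")
    p = n / N
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    w = QUADRATIC_WEIGHTS
    p_o = float(np.sum(w * p))
    p_e = float(np.sum(w * np.outer(r, c)))
    if p_e >= 1.0 - 1e-12:
        raise ValueError("kappa undefined: chance agreement p_e = 1")
    kappa = (p_o - p_e) / (1.0 - p_e)

    from scipy.stats import norm

    z = norm.ppf(0.5 + conf_level / 2.0)
    if method == "asymptotic":
        wbar_row = w @ c          # Σ_j c_j w_ij, per row i
        wbar_col = r @ w          # Σ_i r_i w_ij, per column j
        inner = (
            w * (1.0 - p_e)
            - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - p_o)
        )
        var = (
            np.sum(p * inner**2) - (p_o * p_e - 2.0 * p_e + p_o) ** 2
        ) / (N * (1.0 - p_e) ** 4)
        se = float(np.sqrt(max(var, 0.0)))
        lo, hi = kappa - z * se, kappa + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        cells = np.repeat(np.arange(K * K), cm.counts.ravel())
        stats = []
        for _ in range(n_boot):
            resampled = np.bincount(rng.choice(cells, size=int(N)), minlength=K * K)
            try:
                k_b, _, _ = weighted_kappa(
                    ConfusionMatrix(resampled.reshape(K, K)), method="asymptotic"
                )
            except ValueError:
                continue
            stats.append(k_b)
        lo, hi = np.quantile(stats, [(1 - conf_level) / 2, 0.5 + conf_level / 2])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return kappa, float(max(lo, -1.0)), float(min(hi, 1.0))


def time_in_categories(
    pred: Sequence, window_s: float = 30.0
) -> dict[str, float]:
    """Minutes spent in each category: window count × window_s / 60."""
    arr = _as_int_array(pred)
    return {
        name: float(np.sum(arr == i) * window_s / 60.0)
        for i, name in enumerate(CLASS_NAMES)
    }


def count_breaks(seq: Sequence, include_transitions: bool = True) -> int:
    """Number of breaks in SB: positions t ≥ 1 with seq[t−1] = SB and seq[t]
    non-sedentary.

    With ``include_transitions`` (the DO semantics — transitions involve
    walking, standing, etc.), TRANSITION entries are retained and count as
    non-sedentary; otherwise TRANSITION entries are removed from the
    sequence before counting.
    """
    arr = _as_int_array(seq, allow_transition=True)
    if not include_transitions:
        arr = arr[arr != int(IntensityCategory.TRANSITION)]
    if arr.size < 2:
        return 0
    sb = int(IntensityCategory.SB)
    return int(np.sum((arr[:-1] == sb) & (arr[1:] != sb)))


# ---------------------------------------------------------------------------
# per-subject reporting
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-subject and pooled evaluation statistics for one wear site.

    ``per_subject`` is a tidy table (one row per subject) suitable for
    external inferential statistics; ``pooled`` sums windows over subjects
    (used for the pooled confusion matrix and kappa), while
    ``mean_per_subject`` averages each subject's sensitivities and
    specificities (NaN cells excluded), matching the two reporting modes.
    """

    site: str
    per_subject: pd.DataFrame
    pooled_confusion: ConfusionMatrix
    pooled_kappa: tuple[float, float, float]

    @property
    def mean_per_subject(self) -> dict[str, float]:
        cols = [
            f"{m}_{c.lower()}" for m in ("sensitivity", "specificity")
            for c in CLASS_NAMES
        ]
        return {c: float(self.per_subject[c].mean()) for c in cols}

    def pooled_sensitivity(self, cls) -> float:
        return sensitivity(self.pooled_confusion, cls)

    def pooled_specificity(self, cls) -> float:
        return specificity(self.pooled_confusion, cls)

    def summary(self) -> str:
        k, lo, hi = self.pooled_kappa
        lines = [
            f"Site: {self.site}",
            f"  windows evaluated: {self.pooled_confusion.total}",
            f"  pooled weighted kappa: {k:.3f} (95% CI {lo:.3f}-{hi:.3f})",
        ]
        for i, c in enumerate(CLASS_NAMES):
            lines.append(
                f"  {c}: sensitivity {self.pooled_sensitivity(i):.1f}% "
                f"specificity {self.pooled_specificity(i):.1f}% (pooled)"
            )
        mps = self.mean_per_subject
        lines.append(
            "  mean per-subject sensitivity (SB/LPA/MVPA): "
            + "/".join(f"{mps['sensitivity_' + c.lower()]:.1f}%" for c in CLASS_NAMES)
        )
        lines.append(
            f"  mean predicted breaks in SB: "
            f"{self.per_subject['breaks_pred'].mean():.2f} "
            f"(DO: {self.per_subject['breaks_true'].mean():.2f})"
        )
        return "\n".join(lines)


def per_subject_report(cv, include_transitions: bool = True,
                       window_s: float = 30.0) -> MetricsReport:
    """All §-level evaluation statistics for one site's CV result.

    Sensitivity/specificity/kappa/time are computed on non-transition
    windows; break counts use the full window timeline (predictions exist
    for transition-annotated windows; DO break counting treats transitions
    as non-sedentary when ``include_transitions`` is set).
    """
    rows = []
    pooled = ConfusionMatrix(np.zeros((K, K), dtype=int))
    trans = int(IntensityCategory.TRANSITION)
    for fold in cv.folds:
        y_true = np.asarray(fold.y_true)
        y_pred = np.asarray(fold.y_pred)
        keep = y_true != trans
        cm = confusion(y_true[keep], y_pred[keep])
        pooled = pooled + cm
        times_pred = time_in_categories(y_pred[keep], window_s)
        times_true = time_in_categories(y_true[keep], window_s)
        row = {"site": cv.site, "subject": fold.subject_id,
               "n_windows": int(keep.sum())}
        for i, c in enumerate(CLASS_NAMES):
            row[f"sensitivity_{c.lower()}"] = sensitivity(cm, i)
            row[f"specificity_{c.lower()}"] = specificity(cm, i)
        for c in CLASS_NAMES:
            row[f"time_pred_{c.lower()}_min"] = times_pred[c]
            row[f"time_true_{c.lower()}_min"] = times_true[c]
        # predicted breaks: full prediction timeline (transition windows
        # included); DO breaks: transitions treated as non-sedentary
        row["breaks_pred"] = count_breaks(y_pred, include_transitions=True)
        row["breaks_true"] = count_breaks(
            y_true, include_transitions=include_transitions
        )
        try:
            row["kappa"], _, _ = weighted_kappa(cm)
        except ValueError:
            row["kappa"] = float("nan")
        rows.append(row)
    if not rows:
        raise ValueError("empty CV result")
    return MetricsReport(
        site=cv.site,
        per_subject=pd.DataFrame(rows),
        pooled_confusion=pooled,
        pooled_kappa=weighted_kappa(pooled),
    )
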