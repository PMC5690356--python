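"""30-s windowing and percentile feature extraction.

Each non-overlapping 30-second window of the raw (unfiltered) 20 Hz signal is
summarized by the 10th, 25th, 50th, 75th and 90th percentiles of each axis —
15 features per window (5 percentiles × 3 axes).  No gravity removal, no
vector magnitude, no frequency-domain features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import SignalRecording

logger = logging.getLogger(__name__)

PERCENTILES = (10, 25, 50, 75, 90)

#: Canonical feature ordering: axis-major, percentile-minor.  Model files
#: record this ordering to prevent silent feature permutation.
FEATURE_COLUMNS = tuple(
    f"{axis}_p{p}" for axis in ("x", "y", "z") for p in PERCENTILES
)

# Percentile convention, centralized: linear interpolation between order
# statistics (h = (n-1)q; x[floor(h)] + frac*(x[floor(h)+1]-x[floor(h)])).
# Swap the method here to change the convention package-wide.
_PERCENTILE_METHOD = "linear"


@dataclass(frozen=True)
class FeatureVector:
    """The 15 percentile features for one window, in FEATURE_COLUMNS order."""

    subject_id: str
    site: str
    window_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64).ravel()
        if vals.shape != (15,):
            raise ValueError(f"expected 15 feature values, got {vals.shape}")
        object.__setattr__(self, "values", vals)


def segment_windows(
    rec: SignalRecording, window_s: float = 30.0
) -> list[tuple[int, np.ndarray]]:
    """Split a recording into non-overlapping windows of window_s seconds.

    Returns ``(window_index, block)`` pairs where each block holds exactly
    ``window_s × rate`` samples (600 at 20 Hz).  An incomplete trailing block
    is dropped with a logged warning.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    wlen = int(round(window_s * rec.sampling_rate_hz))
    n_windows = rec.n_samples // wlen
    leftover = rec.n_samples - n_windows * wlen
    if leftover:
        logger.warning(
            "dropping incomplete trailing window (%d samples, subject=%s site=%s)",
            leftover, rec.subject_id, rec.site,
        )
    return [
        (k, rec.samples[k * wlen : (k + 1) * wlen]) for k in range(n_windows)
    ]


def percentile_features(block: np.ndarray) -> np.ndarray:
    """15 percentile features of one sample block, axis-major order.

    Percentiles use the linear-interpolation convention on sorted values;
    the raw samples are used as-is (no filtering).
    """
    block = np.asarray(block, dtype=np.float64)
    if block.size == 0:
        raise ValueError("empty sample block")
    if block.ndim != 2 or block.shape[1] != 3:
        raise ValueError(f"block must have shape (n, 3), got {block.shape}")
    # shape (5, 3) -> transpose to (3, 5) for axis-major flattening
    pct = np.percentile(block, PERCENTILES, axis=0, method=_PERCENTILE_METHOD)
    return pct.T.ravel()


def extract_features(rec: SignalRecording, window_s: float = 30.0) -> pd.DataFrame:
    """Feature table for a whole recording: one row per complete window.

    Columns: ``subject``, ``site``, ``window_index`` and the 15 feature
    columns of :data:`FEATURE_COLUMNS`.  This is the interchange format
    between pipeline stages.
    """
    rows = []
    index = []
    for k, block in segment_windows(rec, window_s):
        rows.append(percentile_features(block))
        index.append(k)
    df = pd.DataFrame(
        np.asarray(rows).reshape(len(rows), 15) if rows else np.empty((0, 15)),
        columns=list(FEATURE_COLUMNS),
    )
    df.insert(0, "subject", rec.subject_id)
    df.insert(1, "site", rec.site)
    df.insert(2, "window_index", index)
    return df


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject", "site", "window_index", *FEATURE_COLUMNS)
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature CSV missing columns {missing}")
    return df
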