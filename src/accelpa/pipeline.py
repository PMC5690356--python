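"""End-to-end orchestration: signals → features → LOSO-CV → metrics.

Glues the pipeline stages together for both in-memory cohorts (synthetic
runs, tests) and on-disk data trees (the CLI).  The shared 30-s window grid
is anchored at each recording's start time, which for generated cohorts is
the protocol start, so DO labels and all four devices line up.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import ActivityEvent, label_windows, read_annotation_csv
from .crossval import CVResult, LabeledDataset, SubjectData, loso_cv
from .features import extract_features, FEATURE_COLUMNS
from .metrics import MetricsReport, per_subject_report
from .signal_io import SignalRecording, read_raw_csv, reintegrate_to_20hz
from .synthetic import Cohort

logger = logging.getLogger(__name__)


def subject_data_from_recording(
    rec: SignalRecording,
    events: Sequence[ActivityEvent],
    window_s: float = 30.0,
) -> SubjectData:
    """Reintegrate to 20 Hz if needed, extract features, and align DO labels
    on the window grid anchored at the recording start."""
    rec = reintegrate_to_20hz(rec) if rec.sampling_rate_hz == 40 else rec
    feats = extract_features(rec, window_s)
    n_windows = len(feats)
    labels = label_windows(
        events, rec.start_time, n_windows, rec.subject_id, window_s
    )
    return SubjectData.from_labels(
        rec.subject_id,
        feats["window_index"].to_numpy(),
        feats[list(FEATURE_COLUMNS)].to_numpy(),
        labels,
    )


def dataset_from_cohort(
    cohort: Cohort, site: str, window_s: float = 30.0
) -> LabeledDataset:
    subjects = {}
    for sid in cohort.subject_ids:
        subjects[sid] = subject_data_from_recording(
            cohort.recording(sid, site), cohort.schedules[sid], window_s
        )
    return LabeledDataset(site=site, subjects=subjects)


def dataset_from_files(
    data_dir: str | Path, site: str, window_s: float = 30.0
) -> LabeledDataset:
    """Build a per-site dataset from a generated directory tree
    (``signals/<subject>_<site>.csv`` + ``annotations/<subject>.csv``)."""
    data_dir = Path(data_dir)
    subjects = {}
    for ann_path in sorted((data_dir / "annotations").glob("*.csv")):
        events_by_subject = read_annotation_csv(ann_path)
        for sid, events in events_by_subject.items():
            sig_path = data_dir / "signals" / f"{sid}_{site}.csv"
            if not sig_path.exists():
                logger.warning("no %s signal for subject %s; skipped", site, sid)
                continue
            rec = read_raw_csv(sig_path, dialect="simple")
            subjects[sid] = subject_data_from_recording(rec, events, window_s)
    return LabeledDataset(site=site, subjects=subjects)


def evaluate_sites(
    datasets: Mapping[str, LabeledDataset],
    hyper: Mapping | None = None,
    seed: int = 0,
    include_transitions: bool = True,
    window_s: float = 30.0,
) -> dict[str, tuple[CVResult, MetricsReport]]:
    """LOSO-CV plus the full metrics report, independently per site."""
    out = {}
    for site, data in datasets.items():
        cv = loso_cv(data, hyper=hyper, seed=seed, keep_models=False)
        report = per_subject_report(
            cv, include_transitions=include_transitions, window_s=window_s
        )
        out[site] = (cv, report)
    return out


def evaluate_cohort(
    cohort: Cohort,
    sites: Sequence[str] | None = None,
    hyper: Mapping | None = None,
    seed: int = 0,
    include_transitions: bool = True,
    window_s: float = 30.0,
) -> dict[str, tuple[CVResult, MetricsReport]]:
    """Convenience wrapper: build per-site datasets from a cohort and run
    the full evaluation."""
    from .signal_io import SITES

    sites = list(sites) if sites is not None else list(SITES)
    datasets = {s: dataset_from_cohort(cohort, s, window_s) for s in sites}
    return evaluate_sites(
        datasets, hyper=hyper, seed=seed,
        include_transitions=include_transitions, window_s=window_s,
    )
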