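"""Synthetic multi-site accelerometer cohort generator.

Emulates the 90-minute semi-structured protocol: each subject performs all
13 activities once, for 3–10 minutes each, in self-chosen (random) order,
with 10–40 s inter-activity gaps.  For each wear site a 20 or 40 Hz
tri-axial signal is synthesized per activity bout as

    sample(t) = gravity orientation (site- and posture-specific,
                subject-jittered)
              + amplitude · sin(2π f t + φ) · oscillation direction
              + white Gaussian noise,

with the dynamic amplitude scaled by activity intensity.  Gaps carry a
standing-like orientation with small-amplitude dynamics.

Site confusability is engineered, not emergent, so the qualitative site
ordering (thigh > left wrist > hip > right wrist for right-hand-dominant
cohorts) is a testable property of the pipeline:

* the hip shares its sit/stand orientation up to a small offset (sitting SB
  vs standing LPA look alike at the hip);
* the dominant wrist moves less than the rest of the body during whole-body
  MVPA (amplitude shrink into the light-activity band), rests in a
  desk-work-like posture during cycling, and carries larger between-subject
  variability and extra noise — so dominant-wrist MVPA is misread as LPA or
  even SB;
* the non-dominant wrist keeps distinct arm postures per activity and is
  degraded only mildly (low wrist travel for squats, walking-family
  orientation overlap).

All randomness flows from one root seed via named streams
(subject/site/purpose), so any single artifact can be regenerated in
isolation.  Handedness is right-dominant with probability 0.9.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._rng import stream, substream_seed
from .annotation import (
    ACTIVITY_INTENSITY,
    Activity,
    ActivityEvent,
    IntensityCategory,
    write_annotation_csv,
)
from .errors import ConfigError
from .signal_io import SignalRecording, SITES, parse_iso8601, write_raw_csv

logger = logging.getLogger(__name__)

#: Device sampling rate per wear site (thigh/hip devices record at 40 Hz and
#: are reintegrated to 20 Hz downstream; wrist devices record at 20 Hz).
SITE_RATE = {"hip": 40.0, "thigh": 40.0, "left_wrist": 20.0, "right_wrist": 20.0}

_POSTURE = {
    Activity.LYING_DOWN: "lying",
    Activity.READING: "sitting",
    Activity.COMPUTER_USE: "sitting",
    Activity.STANDING: "standing",
    Activity.LAUNDRY: "standing",
    Activity.SWEEPING: "standing",
    Activity.BICEPS_CURLS: "standing",
    Activity.WALKING_SLOW: "standing",
    Activity.WALKING_FAST: "standing",
    Activity.JOGGING: "standing",
    Activity.CYCLING: "cycling",
    Activity.STAIRS: "standing",
    Activity.SQUATS: "squat",
}

#: Per-activity signal character: (dominant frequency Hz, leg-segment dynamic
#: amplitude g, arm-segment dynamic amplitude g).
_ACTIVITY_SIGNAL: dict[Activity, tuple[float, float, float]] = {
    Activity.LYING_DOWN: (0.25, 0.003, 0.005),
    Activity.READING: (0.30, 0.005, 0.012),
    Activity.COMPUTER_USE: (0.50, 0.005, 0.020),
    Activity.STANDING: (0.40, 0.007, 0.015),
    Activity.LAUNDRY: (0.90, 0.030, 0.220),
    Activity.SWEEPING: (0.80, 0.050, 0.280),
    Activity.BICEPS_CURLS: (1.00, 0.010, 0.400),
    Activity.WALKING_SLOW: (1.70, 0.160, 0.100),
    Activity.WALKING_FAST: (2.10, 0.380, 0.280),
    Activity.JOGGING: (2.80, 0.800, 0.550),
    Activity.CYCLING: (1.50, 0.500, 0.050),
    Activity.STAIRS: (1.90, 0.450, 0.320),
    Activity.SQUATS: (0.70, 0.420, 0.180),
}

_GAP_SIGNAL = (0.60, 0.040, 0.070)  # standing-like inter-activity dynamics

# Gravity orientation (g) per site and posture; wrist orientations are
# per-activity (arm position varies more than trunk/leg posture).
_ORIENT_HIP = {
    "lying": (0.05, 0.97, 0.10),
    "standing": (0.02, 0.03, 0.995),
    "cycling": (0.30, 0.08, 0.94),
    "squat": (0.22, 0.06, 0.95),
}
_HIP_SIT_OFFSET = np.array([0.08, 0.05, -0.01])  # sitting ≈ standing + offset

_ORIENT_THIGH = {
    "lying": (0.08, 0.97, 0.06),
    "sitting": (0.95, 0.04, 0.26),
    "standing": (0.04, 0.06, 0.99),
    "cycling": (0.64, 0.06, 0.75),
    "squat": (0.50, 0.08, 0.83),
}

_ORIENT_WRIST = {
    Activity.LYING_DOWN: (0.52, 0.60, 0.58),
    Activity.READING: (0.80, 0.35, 0.42),
    Activity.COMPUTER_USE: (0.84, 0.30, 0.38),
    Activity.STANDING: (0.06, 0.12, 0.99),
    Activity.LAUNDRY: (0.35, 0.30, 0.85),
    Activity.SWEEPING: (0.42, 0.35, 0.80),
    Activity.BICEPS_CURLS: (0.45, 0.28, 0.82),
    Activity.WALKING_SLOW: (0.10, 0.14, 0.98),
    Activity.WALKING_FAST: (0.15, 0.18, 0.96),
    Activity.JOGGING: (0.28, 0.25, 0.91),
    Activity.CYCLING: (0.45, 0.20, 0.85),   # hands on handlebars, pronated
    Activity.STAIRS: (0.18, 0.16, 0.96),
    Activity.SQUATS: (0.14, 0.08, 0.97),
}
_WRIST_GAP_ORIENT = (0.07, 0.13, 0.98)
# dominant arm rests on the leg/handlebar while pedaling: forearm posture
# overlaps desk work, making dominant-wrist cycling look sedentary
_DOMINANT_CYCLING_ORIENT = (0.78, 0.30, 0.42)

#: Arm tasks done mainly by the dominant hand; their dominant-wrist
#: amplitude is scaled by ``dominant_lpa_boost`` (a knob, neutral = 1.0).
_DOMINANT_BOOST_ACTIVITIES = frozenset(
    {Activity.LAUNDRY, Activity.SWEEPING, Activity.BICEPS_CURLS}
)


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the protocol design: 13 activities of 3–10 min each in
    random order totalling ~90 min, 10–40 s transition gaps, and a cohort
    that is right-hand dominant with probability 0.9.
    """

    n_subjects: int = 20
    seed: int = 0
    duration_bounds_min: tuple[float, float] = (3.0, 10.0)
    target_total_min: float = 90.0
    gap_bounds_s: tuple[float, float] = (10.0, 40.0)
    protocol_start: str = "2016-03-01T09:00:00+00:00"
    handedness_p_right: float = 0.9

    # per-site noise scale (g)
    noise_scale: dict = field(default_factory=lambda: {
        "hip": 0.012, "thigh": 0.010, "left_wrist": 0.018, "right_wrist": 0.018,
    })
    # between-subject gravity-orientation jitter sd (g), per site
    subject_orient_sigma: dict = field(default_factory=lambda: {
        "hip": 0.100, "thigh": 0.030, "left_wrist": 0.035, "right_wrist": 0.035,
    })
    # between-subject whole-site amplitude multiplier, lognormal sigma
    subject_amp_sigma: float = 0.10
    # per (subject, activity) amplitude multiplier, lognormal sigma
    activity_amp_sigma: float = 0.12
    # per (subject, activity) extra orientation jitter sd (g)
    activity_orient_sigma: float = 0.02
    # slow within-bout amplitude modulation (relative)
    amp_modulation: float = 0.15

    # confusability knobs
    hip_sit_stand_gap: float = 0.75     # scales the hip sit-vs-stand offset
    dominant_lpa_boost: float = 1.0     # dominant-wrist light-task amplitude
    dominant_mvpa_shrink: float = 0.65  # dominant-wrist MVPA amplitude ×
    dominant_amp_sigma: float = 0.55    # dominant-wrist activity_amp_sigma
    dominant_orient_mult: float = 2.5   # dominant-wrist orientation jitter ×
    dominant_noise_mult: float = 2.6    # dominant-wrist noise ×

    def __post_init__(self) -> None:
        lo, hi = self.duration_bounds_min
        glo, ghi = self.gap_bounds_s
        if not (0 < lo <= hi) or not (0 <= glo <= ghi):
            raise ConfigError("duration/gap bounds must be ordered and positive")
        if not 0.0 <= self.handedness_p_right <= 1.0:
            raise ConfigError("handedness probability must be in [0, 1]")
        if any(v < 0 for v in self.noise_scale.values()):
            raise ConfigError("noise scales must be non-negative")
        needed = 13 * lo * 60 + 12 * glo
        if needed > self.target_total_min * 60:
            raise ConfigError(
                f"infeasible schedule: 13 activities at >= {lo} min plus gaps "
                f"need {needed / 60:.1f} min > target {self.target_total_min} min"
            )

    @property
    def start_posix(self) -> float:
        return parse_iso8601(self.protocol_start)


@dataclass
class SubjectProfile:
    """Per-subject random effects, drawn once from named seed streams."""

    subject_id: str
    handedness: str                      # "right" or "left"
    orient_jitter: dict[str, np.ndarray]  # site -> (3,) gravity jitter
    amp_mult: dict[str, float]            # site -> amplitude multiplier

    @property
    def dominant_site(self) -> str:
        return f"{self.handedness}_wrist"


def make_profile(cfg: GeneratorConfig, subject_id: str) -> SubjectProfile:
    rng = stream(cfg.seed, "profile", subject_id)
    handedness = "right" if rng.uniform() < cfg.handedness_p_right else "left"
    orient_jitter: dict[str, np.ndarray] = {}
    amp_mult: dict[str, float] = {}
    for site in SITES:
        sigma = cfg.subject_orient_sigma[site]
        if site == f"{handedness}_wrist":
            sigma *= cfg.dominant_orient_mult
        orient_jitter[site] = rng.normal(0.0, sigma, size=3)
        amp_mult[site] = float(rng.lognormal(0.0, cfg.subject_amp_sigma))
    return SubjectProfile(subject_id, handedness, orient_jitter, amp_mult)


def simulate_schedule(
    cfg: GeneratorConfig, subject: SubjectProfile | str
) -> list[ActivityEvent]:
    """One subject's protocol schedule: all 13 activities exactly once, in
    uniformly random order, durations uniform in bounds then proportionally
    rescaled (within bounds) so activity time + gaps lands on the 90-min
    target (±2 min), with uniform inter-activity gaps."""
    sid = subject.subject_id if isinstance(subject, SubjectProfile) else subject
    rng = stream(cfg.seed, "schedule", sid)
    acts = list(Activity)
    order = [acts[i] for i in rng.permutation(len(acts))]
    lo, hi = (60.0 * b for b in cfg.duration_bounds_min)
    durations = rng.uniform(lo, hi, size=len(order))
    gaps = rng.uniform(*cfg.gap_bounds_s, size=len(order) - 1)
    budget = cfg.target_total_min * 60.0 - gaps.sum()
    # proportional rescale with clipping to the duration bounds, iterated so
    # clipped activities hand their surplus/deficit to the free ones
    for _ in range(30):
        scale = budget / durations.sum()
        scaled = np.clip(durations * scale, lo, hi)
        free = (scaled > lo) & (scaled < hi)
        if abs(scaled.sum() - budget) < 1.0 or not free.any():
            durations = scaled
            break
        residual = budget - scaled[~free].sum()
        durations[free] *= residual / scaled[free].sum()
        durations[~free] = scaled[~free]
        durations = np.clip(durations, lo, hi)
    else:  # pragma: no cover
        durations = scaled
    events = []
    t = cfg.start_posix
    for i, act in enumerate(order):
        events.append(ActivityEvent(t, t + float(durations[i]), act))
        t += float(durations[i])
        if i < len(gaps):
            t += float(gaps[i])
    total_min = (events[-1].end - cfg.start_posix) / 60.0
    if abs(total_min - cfg.target_total_min) > 2.0:
        logger.warning(
            "schedule for %s totals %.1f min (target %.1f)", sid, total_min,
            cfg.target_total_min,
        )
    return events


_OSC_REFERENCE = np.array([0.36, 0.80, 0.48])


def _osc_direction(orient: np.ndarray) -> np.ndarray:
    """Unit oscillation direction: the component of a fixed reference vector
    orthogonal to gravity.  Depending on orientation only (not on the
    activity identity) keeps activities with a shared posture genuinely
    confusable when their amplitudes overlap."""
    ohat = orient / max(np.linalg.norm(orient), 1e-12)
    v = _OSC_REFERENCE - (_OSC_REFERENCE @ ohat) * ohat
    n = np.linalg.norm(v)
    if n < 1e-9:  # pragma: no cover - reference collinear with gravity
        v = np.array([1.0, 0.0, 0.0]) - ohat[0] * ohat
        n = np.linalg.norm(v)
    return v / n


def _site_params(
    site: str, activity: Activity | None, cfg: GeneratorConfig, dominant: bool
) -> tuple[np.ndarray, float, float]:
    """(orientation, amplitude, frequency) for one site × activity (None =
    inter-activity gap)."""
    if activity is None:
        freq, leg, arm = _GAP_SIGNAL
    else:
        freq, leg, arm = _ACTIVITY_SIGNAL[activity]
    if site == "hip":
        posture = "standing" if activity is None else _POSTURE[activity]
        if posture == "sitting":
            orient = (
                np.asarray(_ORIENT_HIP["standing"])
                + cfg.hip_sit_stand_gap * _HIP_SIT_OFFSET
            )
        else:
            orient = np.asarray(_ORIENT_HIP[posture])
        amp = 0.6 * leg
    elif site == "thigh":
        posture = "standing" if activity is None else _POSTURE[activity]
        orient = np.asarray(_ORIENT_THIGH[posture])
        amp = leg
    else:
        if activity is None:
            orient = np.asarray(_WRIST_GAP_ORIENT)
        elif dominant and activity == Activity.CYCLING:
            orient = np.asarray(_DOMINANT_CYCLING_ORIENT)
        else:
            orient = np.asarray(_ORIENT_WRIST[activity])
        amp = arm
        if dominant and activity in _DOMINANT_BOOST_ACTIVITIES:
            amp *= cfg.dominant_lpa_boost
        if dominant and activity is not None and (
            ACTIVITY_INTENSITY[activity] == IntensityCategory.MVPA
        ):
            # little extra wrist travel during whole-body MVPA pushes the
            # dominant wrist's dynamics into the light-activity band
            amp *= cfg.dominant_mvpa_shrink
    return orient.astype(float), float(amp), freq


def simulate_signals(
    schedule: list[ActivityEvent],
    subject: SubjectProfile,
    site: str,
    cfg: GeneratorConfig,
) -> SignalRecording:
    """Synthesize one wear-site recording for one subject's schedule.

    Deterministic given (cfg.seed, subject, site).  The recording spans the
    first event's start to the last event's end at the site's native rate.
    """
    if site not in SITES:
        raise ConfigError(f"unknown site {site!r}")
    rate = SITE_RATE[site]
    start = schedule[0].start
    end = schedule[-1].end
    n = int(round((end - start) * rate))
    sig = np.empty((n, 3))
    dominant = site == subject.dominant_site
    act_sigma = cfg.dominant_amp_sigma if dominant else cfg.activity_amp_sigma
    rng_noise = stream(cfg.seed, "signal", subject.subject_id, site, "noise")
    noise_sd = cfg.noise_scale[site] * (cfg.dominant_noise_mult if dominant else 1.0)

    # build (t_start, t_end, activity-or-None) segments: events + gaps
    segments: list[tuple[float, float, Activity | None]] = []
    for i, ev in enumerate(schedule):
        segments.append((ev.start, ev.end, ev.activity))
        if i + 1 < len(schedule) and schedule[i + 1].start > ev.end:
            segments.append((ev.end, schedule[i + 1].start, None))

    t_rel = np.arange(n) / rate
    for seg_start, seg_end, activity in segments:
        i0 = max(int(np.ceil((seg_start - start) * rate - 1e-9)), 0)
        i1 = min(int(np.ceil((seg_end - start) * rate - 1e-9)), n)
        if i1 <= i0:
            continue
        orient, amp, freq = _site_params(site, activity, cfg, dominant)
        label = "gap" if activity is None else activity.value
        rng_a = stream(cfg.seed, "signal", subject.subject_id, site, label)
        orient = (
            orient
            + subject.orient_jitter[site]
            + rng_a.normal(0.0, cfg.activity_orient_sigma, size=3)
        )
        amp = amp * subject.amp_mult[site] * float(rng_a.lognormal(0.0, act_sigma))
        phase = float(rng_a.uniform(0.0, 2.0 * np.pi))
        mod_phase = float(rng_a.uniform(0.0, 2.0 * np.pi))
        direction = _osc_direction(orient)
        tt = t_rel[i0:i1]
        envelope = 1.0 + cfg.amp_modulation * np.sin(
            2.0 * np.pi * tt / 120.0 + mod_phase
        )
        wave = amp * envelope * np.sin(2.0 * np.pi * freq * tt + phase)
        sig[i0:i1] = orient[None, :] + wave[:, None] * direction[None, :]
    sig += rng_noise.normal(0.0, noise_sd, size=sig.shape)
    return SignalRecording(subject.subject_id, site, rate, start, sig)


@dataclass
class Cohort:
    """A generated cohort: profiles and schedules, with recordings
    materialized on demand (signals are large; schedules are not)."""

    cfg: GeneratorConfig
    profiles: dict[str, SubjectProfile]
    schedules: dict[str, list[ActivityEvent]]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.profiles)

    def recording(self, subject_id: str, site: str) -> SignalRecording:
        return simulate_signals(
            self.schedules[subject_id], self.profiles[subject_id], site, self.cfg
        )

    def write(self, out_dir: str | Path) -> dict:
        """Emit the directory tree (simple-dialect signal CSVs + annotation
        CSVs) and a manifest listing every artifact with its generation
        seed.  Returns the manifest."""
        out = Path(out_dir)
        (out / "signals").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(parents=True, exist_ok=True)
        artifacts = []
        for sid in self.subject_ids:
            ann_path = out / "annotations" / f"{sid}.csv"
            write_annotation_csv({sid: self.schedules[sid]}, ann_path)
            artifacts.append({
                "path": str(ann_path.relative_to(out)),
                "kind": "annotation",
                "subject": sid,
                "seed": substream_seed(self.cfg.seed, "schedule", sid),
            })
            for site in SITES:
                sig_path = out / "signals" / f"{sid}_{site}.csv"
                write_raw_csv(self.recording(sid, site), sig_path)
                artifacts.append({
                    "path": str(sig_path.relative_to(out)),
                    "kind": "signal",
                    "subject": sid,
                    "site": site,
                    "seed": substream_seed(
                        self.cfg.seed, "signal", sid, site, "noise"
                    ),
                })
        manifest = {
            "format_version": 1,
            "root_seed": int(self.cfg.seed),
            "n_subjects": len(self.profiles),
            "config": _config_dict(self.cfg),
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["duration_bounds_min"] = list(d["duration_bounds_min"])
    d["gap_bounds_s"] = list(d["gap_bounds_s"])
    return d


def generate_cohort(
    cfg: GeneratorConfig, out_dir: str | Path | None = None
) -> Cohort:
    """Generate a full synthetic cohort (schedules + per-site recordings).

    With ``out_dir`` set, also writes the directory tree and manifest.
    """
    if cfg.n_subjects < 2:
        raise ConfigError("n_subjects must be >= 2")
    profiles = {}
    schedules = {}
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:02d}"
        profiles[sid] = make_profile(cfg, sid)
        schedules[sid] = simulate_schedule(cfg, sid)
    cohort = Cohort(cfg, profiles, schedules)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
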