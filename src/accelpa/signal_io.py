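"""Raw tri-axial accelerometer recordings: containers, CSV I/O, resampling.

A recording is represented as ``(subject, site, rate, start_time, samples)``;
per-sample timestamps are validated on read and then discarded, so the implied
time of sample *i* is always ``start_time + i / rate``.  Two file dialects are
supported: the package's own "simple" dialect (metadata comment block + ISO
timestamps) and read-only tolerant parsing of the ActiGraph RAW CSV export.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    SignalFormatError,
    SignalParseError,
    SignalTimingError,
    UnsupportedRateError,
)

logger = logging.getLogger(__name__)

SITES = ("hip", "thigh", "left_wrist", "right_wrist")

SIMPLE_HEADER = "timestamp_iso8601,ax_g,ay_g,az_g"


def parse_iso8601(s: str) -> float:
    """Parse an ISO-8601 timestamp to POSIX seconds (naive times = UTC)."""
    dt = datetime.fromisoformat(str(s).strip())
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def format_iso8601(t: float) -> str:
    """Format POSIX seconds as an ISO-8601 UTC timestamp (µs resolution)."""
    return datetime.fromtimestamp(float(t), tz=timezone.utc).isoformat()


@dataclass(frozen=True, eq=False)
class SignalRecording:
    """One wear-site tri-axial acceleration stream for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier; immutable.
    site : str
        Wear site, one of ``hip``, ``thigh``, ``left_wrist``, ``right_wrist``.
    sampling_rate_hz : float
        Sampling rate in Hz (20 or 40 in this study design).
    start_time : float
        Absolute time of the first sample, POSIX seconds (UTC).
    samples : ndarray of shape (n, 3)
        Acceleration triples ``(ax, ay, az)`` in g units.
    """

    subject_id: str
    site: str
    sampling_rate_hz: float
    start_time: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.size == 0:
            arr = arr.reshape(0, 3)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"samples must have shape (n, 3), got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "start_time", float(self.start_time))
        object.__setattr__(self, "sampling_rate_hz", float(self.sampling_rate_hz))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds, n / rate."""
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Implied per-sample POSIX times, start_time + i / rate."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate_hz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.site == other.site
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.start_time == other.start_time
            and np.array_equal(self.samples, other.samples)
        )

    def allclose(self, other: "SignalRecording", atol: float = 1e-6) -> bool:
        """Field-wise equality with an absolute tolerance on axis values."""
        return (
            self.subject_id == other.subject_id
            and self.site == other.site
            and self.sampling_rate_hz == other.sampling_rate_hz
            and abs(self.start_time - other.start_time) < 1e-6
            and self.samples.shape == other.samples.shape
            and np.allclose(self.samples, other.samples, atol=atol, rtol=0.0)
        )


# ---------------------------------------------------------------------------
# simple dialect
# ---------------------------------------------------------------------------

def _read_simple(path: Path) -> SignalRecording:
    meta: dict[str, str] = {}
    header_line = None
    data_start = 0
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*=\s*(.+)", stripped)
            if m:
                meta[m.group(1)] = m.group(2).strip()
            continue
        header_line = stripped
        data_start = i + 1
        break
    if header_line is None or header_line != SIMPLE_HEADER:
        raise SignalFormatError(
            f"{path}: expected header {SIMPLE_HEADER!r}, "
            f"got {header_line!r} at line {data_start}"
        )
    for key in ("subject", "site", "rate_hz"):
        if key not in meta:
            raise SignalFormatError(f"{path}: missing metadata line '# {key}=...'")
    rate = float(meta["rate_hz"])

    body = "".join(lines[data_start:])
    if not body.strip():
        start = parse_iso8601(meta["start"]) if "start" in meta else 0.0
        return SignalRecording(meta["subject"], meta["site"], rate, start,
                               np.empty((0, 3)))

    df = pd.read_csv(io.StringIO(header_line + "\n" + body))
    axes = np.empty((len(df), 3))
    for j, col in enumerate(("ax_g", "ay_g", "az_g")):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise SignalParseError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"{col}, data row {bad[0]}"
            )
        axes[:, j] = vals

    ts = df["timestamp_iso8601"].map(parse_iso8601).to_numpy()
    period = 1.0 / rate
    if len(ts) > 1:
        dt = np.diff(ts)
        off = np.abs(dt - period)
        if np.any(off > 0.1 * period):
            k = int(np.argmax(off))
            raise SignalTimingError(
                f"{path}: non-uniform sample spacing at data row {k + 1}: "
                f"dt={dt[k]:.6f}s vs expected {period:.6f}s (±10%)"
            )
    return SignalRecording(meta["subject"], meta["site"], rate, float(ts[0]), axes)


# ---------------------------------------------------------------------------
# ActiGraph RAW dialect (read only)
# ---------------------------------------------------------------------------

def _read_actigraph_raw(path: Path, subject_id: str, site: str) -> SignalRecording:
    # Header block: lines framed by rows of dashes; fields keyed on labels
    # ("Start Time", "Start Date", "... at NN Hz"), never on line numbers.
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    rate = None
    start_time_s = None
    start_date_s = None
    data_start = None
    dashed_seen = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith("---"):
            dashed_seen += 1
            if dashed_seen >= 2:
                data_start = i + 1
                break
            m = re.search(r"at\s+(\d+(?:\.\d+)?)\s*Hz", stripped)
            if m:
                rate = float(m.group(1))
            continue
        m = re.search(r"at\s+(\d+(?:\.\d+)?)\s*Hz", stripped)
        if m:
            rate = float(m.group(1))
        m = re.match(r"Start Time[,\s]+([\d:]+)", stripped)
        if m:
            start_time_s = m.group(1)
        m = re.match(r"Start Date[,\s]+([\d/\-]+)", stripped)
        if m:
            start_date_s = m.group(1)
    if data_start is None or rate is None:
        raise SignalFormatError(
            f"{path}: could not locate ActiGraph RAW header block or sample rate"
        )
    if start_time_s is None or start_date_s is None:
        raise SignalFormatError(f"{path}: missing Start Time / Start Date fields")
    try:
        mth, day, year = (int(x) for x in re.split(r"[/\-]", start_date_s))
    except ValueError as exc:
        raise SignalFormatError(f"{path}: unparseable Start Date {start_date_s!r}") from exc
    hh, mm, ss = (int(x) for x in start_time_s.split(":"))
    start = datetime(year, mth, day, hh, mm, ss, tzinfo=timezone.utc).timestamp()

    body_lines = [ln for ln in lines[data_start:] if ln.strip()]
    if body_lines and re.search(r"[A-Za-z]", body_lines[0]):
        body_lines = body_lines[1:]  # optional column-name row
    if not body_lines:
        return SignalRecording(subject_id, site, rate, start, np.empty((0, 3)))
    try:
        arr = np.loadtxt(io.StringIO("".join(body_lines)), delimiter=",", ndmin=2)
    except ValueError as exc:
        raise SignalParseError(f"{path}: unparseable data row ({exc})") from exc
    if arr.shape[1] != 3:
        raise SignalFormatError(
            f"{path}: expected 3 acceleration columns, got {arr.shape[1]}"
        )
    return SignalRecording(subject_id, site, rate, start, arr)


def read_raw_csv(
    path: str | Path,
    dialect: str = "simple",
    subject_id: str = "unknown",
    site: str = "hip",
) -> SignalRecording:
    """Read a raw tri-axial signal CSV.

    ``dialect="simple"`` is the package's own format (metadata comment block,
    then ``timestamp_iso8601,ax_g,ay_g,az_g`` rows); subject and site come
    from the file.  ``dialect="actigraph_raw"`` parses the ActiGraph RAW CSV
    export, which carries neither subject nor site, so those are taken from
    the keyword arguments.

    Timestamps are validated to be uniformly spaced at 1/rate (±10% of one
    sample period) and then discarded in favour of ``(start_time, rate)``.
    """
    path = Path(path)
    if dialect == "simple":
        return _read_simple(path)
    if dialect == "actigraph_raw":
        return _read_actigraph_raw(path, subject_id, site)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_raw_csv(rec: SignalRecording, path: str | Path) -> None:
    """Write a recording in the simple dialect (UTF-8, LF, '.' decimals).

    Axis values are written with 6 decimal places, so a write→read round trip
    reproduces the recording to 1e-6 g.
    """
    path = Path(path)
    times = rec.times()
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# subject={rec.subject_id}\n")
            fh.write(f"# site={rec.site}\n")
            fh.write(f"# rate_hz={rec.sampling_rate_hz:g}\n")
            fh.write(f"# start={format_iso8601(rec.start_time)}\n")
            fh.write(SIMPLE_HEADER + "\n")
            for t, (x, y, z) in zip(times, rec.samples):
                fh.write(f"{format_iso8601(t)},{x:.6f},{y:.6f},{z:.6f}\n")
    except OSError as exc:
        raise OSError(f"failed writing signal CSV to {path}: {exc}") from exc


def reintegrate_to_20hz(rec: SignalRecording) -> SignalRecording:
    """Reintegrate a 40 Hz recording to 20 Hz by non-overlapping pair means.

    Each output sample is the per-axis arithmetic mean of one consecutive,
    non-overlapping pair of input samples, which halves the sample count and
    preserves the per-axis mean exactly.  A 20 Hz input is returned unchanged;
    an odd trailing sample at 40 Hz is dropped with a logged warning.
    """
    if rec.sampling_rate_hz == 20:
        return rec
    if rec.sampling_rate_hz != 40:
        raise UnsupportedRateError(
            f"cannot reintegrate rate {rec.sampling_rate_hz} Hz (need 40 or 20)"
        )
    n = rec.n_samples
    if n % 2:
        logger.warning(
            "dropping odd trailing sample during 40->20 Hz reintegration "
            "(subject=%s site=%s)", rec.subject_id, rec.site,
        )
        n -= 1
    pairs = rec.samples[:n].reshape(n // 2, 2, 3)
    return SignalRecording(
        rec.subject_id, rec.site, 20.0, rec.start_time, pairs.mean(axis=1)
    )


def trim(rec: SignalRecording, t0: float, t1: float) -> SignalRecording:
    """Restrict a recording to samples with implied time in [t0, t1).

    The half-open convention means a sample at exactly ``t1`` is excluded,
    preventing double counting at window boundaries.  An interval fully
    outside the recording yields an empty recording, not an error.
    """
    if not t0 < t1:
        raise ValueError(f"need t0 < t1, got {t0} >= {t1}")
    rate = rec.sampling_rate_hz
    i0 = int(np.ceil((t0 - rec.start_time) * rate - 1e-9))
    i1 = int(np.ceil((t1 - rec.start_time) * rate - 1e-9))
    i0 = max(i0, 0)
    i1 = min(max(i1, i0), rec.n_samples)
    return SignalRecording(
        rec.subject_id,
        rec.site,
        rate,
        rec.start_time + i0 / rate,
        rec.samples[i0:i1].copy(),
    )
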