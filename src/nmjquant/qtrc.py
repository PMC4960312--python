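"""Text formats for voltage-clamp sweeps and amplitude tables, plus the
recording-acceptance gate.

The QTRC sweep format is a plain UTF-8 text file:

* header lines starting with ``#`` of the form ``key=value``; mandatory keys
  are ``sample_rate_hz``, ``ca_mm`` and ``holding_current_na``; the key
  ``stim_times_s`` holds a comma-separated list (possibly empty); unknown
  keys are preserved in :attr:`TraceSweep.meta`;
* then one current sample (nA, inward negative) per line.

Amplitude tables are tab-separated with one row per measured event
(``nmj_id, genotype, protocol, ca_mm, stim_index, event_time_s, kind,
amplitude_na``) so simulated and detected events are interchangeable
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Column order of the shared amplitude-table format.
EVENT_COLUMNS = [
    "nmj_id",
    "genotype",
    "protocol",
    "ca_mm",
    "stim_index",
    "event_time_s",
    "kind",
    "amplitude_na",
]

MANDATORY_HEADER_KEYS = ("sample_rate_hz", "ca_mm", "holding_current_na")

#: Holding-current rejection bound, nA (strictly greater rejects).
HOLDING_REJECT_NA = 10.0
#: Below this magnitude a recording is flagged "low-holding" (reporting only).
HOLDING_LOW_NA = 5.0


@dataclass
class TraceSweep:
    """One voltage-clamp current sweep (muscle held at -80 mV, inward
    currents negative) with stimulus times and acquisition metadata."""

    sample_rate_hz: float
    current_na: np.ndarray
    stim_times_s: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current_na = np.asarray(self.current_na, dtype=float)
        self.stim_times_s = np.asarray(self.stim_times_s, dtype=float)
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.current_na.ndim != 1:
            raise ValidationError("current_na must be one-dimensional")
        if not np.all(np.isfinite(self.current_na)):
            raise ValidationError("current samples must be finite")
        if self.stim_times_s.size:
            if np.any(np.diff(self.stim_times_s) <= 0):
                raise ValidationError("stim_times_s must be strictly increasing")
            if self.stim_times_s[0] < 0 or self.stim_times_s[-1] > self.duration_s:
                raise ValidationError("stim_times_s must lie within the sweep")

    @property
    def duration_s(self) -> float:
        return self.current_na.size / self.sample_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.current_na.size) / self.sample_rate_hz


def write_sweep(sweep: TraceSweep, path) -> None:
    """Serialize a sweep to the QTRC text format (samples at 12 significant
    digits, so a round trip is lossless to well below 1e-9 nA)."""
    path = Path(path)
    lines = []
    header = {"sample_rate_hz": sweep.sample_rate_hz}
    header.update(sweep.meta)
    for key in ("ca_mm", "holding_current_na"):
        if key not in header:
            raise ValidationError(f"sweep meta missing mandatory key {key!r}")
    for key, value in header.items():
        lines.append(f"#{key}={value}")
    lines.append("#stim_times_s=" + ",".join(f"{t:.9g}" for t in sweep.stim_times_s))
    for x in sweep.current_na:
        lines.append(f"{x:.12g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sweep(path) -> TraceSweep:
    """Parse a QTRC file into a validated :class:`TraceSweep`.

    Unknown header keys are kept in ``meta`` (forward compatibility).
    Raises :class:`FormatError` naming the missing mandatory key, or citing
    the line number of a non-numeric sample.
    """
    path = Path(path)
    meta: dict = {}
    stim_times: list[float] = []
    samples: list[float] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:]
                if "=" not in body:
                    raise FormatError(f"{path}: malformed header line {lineno}: {line!r}")
                key, _, value = body.partition("=")
                key = key.strip()
                if key == "stim_times_s":
                    value = value.strip()
                    stim_times = [float(v) for v in value.split(",")] if value else []
                else:
                    meta[key] = _coerce(value.strip())
            else:
                try:
                    samples.append(float(line))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric sample on line {lineno}: {line!r}"
                    ) from None
    for key in MANDATORY_HEADER_KEYS:
        if key not in meta:
            raise FormatError(f"{path}: missing mandatory header key {key!r}")
    rate = float(meta.pop("sample_rate_hz"))
    return TraceSweep(
        sample_rate_hz=rate,
        current_na=np.array(samples, dtype=float),
        stim_times_s=np.array(stim_times, dtype=float),
        meta=meta,
    )


def _coerce(value: str):
    """Best-effort numeric coercion for header values."""
    try:
        f = float(value)
    except ValueError:
        return value
    if f.is_integer() and "." not in value and "e" not in value.lower():
        return int(f)
    return f


@dataclass(frozen=True)
class QCDecision:
    """Outcome of the recording-acceptance gate."""

    accepted: bool
    low_holding: bool
    holding_current_na: float
    reason: str


def recording_qc(record) -> QCDecision:
    """Apply the holding-current acceptance rule.

    A recording is rejected iff |holding current| exceeds 10 nA (strictly;
    exactly 10 nA is accepted). Accepted recordings with |holding| < 5 nA are
    flagged ``low_holding`` — a reporting convention, not a gate.

    ``record`` may be a :class:`TraceSweep`, a mapping with a
    ``holding_current_na`` entry, or a bare number.
    """
    if isinstance(record, TraceSweep):
        holding = record.meta.get("holding_current_na")
    elif isinstance(record, (int, float, np.floating, np.integer)):
        holding = record
    else:
        try:
            holding = record["holding_current_na"]
        except (KeyError, TypeError):
            holding = None
    if holding is None or (isinstance(holding, float) and math.isnan(holding)):
        raise ValidationError("holding_current_na is required for recording QC")
    holding = float(holding)
    mag = abs(holding)
    if mag > HOLDING_REJECT_NA:
        return QCDecision(False, False, holding, f"|holding| {mag:g} nA > {HOLDING_REJECT_NA:g} nA")
    return QCDecision(
        True,
        mag < HOLDING_LOW_NA,
        holding,
        "accepted" + (", low-holding" if mag < HOLDING_LOW_NA else ""),
    )


def write_events(events: pd.DataFrame, path) -> None:
    """Write an amplitude table (tab-separated, fixed column order)."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"amplitude table missing columns: {missing}")
    events.loc[:, EVENT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: amplitude table missing columns: {missing}")
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "path" not in df.columns:
        raise FormatError(f"{path}: manifest missing 'path' column")
    if df["path"].duplicated().any():
        raise ValidationError(f"{path}: duplicate paths in manifest")
    if check_paths:
        base = Path(path).parent
        for p in df["path"]:
            candidate = Path(p)
            if not candidate.is_absolute():
                candidate = base / candidate
            if not candidate.exists():
                raise ValidationError(f"manifest references missing file: {p}")
    return df
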