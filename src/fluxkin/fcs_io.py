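"""Reading, writing and merging of FCS kinetic recordings.

A calcium-flux measurement consists of two FCS files per sample: a short
baseline recording (resting Fluo-4 signal) and a post-activation recording
started after the activating agent was added with the sample tube removed
from the instrument.  The wall-clock gap between adding the agent and
restarting acquisition is measured by the operator and supplied when the two
files are appended onto one time axis; the merged curve is standardized to
end at ``t_end`` (default 780 s = 60 s baseline + 720 s activation).

Only FCS 3.0/3.1 list-mode files with float or integer data are supported;
values are assumed compensated and linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventStream",
    "KineticRecording",
    "FCSFormatError",
    "read_fcs",
    "write_fcs",
    "append_recordings",
    "DEFAULT_T_END",
]

logger = logging.getLogger(__name__)

DEFAULT_T_END = 780.0
TIME_CHANNEL = "Time"

_HEADER_LEN = 58
_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")


class FCSFormatError(ValueError):
    """Raised when a file violates the supported subset of the FCS standard."""


@dataclass
class EventStream:
    """Per-event channel values from a single FCS file.

    ``events`` holds one column per channel; the time column (if present) is
    in seconds, already converted with the file's $TIMESTEP keyword.
    ``acquisition_role`` records what the tube was: ``baseline``,
    ``activation``, ``fmo`` or ``unstained``.
    """

    events: pd.DataFrame
    channel_names: list[str]
    acquisition_role: str = "baseline"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.channel_names if c not in self.events.columns]
        if missing:
            raise ValueError(f"channels missing from event table: {missing}")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def times(self) -> np.ndarray:
        if TIME_CHANNEL not in self.events.columns:
            raise FCSFormatError("stream has no time channel")
        return self.events[TIME_CHANNEL].to_numpy(float)


@dataclass
class KineticRecording:
    """Baseline + activation streams merged on one standardized time axis.

    t = 0 at the start of baseline acquisition; ``t_act`` is when the
    activating agent met the cells (baseline duration + measured gap).
    Events beyond ``t_end`` are dropped at append time.
    """

    events: pd.DataFrame
    t_act: float
    t_end: float
    gap_seconds: float
    baseline_duration: float
    source_ids: tuple[str, str] = ("baseline", "activation")
    n_dropped: int = 0

    @property
    def n_events(self) -> int:
        return len(self.events)

    def times(self) -> np.ndarray:
        return self.events[TIME_CHANNEL].to_numpy(float)

    @property
    def channel_names(self) -> list[str]:
        return list(self.events.columns)


# ---------------------------------------------------------------------------
# FCS parsing


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[0:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    # Doubled delimiters inside values are rare; rejoin empty splits.
    fields: list[str] = []
    i = 0
    while i < len(parts):
        piece = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            piece += delim + parts[i + 2]
            i += 2
        fields.append(piece)
        i += 1
    if len(fields) % 2:
        fields = fields[:-1]
    return {fields[j].strip(): fields[j + 1] for j in range(0, len(fields), 2)}


def _dtype_from_keywords(meta: Mapping[str, str], n_par: int) -> np.dtype:
    datatype = meta.get("$DATATYPE", "").upper()
    byteord = meta.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        return np.dtype(endian + "f4")
    if datatype == "D":
        return np.dtype(endian + "f8")
    if datatype == "I":
        bits = {int(meta.get(f"$P{i}B", "0")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) not in (8, 16, 32):
            raise FCSFormatError(
                "integer data requires a uniform $PnB of 8, 16 or 32 bits"
            )
        return np.dtype(f"{endian}u{next(iter(bits)) // 8}")
    raise FCSFormatError(f"unsupported $DATATYPE {datatype!r} (only F, D, I)")


def read_fcs(
    path: str | Path,
    acquisition_role: str = "baseline",
    time_channel: str | None = None,
) -> EventStream:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventStream`.

    The time parameter (identified by its $PnN short name, default ``Time``,
    case-insensitive, overridable via ``time_channel``) is converted to
    seconds using the file's $TIMESTEP keyword.

    Raises
    ------
    FCSFormatError
        For unsupported versions, data types or modes, or when no time
        channel can be identified (kinetic analysis is impossible without
        one).
    """
    path = Path(path)
    raw = path.read_bytes()
    version = raw[0:6].decode("latin-1")
    if version not in _SUPPORTED_VERSIONS:
        raise FCSFormatError(
            f"unsupported FCS version {version!r} (need FCS 3.0 or 3.1)"
        )
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    meta = _parse_text_segment(raw[text_start : text_end + 1])

    mode = meta.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"unsupported $MODE {mode!r} (only list mode)")
    n_par = int(meta["$PAR"])
    n_tot = int(meta["$TOT"])
    data_start = int(meta.get("$BEGINDATA") or raw[26:34])
    data_end = int(meta.get("$ENDDATA") or raw[34:42])

    dtype = _dtype_from_keywords(meta, n_par)
    n_values = n_par * n_tot
    buf = raw[data_start : data_start + n_values * dtype.itemsize]
    if len(buf) < n_values * dtype.itemsize:
        raise FCSFormatError("data segment shorter than $PAR * $TOT values")
    values = np.frombuffer(buf, dtype=dtype, count=n_values).reshape(n_tot, n_par)

    channels = [meta.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    events = pd.DataFrame(np.asarray(values, dtype=float), columns=channels)

    tname = _find_time_channel(channels, time_channel)
    timestep = float(meta.get("$TIMESTEP", 1.0))
    events[tname] = events[tname] * timestep
    if tname != TIME_CHANNEL:
        events = events.rename(columns={tname: TIME_CHANNEL})
        channels = [TIME_CHANNEL if c == tname else c for c in channels]

    return EventStream(
        events=events,
        channel_names=channels,
        acquisition_role=acquisition_role,
        metadata=dict(meta),
    )


def _find_time_channel(channels: Sequence[str], override: str | None) -> str:
    if override is not None:
        if override not in channels:
            raise FCSFormatError(f"time channel {override!r} not in panel {channels}")
        return override
    for c in channels:
        if c.lower() == "time":
            return c
    raise FCSFormatError(
        "no time channel found (no $PnN equals 'Time'); kinetic analysis "
        "is impossible without event times"
    )


def write_fcs(stream: EventStream, path: str | Path) -> Path:
    """Write an :class:`EventStream` as an FCS 3.1 list-mode file (float32).

    The time column is converted back to instrument ticks with the stream's
    $TIMESTEP keyword (default 1.0), so ``read_fcs(write_fcs(s))`` is the
    identity on event values up to float32 representation.
    """
    path = Path(path)
    if not stream.channel_names:
        raise ValueError("cannot write an FCS file with an empty channel list")
    channels = stream.channel_names
    data = stream.events[channels].to_numpy(float).copy()
    timestep = float(stream.metadata.get("$TIMESTEP", 1.0))
    if TIME_CHANNEL in channels:
        data[:, channels.index(TIME_CHANNEL)] /= timestep
    n_tot, n_par = data.shape

    meta: dict[str, str] = {
        k: v
        for k, v in stream.metadata.items()
        if not k.startswith("$P")
        and k
        not in {
            "$BEGINDATA", "$ENDDATA", "$BEGINANALYSIS", "$ENDANALYSIS",
            "$BEGINSTEXT", "$ENDSTEXT", "$NEXTDATA", "$TOT", "$PAR",
            "$DATATYPE", "$MODE", "$BYTEORD",
        }
    }
    meta.update(
        {
            "$DATATYPE": "F",
            "$MODE": "L",
            "$BYTEORD": "1,2,3,4",
            "$PAR": str(n_par),
            "$TOT": str(n_tot),
            "$NEXTDATA": "0",
            "$TIMESTEP": repr(timestep),
        }
    )
    for i, name in enumerate(channels, start=1):
        meta[f"$P{i}N"] = name
        meta[f"$P{i}B"] = "32"
        meta[f"$P{i}E"] = "0,0"
        col = data[:, i - 1]
        rng = float(np.max(col)) if n_tot else 0.0
        meta[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)

    delim = "/"
    # Offsets appear inside TEXT, so reserve fixed-width fields and fill in.
    placeholder = {"$BEGINDATA": "0" * 12, "$ENDDATA": "0" * 12,
                   "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
                   "$BEGINSTEXT": "0", "$ENDSTEXT": "0"}
    ordered = {**placeholder, **meta}

    def render(d: Mapping[str, str]) -> bytes:
        out = delim
        for k, v in d.items():
            v = v if v != "" else " "
            out += f"{k}{delim}{v}{delim}"
        return out.encode("latin-1")

    text = render(ordered)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + n_tot * n_par * 4 - 1 if n_tot else data_start
    ordered["$BEGINDATA"] = str(data_start).rjust(12, "0")
    ordered["$ENDDATA"] = str(data_end).rjust(12, "0")
    text = render(ordered)
    assert len(text) == text_end - text_start + 1

    def hfield(v: int) -> bytes:
        s = str(v)
        return (s if len(s) <= 8 else "0").rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        hfield(v) for v in (text_start, text_end,
                            data_start if data_end < 10**8 else 0,
                            data_end if data_end < 10**8 else 0, 0, 0)
    )
    assert len(header) == _HEADER_LEN

    payload = data.astype("<f4").tobytes()
    path.write_bytes(header + text + payload)
    return path


# ---------------------------------------------------------------------------
# Appending


def append_recordings(
    baseline: EventStream,
    activation: EventStream,
    gap_seconds: float,
    t_end: float = DEFAULT_T_END,
    truncate: bool = True,
) -> KineticRecording:
    """Merge a baseline and an activation stream onto one time axis.

    Activation event times are shifted by ``baseline_duration +
    gap_seconds``, where the baseline duration is the last baseline event
    time (robust to clock drift) and ``gap_seconds`` is the measured
    interval between adding the activating agent and restarting
    acquisition.  Events landing beyond ``t_end`` are dropped (logged)
    unless ``truncate=False``.
    """
    if gap_seconds < 0:
        raise ValueError("gap_seconds must be non-negative")
    mismatch = set(baseline.channel_names) ^ set(activation.channel_names)
    if mismatch:
        raise ValueError(f"channel panel mismatch between files: {sorted(mismatch)}")

    t_base = baseline.times()
    baseline_duration = float(t_base.max()) if len(t_base) else 0.0
    if baseline_duration <= 0:
        raise ValueError("baseline recording spans no positive duration")
    t_act = baseline_duration + gap_seconds
    if t_end <= t_act:
        raise ValueError(f"t_end={t_end} must exceed t_act={t_act}")

    act = activation.events.copy()
    if len(act) == 0:
        logger.warning("activation stream is empty; recording is baseline only")
    else:
        act[TIME_CHANNEL] = act[TIME_CHANNEL].to_numpy(float) + t_act

    merged = pd.concat([baseline.events, act], ignore_index=True)
    n_before = len(merged)
    if truncate:
        merged = merged[merged[TIME_CHANNEL].to_numpy(float) <= t_end]
        merged = merged.reset_index(drop=True)
    n_dropped = n_before - len(merged)
    if n_dropped:
        logger.info("dropped %d events beyond t_end=%.1f s", n_dropped, t_end)

    return KineticRecording(
        events=merged,
        t_act=t_act,
        t_end=float(t_end),
        gap_seconds=float(gap_seconds),
        baseline_duration=baseline_duration,
        source_ids=(
            baseline.metadata.get("$FIL", "baseline"),
            activation.metadata.get("$FIL", "activation"),
        ),
        n_dropped=n_dropped,
    )
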