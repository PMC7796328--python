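"""Reading and writing FCS 3.1 event streams.

Time-lapse recordings are plain list-mode FCS files: one row per detected
cellular event carrying the acquisition time and the pulse-area/height
intensities of the scatter and fluorescence detectors.  This module maps
instrument parameter names (BD Accuri conventions: ``Time``, ``FSC-A``,
``FSC-H``, ``SSC-A``, ``FL1-A``, ``FL4-A``) onto the pipeline's channel
roles and converts the raw time words into seconds using the file's
declared ``$TIMESTEP``.

Only the subset of FCS 3.1 needed for kinetic analysis is supported:
single dataset, list mode, 32-bit float data, linear amplification.
Compensation and display transforms are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "ChannelMap",
    "FcsFormatError",
    "MissingChannelError",
    "read_events",
    "write_events",
    "inspect_fcs",
    "DEFAULT_CHANNEL_ROLES",
    "DEFAULT_TIMESTEP_S",
]

#: instrument parameter short name -> pipeline role
DEFAULT_CHANNEL_ROLES: dict[str, str] = {
    "Time": "time",
    "FSC-A": "fsc_a",
    "FSC-H": "fsc_h",
    "SSC-A": "ssc_a",
    "FL1-A": "fl1",
    "FL4-A": "fl4",
}

#: roles every recording must resolve, with the human-readable dye name
REQUIRED_ROLES: dict[str, str] = {
    "time": "acquisition time",
    "fsc_a": "forward scatter area",
    "fsc_h": "forward scatter height",
    "ssc_a": "side scatter area",
    "fl1": "green fluorescence (Fluo3/BCECF)",
    "fl4": "far-red fluorescence (disc)",
}

#: role -> EventTable column
ROLE_COLUMNS: dict[str, str] = {
    "time": "time_s",
    "fsc_a": "fsc_a",
    "fsc_h": "fsc_h",
    "ssc_a": "ssc_a",
    "fl1": "fl1_a",
    "fl4": "fl4_a",
}

#: assumed when a file declares no $TIMESTEP (a convention, logged loudly)
DEFAULT_TIMESTEP_S = 0.01

_INTENSITY_COLUMNS = ("fsc_a", "fsc_h", "ssc_a", "fl1_a", "fl4_a")


class FcsFormatError(ValueError):
    """The file does not parse as the supported FCS subset."""


class MissingChannelError(FcsFormatError):
    """A required channel role could not be resolved in the file."""


@dataclass
class ChannelMap:
    """Mapping from instrument parameter names to pipeline roles.

    Parameters
    ----------
    roles
        ``{parameter short name ($PnN): role}``; roles are the keys of
        :data:`REQUIRED_ROLES`.
    timestep_s
        Seconds per raw time-channel tick.  ``None`` honours the file's
        declared ``$TIMESTEP`` keyword (falling back to
        :data:`DEFAULT_TIMESTEP_S` with a warning when absent).
    """

    roles: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))
    timestep_s: float | None = None

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, role in self.roles.items():
            if role in seen:
                raise ValueError(
                    f"role {role!r} mapped to both {seen[role]!r} and {name!r}"
                )
            seen[role] = name
        if self.timestep_s is not None and not self.timestep_s > 0:
            raise ValueError("timestep_s must be positive")

    def parameter_for(self, role: str) -> str | None:
        for name, r in self.roles.items():
            if r == role:
                return name
        return None


class EventTable:
    """Per-event acquisition record: time plus five intensity channels.

    The universal carrier between pipeline stages.  Wraps a
    :class:`pandas.DataFrame` with columns ``time_s``, ``fsc_a``,
    ``fsc_h``, ``ssc_a``, ``fl1_a``, ``fl4_a`` and, for simulated data,
    an optional ``label`` column with per-event ground-truth classes.

    Invariants enforced on construction: ``time_s`` is non-decreasing and
    non-negative, all intensities are non-negative and finite.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in ("time_s", *_INTENSITY_COLUMNS) if c not in data.columns]
        if missing:
            raise ValueError(f"EventTable missing columns: {missing}")
        t = data["time_s"].to_numpy()
        if len(t):
            if not np.all(np.isfinite(t)) or t[0] < 0:
                raise ValueError("time_s must be finite and non-negative")
            if np.any(np.diff(t) < 0):
                raise ValueError("time_s must be non-decreasing")
            for col in _INTENSITY_COLUMNS:
                v = data[col].to_numpy()
                if not np.all(np.isfinite(v)) or np.any(v < 0):
                    raise ValueError(f"{col} must be finite and non-negative")
        self.data = data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    @property
    def duration_s(self) -> float:
        return float(self.data["time_s"].iloc[-1]) if len(self) else 0.0

    @property
    def labels(self) -> np.ndarray | None:
        if "label" in self.data.columns:
            return self.data["label"].to_numpy()
        return None

    def select(self, mask: np.ndarray) -> "EventTable":
        """Row subset preserving order (used by the gates)."""
        return EventTable(self.data.loc[np.asarray(mask, bool)].reset_index(drop=True))

    def between(self, start_s: float, end_s: float) -> "EventTable":
        t = self["time_s"]
        return self.select((t >= start_s) & (t < end_s))

    @classmethod
    def from_arrays(cls, time_s, fsc_a, fsc_h, ssc_a, fl1_a, fl4_a, label=None):
        cols = {
            "time_s": np.asarray(time_s, dtype=np.float64),
            "fsc_a": np.asarray(fsc_a, dtype=np.float32),
            "fsc_h": np.asarray(fsc_h, dtype=np.float32),
            "ssc_a": np.asarray(ssc_a, dtype=np.float32),
            "fl1_a": np.asarray(fl1_a, dtype=np.float32),
            "fl4_a": np.asarray(fl4_a, dtype=np.float32),
        }
        if label is not None:
            cols["label"] = pd.Categorical(label)
        return cls(pd.DataFrame(cols))

    def equals(self, other: "EventTable") -> bool:
        cols = ["time_s", *_INTENSITY_COLUMNS]
        return self.data[cols].equals(other.data[cols])


# ---------------------------------------------------------------------------
# FCS 3.1 writing

_DELIM = "/"
_WRITE_ORDER = ("fsc_a", "fsc_h", "ssc_a", "fl1", "fl4", "time")


def _keyword_text(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        if _DELIM in key or _DELIM in str(value):
            raise FcsFormatError("delimiter inside keyword not supported")
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("ascii")


def _write_fcs(path, parameter_names, data, timestep_s):
    """Emit a single-dataset FCS 3.1 file (float32 list mode, little-endian)."""
    data = np.asarray(data, dtype="<f4")
    n_events, n_par = data.shape
    if n_par != len(parameter_names):
        raise ValueError("column/parameter count mismatch")
    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # zero-padded so the TEXT length does not depend on the values
        "$BEGINDATA": "%012d" % 0,
        "$ENDDATA": "%012d" % 0,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$TIMESTEP": repr(float(timestep_s)),
    }
    for i, name in enumerate(parameter_names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(2**24))

    header_len = 58
    text = _keyword_text(keywords)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1
    keywords["$BEGINDATA"] = "%012d" % data_begin
    keywords["$ENDDATA"] = "%012d" % data_end
    text = _keyword_text(keywords)

    def _off(x: int) -> bytes:
        return b"%8d" % x if x <= 99_999_999 else b"%8d" % 0

    header = b"FCS3.1    " + b"".join(
        _off(x) for x in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def write_events(
    events: EventTable,
    path,
    channel_map: ChannelMap | None = None,
    timestep_s: float = DEFAULT_TIMESTEP_S,
) -> None:
    """Write an :class:`EventTable` as a standard-compliant FCS 3.1 file.

    Intensities are stored as 32-bit floats (bit-exact round trip for
    float32 inputs); time is stored in ticks of ``timestep_s`` and the
    file declares ``$TIMESTEP`` accordingly.  Ground-truth labels, if
    present, are not representable in FCS and are dropped (the simulator
    writes them to a JSON sidecar instead).

    Raises
    ------
    ValueError
        For an empty table (zero-event files are rejected).
    """
    if len(events) == 0:
        raise ValueError("refusing to write a zero-event FCS file")
    if not timestep_s > 0:
        raise ValueError("timestep_s must be positive")
    cmap = channel_map or ChannelMap()
    names = []
    columns = []
    for role in _WRITE_ORDER:
        name = cmap.parameter_for(role)
        if name is None:
            raise MissingChannelError(f"channel map resolves no parameter for role {role!r}")
        names.append(name)
        if role == "time":
            columns.append(events["time_s"] / timestep_s)
        else:
            columns.append(events[ROLE_COLUMNS[role]])
    _write_fcs(path, names, np.column_stack(columns), timestep_s)


# ---------------------------------------------------------------------------
# FCS reading


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    if not body.endswith(delim):
        raise FcsFormatError("TEXT segment not terminated by delimiter")
    tokens = body[1:-1].split(delim)
    if len(tokens) % 2:
        raise FcsFormatError("odd number of TEXT tokens (escaped delimiters unsupported)")
    return {
        tokens[i].strip(): tokens[i + 1]
        for i in range(0, len(tokens), 2)
        if tokens[i].strip()
    }


def _read_raw(path) -> tuple[dict[str, str], np.ndarray]:
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58 or not blob[:3] == b"FCS":
        raise FcsFormatError(f"{path}: not an FCS file (missing FCS header)")
    try:
        offsets = [int(blob[10 + 8 * i : 18 + 8 * i]) for i in range(4)]
    except ValueError as exc:
        raise FcsFormatError(f"{path}: malformed header offsets") from exc
    text_begin, text_end, data_begin, data_end = offsets
    keywords = _parse_text_segment(blob[text_begin : text_end + 1])
    if data_begin == 0:
        try:
            data_begin = int(keywords["$BEGINDATA"])
            data_end = int(keywords["$ENDDATA"])
        except (KeyError, ValueError) as exc:
            raise FcsFormatError(f"{path}: no usable DATA offsets") from exc
    for key in ("$PAR", "$TOT", "$DATATYPE", "$MODE", "$BYTEORD"):
        if key not in keywords:
            raise FcsFormatError(f"{path}: required keyword {key} absent")
    if keywords["$MODE"].strip().upper() != "L":
        raise FcsFormatError("only list-mode ($MODE/L) files are supported")
    if keywords["$DATATYPE"].strip().upper() != "F":
        raise FcsFormatError("only float ($DATATYPE/F) files are supported")
    byteord = keywords["$BYTEORD"].strip()
    if byteord == "1,2,3,4":
        dtype = "<f4"
    elif byteord == "4,3,2,1":
        dtype = ">f4"
    else:
        raise FcsFormatError(f"unsupported $BYTEORD {byteord!r}")
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    for i in range(1, n_par + 1):
        bits = keywords.get(f"$P{i}B", "32").strip()
        if bits != "32":
            raise FcsFormatError(f"only 32-bit parameters supported, $P{i}B={bits}")
    raw = blob[data_begin : data_end + 1]
    expected = n_par * n_tot * 4
    if len(raw) < expected:
        raise FcsFormatError(
            f"DATA segment holds {len(raw)} bytes, {expected} required for "
            f"{n_tot} events x {n_par} parameters"
        )
    data = np.frombuffer(raw[:expected], dtype=dtype).reshape(n_tot, n_par)
    return keywords, data


def read_events(
    path,
    channel_map: ChannelMap | None = None,
    required_roles=tuple(REQUIRED_ROLES),
) -> EventTable:
    """Read an FCS file into an :class:`EventTable`.

    Channel roles are resolved through ``channel_map`` (BD Accuri naming
    by default); the time channel is converted to seconds using the
    file's ``$TIMESTEP``, or :data:`DEFAULT_TIMESTEP_S` with a warning
    when the file declares none.  Event order is preserved exactly as
    acquired.

    Raises
    ------
    MissingChannelError
        Naming the unresolved role when a required channel is absent.
    FcsFormatError
        For malformed header/keyword/data segments.
    """
    keywords, data = _read_raw(path)
    cmap = channel_map or ChannelMap()
    n_par = int(keywords["$PAR"])
    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    role_index: dict[str, int] = {}
    for i, name in enumerate(names):
        role = cmap.roles.get(name)
        if role is not None:
            role_index[role] = i
    for role in required_roles:
        if role not in role_index:
            raise MissingChannelError(
                f"{path}: no parameter resolves role {role!r} "
                f"({REQUIRED_ROLES.get(role, role)}); parameters present: {names}"
            )

    if cmap.timestep_s is not None:
        timestep = cmap.timestep_s
    elif "$TIMESTEP" in keywords:
        timestep = float(keywords["$TIMESTEP"])
        if not timestep > 0:
            raise FcsFormatError(f"non-positive $TIMESTEP {timestep}")
    else:
        warnings.warn(
            f"{path}: no $TIMESTEP keyword; assuming {DEFAULT_TIMESTEP_S} s/tick",
            stacklevel=2,
        )
        timestep = DEFAULT_TIMESTEP_S

    def col(role: str) -> np.ndarray:
        return np.asarray(data[:, role_index[role]])

    return EventTable.from_arrays(
        time_s=col("time") .astype(np.float64) * timestep,
        fsc_a=col("fsc_a"),
        fsc_h=col("fsc_h"),
        ssc_a=col("ssc_a"),
        fl1_a=col("fl1"),
        fl4_a=col("fl4"),
    )


def inspect_fcs(path) -> dict:
    """Summarize an FCS file: parameters, event count, duration, timestep."""
    keywords, data = _read_raw(path)
    n_par = int(keywords["$PAR"])
    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    timestep = float(keywords.get("$TIMESTEP", DEFAULT_TIMESTEP_S))
    cmap = ChannelMap()
    duration = None
    for i, name in enumerate(names):
        if cmap.roles.get(name) == "time" and len(data):
            duration = float(data[:, i].max()) * timestep
    return {
        "path": str(path),
        "parameters": names,
        "n_events": int(keywords["$TOT"]),
        "timestep_s": timestep,
        "duration_s": duration,
    }
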