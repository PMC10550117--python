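"""Reading and writing FCS list-mode files and replicate summary CSVs.

Supports FCS versions 3.0 and 3.1, list mode (``$MODE/L``), with integer
(``$DATATYPE/I``), single-float (``F``) and double-float (``D``) data.
The ANALYSIS segment and spillover/compensation keywords are ignored.
Written files are FCS 3.1, little-endian float32 list mode.

Three CSV dialects for per-replicate summary tables are supported:

* ``s11`` — ``CRM, Replicate, MFI, SI, FoldChange``
* ``s12`` — ``CRM, Replicate, Time, Luminescence``
* ``s13`` — ``CRM, Replicate, Time, ControlLucFluorescenceMedian,
  SampleLucFluorescenceMedian``

Column matching is case-insensitive; unrecognized columns are preserved
in ``ReplicateRecord.extra`` but never interpreted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguityError,
    ContractError,
    FormatError,
    IntegrityError,
    ParseError,
    SchemaError,
)

ROLES = ("fsc_a", "fsc_h", "ssc_a", "viability", "cfse", "luciferase")

#: Roles that must be resolved before gating/quantification accepts a table.
REQUIRED_ROLES = ("fsc_a", "fsc_h", "ssc_a", "luciferase")

#: Default channel-name patterns (regex, case-insensitive) for BD-style
#: exports and for this package's simulator output.
DEFAULT_ROLE_MAP: dict[str, str] = {
    "fsc_a": r"^FSC-A$",
    "fsc_h": r"^FSC-H$",
    "ssc_a": r"^SSC-A$",
    "viability": r"(LIVE.?DEAD|Violet|BV421|VL1)",
    "cfse": r"(CFSE|FITC|BL1)",
    "luciferase": r"(Luc|AF647|APC|RL1)",
}


@dataclass
class EventTable:
    """Per-event channel matrix for one acquisition tube.

    Values are stored exactly as acquired (linear units); no transform
    is applied on read.
    """

    tube_id: str
    channel_names: list[str]
    channel_roles: dict[str, str]
    events: np.ndarray  # shape (n_events, n_channels), float

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ContractError("events must be a 2-D matrix")
        if self.events.shape[1] != len(self.channel_names):
            raise ContractError(
                f"events has {self.events.shape[1]} columns but "
                f"{len(self.channel_names)} channel names were given"
            )
        for role, name in self.channel_roles.items():
            if role not in ROLES:
                raise ContractError(f"unknown channel role {role!r}")
            if name not in self.channel_names:
                raise ContractError(
                    f"role {role!r} maps to {name!r}, not a declared channel"
                )
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ContractError("event matrix contains non-finite values")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """Return the column for ``role`` (1-D view)."""
        self.require_roles(role)
        return self.events[:, self.channel_names.index(self.channel_roles[role])]

    def require_roles(self, *roles: str) -> None:
        missing = [r for r in roles if r not in self.channel_roles]
        if missing:
            raise ContractError(
                f"tube {self.tube_id!r}: required channel role(s) not assigned: "
                f"{', '.join(missing)}"
            )

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Return a new table containing only events where ``mask`` is true."""
        return EventTable(
            tube_id=self.tube_id,
            channel_names=list(self.channel_names),
            channel_roles=dict(self.channel_roles),
            events=self.events[np.asarray(mask, dtype=bool)],
        )


@dataclass
class ReplicateRecord:
    """One row of a per-replicate summary table (S11/S12/S13 dialects)."""

    construct: str
    replicate: int
    values: dict[str, float] = field(default_factory=dict)
    extra: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ContractError("replicate number must be >= 1")
        for key, val in self.values.items():
            if not np.isfinite(val):
                raise ContractError(f"non-finite value for statistic {key!r}")


# ---------------------------------------------------------------------------
# FCS binary format
# ---------------------------------------------------------------------------

_SUPPORTED_VERSIONS = (b"FCS3.0", b"FCS3.1")
_HEADER_LEN = 58


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    # First byte is the delimiter; a doubled delimiter inside a value is an
    # escaped literal, which plain split() renders as an empty token.
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")[1:]
    if body.endswith(delim):
        body = body[:-1]
    tokens = body.split(delim)
    merged: list[str] = []
    for tok in tokens:
        if tok == "" and merged:
            merged[-1] += delim  # escaped delimiter
        elif merged and merged[-1].endswith(delim):
            merged[-1] += tok
        else:
            merged.append(tok)
    if len(merged) % 2 != 0:
        raise IntegrityError("TEXT segment has an odd number of tokens")
    keywords: dict[str, str] = {}
    for key, value in zip(merged[::2], merged[1::2]):
        keywords[key.strip().upper()] = value.strip()
    return keywords


def _data_dtype(keywords: Mapping[str, str], n_par: int) -> np.dtype:
    datatype = keywords.get("$DATATYPE", "").upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        return np.dtype(f"{endian}f4")
    if datatype == "D":
        return np.dtype(f"{endian}f8")
    if datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", "0")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32, 64):
            raise FormatError(
                "only uniform 8/16/32/64-bit integer parameters are supported"
            )
        nbytes = int(keywords[f"$P1B"]) // 8
        return np.dtype(f"{endian}u{nbytes}")
    raise FormatError(f"unsupported $DATATYPE {datatype!r}")


def _resolve_roles(
    channel_names: Sequence[str],
    long_names: Sequence[str],
    role_map: Mapping[str, str],
    strict_optional: bool,
) -> dict[str, str]:
    roles: dict[str, str] = {}
    for role, pattern in role_map.items():
        if role not in ROLES:
            raise ContractError(f"unknown role {role!r} in role map")
        rx = re.compile(pattern, re.IGNORECASE)
        hits = [
            name
            for name, long in zip(channel_names, long_names)
            if rx.search(name) or (long and rx.search(long))
        ]
        if len(hits) == 1:
            roles[role] = hits[0]
        elif len(hits) > 1:
            raise AmbiguityError(
                f"role {role!r} pattern {pattern!r} matches multiple channels: {hits}"
            )
        elif role in REQUIRED_ROLES or strict_optional:
            raise AmbiguityError(
                f"role {role!r} pattern {pattern!r} matches no channel; "
                f"candidates were {list(channel_names)}"
            )
    return roles


def read_fcs(
    path: str | Path,
    role_map: Mapping[str, str] | None = None,
    tube_id: str | None = None,
) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventTable`.

    Parameters
    ----------
    path
        Location of the FCS file.
    role_map
        Mapping from role name to a case-insensitive regex matched against
        the file's short (``$PnN``) and long (``$PnS``) channel names. With
        the default map, optional roles (viability, cfse) that match no
        channel are left unassigned; an explicitly supplied map is strict
        and any pattern matching zero or several channels raises
        :class:`~lucflow.errors.AmbiguityError`.
    tube_id
        Label for the tube; defaults to ``$FIL`` or the file stem.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FormatError(f"{path}: too short to hold an FCS header")
    version = raw[0:6]
    if version not in _SUPPORTED_VERSIONS:
        raise FormatError(
            f"{path}: unsupported FCS version {version.decode('latin-1', 'replace')!r}"
        )

    def _offset(lo: int, hi: int) -> int:
        text = raw[lo:hi].decode("latin-1").strip()
        return int(text) if text else 0

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_start or text_end >= len(raw):
        raise IntegrityError(f"{path}: TEXT segment offsets are invalid")
    keywords = _parse_text_segment(raw[text_start : text_end + 1])

    if keywords.get("$MODE", "L").upper() != "L":
        raise FormatError(f"{path}: only list-mode ($MODE/L) data is supported")
    if data_start == 0:
        data_start = int(keywords.get("$BEGINDATA", "0"))
        data_end = int(keywords.get("$ENDDATA", "0"))
    try:
        n_par = int(keywords["$PAR"])
        n_tot = int(keywords["$TOT"])
    except KeyError as exc:
        raise IntegrityError(f"{path}: missing required keyword {exc}") from exc

    dtype = _data_dtype(keywords, n_par)
    expected = n_par * n_tot * dtype.itemsize
    available = data_end - data_start + 1 if n_tot else 0
    if n_tot and (data_end >= len(raw) or available < expected):
        raise IntegrityError(
            f"{path}: DATA segment holds {max(available, 0)} bytes but "
            f"$PAR={n_par} x $TOT={n_tot} requires {expected}"
        )
    if n_tot:
        flat = np.frombuffer(raw, dtype=dtype, count=n_par * n_tot, offset=data_start)
        events = flat.reshape(n_tot, n_par).astype(float)
    else:
        events = np.empty((0, n_par), dtype=float)

    channel_names = [
        keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)
    ]
    long_names = [keywords.get(f"$P{i}S", "") for i in range(1, n_par + 1)]
    strict = role_map is not None
    roles = _resolve_roles(
        channel_names,
        long_names,
        DEFAULT_ROLE_MAP if role_map is None else role_map,
        strict,
    )
    return EventTable(
        tube_id=tube_id or keywords.get("$FIL", path.stem),
        channel_names=channel_names,
        channel_roles=roles,
        events=events,
    )


def write_fcs(table: EventTable, path: str | Path) -> Path:
    """Write ``table`` as an FCS 3.1 little-endian float32 list-mode file.

    Values are preserved to 32-bit float precision; ``read_fcs`` on the
    result round-trips channel names and values exactly at that precision.
    """
    if not table.channel_names:
        raise ContractError("cannot write a table with zero channels")
    if table.events.size and not np.all(np.isfinite(table.events)):
        raise ContractError("cannot write non-finite event values")
    path = Path(path)

    data = np.ascontiguousarray(table.events, dtype="<f4").tobytes()
    n_tot, n_par = table.events.shape

    pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "%012d"),
        ("$ENDDATA", "%012d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$FIL", table.tube_id.replace("/", "_")),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    name_to_role = {v: k for k, v in table.channel_roles.items()}
    for i, name in enumerate(table.channel_names, start=1):
        pairs += [
            (f"$P{i}N", name.replace("/", "_")),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", "262144"),
        ]
        role = name_to_role.get(name)
        if role:
            pairs.append((f"$P{i}S", role))

    def render(begin_data: int, end_data: int) -> bytes:
        parts = ["/"]
        for key, value in pairs:
            if value == "%012d":
                value = "%012d" % (begin_data if key == "$BEGINDATA" else end_data)
            parts.append(f"{key}/{value}/")
        return "".join(parts).encode("latin-1")

    text = render(0, 0)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1  # width-stable: placeholders are fixed
    data_start = text_end + 1
    data_end = data_start + max(len(data), 1) - 1
    text = render(data_start, data_end)

    def hfield(value: int) -> bytes:
        return b"%8d" % value if value <= 99_999_999 else b"%8d" % 0

    header = b"FCS3.1    " + b"".join(
        hfield(v) for v in (text_start, text_end, data_start, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    path.write_bytes(header + text + (data or b"\x00"))
    return path


# ---------------------------------------------------------------------------
# Replicate summary CSV dialects
# ---------------------------------------------------------------------------

#: canonical statistic name -> CSV column name, per dialect
DIALECTS: dict[str, dict[str, str]] = {
    "s11": {"mfi": "MFI", "si": "SI", "fold_change": "FoldChange"},
    "s12": {"time_hours": "Time", "luminescence": "Luminescence"},
    "s13": {
        "time_hours": "Time",
        "control_median": "ControlLucFluorescenceMedian",
        "sample_median": "SampleLucFluorescenceMedian",
    },
}


def read_replicate_csv(path: str | Path, dialect: str) -> list[ReplicateRecord]:
    """Parse a replicate summary CSV into :class:`ReplicateRecord` objects.

    ``dialect`` is one of ``"s11"``, ``"s12"``, ``"s13"``. Column names are
    matched case-insensitively; extra columns are carried in ``extra``.
    """
    if dialect not in DIALECTS:
        raise ContractError(f"unknown dialect {dialect!r}; expected one of "
                            f"{sorted(DIALECTS)}")
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    lower = {c.lower().strip(): c for c in frame.columns}

    def col(name: str) -> str:
        try:
            return lower[name.lower()]
        except KeyError:
            raise SchemaError(
                f"{path}: dialect {dialect!r} requires column {name!r}"
            ) from None

    crm_col, rep_col = col("CRM"), col("Replicate")
    stat_cols = {stat: col(name) for stat, name in DIALECTS[dialect].items()}
    known = {crm_col, rep_col, *stat_cols.values()}

    records: list[ReplicateRecord] = []
    for idx, row in frame.iterrows():
        values: dict[str, float] = {}
        for stat, column in stat_cols.items():
            try:
                values[stat] = float(row[column])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: row {idx}: column {column!r} value "
                    f"{row[column]!r} is not numeric"
                ) from None
        try:
            replicate = int(float(row[rep_col]))
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: row {idx}: column {rep_col!r} value "
                f"{row[rep_col]!r} is not numeric"
            ) from None
        records.append(
            ReplicateRecord(
                construct=str(row[crm_col]).strip(),
                replicate=replicate,
                values=values,
                extra={c: row[c] for c in frame.columns if c not in known},
            )
        )
    return records


def write_replicate_csv(
    records: Sequence[ReplicateRecord], path: str | Path, dialect: str
) -> Path:
    """Inverse of :func:`read_replicate_csv` (extras are not written)."""
    if dialect not in DIALECTS:
        raise ContractError(f"unknown dialect {dialect!r}")
    rows = []
    for rec in records:
        row: dict[str, object] = {"CRM": rec.construct, "Replicate": rec.replicate}
        for stat, column in DIALECTS[dialect].items():
            row[column] = rec.values[stat]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
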