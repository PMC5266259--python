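"""Reading and writing flow-cytometry event data.

Event data live in :class:`EventMatrix`, a channel-named table of raw
per-cell intensities. Two on-disk dialects are supported:

* FCS 3.0 / 3.1 list-mode files with floating-point data ($DATATYPE F or D),
  the format bacterial cytometers of the SYBR-Green era export. Files are
  written as FCS 3.1, single dataset, little-endian 32-bit floats.
* A CSV fallback: one header row of channel names, comma-separated numeric
  rows, no index column. CSV fixtures stay diffable and parser-independent.

No compensation, transformation or reordering happens at the I/O layer;
files round-trip to within float32 precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_PANEL",
    "EventMatrix",
    "FcsFormatError",
    "concat_events",
    "read_events",
    "write_events",
]

#: The 12-parameter panel of a four-colour + two-scatter bacterial cytometer
#: (area and height for each detector), in canonical order.
CANONICAL_PANEL = (
    "FL1-A", "FL1-H", "FL2-A", "FL2-H", "FL3-A", "FL3-H",
    "FL4-A", "FL4-H", "FSC-A", "FSC-H", "SSC-A", "SSC-H",
)


class FcsFormatError(ValueError):
    """A file cannot be interpreted under the requested dialect."""


@dataclass
class EventMatrix:
    """Events x channels table of finite intensities with named channels.

    Parameters
    ----------
    channels:
        Ordered, unique channel names.
    values:
        Array of shape ``(n_events, n_channels)``. Raw acquisition values are
        non-negative by convention; transformed matrices may hold any finite
        float.
    meta:
        Free-form acquisition / provenance metadata.
    """

    channels: list
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = [str(c) for c in self.channels]
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            if vals.size == 0:
                vals = vals.reshape(0, len(self.channels))
            else:
                vals = vals.reshape(1, -1)
        if vals.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={vals.ndim}")
        if vals.shape[1] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel names but values have "
                f"{vals.shape[1]} columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("event intensities must be finite")
        self.values = vals

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not present in {self.channels}") from None

    def column(self, channel: str) -> np.ndarray:
        return self.values[:, self.index(channel)]

    def take(self, indices) -> "EventMatrix":
        """Row subset/reorder; metadata is carried over by shallow copy."""
        return EventMatrix(list(self.channels), self.values[indices], dict(self.meta))

    def with_values(self, values: np.ndarray, meta: dict | None = None) -> "EventMatrix":
        return EventMatrix(list(self.channels), values, dict(self.meta) if meta is None else meta)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channels)


def concat_events(parts: list) -> EventMatrix:
    """Concatenate EventMatrices sharing one panel, preserving event order."""
    if not parts:
        raise ValueError("need at least one EventMatrix to concatenate")
    panel = parts[0].channels
    for p in parts[1:]:
        if p.channels != panel:
            raise ValueError(
                f"panel mismatch: {panel} vs {p.channels}"
            )
    values = np.concatenate([p.values for p in parts], axis=0) if parts else None
    return EventMatrix(list(panel), values, {})


# ---------------------------------------------------------------------------
# FCS 3.1 writing
# ---------------------------------------------------------------------------

_HEADER_LEN = 58  # 10-byte version string + six 8-byte ASCII offset fields
_DELIM = "/"


def _build_text(keywords: dict) -> str:
    parts = [""]
    for key, value in keywords.items():
        key, value = str(key), str(value)
        if _DELIM in key or _DELIM in value:
            raise FcsFormatError(
                f"keyword {key!r}={value!r} contains the TEXT delimiter {_DELIM!r}"
            )
        if value == "":
            value = " "  # FCS forbids zero-length values
        parts.extend([key, value])
    parts.append("")
    return _DELIM.join(parts)


def _write_fcs(events: EventMatrix, path: Path) -> None:
    n_par, n_tot = events.n_channels, events.n_events
    data = np.ascontiguousarray(events.values, dtype="<f4").tobytes()

    keywords: dict = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # zero-padded to fixed width so the TEXT length does not depend on them
        "$BEGINDATA": "0" * 12,
        "$ENDDATA": "0" * 12,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, ch in enumerate(events.channels, start=1):
        col_max = float(events.values[:, i - 1].max()) if n_tot else 0.0
        keywords[f"$P{i}N"] = ch
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, np.ceil(col_max) + 1)))

    text_begin = _HEADER_LEN
    text_len = len(_build_text(keywords))
    data_begin = text_begin + text_len if data else 0
    data_end = data_begin + len(data) - 1 if data else 0
    keywords["$BEGINDATA"] = f"{data_begin:012d}"
    keywords["$ENDDATA"] = f"{data_end:012d}"
    text = _build_text(keywords).encode("ascii")
    assert len(text) == text_len

    if data and data_end > 99_999_999:
        raise FcsFormatError("dataset too large for an FCS 3.1 header offset")
    header = (
        b"FCS3.1    "
        + f"{text_begin:8d}".encode()
        + f"{text_begin + text_len - 1:8d}".encode()
        + f"{data_begin:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    path.write_bytes(header + text + data)


# ---------------------------------------------------------------------------
# FCS reading (3.0 and 3.1, list mode, float data)
# ---------------------------------------------------------------------------

_PARAM_KEY = re.compile(r"^\$P\d+[A-Z]+$")


def _read_fcs(path: Path) -> EventMatrix:
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FcsFormatError(f"{path}: file too short to hold an FCS header")
    version = raw[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(i: int) -> int:
        fieldbytes = raw[10 + 8 * i : 18 + 8 * i].strip()
        return int(fieldbytes) if fieldbytes else 0

    text_begin, text_end = _offset(0), _offset(1)
    data_begin, data_end = _offset(2), _offset(3)

    delim = raw[text_begin : text_begin + 1].decode("latin-1")
    body = raw[text_begin + 1 : text_end + 1].decode("latin-1")
    tokens = body.split(delim)
    if tokens and tokens[-1] == "":
        tokens.pop()
    if any(t == "" for t in tokens):
        raise FcsFormatError(f"{path}: escaped TEXT delimiters are not supported")
    if len(tokens) % 2:
        raise FcsFormatError(f"{path}: unbalanced key/value TEXT segment")
    kw = {tokens[i].strip().upper(): tokens[i + 1] for i in range(0, len(tokens), 2)}

    if kw.get("$MODE", "L").strip() != "L":
        raise FcsFormatError(f"{path}: only list-mode ($MODE L) files are supported")
    dtype_char = kw.get("$DATATYPE", "").strip().upper()
    if dtype_char not in ("F", "D"):
        raise FcsFormatError(
            f"{path}: unsupported $DATATYPE {dtype_char!r} (need F or D)"
        )
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if dtype_char == "F" else 8

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))

    if n_tot > 0:
        need = n_par * n_tot * itemsize
        buf = raw[data_begin : data_begin + need]
        if len(buf) < need:
            raise FcsFormatError(
                f"{path}: DATA segment truncated ({len(buf)} < {need} bytes)"
            )
        values = (
            np.frombuffer(buf, dtype=f"{endian}f{itemsize}")
            .reshape(n_tot, n_par)
            .astype(float)
        )
    else:
        values = np.empty((0, n_par))

    channels = [
        kw.get(f"$P{i}N", "").strip() or kw.get(f"$P{i}S", "").strip() or f"P{i}"
        for i in range(1, n_par + 1)
    ]
    meta = {k: v for k, v in kw.items() if not _PARAM_KEY.match(k)}
    meta["source_version"] = version
    return EventMatrix(channels, values, meta)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_csv(path: Path) -> EventMatrix:
    df = pd.read_csv(path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna().to_numpy()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FcsFormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = coerced
    return EventMatrix(list(df.columns), df.to_numpy(dtype=float), {})


def _write_csv(events: EventMatrix, path: Path) -> None:
    events.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    fmt = fmt.lower()
    if fmt not in ("fcs", "csv"):
        raise ValueError(f"format must be 'fcs' or 'csv', got {fmt!r}")
    return fmt


def read_events(path, format: str | None = None) -> EventMatrix:
    """Read an event file as stored (no transformation, original order).

    ``format`` is inferred from the extension when omitted (``.fcs`` ->
    FCS, anything else -> CSV).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(f"no such event file: {path}")
    if fmt == "fcs":
        return _read_fcs(path)
    return _read_csv(path)


def write_events(events: EventMatrix, path, format: str | None = None):
    """Write ``events`` so that :func:`read_events` round-trips them.

    FCS output is version 3.1, list mode, little-endian 32-bit float, one
    dataset per file. Returns the path written.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if events.n_channels == 0:
        raise ValueError("cannot write an EventMatrix with zero channels")
    if fmt == "fcs":
        _write_fcs(events, path)
    else:
        _write_csv(events, path)
    return path
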