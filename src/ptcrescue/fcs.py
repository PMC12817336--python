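"""Minimal FCS3.0 reader/writer for dual-reporter cytometry event tables.

The on-disk profile is deliberately small: one dataset per file, list-mode
data, ``$DATATYPE`` F (32-bit float) or I (unsigned integer), both byte
orders, no analysis segment.  That is sufficient to round-trip the four
channels the readthrough pipeline consumes (forward scatter, side scatter,
GFP, RFP) and to exercise a reader against files produced elsewhere with the
same profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical channel roles used throughout the pipeline.
CANONICAL_CHANNELS = ("FSC", "SSC", "GFP", "RFP")

#: Default instrument channel names ($PnN), patterned after a green/yellow
#: two-laser bench cytometer.
DEFAULT_CHANNEL_NAMES: dict[str, str] = {
    "FSC": "FSC-HLin",
    "SSC": "SSC-HLin",
    "GFP": "GRN-B-HLin",
    "RFP": "YEL-B-HLin",
}

_HEADER_LEN = 58  # 10-byte version string + six 8-char ASCII offsets
_DELIM = "/"


class FCSFormatError(ValueError):
    """Raised when a file does not parse as the supported FCS3.0 profile."""


class ChannelResolutionError(KeyError):
    """Raised when a required channel cannot be mapped to a $PnN name."""


@dataclass
class EventTable:
    """Per-cell cytometry events with canonical channel columns.

    ``data`` holds one row per event with columns FSC, SSC, GFP, RFP
    (arbitrary linear instrument units).  ``channel_name_map`` records the
    instrument ($PnN) name behind each canonical role.
    """

    data: pd.DataFrame
    sample_id: str = ""
    channel_name_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_NAMES)
    )

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"EventTable missing channel column(s): {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


def _byteord_keyword(byteord: str) -> str:
    if byteord in ("little", "1,2,3,4"):
        return "1,2,3,4"
    if byteord in ("big", "4,3,2,1"):
        return "4,3,2,1"
    raise ValueError(f"unsupported byte order {byteord!r}")


def write_fcs(
    events: EventTable,
    path,
    channel_names: Mapping[str, str] | None = None,
    datatype: str = "F",
    byteord: str = "little",
) -> None:
    """Write an :class:`EventTable` as a minimal valid FCS3.0 file.

    Parameters
    ----------
    events:
        Table with the four canonical channels.
    channel_names:
        Mapping canonical role -> instrument $PnN name; defaults to the
        table's own map.
    datatype:
        ``"F"`` (float32, default) or ``"I"`` (uint32) — the latter exists to
        produce integer-encoded twin fixtures.
    byteord:
        ``"little"`` or ``"big"``.
    """
    names = dict(channel_names or events.channel_name_map)
    missing = [c for c in CANONICAL_CHANNELS if c not in names]
    if missing:
        raise ValueError(f"channel_names must cover {CANONICAL_CHANNELS}; missing {missing}")
    for role in CANONICAL_CHANNELS:
        if role not in events.data.columns:
            raise ValueError(f"event table missing mapped channel {role!r}")

    arr = events.data.loc[:, list(CANONICAL_CHANNELS)].to_numpy()
    endian = "<" if _byteord_keyword(byteord) == "1,2,3,4" else ">"
    if datatype == "F":
        arr = arr.astype(np.dtype(endian + "f4"))
    elif datatype == "I":
        arr = np.rint(arr).astype(np.dtype(endian + "u4"))
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")

    n_tot = arr.shape[0]
    payload = arr.tobytes(order="C")

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        # fixed-width so the TEXT length does not depend on the values
        ("$BEGINDATA", "{begindata:>8}"),
        ("$ENDDATA", "{enddata:>8}"),
        ("$BYTEORD", _byteord_keyword(byteord)),
        ("$DATATYPE", datatype),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(len(CANONICAL_CHANNELS))),
        ("$TOT", str(n_tot)),
    ]
    for i, role in enumerate(CANONICAL_CHANNELS, start=1):
        keywords.append((f"$P{i}N", names[role]))
        keywords.append((f"$P{i}B", "32"))
        keywords.append((f"$P{i}E", "0,0"))
        keywords.append((f"$P{i}R", "16777216"))
    if events.sample_id:
        keywords.append(("$FIL", events.sample_id))

    text_template = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in keywords) + _DELIM
    text_len = len(text_template.format(begindata=0, enddata=0))
    text_begin = _HEADER_LEN
    text_end = text_begin + text_len - 1
    if payload:
        data_begin = text_end + 1
        data_end = data_begin + len(payload) - 1
    else:
        data_begin = data_end = 0
    text = text_template.format(begindata=data_begin, enddata=data_end)
    assert len(text) == text_len

    header = (
        b"FCS3.0    "
        + f"{text_begin:>8}".encode()
        + f"{text_end:>8}".encode()
        + f"{data_begin:>8}".encode()
        + f"{data_end:>8}".encode()
        + f"{0:>8}".encode()
        + f"{0:>8}".encode()
    )
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(payload)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = chr(raw[0])
    body = raw.decode("latin-1")
    parts = body.strip(delim).split(delim)
    if len(parts) % 2 != 0:
        # trailing empty value
        parts.append("")
    kv = {}
    for k, v in zip(parts[::2], parts[1::2]):
        kv[k.strip().upper()] = v.strip()
    return kv


def read_fcs(
    path,
    channel_map: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> EventTable:
    """Read a supported FCS3.0 file into an :class:`EventTable`.

    ``channel_map`` maps canonical roles to $PnN names (defaults to
    :data:`DEFAULT_CHANNEL_NAMES`).  Raises :class:`ChannelResolutionError`
    listing the available $PnN names when a required channel is absent.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < _HEADER_LEN or not blob.startswith(b"FCS3.0"):
        raise FCSFormatError(f"{path}: not an FCS3.0 file")

    def _offset(i: int) -> int:
        fieldb = blob[10 + 8 * i : 18 + 8 * i].strip()
        return int(fieldb) if fieldb else 0

    text_begin, text_end = _offset(0), _offset(1)
    data_begin, data_end = _offset(2), _offset(3)
    kv = _parse_text_segment(blob[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(kv.get("$BEGINDATA", "0"))
        data_end = int(kv.get("$ENDDATA", "0"))

    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord == "1,2,3,4" else ">"
    datatype = kv.get("$DATATYPE", "F")
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "I":
        bits = {int(kv.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if bits != {32}:
            raise FCSFormatError(f"unsupported $PnB widths {sorted(bits)} for $DATATYPE/I")
        dtype = np.dtype(endian + "u4")
    else:
        raise FCSFormatError(f"unsupported $DATATYPE {datatype!r}")

    if n_tot == 0:
        values = np.empty((0, n_par), dtype=np.float64)
    else:
        nbytes = n_tot * n_par * dtype.itemsize
        raw = blob[data_begin : data_begin + nbytes]
        if len(raw) != nbytes:
            raise FCSFormatError(
                f"DATA segment truncated: expected {nbytes} bytes, found {len(raw)}"
            )
        values = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)

    frame = pd.DataFrame(values, columns=names)
    cmap = dict(channel_map or DEFAULT_CHANNEL_NAMES)
    cols = {}
    for role in CANONICAL_CHANNELS:
        pnn = cmap.get(role)
        if pnn is None or pnn not in frame.columns:
            raise ChannelResolutionError(
                f"cannot resolve channel {role!r} (wanted $PnN {pnn!r}); "
                f"available: {names}"
            )
        cols[role] = frame[pnn].to_numpy()
    data = pd.DataFrame(cols)
    if sample_id is None:
        sample_id = kv.get("$FIL", "")
    return EventTable(data=data, sample_id=sample_id, channel_name_map=cmap)


def ensure_nonnegative(events: EventTable) -> None:
    """Warn if intensities are negative (clipped elsewhere by generators)."""
    vals = events.data[list(CANONICAL_CHANNELS)].to_numpy()
    if np.any(vals < 0):
        warnings.warn("event table contains negative intensities", stacklevel=2)
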