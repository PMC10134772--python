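"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Supports the subset of the standard that cytometry snapshot files use in
practice: list mode (``$MODE/L``), float (``$DATATYPE/F`` or ``/D``) or
fixed-width integer (``/I``) events, little- or big-endian byte order, and
channel names from ``$PnN``.  Analysis segments, compensation and
histogram mode are ignored.  The writer emits plain FCS 3.0 float32 files
and exists chiefly so that round-trips can be exercised without binary
fixtures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_fcs", "write_fcs"]


class FCSError(ValueError):
    pass


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    kw = {}
    for key, val in zip(parts[::2], parts[1::2]):
        kw[key.decode("utf-8", "replace").strip().upper()] = val.decode(
            "utf-8", "replace"
        ).strip()
    return kw


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 file into a cells x channels DataFrame."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FCSError(f"{path.name}: too short to be an FCS file")
    version = blob[:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise FCSError(f"{path.name}: bad magic {version!r}")

    def _offset(a: int, b: int) -> int:
        s = blob[a:b].decode("ascii", "replace").strip()
        return int(s) if s else 0

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    kw = _parse_text_segment(blob[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSError(f"{path.name}: only list mode is supported, got $MODE={mode}")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}N", f"P{i}"))

    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
        if any(b != 32 for b in bits):
            raise FCSError(f"{path.name}: $DATATYPE/F requires 32-bit parameters")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
        if any(b != 64 for b in bits):
            raise FCSError(f"{path.name}: $DATATYPE/D requires 64-bit parameters")
    elif datatype == "I":
        width = bits[0]
        if any(b != width for b in bits) or width not in (8, 16, 32, 64):
            raise FCSError(f"{path.name}: unsupported mixed/odd integer widths {bits}")
        dtype = np.dtype(f"{endian}u{width // 8}")
    else:
        raise FCSError(f"{path.name}: unsupported $DATATYPE={datatype}")

    raw = blob[data_begin : data_end + 1]
    needed = n_tot * n_par * dtype.itemsize
    if len(raw) < needed:
        raise FCSError(
            f"{path.name}: data segment holds {len(raw)} bytes, "
            f"expected {needed} for {n_tot} events x {n_par} channels"
        )
    events = np.frombuffer(raw[:needed], dtype=dtype).reshape(n_tot, n_par)
    return pd.DataFrame(events.astype(float), columns=names)


def write_fcs(path: str | Path, data: pd.DataFrame) -> None:
    """Write a cells x channels DataFrame as a minimal FCS 3.0 float32 file."""
    path = Path(path)
    x = np.ascontiguousarray(data.to_numpy(dtype=np.float32))
    n_tot, n_par = x.shape
    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(data.columns, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(x)) if x.size else 1.0)) + 1)
        kw[f"$P{i}E"] = "0,0"

    # keyword segment length depends on the data offsets it records; iterate
    # until the layout is self-consistent (digit counts stabilize quickly)
    header_len = 58
    data_len = x.nbytes
    text = b""
    text_begin = text_end = data_begin = data_end = 0
    for _ in range(5):
        candidate_begin = header_len
        candidate_end = candidate_begin + max(len(text), 1) - 1
        kw["$BEGINDATA"] = str(candidate_end + 1)
        kw["$ENDDATA"] = str(candidate_end + data_len)
        parts = [b"/"]
        for key, val in kw.items():
            parts.append(key.encode() + b"/" + str(val).encode() + b"/")
        new_text = b"".join(parts)
        if len(new_text) == len(text):
            text = new_text
            text_begin = candidate_begin
            text_end = candidate_end
            data_begin = candidate_end + 1
            data_end = candidate_end + data_len
            break
        text = new_text
    else:  # pragma: no cover - layout always stabilizes
        raise FCSError("could not lay out FCS text segment")
    header = (
        b"FCS3.0    "
        + f"{text_begin:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_begin:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == 58
    path.write_bytes(header + text + x.tobytes())
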