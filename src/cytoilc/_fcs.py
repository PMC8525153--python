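"""Minimal FCS 3.1 reader/writer (list-mode, float data).

Covers the subset of the standard that cytometry pipelines actually exchange:
a single list-mode dataset, $DATATYPE F or D, little- or big-endian, with
parameter names taken from $PnS (falling back to $PnN).  Segments HEADER,
TEXT and DATA only; ANALYSIS and supplemental TEXT are ignored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DELIM = b"/"
_HEADER_LEN = 58


def _text_segment(pairs: dict[str, str]) -> bytes:
    out = [_DELIM]
    for k, v in pairs.items():
        out.append(k.encode("ascii") + _DELIM + str(v).encode("latin-1")
                   + _DELIM)
    return b"".join(out)


def write_fcs(path: str | Path, values: np.ndarray, names: list[str],
              src: str = "") -> None:
    """Write a float32 little-endian FCS 3.1 file."""
    values = np.ascontiguousarray(values, dtype="<f4")
    n_events, n_par = values.shape
    if n_par != len(names):
        raise ValueError("names do not match value columns")
    ranges = np.maximum(values.max(axis=0, initial=0.0), 1.0)

    pairs: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BEGINDATA": "0" * 10, "$ENDDATA": "0" * 10,
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_events),
    }
    if src:
        pairs["$SRC"] = src
    for i, name in enumerate(names, start=1):
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}N"] = name.replace("/", "_")
        pairs[f"$P{i}S"] = name.replace("/", "_")
        pairs[f"$P{i}R"] = str(int(np.ceil(ranges[i - 1])) + 1)

    # Fixed-width $BEGINDATA/$ENDDATA keep the TEXT length stable while the
    # true offsets are patched in.
    text = _text_segment(pairs)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + values.nbytes - 1
    pairs["$BEGINDATA"] = f"{data_begin:010d}"
    pairs["$ENDDATA"] = f"{data_end:010d}"
    text = _text_segment(pairs)

    def f8(x: int) -> bytes:
        s = str(x)
        return (s if len(s) <= 8 else "0" * 8).rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        f8(x) for x in (text_begin, text_end,
                        data_begin if data_end <= 99_999_999 else 0,
                        data_end if data_end <= 99_999_999 else 0,
                        0, 0)
    )
    assert len(header) == _HEADER_LEN
    Path(path).write_bytes(header + text + values.tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1]
    parts = raw[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {
        parts[i].decode("latin-1").strip().upper():
        parts[i + 1].decode("latin-1").strip()
        for i in range(0, len(parts), 2)
    }


def read_fcs(path: str | Path
             ) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS 3.0/3.1 file; returns (values, parameter names, TEXT)."""
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER_LEN or not blob[:3] == b"FCS":
        raise ValueError(f"{path}: not an FCS file")

    def off(i: int) -> int:
        s = blob[10 + 8 * i: 18 + 8 * i].decode("ascii", "ignore").strip()
        return int(s) if s else 0

    text_begin, text_end = off(0), off(1)
    text = _parse_text(blob[text_begin: text_end + 1])
    data_begin, data_end = off(2), off(3)
    if not data_begin:
        data_begin = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_char = text.get("$DATATYPE", "F").upper()
    if dtype_char not in ("F", "D"):
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_char}")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    dt = np.dtype(f"{endian}f{4 if dtype_char == 'F' else 8}")

    expected = n_par * n_tot * dt.itemsize
    data = blob[data_begin: data_begin + expected]
    if len(data) < expected:
        raise ValueError(f"{path}: truncated DATA segment")
    values = np.frombuffer(data, dtype=dt).reshape(n_tot, n_par)
    names = [
        text.get(f"$P{i}S") or text.get(f"$P{i}N") or f"P{i}"
        for i in range(1, n_par + 1)
    ]
    return values.astype(float), names, text
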