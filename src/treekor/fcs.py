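"""Minimal FCS 3.1 reader/writer (list-mode, floating-point data).

Cytometry event matrices are stored in FCS files as a fixed-width ASCII
header, a delimited TEXT segment of keyword/value pairs, and a binary DATA
segment.  This module supports the subset of the standard that covers
modern pre-compensated exports: ``$MODE/L`` list mode, ``$DATATYPE`` F or D
(32/64-bit IEEE floats), little- or big-endian ``$BYTEORD``, uniform
``$PnB``.  Compensation/spillover keywords are ignored.

Only marker short names (``$PnN``) are read as channel names.
"""

from __future__ import annotations


import numpy as np

_DELIM = "/"


class FCSError(ValueError):
    """Malformed or unsupported FCS content."""


def write_fcs(path, data: np.ndarray, marker_names: list[str]) -> None:
    """Write an event matrix as a single-dataset FCS 3.1 file.

    Data are written as little-endian float32 in list mode.
    """
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2:
        raise FCSError("data must be a 2-D events x markers matrix")
    n_events, n_par = data.shape
    if n_par != len(marker_names):
        raise FCSError("marker_names length does not match data columns")

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(marker_names, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.ceil(np.abs(data[:, i - 1]).max())) + 1 if n_events else 1)

    data_bytes = data.tobytes(order="C")

    # TEXT offsets depend on the length of the offset strings themselves;
    # iterate the data offset until the layout is a fixed point.
    begin_text = 58
    begin_data = begin_text + 1
    for _ in range(10):
        text = _build_text(kw, begin_text, len(data_bytes), begin_data)
        new_begin = begin_text + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    else:  # pragma: no cover - layout always stabilizes in a few rounds
        raise FCSError("could not lay out TEXT segment")
    end_text = begin_data - 1
    end_data = begin_data + len(data_bytes) - 1

    header = (
        "FCS3.1    "
        + f"{begin_text:>8d}{end_text:>8d}"
        + f"{begin_data:>8d}{end_data:>8d}"
        + f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == 58

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(data_bytes)


def _build_text(kw: dict[str, str], begin_text: int, n_data_bytes: int,
                begin_data: int | None = None) -> str:
    if begin_data is None:
        # placeholder widths: generous 10-digit fields
        bd, ed = 9999999999, 9999999999
    else:
        bd, ed = begin_data, begin_data + n_data_bytes - 1
    items = dict(kw)
    items["$BEGINDATA"] = str(bd)
    items["$ENDDATA"] = str(ed)
    parts = [_DELIM]
    for k in sorted(items):
        parts.append(f"{k}{_DELIM}{items[k]}{_DELIM}")
    return "".join(parts)


def read_fcs(path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS file; returns ``(events x markers matrix, marker names)``."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58 or not raw[:3] == b"FCS":
        raise FCSError(f"not an FCS file: {path}")
    begin_text = int(raw[10:18])
    end_text = int(raw[18:26])
    text = raw[begin_text : end_text + 1].decode("latin-1")
    if not text:
        raise FCSError(f"empty TEXT segment in {path}")
    delim = text[0]
    fields = text[1:].split(delim)
    # trailing delimiter leaves an empty last field
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        raise FCSError(f"odd keyword/value count in {path}")
    kw = {fields[i].strip().upper(): fields[i + 1] for i in range(0, len(fields), 2)}

    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSError(f"unsupported $MODE {mode!r} (only list mode)")
    dtype_code = kw.get("$DATATYPE", "").upper()
    if dtype_code not in ("F", "D"):
        raise FCSError(f"unsupported $DATATYPE {dtype_code!r} (only F/D)")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if dtype_code == "F" else 8
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])

    widths = {kw.get(f"$P{i}B", "32") for i in range(1, n_par + 1)}
    if widths - {str(itemsize * 8)}:
        raise FCSError(f"non-uniform or mismatched $PnB widths {sorted(widths)}")

    begin_data = int(kw.get("$BEGINDATA") or raw[26:34])
    n_bytes = n_par * n_tot * itemsize
    buf = raw[begin_data : begin_data + n_bytes]
    if len(buf) != n_bytes:
        raise FCSError(f"truncated DATA segment in {path}")
    arr = np.frombuffer(buf, dtype=f"{endian}f{itemsize}").reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return np.asarray(arr, dtype=float), names
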