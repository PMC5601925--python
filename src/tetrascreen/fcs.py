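"""Minimal FCS 3.0/3.1 reader and FCS 3.1 writer.

Covers the interchange subset this pipeline needs: a single dataset, list-
mode float (or integer) data, little/big endian, $PnN short names and $PnS
stain names.  Intensities round-trip through float64; channel metadata
round-trips exactly.  No mature FCS library is available in the target
environment, hence the in-repo implementation.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .events import EventTable

DELIM = "/"
TIME_CHANNEL = "Time"


def _keywords(events: EventTable) -> tuple[dict[str, str], np.ndarray]:
    labels = list(events.channels) + [TIME_CHANNEL]
    if len(set(labels)) != len(labels):
        raise ValidationError("channel name collision (duplicate $PnN)")
    data = np.column_stack([events.intensities.to_numpy(dtype=float),
                            events.time.astype(float)])
    kw = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "D", "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(data.shape[1]), "$TOT": str(data.shape[0]),
    }
    for i, lab in enumerate(labels, start=1):
        kw[f"$P{i}B"] = "64"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}N"] = lab
        kw[f"$P{i}R"] = str(int(max(1.0, np.ceil(data[:, i - 1].max(initial=1.0)))))
    return kw, data


def write_fcs(events: EventTable, path) -> None:
    """Write a single-dataset FCS 3.1 file (float64, little endian)."""
    kw, data = _keywords(events)
    payload = data.astype("<f8").tobytes()

    def render_text(begin_data: int, end_data: int) -> bytes:
        kw["$BEGINDATA"] = f"{begin_data:012d}"
        kw["$ENDDATA"] = f"{end_data:012d}"
        parts = [DELIM]
        for k in sorted(kw):
            v = kw[k]
            if DELIM in k or DELIM in v:
                raise ValidationError("delimiter character in keyword/value")
            parts.append(f"{k}{DELIM}{v}{DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58
    text = render_text(0, 0)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1
    text = render_text(data_start, data_end)  # fixed-width, length unchanged

    header = b"FCS3.1    " + b"".join(
        f"{v:>8d}".encode() for v in (text_start, text_end,
                                      data_start if data_start <= 99_999_999 else 0,
                                      data_end if data_end <= 99_999_999 else 0,
                                      0, 0))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def _parse_text(blob: bytes, offset: int) -> dict[str, str]:
    try:
        text = blob.decode("ascii", errors="replace")
    except Exception as exc:  # pragma: no cover
        raise DataError(f"TEXT segment at byte {offset} not decodable: {exc}")
    if not text:
        raise DataError(f"empty TEXT segment at byte {offset}")
    delim = text[0]
    fields = text[1:].split(delim)
    if fields and fields[-1] == "":
        fields.pop()
    if len(fields) % 2:
        raise DataError(f"odd keyword count in TEXT segment at byte {offset}")
    return {fields[i].strip().upper(): fields[i + 1]
            for i in range(0, len(fields), 2)}


def read_fcs(path) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`."""
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise DataError(f"file truncated in header (length {len(raw)} < 58)")
    version = raw[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise DataError(f"unsupported FCS version {version!r} at byte 0")

    def offset(a: int, b: int, what: str) -> int:
        try:
            return int(raw[a:b].decode("ascii").strip() or "0")
        except ValueError as exc:
            raise DataError(f"bad {what} offset at byte {a}") from exc

    text_start = offset(10, 18, "TEXT begin")
    text_end = offset(18, 26, "TEXT end")
    data_start = offset(26, 34, "DATA begin")
    data_end = offset(34, 42, "DATA end")
    if text_end >= len(raw) or text_start >= text_end:
        raise DataError(f"TEXT segment [{text_start}, {text_end}] out of bounds")
    kw = _parse_text(raw[text_start:text_end + 1], text_start)

    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_end >= len(raw) or data_start >= data_end:
        raise DataError(f"DATA segment [{data_start}, {data_end}] out of bounds "
                        f"(file length {len(raw)})")

    par = int(kw["$PAR"])
    tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtypes = [np.dtype(f"{endian}f4")] * par
    elif datatype == "D":
        dtypes = [np.dtype(f"{endian}f8")] * par
    elif datatype == "I":
        dtypes = [np.dtype(f"{endian}u{int(kw[f'$P{i}B']) // 8}")
                  for i in range(1, par + 1)]
    else:
        raise DataError(f"unsupported $DATATYPE {datatype!r}")

    row_bytes = sum(dt.itemsize for dt in dtypes)
    need = tot * row_bytes
    blob = raw[data_start:data_end + 1]
    if len(blob) < need:
        raise DataError(f"DATA segment truncated at byte {data_start + len(blob)}: "
                        f"need {need} bytes for {tot} x {par}")
    if len(set(dtypes)) == 1:
        data = np.frombuffer(blob[:need], dtype=dtypes[0]).reshape(tot, par).astype(float)
    else:
        rec = np.frombuffer(blob[:need], dtype=[(f"c{i}", dt) for i, dt in enumerate(dtypes)])
        data = np.column_stack([rec[f"c{i}"].astype(float) for i in range(par)])

    labels = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, par + 1)]
    if len(set(labels)) != len(labels):
        raise DataError("duplicate $PnN channel names")
    df = pd.DataFrame(data, columns=labels)
    time = None
    if TIME_CHANNEL in df.columns:
        time = df.pop(TIME_CHANNEL).to_numpy()
    return EventTable(df, time)
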