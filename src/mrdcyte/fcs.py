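"""Minimal FCS 3.0/3.1 reading for pre-compensated list-mode data.

Covers the common case produced by clinical cytometers: list mode
(``$MODE L``), float (``$DATATYPE F``/``D``) or fixed-width integer
(``$DATATYPE I``) events, little- or big-endian.  Channel columns are
named from ``$PnS`` (stain name) when present, else ``$PnN``, with an
optional user alias table to map instrument names onto panel names.
Values are taken as-is (linear, pre-compensated); no transformation or
spillover handling is attempted.
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd

from .simulate import EventMatrix


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # a doubled delimiter escapes a literal delimiter inside a value
    parts = body.strip(delim).replace(delim * 2, "\x00").split(delim)
    parts = [p.replace("\x00", delim) for p in parts]
    if len(parts) % 2:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path, channel_aliases: dict[str, str] | None = None,
             sample_id: str | None = None) -> EventMatrix:
    """Read one FCS 3.0/3.1 file into an :class:`EventMatrix`."""
    with open(path, "rb") as fh:
        header = fh.read(58)
        version = header[:6].decode("ascii", "replace")
        if not version.startswith("FCS3"):
            raise ValueError(f"unsupported FCS version {version!r}")
        text_begin, text_end = int(header[10:18]), int(header[18:26])
        fh.seek(text_begin)
        keywords = _parse_text_segment(fh.read(text_end - text_begin + 1))
        data_begin = int(keywords.get("$BEGINDATA") or header[26:34])
        data_end = int(keywords.get("$ENDDATA") or header[34:42])

        if keywords.get("$MODE", "L").upper() != "L":
            raise ValueError("only list-mode ($MODE L) FCS files are supported")
        n_par = int(keywords["$PAR"])
        n_tot = int(keywords["$TOT"])
        datatype = keywords.get("$DATATYPE", "F").upper()
        byteord = keywords.get("$BYTEORD", "1,2,3,4")
        endian = "<" if byteord.startswith("1") else ">"

        names = []
        for i in range(1, n_par + 1):
            name = keywords.get(f"$P{i}S") or keywords.get(f"$P{i}N") or f"P{i}"
            names.append(name.strip())

        fh.seek(data_begin)
        raw = fh.read(data_end - data_begin + 1)

    if datatype == "F":
        data = np.frombuffer(raw, dtype=endian + "f4", count=n_par * n_tot)
    elif datatype == "D":
        data = np.frombuffer(raw, dtype=endian + "f8", count=n_par * n_tot)
    elif datatype == "I":
        bits = {int(keywords[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise ValueError("only uniform 16/32-bit integer data supported")
        width = int(keywords["$P1B"]) // 8
        fmt = {2: "u2", 4: "u4"}[width]
        data = np.frombuffer(raw, dtype=endian + fmt, count=n_par * n_tot)
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")

    table = pd.DataFrame(np.asarray(data, dtype=np.float64).reshape(n_tot, n_par),
                         columns=names)
    if channel_aliases:
        table = table.rename(columns=channel_aliases)
    name = sample_id if sample_id is not None else str(path)
    return EventMatrix(table, None, name)


def write_fcs(path, table: pd.DataFrame, extra_keywords: dict | None = None) -> None:
    """Write a minimal FCS 3.1 file (float32 list mode, little-endian).

    Intended for tests and interoperability round-trips, not for
    instrument-grade output.
    """
    n_tot, n_par = table.shape
    data = np.ascontiguousarray(table.to_numpy(dtype="<f4"))
    keywords = {
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot), "$NEXTDATA": "0",
    }
    for i, col in enumerate(table.columns, start=1):
        keywords[f"$P{i}N"] = str(col)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = "262144"
    if extra_keywords:
        keywords.update({str(k): str(v) for k, v in extra_keywords.items()})

    header_len = 58
    # iterate because the TEXT length depends on the offsets it encodes
    text = b""
    for _ in range(3):
        text_begin = header_len
        text_end = text_begin + len(text) - 1 if text else text_begin
        data_begin = text_end + 1
        data_end = data_begin + data.nbytes - 1
        keywords["$BEGINDATA"] = str(data_begin)
        keywords["$ENDDATA"] = str(data_end)
        text = "/" + "".join(f"{k}/{v}/" for k, v in keywords.items())
        text = text.encode("latin-1")
    text_end = header_len + len(text) - 1
    data_begin, data_end = text_end + 1, text_end + data.nbytes

    header = b"FCS3.1    "
    header += f"{header_len:8d}{text_end:8d}".encode()
    if data_end <= 99_999_999:
        header += f"{data_begin:8d}{data_end:8d}".encode()
    else:
        header += f"{0:8d}{0:8d}".encode()
    header += f"{0:8d}{0:8d}".encode()  # no ANALYSIS segment
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(struct.pack(f"<{data.size}f", *data.ravel()))
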