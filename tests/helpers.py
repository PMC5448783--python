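"""Test-only helpers: a minimal synthetic EDF/EDF+ writer.

No installed package writes EDF, so the fixtures fabricate files directly
following the format description (256-byte fixed header, 256 bytes per
signal header, int16 little-endian data records; EDF+ annotations as TAL
strings in a dedicated 'EDF Annotations' signal).  This writer exists
solely to exercise the package's EDF *reader* on synthetic content; it is
not part of the library surface.
"""

from __future__ import annotations

import numpy as np


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")
    assert len(b) <= n, (s, n)
    return b + b" " * (n - len(b))


def write_edf(
    path,
    signal: np.ndarray,
    fs: float,
    ch_names=None,
    annotations=None,
    phys_range=(-1000.0, 1000.0),
    truncate_at: int = None,
):
    """Write ``signal`` (channels x samples, microvolts) as EDF.

    ``annotations`` is an optional list of (onset_s, duration_s, text);
    providing it switches the file to EDF+C with a TAL annotation signal.
    ``truncate_at`` cuts the byte stream (for error-path tests).
    """
    signal = np.asarray(signal, dtype=float)
    n_ch, n_samp = signal.shape
    if ch_names is None:
        ch_names = [f"E{i + 1}" for i in range(n_ch)]
    record_dur = 1.0
    spr = int(round(fs * record_dur))  # samples per record per channel
    assert n_samp % spr == 0, "signal length must be whole data records"
    n_records = n_samp // spr

    has_ann = annotations is not None
    ann_spr = 64  # 2-byte samples reserved for TALs per record
    n_sig = n_ch + (1 if has_ann else 0)
    header_bytes = 256 + 256 * n_sig

    pmin, pmax = phys_range
    dmin, dmax = -32768, 32767

    head = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2020 X X X", 80),
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(str(header_bytes), 8),
            _pad("EDF+C" if has_ann else "", 44),
            _pad(str(n_records), 8),
            _pad(str(record_dur), 8),
            _pad(str(n_sig), 4),
        ]
    )

    labels = [_pad(n, 16) for n in ch_names]
    transducer = [_pad("", 80)] * n_ch
    dims = [_pad("uV", 8)] * n_ch
    pmins = [_pad(str(pmin), 8)] * n_ch
    pmaxs = [_pad(str(pmax), 8)] * n_ch
    dmins = [_pad(str(dmin), 8)] * n_ch
    dmaxs = [_pad(str(dmax), 8)] * n_ch
    prefilt = [_pad("", 80)] * n_ch
    sprs = [_pad(str(spr), 8)] * n_ch
    reserved = [_pad("", 32)] * n_ch
    if has_ann:
        labels.append(_pad("EDF Annotations", 16))
        transducer.append(_pad("", 80))
        dims.append(_pad("", 8))
        pmins.append(_pad("-1", 8))
        pmaxs.append(_pad("1", 8))
        dmins.append(_pad(str(dmin), 8))
        dmaxs.append(_pad(str(dmax), 8))
        prefilt.append(_pad("", 80))
        sprs.append(_pad(str(ann_spr), 8))
        reserved.append(_pad("", 32))
    head += b"".join(
        b"".join(group)
        for group in (labels, transducer, dims, pmins, pmaxs, dmins, dmaxs,
                      prefilt, sprs, reserved)
    )

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((signal - pmin) * scale + dmin), dmin, dmax).astype("<i2")

    ann_by_record = [[] for _ in range(n_records)]
    if has_ann:
        for onset, dur, text in annotations:
            rec = min(int(onset // record_dur), n_records - 1)
            ann_by_record[rec].append((onset, dur, text))

    body = bytearray()
    for r in range(n_records):
        for c in range(n_ch):
            body += digital[c, r * spr : (r + 1) * spr].tobytes()
        if has_ann:
            tal = f"+{r * record_dur:g}\x14\x14\x00".encode("ascii")
            for onset, dur, text in ann_by_record[r]:
                tal += f"+{onset:g}\x15{dur:g}\x14{text}\x14\x00".encode("ascii")
            tal = tal.ljust(2 * ann_spr, b"\x00")
            assert len(tal) == 2 * ann_spr, "annotations overflow the TAL signal"
            body += tal

    blob = head + bytes(body)
    if truncate_at is not None:
        blob = blob[:truncate_at]
    with open(path, "wb") as fh:
        fh.write(blob)
    return path
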