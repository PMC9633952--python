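"""Minimal independent EDF writer used as an oracle for the EDF reader.

Implements the published EDF layout directly (256-byte fixed header,
256 bytes per signal header, int16 little-endian samples), with one
1-second data record per second of signal.  Test-only helper; supports
plain continuous signals in microvolts, no annotations.
"""

import numpy as np

PHYS_MIN, PHYS_MAX = -1000.0, 1000.0
DIG_MIN, DIG_MAX = -32768, 32767


def _field(value, width):
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_minimal_edf(path, data_uv, fs, labels):
    """Write `data_uv` (channels x samples, µV) as a plain EDF file."""
    data_uv = np.asarray(data_uv, dtype=float)
    n_sig, n_samp = data_uv.shape
    fs = int(fs)
    assert n_samp % fs == 0, "whole seconds only"
    n_rec = n_samp // fs

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field("01.01.20", 8),
        _field("00.00.00", 8),
        _field(256 * (1 + n_sig), 8),
        _field("", 44),
        _field(n_rec, 8),
        _field(1, 8),
        _field(n_sig, 4),
    ])
    sig_header = b"".join([
        b"".join(_field(l, 16) for l in labels),
        b"".join(_field("AgAgCl electrode", 80) for _ in labels),
        b"".join(_field("uV", 8) for _ in labels),
        b"".join(_field(PHYS_MIN, 8) for _ in labels),
        b"".join(_field(PHYS_MAX, 8) for _ in labels),
        b"".join(_field(DIG_MIN, 8) for _ in labels),
        b"".join(_field(DIG_MAX, 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(fs, 8) for _ in labels),
        b"".join(_field("", 32) for _ in labels),
    ])
    gain = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.clip(
        np.round((data_uv - PHYS_MIN) * gain + DIG_MIN), DIG_MIN, DIG_MAX
    ).astype("<i2")
    records = []
    for r in range(n_rec):
        records.append(digital[:, r * fs:(r + 1) * fs].tobytes())
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in records:
            fh.write(rec)
    return path
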