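"""Minimal EDF (European Data Format) writer.

Writes plain EDF: a fixed 256-byte header, one 256-byte header block per
signal, then 1-second data records of little-endian 16-bit integers with
per-channel physical scaling.  Quantization to 16 bits means round-trips are
exact only to ~(phys range)/65535.  The sampling rate must be a positive
integer (samples per 1-s record) and recordings are zero-padded to a whole
number of records.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _ascii_field(value: str, width: int) -> bytes:
    out = value.encode("ascii", errors="replace")[:width]
    return out.ljust(width)


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sfreq: float,
    ch_names: list[str],
    physical_dim: str = "uV",
) -> None:
    """Write a (channels x samples) µV array as an EDF file.

    Parameters
    ----------
    data : ndarray (n_channels, n_samples)
    sfreq : float
        Must be a positive integer number of samples per second.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    if len(ch_names) != data.shape[0]:
        raise ValueError("channel count mismatch")
    if sfreq <= 0 or abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1-s record
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    # per-channel physical range; degenerate (flat) channels get a unit span
    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 0.5
    pmax[flat] += 0.5

    now = datetime.datetime(2000, 1, 1)
    header = b""
    header += _ascii_field("0", 8)
    header += _ascii_field("X X X X", 80)  # patient id
    header += _ascii_field("Startdate X X X X", 80)  # recording id
    header += _ascii_field(now.strftime("%d.%m.%y"), 8)
    header += _ascii_field(now.strftime("%H.%M.%S"), 8)
    header += _ascii_field(str(256 * (1 + n_ch)), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(str(n_rec), 8)
    header += _ascii_field("1", 8)  # record duration, seconds
    header += _ascii_field(str(n_ch), 4)

    def sig_fields(values: list[str], width: int) -> bytes:
        return b"".join(_ascii_field(v, width) for v in values)

    header += sig_fields(list(ch_names), 16)
    header += sig_fields([""] * n_ch, 80)  # transducer
    header += sig_fields([physical_dim] * n_ch, 8)
    header += sig_fields([f"{v:.6g}"[:8] for v in pmin], 8)
    header += sig_fields([f"{v:.6g}"[:8] for v in pmax], 8)
    header += sig_fields([str(_DIG_MIN)] * n_ch, 8)
    header += sig_fields([str(_DIG_MAX)] * n_ch, 8)
    header += sig_fields([""] * n_ch, 80)  # prefiltering
    header += sig_fields([str(spr)] * n_ch, 8)
    header += sig_fields([""] * n_ch, 32)

    # physical -> digital, using the printed (8-char) physical bounds so the
    # reader's inverse mapping reproduces our values
    pmin_r = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    gain = (_DIG_MAX - _DIG_MIN) / (pmax_r - pmin_r)
    digital = np.rint((padded - pmin_r[:, None]) * gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            chunk = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(chunk.tobytes())
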