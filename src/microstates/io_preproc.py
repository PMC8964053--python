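"""Reading EEG files and the standard resting-state preprocessing chain.

The chain mirrors common microstate practice: resample to 500 Hz, broadband
0.1-70 Hz bandpass plus a 48-52 Hz mains notch, segmentation into 2-s
epochs, amplitude-based epoch rejection, common average reference, and a
final 2-20 Hz bandpass per epoch.  All filters are zero-phase (order-4
Butterworth applied forward-backward); epoch filtering uses reflection
padding to limit edge effects.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import EEGRecording, EpochSet, FormatError

__all__ = [
    "read_recording",
    "resample",
    "filter_band",
    "filter_notch",
    "epoch",
    "reject_epochs",
    "average_reference",
    "preprocess_chain",
]


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

def _read_matrix(path: Path) -> EEGRecording:
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing sidecar metadata file {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
        sfreq = float(meta["sfreq"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed sidecar metadata: {exc}") from exc
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"could not parse matrix container: {exc}") from exc
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise FormatError("empty matrix container")
    if "n_channels" in meta and int(meta["n_channels"]) != df.shape[1]:
        raise FormatError(
            f"sidecar declares {meta['n_channels']} channels, "
            f"file has {df.shape[1]}"
        )
    data = df.to_numpy(dtype=float).T
    if not np.all(np.isfinite(data)):
        raise FormatError("matrix container holds non-finite values")
    return EEGRecording(data, sfreq, list(df.columns))


def _read_mne(path: Path, fmt: str) -> EEGRecording:
    import mne

    reader = {
        "edf": mne.io.read_raw_edf,
        "brainvision": mne.io.read_raw_brainvision,
    }[fmt]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = reader(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse {fmt} file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(data_uv, float(raw.info["sfreq"]), list(raw.ch_names))


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF, BrainVision (.vhdr) or the plain
    matrix container (tab-delimited samples x channels with a JSON sidecar).

    ``format`` may be ``"edf"``, ``"brainvision"`` or ``"matrix"``; when
    omitted it is inferred from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {
            ".edf": "edf",
            ".vhdr": "brainvision",
            ".tsv": "matrix",
            ".csv": "matrix",
            ".txt": "matrix",
        }.get(path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "matrix":
        return _read_matrix(path)
    if format in ("edf", "brainvision"):
        return _read_mne(path, format)
    raise ValueError(f"unknown format {format!r}")


# --------------------------------------------------------------------------
# preprocessing operations
# --------------------------------------------------------------------------

def resample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Polyphase resampling to ``target_rate`` Hz (band-preserving)."""
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if np.isclose(target_rate, rec.sfreq):
        return EEGRecording(rec.data.copy(), rec.sfreq, list(rec.ch_names),
                            list(rec.bads))
    from fractions import Fraction

    frac = Fraction(target_rate / rec.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.data, up, down, axis=1)
    n_out = int(np.floor(rec.n_samples * target_rate / rec.sfreq))
    out = out[:, :n_out]
    return EEGRecording(out, target_rate, list(rec.ch_names), list(rec.bads))


def _check_band(low: float, high: float, sfreq: float) -> None:
    nyq = sfreq / 2.0
    if not 0 < low < high:
        raise ValueError("band edges must satisfy 0 < low < high")
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz >= Nyquist ({nyq} Hz)")


def _sosfiltfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    # reflection padding is scipy's default (odd); cap padlen on short epochs
    padlen = min(3 * (2 * sos.shape[0] + 1) * 10, data.shape[-1] - 1)
    return sps.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def filter_band(rec: EEGRecording, low_hz: float, high_hz: float,
                order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth bandpass."""
    _check_band(low_hz, high_hz, rec.sfreq)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=rec.sfreq, output="sos")
    return EEGRecording(_sosfiltfilt(sos, rec.data), rec.sfreq,
                        list(rec.ch_names), list(rec.bads))


def filter_notch(rec: EEGRecording, low_hz: float, high_hz: float,
                 order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-stop (e.g. 48-52 Hz mains notch)."""
    _check_band(low_hz, high_hz, rec.sfreq)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandstop",
                     fs=rec.sfreq, output="sos")
    return EEGRecording(_sosfiltfilt(sos, rec.data), rec.sfreq,
                        list(rec.ch_names), list(rec.bads))


def epoch(rec: EEGRecording, length_s: float = 2.0) -> EpochSet:
    """Cut non-overlapping consecutive epochs; the trailing remainder is
    dropped (an empty :class:`EpochSet` plus a warning if too short)."""
    n_per = int(round(length_s * rec.sfreq))
    if n_per <= 0:
        raise ValueError("epoch length must be positive")
    n_ep = rec.n_samples // n_per
    log = [f"epoch length_s={length_s} -> {n_ep} epochs"]
    if n_ep == 0:
        warnings.warn("recording shorter than one epoch; empty EpochSet")
        log.append("warning: recording shorter than one epoch")
    if n_ep:
        data = np.stack(
            [rec.data[:, i * n_per : (i + 1) * n_per] for i in range(n_ep)]
        )
    else:
        data = np.empty((0, rec.n_channels, n_per))
    return EpochSet(data, rec.sfreq, list(rec.ch_names), log)


def reject_epochs(eps: EpochSet, peak_to_peak_uv_threshold: float = 150.0
                  ) -> EpochSet:
    """Drop epochs whose any-channel peak-to-peak amplitude exceeds the
    threshold (a simple stand-in for manual/ICA artifact removal)."""
    if peak_to_peak_uv_threshold <= 0:
        raise ValueError("threshold must be positive")
    if eps.n_epochs == 0:
        return eps.with_data(eps.data, "reject: no epochs")
    ptp = eps.data.max(axis=2) - eps.data.min(axis=2)  # (epochs, channels)
    keep = np.all(ptp <= peak_to_peak_uv_threshold, axis=1)
    note = (
        f"reject ptp>{peak_to_peak_uv_threshold}uV: removed "
        f"{int((~keep).sum())}/{eps.n_epochs}"
    )
    return eps.with_data(eps.data[keep], note)


def average_reference(eps: EpochSet) -> EpochSet:
    """Re-reference to the common average: channel mean at every sample is 0."""
    if eps.n_channels < 2:
        raise ValueError("average reference requires >= 2 channels")
    data = eps.data - eps.data.mean(axis=1, keepdims=True)
    return eps.with_data(data, "average reference")


def filter_epochs_band(eps: EpochSet, low_hz: float, high_hz: float,
                       order: int = 4) -> EpochSet:
    """Zero-phase bandpass applied per epoch (reflection padding)."""
    _check_band(low_hz, high_hz, eps.sfreq)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=eps.sfreq, output="sos")
    out = _sosfiltfilt(sos, eps.data)
    return eps.with_data(out, f"bandpass {low_hz}-{high_hz} Hz (per epoch)")


def preprocess_chain(
    rec: EEGRecording,
    target_rate: float = 500.0,
    broad_band: tuple[float, float] = (0.1, 70.0),
    notch: tuple[float, float] | None = (48.0, 52.0),
    epoch_s: float = 2.0,
    reject_uv: float | None = 150.0,
    narrow_band: tuple[float, float] = (2.0, 20.0),
) -> EpochSet:
    """The full deterministic preprocessing chain, in flowchart order:
    resample -> broadband filter -> notch -> epoch -> reject -> average
    reference -> narrow bandpass.  Every step is appended to the log."""
    steps = []
    if rec.bads:
        bads = list(rec.bads)
        keep = [i for i, ch in enumerate(rec.ch_names) if ch not in bads]
        warnings.warn(f"dropping bad channels: {bads}")
        rec = EEGRecording(rec.data[keep], rec.sfreq,
                           [rec.ch_names[i] for i in keep])
        steps.append(f"dropped bad channels: {bads}")
    if not np.isclose(rec.sfreq, target_rate):
        rec = resample(rec, target_rate)
        steps.append(f"resample -> {target_rate} Hz")
    if broad_band is not None:
        rec = filter_band(rec, *broad_band)
        steps.append(f"bandpass {broad_band[0]}-{broad_band[1]} Hz")
    if notch is not None and notch[1] < rec.sfreq / 2:
        rec = filter_notch(rec, *notch)
        steps.append(f"notch {notch[0]}-{notch[1]} Hz")
    eps = epoch(rec, epoch_s)
    eps.log = steps + eps.log
    if reject_uv is not None:
        eps = reject_epochs(eps, reject_uv)
    eps = average_reference(eps)
    eps = filter_epochs_band(eps, *narrow_band)
    return eps
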