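"""Shared data containers for the microstate pipeline.

All signal amplitudes are in microvolts (µV), sampling rates in Hz, and
durations in the units named by the attribute (``_ms``, ``_s``).  Topographic
maps ("templates") are always average-referenced (zero mean across channels)
and unit L2 norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel label for samples that could not be assigned to any class.
UNASSIGNED = -1

DEFAULT_CLASS_NAMES = ("A", "B", "C", "D")


class FormatError(ValueError):
    """A file does not parse under the declared standard."""


def class_names(k: int) -> list[str]:
    """Canonical class names: A, B, C, D, then E, F, ... for larger K."""
    if k <= 26:
        return [chr(ord("A") + i) for i in range(k)]
    return [f"M{i:02d}" for i in range(k)]


@dataclass
class EEGRecording:
    """A continuous multichannel EEG signal.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Unique channel names.
    bads : list of str
        Channels flagged as bad (dropped, not interpolated, downstream).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    bads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel-name count does not match data rows")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class EpochSet:
    """Fixed-length, non-overlapping EEG epochs.

    ``data`` has shape (n_epochs, n_channels, n_samples_per_epoch); ``log``
    records the provenance of every processing step applied so far.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_length_s(self) -> float:
        return self.n_samples / self.sfreq

    def with_data(self, data: np.ndarray, note: str) -> "EpochSet":
        return EpochSet(data, self.sfreq, list(self.ch_names), self.log + [note])


@dataclass
class TemplateSet:
    """A set of K microstate template maps (K x C).

    Every row is average-referenced (sums to zero across channels) and has
    unit L2 norm.  ``labels`` gives the ordered class names (A-D for K=4).
    """

    maps: np.ndarray
    labels: list[str]
    ch_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be 2-D (classes x channels)")
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("label count does not match map count")

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def validate(self, rtol: float = 1e-10) -> None:
        """Raise if rows are not zero-mean and unit-norm within tolerance."""
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10, rtol=rtol):
            raise ValueError("template rows must have unit L2 norm")
        sums = self.maps.sum(axis=1)
        if not np.allclose(sums, 0.0, atol=rtol * np.abs(self.maps).max()):
            raise ValueError("template rows must sum to zero across channels")


@dataclass
class GfpSeries:
    """Global field power per sample, per epoch, plus detected peak indices.

    ``values`` has shape (n_epochs, n_samples); ``peaks`` is a list with one
    integer index array per epoch (indices into the epoch's sample axis).
    """

    values: np.ndarray
    sfreq: float
    peaks: list[np.ndarray] | None = None

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


@dataclass
class MicrostateSegmentation:
    """Per-sample class labels from backfitting.

    ``labels`` (n_epochs, n_samples) holds integer class indices into
    ``class_names``, or :data:`UNASSIGNED`.  ``correlation`` holds the
    absolute spatial correlation between the sample topography and the
    assigned template (0 where unassigned).  ``correlation_all`` optionally
    retains the full per-class signed correlation tensor
    (n_epochs, n_classes, n_samples) for label smoothing.
    """

    labels: np.ndarray
    correlation: np.ndarray
    class_names: list[str]
    sfreq: float
    correlation_all: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.labels.shape != self.correlation.shape:
            raise ValueError("labels and correlation must share shape")

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.labels.shape[1]

    def copy(self) -> "MicrostateSegmentation":
        return MicrostateSegmentation(
            self.labels.copy(),
            self.correlation.copy(),
            list(self.class_names),
            self.sfreq,
            None if self.correlation_all is None else self.correlation_all.copy(),
        )


@dataclass
class SubjectMetrics:
    """Per-class temporal dynamics of one subject's segmentation.

    duration_ms
        Mean length of same-label segments, in ms (NaN if a class never
        occurs).
    occurrence_per_s
        Counted segment onsets per analyzed second.
    contribution
        Fraction of analyzed samples carrying the label (sums to 1 across
        classes when no sample is unassigned).
    """

    class_names: list[str]
    duration_ms: np.ndarray
    occurrence_per_s: np.ndarray
    contribution: np.ndarray
    total_time_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_names,
                "duration_ms": self.duration_ms,
                "occurrence_per_s": self.occurrence_per_s,
                "contribution": self.contribution,
            }
        )
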