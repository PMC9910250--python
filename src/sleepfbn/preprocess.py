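"""EEG recording containers, band-pass filtering and NREM-II segment extraction.

The pipeline analyses ten 15-s windows taken from stage-2 NREM sleep of an
8-channel recording (C3, C4, P3, P4, O1, O2, P7, P8; Cz reference; 128 Hz).
Sleep staging itself is out of scope: segments are taken from the supplied
recording either sequentially or at seeded random non-overlapping positions,
standing in for the windows a technician would mark.

Filtering is a 4th-order Butterworth band-pass (0.30–30 Hz by default) applied
forward and backward (zero phase), since phase distortion would bias the
cross-channel Pearson correlations downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidBandError,
)
from .reference import EEG_CHANNELS, FILTER_BAND, N_SEGMENTS, SAMPLING_RATE, SEGMENT_DURATION

logger = logging.getLogger(__name__)


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in µV with montage and sampling metadata.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Physical-unit signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Ordered, unique channel names; the order is preserved through the
        whole pipeline.
    reference_label : str
        Reference electrode at acquisition (Cz; no re-referencing is done).
    """

    signal: np.ndarray
    fs: float = SAMPLING_RATE
    channel_labels: tuple = EEG_CHANNELS
    reference_label: str = "Cz"
    subject_id: str = ""
    timepoint: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.signal.ndim != 2:
            raise InvalidArgumentError("signal must be a channels x samples matrix")
        if self.fs <= 0:
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.shape[1] < 1:
            raise InvalidArgumentError("recording must contain at least one sample")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise InvalidArgumentError(
                f"{len(self.channel_labels)} labels for {self.signal.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidArgumentError("channel labels must be unique")
        if not np.all(np.isfinite(self.signal)):
            raise InvalidArgumentError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class SegmentSet:
    """The analysis windows of one subject x timepoint.

    ``segments`` is a list of channels x samples arrays; ``starts`` records
    the start sample of each window in the source recording (provenance).
    Windows are non-overlapping and stored in temporal order.
    """

    segments: list
    fs: float
    channel_labels: tuple
    starts: tuple
    subject_id: str = ""
    timepoint: str = ""

    def __post_init__(self):
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        self.channel_labels = tuple(self.channel_labels)
        self.starts = tuple(int(s) for s in self.starts)
        if len(self.segments) != len(self.starts):
            raise InvalidArgumentError("one start index required per segment")
        n_samp = {s.shape[1] for s in self.segments}
        if len(n_samp) > 1:
            raise InvalidArgumentError("all segments must have the same length")
        # non-overlap + temporal order, asserted on provenance indices
        if self.segments:
            dur = self.segments[0].shape[1]
            for a, b in zip(self.starts, self.starts[1:]):
                if b < a + dur:
                    raise InvalidArgumentError(
                        f"segments overlap or are out of order (starts {a}, {b}, length {dur})"
                    )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def segment_duration(self) -> float:
        return self.segments[0].shape[1] / self.fs if self.segments else 0.0


def bandpass_filter(
    rec: EEGRecording,
    low: float = FILTER_BAND[0],
    high: float = FILTER_BAND[1],
    order: int = 4,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass of an EEG recording.

    A ``order``-th order Butterworth band-pass is applied forward-backward
    (``sosfiltfilt``), doubling the effective attenuation and cancelling the
    phase response. DC is removed by the high-pass branch.

    Raises
    ------
    InvalidBandError
        If the corners do not satisfy ``0 < low < high < fs/2``.
    """
    nyq = rec.fs / 2.0
    if not (0.0 < low < high):
        raise InvalidBandError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise InvalidBandError(f"high corner {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return EEGRecording(
        signal=filtered,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        reference_label=rec.reference_label,
        subject_id=rec.subject_id,
        timepoint=rec.timepoint,
    )


def extract_segments(
    rec: EEGRecording,
    n: int = N_SEGMENTS,
    dur: float = SEGMENT_DURATION,
    strategy: str = "sequential",
    seed: int | None = None,
) -> SegmentSet:
    """Extract ``n`` non-overlapping ``dur``-second windows from a recording.

    ``strategy="sequential"`` tiles windows from the start of the recording;
    ``strategy="random"`` places them uniformly at random among all
    non-overlapping configurations (seeded), emulating random interception of
    NREM-II epochs by a technician.

    Raises
    ------
    InsufficientDataError
        If the recording is shorter than ``n * dur`` seconds.
    """
    seg_len = int(round(dur * rec.fs))
    if seg_len < 1 or n < 1:
        raise InvalidArgumentError("need n >= 1 segments of >= 1 sample")
    required = n * seg_len
    if rec.n_samples < required:
        raise InsufficientDataError(
            f"recording has {rec.n_samples} samples but {required} are required "
            f"({n} segments x {seg_len} samples)"
        )
    if strategy == "sequential":
        starts = [i * seg_len for i in range(n)]
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        # exactly uniform over all non-overlapping placements: a sorted
        # n-combination of {0..spare+n-1} minus its index gives the n cut
        # positions among the spare samples (stars-and-bars bijection)
        spare = rec.n_samples - required
        cuts = np.sort(rng.choice(spare + n, size=n, replace=False)) - np.arange(n)
        starts = [int(c + i * seg_len) for i, c in enumerate(cuts)]
    else:
        raise InvalidArgumentError(f"unknown strategy {strategy!r}")
    segments = [rec.signal[:, s : s + seg_len] for s in starts]
    return SegmentSet(
        segments=segments,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        starts=starts,
        subject_id=rec.subject_id,
        timepoint=rec.timepoint,
    )
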