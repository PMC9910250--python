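"""File I/O: EDF recordings, delimited tables, networks and segment sets.

Reading EDF goes through :func:`mne.io.read_raw_edf`.  Writing uses a small
16-bit EDF writer implemented here (physical dimension µV, one channel per
signal), sufficient for round-tripping pipeline fixtures and outputs through
any clinical EDF reader.

Tables (scale scores, regional volumes, metrics) are UTF-8 comma-delimited
text with a one-line header; networks are labelled square matrices in the
same format.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelMissingError, FormatError, InvalidArgumentError
from .preprocess import EEGRecording, SegmentSet
from .reference import EEG_CHANNELS

logger = logging.getLogger(__name__)

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_float(value: float, width: int = 8) -> str:
    """Format a float into at most ``width`` ASCII chars, parseable back."""
    for fmt in (f"{value:.7g}", f"{value:.5g}", f"{value:.3g}", f"{value:.2g}", f"{value:.1g}"):
        if len(fmt) <= width:
            return fmt
    raise FormatError(f"cannot format {value} in {width} chars")


def write_edf(rec: EEGRecording, path) -> Path:
    """Write a recording as 16-bit EDF with physical dimension µV.

    Uses 1-second data records when the sample count divides evenly, else a
    single record spanning the whole signal.  Quantization to the 16-bit
    digital range bounds the round-trip error by half a quantization step
    (~(max-min)/65535 µV per channel).
    """
    path = Path(path)
    n_ch, n_samples = rec.signal.shape
    fs = rec.fs
    if float(fs).is_integer() and n_samples % int(fs) == 0:
        samples_per_record = int(fs)
        n_records = n_samples // samples_per_record
        record_duration = 1.0
    else:
        samples_per_record = n_samples
        n_records = 1
        record_duration = n_samples / fs

    # physical ranges are written as ASCII then parsed back, so the scaling
    # used for quantization matches the header bit-for-bit
    pmin_s, pmax_s = [], []
    for ch in range(n_ch):
        lo, hi = float(rec.signal[ch].min()), float(rec.signal[ch].max())
        if hi <= lo:
            hi = lo + 1.0
        pmin_s.append(_fmt_float(lo))
        pmax_s.append(_fmt_float(hi))
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.array([float(s) for s in pmax_s])

    header = b""
    header += _ascii_field("0", 8)
    header += _ascii_field(rec.subject_id or "X", 80)
    header += _ascii_field(f"Startdate 01-JAN-2020 {rec.timepoint or 'X'}", 80)
    header += _ascii_field("01.01.20", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (1 + n_ch), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(_fmt_float(record_duration), 8)
    header += _ascii_field(n_ch, 4)
    for label in rec.channel_labels:
        header += _ascii_field(label, 16)
    header += _ascii_field("", 80) * n_ch                     # transducer
    header += _ascii_field("uV", 8) * n_ch                    # physical dimension
    header += b"".join(_ascii_field(s, 8) for s in pmin_s)
    header += b"".join(_ascii_field(s, 8) for s in pmax_s)
    header += _ascii_field(_DIG_MIN, 8) * n_ch
    header += _ascii_field(_DIG_MAX, 8) * n_ch
    header += _ascii_field("", 80) * n_ch                     # prefiltering
    header += _ascii_field(samples_per_record, 8) * n_ch
    header += _ascii_field("", 32) * n_ch

    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.signal - pmin[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * samples_per_record, (r + 1) * samples_per_record)
            for ch in range(n_ch):
                fh.write(digital[ch, sl].tobytes())
    return path


def read_edf(
    path,
    required_channels=EEG_CHANNELS,
    subject_id: str = "",
    timepoint: str = "",
) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` in µV.

    Non-EEG channels (e.g. a separate ECG channel) and any channel not in
    ``required_channels`` are dropped with a logged notice, and the remaining
    channels are reordered into the canonical montage order.

    Raises
    ------
    FormatError
        If the file is missing or not valid EDF.
    ChannelMissingError
        If any required channel is absent (the error names it).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted exceptions on bad files
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc

    available = list(raw.ch_names)
    required = list(required_channels)
    missing = [ch for ch in required if ch not in available]
    if missing:
        raise ChannelMissingError(missing, available)
    dropped = [ch for ch in available if ch not in required]
    if dropped:
        logger.info("dropping non-montage channel(s) from %s: %s", path.name, ", ".join(dropped))
    raw.pick(required)
    raw.reorder_channels(required)
    data_uv = raw.get_data() * 1e6  # mne holds EEG in volts
    return EEGRecording(
        signal=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(required),
        subject_id=subject_id,
        timepoint=timepoint,
    )


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as UTF-8 comma-delimited text with a one-line header."""
    path = Path(path)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def read_table(path, required_columns=()) -> pd.DataFrame:
    """Read a comma-delimited table, checking required columns are present."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path} lacks required column(s): {', '.join(missing)}")
    return df


def write_network(weights: np.ndarray, labels, path) -> Path:
    """Serialize a labelled square weight matrix as delimited text."""
    df = pd.DataFrame(np.asarray(weights), index=list(labels), columns=list(labels))
    df.to_csv(Path(path), index_label="node")
    return Path(path)


def read_network(path):
    """Read a labelled square weight matrix written by :func:`write_network`."""
    df = pd.read_csv(Path(path), index_col="node")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_segments(segs: SegmentSet, path) -> Path:
    """Store a segment set as an .npz container with JSON provenance."""
    meta = {
        "fs": segs.fs,
        "channel_labels": list(segs.channel_labels),
        "starts": list(segs.starts),
        "subject_id": segs.subject_id,
        "timepoint": segs.timepoint,
    }
    np.savez(
        Path(path),
        data=np.stack(segs.segments) if segs.segments else np.empty((0, 0, 0)),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )
    return Path(path)


def read_segments(path) -> SegmentSet:
    """Load a segment set written by :func:`write_segments`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"segment file not found: {path}")
    with np.load(path) as z:
        data = z["data"]
        meta = json.loads(bytes(z["meta"]).decode())
    return SegmentSet(
        segments=list(data),
        fs=meta["fs"],
        channel_labels=tuple(meta["channel_labels"]),
        starts=tuple(meta["starts"]),
        subject_id=meta["subject_id"],
        timepoint=meta["timepoint"],
    )
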