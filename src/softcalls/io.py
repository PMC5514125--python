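"""WAV and event-table input/output.

Event streams are plain :class:`pandas.DataFrame` objects with the
columns ``bird_id, call_type, onset_s, offset_s`` (one row per
vocalization, time-sorted).  Audio travels as float arrays in [-1, 1];
on disk it is 16-bit PCM by default, with 32-bit float available when a
lossless round trip matters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import wavfile

EVENT_COLUMNS = ["bird_id", "call_type", "onset_s", "offset_s"]

__all__ = ["EVENT_COLUMNS", "write_wav", "read_wav", "write_events", "read_events"]


def write_wav(path, samples: np.ndarray, sample_rate: int, subtype: str = "PCM_16") -> None:
    """Write mono audio to ``path``.

    subtype: ``"PCM_16"`` (default) or ``"FLOAT"`` (32-bit, lossless for
    float32 data).
    """
    samples = np.asarray(samples, dtype=np.float64)
    if subtype == "PCM_16":
        clipped = np.clip(samples, -1.0, 1.0)
        data = np.round(clipped * 32767.0).astype(np.int16)
    elif subtype == "FLOAT":
        data = samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV subtype: {subtype!r}")
    wavfile.write(path, int(sample_rate), data)


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read mono audio; returns ``(samples_float64, sample_rate)``.

    Integer PCM is rescaled to [-1, 1] with the same factor used when
    writing, so a PCM_16 round trip is exact up to quantization.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    else:
        samples = data.astype(np.float64)
    return samples, int(rate)


def write_events(path, events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    events.loc[:, EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    return events
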