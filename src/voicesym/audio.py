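"""Audio containers, PCM WAV input/output and signal framing.

Recordings are mono PCM waveforms held as float64 in [-1, 1].  The study
format is 16-bit linear PCM at 11.025 kHz, one channel; the reader accepts
any PCM-integer or float mono WAV and normalizes to float.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass
class AudioRecording:
    """Mono waveform with its sample rate and provenance ids.

    ``samples`` are float amplitudes in [-1, 1]; ``phrase_id`` indexes the
    fixed-phrase catalogue (1-21), ``subject_id`` is opaque.
    """

    samples: np.ndarray
    rate: float
    phrase_id: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("recording must be mono (1-D samples)")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class FrameSeries:
    """Per-frame values of one feature with frame times and a voicing mask.

    Unvoiced or invalid frames hold NaN in ``values``; ``voiced_mask`` marks
    frames whose value is meaningful.
    """

    values: np.ndarray
    frame_times: np.ndarray
    voiced_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.voiced_mask is None:
            self.voiced_mask = np.isfinite(self.values)
        self.voiced_mask = np.asarray(self.voiced_mask, dtype=bool)
        if not (len(self.values) == len(self.frame_times) == len(self.voiced_mask)):
            raise ValueError("values, frame_times and voiced_mask must have equal length")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    def voiced_values(self) -> np.ndarray:
        v = self.values[self.voiced_mask]
        return v[np.isfinite(v)]


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as 16-bit PCM mono WAV."""
    x = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(rec.rate), pcm)


def read_wav(path: str | Path, phrase_id: int = 0, subject_id: str = "") -> AudioRecording:
    """Read a mono WAV file into an :class:`AudioRecording`.

    Integer PCM is scaled to [-1, 1]; stereo input is rejected.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got {data.ndim} channels")
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    return AudioRecording(samples=x, rate=float(rate), phrase_id=phrase_id, subject_id=subject_id)


def frame_signal(
    rec: AudioRecording,
    frame_len: float = 0.025,
    hop: float = 0.010,
    window: str | None = "hamming",
) -> tuple[np.ndarray, np.ndarray]:
    """Slice a recording into overlapping windowed frames.

    Parameters
    ----------
    frame_len, hop:
        Frame length and hop in seconds; ``frame_len >= hop > 0``.  The final
        partial frame is dropped.
    window:
        ``"hamming"`` (default) or ``None`` for rectangular frames.

    Returns
    -------
    frames : (n_frames, frame_samples) array
    times : frame-center times in seconds
    """
    if hop <= 0 or frame_len < hop:
        raise ValueError("require frame_len >= hop > 0")
    n_frame = int(round(frame_len * rec.rate))
    n_hop = int(round(hop * rec.rate))
    x = rec.samples
    if len(x) < n_frame or n_frame < 2:
        raise ValueError("recording shorter than one frame")
    n_frames = (len(x) - n_frame) // n_hop + 1
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    if window == "hamming":
        frames = frames * np.hamming(n_frame)[None, :]
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    times = (np.arange(n_frames) * n_hop + n_frame / 2) / rec.rate
    return frames, times
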