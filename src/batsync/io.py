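"""Readers and writers for the on-disk interchange formats.

Frames travel as multi-page 16-bit grayscale TIFF with a ``frames.csv``
timestamp sidecar; pulses and events as plain CSV; audio as 192 kHz mono
WAV (one file per acoustic trigger, as a field detector would write).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.io import wavfile

from .acoustics import CallFile, Pulse, pulses_from_frame, pulses_to_frame
from .synthetic import FrameSequence, GroundTruthLog, synthesize_waveform

__all__ = [
    "write_frames", "read_frames", "write_pulses_csv", "read_pulses_csv",
    "write_truth_csv", "write_call_file_wavs", "read_wav",
]


def write_frames(out_dir: str | Path, frames: FrameSequence,
                 stem: str = "frames") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pixels = np.clip(frames.pixels, 0, 65535).astype(np.uint16)
    tifffile.imwrite(out_dir / f"{stem}.tif", pixels, photometric="minisblack")
    pd.DataFrame({"frame_index": np.arange(len(frames)),
                  "t_seconds": frames.times_s}).to_csv(out_dir / f"{stem}.csv",
                                                       index=False)


def read_frames(in_dir: str | Path, stem: str = "frames") -> FrameSequence:
    in_dir = Path(in_dir)
    pixels = tifffile.imread(in_dir / f"{stem}.tif")
    if pixels.ndim == 2:
        pixels = pixels[None]
    sidecar = pd.read_csv(in_dir / f"{stem}.csv")
    return FrameSequence(times_s=sidecar["t_seconds"].to_numpy(), pixels=pixels)


def write_pulses_csv(path: str | Path, pulses: list[Pulse]) -> None:
    pulses_to_frame(pulses).to_csv(path, index=False)


def read_pulses_csv(path: str | Path) -> list[Pulse]:
    return pulses_from_frame(pd.read_csv(path))


def write_truth_csv(path: str | Path, truth: GroundTruthLog) -> None:
    truth.to_frame().to_csv(path, index=False)


def write_call_file_wavs(out_dir: str | Path, call_files: list[CallFile],
                         sample_rate: float = 192_000.0, pad_s: float = 0.2,
                         rng: np.random.Generator | None = None) -> list[Path]:
    """Synthesize one WAV per trigger file (FM sweeps in noise)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cf in call_files:
        local = [Pulse(onset_s=p.onset_s - cf.t_start_s + pad_s,
                       duration_ms=p.duration_ms, fmin_khz=p.fmin_khz,
                       fmax_khz=p.fmax_khz, fpeak_khz=p.fpeak_khz,
                       amplitude_db=p.amplitude_db) for p in cf.pulses]
        dur = max(p.end_s for p in local) + pad_s
        x = synthesize_waveform(local, dur, sample_rate, rng=rng)
        x16 = np.clip(x / max(np.abs(x).max(), 1e-9) * 0.8 * 32767, -32768, 32767)
        path = out_dir / f"call_{cf.file_id:05d}.wav"
        wavfile.write(path, int(sample_rate), x16.astype(np.int16))
        paths.append(path)
    return paths


def read_wav(path: str | Path) -> tuple[float, np.ndarray]:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data.astype(float) / 32768.0
    return float(rate), np.asarray(data, dtype=float)
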