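"""Grayscale frame-sequence container and lossless frame-stack I/O.

Clips are stored on disk as a stack of numbered PNG frames
(``frame_000000.png`` ...) plus a JSON sidecar (``clip.json``) carrying the
frame rate, because the rate cannot be recovered from still images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

SIDECAR_NAME = "clip.json"
FRAME_PATTERN = "frame_{:06d}.png"


@dataclass
class FrameSequence:
    """Time-ordered stack of equal-shaped grayscale frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``; uint8 or float.
        Pixel coordinates are (row, col), 0-based, origin at the top left.
    fps
        Frame rate in frames per second; must be positive.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a FrameSequence needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        """Per-frame acquisition times in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) / self.fps


def write_frames(path: str | Path, seq: FrameSequence) -> Path:
    """Write a clip as a numbered PNG stack with a JSON sidecar.

    The round trip through :func:`read_frames` is lossless for uint8 frames.
    Float frames are clipped to [0, 1] and quantized to 8 bits.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = seq.frames
    if frames.dtype != np.uint8:
        frames = np.clip(np.round(np.asarray(frames, float) * 255), 0, 255).astype(np.uint8)
    for i, frame in enumerate(frames):
        iio.imwrite(path / FRAME_PATTERN.format(i), frame)
    sidecar = {"fps": float(seq.fps), "n_frames": int(seq.n_frames)}
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def read_frames(path: str | Path) -> FrameSequence:
    """Read a PNG frame stack written by :func:`write_frames`.

    Raises
    ------
    FileNotFoundError
        If the directory or sidecar is missing.
    ValueError
        If the sidecar lacks the ``fps`` field, frame numbering has gaps,
        or frames disagree in shape.
    """
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "fps" not in sidecar:
        raise ValueError(f"sidecar {sidecar_path} lacks required field 'fps'")
    fps = float(sidecar["fps"])

    frame_files = sorted(path.glob("frame_*.png"))
    if not frame_files:
        raise FileNotFoundError(f"no frames found under {path}")
    indices = [int(f.stem.split("_")[1]) for f in frame_files]
    expected = list(range(len(frame_files)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise ValueError(f"gap in frame numbering under {path}: missing {missing}")
    if "n_frames" in sidecar and int(sidecar["n_frames"]) != len(frame_files):
        raise ValueError(
            f"sidecar declares {sidecar['n_frames']} frames but {len(frame_files)} found"
        )

    frames = [np.asarray(iio.imread(f)) for f in frame_files]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame dimensions: {sorted(shapes)}")
    return FrameSequence(frames=np.stack(frames), fps=fps)
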