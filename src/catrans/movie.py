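"""In-memory time-lapse movie container with multi-page TIFF I/O.

A :class:`Movie` is a ``(frames, height, width)`` luminance stack plus the two
pieces of acquisition metadata the analysis needs: the frame duration (s) and
the pixel size (um/pixel).  Metadata travels in a JSON sidecar next to the
TIFF so the stack itself stays a plain grayscale multi-page image readable by
any viewer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: frame duration of the acquisition system emulated by default (~4 fps)
DEFAULT_FRAME_DURATION_S = 0.249
#: default pixel size at 512 x 512 resolution
DEFAULT_PIXEL_SIZE_UM = 1.183


@dataclass
class Movie:
    """Grayscale time-lapse stack: ``data[frame, row, col]``."""

    data: np.ndarray
    frame_duration_s: float = DEFAULT_FRAME_DURATION_S
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D (frames, h, w), got {self.data.shape}")
        if self.frame_duration_s <= 0:
            raise ValueError("frame_duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (height, width)."""
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_duration_s

    def save(self, path: str | Path) -> Path:
        """Write a multi-page TIFF plus a ``.json`` metadata sidecar."""
        path = Path(path)
        data = self.data
        if data.dtype.kind == "f":
            data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "frame_duration_s": self.frame_duration_s,
            "pixel_size_um": self.pixel_size_um,
        }))
        return path

    @classmethod
    def load(cls, path: str | Path,
             frame_duration_s: float | None = None,
             pixel_size_um: float | None = None) -> "Movie":
        """Read a multi-page TIFF; metadata comes from the sidecar if present."""
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 2:  # single-frame TIFF
            data = data[None]
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            data=data,
            frame_duration_s=frame_duration_s or meta.get("frame_duration_s", DEFAULT_FRAME_DURATION_S),
            pixel_size_um=pixel_size_um or meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM),
            source=str(path),
        )
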