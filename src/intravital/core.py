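"""Shared containers and movie I/O.

A movie is a ``(T, C, H, W)`` unsigned-integer array: ``T`` time points,
``C`` fluorescence channels, plus the physical metadata needed to convert
between pixels and micrometres and between frames and hours.  By convention
channel roles are lower-case strings; the default two-channel layout is
``("rfp", "gfp")`` — RFP marks all tumor cells (the registration/detection
channel), eGFP marks the Lgr5-positive subset (the classification channel).

Coordinate convention used throughout the package: ``x`` is the column
index increasing rightward, ``y`` is the row index increasing downward,
origin at the top-left pixel center.  A shift ``(dx, dy)`` moves image
content ``dx`` pixels rightward and ``dy`` pixels downward.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("intravital")

DEFAULT_CHANNELS: tuple[str, ...] = ("rfp", "gfp")
DEFAULT_BIT_DEPTH = 12


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


@dataclasses.dataclass
class MovieStack:
    """A multi-frame, multi-channel 2D intensity stack with physical metadata.

    Parameters
    ----------
    data
        Array of shape ``(T, C, H, W)``; values must lie in the bit-depth
        range ``[0, 2**bit_depth - 1]``.
    pixel_size_um
        Lateral pixel size in micrometres (> 0).
    frame_interval_h
        Time between consecutive frames in hours (> 0).
    channels
        Role of each channel, e.g. ``("rfp", "gfp")``.
    bit_depth
        Acquisition bit depth (default 12, matching multiphoton acquisition).
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_h: float = 1.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    bit_depth: int = DEFAULT_BIT_DEPTH

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"movie data must be (T, C, H, W), got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[1]} channel planes but "
                f"{len(self.channels)} channel roles"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        self.channels = tuple(str(c).lower() for c in self.channels)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def duration_h(self) -> float:
        """Elapsed time from the first to the last frame, in hours."""
        return (self.n_frames - 1) * self.frame_interval_h

    def channel_index(self, role: str) -> int:
        try:
            return self.channels.index(role.lower())
        except ValueError:
            raise KeyError(
                f"channel {role!r} not in movie (have {self.channels})"
            ) from None

    def frame(self, t: int, channel: str) -> np.ndarray:
        """Return the 2D plane for time point ``t`` and channel role."""
        return self.data[t, self.channel_index(channel)]

    def copy(self) -> "MovieStack":
        return MovieStack(
            data=self.data.copy(),
            pixel_size_um=self.pixel_size_um,
            frame_interval_h=self.frame_interval_h,
            channels=self.channels,
            bit_depth=self.bit_depth,
        )


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def write_movie(path: str | Path, stack: MovieStack) -> Path:
    """Write a movie as a channel-interleaved multi-page TIFF plus sidecar JSON.

    Pages are ordered frame-major: ``(t0,c0), (t0,c1), (t1,c0), ...``.
    Returns the sidecar path.
    """
    path = Path(path)
    t, c, h, w = stack.data.shape
    pages = stack.data.reshape(t * c, h, w).astype(np.uint16)
    tifffile.imwrite(path, pages)
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_h": stack.frame_interval_h,
        "channels": list(stack.channels),
        "bit_depth": stack.bit_depth,
        "n_frames": t,
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_movie(path: str | Path, meta_path: str | Path | None = None) -> MovieStack:
    """Read a movie written by :func:`write_movie`."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar_path(path)
    meta = json.loads(Path(meta_path).read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_channels = len(meta["channels"])
    t = pages.shape[0] // n_channels
    data = pages.reshape(t, n_channels, *pages.shape[1:])
    return MovieStack(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_h=float(meta["frame_interval_h"]),
        channels=tuple(meta["channels"]),
        bit_depth=int(meta.get("bit_depth", DEFAULT_BIT_DEPTH)),
    )
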