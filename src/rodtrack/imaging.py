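"""Image-stack container, TIRF preprocessing and kymograph extraction.

Coordinate convention used throughout the package: x = column, y = row, with
the origin at the centre of the top-left pixel; physical positions in µm are
pixel index × ``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage


@dataclass
class ImageStack:
    """A time-lapse fluorescence stack with its physical calibration.

    Parameters
    ----------
    pixels
        Array of shape ``(n_frames, n_rows, n_cols)``, intensity counts.
    pixel_size
        Lateral pixel size, µm per pixel. There is no default: the value
        must come from the acquisition metadata.
    t_lag
        Interval between consecutive frames, seconds.
    """

    pixels: np.ndarray
    pixel_size: float
    t_lag: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ValueError("pixels must be a (frame, row, col) array with >=1 frame")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.t_lag > 0:
            raise ValueError("t_lag must be > 0")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


@dataclass
class Kymograph:
    """Space-time intensity image along a line.

    ``pixels[t, s]`` is the intensity at frame ``t`` and position ``s`` along
    the line (sampled once per pixel length), averaged over ``width_px``
    perpendicular offsets.
    """

    pixels: np.ndarray
    line: tuple[tuple[float, float], tuple[float, float]]
    width_px: int
    pixel_size: float
    t_lag: float


def read_stack(path, pixel_size: float, t_lag: float) -> ImageStack:
    """Read a (multi-page) TIFF into an :class:`ImageStack`."""
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    return ImageStack(pixels=np.asarray(pixels, dtype=float), pixel_size=pixel_size, t_lag=t_lag)


def write_stack(stack: ImageStack, path) -> None:
    """Write the stack as a multi-page float32 TIFF."""
    tifffile.imwrite(path, np.asarray(stack.pixels, dtype=np.float32))


def preprocess_stack(stack: ImageStack) -> ImageStack:
    """Background-subtract and temporally average a TIRF stack.

    The per-pixel minimum projection over the whole stack is subtracted from
    every frame (removing stationary background), then frames are averaged by
    a sliding window over two consecutive images (stride 1). Output frame
    ``k`` is the mean of background-subtracted frames ``k`` and ``k+1``, so
    the result has one frame fewer than the input and no negative values.
    """
    if stack.n_frames < 2:
        raise ValueError("preprocess_stack requires >= 2 frames")
    sub = stack.pixels - stack.pixels.min(axis=0, keepdims=True)
    out = 0.5 * (sub[:-1] + sub[1:])
    return replace(stack, pixels=out)


def extract_kymograph(
    stack: ImageStack,
    line: tuple[tuple[float, float], tuple[float, float]],
    width_px: int = 1,
) -> Kymograph:
    """Sample the intensity profile along a line in every frame.

    Parameters
    ----------
    stack
        The image stack (typically preprocessed).
    line
        Two endpoints ``((x1, y1), (x2, y2))`` in µm. Both must lie inside
        the frame.
    width_px
        Number of perpendicular 1-px-spaced offsets averaged per sample
        (odd; 1 means no perpendicular averaging).

    Returns
    -------
    Kymograph
        Rows are frames, columns positions along the line (one sample per
        pixel length), bilinearly interpolated.
    """
    (x1, y1), (x2, y2) = line
    p1 = np.array([x1, y1]) / stack.pixel_size
    p2 = np.array([x2, y2]) / stack.pixel_size
    n_rows, n_cols = stack.frame_shape
    for p in (p1, p2):
        if not (0 <= p[0] <= n_cols - 1 and 0 <= p[1] <= n_rows - 1):
            raise ValueError(f"line endpoint {tuple(p * stack.pixel_size)} µm is outside the frame")
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be a positive odd integer")

    length = float(np.hypot(*(p2 - p1)))
    n_samples = max(int(np.round(length)) + 1, 2)
    t = np.linspace(0.0, 1.0, n_samples)
    xs = p1[0] + t * (p2[0] - p1[0])
    ys = p1[1] + t * (p2[1] - p1[1])
    direction = (p2 - p1) / max(length, 1e-12)
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(width_px) - (width_px - 1) / 2

    profiles = np.zeros((stack.n_frames, n_samples))
    for off in offsets:
        cx = xs + off * normal[0]
        cy = ys + off * normal[1]
        coords = np.vstack([cy, cx])  # map_coordinates wants (row, col)
        for k in range(stack.n_frames):
            profiles[k] += ndimage.map_coordinates(
                stack.pixels[k], coords, order=1, mode="nearest"
            )
    profiles /= len(offsets)
    return Kymograph(
        pixels=profiles,
        line=line,
        width_px=width_px,
        pixel_size=stack.pixel_size,
        t_lag=stack.t_lag,
    )


def kymograph_to_frame(kymo: Kymograph) -> pd.DataFrame:
    """Tabulate a kymograph as (t_s, position_um, intensity) rows for CSV export."""
    n_t, n_s = kymo.pixels.shape
    t = np.repeat(np.arange(n_t) * kymo.t_lag, n_s)
    s = np.tile(np.arange(n_s) * kymo.pixel_size, n_t)
    return pd.DataFrame({"t_s": t, "position_um": s, "intensity": kymo.pixels.ravel()})
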