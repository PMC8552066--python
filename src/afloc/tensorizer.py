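"""64-electrode BSP frames -> image tensors.

Two layouts:

* 3-channel (6 x 4 x 3): channel 0 = front grid, channel 2 = back grid,
  channel 1 = the four side columns on the last 4 rows (8 cells zero).
* 1-channel (6 x 16): the vest unrolled as a 12-column cylinder
  (front 4 | left side 2 | back 4 | right side 2), the 8 empty side cells
  (rows 0–1 of each side column) filled with the mean of the 3 nearest
  occupied electrodes (wrap-aware Chebyshev grid distance, ties broken by
  (row, col)), then two mirror columns prepended/appended -> 16 columns.

Bilinear resizing uses the align-corners convention.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np

N_ROWS = 6
N_CYL_COLS = 12
MIRROR_WIDTH = 2


@dataclasses.dataclass(frozen=True)
class VestLayout:
    """Maps canonical channel index (0..63) to grid positions.

    Canonical order: 24 front (row-major), 24 back (row-major), 16 side
    (left column pair then right pair, rows top to bottom).
    """

    #: channel -> (cylinder column, row); side columns occupy rows 2..5
    cylinder_pos: Tuple[Tuple[int, int], ...]
    #: cylinder column -> ("front"|"side"|"back", panel-local column)
    column_panels: Tuple[Tuple[str, int], ...]

    @property
    def n_electrodes(self) -> int:
        return len(self.cylinder_pos)

    def channel_grid(self) -> np.ndarray:
        """(6, 12) array of channel indices, -1 where empty."""
        grid = np.full((N_ROWS, N_CYL_COLS), -1, dtype=np.int64)
        for ch, (col, row) in enumerate(self.cylinder_pos):
            if grid[row, col] != -1:
                raise ValueError("layout places two electrodes in one cell")
            grid[row, col] = ch
        return grid


def default_layout() -> VestLayout:
    pos: List[Tuple[int, int]] = []
    # front 6x4 row-major on cylinder columns 0..3
    for row in range(N_ROWS):
        for col in range(4):
            pos.append((col, row))
    # back 6x4 row-major on cylinder columns 6..9
    for row in range(N_ROWS):
        for col in range(4):
            pos.append((6 + col, row))
    # sides: left pair (4, 5) then right pair (10, 11), rows 2..5
    for cyl in (4, 5, 10, 11):
        for row in (2, 3, 4, 5):
            pos.append((cyl, row))
    panels = tuple(
        ("front", c) if c < 4 else (("side", {4: 0, 5: 1, 10: 2, 11: 3}[c]) if c in (4, 5, 10, 11) else ("back", c - 6))
        for c in range(N_CYL_COLS)
    )
    return VestLayout(cylinder_pos=tuple(pos), column_panels=panels)


def _check_frame(frame64: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame64, dtype=float).ravel()
    if frame.shape[0] != 64:
        raise ValueError(f"expected 64 electrode values, got {frame.shape[0]}")
    return frame


def make_3channel(frame64: np.ndarray, layout: Optional[VestLayout] = None) -> np.ndarray:
    """(6, 4, 3) tensor: front / sides / back."""
    layout = layout or default_layout()
    frame = _check_frame(frame64)
    grid = layout.channel_grid()
    out = np.zeros((N_ROWS, 4, 3))
    for cyl in range(N_CYL_COLS):
        panel, pcol = layout.column_panels[cyl]
        chan_idx = {"front": 0, "side": 1, "back": 2}[panel]
        for row in range(N_ROWS):
            ch = grid[row, cyl]
            if ch >= 0:
                out[row, pcol, chan_idx] = frame[ch]
    return out


def _wrap_chebyshev(r1: int, c1: int, r2: int, c2: int) -> int:
    dc = abs(c1 - c2)
    dc = min(dc, N_CYL_COLS - dc)
    return max(abs(r1 - r2), dc)


def _gap_fill_map(layout: VestLayout) -> Dict[Tuple[int, int], List[Tuple[int, int]]]:
    """Empty cell -> 3 nearest occupied cells on the 12-column cylinder."""
    grid = layout.channel_grid()
    occupied = [(r, c) for r in range(N_ROWS) for c in range(N_CYL_COLS) if grid[r, c] >= 0]
    gaps = {}
    for r in range(N_ROWS):
        for c in range(N_CYL_COLS):
            if grid[r, c] >= 0:
                continue
            ranked = sorted(
                occupied, key=lambda rc: (_wrap_chebyshev(r, c, rc[0], rc[1]), rc[0], rc[1])
            )
            gaps[(r, c)] = ranked[:3]
    return gaps


def make_1channel(frame64: np.ndarray, layout: Optional[VestLayout] = None) -> np.ndarray:
    """(6, 16) unrolled-cylinder matrix with gap filling and mirror columns."""
    layout = layout or default_layout()
    frame = _check_frame(frame64)
    grid = layout.channel_grid()
    base = np.zeros((N_ROWS, N_CYL_COLS))
    mask = grid >= 0
    base[mask] = frame[grid[mask]]
    for (r, c), sources in _gap_fill_map(layout).items():
        base[r, c] = np.mean([base[sr, sc] for sr, sc in sources])
    return np.concatenate([base[:, -MIRROR_WIDTH:], base, base[:, :MIRROR_WIDTH]], axis=1)


def bilinear_resize(image: np.ndarray, out_height: int, out_width: int) -> np.ndarray:
    """Separable align-corners bilinear resize; channels handled independently."""
    if out_height < 2 or out_width < 2:
        raise ValueError("output dimensions must be >= 2")
    img = np.asarray(image, dtype=float)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[:, :, None]
    h, w, _ = img.shape
    if h < 2 or w < 2:
        raise ValueError("input dimensions must be >= 2")

    def coords(n_in, n_out):
        src = np.linspace(0.0, n_in - 1.0, n_out)
        lo = np.clip(np.floor(src).astype(int), 0, n_in - 2)
        frac = src - lo
        return lo, frac

    ry, fy = coords(h, out_height)
    rx, fx = coords(w, out_width)
    top = img[ry][:, rx] * (1 - fx)[None, :, None] + img[ry][:, rx + 1] * fx[None, :, None]
    bot = img[ry + 1][:, rx] * (1 - fx)[None, :, None] + img[ry + 1][:, rx + 1] * fx[None, :, None]
    out = top * (1 - fy)[:, None, None] + bot * fy[:, None, None]
    return out[:, :, 0] if squeeze else out


def replicate_channels(single_channel_image: np.ndarray, k: int = 3) -> np.ndarray:
    """Stack k identical channels from a single-channel image."""
    img = np.asarray(single_channel_image)
    if img.ndim == 3:
        if img.shape[2] != 1:
            raise ValueError("input must be single-channel")
        img = img[:, :, 0]
    return np.repeat(img[:, :, None], k, axis=2)


@dataclasses.dataclass
class NormalizedImage:
    image: np.ndarray
    mode: str
    constant_input: bool = False


def normalize_tensor(image: np.ndarray, mode: str = "zscore") -> NormalizedImage:
    """Per-tensor normalization: 'zscore' (default), 'minmax' or 'none'."""
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains NaN/Inf")
    if mode == "none":
        return NormalizedImage(img, mode)
    if mode == "zscore":
        sd = img.std()
        if sd == 0:
            return NormalizedImage(np.zeros_like(img), mode, constant_input=True)
        return NormalizedImage((img - img.mean()) / sd, mode)
    if mode == "minmax":
        span = img.max() - img.min()
        if span == 0:
            return NormalizedImage(np.zeros_like(img), mode, constant_input=True)
        return NormalizedImage((img - img.min()) / span, mode)
    raise ValueError(f"unknown normalization mode '{mode}'")
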