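"""XY downscaling and 3x3x3 block-grid classification.

The volume is first reduced by 50% in X and Y (nearest neighbour; Z
unchanged), then partitioned into non-overlapping 3x3x3 blocks whose mean
intensities form the block grid. A block is classified as nucleus when its
mean exceeds ``I_Max * Th_Init`` (strict inequality); the surviving means are
kept in ``init_result`` for the local second-pass re-thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack_io import IntensityVolume

BLOCK = 3
SCALE_XY = 0.5


@dataclass
class BlockGrid:
    """Block-mean grid plus its binary classification.

    ``means`` has shape ``ceil(scaled_shape / 3)`` per axis. ``result`` is the
    binary nucleus mask (filled by :func:`classify_blocks`), ``init_result``
    holds the means where ``result`` is 1 and 0 elsewhere.
    """

    means: np.ndarray
    scaled_shape: tuple[int, int, int]
    result: np.ndarray | None = field(default=None)
    init_result: np.ndarray | None = field(default=None)
    scale_xy: float = SCALE_XY
    block: int = BLOCK


def downscale_xy(vol: IntensityVolume, factor: float = SCALE_XY) -> IntensityVolume:
    """Nearest-neighbour reduction of X and Y (floor halving); Z unchanged.

    Spacing metadata is scaled up accordingly.
    """
    if factor != 0.5:
        raise ValueError("only the 50% reduction used by the pipeline is supported")
    z, y, x = vol.shape
    if y < 2 or x < 2:
        raise ValueError("XY dimensions must be at least 2")
    ny, nx = y // 2, x // 2
    data = vol.data[:, : 2 * ny : 2, : 2 * nx : 2]
    sz, sy, sx = vol.spacing
    return IntensityVolume(
        data=data.copy(), spacing=(sz, sy * 2, sx * 2), bit_depth=vol.bit_depth
    )


def block_means(vol: IntensityVolume | np.ndarray, block: int = BLOCK) -> BlockGrid:
    """Mean intensity of each non-overlapping ``block``-cubed sub-matrix.

    Edge blocks that do not fill the cube are padded by edge replication
    before averaging, so the grid shape is ``ceil(shape / block)`` per axis.
    """
    data = vol.data if isinstance(vol, IntensityVolume) else np.asarray(vol)
    pads = [(0, (-s) % block) for s in data.shape]
    padded = np.pad(data.astype(np.float64), pads, mode="edge")
    gz, gy, gx = (s // block for s in padded.shape)
    means = (
        padded.reshape(gz, block, gy, block, gx, block)
        .mean(axis=(1, 3, 5))
    )
    return BlockGrid(means=means, scaled_shape=data.shape)


def classify_blocks(grid: BlockGrid, i_max: float, th: float) -> BlockGrid:
    """Fill ``result``/``init_result`` by thresholding block means.

    A block is nucleus iff ``mean > i_max * th`` (strict, so raising ``th``
    never turns a background block into nucleus).
    """
    if not 0 < th <= 1:
        raise ValueError("threshold fraction must lie in (0, 1]")
    result = (grid.means > i_max * th).astype(np.uint8)
    return BlockGrid(
        means=grid.means,
        scaled_shape=grid.scaled_shape,
        result=result,
        init_result=grid.means * result,
        scale_xy=grid.scale_xy,
        block=grid.block,
    )
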