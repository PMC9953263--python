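"""Synthetic microfluidic transit experiments.

Two levels of realism are provided: :func:`simulate_velocity_dataset` draws
normalized per-cell transit velocities directly from the declared mixture
(plus per-channel occlusion events), while :func:`render_microchannel_frames`
renders programmed cells as dark elliptical blobs moving along a bright
channel so the image-based tracker can be exercised against an exact ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from .population import PopulationSpec, sample_population


@dataclass
class VelocityDataset:
    """Normalized transit velocities of one experiment (donor/replicate)."""

    velocities: np.ndarray  # a.u., 1 = bulk flow
    experiment_id: str = ""
    channel_occluded: np.ndarray | None = None  # per-channel boolean
    wide_channel_mean: float = 2000.0  # µm/s reference used for normalization

    def __post_init__(self):
        self.velocities = np.asarray(self.velocities, dtype=float)
        if np.any(self.velocities < 0):
            raise ConfigurationError("normalized velocities must be nonnegative")
        if self.wide_channel_mean <= 0:
            raise ConfigurationError("wide_channel_mean must be positive")
        if self.channel_occluded is not None:
            self.channel_occluded = np.asarray(self.channel_occluded, dtype=bool)


def simulate_velocity_dataset(
    spec: PopulationSpec, n_channels: int = 16, seed: int | None = None
) -> VelocityDataset:
    """Draw one experiment's velocities and occlusion flags from ``spec``.

    Cells are assigned to channels uniformly at random; a channel is occluded
    when any of its cells arrests (Bernoulli with the cell's adhesion
    propensity).  Bit-reproducible for fixed (spec, seed).
    """
    if n_channels < 1:
        raise ConfigurationError("n_channels must be at least 1")
    seed = spec.seed if seed is None else seed
    cells = sample_population(spec, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0CC1]))
    channel = rng.integers(0, n_channels, size=len(cells))
    arrested = rng.random(len(cells)) < cells.adhesion_propensity
    occluded = np.zeros(n_channels, dtype=bool)
    np.logical_or.at(occluded, channel[arrested], True)
    return VelocityDataset(
        velocities=cells.velocity_factor,
        experiment_id=f"{spec.group_label}/seed{seed}",
        channel_occluded=occluded,
    )


@dataclass(frozen=True)
class ChannelGeometry:
    """Rendered channel geometry, in pixels."""

    length_px: int = 200
    width_px: int = 24
    cell_rx_px: float = 4.0  # semi-axis along the flow (x) direction
    cell_ry_px: float = 3.0

    def __post_init__(self):
        if self.length_px < 1 or self.width_px < 1:
            raise ConfigurationError("channel dimensions must be positive")


@dataclass(frozen=True)
class ProgrammedCell:
    """A cell scripted into a rendered stack."""

    cell_id: int
    entry_frame: int
    velocity_px_per_frame: float | None = None
    velocity_um_s: float | None = None
    y_px: float | None = None


_BACKGROUND = 210.0
_CELL_DEPTH = 150.0


def render_microchannel_frames(
    cells: list[ProgrammedCell],
    geometry: ChannelGeometry = ChannelGeometry(),
    fps: float = 400.0,
    pixel_size_um: float = 0.5,
    n_frames: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render dark moving ellipses on a bright background.

    Returns an 8-bit grayscale stack of shape (n_frames, width_px, length_px)
    and a ground-truth table with one row per cell per frame while the cell
    centre is inside the channel (columns frame, cell_id, x_px, y_px; frames
    are 0-based, pixel centres at integer coordinates).
    """
    resolved = []
    for c in cells:
        if c.velocity_px_per_frame is not None:
            v = float(c.velocity_px_per_frame)
        elif c.velocity_um_s is not None:
            v = c.velocity_um_s / (fps * pixel_size_um)
        else:
            raise ConfigurationError(f"cell {c.cell_id} has no programmed velocity")
        if v > geometry.length_px:
            raise ConfigurationError(
                f"cell {c.cell_id} would cross the whole channel in a single frame"
            )
        y = geometry.width_px / 2.0 if c.y_px is None else float(c.y_px)
        resolved.append((c.cell_id, int(c.entry_frame), v, y))

    # cells enter fully inside the channel so rendered centroids are unclipped
    x_entry = float(np.ceil(geometry.cell_rx_px)) + 1.0
    x_exit = geometry.length_px - 1 - x_entry
    if n_frames is None:
        n_frames = 1
        for _, entry, v, _ in resolved:
            if v > 0:
                n_frames = max(n_frames, entry + int(np.ceil((x_exit - x_entry) / v)) + 2)

    stack = np.full((n_frames, geometry.width_px, geometry.length_px), _BACKGROUND)
    yy, xx = np.mgrid[0 : geometry.width_px, 0 : geometry.length_px]
    rows = []
    for cell_id, entry, v, y in resolved:
        for frame in range(entry, n_frames):
            x = x_entry + v * (frame - entry)
            if x > x_exit:
                break
            rows.append((frame, cell_id, x, y))
            r = np.sqrt(
                ((xx - x) / geometry.cell_rx_px) ** 2 + ((yy - y) / geometry.cell_ry_px) ** 2
            )
            coverage = np.clip((1.15 - r) / 0.3, 0.0, 1.0)
            stack[frame] -= _CELL_DEPTH * coverage

    truth = pd.DataFrame(rows, columns=["frame", "cell_id", "x_px", "y_px"])
    return np.clip(stack, 0, 255).astype(np.uint8), truth
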