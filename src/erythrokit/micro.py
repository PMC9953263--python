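"""Microfluidic transit-velocity analysis.

Covers the full chain from raw microchannel image stacks to subpopulation
statistics: threshold-based cell detection and nearest-neighbour track
linking, robust per-track velocity estimation, normalization to the bulk
flow velocity measured in wide channels, experiment-averaged probability
densities, the slow/fast subpopulation fractions around the 0.175 a.u.
counting cutoff, and the channel occlusion rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import AnalysisError
from .synth.micro import VelocityDataset

log = logging.getLogger(__name__)

#: normalized velocity below which a cell counts as slow (a.u.)
DEFAULT_CUTOFF_SLOW = 0.175
#: control tail mass used to place the slow cutoff
DEFAULT_TAIL_MASS = 0.0045


@dataclass(frozen=True)
class TrackingParams:
    threshold: float | None = None  # intensity threshold; None = Otsu
    min_area: int = 4  # px, connected-component gate
    max_displacement: float = 20.0  # px, per-frame linking gate
    min_contrast: float = 30.0  # intensity range below which frames count as blank


def _detect(frame: np.ndarray, threshold: float, min_area: int) -> list[tuple[float, float]]:
    lab = label(frame < threshold, connectivity=2)
    out = []
    for region in regionprops(lab):
        if region.area >= min_area:
            y, x = region.centroid
            out.append((x, y))
    return out


def track_cells(frames: np.ndarray, params: TrackingParams = TrackingParams()) -> pd.DataFrame:
    """Detect and link dark cells through an image stack.

    Detection is by intensity thresholding plus connected components with an
    area gate; linking is nearest-neighbour within ``max_displacement`` px
    per frame, ties broken by smallest displacement then lowest track id.
    Returns a table with columns (frame, track_id, x, y).
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise AnalysisError("expected a non-empty (frames, height, width) grayscale stack")
    empty = pd.DataFrame(columns=["frame", "track_id", "x", "y"])
    thr = params.threshold
    if thr is None:
        if float(frames.max()) - float(frames.min()) < params.min_contrast:
            return empty  # blank stack: nothing to detect
        thr = threshold_otsu(frames)

    rows = []
    heads: dict[int, tuple[int, float, float]] = {}  # id -> (last_frame, x, y)
    next_id = 0
    for f in range(frames.shape[0]):
        dets = _detect(frames[f], thr, params.min_area)
        candidates = []
        for tid, (last_f, hx, hy) in heads.items():
            if last_f != f - 1:
                continue
            for d, (x, y) in enumerate(dets):
                dist = np.hypot(x - hx, y - hy)
                if dist <= params.max_displacement:
                    candidates.append((dist, tid, d))
        candidates.sort()
        used_tracks, used_dets = set(), set()
        for dist, tid, d in candidates:
            if tid in used_tracks or d in used_dets:
                continue
            used_tracks.add(tid)
            used_dets.add(d)
            x, y = dets[d]
            heads[tid] = (f, x, y)
            rows.append((f, tid, x, y))
        for d, (x, y) in enumerate(dets):
            if d in used_dets:
                continue
            heads[next_id] = (f, x, y)
            rows.append((f, next_id, x, y))
            next_id += 1
    if not rows:
        return empty
    return pd.DataFrame(rows, columns=["frame", "track_id", "x", "y"])


def transit_velocities(
    trajectories: pd.DataFrame,
    fps: float = 400.0,
    pixel_size_um: float = 0.5,
    min_track_length: int = 3,
) -> np.ndarray:
    """Per-track transit velocity (µm/s) from a robust Theil-Sen slope of x vs time.

    Tracks spanning fewer than ``min_track_length`` frames are dropped (the
    dropped count is logged).
    """
    velocities = []
    dropped = 0
    for _, grp in trajectories.groupby("track_id"):
        if len(grp) < min_track_length:
            dropped += 1
            continue
        slope = stats.theilslopes(grp["x"].to_numpy(), grp["frame"].to_numpy()).slope
        velocities.append(slope * fps * pixel_size_um)
    if dropped:
        log.info("dropped %d track(s) shorter than %d frames", dropped, min_track_length)
    return np.asarray(velocities, dtype=float)


def normalize_velocities(velocities_um_s, wide_channel_mean: float) -> np.ndarray:
    """Normalize to the mean cell velocity in wide channels (= bulk flow)."""
    if wide_channel_mean <= 0:
        raise AnalysisError("wide-channel reference velocity must be positive")
    return np.asarray(velocities_um_s, dtype=float) / wide_channel_mean


def detect_occlusions(
    trajectories: pd.DataFrame, stationary_frames: int = 100, tol_px: float = 2.0
) -> list[int]:
    """Track ids that sit within ``tol_px`` for at least ``stationary_frames`` frames."""
    occluded = []
    for tid, grp in trajectories.sort_values("frame").groupby("track_id"):
        frames = grp["frame"].to_numpy()
        xs = grp["x"].to_numpy()
        ys = grp["y"].to_numpy()
        i = 0
        for j in range(len(frames)):
            while (
                frames[j] - frames[i] > j - i  # non-consecutive: restart window
                or np.ptp(xs[i : j + 1]) > tol_px
                or np.ptp(ys[i : j + 1]) > tol_px
            ):
                i += 1
            if j - i + 1 >= stationary_frames:
                occluded.append(int(tid))
                break
    return occluded


@dataclass
class SlowFastFractions:
    slow_pct: float
    fast_pct: float | None
    cutoff_slow: float
    cutoff_fast: float | None
    n: int


def slow_fast_fractions(
    velocities, cutoff_slow: float = DEFAULT_CUTOFF_SLOW, cutoff_fast: float | None = None
) -> SlowFastFractions:
    """Percent of cells below ``cutoff_slow`` and, optionally, above ``cutoff_fast``."""
    if isinstance(velocities, VelocityDataset):
        velocities = velocities.velocities
    v = np.asarray(velocities, dtype=float)
    if v.size == 0:
        raise AnalysisError("no velocities supplied")
    slow = 100.0 * float(np.mean(v < cutoff_slow))
    fast = None if cutoff_fast is None else 100.0 * float(np.mean(v > cutoff_fast))
    return SlowFastFractions(slow, fast, cutoff_slow, cutoff_fast, v.size)


def calibrate_cutoff(control_velocities, tail_mass: float = DEFAULT_TAIL_MASS) -> float:
    """Empirical ``tail_mass`` quantile of a control velocity sample.

    Inverts the cutoff construction: the region below the returned value
    holds ``tail_mass`` of the control cells.  Requires at least 1000 cells.
    """
    if isinstance(control_velocities, VelocityDataset):
        control_velocities = control_velocities.velocities
    v = np.asarray(control_velocities, dtype=float)
    if v.size < 1000:
        raise AnalysisError(f"cutoff calibration needs >= 1000 control cells, got {v.size}")
    if not 0.0 <= tail_mass <= 1.0:
        raise AnalysisError("tail_mass must lie in [0, 1]")
    return float(np.quantile(v, tail_mass))


def calibrate_fast_cutoff(control_velocities, tail_mass: float = 0.0025) -> float:
    """Upper-tail mirror of :func:`calibrate_cutoff` (99.75th percentile by default).

    No field-standard fast threshold exists; this mirrors the slow-tail
    construction on the upper flank of the control distribution.
    """
    if isinstance(control_velocities, VelocityDataset):
        control_velocities = control_velocities.velocities
    v = np.asarray(control_velocities, dtype=float)
    if v.size < 1000:
        raise AnalysisError(f"cutoff calibration needs >= 1000 control cells, got {v.size}")
    if not 0.0 <= tail_mass <= 1.0:
        raise AnalysisError("tail_mass must lie in [0, 1]")
    return float(np.quantile(v, 1.0 - tail_mass))


def velocity_pdf(
    datasets: list[VelocityDataset] | list[np.ndarray],
    bin_width: float = 0.025,
    vmax: float = 2.0,
) -> pd.DataFrame:
    """Experiment-averaged probability density of normalized velocities.

    Each experiment gets its own density histogram on a common grid (each
    integrating to one), then the pointwise mean and standard error across
    experiments are taken.  The grid extends beyond ``vmax`` if any velocity
    exceeds it, so normalization is exact.
    """
    if bin_width <= 0:
        raise AnalysisError("bin_width must be positive")
    arrays = [
        np.asarray(d.velocities if isinstance(d, VelocityDataset) else d, dtype=float)
        for d in datasets
    ]
    if not arrays or any(a.size == 0 for a in arrays):
        raise AnalysisError("velocity_pdf needs at least one non-empty experiment")
    top = max(vmax, max(float(a.max()) for a in arrays) + bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    dens = np.vstack([np.histogram(a, bins=edges, density=True)[0] for a in arrays])
    mean = dens.mean(axis=0)
    se = (
        dens.std(axis=0, ddof=1) / np.sqrt(len(arrays))
        if len(arrays) > 1
        else np.zeros_like(mean)
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center": centers, "density_mean": mean, "density_se": se})


@dataclass
class OcclusionRate:
    rate_pct: float
    se_pct: float
    n_channels: int
    n_occluded: int


def occlusion_rate(datasets) -> OcclusionRate:
    """Percent of occluded channels across experiments, with binomial SE."""
    flags = []
    for d in datasets:
        f = d.channel_occluded if isinstance(d, VelocityDataset) else np.asarray(d)
        if f is None:
            raise AnalysisError("dataset carries no per-channel occlusion flags")
        flags.append(np.asarray(f, dtype=bool))
    flags = np.concatenate(flags) if flags else np.array([], dtype=bool)
    n = flags.size
    if n == 0:
        raise AnalysisError("occlusion rate is undefined for zero channels")
    k = int(flags.sum())
    p = k / n
    return OcclusionRate(100.0 * p, 100.0 * np.sqrt(p * (1.0 - p) / n), n, k)


@dataclass
class VelocityDistributionResult:
    pdf: pd.DataFrame
    slow_fraction_pct: float
    fast_fraction_pct: float | None
    cutoff_slow: float
    cutoff_fast: float | None
    occlusion_rate_pct: float | None = None
    occlusion_se_pct: float | None = None
    per_experiment_slow_pct: list[float] = field(default_factory=list)


def analyze_velocity_datasets(
    datasets: list[VelocityDataset],
    cutoff_slow: float = DEFAULT_CUTOFF_SLOW,
    cutoff_fast: float | None = None,
    bin_width: float = 0.025,
) -> VelocityDistributionResult:
    """PDF, pooled slow/fast fractions, and occlusion rate for one group."""
    pdf = velocity_pdf(datasets, bin_width=bin_width)
    pooled = np.concatenate([np.asarray(d.velocities) for d in datasets])
    fr = slow_fast_fractions(pooled, cutoff_slow, cutoff_fast)
    per_exp = [slow_fast_fractions(d, cutoff_slow).slow_pct for d in datasets]
    occ = se = None
    if all(d.channel_occluded is not None for d in datasets):
        try:
            o = occlusion_rate(datasets)
            occ, se = o.rate_pct, o.se_pct
        except AnalysisError:
            pass
    return VelocityDistributionResult(
        pdf=pdf,
        slow_fraction_pct=fr.slow_pct,
        fast_fraction_pct=fr.fast_pct,
        cutoff_slow=cutoff_slow,
        cutoff_fast=cutoff_fast,
        occlusion_rate_pct=occ,
        occlusion_se_pct=se,
        per_experiment_slow_pct=per_exp,
    )
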