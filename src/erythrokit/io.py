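"""Readers and writers for the toolkit's plain-text and TIFF formats.

All tabular data travels as CSV with documented column names; image stacks
as multi-frame grayscale TIFF; results as JSON written with sorted keys so
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .spectro import AbsorbanceSpectrum
from .synth.micro import VelocityDataset
from .synth.oft import OFTRecording


def write_recording_csv(rec: OFTRecording, path) -> None:
    rec.to_frame().to_csv(path, index=False)


def read_recording_csv(path) -> OFTRecording:
    """Rebuild a recording from CSV; plateau structure is inferred from the
    osmolality column, and the generator's lysis bookkeeping is not carried."""
    frame = pd.read_csv(path)
    angles = tuple(
        float(c.removeprefix("sli_").removesuffix("deg"))
        for c in frame.columns
        if c.startswith("sli_")
    )
    time = frame["time_s"].to_numpy(float)
    osm = frame["osmolality_mosmol"].to_numpy(float)
    sli = frame[[c for c in frame.columns if c.startswith("sli_")]].to_numpy(float)
    rate = 1.0 / np.median(np.diff(time)) if len(time) > 1 else 1.0
    schedule = []
    for o in pd.unique(osm):
        n = int(np.sum(osm == o))
        schedule.append((n / rate, float(o)))
    return OFTRecording(
        schedule=schedule,
        angles=angles,
        time_s=time,
        osmolality=osm,
        sli=sli,
        sampling_rate=rate,
    )


def write_velocity_dataset(ds: VelocityDataset, velocities_path, channels_path=None) -> None:
    pd.DataFrame(
        {"cell_id": np.arange(len(ds.velocities)), "velocity_au": ds.velocities}
    ).to_csv(velocities_path, index=False)
    if channels_path is not None and ds.channel_occluded is not None:
        pd.DataFrame(
            {
                "channel": np.arange(len(ds.channel_occluded)),
                "occluded": ds.channel_occluded.astype(int),
            }
        ).to_csv(channels_path, index=False)


def read_velocity_dataset(velocities_path, channels_path=None, experiment_id="") -> VelocityDataset:
    v = pd.read_csv(velocities_path)["velocity_au"].to_numpy(float)
    occ = None
    if channels_path is not None and Path(channels_path).exists():
        occ = pd.read_csv(channels_path)["occluded"].to_numpy(bool)
    return VelocityDataset(velocities=v, experiment_id=experiment_id, channel_occluded=occ)


def write_spectrum_csv(spectrum: AbsorbanceSpectrum, path) -> None:
    spectrum.to_frame().to_csv(path, index=False)


def read_spectrum_csv(path, dilution_factor: float = 1.0, role: str = "supernatant") -> AbsorbanceSpectrum:
    frame = pd.read_csv(path)
    od = dict(zip(frame["wavelength_nm"].astype(float), frame["od"].astype(float)))
    return AbsorbanceSpectrum(od=od, dilution_factor=dilution_factor, role=role)


def write_stack_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_results_json(results, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
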