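"""OME-TIFF, ground-truth sidecar and preset serialisation."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .movie import Movie
from .params import ImagingParams
from .presets import ConditionPreset

__all__ = ["write_movie", "read_movie", "write_truths", "read_truths",
           "preset_to_yaml", "preset_from_yaml"]


def write_movie(movie: Movie, path) -> None:
    """Write a movie as OME-TIFF (TCZYX) with physical calibration."""
    p = movie.params
    vx, vy, vz = p.voxel_size_xyz
    tifffile.imwrite(
        str(path),
        movie.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TCZYX",
            "PhysicalSizeX": vx, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz, "PhysicalSizeZUnit": "µm",
            "TimeIncrement": p.frame_interval, "TimeIncrementUnit": "s",
            "Channel": {"Name": list(p.channel_names)},
        },
    )


def read_movie(path, params: ImagingParams | None = None) -> Movie:
    """Read an OME-TIFF written by :func:`write_movie`.

    When ``params`` is omitted, calibration is reconstructed from the OME
    metadata.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        if params is None:
            ome = tif.ome_metadata
            import xml.etree.ElementTree as ET
            root = ET.fromstring(ome)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            names = [c.get("Name") or f"ch{i}" for i, c in
                     enumerate(px.findall("ome:Channel", ns))]
            data5 = data.reshape(
                int(px.get("SizeT")), int(px.get("SizeC")),
                int(px.get("SizeZ")), int(px.get("SizeY")),
                int(px.get("SizeX")))
            params = ImagingParams(
                voxel_size_xyz=(float(px.get("PhysicalSizeX")),
                                float(px.get("PhysicalSizeY")),
                                float(px.get("PhysicalSizeZ"))),
                frame_interval=float(px.get("TimeIncrement") or 1.0),
                n_frames=data5.shape[0],
                volume_shape=data5.shape[2:],
                channel_names=tuple(names),
            )
            return Movie(data=data5.astype(np.float32), params=params)
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 4:          # single channel stored without C axis
        data = data[:, None]
    return Movie(data=data, params=params)


def write_truths(truths, path) -> None:
    """Ground-truth sidecar as JSON (one record per simulated CTL)."""
    payload = [t.to_dict() for t in truths]

    def _np(o):
        if isinstance(o, (np.bool_, np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=1, default=_np))


def read_truths(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"_type": type(obj).__name__}
        d.update({k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()})
        return d
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    return obj


def preset_to_yaml(preset: ConditionPreset, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(preset), sort_keys=False))


def preset_from_yaml(path) -> dict:
    """Load a preset dump as a plain dict (inspection / provenance)."""
    return yaml.safe_load(Path(path).read_text())
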