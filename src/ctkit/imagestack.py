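"""Containers for multi-channel 3D microscopy data.

An :class:`ImageStack` holds named intensity channels on a common (z, y, x)
voxel grid with physical voxel dimensions in micrometres; a :class:`LabelMask`
holds an integer segmentation of one channel on the same grid.  Stacks round-
trip through multi-channel TIFF plus a JSON sidecar carrying the voxel size
and channel names, so downstream stages never guess physical scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = ["ImageStack", "LabelMask", "voxel_volume"]


def voxel_volume(voxel_size: Sequence[float]) -> float:
    """Physical volume of one voxel in µm³ from a (z, y, x) size triple."""
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be three positive lengths, got {voxel_size!r}")
    return vs[0] * vs[1] * vs[2]


@dataclass
class ImageStack:
    """Multi-channel 3D intensity image with physical voxel size.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"dna"``, ``"X"``, ``"2"``, ``"3"``)
        to a 3D float array in (z, y, x) order.  All channels share a shape.
    voxel_size
        Physical voxel edge lengths (z, y, x) in µm.
    cell_id
        Identifier of the imaged cell/nucleus.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    cell_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {sorted(shapes)}")
        shape = next(iter(shapes))
        if len(shape) != 3:
            raise ValueError(f"channels must be 3D (z, y, x), got shape {shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        voxel_volume(self.voxel_size)  # validates positivity

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        return voxel_volume(self.voxel_size)

    def write_tiff(self, path: str | Path) -> None:
        """Write channels as a (C, Z, Y, X) TIFF with a JSON sidecar."""
        path = Path(path)
        names = list(self.channels)
        data = np.stack([np.asarray(self.channels[n], dtype=np.float32) for n in names])
        tifffile.imwrite(path, data, metadata=None)
        sidecar = {
            "channels": names,
            "voxel_size_um": list(self.voxel_size),
            "cell_id": self.cell_id,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = tifffile.imread(path)
        names = sidecar["channels"]
        if data.ndim == 3:
            # pages come back flattened as (C*Z, Y, X); restore channel axis
            if data.shape[0] % len(names):
                raise ValueError(
                    f"TIFF page count {data.shape[0]} not divisible by "
                    f"{len(names)} sidecar channels"
                )
            data = data.reshape(len(names), -1, *data.shape[1:])
        if data.shape[0] != len(names):
            raise ValueError(
                f"TIFF has {data.shape[0]} channels but sidecar names {len(names)}"
            )
        return cls(
            channels={n: np.asarray(data[i], dtype=np.float32) for i, n in enumerate(names)},
            voxel_size=tuple(sidecar["voxel_size_um"]),
            cell_id=sidecar.get("cell_id", ""),
        )


@dataclass
class LabelMask:
    """Integer-labelled 3D segmentation of one channel (0 = background)."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = ""
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z, y, x) grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        voxel_volume(self.voxel_size)

    @property
    def voxel_volume_um3(self) -> float:
        return voxel_volume(self.voxel_size)

    def foreground(self) -> np.ndarray:
        """Boolean union of all labelled objects."""
        return self.labels > 0

    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def write_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(Path(path), self.labels.astype(np.int32))
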