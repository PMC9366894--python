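"""Multi-channel image container with physical voxel metadata.

The pipeline operates on ``(C, Z, Y, X)`` float arrays.  2D images are
represented with ``Z = 1`` so that every downstream operation is written
once, for the 3D case.  Physical voxel sizes (micrometres, z/y/x order)
travel with the pixels because object sizes and docking distances are
reported in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A multi-channel, optionally 3D, fluorescence image.

    Parameters
    ----------
    data
        Array of shape ``(C, Z, Y, X)``; ``Z == 1`` for single planes.
    channel_names
        One name per channel, e.g. ``["dapi", "gfp", "stain"]``.
    voxel_size
        Micrometres per voxel along ``(z, y, x)``.
    """

    data: np.ndarray
    channel_names: list[str]
    voxel_size: tuple[float, float, float] | None = (0.5, 0.1, 0.1)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (C, Z, Y, X), got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def is_3d(self) -> bool:
        return self.data.shape[1] > 1

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(Z, Y, X)`` array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]

    def voxel_volume(self) -> float | None:
        """Volume of one voxel in µm³ (area in µm² when the stack is 2D)."""
        if self.voxel_size is None:
            return None
        vz, vy, vx = self.voxel_size
        return vy * vx if not self.is_3d else vz * vy * vx

    # ------------------------------------------------------------------ I/O

    def to_tiff(self, path) -> None:
        """Write as OME-TIFF with channel names and voxel size in metadata."""
        meta = {"axes": "CZYX", "Channel": {"Name": list(self.channel_names)}}
        if self.voxel_size is not None:
            vz, vy, vx = self.voxel_size
            meta.update(
                PhysicalSizeZ=vz, PhysicalSizeZUnit="µm",
                PhysicalSizeY=vy, PhysicalSizeYUnit="µm",
                PhysicalSizeX=vx, PhysicalSizeXUnit="µm",
            )
        tifffile.imwrite(path, self.data.astype(np.float32), ome=True, metadata=meta)

    @classmethod
    def from_tiff(cls, path, channel_names: list[str] | None = None,
                  voxel_size: tuple[float, float, float] | None = None) -> "ImageStack":
        """Read an OME-TIFF (or plain multi-page TIFF with channel order supplied).

        For plain TIFFs the axes are assumed ``(C, Y, X)`` or ``(C, Z, Y, X)``
        and ``channel_names`` must be given.
        """
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            names, vsize = channel_names, voxel_size
            if tf.ome_metadata is not None:
                try:
                    import xml.etree.ElementTree as ET

                    root = ET.fromstring(tf.ome_metadata)
                    ns = {"ome": root.tag.split("}")[0].strip("{")}
                    pix = root.find(".//ome:Pixels", ns)
                    if names is None:
                        names = [c.get("Name") or f"ch{i}"
                                 for i, c in enumerate(pix.findall("ome:Channel", ns))]
                    if vsize is None and pix.get("PhysicalSizeX"):
                        vsize = (float(pix.get("PhysicalSizeZ") or 1.0),
                                 float(pix.get("PhysicalSizeY")),
                                 float(pix.get("PhysicalSizeX")))
                except Exception:
                    pass
        if data.ndim == 3:
            data = data[:, None, :, :]
        if names is None:
            names = [f"ch{i}" for i in range(data.shape[0])]
        return cls(data=np.asarray(data, dtype=np.float64), channel_names=list(names),
                   voxel_size=vsize)
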