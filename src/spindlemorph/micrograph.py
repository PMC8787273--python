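"""Multi-channel fluorescence micrograph container.

A micrograph is a set of registered single-channel 2-D intensity arrays
(conventionally ``actin`` for the phalloidin cytoskeleton stain, ``dapi``
for nuclei and ``marker`` for an antibody stain such as Egr3) together
with the physical pixel size in micrometres per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile


class MissingChannelError(KeyError):
    """Raised when an operation needs a channel the micrograph lacks."""


@dataclass
class Micrograph:
    channels: dict[str, np.ndarray]
    pixel_size: float  # um / px
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(
                f"micrograph has no {name!r} channel (available: {sorted(self.channels)})"
            ) from None

    def to_tiff(self, directory: str | Path, stem: str) -> list[Path]:
        """Write one 16-bit TIFF per channel as ``<stem>_<channel>.tif``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, arr in self.channels.items():
            path = directory / f"{stem}_{name}.tif"
            tifffile.imwrite(path, np.asarray(arr, dtype=np.uint16))
            written.append(path)
        return written

    @classmethod
    def from_tiffs(
        cls, paths: Mapping[str, str | Path], pixel_size: float
    ) -> "Micrograph":
        channels = {name: tifffile.imread(p) for name, p in paths.items()}
        return cls(channels=channels, pixel_size=pixel_size,
                   provenance=";".join(str(p) for p in paths.values()))
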