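"""Container for one acquired field: two channels plus plate metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FieldImage:
    """One field of view: nuclear channel and pro-vWF channel.

    Arrays are 2-D integer rasters (typically uint16) of identical shape.
    ``pixel_size`` is um per pixel; ``condition``/``well``/``field_id``
    locate the field on the plate.
    """

    nuclear: np.ndarray
    vwf: np.ndarray
    pixel_size: float
    condition: str = ""
    well: str = ""
    field_id: str = ""

    def __post_init__(self) -> None:
        if self.nuclear is not None and self.nuclear.ndim != 2:
            raise ValueError("nuclear channel must be 2-D")
        if self.vwf is not None and self.vwf.ndim != 2:
            raise ValueError("vWF channel must be 2-D")

    @property
    def image_id(self) -> str:
        return f"{self.condition}/{self.well}/{self.field_id}"
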