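"""In-memory multi-channel time-lapse container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ImagingParams


@dataclass
class Movie:
    """A T x C x Z x Y x X intensity volume with physical calibration."""

    data: np.ndarray
    params: ImagingParams

    def __post_init__(self):
        if self.data.ndim != 5:
            raise ValueError("movie data must be 5-D (T, C, Z, Y, X)")
        t, c, *zyx = self.data.shape
        if c != len(self.params.channel_names):
            raise ValueError("channel count does not match channel_names")
        if tuple(zyx) != tuple(self.params.volume_shape):
            raise ValueError("spatial shape does not match volume_shape")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """The (T, Z, Y, X) stack for one named channel."""
        return self.data[:, self.params.channel_index(name)]
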