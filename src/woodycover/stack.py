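"""Scene-stack container: dated multiband observations on a pixel grid."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")


@dataclass
class SceneStack:
    """Time-stamped multiband reflectance observations grouped into epochs.

    dates: decimal years, shape (N,); epoch: epoch index per observation,
    shape (N,); sensor: sensor label per observation, shape (N,);
    refl: reflectance, shape (N, B, ny, nx); valid: per-pixel validity
    (False = cloudy/invalid), shape (N, ny, nx).
    """

    dates: np.ndarray
    epoch: np.ndarray
    sensor: np.ndarray
    refl: np.ndarray
    valid: np.ndarray
    bands: tuple[str, ...] = BANDS

    def __post_init__(self) -> None:
        n = self.dates.shape[0]
        if not (self.epoch.shape[0] == self.sensor.shape[0] == self.refl.shape[0] == self.valid.shape[0] == n):
            raise ValueError("observation axes are inconsistent")
        if self.refl.shape[1] != len(self.bands):
            raise ValueError("band axis does not match band names")

    @property
    def n_obs(self) -> int:
        return int(self.dates.shape[0])

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.refl.shape[2], self.refl.shape[3]

    def band(self, name: str) -> np.ndarray:
        return self.refl[:, self.bands.index(name)]

    def copy(self) -> "SceneStack":
        return replace(
            self,
            dates=self.dates.copy(),
            epoch=self.epoch.copy(),
            sensor=self.sensor.copy(),
            refl=self.refl.copy(),
            valid=self.valid.copy(),
        )
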