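"""Analysis mask: closed forest, forestry and non-natural landcover exclusion.

Woody encroachment is a non-forest phenomenon, so the analysis excludes
(i) closed forest — pixels with more than 40% cover by tall (>5 m) trees,
(ii) forestry — pixels that both lost and gained woody cover over the
reference period, and (iii) non-natural landcover classes (urban, water,
wetland, cropland, cropland mosaics).  The combined mask is applied to every
raster entering the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaskInputs", "AnalysisMask", "build_mask", "apply_mask"]

#: default categorical sentinel for masked integer rasters
CATEGORICAL_SENTINEL = -1


@dataclass
class MaskInputs:
    """Aligned input rasters for mask construction.

    tree_cover: fraction in [0, 1]; tall: bool, True where trees exceed the
    height cutoff; loss/gain: bool forest-change flags over the reference
    period; landcover: integer class codes.
    """

    tree_cover: np.ndarray
    tall: np.ndarray
    loss: np.ndarray
    gain: np.ndarray
    landcover: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.tree_cover, self.tall, self.loss, self.gain, self.landcover)}
        if len(shapes) != 1:
            raise ValueError(f"mask input rasters are not on a common grid: {shapes}")
        tc = np.asarray(self.tree_cover, dtype=float)
        if np.nanmin(tc) < 0 or np.nanmax(tc) > 1:
            raise ValueError("tree_cover must be a unit fraction")


@dataclass
class AnalysisMask:
    """Boolean exclusion raster plus per-reason pixel counts.

    Reason counts overlap (a pixel can be both forest and excluded
    landcover); ``counts['total']`` is the size of the union.
    """

    excluded: np.ndarray
    counts: dict = field(default_factory=dict)


def build_mask(
    inputs: MaskInputs,
    forest_cover_threshold: float = 0.40,
    excluded_classes: tuple[int, ...] = (),
) -> AnalysisMask:
    """Combine the forest, forestry and landcover exclusion rules.

    A pixel is excluded iff (tree cover strictly above the threshold AND
    tall class) OR (loss AND gain flags both set) OR (landcover code in the
    excluded set).  The inequality at the threshold is strict: a pixel at
    exactly 40% tree cover is retained.
    """
    lc = np.asarray(inputs.landcover)
    known = set(np.unique(lc).tolist())
    unknown = [c for c in excluded_classes if c not in known]
    # unknown codes are legal (class absent from this scene) but flag typos
    # on obviously invalid negatives
    if any(c < 0 for c in excluded_classes):
        raise ValueError(f"negative landcover codes in excluded set: {excluded_classes}")
    del unknown

    forest = (np.asarray(inputs.tree_cover, dtype=float) > forest_cover_threshold) & np.asarray(
        inputs.tall, dtype=bool
    )
    forestry = np.asarray(inputs.loss, dtype=bool) & np.asarray(inputs.gain, dtype=bool)
    landcover = np.isin(lc, list(excluded_classes))
    excluded = forest | forestry | landcover
    counts = {
        "forest": int(forest.sum()),
        "forestry": int(forestry.sum()),
        "landcover": int(landcover.sum()),
        "total": int(excluded.sum()),
    }
    return AnalysisMask(excluded=excluded, counts=counts)


def apply_mask(raster: np.ndarray, mask: AnalysisMask, sentinel: int = CATEGORICAL_SENTINEL) -> np.ndarray:
    """Set excluded pixels to the missing value; idempotent.

    Continuous (float) rasters get NaN; integer rasters get ``sentinel``.
    """
    arr = np.asarray(raster)
    if arr.shape[-2:] != mask.excluded.shape:
        raise ValueError("raster grid does not match mask grid")
    out = arr.copy()
    if np.issubdtype(arr.dtype, np.floating):
        out[..., mask.excluded] = np.nan
    else:
        out[..., mask.excluded] = sentinel
    return out
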