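"""Colony photosynthetic growth from plate images.

Colony arrays (16 x 24 = 384 positions) are photographed after growth under
high light on minimal medium and in the dark on acetate.  A colony's size is
the number of green pixels it occupies, adjusted by a darkness factor in
[0.5, 1] (denser colonies are darker green), normalized within each plate by
the median of the ten largest colonies, and finally expressed as the
light/dark ratio of the matched positions -- a mutant that grows in the dark
but not in the light is photosynthesis-deficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "ColonyParams",
    "segment_plate",
    "colony_size",
    "darkness_factor",
    "measure_plate",
    "plate_normalize",
    "photosynthetic_growth",
    "median_growth",
]


@dataclass
class ColonyParams:
    """Parameters of the colony metric.

    ``green_margin``: a pixel is "green" (colony) when its green channel
    exceeds both red and blue by this margin.  ``green_ref_light`` /
    ``green_ref_dark`` anchor the linear darkness score: mean colony green
    intensity at ``green_ref_light`` maps to score 0 (palest) and
    ``green_ref_dark`` to 1 (darkest); the score is then clamped to
    ``clamp`` before multiplying the pixel count.
    """

    grid_shape: tuple[int, int] = (16, 24)
    clamp: tuple[float, float] = (0.5, 1.0)
    top_n_for_plate_norm: int = 10
    green_margin: int = 10
    green_ref_light: float = 200.0
    green_ref_dark: float = 60.0

    def __post_init__(self) -> None:
        lo, hi = self.clamp
        if not lo < hi:
            raise ValueError("clamp bounds must be ordered")
        if self.top_n_for_plate_norm < 1:
            raise ValueError("top_n_for_plate_norm must be >= 1")


def _green_mask(image: np.ndarray, params: ColonyParams) -> np.ndarray:
    img = image.astype(int)
    return (img[..., 1] >= img[..., 0] + params.green_margin) & (
        img[..., 1] >= img[..., 2] + params.green_margin
    )


def segment_plate(
    image: np.ndarray, params: ColonyParams | None = None
) -> pd.DataFrame:
    """Segment a plate image into per-grid-position colony pixel stats.

    Background is removed by the green-dominance color rule; connected
    components of colony pixels are assigned to the grid position nearest
    their centroid (a component straddling cell boundaries triggers a
    warning).  Returns one row per grid position: ``row``, ``col``,
    ``n_pixels``, ``mean_green`` (NaN where empty).
    """
    params = params or ColonyParams()
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an RGB image array")
    n_rows, n_cols = params.grid_shape
    h, w = image.shape[:2]
    if h < n_rows or w < n_cols:
        raise ValueError("image dimensions incompatible with grid")
    cell_h, cell_w = h / n_rows, w / n_cols

    mask = _green_mask(image, params)
    labels = measure.label(mask)
    green = image[..., 1].astype(float)

    pix_count = np.zeros(params.grid_shape, dtype=int)
    green_sum = np.zeros(params.grid_shape, dtype=float)
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        r = min(int(cy // cell_h), n_rows - 1)
        c = min(int(cx // cell_w), n_cols - 1)
        rows_px = region.coords[:, 0]
        row_bins = (rows_px // cell_h).astype(int)
        col_bins = (region.coords[:, 1] // cell_w).astype(int)
        if np.ptp(row_bins) > 0 or np.ptp(col_bins) > 0:
            warnings.warn(
                f"colony straddles grid cells near ({r}, {c}); assigned by centroid",
                stacklevel=2,
            )
        pix_count[r, c] += region.area
        green_sum[r, c] += green[rows_px, region.coords[:, 1]].sum()

    rows = []
    for r in range(n_rows):
        for c in range(n_cols):
            n = pix_count[r, c]
            rows.append(
                {"row": r, "col": c, "n_pixels": int(n),
                 "mean_green": green_sum[r, c] / n if n else np.nan}
            )
    return pd.DataFrame(rows)


def darkness_factor(mean_green: float, params: ColonyParams | None = None) -> float:
    """Map mean green intensity to the clamped darkness factor.

    Linear between the light and dark references, clamped to
    ``params.clamp`` (default [0.5, 1]) to keep the emphasis on colony area.
    """
    params = params or ColonyParams()
    if np.isnan(mean_green):
        return np.nan
    score = (params.green_ref_light - mean_green) / (
        params.green_ref_light - params.green_ref_dark
    )
    lo, hi = params.clamp
    return float(np.clip(score, lo, hi))


def colony_size(
    green_values: np.ndarray, params: ColonyParams | None = None
) -> float:
    """Darkness-adjusted colony size from the colony's green-channel pixels."""
    params = params or ColonyParams()
    green_values = np.asarray(green_values, dtype=float)
    if green_values.size == 0:
        return 0.0
    return green_values.size * darkness_factor(float(green_values.mean()), params)


def measure_plate(
    image: np.ndarray, params: ColonyParams | None = None
) -> pd.DataFrame:
    """Segment a plate and compute adjusted sizes for all 384 positions."""
    params = params or ColonyParams()
    df = segment_plate(image, params)
    factors = df["mean_green"].map(lambda g: darkness_factor(g, params))
    df["darkness_factor"] = factors
    df["size"] = (df["n_pixels"] * factors).fillna(0.0)
    return df


def plate_normalize(
    sizes: pd.Series, params: ColonyParams | None = None
) -> pd.Series:
    """Normalize colony sizes by the median of the plate's largest colonies.

    Uses the ``top_n_for_plate_norm`` (default 10) largest sizes; with fewer
    nonzero colonies than that, the median of all nonzero sizes is used with
    a warning.  An all-zero plate is undefined and raises.
    """
    params = params or ColonyParams()
    nonzero = sizes[sizes > 0]
    if nonzero.empty:
        raise ValueError("all-zero plate: normalization undefined")
    top = nonzero.nlargest(params.top_n_for_plate_norm)
    if len(nonzero) < params.top_n_for_plate_norm:
        warnings.warn(
            f"only {len(nonzero)} nonzero colonies; using median of all",
            stacklevel=2,
        )
    return sizes / top.median()


def photosynthetic_growth(light_sizes: pd.Series, dark_sizes: pd.Series) -> pd.Series:
    """Normalized photosynthetic growth: light size / matched dark size.

    Positions absent in the dark (size 0) are undefined (NaN) -- the strain
    did not grow at all, so no photosynthesis-specific statement can be made.
    """
    if not light_sizes.index.equals(dark_sizes.index):
        raise ValueError("light and dark plates have mismatched positions")
    dark = dark_sizes.replace(0, np.nan)
    return light_sizes / dark


def median_growth(replicate_ratios: list[pd.Series]) -> pd.Series:
    """Median normalized growth across replicate plate pairs."""
    return pd.concat(replicate_ratios, axis=1).median(axis=1)
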