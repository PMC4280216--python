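"""Quantitative nuclear shape descriptors from segmented mask images.

Five parameters characterise each case, computed from labeled nucleus
masks and a pixel calibration (µm per pixel edge):

* nuclear area           A = (pixel count) * calibration^2          [µm^2]
* nuclear perimeter      P = boundary contour length * calibration  [µm]
* circular rate          4*pi*A / P^2   (1 for a circle, <1 otherwise)
* aspect ratio           major/minor axis of the moment-equivalent ellipse
* NACV                   100 * SD(area) / mean(area) over the case's nuclei

The perimeter is measured on the sub-pixel iso-contour at level 0.5
(marching squares) of the lightly smoothed mask rather than by counting
exposed pixel edges: edge counting overestimates a digital circle's
perimeter by up to ~27% (and the raw binary iso-contour by ~5%), which
would push the circular rate of a circle far below 1 and break the
descriptor's normalisation.  With a Gaussian pre-smoothing of sigma = 1
pixel the estimate is within 0.5% of the true perimeter for discs of
radius 20-100 px.  The edge-count estimator is retained as
``perimeter_method="edge_count"`` for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import MORPHOMETRIC_FIELDS

__all__ = [
    "NucleusMask",
    "NucleusShape",
    "CaseMorphometry",
    "DegenerateShapeError",
    "label_nuclei",
    "nucleus_shape",
    "aggregate_case",
    "measure_image",
    "NucleusFeatureExtractor",
]

#: Below this per-case nucleus count a warning is emitted (study protocol
#: measured at least 100 nuclei per case).
MIN_RECOMMENDED_NUCLEI = 100


class DegenerateShapeError(ValueError):
    """Mask too thin for a defined aspect ratio (zero minor axis)."""


@dataclass(frozen=True)
class NucleusMask:
    """One segmented nucleus: cropped boolean patch + calibration.

    ``patch`` is the tight bounding-box crop; ``offset`` its (row, col)
    origin in the source image, so absolute pixel coordinates are
    recoverable via :attr:`pixels`.
    """

    label_id: int
    patch: np.ndarray
    offset: tuple[int, int]
    calibration: float
    touches_border: bool = False

    def __post_init__(self) -> None:
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0 µm/pixel")
        if self.patch.ndim != 2 or not self.patch.any():
            raise ValueError("mask patch must be a nonempty 2-D boolean array")

    @property
    def pixels(self) -> np.ndarray:
        """(N, 2) array of absolute (row, col) foreground coordinates."""
        rc = np.argwhere(self.patch)
        return rc + np.asarray(self.offset)

    @property
    def n_pixels(self) -> int:
        return int(self.patch.sum())


@dataclass(frozen=True)
class NucleusShape:
    label_id: int
    area: float            # µm^2
    perimeter: float       # µm
    circular_rate: float   # dimensionless, ~(0, 1]
    aspect_ratio: float    # dimensionless, >= 1


@dataclass(frozen=True)
class CaseMorphometry:
    n_nuclei: int
    mean_area: float
    sd_area: float
    mean_perimeter: float
    mean_circular_rate: float
    mean_aspect_ratio: float
    nacv: float            # percent, 100 * sd_area / mean_area


def label_nuclei(
    mask_image: np.ndarray,
    calibration: float,
    *,
    min_size: int = 15,
    exclude_border: bool = True,
    connectivity: int = 2,
) -> list[NucleusMask]:
    """Extract per-nucleus masks from a binary or pre-labeled raster.

    A binary raster is segmented into 8-connected components (default
    ``connectivity=2``); a raster with values > 1 is treated as already
    labeled, one object per positive integer, preserving label ids.
    Objects smaller than ``min_size`` pixels are dropped as debris;
    objects touching the image border are flagged and, by default,
    excluded (their shape is truncated, hence biased).
    """
    arr = np.asarray(mask_image)
    if arr.ndim != 2:
        raise ValueError(f"mask image must be 2-D, got shape {arr.shape}")
    if calibration <= 0:
        raise ValueError("calibration must be > 0 µm/pixel")
    if not np.any(arr > 0):
        return []

    if arr.max() > 1:
        labeled = arr.astype(np.int64)
    else:
        labeled = measure.label(arr > 0, connectivity=connectivity)

    nrow, ncol = labeled.shape
    masks: list[NucleusMask] = []
    for region in measure.regionprops(labeled):
        if region.area < min_size:
            continue
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == nrow or c1 == ncol
        if touches and exclude_border:
            continue
        masks.append(
            NucleusMask(
                label_id=int(region.label),
                patch=region.image.copy(),
                offset=(r0, c0),
                calibration=calibration,
                touches_border=touches,
            )
        )
    return masks


#: Gaussian pre-smoothing (pixels) applied before contour extraction; 1 px
#: removes the staircase bias of the binary iso-contour without visibly
#: eroding structures at the nuclear scale (hundreds of pixels).
SMOOTHING_SIGMA = 1.0


def _contour_perimeter(patch: np.ndarray, sigma: float = SMOOTHING_SIGMA) -> float:
    """Length (in pixels) of the 0.5-level iso-contour around the object.

    The patch is zero-padded so the contour closes and Gaussian-smoothed
    so the contour tracks the underlying smooth boundary instead of the
    pixel staircase; with several contours (object holes) only the
    longest — the outer boundary — is used.  Objects too small to
    survive smoothing fall back to the unsmoothed contour.
    """
    padded = np.pad(patch.astype(float), 4)
    field = ndimage.gaussian_filter(padded, sigma) if sigma > 0 else padded
    contours = measure.find_contours(field, level=0.5)
    if not contours and sigma > 0:
        contours = measure.find_contours(padded, level=0.5)
    if not contours:
        raise ValueError("no contour found for mask")
    lengths = [
        float(np.sum(np.hypot(*(np.diff(c, axis=0).T)))) for c in contours
    ]
    return max(lengths)


def _edge_count_perimeter(patch: np.ndarray) -> float:
    """Naive estimator: number of exposed pixel edges (4-neighborhood)."""
    padded = np.pad(patch.astype(np.int8), 1)
    exposed = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        exposed += np.sum((padded == 1) & (np.roll(padded, shift, (0, 1)) == 0))
    return float(exposed)


def nucleus_shape(
    mask: NucleusMask, *, perimeter_method: str = "contour"
) -> NucleusShape:
    """Compute the per-nucleus shape descriptors for one mask.

    The aspect ratio is the major/minor axis-length ratio of the ellipse
    with the same second central moments as the pixel set — rotation
    invariant, unlike a bounding box.  A mask whose moment ellipse has a
    zero minor axis (single pixel row/column) raises
    :class:`DegenerateShapeError`.
    """
    if perimeter_method not in ("contour", "edge_count"):
        raise ValueError("perimeter_method must be 'contour' or 'edge_count'")
    cal = mask.calibration
    area = mask.n_pixels * cal**2
    per_px = (
        _contour_perimeter(mask.patch)
        if perimeter_method == "contour"
        else _edge_count_perimeter(mask.patch)
    )
    perimeter = per_px * cal
    circular_rate = 4.0 * np.pi * area / perimeter**2

    region = measure.regionprops(mask.patch.astype(np.uint8))[0]
    minor = region.axis_minor_length
    if minor == 0:
        raise DegenerateShapeError(
            f"label {mask.label_id}: zero minor axis, aspect ratio undefined"
        )
    aspect = region.axis_major_length / minor
    return NucleusShape(
        label_id=mask.label_id,
        area=float(area),
        perimeter=float(perimeter),
        circular_rate=float(circular_rate),
        aspect_ratio=float(max(aspect, 1.0)),
    )


def aggregate_case(shapes: list[NucleusShape] | tuple[NucleusShape, ...]) -> CaseMorphometry:
    """Aggregate per-nucleus shapes into the per-case parameters.

    Area, perimeter, circular rate and aspect ratio are averaged over
    nuclei; NACV = 100 * SD(area)/mean(area) with the sample (n-1) SD.
    Fewer than 100 nuclei triggers a warning (not an error), mirroring
    the measurement protocol's floor.
    """
    if not shapes:
        raise ValueError("cannot aggregate an empty list of nuclei")
    n = len(shapes)
    if n < MIN_RECOMMENDED_NUCLEI:
        warnings.warn(
            f"only {n} nuclei in case (recommended >= {MIN_RECOMMENDED_NUCLEI})",
            UserWarning,
            stacklevel=2,
        )
    areas = np.array([s.area for s in shapes])
    sd_area = float(areas.std(ddof=1)) if n > 1 else 0.0
    mean_area = float(areas.mean())
    return CaseMorphometry(
        n_nuclei=n,
        mean_area=mean_area,
        sd_area=sd_area,
        mean_perimeter=float(np.mean([s.perimeter for s in shapes])),
        mean_circular_rate=float(np.mean([s.circular_rate for s in shapes])),
        mean_aspect_ratio=float(np.mean([s.aspect_ratio for s in shapes])),
        nacv=100.0 * sd_area / mean_area,
    )


def measure_image(
    mask_image: np.ndarray,
    calibration: float,
    *,
    min_size: int = 15,
    exclude_border: bool = True,
    perimeter_method: str = "contour",
) -> pd.DataFrame:
    """Per-nucleus measurement table for one mask image.

    Columns: label_id, area, perimeter, circular_rate, aspect_ratio.
    """
    masks = label_nuclei(
        mask_image, calibration, min_size=min_size, exclude_border=exclude_border
    )
    shapes = [nucleus_shape(m, perimeter_method=perimeter_method) for m in masks]
    return pd.DataFrame(
        [
            {
                "label_id": s.label_id,
                "area": s.area,
                "perimeter": s.perimeter,
                "circular_rate": s.circular_rate,
                "aspect_ratio": s.aspect_ratio,
            }
            for s in shapes
        ],
        columns=["label_id", "area", "perimeter", "circular_rate", "aspect_ratio"],
    )


class NucleusFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer turning mask images into per-case morphometric features.

    ``transform`` accepts a single 2-D raster or an iterable of rasters and
    returns one row per case with the five per-case parameters plus the
    nucleus count, in the cohort CSV's column names.  Stateless: ``fit``
    only validates parameters.

    Parameters
    ----------
    calibration : float
        µm per pixel edge; never inferred from the image.
    min_size : int
        Minimum object size in pixels; smaller components are debris.
    exclude_border : bool
        Drop nuclei touching the image border (truncated shapes).
    perimeter_method : {"contour", "edge_count"}
        Sub-pixel iso-contour length (default) or exposed-edge count.
    """

    def __init__(
        self,
        calibration: float = 1.0,
        min_size: int = 15,
        exclude_border: bool = True,
        perimeter_method: str = "contour",
    ) -> None:
        self.calibration = calibration
        self.min_size = min_size
        self.exclude_border = exclude_border
        self.perimeter_method = perimeter_method

    def fit(self, X=None, y=None) -> "NucleusFeatureExtractor":
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0")
        if self.perimeter_method not in ("contour", "edge_count"):
            raise ValueError("perimeter_method must be 'contour' or 'edge_count'")
        self.n_features_out_ = len(MORPHOMETRIC_FIELDS) + 1
        return self

    def transform(self, X) -> pd.DataFrame:
        self.fit()
        images = [X] if (hasattr(X, "ndim") and X.ndim == 2) else list(X)
        rows = []
        for img in images:
            masks = label_nuclei(
                img,
                self.calibration,
                min_size=self.min_size,
                exclude_border=self.exclude_border,
            )
            case = aggregate_case(
                [nucleus_shape(m, perimeter_method=self.perimeter_method) for m in masks]
            )
            rows.append(
                {
                    "n_nuclei": case.n_nuclei,
                    "mean_nuclear_area": case.mean_area,
                    "mean_perimeter": case.mean_perimeter,
                    "circular_rate": case.mean_circular_rate,
                    "aspect_ratio": case.mean_aspect_ratio,
                    "nacv": case.nacv,
                }
            )
        return pd.DataFrame(rows)
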