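"""Plaque load, peri-plaque microglial response, and neuron counting.

Quantification operates inside expert-annotated regions (prefrontal
cortex, hippocampus) from which damaged or artifact areas have been
subtracted.  Amyloid plaques are segmented from the congophilic
(methoxy-X04) channel with a simple global-threshold stand-in for the
study's trained pixel classifier; the microglial response is the ratio
of mean Iba-1 intensity in a near annulus (plaque edge → 12 μm) to a far
annulus (18 → 60 μm from the edge), so a spatially uniform microglia
density gives a ratio of exactly 1.  Distances are Euclidean distances
from the plaque mask edge, measured in μm (0.6 μm/pixel by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, filters, measure, morphology

log = logging.getLogger(__name__)

__all__ = [
    "RegionAnnotation",
    "MicrogliaResponse",
    "segment_plaques",
    "plaque_load",
    "microglia_response",
    "count_neurons",
]

DEFAULT_PIXEL_SIZE_UM = 0.6
NEAR_ANNULUS_UM = (0.0, 12.0)
FAR_ANNULUS_UM = (18.0, 60.0)


@dataclass
class RegionAnnotation:
    """An annotated analysis region with artifact exclusions.

    Polygons are arrays of (row, col) pixel vertices (0-based, y-down);
    ``exclude_polygons`` are subtracted from the union of
    ``include_polygons`` before any area or intensity computation.
    Alternatively a region can wrap a precomputed boolean mask.
    """

    region_label: str
    include_polygons: list[np.ndarray] = field(default_factory=list)
    exclude_polygons: list[np.ndarray] = field(default_factory=list)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    _mask: np.ndarray | None = None

    @classmethod
    def full_frame(
        cls, shape: tuple[int, int], region_label: str = "region",
        pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    ) -> "RegionAnnotation":
        """Region covering the whole image with no exclusions."""
        return cls(region_label, _mask=np.ones(shape, dtype=bool), pixel_size_um=pixel_size_um)

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, region_label: str = "region",
        pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    ) -> "RegionAnnotation":
        return cls(region_label, _mask=np.asarray(mask, dtype=bool), pixel_size_um=pixel_size_um)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean included-pixel mask on the given image grid."""
        if self._mask is not None:
            if self._mask.shape != tuple(shape):
                raise ValueError("region mask does not match the image grid")
            base = self._mask.copy()
        else:
            base = np.zeros(shape, dtype=bool)
            for poly in self.include_polygons:
                base |= draw.polygon2mask(shape, np.asarray(poly))
        for poly in self.exclude_polygons:
            base &= ~draw.polygon2mask(shape, np.asarray(poly))
        return base

    def area_um2(self, shape: tuple[int, int]) -> float:
        return float(self.mask(shape).sum()) * self.pixel_size_um**2


def segment_plaques(
    plaque_channel: np.ndarray,
    region: RegionAnnotation,
    min_area_um2: float = 20.0,
    threshold_method: str | float = "otsu",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold-based plaque segmentation (stand-in for a trained
    pixel classifier).

    Pixels above the threshold (Otsu computed over included pixels, or a
    numeric value) and inside the included region form connected
    components; components smaller than ``min_area_um2`` are discarded.

    Returns
    -------
    labels : ndarray of int
        Instance label mask (0 = background).
    table : DataFrame
        One row per plaque: ``plaque_id, centroid_row_px, centroid_col_px,
        centroid_x_um, centroid_y_um, area_um2, equivalent_radius_um,
        region_label``.  ``equivalent_radius_um`` is the equal-area circle
        radius sqrt(area/π).
    """
    img = np.asarray(plaque_channel, dtype=float)
    reg_mask = region.mask(img.shape)
    px = region.pixel_size_um
    if not reg_mask.any():
        log.warning("region %s empty after exclusions", region.region_label)
        return np.zeros(img.shape, dtype=np.int32), _empty_plaque_table()
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold_method {threshold_method!r}")
        vals = img[reg_mask]
        if np.ptp(vals) == 0:
            return np.zeros(img.shape, dtype=np.int32), _empty_plaque_table()
        thr = filters.threshold_otsu(vals)
    else:
        thr = float(threshold_method)
    binary = (img > thr) & reg_mask
    min_px = max(int(round(min_area_um2 / px**2)), 1)
    binary = morphology.remove_small_objects(binary, max_size=min_px - 1)
    labels = measure.label(binary).astype(np.int32)
    rows = []
    for prop in measure.regionprops(labels):
        area_um2 = prop.area * px**2
        rows.append(
            {
                "plaque_id": prop.label,
                "centroid_row_px": prop.centroid[0],
                "centroid_col_px": prop.centroid[1],
                "centroid_x_um": prop.centroid[1] * px,
                "centroid_y_um": prop.centroid[0] * px,
                "area_um2": area_um2,
                "equivalent_radius_um": float(np.sqrt(area_um2 / np.pi)),
                "region_label": region.region_label,
            }
        )
    table = pd.DataFrame(rows) if rows else _empty_plaque_table()
    return labels, table


def _empty_plaque_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "plaque_id", "centroid_row_px", "centroid_col_px", "centroid_x_um",
            "centroid_y_um", "area_um2", "equivalent_radius_um", "region_label",
        ]
    )


def plaque_load(mask: np.ndarray, region: RegionAnnotation) -> float:
    """Fraction of the included region area covered by plaque, in [0, 1]."""
    mask = np.asarray(mask)
    plaque = mask > 0
    reg = region.mask(mask.shape)
    denom = reg.sum()
    if denom == 0:
        raise ValueError("included region has zero area")
    return float((plaque & reg).sum() / denom)


@dataclass
class MicrogliaResponse:
    """Per-plaque near/far annulus intensity means and ratios, plus the
    region-level summaries (mean and median of per-plaque ratios)."""

    per_plaque: pd.DataFrame
    summary_mean: float
    summary_median: float
    n_dropped: int


def microglia_response(
    microglia_channel: np.ndarray,
    plaque_labels: np.ndarray,
    region: RegionAnnotation,
    near_um: tuple[float, float] = NEAR_ANNULUS_UM,
    far_um: tuple[float, float] = FAR_ANNULUS_UM,
    strict: bool = False,
) -> MicrogliaResponse:
    """Peri-plaque intensity ratio: mean in the near annulus over mean in
    the far annulus, per plaque.

    Annulus membership uses the Euclidean distance (in μm) from each
    pixel to the nearest pixel of that plaque's mask.  Pixels inside any
    plaque, outside the included region, or within an exclusion polygon
    never contribute.  In ``strict`` mode pixels claimed by the
    neighbourhood (≤ far outer bound) of more than one plaque are dropped
    from every annulus; by default shared pixels contribute to both
    plaques.  Plaques with an empty near or far annulus (e.g. at the
    region border) are dropped from the ratio statistics and logged.
    """
    img = np.asarray(microglia_channel, dtype=float)
    labels = np.asarray(plaque_labels)
    if img.shape != labels.shape:
        raise ValueError("image and label mask must share a pixel grid")
    px = region.pixel_size_um
    reg_mask = region.mask(img.shape)
    any_plaque = labels > 0
    usable = reg_mask & ~any_plaque
    ids = [int(i) for i in np.unique(labels) if i != 0]
    pad = int(np.ceil(far_um[1] / px)) + 2

    slices = {}
    objects = ndimage.find_objects(labels)
    for pid in ids:
        sl = objects[pid - 1]
        slices[pid] = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, n))
            for s, n in zip(sl, img.shape)
        )

    if strict:
        claims = np.zeros(img.shape, dtype=np.int16)
        for pid in ids:
            sl = slices[pid]
            d = ndimage.distance_transform_edt(labels[sl] != pid) * px
            claims[sl] += (d <= far_um[1]).astype(np.int16)
        usable = usable & (claims < 2)

    rows, dropped = [], 0
    for pid in ids:
        sl = slices[pid]
        d_um = ndimage.distance_transform_edt(labels[sl] != pid) * px
        ok = usable[sl]
        near = ok & (d_um > near_um[0]) & (d_um <= near_um[1])
        far = ok & (d_um >= far_um[0]) & (d_um <= far_um[1])
        if not near.any() or not far.any():
            dropped += 1
            log.warning("plaque %d dropped: empty annulus at region border", pid)
            continue
        sub = img[sl]
        mean_near = float(sub[near].mean())
        mean_far = float(sub[far].mean())
        rows.append(
            {
                "plaque_id": pid,
                "mean_intensity_near": mean_near,
                "mean_intensity_far": mean_far,
                "ratio": mean_near / mean_far,
                "n_near_px": int(near.sum()),
                "n_far_px": int(far.sum()),
            }
        )
    per_plaque = pd.DataFrame(
        rows,
        columns=[
            "plaque_id", "mean_intensity_near", "mean_intensity_far",
            "ratio", "n_near_px", "n_far_px",
        ],
    )
    ratios = per_plaque["ratio"].to_numpy()
    return MicrogliaResponse(
        per_plaque=per_plaque,
        summary_mean=float(np.mean(ratios)) if len(ratios) else float("nan"),
        summary_median=float(np.median(ratios)) if len(ratios) else float("nan"),
        n_dropped=dropped,
    )


def count_neurons(
    label_mask: np.ndarray, region: RegionAnnotation
) -> tuple[int, float]:
    """Count nucleus instances whose centroid lies in the included region.

    ``label_mask`` must be an instance label mask (one integer id per
    nucleus), as produced by an instance-segmentation step.  A plain
    binary mask is rejected — run connected-component labelling
    (``skimage.measure.label``) first if that is what you have.

    Returns the count and the density in neurons/μm².
    """
    mask = np.asarray(label_mask)
    binary_valued = mask.dtype == bool or (mask.any() and mask.max() == 1)
    # values {0,1} with several disconnected components is a binary mask,
    # not an instance mask with a single (connected) nucleus labelled 1
    if binary_valued and (mask.dtype == bool or measure.label(mask > 0).max() > 1):
        raise ValueError(
            "count_neurons requires an instance label mask; for a binary mask "
            "run connected-component labelling (skimage.measure.label) first"
        )
    reg = region.mask(mask.shape)
    area = reg.sum() * region.pixel_size_um**2
    if area == 0:
        raise ValueError("included region has zero area")
    count = 0
    for prop in measure.regionprops(mask.astype(np.int32)):
        r, c = (int(round(v)) for v in prop.centroid)
        r = min(max(r, 0), mask.shape[0] - 1)
        c = min(max(c, 0), mask.shape[1] - 1)
        if reg[r, c]:
            count += 1
    return count, count / area
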