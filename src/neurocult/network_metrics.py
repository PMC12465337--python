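"""Soma-aggregation and neurite-alignment network metrics.

Two scalar indices summarise soma clustering in a segmented field:

* Disaggregation Index, ``DI = s0 * m_n / a_n`` — s0 is the reference
  average soma area fixed at the initial timepoint, m_n the number of
  soma objects (single cells and fused clusters alike) and a_n their
  total area.  High DI means small, uniformly spread somata; low DI means
  organised clustering into large aggregates.
* Cluster Density Factor, ``CDF = m0 / p_n`` — m0 is the initial number
  of individual somata and p_n the summed object perimeter.  Merging
  somata shrinks the total perimeter, so tight compact clusters raise
  the CDF.

Neurite fasciculation is quantified by structure-tensor coherency,
``(l1 - l2) / (l1 + l2)`` with l1 >= l2 the eigenvalues of the
Gaussian-smoothed structure tensor — 1 for perfectly parallel texture, 0
for isotropic or constant texture.  The region-based configuration
evaluates coherency in angular sectors of an annulus around each soma
object, so that only neurites emanating from that object contribute;
sector values average per object, object values average per image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError
from .imaging_io import FieldImage
from .segmentation import SomaObjects

logger = logging.getLogger(__name__)


@dataclass
class BaselineReference:
    """Per-well reference values fixed at the initial timepoint.

    s0 is the average soma area (pixels) and m0 the number of individual
    somata, both at the first imaging day.  They stay fixed for the whole
    series; s0 may be overridden by the user, and defaults to the day-1
    mean object area so that DI equals exactly 1 at baseline.
    """

    s0: float
    m0: int

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ParameterError(f"s0: must be > 0, got {self.s0}")
        if self.m0 < 1:
            raise ParameterError(f"m0: must be >= 1, got {self.m0}")

    @classmethod
    def from_initial_objects(cls, objects: SomaObjects, s0: float | None = None) -> "BaselineReference":
        """Build the reference from the first timepoint's soma objects."""
        if objects.object_count == 0:
            raise ParameterError("objects: initial timepoint has no soma objects")
        if s0 is None:
            s0 = objects.total_area / objects.object_count
        return cls(s0=float(s0), m0=int(objects.object_count))


def disaggregation_index(baseline: BaselineReference, objects: SomaObjects) -> float:
    """DI = s0 * m_n / a_n for the soma objects of one timepoint.

    NaN with a warning when the total soma area a_n is zero.
    """
    a_n = objects.total_area
    if a_n == 0:
        logger.warning("disaggregation_index: zero total soma area, returning NaN")
        return float("nan")
    return baseline.s0 * objects.object_count / a_n


def cluster_density_factor(baseline: BaselineReference, objects: SomaObjects) -> float:
    """CDF = m0 / p_n, with p_n the summed pixel-edge perimeter.

    NaN with a warning when the summed perimeter is zero.
    """
    p_n = objects.total_perimeter
    if p_n == 0:
        logger.warning("cluster_density_factor: zero summed perimeter, returning NaN")
        return float("nan")
    return baseline.m0 / p_n


# ---------------------------------------------------------------------------
# Coherency
# ---------------------------------------------------------------------------

@dataclass
class CoherencyParams:
    """Geometry and smoothing of the region-based coherency measurement.

    reach
        Annulus width in pixels around each soma object (default 30 px,
        about 18.6 um at 0.62 um/px).
    n_sectors
        Angular sectors per annulus (default 8).
    min_cover
        Minimum fraction of a sector's annulus pixels that must be
        neurite for the sector to be scored (default 0.01).
    sigma
        Gaussian smoothing of the structure tensor, pixels (default 2).
    """

    reach: int = 30
    n_sectors: int = 8
    min_cover: float = 0.01
    sigma: float = 2.0


@dataclass
class CoherencyResult:
    """Per-object and image-level coherency values, all in [0, 1]."""

    per_object: np.ndarray
    image_coherency: float
    n_objects_used: int


def _tensor_fields(image: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-smoothed structure tensor components (Jrr, Jrc, Jcc)."""
    img = np.asarray(image, dtype=np.float64)
    gr, gc = np.gradient(img)
    jrr = ndi.gaussian_filter(gr * gr, sigma)
    jrc = ndi.gaussian_filter(gr * gc, sigma)
    jcc = ndi.gaussian_filter(gc * gc, sigma)
    return jrr, jrc, jcc


def _coherency_from_moments(jrr: float, jrc: float, jcc: float) -> float:
    trace = jrr + jcc
    if trace <= 0 or not np.isfinite(trace):
        return 0.0  # gradient-free region: defined as 0
    contrast = np.sqrt((jrr - jcc) ** 2 + 4.0 * jrc**2)
    return float(np.clip(contrast / trace, 0.0, 1.0))


def structure_tensor_coherency(window: np.ndarray, sigma: float = 2.0) -> float:
    """Coherency of one intensity patch, in [0, 1].

    The structure tensor is smoothed with ``sigma`` and averaged over the
    whole window; coherency is the eigenvalue contrast
    ``(l1 - l2) / (l1 + l2)``.  A constant (gradient-free) window is
    defined to have coherency 0.  Invariant to global intensity scaling.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2 or min(window.shape) <= 3:
        raise ParameterError(f"window: need a 2-D patch larger than 3x3, got {window.shape}")
    jrr, jrc, jcc = _tensor_fields(window, sigma)
    return _coherency_from_moments(jrr.mean(), jrc.mean(), jcc.mean())


def region_coherency(
    image: FieldImage,
    objects: SomaObjects,
    neurite_mask: np.ndarray,
    params: CoherencyParams | None = None,
) -> CoherencyResult:
    """Region-based coherency of neurites emanating from each soma object.

    For every soma object an annulus (object dilated by ``params.reach``
    minus the object) is split into ``params.n_sectors`` angular sectors
    about the object centroid.  A sector is scored when its neurite
    coverage reaches ``params.min_cover``; its coherency is the averaged
    structure tensor over the sector's neurite pixels.  Sectors average
    (unweighted) per object, and objects with at least one valid sector
    average into the image value.  NaN with a warning when no object has
    a valid sector.
    """
    params = params or CoherencyParams()
    neurite_mask = np.asarray(neurite_mask, dtype=bool)
    if objects.object_count == 0:
        logger.warning("region_coherency: no soma objects, returning NaN")
        return CoherencyResult(np.empty(0), float("nan"), 0)

    jrr, jrc, jcc = _tensor_fields(image.pixels, params.sigma)
    h, w = image.shape
    reach = params.reach

    per_object = np.full(objects.object_count, np.nan)
    for i in range(objects.object_count):
        # work in the object's bounding box padded by reach
        obj_rows, obj_cols = np.nonzero(objects.labels == (i + 1))
        r0 = max(obj_rows.min() - reach, 0)
        r1 = min(obj_rows.max() + reach + 1, h)
        c0 = max(obj_cols.min() - reach, 0)
        c1 = min(obj_cols.max() + reach + 1, w)
        obj = objects.labels[r0:r1, c0:c1] == (i + 1)
        dist = ndi.distance_transform_edt(~obj)
        annulus = (dist > 0) & (dist <= reach)
        cr, cc = objects.centroids[i]
        rows, cols = np.indices(obj.shape)
        angle = np.arctan2(rows - (cr - r0), cols - (cc - c0)) % (2 * np.pi)
        sector_idx = np.floor(angle / (2 * np.pi / params.n_sectors)).astype(int)
        sector_idx = np.clip(sector_idx, 0, params.n_sectors - 1)
        fibers_local = neurite_mask[r0:r1, c0:c1]
        sector_vals = []
        for s in range(params.n_sectors):
            sector = annulus & (sector_idx == s)
            n_px = sector.sum()
            if n_px == 0:
                continue
            fibers = sector & fibers_local
            if fibers.sum() / n_px < params.min_cover or not fibers.any():
                continue
            sector_vals.append(
                _coherency_from_moments(
                    jrr[r0:r1, c0:c1][fibers].mean(),
                    jrc[r0:r1, c0:c1][fibers].mean(),
                    jcc[r0:r1, c0:c1][fibers].mean(),
                )
            )
        if sector_vals:
            per_object[i] = float(np.mean(sector_vals))

    valid = np.isfinite(per_object)
    if not valid.any():
        logger.warning("region_coherency: no object with a valid sector, returning NaN")
        return CoherencyResult(per_object, float("nan"), 0)
    return CoherencyResult(per_object, float(per_object[valid].mean()), int(valid.sum()))


def select_coherency_fovs(mosaic_shape: tuple[int, int]) -> list[int]:
    """Pick 9 uniformly spaced FOVs from a well mosaic, as flat indices.

    For each axis of length n, the three selected positions are
    ``floor((i + 0.5) * n / 3)`` for i in {0, 1, 2} — the centres of the
    axis thirds — giving a consistent 3x3 spatial grid across days.
    Mosaics with fewer than 9 FOVs are used whole (logged note).
    FOV indices are row-major over the mosaic.
    """
    n_rows, n_cols = mosaic_shape
    if n_rows < 1 or n_cols < 1:
        raise ParameterError(f"mosaic_shape: dims must be >= 1, got {mosaic_shape}")
    total = n_rows * n_cols
    if total < 9:
        logger.info("select_coherency_fovs: only %d FOVs available, using all", total)
        return list(range(total))
    picks_r = sorted({int(np.floor((i + 0.5) * n_rows / 3)) for i in range(3)})
    picks_c = sorted({int(np.floor((i + 0.5) * n_cols / 3)) for i in range(3)})
    return [r * n_cols + c for r in picks_r for c in picks_c]
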