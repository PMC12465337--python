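"""Soma / neurite segmentation and soma-object extraction.

The segmenter is a deterministic classical pipeline: Gaussian smoothing,
Otsu thresholding, then a morphological width criterion that splits the
foreground into compact bright somata versus thin elongated neurites
(opening with a disc of roughly half the soma radius removes neurites;
whatever the opening removes is classified as neurite).  Externally
produced masks — e.g. from a trained pixel classifier — can be ingested
instead through :func:`ingest_masks`, which preserves fidelity to
classifier-based workflows.

Soma objects are connected components of the soma mask under
8-connectivity.  The perimeter convention throughout the package is the
pixel-edge count: the number of unit edges between an object pixel and a
non-object pixel (or the image border).  Downstream cluster metrics only
require a convention that is consistent across timepoints, and the
pixel-edge walk is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

from .errors import ParameterError, ShapeMismatchError
from .imaging_io import FieldImage

logger = logging.getLogger(__name__)


@dataclass
class SegmentationMasks:
    """Paired binary soma and neurite masks registered to one image.

    Pixels belong to exactly one class or to background:
    ``soma_mask & neurite_mask`` is empty by construction.
    """

    soma_mask: np.ndarray
    neurite_mask: np.ndarray
    source: str = "internal"  # {"internal", "external"}

    def __post_init__(self) -> None:
        self.soma_mask = np.asarray(self.soma_mask, dtype=bool)
        self.neurite_mask = np.asarray(self.neurite_mask, dtype=bool)
        if self.soma_mask.shape != self.neurite_mask.shape:
            raise ShapeMismatchError(
                f"soma mask shape {self.soma_mask.shape} != neurite mask shape "
                f"{self.neurite_mask.shape}"
            )
        if np.any(self.soma_mask & self.neurite_mask):
            raise ParameterError("masks: soma and neurite masks overlap")

    @property
    def union(self) -> np.ndarray:
        return self.soma_mask | self.neurite_mask


@dataclass
class SomaObjects:
    """Labelled soma connected components with per-object measurements.

    ``areas`` are pixel counts; ``perimeters`` are pixel-edge counts;
    ``centroids`` are (row, col).  Objects touching the image border are
    retained — whole wells are tiled, so dropping border objects would
    bias the object count.
    """

    labels: np.ndarray
    areas: np.ndarray = field(default_factory=lambda: np.empty(0))
    perimeters: np.ndarray = field(default_factory=lambda: np.empty(0))
    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def object_count(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def total_perimeter(self) -> float:
        return float(self.perimeters.sum())


@dataclass
class SegmentationParams:
    """Tuning knobs of the classical segmenter.

    soma_opening_radius is roughly half the expected soma radius in
    pixels: foreground that survives opening with this disc is a soma
    candidate.  Candidates are additionally gated by an intensity
    marker — a heavily smoothed image (``marker_sigma``) thresholded at
    ``marker_frac`` of the way from the foreground threshold to the
    maximum — because compact hubs of crossing neurites can pass the
    width criterion but are dimmer in local average than true cell
    bodies.
    """

    smooth_sigma: float = 0.6
    soma_opening_radius: int = 4
    marker_sigma: float = 2.5
    marker_frac: float = 0.5


def segment(image: FieldImage, params: SegmentationParams | None = None) -> SegmentationMasks:
    """Split foreground into soma and neurite masks.

    Gaussian smooth -> Otsu threshold -> morphological opening with a
    disc of ``soma_opening_radius``.  Opened components that contain a
    bright-marker pixel are soma; all remaining foreground is neurite.
    An image with empty foreground yields empty masks with a logged
    warning.
    """
    params = params or SegmentationParams()
    px = image.pixels.astype(np.float64)
    smoothed = ndi.gaussian_filter(px, params.smooth_sigma)
    if smoothed.max() == smoothed.min():
        logger.warning("segment: constant image, empty masks returned")
        empty = np.zeros(px.shape, dtype=bool)
        return SegmentationMasks(empty, empty.copy(), source="internal")
    thresh = filters.threshold_otsu(smoothed)
    fg = smoothed > thresh
    if not fg.any():
        logger.warning("segment: empty foreground, empty masks returned")
        return SegmentationMasks(fg, fg.copy(), source="internal")
    opened = morphology.opening(fg, morphology.disk(params.soma_opening_radius))
    heavy = ndi.gaussian_filter(px, params.marker_sigma)
    markers = heavy > thresh + params.marker_frac * (heavy.max() - thresh)
    labels = measure.label(opened, connectivity=2)
    keep = np.unique(labels[markers & (labels > 0)])
    soma = np.isin(labels, keep[keep > 0])
    neurite = fg & ~soma
    return SegmentationMasks(soma_mask=soma, neurite_mask=neurite, source="internal")


def ingest_masks(soma: np.ndarray, neurite: np.ndarray, image: FieldImage) -> SegmentationMasks:
    """Adopt externally produced masks for an image.

    Masks are binarised (any value > 0 is foreground).  A pixel claimed by
    both masks is resolved soma-priority.  Shapes must match the image.
    """
    soma = np.asarray(soma)
    neurite = np.asarray(neurite)
    for name, m in (("soma", soma), ("neurite", neurite)):
        if m.shape != image.shape:
            raise ShapeMismatchError(
                f"{name} mask shape {m.shape} does not match image shape {image.shape}"
            )
    soma_b = soma > 0
    neurite_b = (neurite > 0) & ~soma_b  # overlap resolved soma-priority
    return SegmentationMasks(soma_mask=soma_b, neurite_mask=neurite_b, source="external")


def pixel_edge_perimeter(mask: np.ndarray) -> int:
    """Pixel-edge perimeter: unit edges between mask and non-mask/border."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    edges = 0
    for axis in (0, 1):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        edges += int(np.abs(diff).sum())
    return edges


def label_somata(masks: SegmentationMasks) -> SomaObjects:
    """Extract labelled soma objects (8-connectivity) with measurements.

    Area is the pixel count, perimeter the pixel-edge count, centroid the
    unweighted pixel centroid.  An empty mask yields zero objects.
    """
    labels = measure.label(masks.soma_mask, connectivity=2)
    n = labels.max()
    if n == 0:
        return SomaObjects(labels=labels, areas=np.empty(0), perimeters=np.empty(0),
                           centroids=np.empty((0, 2)))
    areas = np.zeros(n)
    perimeters = np.zeros(n)
    centroids = np.zeros((n, 2))
    for i, props in enumerate(measure.regionprops(labels)):
        areas[i] = props.area
        centroids[i] = props.centroid
        perimeters[i] = pixel_edge_perimeter(labels == props.label)
    return SomaObjects(labels=labels, areas=areas, perimeters=perimeters, centroids=centroids)


def mean_fluorescence(image: FieldImage, masks: SegmentationMasks) -> float:
    """Mean intensity over the union of soma and neurite mask pixels.

    Intensities outside the masks never contribute.  An empty union yields
    0 with a logged warning.
    """
    union = masks.union
    if not union.any():
        logger.warning("mean_fluorescence: empty mask union, returning 0")
        return 0.0
    return float(image.pixels[union].mean())


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks; 1.0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
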