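"""Image and metadata input/output plus intensity preprocessing.

Widefield live-imaging datasets arrive as one single-channel TIFF per field
of view (FOV), organised on disk as ``plate/<condition>/<day>/<fov>.tif``
with a sidecar CSV manifest carrying the design metadata.  This module reads
and writes that layout, applies the standard preprocessing (32-bit to 16-bit
conversion, min-max rescaling), and builds the dataset index used to locate
every image of a longitudinal series.

Conventions
-----------
* Coordinates are (row, col), 0-based; masks share the image grid exactly.
* Bit conversion rounds half up; the rescaled output range is the unit
  interval by default, with a 16-bit full-scale option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ParameterError, PlatemapError

logger = logging.getLogger(__name__)

#: Physical pixel pitch of the imaging platform, micrometres per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.62

MANIFEST_COLUMNS = ["plate", "well", "condition", "day", "fov", "path"]


@dataclass
class FieldImage:
    """One single-channel 2-D fluorescence image with acquisition metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D grid of finite, non-negative intensities.
    bit_depth : {16, 32}
        Nominal acquisition depth.  16-bit images are stored as ``uint16``,
        32-bit as ``float32``.
    pixel_size : float
        Physical pixel pitch in micrometres (default 0.62).
    plate_id, condition_id, well_id : str
        Design metadata.
    day : int
        Imaging day (calendar day index within the series).
    fov_index : int
        Position of this tile in the well mosaic.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    plate_id: str = ""
    condition_id: str = ""
    well_id: str = ""
    day: int = 0
    fov_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError(f"pixels: expected 2-D grid, got ndim={self.pixels.ndim}")
        if self.bit_depth not in (16, 32):
            raise ParameterError(f"bit_depth: must be 16 or 32, got {self.bit_depth}")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("pixels: non-finite intensities present")
        if np.any(self.pixels < 0):
            raise ParameterError("pixels: negative intensities present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def to_16bit(image: FieldImage) -> FieldImage:
    """Linearly map a 32-bit image onto the full 16-bit range.

    The value range [min, max] maps to [0, 65535] and is rounded half-up.
    A constant-valued image maps to all zeros (documented degenerate case,
    not an error).
    """
    if image.bit_depth != 32:
        raise ParameterError(f"bit_depth: to_16bit requires 32, got {image.bit_depth}")
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px, dtype=np.uint16)
    else:
        scaled = (px - lo) / (hi - lo) * 65535.0
        out = np.floor(scaled + 0.5).astype(np.uint16)  # round half up
    return replace(image, pixels=out, bit_depth=16)


def rescale_minmax(image: FieldImage, full_scale: bool = False) -> FieldImage:
    """Rescale intensities to their min-max range.

    The minimum maps to 0 and the maximum to full range — the unit interval
    by default, or [0, 65535] when ``full_scale`` is set.  The rank order of
    pixel intensities is preserved.  A constant image yields all zeros with
    a logged warning.
    """
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        logger.warning(
            "rescale_minmax: constant image (value %s) in %s/%s day %s fov %s; output all zeros",
            lo, image.well_id, image.condition_id, image.day, image.fov_index,
        )
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    if full_scale:
        out = out * 65535.0
    return replace(image, pixels=out, bit_depth=image.bit_depth)


def exposure_per_well(n_captures: int = 64, exposure_ms: float = 300.0) -> float:
    """Total light exposure per well per scan, in seconds.

    Each daily scan tiles the well with ``n_captures`` non-overlapping
    acquisitions of ``exposure_ms`` each, so the phototoxic light dose per
    well per scan is their product.
    """
    if n_captures < 1:
        raise ParameterError(f"n_captures: must be >= 1, got {n_captures}")
    if exposure_ms <= 0:
        raise ParameterError(f"exposure_ms: must be > 0, got {exposure_ms}")
    return n_captures * exposure_ms / 1000.0


@dataclass
class DatasetIndex:
    """Index of every image in a longitudinal dataset.

    ``manifest`` has one row per image with columns plate, well, condition,
    day, fov, path (path may be empty for planned-but-unmaterialised
    layouts).  Missing (well, day) combinations relative to the full grid
    are recorded in ``gaps``.
    """

    manifest: pd.DataFrame
    gaps: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_images(self) -> int:
        return len(self.manifest)

    def images_per_condition(self) -> pd.Series:
        """Number of indexed images for each condition."""
        return self.manifest.groupby("condition").size()

    @classmethod
    def from_layout(
        cls,
        n_fovs_per_well: int,
        n_days: int,
        n_wells_per_condition: int,
        conditions: Iterable[str],
        first_day: int = 7,
    ) -> "DatasetIndex":
        """Enumerate the full acquisition grid of a planned experiment.

        Builds the manifest for a complete design — every condition, well,
        daily scan and FOV — without requiring files on disk.  Used to audit
        expected dataset sizes before or after acquisition.
        """
        conditions = list(conditions)
        if n_fovs_per_well < 1 or n_days < 1 or n_wells_per_condition < 1:
            raise ParameterError("layout counts: all layout counts must be >= 1")
        days = np.arange(first_day, first_day + n_days)
        rows = []
        for ci, cond in enumerate(conditions):
            for w in range(n_wells_per_condition):
                well = f"{cond}-w{w}"
                for day in days:
                    for fov in range(n_fovs_per_well):
                        rows.append((f"plate{w % 3}", well, cond, int(day), fov, ""))
        manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
        return cls(manifest=manifest)


def load_platemap(path: str | Path) -> dict:
    """Load a YAML platemap mapping well ids to plate/condition metadata."""
    with open(path) as fh:
        platemap = yaml.safe_load(fh)
    if not isinstance(platemap, Mapping) or "wells" not in platemap:
        raise ParameterError(f"platemap: file {path} lacks a top-level 'wells' mapping")
    return dict(platemap)


def write_field_image(image: FieldImage, path: str | Path) -> None:
    """Write one image as a single-plane TIFF; lossless round-trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px = image.pixels
    if image.bit_depth == 16 and px.dtype != np.uint16:
        px = px.astype(np.uint16)
    elif image.bit_depth == 32 and px.dtype != np.float32:
        px = px.astype(np.float32)
    tifffile.imwrite(path, px)


def read_field_image(
    path: str | Path,
    *,
    plate_id: str = "",
    condition_id: str = "",
    well_id: str = "",
    day: int = 0,
    fov_index: int = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
) -> FieldImage:
    """Read a single-plane TIFF back as a :class:`FieldImage`."""
    px = tifffile.imread(path)
    if px.ndim == 3 and px.shape[0] == 1:
        px = px[0]
    bit_depth = 32 if px.dtype.kind == "f" else 16
    return FieldImage(
        pixels=px,
        bit_depth=bit_depth,
        pixel_size=pixel_size,
        plate_id=plate_id,
        condition_id=condition_id,
        well_id=well_id,
        day=day,
        fov_index=fov_index,
    )


def read_dataset(root_path: str | Path, platemap: Mapping) -> tuple[list[FieldImage], DatasetIndex]:
    """Read a ``plate/<condition>/<day>/<fov>.tif`` tree into FieldImages.

    Every image is tagged with the design metadata from ``platemap``
    (``{"wells": {well_id: {"plate": ..., "condition": ...}}}``).  A well
    found on disk but absent from the platemap raises
    :class:`PlatemapError` naming the well.  Unreadable files are skipped
    with a logged warning.  Missing days relative to the per-well day span
    are recorded as gaps in the returned index.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise ParameterError(f"root_path: {root} is not a directory")
    wells: Mapping = platemap.get("wells", {})
    manifest_csv = root / "manifest.csv"
    if manifest_csv.exists():
        entries = pd.read_csv(manifest_csv)
    else:
        rows = []
        for tif in sorted(root.rglob("*.tif")):
            day_dir = tif.parent
            cond_dir = day_dir.parent
            plate_dir = cond_dir.parent
            rows.append(
                {
                    "plate": plate_dir.name,
                    "well": f"{cond_dir.name}",
                    "condition": cond_dir.name,
                    "day": int(day_dir.name.lstrip("day")),
                    "fov": int(tif.stem.lstrip("fov")),
                    "path": str(tif.relative_to(root)),
                }
            )
        entries = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    images: list[FieldImage] = []
    kept_rows = []
    for _, row in entries.iterrows():
        well = str(row["well"])
        if well not in wells:
            raise PlatemapError(f"well '{well}' present in dataset but missing from platemap")
        meta = wells[well]
        try:
            img = read_field_image(
                root / row["path"],
                plate_id=str(meta.get("plate", row.get("plate", ""))),
                condition_id=str(meta.get("condition", row.get("condition", ""))),
                well_id=well,
                day=int(row["day"]),
                fov_index=int(row["fov"]),
            )
        except (OSError, ValueError) as exc:
            logger.warning("read_dataset: skipping unreadable file %s (%s)", row["path"], exc)
            continue
        images.append(img)
        kept_rows.append(row)
    manifest = pd.DataFrame(kept_rows).reset_index(drop=True)

    gaps = _find_day_gaps(manifest)
    if len(gaps):
        logger.info("read_dataset: %d (well, day) gaps recorded", len(gaps))
    return images, DatasetIndex(manifest=manifest, gaps=gaps)


def _find_day_gaps(manifest: pd.DataFrame) -> pd.DataFrame:
    """Missing (well, day) pairs relative to each well's observed day span."""
    if manifest.empty:
        return pd.DataFrame(columns=["well", "day"])
    rows = []
    for well, grp in manifest.groupby("well"):
        days = np.sort(grp["day"].unique())
        expected = np.arange(days.min(), days.max() + 1)
        for d in np.setdiff1d(expected, days):
            rows.append({"well": well, "day": int(d)})
    return pd.DataFrame(rows, columns=["well", "day"])


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)
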