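"""Synthetic neuronal-culture image generator with recorded ground truth.

Emulates the phenomena a longitudinal live-imaging experiment produces —
somata that drift into clusters and merge, neurites that elongate and
fasciculate into aligned bundles, day-on-day photobleaching, and optional
abrupt death events — so that every downstream stage (segmentation,
morphometrics, aggregation metrics, coherency, death detection, AUC
statistics) can be exercised against known ground truth without any
external image download.

Model summary
-------------
* Somata are Gaussian-profile discs at continuous positions.  Each day
  they move a fraction ``cluster_attraction`` of the way toward their
  cluster centroid (k-means-style assignment to evolving centroids); two
  discs whose circular overlap reaches 50% of the smaller disc merge
  into one disc of conserved area, so the soma count never increases.
* Neurites are quadratic Bezier curves of width 2-3 px anchored to the
  rim of their parent soma, growing ``neurite_growth_rate`` px/day.
  Their orientations interpolate between isotropic (uniform on [0, pi))
  and a single bundle direction as ``fasciculation_strength`` goes from
  0 to 1; curvature also shrinks with fasciculation, since bundled
  tracts are straight.
* Intensity decays multiplicatively by ``bleach_rate`` per day over the
  whole frame; a death event multiplies every later frame by
  ``1 - death_drop``.  Gaussian read noise is added last.

The generator is a pure function of its spec: the same seed and spec
give a bit-identical image sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError
from .imaging_io import FieldImage, MANIFEST_COLUMNS, write_field_image
from .segmentation import pixel_edge_perimeter

SOMA_AMPLITUDE = 1000.0
NEURITE_AMPLITUDE = 600.0
BACKGROUND = 20.0
NEURITE_HALF_WIDTH = 1.25  # px -> tubes 2-3 px wide


@dataclass(frozen=True)
class CultureSpec:
    """Ground-truth parameters of one synthetic culture field.

    Defaults describe a realistic small field: ~12 somata of radius
    ~6 px on a 192x192 grid, 3 neurites each growing 12 px/day, mild
    clustering, 5% daily bleaching and low read noise.
    """

    seed: int = 0
    image_shape: tuple[int, int] = (192, 192)
    n_days: int = 5
    n_somata_initial: int = 12
    soma_radius_mean: float = 6.0
    soma_radius_sd: float = 1.0
    cluster_attraction: float = 0.15
    n_neurites_per_soma: int = 3
    neurite_initial_length: float = 30.0
    neurite_growth_rate: float = 12.0
    fasciculation_strength: float = 0.3
    bleach_rate: float = 0.05
    death_day: Optional[int] = None
    death_drop: float = 0.5
    noise_sd: float = 2.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ParameterError(f"n_days: must be >= 1, got {self.n_days}")
        if min(self.image_shape) < 64:
            raise ParameterError(f"image_shape: each dim must be >= 64, got {self.image_shape}")
        if self.n_somata_initial < 1:
            raise ParameterError(f"n_somata_initial: must be >= 1, got {self.n_somata_initial}")
        if not 0 <= self.cluster_attraction <= 1:
            raise ParameterError(f"cluster_attraction: must be in [0, 1], got {self.cluster_attraction}")
        if not 0 <= self.fasciculation_strength <= 1:
            raise ParameterError(
                f"fasciculation_strength: must be in [0, 1], got {self.fasciculation_strength}")
        if not 0 <= self.bleach_rate < 1:
            raise ParameterError(f"bleach_rate: must be in [0, 1), got {self.bleach_rate}")
        if not 0 < self.death_drop <= 1:
            raise ParameterError(f"death_drop: must be in (0, 1], got {self.death_drop}")
        if self.death_day is not None and not 1 <= self.death_day <= self.n_days:
            raise ParameterError(f"death_day: must be in [1, n_days], got {self.death_day}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if self.soma_radius_mean <= 0:
            raise ParameterError(f"soma_radius_mean: must be > 0, got {self.soma_radius_mean}")
        if self.neurite_growth_rate < 0:
            raise ParameterError(f"neurite_growth_rate: must be >= 0, got {self.neurite_growth_rate}")
        if self.neurite_initial_length < 0:
            raise ParameterError(
                f"neurite_initial_length: must be >= 0, got {self.neurite_initial_length}")
        if self.bit_depth not in (16, 32):
            raise ParameterError(f"bit_depth: must be 16 or 32, got {self.bit_depth}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class GroundTruth:
    """Per-day true masks and measurements recorded by the generator.

    Soma and neurite masks are binary and disjoint; the orientation
    field carries the local neurite tangent orientation in [0, pi) on
    neurite pixels and NaN elsewhere.  ``mean_intensity`` is the
    noiseless masked-union mean per day.
    """

    soma_masks: list = field(default_factory=list)
    neurite_masks: list = field(default_factory=list)
    orientation_fields: list = field(default_factory=list)
    soma_areas: list = field(default_factory=list)
    soma_perimeters: list = field(default_factory=list)
    soma_centroids: list = field(default_factory=list)
    mean_intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    bundle_angle: float = 0.0

    @property
    def soma_counts(self) -> np.ndarray:
        return np.array([len(a) for a in self.soma_areas])


def circular_variance(orientations: np.ndarray) -> float:
    """Circular variance of axial orientations on [0, pi).

    Angles are doubled to handle axial symmetry; 0 for a perfectly
    aligned field, up to 1 for an isotropic one.
    """
    theta = 2.0 * np.asarray(orientations, dtype=float).ravel()
    theta = theta[np.isfinite(theta)]
    if theta.size == 0:
        return float("nan")
    return float(1.0 - np.abs(np.exp(1j * theta).mean()))


def _circle_overlap_fraction(p0, r0, p1, r1) -> float:
    """Intersection area of two discs over the smaller disc's area."""
    d = float(np.hypot(*(np.asarray(p0) - np.asarray(p1))))
    rs, rl = min(r0, r1), max(r0, r1)
    if d >= r0 + r1:
        return 0.0
    if d <= rl - rs:
        return 1.0
    a0 = r0**2 * math.acos(np.clip((d**2 + r0**2 - r1**2) / (2 * d * r0), -1, 1))
    a1 = r1**2 * math.acos(np.clip((d**2 + r1**2 - r0**2) / (2 * d * r1), -1, 1))
    tri = 0.5 * math.sqrt(max(0.0, (-d + r0 + r1) * (d + r0 - r1) * (d - r0 + r1) * (d + r0 + r1)))
    return (a0 + a1 - tri) / (math.pi * rs**2)


def _merge_overlapping(pos: np.ndarray, rad: np.ndarray, owner: np.ndarray):
    """Merge disc pairs overlapping >= 50% of the smaller disc (area conserved)."""
    pos, rad = pos.copy(), rad.copy()
    merged = True
    while merged and len(rad) > 1:
        merged = False
        n = len(rad)
        for i in range(n):
            for j in range(i + 1, n):
                if _circle_overlap_fraction(pos[i], rad[i], pos[j], rad[j]) >= 0.5:
                    ai, aj = rad[i] ** 2, rad[j] ** 2
                    new_pos = (pos[i] * ai + pos[j] * aj) / (ai + aj)
                    new_rad = math.sqrt(ai + aj)
                    pos[i], rad[i] = new_pos, new_rad
                    pos = np.delete(pos, j, axis=0)
                    rad = np.delete(rad, j)
                    owner[owner == j] = i
                    owner[owner > j] -= 1
                    merged = True
                    break
            if merged:
                break
    return pos, rad, owner


def _render_somata(shape, pos, rad):
    """Gaussian-profile discs; returns (intensity, mask)."""
    intensity = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.indices(shape)
    for (r0, c0), radius in zip(pos, rad):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        disc = d2 <= radius**2
        mask |= disc
        sigma = radius  # flat-topped profile: rim stays bright, edge stays sharp
        np.maximum(intensity, SOMA_AMPLITUDE * np.exp(-d2 / (2 * sigma**2)) * disc, out=intensity)
    return intensity, mask


def _render_neurites(shape, curves):
    """Anti-aliased Bezier tubes; returns (intensity, mask, orientation field)."""
    weight = np.zeros(shape)
    orientation = np.full(shape, np.nan)
    pts_all, tang_all = [], []
    for p0, p1, p2 in curves:
        length = np.hypot(*(p2 - p0))
        n_steps = max(int(length / 0.3), 4)
        t = np.linspace(0.0, 1.0, n_steps)[:, None]
        pts_all.append((1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2)
        d = 2 * (1 - t) * (p1 - p0) + 2 * t * (p2 - p1)
        tang_all.append(np.mod(np.arctan2(d[:, 0], d[:, 1]), np.pi))
    if not pts_all:
        return NEURITE_AMPLITUDE * weight, weight >= 0.5, orientation
    pts = np.concatenate(pts_all)
    tang = np.concatenate(tang_all)
    base = np.round(pts).astype(int)
    for dr in (-2, -1, 0, 1, 2):
        for dc in (-2, -1, 0, 1, 2):
            r = base[:, 0] + dr
            c = base[:, 1] + dc
            inside = (r >= 0) & (r < shape[0]) & (c >= 0) & (c < shape[1])
            dist = np.hypot(r - pts[:, 0], c - pts[:, 1])
            w = NEURITE_HALF_WIDTH + 0.5 - dist
            sel = inside & (w > 0)
            np.maximum.at(weight, (r[sel], c[sel]), w[sel])
            core = inside & (dist <= NEURITE_HALF_WIDTH)
            orientation[r[core], c[core]] = tang[core]
    mask = weight >= 0.5
    intensity = NEURITE_AMPLITUDE * np.clip(weight, 0.0, 1.0)
    orientation[~mask] = np.nan
    return intensity, mask, orientation


def generate_timecourse(spec: CultureSpec) -> tuple[list[FieldImage], GroundTruth]:
    """Generate one field of view's daily image sequence plus ground truth.

    Returns ``n_days`` images (days 1..n_days) and the per-day true
    masks, object measurements, orientation field and noiseless mean
    intensity.  Deterministic: the same spec yields bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    margin = spec.soma_radius_mean * 2 + 4

    n = spec.n_somata_initial
    radii = np.clip(rng.normal(spec.soma_radius_mean, spec.soma_radius_sd, n), 2.0, None)
    pos = np.column_stack(
        [rng.uniform(margin, shape[0] - margin, n), rng.uniform(margin, shape[1] - margin, n)]
    )
    bundle_angle = rng.uniform(0, np.pi)

    # all neurite randomness drawn up front so merging never shifts the stream
    n_neur = n * spec.n_neurites_per_soma
    spread = rng.uniform(-np.pi / 2, np.pi / 2, n_neur)
    sides = rng.integers(0, 2, n_neur)
    bends = rng.uniform(-1.0, 1.0, n_neur)
    neur_parent = np.repeat(np.arange(n), spec.n_neurites_per_soma)
    orientations = np.mod(bundle_angle + (1.0 - spec.fasciculation_strength) * spread, np.pi)
    directions = orientations + sides * np.pi  # travel direction of each neurite
    curvature = 3.0 * (1.0 - spec.fasciculation_strength)

    n_clusters = max(1, int(round(n / 4)))
    centroids = pos[:n_clusters].copy()

    owner = np.arange(n)  # original soma -> current object index
    images: list[FieldImage] = []
    truth = GroundTruth(bundle_angle=float(bundle_angle))
    means = []

    for day in range(1, spec.n_days + 1):
        if day > 1 and spec.cluster_attraction > 0:
            d2 = ((pos[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            assign = d2.argmin(axis=1)
            for k in range(len(centroids)):
                members = assign == k
                if members.any():
                    centroids[k] = pos[members].mean(axis=0)
            pos = pos + spec.cluster_attraction * (centroids[assign] - pos)
            pos, radii, owner = _merge_overlapping(pos, radii, owner)

        soma_int, soma_mask = _render_somata(shape, pos, radii)

        # neurites already exist when imaging starts (cultures are several
        # days old at the first scan), then elongate at the growth rate
        curves = []
        length = spec.neurite_initial_length + spec.neurite_growth_rate * (day - 1)
        if length > 0:
            for k in range(n_neur):
                parent = owner[neur_parent[k]]
                direction = directions[k]
                unit = np.array([math.sin(direction), math.cos(direction)])
                perp = np.array([math.cos(direction), -math.sin(direction)])
                p0 = pos[parent] + radii[parent] * unit
                p2 = p0 + length * unit
                p1 = (p0 + p2) / 2 + bends[k] * curvature * perp
                curves.append((p0, p1, p2))
        neur_int, neur_mask, ori_field = _render_neurites(shape, curves)
        neur_mask &= ~soma_mask
        ori_field = np.where(neur_mask, ori_field, np.nan)

        decay = (1.0 - spec.bleach_rate) ** (day - 1)
        if spec.death_day is not None and day >= spec.death_day:
            decay *= 1.0 - spec.death_drop
        noiseless = (np.maximum(soma_int, neur_int) + BACKGROUND) * decay

        union = soma_mask | neur_mask
        means.append(float(noiseless[union].mean()) if union.any() else float(noiseless.mean()))

        frame = noiseless
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, shape)
        frame = np.clip(frame, 0.0, None)
        if spec.bit_depth == 16:
            pixels = np.floor(np.clip(frame, 0, 65535) + 0.5).astype(np.uint16)
        else:
            pixels = frame.astype(np.float32)
        images.append(FieldImage(pixels=pixels, bit_depth=spec.bit_depth, day=day))

        # per-object truth from the analytic discs (label = index order)
        areas, perims, cents = [], [], []
        from skimage import measure

        labels = measure.label(soma_mask, connectivity=2)
        for p in measure.regionprops(labels):
            areas.append(p.area)
            cents.append(p.centroid)
            perims.append(pixel_edge_perimeter(labels == p.label))
        truth.soma_masks.append(soma_mask)
        truth.neurite_masks.append(neur_mask)
        truth.orientation_fields.append(ori_field)
        truth.soma_areas.append(np.array(areas, dtype=float))
        truth.soma_perimeters.append(np.array(perims, dtype=float))
        truth.soma_centroids.append(np.array(cents, dtype=float).reshape(-1, 2))

    truth.mean_intensity = np.array(means)
    return images, truth


# ---------------------------------------------------------------------------
# Factorial AUC dataset
# ---------------------------------------------------------------------------

def generate_factorial_dataset(
    effects: dict,
    n_wells_per_condition: int,
    plate_effects: tuple = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 10.0,
    interactions: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-well AUCs from the factorial linear model with known betas.

    ``effects`` maps factor names (media, laminin, density) to additive
    effect sizes under 0/1 treatment coding (reference levels NB, mouse,
    low); ``interactions`` optionally maps pairs like "media:laminin".
    Wells are assigned to plates round-robin; ``plate_effects`` are the
    additive per-plate offsets.  Returns (auc_table, design) dataframes
    keyed by well.
    """
    from .stats_analysis import FACTORS, OTHER_LEVELS, REFERENCE_LEVELS

    if n_wells_per_condition < 2:
        raise ParameterError(
            f"n_wells_per_condition: must be >= 2, got {n_wells_per_condition}")
    unknown = set(effects) - set(FACTORS)
    if unknown:
        raise ParameterError(f"effects: unknown factors {sorted(unknown)}")
    plate_effects = tuple(plate_effects)
    if any(p != 0 for p in plate_effects) and len(plate_effects) < 2:
        raise ParameterError("plate_effects: need >= 2 plates when plate effects are nonzero")
    interactions = interactions or {}

    rng = np.random.default_rng(seed)
    design_rows, auc_rows = [], []
    for x1 in (0, 1):
        for x2 in (0, 1):
            for x3 in (0, 1):
                cond = "-".join(
                    (OTHER_LEVELS if x else REFERENCE_LEVELS)[f]
                    for f, x in zip(FACTORS, (x1, x2, x3))
                )
                for w in range(n_wells_per_condition):
                    well = f"{cond}-w{w}"
                    plate_idx = w % max(len(plate_effects), 1)
                    y = (
                        intercept
                        + effects.get("media", 0.0) * x1
                        + effects.get("laminin", 0.0) * x2
                        + effects.get("density", 0.0) * x3
                        + interactions.get("media:laminin", 0.0) * x1 * x2
                        + interactions.get("media:density", 0.0) * x1 * x3
                        + interactions.get("laminin:density", 0.0) * x2 * x3
                        + (plate_effects[plate_idx] if plate_effects else 0.0)
                    )
                    if noise_sd > 0:
                        y += rng.normal(0.0, noise_sd)
                    design_rows.append(
                        {"well": well, "condition": cond,
                         "media": OTHER_LEVELS["media"] if x1 else REFERENCE_LEVELS["media"],
                         "laminin": OTHER_LEVELS["laminin"] if x2 else REFERENCE_LEVELS["laminin"],
                         "density": OTHER_LEVELS["density"] if x3 else REFERENCE_LEVELS["density"],
                         "plate": f"plate{plate_idx}"}
                    )
                    auc_rows.append({"well": well, "auc": y})
    return pd.DataFrame(auc_rows), pd.DataFrame(design_rows)


# ---------------------------------------------------------------------------
# ROS-assay synthetic inputs
# ---------------------------------------------------------------------------

def generate_nuclei_field(
    n_nuclei: int,
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 1.25,
    diameter_um: float = 5.83,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping Gaussian nuclei spots; returns (image, centres)."""
    rng = np.random.default_rng(seed)
    radius_px = diameter_um / pixel_size / 2.0
    min_sep = 4.0 * radius_px
    margin = 2.0 * radius_px + 2
    centres: list[np.ndarray] = []
    attempts = 0
    while len(centres) < n_nuclei and attempts < 20000:
        cand = np.array([rng.uniform(margin, shape[0] - margin),
                         rng.uniform(margin, shape[1] - margin)])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centres):
            centres.append(cand)
        attempts += 1
    if len(centres) < n_nuclei:
        raise ParameterError(
            f"n_nuclei: could not place {n_nuclei} non-overlapping nuclei in {shape}")
    img = np.zeros(shape)
    rr, cc = np.indices(shape)
    sigma = radius_px / 1.5
    for r0, c0 in centres:
        img += 1000.0 * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    return img, np.array(centres)


def generate_ros_stacks(
    group_offsets: dict,
    n_fovs_per_group: int = 4,
    shape: tuple[int, int] = (96, 96),
    n_z: int = 5,
    n_nuclei: int = 12,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Synthetic ROS z-stacks whose group means differ by known offsets.

    ``group_offsets`` maps group name to the per-nucleus signal offset
    added on top of a common base; negative-control wells carry only the
    base.  Returns a list of :class:`~neurocult.ros_assay.RosStack`.
    """
    from .ros_assay import GROUPS, RosStack

    unknown = set(group_offsets) - set(GROUPS)
    if unknown:
        raise ParameterError(f"group_offsets: unknown groups {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    base = 50.0
    stacks = []
    for group in GROUPS:
        offset = group_offsets.get(group, 0.0)
        for _ in range(n_fovs_per_group):
            img, centres = generate_nuclei_field(
                n_nuclei, shape, seed=int(rng.integers(0, 2**31)))
            nuclei_mask = img > 100.0
            signal = (base + offset) * nuclei_mask / n_z
            stack = np.repeat(signal[None], n_z, axis=0)
            if noise_sd > 0:
                stack = np.clip(stack + rng.normal(0, noise_sd, stack.shape), 0, None)
            stacks.append(RosStack(ros_channel=stack, nuclei_mask=nuclei_mask,
                                   nuclei_count=len(centres), group=group))
    return stacks


# ---------------------------------------------------------------------------
# Materialisation to disk
# ---------------------------------------------------------------------------

def materialize_dataset(
    conditions: dict,
    root: str | Path,
    n_wells: int = 2,
    n_fovs: int = 4,
    base_seed: int = 0,
    plates: tuple = ("plateA", "plateB"),
) -> tuple[pd.DataFrame, dict]:
    """Write a small multi-condition TIFF dataset with ground truth.

    ``conditions`` maps condition id to a :class:`CultureSpec` template;
    each (well, fov) gets a seed derived deterministically from
    ``base_seed``.  Layout: ``<plate>/<condition>/day<d>/<well>_fov<i>.tif``
    plus ``manifest.csv``, a ``platemap.yaml``, ground-truth arrays under
    ``ground_truth/`` and a CSV parameter manifest.  Returns the manifest
    and a dict of GroundTruth keyed by (well, fov).
    """
    import yaml

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truths = {}
    params_rows = []
    wells_meta = {}
    for ci, (cond, spec_template) in enumerate(sorted(conditions.items())):
        for w in range(n_wells):
            plate = plates[w % len(plates)]
            well = f"{cond}-w{w}"
            wells_meta[well] = {"plate": plate, "condition": cond}
            for fov in range(n_fovs):
                seed = (base_seed * 100003 + ci * 1009 + w * 101 + fov) % (2**31)
                spec = CultureSpec(**{**spec_template.to_dict(), "seed": seed})
                images, truth = generate_timecourse(spec)
                truths[(well, fov)] = truth
                params_rows.append({"well": well, "fov": fov, **spec.to_dict()})
                for img in images:
                    rel = Path(plate) / cond / f"day{img.day}" / f"{well}_fov{fov}.tif"
                    write_field_image(img, root / rel)
                    manifest_rows.append(
                        {"plate": plate, "well": well, "condition": cond,
                         "day": img.day, "fov": fov, "path": str(rel)}
                    )
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(root / "manifest.csv", index=False)
    with open(root / "platemap.yaml", "w") as fh:
        yaml.safe_dump({"wells": wells_meta}, fh)
    gt_dir = root / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    for (well, fov), truth in truths.items():
        np.savez_compressed(
            gt_dir / f"{well}_fov{fov}.npz",
            soma_masks=np.array(truth.soma_masks),
            neurite_masks=np.array(truth.neurite_masks),
            mean_intensity=truth.mean_intensity,
        )
    pd.DataFrame(params_rows).to_csv(gt_dir / "parameters.csv", index=False)
    return manifest, truths
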