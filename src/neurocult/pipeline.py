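"""End-to-end orchestration: simulate -> segment -> metrics -> stats -> report.

A run is fully described by a :class:`RunConfig` (loadable from YAML).
All randomness flows from the single config seed; per-field seeds derive
deterministically from it, so two runs with the same config produce
bit-identical CSV outputs.  Per-image failures are logged and skipped,
never silently dropped; a stage failure aborts with the stage name while
partial outputs are retained.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    imaging_io,
    morphometrics,
    network_metrics,
    segmentation,
    stats_analysis,
    synthetic_data,
    timeseries,
)
from .errors import NeurocultError, ParameterError

logger = logging.getLogger(__name__)

#: The five structural metrics tracked as trajectories (branch points enter
#: as the length-normalised count); raw branch_count stays in the per-image
#: table as an auxiliary column.
STRUCTURAL_METRICS = ["neurite_length_px", "branch_per_px", "di", "cdf", "coherency"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    output_dir: str = "neurocult_run"
    seed: int = 0
    # input: either an existing dataset root + platemap, or a synthetic spec
    input_root: str | None = None
    platemap: str | None = None
    synthetic: dict = field(default_factory=lambda: {
        "conditions": {"NB-mouse-low": {}, "BPI-mouse-low": {"cluster_attraction": 0.3}},
        "n_wells": 2,
        "n_fovs": 4,
        "spec": {"n_days": 5, "image_shape": [160, 160]},
    })
    # metric parameters
    coherency_reach: int = 30
    coherency_sectors: int = 8
    coherency_min_cover: float = 0.01
    coherency_sigma: float = 2.0
    s0_override: float | None = None
    death_threshold: float = 0.10
    include_death_day: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ParameterError(f"platemap/config: config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _coherency_params(config: RunConfig) -> network_metrics.CoherencyParams:
    return network_metrics.CoherencyParams(
        reach=config.coherency_reach,
        n_sectors=config.coherency_sectors,
        min_cover=config.coherency_min_cover,
        sigma=config.coherency_sigma,
    )


def compute_image_metrics(
    images: list[imaging_io.FieldImage],
    config: RunConfig,
    coherency_fovs: set[int] | None = None,
) -> pd.DataFrame:
    """Per-image metric table over a collection of FieldImages.

    Images are preprocessed (min-max rescale), segmented, and measured.
    The aggregation-index baseline (s0, m0) is fixed per (well, fov)
    series from its first imaged day.  Coherency — the costly metric —
    is evaluated only on the FOV subset in ``coherency_fovs`` (all FOVs
    when None).
    """
    params = _coherency_params(config)
    baselines: dict[tuple[str, int], network_metrics.BaselineReference] = {}
    rows = []
    for img in sorted(images, key=lambda im: (im.well_id, im.fov_index, im.day)):
        try:
            pre = imaging_io.rescale_minmax(img)
            masks = segmentation.segment(pre)
            objects = segmentation.label_somata(masks)
            fluor = segmentation.mean_fluorescence(img, masks)
            skel = morphometrics.skeletonize_neurites(masks.neurite_mask)
            key = (img.well_id, img.fov_index)
            if key not in baselines and objects.object_count > 0:
                baselines[key] = network_metrics.BaselineReference.from_initial_objects(
                    objects, s0=config.s0_override)
            if key in baselines and objects.object_count > 0:
                di = network_metrics.disaggregation_index(baselines[key], objects)
                cdf = network_metrics.cluster_density_factor(baselines[key], objects)
            else:
                di = cdf = float("nan")
            if coherency_fovs is None or img.fov_index in coherency_fovs:
                coh = network_metrics.region_coherency(pre, objects, masks.neurite_mask, params)
                coh_val = coh.image_coherency
            else:
                coh_val = float("nan")
            rows.append(
                {"plate": img.plate_id, "well": img.well_id, "condition": img.condition_id,
                 "day": img.day, "fov": img.fov_index,
                 "mean_fluorescence": fluor,
                 "neurite_length_px": skel.length_px,
                 "branch_count": skel.branch_count,
                 "branch_per_px": morphometrics.normalized_branch_points(skel),
                 "di": di, "cdf": cdf, "coherency": coh_val,
                 "n_objects": objects.object_count}
            )
        except NeurocultError as exc:
            logger.warning("metrics: skipping %s/%s day %s fov %s: %s",
                           img.well_id, img.condition_id, img.day, img.fov_index, exc)
    return pd.DataFrame(rows)


def _design_from_conditions(manifest: pd.DataFrame) -> pd.DataFrame | None:
    """Parse media-laminin-density factor levels out of condition ids."""
    rows = []
    for well, grp in manifest.groupby("well"):
        cond = str(grp["condition"].iloc[0])
        parts = cond.split("-")
        if len(parts) != 3:
            return None
        media, laminin, density = parts
        if media not in ("NB", "BPI") or laminin not in ("mouse", "human") \
                or density not in ("low", "high"):
            return None
        rows.append({"well": well, "media": media, "laminin": laminin, "density": density,
                     "plate": str(grp["plate"].iloc[0])})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the result bundle.

    Returns the output directory.  Raises with the failing stage named;
    partial outputs are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    config.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        if config.input_root is None:
            syn = config.synthetic
            base_spec = synthetic_data.CultureSpec(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in syn.get("spec", {}).items()})
            conditions = {
                name: synthetic_data.CultureSpec(
                    **{**base_spec.to_dict(),
                       **{k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()}})
                for name, overrides in syn["conditions"].items()
            }
            root = out / "images"
            synthetic_data.materialize_dataset(
                conditions, root,
                n_wells=syn.get("n_wells", 2), n_fovs=syn.get("n_fovs", 4),
                base_seed=config.seed)
            platemap_path = root / "platemap.yaml"
        else:
            root = Path(config.input_root)
            if config.platemap is None or not Path(config.platemap).exists():
                raise ParameterError(f"platemap: file not found: {config.platemap}")
            platemap_path = Path(config.platemap)

        stage = "read"
        platemap = imaging_io.load_platemap(platemap_path)
        images, index = imaging_io.read_dataset(root, platemap)
        imaging_io.write_manifest(index.manifest, out / "manifest.csv")

        stage = "metrics"
        n_fovs = int(index.manifest["fov"].nunique())
        side = max(1, int(math.isqrt(n_fovs)))
        coherency_fovs = set(network_metrics.select_coherency_fovs((side, max(1, n_fovs // side))))
        per_image = compute_image_metrics(images, config, coherency_fovs)
        per_image.to_csv(out / "per_image_metrics.csv", index=False)

        stage = "trajectories"
        metrics = ["mean_fluorescence"] + STRUCTURAL_METRICS
        traj, auc = timeseries.assemble_trajectories(
            per_image[["well", "condition", "day", "fov"] + metrics],
            metrics=metrics,
            death_threshold=config.death_threshold,
            include_death_day=config.include_death_day,
        )
        cond_map = per_image.groupby("well")["condition"].first()
        traj.to_csv(out / "trajectories.csv", index=False)
        auc.to_csv(out / "auc_summary.csv", index=False)

        stage = "stats"
        design = _design_from_conditions(index.manifest)
        if design is not None and design["plate"].nunique() >= 2:
            for metric in STRUCTURAL_METRICS:
                table = auc[auc["metric"] == metric][["well", "auc"]].dropna()
                try:
                    result = stats_analysis.fit_interaction_model(table, design)
                    result.terms.to_csv(out / f"model_{metric}.csv", index=False)
                except ParameterError as exc:
                    logger.info("stats: model for %s not estimable (%s)", metric, exc)
        else:
            logger.info("stats: design not a full factorial with >= 2 plates; models skipped")

        stage = "network_score"
        cond_auc = auc.merge(cond_map.rename("cond"), left_on="well", right_index=True)
        means = cond_auc.pivot_table(index="cond", columns="metric", values="auc", aggfunc="mean")
        if {"cdf", "coherency"} <= set(means.columns):
            score_in = means.reset_index().rename(
                columns={"cond": "condition", "cdf": "cdf_auc", "coherency": "coherency_auc"})
            try:
                scores = stats_analysis.network_score(
                    score_in[["condition", "cdf_auc", "coherency_auc"]])
                scores.to_csv(out / "network_score.csv", index=False)
            except ParameterError as exc:
                logger.info("network_score: skipped (%s)", exc)
    except Exception:
        logger.error("run_pipeline: stage '%s' failed", stage)
        raise
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()
    return out


def make_report(bundle_dir: str | Path) -> list[Path]:
    """Figures and summary from a completed result bundle.

    One trajectory plot per metric (the 5 structural metrics plus mean
    fluorescence) with death-day markers, AUC boxplots per factor when
    the design is factorial, and the network-score table.  Returns the
    list of files written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bundle = Path(bundle_dir)
    traj_path = bundle / "trajectories.csv"
    if not traj_path.exists():
        raise ParameterError(f"bundle: incomplete bundle, missing {traj_path}")
    traj = pd.read_csv(traj_path)
    if traj.empty:
        raise ParameterError("bundle: empty trajectory table")
    fig_dir = bundle / "figures"
    fig_dir.mkdir(exist_ok=True)
    written = []

    for metric, grp in traj.groupby("metric"):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for cond, cgrp in grp.groupby("condition"):
            daily = cgrp.groupby("day")["normalized"].agg(["mean", "sem"])
            ax.errorbar(daily.index, daily["mean"], yerr=daily["sem"], label=cond, capsize=2)
        deaths = grp[grp["dead"] == 1].groupby("well")["day"].min()
        for day in deaths:
            ax.axvline(day, color="k", ls="--", lw=0.8)
            ax.plot([day], [grp[grp["day"] == day]["normalized"].mean()], "ks", ms=5)
        ax.set_xlabel("day")
        ax.set_ylabel(f"{metric} (normalised to first day)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = fig_dir / f"trajectory_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    auc_path = bundle / "auc_summary.csv"
    if auc_path.exists():
        auc = pd.read_csv(auc_path)
        if not auc.empty and auc["condition"].str.count("-").eq(2).all():
            factors = auc["condition"].str.split("-", expand=True)
            auc = auc.assign(media=factors[0], laminin=factors[1], density=factors[2])
            for factor in ("media", "laminin", "density"):
                if auc[factor].nunique() < 2:
                    continue
                fig, axes = plt.subplots(1, auc["metric"].nunique(),
                                         figsize=(2.2 * auc["metric"].nunique(), 3))
                for ax, (metric, grp) in zip(np.atleast_1d(axes), auc.groupby("metric")):
                    grp.boxplot(column="auc", by=factor, ax=ax)
                    ax.set_title(metric, fontsize=8)
                fig.suptitle(f"AUC by {factor}")
                fig.tight_layout()
                path = fig_dir / f"auc_by_{factor}.png"
                fig.savefig(path, dpi=120)
                plt.close(fig)
                written.append(path)
    return written
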