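"""Batch orchestration: per-image metrics -> per-animal aggregation ->
group statistics, driven by a YAML-serializable run configuration.

The test is chosen by group count: unpaired t for two groups, one-way
ANOVA with Tukey HSD for three or more.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detection, morphometry, segmentation, stats
from .imagecore import FilterParams, Micrograph, normalize_to_8bit, read_image

__all__ = ["RunConfig", "run_pipeline", "compute_image_metrics"]

log = logging.getLogger("nvuquant")


@dataclass
class RunConfig:
    """Everything a batch run needs, serializable to YAML for provenance."""

    vessel_channel: str | None = "COL4"
    pericyte_channel: str | None = None
    area_channels: list = field(default_factory=list)  # percent-area stains
    count_channels: list = field(default_factory=list)
    coloc_pair: list | None = None  # [channel_a, channel_b]

    filter_params: FilterParams = field(default_factory=FilterParams)
    min_particle_area: float = 25.0
    max_particle_area: float = float("inf")
    area_threshold: float | str = "otsu"  # fixed 0-255 value or "otsu"
    detection: dict = field(
        default_factory=lambda: {
            "min_scale": 3.0,
            "max_scale": 8.0,
            "score_threshold": 8.0,
            "min_distance": 5.0,
        }
    )
    pairing_radius: float = 5.0
    tolerance_radius: float = 2.0

    control_group: str = "young"
    welch: bool = False
    relative_to_control: bool = True
    pixel_size: float = 0.6
    seed: int = 0
    out_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["max_particle_area"] = (
            None
            if np.isinf(self.max_particle_area)
            else self.max_particle_area
        )
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        fp = d.pop("filter_params", None)
        cfg = cls(**d)
        if fp is not None:
            cfg.filter_params = FilterParams(**fp)
        if cfg.max_particle_area is None:
            cfg.max_particle_area = float("inf")
        return cfg


def _resolve_threshold(config: RunConfig, images: list[np.ndarray]) -> float:
    """Freeze a single percent-area threshold for the whole experiment."""
    if config.area_threshold != "otsu":
        return float(config.area_threshold)
    from skimage.filters import threshold_otsu

    pooled = np.concatenate([normalize_to_8bit(a).ravel() for a in images])
    return float(threshold_otsu(pooled, nbins=256))


def compute_image_metrics(
    img: Micrograph, config: RunConfig, area_threshold: float | None = None
) -> dict:
    """All configured metrics for one multi-channel image."""
    metrics: dict[str, float] = {}
    if config.vessel_channel and config.vessel_channel in img.channels:
        seg = segmentation.segment_vessels(
            img,
            params=config.filter_params,
            min_area=config.min_particle_area,
            max_area=config.max_particle_area,
            channel=config.vessel_channel,
        )
        metrics["vessel_percent_area"] = seg.percent_area
        metrics["vessel_particle_count"] = seg.particles.particle_count
        metrics["vessel_sigma_used"] = seg.params_used["sigma_used"]
        if config.pericyte_channel and config.pericyte_channel in img.channels:
            peri = normalize_to_8bit(img.channel(config.pericyte_channel))
            thr = area_threshold if area_threshold is not None else 0.0
            cov = morphometry.pericyte_coverage(
                seg.mask,
                peri > thr,
                tolerance_radius=config.tolerance_radius,
                pixel_size=img.pixel_size,
            )
            metrics["vessel_length_um"] = cov.vessel_length
            metrics["covered_length_um"] = cov.covered_length
            metrics["coverage_fraction"] = cov.coverage_fraction
    for ch in config.area_channels:
        if ch in img.channels:
            a = normalize_to_8bit(img.channel(ch))
            thr = area_threshold if area_threshold is not None else 0.0
            metrics[f"percent_area_{ch}"] = 100.0 * morphometry.percent_area(
                a, thr
            )
    dets: dict[str, detection.DetectionSet] = {}
    for ch in config.count_channels:
        if ch in img.channels:
            d = detection.detect_cells(
                normalize_to_8bit(img.channel(ch)),
                channel=ch,
                pixel_size=img.pixel_size,
                **config.detection,
            )
            dets[ch] = d
            metrics[f"count_{ch}"] = d.count
            metrics[f"density_{ch}_per_mm2"] = detection.density(d)
    if config.coloc_pair:
        ca, cb = config.coloc_pair
        if ca in dets and cb in dets:
            dp = detection.double_positive(
                dets[ca], dets[cb], config.pairing_radius
            )
            metrics[f"count_{ca}_{cb}_double"] = dp["count_ab"]
    return metrics


def run_pipeline(
    config: RunConfig,
    manifest: pd.DataFrame,
    images: dict | None = None,
    image_root: str | Path | None = None,
) -> dict:
    """Run the full quantification batch.

    ``manifest`` needs columns file, animal_id, group (one row per image;
    per-channel rows are collapsed).  Images are looked up in ``images``
    (file -> Micrograph) when given, else read from ``image_root``/file
    with channel names taken from the manifest's channel rows.

    Writes per_image.csv, per_animal.csv, group_stats.csv, summary.json
    and a config echo into ``config.out_dir``; returns the summary dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config_used.yaml")

    per_file = manifest.sort_values("file").groupby("file", sort=True)
    loaded: list[tuple[str, str, str, Micrograph]] = []
    failures: list[str] = []
    for fname, rows in per_file:
        meta = rows.iloc[0]
        if pd.isna(meta.get("animal_id")) or pd.isna(meta.get("group")):
            raise ValueError(f"{fname}: missing animal/group metadata")
        try:
            if images is not None and fname in images:
                img = images[fname]
            else:
                if "channel_index" in rows:
                    rows = rows.sort_values("channel_index")
                chans = (
                    list(rows["channel"]) if "channel" in rows else None
                )
                root = Path(image_root) if image_root else Path(".")
                img = read_image(
                    root / fname, channels=chans, pixel_size=config.pixel_size
                )
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            log.error("unreadable image %s: %s", fname, exc)
            failures.append(str(fname))
            continue
        loaded.append((str(fname), meta["animal_id"], meta["group"], img))

    area_threshold = None
    if config.area_channels or config.pericyte_channel:
        pool = []
        for _, _, grp, img in loaded:
            if grp != config.control_group:
                continue
            for ch in set(config.area_channels) | (
                {config.pericyte_channel} if config.pericyte_channel else set()
            ):
                if ch in img.channels:
                    pool.append(img.channel(ch))
        if not pool:  # fall back to all groups
            for _, _, _, img in loaded:
                for ch in config.area_channels:
                    if ch in img.channels:
                        pool.append(img.channel(ch))
        if pool:
            area_threshold = _resolve_threshold(config, pool)

    rows = []
    for fname, animal, group, img in loaded:
        try:
            metrics = compute_image_metrics(img, config, area_threshold)
        except Exception as exc:  # noqa: BLE001
            log.error("quantification failed for %s: %s", fname, exc)
            failures.append(fname)
            continue
        for metric, value in metrics.items():
            rows.append(
                {
                    "file": fname,
                    "animal_id": animal,
                    "group": group,
                    "metric": metric,
                    "value": value,
                }
            )
    per_image = pd.DataFrame(
        rows, columns=["file", "animal_id", "group", "metric", "value"]
    )
    per_image.to_csv(out_dir / "per_image.csv", index=False)

    per_animal = (
        stats.aggregate_per_animal(per_image)
        if len(per_image)
        else pd.DataFrame(columns=["animal_id", "group", "metric", "value"])
    )
    per_animal.to_csv(out_dir / "per_animal.csv", index=False)

    stat_rows = []
    summary: dict = {
        "n_images": len(loaded),
        "n_failures": len(failures),
        "failures": failures,
        "area_threshold": area_threshold,
        "metrics": {},
    }
    for metric, sub in per_animal.groupby("metric"):
        groups = {
            g: s["value"].to_numpy() for g, s in sub.groupby("group")
        }
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        entry: dict = {
            "group_means": {g: float(v.mean()) for g, v in groups.items()},
            "group_sems": {
                g: float(v.std(ddof=1) / np.sqrt(len(v)))
                for g, v in groups.items()
            },
        }
        if config.relative_to_control and config.control_group in groups:
            cm = groups[config.control_group].mean()
            if cm != 0:
                entry["relative_means"] = {
                    g: float(v.mean() / cm) for g, v in groups.items()
                }
        try:
            if len(groups) == 2:
                (ga, va), (gb, vb) = sorted(groups.items())
                res = stats.unpaired_t(va, vb, welch=config.welch)
                entry["test"] = "unpaired_t"
                entry["t"] = res.t
                entry["p"] = res.p
                stat_rows.append(
                    {"metric": metric, "test": "unpaired_t",
                     "comparison": f"{ga} vs {gb}", "statistic": res.t,
                     "p": res.p}
                )
            elif len(groups) >= 3:
                res = stats.anova_tukey(groups)
                entry["test"] = "anova_tukey"
                entry["F"] = res.f
                entry["p"] = res.p
                entry["pairwise"] = res.pairwise.to_dict("records")
                stat_rows.append(
                    {"metric": metric, "test": "anova", "comparison": "all",
                     "statistic": res.f, "p": res.p}
                )
                for pw in res.pairwise.itertuples():
                    stat_rows.append(
                        {"metric": metric, "test": "tukey",
                         "comparison": f"{pw.group_a} vs {pw.group_b}",
                         "statistic": pw.q, "p": pw.p_adj}
                    )
        except ValueError as exc:
            entry["test_error"] = str(exc)
        summary["metrics"][metric] = entry

    pd.DataFrame(
        stat_rows, columns=["metric", "test", "comparison", "statistic", "p"]
    ).to_csv(out_dir / "group_stats.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float)
    )
    summary["exit_code"] = 1 if failures else 0
    return summary
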