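"""Seeded generator of multi-channel neurovascular scenes with ground truth.

Scenes contain bright curvilinear vessel tubes (random-walk centerlines of
constant per-vessel width), pericyte coverage bands with somata on the
vessel wall, Gaussian soma-like cells in one or more cell channels (with
optional double-positive pairing between two channels), punctate deposits,
a background gradient, and Poisson-then-Gaussian noise.  Ground truth
(masks, centerline lengths, object coordinates) is captured pre-noise and
is exact for the realized scene.

Randomness is driven by ``numpy.random.Generator`` (PCG64); the same spec
and seed always reproduce the identical scene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imagecore import Micrograph, write_image

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "GroupEffect",
    "CohortSpec",
    "generate_scene",
    "generate_cohort",
    "DEFAULT_GROUP_EFFECTS",
]

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass
class SceneSpec:
    """Parameters of one synthetic field."""

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.6  # um/px, approximating a 20x field

    # vessels (vessel-marker channel, e.g. COL4)
    n_vessels: int = 6
    vessel_width: tuple[float, float] = (3.0, 10.0)
    vessel_intensity: float = 170.0
    target_vessel_fraction: float | None = None

    # pericytes (PDGFRB-like channel)
    pericyte_per_100um: float = 0.0  # somata per 100 um of vessel
    pericyte_coverage: float = 0.0  # fraction of vessel length banded
    pericyte_intensity: float = 140.0

    # soma-like cell channels
    n_iba1: float = 0.0  # expected IBA1-like cells (Poisson-drawn)
    c1qa_fraction: float = 0.0  # fraction of IBA1 cells also C1qa+
    n_c1qa_solo: float = 0.0  # C1qa+ cells off microglia
    n_neun: float = 0.0
    soma_sigma: float = 4.0
    soma_intensity: float = 120.0
    min_cell_sep: float = 14.0

    # fibrin-like puncta
    n_deposits: float = 0.0
    deposit_radius: tuple[float, float] = (2.0, 4.0)
    deposit_intensity: float = 200.0
    deposit_on_vessel_fraction: float = 0.5

    # background and noise
    background: float = 20.0
    gradient_amplitude: float = 8.0
    poisson_scale: float = 2.0  # photons per intensity unit; 0 disables
    gaussian_sd: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_iba1", "n_c1qa_solo", "n_neun", "n_deposits",
                     "pericyte_per_100um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.pericyte_coverage <= 1:
            raise ValueError("pericyte_coverage must be in [0, 1]")
        if not 0 <= self.c1qa_fraction <= 1:
            raise ValueError("c1qa_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Exact per-scene truth, captured before noise is applied."""

    masks: dict  # channel -> boolean truth mask
    area_fractions: dict  # channel -> true mask fraction
    centerlines: list  # per vessel: (N, 2) float array of (row, col)
    centerline_lengths_um: list  # per vessel
    vessel_length_um: float
    coverage_fraction: float  # realized banded fraction of vessel length
    points: dict  # channel -> (N, 2) array of planted (row, col) centers
    double_pairs: np.ndarray  # (K, 2) indices into points[a], points[b]

    def check(self) -> None:
        for ch, m in self.masks.items():
            assert abs(m.mean() - self.area_fractions[ch]) < 1e-12
        assert abs(
            sum(self.centerline_lengths_um) - self.vessel_length_um
        ) < 1e-9


# ---------------------------------------------------------------------------
# scene construction


def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    h, w = mask.shape
    ir, ic = int(round(r)), int(round(c))
    rad = int(np.ceil(radius))
    r0, r1 = max(ir - rad, 0), min(ir + rad + 1, h)
    c0, c1 = max(ic - rad, 0), min(ic + rad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (yy - r) ** 2 + (xx - c) ** 2 <= radius**2


def _walk_vessel(
    rng: np.random.Generator, shape: tuple[int, int], max_steps: int = 900
) -> np.ndarray:
    """Smoothed unit-step random walk crossing the field."""
    h, w = shape
    margin = 4.0
    side = rng.integers(4)
    if side == 0:  # left edge, heading right
        p = np.array([rng.uniform(0, h), 0.0])
        theta = rng.uniform(-0.6, 0.6)
    elif side == 1:  # right edge
        p = np.array([rng.uniform(0, h), float(w - 1)])
        theta = np.pi + rng.uniform(-0.6, 0.6)
    elif side == 2:  # top edge, heading down
        p = np.array([0.0, rng.uniform(0, w)])
        theta = np.pi / 2 + rng.uniform(-0.6, 0.6)
    else:
        p = np.array([float(h - 1), rng.uniform(0, w)])
        theta = -np.pi / 2 + rng.uniform(-0.6, 0.6)
    pts = [p.copy()]
    for _ in range(max_steps):
        theta += rng.normal(0.0, 0.07)
        p = p + np.array([np.sin(theta), np.cos(theta)])
        if not (-margin <= p[0] < h + margin and -margin <= p[1] < w + margin):
            break
        pts.append(p.copy())
    return np.array(pts)


def _rasterize_tube(
    mask: np.ndarray, centerline: np.ndarray, width: float
) -> None:
    for r, c in centerline:
        _stamp_disk(mask, r, c, width / 2.0)


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_sep: float,
    max_tries: int = 40,
    avoid: np.ndarray | None = None,
) -> np.ndarray:
    """Rejection-sample n centers with pairwise separation >= min_sep."""
    h, w = shape
    placed: list[np.ndarray] = [] if avoid is None else [p for p in avoid]
    n_avoid = len(placed)
    for _ in range(n):
        for _try in range(max_tries):
            cand = np.array(
                [rng.uniform(8, h - 8), rng.uniform(8, w - 8)]
            )
            if all(
                np.hypot(*(cand - q)) >= min_sep for q in placed
            ):
                placed.append(cand)
                break
        # crowded field: silently place fewer; realized truth is recorded
    return (
        np.array(placed[n_avoid:])
        if len(placed) > n_avoid
        else np.empty((0, 2))
    )


def _render_somata(
    shape: tuple[int, int],
    points: np.ndarray,
    sigma: float,
    amplitude: float,
) -> np.ndarray:
    img = np.zeros(shape)
    rad = int(np.ceil(4 * sigma))
    h, w = shape
    for r, c in points:
        ir, ic = int(round(r)), int(round(c))
        r0, r1 = max(ir - rad, 0), min(ir + rad + 1, h)
        c0, c1 = max(ic - rad, 0), min(ic + rad + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sigma**2)
        )
    return img


def _apply_noise(
    rng: np.random.Generator, img: np.ndarray, spec: SceneSpec
) -> np.ndarray:
    out = img
    if spec.poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0) * spec.poisson_scale) / (
            spec.poisson_scale
        )
    if spec.gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.gaussian_sd, size=img.shape)
    return np.maximum(out, 0.0)


def generate_scene(spec: SceneSpec) -> tuple[Micrograph, GroundTruth]:
    """Render one multi-channel scene and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    h, w = shape

    # --- vessels -----------------------------------------------------------
    vessel_mask = np.zeros(shape, dtype=bool)
    centerlines: list[np.ndarray] = []
    lengths_um: list[float] = []
    widths: list[float] = []

    def add_vessel() -> None:
        cl = _walk_vessel(rng, shape)
        if len(cl) < 2:
            return
        width = rng.uniform(*spec.vessel_width)
        _rasterize_tube(vessel_mask, cl, width)
        centerlines.append(cl)
        widths.append(width)
        # unit steps -> length = (n_points - 1) px
        lengths_um.append((len(cl) - 1) * spec.pixel_size)

    if spec.target_vessel_fraction is not None:
        tries = 0
        while vessel_mask.mean() < spec.target_vessel_fraction and tries < 400:
            add_vessel()
            tries += 1
    else:
        for _ in range(spec.n_vessels):
            add_vessel()
    if (spec.n_vessels > 0 or spec.target_vessel_fraction) and not centerlines:
        raise RuntimeError("vessel generation failed for this spec")

    # --- pericyte bands and somata ----------------------------------------
    pericyte_mask = np.zeros(shape, dtype=bool)
    covered_um = 0.0
    pericyte_points: list[np.ndarray] = []
    if spec.pericyte_coverage > 0 and centerlines:
        for cl, width, lum in zip(centerlines, widths, lengths_um):
            n_pts = len(cl)
            n_band = int(round(spec.pericyte_coverage * (n_pts - 1)))
            if n_band <= 0:
                continue
            start = int(rng.integers(0, n_pts - n_band)) if n_pts > n_band else 0
            band = cl[start : start + n_band + 1]
            _rasterize_tube(pericyte_mask, band, width + 2.0)
            covered_um += n_band * spec.pixel_size
            if spec.pericyte_per_100um > 0:
                n_soma = rng.poisson(
                    spec.pericyte_per_100um * (n_band * spec.pixel_size) / 100.0
                )
                if n_soma > 0:
                    idx = rng.choice(len(band), size=min(n_soma, len(band)),
                                     replace=False)
                    for p in band[np.sort(idx)]:
                        pericyte_points.append(p)
    total_um = float(sum(lengths_um))
    coverage_fraction = covered_um / total_um if total_um > 0 else 0.0

    # --- cells -------------------------------------------------------------
    n_iba1 = int(rng.poisson(spec.n_iba1)) if spec.n_iba1 > 0 else 0
    iba1_pts = _place_points(rng, n_iba1, shape, spec.min_cell_sep)
    n_dp = (
        int(round(spec.c1qa_fraction * len(iba1_pts)))
        if spec.c1qa_fraction > 0
        else 0
    )
    dp_idx = (
        np.sort(rng.choice(len(iba1_pts), size=n_dp, replace=False))
        if n_dp
        else np.empty(0, dtype=int)
    )
    n_solo = int(rng.poisson(spec.n_c1qa_solo)) if spec.n_c1qa_solo > 0 else 0
    solo_pts = _place_points(
        rng, n_solo, shape, spec.min_cell_sep,
        avoid=iba1_pts if len(iba1_pts) else None,
    )
    c1qa_pts = (
        np.vstack([iba1_pts[dp_idx], solo_pts])
        if (len(dp_idx) or len(solo_pts))
        else np.empty((0, 2))
    )
    # pairs are (index into C1QA points, index into IBA1 points)
    double_pairs = (
        np.column_stack([np.arange(len(dp_idx)), dp_idx])
        if len(dp_idx)
        else np.empty((0, 2), dtype=int)
    )
    n_neun = int(rng.poisson(spec.n_neun)) if spec.n_neun > 0 else 0
    neun_pts = _place_points(rng, n_neun, shape, spec.min_cell_sep)

    # --- fibrin-like deposits ---------------------------------------------
    deposit_mask = np.zeros(shape, dtype=bool)
    deposit_points: list[np.ndarray] = []
    n_dep = int(rng.poisson(spec.n_deposits)) if spec.n_deposits > 0 else 0
    vessel_px = np.argwhere(vessel_mask)
    for _ in range(n_dep):
        on_vessel = (
            rng.random() < spec.deposit_on_vessel_fraction and len(vessel_px)
        )
        if on_vessel:
            r, c = vessel_px[rng.integers(len(vessel_px))].astype(float)
        else:
            r, c = rng.uniform(0, h), rng.uniform(0, w)
        rad = rng.uniform(*spec.deposit_radius)
        _stamp_disk(deposit_mask, r, c, rad)
        deposit_points.append(np.array([r, c]))

    # --- compose channels --------------------------------------------------
    yy, xx = np.mgrid[0:h, 0:w]
    phi = rng.uniform(0, 2 * np.pi)
    gradient = spec.gradient_amplitude * (
        (np.cos(phi) * xx + np.sin(phi) * yy) / max(h, w) + 0.5
    )
    base = spec.background + gradient

    channels: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    points: dict[str, np.ndarray] = {}

    channels["COL4"] = base + spec.vessel_intensity * ndimage.gaussian_filter(
        vessel_mask.astype(float), 1.0
    )
    masks["COL4"] = vessel_mask

    if spec.pericyte_coverage > 0 or spec.pericyte_per_100um > 0:
        peri = spec.pericyte_intensity * ndimage.gaussian_filter(
            pericyte_mask.astype(float), 1.0
        )
        if pericyte_points:
            peri += _render_somata(
                shape, np.array(pericyte_points), 3.0, spec.pericyte_intensity
            )
        channels["PDGFRB"] = base + peri
        masks["PDGFRB"] = pericyte_mask
        points["PDGFRB"] = (
            np.array(pericyte_points)
            if pericyte_points
            else np.empty((0, 2))
        )

    if spec.n_iba1 > 0:
        channels["IBA1"] = base + _render_somata(
            shape, iba1_pts, spec.soma_sigma, spec.soma_intensity
        )
        points["IBA1"] = iba1_pts
    if spec.c1qa_fraction > 0 or spec.n_c1qa_solo > 0:
        channels["C1QA"] = base + _render_somata(
            shape, c1qa_pts, spec.soma_sigma, spec.soma_intensity
        )
        points["C1QA"] = c1qa_pts
    if spec.n_neun > 0:
        channels["NEUN"] = base + _render_somata(
            shape, neun_pts, spec.soma_sigma, spec.soma_intensity
        )
        points["NEUN"] = neun_pts
    if spec.n_deposits > 0:
        channels["FIB"] = base + spec.deposit_intensity * (
            ndimage.gaussian_filter(deposit_mask.astype(float), 0.8)
        )
        masks["FIB"] = deposit_mask
        points["FIB"] = (
            np.array(deposit_points) if deposit_points else np.empty((0, 2))
        )

    # --- noise (truth is pre-noise) ---------------------------------------
    names = tuple(channels.keys())
    noisy = np.stack([_apply_noise(rng, channels[n], spec) for n in names])
    img = Micrograph(
        pixels=noisy,
        channels=names,
        bit_depth=8,
        pixel_size=spec.pixel_size,
    )
    truth = GroundTruth(
        masks=masks,
        area_fractions={ch: float(m.mean()) for ch, m in masks.items()},
        centerlines=centerlines,
        centerline_lengths_um=lengths_um,
        vessel_length_um=total_um,
        coverage_fraction=float(coverage_fraction),
        points=points,
        double_pairs=double_pairs,
    )
    return img, truth


# ---------------------------------------------------------------------------
# cohorts with planted group effects


@dataclass
class GroupEffect:
    """Multiplicative effects applied to a group's SceneSpec fields."""

    fibrin: float = 1.0  # n_deposits
    pericyte_count: float = 1.0  # pericyte_per_100um
    coverage: float = 1.0  # pericyte_coverage (capped at 1)
    microglia: float = 1.0  # n_iba1
    c1qa: float = 1.0  # c1qa_fraction (capped at 1) and n_c1qa_solo

    def apply(self, spec: SceneSpec) -> SceneSpec:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"effect multiplier {name} must be > 0")
        return replace(
            spec,
            n_deposits=spec.n_deposits * self.fibrin,
            pericyte_per_100um=spec.pericyte_per_100um * self.pericyte_count,
            pericyte_coverage=min(spec.pericyte_coverage * self.coverage, 1.0),
            n_iba1=spec.n_iba1 * self.microglia,
            c1qa_fraction=min(spec.c1qa_fraction * self.c1qa, 1.0),
            n_c1qa_solo=spec.n_c1qa_solo * self.c1qa,
        )


#: Default four-arm design with planted effect magnitudes: aged animals get
#: 3x fibrin deposits, 0.8x pericyte counts, 0.5x coverage, 3x microglial
#: C1qa signal; aged runners recover to 0.65x of the aged C1qa level.
DEFAULT_GROUP_EFFECTS: dict[str, GroupEffect] = {
    "young": GroupEffect(),
    "aging": GroupEffect(fibrin=2.0, pericyte_count=0.9, coverage=0.75,
                         microglia=2.0, c1qa=2.0),
    "aged_sd": GroupEffect(fibrin=3.0, pericyte_count=0.8, coverage=0.5,
                           microglia=3.0, c1qa=3.0),
    "aged_rn": GroupEffect(fibrin=3.0, pericyte_count=0.8, coverage=0.5,
                           microglia=3.0, c1qa=3.0 * 0.65),
}


@dataclass
class CohortSpec:
    base: SceneSpec = field(default_factory=SceneSpec)
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    n_animals: int = 6
    images_per_animal: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if self.n_animals < 2:
            import warnings

            warnings.warn(
                "fewer than 2 animals per group: inference impossible",
                stacklevel=2,
            )


def generate_cohort(
    cohort: CohortSpec, out_dir: str | Path | None = None
) -> list[dict]:
    """Generate group x animal x image scenes with planted effects.

    Returns one record per image: ``{group, animal_id, image_index, scene,
    truth, file}``.  When ``out_dir`` is given, scenes are written as
    multi-page TIFFs alongside ``manifest.csv`` (file, animal_id, group,
    channel) and ``truth.csv`` with per-image planted values.
    """
    records: list[dict] = []
    ss = np.random.SeedSequence(cohort.seed)
    group_seeds = ss.spawn(len(cohort.groups))
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for (label, effect), gseed in zip(cohort.groups.items(), group_seeds):
        spec = effect.apply(cohort.base)
        animal_seeds = gseed.spawn(cohort.n_animals)
        for a, aseed in enumerate(animal_seeds):
            animal_id = f"{label}_m{a + 1:02d}"
            image_seeds = aseed.spawn(cohort.images_per_animal)
            for i, iseed in enumerate(image_seeds):
                scene_spec = replace(
                    spec, seed=int(iseed.generate_state(1)[0])
                )
                img, truth = generate_scene(scene_spec)
                rec = {
                    "group": label,
                    "animal_id": animal_id,
                    "image_index": i,
                    "scene": img,
                    "truth": truth,
                    "file": None,
                }
                if out_dir is not None:
                    fname = f"{animal_id}_img{i:02d}.tif"
                    write_image(out_dir / fname, img)
                    rec["file"] = fname
                records.append(rec)

    if out_dir is not None:
        manifest_rows = []
        truth_rows = []
        for rec in records:
            for idx, ch in enumerate(rec["scene"].channels):
                manifest_rows.append(
                    {
                        "file": rec["file"],
                        "animal_id": rec["animal_id"],
                        "group": rec["group"],
                        "channel": ch,
                        "channel_index": idx,
                    }
                )
            t: GroundTruth = rec["truth"]
            truth_rows.append(
                {
                    "file": rec["file"],
                    "animal_id": rec["animal_id"],
                    "group": rec["group"],
                    "vessel_length_um": t.vessel_length_um,
                    "coverage_fraction": t.coverage_fraction,
                    **{
                        f"area_fraction_{ch}": f
                        for ch, f in t.area_fractions.items()
                    },
                    **{
                        f"n_{ch}": len(p) for ch, p in t.points.items()
                    },
                    "n_double_positive": len(t.double_pairs),
                }
            )
        pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False)
        pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
        (out_dir / "generator.json").write_text(
            json.dumps({"rng": RNG_ALGORITHM, "seed": cohort.seed}, indent=2)
        )
    return records
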