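"""Seeded synthetic mitochondrial scenes, cohorts, time-lapses and calibrations.

Everything downstream of raw data is testable against this module's
ground truth: rendered scenes come with a truth mask and per-object
truth table, feature cohorts with planted condition shifts, time-lapses
with exact centroid tracks, and calibration series with known slope and
noise.  All generators are deterministic: identical (spec, seed) gives
bit-identical output.

Shape construction:

* dot     — a filled disc;
* rod     — a capsule (rectangle with semicircular caps), the simplest
  branchless elongated region;
* network — a random star/loop skeleton (a hub with >= 3 arms, plus
  optional tangent rings contributing one independent cycle each)
  dilated by a width kernel, the simplest region guaranteeing the
  intended branch and loop topology.

Objects are placed by rejection sampling (<= 100 retries per object)
so scenes contain only resolved, non-overlapping organelles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from mitoscope.imaging import ImageFrame, LabeledMask, write_stack


class PlacementError(ValueError):
    """A shape does not fit inside the canvas."""


class GenerationError(RuntimeError):
    """An object could not be placed after the retry budget."""


# ---------------------------------------------------------------------------
# Specs


@dataclass
class ShapeSpec:
    """Intent for one synthetic mitochondrion.

    ``kind`` selects the morphotype; the size parameters used depend on
    it: ``radius_px`` (dot); ``length_px``, ``width_px``,
    ``orientation_deg`` (rod); ``branch_count``, ``loop_count``,
    ``segment_length_px``, ``width_px`` (network).  ``center`` may be
    None for random placement by the scene renderer.
    """

    kind: str  # dot | rod | network
    radius_px: float = 5.0
    length_px: float = 30.0
    width_px: float = 4.0
    orientation_deg: float = 0.0
    branch_count: int = 3
    loop_count: int = 0
    segment_length_px: float = 15.0
    center: tuple[float, float] | None = None
    intensity_mean: float = 200.0
    intensity_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("dot", "rod", "network"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind == "dot" and self.radius_px < 1:
            raise ValueError("dot radius must be >= 1 px")
        if self.kind == "rod" and not self.length_px > self.width_px >= 1:
            raise ValueError("rod needs length > width >= 1")
        if self.kind == "network" and self.branch_count < 1:
            raise ValueError("network needs branch_count >= 1")
        if self.kind == "network" and self.loop_count < 0:
            raise ValueError("loop_count must be >= 0")


@dataclass
class SceneSpec:
    """A full synthetic field of view."""

    shapes: list[ShapeSpec]
    canvas: tuple[int, int] = (512, 512)
    background: float = 10.0
    noise_sd: float = 2.0
    pixel_size_um: float = 0.05
    seed: int = 0
    min_separation_px: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class SyntheticScene:
    image: ImageFrame
    truth_mask: LabeledMask
    truth_table: pd.DataFrame  # label, kind, branch_count, loop_count, ...
    spec: SceneSpec


@dataclass
class CohortSpec:
    """Planted-feature cohort emulating per-condition single-organelle tables.

    Each feature is Gaussian with the given (mean, sd); condition c at
    level index i (0-based over L levels) is shifted by
    ``effect_size * sd * i / (L - 1)``, so the extreme contrast equals
    the stated effect size in sd units.  Morphotype is drawn from
    per-condition class probabilities and one-hot encoded.
    """

    n_per_condition: int = 5000
    conditions: tuple[str, ...] = ("control", "hypoxia")
    feature_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    type_probs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    effect_scale: float = 1.0  # global multiplier on every effect size (0 = null cohort)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if len(self.conditions) not in (2, 4):
            raise ValueError("condition label set must have 2 or 4 levels")
        for name, (_, sd) in self.feature_params.items():
            if sd <= 0:
                raise ValueError(f"feature {name!r} needs sd > 0")


@dataclass
class TrackSpec:
    """Persistent-random-walk motion model for synthetic time-lapses."""

    n_frames: int = 30
    frame_interval_s: float = 1.0
    n_objects: int = 10
    step_mean_px: float = 3.0
    persistence: float = 0.8
    canvas: tuple[int, int] = (512, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")


# ---------------------------------------------------------------------------
# Shape rendering

#: fraction-of-bound default intensity means per condition-free scenes
DEFAULT_INTENSITY = 200.0


def _capsule(canvas: tuple[int, int], center, length, width, orientation_deg) -> np.ndarray:
    rows, cols = np.mgrid[0 : canvas[0], 0 : canvas[1]]
    theta = math.radians(orientation_deg)
    d = np.array([-math.sin(theta), math.cos(theta)])  # (drow, dcol), row down
    half = max((length - width) / 2.0, 0.0)
    p = np.stack([rows - center[0], cols - center[1]], axis=-1).astype(float)
    t = np.clip(p @ d, -half, half)
    closest = t[..., None] * d
    dist = np.linalg.norm(p - closest, axis=-1)
    return dist <= width / 2.0


def _disc(canvas: tuple[int, int], center, radius) -> np.ndarray:
    rows, cols = np.mgrid[0 : canvas[0], 0 : canvas[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def _draw_segment(mask: np.ndarray, a, b) -> tuple[float, float]:
    """Rasterize the segment a->b into mask; returns the endpoint."""
    n = int(max(abs(b[0] - a[0]), abs(b[1] - a[1])) * 2) + 1
    rr = np.round(np.linspace(a[0], b[0], n)).astype(int)
    cc = np.round(np.linspace(a[1], b[1], n)).astype(int)
    ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    mask[rr[ok], cc[ok]] = True
    return b


def make_shape(spec: ShapeSpec, canvas: tuple[int, int]) -> np.ndarray:
    """Render one shape intent as a full-canvas boolean mask.

    Raises :class:`PlacementError` when the shape would exceed the
    canvas bounds.
    """
    if spec.center is None:
        raise ValueError("make_shape requires an explicit center")
    r0, c0 = spec.center
    if spec.kind == "dot":
        margin = spec.radius_px + 1
    elif spec.kind == "rod":
        margin = spec.length_px / 2 + 1
    else:
        margin = spec.segment_length_px + spec.width_px + 1
    if (
        r0 - margin < 0
        or c0 - margin < 0
        or r0 + margin >= canvas[0]
        or c0 + margin >= canvas[1]
    ):
        raise PlacementError(f"{spec.kind} at {spec.center} exceeds canvas {canvas}")

    if spec.kind == "dot":
        return _disc(canvas, spec.center, spec.radius_px)
    if spec.kind == "rod":
        return _capsule(canvas, spec.center, spec.length_px, spec.width_px, spec.orientation_deg)

    # network: star skeleton dilated to width; each loop is a chord
    # closing two adjacent arm tips, adding exactly one independent cycle
    skeleton = np.zeros(canvas, dtype=bool)
    n_arms = max(3, spec.branch_count)
    if spec.loop_count > n_arms:
        raise ValueError("loop_count cannot exceed the number of arms")
    base = math.radians(spec.orientation_deg)
    skeleton[int(round(r0)), int(round(c0))] = True
    tips = []
    for i in range(n_arms):
        ang = base + 2 * math.pi * i / n_arms
        d = np.array([-math.sin(ang), math.cos(ang)])
        tip = (r0 + spec.segment_length_px * d[0], c0 + spec.segment_length_px * d[1])
        _draw_segment(skeleton, (r0, c0), tip)
        tips.append(tip)
    for i in range(spec.loop_count):
        _draw_segment(skeleton, tips[i], tips[(i + 1) % n_arms])
    radius = max(int(round(spec.width_px / 2)), 1)
    structure = _disc((2 * radius + 1, 2 * radius + 1), (radius, radius), radius)
    return ndi.binary_dilation(skeleton, structure=structure)


def random_shape_spec(
    kind: str, rng: np.random.Generator, margin: float = 0.10
) -> ShapeSpec:
    """Draw a shape spec safely inside the morphotype decision boundaries.

    ``margin`` is the fractional distance kept from the dot/rod rule
    thresholds (elongation ratio 2, roundness 0.25), so the intended
    class is recoverable by the rule classifier.
    """
    if kind == "dot":
        return ShapeSpec("dot", radius_px=float(rng.uniform(4, 9)))
    if kind == "rod":
        width = float(rng.uniform(3, 5))
        # capsule ratio ~ length/width; stay >= (1+margin) * threshold
        length = float(rng.uniform(2.6, 6.0) * (1 + margin) * width + 4)
        return ShapeSpec(
            "rod",
            length_px=length,
            width_px=width,
            orientation_deg=float(rng.uniform(0, 180)),
        )
    if kind == "network":
        return ShapeSpec(
            "network",
            branch_count=int(rng.integers(3, 6)),
            loop_count=int(rng.integers(0, 2)),
            segment_length_px=float(rng.uniform(12, 18)),
            width_px=float(rng.uniform(2.5, 3.5)),
            orientation_deg=float(rng.uniform(0, 180)),
        )
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Scene rendering


def render_scene(spec: SceneSpec) -> SyntheticScene:
    """Place and render all shapes; returns image, truth mask and table.

    Shapes without an explicit center are placed uniformly at random
    with rejection sampling (<= 100 retries each) so that rendered
    objects stay pairwise separated by ``min_separation_px``.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = spec.canvas
    occupied = np.zeros(canvas, dtype=bool)
    sep = ndi.generate_binary_structure(2, 2)
    labels = np.zeros(canvas, dtype=np.int32)
    rows = []
    for idx, shape in enumerate(spec.shapes, start=1):
        placed = None
        if shape.center is not None:
            mask = make_shape(shape, canvas)
            if (mask & occupied).any():
                raise GenerationError(f"object {idx} overlaps an earlier object")
            placed = mask
        else:
            for _ in range(100):
                center = (
                    float(rng.uniform(0, canvas[0])),
                    float(rng.uniform(0, canvas[1])),
                )
                candidate = ShapeSpec(**{**shape.__dict__, "center": center})
                try:
                    mask = make_shape(candidate, canvas)
                except PlacementError:
                    continue
                if not (mask & occupied).any():
                    placed = mask
                    break
            if placed is None:
                raise GenerationError(
                    f"could not place object {idx} ({shape.kind}) after 100 retries"
                )
        labels[placed] = idx
        occupied |= ndi.binary_dilation(
            placed, structure=sep, iterations=spec.min_separation_px
        )
        rows.append(
            {
                "label": idx,
                "kind": shape.kind,
                "branch_count": max(3, shape.branch_count) if shape.kind == "network" else 0,
                "loop_count": shape.loop_count if shape.kind == "network" else 0,
                "intensity_mean": shape.intensity_mean,
            }
        )
    truth = pd.DataFrame(rows)
    if len(truth):
        truth["fraction_intent"] = truth["intensity_mean"] / truth["intensity_mean"].max()

    image = np.full(canvas, float(spec.background))
    for idx, shape in enumerate(spec.shapes, start=1):
        obj = labels == idx
        n = int(obj.sum())
        image[obj] = shape.intensity_mean + (
            rng.normal(0.0, shape.intensity_sd, size=n) if shape.intensity_sd > 0 else 0.0
        )
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=canvas)
    image = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    frame = ImageFrame(image, pixel_size_um=spec.pixel_size_um)
    return SyntheticScene(frame, LabeledMask(labels), truth, spec)


def write_scene(scene: SyntheticScene, outdir: str | Path, stem: str = "scene") -> dict:
    """Write a scene as TIFFs plus sidecar truth CSV and JSON spec echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / f"{stem}_image.tif",
        "mask": outdir / f"{stem}_mask.tif",
        "truth": outdir / f"{stem}_truth.csv",
        "spec": outdir / f"{stem}_spec.json",
    }
    write_stack([scene.image.pixels], paths["image"])
    write_stack([scene.truth_mask.labels.astype(np.uint16)], paths["mask"])
    scene.truth_table.to_csv(paths["truth"], index=False)
    echo = {
        "canvas": list(scene.spec.canvas),
        "background": scene.spec.background,
        "noise_sd": scene.spec.noise_sd,
        "seed": scene.spec.seed,
        "n_objects": len(scene.spec.shapes),
    }
    paths["spec"].write_text(json.dumps(echo, indent=2))
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Condition cohorts

#: baseline feature distributions for a resting (control) population;
#: biomarker fractions live in [0,1], geometry in pixel units.
DEFAULT_FEATURE_PARAMS: dict[str, tuple[float, float]] = {
    "area_px2": (120.0, 40.0),
    "solidity": (0.82, 0.08),
    "extent": (0.60, 0.10),
    "form_factor": (0.65, 0.12),
    "roundness": (0.40, 0.15),
    "ratio_major_minor": (2.5, 1.0),
    "length_px": (25.0, 8.0),
    "branch_count": (1.2, 1.0),
    "loops": (0.2, 0.4),
    "mean_branch_length_px": (10.0, 4.0),
    "viscosity_fraction": (0.45, 0.12),
    "ros_fraction": (0.45, 0.12),
    "mmp_fraction": (0.60, 0.12),
    "speed_px_s": (2.0, 0.6),
    "directionality": (0.55, 0.15),
    "net_displacement_px": (20.0, 7.0),
}

#: stress response planted by default, in sd units of each feature:
#: viscosity rises most (the dominant hypoxia marker), ROS rises,
#: membrane potential falls, shapes fragment (rounder, more compact,
#: less branched), motility drops.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "viscosity_fraction": 1.0,
    "ros_fraction": 0.7,
    "mmp_fraction": -0.7,
    "solidity": 0.5,
    "extent": 0.3,
    "form_factor": 0.5,
    "roundness": 0.5,
    "ratio_major_minor": -0.4,
    "length_px": -0.5,
    "branch_count": -0.5,
    "loops": -0.3,
    "mean_branch_length_px": -0.4,
    "area_px2": -0.4,
    "speed_px_s": -0.6,
    "directionality": -0.6,
    "net_displacement_px": -0.6,
}

#: dot/rod/network class probabilities per condition archetype
DEFAULT_TYPE_PROBS = {
    "control": (0.20, 0.30, 0.50),
    "stressed": (0.40, 0.35, 0.25),
}

FRACTION_FEATURES = ("viscosity_fraction", "ros_fraction", "mmp_fraction", "directionality")


def simulate_condition_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-object feature table with planted condition shifts.

    Returns one row per simulated mitochondrion with an ``object_id``,
    all continuous features, a one-hot morphotype, and the condition
    label.  Bounded features (fractions, directionality) are clipped to
    [0, 1] after shifting.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.feature_params or DEFAULT_FEATURE_PARAMS
    effects = {**DEFAULT_EFFECT_SIZES, **spec.effect_sizes} if not spec.feature_params else spec.effect_sizes
    levels = spec.conditions
    n_levels = len(levels)
    frames = []
    for i, condition in enumerate(levels):
        grade = i / (n_levels - 1)
        n = spec.n_per_condition
        data = {"condition": condition}
        for name, (mean, sd) in params.items():
            shift = effects.get(name, 0.0) * spec.effect_scale * sd * grade
            values = rng.normal(mean + shift, sd, size=n)
            if name in FRACTION_FEATURES:
                values = np.clip(values, 0.0, 1.0)
            data[name] = values
        if spec.type_probs:
            probs = np.asarray(spec.type_probs[condition], dtype=float)
        else:
            p0 = np.asarray(DEFAULT_TYPE_PROBS["control"], dtype=float)
            p1 = np.asarray(DEFAULT_TYPE_PROBS["stressed"], dtype=float)
            probs = p0 + (p1 - p0) * grade * spec.effect_scale
        probs = probs / probs.sum()
        kinds = rng.choice(("dot", "rod", "network"), size=n, p=probs)
        for k in ("dot", "rod", "network"):
            data[f"type_{k}"] = (kinds == k).astype(int)
        frames.append(pd.DataFrame(data))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "object_id", np.arange(len(table)))
    return table


# ---------------------------------------------------------------------------
# Time-lapse motion


def simulate_timelapse(spec: TrackSpec) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Persistent random walks with ground truth.

    Returns ``(frames, truth_tracks)``: per-frame (n_objects, 2) centroid
    arrays (all objects present in every frame) and per-object (n_frames,
    2) true trajectories.  At persistence 1 every step repeats the
    initial heading (straight line); at 0 every step heading is drawn
    uniformly (isotropic random walk).  Step length is exactly
    ``step_mean_px``.
    """
    rng = np.random.default_rng(spec.seed)
    n, t = spec.n_objects, spec.n_frames
    # seed positions on a coarse grid with jitter, away from borders
    grid = max(int(math.ceil(math.sqrt(n))), 1)
    pitch_r = spec.canvas[0] * 0.6 / grid
    pitch_c = spec.canvas[1] * 0.6 / grid
    starts = []
    for k in range(n):
        gr, gc = divmod(k, grid)
        starts.append(
            (
                spec.canvas[0] * 0.2 + gr * pitch_r + rng.uniform(-2, 2),
                spec.canvas[1] * 0.2 + gc * pitch_c + rng.uniform(-2, 2),
            )
        )
    tracks = []
    for k in range(n):
        pos = np.empty((t, 2))
        pos[0] = starts[k]
        angle = rng.uniform(0, 2 * math.pi)
        for f in range(1, t):
            if rng.uniform() >= spec.persistence:
                angle = rng.uniform(0, 2 * math.pi)
            step = spec.step_mean_px
            pos[f] = pos[f - 1] + step * np.array([math.sin(angle), math.cos(angle)])
        tracks.append(pos)
    frames = [np.array([tracks[k][f] for k in range(n)]) for f in range(t)]
    return frames, tracks


def render_timelapse(
    frames: list[np.ndarray], canvas: tuple[int, int], radius: int = 3,
    intensity: float = 200.0, background: float = 10.0,
) -> list[np.ndarray]:
    """Rasterize centroid frames into a uint16 image stack of discs."""
    stack = []
    for centroids in frames:
        img = np.full(canvas, background)
        for r0, c0 in np.asarray(centroids).reshape(-1, 2):
            rr, cc = np.mgrid[0 : canvas[0], 0 : canvas[1]]
            img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = intensity
        stack.append(np.clip(np.round(img), 0, 65535).astype(np.uint16))
    return stack


# ---------------------------------------------------------------------------
# Calibration series


def simulate_calibration(
    slope: float = 0.8,
    intercept: float = 1.0,
    noise_sd: float = 0.01,
    levels: int | np.ndarray = 10,
    n_blanks: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic cuvette calibration: power-law intensity vs viscosity.

    log10(intensity) = intercept + slope * log10(viscosity) + N(0, noise_sd).
    Blanks are replicate draws at the lowest viscosity level.  Returns
    ``(series, blanks)`` with the series as a (viscosity, intensity)
    DataFrame and blanks on the raw intensity scale.
    """
    for name, v in (("slope", slope), ("intercept", intercept), ("noise_sd", noise_sd)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if np.isscalar(levels):
        if int(levels) < 3:
            raise ValueError("need >= 3 viscosity levels")
        eta = np.logspace(0, 3, int(levels))  # 1 .. 1000 cP, glycerol-series-like
    else:
        eta = np.asarray(levels, dtype=float)
        if eta.size < 3:
            raise ValueError("need >= 3 viscosity levels")
    if n_blanks < 2:
        raise ValueError("need >= 2 blank replicates")
    rng = np.random.default_rng(seed)
    log_i = intercept + slope * np.log10(eta)
    if noise_sd > 0:
        log_i = log_i + rng.normal(0.0, noise_sd, size=eta.size)
    series = pd.DataFrame({"viscosity_cP": eta, "intensity": 10.0**log_i})
    blank_log = intercept + slope * math.log10(eta.min())
    blanks = 10.0 ** (
        blank_log + (rng.normal(0.0, noise_sd, size=n_blanks) if noise_sd > 0 else np.zeros(n_blanks))
    )
    return series, blanks
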