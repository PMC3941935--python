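"""Synthetic leaflet-cross-section scenes with ground truth.

Each scene renders two bright elongated major-bundle (MjVB) blobs flanking a
row of small minor-bundle (MnVB) blobs scattered about the line joining the
MjVB centres.  Signal goes into the blue channel of an 8-bit RGB canvas, the
analysis channel of the real micrographs.  The generator returns both the
image and the exact annotation (rectangles, oval centres, class label), so
every downstream stage can be tested against known truth.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning, so cohorts are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import line, polygon

from .imageprep import preprocess_image
from .vbfeatures import (
    FEATURE_NAMES,
    OvalAnnotation,
    RectAnnotation,
    SceneAnnotation,
    assemble_feature_vector,
    mjvb_features,
    mnvb_features,
)

__all__ = ["ClassSpec", "SyntheticScene", "DEFAULT_CLASS_SPECS", "generate_scene",
           "generate_cohort", "extract_mjvb_contours", "cohort_feature_table"]


@dataclass(frozen=True)
class ClassSpec:
    """Rendering statistics of one synthetic cultivar."""

    name: str
    mnvb_count_range: tuple[int, int] = (6, 9)  # inclusive
    mnvb_scatter_sd: float = 6.0       # px, perpendicular to the baseline
    mnvb_spacing_jitter: float = 6.0   # px, along the baseline
    mnvb_radius: float = 5.0           # px, rendered blob radius
    baseline_length: float = 700.0     # px between MjVB centres
    mjvb_semi_axes: tuple[float, float] = (45.0, 30.0)
    mjvb_axis_jitter: float = 0.03     # relative sd applied to each semi-axis
    boundary_noise_sd: float = 1.0     # px radial roughness of the MjVB outline
    hair_spike_count: float = 0.0      # expected spikes per MjVB contour
    hair_spike_height: float = 8.0     # px
    foreground_intensity: int = 220
    background_noise_sd: float = 5.0

    def __post_init__(self):
        lo, hi = self.mnvb_count_range
        if lo > hi or lo < 0:
            raise ValueError("mnvb_count_range must be a non-empty range of non-negative counts")
        if min(self.mjvb_semi_axes) <= 0:
            raise ValueError("MjVB semi-axes must be positive")
        for v in (self.mnvb_scatter_sd, self.mnvb_spacing_jitter, self.boundary_noise_sd,
                  self.background_noise_sd, self.mjvb_axis_jitter):
            if v < 0:
                raise ValueError("scatter/jitter/noise parameters must be non-negative")


#: Five well-separated default classes.  Counts, scatter, baseline length and
#: MjVB elongation all differ; the first class exceeds 13 bundles to exercise
#: the heuristic tour branch.
DEFAULT_CLASS_SPECS = (
    ClassSpec(name="class_a", mnvb_count_range=(14, 16), mnvb_scatter_sd=4.0,
              baseline_length=820.0, mjvb_semi_axes=(40.0, 36.0), boundary_noise_sd=0.8),
    ClassSpec(name="class_b", mnvb_count_range=(10, 12), mnvb_scatter_sd=14.0,
              baseline_length=740.0, mjvb_semi_axes=(48.0, 28.0), boundary_noise_sd=1.2),
    ClassSpec(name="class_c", mnvb_count_range=(7, 9), mnvb_scatter_sd=26.0,
              baseline_length=660.0, mjvb_semi_axes=(55.0, 20.0), boundary_noise_sd=1.6,
              hair_spike_count=2.0),
    ClassSpec(name="class_d", mnvb_count_range=(5, 6), mnvb_scatter_sd=9.0,
              baseline_length=580.0, mjvb_semi_axes=(38.0, 33.0), boundary_noise_sd=2.6),
    ClassSpec(name="class_e", mnvb_count_range=(3, 4), mnvb_scatter_sd=18.0,
              baseline_length=500.0, mjvb_semi_axes=(58.0, 16.0), boundary_noise_sd=1.0,
              hair_spike_count=4.0),
)


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    truth: SceneAnnotation
    class_name: str
    seed: int = 0


def _smooth_radial_noise(theta: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited radial perturbation (low-order Fourier series), sd in px."""
    if sd == 0:
        return np.zeros_like(theta)
    out = np.zeros_like(theta)
    for k in range(2, 7):
        out += rng.normal() * np.cos(k * theta) + rng.normal() * np.sin(k * theta)
    s = out.std()
    return out * (sd / s) if s > 0 else out


def _render_blob(blue: np.ndarray, centre, semi_axes, noise_sd, rng,
                 intensity: int, spikes: int = 0, spike_height: float = 8.0) -> None:
    """Fill a noisy ellipse (plus optional hair spikes) into the blue channel."""
    cx, cy = centre
    a, b = semi_axes
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r_x = a * np.cos(theta)
    r_y = b * np.sin(theta)
    base_r = np.hypot(r_x, r_y)
    bump = _smooth_radial_noise(theta, noise_sd, rng)
    scale = 1 + bump / np.maximum(base_r, 1e-9)
    xs = cx + r_x * scale
    ys = cy + r_y * scale
    rr, cc = polygon(ys, xs, shape=blue.shape)
    blue[rr, cc] = intensity
    for _ in range(spikes):
        t = rng.uniform(0, 2 * np.pi)
        bx, by = cx + a * np.cos(t), cy + b * np.sin(t)
        # outward normal of the ellipse
        nx, ny = np.cos(t) / a, np.sin(t) / b
        norm = np.hypot(nx, ny)
        ex, ey = bx + spike_height * nx / norm, by + spike_height * ny / norm
        rr, cc = line(int(round(by)), int(round(bx)), int(round(ey)), int(round(ex)))
        keep = (rr >= 0) & (rr < blue.shape[0]) & (cc >= 0) & (cc < blue.shape[1])
        blue[rr[keep], cc[keep]] = intensity


def generate_scene(spec: ClassSpec, seed: int, image_size: tuple[int, int] = (512, 1024)) -> SyntheticScene:
    """Render one scene from a class spec, fully determined by the seed."""
    H, W = image_size
    rng = np.random.default_rng(seed)

    a0, b0 = spec.mjvb_semi_axes
    jit = spec.mjvb_axis_jitter
    axes_left = (a0 * (1 + rng.normal(0, jit)), b0 * (1 + rng.normal(0, jit)))
    axes_right = (a0 * (1 + rng.normal(0, jit)), b0 * (1 + rng.normal(0, jit)))

    cy = H / 2.0
    x_left = (W - spec.baseline_length) / 2.0
    x_right = x_left + spec.baseline_length
    margin = max(axes_left + axes_right) + spec.hair_spike_height + 4
    if x_left - margin < 0 or x_right + margin > W or cy - margin < 0 or cy + margin > H:
        raise ValueError(
            f"class {spec.name!r}: geometry exceeds the {W}x{H} canvas; use a larger image_size"
        )

    n = int(rng.integers(spec.mnvb_count_range[0], spec.mnvb_count_range[1] + 1))
    gap = 2.5 * max(axes_left[0], axes_right[0])
    if n > 0:
        slots = np.linspace(x_left + gap, x_right - gap, n)
        xs = slots + rng.normal(0, spec.mnvb_spacing_jitter, n)
        ys = cy + rng.normal(0, spec.mnvb_scatter_sd, n)
        xs = np.clip(xs, 2 * spec.mnvb_radius, W - 2 * spec.mnvb_radius)
        ys = np.clip(ys, 2 * spec.mnvb_radius, H - 2 * spec.mnvb_radius)
    else:
        xs = ys = np.empty(0)

    blue = np.zeros((H, W), dtype=float)
    spikes_l = int(rng.poisson(spec.hair_spike_count))
    spikes_r = int(rng.poisson(spec.hair_spike_count))
    _render_blob(blue, (x_left, cy), axes_left, spec.boundary_noise_sd, rng,
                 spec.foreground_intensity, spikes_l, spec.hair_spike_height)
    _render_blob(blue, (x_right, cy), axes_right, spec.boundary_noise_sd, rng,
                 spec.foreground_intensity, spikes_r, spec.hair_spike_height)
    for x, y in zip(xs, ys):
        r = spec.mnvb_radius * (1 + rng.normal(0, 0.1))
        _render_blob(blue, (x, y), (r, r), 0.3, rng, spec.foreground_intensity)

    img = np.zeros((H, W, 3), dtype=float)
    img[:, :, 2] = blue
    img[:, :, 0] = 0.15 * blue  # faint bleed-through into red/green
    img[:, :, 1] = 0.25 * blue
    img += rng.normal(0, spec.background_noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    rects = (
        RectAnnotation(centre=(x_left, cy), width=2 * axes_left[0], height=2 * axes_left[1]),
        RectAnnotation(centre=(x_right, cy), width=2 * axes_right[0], height=2 * axes_right[1]),
    )
    ovals = [
        OvalAnnotation(centre=(float(x), float(y)), semi_axes=(spec.mnvb_radius, spec.mnvb_radius))
        for x, y in zip(xs, ys)
    ]
    truth = SceneAnnotation(mjvb_rects=rects, mnvb_ovals=ovals, label=spec.name)
    return SyntheticScene(image=img, truth=truth, class_name=spec.name, seed=seed)


def extract_mjvb_contours(scene: SyntheticScene, margin_factor: float = 1.6,
                          n_segments: int = 18, n_samples: int = 512) -> list[np.ndarray]:
    """Run the preprocessing chain on a crop around each annotated MjVB.

    Cropping isolates each major bundle so the largest-component rule picks
    it; contour coordinates are mapped back to the full-image frame.
    """
    H, W = scene.image.shape[:2]
    contours = []
    for rect in scene.truth.mjvb_rects:
        cx, cy = rect.centre
        half = margin_factor * max(rect.width, rect.height) / 2.0
        r0, r1 = max(0, int(cy - half)), min(H, int(cy + half) + 1)
        c0, c1 = max(0, int(cx - half)), min(W, int(cx + half) + 1)
        crop = scene.image[r0:r1, c0:c1]
        contour = preprocess_image(crop, n_segments=n_segments, n_samples=n_samples)
        contour = contour + np.array([c0, r0], dtype=float)
        contours.append(contour)
    return contours


def generate_cohort(
    specs=DEFAULT_CLASS_SPECS,
    counts=(14, 22, 17, 20, 12),
    seed: int = 0,
    image_size: tuple[int, int] = (512, 1024),
    tsp_budget: float = 5.0,
) -> tuple[list[SyntheticScene], pd.DataFrame]:
    """Generate ``counts[i]`` scenes of ``specs[i]`` and extract features.

    Feature extraction runs the real pipeline: MjVB contours come from image
    preprocessing on the rendered scenes, MnVB features from the ground-truth
    annotation (the semi-automatic route of the original workflow).
    """
    specs = list(specs)
    counts = list(counts)
    if len(specs) != len(counts):
        raise ValueError("one count per class spec required")
    if any(c < 1 for c in counts):
        raise ValueError("counts must be >= 1 per class")
    children = np.random.SeedSequence(seed).spawn(sum(counts))
    scene_seeds = [int(c.generate_state(1)[0]) for c in children]

    scenes: list[SyntheticScene] = []
    rows = []
    k = 0
    for spec, count in zip(specs, counts):
        for j in range(count):
            scene = generate_scene(spec, scene_seeds[k], image_size=image_size)
            scene.truth.scene_id = f"{spec.name}_{j:03d}"
            scenes.append(scene)
            contours = extract_mjvb_contours(scene)
            mn = mnvb_features(scene.truth, time_budget=tsp_budget)
            mj = [mjvb_features(c) for c in contours]
            fv = assemble_feature_vector(mn, mj, label=spec.name)
            rows.append({"scene_id": scene.truth.scene_id,
                         **{name: getattr(fv, name) for name in FEATURE_NAMES},
                         "label": spec.name})
            k += 1
    return scenes, pd.DataFrame(rows)


def cohort_feature_table(seed: int = 0, counts=(14, 22, 17, 20, 12)) -> pd.DataFrame:
    """Convenience: default cohort, features only."""
    _, table = generate_cohort(counts=counts, seed=seed)
    return table
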