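"""Vascular-bundle descriptors.

Four minor-bundle (MnVB) distribution features measured against the baseline
joining the two major-bundle (MjVB) rectangle centres, and five MjVB shape
features measured on a closed contour:

========  =================================================================
number    count of MnVB ovals between the two MjVBs
ratio     sum of |perpendicular distance(centre, baseline line)| / baseline
ratio2    sum of distance(centre, baseline midpoint) / baseline
salesman  shortest closed tour through all MnVB centres / baseline
form      4*pi*area / perimeter**2
aspect    length / width (minimum-area oriented bounding rectangle)
rect      length * width / perimeter          (carries pixel units)
ecc       sqrt(1 - (b/a)**2) of the least-squares fitted ellipse
residual  RMS approximate point-to-ellipse distance of that fit (px)
========  =================================================================
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "FEATURE_NAMES",
    "RectAnnotation",
    "OvalAnnotation",
    "Baseline",
    "SceneAnnotation",
    "MnVBFeatures",
    "EllipseFit",
    "ContourGeometry",
    "MjVBFeatures",
    "FeatureVector",
    "baseline_from_rects",
    "mnvb_ratio",
    "mnvb_ratio2",
    "shortest_tour_length",
    "brute_force_tour_length",
    "salesman_ratio",
    "mnvb_features",
    "contour_geometry",
    "fit_ellipse",
    "eccentricity",
    "mjvb_features",
    "assemble_feature_vector",
    "scene_features",
]

#: Canonical feature order used everywhere (CSV columns, classifier input).
FEATURE_NAMES = (
    "number",
    "ratio",
    "ratio2",
    "salesman_ratio",
    "form_factor",
    "aspect_ratio",
    "rectangularity",
    "eccentricity",
    "residual",
)

#: Largest instance solved exactly by dynamic programming.
EXACT_TSP_MAX = 13


# ---------------------------------------------------------------------------
# annotation types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RectAnnotation:
    """Axis-aligned rectangle fitted to a MjVB."""

    centre: tuple[float, float]
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("rectangle width and height must be positive")


@dataclass(frozen=True)
class OvalAnnotation:
    """Oval fitted to a MnVB; only the centre enters the features."""

    centre: tuple[float, float]
    semi_axes: tuple[float, float] = (1.0, 1.0)
    angle: float = 0.0

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("oval semi-axes must be positive")


@dataclass(frozen=True)
class Baseline:
    """Segment joining the two MjVB rectangle centres."""

    p1: tuple[float, float]
    p2: tuple[float, float]

    @property
    def length(self) -> float:
        return math.dist(self.p1, self.p2)

    @property
    def midpoint(self) -> tuple[float, float]:
        return ((self.p1[0] + self.p2[0]) / 2, (self.p1[1] + self.p2[1]) / 2)


@dataclass
class SceneAnnotation:
    """One annotated cross-section scene."""

    mjvb_rects: tuple[RectAnnotation, RectAnnotation]
    mnvb_ovals: list[OvalAnnotation] = field(default_factory=list)
    mjvb_contours: list[np.ndarray] = field(default_factory=list)
    label: str | None = None
    scene_id: str = ""

    def __post_init__(self):
        if len(self.mjvb_rects) != 2:
            raise ValueError(
                f"scene {self.scene_id or '<unnamed>'}: exactly two MjVB rectangles "
                f"required, got {len(self.mjvb_rects)}"
            )
        if len(self.mjvb_contours) > 2:
            raise ValueError("at most two MjVB contours per scene")
        b = baseline_from_rects(*self.mjvb_rects)
        axis = np.subtract(b.p2, b.p1) / b.length
        for oval in self.mnvb_ovals:
            t = float(np.dot(np.subtract(oval.centre, b.p1), axis))
            if not 0.0 <= t <= b.length:
                warnings.warn(
                    f"scene {self.scene_id or '<unnamed>'}: MnVB centre {oval.centre} "
                    "projects outside the segment between the MjVB centres",
                    stacklevel=2,
                )


# ---------------------------------------------------------------------------
# feature containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MnVBFeatures:
    number: int
    ratio: float
    ratio2: float
    salesman_ratio: float


@dataclass(frozen=True)
class EllipseFit:
    centre: tuple[float, float]
    major_a: float
    minor_b: float
    angle: float
    residual: float


@dataclass(frozen=True)
class ContourGeometry:
    area: float
    perimeter: float
    length: float
    width: float


@dataclass(frozen=True)
class MjVBFeatures:
    form_factor: float
    aspect_ratio: float
    rectangularity: float
    eccentricity: float
    residual: float


@dataclass(frozen=True)
class FeatureVector:
    number: float
    ratio: float
    ratio2: float
    salesman_ratio: float
    form_factor: float
    aspect_ratio: float
    rectangularity: float
    eccentricity: float
    residual: float
    label: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# MnVB distribution features
# ---------------------------------------------------------------------------

def baseline_from_rects(rect_a: RectAnnotation, rect_b: RectAnnotation) -> Baseline:
    """Baseline between the two rectangle centres."""
    b = Baseline(tuple(map(float, rect_a.centre)), tuple(map(float, rect_b.centre)))
    if b.length == 0:
        raise ValueError("degenerate baseline: rectangle centres coincide")
    return b


def _as_points(centres) -> np.ndarray:
    pts = np.asarray(centres, dtype=float).reshape(-1, 2)
    return pts


def mnvb_ratio(centres, baseline: Baseline) -> float:
    """Sum of unsigned perpendicular distances to the (infinite) baseline
    over the baseline length."""
    pts = _as_points(centres)
    if len(pts) == 0:
        return 0.0
    p1 = np.asarray(baseline.p1)
    d = np.asarray(baseline.p2) - p1
    # unsigned distance to the infinite line: |cross(d, p - p1)| / |d|
    cross = np.abs(d[0] * (pts[:, 1] - p1[1]) - d[1] * (pts[:, 0] - p1[0]))
    return float(cross.sum() / baseline.length**2)


def mnvb_ratio2(centres, baseline: Baseline) -> float:
    """Sum of distances from the centres to the baseline midpoint over the
    baseline length."""
    pts = _as_points(centres)
    if len(pts) == 0:
        return 0.0
    mid = np.asarray(baseline.midpoint)
    return float(np.linalg.norm(pts - mid, axis=1).sum() / baseline.length)


# ---------------------------------------------------------------------------
# travelling-salesman statistic
# ---------------------------------------------------------------------------

def _held_karp(dist: np.ndarray) -> tuple[float, list[int]]:
    """Exact shortest closed tour by Held-Karp dynamic programming.

    Point 0 is fixed as the start; states are (visited-subset of 1..n-1,
    last point).  O(n^2 * 2^n) time, fine up to EXACT_TSP_MAX points.
    """
    n = len(dist)
    m = n - 1  # points 1..n-1
    full = 1 << m
    INF = np.inf
    dp = np.full((full, m), INF)
    parent = np.full((full, m), -1, dtype=np.int32)
    for j in range(m):
        dp[1 << j, j] = dist[0, j + 1]
    for mask in range(1, full):
        row = dp[mask]
        if not np.isfinite(row).any():
            continue
        # extend every finite (mask, last) state to each unvisited j
        lasts = np.nonzero(np.isfinite(row))[0]
        for j in range(m):
            if mask & (1 << j):
                continue
            cand = row[lasts] + dist[lasts + 1, j + 1]
            k = int(np.argmin(cand))
            nmask = mask | (1 << j)
            if cand[k] < dp[nmask, j]:
                dp[nmask, j] = cand[k]
                parent[nmask, j] = lasts[k]
    final = dp[full - 1] + dist[1:, 0]
    j = int(np.argmin(final))
    best = float(final[j])
    # reconstruct
    tour = [0]
    mask, cur = full - 1, j
    rev = []
    while cur != -1:
        rev.append(cur + 1)
        nxt = parent[mask, cur]
        mask ^= 1 << cur
        cur = int(nxt)
    tour += rev[::-1]
    return best, tour


def _tour_length(dist: np.ndarray, tour: list[int]) -> float:
    idx = np.asarray(tour)
    return float(dist[idx, np.roll(idx, -1)].sum())


def _nearest_neighbour(dist: np.ndarray) -> list[int]:
    n = len(dist)
    unvisited = set(range(1, n))
    tour = [0]
    while unvisited:
        last = tour[-1]
        nxt = min(unvisited, key=lambda j: dist[last, j])
        tour.append(nxt)
        unvisited.remove(nxt)
    return tour


def _two_opt(dist: np.ndarray, tour: list[int], deadline: float) -> list[int]:
    n = len(tour)
    improved = True
    while improved and time.monotonic() < deadline:
        improved = False
        for i in range(n - 1):
            for k in range(i + 2, n if i > 0 else n - 1):
                a, b = tour[i], tour[i + 1]
                c, d = tour[k], tour[(k + 1) % n]
                delta = dist[a, c] + dist[b, d] - dist[a, b] - dist[c, d]
                if delta < -1e-12:
                    tour[i + 1 : k + 1] = tour[i + 1 : k + 1][::-1]
                    improved = True
            if time.monotonic() >= deadline:
                break
    return tour


def shortest_tour_length(points, time_budget: float = 300.0) -> tuple[float, list[int]]:
    """Length (and visiting order) of the shortest closed tour through all
    points.

    Exact Held-Karp dynamic programming for up to EXACT_TSP_MAX points;
    beyond that, nearest-neighbour construction improved by 2-opt until the
    time budget runs out, mirroring the original truncated search.
    Degenerate cases: fewer than 2 points give length 0; exactly 2 give
    twice their distance.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        return 0.0, list(range(n))
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    if n == 2:
        return float(2 * dist[0, 1]), [0, 1]
    if n <= EXACT_TSP_MAX:
        return _held_karp(dist)
    deadline = time.monotonic() + time_budget
    tour = _two_opt(dist, _nearest_neighbour(dist), deadline)
    return _tour_length(dist, tour), tour


def brute_force_tour_length(points) -> float:
    """Exhaustive-permutation optimum (independent oracle; n <= 10)."""
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        return 0.0
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    if n == 2:
        return float(2 * dist[0, 1])
    d = dist.tolist()  # plain lists: the tight permutation loop stays fast
    best = math.inf
    for perm in permutations(range(1, n)):
        total = d[0][perm[0]] + d[perm[-1]][0]
        prev = perm[0]
        for j in perm[1:]:
            total += d[prev][j]
            prev = j
        if total < best:
            best = total
    return best


def salesman_ratio(centres, baseline: Baseline, time_budget: float = 300.0) -> float:
    length, _ = shortest_tour_length(centres, time_budget)
    return length / baseline.length


def mnvb_features(scene: SceneAnnotation, time_budget: float = 300.0) -> MnVBFeatures:
    """The four MnVB distribution features of a scene."""
    b = baseline_from_rects(*scene.mjvb_rects)
    centres = [o.centre for o in scene.mnvb_ovals]
    return MnVBFeatures(
        number=len(centres),
        ratio=mnvb_ratio(centres, b),
        ratio2=mnvb_ratio2(centres, b),
        salesman_ratio=salesman_ratio(centres, b, time_budget),
    )


# ---------------------------------------------------------------------------
# MjVB shape features
# ---------------------------------------------------------------------------

def contour_geometry(contour: np.ndarray) -> ContourGeometry:
    """Area (shoelace), perimeter, and oriented-bounding-box length/width."""
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("contour must have at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area == 0:
        raise ValueError("contour encloses zero area")
    perimeter = float(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1).sum())
    rect = Polygon(pts).minimum_rotated_rectangle
    rc = np.asarray(rect.exterior.coords)
    side1 = float(np.linalg.norm(rc[1] - rc[0]))
    side2 = float(np.linalg.norm(rc[2] - rc[1]))
    length, width = max(side1, side2), min(side1, side2)
    return ContourGeometry(area=float(area), perimeter=perimeter, length=length, width=width)


def fit_ellipse(contour: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit (ellipse-constrained conic).

    Solves the constrained conic problem of Halir & Flusser, which always
    yields an ellipse when one exists.  The residual is the RMS Sampson
    distance (algebraic distance rescaled by the conic gradient norm), an
    approximation of orthogonal point-to-ellipse distance in pixels.
    """
    pts = np.unique(np.asarray(contour, dtype=float).reshape(-1, 2), axis=0)
    if len(pts) < 6:
        raise ValueError("ellipse fit requires at least 6 distinct points")
    # centre/scale for conditioning
    mean = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale == 0:
        raise ValueError("degenerate input: all points coincide")
    x, y = ((pts - mean) / scale).T

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError:
        raise ValueError("degenerate (collinear) input: cannot fit an ellipse") from None
    M = S1 + S2 @ T
    C_inv = np.array([[0, 0, 0.5], [0, -1.0, 0], [0.5, 0, 0]])
    eigval, eigvec = np.linalg.eig(C_inv @ M)
    # ellipse condition 4ac - b^2 > 0
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.where(np.isfinite(eigval) & (cond > 0))[0]
    if len(ok) == 0:
        raise ValueError("degenerate input: no ellipse solution")
    a1 = np.real(eigvec[:, ok[0]])
    coeffs_scaled = np.concatenate([a1, T @ a1])  # A,B,C,D,E,F in scaled frame

    # un-scale the conic: x_s = (x - mx)/s etc.
    A, B, C, D, E, F = coeffs_scaled
    s, (mx, my) = scale, mean
    A2, B2, C2 = A / s**2, B / s**2, C / s**2
    D2_ = -2 * A * mx / s**2 - B * my / s**2 + D / s
    E2_ = -2 * C * my / s**2 - B * mx / s**2 + E / s
    F2_ = (A * mx**2 + B * mx * my + C * my**2) / s**2 - (D * mx + E * my) / s + F
    coeffs = np.array([A2, B2, C2, D2_, E2_, F2_])

    centre, major, minor, angle = _conic_to_geometric(coeffs)
    residual = _sampson_rms(coeffs, pts)
    return EllipseFit(centre=centre, major_a=major, minor_b=minor, angle=angle, residual=residual)


def _conic_to_geometric(coeffs: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    A, B, C, D, E, F = coeffs
    den = 4 * A * C - B * B
    if den <= 0:
        raise ValueError("conic is not an ellipse")
    cx = (B * E - 2 * C * D) / den
    cy = (B * D - 2 * A * E) / den
    # value of the quadratic form at the centre
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    M = np.array([[A, B / 2], [B / 2, C]])
    eigval, eigvec = np.linalg.eigh(M)
    axes = np.sqrt(-Fc / eigval)  # semi-axes; eigval and -Fc share sign for an ellipse
    order = np.argsort(axes)[::-1]
    major, minor = float(axes[order[0]]), float(axes[order[1]])
    v = eigvec[:, order[0]]
    angle = float(math.atan2(v[1], v[0]))
    return (float(cx), float(cy)), major, minor, angle


def _sampson_rms(coeffs: np.ndarray, pts: np.ndarray) -> float:
    A, B, C, D, E, F = coeffs
    x, y = pts[:, 0], pts[:, 1]
    alg = A * x * x + B * x * y + C * y * y + D * x + E * y + F
    gx = 2 * A * x + B * y + D
    gy = B * x + 2 * C * y + E
    grad = np.hypot(gx, gy)
    grad = np.where(grad == 0, np.finfo(float).tiny, grad)
    return float(np.sqrt(np.mean((alg / grad) ** 2)))


def eccentricity(major_a: float, minor_b: float) -> float:
    """sqrt(1 - (b/a)^2): 0 for a circle, 1 in the degenerate flat limit."""
    if major_a <= 0:
        raise ValueError("major axis must be positive")
    if minor_b < 0 or minor_b > major_a:
        raise ValueError("minor axis must satisfy 0 <= b <= a")
    return math.sqrt(1.0 - (minor_b / major_a) ** 2)


def mjvb_features(contour: np.ndarray) -> MjVBFeatures:
    """The five MjVB shape features of one contour."""
    g = contour_geometry(contour)
    fit = fit_ellipse(contour)
    return MjVBFeatures(
        form_factor=4 * math.pi * g.area / g.perimeter**2,
        aspect_ratio=g.length / g.width,
        rectangularity=g.length * g.width / g.perimeter,
        eccentricity=eccentricity(fit.major_a, fit.minor_b),
        residual=fit.residual,
    )


def assemble_feature_vector(
    mn: MnVBFeatures,
    mj_list,
    label: str | None = None,
    combine: str = "mean",
) -> FeatureVector:
    """Combine MnVB features and 1-2 MjVB feature sets into the 9-vector.

    With two MjVB feature sets the shape features are averaged by default
    (``combine="first"`` keeps only the first).
    """
    mj_list = list(mj_list)
    if not mj_list:
        raise ValueError("at least one MjVB feature set is required")
    if combine == "first":
        mj_list = mj_list[:1]
    elif combine != "mean":
        raise ValueError(f"unknown combine mode {combine!r}")
    shape = {
        name: float(np.mean([getattr(mj, name) for mj in mj_list]))
        for name in ("form_factor", "aspect_ratio", "rectangularity", "eccentricity", "residual")
    }
    return FeatureVector(
        number=float(mn.number),
        ratio=mn.ratio,
        ratio2=mn.ratio2,
        salesman_ratio=mn.salesman_ratio,
        label=label,
        **shape,
    )


def scene_features(scene: SceneAnnotation, time_budget: float = 300.0, combine: str = "mean") -> FeatureVector:
    """End-to-end feature vector for an annotated scene with contours."""
    if not scene.mjvb_contours:
        raise ValueError(f"scene {scene.scene_id or '<unnamed>'} has no MjVB contours")
    mn = mnvb_features(scene, time_budget)
    mj = [mjvb_features(c) for c in scene.mjvb_contours]
    return assemble_feature_vector(mn, mj, label=scene.label, combine=combine)
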