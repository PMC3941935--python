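"""Image preprocessing: from an RGB fluorescence micrograph to a smoothed
closed contour of the largest bright object.

Conventions
-----------
* Images are ``numpy`` arrays, ``(H, W)`` for single-channel or ``(H, W, 3)``
  for RGB, dtype ``uint8`` (values 0..255).
* Binary masks are boolean ``(H, W)`` arrays.
* A contour is an ``(N, 2)`` float array of ``(x, y)`` points in pixel
  units, origin at the top-left corner, x rightward, y downward.  Contours
  are cyclic: the last point connects back to the first (no duplicated
  endpoint).
* Pixel ``(row=i, col=j)`` occupies the unit square ``[j, j+1] x [i, i+1]``;
  traced contours live on this square grid, so the shoelace area of a traced
  contour equals the pixel count of the component.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from shapely import union_all
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.geometry.polygon import orient
from skimage.filters import threshold_otsu

__all__ = [
    "CHANNELS",
    "read_image",
    "extract_channel",
    "adjust_brightness_contrast",
    "binarize",
    "remove_small_particles",
    "trace_contour",
    "smooth_contour_bspline",
    "preprocess_image",
]

CHANNELS = {"red": 0, "green": 1, "blue": 2}

#: 8-connected neighbourhood used for all component labelling.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def read_image(path) -> np.ndarray:
    """Read an 8-bit PNG or TIFF image as a uint8 array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    if img.ndim not in (2, 3) or (img.ndim == 3 and img.shape[2] != 3):
        raise ValueError(f"unsupported image shape {img.shape}; expected grayscale or RGB")
    if img.dtype != np.uint8:
        raise ValueError(f"unsupported dtype {img.dtype}; expected 8-bit")
    return img


def extract_channel(img: np.ndarray, channel: str = "blue") -> np.ndarray:
    """Return one colour channel of an RGB image, values unchanged."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            "channel extraction requires a 3-channel RGB image; "
            f"got shape {img.shape}"
        )
    try:
        idx = CHANNELS[channel]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}; expected one of {sorted(CHANNELS)}") from None
    return img[:, :, idx].copy()


def adjust_brightness_contrast(img: np.ndarray, gain: float = 1.0, offset: float = 0.0) -> np.ndarray:
    """Linear intensity rescale ``gain*x + offset``, clipped to [0, 255].

    Identity by default; stands in for the manual brightness/contrast step.
    """
    out = np.asarray(img, dtype=float) * gain + offset
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def binarize(img: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Threshold a single-channel image to a boolean mask.

    A pixel is foreground iff its intensity is >= the threshold.  With
    ``method="otsu"`` the level is chosen by Otsu's criterion (maximum
    between-class variance); with ``method="fixed"`` the caller supplies it.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"binarize expects a single-channel image, got shape {img.shape}")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires an explicit threshold")
        return img >= threshold
    if method == "otsu":
        if img.min() == img.max():
            return np.ones_like(img, dtype=bool)  # flat image: everything >= the single level
        t = threshold_otsu(img)
        # skimage's convention is foreground = img > t; expressed with the
        # >=-convention the selected level is the smallest value above t.
        return img > t
    raise ValueError(f"unknown binarization method {method!r}")


def remove_small_particles(mask: np.ndarray, min_area: int = 64) -> np.ndarray:
    """Delete 8-connected foreground components with area < ``min_area``."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labels]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    if n == 0:
        raise ValueError("mask contains no foreground object")
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Outer boundary polygon of the largest 8-connected component.

    The polygon is traced on the pixel-square grid (pixel (i, j) is the unit
    square [j, j+1] x [i, i+1]) and oriented so its shoelace signed area is
    positive.  Components joined only through a corner contribute their
    largest edge-connected part.
    """
    comp = _largest_component(np.asarray(mask, dtype=bool))
    rows, cols = np.nonzero(comp)
    boxes = [box(float(c), float(r), float(c) + 1.0, float(r) + 1.0) for r, c in zip(rows, cols)]
    merged = union_all(boxes)
    if isinstance(merged, MultiPolygon):
        merged = max(merged.geoms, key=lambda g: g.area)
    merged = merged.simplify(0)  # drop collinear vertices along straight runs
    poly: Polygon = orient(merged, sign=1.0)
    coords = np.asarray(poly.exterior.coords)[:-1]  # drop duplicated closing point
    return coords.astype(float)


def _periodic_bspline_basis(u: np.ndarray, n_ctrl: int) -> np.ndarray:
    """Design matrix of the uniform periodic cubic B-spline at parameters u in [0,1)."""
    s = np.asarray(u, dtype=float) * n_ctrl
    i = np.floor(s).astype(int) % n_ctrl
    f = s - np.floor(s)
    blend = (
        (1 - f) ** 3 / 6,
        (3 * f**3 - 6 * f**2 + 4) / 6,
        (-3 * f**3 + 3 * f**2 + 3 * f + 1) / 6,
        f**3 / 6,
    )
    B = np.zeros((len(s), n_ctrl))
    rows = np.arange(len(s))
    for k, bk in enumerate(blend):
        B[rows, (i + k - 1) % n_ctrl] += bk
    return B


def smooth_contour_bspline(
    contour: np.ndarray,
    n_segments: int = 18,
    n_samples: int = 512,
    robust: bool = True,
) -> np.ndarray:
    """Least-squares fit of a closed contour with a periodic cubic B-spline.

    The spline has ``n_segments`` control points on a uniform periodic knot
    vector; input points are parameterized by normalized chord length.  One
    robust refit pass discards gross outliers (hair-like spikes) before the
    final fit, unless that would drop more than a quarter of the points.

    Returns ``n_samples`` points sampled uniformly in parameter.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (N, 2) array")
    if len(pts) < n_segments:
        raise ValueError(
            f"contour has {len(pts)} points, fewer than the {n_segments} control points"
        )
    if n_samples < 3 * n_segments:
        raise ValueError("n_samples must be at least 3 * n_segments")

    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        raise ValueError("contour has zero length")
    u = np.concatenate([[0.0], np.cumsum(seg)[:-1]]) / total

    A = _periodic_bspline_basis(u, n_segments)
    ctrl, *_ = np.linalg.lstsq(A, pts, rcond=None)
    if robust:
        resid = np.linalg.norm(A @ ctrl - pts, axis=1)
        med = np.median(resid)
        mad = np.median(np.abs(resid - med))
        keep = resid <= med + 5 * 1.4826 * mad + 1e-12
        if keep.sum() >= max(n_segments, int(0.75 * len(pts))):
            ctrl, *_ = np.linalg.lstsq(A[keep], pts[keep], rcond=None)

    u_out = np.linspace(0.0, 1.0, n_samples, endpoint=False)
    return _periodic_bspline_basis(u_out, n_segments) @ ctrl


def preprocess_image(
    img: np.ndarray,
    channel: str = "blue",
    method: str = "otsu",
    threshold: float | None = None,
    gain: float = 1.0,
    offset: float = 0.0,
    min_area: int = 64,
    n_segments: int = 18,
    n_samples: int = 512,
) -> np.ndarray:
    """Full preprocessing chain: channel -> rescale -> threshold -> particle
    removal -> contour trace -> B-spline smoothing.  Returns the smoothed
    contour of the largest object."""
    gray = extract_channel(img, channel) if np.asarray(img).ndim == 3 else np.asarray(img)
    gray = adjust_brightness_contrast(gray, gain=gain, offset=offset)
    mask = binarize(gray, method=method, threshold=threshold)
    mask = remove_small_particles(mask, min_area=min_area)
    raw = trace_contour(mask)
    return smooth_contour_bspline(raw, n_segments=n_segments, n_samples=n_samples)
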