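"""Colony morphology statistics on binary masks.

Three image-derived statistics quantify how filamentous a colony is:

``I_R`` (radius ratio)
    ``r_csr / r_max``, where ``r_max`` is the maximum centroid-to-occupied
    pixel distance and ``r_csr`` is the radius at which the local occupied
    pixel density drops below the complete-spatial-randomness reference
    density ``rho_csr = N / (pi r_max^2)``.  ``I_R`` measures the fraction
    of the colony radius taken up by the compact Eden-like core.
``I_F`` (filamentous area ratio)
    fraction of occupied pixels in the annulus ``[r_csr, r_max]``; measures
    how much colony material sits in the filamentous fringe.
``I_B`` (sub-branch count)
    number of branch segments of the skeletonised filament region,
    counted in the single quadrant ``theta in [pi/2, pi]`` (anticlockwise
    from +x, y axis up) to bound the cost of skeletonisation.

All statistics are ratios or counts and are therefore robust to the
pixel resolution of the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "BinaryImage",
    "SummaryStats",
    "binarize",
    "centroid_and_radii",
    "csr_radius",
    "radius_ratio",
    "filament_area_ratio",
    "sub_branch_count",
    "summarise",
    "ColonyMorphometry",
]

#: Minimum skeleton-segment length, in pixels, counted as a branch.
MIN_BRANCH_PX = 3

#: Minimum radial extent beyond r_csr, in pixels, for a segment to count
#: as a filament branch.  A perfectly compact colony still leaves a
#: sub-pixel sliver of occupied pixels between r_csr and r_max; skeleton
#: segments that hug the core boundary this closely are discretisation
#: artifacts, not filaments.
MIN_RADIAL_EXTENT_PX = 2.0


@dataclass
class BinaryImage:
    """A binary colony mask plus its physical pixel size (length per px)."""

    pixels: np.ndarray
    px_size: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask values must be strictly binary")
            arr = arr.astype(bool)
        self.pixels = arr
        if self.px_size <= 0:
            raise ValueError("px_size must be positive")

    @property
    def n_occupied(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class SummaryStats:
    """The three morphology statistics plus the geometry they derive from."""

    I_B: int
    I_F: float
    I_R: float
    r_csr: float
    r_max: float
    centroid: tuple[float, float]
    N: int

    def as_vector(self) -> np.ndarray:
        """(I_B, I_F, I_R) in the order used by the inference distance."""
        return np.array([float(self.I_B), self.I_F, self.I_R])


def _as_image(img) -> BinaryImage:
    if isinstance(img, BinaryImage):
        return img
    return BinaryImage(np.asarray(img))


def binarize(gray_image, method: str = "otsu") -> BinaryImage:
    """Global-threshold binarisation of a grayscale colony photograph.

    Dark pixels are the colony; polarity is auto-detected from the image
    border, which is assumed to be background.  Already-binary input is
    passed through unchanged.
    """
    arr = np.asarray(gray_image)
    if arr.ndim == 3:  # collapse colour channels
        arr = arr.mean(axis=2)
    vals = np.unique(arr)
    if len(vals) < 2:
        raise ValueError("constant image cannot be binarised")
    if len(vals) == 2 and set(vals.tolist()) <= {0, 1}:
        return BinaryImage(arr.astype(bool))
    if method != "otsu":
        raise ValueError(f"unknown binarisation method {method!r}")
    thr = threshold_otsu(arr)
    border = np.concatenate([arr[0], arr[-1], arr[1:-1, 0], arr[1:-1, -1]])
    dark_is_occupied = border.mean() > thr
    occ = arr <= thr if dark_is_occupied else arr > thr
    return BinaryImage(occ)


def _occupied_coords(img: BinaryImage) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(img.pixels)
    if len(rows) == 0:
        raise ValueError("mask has no occupied pixels")
    return rows, cols


def centroid_and_radii(img) -> tuple[tuple[float, float], float, float]:
    """Centroid, maximum radius and CSR reference density of a mask.

    Returns ``(centroid, r_max, rho_csr)`` where the centroid is the mean
    occupied-pixel coordinate in (row, col) pixels, ``r_max`` the maximum
    centroid-to-occupied-pixel distance, and
    ``rho_csr = N / (pi r_max^2)`` the complete-spatial-randomness
    density.
    """
    img = _as_image(img)
    rows, cols = _occupied_coords(img)
    cr, cc = rows.mean(), cols.mean()
    dist = np.hypot(rows - cr, cols - cc)
    r_max = float(dist.max())
    if r_max == 0.0:
        raise ValueError("single-pixel mask: r_max = 0, rho_csr undefined")
    n = len(rows)
    rho_csr = n / (np.pi * r_max**2)
    return (float(cr), float(cc)), r_max, float(rho_csr)


def _radial_density(dist: np.ndarray, r_max: float):
    """Occupied-pixel density in unit-pixel-width annuli about the centroid."""
    n_bins = int(np.ceil(r_max)) + 2  # trailing empty annulus => a crossing exists
    counts = np.bincount(dist.astype(np.int64), minlength=n_bins)[:n_bins]
    edges = np.arange(n_bins + 1, dtype=float)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    density = counts / areas
    mids = edges[:-1] + 0.5
    return mids, density


def csr_radius(img) -> float:
    """The CSR radius ``r_csr``.

    The radial density profile is computed in unit-pixel-width annuli;
    ``r_csr`` is the outermost radius at which the density crosses from
    ``>= rho_csr`` to ``< rho_csr``, linearly interpolated between
    annulus midpoints and clamped to ``(0, r_max]``.
    """
    return _compute_core(_as_image(img)).r_csr


@dataclass(frozen=True)
class _Core:
    """Shared geometry of one mask, computed once per summary."""

    cr: float
    cc: float
    dist_occ: np.ndarray
    r_max: float
    rho: float
    r_csr: float
    n: int


def _compute_core(img: BinaryImage) -> _Core:
    rows, cols = _occupied_coords(img)
    cr, cc = rows.mean(), cols.mean()
    dist = np.hypot(rows - cr, cols - cc)
    r_max = float(dist.max())
    if r_max == 0.0:
        raise ValueError("single-pixel mask: r_max = 0, rho_csr undefined")
    n = len(rows)
    rho = n / (np.pi * r_max**2)
    mids, density = _radial_density(dist, r_max)
    above = density >= rho
    crossings = np.flatnonzero(above[:-1] & ~above[1:])
    if len(crossings) == 0:
        warnings.warn("radial density never reaches rho_csr; returning r_max")
        r_csr = r_max
    else:
        k = crossings[-1]
        d0, d1 = density[k], density[k + 1]
        r_csr = float(
            min(max(mids[k] + (d0 - rho) / (d0 - d1), np.finfo(float).tiny), r_max)
        )
    return _Core(float(cr), float(cc), dist, r_max, float(rho), r_csr, n)


def radius_ratio(img) -> float:
    """``I_R = r_csr / r_max``."""
    core = _compute_core(_as_image(img))
    return core.r_csr / core.r_max


def filament_area_ratio(img) -> float:
    """``I_F``: occupied-pixel fraction in the annulus ``[r_csr, r_max]``.

    Pixels exactly at ``r_csr`` count as filament (closed lower bound).
    """
    core = _compute_core(_as_image(img))
    return float((core.dist_occ >= core.r_csr).sum() / core.n)


def _segment_count(
    skel: np.ndarray,
    dist: np.ndarray | None = None,
    r_csr: float = 0.0,
    min_len: int = MIN_BRANCH_PX,
) -> int:
    """Branch segments of a skeleton: connected components after deleting
    branch-point pixels (>= 3 skeleton neighbours), keeping segments of at
    least ``min_len`` pixels that reach beyond ``r_csr`` radially (when a
    distance field is given)."""
    if not skel.any():
        return 0
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    nbrs = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    segments = skel & (nbrs < 3)
    labels, n_lab = ndimage.label(segments, structure=np.ones((3, 3), dtype=int))
    if n_lab == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    keep = sizes >= min_len
    if dist is not None:
        reach = ndimage.maximum(dist, labels, index=np.arange(1, n_lab + 1))
        keep &= np.asarray(reach) >= r_csr + MIN_RADIAL_EXTENT_PX
    return int(keep.sum())


def sub_branch_count(img) -> int:
    """``I_B``: branch segments of the skeletonised filament region in the
    quadrant ``theta in [pi/2, pi]``.

    The compact core (pixels with centroid distance below ``r_csr``) is
    removed, the remainder thinned to an 8-connected one-pixel skeleton,
    the skeleton restricted to the quadrant (angle measured anticlockwise
    from +x with the y axis pointing up, i.e. the top-left corner of the
    image), and segments between branch points counted, discarding
    segments shorter than 3 px.
    """
    img = _as_image(img)
    return _sub_branch_count(img, _compute_core(img))


def _sub_branch_count(img: BinaryImage, core: _Core) -> int:
    # Restrict the costly full-grid work to the bounding box of the
    # occupied pixels; quadrant angles use the y-up convention (dy = cr - row).
    occ_rows, occ_cols = _occupied_coords(img)
    r0, r1 = occ_rows.min(), occ_rows.max() + 1
    c0, c1 = occ_cols.min(), occ_cols.max() + 1
    sub = img.pixels[r0:r1, c0:c1]
    rows, cols = np.indices(sub.shape)
    dy = core.cr - (rows + r0)
    dx = (cols + c0) - core.cc
    dist = np.hypot(dy, dx)
    filament = sub & (dist >= core.r_csr)
    if not filament.any():
        return 0
    skel = skeletonize(filament)
    theta = np.arctan2(dy, dx)
    quadrant = (theta >= np.pi / 2) & (dist >= core.r_csr) & (dist <= core.r_max)
    return _segment_count(skel & quadrant, dist=dist, r_csr=core.r_csr)


def summarise(img) -> SummaryStats:
    """Compute all three statistics (and the radii) of one mask."""
    img = _as_image(img)
    core = _compute_core(img)
    return SummaryStats(
        I_B=_sub_branch_count(img, core),
        I_F=float((core.dist_occ >= core.r_csr).sum() / core.n),
        I_R=core.r_csr / core.r_max,
        r_csr=core.r_csr,
        r_max=core.r_max,
        centroid=(core.cr, core.cc),
        N=core.n,
    )


class ColonyMorphometry:
    """Transformer mapping colony masks to ``(I_B, I_F, I_R)`` rows.

    Stateless scikit-learn-style transformer: ``fit`` is a no-op and
    ``transform`` accepts a sequence of masks (:class:`BinaryImage`,
    boolean arrays, or grayscale arrays, which are binarised first) and
    returns an ``(n_masks, 3)`` float array with columns
    ``I_B, I_F, I_R``.
    """

    def __init__(self, binarize_method: str = "otsu"):
        self.binarize_method = binarize_method

    def get_params(self, deep: bool = True) -> dict:
        return {"binarize_method": self.binarize_method}

    def set_params(self, **params) -> "ColonyMorphometry":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "ColonyMorphometry":
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for item in X:
            img = self._coerce(item)
            rows.append(summarise(img).as_vector())
        return np.asarray(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def _coerce(self, item) -> BinaryImage:
        if isinstance(item, BinaryImage):
            return item
        arr = np.asarray(item)
        if arr.dtype == bool:
            return BinaryImage(arr)
        vals = np.unique(arr)
        if len(vals) <= 2 and np.isin(vals, (0, 1)).all():
            return BinaryImage(arr.astype(bool))
        return binarize(arr, method=self.binarize_method)
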