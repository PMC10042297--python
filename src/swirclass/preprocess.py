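"""Spectral normalization, ROI-based spectrum extraction and line profiles.

Each cube pixel is an F-element spectrum (F = 6 filters by default).  Four
row-wise normalizations are supported:

* ``none`` — raw counts/s (exposure-sensitive),
* ``max``  — division by the spectrum's maximum,
* ``auc``  — division by the element sum (L1 normalization, "area under the
  curve = 1"),
* ``snv``  — standard normal variate: subtract the row mean, divide by the
  row standard deviation.

For ``max``/``auc``/``snv`` a positive scalar applied to a spectrum cancels
out, which is what makes classification on normalized spectra invariant to
multiplicative exposure changes.  Degenerate rows (zero sum / zero max /
zero variance — legitimately produced by dark background pixels) map to the
all-zero row and are flagged rather than raising, keeping per-pixel
classification total over the image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "NORMALIZATION_MODES",
    "CLASS_TUMOR",
    "CLASS_NON_TUMOR",
    "CLASS_BACKGROUND",
    "CLASS_NAMES",
    "RoiSet",
    "LabeledSpectra",
    "LineProfile",
    "normalize_spectra",
    "extract_labeled_spectra",
    "line_profile",
    "polygons_to_mask",
]

NORMALIZATION_MODES = ("none", "max", "auc", "snv")

CLASS_TUMOR, CLASS_NON_TUMOR, CLASS_BACKGROUND = 1, 2, 3
CLASS_LABELS = (CLASS_TUMOR, CLASS_NON_TUMOR, CLASS_BACKGROUND)
CLASS_NAMES = {0: "unlabeled", 1: "tumor", 2: "non_tumor", 3: "background"}


@dataclass(frozen=True)
class RoiSet:
    """Label map with classes {1: tumor, 2: non-tumor tissue, 3: background}.

    0 marks unlabeled pixels.  Classes are mutually exclusive by
    construction (a single integer map).
    """

    masks: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 2 or not np.issubdtype(m.dtype, np.integer):
            raise ValueError("label map must be a 2-D integer array")
        if m.size and (m.min() < 0 or m.max() > 3):
            raise ValueError("labels must be in {0, 1, 2, 3}")
        object.__setattr__(self, "masks", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks.shape

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.count_nonzero(self.masks == c)) for c in CLASS_LABELS}

    def labeled(self) -> np.ndarray:
        return self.masks > 0


@dataclass
class LabeledSpectra:
    """N x F pixel-spectrum matrix with class labels and a normalization tag."""

    X: np.ndarray
    y: np.ndarray
    normalization: str
    source_cube_id: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValueError("X must be N x F with one label per row")
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.count_nonzero(self.y == c)) for c in CLASS_LABELS}


@dataclass(frozen=True)
class LineProfile:
    """Averaged intensity profile along a user-drawn line across the tumor."""

    positions_px: np.ndarray
    intensity: np.ndarray                  # C x L
    width_px: int = 3


def normalize_spectra(X, mode: str, return_flags: bool = False):
    """Row-wise spectral normalization.

    Returns the normalized matrix; with ``return_flags=True`` also returns a
    boolean array marking degenerate rows (mapped to all-zero rows).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D N x F matrix")
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization {mode!r}")
    if mode != "none" and X.shape[1] < 2:
        raise ValueError("normalization requires at least 2 spectral channels; "
                         "it is not possible with a single wavelength")

    if mode == "none":
        return (X.copy(), np.zeros(X.shape[0], bool)) if return_flags else X.copy()

    if mode == "max":
        denom = X.max(axis=1)
        degenerate = denom <= 0
        out = np.where(degenerate[:, None], 0.0,
                       X / np.where(degenerate, 1.0, denom)[:, None])
    elif mode == "auc":
        denom = X.sum(axis=1)
        degenerate = denom <= 0
        out = np.where(degenerate[:, None], 0.0,
                       X / np.where(degenerate, 1.0, denom)[:, None])
    else:  # snv
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        degenerate = sd <= 0
        out = np.where(degenerate[:, None], 0.0,
                       (X - mu[:, None]) / np.where(degenerate, 1.0, sd)[:, None])

    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("%d/%d degenerate rows mapped to zero under %s normalization",
                    n_deg, X.shape[0], mode)
    return (out, degenerate) if return_flags else out


def extract_labeled_spectra(cube, rois: RoiSet, mode: str = "none",
                            require_all_classes: bool = True) -> LabeledSpectra:
    """Pull the pixel spectra under the labeled ROI pixels out of a cube.

    ``require_all_classes`` enforces the training-image contract that each of
    the three classes is non-empty; with ``False`` (test images) empty
    classes only produce a warning.
    """
    if rois.shape != cube.data.shape[:2]:
        raise ValueError("ROI label map shape does not match the cube")
    counts = rois.class_counts()
    empty = [CLASS_NAMES[c] for c, n in counts.items() if n == 0]
    if empty:
        if require_all_classes:
            raise ValueError(f"empty ROI classes for a training image: {empty}")
        logger.warning("empty ROI classes: %s", empty)
    sel = rois.labeled()
    X = cube.data[sel]
    y = rois.masks[sel].astype(int)
    logger.info("extracted %d labeled spectra %s", X.shape[0], counts)
    return LabeledSpectra(normalize_spectra(X, mode), y, mode, cube.cube_id)


def _as_planes(image) -> np.ndarray:
    # an ImageCube carries its array in .data; note a bare ndarray also has a
    # .data attribute (a memoryview), so test for the cube interface instead
    data = image.data if hasattr(image, "pixel_spectra") \
        else np.asarray(image, dtype=float)
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValueError("image must be H x W or H x W x C")
    return data


def line_profile(image, p0, p1, width_px: int = 3) -> LineProfile:
    """Average profile along the segment ``p0 -> p1`` ((row, col), 0-based).

    Equivalent to rotating the image so the segment is horizontal (bilinear
    interpolation, 0 outside the image) and averaging ``width_px`` adjacent
    single-pixel rows of the enclosing rectangle.
    """
    data = _as_planes(image)
    H, W, C = data.shape
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    for p in (p0, p1):
        if not (0 <= p[0] <= H - 1 and 0 <= p[1] <= W - 1):
            raise ValueError("line endpoints must lie inside the image")
    d = np.linalg.norm(p1 - p0)
    if d < 2.0:
        raise ValueError("line segment must be at least 2 pixels long")
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be a positive odd integer")

    u = (p1 - p0) / d                        # along-line unit vector
    nvec = np.array([-u[1], u[0]])           # perpendicular unit vector
    L = int(np.floor(d)) + 1
    t = np.arange(L)
    offsets = np.arange(width_px) - width_px // 2
    # sample points: width_px x L x 2
    pts = (p0[None, None, :] + t[None, :, None] * u[None, None, :]
           + offsets[:, None, None] * nvec[None, None, :])
    coords = np.stack([pts[..., 0].ravel(), pts[..., 1].ravel()])
    intensity = np.empty((C, L))
    for c in range(C):
        samples = ndimage.map_coordinates(data[..., c], coords, order=1,
                                          mode="constant", cval=0.0)
        intensity[c] = samples.reshape(width_px, L).mean(axis=0)
    return LineProfile(t, intensity, width_px)


def polygons_to_mask(polygons, shape) -> RoiSet:
    """Rasterize ``[(class_label, [[row, col], ...]), ...]`` into a label map."""
    from skimage.draw import polygon as _polygon

    mask = np.zeros(shape, dtype=np.int64)
    for label, verts in polygons:
        verts = np.asarray(verts, dtype=float)
        rr, cc = _polygon(verts[:, 0], verts[:, 1], shape=shape)
        mask[rr, cc] = int(label)
    return RoiSet(mask)
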