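"""Assembly of exposure-normalized multispectral image cubes.

Raw acquisitions are 16-bit frames captured through each long-pass filter at
a ladder of exposure times.  For each filter the longest exposure without
saturation (raw counts above a threshold, default 35,000) is retained, a dark
frame is subtracted, and the frame is divided by its exposure time; the
resulting channels (counts/s) are stacked into an H x W x F cube ordered by
ascending cut-off.  "Band images" isolating ~100 nm wavelength bands are
formed by subtracting consecutive-filter channels and are used for
visualization only; classification consumes the long-pass channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FULL_WELL_DN",
    "DEFAULT_SATURATION_THRESHOLD",
    "RawFrame",
    "ImageCube",
    "BandImageSet",
    "saturated_pixel_count",
    "select_best_exposure",
    "assemble_cube",
    "build_cube",
    "band_images",
    "apply_exposure_factor",
]

FULL_WELL_DN = 65535
DEFAULT_SATURATION_THRESHOLD = 35000


@dataclass(frozen=True)
class RawFrame:
    """One acquired frame: 16-bit pixels plus exposure and filter metadata.

    ``pixels`` may be an integer array (real acquisitions) or a float array
    (noiseless synthetic acquisitions with quantization disabled); values must
    lie within the 16-bit range either way.
    """

    pixels: np.ndarray
    exposure_s: float
    filter_cutoff_nm: float
    role: str = "signal"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be positive")
        if self.role not in ("signal", "dark"):
            raise ValueError("role must be 'signal' or 'dark'")
        if px.size and (px.min() < 0 or px.max() > FULL_WELL_DN):
            raise ValueError("pixel values must lie within the 16-bit range [0, 65535]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageCube:
    """Dark-subtracted, exposure-normalized image cube in counts/s."""

    data: np.ndarray                       # H x W x F
    filter_cutoffs_nm: tuple
    exposure_factor: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x F")
        cutoffs = tuple(float(c) for c in self.filter_cutoffs_nm)
        if len(cutoffs) != self.data.shape[2]:
            raise ValueError("one cut-off per channel is required")
        if len(cutoffs) > 1 and np.any(np.diff(cutoffs) <= 0):
            raise ValueError("channels must be ordered by ascending cut-off")
        if self.exposure_factor <= 0:
            raise ValueError("exposure_factor must be positive")
        self.filter_cutoffs_nm = cutoffs

    @property
    def n_filters(self) -> int:
        return self.data.shape[2]

    @property
    def cube_id(self) -> str | None:
        return self.provenance.get("cube_id")

    def pixel_spectra(self) -> np.ndarray:
        """All pixel spectra as an (H*W) x F matrix (row-major pixel order)."""
        return self.data.reshape(-1, self.n_filters)


@dataclass(frozen=True)
class BandImageSet:
    """Consecutive-filter difference images isolating ~100 nm bands."""

    bands: np.ndarray                      # H x W x (F-1)
    band_centers_nm: tuple


def saturated_pixel_count(frame: RawFrame,
                          threshold: int = DEFAULT_SATURATION_THRESHOLD) -> int:
    return int(np.count_nonzero(frame.pixels > threshold))


def select_best_exposure(frames,
                         saturation_threshold: int = DEFAULT_SATURATION_THRESHOLD
                         ) -> RawFrame:
    """Pick the longest-exposure frame with no saturated pixels.

    If every frame has saturated pixels, the frame with the fewest is
    returned (ties broken toward shorter exposure); the saturated-pixel
    count of the chosen frame is logged.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to select from")
    cutoffs = {f.filter_cutoff_nm for f in frames}
    shapes = {f.shape for f in frames}
    if len(cutoffs) > 1 or len(shapes) > 1:
        raise ValueError("frames must share a filter and shape")
    counts = [saturated_pixel_count(f, saturation_threshold) for f in frames]
    clean = [(f, c) for f, c in zip(frames, counts) if c == 0]
    if clean:
        chosen, n_sat = max(clean, key=lambda fc: fc[0].exposure_s)
    else:
        chosen, n_sat = min(zip(frames, counts),
                            key=lambda fc: (fc[1], fc[0].exposure_s))
        logger.warning("all frames at %.0f nm saturated; using %g s with %d saturated pixels",
                       chosen.filter_cutoff_nm, chosen.exposure_s, n_sat)
    logger.info("filter %.0f nm: chose %g s exposure (%d saturated pixels)",
                chosen.filter_cutoff_nm, chosen.exposure_s, n_sat)
    return chosen


def _match_dark(signal: RawFrame, darks) -> tuple[np.ndarray, str]:
    """Dark image for a signal frame: exposure-matched if available, else a
    reference dark scaled linearly by the exposure ratio."""
    darks = [d for d in darks if d.role == "dark"]
    if not darks:
        raise ValueError("no dark frames provided")
    exact = [d for d in darks if np.isclose(d.exposure_s, signal.exposure_s)]
    if exact:
        return np.asarray(exact[0].pixels, dtype=float), "matched"
    ref = min(darks, key=lambda d: abs(np.log(d.exposure_s / signal.exposure_s)))
    scaled = np.asarray(ref.pixels, dtype=float) * (signal.exposure_s / ref.exposure_s)
    return scaled, f"scaled_from_{ref.exposure_s:g}s"


def assemble_cube(chosen, darks, expected_cutoffs_nm=None) -> ImageCube:
    """Stack dark-subtracted, exposure-normalized channels into a cube.

    Each channel is ``max(signal - dark, 0) / exposure_s``.  One chosen
    signal frame per filter is required; channels are ordered by ascending
    cut-off and ``exposure_factor`` is 1.
    """
    chosen = sorted(chosen, key=lambda f: f.filter_cutoff_nm)
    if not chosen:
        raise ValueError("no frames provided")
    cutoffs = [f.filter_cutoff_nm for f in chosen]
    if len(set(cutoffs)) != len(cutoffs):
        raise ValueError("more than one chosen frame for a filter")
    if expected_cutoffs_nm is not None:
        missing = sorted(set(float(c) for c in expected_cutoffs_nm) - set(cutoffs))
        if missing:
            raise ValueError(f"missing filter channels at cut-offs {missing} nm")
    shapes = {f.shape for f in chosen}
    if len(shapes) > 1:
        raise ValueError("frame shape mismatch across filters")

    channels, chosen_exposures, dark_modes = [], {}, {}
    for frame in chosen:
        dark, mode = _match_dark(frame, darks)
        if dark.shape != frame.shape:
            raise ValueError("dark frame shape mismatch")
        ch = (np.asarray(frame.pixels, dtype=float) - dark) / frame.exposure_s
        channels.append(np.maximum(ch, 0.0))
        chosen_exposures[frame.filter_cutoff_nm] = frame.exposure_s
        dark_modes[frame.filter_cutoff_nm] = mode
    data = np.stack(channels, axis=-1)
    return ImageCube(data, tuple(cutoffs), exposure_factor=1.0,
                     provenance={"chosen_exposures_s": chosen_exposures,
                                 "dark_mode": dark_modes})


def build_cube(frames, darks,
               saturation_threshold: int = DEFAULT_SATURATION_THRESHOLD,
               cube_id: str | None = None) -> ImageCube:
    """Full acquisition-to-cube path: per-filter exposure selection, then
    dark subtraction and exposure normalization."""
    signal = [f for f in frames if f.role == "signal"]
    if not signal:
        raise ValueError("no signal frames provided")
    by_filter: dict[float, list[RawFrame]] = {}
    for f in signal:
        by_filter.setdefault(f.filter_cutoff_nm, []).append(f)
    chosen = [select_best_exposure(fs, saturation_threshold)
              for _, fs in sorted(by_filter.items())]
    cube = assemble_cube(chosen, darks)
    if cube_id is not None:
        cube.provenance["cube_id"] = cube_id
    return cube


def band_images(cube: ImageCube) -> BandImageSet:
    """Difference consecutive long-pass channels into band images.

    Band ``b`` equals channel ``b`` minus channel ``b+1``; negative pixels
    are retained (they are noise on valid channel differences), so the bands
    plus the last channel telescope back to the first channel.
    """
    if cube.n_filters < 2:
        raise ValueError("band images require at least 2 channels")
    bands = cube.data[..., :-1] - cube.data[..., 1:]
    cutoffs = np.asarray(cube.filter_cutoffs_nm)
    centers = tuple(0.5 * (cutoffs[:-1] + cutoffs[1:]))
    return BandImageSet(bands, centers)


def apply_exposure_factor(cube: ImageCube, E: float) -> ImageCube:
    """Scale a cube by a multiplicative exposure factor ``E``.

    The exposure factor summarizes working distance, illumination power,
    exposure time and dose as a single post-acquisition multiplier; no
    re-quantization or clipping is applied.
    """
    if E <= 0:
        raise ValueError("exposure factor must be positive")
    return ImageCube(cube.data * E, cube.filter_cutoffs_nm,
                     exposure_factor=cube.exposure_factor * E,
                     provenance=dict(cube.provenance))
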