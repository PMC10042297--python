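"""Synthetic multispectral SWIR acquisitions with ground truth.

The generator emulates the statistical structure a spectral tumor classifier
relies on, without modeling photon transport:

* an elliptical tumor inside an animal body emits the "pure" fluorophore
  spectrum (the 6-filter signal vector predicted by the packaged forward
  model);
* the surrounding tissue carries the same fluorophore seen through tissue,
  i.e. the pure spectrum attenuated per band by a coloring profile shaped by
  SWIR water absorption (strongest in the 1150-1350 nm channels) — a subtle
  shape change (a few degrees of spectral angle) rather than a large one;
* optional off-target sites (liver- and femur-like blobs) and a scattered
  halo around every source carry the colored spectrum as well;
* tumor and tissue brightness distributions are overlapping lognormals, so
  single-band intensity thresholds cannot survive exposure changes;
* each simulated individual jitters the endmember slightly (the spectra are
  conserved between individuals) and scales global brightness (emulating
  time since injection);
* the sensor model integrates radiance over a ladder of exposure times and
  adds dark offset, shot noise, Gaussian read noise, quantization to integer
  counts and clipping at the 16-bit full well.

Everything is driven by a single seed; identical configurations reproduce
byte-identical frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from . import spectral
from .cube import FULL_WELL_DN, ImageCube, RawFrame
from .preprocess import (CLASS_BACKGROUND, CLASS_NON_TUMOR, CLASS_TUMOR, RoiSet)

logger = logging.getLogger(__name__)

__all__ = [
    "EllipseSpec",
    "PhantomConfig",
    "PhantomOutput",
    "default_endmember",
    "coloring_profile_for_angle",
    "render_scene",
    "acquire",
    "generate_study",
    "noiseless_config",
    "negative_control_config",
]

#: per-band attenuation shape (ascending cut-off channels); larger weight =
#: stronger attenuation, concentrated in the water-absorption channels.
_COLORING_WEIGHTS = np.array([0.00, 0.05, 0.15, 0.55, 0.85, 1.00])


@dataclass(frozen=True)
class EllipseSpec:
    """An axis-aligned ellipse in fractional image coordinates (row, col)."""

    center: tuple          # (row_frac, col_frac)
    axes: tuple            # (row_semiaxis_frac, col_semiaxis_frac)

    def validate(self) -> None:
        for c, a in zip(self.center, self.axes):
            if a <= 0:
                raise ValueError("ellipse axes must be positive")
            if c - a < -1e-9 or c + a > 1 + 1e-9:
                raise ValueError("ellipse geometry extends outside the image")

    def mask(self, shape) -> np.ndarray:
        H, W = shape
        r = np.arange(H)[:, None]
        c = np.arange(W)[None, :]
        return (((r - self.center[0] * H) / (self.axes[0] * H)) ** 2
                + ((c - self.center[1] * W) / (self.axes[1] * W)) ** 2) <= 1.0

    def area_px(self, shape) -> float:
        H, W = shape
        return np.pi * self.axes[0] * H * self.axes[1] * W


def default_endmember() -> np.ndarray:
    """L1-normalized 6-filter signal of the packaged dye/detector model."""
    signals = spectral.predict_filter_signals(
        spectral.default_emission_spectrum(),
        spectral.default_filter_bank(),
        spectral.default_quantum_efficiency()).per_filter
    return signals / signals.sum()


def _l1(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def coloring_profile_for_angle(endmember: np.ndarray,
                               target_angle_deg: float = 4.0) -> np.ndarray:
    """Per-band attenuation vector giving a chosen endmember separation.

    Solves for the strength ``s`` in ``a = exp(-s * w)`` (``w`` the
    water-absorption weight shape) such that the spectral angle between the
    pure endmember and the colored endmember equals ``target_angle_deg``.
    """
    def gap(s: float) -> float:
        return _angle_deg(endmember, endmember * np.exp(-s * _COLORING_WEIGHTS)) \
            - target_angle_deg

    strength = brentq(gap, 1e-6, 20.0, xtol=1e-10)
    return np.exp(-strength * _COLORING_WEIGHTS)


@dataclass(frozen=True)
class PhantomConfig:
    """Full generative description of a synthetic acquisition study."""

    image_shape: tuple = (640, 512)
    body: EllipseSpec = EllipseSpec((0.50, 0.50), (0.46, 0.44))
    tumor: EllipseSpec = EllipseSpec((0.38, 0.64), (0.085, 0.105))
    offtarget_sites: tuple = (EllipseSpec((0.68, 0.30), (0.10, 0.085)),   # liver-like
                              EllipseSpec((0.26, 0.28), (0.035, 0.10)))  # femur-like
    include_offtarget: bool = True
    endmember_tumor: np.ndarray | None = None       # default: forward-model signals
    coloring_profile: np.ndarray | None = None      # default: 4 deg separation
    scatter_halo_frac: float = 0.04                 # halo decay scale / image height
    halo_strength: float = 0.5
    tumor_brightness_median: float = 6000.0         # counts/s summed over channels
    tumor_brightness_sigma: float = 0.30            # lognormal log-sd
    tissue_brightness_median: float = 2000.0
    tissue_brightness_sigma: float = 0.30
    offtarget_brightness_median: float = 9000.0
    offtarget_brightness_sigma: float = 0.4
    individual_brightness: tuple = (1.0, 0.75, 0.55, 0.40)
    individual_variation_cv: float = 0.02
    exposure_ladder_s: tuple = (0.01, 0.05, 0.25, 1.0, 5.0)
    dark_offset_counts: float = 100.0
    read_noise_sd: float = 10.0
    shot_noise: bool = True
    quantize: bool = True
    full_well_dn: int = FULL_WELL_DN
    saturation_threshold: int = 35000
    roi_tumor_erosion_px: int = 2
    roi_tissue: EllipseSpec = EllipseSpec((0.64, 0.70), (0.060, 0.075))
    roi_background: EllipseSpec = EllipseSpec((0.08, 0.08), (0.050, 0.060))
    filter_cutoffs_nm: tuple = spectral.DEFAULT_CUTOFFS_NM
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.exposure_ladder_s) == 0:
            raise ValueError("exposure ladder must be non-empty")
        for spec in (self.body, self.tumor, self.roi_tissue, self.roi_background,
                     *self.offtarget_sites):
            spec.validate()
        em = self.endmember_tumor
        em = default_endmember() if em is None else np.asarray(em, dtype=float)
        if np.any(em <= 0) or np.any(np.diff(em) > 0):
            raise ValueError("tumor endmember must be strictly positive and "
                             "non-increasing across ascending cut-off channels")
        cp = self.coloring_profile
        cp = coloring_profile_for_angle(em) if cp is None else np.asarray(cp, dtype=float)
        if np.any(cp <= 0):
            raise ValueError("coloring profile must be positive")
        object.__setattr__(self, "endmember_tumor", _l1(em))
        object.__setattr__(self, "coloring_profile", cp)

    @property
    def n_filters(self) -> int:
        return len(self.filter_cutoffs_nm)


@dataclass
class PhantomOutput:
    """One simulated individual: raw frames, darks, ground truth, provenance."""

    frames: list
    darks: list
    rois: RoiSet
    truth: ImageCube
    config: PhantomConfig
    individual_id: int
    is_control: bool = False

    @property
    def cube_id(self) -> str:
        kind = "control" if self.is_control else "individual"
        return f"phantom-{kind}-{self.individual_id}"


def _scene_rng(config: PhantomConfig, individual_id: int, stream: int):
    return np.random.default_rng([config.seed & 0x7FFFFFFF, individual_id, stream])


def _lognormal_field(rng, median: float, sigma: float, size) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, sigma, size=size))


def render_scene(config: PhantomConfig, individual_id: int,
                 dye: bool = True) -> tuple[ImageCube, RoiSet]:
    """Noiseless radiance cube (counts/s) and ground-truth ROI label map.

    ``dye=False`` renders a negative-control individual: identical geometry
    and ROIs with zero fluorophore radiance everywhere.
    """
    H, W = config.image_shape
    F = config.n_filters
    rng = _scene_rng(config, individual_id, 0)

    s = config.endmember_tumor
    cv = config.individual_variation_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv ** 2))
        s = _l1(s * np.exp(rng.normal(0.0, sigma, size=F)))
    colored = _l1(s * config.coloring_profile)

    body = config.body.mask((H, W))
    tumor = config.tumor.mask((H, W)) & body
    blobs = np.zeros((H, W), bool)
    if config.include_offtarget:
        for site in config.offtarget_sites:
            blobs |= site.mask((H, W)) & body
    blobs &= ~tumor
    tissue = body & ~tumor & ~blobs

    radiance = np.zeros((H, W, F))
    if dye:
        gb = config.individual_brightness[individual_id % len(config.individual_brightness)]
        b_tis = _lognormal_field(rng, gb * config.tissue_brightness_median,
                                 config.tissue_brightness_sigma, (H, W))
        b_tum = _lognormal_field(rng, gb * config.tumor_brightness_median,
                                 config.tumor_brightness_sigma, (H, W))
        b_off = _lognormal_field(rng, gb * config.offtarget_brightness_median,
                                 config.offtarget_brightness_sigma, (H, W))
        amp = np.zeros((H, W))
        amp[tissue] = b_tis[tissue]
        amp[blobs] = b_off[blobs]
        radiance[tissue | blobs] = amp[tissue | blobs, None] * colored[None, :]
        radiance[tumor] = b_tum[tumor, None] * s[None, :]

        # scattered halo around fluorescent sources, colored, decaying spatially
        source_amp = np.zeros((H, W))
        source_amp[tumor] = b_tum[tumor]
        source_amp[blobs] = b_off[blobs]
        halo = ndimage.gaussian_filter(source_amp, sigma=config.scatter_halo_frac * H)
        halo_px = tissue
        radiance[halo_px] += (config.halo_strength * halo[halo_px, None]
                              * colored[None, :])

    roi = np.zeros((H, W), dtype=np.int64)
    tumor_roi = ndimage.binary_erosion(tumor, iterations=config.roi_tumor_erosion_px)
    roi[tumor_roi] = CLASS_TUMOR
    roi[config.roi_tissue.mask((H, W)) & tissue] = CLASS_NON_TUMOR
    roi[config.roi_background.mask((H, W)) & ~body] = CLASS_BACKGROUND

    kind = "individual" if dye else "control"
    cube = ImageCube(radiance, config.filter_cutoffs_nm, exposure_factor=1.0,
                     provenance={"cube_id": f"phantom-{kind}-{individual_id}",
                                 "synthetic": True, "individual_id": individual_id,
                                 "dye": dye, "seed": config.seed})
    return cube, RoiSet(roi)


def acquire(truth: ImageCube, config: PhantomConfig,
            individual_id: int = 0) -> tuple[list, list]:
    """Simulate the multi-exposure acquisition ladder for a noiseless cube.

    For each filter channel and exposure ``t``:
    ``counts = round(Poisson(radiance * t) + dark + N(0, read_sd))`` clipped
    to the 16-bit range (Poisson and rounding subject to the config flags).
    Dark frames (one per exposure) carry offset and read noise only.
    """
    rng = _scene_rng(config, individual_id, 1)
    H, W = truth.data.shape[:2]

    def _sensor(expected: np.ndarray, shot: bool) -> np.ndarray:
        counts = rng.poisson(expected).astype(float) if shot else expected.copy()
        counts += config.dark_offset_counts
        if config.read_noise_sd > 0:
            counts += rng.normal(0.0, config.read_noise_sd, size=expected.shape)
        if config.quantize:
            counts = np.rint(counts)
        counts = np.clip(counts, 0, config.full_well_dn)
        return counts.astype(np.uint16) if config.quantize else counts

    frames = []
    for f, cutoff in enumerate(truth.filter_cutoffs_nm):
        for t in config.exposure_ladder_s:
            px = _sensor(truth.data[..., f] * t, config.shot_noise)
            frames.append(RawFrame(px, t, cutoff, role="signal"))
    darks = [RawFrame(_sensor(np.zeros((H, W)), False), t, 0.0, role="dark")
             for t in config.exposure_ladder_s]
    return frames, darks


def generate_study(config: PhantomConfig, n_individuals: int = 4,
                   n_controls: int = 2) -> list:
    """Simulate a full study: dye-injected individuals plus negative controls.

    Individuals carry per-individual endmember jitter and decreasing global
    brightness (emulating time since injection); controls have zero
    fluorophore radiance (dark frames plus noise only) but identical geometry.
    """
    if n_individuals < 2:
        raise ValueError("at least 2 dye-positive individuals are required "
                         "for the cross-validation protocol")
    outputs = []
    for i in range(n_individuals + n_controls):
        dye = i < n_individuals
        truth, rois = render_scene(config, i, dye=dye)
        frames, darks = acquire(truth, config, i)
        outputs.append(PhantomOutput(frames, darks, rois, truth, config, i,
                                     is_control=not dye))
        logger.info("simulated %s", outputs[-1].cube_id)
    return outputs


def noiseless_config(config: PhantomConfig | None = None, **overrides) -> PhantomConfig:
    """A noiseless, unquantized sensor variant (exact pipeline-identity checks)."""
    base = config or PhantomConfig()
    return replace(base, shot_noise=False, read_noise_sd=0.0, quantize=False,
                   dark_offset_counts=0.0, **overrides)


def negative_control_config(config: PhantomConfig | None = None, **overrides) -> PhantomConfig:
    """Degenerate scene: identical class spectral shapes and fully overlapping
    intensities (tumor and tissue differ by nothing but noise).

    A shape-based classifier should collapse toward chance on tumor versus
    tissue here; this is the package's negative control.
    """
    base = config or PhantomConfig()
    return replace(base,
                   coloring_profile=np.ones(base.n_filters),
                   tissue_brightness_median=base.tumor_brightness_median,
                   tissue_brightness_sigma=base.tumor_brightness_sigma,
                   offtarget_brightness_median=base.tumor_brightness_median,
                   offtarget_brightness_sigma=base.tumor_brightness_sigma,
                   **overrides)
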