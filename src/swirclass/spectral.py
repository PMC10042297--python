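"""Forward optical model of a multispectral SWIR fluorescence detector.

The imaging chain collects fluorescence through a wheel of long-pass filters
onto an InGaAs sensor.  The signal recorded through one filter is

    S_filter = integral( T_filter(lam) * QE(lam) * E_em(lam) dlam )

where ``T_filter`` is the filter transmission, ``QE`` the sensor quantum
efficiency and ``E_em`` the fluorophore emission spectrum.  Because published
emission curves of NIR-I dyes were measured with silicon detectors, the SWIR
emission tail is suppressed; the full emission curve is reconstructed by
mirror-reflecting the absorption spectrum about the 0-0 transition
(Franck-Condon mirror-image rule) and stitching it to a measured SWIR tail.

All curves are tabulated wavelength/value pairs (:class:`TabulatedSpectrum`)
with linear interpolation inside the tabulated support and zero outside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPECTRUM_KINDS",
    "DEFAULT_CUTOFFS_NM",
    "TabulatedSpectrum",
    "LongPassFilterBank",
    "PredictedFilterSignals",
    "resample_to_grid",
    "mirror_emission_spectrum",
    "predict_filter_signals",
    "ideal_step_filter_bank",
    "default_filter_bank",
    "default_quantum_efficiency",
    "default_emission_spectrum",
    "default_absorption_spectrum",
    "default_swir_tail_spectrum",
]

SPECTRUM_KINDS = ("emission", "absorption", "transmission", "qe")

#: Long-pass cut-off wavelengths (nm) of the six-position filter wheel.
DEFAULT_CUTOFFS_NM = (850.0, 950.0, 1050.0, 1150.0, 1250.0, 1350.0)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


@dataclass(frozen=True)
class TabulatedSpectrum:
    """A wavelength-indexed curve (emission, absorption, transmission or QE).

    Values are linearly interpolated inside the tabulated wavelength range
    and are zero outside it.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a tabulated spectrum needs at least 2 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        if self.kind in ("transmission", "qe"):
            if np.any(vals < 0) or np.any(vals > 1.0 + 1e-9):
                raise ValueError(f"{self.kind} values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def __call__(self, grid_nm) -> np.ndarray:
        """Interpolated values on ``grid_nm`` (0 outside the support)."""
        return np.interp(np.asarray(grid_nm, dtype=float),
                         self.wavelengths_nm, self.values, left=0.0, right=0.0)

    def resample(self, grid_nm) -> "TabulatedSpectrum":
        return resample_to_grid(self, grid_nm)

    def scaled(self, factor: float) -> "TabulatedSpectrum":
        return TabulatedSpectrum(self.wavelengths_nm, self.values * float(factor), self.kind)

    @classmethod
    def from_csv(cls, path, kind: str) -> "TabulatedSpectrum":
        """Read a two-column ``wavelength_nm,value`` CSV with a header line."""
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1], kind)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.wavelengths_nm, self.values]),
                   delimiter=",", header="wavelength_nm,value", comments="")


def resample_to_grid(s: TabulatedSpectrum, grid_nm) -> TabulatedSpectrum:
    """Linearly resample ``s`` onto ``grid_nm``; queries outside the support are 0."""
    grid = np.asarray(grid_nm, dtype=float)
    if grid.size == 0:
        raise ValueError("resampling grid is empty")
    if grid.size >= 2 and np.any(np.diff(grid) <= 0):
        raise ValueError("resampling grid must be strictly increasing")
    if grid.size < 2:
        raise ValueError("resampling grid needs at least 2 points")
    return TabulatedSpectrum(grid, s(grid), s.kind)


@dataclass(frozen=True)
class LongPassFilterBank:
    """A set of long-pass filters ordered by ascending cut-off wavelength."""

    cutoffs_nm: tuple
    transmissions: tuple

    def __post_init__(self) -> None:
        cutoffs = tuple(float(c) for c in self.cutoffs_nm)
        trans = tuple(self.transmissions)
        if len(cutoffs) != len(trans):
            raise ValueError("one transmission curve per cut-off is required")
        if np.any(np.diff(cutoffs) <= 0):
            raise ValueError("cut-offs must be strictly increasing")
        for c, t in zip(cutoffs, trans):
            if t.kind != "transmission":
                raise ValueError("filter curves must have kind='transmission'")
            # near-zero in the stop band, monotone non-decreasing up to tolerance
            lo = t.support[0]
            if c - 30.0 > lo and t(c - 30.0) > 0.05:
                raise ValueError(f"filter at {c} nm transmits in its stop band")
            if np.any(np.diff(t.values) < -1e-6):
                raise ValueError(f"filter at {c} nm is not monotone non-decreasing")
        object.__setattr__(self, "cutoffs_nm", cutoffs)
        object.__setattr__(self, "transmissions", trans)

    def __len__(self) -> int:
        return len(self.cutoffs_nm)


@dataclass(frozen=True)
class PredictedFilterSignals:
    """Predicted per-filter signals, ordered by ascending cut-off."""

    per_filter: np.ndarray
    cutoffs_nm: tuple
    empty_overlap: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_filter", np.asarray(self.per_filter, dtype=float))


def mirror_emission_spectrum(absorption: TabulatedSpectrum,
                             measured_tail: TabulatedSpectrum,
                             peak_nm: float) -> TabulatedSpectrum:
    """Reconstruct a full emission spectrum by Franck-Condon mirroring.

    The absorption spectrum is reflected about ``peak_nm`` (wavelength ``lam``
    maps to ``2*peak_nm - lam``), rescaled by a single least-squares factor so
    it matches ``measured_tail`` on their overlap, then stitched: mirrored
    curve below the overlap midpoint, measured tail above.  The result is
    normalized to a peak value of 1.
    """
    if peak_nm <= 0:
        raise ValueError("peak_nm must be positive")
    mir_wl = (2.0 * peak_nm - absorption.wavelengths_nm)[::-1]
    mir_vals = absorption.values[::-1]
    mirrored = TabulatedSpectrum(mir_wl, mir_vals, "emission")

    lo = max(mirrored.support[0], measured_tail.support[0])
    hi = min(mirrored.support[1], measured_tail.support[1])
    if lo >= hi:
        raise ValueError("no stitch region: mirrored curve and measured tail do not overlap")

    grid = np.linspace(lo, hi, max(16, int(np.ceil(hi - lo)) + 1))
    m = mirrored(grid)
    t = measured_tail(grid)
    denom = float(np.dot(m, m))
    if denom <= 0:
        raise ValueError("no stitch region: mirrored curve vanishes on the overlap")
    scale = float(np.dot(m, t)) / denom

    mid = 0.5 * (lo + hi)
    below = mirrored.wavelengths_nm <= mid
    above = measured_tail.wavelengths_nm > mid
    wl = np.concatenate([mirrored.wavelengths_nm[below], measured_tail.wavelengths_nm[above]])
    vals = np.concatenate([mirrored.values[below] * scale, measured_tail.values[above]])
    order = np.argsort(wl)
    wl, vals = wl[order], vals[order]
    keep = np.concatenate([[True], np.diff(wl) > 0])
    wl, vals = wl[keep], vals[keep]
    peak = vals.max()
    if peak <= 0:
        raise ValueError("stitched spectrum has no positive values")
    return TabulatedSpectrum(wl, vals / peak, "emission")


def _quadrature_grid(lo: float, hi: float, step: float, knot_sets) -> np.ndarray:
    """Uniform grid on [lo, hi] unioned with every tabulation knot inside it.

    With all knots on the grid the integrand is piecewise linear between
    nodes wherever at most one factor varies, making the trapezoid rule exact
    for box/step-type inputs.
    """
    grid = np.arange(lo, hi + 0.5 * step, step)
    pieces = [grid, np.asarray([lo, hi])]
    for knots in knot_sets:
        k = knots[(knots >= lo) & (knots <= hi)]
        if k.size:
            pieces.append(k)
    return np.unique(np.concatenate(pieces))


def predict_filter_signals(emission: TabulatedSpectrum,
                           bank: LongPassFilterBank,
                           qe: TabulatedSpectrum,
                           grid_step_nm: float = 1.0) -> PredictedFilterSignals:
    """Propagate an emission spectrum through the filter bank and sensor QE.

    Evaluates ``S_f = integral(T_f * QE * E_em)`` by trapezoidal quadrature on
    a common wavelength grid (default step 1 nm, augmented with all input
    tabulation knots).  If the emission and QE supports do not overlap, the
    signals are all zero and ``empty_overlap`` is set (with a warning).
    """
    if grid_step_nm <= 0:
        raise ValueError("grid_step_nm must be positive")
    lo = max(emission.support[0], qe.support[0])
    hi = min(emission.support[1], qe.support[1])
    if lo >= hi:
        warnings.warn("emission and QE supports do not overlap; all signals are zero",
                      stacklevel=2)
        return PredictedFilterSignals(np.zeros(len(bank)), bank.cutoffs_nm, empty_overlap=True)

    knots = [emission.wavelengths_nm, qe.wavelengths_nm]
    knots += [t.wavelengths_nm for t in bank.transmissions]
    grid = _quadrature_grid(lo, hi, grid_step_nm, knots)
    base = emission(grid) * qe(grid)
    signals = np.array([np.trapezoid(t(grid) * base, grid) for t in bank.transmissions])
    return PredictedFilterSignals(signals, bank.cutoffs_nm)


# ---------------------------------------------------------------------------
# Packaged default curves.  The shipped defaults are parameterized stand-ins
# for data-book curves and are overridable from two-column CSV files.
# ---------------------------------------------------------------------------

def ideal_step_filter_bank(cutoffs_nm=DEFAULT_CUTOFFS_NM,
                           wavelength_range=(400.0, 1800.0),
                           edge_half_width_nm: float = 1e-6) -> LongPassFilterBank:
    """Ideal long-pass filters: 0 below the cut-off, 1 above.

    Each edge is a symmetric linear ramp of half-width ``edge_half_width_nm``
    about the cut-off, whose trapezoid integral equals the true step integral
    exactly when the ramp knots lie on the quadrature grid.
    """
    lo, hi = wavelength_range
    trans = []
    for c in cutoffs_nm:
        wl = np.array([lo, c - edge_half_width_nm, c + edge_half_width_nm, hi])
        trans.append(TabulatedSpectrum(wl, np.array([0.0, 0.0, 1.0, 1.0]), "transmission"))
    return LongPassFilterBank(tuple(cutoffs_nm), tuple(trans))


def default_filter_bank(cutoffs_nm=DEFAULT_CUTOFFS_NM,
                        plateau: float = 0.98,
                        edge_width_nm: float = 10.0,
                        wavelength_range=(400.0, 1800.0),
                        step_nm: float = 2.0) -> LongPassFilterBank:
    """Logistic-edge long-pass transmissions (plateau 0.98, 10-90% edge 10 nm)."""
    grid = np.arange(wavelength_range[0], wavelength_range[1] + step_nm, step_nm)
    scale = edge_width_nm / (2.0 * np.log(9.0))
    trans = tuple(
        TabulatedSpectrum(grid, plateau * _logistic((grid - c) / scale), "transmission")
        for c in cutoffs_nm
    )
    return LongPassFilterBank(tuple(cutoffs_nm), trans)


def default_quantum_efficiency(step_nm: float = 2.0) -> TabulatedSpectrum:
    """InGaAs-like QE: ~0.85 plateau over 950-1600 nm with soft roll-offs."""
    grid = np.arange(700.0, 1750.0 + step_nm, step_nm)
    qe = 0.85 * _logistic((grid - 880.0) / 25.0) * _logistic((1680.0 - grid) / 25.0)
    return TabulatedSpectrum(grid, qe, "qe")


def default_emission_spectrum(step_nm: float = 1.0) -> TabulatedSpectrum:
    """IRDye800CW-like emission: NIR-I peak near 800 nm plus a broad SWIR tail."""
    grid = np.arange(700.0, 1700.0 + step_nm, step_nm)
    em = (np.exp(-0.5 * ((grid - 800.0) / 35.0) ** 2)
          + 0.10 * np.exp(-0.5 * ((grid - 1150.0) / 190.0) ** 2))
    return TabulatedSpectrum(grid, em / em.max(), "emission")


def default_absorption_spectrum(step_nm: float = 1.0) -> TabulatedSpectrum:
    """Schematic NIR-I dye absorption band peaked near 774 nm."""
    grid = np.arange(600.0, 820.0 + step_nm, step_nm)
    ab = np.exp(-0.5 * ((grid - 774.0) / 30.0) ** 2) \
        + 0.25 * np.exp(-0.5 * ((grid - 705.0) / 28.0) ** 2)
    return TabulatedSpectrum(grid, ab / ab.max(), "absorption")


def default_swir_tail_spectrum(step_nm: float = 2.0) -> TabulatedSpectrum:
    """Schematic measured SWIR emission tail (silicon-blind wavelength region)."""
    grid = np.arange(900.0, 1600.0 + step_nm, step_nm)
    tail = 0.2 * np.exp(-(grid - 900.0) / 350.0)
    return TabulatedSpectrum(grid, tail, "emission")
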