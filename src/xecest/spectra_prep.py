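"""Assemble z-spectra from per-scan 1-D xenon spectra.

Each CEST scan applies saturation at one irradiation offset and then
records a direct-detection spectrum of freely dissolved xenon.  The scan
is reduced to a single intensity by trapezoidal integration over a 7 ppm
window centred on the maximum signal amplitude; stacking the integrals
against the irradiation offsets yields the z-spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scan1D",
    "ZSpectrum",
    "integrate_scan",
    "assemble_zspectrum",
    "normalize_baseline",
]


@dataclass(frozen=True)
class Scan1D:
    """One absorption-mode direct-detection spectrum.

    axis : ppm grid, strictly monotone.
    amplitude : real intensities on that grid.
    irradiation_offset : ppm position of the saturation applied before
        this scan (the z-spectrum abscissa).
    """

    axis: np.ndarray
    amplitude: np.ndarray
    irradiation_offset: float

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if axis.ndim != 1 or axis.shape != amp.shape:
            raise ValueError("axis and amplitude must be matching 1-D arrays")
        d = np.diff(axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("scan axis must be strictly monotone")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "amplitude", amp)


@dataclass(frozen=True)
class ZSpectrum:
    """Sampled saturation response: normalized signal vs irradiation offset.

    offsets : ppm, strictly increasing.  intensities : dimensionless.
    sigma : optional per-point noise estimate (same scale as intensities).
    metadata : free-form provenance (acquisition settings, normalization).
    """

    offsets: np.ndarray
    intensities: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if off.ndim != 1 or off.shape != inten.shape:
            raise ValueError("offsets and intensities must be matching 1-D arrays")
        order = np.argsort(off)
        off, inten = off[order], inten[order]
        if np.any(np.diff(off) <= 0):
            raise ValueError("offsets must be distinct")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        sig = self.sigma
        if sig is not None:
            sig = np.asarray(sig, dtype=float)[order]
            if sig.shape != off.shape or np.any(sig < 0):
                raise ValueError("sigma must be non-negative and match offsets")
        object.__setattr__(self, "offsets", off)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "sigma", sig)

    def __len__(self) -> int:
        return self.offsets.size


def integrate_scan(
    scan: Scan1D,
    window_ppm: float = 7.0,
    center: float | None = None,
    median_smooth: bool = False,
) -> float:
    """Trapezoidal integral over a window centred on the signal maximum.

    Parameters
    ----------
    window_ppm : full integration window width in ppm (default 7).
    center : fix the window centre instead of re-locating the peak
        (useful to keep the window identical across a scan series).
    median_smooth : locate the peak on a 3-point running median of the
        amplitudes (robustness against single-point spikes); the
        integral always uses the raw amplitudes.
    """
    if window_ppm <= 0:
        raise ValueError("window_ppm must be > 0")
    amp = scan.amplitude
    if not np.all(np.isfinite(amp)):
        raise ValueError("scan amplitudes must be finite")
    if np.all(amp == 0):
        raise ValueError("scan is identically zero: no signal maximum")
    axis = scan.axis
    if axis[0] > axis[-1]:  # integrate on an ascending axis
        axis, amp = axis[::-1], amp[::-1]
    if center is None:
        search = amp
        if median_smooth and amp.size >= 3:
            stacked = np.vstack([amp[:-2], amp[1:-1], amp[2:]])
            search = amp.copy()
            search[1:-1] = np.median(stacked, axis=0)
        center = float(axis[np.argmax(search)])
    half = window_ppm / 2.0
    lo, hi = center - half, center + half
    if lo < axis[0] or hi > axis[-1]:
        warnings.warn(
            f"integration window [{lo:.2f}, {hi:.2f}] ppm clipped to scan "
            f"axis [{axis[0]:.2f}, {axis[-1]:.2f}] ppm",
            stacklevel=2,
        )
        lo, hi = max(lo, axis[0]), min(hi, axis[-1])
    # native grid points inside the window plus interpolated edge points
    inside = (axis > lo) & (axis < hi)
    grid = np.concatenate(([lo], axis[inside], [hi]))
    vals = np.interp(grid, axis, amp)
    return float(np.trapezoid(vals, grid))


def assemble_zspectrum(scans: list[Scan1D], **integrate_kwargs) -> ZSpectrum:
    """Integrate a scan series into a z-spectrum sorted by offset.

    Intensities are the raw integrals; normalization is a separate step
    (:func:`normalize_baseline` or the fitted baseline amplitude A).
    """
    if len(scans) < 3:
        raise ValueError("need at least 3 scans to assemble a z-spectrum")
    offsets = np.array([s.irradiation_offset for s in scans], dtype=float)
    if np.unique(offsets).size != offsets.size:
        raise ValueError("duplicate irradiation offsets in scan set")
    intensities = np.array([integrate_scan(s, **integrate_kwargs) for s in scans])
    return ZSpectrum(offsets=offsets, intensities=intensities)


def normalize_baseline(z: ZSpectrum, quantile: float = 0.9) -> ZSpectrum:
    """Scale intensities by an upper quantile (baseline estimate).

    On a z-spectrum most points sit on the unsaturated baseline, so a
    high quantile of the intensities estimates the off-resonance level;
    dividing by it conditions the data without touching the fitted
    baseline amplitude A.  The scale used is recorded in metadata.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    scale = float(np.quantile(z.intensities, quantile))
    if scale == 0:
        raise ValueError("baseline quantile is zero; cannot normalize")
    meta = dict(z.metadata)
    meta["baseline_scale"] = scale
    meta["baseline_quantile"] = quantile
    return ZSpectrum(
        offsets=z.offsets.copy(),
        intensities=z.intensities / scale,
        sigma=None if z.sigma is None else z.sigma / scale,
        metadata=meta,
    )
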