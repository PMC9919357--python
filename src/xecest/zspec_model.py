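"""Forward model for hyperCEST z-spectra of cage-bound xenon.

Saturation of xenon transiently bound to a cryptophane host depletes the
signal of freely dissolved hyperpolarized xenon.  Stepping the saturation
frequency yields a z-spectrum whose dips are, to excellent approximation,
*exponential Lorentzians*: the response to ``N`` exchanging pools is

    S(x) = A * prod_i exp(-B_i * a_i^2 / (a_i^2 + (b_i - x)^2))

with ``x`` the irradiation frequency, ``b_i`` the resonance position,
``B_i`` a dimensionless saturation amplitude and ``a_i`` the angular
half-width (rad/s).  Positions are handled in ppm referenced to xenon
gas (0 ppm; freely dissolved xenon appears at 196 ppm) and converted to
angular frequency through the observe frequency.

The (B, a) parameters are not free lineshape descriptors but encode the
exchange mechanism: with saturation time ``t``, RF nutation frequency
``omega1``, exchange rates ``k_on``/``k_off`` and bound-pool transverse
relaxation ``R2``,

    B = t * k_on * omega1^2 / (omega1^2 + k_off^2 + k_off * R2)
    a = sqrt(omega1^2 + k_off^2 + R2^2 + (R2/k_off) * (omega1^2 + 2*k_off^2))

Widths are stored internally in rad/s; every file and report interface
uses ``a/pi`` in Hz (the FWHM of the underlying Lorentzian).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_F_OBS_HZ",
    "FREE_XE_PPM",
    "Resonance",
    "ZSpecModelParams",
    "AcquisitionParams",
    "ExchangeParams",
    "evaluate_zspectrum",
    "evaluate_zspectrum_linearized",
    "cest_amplitude",
    "cest_width",
    "width_high_power_limit",
    "ppm_to_hz",
    "hz_to_ppm",
    "koff_from_linewidth",
]

#: 129Xe observe frequency at 7 T, Hz.  A default, never hard-wired into
#: the math: every evaluator takes ``f_obs`` explicitly.
DEFAULT_F_OBS_HZ = 83.0e6

#: Chemical shift of freely dissolved xenon, ppm (xenon gas = 0 ppm).
FREE_XE_PPM = 196.0


@dataclass(frozen=True)
class Resonance:
    """One CEST resonance.

    Parameters
    ----------
    b_ppm : float
        Position, ppm referenced to xenon gas (0 ppm).
    B : float
        Dimensionless exponential amplitude (>= 0).
    a : float
        Angular half-width, rad/s (> 0).  ``a / pi`` is the Lorentzian
        FWHM in Hz reported externally.
    """

    b_ppm: float
    B: float
    a: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.b_ppm) and math.isfinite(self.B) and math.isfinite(self.a)):
            raise ValueError("resonance parameters must be finite")
        if self.B < 0:
            raise ValueError(f"amplitude B must be >= 0, got {self.B}")
        if self.a <= 0:
            raise ValueError(f"angular half-width a must be > 0, got {self.a}")

    @property
    def width_hz(self) -> float:
        """Reported width ``a/pi`` in Hz (Lorentzian FWHM)."""
        return self.a / math.pi

    @classmethod
    def from_width_hz(cls, b_ppm: float, B: float, width_hz: float) -> "Resonance":
        """Build from the externally reported ``a/pi`` width in Hz."""
        return cls(b_ppm=b_ppm, B=B, a=width_hz * math.pi)


@dataclass(frozen=True)
class ZSpecModelParams:
    """Baseline amplitude plus resonances, ordered downfield to upfield.

    Resonances are numbered in order of appearance upfield toward the
    196 ppm free-xenon line, i.e. by strictly decreasing ppm.  The
    constructor sorts; coincident positions are rejected (they are not
    identifiable in a product of Lorentzians).
    """

    A: float
    resonances: tuple[Resonance, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A) and self.A > 0):
            raise ValueError(f"baseline amplitude A must be positive, got {self.A}")
        res = tuple(sorted(self.resonances, key=lambda r: -r.b_ppm))
        positions = [r.b_ppm for r in res]
        if len(set(positions)) != len(positions):
            raise ValueError(f"degenerate resonance positions: {positions}")
        object.__setattr__(self, "resonances", res)

    @property
    def n_resonances(self) -> int:
        return len(self.resonances)

    def to_dict(self) -> dict:
        """JSON-ready form: positions ppm, amplitudes B, widths a/pi Hz."""
        return {
            "A": self.A,
            "resonances": [
                {"b_ppm": r.b_ppm, "B": r.B, "width_hz_over_pi": r.width_hz}
                for r in self.resonances
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZSpecModelParams":
        return cls(
            A=d["A"],
            resonances=tuple(
                Resonance.from_width_hz(r["b_ppm"], r["B"], r["width_hz_over_pi"])
                for r in d["resonances"]
            ),
        )


@dataclass(frozen=True)
class AcquisitionParams:
    """CEST acquisition settings.

    Defaults mirror the measurement protocol: cw saturation at a xenon
    nutation frequency of 2*pi*99 rad/s applied for 20 s, irradiation
    offsets stepped from 5 kHz downfield to 13 kHz upfield of the
    free-xenon line in 200 Hz steps.

    ``grid`` is (start, stop, step) in Hz relative to the free-xenon
    line; start is the downfield (positive) edge.
    """

    omega1: float = 2.0 * math.pi * 99.0
    t_sat: float = 20.0
    f_obs: float = DEFAULT_F_OBS_HZ
    ref_free_xe_ppm: float = FREE_XE_PPM
    grid: tuple[float, float, float] = (5000.0, -13000.0, 200.0)

    def __post_init__(self) -> None:
        if self.omega1 < 0:
            raise ValueError("omega1 must be >= 0")
        if self.t_sat <= 0:
            raise ValueError("t_sat must be > 0")
        if self.f_obs <= 0:
            raise ValueError("f_obs must be > 0")
        start, stop, step = self.grid
        if step <= 0:
            raise ValueError("grid step must be > 0")
        if start <= stop:
            raise ValueError("grid start must lie downfield (greater Hz) of stop")

    def offsets_hz(self) -> np.ndarray:
        """Irradiation offsets in Hz relative to the free-xenon line,
        ascending (upfield edge first)."""
        start, stop, step = self.grid
        n = int(round((start - stop) / step)) + 1
        return stop + step * np.arange(n)

    def offsets_ppm(self) -> np.ndarray:
        """Irradiation offsets on the ppm axis (xenon gas = 0), ascending."""
        return self.ref_free_xe_ppm + hz_to_ppm(self.offsets_hz(), self.f_obs)


@dataclass(frozen=True)
class ExchangeParams:
    """Mechanistic description of xenon exchange with one host pool.

    k_on : pseudo-first-order rate of xenon entering the host, 1/s
        (the bound-pool fraction times the host association rate).
    k_off : rate of xenon leaving the host, 1/s.
    R2 : transverse relaxation rate of host-bound xenon, 1/s.
    """

    k_on: float
    k_off: float
    R2: float

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0 or self.R2 < 0:
            raise ValueError("exchange rates must be >= 0")


# --------------------------------------------------------------------------
# unit plumbing


def ppm_to_hz(x_ppm, f_obs: float = DEFAULT_F_OBS_HZ):
    """Convert a chemical-shift interval in ppm to Hz: ``hz = x * f_obs * 1e-6``."""
    if f_obs <= 0:
        raise ValueError("f_obs must be > 0")
    return np.multiply(x_ppm, f_obs * 1e-6)


def hz_to_ppm(x_hz, f_obs: float = DEFAULT_F_OBS_HZ):
    """Inverse of :func:`ppm_to_hz`."""
    if f_obs <= 0:
        raise ValueError("f_obs must be > 0")
    return np.divide(x_hz, f_obs * 1e-6)


def _delta_omega(params: ZSpecModelParams, offsets_ppm: np.ndarray, f_obs: float) -> np.ndarray:
    """(n_res, n_offsets) angular frequency differences b_i - x in rad/s."""
    b = np.array([r.b_ppm for r in params.resonances])
    return 2.0 * math.pi * ppm_to_hz(b[:, None] - offsets_ppm[None, :], f_obs)


def _check_offsets(offsets_ppm) -> np.ndarray:
    x = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("offsets must be finite")
    return x


# --------------------------------------------------------------------------
# forward evaluation


def evaluate_zspectrum(
    params: ZSpecModelParams,
    offsets_ppm,
    f_obs: float = DEFAULT_F_OBS_HZ,
) -> np.ndarray:
    """Exact exponential-Lorentzian z-spectrum.

    S(x) = A * prod_i exp(-B_i a_i^2 / (a_i^2 + omega(b_i - x)^2)) with the
    ppm difference converted to rad/s through ``f_obs``.  The empty
    product (no resonances) gives the flat baseline A.
    """
    x = _check_offsets(offsets_ppm)
    if not params.resonances:
        return np.full(x.shape, params.A)
    dw = _delta_omega(params, x, f_obs)
    a = np.array([r.a for r in params.resonances])[:, None]
    B = np.array([r.B for r in params.resonances])[:, None]
    exponent = B * a**2 / (a**2 + dw**2)
    return params.A * np.exp(-exponent.sum(axis=0))


def evaluate_zspectrum_linearized(
    params: ZSpecModelParams,
    offsets_ppm,
    f_obs: float = DEFAULT_F_OBS_HZ,
    strong_index: int | None = None,
) -> np.ndarray:
    """Mixed linearized z-spectrum: weak dips as reflected Lorentzians.

    The strongest resonance keeps its exact exponential; for every other
    resonance ``exp(-L_i)`` is expanded to first order, so those signals
    become plain Lorentzians reflected at the baseline:

        S(x) ~= A * exp(-L_strong(x)) * (1 - sum_{i != strong} L_i(x))

    Valid when the non-strong exponents B_i are small (< 0.2 in the
    fitted spectra); a warning is emitted when some non-strong B_i >= 1.

    Parameters
    ----------
    strong_index : int, optional
        Index into ``params.resonances`` (downfield-to-upfield order) of
        the resonance kept exact.  Default: largest B.
    """
    x = _check_offsets(offsets_ppm)
    if not params.resonances:
        return np.full(x.shape, params.A)
    B = np.array([r.B for r in params.resonances])
    if strong_index is None:
        strong_index = int(np.argmax(B))
    if not 0 <= strong_index < len(B):
        raise ValueError(f"strong_index {strong_index} out of range")
    weak_B = np.delete(B, strong_index)
    if weak_B.size and weak_B.max() >= 1.0:
        warnings.warn(
            "linearized evaluation with non-strong B >= 1: first-order "
            "expansion is inaccurate",
            stacklevel=2,
        )
    dw = _delta_omega(params, x, f_obs)
    a = np.array([r.a for r in params.resonances])[:, None]
    lorentz = B[:, None] * a**2 / (a**2 + dw**2)
    strong = np.exp(-lorentz[strong_index])
    weak = np.delete(lorentz, strong_index, axis=0).sum(axis=0)
    return params.A * strong * (1.0 - weak)


# --------------------------------------------------------------------------
# exchange mechanism -> lineshape parameters


def cest_amplitude(ex: ExchangeParams, acq: AcquisitionParams) -> float:
    """Saturation amplitude B from exchange and acquisition parameters.

    B = t_sat * k_on * omega1^2 / (omega1^2 + k_off^2 + k_off * R2).
    Linear in t_sat and in k_on; zero without RF or without exchange
    into the host.
    """
    denom = acq.omega1**2 + ex.k_off**2 + ex.k_off * ex.R2
    if denom == 0.0:
        if ex.k_on == 0.0:
            return 0.0
        raise ValueError("cest_amplitude undefined: omega1 = k_off = 0")
    return acq.t_sat * ex.k_on * acq.omega1**2 / denom


def cest_width(ex: ExchangeParams, acq: AcquisitionParams) -> float:
    """Angular half-width a (rad/s) of a CEST resonance.

    a = sqrt(omega1^2 + k_off^2 + R2^2 + (R2/k_off) * (omega1^2 + 2*k_off^2))

    This is the saturation-broadened Lorentzian half-width of the
    exchange-mediated depletion rate; it collapses to ``omega1`` when
    k_off = R2 = 0 (pure RF broadening) and is monotone non-decreasing
    in omega1 and in R2.  For R2 > 0 the width diverges as k_off -> 0
    (saturation is never carried out of the host), which is rejected.
    """
    w2 = acq.omega1**2
    if ex.R2 == 0.0:
        a2 = w2 + ex.k_off**2
    elif ex.k_off == 0.0:
        raise ValueError("cest_width diverges: R2 > 0 with k_off = 0")
    else:
        a2 = w2 + ex.k_off**2 + ex.R2**2 + (ex.R2 / ex.k_off) * (w2 + 2.0 * ex.k_off**2)
    if a2 <= 0.0:
        raise ValueError("cest_width undefined: all rates zero")
    return math.sqrt(a2)


def width_high_power_limit(ex: ExchangeParams, acq: AcquisitionParams) -> float:
    """Simplified width valid when the RF amplitude dominates exchange.

    For omega1 >> k_off the k_off^2 terms drop out of :func:`cest_width`:

        a ~= sqrt(omega1^2 + R2^2 + (R2/k_off) * omega1^2)

    displaying the possible dominance of R2 processes over exchange
    broadening.  Warns when k_off is comparable to omega1.
    """
    if ex.k_off > 0 and acq.omega1 < 3.0 * ex.k_off:
        warnings.warn(
            "high-power width requested with k_off comparable to omega1 "
            f"(omega1={acq.omega1:.3g}, k_off={ex.k_off:.3g}); the "
            "simplification drops k_off^2 terms",
            stacklevel=2,
        )
    w2 = acq.omega1**2
    if ex.R2 == 0.0:
        a2 = w2
    elif ex.k_off == 0.0:
        raise ValueError("width diverges: R2 > 0 with k_off = 0")
    else:
        a2 = w2 + ex.R2**2 + (ex.R2 / ex.k_off) * w2
    if a2 <= 0.0:
        raise ValueError("width undefined: all rates zero")
    return math.sqrt(a2)


def koff_from_linewidth(fwhm_hz: float, convention: str = "numeric") -> float:
    """Exchange rate of xenon leaving the host from an observed linewidth.

    In the slow-exchange regime the natural width is negligible against
    exchange broadening, so the bound-xenon linewidth reports k_off.

    convention "numeric" (default) takes the numeric Hz value as the
    rate in 1/s (a 320 Hz line means k_off = 320 1/s); "lorentzian"
    applies the Lorentzian FWHM relation k_off = pi * fwhm.
    """
    if fwhm_hz <= 0:
        raise ValueError("fwhm_hz must be > 0")
    if convention == "numeric":
        return float(fwhm_hz)
    if convention == "lorentzian":
        return math.pi * float(fwhm_hz)
    raise ValueError(f"unknown linewidth convention: {convention!r}")

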