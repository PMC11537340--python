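"""Single-Lorentzian fitting of the direct water saturation line.

In the low-B1, short-saturation regime the water direct-saturation dip of a
Z-spectrum is well approximated by a Lorentzian; its full width at half
maximum (FWHM) grows with exchange-mediated transverse relaxation and is
the quantity tracked by DS-DGE imaging.  Fitting is deterministic bounded
nonlinear least squares with data-driven initialization, so identical input
always yields identical output.

The closed-form linewidth of a single water pool under continuous-wave
saturation,

    LW = (1/pi) * sqrt( (R1 R2^2 + w1^2 R2) / R1 ),   w1 = gamma B1,

is provided both in full and in its low-relaxation approximation
``(w1/pi) sqrt(R2/R1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .bm_core import GAMMA_MHZ_PER_T, GAMMA_RAD_PER_S_PER_UT, ZSpectrum

__all__ = [
    "LorentzianFitResult",
    "lorentzian_model",
    "fit_lorentzian",
    "analytic_lw",
    "DEFAULT_LARMOR_MHZ",
]

#: Larmor frequency at 3 T, MHz (ppm -> Hz conversion).
DEFAULT_LARMOR_MHZ = 3.0 * GAMMA_MHZ_PER_T  # 127.731

_FWHM_BOUNDS_HZ = (1.0, 1000.0)
_CENTER_BOUNDS_PPM = (-1.0, 1.0)
_BASELINE_BOUNDS = (0.8, 1.1)
_AMPLITUDE_BOUNDS = (0.0, 1.5)


@dataclass(frozen=True)
class LorentzianFitResult:
    """Parameters of a fitted single-Lorentzian DS line."""

    amplitude: float
    center_ppm: float
    fwhm_ppm: float
    baseline: float
    residual_rms: float
    converged: bool
    larmor_MHz: float = DEFAULT_LARMOR_MHZ

    @property
    def fwhm_hz(self) -> float:
        return self.fwhm_ppm * self.larmor_MHz


def lorentzian_model(
    offset_ppm, amplitude: float, center_ppm: float, fwhm_ppm: float,
    baseline: float = 1.0,
):
    """Inverted Lorentzian dip evaluated at ``offset_ppm``.

    ``baseline - amplitude`` at the center, ``baseline - amplitude/2`` at
    center +/- fwhm/2, ``baseline`` in the wings.
    """
    hw = fwhm_ppm / 2.0
    x = np.asarray(offset_ppm, dtype=float) - center_ppm
    return baseline - amplitude * hw**2 / (x**2 + hw**2)


def _initial_guess(offsets: np.ndarray, z: np.ndarray,
                   larmor_MHz: float) -> np.ndarray:
    imin = int(np.argmin(z))
    center0 = float(offsets[imin])
    wings = np.abs(offsets) >= 4.0
    baseline0 = float(np.mean(z[wings])) if np.any(wings) else float(np.max(z))
    baseline0 = float(np.clip(baseline0, *_BASELINE_BOUNDS))
    amp0 = float(np.clip(baseline0 - z[imin], *_AMPLITUDE_BOUNDS))

    # half-depth crossing distance on either side of the minimum
    half_level = baseline0 - amp0 / 2.0
    fwhm0 = None
    left = right = None
    for i in range(imin, 0, -1):
        if z[i - 1] >= half_level > z[i]:
            frac = (half_level - z[i]) / (z[i - 1] - z[i])
            left = offsets[i] + frac * (offsets[i - 1] - offsets[i])
            break
    for i in range(imin, len(z) - 1):
        if z[i + 1] >= half_level > z[i]:
            frac = (half_level - z[i]) / (z[i + 1] - z[i])
            right = offsets[i] + frac * (offsets[i + 1] - offsets[i])
            break
    if left is not None and right is not None:
        fwhm0 = float(right - left)
    elif left is not None:
        fwhm0 = 2.0 * float(center0 - left)
    elif right is not None:
        fwhm0 = 2.0 * float(right - center0)
    if fwhm0 is None or fwhm0 <= 0:
        fwhm0 = 60.0 / larmor_MHz  # generic tissue-scale linewidth
    lo, hi = (_FWHM_BOUNDS_HZ[0] / larmor_MHz, _FWHM_BOUNDS_HZ[1] / larmor_MHz)
    fwhm0 = float(np.clip(fwhm0, lo, hi))
    center0 = float(np.clip(center0, *_CENTER_BOUNDS_PPM))
    return np.array([amp0, center0, fwhm0, baseline0])


def fit_lorentzian(
    spec: ZSpectrum,
    larmor_MHz: float = DEFAULT_LARMOR_MHZ,
    fit_window_ppm: float = 5.0,
) -> LorentzianFitResult:
    """Fit a single Lorentzian to a Z-spectrum and report its FWHM.

    Only offsets with ``|offset| <= fit_window_ppm`` enter the fit (the
    +/-10 ppm normalization acquisitions are excluded by default).  The fit
    is deterministic: initialization is computed from the data and bounded
    trust-region least squares does the refinement.
    """
    src = spec.sorted()
    sel = np.abs(src.offsets_ppm) <= fit_window_ppm + 1e-9
    offsets = src.offsets_ppm[sel]
    z = src.intensities[sel]
    if offsets.size < 6:
        raise ValueError("need at least 6 offsets inside the fit window")

    p0 = _initial_guess(offsets, z, larmor_MHz)
    lo = np.array([_AMPLITUDE_BOUNDS[0], _CENTER_BOUNDS_PPM[0],
                   _FWHM_BOUNDS_HZ[0] / larmor_MHz, _BASELINE_BOUNDS[0]])
    hi = np.array([_AMPLITUDE_BOUNDS[1], _CENTER_BOUNDS_PPM[1],
                   _FWHM_BOUNDS_HZ[1] / larmor_MHz, _BASELINE_BOUNDS[1]])
    p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)

    def residual(p):
        return lorentzian_model(offsets, *p) - z

    sol = least_squares(residual, p0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    amp, center, fwhm, base = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    converged = bool(sol.success) and fwhm > 0
    return LorentzianFitResult(
        amplitude=float(amp),
        center_ppm=float(center),
        fwhm_ppm=float(fwhm),
        baseline=float(base),
        residual_rms=rms,
        converged=converged,
        larmor_MHz=larmor_MHz,
    )


def analytic_lw(
    R1_hz: float, R2_hz: float, b1_uT: float,
    gamma_rad_per_s_per_uT: float = GAMMA_RAD_PER_S_PER_UT,
    approximate: bool = False,
) -> float:
    """Closed-form CW direct-saturation linewidth (FWHM, Hz).

    Full form ``(1/pi) sqrt((R1 R2^2 + w1^2 R2)/R1)``; with
    ``approximate=True`` the low-relaxation limit ``(w1/pi) sqrt(R2/R1)``.
    """
    if R1_hz <= 0 or R2_hz <= 0:
        raise ValueError("relaxation rates must be positive")
    if b1_uT < 0:
        raise ValueError("b1 must be non-negative")
    w1 = gamma_rad_per_s_per_uT * b1_uT
    if approximate:
        return (w1 / np.pi) * np.sqrt(R2_hz / R1_hz)
    return (1.0 / np.pi) * np.sqrt((R1_hz * R2_hz**2 + w1**2 * R2_hz) / R1_hz)
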