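"""Raman spectrum preprocessing: baseline removal, area normalization, crop.

Spectra move through a forward-only state machine raw -> baseline_corrected
-> normalized, which mirrors the order required before clustering.  Baseline
estimation uses asymmetric least squares (Whittaker smoother with asymmetric
weights), a standard choice for broad fluorescence-type backgrounds under
narrow Raman bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = ["RamanSpectrum", "baseline_correct", "area_normalize", "crop",
           "asls_baseline"]

_STATES = ("raw", "baseline_corrected", "normalized")


@dataclass
class RamanSpectrum:
    """Intensity versus wavenumber with preprocessing state.

    ``quality`` is "ok" for regular spectra, "blank" when baseline removal
    left no detectable signal, and "failed" when normalization was not
    possible; blank/failed spectra are retained (they form the discarded
    off-target cluster downstream) but flagged.
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    state: str = "raw"
    quality: str = "ok"
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.size != self.intensity.size:
            raise ValueError("axis and intensity must have equal length")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")


def _require_state(spectrum: RamanSpectrum, state: str, op: str) -> None:
    if spectrum.state != state:
        raise ValueError(
            f"{op} requires state {state!r}, got {spectrum.state!r} "
            "(preprocessing is forward-only: raw -> baseline_corrected "
            "-> normalized)")


def asls_baseline(y: np.ndarray, lam: float = 1e7, p: float = 0.001,
                  n_iter: int = 20) -> np.ndarray:
    """Asymmetric least-squares baseline (Whittaker smoother).

    Minimises sum(w_i (y_i - z_i)^2) + lam * sum((D2 z)_i^2) with weights
    w_i = p for points above the baseline and 1 - p below, re-estimated for
    ``n_iter`` rounds.  ``lam`` controls smoothness, ``p`` the asymmetry.
    """
    n = y.size
    if n < 10:
        raise ValueError("spectrum too short for baseline estimation")
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        wmat = sparse.diags(w)
        z = spsolve((wmat + dtd).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(spectrum: RamanSpectrum, lam: float = 1e7,
                     p: float = 0.001, n_iter: int = 20,
                     blank_snr: float = 6.0) -> RamanSpectrum:
    """Subtract the estimated smooth background from a raw spectrum.

    After subtraction, the residual noise level is estimated from the
    first-difference MAD; if no point rises above ``blank_snr`` times that
    level the spectrum carries no detectable bands and is flagged "blank".
    """
    _require_state(spectrum, "raw", "baseline_correct")
    z = asls_baseline(spectrum.intensity, lam=lam, p=p, n_iter=n_iter)
    corrected = spectrum.intensity - z
    d = np.diff(corrected)
    noise = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2)
    quality = spectrum.quality
    # no point above blank_snr x noise, with an absolute floor of 1 % of
    # the raw dynamic range for (near-)noiseless smooth inputs
    floor = max(blank_snr * noise, 0.01 * np.ptp(spectrum.intensity))
    if corrected.max() < floor:
        quality = "blank"
    return replace(spectrum, intensity=corrected,
                   state="baseline_corrected", quality=quality)


def area_normalize(spectrum: RamanSpectrum,
                   method: str = "sum") -> RamanSpectrum:
    """Scale a baseline-corrected spectrum to unit area.

    ``method`` is "sum" (divide by the intensity sum, default) or "trapz"
    (trapezoidal integral over the axis).  A non-positive total area means
    the spectrum has no usable signal: it is flagged "failed" and rescaled
    by its L1 norm instead, so it stays on a comparable scale for
    clustering, where such points collect into the discarded off-target
    cluster.
    """
    _require_state(spectrum, "baseline_corrected", "area_normalize")
    if method == "sum":
        area = float(np.sum(spectrum.intensity))
    elif method == "trapz":
        area = float(np.trapezoid(spectrum.intensity, spectrum.wavenumber))
    else:
        raise ValueError("method must be 'sum' or 'trapz'")
    eps = 1e-3 * float(np.sum(np.abs(spectrum.intensity)))
    if area <= eps:
        l1 = float(np.sum(np.abs(spectrum.intensity)))
        scale = l1 if l1 > 0 else 1.0
        return replace(spectrum, intensity=spectrum.intensity / scale,
                       state="normalized", quality="failed")
    return replace(spectrum, intensity=spectrum.intensity / area,
                   state="normalized")


def crop(spectrum: RamanSpectrum, lo: float = 600.0,
         hi: float = 1800.0) -> RamanSpectrum:
    """Restrict the spectrum to [lo, hi] cm-1 (endpoints inclusive)."""
    if lo >= hi:
        raise ValueError("crop requires lo < hi")
    sel = (spectrum.wavenumber >= lo) & (spectrum.wavenumber <= hi)
    if not np.any(sel):
        raise ValueError("crop range contains no points")
    return replace(spectrum, wavenumber=spectrum.wavenumber[sel],
                   intensity=spectrum.intensity[sel])
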