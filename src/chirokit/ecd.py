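"""ECD spectrum construction, scaling and enantiomer comparison.

Stick transitions (E_i, R_i) are broadened with Gauss-type bands on the
energy axis,

    Δε(E) = 1/(2.297e-39 √π ζ) Σ_i E_i R_i·1e-40 exp(−((E − E_i)/ζ)²),

where ζ (eV) is the 1/e half-width, and rendered on a wavelength grid
(E = 1239.84193/λ).  Conformer spectra are Boltzmann-averaged, an optional
UV shift Δλ translates the curve on the wavelength axis, and amplitude
calibration is removed by dividing the spectrum by the magnitude of its
positive characteristic band near 290 nm:

    Δε_sc(λ) = Δε(λ) / |Δε(λ_peak)|.

Enantiomer assignment compares a scaled theoretical spectrum with a scaled
experimental one by cosine similarity; mirror-image spectra score −1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .conformers import EV_NM, Ensemble, TransitionRecord, WeightVector, boltzmann_weights

__all__ = [
    "BandShapeParams",
    "SpectrumGrid",
    "default_grid",
    "stick_to_spectrum",
    "ensemble_spectrum",
    "apply_uv_shift",
    "scale_spectrum",
    "compare_spectra",
    "assign_enantiomer",
    "theoretical_spectrum",
]

#: Dipole/rotatory strength prefactor in cgs; with R in 1e-40 cgs units the
#: band-area relation becomes ∫Δε/E dE = Σ R_i / 22.97.
_CGS_PREFACTOR = 2.297e-39


@dataclass(frozen=True)
class BandShapeParams:
    """Gaussian bandwidth ζ (eV, 1/e half-width) and UV shift Δλ (nm)."""

    zeta: float = 0.36
    uv_shift: float = 4.0

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass(frozen=True)
class SpectrumGrid:
    """Δε(λ) sampled on a strictly increasing wavelength grid (nm).

    ``provenance`` tags the curve: "theoretical", "experimental" or
    "scaled"; ``scale_peak_nm`` records the λ_peak used when scaled.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    provenance: str = "theoretical"
    scale_peak_nm: Optional[float] = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or wl.shape != v.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(wl <= 0):
            raise ValueError("wavelengths must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum contains non-finite values")

    def __neg__(self) -> "SpectrumGrid":
        return replace(self, values=-self.values)

    def interp(self, wl: np.ndarray) -> np.ndarray:
        """Linear interpolation, edge-held outside the stored range."""
        return np.interp(wl, self.wavelengths, self.values)


def default_grid(start: float = 190.0, stop: float = 400.0, step: float = 1.0) -> np.ndarray:
    """Default wavelength grid: 190–400 nm, 1 nm step."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def stick_to_spectrum(
    transitions: Sequence[TransitionRecord],
    params: BandShapeParams,
    grid: np.ndarray,
) -> SpectrumGrid:
    """Broaden stick transitions into Δε(λ) with Gauss-type bands.

    The sum is evaluated on the energy axis at E = 1239.84193/λ; each band
    is centered at its E_i, signed by its R_i, and the whole construction
    is linear in the rotatory strengths.  The UV shift in ``params`` is NOT
    applied here (see :func:`apply_uv_shift`).
    """
    if len(transitions) == 0:
        raise ValueError("at least one transition is required")
    grid = np.asarray(grid, dtype=float)
    energies = EV_NM / grid  # eV at each grid wavelength
    zeta = params.zeta
    pref = 1.0 / (_CGS_PREFACTOR * math.sqrt(math.pi) * zeta)
    vals = np.zeros_like(grid)
    for t in transitions:
        vals += (
            t.energy_ev
            * (t.rotatory_strength * 1e-40)
            * np.exp(-(((energies - t.energy_ev) / zeta) ** 2))
        )
    return SpectrumGrid(grid, pref * vals, provenance="theoretical")


def ensemble_spectrum(
    ensemble: Ensemble,
    weights: WeightVector,
    params: BandShapeParams,
    grid: np.ndarray,
) -> SpectrumGrid:
    """Statistically averaged spectrum: Σ_i g_i × (conformer i spectrum)."""
    ids = set(ensemble.ids())
    if set(weights) != ids:
        missing = ids.symmetric_difference(weights)
        raise ValueError(f"weights do not match ensemble conformers: {sorted(missing)}")
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for conf in ensemble.conformers:
        spec = stick_to_spectrum(conf.transitions, params, grid)
        total += weights[conf.identifier] * spec.values
    return SpectrumGrid(grid, total, provenance="theoretical")


def apply_uv_shift(spectrum: SpectrumGrid, shift_nm: float) -> SpectrumGrid:
    """Translate the curve by Δλ on the wavelength axis.

    Δε_shifted(λ) = Δε(λ − Δλ), re-sampled on the original grid by linear
    interpolation with edge-held extrapolation.
    """
    if shift_nm == 0:
        return spectrum
    shifted = spectrum.interp(spectrum.wavelengths - shift_nm)
    return replace(spectrum, values=shifted)


def scale_spectrum(
    spectrum: SpectrumGrid,
    reference_band: float = 290.0,
    window_nm: float = 25.0,
) -> SpectrumGrid:
    """Normalize by the positive characteristic band near ``reference_band``.

    Searches ±``window_nm`` around the reference wavelength for a positive
    local maximum (the tallest if several) and divides the whole curve by
    its magnitude, so the selected peak sits at exactly +1.  Scaling is
    idempotent and invariant under multiplication of the input by any
    positive constant.
    """
    wl, v = spectrum.wavelengths, spectrum.values
    peaks, _ = find_peaks(v)
    in_window = [
        p for p in peaks
        if abs(wl[p] - reference_band) <= window_nm and v[p] > 0
    ]
    if not in_window:
        raise ValueError(
            "no positive local maximum in "
            f"[{reference_band - window_nm:g}, {reference_band + window_nm:g}] nm"
        )
    best = max(in_window, key=lambda p: v[p])
    return SpectrumGrid(
        wl, v / abs(v[best]), provenance="scaled", scale_peak_nm=float(wl[best])
    )


def _common_grid(
    a: SpectrumGrid, b: SpectrumGrid, window: Optional[Tuple[float, float]]
) -> np.ndarray:
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    if hi <= lo:
        raise ValueError("spectra have no overlapping wavelength coverage in the window")
    step = min(np.diff(a.wavelengths).min(), np.diff(b.wavelengths).min())
    n = max(int(round((hi - lo) / step)), 1)
    return np.linspace(lo, hi, n + 1)


def compare_spectra(
    a: SpectrumGrid,
    b: SpectrumGrid,
    window: Optional[Tuple[float, float]] = (200.0, 400.0),
) -> float:
    """Cosine similarity of two spectra on a common grid in ``window``.

    +1 for proportional curves of the same sign, −1 for mirror images,
    0 for orthogonal shapes.
    """
    grid = _common_grid(a, b, window)
    va, vb = a.interp(grid), b.interp(grid)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cannot compare an identically zero spectrum")
    return float(np.dot(va, vb) / (na * nb))


def assign_enantiomer(
    theoretical: SpectrumGrid,
    experimental: SpectrumGrid,
    window: Optional[Tuple[float, float]] = (200.0, 400.0),
    tie_tolerance: float = 1e-12,
) -> Tuple[str, float]:
    """Decide which enantiomer the experimental spectrum matches.

    Compares the experimental curve against the modeled spectrum and its
    mirror image (all rotatory strengths negated, i.e. the pointwise
    negation).  Returns ``("as-modeled", score)`` when the modeled
    enantiomer fits at least as well, ``("mirror", score)`` otherwise;
    the score is the winning similarity.  A tie within ``tie_tolerance``
    raises ``UndecidableError``.
    """
    s = compare_spectra(theoretical, experimental, window)
    if abs(s) < tie_tolerance:
        raise UndecidableError(
            f"similarities for the two enantiomers differ by {2 * abs(s):.2e}"
        )
    return ("as-modeled", s) if s > 0 else ("mirror", -s)


class UndecidableError(ValueError):
    """Raised when the two enantiomer hypotheses fit equally well."""


def theoretical_spectrum(
    ensemble: Ensemble,
    params: BandShapeParams,
    grid: Optional[np.ndarray] = None,
    cutoff: float = 4.0,
    weights: Optional[WeightVector] = None,
) -> SpectrumGrid:
    """Full modeling pipeline: ΔG cutoff → Boltzmann weights → average → UV shift.

    Convenience wrapper tying the conformer bookkeeping to band-shape
    construction; ``weights`` overrides the Boltzmann weights (for
    class-mixture reweighting) and must then match the post-cutoff ensemble.
    """
    from .conformers import select_conformers

    if grid is None:
        grid = default_grid()
    kept = select_conformers(ensemble, cutoff)
    if weights is None:
        weights = boltzmann_weights(kept)
    spec = ensemble_spectrum(kept, weights, params, grid)
    return apply_uv_shift(spec, params.uv_shift)
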