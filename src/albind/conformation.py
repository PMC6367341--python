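"""Protein conformation readouts: CD helicity and synchronous-fluorescence shifts.

Circular dichroism ellipticity θ (mdeg) is normalised to mean residue
ellipticity

    MRE = θ / (10 · C_p · n_res · l)      [deg·cm²·dmol⁻¹]

with C_p the molar protein concentration, n_res the residue count and l
the path length in cm.  The α-helix fraction follows from the 208 nm
value between the random-coil (−4000) and pure-helix (−33000)
references:

    α-helix (%) = (−MRE₂₀₈ − 4000) / (33000 − 4000) × 100.

Synchronous fluorescence scanned at Δλ = 15 or 60 nm probes the tyrosine
and tryptophan microenvironments; a blue/red shift of the emission
maximum on ligand binding reports polarity changes around those residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CDSpectrum", "SyncSpectrum", "mre", "helix_fraction", "helix_change",
    "peak_shift",
]

MRE_RANDOM_COIL = -4000.0   # deg cm^2 dmol^-1 at 208 nm
MRE_PURE_HELIX = -33000.0


@dataclass(frozen=True)
class CDSpectrum:
    """CD spectrum with the metadata needed for MRE normalisation."""

    wavelength: np.ndarray   # nm, ascending
    theta: np.ndarray        # ellipticity, mdeg
    C_p: float               # protein concentration, mol/L
    n_res: int               # residues per protein
    path_length: float       # cm
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "theta", th)
        if wl.shape != th.shape or wl.ndim != 1:
            raise ValueError("wavelength and theta must be 1-D arrays of equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be ascending")
        if wl[0] < 185 or wl[-1] > 300:
            raise ValueError("wavelengths must lie within [185, 300] nm")
        if self.C_p <= 0 or self.n_res <= 0 or self.path_length <= 0:
            raise ValueError("C_p, n_res and path length must be positive")

    def mre_at(self, wavelength_nm: float) -> float:
        """MRE at the grid point nearest ``wavelength_nm``."""
        if not self.wavelength[0] <= wavelength_nm <= self.wavelength[-1]:
            raise ValueError(f"{wavelength_nm} nm outside the measured range")
        i = int(np.argmin(np.abs(self.wavelength - wavelength_nm)))
        return mre(float(self.theta[i]), self.C_p, self.n_res, self.path_length)


@dataclass(frozen=True)
class SyncSpectrum:
    """Synchronous fluorescence scan at fixed Δλ (15 nm: Tyr, 60 nm: Trp)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    delta_lambda: int

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", it)
        if self.delta_lambda not in (15, 60):
            raise ValueError("delta_lambda must be 15 or 60 nm")
        if wl.shape != it.shape or wl.ndim != 1:
            raise ValueError("wavelength and intensity must match")


def mre(theta_mdeg: float, C_p: float, n_res: int, path_length_cm: float) -> float:
    """Mean residue ellipticity, θ/(10·C_p·n_res·l), deg·cm²·dmol⁻¹."""
    if C_p <= 0 or n_res <= 0 or path_length_cm <= 0:
        raise ValueError("C_p, n_res and path length must be positive")
    return theta_mdeg / (C_p * n_res * path_length_cm * 10.0)


def helix_fraction(mre_208: float) -> float:
    """α-helix percentage from the 208 nm mean residue ellipticity.

    Linear interpolation between the random-coil (−4000) and pure-helix
    (−33000) MRE references.  Values outside [0, 100] are returned
    unclipped with a warning — they flag inconsistent inputs rather than
    being silently hidden.
    """
    if not np.isfinite(mre_208):
        raise ValueError("MRE must be finite")
    pct = (-mre_208 + MRE_RANDOM_COIL) / (MRE_RANDOM_COIL - MRE_PURE_HELIX) * 100.0
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"helix fraction {pct:.2f}% outside [0, 100]")
    return float(pct)


def helix_change(spectra) -> list:
    """α-helix content per spectrum and change vs the first (reference).

    Returns a list of dicts ``{label, helix_percent, delta_vs_reference}``
    using each spectrum's MRE at the grid point nearest 208 nm.
    """
    spectra = list(spectra)
    if len(spectra) < 2:
        raise ValueError("helix_change needs at least 2 spectra")
    out = []
    ref = None
    for sp in spectra:
        pct = helix_fraction(sp.mre_at(208.0))
        if ref is None:
            ref = pct
        out.append({
            "label": sp.label,
            "helix_percent": pct,
            "delta_vs_reference": pct - ref,
        })
    return out


def _interpolated_argmax(x: np.ndarray, y: np.ndarray) -> float:
    """Peak position by 3-point quadratic interpolation around the max bin."""
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i])
    offset = 0.5 * (y0 - y2) / denom
    return float(x[i] + offset * (x[1] - x[0]))


def peak_shift(reference: SyncSpectrum, perturbed: SyncSpectrum,
               threshold_nm: float = 0.5):
    """Emission-maximum shift between two synchronous spectra.

    Returns ``(delta_lambda_max, direction)`` with direction "blue" for
    shifts below −``threshold_nm``, "red" above +``threshold_nm``, else
    "none".  Peak positions use quadratic interpolation so sub-grid
    shifts are resolved.
    """
    if reference.delta_lambda != perturbed.delta_lambda:
        raise ValueError("spectra were scanned at different delta_lambda")
    if (reference.wavelength.shape != perturbed.wavelength.shape
            or not np.allclose(reference.wavelength, perturbed.wavelength)):
        raise ValueError("wavelength grids do not match")
    lam_ref = _interpolated_argmax(reference.wavelength, reference.intensity)
    lam_per = _interpolated_argmax(perturbed.wavelength, perturbed.intensity)
    shift = lam_per - lam_ref
    if shift < -threshold_nm:
        direction = "blue"
    elif shift > threshold_nm:
        direction = "red"
    else:
        direction = "none"
    return shift, direction
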