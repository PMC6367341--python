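"""Binding thermodynamics from the temperature dependence of K_a.

ΔG = −RT ln K_a at each temperature, and a van't Hoff regression of
ln K_a on 1/T yields ΔH (from the slope) and ΔS (from the intercept):

    ln K_a = −ΔH/(R T) + ΔS/R

The signs of ΔH and ΔS indicate the dominant non-covalent driving force
(Ross–Subramanian sign rules): ΔH < 0 with ΔS > 0 → electrostatic,
ΔH < 0 with ΔS < 0 → hydrogen bonding / van der Waals, ΔH > 0 with
ΔS > 0 → hydrophobic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

R_GAS = 8.314  # J mol^-1 K^-1

__all__ = ["R_GAS", "ThermoResult", "delta_g", "vant_hoff_fit", "classify_forces"]


@dataclass(frozen=True)
class ThermoResult:
    """van't Hoff fit results.

    ``delta_G`` maps each input temperature (K) to ΔG in kJ/mol computed
    from its K_a; ΔH is in kJ/mol, ΔS in J/mol/K, standard errors from
    the regression.
    """

    delta_H: float
    delta_H_stderr: float
    delta_S: float
    delta_S_stderr: float
    delta_G: dict  # {T_kelvin: kJ/mol}
    r_squared: float
    force_label: str
    spontaneous: dict = field(default_factory=dict)  # {T: bool}


def delta_g(K_a: float, T: float) -> float:
    """Gibbs free energy of binding, ΔG = −RT ln K_a, in kJ/mol."""
    if K_a <= 0 or T <= 0:
        raise ValueError("K_a and T must be positive")
    return -R_GAS * T * np.log(K_a) / 1000.0


def vant_hoff_fit(points) -> ThermoResult:
    """Fit ln K_a against 1/T to estimate ΔH and ΔS.

    Parameters
    ----------
    points : sequence of (T_kelvin, K_a) pairs
        At least two distinct temperatures.  Duplicate temperatures are
        collapsed to their mean ln K_a with a warning.

    Notes
    -----
    The regression uses natural log (thermodynamically exact; the slope
    converts base-independently to ΔH).  ΔS comes from the intercept, a
    single authoritative estimate rather than (ΔH − ΔG)/T at one
    temperature.  The fit is unweighted: printed K_a uncertainties are
    not propagated.
    """
    T = np.array([p[0] for p in points], dtype=float)
    K = np.array([p[1] for p in points], dtype=float)
    if np.any(T <= 0) or np.any(K <= 0):
        raise ValueError("temperatures and K_a must be positive")
    uniq = np.unique(T)
    if uniq.size < 2:
        raise ValueError("van't Hoff fit needs at least 2 distinct temperatures")
    if uniq.size < T.size:
        warnings.warn("duplicate temperatures collapsed to mean ln K_a")
        lnK = np.array([np.mean(np.log(K[T == t])) for t in uniq])
        T_fit = uniq
    else:
        lnK, T_fit = np.log(K), T
    res = stats.linregress(1.0 / T_fit, lnK)
    dH = -R_GAS * res.slope / 1000.0           # kJ/mol
    dS = R_GAS * res.intercept                 # J/mol/K
    dH_se = R_GAS * (res.stderr or 0.0) / 1000.0
    dS_se = R_GAS * (res.intercept_stderr or 0.0)
    dG = {float(t): delta_g(k, t) for t, k in zip(T, K)}
    r2 = res.rvalue ** 2
    if not np.isfinite(r2):  # constant ln K_a: zero slope fits exactly
        r2 = 1.0
    return ThermoResult(
        delta_H=dH, delta_H_stderr=dH_se,
        delta_S=dS, delta_S_stderr=dS_se,
        delta_G=dG, r_squared=r2,
        force_label=classify_forces(dH, dS),
        spontaneous={t: g < 0 for t, g in dG.items()},
    )


def classify_forces(delta_H: float, delta_S: float) -> str:
    """Dominant interaction force from the signs of ΔH (kJ/mol) and ΔS (J/mol/K)."""
    if not (np.isfinite(delta_H) and np.isfinite(delta_S)):
        raise ValueError("delta_H and delta_S must be finite")
    if delta_H < 0 and delta_S > 0:
        return "electrostatic"
    if delta_H < 0 and delta_S < 0:
        return "hydrogen_bond_vdw"
    if delta_H > 0 and delta_S > 0:
        return "hydrophobic"
    return "mixed"
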