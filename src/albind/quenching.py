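"""Fluorescence-quenching titration analysis.

A fluorophore-bearing protein (here serum albumin, whose tryptophan
emission is quenched on ligand binding) is titrated with increasing
quencher concentration [Q] at fixed protein concentration.  Two linear
stages are fitted on the inner-filter-corrected intensities:

* Stern–Volmer:      F0/F = 1 + K_SV [Q]
* double-logarithm:  log10((F0 − F)/F) = log10 K_a + n log10 [Q]

K_SV is the Stern–Volmer quenching constant, K_a the association
(binding) constant and n the Hill coefficient.  The temperature trend of
K_SV together with fluorescence-lifetime invariance classifies the
quenching mechanism as static (ground-state complex) or dynamic
(collisional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TitrationSeries", "QuenchingResult", "BindingResult",
    "correct_inner_filter", "concentration_from_absorbance",
    "fit_stern_volmer", "fit_double_log", "classify_mechanism",
    "classify_affinity",
]


@dataclass(frozen=True)
class TitrationSeries:
    """One temperature's fluorescence titration.

    Parameters
    ----------
    temperature : float
        Kelvin.
    Q : ndarray
        Quencher concentrations, mol/L, non-negative and strictly
        increasing; exactly one zero entry (the reference point).
    F : ndarray
        Fluorescence intensities (arbitrary units), positive.
    A_ex, A_em : ndarray
        Per-point absorbances at the excitation and emission wavelengths,
        used for inner-filter correction; zero when not measured.
    """

    temperature: float
    Q: np.ndarray
    F: np.ndarray
    A_ex: np.ndarray = None
    A_em: np.ndarray = None
    corrected: bool = False

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "F", F)
        for name in ("A_ex", "A_em"):
            a = getattr(self, name)
            a = np.zeros_like(Q) if a is None else np.asarray(a, dtype=float)
            object.__setattr__(self, name, a)
        if self.temperature <= 0:
            raise ValueError("temperature must be in kelvin and positive")
        if Q.shape != F.shape or Q.ndim != 1:
            raise ValueError("Q and F must be 1-D arrays of equal length")
        if np.any(Q < 0):
            raise ValueError("quencher concentrations must be non-negative")
        if np.any(np.diff(Q) <= 0):
            raise ValueError("quencher concentrations must be strictly increasing")
        if np.count_nonzero(Q == 0) != 1:
            raise ValueError("no reference intensity: exactly one [Q]=0 row required")
        if np.any(F <= 0):
            raise ValueError("intensities must be positive")
        if np.any(self.A_ex < 0) or np.any(self.A_em < 0):
            raise ValueError("absorbances must be non-negative")

    @property
    def F0(self) -> float:
        """Reference intensity at [Q] = 0."""
        return float(self.F[self.Q == 0][0])

    def correct_inner_filter(self) -> "TitrationSeries":
        """Return a new series with inner-filter-corrected intensities."""
        F_corr = correct_inner_filter(self.F, self.A_ex, self.A_em)
        return replace(self, F=F_corr, corrected=True)


@dataclass(frozen=True)
class QuenchingResult:
    """Stern–Volmer fit: K_SV (L/mol) with standard error, intercept, R²."""

    K_SV: float
    K_SV_stderr: float
    intercept: float
    r_squared: float
    temperature: float

    def __post_init__(self):
        if not np.isfinite(self.K_SV):
            raise ValueError("K_SV must be finite")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class BindingResult:
    """Double-log fit: association constant K_a (L/mol) and Hill coefficient n."""

    K_a: float
    K_a_stderr: float
    n: float
    n_stderr: float
    temperature: float
    r_squared: float = field(default=np.nan)

    def __post_init__(self):
        if self.K_a <= 0:
            raise ValueError("K_a must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")


def correct_inner_filter(F_obs, A_ex, A_em):
    """Inner-filter correction F_corr = F_obs · exp((A_ex + A_em)/2).

    Absorption of the excitation beam and re-absorption of the emitted
    light attenuate the observed intensity; the multiplicative factor
    restores the intensity that would be seen in a non-absorbing sample.
    """
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValueError("absorbances must be non-negative")
    return F_obs * np.exp((A_ex + A_em) / 2.0)


def concentration_from_absorbance(A, epsilon, path_length_cm=1.0):
    """Beer–Lambert concentration c = A / (ε · l), mol/L.

    ``epsilon`` is the molar extinction coefficient in L·mol⁻¹·cm⁻¹
    (36 850 for serum albumin at 280 nm).
    """
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    if path_length_cm <= 0:
        raise ValueError("path length must be positive")
    return A / (epsilon * path_length_cm)


def _linregress(x, y):
    """OLS of y on x with heteroscedasticity-consistent (HC3) standard errors.

    Both regressions here run on transformed variables (F0/F and
    log-ratios) whose noise is strongly non-uniform across the quencher
    range, so the classical homoscedastic standard errors undercover;
    HC3 is the standard small-sample robust choice.  The point estimates
    are plain OLS either way.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    XtXi = np.linalg.inv(X.T @ X)
    beta = XtXi @ X.T @ y
    resid = y - X @ beta
    leverage = np.einsum("ij,jk,ik->i", X, XtXi, X)
    u = resid / (1.0 - leverage)
    cov = XtXi @ (X.T * u ** 2) @ X @ XtXi
    se_intercept, se_slope = np.sqrt(np.diag(cov))
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        r2 = 1.0 if np.allclose(resid, 0.0) else 0.0
    else:
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
    return beta[1], beta[0], se_slope, se_intercept, r2


def fit_stern_volmer(series: TitrationSeries) -> QuenchingResult:
    """Ordinary least squares of F0/F on [Q]; the slope is K_SV.

    The [Q] = 0 point is excluded (its ratio is 1 by construction) and the
    intercept is left free; an intercept far from 1 flags a miscalibrated
    reference intensity.
    """
    mask = series.Q > 0
    Q = series.Q[mask]
    ratio = series.F0 / series.F[mask]
    if Q.size < 3:
        raise ValueError("Stern-Volmer fit needs at least 3 nonzero-[Q] points")
    if not np.all(np.isfinite(ratio)):
        raise ValueError("non-finite F0/F ratio")
    slope, intercept, se, _, r2 = _linregress(Q, ratio)
    return QuenchingResult(
        K_SV=slope, K_SV_stderr=se, intercept=intercept,
        r_squared=r2, temperature=series.temperature,
    )


def fit_double_log(series: TitrationSeries) -> BindingResult:
    """Double-logarithm binding fit (base 10).

    OLS of log10((F0 − F)/F) on log10[Q]; the intercept gives
    K_a = 10^intercept and the slope the Hill coefficient n.  Points with
    F ≥ F0 at [Q] > 0 (no net quenching, typically low-quencher noise)
    are dropped with a warning.
    """
    F0 = series.F0
    mask = series.Q > 0
    Q, F = series.Q[mask], series.F[mask]
    bad = F >= F0
    if np.any(bad):
        warnings.warn(
            f"dropping {int(bad.sum())} point(s) with F >= F0 from double-log fit"
        )
        Q, F = Q[~bad], F[~bad]
    if Q.size < 3:
        raise ValueError("double-log fit needs at least 3 usable points")
    x = np.log10(Q)
    y = np.log10((F0 - F) / F)
    slope, intercept, se_slope, se_intercept, r2 = _linregress(x, y)
    K_a = 10.0 ** intercept
    # delta method: se(K_a) = K_a ln(10) se(intercept)
    K_a_se = K_a * np.log(10.0) * se_intercept
    return BindingResult(
        K_a=K_a, K_a_stderr=K_a_se, n=slope, n_stderr=se_slope,
        temperature=series.temperature, r_squared=r2,
    )


def classify_mechanism(ksv_by_T, lifetime_change=None, tolerance=0.05) -> str:
    """Classify the quenching mechanism from the K_SV–temperature trend.

    Static quenching (ground-state complex) weakens on heating, so K_SV
    decreases with temperature and the excited-state lifetime is
    unaffected; dynamic (collisional) quenching strengthens on heating
    and shortens the lifetime.

    Parameters
    ----------
    ksv_by_T : sequence of QuenchingResult
    lifetime_change : float or None
        Relative change of the amplitude-weighted lifetime on binding,
        e.g. +0.017 for +1.7%; None when no lifetime data exist.
    tolerance : float
        Relative lifetime change below which the lifetime counts as
        unaffected (default 5%).

    Returns
    -------
    {"static", "dynamic", "inconclusive"}
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    results = sorted(ksv_by_T, key=lambda r: r.temperature)
    ksv = [r.K_SV for r in results]
    if len(ksv) < 2:
        return "inconclusive"
    decreasing = all(b < a for a, b in zip(ksv, ksv[1:]))
    increasing = all(b > a for a, b in zip(ksv, ksv[1:]))
    if decreasing and (lifetime_change is None or abs(lifetime_change) < tolerance):
        return "static"
    if increasing and lifetime_change is not None and lifetime_change < -tolerance:
        return "dynamic"
    return "inconclusive"


def classify_affinity(K_a: float) -> str:
    """Bin K_a into weak (<10³), moderate (10³–10⁶) or strong (>10⁶ L/mol)."""
    if K_a <= 0:
        raise ValueError("K_a must be positive")
    if K_a < 1e3:
        return "weak"
    if K_a <= 1e6:
        return "moderate"
    return "strong"
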