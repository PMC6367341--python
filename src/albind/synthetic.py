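"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is the exact inverse of its analysis stage in the
noiseless limit, so recovered parameters can be compared against the
planted truth.  Defaults emulate the study conditions of a moderate-
affinity dye–albumin system: 2 µM protein titrated with 0–6 µM ligand
at 298/304/310 K, K_SV ≈ 1.26×10⁵ L/mol and K_a ≈ 1.14×10⁵ L/mol at
298 K, tri-exponential tryptophan decays with τ_avg ≈ 5.6 ns, ~52%
α-helix, site-I binding, and an MD-like RMSD/Rg plateau near
3.4 Å / 27.6 Å.

All randomness flows through a ``numpy.random.Generator`` derived from
an explicit seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quenching import TitrationSeries
from .lifetime import DecayHistogram
from .competition import CompetitionSeries, PROBE_SITES
from .conformation import CDSpectrum, SyncSpectrum, mre
from .structure import StructureModel, Trajectory
from .thermo import R_GAS

__all__ = [
    "GroundTruth", "gen_titration", "gen_titration_dynamic", "gen_decay",
    "gen_cd", "gen_sync", "gen_competition", "gen_trajectory",
    "ka_from_thermo",
]

DEFAULT_Q_GRID = np.arange(0.0, 7.0) * 1e-6  # 0..6 µM ligand
DEFAULT_TEMPERATURES = (298.0, 304.0, 310.0)


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters shared by the generators (study-condition defaults)."""

    temperatures: tuple = DEFAULT_TEMPERATURES
    K_SV: tuple = (1.26e5, 1.11e5, 1.00e5)        # L/mol per temperature
    K_a: tuple = (1.14e5, 1.03e5, 0.85e5)         # L/mol per temperature
    n_hill: float = 1.0
    delta_H: float = -18.78                        # kJ/mol
    delta_S: float = 33.92                         # J/mol/K
    lifetime_free: tuple = ((3.09, 0.31), (4.72, 0.04), (6.83, 0.65))
    lifetime_bound: tuple = ((3.23, 0.33), (5.32, 0.03), (6.96, 0.64))
    helix_percent: tuple = (52.08, 49.25, 47.69)   # per molar ratio 1:0, 1:1, 1:3
    planted_site: str = "site_I"
    plateau_rmsd: float = 3.4                      # Å
    plateau_rg: float = 27.6                       # Å
    seed: int = 0

    def __post_init__(self):
        if any(k <= 0 for k in self.K_SV + self.K_a):
            raise ValueError("equilibrium constants must be positive")
        for comps in (self.lifetime_free, self.lifetime_bound):
            if abs(sum(a for _, a in comps) - 1.0) > 1e-6:
                raise ValueError("lifetime amplitudes must sum to 1")
        if any(not 0 <= h <= 100 for h in self.helix_percent):
            raise ValueError("helix percentages must lie in [0, 100]")


def ka_from_thermo(delta_H_kJ: float, delta_S_J: float, T: float) -> float:
    """K_a implied by ΔH and ΔS at temperature T (inverse van't Hoff)."""
    lnK = (-delta_H_kJ * 1000.0 / T + delta_S_J) / R_GAS
    return float(np.exp(lnK))


def gen_titration(K: float, n: float = 1.0, temperature: float = 298.0,
                  F0: float = 1000.0, Q_grid=None, noise_cv: float = 0.0,
                  ife_coeffs: tuple = None, seed: int = 0) -> TitrationSeries:
    """Static-quenching titration F = F0 / (1 + K [Q]^n).

    ``ife_coeffs = (c_ex, c_em)`` adds a simulated inner-filter effect:
    absorbances grow linearly with [Q] (A = c·[Q]) and the observed
    intensity is attenuated by exp(−(A_ex+A_em)/2), exactly what the
    correction removes.  ``noise_cv`` applies multiplicative Gaussian
    noise to the nonzero-[Q] intensities.
    """
    rng = np.random.default_rng(seed)
    Q = DEFAULT_Q_GRID.copy() if Q_grid is None else np.asarray(Q_grid, float)
    with np.errstate(divide="ignore"):
        F = F0 / (1.0 + K * np.where(Q > 0, Q, 0.0) ** n)
    F[Q == 0] = F0
    if ife_coeffs is not None:
        c_ex, c_em = ife_coeffs
        A_ex, A_em = c_ex * Q, c_em * Q
        F = F * np.exp(-(A_ex + A_em) / 2.0)
    else:
        A_ex = A_em = np.zeros_like(Q)
    if noise_cv > 0:
        mult = 1.0 + noise_cv * rng.standard_normal(Q.size)
        mult[Q == 0] = 1.0  # reference intensity kept exact
        F = F * np.abs(mult)
    return TitrationSeries(temperature=temperature, Q=Q, F=F,
                           A_ex=A_ex, A_em=A_em)


def gen_titration_dynamic(K_SV_by_T=None, temperatures=DEFAULT_TEMPERATURES,
                          **kwargs):
    """Collisional-quenching contrast case: K_SV *increases* with temperature.

    Produces one series per temperature with K_SV rising (diffusion
    speeds up on heating); used to exercise the "dynamic" branch of the
    mechanism classifier, whose lifetime evidence must come from a
    matching shortened-lifetime decay.
    """
    if K_SV_by_T is None:
        K_SV_by_T = (1.00e5, 1.13e5, 1.26e5)
    return [
        gen_titration(K=k, temperature=T, seed=kwargs.pop("seed", 0) + i,
                      **kwargs)
        for i, (T, k) in enumerate(zip(temperatures, K_SV_by_T))
    ]


def gen_decay(components, peak_counts: float = 1e4, n_channels: int = 1024,
              channel_width: float = 0.05, baseline: float = 0.0,
              poisson: bool = True, seed: int = 0) -> DecayHistogram:
    """TCSPC decay histogram from (τ_i, α_i) components.

    Expected counts μ(t) = baseline + s·Σ α_i exp(−t/τ_i) with s chosen
    so the peak expectation equals ``peak_counts``; counts are drawn
    Poisson(μ) (or equal μ exactly with ``poisson=False`` for noiseless
    oracle tests).
    """
    if peak_counts < 100:
        raise ValueError("peak_counts must be at least 100")
    rng = np.random.default_rng(seed)
    t = np.arange(n_channels, dtype=float) * channel_width
    taus = np.array([c[0] for c in components], float)
    alphas = np.array([c[1] for c in components], float)
    decay = np.sum(alphas[None, :] * np.exp(-t[:, None] / taus[None, :]), axis=1)
    scale = peak_counts / decay.max()
    mu = baseline + scale * decay
    counts = rng.poisson(mu).astype(float) if poisson else mu
    return DecayHistogram(t=t, counts=counts)


# Two-Gaussian far-UV template: minima at 208 nm (π→π*) and 220 nm (n→π*)
_CD_CENTERS = (208.0, 220.0)
_CD_WIDTHS = (6.5, 8.0)
_CD_WEIGHTS = (1.0, 0.95)


def gen_cd(helix_percent: float, C_p: float = 2e-6, n_res: int = 585,
           path_length: float = 1.0, wavelengths=None,
           noise_mdeg: float = 0.0, label: str = "", seed: int = 0) -> CDSpectrum:
    """CD spectrum whose 208 nm MRE encodes the requested helix content.

    A smooth two-minimum template (208/220 nm) is scaled so that
    MRE(208) = −(4000 + 290·helix_percent) — the exact inverse of the
    helix estimator — then converted to machine ellipticity in mdeg.
    """
    if not 0 <= helix_percent <= 100:
        raise ValueError("helix_percent must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    wl = (np.arange(190.0, 260.5, 0.5) if wavelengths is None
          else np.asarray(wavelengths, float))
    template = sum(
        w * np.exp(-((wl - c) ** 2) / (2 * s ** 2))
        for c, s, w in zip(_CD_CENTERS, _CD_WIDTHS, _CD_WEIGHTS)
    )
    t208 = sum(
        w * np.exp(-((208.0 - c) ** 2) / (2 * s ** 2))
        for c, s, w in zip(_CD_CENTERS, _CD_WIDTHS, _CD_WEIGHTS)
    )
    target_mre_208 = -(4000.0 + 290.0 * helix_percent)
    mre_curve = template * (target_mre_208 / t208)
    theta = mre_curve * (C_p * n_res * path_length * 10.0)
    if noise_mdeg > 0:
        theta = theta + noise_mdeg * rng.standard_normal(wl.size)
    return CDSpectrum(wavelength=wl, theta=theta, C_p=C_p, n_res=n_res,
                      path_length=path_length, label=label)


def gen_sync(delta_lambda: int = 15, peak_nm: float = 285.0,
             shift_nm: float = 0.0, width_nm: float = 10.0,
             amplitude: float = 100.0, wavelengths=None,
             noise: float = 0.0, seed: int = 0) -> SyncSpectrum:
    """Gaussian synchronous-fluorescence band, optionally translated by ``shift_nm``."""
    rng = np.random.default_rng(seed)
    wl = (np.arange(250.0, 320.5, 0.5) if wavelengths is None
          else np.asarray(wavelengths, float))
    intensity = amplitude * np.exp(
        -((wl - (peak_nm + shift_nm)) ** 2) / (2 * width_nm ** 2))
    if noise > 0:
        intensity = intensity + noise * rng.standard_normal(wl.size)
    return SyncSpectrum(wavelength=wl, intensity=intensity,
                        delta_lambda=delta_lambda)


DEFAULT_COMPETITION_PROFILE = {
    # probe: (total drop of I over the ratio range, curve shape)
    "warfarin": (0.35, "linear"),
    "ibuprofen": (0.03, "linear"),
    "dansyl-L-sarcosine": (0.12, "step"),
}


def gen_competition(profile=None, ratios=None, F0: float = 100.0,
                    noise: float = 0.0, seed: int = 0):
    """Displacement curves per probe from planted drops and shapes.

    Shapes: ``linear`` (steady decline, same-site displacement), ``flat``
    (no effect) and ``step`` (drop at the first addition then flat — the
    cooperative-binding signature).  Returns one
    :class:`CompetitionSeries` per probe.
    """
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = DEFAULT_COMPETITION_PROFILE
    if ratios is None:
        ratios = np.concatenate([[0.0], np.arange(0.5, 3.01, 0.5)])
    ratios = np.asarray(ratios, float)
    out = []
    for probe, (drop, shape) in sorted(profile.items()):
        if not 0 <= drop <= 1:
            raise ValueError("drops must lie in [0, 1]")
        if shape == "linear":
            I = 1.0 - drop * ratios / ratios[-1]
        elif shape == "flat":
            I = np.ones_like(ratios)
        elif shape == "step":
            I = np.where(ratios > 0, 1.0 - drop, 1.0)
        else:
            raise ValueError(f"unknown shape {shape!r}")
        if noise > 0:
            jitter = noise * rng.standard_normal(ratios.size)
            jitter[0] = 0.0
            I = I + jitter
        out.append(CompetitionSeries(
            probe_name=probe, probe_site=PROBE_SITES[probe],
            ratios=ratios, F=F0 * I,
        ))
    return out


def gen_trajectory(n_atoms: int = 120, n_frames: int = 121,
                   plateau_rmsd: float = 3.4, plateau_rg: float = 27.6,
                   ramp_fraction: float = 0.4, dt_ps: float = 500.0,
                   seed: int = 0):
    """Reference structure plus a trajectory with a planted RMSD plateau.

    The reference is a compact Gaussian coil rescaled to the requested
    Rg.  Frame k adds isotropic Gaussian displacement whose standard
    deviation ramps linearly over the first ``ramp_fraction`` of the run
    and then holds at plateau_rmsd/√3, plus a random rigid motion that
    the analysis must undo by superposition.  Returns
    ``(StructureModel, Trajectory)``.
    """
    if plateau_rmsd < 0 or plateau_rg <= 0:
        raise ValueError("plateau_rg must be positive and plateau_rmsd non-negative")
    rng = np.random.default_rng(seed)
    # superposition absorbs ~7 of the 3N noise degrees of freedom; inflate
    # sigma so the post-fit RMSD plateau is centred on the requested value
    dof_factor = np.sqrt(1.0 - 7.0 / (3.0 * n_atoms))
    sigma_plateau = plateau_rmsd / np.sqrt(3.0) / dof_factor
    # isotropic noise inflates the apparent Rg; shrink the reference so the
    # plateau-frame Rg is centred on the requested value
    rg_ref_sq = plateau_rg ** 2 - 3 * sigma_plateau ** 2 * (1 - 1.0 / n_atoms)
    if rg_ref_sq <= 0:
        raise ValueError("plateau_rg too small for the requested plateau_rmsd")
    ref = rng.standard_normal((n_atoms, 3))
    ref -= ref.mean(axis=0)
    ref *= np.sqrt(rg_ref_sq) / np.sqrt(np.mean(np.sum(ref ** 2, axis=1)))
    frames = np.empty((n_frames, n_atoms, 3))
    ramp_end = max(1, int(round(ramp_fraction * (n_frames - 1))))
    for k in range(n_frames):
        sigma = sigma_plateau * min(1.0, k / ramp_end)
        displaced = ref + sigma * rng.standard_normal((n_atoms, 3))
        # random rigid motion (QR-orthogonalised rotation + translation)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        frames[k] = displaced @ Q.T + rng.uniform(-20, 20, 3)
    times = np.arange(n_frames, dtype=float) * dt_ps
    model = StructureModel(
        coords=ref,
        elements=np.full(n_atoms, "C"),
        names=np.full(n_atoms, "CA"),
        res_names=np.full(n_atoms, "ALA"),
        res_ids=np.arange(1, n_atoms + 1),
        chains=np.full(n_atoms, "A"),
        masses=np.full(n_atoms, 12.011),
    )
    return model, Trajectory(coords=frames, times=times)
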