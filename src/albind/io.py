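"""CSV/JSON readers and writers, configuration, and the pipeline driver.

All tabular inputs are plain comma-separated files with a header row and
dot decimals; units are fixed (mol/L, K, ns, nm, mdeg, Å) and never
inferred — malformed inputs fail loudly.  Temperatures are kelvin
everywhere; Celsius is never accepted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import quenching as qn
from . import thermo as th
from . import lifetime as lt
from . import competition as cp
from . import conformation as cf
from . import structure as st

logger = logging.getLogger("albind")

__all__ = [
    "AnalysisConfig", "Report", "read_titration", "write_titration",
    "read_decay", "write_decay", "read_cd", "write_cd",
    "read_competition", "write_competition", "run_pipeline",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide settings (units fixed: K, ns, Å)."""

    temperatures: tuple = (298.0, 304.0, 310.0)
    lifetime_fit_window: tuple = None      # (t_start, t_end) ns; None = auto
    lifetime_n_components: int = 3
    mechanism_lifetime_tolerance: float = 0.05
    contact_cutoff: float = 3.5            # Å
    min_site_drop: float = 0.10
    site_margin: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if any(T <= 0 for T in self.temperatures):
            raise ValueError("temperatures must be positive kelvin")
        if not 0 < self.mechanism_lifetime_tolerance < 1:
            raise ValueError("mechanism tolerance must be in (0, 1)")
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        d = json.loads(text)
        for key in ("temperatures", "lifetime_fit_window"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Report:
    """Per-stage results plus provenance; JSON round-trip safe."""

    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages, "provenance": self.provenance},
                          sort_keys=True, indent=2, default=_jsonify)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        d = json.loads(text)
        return cls(stages=d["stages"], provenance=d["provenance"])


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} CSV missing column(s): {missing}")
    if df.empty:
        raise ValueError(f"{what} CSV contains no rows")


# ---------------------------------------------------------------- titration

def read_titration(path) -> list:
    """Read a titration CSV into one :class:`TitrationSeries` per temperature.

    Columns: temperature_K, Q_molar, F_obs and optionally A_ex, A_em.
    Rows are sorted by ascending [Q] within each temperature block; the
    [Q]=0 row defines F0 and must be present exactly once per block.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["temperature_K", "Q_molar", "F_obs"], "titration")
    for col in ("A_ex", "A_em"):
        if col not in df.columns:
            df[col] = 0.0
    out = []
    for T, block in df.groupby("temperature_K", sort=True):
        block = block.sort_values("Q_molar")
        if block["Q_molar"].duplicated().any():
            raise ValueError(f"duplicate [Q] values at {T} K")
        if not (block["Q_molar"] == 0).any():
            raise ValueError("no reference intensity")
        out.append(qn.TitrationSeries(
            temperature=float(T),
            Q=block["Q_molar"].to_numpy(),
            F=block["F_obs"].to_numpy(),
            A_ex=block["A_ex"].to_numpy(),
            A_em=block["A_em"].to_numpy(),
        ))
    return out


def write_titration(series_list, path):
    rows = []
    for s in series_list:
        for q, f, aex, aem in zip(s.Q, s.F, s.A_ex, s.A_em):
            rows.append({"temperature_K": s.temperature, "Q_molar": q,
                         "F_obs": f, "A_ex": aex, "A_em": aem})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# -------------------------------------------------------------------- decay

def read_decay(path, fit_window=None) -> lt.DecayHistogram:
    """Read a decay CSV (columns time_ns, counts)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_ns", "counts"], "decay")
    return lt.DecayHistogram(t=df["time_ns"].to_numpy(),
                             counts=df["counts"].to_numpy(),
                             fit_window=fit_window)


def write_decay(hist: lt.DecayHistogram, path):
    pd.DataFrame({"time_ns": hist.t, "counts": hist.counts}).to_csv(
        path, index=False, float_format="%.17g")


# ----------------------------------------------------------------------- CD

def read_cd(path, C_p: float, n_res: int, path_length: float,
            label: str = "") -> cf.CDSpectrum:
    """Read a CD CSV (columns wavelength_nm, theta_mdeg) with its metadata."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["wavelength_nm", "theta_mdeg"], "CD")
    return cf.CDSpectrum(wavelength=df["wavelength_nm"].to_numpy(),
                         theta=df["theta_mdeg"].to_numpy(),
                         C_p=C_p, n_res=n_res, path_length=path_length,
                         label=label)


def write_cd(spectrum: cf.CDSpectrum, path):
    pd.DataFrame({"wavelength_nm": spectrum.wavelength,
                  "theta_mdeg": spectrum.theta}).to_csv(
        path, index=False, float_format="%.17g")


# -------------------------------------------------------------- competition

def read_competition(path) -> list:
    """Read a competition CSV (columns probe, ratio, F), one series per probe."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["probe", "ratio", "F"], "competition")
    out = []
    for probe, block in df.groupby("probe", sort=True):
        block = block.sort_values("ratio")
        site = cp.PROBE_SITES.get(str(probe))
        if site is None:
            raise ValueError(f"unknown probe {probe!r}; add it to PROBE_SITES")
        out.append(cp.CompetitionSeries(
            probe_name=str(probe), probe_site=site,
            ratios=block["ratio"].to_numpy(), F=block["F"].to_numpy(),
        ))
    return out


def write_competition(series_list, path):
    rows = []
    for s in series_list:
        for r, f in zip(s.ratios, s.F):
            rows.append({"probe": s.probe_name, "ratio": r, "F": f})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ----------------------------------------------------------------- pipeline

def _digest(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def _stage_quenching(config, titrations):
    sv_results, binding_results = [], []
    rows = []
    for series in sorted(titrations, key=lambda s: s.temperature):
        corrected = series.correct_inner_filter()
        sv = qn.fit_stern_volmer(corrected)
        bind = qn.fit_double_log(corrected)
        sv_results.append(sv)
        binding_results.append(bind)
        logger.info("quench T=%.0fK: K_SV=%.4g±%.2g (R²=%.4f) "
                    "K_a=%.4g±%.2g n=%.3f±%.3f",
                    sv.temperature, sv.K_SV, sv.K_SV_stderr, sv.r_squared,
                    bind.K_a, bind.K_a_stderr, bind.n, bind.n_stderr)
        rows.append({
            "temperature_K": sv.temperature,
            "K_SV": sv.K_SV, "K_SV_stderr": sv.K_SV_stderr,
            "sv_intercept": sv.intercept, "sv_r_squared": sv.r_squared,
            "K_a": bind.K_a, "K_a_stderr": bind.K_a_stderr,
            "n": bind.n, "n_stderr": bind.n_stderr,
            "affinity_class": qn.classify_affinity(bind.K_a),
        })
    return {"per_temperature": rows}, sv_results, binding_results


def run_pipeline(config: AnalysisConfig, inputs: dict) -> Report:
    """Run every stage whose input is present; collect results in a Report.

    ``inputs`` may contain: ``titrations`` (list of TitrationSeries),
    ``decay_free``/``decay_bound`` (DecayHistogram), ``competition``
    (list of CompetitionSeries), ``cd`` (list of CDSpectrum),
    ``sync_pairs`` (list of (reference, perturbed) SyncSpectrum pairs),
    ``ligand``/``protein`` (StructureModel), and
    ``trajectory``/``trajectory_reference``.  A failing stage records
    its error without aborting the others.
    """
    if not inputs:
        raise ValueError("at least one stage input is required")
    report = Report()
    report.provenance = {
        "config": json.loads(config.to_json()),
        "input_digests": {k: _digest(v) for k, v in sorted(inputs.items())},
    }
    sv_results = binding_results = None
    lifetime_change = None

    def run_stage(name, fn):
        try:
            report.stages[name] = fn()
        except Exception as exc:
            logger.warning("stage %s failed: %s", name, exc)
            report.stages[name] = {"error": str(exc)}

    if "decay_free" in inputs:
        def lifetime_stage():
            nonlocal lifetime_change
            out = {}
            fits = {}
            for key in ("decay_free", "decay_bound"):
                if key not in inputs:
                    continue
                hist = inputs[key]
                if config.lifetime_fit_window is not None:
                    hist = lt.DecayHistogram(t=hist.t, counts=hist.counts,
                                             fit_window=config.lifetime_fit_window)
                fit = lt.fit_decay(hist, config.lifetime_n_components,
                                   seed=config.seed)
                fits[key] = fit
                logger.info("lifetime %s: tau_avg=%.4f±%.4f ns chi2_red=%.3f",
                            key, fit.tau_avg, fit.tau_avg_stderr,
                            fit.chi_square_reduced)
                out[key] = {
                    "components": [{"tau_ns": tau, "alpha": a}
                                   for tau, a in fit.components],
                    "tau_avg_ns": fit.tau_avg,
                    "tau_avg_stderr_ns": fit.tau_avg_stderr,
                    "chi_square_reduced": fit.chi_square_reduced,
                }
            if "decay_free" in fits and "decay_bound" in fits:
                rel, supported = lt.compare_lifetimes(
                    fits["decay_free"], fits["decay_bound"],
                    config.mechanism_lifetime_tolerance)
                lifetime_change = rel
                out["relative_change"] = rel
                out["static_supported"] = supported
            return out
        run_stage("lifetime", lifetime_stage)

    if "titrations" in inputs:
        def quench_stage():
            nonlocal sv_results, binding_results
            out, sv_results, binding_results = _stage_quenching(
                config, inputs["titrations"])
            out["mechanism"] = qn.classify_mechanism(
                sv_results, lifetime_change,
                config.mechanism_lifetime_tolerance)
            return out
        run_stage("quenching", quench_stage)

        def thermo_stage():
            if not binding_results or len(binding_results) < 2:
                raise ValueError("thermodynamics needs >= 2 temperatures")
            res = th.vant_hoff_fit([(b.temperature, b.K_a)
                                    for b in binding_results])
            logger.info("thermo: dH=%.3f±%.3f kJ/mol dS=%.3f±%.3f J/mol/K (R²=%.4f)",
                        res.delta_H, res.delta_H_stderr, res.delta_S,
                        res.delta_S_stderr, res.r_squared)
            return {
                "delta_H_kJ_mol": res.delta_H,
                "delta_H_stderr": res.delta_H_stderr,
                "delta_S_J_mol_K": res.delta_S,
                "delta_S_stderr": res.delta_S_stderr,
                "delta_G_kJ_mol": {f"{T:g}": g for T, g in res.delta_G.items()},
                "r_squared": res.r_squared,
                "force_label": res.force_label,
                "spontaneous": {f"{T:g}": s for T, s in res.spontaneous.items()},
            }
        run_stage("thermo", thermo_stage)

    if "competition" in inputs:
        def competition_stage():
            site, ranking, ambiguous = cp.assign_site(
                inputs["competition"], config.min_site_drop,
                config.site_margin)
            return {"site": site, "ambiguous": ambiguous, "ranking": ranking}
        run_stage("competition", competition_stage)

    if "cd" in inputs:
        def cd_stage():
            out = {"helix": cf.helix_change(inputs["cd"])}
            if "sync_pairs" in inputs:
                shifts = []
                for ref, per in inputs["sync_pairs"]:
                    dl, direction = cf.peak_shift(ref, per)
                    shifts.append({"delta_lambda_scan_nm": ref.delta_lambda,
                                   "shift_nm": dl, "direction": direction})
                out["sync_shifts"] = shifts
            return out
        run_stage("cd", cd_stage)

    if "trajectory" in inputs:
        def structure_stage():
            stats = st.trajectory_stats(inputs["trajectory"],
                                        inputs["trajectory_reference"])
            out = {
                "plateau_start_ps": stats["plateau_start"],
                "plateau_mean_rmsd_A": stats["plateau_mean_rmsd"],
                "plateau_mean_rg_A": stats["plateau_mean_rg"],
            }
            return out
        run_stage("structure", structure_stage)

    if "ligand" in inputs and "protein" in inputs:
        def contacts_stage():
            records = st.find_polar_contacts(inputs["ligand"],
                                             inputs["protein"],
                                             config.contact_cutoff)
            return {"contacts": [
                {"ligand_atom": r.ligand_atom, "protein_atom": r.protein_atom,
                 "protein_residue": r.protein_residue,
                 "distance_A": r.distance, "classification": r.classification}
                for r in records]}
        run_stage("contacts", contacts_stage)

    if not report.stages:
        raise ValueError("no recognized stage inputs were provided")
    return report
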