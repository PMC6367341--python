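"""Site-marker competitive displacement analysis.

Serum albumin carries two principal drug pockets (Sudlow's site I in
subdomain IIA and site II in IIIA) plus the heme cleft (site III,
subdomain IB / FA1).  A ligand's binding site is located by titrating
the preformed ligand–protein complex with probes of known site
(warfarin → site I, ibuprofen → site II, dansyl amino acids → FA7/FA1)
and following the complex fluorescence ratio I = F/F0: a probe sharing
the ligand's site displaces it and depresses I steadily, while probes
of other sites leave it flat.  A step-then-flat curve signals
cooperative binding at a different site and is excluded from the site
verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PROBE_SITES", "CompetitionSeries", "displacement_ratio",
    "displacement_trend", "assign_site",
]

# probe -> canonical albumin site (data, not logic)
PROBE_SITES = {
    "warfarin": "site_I",
    "ibuprofen": "site_II",
    "dansyl-L-arginine": "site_I",   # FA7, overlaps Sudlow site I
    "dansyl-L-sarcosine": "site_III",  # FA1, heme cleft
}

SITES = ("site_I", "site_II", "site_III")


@dataclass(frozen=True)
class CompetitionSeries:
    """Fluorescence of the ligand–protein complex vs probe:ligand molar ratio."""

    probe_name: str
    probe_site: str
    ratios: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.ratios, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "F", F)
        if self.probe_site not in SITES:
            raise ValueError(f"unknown site {self.probe_site!r}")
        if r.shape != F.shape or r.ndim != 1:
            raise ValueError("ratios and F must be 1-D arrays of equal length")
        if np.any(r < 0) or np.any(np.diff(r) <= 0):
            raise ValueError("ratios must be non-negative and strictly increasing")
        if r[0] != 0:
            raise ValueError("a ratio-0 reference point is required")
        if F[0] <= 0:
            raise ValueError("reference intensity F0 must be positive")

    @property
    def F0(self) -> float:
        return float(self.F[0])

    @property
    def I(self) -> np.ndarray:
        """Displacement ratios I = F/F0 at each probe ratio."""
        return self.F / self.F0


def displacement_ratio(F: float, F0: float) -> float:
    """Relative complex fluorescence I = F/F0 in the presence of a probe."""
    if F0 <= 0:
        raise ValueError("F0 must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    return F / F0


def displacement_trend(series: CompetitionSeries, tol: float = 0.01):
    """Summarise one probe's displacement curve.

    Returns ``(slope, total_drop, monotone_decreasing, step_then_flat)``:
    the OLS slope of I vs ratio, the total drop 1 − I(final), a monotone
    flag (pairwise, within ``tol``), and a flag for the step-then-flat
    shape in which essentially the whole drop happens at the first probe
    addition — the cooperative-binding signature.
    """
    if series.ratios.size < 3:
        raise ValueError("displacement trend needs at least 3 ratios")
    I = series.I
    slope = stats.linregress(series.ratios, I).slope
    total_drop = 1.0 - float(I[-1])
    monotone = bool(np.all(np.diff(I) <= tol))
    first_drop = 1.0 - float(I[1])
    later_span = float(np.max(I[1:]) - np.min(I[1:]))
    step = (total_drop > 2 * tol and first_drop >= 0.8 * total_drop
            and later_span <= max(tol, 0.2 * total_drop))
    return float(slope), total_drop, monotone, step


def assign_site(curves, min_drop: float = 0.10, margin: float = 0.05):
    """Assign the ligand's binding site from a panel of probe curves.

    Monotone-declining curves are ranked by total drop; step-then-flat
    curves (cooperative pattern) are excluded from the ranking but
    reported.  The top probe's site is returned if its drop reaches
    ``min_drop`` and exceeds the best drop among probes of any *other*
    site by at least ``margin`` (absolute, in displacement fraction);
    otherwise the verdict is ambiguous.

    Returns ``(site, ranking, ambiguous)`` where ``ranking`` is a list of
    dicts (probe, site, drop, slope, monotone, step_then_flat) sorted by
    descending drop among eligible curves, then the excluded ones.
    """
    sites_seen = {c.probe_site for c in curves}
    if len(curves) < 2 or len(sites_seen) < 2:
        raise ValueError("need at least 2 probes covering at least 2 sites")
    rows = []
    for c in sorted(curves, key=lambda c: c.probe_name):
        slope, drop, mono, step = displacement_trend(c)
        rows.append({
            "probe": c.probe_name, "site": c.probe_site, "drop": drop,
            "slope": slope, "monotone": mono, "step_then_flat": step,
        })
    eligible = [r for r in rows if r["monotone"] and not r["step_then_flat"]]
    eligible.sort(key=lambda r: -r["drop"])
    excluded = [r for r in rows if r not in eligible]
    ranking = eligible + excluded
    if not eligible:
        return None, ranking, True
    top = eligible[0]
    others = [r["drop"] for r in eligible if r["site"] != top["site"]]
    runner_up = max(others) if others else 0.0
    if top["drop"] >= min_drop and top["drop"] - runner_up >= margin:
        return top["site"], ranking, False
    return None, ranking, True
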