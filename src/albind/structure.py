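"""Docking/MD post-processing: coordinates, superposition, RMSD/Rg, contacts.

PDB parsing is delegated to biotite; on top of it sit the metrics used
to judge a docked or simulated ligand–protein system: Kabsch
least-squares superposition, heavy-atom RMSD and mass-weighted radius of
gyration per trajectory frame with automatic plateau detection, and a
distance-based polar-contact (hydrogen-bond candidate) scan of a bound
pose.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.structure.info import mass as _element_mass

__all__ = [
    "StructureModel", "Trajectory", "ContactRecord", "parse_structure",
    "parse_trajectory", "kabsch_superpose", "radius_of_gyration",
    "trajectory_stats", "find_polar_contacts",
]

POLAR_ELEMENTS = frozenset({"N", "O", "S"})
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})
WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})


@dataclass(frozen=True)
class StructureModel:
    """Atoms with coordinates (Å) and masses (amu), plus selection helpers."""

    coords: np.ndarray      # (N, 3)
    elements: np.ndarray    # str
    names: np.ndarray       # atom names
    res_names: np.ndarray
    res_ids: np.ndarray
    chains: np.ndarray
    masses: np.ndarray      # amu

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.names, list(BACKBONE_NAMES))

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chains == chain_id

    def select(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            coords=self.coords[mask], elements=self.elements[mask],
            names=self.names[mask], res_names=self.res_names[mask],
            res_ids=self.res_ids[mask], chains=self.chains[mask],
            masses=self.masses[mask],
        )


@dataclass(frozen=True)
class Trajectory:
    """Frame series sharing one atom ordering; times in ps, ascending."""

    coords: np.ndarray   # (n_frames, N, 3)
    times: np.ndarray    # ps

    def __post_init__(self):
        if self.coords.ndim != 3 or self.coords.shape[0] != self.times.size:
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be ascending")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ContactRecord:
    """One ligand-atom/protein-atom contact within the cutoff."""

    ligand_atom: str
    ligand_element: str
    protein_atom: str
    protein_element: str
    protein_residue: str
    distance: float
    classification: str  # hbond_candidate | polar_contact | nonpolar

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Fe", "Zn",
                                                            "Mg", "Na", "Ca", "Se"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


def _sanitize_pdb(pdb_text: str) -> str:
    """Drop malformed coordinate records with a warning before parsing."""
    kept = []
    for line in pdb_text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                warnings.warn(f"skipping malformed PDB line: {line!r}")
                continue
            try:
                [float(line[i:i + 8]) for i in (30, 38, 46)]
            except ValueError:
                warnings.warn(f"skipping malformed PDB line: {line!r}")
                continue
        kept.append(line)
    return "\n".join(kept) + "\n"


def _atoms_to_model(atoms) -> StructureModel:
    elements = np.array([
        el.capitalize() if el else _element_from_name(nm)
        for el, nm in zip(atoms.element, atoms.atom_name)
    ])
    masses = np.array([max(_element_mass(el) or 0.0, 1.0) for el in elements])
    return StructureModel(
        coords=np.asarray(atoms.coord, dtype=float),
        elements=elements,
        names=np.asarray(atoms.atom_name),
        res_names=np.asarray(atoms.res_name),
        res_ids=np.asarray(atoms.res_id),
        chains=np.asarray(atoms.chain_id),
        masses=masses,
    )


def parse_structure(pdb_text: str, strip_water: bool = False) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Elements come from columns 77–78 with an atom-name fallback; for
    alternate locations only 'A' (or blank) is kept; ``strip_water``
    removes water residues.  Malformed coordinate lines are skipped with
    a warning; a file with no atoms is an error.
    """
    pdb = pdbio.PDBFile.read(_io.StringIO(_sanitize_pdb(pdb_text)))
    atoms = pdbio.get_structure(pdb, model=1, altloc="first")
    if strip_water:
        atoms = atoms[~np.isin(atoms.res_name, list(WATER_NAMES))]
    if atoms.array_length() == 0:
        raise ValueError("no atoms in PDB input")
    return _atoms_to_model(atoms)


def parse_trajectory(pdb_text: str, dt_ps: float = 10.0,
                     strip_water: bool = False):
    """Parse a multi-model PDB as a trajectory.

    Frames are assumed evenly spaced ``dt_ps`` apart (MD snapshots);
    returns ``(reference_model, Trajectory)`` where the reference is the
    first frame.
    """
    pdb = pdbio.PDBFile.read(_io.StringIO(_sanitize_pdb(pdb_text)))
    stack = pdbio.get_structure(pdb, altloc="first")
    if strip_water:
        stack = stack[..., ~np.isin(stack.res_name, list(WATER_NAMES))]
    if stack.array_length() == 0:
        raise ValueError("no atoms in PDB input")
    reference = _atoms_to_model(stack[0])
    coords = np.asarray(stack.coord, dtype=float)
    times = np.arange(coords.shape[0], dtype=float) * dt_ps
    return reference, Trajectory(coords=coords, times=times)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference in the
    least-squares sense.  A proper rotation (det = +1) is enforced, so
    reflections can never occur.  Fewer than 3 atoms or a collinear set
    leave the rotation underdetermined and raise an error.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    H = mob_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) atom set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = reference.mean(axis=0) - R @ mobile.mean(axis=0)
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return R, t, rmsd


def radius_of_gyration(coords: np.ndarray, masses=None) -> float:
    """Mass-weighted radius of gyration √(Σ mᵢ|rᵢ − r_com|² / Σ mᵢ), Å.

    With ``masses=None`` all atoms weigh equally (unweighted variant).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("coords must be a non-empty (N, 3) array")
    if masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def _detect_plateau(series: np.ndarray, times: np.ndarray, rel_tol: float = 0.02):
    """First time after which a sliding-window mean changes < ``rel_tol``.

    The window is 10% of the trajectory length (at least 2 frames); the
    plateau starts at the earliest frame from which every subsequent
    window-to-window relative change stays below the tolerance.
    """
    n = series.size
    w = max(2, int(round(0.1 * n)))
    if n < 2 * w:
        return float(times[0])
    means = np.convolve(series, np.ones(w) / w, mode="valid")  # len n-w+1
    denom = np.maximum(np.abs(means[:-w]), 1e-12)
    change = np.abs(means[w:] - means[:-w]) / denom
    ok = change < rel_tol
    # earliest index i such that ok[i:] all True
    idx = n - 2 * w + 1  # default: last comparable window
    for i in range(ok.size - 1, -1, -1):
        if not ok[i]:
            break
        idx = i
    return float(times[min(idx, n - 1)])


def trajectory_stats(traj: Trajectory, reference: StructureModel,
                     selection: np.ndarray = None, window: tuple = None,
                     superpose: bool = True, mass_weighted_rg: bool = True):
    """Per-frame RMSD and Rg with plateau statistics.

    Each frame's selected atoms (default: heavy atoms) are superposed on
    the reference before RMSD; Rg is computed on the (superposed) frame.
    The plateau start is detected from the RMSD series by the
    sliding-window rule (window 10% of the trajectory, < 2% change), or
    fixed with ``window=(t0, t1)`` ps.  Returns a dict with the two
    series, plateau means and plateau start time.
    """
    if selection is None:
        selection = reference.heavy_mask()
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        raise ValueError("empty atom selection")
    ref_xyz = reference.coords[selection]
    masses = reference.masses[selection] if mass_weighted_rg else None
    rmsd = np.empty(traj.n_frames)
    rg = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        xyz = traj.coords[k][selection]
        if superpose:
            R, t, r = kabsch_superpose(xyz, ref_xyz)
            xyz = xyz @ R.T + t
            rmsd[k] = r
        else:
            rmsd[k] = float(np.sqrt(np.mean(np.sum((xyz - ref_xyz) ** 2, axis=1))))
        rg[k] = radius_of_gyration(xyz, masses)
    if window is not None:
        t0, t1 = window
        if not traj.times[0] <= t0 < t1 <= traj.times[-1]:
            raise ValueError("window outside trajectory span")
        plateau_start = float(t0)
        in_plateau = (traj.times >= t0) & (traj.times <= t1)
    else:
        plateau_start = _detect_plateau(rmsd, traj.times)
        in_plateau = traj.times >= plateau_start
    return {
        "times": traj.times.copy(),
        "rmsd": rmsd,
        "rg": rg,
        "plateau_start": plateau_start,
        "plateau_mean_rmsd": float(rmsd[in_plateau].mean()),
        "plateau_mean_rg": float(rg[in_plateau].mean()),
    }


def find_polar_contacts(ligand: StructureModel, protein: StructureModel,
                        cutoff: float = 3.5):
    """Distance-based polar contacts between a ligand pose and the protein.

    Hydrogens are ignored; every heavy-atom pair within ``cutoff`` Å is
    classified: both atoms N/O/S → ``hbond_candidate``, exactly one →
    ``polar_contact``, neither → ``nonpolar`` (reported but not a
    hydrogen-bond candidate).  No angle criterion is applied — only
    donor–acceptor distances are used.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = ligand.select(ligand.heavy_mask())
    pro = protein.select(protein.heavy_mask())
    dists = cdist(lig.coords, pro.coords)
    records = []
    for i, j in zip(*np.nonzero(dists <= cutoff)):
        el_l, el_p = lig.elements[i], pro.elements[j]
        polar_l, polar_p = el_l in POLAR_ELEMENTS, el_p in POLAR_ELEMENTS
        if polar_l and polar_p:
            cls = "hbond_candidate"
        elif polar_l or polar_p:
            cls = "polar_contact"
        else:
            cls = "nonpolar"
        records.append(ContactRecord(
            ligand_atom=str(lig.names[i]), ligand_element=str(el_l),
            protein_atom=str(pro.names[j]), protein_element=str(el_p),
            protein_residue=f"{pro.res_names[j]}{pro.res_ids[j]}",
            distance=float(dists[i, j]), classification=cls,
        ))
    records.sort(key=lambda r: r.distance)
    return records
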