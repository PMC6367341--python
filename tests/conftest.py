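"""Shared fixtures: hand-written PDB snippets and fixture builders."""

import numpy as np
import pytest


def pdb_line(serial, name, resname, chain, resseq, x, y, z, element,
             altloc=" ", record="ATOM"):
    """One correctly column-aligned PDB coordinate record."""
    return (f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


@pytest.fixture
def three_atom_pdb():
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0, "N"),
        pdb_line(2, "CA", "ALA", "A", 1, 2.5, 2.0, 3.0, "C"),
        pdb_line(3, "C", "ALA", "A", 1, 3.0, 3.5, 3.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def altloc_pdb():
    lines = [
        pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C", altloc="A"),
        pdb_line(2, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, "C", altloc="B"),
        pdb_line(3, "CB", "ALA", "A", 1, 1.0, 0.0, 0.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def water_pdb():
    lines = [
        pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
        pdb_line(2, "O", "HOH", "A", 2, 5.0, 0.0, 0.0, "O", record="HETATM"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def arg_contact_pair():
    """Ligand oxygen near an arginine guanidinium: planted 3.09/3.23 Å contacts."""
    from albind import parse_structure
    ligand = parse_structure("\n".join([
        pdb_line(1, "O1", "LIG", "L", 1, 0.0, 0.0, 0.0, "O", record="HETATM"),
        "END",
    ]) + "\n")
    protein = parse_structure("\n".join([
        pdb_line(1, "NH1", "ARG", "A", 197, 3.09, 0.0, 0.0, "N"),
        pdb_line(2, "NH2", "ARG", "A", 197, 0.0, 3.23, 0.0, "N"),
        pdb_line(3, "CZ", "ARG", "A", 197, 0.0, 0.0, 3.00, "C"),
        pdb_line(4, "OD1", "ASP", "A", 10, 5.0, 0.0, 0.0, "O"),
        "END",
    ]) + "\n")
    return ligand, protein
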