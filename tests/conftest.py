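"""Shared fixtures: idealized structures and deterministic rigid motions."""

from __future__ import annotations

import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from isoformetrics.io import Atom, ProteinStructure, Residue
from isoformetrics.metrics import _fibonacci_sphere
from isoformetrics.synth import StructureSpec, make_ideal_structure

# Rigid placement of a second ideal strand against the first so that the
# Kabsch-Sander bridge pattern forms an antiparallel sheet. Found once by
# minimizing the hydrogen-bond energy of the paired registers; frozen here
# so the fixture is deterministic and cheap.
SHEET_PARTNER_PARAMS = np.array(
    [0.118913, 0.18792, -3.19185, 27.084395, 16.973521, -2.76903]
)


def rigid_apply(structure: ProteinStructure, R: np.ndarray, t: np.ndarray) -> ProteinStructure:
    """Deep-copied structure with coords mapped x -> R x + t."""
    out = copy.deepcopy(structure)
    for res in out.residues:
        for atom in res.atoms:
            atom.coords = R @ atom.coords + t
    return out


def random_rigid(seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.normal(scale=30.0, size=3)
    return R, t


@pytest.fixture(scope="session")
def helix30() -> ProteinStructure:
    return make_ideal_structure(StructureSpec([("helix", 30, 90.0)]), seed=1)


@pytest.fixture(scope="session")
def mixed_structure() -> ProteinStructure:
    spec = StructureSpec([("helix", 20, 90.0), ("coil", 15, 80.0), ("strand", 10, 85.0)])
    return make_ideal_structure(spec, seed=5)


@pytest.fixture(scope="session")
def sheet20() -> ProteinStructure:
    """Two antiparallel ideal strands assembled into one 20-residue chain."""
    s1 = make_ideal_structure(
        StructureSpec([("strand", 10, 90.0)], sequence="VTVTVTVTVT"), seed=1
    )
    R = Rotation.from_rotvec(SHEET_PARTNER_PARAMS[:3]).as_matrix()
    s2 = rigid_apply(s1, R, SHEET_PARTNER_PARAMS[3:])
    residues = [
        Residue(i + 1, r.name, copy.deepcopy(r.atoms))
        for i, r in enumerate(s1.residues + s2.residues)
    ]
    return ProteinStructure("sheet", residues)


def build_cage_pair(site_pos: int, seed: int = 11):
    """A lone exposed helix and a copy whose ``site_pos`` CB is caged by
    appended CA-only alanines, burying the site. Returns (ref, iso)."""
    ref = make_ideal_structure(StructureSpec([("helix", 30, 90.0)]), seed=seed, id="REF")
    iso = copy.deepcopy(ref)
    iso.id = "ISO"
    cb = ref.residues[site_pos - 1].atom("CB").coords
    n_extra = len(ref.residues)
    k = 0
    for p in _fibonacci_sphere(14) * 4.5 + cb:
        clash = min(
            np.linalg.norm(p - a.coords) for r in ref.residues for a in r.atoms
        )
        if clash < 2.0:
            continue
        k += 1
        iso.residues.append(
            Residue(n_extra + k, "ALA", [Atom("CA", "C", p, bfactor=90.0)])
        )
    return ref, iso
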