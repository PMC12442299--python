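"""Structure metrics: analytic oracles, rigid invariance, cross-engine checks."""

import copy
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from isoformetrics.align import PairAlignment, global_align
from isoformetrics.io import Atom, ProteinStructure, Residue
from isoformetrics.metrics import (
    SasaResult,
    classify_outliers,
    contact_map,
    idr_fraction,
    idr_regions,
    isolated_helices,
    mean_plddt,
    outlier_bounds,
    pair_report,
    quality_class,
    radius_of_gyration,
    relative_accessibility,
    secondary_structure,
    shrake_rupley_sasa,
    ss_percentages,
    surface_charge,
    surface_residues,
    tm_score,
    top_event_types,
    MAX_ASA_TIEN,
    compute_metrics,
)
from isoformetrics.splice import SpliceEvent, SpliceEventSet
from isoformetrics.synth import StructureSpec, make_ideal_structure

from conftest import build_cage_pair, random_rigid, rigid_apply


def _ca_only(letter_coords, resname="ALA", plddt=90.0):
    return ProteinStructure(
        "toy",
        [
            Residue(i + 1, name, [Atom("CA", "C", c, bfactor=plddt)])
            for i, (name, c) in enumerate(letter_coords)
        ],
    )


# ---------------------------------------------------------------------------
# SASA


def test_isolated_carbon_matches_analytic_sphere():
    s = _ca_only([("ALA", [0.0, 0.0, 0.0])])
    result = shrake_rupley_sasa(s)
    analytic = 4.0 * math.pi * (1.7 + 1.4) ** 2
    assert result.sasa[0] == pytest.approx(analytic, rel=0.01)


def test_coincident_atoms_counted_once():
    one = _ca_only([("ALA", [0.0, 0.0, 0.0])])
    two = ProteinStructure(
        "two",
        [Residue(1, "ALA", [Atom("CA", "C", [0, 0, 0]), Atom("CB", "C", [0, 0, 0])])],
    )
    assert shrake_rupley_sasa(two).sasa.sum() == pytest.approx(
        shrake_rupley_sasa(one).sasa.sum()
    )


def test_adding_atoms_never_increases_existing_sasa(mixed_structure):
    base = shrake_rupley_sasa(mixed_structure)
    grown = copy.deepcopy(mixed_structure)
    grown.residues.append(
        Residue(len(grown) + 1, "ALA",
                [Atom("CA", "C", grown.residues[10].atom("CA").coords + [0, 0, 4.0])])
    )
    after = shrake_rupley_sasa(grown)
    # the canonical frame shifts slightly with the new atom, so allow
    # quadrature-level jitter; no residue may gain real area
    assert np.all(after.sasa[: len(base.sasa)] <= base.sasa + 2.5)
    shielded = after.sasa[10] - base.sasa[10]
    assert shielded < 0


def test_unknown_element_rejected():
    s = ProteinStructure("x", [Residue(1, "ALA", [Atom("FE", "FE", [0, 0, 0])])])
    with pytest.raises(ValueError, match="FE"):
        shrake_rupley_sasa(s)


def test_sasa_cross_checked_against_biotite(helix30, tmp_path):
    """Independent engine (biotite Shrake-Rupley, element radii) agrees."""
    import biotite.structure.io.pdb as pdb_io
    from biotite.structure import sasa as biotite_sasa

    from isoformetrics.io import write_pdb

    path = tmp_path / "helix.pdb"
    write_pdb(helix30, path)
    arr = pdb_io.PDBFile.read(str(path)).get_structure(model=1)
    per_atom = biotite_sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single")
    res_ids = arr.res_id
    oracle = np.array([per_atom[res_ids == i].sum() for i in range(1, len(helix30) + 1)])
    ours = shrake_rupley_sasa(helix30).sasa
    assert np.abs(ours - oracle).max() < 0.05 * oracle.max()


def test_buried_residue_less_exposed_than_surface():
    ref, iso = build_cage_pair(site_pos=15)
    ref_rsa = shrake_rupley_sasa(ref).rsa
    iso_rsa = shrake_rupley_sasa(iso).rsa
    assert iso_rsa[14] < ref_rsa[14]


# ---------------------------------------------------------------------------
# RSA, surface, charge


def test_relative_accessibility_uses_type_maxima():
    s = _ca_only([("ALA", [0, 0, 0])])
    sasa = np.array([64.5])
    rsa = relative_accessibility(sasa, s)
    assert rsa[0] == pytest.approx(64.5 / MAX_ASA_TIEN["ALA"])
    assert relative_accessibility(np.array([0.0]), s)[0] == 0.0


def test_surface_residue_thresholding():
    rsa = np.array([0.0, 0.25, 0.26, 0.9])
    assert surface_residues(rsa) == {3, 4}
    assert surface_residues(np.zeros(4)) == set()
    assert surface_residues(rsa, threshold=0.0) == {2, 3, 4}


def test_surface_charge_formal_model():
    # spread CA-only residues far apart: all fully exposed
    kgd = _ca_only([("LYS", [0, 0, 0]), ("GLY", [20, 0, 0]), ("ASP", [40, 0, 0])])
    rsa = shrake_rupley_sasa(kgd).rsa
    assert surface_charge(kgd, rsa) == 0

    deca_k = _ca_only([("LYS", [20 * i, 0, 0]) for i in range(10)])
    rsa = shrake_rupley_sasa(deca_k).rsa
    assert surface_charge(deca_k, rsa) == 10


def test_surface_charge_rigid_invariance(mixed_structure):
    base = shrake_rupley_sasa(mixed_structure)
    q = surface_charge(mixed_structure, base.rsa)
    for seed in range(5):
        R, t = random_rigid(seed)
        moved = rigid_apply(mixed_structure, R, t)
        assert surface_charge(moved, shrake_rupley_sasa(moved).rsa) == q


# ---------------------------------------------------------------------------
# radius of gyration


def test_rg_single_and_two_point():
    assert radius_of_gyration(_ca_only([("ALA", [3, 4, 5])])) == pytest.approx(0.0, abs=1e-12)
    two = _ca_only([("ALA", [0, 0, 0]), ("ALA", [2, 0, 0])])
    assert radius_of_gyration(two) == pytest.approx(1.0)


def test_rg_rigid_invariance(mixed_structure):
    rg = radius_of_gyration(mixed_structure)
    for seed in range(5):
        R, t = random_rigid(seed)
        assert radius_of_gyration(rigid_apply(mixed_structure, R, t)) == pytest.approx(
            rg, abs=1e-9
        )


# ---------------------------------------------------------------------------
# secondary structure


def test_ideal_helix_assigned_helix(helix30, tmp_path):
    states = secondary_structure(helix30)
    interior = states[1:-1]
    assert interior.count("H") / len(interior) >= 0.8

    # independent oracle: mdtraj's DSSP implementation on the same model
    import mdtraj

    from isoformetrics.io import write_pdb

    path = tmp_path / "helix.pdb"
    write_pdb(helix30, path)
    oracle = mdtraj.compute_dssp(mdtraj.load(str(path)), simplified=True)[0]
    agree = sum(a == b for a, b in zip(states, oracle) if b in "HE")
    total = sum(1 for b in oracle if b in "HE")
    assert agree / total >= 0.9


def test_paired_strands_assigned_sheet(sheet20, tmp_path):
    states = secondary_structure(sheet20)
    # interior residues of both strands
    for block in (states[1:9], states[11:19]):
        assert block.count("E") / len(block) >= 0.75

    import mdtraj

    from isoformetrics.io import write_pdb

    path = tmp_path / "sheet.pdb"
    write_pdb(sheet20, path)
    oracle = mdtraj.compute_dssp(mdtraj.load(str(path)), simplified=True)[0]
    assert list(oracle).count("E") >= 12  # oracle agrees the sheet is there


def test_random_coil_rarely_structured():
    fracs = []
    for seed in range(10):
        s = make_ideal_structure(StructureSpec([("coil", 40, 70.0)]), seed=seed)
        states = secondary_structure(s)
        fracs.append((states.count("H") + states.count("E")) / len(states))
    assert np.mean(fracs) <= 0.2


def test_ss_percentages():
    assert ss_percentages(["H"] * 5) == (100.0, 0.0, 0.0)
    h, e, l = ss_percentages(["H", "E", "L", "L"])
    assert (h, e, l) == (25.0, 25.0, 50.0)
    assert h + e + l == pytest.approx(100.0)
    with pytest.raises(ValueError):
        ss_percentages([])


# ---------------------------------------------------------------------------
# TM-score


def test_tm_score_self_is_one(helix30):
    aln = PairAlignment.identity(helix30.sequence)
    assert tm_score(helix30, helix30, aln) == pytest.approx(1.0, abs=1e-12)


def test_tm_score_rigid_copy(mixed_structure):
    aln = PairAlignment.identity(mixed_structure.sequence)
    for seed in range(5):
        R, t = random_rigid(seed)
        moved = rigid_apply(mixed_structure, R, t)
        assert tm_score(mixed_structure, moved, aln) >= 1.0 - 1e-6


def test_tm_score_symmetric(helix30):
    other = make_ideal_structure(StructureSpec([("helix", 30, 90.0)]), seed=77)
    other.residues = other.residues[:28]
    aln = global_align(helix30.sequence, other.sequence)
    assert tm_score(helix30, other, aln) == pytest.approx(
        tm_score(other, helix30, aln.mirror()), abs=1e-12
    )


def test_tm_score_displaced_segment_matches_search_oracle():
    s = make_ideal_structure(StructureSpec([("helix", 60, 90.0)]), seed=2)
    moved = copy.deepcopy(s)
    for r in moved.residues[20:40]:
        for a in r.atoms:
            a.coords = a.coords + np.array([20.0, 0.0, 0.0])
    aln = PairAlignment.identity(s.sequence)
    ours = tm_score(s, moved, aln)

    # oracle: multi-start rigid-body optimization of the TM objective
    x, y = s.ca_coords(), moved.ca_coords()
    d0 = max(0.5, 1.24 * (60 - 15) ** (1 / 3) - 1.8)

    def neg_tm(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        d = np.linalg.norm(x @ R.T + params[3:] - y, axis=1)
        return -(1.0 / (1.0 + (d / d0) ** 2)).sum() / 60

    best = 0.0
    rng = np.random.default_rng(0)
    for k in range(20):
        p0 = np.zeros(6) if k == 0 else np.concatenate(
            [rng.normal(scale=1.5, size=3), rng.normal(scale=10, size=3)]
        )
        res = minimize(neg_tm, p0, method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-12})
        best = max(best, -res.fun)
    assert ours == pytest.approx(best, abs=1e-3)


def test_tm_score_needs_three_pairs(helix30):
    tiny = PairAlignment("r", "i", "AC", "AC", [(1, 1), (2, 2)], 0.0)
    small = ProteinStructure("s", copy.deepcopy(helix30.residues[:2]))
    with pytest.raises(ValueError, match="3"):
        tm_score(small, small, tiny)


# ---------------------------------------------------------------------------
# pLDDT bands, IDRs, isolated helices


@pytest.mark.parametrize(
    "value,expected",
    [(95.0, "high"), (90.0, "confident"), (80.0, "confident"),
     (70.0, "low"), (60.0, "low"), (50.0, "very_low"), (30.0, "very_low")],
)
def test_quality_classes(value, expected):
    assert quality_class(value) == expected


def test_idr_detection_against_window_mean_oracle():
    spec = StructureSpec([("coil", 60, 40.0), ("helix", 140, 90.0)])
    s = make_ideal_structure(spec, seed=8)
    intervals = idr_regions(s)
    assert len(intervals) == 1
    start, end = intervals[0]
    assert start == 1 and abs(end - 60) <= 13  # within half a window of the edit
    frac = idr_fraction(s)
    assert frac == pytest.approx(0.3, abs=0.07)

    # direct oracle: recompute centered window means
    plddt = s.plddt()
    half = 12
    for i in range(len(plddt)):
        window = plddt[max(0, i - half): i + half + 1]
        assert (window.mean() < 70.0) == (start - 1 <= i <= end - 1 or False) or not (
            start - 1 <= i <= end - 1
        )


def test_idr_extremes():
    confident = make_ideal_structure(StructureSpec([("helix", 50, 90.0)]), seed=1)
    assert idr_regions(confident) == []
    assert idr_fraction(confident) == 0.0
    low = make_ideal_structure(StructureSpec([("coil", 50, 60.0)]), seed=1)
    assert idr_regions(low) == [(1, 50)]
    assert idr_fraction(low) == 1.0


def test_isolated_helix_detection(helix30):
    sasa = shrake_rupley_sasa(helix30)
    intervals = isolated_helices(helix30, sasa)
    assert len(intervals) == 1
    s, e = intervals[0]
    assert e - s + 1 >= 21

    short = make_ideal_structure(StructureSpec([("helix", 15, 90.0)]), seed=1)
    assert isolated_helices(short, shrake_rupley_sasa(short)) == []

    # same helix but treated as fully buried: no isolated helix
    fake = SasaResult(sasa=sasa.sasa, rsa=np.zeros(len(helix30)), probe_radius=1.4,
                      n_points=960)
    assert isolated_helices(helix30, fake) == []


# ---------------------------------------------------------------------------
# contact map, reports, outliers


def test_contact_map_matches_brute_force(mixed_structure):
    m = contact_map(mixed_structure)
    assert np.array_equal(m, m.T)
    assert not m.diagonal().any()
    pts = []
    for r in mixed_structure.residues:
        a = r.atom("CB") or r.atom("CA")
        pts.append(a.coords)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            assert m[i, j] == (np.linalg.norm(pts[i] - pts[j]) < 8.0)
    # chain neighbours are always in contact
    assert all(m[i, i + 1] for i in range(len(pts) - 1))


def test_pair_report_antisymmetry(helix30, mixed_structure):
    a = compute_metrics(helix30)
    b = compute_metrics(mixed_structure)
    fwd = pair_report(a, b, tm=0.7)
    rev = pair_report(b, a, tm=0.7)
    for fieldname in ("d_helix", "d_sheet", "d_loop", "d_charge", "d_rg", "d_idr",
                      "d_plddt"):
        assert getattr(fwd, fieldname) == pytest.approx(-getattr(rev, fieldname))
    identical = pair_report(a, a, tm=1.0)
    assert identical.d_charge == 0 and identical.d_rg == 0.0


def test_outlier_rule_against_quantile_oracle():
    values = list(range(1, 10)) + [100]
    low, high = outlier_bounds(values)
    q1, q3 = np.percentile(values, [25, 75])
    assert (low, high) == (q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1))
    labels = classify_outliers(values)
    assert labels[-1] == "positive"
    assert labels[:-1] == ["inlier"] * 9

    assert classify_outliers([5.0] * 8) == ["inlier"] * 8

    sym = [-3, -2, -1, 0, 1, 2, 3]
    lo, hi = outlier_bounds(sym)
    assert lo == pytest.approx(-hi)


def test_top_event_types_tally():
    sets = {
        "i1": SpliceEventSet("r1", "i1", [SpliceEvent("ES", [], [], host="isoform")]),
        "i2": SpliceEventSet("r2", "i2", [SpliceEvent("ES", [], [], host="isoform"),
                                          SpliceEvent("ALE", [], [])]),
        "i3": SpliceEventSet("r3", "i3", [SpliceEvent("IR", [], [], host="reference")]),
    }
    labels = {"i1": "positive", "i2": "positive", "i3": "negative"}
    ranked = top_event_types(labels, sets, k=5)
    assert ranked["positive"][0] == ("ES", 2)
    assert ranked["negative"] == [("IR", 1)]
    assert top_event_types({}, sets)["positive"] == []
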