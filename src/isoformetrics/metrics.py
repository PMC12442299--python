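"""Per-structure and per-pair geometric metrics for predicted protein models.

Solvent accessibility (Shrake–Rupley with a deterministic Fibonacci sphere),
relative accessibility against the Tien et al. theoretical maxima, surface
charge under a formal-charge model, radius of gyration, simplified
Kabsch–Sander secondary structure, sequence-guided TM-score with the
two-normalization averaging protocol, pLDDT quality classes, window-averaged
pLDDT disorder detection, isolated-helix detection, residue contact maps,
and the IQR outlier rule used for cohort-level comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .align import PairAlignment
from .io import ProteinStructure

__all__ = [
    "VDW_RADII",
    "ATOMIC_MASSES",
    "MAX_ASA_TIEN",
    "RESIDUE_FORMAL_CHARGE",
    "SasaResult",
    "MetricReport",
    "PairReport",
    "shrake_rupley_sasa",
    "relative_accessibility",
    "surface_residues",
    "surface_charge",
    "radius_of_gyration",
    "secondary_structure",
    "ss_percentages",
    "tm_score",
    "mean_plddt",
    "quality_class",
    "idr_regions",
    "idr_fraction",
    "isolated_helices",
    "contact_map",
    "compute_metrics",
    "pair_report",
    "outlier_bounds",
    "classify_outliers",
    "top_event_types",
]

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

# Theoretical maximum ASA per residue type (Å²), Tien et al. 2013.
MAX_ASA_TIEN = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Integer formal charges at pH 7; His neutral, termini uncharged.
RESIDUE_FORMAL_CHARGE = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}


@dataclass
class SasaResult:
    """Per-residue solvent accessibility (absolute Å² and relative fraction)."""

    sasa: np.ndarray
    rsa: np.ndarray | None
    probe_radius: float
    n_points: int


@dataclass
class MetricReport:
    """All per-structure metrics for one model."""

    id: str
    length: int
    mean_plddt: float
    quality_class: str
    ss_percent: tuple[float, float, float]  # helix, sheet, loop (%)
    surface_charge: int
    rg: float
    idr_fraction: float
    isolated_helix_intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class PairReport:
    """Metric differences (isoform − reference) for one pair, plus TM-score."""

    ref_id: str
    iso_id: str
    tm: float
    d_helix: float
    d_sheet: float
    d_loop: float
    d_charge: float
    d_rg: float
    d_idr: float
    d_plddt: float


# ---------------------------------------------------------------------------
# SASA

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere quadrature points."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _canonical_coords(coords: np.ndarray) -> np.ndarray:
    """Rotate/translate coordinates into a canonical molecular frame.

    Principal axes of the centered coordinates, ordered by decreasing
    variance, with signs fixed by the third central moment along each axis
    (falling back to the largest-magnitude component) and det forced to +1.
    Because the quadrature directions are fixed in space, evaluating SASA in
    this frame makes the result exactly invariant under rigid motions of the
    input.
    """
    c = coords - coords.mean(axis=0)
    if len(c) < 2:
        return c
    cov = c.T @ c
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    V = evecs[:, order]
    for k in range(3):
        proj = c @ V[:, k]
        skew = (proj ** 3).sum()
        if abs(skew) > 1e-9:
            sign = np.sign(skew)
        else:
            sign = np.sign(proj[np.argmax(np.abs(proj))]) or 1.0
        V[:, k] *= sign
    if np.linalg.det(V) < 0:
        V[:, 2] *= -1
    return c @ V


def shrake_rupley_sasa(
    structure: ProteinStructure,
    probe: float = 1.4,
    n_points: int = 960,
    max_asa: dict | None = None,
) -> SasaResult:
    """Shrake–Rupley solvent accessible surface area, summed per residue.

    Each atom's solvent sphere (vdW radius + probe) is sampled with a
    deterministic Fibonacci point set evaluated in a canonical molecular
    frame, so the result is exactly invariant under rigid motions of the
    input. Points strictly inside any neighbouring solvent sphere are
    occluded; the exposed fraction scales the sphere area. Of exactly
    coincident equal-radius atoms only the first contributes area.
    """
    atoms = [(ri, a) for ri, r in enumerate(structure.residues) for a in r.atoms]
    if not atoms:
        raise ValueError("structure has no atoms")
    unknown = sorted({a.element for _, a in atoms if a.element not in VDW_RADII})
    if unknown:
        raise ValueError(f"unknown element(s) for SASA radii: {unknown}")
    coords = _canonical_coords(np.array([a.coords for _, a in atoms]))
    radii = np.array([VDW_RADII[a.element] + probe for _, a in atoms])
    sphere = _fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    per_res = np.zeros(len(structure.residues))
    for k, ((ri, _atom), c, r) in enumerate(zip(atoms, coords, radii)):
        pts = c + r * sphere
        neighbours = [j for j in tree.query_ball_point(c, r + max_r) if j != k]
        exposed = np.ones(n_points, dtype=bool)
        duplicate = False
        for j in neighbours:
            if j < k and radii[j] == r and np.array_equal(coords[j], c):
                duplicate = True  # coincident twin: count its sphere once
                break
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 >= radii[j] ** 2 - 1e-9
        if duplicate:
            continue
        area = 4.0 * math.pi * r * r * exposed.sum() / n_points
        per_res[ri] += area

    rsa = relative_accessibility(per_res, structure, max_asa or MAX_ASA_TIEN)
    return SasaResult(sasa=per_res, rsa=rsa, probe_radius=probe, n_points=n_points)


def relative_accessibility(
    sasa: np.ndarray, structure: ProteinStructure, max_asa: dict | None = None
) -> np.ndarray:
    """RSA = SASA / residue-type maximum ASA (unknown residues use the mean)."""
    table = max_asa or MAX_ASA_TIEN
    fallback = float(np.mean(list(table.values())))
    denom = np.array([table.get(r.name, fallback) for r in structure.residues])
    return np.asarray(sasa, dtype=float) / denom


def surface_residues(rsa: np.ndarray, threshold: float = 0.25) -> set[int]:
    """1-based indices of residues with RSA above the threshold."""
    return {i + 1 for i, v in enumerate(np.asarray(rsa)) if v > threshold}


def surface_charge(
    structure: ProteinStructure,
    rsa: np.ndarray,
    threshold: float = 0.25,
    charge_table: dict | None = None,
) -> int:
    """Sum of formal residue charges over surface residues."""
    table = charge_table or RESIDUE_FORMAL_CHARGE
    surf = surface_residues(rsa, threshold)
    return int(sum(table.get(structure.residues[i - 1].name, 0) for i in surf))


# ---------------------------------------------------------------------------
# Radius of gyration

def radius_of_gyration(structure: ProteinStructure) -> float:
    """Mass-weighted RMS distance of atoms from the center of mass (Å)."""
    coords = []
    masses = []
    for r in structure.residues:
        for a in r.atoms:
            if a.element not in ATOMIC_MASSES:
                raise ValueError(f"unknown element {a.element!r} for atomic mass")
            coords.append(a.coords)
            masses.append(ATOMIC_MASSES[a.element])
    coords = np.array(coords)
    masses = np.array(masses)
    center = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    sq = np.einsum("ij,ij->i", coords - center, coords - center)
    return float(math.sqrt((masses * sq).sum() / masses.sum()))


# ---------------------------------------------------------------------------
# Secondary structure (simplified Kabsch–Sander)

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_HB_Q = 0.084 * 332.0


def _backbone_arrays(structure: ProteinStructure):
    n = len(structure.residues)
    N = np.full((n, 3), np.nan)
    CA = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    for i, res in enumerate(structure.residues):
        for name, arr in (("N", N), ("CA", CA), ("C", C), ("O", O)):
            a = res.atom(name)
            if a is not None:
                arr[i] = a.coords
    return N, CA, C, O


def _hbond_matrix(structure: ProteinStructure) -> np.ndarray:
    """hb[d, a] = True if the N-H of residue d donates to the C=O of residue a.

    Amide H is placed 1 Å from N along the previous residue's C=O direction
    (the classic DSSP convention); the first residue has no H and never
    donates. Residues missing backbone atoms never bond.
    """
    N, CA, C, O = _backbone_arrays(structure)
    n = len(N)
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        co = C[i - 1] - O[i - 1]
        norm = np.linalg.norm(co)
        if norm > 0 and np.all(np.isfinite(co)) and np.all(np.isfinite(N[i])):
            H[i] = N[i] + co / norm

    hb = np.zeros((n, n), dtype=bool)
    for d in range(1, n):
        if not np.all(np.isfinite(H[d])):
            continue
        for a in range(n):
            if abs(d - a) < 2:
                continue
            if not (np.all(np.isfinite(O[a])) and np.all(np.isfinite(C[a]))):
                continue
            r_on = np.linalg.norm(O[a] - N[d])
            r_ch = np.linalg.norm(C[a] - H[d])
            r_oh = np.linalg.norm(O[a] - H[d])
            r_cn = np.linalg.norm(C[a] - N[d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clash guard
                continue
            energy = _HB_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if energy < _HB_ENERGY_CUTOFF:
                hb[d, a] = True
    return hb


def secondary_structure(structure: ProteinStructure) -> list[str]:
    """Three-state per-residue assignment: H (helix), E (sheet), L (loop).

    Helices come from consecutive i→i+4 (or i→i+3) hydrogen-bond turns and
    sheets from Kabsch–Sander bridge patterns; everything else is loop.
    Residues with missing backbone atoms are assigned loop.
    """
    n = len(structure.residues)
    if n == 0:
        raise ValueError("empty structure")
    hb = _hbond_matrix(structure)

    def turn(i: int, step: int) -> bool:
        return i + step < n and hb[i + step, i]

    states = ["L"] * n
    # 4-helix (alpha) and 3-helix (3-10, collapsed to H)
    for step in (4, 3):
        for i in range(n - step - 1):
            if turn(i, step) and turn(i + 1, step):
                for j in range(i + 1, i + step + 1):
                    states[j] = "H"

    # bridges
    def hbond(a: int, d: int) -> bool:  # CO of a accepts from NH of d
        return 0 <= a < n and 0 <= d < n and hb[d, a]

    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            antiparallel = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            if parallel or antiparallel:
                if states[i] == "L":
                    states[i] = "E"
                if states[j] == "L":
                    states[j] = "E"
    return states


def ss_percentages(states: list[str]) -> tuple[float, float, float]:
    """(helix %, sheet %, loop %); sums to 100."""
    if not states:
        raise ValueError("empty secondary-structure state list")
    n = len(states)
    h = 100.0 * states.count("H") / n
    e = 100.0 * states.count("E") / n
    return (h, e, 100.0 - h - e)


# ---------------------------------------------------------------------------
# TM-score

def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |R·P + t − Q|²."""
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _tm_d0(L: int) -> float:
    if L <= 15:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def _tm_one_normalization(x: np.ndarray, y: np.ndarray, L_target: int) -> float:
    """Max over fragment-seeded, iteratively refined superpositions."""
    n = len(x)
    d0 = _tm_d0(L_target)

    def score(R, t) -> tuple[float, np.ndarray]:
        d = np.linalg.norm((x @ R.T + t) - y, axis=1)
        return float((1.0 / (1.0 + (d / d0) ** 2)).sum() / L_target), d

    best = 0.0
    frag_lengths = sorted({n, max(n // 2, 4), max(n // 4, 4), 4}, reverse=True)
    for Lf in frag_lengths:
        if Lf > n:
            continue
        step = max(1, Lf // 2)
        starts = list(range(0, n - Lf + 1, step))
        if starts[-1] != n - Lf:
            starts.append(n - Lf)
        for s in starts:
            idx = np.arange(s, s + Lf)
            for _ in range(20):
                R, t = _kabsch(x[idx], y[idx])
                tm, d = score(R, t)
                best = max(best, tm)
                cutoff = d0
                sel = np.where(d < cutoff)[0]
                while len(sel) < 3:
                    cutoff += 0.5
                    sel = np.where(d < cutoff)[0]
                if np.array_equal(sel, idx):
                    break
                idx = sel
    return best


def tm_score(ref: ProteinStructure, iso: ProteinStructure, aln: PairAlignment) -> float:
    """Sequence-guided TM-score averaged over both normalization lengths.

    The residue correspondence is fixed by the alignment; the rigid
    superposition is optimized by fragment-seeded iterative Kabsch
    refinement. The score is computed normalizing by the reference length and
    by the isoform length, and the mean of the two is returned.
    """
    pairs = aln.mapped_pairs()
    if len(pairs) < 3:
        raise ValueError(f"alignment maps only {len(pairs)} residue pairs; need >= 3")
    ref_ca = ref.ca_coords()
    iso_ca = iso.ca_coords()
    x = np.array([ref_ca[r - 1] for r, _ in pairs])
    y = np.array([iso_ca[i - 1] for _, i in pairs])
    tm_ref = _tm_one_normalization(x, y, len(ref))
    tm_iso = _tm_one_normalization(x, y, len(iso))
    return 0.5 * (tm_ref + tm_iso)


# ---------------------------------------------------------------------------
# pLDDT, disorder, isolated helices

def mean_plddt(structure: ProteinStructure) -> float:
    return float(structure.plddt().mean())


def quality_class(mean: float) -> str:
    """pLDDT quality band; boundary values fall into the lower class."""
    if mean > 90.0:
        return "high"
    if mean > 70.0:
        return "confident"
    if mean > 50.0:
        return "low"
    return "very_low"


def _window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at the chain ends."""
    n = len(values)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def idr_regions(
    structure: ProteinStructure,
    window: int = 25,
    cutoff: float = 70.0,
    min_len: int = 20,
) -> list[tuple[int, int]]:
    """Maximal runs (1-based inclusive) of window-averaged pLDDT below cutoff.

    A residue is disordered when the centered ``window``-mean of pLDDT falls
    below ``cutoff``; only runs of at least ``min_len`` residues are reported.
    """
    means = _window_means(structure.plddt(), window)
    disordered = means < cutoff
    intervals = []
    i = 0
    n = len(disordered)
    while i < n:
        if disordered[i]:
            j = i
            while j + 1 < n and disordered[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                intervals.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return intervals


def idr_fraction(structure: ProteinStructure, **kwargs) -> float:
    """Fraction of residues inside reported disordered regions."""
    intervals = idr_regions(structure, **kwargs)
    covered = sum(e - s + 1 for s, e in intervals)
    return covered / len(structure)


def isolated_helices(
    structure: ProteinStructure,
    sasa: SasaResult,
    states: list[str] | None = None,
    min_run: int = 21,
    rsa_threshold: float = 0.25,
) -> list[tuple[int, int]]:
    """Runs of > 20 consecutive exposed helical residues (1-based inclusive).

    These extended solvent-exposed helices are a known artifact of predicted
    models and are used as a filtering criterion, not a structural feature.
    """
    if states is None:
        states = secondary_structure(structure)
    surf = surface_residues(sasa.rsa, rsa_threshold)
    flags = [st == "H" and (i + 1) in surf for i, st in enumerate(states)]
    intervals = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                intervals.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return intervals


# ---------------------------------------------------------------------------
# Contact map

def contact_map(structure: ProteinStructure, cutoff: float = 8.0) -> np.ndarray:
    """Boolean residue×residue CB–CB (CA for Gly) contact matrix."""
    pts = []
    for r in structure.residues:
        a = r.atom("CB") or r.atom("CA")
        if a is None:
            raise ValueError(f"residue {r.index} has neither CB nor CA")
        pts.append(a.coords)
    pts = np.array(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    m = d < cutoff
    np.fill_diagonal(m, False)
    return m


# ---------------------------------------------------------------------------
# Reports

def compute_metrics(
    structure: ProteinStructure,
    rsa_threshold: float = 0.25,
    idr_window: int = 25,
    idr_cutoff: float = 70.0,
    idr_min_len: int = 20,
    helix_min_run: int = 21,
    sasa_n_points: int = 960,
) -> MetricReport:
    """All per-structure metrics in one report."""
    sasa = shrake_rupley_sasa(structure, n_points=sasa_n_points)
    states = secondary_structure(structure)
    mp = mean_plddt(structure)
    return MetricReport(
        id=structure.id,
        length=len(structure),
        mean_plddt=mp,
        quality_class=quality_class(mp),
        ss_percent=ss_percentages(states),
        surface_charge=surface_charge(structure, sasa.rsa, rsa_threshold),
        rg=radius_of_gyration(structure),
        idr_fraction=idr_fraction(
            structure, window=idr_window, cutoff=idr_cutoff, min_len=idr_min_len
        ),
        isolated_helix_intervals=isolated_helices(
            structure, sasa, states, min_run=helix_min_run, rsa_threshold=rsa_threshold
        ),
    )


def pair_report(ref: MetricReport, iso: MetricReport, tm: float) -> PairReport:
    """Metric differences isoform − reference."""
    return PairReport(
        ref_id=ref.id,
        iso_id=iso.id,
        tm=tm,
        d_helix=iso.ss_percent[0] - ref.ss_percent[0],
        d_sheet=iso.ss_percent[1] - ref.ss_percent[1],
        d_loop=iso.ss_percent[2] - ref.ss_percent[2],
        d_charge=iso.surface_charge - ref.surface_charge,
        d_rg=iso.rg - ref.rg,
        d_idr=iso.idr_fraction - ref.idr_fraction,
        d_plddt=iso.mean_plddt - ref.mean_plddt,
    )


# ---------------------------------------------------------------------------
# Outliers

def outlier_bounds(values) -> tuple[float, float]:
    """(Q1 − 1.5·IQR, Q3 + 1.5·IQR) with linearly interpolated quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    return (q1 - 1.5 * iqr, q3 + 1.5 * iqr)


def classify_outliers(values) -> list[str]:
    """Per-value label: 'negative' below, 'positive' above, else 'inlier'."""
    low, high = outlier_bounds(values)
    out = []
    for v in np.asarray(values, dtype=float):
        if v < low:
            out.append("negative")
        elif v > high:
            out.append("positive")
        else:
            out.append("inlier")
    return out


def top_event_types(
    outlier_labels: dict[str, str],
    event_sets: dict[str, "SpliceEventSet"],  # noqa: F821 - forward ref to splice
    k: int = 5,
) -> dict[str, list[tuple[str, int]]]:
    """Top-k splicing-event-type frequencies among positive/negative outliers.

    ``outlier_labels`` maps isoform id → 'positive' / 'negative' / 'inlier';
    ``event_sets`` maps isoform id → its classified SpliceEventSet.
    """
    from collections import Counter

    counts = {"positive": Counter(), "negative": Counter()}
    for iso_id, label in outlier_labels.items():
        if label not in counts or iso_id not in event_sets:
            continue
        for ev in event_sets[iso_id].events:
            counts[label][ev.type] += 1
    return {
        sign: sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        for sign, c in counts.items()
    }
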