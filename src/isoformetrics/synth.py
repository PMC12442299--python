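"""Synthetic-data generators with machine-readable ground truth.

Every input class the pipeline consumes can be generated here: paired
reference/isoform exon chains exhibiting each of the nine splicing types,
idealized protein structures with controlled secondary structure and pLDDT
profiles, structure pairs with planted deletions/insertions, MSAs with
controlled identity to the query, single-cell expression matrices with
planted cell-type-specific isoform switches, regression datasets with known
coefficients, and homology-hit tables with controlled GO labels.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    Atom,
    GenomicInterval,
    MSA,
    ProteinStructure,
    Residue,
    TranscriptModel,
    one_to_three,
)

__all__ = [
    "StructureSpec",
    "SwitchSpec",
    "make_ideal_structure",
    "make_structure_pair",
    "make_transcript_pair",
    "EVENT_TYPES",
    "make_msa",
    "make_expression",
    "make_regression_dataset",
    "make_hit_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Ideal backbone internal coordinates (Engh & Huber averages).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.229, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.6, 121.7, 120.8
_DIHEDRALS = {"helix": (-57.0, -47.0), "strand": (-119.0, 113.0)}


@dataclass
class StructureSpec:
    """Blueprint for an idealized structure: secondary-structure segments.

    Each segment is ``(kind, length, plddt)`` with kind in
    ``{"helix", "strand", "coil"}``; pLDDT is written to the B-factor column.
    """

    segments: list[tuple[str, int, float]]
    sequence: str | None = None

    def __post_init__(self) -> None:
        for kind, length, plddt in self.segments:
            if kind not in ("helix", "strand", "coil"):
                raise ValueError(f"unknown segment kind {kind!r}")
            if length < 1:
                raise ValueError("segment length must be >= 1")
            if not 0.0 <= plddt <= 100.0:
                raise ValueError("pLDDT must lie in [0, 100]")
        n = sum(length for _, length, _ in self.segments)
        if self.sequence is not None and len(self.sequence) != n:
            raise ValueError(
                f"sequence length {len(self.sequence)} != total segment length {n}"
            )

    @property
    def length(self) -> int:
        return sum(length for _, length, _ in self.segments)

    def per_residue(self) -> list[tuple[str, float]]:
        out = []
        for kind, length, plddt in self.segments:
            out.extend([(kind, plddt)] * length)
        return out


@dataclass
class SwitchSpec:
    """Planted cell-type-specific isoform switch for one gene.

    ``preferred_map`` assigns each switching isoform the cell type in which its
    mean log2 expression is raised by ``effect``; counts are drawn from a
    negative binomial (dispersion ``dispersion``) around cell-wise means with
    log-normal noise of sd ``noise_sd``.
    """

    gene_id: str
    isoform_ids: list[str]
    cell_types: list[str]
    preferred_map: dict[str, str]
    effect: float = 5.0
    noise_sd: float = 0.5
    n_cells: int = 100
    seed: int = 0
    base_log2_tpm: float = 4.0
    dispersion: float = 0.1
    tissues: list[str] | None = None
    tissue_preferred_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        prefs = list(self.preferred_map.values())
        if len(prefs) != len(set(prefs)):
            raise ValueError("switching isoforms must prefer distinct cell types")
        for iso, ct in self.preferred_map.items():
            if iso not in self.isoform_ids or ct not in self.cell_types:
                raise ValueError(f"preferred_map entry {iso!r}->{ct!r} outside spec")


# ---------------------------------------------------------------------------
# Geometry

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a new atom from three predecessors by internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _default_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _build_backbone(per_residue: list[tuple[str, float]], sequence: str,
                    rng: np.random.Generator) -> ProteinStructure:
    n = len(per_residue)
    phis = np.empty(n)
    psis = np.empty(n)
    for i, (kind, _) in enumerate(per_residue):
        if kind == "coil":
            # random-walk dihedrals, drawn per residue from the seeded stream
            phis[i] = rng.uniform(-180.0, 180.0)
            psis[i] = rng.uniform(-180.0, 180.0)
        else:
            phis[i], psis[i] = _DIHEDRALS[kind]

    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psis[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phis[i])

    residues = []
    for i in range(n):
        plddt = per_residue[i][1]
        resname = one_to_three(sequence[i])
        atoms = [
            Atom("N", "N", N[i], bfactor=plddt),
            Atom("CA", "C", CA[i], bfactor=plddt),
            Atom("C", "C", C[i], bfactor=plddt),
        ]
        # carbonyl O in the peptide plane (anti to the next N; psi-based at the C-terminus)
        if i < n - 1:
            O = _place_atom(N[i + 1], CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0)
        else:
            O = _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psis[i] + 180.0)
        atoms.append(Atom("O", "O", O, bfactor=plddt))
        if resname != "GLY":
            CB = _place_atom(C[i], N[i], CA[i], _B_CA_CB, 110.4, -122.55)
            atoms.append(Atom("CB", "C", CB, bfactor=plddt))
        residues.append(Residue(index=i + 1, name=resname, atoms=atoms))
    return ProteinStructure(id="synthetic", residues=residues)


def make_ideal_structure(spec: StructureSpec, seed: int = 0,
                         id: str = "synthetic") -> ProteinStructure:
    """Build an idealized backbone (N, CA, C, O, CB except Gly) from a spec.

    α-helix uses φ=−57°, ψ=−47°; β-strand φ=−119°, ψ=113°; coil residues get
    seeded random-walk dihedrals. B-factors carry the spec's pLDDT values.
    """
    rng = np.random.default_rng(seed)
    per_res = spec.per_residue()
    sequence = spec.sequence or _default_sequence(len(per_res), rng)
    structure = _build_backbone(per_res, sequence, rng)
    structure.id = id
    return structure


def make_structure_pair(
    ref_spec: StructureSpec,
    edit: dict | None = None,
    seed: int = 0,
) -> tuple[ProteinStructure, ProteinStructure, dict]:
    """Build a reference structure and an isoform carrying planted edits.

    ``edit`` holds ``delete``: list of 1-based inclusive residue intervals of
    the reference to remove, and ``insert``: list of ``(pos, (kind, length,
    plddt))`` segments inserted *after* reference position ``pos`` (0 = before
    the first residue). The isoform is rebuilt from the edited per-residue
    spec, so geometry downstream of an edit is regenerated. ``truth`` records
    the deleted reference positions and inserted isoform positions.
    """
    edit = edit or {}
    deletions: list[tuple[int, int]] = [tuple(iv) for iv in edit.get("delete", [])]
    insertions: list[tuple[int, tuple[str, int, float]]] = [
        (int(pos), tuple(seg)) for pos, seg in edit.get("insert", [])
    ]
    n_ref = ref_spec.length
    covered: set[int] = set()
    for start, end in deletions:
        if not (1 <= start <= end <= n_ref):
            raise ValueError(f"delete interval ({start},{end}) outside 1..{n_ref}")
        span = set(range(start, end + 1))
        if covered & span:
            raise ValueError("overlapping delete intervals")
        covered |= span
    ins_positions = [pos for pos, _ in insertions]
    if len(ins_positions) != len(set(ins_positions)):
        raise ValueError("overlapping insertions (duplicate positions)")
    for pos in ins_positions:
        if not 0 <= pos <= n_ref:
            raise ValueError(f"insert position {pos} outside 0..{n_ref}")

    rng = np.random.default_rng(seed)
    per_res_ref = ref_spec.per_residue()
    ref_sequence = ref_spec.sequence or _default_sequence(n_ref, rng)

    # assemble the edited per-residue blueprint 5'→3'
    ins_by_pos = dict(insertions)
    iso_entries: list[tuple[str, float, str, int | None]] = []  # kind, plddt, aa, ref_pos
    inserted_iso_positions: list[int] = []

    def _append_insert(pos: int) -> None:
        if pos in ins_by_pos:
            kind, length, plddt = ins_by_pos[pos]
            aa = _default_sequence(length, np.random.default_rng(seed + 7919 + pos))
            for j in range(length):
                iso_entries.append((kind, plddt, aa[j], None))

    _append_insert(0)
    for i in range(1, n_ref + 1):
        if i not in covered:
            kind, plddt = per_res_ref[i - 1]
            iso_entries.append((kind, plddt, ref_sequence[i - 1], i))
        _append_insert(i)

    iso_per_res = [(k, p) for k, p, _, _ in iso_entries]
    iso_sequence = "".join(aa for _, _, aa, _ in iso_entries)
    inserted_iso_positions = [j + 1 for j, (_, _, _, rp) in enumerate(iso_entries) if rp is None]

    ref = _build_backbone(per_res_ref, ref_sequence, np.random.default_rng(seed))
    ref.id = "ref"
    iso = _build_backbone(iso_per_res, iso_sequence, np.random.default_rng(seed))
    iso.id = "iso"
    truth = {
        "deleted": sorted(covered),
        "inserted": inserted_iso_positions,
        "ref_sequence": ref_sequence,
        "iso_sequence": iso_sequence,
    }
    return ref, iso, truth


# ---------------------------------------------------------------------------
# Transcript pairs for the nine splicing event types

EVENT_TYPES = ("ES", "ADS", "AAS", "MXE", "IR", "AFE", "ALE", "MXE-AFE", "MXE-ALE")

# canonical '+'-strand fixtures: (ref exons, iso exons, delta_nt, host)
_FIXTURES: dict[str, tuple[list, list, int, str]] = {
    "ES": ([(1, 100), (201, 300), (401, 500)], [(1, 100), (401, 500)], -100, "isoform"),
    "ADS": ([(1, 100), (201, 300)], [(1, 150), (201, 300)], 50, "both"),
    "AAS": ([(1, 100), (201, 300)], [(1, 100), (151, 300)], 50, "both"),
    "MXE": ([(1, 100), (201, 300), (401, 500)], [(1, 100), (321, 380), (401, 500)], -40, "both"),
    "IR": ([(1, 100), (201, 300)], [(1, 300)], 100, "isoform"),
    "AFE": ([(1, 100), (201, 300)], [(31, 100), (201, 300)], -30, "both"),
    "ALE": ([(1, 100), (201, 300)], [(1, 100), (201, 270)], -30, "both"),
    "MXE-AFE": ([(1, 100), (201, 300)], [(121, 160), (201, 300)], -60, "both"),
    "MXE-ALE": ([(1, 100), (201, 300)], [(1, 100), (321, 390)], -30, "both"),
}


def make_transcript_pair(
    event_type: str,
    strand: str = "+",
    chrom: str = "chr1",
    gene_id: str = "GENE1",
    offset: int = 0,
) -> tuple[TranscriptModel, TranscriptModel, dict]:
    """Build a reference/isoform transcript pair exhibiting exactly one event.

    The '−'-strand variant mirrors the '+'-strand fixture through the genomic
    axis, so classification must be identical after orientation normalization.
    """
    if event_type not in _FIXTURES:
        raise ValueError(f"unknown event type {event_type!r}; expected one of {EVENT_TYPES}")
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    ref_iv, iso_iv, delta, host = _FIXTURES[event_type]

    span = 1000  # mirror axis for '-' strand

    def _to_exons(pairs: list) -> list[GenomicInterval]:
        out = []
        for s, e in pairs:
            if strand == "-":
                s, e = span + 1 - e, span + 1 - s
            out.append(GenomicInterval(chrom, s + offset, e + offset, strand))
        # order 5'→3' in transcript orientation
        out.sort(key=lambda iv: iv.start, reverse=(strand == "-"))
        return out

    ref = TranscriptModel(f"{gene_id}-ref", gene_id, _to_exons(ref_iv), is_reference=True)
    iso = TranscriptModel(f"{gene_id}-iso", gene_id, _to_exons(iso_iv))
    truth = {"type": event_type, "delta_nt": delta, "host": host}
    return ref, iso, truth


# ---------------------------------------------------------------------------
# MSAs

def make_msa(n_rows: int, identity_to_query: float, seed: int = 0,
             query_length: int = 80) -> MSA:
    """Generate an MSA whose rows are mutated copies of a random query.

    Each non-query row differs from the query independently per position at
    rate ``1 − identity_to_query``; substitutions never recreate the original
    residue. The first row is the query itself.
    """
    if not 0.0 <= identity_to_query <= 1.0:
        raise ValueError("identity_to_query must lie in [0, 1]")
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    query = _default_sequence(query_length, rng)
    rows = [query]
    alphabet = np.array(list(AMINO_ACIDS))
    for _ in range(n_rows - 1):
        chars = np.array(list(query))
        mutate = rng.random(query_length) < (1.0 - identity_to_query)
        for i in np.where(mutate)[0]:
            choices = alphabet[alphabet != chars[i]]
            chars[i] = rng.choice(choices)
        rows.append("".join(chars))
    return MSA(query=query, rows=rows)


# ---------------------------------------------------------------------------
# Expression matrices with planted switches

def make_expression(
    specs: SwitchSpec | Sequence[SwitchSpec],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, dict]:
    """Generate a cells × transcripts count matrix with planted switches.

    Accepts one spec or a list sharing ``cell_types``/``n_cells``/``tissues``
    (genes are concatenated column-wise over the same cells). Returns
    ``(counts, cell_metadata, transcript_lengths, truth)`` where truth maps
    gene_id → its spec.
    """
    if isinstance(specs, SwitchSpec):
        specs = [specs]
    if not specs:
        raise ValueError("no switch specs given")
    first = specs[0]
    for s in specs[1:]:
        if (s.cell_types, s.n_cells, s.tissues) != (first.cell_types, first.n_cells, first.tissues):
            raise ValueError("all specs must share cell_types, n_cells and tissues")

    tissues = first.tissues or ["primary"]
    cells = []
    for ct in first.cell_types:
        for tis in tissues:
            for i in range(first.n_cells):
                cells.append((f"{ct}.{tis}.{i}", ct, tis))
    meta = pd.DataFrame(cells, columns=["cell_id", "cell_type", "tissue"]).set_index("cell_id")

    columns = {}
    lengths = {}
    truth = {}
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        for iso in spec.isoform_ids:
            lengths[iso] = int(rng.integers(500, 3001))
            log2_mu = np.full(len(meta), spec.base_log2_tpm)
            pref_ct = spec.preferred_map.get(iso)
            if pref_ct is not None:
                log2_mu[meta["cell_type"].to_numpy() == pref_ct] += spec.effect
            pref_tis = (spec.tissue_preferred_map or {}).get(iso)
            if pref_tis is not None:
                log2_mu[meta["tissue"].to_numpy() == pref_tis] += spec.effect
            log2_mu = log2_mu + rng.normal(0.0, spec.noise_sd, size=len(meta))
            mu = np.exp2(log2_mu)
            # negative binomial: var = mu + dispersion * mu^2
            if spec.dispersion > 0:
                r = 1.0 / spec.dispersion
                p = r / (r + mu)
                counts = rng.negative_binomial(r, p)
            else:
                counts = rng.poisson(mu)
            columns[iso] = counts
        truth[spec.gene_id] = spec
    counts = pd.DataFrame(columns, index=meta.index)
    return counts, meta, pd.Series(lengths, name="length"), truth


# ---------------------------------------------------------------------------
# Regression datasets

def make_regression_dataset(
    beta: Sequence[float] | dict[str, float],
    n: int,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian design with outcomes ``X @ beta + N(0, noise_sd)``."""
    if isinstance(beta, dict):
        names = list(beta)
        b = np.array([beta[k] for k in names], dtype=float)
    else:
        b = np.asarray(beta, dtype=float)
        names = [f"x{i}" for i in range(len(b))]
    if n <= len(b):
        raise ValueError("n must exceed the number of features")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(b)))
    y = X @ b + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(X, columns=names), y


# ---------------------------------------------------------------------------
# Homology-hit tables

def make_hit_table(
    n_hits: int,
    fraction_with_term: float,
    score_ranges: dict | None = None,
    seed: int = 0,
    term: str = "GO:0000001",
) -> pd.DataFrame:
    """Hit table with bitscore/identity/tm/string_score and GO label sets.

    A hit carries ``term`` with probability ``fraction_with_term`` (the first
    ``round(n_hits * fraction)`` hits carry it, so the fraction is exact).
    """
    if not 0.0 <= fraction_with_term <= 1.0:
        raise ValueError("fraction_with_term must lie in [0, 1]")
    ranges = {
        "bitscore": (50.0, 500.0),
        "identity": (0.2, 1.0),
        "tm": (0.3, 1.0),
        "string_score": (150.0, 999.0),
    }
    ranges.update(score_ranges or {})
    rng = np.random.default_rng(seed)
    n_with = int(round(n_hits * fraction_with_term))
    rows = []
    for i in range(n_hits):
        rows.append({
            "hit_id": f"hit{i}",
            "bitscore": rng.uniform(*ranges["bitscore"]),
            "identity": rng.uniform(*ranges["identity"]),
            "tm": rng.uniform(*ranges["tm"]),
            "string_score": rng.uniform(*ranges["string_score"]),
            "go_terms": frozenset({term}) if i < n_with else frozenset(),
        })
    return pd.DataFrame(rows)
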