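"""Readers/writers for the standard formats the pipeline touches, and shared domain types.

The pipeline consumes AlphaFold-style single-chain PDB models (per-residue
confidence in the B-factor column), GENCODE-style GTF transcript annotations,
aligned FASTA / A3M multiple sequence alignments, and headered TSV tables
(PTM sites, homology hits, expression counts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "GenomicInterval",
    "TranscriptModel",
    "MSA",
    "PTMRecord",
    "PTM_TYPES",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_msa",
    "read_table",
    "read_ptm_table",
    "three_to_one",
]

# Standard 20 amino acids; anything else maps to 'X'.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

PTM_TYPES = frozenset({
    "phosphorylation", "ubiquitination", "acetylation", "methylation",
    "O-GalNAc", "O-GlcNAc", "sumoylation",
})


def three_to_one(resname: str) -> str:
    """Map a 3-letter residue code to its 1-letter code ('X' if non-standard)."""
    return _THREE_TO_ONE.get(resname.strip().upper(), "X")


def one_to_three(letter: str) -> str:
    try:
        return _ONE_TO_THREE[letter.upper()]
    except KeyError:
        raise ValueError(f"no 3-letter code for residue letter {letter!r}") from None


class PDBParseError(ValueError):
    """Raised for malformed ATOM records; carries the offending line number."""


@dataclass
class Atom:
    """A single atom: label, element, coordinates (Å) and per-atom confidence.

    ``bfactor`` holds pLDDT (0-100) for AlphaFold-derived models.
    """

    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")


@dataclass
class Residue:
    """One residue: 1-based index, 3-letter name, ordered atoms."""

    index: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def letter(self) -> str:
        return three_to_one(self.name)


@dataclass
class ProteinStructure:
    """A parsed single-chain atomic model; substrate of all geometry."""

    id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self, atom_names: Sequence[str] | None = None) -> np.ndarray:
        """All atom coordinates (optionally restricted to named atoms), (n, 3)."""
        pts = [
            a.coords
            for r in self.residues
            for a in r.atoms
            if atom_names is None or a.name in atom_names
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def ca_coords(self) -> np.ndarray:
        out = []
        for r in self.residues:
            ca = r.atom("CA")
            if ca is None:
                raise ValueError(f"residue {r.index} ({r.name}) has no CA atom")
            out.append(ca.coords)
        return np.array(out, dtype=float)

    def plddt(self) -> np.ndarray:
        """Per-residue pLDDT = B-factor of the CA atom (first atom if no CA)."""
        vals = []
        for r in self.residues:
            ca = r.atom("CA") or r.atoms[0]
            vals.append(ca.bfactor)
        return np.array(vals, dtype=float)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass
class TranscriptModel:
    """Ordered exon chain of one transcript (5'→3' in transcript orientation)."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple chromosomes/strands"
            )
        starts = [e.start for e in self.exons]
        if self.strand == "+":
            ok = all(self.exons[i].end < self.exons[i + 1].start for i in range(len(self.exons) - 1))
        else:
            ok = all(self.exons[i].start > self.exons[i + 1].end for i in range(len(self.exons) - 1))
        if not ok:
            raise ValueError(
                f"transcript {self.transcript_id}: exons overlap or are out of "
                f"transcription order (starts={starts}, strand={self.strand})"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length_nt(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass
class MSA:
    """A multiple sequence alignment; first row is the ungapped-relative query."""

    query: str
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA has no rows")
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(f"MSA row {i} has length {len(row)}, expected {width}")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class PTMRecord:
    """One post-translational-modification site on one protein."""

    protein_id: str
    position: int
    residue: str
    ptm_type: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"PTM position must be >= 1, got {self.position}")
        if self.ptm_type not in PTM_TYPES:
            raise ValueError(
                f"unknown ptm_type {self.ptm_type!r}; expected one of {sorted(PTM_TYPES)}"
            )


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path: str | Path, id: str | None = None) -> ProteinStructure:
    """Parse ATOM records of a PDB file into a :class:`ProteinStructure`.

    Only the first chain is kept (the pipeline handles monomer models); for
    alternate locations the first altloc is kept. The B-factor column is
    preserved per atom, so AlphaFold pLDDT values survive a round-trip.
    """
    path = Path(path)
    residues: list[Residue] = []
    current: Residue | None = None
    kept_chain: str | None = None
    seen_other_chain = False
    seen_altloc: set[tuple[int, str]] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                if line.startswith(("TER", "ENDMDL", "END")) and residues:
                    break
                continue
            try:
                name = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:20].strip()
                chain = line[21]
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
                bfac = float(line[60:66]) if line[60:66].strip() else 0.0
                element = line[76:78].strip() if len(line) >= 78 else ""
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"{path.name}: malformed ATOM record at line {lineno}: {exc}")
            if kept_chain is None:
                kept_chain = chain
            if chain != kept_chain:
                seen_other_chain = True
                continue
            if not element:
                element = name[0] if name and name[0].isalpha() else "C"
            if altloc:
                key = (resseq, name)
                if key in seen_altloc:
                    continue
                seen_altloc.add(key)
            if current is None or current.index != resseq:
                if current is not None and resseq < current.index:
                    raise PDBParseError(
                        f"{path.name}: residue numbering decreases at line {lineno}"
                    )
                current = Residue(index=resseq, name=resname)
                residues.append(current)
            current.atoms.append(
                Atom(name=name, element=element, coords=np.array([x, y, z]), bfactor=bfac,
                     occupancy=occ)
            )
    if not residues:
        raise PDBParseError(f"{path.name}: no ATOM records found")
    if seen_other_chain:
        warnings.warn(f"{path.name}: multiple chains found, kept chain {kept_chain!r}")
    return ProteinStructure(id=id or path.stem, residues=residues)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write fixed-column PDB ATOM records (coords at 3 decimals, B at 2)."""
    lines = []
    serial = 0
    for res in structure.residues:
        if len(res.name.strip()) != 3:
            raise ValueError(f"residue name {res.name!r} is not 3 letters")
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.coords
            if max(abs(x), abs(y), abs(z)) > 9999.999:
                raise ValueError(
                    f"coordinate overflow at residue {res.index} atom {atom.name}: "
                    "PDB fixed columns hold at most 9999.999 Å"
                )
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.name:>3s} A{res.index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                f"          {atom.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features of a GTF into :class:`TranscriptModel` objects.

    Exons are sorted 5'→3' in transcript orientation (descending genomic start
    on the '−' strand). Non-exon features are ignored.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tids = feat.attributes.get("transcript_id")
        gids = feat.attributes.get("gene_id")
        if not tids:
            raise ValueError(f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks transcript_id")
        tid = tids[0]
        gid = gids[0] if gids else tid
        entry = by_tx.setdefault(tid, {"gene_id": gid, "exons": []})
        entry["exons"].append(
            GenomicInterval(chrom=feat.seqid, start=feat.start, end=feat.end, strand=feat.strand)
        )
    models = []
    for tid, entry in by_tx.items():
        exons = entry["exons"]
        strands = {e.strand for e in exons}
        if len(strands) > 1:
            raise ValueError(f"transcript {tid}: exons on mixed strands {sorted(strands)}")
        reverse = exons[0].strand == "-"
        exons = sorted(exons, key=lambda e: e.start, reverse=reverse)
        models.append(TranscriptModel(transcript_id=tid, gene_id=entry["gene_id"], exons=exons))
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    lines = []
    for tx in transcripts:
        for exon in sorted(tx.exons, key=lambda e: e.start):
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            lines.append(
                f"{exon.chrom}\tisoformetrics\texon\t{exon.start}\t{exon.end}\t.\t"
                f"{exon.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA / A3M

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA or A3M file; the first record is the query.

    A3M lowercase columns are insertions relative to the query and are removed,
    so every row has exactly the query's aligned length.
    """
    records = read_fasta(path)
    if not records:
        raise ValueError(f"{path}: empty alignment file")
    rows = []
    for name, seq in records:
        mapped = "".join(c for c in seq if not c.islower()).replace(".", "-").upper()
        rows.append(mapped)
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: row {i} ({records[i][0]}) has mapped length {len(row)}, "
                f"expected {width}"
            )
    query = rows[0].replace("-", "")
    return MSA(query=query, rows=rows)


# ---------------------------------------------------------------------------
# TSV tables

def read_table(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    """Read a headered TSV, checking and coercing required columns.

    ``schema`` maps required column names to dtypes; unknown extra columns are
    preserved untouched.
    """
    df = pd.read_csv(path, sep="\t")
    for col, dtype in schema.items():
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {col!r} is not coercible to {dtype}: {exc}")
    return df


def read_ptm_table(path: str | Path) -> list[PTMRecord]:
    df = read_table(path, {"protein_id": str, "position": int, "residue": str, "ptm_type": str})
    return [
        PTMRecord(
            protein_id=row.protein_id, position=int(row.position),
            residue=row.residue, ptm_type=row.ptm_type,
        )
        for row in df.itertuples()
    ]
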