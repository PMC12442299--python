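"""Mapping and classification of PTM sites between isoform pairs.

Each site is mapped through the pair alignment and classified into exactly
one of five categories: unchanged, spliced_out (reference site with no
isoform partner), spliced_in (isoform-only site with no reference partner),
buried_to_exposed, or exposed_to_buried. Exposure uses relative solvent
accessibility with the same threshold as surface-residue detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import PairAlignment
from .io import ProteinStructure, PTMRecord
from .metrics import SasaResult, shrake_rupley_sasa

__all__ = [
    "PTM_CATEGORIES",
    "PTMClassification",
    "map_site",
    "classify_ptm",
    "ptm_summary",
]

PTM_CATEGORIES = (
    "unchanged",
    "spliced_out",
    "spliced_in",
    "buried_to_exposed",
    "exposed_to_buried",
)


@dataclass
class PTMClassification:
    record: PTMRecord
    category: str
    ref_position: int | None = None
    iso_position: int | None = None
    ref_sasa: float | None = None
    iso_sasa: float | None = None
    ref_rsa: float | None = None
    iso_rsa: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in PTM_CATEGORIES:
            raise ValueError(f"unknown PTM category {self.category!r}")

    @property
    def flagged(self) -> bool:
        return "sequence_mismatch" in self.flags


def map_site(site: PTMRecord, aln: PairAlignment, direction: str) -> int | None:
    """Map a site position through the alignment; None when it hits a gap.

    ``direction`` is 'ref_to_iso' or 'iso_to_ref'. Mapping is an involution:
    a mapped site maps back to its original position.
    """
    if direction not in ("ref_to_iso", "iso_to_ref"):
        raise ValueError(f"direction must be 'ref_to_iso' or 'iso_to_ref', got {direction!r}")
    src, dst = (0, 1) if direction == "ref_to_iso" else (1, 0)
    for col in aln.columns:
        if col[src] == site.position:
            return col[dst]
    raise ValueError(
        f"position {site.position} of {site.protein_id} not covered by the alignment"
    )


def classify_ptm(
    site: PTMRecord,
    ref_struct: ProteinStructure,
    iso_struct: ProteinStructure,
    aln: PairAlignment,
    rsa_threshold: float = 0.25,
    ref_sasa: SasaResult | None = None,
    iso_sasa: SasaResult | None = None,
) -> PTMClassification:
    """Classify one PTM site's fate between reference and isoform.

    The site lives on the side whose id matches ``site.protein_id`` (the
    reference by default). Reference-side sites that map to an isoform gap are
    spliced_out; isoform-only sites that cannot be reverse-mapped are
    spliced_in; mapped sites are compared by exposure (RSA > threshold).
    A mismatch between the site's stated residue and the sequence flags the
    record (excluded from summary counts); a mapped column whose two amino
    acids differ is classified normally but flagged ``residue_changed``.
    """
    on_iso = site.protein_id == aln.iso_id
    src_seq = aln.iso_seq if on_iso else aln.ref_seq
    flags: list[str] = []
    if site.position > len(src_seq):
        raise ValueError(
            f"site position {site.position} beyond {site.protein_id} length {len(src_seq)}"
        )
    if src_seq[site.position - 1] != site.residue.upper():
        flags.append("sequence_mismatch")

    partner = map_site(site, aln, "iso_to_ref" if on_iso else "ref_to_iso")
    ref_pos = partner if on_iso else site.position
    iso_pos = site.position if on_iso else partner

    if iso_pos is None:
        return PTMClassification(site, "spliced_out", ref_position=ref_pos, flags=flags)
    if ref_pos is None:
        return PTMClassification(site, "spliced_in", iso_position=iso_pos, flags=flags)

    if aln.ref_seq[ref_pos - 1] != aln.iso_seq[iso_pos - 1]:
        flags.append("residue_changed")

    ref_sasa = ref_sasa or shrake_rupley_sasa(ref_struct)
    iso_sasa = iso_sasa or shrake_rupley_sasa(iso_struct)
    r_abs = float(ref_sasa.sasa[ref_pos - 1])
    i_abs = float(iso_sasa.sasa[iso_pos - 1])
    r_rsa = float(ref_sasa.rsa[ref_pos - 1])
    i_rsa = float(iso_sasa.rsa[iso_pos - 1])
    ref_exposed = r_rsa > rsa_threshold
    iso_exposed = i_rsa > rsa_threshold
    if ref_exposed == iso_exposed:
        category = "unchanged"
    elif iso_exposed:
        category = "buried_to_exposed"
    else:
        category = "exposed_to_buried"
    return PTMClassification(
        site, category, ref_position=ref_pos, iso_position=iso_pos,
        ref_sasa=r_abs, iso_sasa=i_abs, ref_rsa=r_rsa, iso_rsa=i_rsa, flags=flags,
    )


def ptm_summary(classifications: list[PTMClassification]) -> pd.DataFrame:
    """Category × PTM-type contingency table (flagged records excluded)."""
    from .io import PTM_TYPES

    table = pd.DataFrame(
        0, index=list(PTM_CATEGORIES), columns=sorted(PTM_TYPES), dtype=int
    )
    for c in classifications:
        if c.flagged:
            continue
        table.loc[c.category, c.record.ptm_type] += 1
    return table
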