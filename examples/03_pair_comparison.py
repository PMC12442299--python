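"""Pairwise comparison: alignment, region labels, TM-score, metric deltas.

Builds a reference structure and an isoform missing a 10-residue segment,
then reports sequence identity, the splicing-region labels, the averaged
TM-score and the metric differences (isoform minus reference).
"""

from isoformetrics.align import global_align, label_regions, sequence_identity
from isoformetrics.metrics import compute_metrics, pair_report, tm_score
from isoformetrics.synth import StructureSpec, make_structure_pair

spec = StructureSpec([("helix", 25, 92.0), ("coil", 10, 80.0), ("helix", 15, 92.0)])
ref, iso, truth = make_structure_pair(spec, {"delete": [(26, 35)]}, seed=42)

aln = global_align(ref.sequence, iso.sequence, ref_id="ref", iso_id="iso")
labels = label_regions(aln)
missing = labels.positions("missing", "ref", aln)
print(f"identity {sequence_identity(aln):.3f}; "
      f"missing region = residues {min(missing)}-{max(missing)} "
      f"(planted: {truth['deleted'][0]}-{truth['deleted'][-1]})")

tm = tm_score(ref, iso, aln)
pr = pair_report(compute_metrics(ref), compute_metrics(iso), tm)
print(f"TM-score (mean of both normalizations): {tm:.3f}")
print(f"d_helix {pr.d_helix:+.1f}%  d_charge {pr.d_charge:+d}  "
      f"d_rg {pr.d_rg:+.2f} A  d_pLDDT {pr.d_plddt:+.1f}")
# Deleting the coil linker makes the isoform proportionally more helical
# (d_helix > 0); because the chain is rebuilt downstream of the edit, the
# two helices adopt a new relative orientation, which shows up in both the
# TM-score and the radius-of-gyration difference.
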