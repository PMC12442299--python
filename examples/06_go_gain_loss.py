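"""Template-based GO scoring, isoform gain/loss, and enrichment.

Channel scores are weighted fractions of annotated homology hits / PPI
partners; the consensus (default: mean of available channels) is thresholded
at 0.6 to form each isoform's confident term set.
"""

from isoformetrics.go import (
    combine_scores,
    confident_terms,
    cscore_ppi,
    cscore_sequence,
    cscore_structure,
    enrichment_test,
    gain_loss,
)
from isoformetrics.synth import make_hit_table

ref_scores = {}
iso_scores = {}
for term, ref_frac, iso_frac in [("GO:0003841", 0.9, 0.2), ("GO:0016411", 0.8, 0.8),
                                 ("GO:0005515", 0.3, 0.9)]:
    for scores, frac, seed in ((ref_scores, ref_frac, 1), (iso_scores, iso_frac, 2)):
        hits = make_hit_table(20, frac, seed=seed, term=term)
        scores[term] = combine_scores({
            "sequence": cscore_sequence(hits, term),
            "structure": cscore_structure(hits, term),
            "ppi": cscore_ppi(hits, term),
        })
        print(f"{term} ({'ref' if scores is ref_scores else 'iso'}): "
              f"consensus {scores[term]:.2f}")

ref_terms = confident_terms(ref_scores)
iso_terms = confident_terms(iso_scores)
gained, lost = gain_loss(ref_terms, iso_terms)
print(f"\nconfident ref terms: {sorted(ref_terms)}")
print(f"confident iso terms: {sorted(iso_terms)}")
print(f"gained: {sorted(gained)}  lost: {sorted(lost)}")

# is losing this term enriched among, say, exon-skipping isoforms?
p = enrichment_test(k=4, M=40, n=8, N=10)
print(f"\nenrichment of a term lost by 4 of 10 ES isoforms "
      f"(8 losers among 40 total): p = {p:.4f}")
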