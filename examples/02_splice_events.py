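"""Splice-event classification between a reference and isoform transcript.

Generates an exon-skipping pair plus a two-event isoform and prints the
classified events with their nt length changes and the regression features.
"""

from isoformetrics.io import GenomicInterval, TranscriptModel
from isoformetrics.splice import compare_exon_chains, event_length_features
from isoformetrics.synth import make_transcript_pair

ref, iso, truth = make_transcript_pair("ES")
events = compare_exon_chains(ref, iso)
print(f"planted {truth['type']}: classified as "
      f"{[(e.type, e.host, e.delta_nt) for e in events.events]}")

# an isoform carrying two events at once: a donor-site shift plus a skipped exon
ref2 = TranscriptModel("r2", "G2", [GenomicInterval("chr1", s, e, "+")
                                    for s, e in [(1, 100), (201, 300), (401, 500), (601, 700)]])
iso2 = TranscriptModel("i2", "G2", [GenomicInterval("chr1", s, e, "+")
                                    for s, e in [(1, 130), (201, 300), (601, 700)]])
events2 = compare_exon_chains(ref2, iso2)
print("two-event isoform:", [(e.type, e.delta_nt) for e in events2.events])

feats, ambiguous = event_length_features(events2, mode="signed", units="nt")
print("signed features (nt):")
print(feats[feats != 0].to_string())
# delta_nt is isoform minus reference; ES host=isoform means the reference
# exon is skipped in the isoform, so its delta is negative.
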