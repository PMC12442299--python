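"""Classification of alternative-splicing events between transcript pairs.

Nine event types are distinguished: exon skipping (ES), alternative donor
site (ADS), alternative acceptor site (AAS), mutually exclusive exons (MXE),
intron retention (IR), alternative first/last exon (AFE/ALE) and their
mutually exclusive variants (MXE-AFE/MXE-ALE). Multiple events may occur in
a single isoform.

The classifier normalizes both transcripts to transcription orientation,
anchors on exactly-shared exons (longest common subsequence), then walks
the unmatched gaps 5'→3' and assigns every unmatched exon to exactly one
event according to a fixed rule set:

* internal ref-only gap with the isoform junction preserved → ES (host =
  isoform; symmetric case host = reference);
* internal one-exon-per-side, mutually non-overlapping → MXE;
* one side a single exon exactly spanning the other side's exon–intron–exon
  span → IR (host = the side retaining the intron);
* single overlapping exon pair with a shifted inner boundary → ADS (3'/donor
  shift) or AAS (5'/acceptor shift);
* terminal gaps: disjoint terminal exons joined to the same adjacent
  junction → MXE-AFE / MXE-ALE; any other terminal difference (shifted outer
  boundary, extra or missing terminal exon cascade) → AFE / ALE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import GenomicInterval, TranscriptModel

__all__ = [
    "SpliceEvent",
    "SpliceEventSet",
    "EVENT_TYPES",
    "SIGNED_FEATURES",
    "ABSOLUTE_FEATURES",
    "compare_exon_chains",
    "event_length_features",
]

EVENT_TYPES = ("ES", "ADS", "AAS", "MXE", "IR", "AFE", "ALE", "MXE-AFE", "MXE-ALE")

# feature vocabularies for the per-residue-effect regression
_AS_TYPES = ("ADS", "AAS", "MXE", "AFE", "ALE", "MXE-AFE", "MXE-ALE")
SIGNED_FEATURES = tuple(
    [f"dL_{t}" for t in _AS_TYPES] + ["dL_ES(R)", "dL_ES(I)", "dL_IR(R)", "dL_IR(I)"]
)
ABSOLUTE_FEATURES = tuple([f"absdL_{t}" for t in _AS_TYPES] + ["absdL_ES", "absdL_IR"])


@dataclass
class SpliceEvent:
    """One typed splicing event with its genomic intervals and nt length change."""

    type: str
    ref_intervals: list[GenomicInterval]
    iso_intervals: list[GenomicInterval]
    host: str = "both"  # which transcript hosts the extra sequence (ES/IR only)

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.host not in ("reference", "isoform", "both"):
            raise ValueError(f"unknown host {self.host!r}")

    @property
    def delta_nt(self) -> int:
        """Signed nt length change (isoform − reference)."""
        return sum(iv.length for iv in self.iso_intervals) - sum(
            iv.length for iv in self.ref_intervals
        )


@dataclass
class SpliceEventSet:
    ref_id: str
    iso_id: str
    events: list[SpliceEvent] = field(default_factory=list)

    @property
    def types(self) -> set[str]:
        return {e.type for e in self.events}

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------

def _orient(tx: TranscriptModel) -> list[tuple[int, int, GenomicInterval]]:
    """Exons as ascending oriented (start, end) tuples in transcription direction.

    On the '−' strand genomic coordinates are negated and swapped so that the
    3' boundary of every oriented exon is its 'end' (the donor side).
    """
    out = []
    for iv in tx.exons:
        if tx.strand == "+":
            out.append((iv.start, iv.end, iv))
        else:
            out.append((-iv.end, -iv.start, iv))
    return out


def _lcs_anchors(ref: list, iso: list) -> list[tuple[int, int]]:
    """Longest common subsequence of exactly-equal oriented exons."""
    m, k = len(ref), len(iso)
    dp = [[0] * (k + 1) for _ in range(m + 1)]
    for i in range(m - 1, -1, -1):
        for j in range(k - 1, -1, -1):
            if ref[i][:2] == iso[j][:2]:
                dp[i][j] = dp[i + 1][j + 1] + 1
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    pairs = []
    i = j = 0
    while i < m and j < k:
        if ref[i][:2] == iso[j][:2]:
            pairs.append((i, j))
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def _span_matches(single: tuple, chain: list[tuple]) -> bool:
    """True if ``single`` exactly spans ``chain``'s exon–intron–exon extent."""
    return (
        len(chain) >= 2
        and single[0] == chain[0][0]
        and single[1] == chain[-1][1]
    )


def _classify_gap(
    ref_gap: list, iso_gap: list, left_anchored: bool, right_anchored: bool
) -> list[SpliceEvent]:
    """Classify one inter-anchor gap into one or more events."""
    refs = [t[2] for t in ref_gap]
    isos = [t[2] for t in iso_gap]

    if not ref_gap and not iso_gap:
        return []

    # intron retention: one side is a single exon exactly spanning the other
    if len(iso_gap) == 1 and _span_matches(iso_gap[0], ref_gap):
        return [SpliceEvent("IR", refs, isos, host="isoform")]
    if len(ref_gap) == 1 and _span_matches(ref_gap[0], iso_gap):
        return [SpliceEvent("IR", refs, isos, host="reference")]

    internal = left_anchored and right_anchored
    if internal:
        if ref_gap and not iso_gap:
            return [SpliceEvent("ES", refs, [], host="isoform")]
        if iso_gap and not ref_gap:
            return [SpliceEvent("ES", [], isos, host="reference")]
        if len(ref_gap) == 1 and len(iso_gap) == 1:
            (rs, re, riv), (is_, ie, iiv) = ref_gap[0], iso_gap[0]
            if re < is_ or ie < rs:  # mutually non-overlapping
                return [SpliceEvent("MXE", refs, isos)]
            events = []
            if rs == is_ and re != ie:
                return [SpliceEvent("ADS", refs, isos)]
            if re == ie and rs != is_:
                return [SpliceEvent("AAS", refs, isos)]
            # both boundaries shifted: donor and acceptor events in one gap
            return [SpliceEvent("ADS", refs, isos)]
        # complex internal substitution: treated as a mutually exclusive block
        return [SpliceEvent("MXE", refs, isos)]

    # terminal gap
    first_terminal = not left_anchored
    if first_terminal and right_anchored:
        outer_type, shift_type, mxe_type = "AFE", "ADS", "MXE-AFE"
        inner_idx = 1  # donor boundary of a first exon is its oriented end
    elif left_anchored:
        outer_type, shift_type, mxe_type = "ALE", "AAS", "MXE-ALE"
        inner_idx = 0  # acceptor boundary of a last exon is its oriented start
    else:
        # no anchors at all and not IR: fall back to an alternative-first-exon call
        return [SpliceEvent("AFE", refs, isos)]

    if ref_gap and iso_gap:
        disjoint = all(
            r_end < i_start or i_end < r_start
            for r_start, r_end, _ in ref_gap
            for i_start, i_end, _ in iso_gap
        )
        if disjoint:
            return [SpliceEvent(mxe_type, refs, isos)]
        if len(ref_gap) == 1 and len(iso_gap) == 1:
            r, i = ref_gap[0], iso_gap[0]
            if r[inner_idx] != i[inner_idx] and r[1 - inner_idx] == i[1 - inner_idx]:
                # inner (junction-side) boundary shifted, outer preserved
                return [SpliceEvent(shift_type, refs, isos)]
        return [SpliceEvent(outer_type, refs, isos)]
    # extra/missing terminal exon cascade on one side only
    return [SpliceEvent(outer_type, refs, isos)]


def compare_exon_chains(ref: TranscriptModel, iso: TranscriptModel) -> SpliceEventSet:
    """Classify all splicing events distinguishing ``iso`` from ``ref``."""
    if ref.chrom != iso.chrom or ref.strand != iso.strand:
        raise ValueError(
            f"transcripts {ref.transcript_id}/{iso.transcript_id} are on different "
            "chromosomes or strands"
        )
    oref = _orient(ref)
    oiso = _orient(iso)
    anchors = _lcs_anchors(oref, oiso)

    events: list[SpliceEvent] = []
    prev_r, prev_i = 0, 0
    bounds = anchors + [(len(oref), len(oiso))]
    for idx, (ai, aj) in enumerate(bounds):
        ref_gap = oref[prev_r:ai]
        iso_gap = oiso[prev_i:aj]
        left_anchored = prev_r > 0 or prev_i > 0
        right_anchored = idx < len(anchors)
        events.extend(_classify_gap(ref_gap, iso_gap, left_anchored, right_anchored))
        prev_r, prev_i = ai + 1, aj + 1
    return SpliceEventSet(ref_id=ref.transcript_id, iso_id=iso.transcript_id, events=events)


# ---------------------------------------------------------------------------

def _nt_to_aa(nt: int) -> tuple[int, bool]:
    """Signed integer division of a nt length by 3; flags frame-ambiguous lengths."""
    aa = int(abs(nt) // 3) * (1 if nt >= 0 else -1)
    return aa, abs(nt) % 3 != 0


def event_length_features(
    events: SpliceEventSet, mode: str = "signed", units: str = "aa"
) -> tuple[pd.Series, bool]:
    """Per-type event-length feature vector for the effect regression.

    ``signed`` mode keeps the sign of each length change and splits ES and IR
    by host transcript; ``absolute`` mode sums absolute length changes with ES
    and IR unsplit. Returns ``(features, frame_ambiguous)`` where the flag
    marks any nt length that is not a multiple of 3 (UTRs are not modeled, so
    the nt→aa conversion ignores reading frame).
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    if units not in ("nt", "aa"):
        raise ValueError(f"units must be 'nt' or 'aa', got {units!r}")
    names = SIGNED_FEATURES if mode == "signed" else ABSOLUTE_FEATURES
    feats = dict.fromkeys(names, 0.0)
    ambiguous = False
    for ev in events.events:
        delta = ev.delta_nt
        if units == "aa":
            delta, flag = _nt_to_aa(delta)
            ambiguous = ambiguous or flag
        if mode == "signed":
            if ev.type in ("ES", "IR"):
                suffix = "R" if ev.host == "reference" else "I"
                key = f"dL_{ev.type}({suffix})"
            else:
                key = f"dL_{ev.type}"
            feats[key] += delta
        else:
            key = f"absdL_{ev.type}" if ev.type in ("ES", "IR") else f"absdL_{ev.type}"
            feats[key] += abs(delta)
    return pd.Series(feats, dtype=float), ambiguous
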