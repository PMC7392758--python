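"""Merging automatic and lifted-manual pseudogene calls.

The two annotation channels are reconciled into a single confidence-levelled
set: Level 1 records are supported by both channels (their boundaries are
extended to the union of the two calls), Level 2 by manual lift-over only,
Level 3 by the automatic pipeline only.  A false-positive filter removes
calls outside plausible length/similarity bounds, and haplotype segment
tracks are intersected to label each pseudogene with its most likely
subspecies origin.
"""

from __future__ import annotations

from collections import defaultdict

from .records import HaplotypeSegment, PseudogeneRecord


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def merge_calls(auto: list, manual: list, min_overlap_bp: int = 1) -> list:
    """Merge the two channels into one confidence-levelled record set.

    Pairing is one-to-one: every candidate (auto, manual) pair with a
    same-chromosome overlap of at least ``min_overlap_bp`` competes, larger
    overlaps win, ties break on the smaller start coordinate (manual, then
    auto); losers stay unmatched and keep their single-channel level.
    """
    if min_overlap_bp < 0:
        raise ValueError("min_overlap_bp must be >= 0")
    strains = {r.strain_id for r in auto} | {r.strain_id for r in manual}
    if len(strains) > 1:
        raise ValueError(f"mixed-strain inputs: {sorted(strains)}")

    by_chrom = defaultdict(list)
    for j, m in enumerate(manual):
        by_chrom[m.chrom].append(j)

    pairs = []
    for i, a in enumerate(auto):
        for j in by_chrom.get(a.chrom, ()):
            m = manual[j]
            ov = _overlap(a.start, a.end, m.start, m.end)
            if ov >= max(min_overlap_bp, 1):
                pairs.append((ov, i, j))
    # larger overlap first; ties by smaller manual start, then auto start
    pairs.sort(key=lambda t: (-t[0], manual[t[2]].start, auto[t[1]].start, t[1], t[2]))

    matched_auto, matched_manual = set(), set()
    out = []
    for ov, i, j in pairs:
        if i in matched_auto or j in matched_manual:
            continue
        matched_auto.add(i)
        matched_manual.add(j)
        a, m = auto[i], manual[j]
        merged = m.copy(start=min(a.start, m.start), end=max(a.end, m.end),
                        level=1, source="merged")
        out.append(merged)
    for j, m in enumerate(manual):
        if j not in matched_manual:
            out.append(m.copy(level=2))
    for i, a in enumerate(auto):
        if i not in matched_auto:
            out.append(a.copy(level=3))
    return out


FILTER_REASONS = ("too_short", "too_long", "low_identity", "low_coverage")


def filter_false_positives(records: list, min_len_bp: int = 100, max_len_bp: int = 5000,
                           min_identity: float = 40.0, min_coverage: float = 0.5):
    """Remove implausible calls; boundary values are kept.

    Returns (kept, removed) where removed items are (record, [reasons]).
    """
    kept, removed = [], []
    for r in records:
        reasons = []
        if r.length < min_len_bp:
            reasons.append("too_short")
        if r.length > max_len_bp:
            reasons.append("too_long")
        if r.pct_identity < min_identity:
            reasons.append("low_identity")
        if r.query_coverage < min_coverage:
            reasons.append("low_coverage")
        if reasons:
            removed.append((r, reasons))
        else:
            kept.append(r)
    return kept, removed


def merge_segments(segments: list) -> list:
    """Merge overlapping or abutting segments that share a label."""
    merged = []
    keyed = sorted(segments, key=lambda s: (s.chrom, s.label, s.start, s.end))
    for seg in keyed:
        if (merged and merged[-1].chrom == seg.chrom and merged[-1].label == seg.label
                and seg.start <= merged[-1].end):
            merged[-1] = HaplotypeSegment(seg.chrom, merged[-1].start,
                                          max(merged[-1].end, seg.end), seg.label)
        else:
            merged.append(HaplotypeSegment(seg.chrom, seg.start, seg.end, seg.label))
    merged.sort(key=lambda s: (s.chrom, s.start, s.end, s.label))
    return merged


def assign_haplotypes(records: list, segments: list) -> list:
    """Label each record with the haplotype of maximal base-pair overlap.

    Same-label segments are merged first; records overlapping nothing get
    ``haplotype=None``.  Ties break on the lexicographically smaller label.
    """
    segs = merge_segments(segments)
    by_chrom = defaultdict(list)
    for s in segs:
        by_chrom[s.chrom].append(s)
    out = []
    for r in records:
        best = defaultdict(int)
        for s in by_chrom.get(r.chrom, ()):
            ov = _overlap(r.start, r.end, s.start, s.end)
            if ov > 0:
                best[s.label] += ov
        label = min(best, key=lambda k: (-best[k], k)) if best else None
        out.append(r.copy(haplotype=label))
    return out
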