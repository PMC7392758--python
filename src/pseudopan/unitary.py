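"""Cross-organism unitary pseudogene calling.

A unitary pseudogene is a once-functional gene disabled in one lineage
while its ortholog remains functional in another.  Candidates (pseudogene
calls in the "non-functional" query organism made with proteins from the
"functional" organism) pass a filter cascade: not a previously known
pseudogene, parent without a functional ortholog in the query, no overlap
with annotated coding or ncRNA loci, minimum length, and conservation of
location against the lifted coding annotation.  Parents with functional
paralogs in the query are flagged, not removed.
"""

from __future__ import annotations

from collections import defaultdict

from intervaltree import IntervalTree

from .records import UnitaryCandidate

FILTER_ORDER = ("known_pseudogene", "parent_ortholog", "coding_overlap",
                "min_length", "location_conserved")


def _build_trees(intervals) -> dict:
    trees = defaultdict(IntervalTree)
    for chrom, start, end in intervals:
        if start < end:
            trees[chrom].addi(start, end)
    return dict(trees)


def _overlaps(trees: dict, chrom: str, start: int, end: int) -> bool:
    t = trees.get(chrom)
    return bool(t is not None and t.overlap(start, end))


def first_failing_filter(cand: UnitaryCandidate) -> str | None:
    for name, ok in cand.filter_trace:
        if not ok:
            return name
    return None


def call_unitaries(candidates: list, known_pseudogenes: list, ortholog_table: dict,
                   coding_loci: list, ncrna_loci: list, lifted_coding: list,
                   paralog_table: dict, min_len_bp: int = 100,
                   functional_org: str = "reference", nonfunctional_org: str = "query",
                   strict_paralog: bool = False):
    """Run the unitary filter cascade.

    Every filter is evaluated for every candidate (the trace covers all of
    them), so the accepted set is invariant to filter order; a rejected
    candidate reports the first failing filter in the canonical order.
    Returns (unitaries, rejected), both lists of UnitaryCandidate.
    """
    ann_chroms = {c for c, *_ in list(known_pseudogenes) + list(coding_loci)
                  + list(ncrna_loci) + list(lifted_coding)}
    if ann_chroms:
        foreign = sorted({r.chrom for r in candidates} - ann_chroms)
        if foreign:
            raise ValueError(
                f"candidate chromosomes {foreign} are absent from every query-organism "
                f"annotation track; candidates may be in the functional organism's "
                f"coordinate space")

    known_t = _build_trees(known_pseudogenes)
    coding_t = _build_trees(list(coding_loci) + list(ncrna_loci))
    lifted_t = _build_trees(lifted_coding)

    unitaries, rejected = [], []
    for rec in candidates:
        trace = [
            ("known_pseudogene", not _overlaps(known_t, rec.chrom, rec.start, rec.end)),
            ("parent_ortholog", not ortholog_table.get(rec.parent_id, False)),
            ("coding_overlap", not _overlaps(coding_t, rec.chrom, rec.start, rec.end)),
            ("min_length", rec.length >= min_len_bp),
            ("location_conserved", _overlaps(lifted_t, rec.chrom, rec.start, rec.end)),
        ]
        flag = paralog_table.get(rec.parent_id, 0) > 0
        cand = UnitaryCandidate(record=rec, functional_org=functional_org,
                                nonfunctional_org=nonfunctional_org,
                                filter_trace=trace, paralog_flag=flag)
        ok = all(v for _, v in trace) and not (strict_paralog and flag)
        (unitaries if ok else rejected).append(cand)
    return unitaries, rejected


def review_report(candidates: list):
    """Alignment-statistics table standing in for manual inspection."""
    import pandas as pd

    rows = []
    for c in candidates:
        r = c.record
        rows.append({
            "uid": r.uid, "chrom": r.chrom, "start": r.start, "end": r.end,
            "parent_id": r.parent_id, "pct_identity": r.pct_identity,
            "query_coverage": r.query_coverage, "length": r.length,
            "paralog_flag": c.paralog_flag,
            "first_failing_filter": first_failing_filter(c) or "pass",
        })
    return pd.DataFrame(rows)


STOPS = {"TAA", "TAG", "TGA"}


def detect_gof_reversion(ref_codon: str, position_in_codon: int, strain_alleles: dict,
                         strains: list | None = None) -> set:
    """Strains where a reference stop codon has reverted to a sense codon.

    ``ref_codon`` is the disabling stop on the coding strand,
    ``position_in_codon`` (0-2) the varying site, and ``strain_alleles`` the
    per-strain base at that site.  Strains whose reconstructed codon is no
    longer a stop are reported as gain-of-function reversions; a
    stop-to-stop change is not a reversion.
    """
    ref_codon = ref_codon.upper()
    if len(ref_codon) != 3 or any(b not in "ACGT" for b in ref_codon):
        raise ValueError(f"bad codon {ref_codon!r}")
    if ref_codon not in STOPS:
        raise ValueError(f"reference codon {ref_codon} is not a stop codon")
    if not 0 <= position_in_codon <= 2:
        raise ValueError("position_in_codon must be 0, 1 or 2")
    if strains is not None:
        missing = sorted(set(strains) - set(strain_alleles))
        if missing:
            raise ValueError(f"allele table incomplete; missing strains: {missing}")
    reverted = set()
    for strain, base in strain_alleles.items():
        base = base.upper()
        if base not in "ACGT":
            raise ValueError(f"bad allele {base!r} for strain {strain}")
        codon = ref_codon[:position_in_codon] + base + ref_codon[position_in_codon + 1:]
        if codon not in STOPS:
            reverted.add(strain)
    return reverted
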