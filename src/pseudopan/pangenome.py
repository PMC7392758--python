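"""Pan-strain pseudogene set construction.

Pseudogene annotations are lifted all-against-all between strains; a pair
of records is called orthologous when the lifted copy reciprocally overlaps
the native record by at least 90% and agrees in parent gene, biotype,
annotation ID (where both carry one), length, and exon structure.
Connected components of the resulting match graph are collapsed into
pangenome entries, classified as universally conserved, group-conserved,
or strain-specific.  Relaxing the locus-overlap cut-off down to zero turns
the strain-specific count from an upper into a lower bound.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd
from intervaltree import IntervalTree

from .records import LiftoverMap, OrthologMatch, PangenomeEntry


def reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    ov = max(0, min(a_end, b_end) - max(a_start, b_start))
    la, lb = a_end - a_start, b_end - b_start
    if la <= 0 or lb <= 0:
        return 0.0
    return min(ov / la, ov / lb)


def map_orthologs(records_a: list, records_b: list, liftover: LiftoverMap,
                  overlap_threshold: float = 0.90, length_ratio_min: float = 0.5,
                  exon_count_diff_max: int = 1, require_same_parent: bool = True,
                  require_same_biotype: bool = True, check_ens_id: bool = True,
                  exclude_loci: list | None = None) -> list:
    """Ortholog matches from strain a onto strain b via ``liftover``.

    Records that fail to lift produce no match; lifted records overlapping
    ``exclude_loci`` (protein-coding/ncRNA annotations of b) are dropped.
    A match requires reciprocal overlap >= ``overlap_threshold`` with at
    least 1 bp of raw overlap, plus the conservation filters.
    """
    if not 0.0 <= overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must be in [0, 1]")
    unknown = sorted({r.chrom for r in records_a} - liftover.chromosomes())
    if unknown and records_a:
        raise ValueError(f"liftover map does not cover chromosomes: {unknown}")

    b_tree = defaultdict(IntervalTree)
    for j, r in enumerate(records_b):
        b_tree[r.chrom].addi(r.start, r.end, j)
    excl = defaultdict(IntervalTree)
    for chrom, start, end in exclude_loci or ():
        if start < end:
            excl[chrom].addi(start, end)

    matches = []
    for a in records_a:
        lifted = liftover.lift_interval(a.chrom, a.start, a.end)
        if lifted is None:
            continue
        chrom, ls, le, _frac = lifted
        if chrom in excl and excl[chrom].overlap(ls, le):
            continue
        for iv in b_tree.get(chrom, IntervalTree()).overlap(ls, le):
            b = records_b[iv.data]
            ro = reciprocal_overlap(ls, le, b.start, b.end)
            same_parent = a.parent_id == b.parent_id
            same_biotype = a.biotype == b.biotype
            same_id = (a.ens_id == b.ens_id) if (a.ens_id and b.ens_id) else True
            lr = min(a.length, b.length) / max(a.length, b.length)
            struct = abs(a.n_exons - b.n_exons) <= exon_count_diff_max
            ok = (ro >= overlap_threshold and ro > 0.0
                  and (same_parent or not require_same_parent)
                  and (same_biotype or not require_same_biotype)
                  and (same_id or not check_ens_id)
                  and lr >= length_ratio_min and struct)
            if ok:
                matches.append(OrthologMatch(
                    record_a=a.uid, record_b=b.uid,
                    strain_a=a.strain_id, strain_b=b.strain_id,
                    reciprocal_overlap=ro, same_parent=same_parent,
                    same_biotype=same_biotype, same_id=same_id,
                    length_compatible=lr >= length_ratio_min,
                    structure_compatible=struct))
    return matches


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def collapse_pangenome(all_matches: list, all_records: list) -> list:
    """Collapse match-graph connected components into pangenome entries.

    Unmatched records become singleton entries.  An entry containing two or
    more records of one strain is flagged multi-matching (it still counts
    once in the pangenome total).
    """
    uf = _UnionFind()
    strain_of = {r.uid: r.strain_id for r in all_records}
    for r in all_records:
        uf.find(r.uid)
    for m in all_matches:
        for uid in (m.record_a, m.record_b):
            if uid not in strain_of:
                raise ValueError(f"match references unknown record {uid}")
        uf.union(m.record_a, m.record_b)
    comps = defaultdict(list)
    for r in all_records:
        comps[uf.find(r.uid)].append(r.uid)
    entries = []
    for i, key in enumerate(sorted(comps, key=lambda k: min(comps[k]))):
        members = defaultdict(list)
        for uid in sorted(comps[key]):
            members[strain_of[uid]].append(uid)
        entries.append(PangenomeEntry(
            pan_uid=f"pan{i:06d}", members=dict(members),
            multi_match_flag=any(len(v) > 1 for v in members.values())))
    return entries


def classify_conservation(entries: list, strain_list: list, groups: dict | None = None):
    """Label entries universal / group / strain_specific.

    ``groups`` maps a group name to a strain subset; an entry whose members
    fall entirely inside one named group (and span more than one strain)
    gets that group's name recorded alongside the generic class.
    Returns (labels DataFrame indexed by pan_uid, class counts dict).
    """
    strain_set = set(strain_list)
    groups = groups or {}
    rows = []
    for e in entries:
        unknown = e.strains - strain_set
        if unknown:
            raise ValueError(f"entry {e.pan_uid} contains unknown strains {sorted(unknown)}")
        if e.strains == strain_set:
            cls = "universal"
        elif len(e.strains) == 1:
            cls = "strain_specific"
        else:
            cls = "group"
        gname = next((name for name, members in sorted(groups.items())
                      if len(e.strains) > 1 and e.strains <= set(members)), None)
        e.conservation_class = cls
        rows.append((e.pan_uid, cls, gname))
    labels = pd.DataFrame(rows, columns=["pan_uid", "conservation_class", "group"]
                          ).set_index("pan_uid")
    counts = labels["conservation_class"].value_counts().to_dict()
    for k in ("universal", "group", "strain_specific"):
        counts.setdefault(k, 0)
    return labels, counts


def strain_specific_counts(records_by_strain: dict, liftovers: dict,
                           overlap_threshold: float, **match_kwargs) -> dict:
    """Per-strain count of records with no ortholog in any other strain."""
    strains = sorted(records_by_strain)
    has_ortholog = {s: set() for s in strains}
    for a in strains:
        for b in strains:
            if a == b:
                continue
            for m in map_orthologs(records_by_strain[a], records_by_strain[b],
                                   liftovers[(a, b)], overlap_threshold=overlap_threshold,
                                   **match_kwargs):
                has_ortholog[a].add(m.record_a)
                has_ortholog[b].add(m.record_b)
    return {s: len(records_by_strain[s]) - len(has_ortholog[s]) for s in strains}


def strain_specific_bounds(records_by_strain: dict, liftovers: dict,
                           threshold_grid: list = (0.90, 0.75, 0.5, 0.25, 0.0),
                           **match_kwargs) -> pd.DataFrame:
    """Strain-specific counts along a descending locus-overlap relaxation grid.

    The count at 0.90 is the upper bound; the count at 0 (any annotated
    overlap at all disqualifies) is the lower bound.  Only the locus-overlap
    criterion moves; all other conservation filters stay fixed.
    """
    grid = list(threshold_grid)
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly decreasing")
    if 0.90 not in grid or 0.0 not in grid:
        raise ValueError("threshold grid must include 0.90 and 0")
    rows = []
    for thr in grid:
        counts = strain_specific_counts(records_by_strain, liftovers, thr, **match_kwargs)
        counts["threshold"] = thr
        counts["mean_strain_specific"] = (
            sum(v for k, v in counts.items() if k != "threshold") / len(records_by_strain))
        rows.append(counts)
    return pd.DataFrame(rows).set_index("threshold")
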