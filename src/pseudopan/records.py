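"""Core record types shared by every stage of the pipeline.

Coordinates are 0-based half-open throughout the package; GFF3 is converted
to/from 1-based inclusive only at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_BIOTYPES = ("processed", "duplicated", "unitary", "ambiguous")
VALID_SOURCES = ("auto", "manual", "merged")


@dataclass
class PseudogeneRecord:
    """One pseudogene call in one strain.

    ``pct_identity`` is percent nucleotide identity to the parent gene in
    [0, 100]; ``query_coverage`` is the fraction of the parent covered in
    [0, 1].  ``level`` is the annotation confidence tier (1: supported by
    both manual and automatic annotation, 2: manual only, 3: automatic
    only) and is set only by the merge step.
    """

    uid: str
    strain_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "processed"
    parent_id: str | None = None
    pct_identity: float = 100.0
    query_coverage: float = 1.0
    disablements: dict = field(default_factory=lambda: {"stop": 0, "deletion": 0, "insertion": 0})
    level: int | None = None
    source: str = "auto"
    haplotype: str | None = None
    exon_intervals: list = field(default_factory=list)
    ens_id: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"record {self.uid}: start must be < end, got [{self.start}, {self.end})"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"record {self.uid}: pct_identity {self.pct_identity} outside [0, 100]")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"record {self.uid}: bad strand {self.strand!r}")
        for s, e in self.exon_intervals:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"record {self.uid}: exon [{s}, {e}) outside [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return len(self.exon_intervals) if self.exon_intervals else 1

    def copy(self, **changes) -> "PseudogeneRecord":
        rec = replace(self, **changes)
        rec.disablements = dict(self.disablements)
        if "exon_intervals" not in changes:
            rec.exon_intervals = [tuple(x) for x in self.exon_intervals]
        return rec


@dataclass
class HaplotypeSegment:
    """A genome segment labelled with its inferred subspecies/haplotype origin."""

    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"haplotype segment: start must be < end, got [{self.start}, {self.end})")


class LiftoverMap:
    """Piecewise monotone coordinate mapping between two strain genomes.

    Stored as a block table (src_chrom, src_start, src_end, dst_chrom,
    dst_start, dst_end, strand).  Blocks are non-overlapping on both sides
    and length-preserving within a block; positions outside every block are
    unmapped.
    """

    COLUMNS = ["src_chrom", "src_start", "src_end", "dst_chrom", "dst_start", "dst_end", "strand"]

    def __init__(self, blocks: pd.DataFrame, src: str = "", dst: str = ""):
        blocks = blocks.reset_index(drop=True)
        missing = [c for c in self.COLUMNS if c not in blocks.columns]
        if missing:
            raise ValueError(f"liftover table missing columns: {missing}")
        bad = blocks[(blocks.src_end - blocks.src_start) != (blocks.dst_end - blocks.dst_start)]
        if len(bad):
            raise ValueError("liftover blocks must be length-preserving")
        self.blocks = blocks.sort_values(["src_chrom", "src_start"]).reset_index(drop=True)
        self.src = src
        self.dst = dst
        self._by_chrom = {
            chrom: (g.src_start.to_numpy(), g.src_end.to_numpy(),
                    g.dst_chrom.to_numpy(), g.dst_start.to_numpy())
            for chrom, g in self.blocks.groupby("src_chrom")
        }

    def chromosomes(self) -> set:
        return set(self._by_chrom)

    def lift_interval(self, chrom: str, start: int, end: int):
        """Map [start, end) on ``chrom`` into the destination genome.

        Returns (dst_chrom, dst_start, dst_end, mapped_fraction) covering the
        lifted pieces, or None when no base maps.  Intervals whose pieces lift
        onto more than one destination chromosome also return None.
        """
        if chrom not in self._by_chrom:
            return None
        s, e, dchrom, ds = self._by_chrom[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if lo >= hi:
            return None
        pieces, mapped = [], 0
        for i in range(lo, hi):
            a, b = max(start, s[i]), min(end, e[i])
            if a >= b:
                continue
            off = ds[i] - s[i]
            pieces.append((dchrom[i], a + off, b + off))
            mapped += b - a
        if not pieces:
            return None
        chroms = {p[0] for p in pieces}
        if len(chroms) > 1:
            return None
        dst_chrom = pieces[0][0]
        return dst_chrom, min(p[1] for p in pieces), max(p[2] for p in pieces), mapped / (end - start)

    def inverse(self) -> "LiftoverMap":
        inv = self.blocks.rename(columns={
            "src_chrom": "dst_chrom", "src_start": "dst_start", "src_end": "dst_end",
            "dst_chrom": "src_chrom", "dst_start": "src_start", "dst_end": "src_end",
        })[self.COLUMNS]
        return LiftoverMap(inv, src=self.dst, dst=self.src)


@dataclass
class EstimationInputs:
    """Counts feeding the total-complement estimator.

    ``n_t_*`` are input protein-coding transcript counts and ``n_p_*`` are
    automatic-pipeline pseudogene counts, for strain i, the reference, and
    the calibration strain.
    """

    n_t_i: int
    n_t_ref: int
    n_t_cal: int
    n_p_i: int
    n_p_cal: int
    n_p_ref: int

    def __post_init__(self):
        for name in ("n_t_i", "n_t_ref", "n_t_cal", "n_p_i", "n_p_cal", "n_p_ref"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v}")


@dataclass
class OrthologMatch:
    """A pairwise cross-strain ortholog call between two pseudogene records."""

    record_a: str
    record_b: str
    strain_a: str
    strain_b: str
    reciprocal_overlap: float
    same_parent: bool = True
    same_biotype: bool = True
    same_id: bool = True
    length_compatible: bool = True
    structure_compatible: bool = True


@dataclass
class PangenomeEntry:
    """An equivalence class of orthologous pseudogene records across strains."""

    pan_uid: str
    members: dict  # strain -> list of record uids
    conservation_class: str | None = None
    multi_match_flag: bool = False

    @property
    def strains(self) -> set:
        return set(self.members)

    @property
    def member_uids(self) -> list:
        return [u for uids in self.members.values() for u in uids]


@dataclass
class UnitaryCandidate:
    """A cross-organism unitary pseudogene candidate with its filter trace."""

    record: PseudogeneRecord
    functional_org: str
    nonfunctional_org: str
    filter_trace: list = field(default_factory=list)
    paralog_flag: bool = False

    @property
    def passed_all(self) -> bool:
        return bool(self.filter_trace) and all(ok for _, ok in self.filter_trace)
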