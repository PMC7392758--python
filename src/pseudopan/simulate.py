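"""Synthetic multi-strain pseudogene dataset generator.

Emulates the study design of a multi-strain pseudogene survey: pseudogene
births are placed on the branches of a known strain tree (so clade-shared
classes are inherited by all descendant strains), processed pseudogenes are
retrotransposed in proportion to parent-gene expression with optional
burst epochs, duplicated pseudogenes arise in proportion to family size,
and sequences diverge neutrally from the moment of birth.  Two annotation
channels ("auto" with configurable false positives/negatives and
annotation-depth deflation, "manual" with per-record dropout) feed the
merge step, and liftover maps with unmapped gaps feed the pangenome step.
Every downstream stage has its ground truth recorded.

All strain genomes are derived from a shared ancestral coordinate frame:
each strain applies per-block insertions between fixed-size blocks, so
coordinates differ between strains while orthologous loci stay aligned
block-wise.  Elements never span block boundaries, which keeps liftover
exact away from unmapped gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import seqevo
from .records import HaplotypeSegment, LiftoverMap, PseudogeneRecord
from .trees import StrainTree, random_strain_tree

SUBSPECIES = ("domesticus", "musculus", "castaneus")
SUBSPECIES_WEIGHTS = (0.943, 0.054, 0.003)


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults are a scaled-down analogue of the real survey: 8 strains (one
    outgroup), a 4:1 processed:duplicated biotype ratio, retrotransposition
    bursts whose expected percent identities sit at 92.5 and 97, disablement
    accumulation ordered stop > deletion > insertion, and annotation-channel
    noise producing non-degenerate confidence-level proportions.
    """

    seed: int = 0
    n_strains: int = 8
    strain_names: list | None = None
    tree: StrainTree | None = None
    outgroup: str = "OUT"
    reference_strain: str = "REF"

    n_genes: int = 500
    n_chromosomes: int = 2
    genome_length: int = 8_000_000
    block_size: int = 50_000
    gene_length_range: tuple = (500, 3000)

    frac_essential: float = 0.25
    essentiality_enrichment: float = 3.0
    expression_mu: float = 1.0
    expression_sigma: float = 1.0
    paralog_expression_slope: float = -0.4

    # Birth process.  None rates are auto-calibrated so that the expected
    # per-strain record count and biotype ratio hit the targets below.
    retro_rate_scale: float | None = None
    dup_rate: float | None = None
    expected_pseudogenes_per_strain: int = 1200
    target_biotype_ratio: float = 4.0  # processed : duplicated
    burst_times: list | None = None    # [(age, weight), ...]; None -> from identities
    burst_identities: tuple = (92.5, 97.0)
    burst_weight: float = 0.35
    stem_time: float = 1.0
    tree_depth: float = 1.0

    # Mutation processes (per site per unit time).
    subst_rate: float = 0.1
    kappa: float = 2.0
    stop_gain_rate: float = 0.001
    deletion_rate: float = 0.0005
    insertion_rate: float = 0.00025

    min_coverage_draw: float = 0.55
    pg_length_bounds: tuple = (150, 4000)
    # Per-strain annotation imprecision: each record boundary extends outward
    # by up to min(12% of length, this many bp).  Drives reciprocal overlaps
    # of true orthologs below 1, so relaxing the pangenome locus cut-off has
    # something to recover; 0 disables (noise-free annotations).
    boundary_jitter_bp: int = 120
    # Fragmentary annotation: with this probability a record is truncated by
    # up to 45% of its length in one strain, pushing its reciprocal overlap
    # with orthologs below the 0.9 cut-off (a false strain-specific call
    # that only the relaxed lower-bound sweep recovers).
    truncation_prob: float = 0.12

    # Annotation channels.
    auto_fp_rate: float = 0.05
    auto_fn_rate: float = 0.05
    manual_dropout: float = 0.30
    detection_decay: float = 0.15   # transcript-annotation deflation per unit time distance
    assembly_quality: float = 0.95  # shared auto-pipeline efficiency outside the reference

    liftover_gap_fraction: float = 0.02
    gap_length_bp: int = 2000
    block_insert_max: int = 300

    n_tissues: int = 3
    tissue_noise_sigma: float = 0.4
    frac_transcribed: float = 0.15
    transcription_cutoff: float = 2.0
    unmappable_fraction: float = 0.05
    haplotype_segments_per_chrom: int = 20

    def __post_init__(self):
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        for name in ("frac_essential", "auto_fp_rate", "auto_fn_rate", "manual_dropout",
                     "liftover_gap_fraction", "frac_transcribed", "unmappable_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("subst_rate", "stop_gain_rate", "deletion_rate", "insertion_rate",
                     "detection_decay", "target_biotype_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("retro_rate_scale", "dup_rate"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def strains(self) -> list:
        if self.strain_names is not None:
            return list(self.strain_names)
        ingroup = [self.reference_strain] + [f"S{i}" for i in range(2, self.n_strains)]
        return ingroup + [self.outgroup]

    def mutation_params(self, apply_indels: bool = False) -> seqevo.MutationParams:
        return seqevo.MutationParams(
            kappa=self.kappa, subst_rate=self.subst_rate,
            stop_gain_rate=self.stop_gain_rate, deletion_rate=self.deletion_rate,
            insertion_rate=self.insertion_rate, apply_indels=apply_indels)

    def resolved_bursts(self) -> list:
        """Burst epochs as (age, weight) pairs on the time scale of the tree."""
        if self.burst_times is not None:
            return [(float(t), float(w)) for t, w in self.burst_times]
        if self.subst_rate == 0:
            return []
        return [
            (seqevo.divergence_for_identity(i, self.kappa) / self.subst_rate, self.burst_weight)
            for i in self.burst_identities
        ]


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its ground truth."""

    config: SimConfig
    tree: StrainTree                     # time units
    strains: list
    genes: pd.DataFrame                  # gene_id, chrom, anc_start, anc_end, expression, paralogs, essential, is_parent
    classes: pd.DataFrame                # class_id, parent_id, biotype, birth_age, chrom, anc_start, anc_end, n_exons, strains
    truth_records: dict                  # strain -> [PseudogeneRecord]
    auto: dict                           # strain -> [PseudogeneRecord]
    manual: dict                         # strain -> [PseudogeneRecord]
    sequences: dict                      # strain -> {class_id: np.uint8 codes}
    parent_seqs: dict                    # gene_id -> np.uint8 codes
    liftovers: dict                      # (a, b) -> LiftoverMap
    gene_fpkm: pd.DataFrame              # gene x tissue
    pseudogene_fpkm: dict                # strain -> DataFrame (record uid x tissue)
    transcribed_truth: dict              # strain -> set of record uids
    essentiality: pd.DataFrame           # gene_id, essential
    haplotypes: dict                     # strain -> [HaplotypeSegment]
    mappability: dict                    # strain -> DataFrame chrom/start/end
    counts: pd.DataFrame                 # strain, n_transcripts_input, n_pseudogenes_auto
    gene_coords: dict                    # strain -> DataFrame gene_id/chrom/start/end
    calibration_strain: str = ""
    processed_fraction: float = float("nan")

    def conservation_truth(self) -> pd.Series:
        """True conservation class per pseudogene class id."""
        n = len(self.strains)

        def classify(strs):
            if len(strs) == n:
                return "universal"
            if len(strs) == 1:
                return "strain_specific"
            return "group"

        return self.classes.set_index("class_id")["strains"].map(classify)


def _distinct_sorted(rng: np.random.Generator, lo: int, hi: int, k: int) -> np.ndarray:
    """k distinct sorted integers in [lo, hi) without materialising the range."""
    vals = np.unique(rng.integers(lo, hi, size=k))
    while len(vals) < k:
        vals = np.unique(np.concatenate([vals, rng.integers(lo, hi, size=k - len(vals))]))
    return np.sort(vals)


# ---------------------------------------------------------------------------
# placement helpers


class _Allocator:
    """Sequential non-overlapping interval allocator over the ancestral frame.

    Keeps every element inside a single block, leaving a spacer at block
    ends so per-strain insertion offsets can never cause overlap.
    """

    SPACER = 500

    def __init__(self, n_chromosomes: int, genome_length: int, block_size: int,
                 rng: np.random.Generator):
        self.chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
        self.genome_length = genome_length
        self.block_size = block_size
        self.cursor = {c: 0 for c in self.chroms}
        self.rng = rng
        self._next = 0

    def place(self, length: int):
        chrom = self.chroms[self._next % len(self.chroms)]
        self._next += 1
        # gap >= 300 bp so jittered boundaries (<= 120 bp per end) never
        # make neighbouring elements overlap
        pos = self.cursor[chrom] + int(self.rng.integers(300, 800))
        block_end = (pos // self.block_size + 1) * self.block_size - self.SPACER
        if pos + length > block_end:
            pos = (pos // self.block_size + 1) * self.block_size
        if pos + length > self.genome_length - self.SPACER:
            raise ValueError("ancestral genome too small for the requested elements")
        self.cursor[chrom] = pos + length
        return chrom, pos, pos + length


def _strain_frames(cfg: SimConfig, strains: list, rng: np.random.Generator,
                   gap_fraction: dict | None = None):
    """Per-strain block offset tables and unmapped-gap interval lists.

    Gaps are short (~``gap_length_bp``) alignment failures scattered over
    the ancestral frame; ``gap_fraction`` gives each strain's genome
    fraction lost to them (rearrangement load grows with divergence).
    """
    n_blocks = -(-cfg.genome_length // cfg.block_size)
    offsets, gaps = {}, {}
    for strain in strains:
        offs = {}
        gapset = {}
        frac = (gap_fraction or {}).get(strain, cfg.liftover_gap_fraction)
        for chrom_i in range(cfg.n_chromosomes):
            chrom = f"chr{chrom_i + 1}"
            if strain == cfg.reference_strain:
                offs[chrom] = np.zeros(n_blocks, dtype=np.int64)
                gapset[chrom] = np.empty((0, 2), dtype=np.int64)
            else:
                ins = rng.integers(0, cfg.block_insert_max + 1, size=n_blocks)
                offs[chrom] = np.concatenate([[0], np.cumsum(ins[:-1])])
                n_gaps = int(round(frac * cfg.genome_length / cfg.gap_length_bp))
                if n_gaps > 0:
                    starts = _distinct_sorted(rng, 0,
                                              cfg.genome_length - cfg.gap_length_bp,
                                              n_gaps)
                    gapset[chrom] = np.column_stack(
                        [starts, starts + cfg.gap_length_bp])
                else:
                    gapset[chrom] = np.empty((0, 2), dtype=np.int64)
        offsets[strain] = offs
        gaps[strain] = gapset
    return offsets, gaps, n_blocks


def _to_strain_coords(offsets, strain, chrom, start, end, block_size):
    off = int(offsets[strain][chrom][start // block_size])
    return start + off, end + off


def _subtract_gaps(start, end, gap_arr):
    """Pieces of [start, end) not covered by the sorted gap intervals."""
    pieces = []
    cur = start
    for gs, ge in gap_arr:
        if ge <= cur:
            continue
        if gs >= end:
            break
        if gs > cur:
            pieces.append((cur, min(gs, end)))
        cur = max(cur, ge)
        if cur >= end:
            break
    if cur < end:
        pieces.append((cur, end))
    return pieces


def _build_liftover(cfg, offsets, gaps, n_blocks, a, b) -> LiftoverMap:
    rows = []
    for chrom_i in range(cfg.n_chromosomes):
        chrom = f"chr{chrom_i + 1}"
        merged = np.concatenate([gaps[a][chrom], gaps[b][chrom]])
        merged = merged[np.argsort(merged[:, 0])] if len(merged) else merged
        for k in range(n_blocks):
            s = k * cfg.block_size
            e = min((k + 1) * cfg.block_size, cfg.genome_length)
            oa, ob = int(offsets[a][chrom][k]), int(offsets[b][chrom][k])
            for ps, pe in _subtract_gaps(s, e, merged):
                rows.append((chrom, ps + oa, pe + oa, chrom, ps + ob, pe + ob, "+"))
    blocks = pd.DataFrame(rows, columns=LiftoverMap.COLUMNS)
    return LiftoverMap(blocks, src=a, dst=b)


# ---------------------------------------------------------------------------
# birth placement on the tree


def _tree_edges(tree: StrainTree, stem_time: float):
    """Edges as dicts with top/bottom ages and descendant leaves; stem first."""
    ages = tree.node_ages()
    root = tree.tree.seed_node
    root_age = ages[root]
    edges = [{
        "child": root, "top": root_age + stem_time, "bottom": root_age,
        "leaves": tuple(sorted(lf.taxon.label for lf in tree.tree.leaf_node_iter())),
    }]
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        edges.append({
            "child": node,
            "top": ages[node.parent_node],
            "bottom": ages[node],
            "leaves": tuple(sorted(lf.taxon.label for lf in node.leaf_iter())),
        })
    return edges


def _calibrate_rates(cfg: SimConfig, expr: np.ndarray, paralogs: np.ndarray,
                     bursts: list):
    """Resolve None birth rates so the expected per-strain record count and
    biotype ratio equal the configured targets."""
    frac_proc = cfg.target_biotype_ratio / (1.0 + cfg.target_biotype_ratio)
    path_time = cfg.tree_depth + cfg.stem_time
    w_proc = path_time + sum(w for t, w in bursts if t <= path_time)
    retro = cfg.retro_rate_scale
    dup = cfg.dup_rate
    if retro is None:
        retro = frac_proc * cfg.expected_pseudogenes_per_strain / max(expr.sum() * w_proc, 1e-12)
    if dup is None:
        dup_weight = (1.0 + 0.5 * paralogs).sum() * path_time
        dup = (1.0 - frac_proc) * cfg.expected_pseudogenes_per_strain / max(dup_weight, 1e-12)
    return retro, dup


# ---------------------------------------------------------------------------
# main generator


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset; deterministic for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    strains = cfg.strains
    if len(strains) != cfg.n_strains:
        raise ValueError(f"{len(strains)} strain names for n_strains={cfg.n_strains}")

    tree = cfg.tree or random_strain_tree(strains, seed=int(rng.integers(2 ** 31)),
                                          depth=cfg.tree_depth, outgroup=cfg.outgroup)
    if set(tree.leaf_names) != set(strains):
        raise ValueError(
            f"tree leaves {sorted(tree.leaf_names)} do not match strains {sorted(strains)}")

    # -- genes -------------------------------------------------------------
    n = cfg.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    gene_len = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n)
    paralogs = rng.poisson(1.2, size=n)
    big = rng.random(n) < 0.03
    paralogs[big] = rng.integers(20, 100, size=int(big.sum()))
    log_expr = (cfg.expression_mu
                + cfg.paralog_expression_slope * np.log1p(paralogs)
                + cfg.expression_sigma * rng.standard_normal(n))
    expr = np.exp(log_expr)

    # -- births on the tree --------------------------------------------------
    bursts = cfg.resolved_bursts()
    retro, dup = _calibrate_rates(cfg, expr, paralogs, bursts)
    edges = _tree_edges(tree, cfg.stem_time)
    dup_weight = 1.0 + 0.5 * paralogs

    class_rows = []
    births_by_edge = {i: [] for i in range(len(edges))}

    def add_birth(edge_i, gene_i, biotype, age):
        cid = f"pg{len(class_rows):05d}"
        glen = int(gene_len[gene_i])
        lo, hi = cfg.pg_length_bounds
        cov = rng.uniform(cfg.min_coverage_draw, 1.0)
        plen = int(np.clip(round(cov * glen), lo, min(hi, glen)))
        goff = int(rng.integers(0, glen - plen + 1))
        n_ex = 1 if biotype == "processed" else int(rng.integers(2, 6))
        class_rows.append({
            "class_id": cid, "parent_id": gene_ids[gene_i], "biotype": biotype,
            "birth_age": float(age), "length": plen, "gene_offset": goff,
            "n_exons": n_ex, "strains": edges[edge_i]["leaves"],
        })
        births_by_edge[edge_i].append(len(class_rows) - 1)

    for ei, edge in enumerate(edges):
        span = edge["top"] - edge["bottom"]
        # Poisson draws per gene (base process)
        n_p = rng.poisson(retro * expr * span)
        for gi in np.nonzero(n_p)[0]:
            for _ in range(int(n_p[gi])):
                add_birth(ei, int(gi), "processed", rng.uniform(edge["bottom"], edge["top"]))
        for t_b, w in bursts:
            if edge["bottom"] < t_b <= edge["top"]:
                n_b = rng.poisson(retro * expr * w)
                for gi in np.nonzero(n_b)[0]:
                    for _ in range(int(n_b[gi])):
                        add_birth(ei, int(gi), "processed", t_b)
        n_d = rng.poisson(dup * dup_weight * span)
        for gi in np.nonzero(n_d)[0]:
            for _ in range(int(n_d[gi])):
                add_birth(ei, int(gi), "duplicated", rng.uniform(edge["bottom"], edge["top"]))

    classes = pd.DataFrame(class_rows, columns=[
        "class_id", "parent_id", "biotype", "birth_age", "length", "gene_offset",
        "n_exons", "strains"])

    # -- ancestral placement -------------------------------------------------
    alloc = _Allocator(cfg.n_chromosomes, cfg.genome_length, cfg.block_size, rng)
    gene_pos = [alloc.place(int(l)) for l in gene_len]
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": [p[0] for p in gene_pos],
        "anc_start": [p[1] for p in gene_pos],
        "anc_end": [p[2] for p in gene_pos],
        "length": gene_len, "paralogs": paralogs, "expression": expr,
    })
    if len(classes):
        # place classes in random order so genomic position is independent
        # of birth age (gaps and rearrangements must hit old and young
        # classes alike)
        perm = rng.permutation(len(classes))
        cls_pos = [None] * len(classes)
        lengths = classes["length"].to_numpy()
        for idx in perm:
            cls_pos[idx] = alloc.place(int(lengths[idx]))
        classes["chrom"] = [p[0] for p in cls_pos]
        classes["anc_start"] = [p[1] for p in cls_pos]
        classes["anc_end"] = [p[2] for p in cls_pos]
    else:
        classes["chrom"] = []
        classes["anc_start"] = []
        classes["anc_end"] = []

    # exon layouts, fixed per class (inherited by every strain)
    exon_layouts = {}
    for row in classes.itertuples():
        if row.n_exons == 1:
            exon_layouts[row.class_id] = [(0, row.length)]
        else:
            k = row.n_exons
            cuts = np.sort(rng.choice(np.arange(1, row.length), size=2 * k - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [row.length]])
            exon_layouts[row.class_id] = [
                (int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(k)]

    # -- strain frames and liftovers -----------------------------------------
    names_sorted, time_dist = tree.leaf_distance_matrix()
    ref_i = names_sorted.index(cfg.reference_strain)
    dist_to_ref = {names_sorted[i]: float(time_dist[ref_i, i])
                   for i in range(len(strains))}
    # alignment gaps accumulate with divergence from the reference
    others = [s for s in strains if s != cfg.reference_strain]
    mean_dist = np.mean([dist_to_ref[s] for s in others]) if others else 1.0
    gap_fraction = {s: min(0.5, cfg.liftover_gap_fraction * dist_to_ref[s] / mean_dist)
                    for s in others}
    offsets, gaps, n_blocks = _strain_frames(cfg, strains, rng, gap_fraction)
    liftovers = {}
    for a in strains:
        for b in strains:
            if a != b:
                liftovers[(a, b)] = _build_liftover(cfg, offsets, gaps, n_blocks, a, b)

    gene_coords = {}
    for s in strains:
        rows = []
        for row in genes.itertuples():
            st, en = _to_strain_coords(offsets, s, row.chrom, row.anc_start,
                                       row.anc_end, cfg.block_size)
            rows.append((row.gene_id, row.chrom, st, en))
        gene_coords[s] = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    # -- sequence evolution down the tree ------------------------------------
    parent_seqs = {gid: rng.integers(0, 4, size=int(l)).astype(np.uint8)
                   for gid, l in zip(gene_ids, gene_len)}
    mut = cfg.mutation_params()
    leaf_seqs = {s: {} for s in strains}
    leaf_disable = {s: {} for s in strains}
    edge_index = {id(e["child"]): i for i, e in enumerate(edges)}

    def birth_seq(ci, down_time):
        row = class_rows[ci]
        seq0 = parent_seqs[row["parent_id"]][row["gene_offset"]:row["gene_offset"] + row["length"]].copy()
        seq = seqevo.evolve_codes(seq0, cfg.subst_rate * down_time, rng, cfg.kappa)
        counts = np.array([
            rng.poisson(cfg.stop_gain_rate * row["length"] * down_time),
            rng.poisson(cfg.deletion_rate * row["length"] * down_time),
            rng.poisson(cfg.insertion_rate * row["length"] * down_time),
        ], dtype=np.int64)
        return seq, counts

    def apply_stops(seq, n_stop):
        n_codons = len(seq) // 3
        for _ in range(int(n_stop)):
            if n_codons == 0:
                break
            ci_ = int(rng.integers(n_codons))
            seq[3 * ci_:3 * ci_ + 3] = seqevo.encode(seqevo.STOP_CODONS[int(rng.integers(3))])
        return seq

    def process_edge(ei, state):
        """Evolve inherited state across edge ei, add its newborns."""
        edge = edges[ei]
        span = edge["top"] - edge["bottom"]
        d = cfg.subst_rate * span
        if state and d > 0:
            cids = list(state)
            lens = np.array([state[c][0].shape[0] for c in cids])
            flat = np.concatenate([state[c][0] for c in cids])
            flat = seqevo.evolve_codes(flat, d, rng, cfg.kappa)
            splits = np.cumsum(lens)[:-1]
            pieces = np.split(flat, splits)
            extra = np.stack([
                rng.poisson(cfg.stop_gain_rate * lens * span),
                rng.poisson(cfg.deletion_rate * lens * span),
                rng.poisson(cfg.insertion_rate * lens * span),
            ], axis=1)
            for c, piece, ex in zip(cids, pieces, extra):
                state[c] = (piece, state[c][1] + ex)
        for ci in births_by_edge[ei]:
            row = class_rows[ci]
            seq, counts = birth_seq(ci, row["birth_age"] - edge["bottom"])
            state[row["class_id"]] = (seq, counts)
        return state

    def descend(node, state):
        if node.is_leaf():
            name = node.taxon.label
            for cid, (seq, counts) in state.items():
                seq = apply_stops(seq.copy(), counts[0])
                leaf_seqs[name][cid] = seq
                leaf_disable[name][cid] = counts
            return
        for child in node.child_nodes():
            ei = edge_index[id(child)]
            child_state = {c: (s.copy(), cnt.copy()) for c, (s, cnt) in state.items()}
            child_state = process_edge(ei, child_state)
            descend(child, child_state)

    stem_state = process_edge(0, {})
    descend(tree.tree.seed_node, stem_state)

    # -- truth records per strain --------------------------------------------
    cls_by_id = {r["class_id"]: r for r in class_rows}
    cls_anc = {cid: (int(s_), int(e_)) for cid, s_, e_ in
               zip(classes["class_id"], classes["anc_start"], classes["anc_end"])}
    cls_chrom = dict(zip(classes["class_id"], classes["chrom"]))
    glen_by_id = dict(zip(gene_ids, (int(x) for x in gene_len)))
    truth_records = {s: [] for s in strains}
    for s in strains:
        for cid in sorted(leaf_seqs[s]):
            row = cls_by_id[cid]
            anc_s, anc_e = cls_anc[cid]
            if cfg.boundary_jitter_bp > 0:
                cap = min(0.12 * (anc_e - anc_s), cfg.boundary_jitter_bp)
                block = anc_s // cfg.block_size
                bs = block * cfg.block_size
                be = min((block + 1) * cfg.block_size, cfg.genome_length)
                js = max(anc_s - int(rng.uniform(0, cap)), bs)
                je = min(anc_e + int(rng.uniform(0, cap)), be)
            else:
                js, je = anc_s, anc_e
            if cfg.truncation_prob > 0 and rng.random() < cfg.truncation_prob:
                cut = int(rng.uniform(0.1, 0.45) * (je - js))
                cut = min(cut, je - js - 120)
                if cut > 0:
                    from_start = int(rng.integers(0, cut + 1))
                    js, je = js + from_start, je - (cut - from_start)
            st, en = _to_strain_coords(offsets, s, cls_chrom[cid],
                                       js, je, cfg.block_size)
            shift = anc_s - js  # exon layout is anchored at the true start
            pid = row["parent_id"]
            glen = glen_by_id[pid]
            pseq = parent_seqs[pid][row["gene_offset"]:row["gene_offset"] + row["length"]]
            ident = seqevo.identity_pct(leaf_seqs[s][cid], pseq)
            cnt = leaf_disable[s][cid]
            rec = PseudogeneRecord(
                uid=f"{cid}.{s}", strain_id=s, chrom=cls_chrom[cid], start=st, end=en,
                strand="+" if int(cid[2:]) % 2 == 0 else "-",
                biotype=row["biotype"], parent_id=pid,
                pct_identity=ident, query_coverage=row["length"] / glen,
                disablements={"stop": int(cnt[0]), "deletion": int(cnt[1]),
                              "insertion": int(cnt[2])},
                source="merged", ens_id=cid,
                exon_intervals=[(max(st + shift + a, st), min(st + shift + b, en))
                                for a, b in exon_layouts[cid]
                                if max(st + shift + a, st) < min(st + shift + b, en)],
            )
            truth_records[s].append(rec)

    # -- annotation channels --------------------------------------------------
    deflation = {s: 1.0 if s == cfg.reference_strain
                 else float(np.exp(-cfg.detection_decay * dist_to_ref[s]))
                 for s in strains}
    ingroup = [s for s in strains if s != cfg.outgroup]
    calibration = min((s for s in ingroup if s != cfg.reference_strain),
                      key=lambda s: dist_to_ref[s], default=cfg.reference_strain)

    auto, manual = {}, {}
    for s in strains:
        keep_auto = (1.0 - cfg.auto_fn_rate)
        if s != cfg.reference_strain:
            keep_auto *= deflation[s] * cfg.assembly_quality
        autos, manuals = [], []
        for rec in truth_records[s]:
            if rng.random() < keep_auto:
                autos.append(rec.copy(source="auto", ens_id=None, level=None))
            if rng.random() >= cfg.manual_dropout:
                manuals.append(rec.copy(source="manual", level=None))
        n_fp = int(round(cfg.auto_fp_rate * len(autos)))
        for j in range(n_fp):
            ln = int(rng.integers(80, 6000))
            try:
                chrom, st, en = alloc.place(ln)
            except ValueError:
                break
            st, en = _to_strain_coords(offsets, s, chrom, st, en, cfg.block_size)
            autos.append(PseudogeneRecord(
                uid=f"fp{j:04d}.{s}", strain_id=s, chrom=chrom, start=st, end=en,
                strand="+", biotype=str(rng.choice(["processed", "duplicated"])),
                parent_id=f"g{int(rng.integers(cfg.n_genes)):05d}",
                pct_identity=float(rng.uniform(20, 95)),
                query_coverage=float(rng.uniform(0.2, 1.0)),
                source="auto"))
        auto[s] = autos
        manual[s] = manuals

    counts = pd.DataFrame({
        "strain": strains,
        "n_transcripts_input": [
            cfg.n_genes if s == cfg.reference_strain
            else int(rng.binomial(cfg.n_genes, deflation[s])) for s in strains],
        "n_pseudogenes_auto": [len(auto[s]) for s in strains],
    })

    # -- essentiality ---------------------------------------------------------
    parent_set = set(classes["parent_id"]) if len(classes) else set()
    is_parent = genes["gene_id"].isin(parent_set).to_numpy()
    genes["is_parent"] = is_parent
    q = is_parent.mean()
    p0 = cfg.frac_essential / max(1.0 + (cfg.essentiality_enrichment - 1.0) * q, 1e-12)
    p_parent = min(cfg.essentiality_enrichment * p0, 1.0)
    ess_prob = np.where(is_parent, p_parent, p0)
    essential = (rng.random(cfg.n_genes) < ess_prob).astype(int)
    genes["essential"] = essential
    essentiality = genes[["gene_id", "essential"]].copy()

    # -- expression tables ----------------------------------------------------
    tissues = [f"tissue{i + 1}" for i in range(cfg.n_tissues)]
    gene_fpkm = pd.DataFrame(
        expr[:, None] * np.exp(cfg.tissue_noise_sigma * rng.standard_normal((cfg.n_genes, cfg.n_tissues))),
        index=gene_ids, columns=tissues)
    gene_fpkm.index.name = "uid"

    pseudogene_fpkm, transcribed_truth = {}, {}
    for s in strains:
        uids = [rec.uid for rec in truth_records[s]]
        m = len(uids)
        is_tx = rng.random(m) < cfg.frac_transcribed
        fpkm = np.zeros((m, cfg.n_tissues))
        for i in range(m):
            if is_tx[i]:
                on = rng.random(cfg.n_tissues) < 0.7
                if not on.any():
                    on[int(rng.integers(cfg.n_tissues))] = True
                fpkm[i, on] = cfg.transcription_cutoff * (1.0 + rng.lognormal(0.0, 1.0, size=int(on.sum())))
            else:
                noisy = rng.random(cfg.n_tissues) < 0.2
                fpkm[i, noisy] = rng.uniform(0, cfg.transcription_cutoff * 0.8, size=int(noisy.sum()))
        df = pd.DataFrame(fpkm, index=uids, columns=tissues)
        df.index.name = "uid"
        pseudogene_fpkm[s] = df
        transcribed_truth[s] = {u for u, t in zip(uids, is_tx) if t}

    # -- haplotypes and mappability -------------------------------------------
    haplotypes, mappability = {}, {}
    for s in strains:
        segs = []
        for chrom_i in range(cfg.n_chromosomes):
            chrom = f"chr{chrom_i + 1}"
            k = cfg.haplotype_segments_per_chrom
            cuts = _distinct_sorted(rng, 1, cfg.genome_length, k - 1)
            bounds = np.concatenate([[0], cuts, [cfg.genome_length]])
            labels = rng.choice(SUBSPECIES, size=k, p=SUBSPECIES_WEIGHTS)
            segs.extend(HaplotypeSegment(chrom, int(bounds[i]), int(bounds[i + 1]), str(labels[i]))
                        for i in range(k))
        haplotypes[s] = segs
        rows = []
        for chrom_i in range(cfg.n_chromosomes):
            chrom = f"chr{chrom_i + 1}"
            n_isl = max(1, int(cfg.genome_length * cfg.unmappable_fraction / 2000))
            isl_start = _distinct_sorted(rng, 0, cfg.genome_length - 2000, n_isl)
            prev = 0
            for st in isl_start:
                if st > prev:
                    rows.append((chrom, int(prev), int(st)))
                prev = max(prev, int(st) + 2000)
            if prev < cfg.genome_length:
                rows.append((chrom, int(prev), cfg.genome_length))
        mappability[s] = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    # realized biotype mix, averaged over per-strain annotation sets (the
    # scale on which the 4:1 ratio is reported)
    per_strain = [np.mean([r.biotype == "processed" for r in truth_records[s]])
                  for s in strains if truth_records[s]]
    frac = float(np.mean(per_strain)) if per_strain else float("nan")

    return SyntheticDataset(
        config=cfg, tree=tree, strains=strains, genes=genes, classes=classes,
        truth_records=truth_records, auto=auto, manual=manual,
        sequences=leaf_seqs, parent_seqs=parent_seqs, liftovers=liftovers,
        gene_fpkm=gene_fpkm, pseudogene_fpkm=pseudogene_fpkm,
        transcribed_truth=transcribed_truth, essentiality=essentiality,
        haplotypes=haplotypes, mappability=mappability, counts=counts,
        gene_coords=gene_coords, calibration_strain=calibration,
        processed_fraction=frac)


# ---------------------------------------------------------------------------
# focused scenario generators


def plant_unitary_scenario(seed: int = 0, n_candidates: int = 50, n_true: int = 10):
    """Planted unitary-pseudogene scenario on a query genome with known truth.

    Returns a dict of caller inputs plus ``true_uids``: ``n_true`` genuine
    unitaries (parent lost in the query genome, locus conserved under the
    lifted coding annotation) and decoys each violating exactly one filter.
    """
    if n_true > n_candidates:
        raise ValueError("n_true cannot exceed n_candidates")
    rng = np.random.default_rng(seed)
    chrom = "chrQ"
    slot = 20_000
    candidates, known, coding, ncrna, lifted = [], [], [], [], []
    ortholog, paralog = {}, {}
    true_uids = set()

    fail_kinds = ["known", "ortholog", "coding", "short", "no_lift"]
    kind_to_filter = {"known": "known_pseudogene", "ortholog": "parent_ortholog",
                      "coding": "coding_overlap", "short": "min_length",
                      "no_lift": "location_conserved"}
    kinds = ["true"] * n_true + [fail_kinds[i % len(fail_kinds)]
                                 for i in range(n_candidates - n_true)]
    expected_failures = {}
    for i, kind in enumerate(kinds):
        base = 10_000 + i * slot
        length = 120 if kind != "short" else int(rng.integers(40, 100))
        start = base + int(rng.integers(0, 500))
        end = start + length
        pid = f"q{i:03d}"
        uid = f"uc{i:03d}"
        rec = PseudogeneRecord(uid=uid, strain_id="query", chrom=chrom, start=start,
                               end=end, strand="+", biotype="unitary", parent_id=pid,
                               pct_identity=float(rng.uniform(70, 99)),
                               query_coverage=float(rng.uniform(0.6, 1.0)))
        candidates.append(rec)
        ortholog[pid] = kind == "ortholog"
        paralog[pid] = int(rng.integers(0, 3)) if kind == "true" else 0
        if kind == "known":
            known.append((chrom, start + 10, end + 50))
        if kind == "coding":
            coding.append((chrom, end - 5, end + 300))
        if kind != "no_lift":
            lifted.append((chrom, start - 20, end + 20))
        if kind == "true":
            true_uids.add(uid)
        expected_failures[uid] = kind_to_filter.get(kind)
    # unrelated background annotations, far from every candidate
    far = 10_000 + n_candidates * slot + 100_000
    coding.append((chrom, far, far + 2_000))
    ncrna.append((chrom, far + 5_000, far + 5_400))
    return {
        "candidates": candidates,
        "known_pseudogenes": known,
        "coding_loci": coding,
        "ncrna_loci": ncrna,
        "lifted_coding": lifted,
        "ortholog_table": ortholog,
        "paralog_table": paralog,
        "true_uids": true_uids,
        "expected_failures": expected_failures,
    }


def simulate_essentiality_data(n: int, parent_effect: float, seed: int = 0,
                               model: str = "probit", beta0: float = -0.85,
                               beta_expr: float = 0.3, parent_frac: float = 0.3):
    """Regression data with a known parent-status marginal effect.

    ``parent_effect`` is the marginal effect of parent status on the
    probability of essentiality, evaluated at the covariate means.  For the
    probit model the parent coefficient is solved so that
    Phi(b0 + b_p + b_e*mean(x)) - Phi(b0 + b_e*mean(x)) equals the target;
    for the linear probability model the coefficient is the effect itself.
    """
    rng = np.random.default_rng(seed)
    parent = (rng.random(n) < parent_frac).astype(float)
    expression = rng.standard_normal(n)
    if model == "probit":
        base = beta0  # expression is centred, so the mean linear index is beta0
        beta_parent = float(norm.ppf(norm.cdf(base) + parent_effect) - base)
        p = norm.cdf(beta0 + beta_parent * parent + beta_expr * expression)
    elif model == "lpm":
        beta_parent = parent_effect
        p = np.clip(0.3 + beta_parent * parent + 0.05 * expression, 0.02, 0.98)
    else:
        raise ValueError(f"unknown model {model!r}")
    essential = (rng.random(n) < p).astype(float)
    return {
        "essential": essential, "parent_status": parent, "expression": expression,
        "beta_parent": beta_parent,
    }
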