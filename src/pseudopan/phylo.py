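"""Pseudogene-based evolutionary analyses.

Two independent tree signals are extracted from the pangenome: (i) the
binary presence/absence profile of pangenome entries across strains,
clustered hierarchically, and (ii) the sequences of universally conserved
pseudogenes, concatenated per strain into a "supergene" and analysed with
Tamura-Nei (TN93) distances and neighbour joining.  Percent identity to the
parent gene serves as a pseudogene age proxy (retrotransposition bursts
appear as modes of its distribution), and locus-conservation fractions
against the reference strain follow an inverse-logarithmic divergence-time
curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.signal import find_peaks
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from . import seqevo
from .records import LiftoverMap
from .trees import StrainTree


# ---------------------------------------------------------------------------
# presence/absence clustering


def presence_absence_matrix(entries: list, strains: list) -> pd.DataFrame:
    """Binary entries x strains matrix (1 iff the entry has a member there)."""
    mat = pd.DataFrame(0, index=[e.pan_uid for e in entries], columns=list(strains),
                       dtype=np.int8)
    for e in entries:
        for s in e.strains:
            mat.loc[e.pan_uid, s] = 1
    return mat


def binary_cluster_tree(matrix: pd.DataFrame, metric: str = "jaccard",
                        method: str = "average") -> StrainTree:
    """Hierarchical clustering of strains on entry presence/absence."""
    strains = list(matrix.columns)
    if len(strains) < 3:
        raise ValueError("need at least 3 strains to cluster")
    profiles = matrix.to_numpy().T.astype(bool)
    if all((profiles[0] == profiles[i]).all() for i in range(1, len(strains))):
        raise ValueError("no variation: all strain profiles are identical")
    dists = pdist(profiles, metric=metric)
    Z = linkage(dists, method=method)

    def newick(node_id):
        n = len(strains)
        if node_id < n:
            return strains[node_id], 0.0
        row = Z[node_id - n]
        (ln, lh), (rn, rh) = newick(int(row[0])), newick(int(row[1]))
        h = row[2] / 2.0
        return f"({ln}:{h - lh:.10f},{rn}:{h - rh:.10f})", h

    frag, _ = newick(2 * len(strains) - 2)
    return StrainTree.from_newick(frag + ";")


# ---------------------------------------------------------------------------
# supergenes


@dataclass
class SupergeneSet:
    """Per-strain concatenations of sampled conserved pseudogene sequences."""

    sequences: dict          # strain -> np.uint8 codes
    members: list            # ordered entry/class ids, identical for every strain
    sample_fraction: float
    seed: int | None

    def __post_init__(self):
        lengths = {len(v) for v in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("supergene sequences must have equal length across strains")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def build_supergenes(entry_ids: list, seq_by_strain: dict, sample_fraction: float = 0.5,
                     seed: int | None = None, order_key: dict | None = None) -> SupergeneSet:
    """Sample conserved entries and concatenate their sequences per strain.

    ``seq_by_strain`` maps strain -> {entry_id: encoded sequence}; every
    strain must provide every sampled entry.  ``floor(fraction * N)``
    entries are drawn without replacement; concatenation follows
    ``order_key`` (reference genomic order) or lexicographic entry id.
    """
    if not 0.0 < sample_fraction <= 1.0:
        raise ValueError("sample_fraction must be in (0, 1]")
    ids = list(entry_ids)
    rng = np.random.default_rng(seed)
    k = int(np.floor(sample_fraction * len(ids))) if sample_fraction < 1.0 else len(ids)
    chosen = list(rng.choice(np.array(ids, dtype=object), size=k, replace=False)) \
        if k < len(ids) else ids
    key = order_key or {}
    chosen.sort(key=lambda e: (key.get(e, ()), e))
    for strain, seqs in seq_by_strain.items():
        missing = [e for e in chosen if e not in seqs]
        if missing:
            raise ValueError(f"strain {strain} lacks sequences for entries: {missing[:5]}")
    sequences = {
        strain: (np.concatenate([seq_by_strain[strain][e] for e in chosen])
                 if chosen else np.empty(0, dtype=np.uint8))
        for strain in seq_by_strain
    }
    return SupergeneSet(sequences=sequences, members=chosen,
                        sample_fraction=sample_fraction, seed=seed)


# ---------------------------------------------------------------------------
# TN93 distance


def tn93_distance(seq_a, seq_b, saturation: float = np.inf) -> float:
    """Tamura-Nei (1993) distance in expected substitutions per site.

    Base frequencies are estimated from the two sequences pooled.  Sites
    that are non-ACGT in either sequence are excluded pairwise.  When a
    logarithm argument is non-positive (saturation) the ``saturation``
    value (default +inf) is returned.
    """
    a = seq_a if isinstance(seq_a, np.ndarray) else _encode_loose(seq_a)
    b = seq_b if isinstance(seq_b, np.ndarray) else _encode_loose(seq_b)
    if a.shape != b.shape:
        raise ValueError(f"sequence length mismatch: {a.shape[0]} vs {b.shape[0]}")
    keep = (a < 4) & (b < 4)
    a, b = a[keep], b[keep]
    n = a.shape[0]
    if n == 0:
        raise ValueError("no comparable sites")
    freqs = np.bincount(np.concatenate([a, b]), minlength=4) / (2.0 * n)
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    diff = a != b
    # transitions: A<->G (codes 0,2) and C<->T (codes 1,3)
    p1 = float(np.mean(diff & ((a + b) == 2) & ((a % 2) == 0)))   # A<->G
    p2 = float(np.mean(diff & ((a % 2) == 1) & ((b % 2) == 1)))   # C<->T
    q = float(np.mean(diff)) - p1 - p2
    if p1 == 0.0 and p2 == 0.0 and q == 0.0:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = 2.0 * pa * pg / pr if pr > 0 else 0.0
        k2 = 2.0 * pc * pt / py if py > 0 else 0.0
        k3 = 2.0 * (pr * py - (pa * pg * py / pr if pr > 0 else 0.0)
                    - (pc * pt * pr / py if py > 0 else 0.0))
        w1 = 1.0 - p1 / k1 - q / (2.0 * pr) if k1 > 0 else (1.0 if p1 == 0 else -1.0)
        w2 = 1.0 - p2 / k2 - q / (2.0 * py) if k2 > 0 else (1.0 if p2 == 0 else -1.0)
        w3 = 1.0 - q / (2.0 * pr * py) if pr * py > 0 else (1.0 if q == 0 else -1.0)
        if w1 <= 0 or w2 <= 0 or w3 <= 0:
            return saturation
        d = -(k1 * np.log(w1)) - (k2 * np.log(w2)) - (k3 * np.log(w3))
    return float(d)


def _encode_loose(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        codes[arr == ord(c)] = i
    return codes


def distance_matrix(sequences: dict, saturation_ceiling: float = 5.0) -> pd.DataFrame:
    """Pairwise TN93 matrix over a dict of equal-length sequences.

    Saturated distances are capped at ``saturation_ceiling`` so the matrix
    stays usable as neighbour-joining input.
    """
    names = sorted(sequences)
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tn93_distance(sequences[names[i]], sequences[names[j]],
                              saturation=saturation_ceiling)
            mat[i, j] = mat[j, i] = min(d, saturation_ceiling)
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# neighbour joining


def neighbor_joining(dist: pd.DataFrame, outgroup: str | None = None) -> StrainTree:
    """Canonical neighbour joining; negative branch lengths clamp to zero."""
    mat = dist.to_numpy(dtype=float)
    names = list(dist.columns)
    if list(dist.index) != names:
        raise ValueError("distance matrix index and columns must agree")
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if outgroup is not None and outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} not in matrix")

    def clamp(x):
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            return 0.0
        return x

    nodes = list(names)           # newick fragments
    D = mat.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li_raw = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        li, lj = clamp(li_raw), clamp(dij - li_raw)
        new_frag = f"({nodes[ai]}:{li:.10f},{nodes[aj]}:{lj:.10f})"
        # distances from the new node to the rest
        newD = np.zeros(D.shape[0])
        for k_ in active:
            if k_ in (ai, aj):
                continue
            newD[k_] = 0.5 * (D[ai, k_] + D[aj, k_] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newD
        D[:-1, -1] = newD
        nodes.append(new_frag)
        active = [k_ for k_ in active if k_ not in (ai, aj)] + [D.shape[0] - 1]
    # resolve the final three lineages around a central node
    a, b, c = active
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    newick = f"({nodes[a]}:{la:.10f},{nodes[b]}:{lb:.10f},{nodes[c]}:{lc:.10f});"
    tree = StrainTree.from_newick(newick, outgroup=outgroup)
    if outgroup is not None:
        dtree = tree.tree
        og = next(lf for lf in dtree.leaf_node_iter() if lf.taxon.label == outgroup)
        dtree.is_rooted = True
        dtree.reroot_at_edge(og.edge, update_bipartitions=False,
                             length1=(og.edge.length or 0.0) / 2.0,
                             length2=(og.edge.length or 0.0) / 2.0)
        tree = StrainTree(dtree, outgroup=outgroup)
    return tree


# ---------------------------------------------------------------------------
# age distribution


def age_distribution(records: list, bin_width_pct: float = 0.5):
    """Histogram of percent identity to parent, with detected modes.

    Returns (DataFrame with bin_left/bin_right/count, list of mode bin
    centres ordered by decreasing peak height).
    """
    idents = np.array([r.pct_identity for r in records], dtype=float)
    edges = np.arange(0.0, 100.0 + bin_width_pct, bin_width_pct)
    counts, _ = np.histogram(idents, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    if counts.sum() == 0:
        return hist, []
    padded = np.concatenate([[0], counts, [0]])
    peaks, props = find_peaks(padded, prominence=max(1.0, 0.05 * counts.max()))
    centres = edges[peaks - 1] + bin_width_pct / 2.0
    order = np.argsort(props["prominences"])[::-1]
    return hist, [float(centres[i]) for i in order]


# ---------------------------------------------------------------------------
# locus conservation and divergence fit


def locus_conservation(records_strain: list, ref_records: list, liftover: LiftoverMap):
    """Fraction of one-to-one ortholog loci preserved against the reference.

    Pairs are matched on the shared annotation id (ens_id, falling back to
    uid).  A locus is preserved when the lifted strain record lands on the
    reference ortholog's chromosome and overlaps it by at least 1 bp;
    failed lifts and relocations count as changed.
    """
    ref_by_id = {(r.ens_id or r.uid): r for r in ref_records}
    preserved = changed = 0
    for rec in records_strain:
        key = rec.ens_id or rec.uid
        ref = ref_by_id.get(key)
        if ref is None:
            continue
        lifted = liftover.lift_interval(rec.chrom, rec.start, rec.end)
        if lifted is None:
            changed += 1
            continue
        chrom, ls, le, _ = lifted
        if chrom == ref.chrom and max(0, min(le, ref.end) - max(ls, ref.start)) >= 1:
            preserved += 1
        else:
            changed += 1
    total = preserved + changed
    return preserved, changed, (preserved / total if total else float("nan"))


def fit_divergence_curve(points: list):
    """Fit divergence time against conserved fraction: t = a + b * ln(f).

    ``points`` is a sequence of (conserved_fraction, divergence_time_my);
    returns (a, b, r_squared).  Fractions must be in (0, 1].
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    f = np.array([p[0] for p in pts], dtype=float)
    t = np.array([p[1] for p in pts], dtype=float)
    if (f <= 0).any() or (f > 1).any():
        raise ValueError("conserved fractions must be in (0, 1]")
    X = np.column_stack([np.ones_like(f), np.log(f)])
    beta, *_ = np.linalg.lstsq(X, t, rcond=None)
    resid = t - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(beta[0]), float(beta[1]), r2


def introgression_correlation(conserved_counts: list, subspecies_fractions: list):
    """Pearson correlation between normalised conserved-pseudogene counts and
    genome fractions attributable to a subspecies."""
    x = np.asarray(conserved_counts, dtype=float)
    y = np.asarray(subspecies_fractions, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input vector")
    r, p = pearsonr(x, y)
    return float(r), float(p)
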