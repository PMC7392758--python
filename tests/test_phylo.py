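"""Phylogenetics: clustering, supergenes, TN93, neighbour joining, curves."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from pseudopan import seqevo
from pseudopan.pangenome import PangenomeEntry
from pseudopan.phylo import (age_distribution, binary_cluster_tree,
                             build_supergenes, distance_matrix,
                             fit_divergence_curve, introgression_correlation,
                             locus_conservation, neighbor_joining,
                             presence_absence_matrix, tn93_distance)
from pseudopan.records import LiftoverMap
from pseudopan.trees import StrainTree
from tests.conftest import make_record


def entry(pan_uid, strains):
    return PangenomeEntry(pan_uid=pan_uid,
                          members={s: [f"{pan_uid}.{s}"] for s in strains})


# ---------------------------------------------------------------------------
# presence/absence and binary clustering


def test_presence_absence_rows_and_column_sums():
    strains = ["A", "B", "C"]
    entries = [entry("e1", strains), entry("e2", ["A"]), entry("e3", ["A", "B"])]
    m = presence_absence_matrix(entries, strains)
    assert m.loc["e1"].tolist() == [1, 1, 1]
    assert m.loc["e2"].tolist() == [1, 0, 0]
    assert (m.sum(axis=1) >= 1).all()
    # column sums recount per-strain participation
    assert m.sum(axis=0).to_dict() == {"A": 3, "B": 2, "C": 1}


def test_identical_pair_clusters_first_and_order_invariance():
    strains = ["A", "B", "C"]
    entries = ([entry(f"ab{i}", ["A", "B"]) for i in range(10)]
               + [entry(f"c{i}", ["C"]) for i in range(10)])
    m = presence_absence_matrix(entries, strains)
    t = binary_cluster_tree(m)
    # A and B share every entry, C none: (A,B) must be the cherry
    assert t.rf_distance(StrainTree.from_newick("((A:1,B:1):1,C:1);")) == 0
    shuffled = m.sample(frac=1.0, random_state=1)
    assert binary_cluster_tree(shuffled).rf_distance(t) == 0


def test_binary_clustering_errors():
    m = presence_absence_matrix([entry("e", ["A", "B"])], ["A", "B"])
    with pytest.raises(ValueError, match="at least 3"):
        binary_cluster_tree(m)
    m3 = presence_absence_matrix([entry("e", ["A", "B", "C"])], ["A", "B", "C"])
    with pytest.raises(ValueError, match="no variation"):
        binary_cluster_tree(m3)


# ---------------------------------------------------------------------------
# supergenes


def _seqs(rng, ids, n_strains=3, length=40):
    base = {e: rng.integers(0, 4, length).astype(np.uint8) for e in ids}
    return {f"s{k}": dict(base) for k in range(n_strains)}


def test_fraction_one_includes_all_entries(rng):
    ids = [f"e{i}" for i in range(7)]
    sg = build_supergenes(ids, _seqs(rng, ids), sample_fraction=1.0, seed=0)
    assert sorted(sg.members) == sorted(ids)
    assert sg.length == 7 * 40


def test_sampling_uses_floor_of_fraction_times_n(rng):
    ids = [f"e{i}" for i in range(2925)]
    seqs = {"s0": {e: np.zeros(1, dtype=np.uint8) for e in ids}}
    sg = build_supergenes(ids, seqs, sample_fraction=0.5, seed=1)
    assert len(sg.members) == 1462  # floor(0.5 * 2925)


def test_same_seed_reproduces_supergene(rng):
    ids = [f"e{i}" for i in range(20)]
    seqs = _seqs(rng, ids)
    a = build_supergenes(ids, seqs, seed=9)
    b = build_supergenes(ids, seqs, seed=9)
    assert a.members == b.members
    assert all(np.array_equal(a.sequences[s], b.sequences[s]) for s in seqs)


def test_missing_strain_sequence_raises_with_entry_name(rng):
    ids = ["e0", "e1"]
    seqs = _seqs(rng, ids)
    del seqs["s1"]["e1"]
    with pytest.raises(ValueError, match="e1"):
        build_supergenes(ids, seqs, sample_fraction=1.0, seed=0)
    with pytest.raises(ValueError, match="sample_fraction"):
        build_supergenes(ids, seqs, sample_fraction=0.0)


# ---------------------------------------------------------------------------
# TN93


def test_identical_sequences_distance_zero(rng):
    s = seqevo.decode(rng.integers(0, 4, 500).astype(np.uint8))
    assert tn93_distance(s, s) == 0.0


def test_length_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        tn93_distance("ACGT", "ACG")


def _tn93_counting_oracle(sa: str, sb: str) -> float:
    """Explicit per-site classification then the closed-form TN93 formula,
    written independently of the vectorised implementation."""
    pairs = [(x, y) for x, y in zip(sa, sb) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    counts = {b: 0 for b in "ACGT"}
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
    freq = {b: counts[b] / (2 * n) for b in "ACGT"}
    gr = freq["A"] + freq["G"]
    gy = freq["C"] + freq["T"]
    p1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    p2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    q = sum(1 for x, y in pairs if x != y and {x, y} not in ({"A", "G"}, {"C", "T"})) / n
    k1 = 2 * freq["A"] * freq["G"] / gr
    k2 = 2 * freq["C"] * freq["T"] / gy
    k3 = 2 * (gr * gy - freq["A"] * freq["G"] * gy / gr - freq["C"] * freq["T"] * gr / gy)
    import math
    w1 = 1 - p1 / k1 - q / (2 * gr)
    w2 = 1 - p2 / k2 - q / (2 * gy)
    w3 = 1 - q / (2 * gr * gy)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return float("inf")
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def test_tn93_matches_counting_oracle_on_random_pairs():
    rng = np.random.default_rng(17)
    for _ in range(100):
        base = rng.integers(0, 4, 600).astype(np.uint8)
        mut = seqevo.evolve_codes(base, float(rng.uniform(0.01, 0.5)), rng)
        sa, sb = seqevo.decode(base), seqevo.decode(mut)
        assert tn93_distance(sa, sb) == pytest.approx(_tn93_counting_oracle(sa, sb),
                                                      abs=1e-12)


def test_tn93_matches_ape_reference_implementation(tmp_path):
    """Cross-check against the independent TN93 implementation in R ape."""
    rng = np.random.default_rng(3)
    pairs = []
    for i in range(3):
        base = rng.integers(0, 4, 1500).astype(np.uint8)
        mut = seqevo.evolve_codes(base, 0.05 * (i + 1), rng)
        pairs.append((seqevo.decode(base), seqevo.decode(mut)))
    fa = tmp_path / "pairs.fa"
    fa.write_text("".join(f">p{i}a\n{a}\n>p{i}b\n{b}\n"
                          for i, (a, b) in enumerate(pairs)))
    script = textwrap.dedent(f"""
        library(ape); s <- read.dna("{fa}", format="fasta")
        for (i in 0:2) {{
          d <- dist.dna(s[c(paste0("p",i,"a"), paste0("p",i,"b")),], model="TN93")
          cat(sprintf("%.12f\\n", as.numeric(d)))
        }}""")
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                         check=True)
    ape_vals = [float(x) for x in out.stdout.split()]
    for (a, b), expect in zip(pairs, ape_vals):
        assert tn93_distance(a, b) == pytest.approx(expect, abs=1e-9)


def test_tn93_at_least_p_distance(rng):
    for _ in range(25):
        base = rng.integers(0, 4, 800).astype(np.uint8)
        mut = seqevo.evolve_codes(base, float(rng.uniform(0.02, 0.6)), rng)
        d = tn93_distance(base, mut)
        assert d >= seqevo.p_distance(base, mut) - 1e-12


def test_tn93_simulated_branch_length_recovered():
    """Mean TN93 estimate at true branch length 0.05 within 3 SE (50 reps)."""
    rng = np.random.default_rng(5)
    ests = []
    for _ in range(50):
        base = rng.integers(0, 4, 10_000).astype(np.uint8)
        mut = seqevo.evolve_codes(base, 0.05, rng)
        ests.append(tn93_distance(base, mut))
    se = np.std(ests, ddof=1) / np.sqrt(len(ests))
    assert abs(np.mean(ests) - 0.05) < 3 * se


def test_saturated_distance_returns_ceiling():
    a = "A" * 200 + "C" * 200
    b = "C" * 200 + "A" * 200  # every site differs, transversion-free pattern
    d = tn93_distance(a, b, saturation=5.0)
    assert d == 5.0


def test_non_acgt_sites_excluded_pairwise():
    assert tn93_distance("ACGTNN", "ACGTAC") == 0.0


# ---------------------------------------------------------------------------
# neighbour joining


def test_four_taxon_additive_matrix_recovered_exactly():
    # tree ((A:2,B:3):1,(C:4,D:5)); pairwise path lengths are additive
    names = ["A", "B", "C", "D"]
    dm = pd.DataFrame([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
                      index=names, columns=names, dtype=float)
    t = neighbor_joining(dm)
    truth = StrainTree.from_newick("((A:2,B:3):1,(C:4,D:5):0);")
    assert t.rf_distance(truth) == 0
    got_names, got = t.leaf_distance_matrix()
    assert got_names == names
    assert np.allclose(got, dm.to_numpy(), atol=1e-9)


def test_three_taxon_closed_form():
    names = ["A", "B", "C"]
    dm = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=names, columns=names,
                      dtype=float)
    t = neighbor_joining(dm)
    # closed form: la=1, lb=2, lc=3
    _, got = t.leaf_distance_matrix()
    assert np.allclose(got, dm.to_numpy(), atol=1e-12)


def test_nj_matches_skbio_on_random_matrices():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 6
        m = rng.random((n, n)) + 0.2
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        names = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(pd.DataFrame(m, index=names, columns=names))
        theirs = StrainTree.from_newick(str(skbio_nj(DistanceMatrix(m, names))))
        assert mine.rf_distance(theirs) == 0


def test_nj_validation_and_negative_clamping():
    names = ["A", "B", "C", "D"]
    bad = pd.DataFrame(np.arange(16.0).reshape(4, 4), index=names, columns=names)
    with pytest.raises(ValueError, match="symmetric"):
        neighbor_joining(bad)
    with pytest.raises(ValueError, match="at least 3"):
        neighbor_joining(pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"],
                                      columns=["A", "B"], dtype=float))
    # triangle-violating matrix forces a negative branch estimate
    m = pd.DataFrame([[0, 1, 5], [1, 0, 3], [5, 3, 0]],
                     index=["A", "B", "C"], columns=["A", "B", "C"], dtype=float)
    with pytest.warns(UserWarning, match="clamped"):
        t = neighbor_joining(m)
    assert all((e.length or 0) >= 0 for e in t.tree.preorder_edge_iter())


def test_nj_rooted_on_outgroup():
    names = ["A", "B", "C", "OUT"]
    dm = pd.DataFrame([[0, 2, 6, 10], [2, 0, 6, 10], [6, 6, 0, 10], [10, 10, 10, 0]],
                      index=names, columns=names, dtype=float)
    t = neighbor_joining(dm, outgroup="OUT")
    kids = t.tree.seed_node.child_nodes()
    assert any(c.is_leaf() and c.taxon.label == "OUT" for c in kids)


# ---------------------------------------------------------------------------
# age distribution


def test_single_value_records_give_single_mode(mk_rec):
    recs = [mk_rec(uid=f"r{i}", identity=92.5) for i in range(50)]
    hist, modes = age_distribution(recs)
    assert len(modes) == 1
    assert abs(modes[0] - 92.5) <= 0.5
    assert hist["count"].sum() == 50


def test_empty_input_gives_empty_histogram():
    hist, modes = age_distribution([])
    assert hist["count"].sum() == 0
    assert modes == []


# ---------------------------------------------------------------------------
# locus conservation


def _lift_shift(offset=0, chrom_map=None, length=10 ** 7):
    chrom_map = chrom_map or {"chr1": "chr1", "chr2": "chr2"}
    rows = [(src, 0, length, dst, offset, length + offset, "+")
            for src, dst in chrom_map.items()]
    return LiftoverMap(pd.DataFrame(rows, columns=LiftoverMap.COLUMNS))


def test_overlapping_same_chromosome_ortholog_is_preserved(mk_rec):
    rec = mk_rec(uid="x", strain="S", start=1000, end=2000, ens_id="cls1")
    ref = mk_rec(uid="y", strain="R", start=1100, end=2100, ens_id="cls1")
    pres, chg, frac = locus_conservation([rec], [ref], _lift_shift())
    assert (pres, chg, frac) == (1, 0, 1.0)


def test_lift_to_different_chromosome_counts_as_changed(mk_rec):
    rec = mk_rec(uid="x", strain="S", chrom="chr1", start=1000, end=2000, ens_id="c")
    ref = mk_rec(uid="y", strain="R", chrom="chr2", start=1000, end=2000, ens_id="c")
    pres, chg, frac = locus_conservation([rec], [ref], _lift_shift())
    assert (pres, chg, frac) == (0, 1, 0.0)


def test_identity_liftover_gives_fraction_one(clean_dataset):
    ds = clean_dataset
    s, ref = ds.strains[1], ds.strains[0]
    common = {r.ens_id for r in ds.truth_records[s]} & \
        {r.ens_id for r in ds.truth_records[ref]}
    recs = [r for r in ds.truth_records[s] if r.ens_id in common]
    pres, chg, frac = locus_conservation(recs, ds.truth_records[ref],
                                         ds.liftovers[(s, ref)])
    assert frac == 1.0 and chg == 0


def test_conservation_invariant_under_consistent_chromosome_renaming(mk_rec):
    rec = mk_rec(uid="x", strain="S", chrom="chr1", start=500, end=900, ens_id="c")
    ref = mk_rec(uid="y", strain="R", chrom="chr1", start=500, end=900, ens_id="c")
    out1 = locus_conservation([rec], [ref], _lift_shift())
    rec2, ref2 = rec.copy(chrom="alpha"), ref.copy(chrom="alpha")
    lift = _lift_shift(chrom_map={"alpha": "alpha"})
    out2 = locus_conservation([rec2], [ref2], lift)
    assert out1 == out2


# ---------------------------------------------------------------------------
# divergence curve and introgression correlation


def test_noiseless_inverse_log_curve_recovered_exactly():
    f = np.array([1.0, 0.9, 0.7, 0.5, 0.2])
    t = 2.0 - 5.0 * np.log(f)
    a, b, r2 = fit_divergence_curve(list(zip(f, t)))
    assert a == pytest.approx(2.0, abs=1e-9)
    assert b == pytest.approx(-5.0, abs=1e-9)
    assert r2 == pytest.approx(1.0)
    with pytest.raises(ValueError, match="\\(0, 1\\]"):
        fit_divergence_curve([(0.0, 1.0), (0.5, 2.0), (0.9, 3.0)])


def test_fraction_one_point_pins_the_intercept():
    # at f=1, ln f = 0, so the fitted value there equals a
    pts = [(1.0, 3.0), (np.exp(-1), 8.0), (np.exp(-2), 13.0)]
    a, b, _ = fit_divergence_curve(pts)
    assert a == pytest.approx(3.0, abs=1e-9)
    assert b == pytest.approx(-5.0, abs=1e-9)


def test_noisy_curve_parameters_recovered_within_three_se():
    rng = np.random.default_rng(8)
    a_true, b_true, sigma = 2.0, -5.0, 0.3
    a_hats, b_hats = [], []
    for _ in range(100):
        f = rng.uniform(0.1, 1.0, size=12)
        t = a_true + b_true * np.log(f) + sigma * rng.standard_normal(12)
        a, b, _ = fit_divergence_curve(list(zip(f, t)))
        a_hats.append(a)
        b_hats.append(b)
    for est, truth in ((a_hats, a_true), (b_hats, b_true)):
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - truth) < 3 * se


def test_perfect_correlation_and_preconditions():
    x = [1.0, 2.0, 3.0, 4.0]
    r, p = introgression_correlation(x, x)
    assert r == pytest.approx(1.0)
    with pytest.raises(ValueError, match="at least 3"):
        introgression_correlation([1, 2], [3, 4])
    with pytest.raises(ValueError, match="zero variance"):
        introgression_correlation([1, 1, 1], [1, 2, 3])


def test_type_one_error_rate_calibrated():
    """|r| exceeds the 5% critical value in about 5% of independent draws."""
    rng = np.random.default_rng(21)
    n, reps, hits = 12, 1000, 0
    for _ in range(reps):
        _, p = introgression_correlation(rng.standard_normal(n),
                                         rng.standard_normal(n))
        hits += p < 0.05
    rate = hits / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < 3 * se
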