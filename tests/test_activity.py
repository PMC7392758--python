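"""Transcription calling, expression contrasts, essentiality models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pseudopan.activity import (call_transcribed, disablement_density_trend,
                                essentiality_enrichment, fit_lpm, fit_probit,
                                mappability_filter, paralog_pseudogene_fit,
                                parent_expression_contrast,
                                probit_log_likelihood, quantifiable_records,
                                transcribed_any)
from pseudopan.simulate import simulate_essentiality_data


def track(*intervals):
    return pd.DataFrame(list(intervals), columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# mappability


def test_fully_mappable_exon_retained_whole():
    out = mappability_filter([("chr1", 1000, 1150)], track(("chr1", 0, 10_000)))
    assert out == [("chr1", 1000, 1150)]


def test_exon_with_only_short_mappable_piece_is_dropped():
    out = mappability_filter([("chr1", 1000, 1150)], track(("chr1", 1000, 1080)))
    assert out == []
    # strictly-greater-than: an exactly-100 bp piece does not survive
    out = mappability_filter([("chr1", 1000, 1150)], track(("chr1", 1000, 1100)))
    assert out == []
    out = mappability_filter([("chr1", 1000, 1150)], track(("chr1", 1000, 1101)))
    assert out == [("chr1", 1000, 1101)]


def test_empty_track_excludes_everything(mk_rec):
    assert mappability_filter([("chr1", 0, 500)], track()) == []
    recs = [mk_rec(uid="x", start=0, end=500)]
    assert quantifiable_records(recs, track()) == []
    assert quantifiable_records(recs, track(("chr1", 0, 500))) == recs


# ---------------------------------------------------------------------------
# transcription calls


def test_strict_cutoff_behaviour_at_fpkm_boundary():
    table = pd.DataFrame({"brain": [3.4, 3.3, 0.0]}, index=["a", "b", "c"])
    per_col, breadth = call_transcribed(table, 3.3)
    assert per_col["brain"] == {"a"}
    assert breadth.to_dict() == {"a": 1, "b": 0, "c": 0}


def test_raising_cutoff_never_adds_transcribed_calls(rng):
    table = pd.DataFrame(rng.exponential(2.0, size=(100, 4)),
                         index=[f"p{i}" for i in range(100)],
                         columns=list("wxyz"))
    prev = None
    for cutoff in (0.0, 1.0, 2.0, 3.3, 10.0):
        called = transcribed_any(table, cutoff)
        if prev is not None:
            assert called <= prev
        prev = called


def test_breadth_counts_columns_above_cutoff():
    table = pd.DataFrame({"t1": [5.0, 0.1], "t2": [4.0, 0.2], "t3": [0.0, 9.0]},
                         index=["a", "b"])
    _, breadth = call_transcribed(table, 1.0)
    assert breadth.to_dict() == {"a": 2, "b": 1}


def test_transcribed_fraction_matches_generator_truth(slim_dataset):
    ds = slim_dataset
    cfg = ds.config
    frac_called = []
    for s in ds.strains:
        called = transcribed_any(ds.pseudogene_fpkm[s], cfg.transcription_cutoff)
        truth = ds.transcribed_truth[s]
        assert called == truth  # above-cutoff by construction in the generator
        frac_called.append(len(called) / len(ds.truth_records[s]))
    n = sum(len(ds.truth_records[s]) for s in ds.strains)
    se = np.sqrt(cfg.frac_transcribed * (1 - cfg.frac_transcribed) / n)
    assert abs(np.mean(frac_called) - cfg.frac_transcribed) < 3 * se


# ---------------------------------------------------------------------------
# parent contrast


def test_identical_groups_give_null_contrast():
    x = np.tile(np.arange(50, dtype=float), 2)
    flags = np.repeat([True, False], 50)
    out = parent_expression_contrast(x, flags)
    assert out["median_difference"] == 0.0
    assert out["p_value"] > 0.9


def test_contrast_requires_both_groups():
    with pytest.raises(ValueError, match="non-empty"):
        parent_expression_contrast([1.0, 2.0], [True, True])


def test_twofold_parent_expression_detected_reliably():
    """Parents at 2x median FPKM (n=500 vs 500) are significant at 1% in at
    least 95% of replicates."""
    rng = np.random.default_rng(2)
    hits = 0
    reps = 100
    for _ in range(reps):
        parents = rng.lognormal(np.log(4.0), 1.0, 500)
        others = rng.lognormal(np.log(2.0), 1.0, 500)
        out = parent_expression_contrast(
            np.concatenate([parents, others]),
            np.repeat([True, False], 500))
        hits += out["p_value"] < 0.01 and out["median_difference"] > 0
    assert hits >= 95


def test_tied_data_uses_midrank_u_statistic():
    # all-equal values: mid-rank U equals n1*n2/2 and the contrast is null
    out = parent_expression_contrast([2.0] * 6 + [2.0] * 4,
                                     [True] * 6 + [False] * 4)
    assert out["statistic"] == pytest.approx(6 * 4 / 2)
    assert out["p_value"] > 0.9


def test_small_sample_p_matches_exact_enumeration():
    """Two-sided p from the rank test agrees with exhaustive enumeration of
    group assignments on a tie-free n<=8 fixture."""
    values = [1.0, 3.0, 5.0, 9.0, 2.0, 4.0, 6.0, 8.0]
    flags = [True] * 4 + [False] * 4
    out = parent_expression_contrast(values, flags)

    def u_stat(group_a):
        group_b = [v for v in values if v not in group_a]
        return sum(1 for a in group_a for b in group_b if a > b)

    observed = u_stat(values[:4])
    us = [u_stat(list(c)) for c in itertools.combinations(values, 4)]
    # two-sided: distance of U from its mean
    mu = 4 * 4 / 2
    p_exact = np.mean([abs(u - mu) >= abs(observed - mu) for u in us])
    assert out["p_value"] == pytest.approx(p_exact, abs=0.02)


# ---------------------------------------------------------------------------
# paralog fits


def test_exact_line_recovered_in_duplicated_mode():
    x = np.arange(10, dtype=float)
    fit = paralog_pseudogene_fit(x, 1 + 2 * x, biotype="duplicated")
    assert fit["a"] == pytest.approx(1.0, abs=1e-9)
    assert fit["b"] == pytest.approx(2.0, abs=1e-9)
    with pytest.raises(ValueError, match="zero variance"):
        paralog_pseudogene_fit([2, 2, 2], [1, 2, 3])


def test_gapdh_like_versus_prame_like_gives_negative_log_slope():
    """Few-paralog high-output families (GAPDH-like: 7 paralogs, ~200
    processed copies) against many-paralog low-output families (PRAME-like:
    >80 paralogs, <2 copies) produce a negative log-fit slope."""
    rng = np.random.default_rng(6)
    paralogs = np.concatenate([rng.integers(5, 9, 20), rng.integers(80, 120, 20)])
    counts = np.concatenate([rng.poisson(200, 20), rng.poisson(1.0, 20)]).astype(float)
    fit = paralog_pseudogene_fit(paralogs, counts, biotype="processed")
    assert fit["b"] < 0
    assert fit["spearman_rho"] < 0


def test_shuffled_counts_rarely_reach_significance():
    rng = np.random.default_rng(9)
    x = rng.poisson(3.0, 50).astype(float) + rng.random(50)  # tie-free
    y = rng.poisson(5.0, 50).astype(float) + rng.random(50)
    hits = 0
    reps = 1000
    for _ in range(reps):
        fit = paralog_pseudogene_fit(x, rng.permutation(y))
        hits += fit["spearman_p"] < 0.05
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(hits / reps - 0.05) < 3 * se


# ---------------------------------------------------------------------------
# linear probability model


def test_lpm_recovers_known_parent_effect():
    d = simulate_essentiality_data(5000, 0.20, seed=1, model="lpm")
    fit = fit_lpm(d["essential"], d["parent_status"], d["expression"])
    assert abs(fit.marginal_effect - 0.20) < 3 * fit.marginal_effect_se


def test_lpm_matches_statsmodels_ols():
    import statsmodels.api as sm

    d = simulate_essentiality_data(800, 0.15, seed=3, model="lpm")
    fit = fit_lpm(d["essential"], d["parent_status"], d["expression"])
    X = sm.add_constant(np.column_stack([d["parent_status"], d["expression"]]))
    ref = sm.OLS(d["essential"], X).fit()
    assert np.allclose(list(fit.coefficients.values()), ref.params, atol=1e-10)
    assert np.allclose(list(fit.standard_errors.values()), ref.bse, atol=1e-10)


def test_lpm_zero_effect_confidence_interval_coverage():
    """95% CI covers zero in ~95% of zero-effect replicates."""
    covered = 0
    reps = 1000
    for seed in range(reps):
        d = simulate_essentiality_data(300, 0.0, seed=seed, model="lpm")
        fit = fit_lpm(d["essential"], d["parent_status"], d["expression"])
        half = 1.96 * fit.standard_errors["parent_status"]
        covered += abs(fit.coefficients["parent_status"]) <= half
    se = np.sqrt(0.95 * 0.05 / reps)
    assert abs(covered / reps - 0.95) < 3 * se + 0.005


def test_lpm_degenerate_inputs_raise():
    with pytest.raises(ValueError, match="zero-variance"):
        fit_lpm([1, 1, 1, 1, 1], [0, 1, 0, 1, 0], [0.1, 0.2, 0.3, 0.4, 0.5])
    with pytest.raises(ValueError, match="rank"):
        fit_lpm([0, 1, 0, 1, 1], [1, 1, 1, 1, 1], [1, 1, 1, 1, 1])


# ---------------------------------------------------------------------------
# probit model


def _grid_search_ll(y, X, centre, width=2.0, rounds=14, points=9):
    """Brute-force maximum of the probit likelihood by iterative grid
    refinement around ``centre``; the window shrinks slowly enough that
    successive cubes overlap and a diagonal likelihood valley is followed."""
    best = np.array(centre, dtype=float)
    best_ll = probit_log_likelihood(best, y, X)
    for _ in range(rounds):
        axes = [np.linspace(b - width, b + width, points) for b in best]
        for b0 in axes[0]:
            for b1 in axes[1]:
                for b2 in axes[2]:
                    ll = probit_log_likelihood([b0, b1, b2], y, X)
                    if ll > best_ll:
                        best_ll, best = ll, np.array([b0, b1, b2])
        width /= 2.5
    return best_ll


@pytest.mark.parametrize("n,seed", [(50, 4), (60, 7)])
def test_probit_optimum_matches_grid_search_oracle(n, seed):
    d = simulate_essentiality_data(n, 0.2, seed=seed)
    fit = fit_probit(d["essential"], d["parent_status"], d["expression"])
    X = np.column_stack([np.ones(n), d["parent_status"], d["expression"]])
    grid_ll = _grid_search_ll(d["essential"], X, centre=[0.0, 0.0, 0.0], width=2.0)
    assert fit.log_likelihood >= grid_ll - 1e-9
    assert abs(fit.log_likelihood - grid_ll) < 1e-4


def test_probit_matches_statsmodels():
    import statsmodels.api as sm

    d = simulate_essentiality_data(1500, 0.2, seed=5)
    fit = fit_probit(d["essential"], d["parent_status"], d["expression"])
    X = sm.add_constant(np.column_stack([d["parent_status"], d["expression"]]))
    ref = sm.Probit(d["essential"], X).fit(disp=0)
    assert np.allclose(list(fit.coefficients.values()), ref.params, atol=1e-6)
    assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)


def test_probit_recovers_known_marginal_effect():
    d = simulate_essentiality_data(5000, 0.20, seed=2)
    fit = fit_probit(d["essential"], d["parent_status"], d["expression"])
    assert fit.converged
    assert abs(fit.marginal_effect - 0.20) < 3 * fit.marginal_effect_se


def test_probit_zero_effect_ci_covers_zero():
    d = simulate_essentiality_data(2000, 0.0, seed=6)
    fit = fit_probit(d["essential"], d["parent_status"], d["expression"])
    half = 1.96 * fit.standard_errors["parent_status"]
    assert abs(fit.coefficients["parent_status"]) <= 3 * half


def test_probit_perfect_separation_raises():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(60)
    y = (x > 0).astype(float)
    parent = (rng.random(60) < 0.5).astype(float)
    with pytest.raises(ValueError, match="separation|singular"):
        fit_probit(y, parent, x)


def test_lpm_and_probit_marginal_effects_agree_on_moderate_data():
    d = simulate_essentiality_data(4000, 0.2, seed=9)
    lpm = fit_lpm(d["essential"], d["parent_status"], d["expression"])
    prob = fit_probit(d["essential"], d["parent_status"], d["expression"])
    assert abs(lpm.marginal_effect - prob.marginal_effect) < 0.03


def test_parent_essentiality_enrichment_near_three():
    """With the generator's 3x enrichment design and enough genes for the
    ratio to stabilise, the naive enrichment lands within 0.3 of 3."""
    from pseudopan.simulate import SimConfig, simulate_dataset

    ds = simulate_dataset(SimConfig(seed=31, n_strains=4, n_genes=4000,
                                    expected_pseudogenes_per_strain=300))
    tab = ds.genes
    ratio = essentiality_enrichment(tab["essential"].to_numpy(),
                                    tab["is_parent"].to_numpy())
    assert abs(ratio - 3.0) < 0.3


# ---------------------------------------------------------------------------
# disablement density


def test_density_proportional_to_divergence_gives_perfect_rank_corr(mk_rec):
    recs = []
    for i, ident in enumerate((98.0, 95.0, 90.0, 85.0)):
        div = 100 - ident
        recs.append(mk_rec(uid=f"r{i}", start=0, end=1000, identity=ident,
                           disablements={"stop": int(div * 10), "deletion": 0,
                                         "insertion": 0}))
    out = disablement_density_trend(recs)
    assert out["spearman_rho"] == pytest.approx(1.0)
    assert out["slope"] > 0


def test_constant_density_gives_zero_slope(mk_rec):
    recs = [mk_rec(uid=f"r{i}", start=0, end=1000, identity=ident,
                   disablements={"stop": 5, "deletion": 0, "insertion": 0})
            for i, ident in enumerate((98.0, 95.0, 90.0))]
    out = disablement_density_trend(recs)
    assert out["slope"] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="at least 3"):
        disablement_density_trend(recs[:2])


def test_synthetic_records_show_positive_disablement_trend(slim_dataset):
    ds = slim_dataset
    recs = [r for s in ds.strains for r in ds.truth_records[s]]
    out = disablement_density_trend(recs)
    assert out["slope"] > 0
    assert out["spearman_rho"] > 0.5
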