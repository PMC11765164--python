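import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methyldiag.io import MethylationMatrix, SampleMetadataTable, ValidationError
from methyldiag.screening import (
    bin_beta_values,
    chi_square_tissue_test,
    rank_disease_sites,
    screen_tissue_specific,
    site_summary,
)
from methyldiag.simulate import SyntheticCohortConfig, generate_cohort, null_cohort


# ---------------------------------------------------------------- binning
def test_bin_boundary_convention():
    np.testing.assert_array_equal(
        bin_beta_values([0.0, 0.5, 1.0], 10), [0, 5, 9]
    )
    assert bin_beta_values([0.999], 10)[0] == 9


def test_uniform_grid_fills_bins_evenly():
    grid = (np.arange(1000) + 0.5) / 1000
    bins = bin_beta_values(grid, 10)
    counts = np.bincount(bins, minlength=10)
    np.testing.assert_array_equal(counts, [100] * 10)


def test_bin_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bin_beta_values([0.5, 1.2], 10)
    with pytest.raises(ValidationError):
        bin_beta_values([0.5], 1)


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50),
    st.integers(2, 20),
)
def test_bin_indices_always_in_range(values, n_bins):
    bins = bin_beta_values(values, n_bins)
    assert np.all((bins >= 0) & (bins < n_bins))


# ---------------------------------------------------------- chi-square test
def test_chi_square_hand_example_two_by_two():
    """Counts [[10,0],[0,10]]: expected 5 per cell, statistic 4*(25/5)=20."""
    values = [0.1] * 10 + [0.9] * 10
    labels = ["a"] * 10 + ["b"] * 10
    r = chi_square_tissue_test(values, labels, n_bins=2)
    assert r.statistic == pytest.approx(20.0, abs=1e-12)
    assert r.df == 1
    assert r.p_value == pytest.approx(float(stats.chi2.sf(20.0, 1)), abs=1e-12)


def test_chi_square_identical_distributions_give_zero():
    values = [0.1, 0.5, 0.9] * 4
    labels = ["a"] * 6 + ["b"] * 6
    r = chi_square_tissue_test(values, labels, n_bins=5)
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == 1.0


def test_chi_square_matches_scipy_on_random_tables():
    """Statistic and p agree with the standard contingency routine to 1e-9."""
    rng = np.random.default_rng(17)
    tissues = np.array(["a", "b", "c"])
    for _ in range(50):
        n = int(rng.integers(30, 150))
        values = rng.random(n)
        labels = tissues[rng.integers(0, 3, n)]
        n_bins = int(rng.integers(2, 8))
        r = chi_square_tissue_test(values, labels, n_bins=n_bins)
        bins = np.minimum((values * n_bins).astype(int), n_bins - 1)
        table = np.zeros((n_bins, 3))
        for b, l in zip(bins, labels):
            table[b, np.flatnonzero(tissues == l)[0]] += 1
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        expect = stats.chi2_contingency(table, correction=False)
        assert r.statistic == pytest.approx(expect.statistic, abs=1e-9)
        assert r.p_value == pytest.approx(expect.pvalue, abs=1e-9)
        assert r.df == expect.dof


def test_chi_square_single_tissue_is_error():
    with pytest.raises(ValidationError, match="2 tissues"):
        chi_square_tissue_test([0.1, 0.2], ["a", "a"])


def test_chi_square_single_occupied_bin_degenerate():
    r = chi_square_tissue_test([0.11, 0.12, 0.13, 0.14], ["a", "a", "b", "b"], n_bins=5)
    assert r.statistic == 0.0
    assert r.df == 0
    assert r.p_value == 1.0


def test_missing_values_dropped_pairwise():
    values = [0.1] * 10 + [0.9] * 10 + [np.nan] * 3
    labels = ["a"] * 10 + ["b"] * 10 + ["a", "b", "a"]
    r = chi_square_tissue_test(values, labels, n_bins=2)
    assert r.statistic == pytest.approx(20.0, abs=1e-12)


# ------------------------------------------------------------- full screen
def _screen_cohort(seed=11):
    cfg = SyntheticCohortConfig(
        tissues=("brain", "kidney", "lung"),
        n_healthy_per_tissue=40,
        n_disease_per_tissue=0,
        n_sites=300,
        n_tissue_specific=30,
        n_disease_specific_per_tissue=0,
        tissue_shift=0.25,
        seed=seed,
    )
    return generate_cohort(cfg)


def test_screen_tau_zero_selects_nothing():
    m, meta, _ = _screen_cohort()
    res = screen_tissue_specific(m, meta, tau_p=0.0)
    assert res.selected_sites == []


def test_screen_recovers_planted_sites():
    m, meta, truth = _screen_cohort()
    res = screen_tissue_specific(m, meta, tau_p=0.01)
    recall = len(set(res.selected_sites) & truth.tissue_specific_sites) / 30
    assert recall >= 0.9


def test_screen_selection_consistent_with_p_values():
    """selected_sites is exactly {p < tau_p}, ordered by (p, site_id)."""
    m, meta, _ = _screen_cohort(seed=23)
    res = screen_tissue_specific(m, meta, tau_p=0.05)
    expected = sorted(
        (r for r in res.results if r.p_value < 0.05),
        key=lambda r: (r.p_value, r.site_id),
    )
    assert res.selected_sites == [r.site_id for r in expected]


def test_screen_uses_healthy_samples_only():
    """A disease-only shift must not register as tissue specificity."""
    rng = np.random.default_rng(0)
    n = 60  # 15 healthy + 15 disease per tissue
    betas = rng.uniform(0.4, 0.6, (n, 5))
    status = np.tile([0] * 15 + [1] * 15, 2)
    tissue = ["brain"] * 30 + ["kidney"] * 30
    # site 0: large shift in diseased brain samples only
    betas[(np.array(tissue) == "brain") & (status == 1), 0] = 0.95
    m = MethylationMatrix([f"s{i}" for i in range(n)], [f"cg{j}" for j in range(5)], betas)
    meta = SampleMetadataTable(
        pd.DataFrame({"sample_id": m.sample_ids, "tissue": tissue, "status": status}),
        tissue_vocabulary=("brain", "kidney"),
    )
    res = screen_tissue_specific(m, meta, tau_p=0.05, n_bins=5)
    assert res.results[0].p_value > 0.05


def test_screen_requires_healthy_and_two_tissues():
    m, meta, _ = _screen_cohort()
    sick = meta.frame.copy()
    sick["status"] = 1
    with pytest.raises(ValidationError, match="healthy"):
        screen_tissue_specific(
            m, SampleMetadataTable(sick, meta.tissue_vocabulary)
        )
    with pytest.raises(ValidationError):
        screen_tissue_specific(m, meta, tau_p=1.5)


def test_type_one_error_small_null():
    m, meta = null_cohort(40, 1000, ["a", "b", "c"], seed=2)
    res = screen_tissue_specific(m, meta, tau_p=0.05)
    frac = len(res.selected_sites) / 1000
    se = np.sqrt(0.05 * 0.95 / 1000)
    assert abs(frac - 0.05) < 3 * se


def test_statistic_grows_with_planted_shift():
    """Mean planted-site statistic increases with tissue_shift (20 seeds)."""
    mean_stats = []
    for shift in (0.05, 0.15, 0.25):
        per_seed = []
        for seed in range(20):
            cfg = SyntheticCohortConfig(
                tissues=("a", "b"),
                n_healthy_per_tissue=25,
                n_disease_per_tissue=0,
                n_sites=40,
                n_tissue_specific=8,
                n_disease_specific_per_tissue=0,
                tissue_shift=shift,
                seed=seed,
            )
            m, meta, truth = generate_cohort(cfg)
            res = screen_tissue_specific(m, meta)
            by_id = {r.site_id: r.statistic for r in res.results}
            per_seed.append(
                np.mean([by_id[s] for s in truth.tissue_specific_sites])
            )
        mean_stats.append(np.mean(per_seed))
    assert mean_stats[0] < mean_stats[1] < mean_stats[2]


# ------------------------------------------------------------------ ranking
def test_rank_topk_exceeding_candidates_keeps_all(two_tissue_cohort):
    m, meta = two_tissue_cohort
    r = rank_disease_sites(m, meta, "brain", m.site_ids, top_k=1000)
    assert sorted(r.selected_sites) == sorted(m.site_ids)
    assert sorted(r.site_ids_ranked) == sorted(m.site_ids)


def test_rank_perfect_separator_first(two_tissue_cohort):
    """A site fully separating status must outrank pure-noise sites."""
    m, meta = two_tissue_cohort
    r = rank_disease_sites(m, meta, "brain", m.site_ids, top_k=5)
    assert r.site_ids_ranked[0] == "cg000"
    # univariate oracle agrees: cg000 has the largest |mean difference|
    brain = meta.select(tissue="brain")
    y = meta.status_for(brain)
    sub = m.subset_samples(brain)
    diffs = np.abs(
        sub.betas[y == 1].mean(axis=0) - sub.betas[y == 0].mean(axis=0)
    )
    assert m.site_ids[int(np.argmax(diffs))] == "cg000"


def test_rank_deterministic(two_tissue_cohort):
    m, meta = two_tissue_cohort
    r1 = rank_disease_sites(m, meta, "brain", m.site_ids)
    r2 = rank_disease_sites(m, meta, "brain", m.site_ids)
    assert r1.site_ids_ranked == r2.site_ids_ranked
    assert r1.coefficients == r2.coefficients


def test_rank_signed_criterion_orders_by_signed_coefficient(two_tissue_cohort):
    m, meta = two_tissue_cohort
    r = rank_disease_sites(m, meta, "brain", m.site_ids, criterion="signed")
    coefs = [r.coefficients[s] for s in r.site_ids_ranked]
    assert coefs == sorted(coefs, reverse=True)


def test_rank_errors(two_tissue_cohort):
    m, meta = two_tissue_cohort
    with pytest.raises(ValidationError, match="single health status"):
        rank_disease_sites(m, meta, "kidney", m.site_ids)
    with pytest.raises(ValidationError):
        rank_disease_sites(m, meta, "brain", [])


# ----------------------------------------------------------------- summary
def _cohort_from_values(healthy, disease, site="cgX", tissue="brain"):
    vals = list(healthy) + list(disease)
    n = len(vals)
    m = MethylationMatrix(
        [f"s{i}" for i in range(n)], [site], np.array(vals)[:, None]
    )
    meta = SampleMetadataTable(
        pd.DataFrame(
            {
                "sample_id": m.sample_ids,
                "tissue": tissue,
                "status": [0] * len(healthy) + [1] * len(disease),
            }
        ),
        tissue_vocabulary=(tissue,),
    )
    return m, meta


def test_summary_reproduces_reported_fold_change():
    m, meta = _cohort_from_values([0.03, 0.04, 0.05], [0.39, 0.399, 0.41])
    s = site_summary(m, meta, "brain", "cgX")
    assert s.h_m == pytest.approx(0.04)
    assert s.d_m == pytest.approx(0.399)
    assert s.magnification == pytest.approx(9.975)


def test_summary_even_n_median_and_identity():
    m, meta = _cohort_from_values([0.1, 0.3], [0.2, 0.6])
    s = site_summary(m, meta, "brain", "cgX")
    assert (s.h_m, s.d_m) == (pytest.approx(0.2), pytest.approx(0.4))
    assert s.magnification == pytest.approx(2.0)
    m2, meta2 = _cohort_from_values([0.2, 0.4], [0.2, 0.4])
    assert site_summary(m2, meta2, "brain", "cgX").magnification == pytest.approx(1.0)


def test_summary_zero_healthy_median_undefined():
    m, meta = _cohort_from_values([0.0, 0.0, 0.0], [0.2, 0.3, 0.4])
    assert site_summary(m, meta, "brain", "cgX").magnification is None


def test_summary_standard_error_of_mean():
    h = [0.1, 0.2, 0.3, 0.4]
    m, meta = _cohort_from_values(h, [0.5, 0.6])
    s = site_summary(m, meta, "brain", "cgX")
    assert s.h_se == pytest.approx(np.std(h, ddof=1) / 2.0)


def test_summary_bootstrap_se_is_seeded():
    m, meta = _cohort_from_values([0.1, 0.2, 0.3, 0.4, 0.5], [0.5, 0.6, 0.7])
    a = site_summary(m, meta, "brain", "cgX", se_method="median", seed=4)
    b = site_summary(m, meta, "brain", "cgX", se_method="median", seed=4)
    assert (a.h_se, a.d_se) == (b.h_se, b.d_se)
    assert a.h_se > 0
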