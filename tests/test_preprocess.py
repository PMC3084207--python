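"""QC filters, HWE imputation, marker subsetting and phenotype adjustment."""

import numpy as np
import pytest
from scipy import stats

from wgpred import (
    GenotypeMatrix,
    PhenotypeTable,
    SimConfig,
    adjust_phenotype,
    filter_adults,
    filter_markers,
    impute_missing,
    simulate_cohort,
    subset_evenly_spaced,
)
from wgpred.data import MISSING
from wgpred.preprocess import EmptyPanelError

import pandas as pd


def _toy_panel():
    """Five markers: two good, one 50% missing, one MAF 0.01, one monomorphic-ish."""
    rng = np.random.default_rng(0)
    n = 100
    counts = np.zeros((n, 5), dtype=np.int8)
    counts[:, 0] = rng.binomial(2, 0.3, n)
    counts[:, 1] = rng.binomial(2, 0.4, n)
    counts[: n // 2, 1] = MISSING          # 50% missing
    counts[:, 2] = 0
    counts[0, 2] = 1                       # MAF = 1/200 = 0.005
    counts[:, 3] = rng.binomial(2, 0.45, n)
    counts[:, 4] = rng.binomial(2, 0.25, n)
    ids = np.array([f"i{k}" for k in range(n)], dtype=object)
    markers = np.array([f"m{k}" for k in range(5)], dtype=object)
    return GenotypeMatrix(ids, counts, markers)


def test_filter_removes_planted_failures_exactly():
    gm = _toy_panel()
    out, report = filter_markers(gm)
    assert report.n_markers_out == 3
    assert list(out.marker_ids) == ["m0", "m3", "m4"]
    assert report.n_failed_callrate == 1 and report.n_failed_maf == 1
    assert report.n_markers_in - report.n_markers_out == 2


def test_filter_is_noop_on_clean_panel():
    gm = _toy_panel().subset_markers(np.array([0, 3, 4]))
    out, report = filter_markers(gm)
    np.testing.assert_array_equal(out.counts, gm.counts)
    assert report.n_failed_callrate == report.n_failed_maf == 0


def test_monomorphic_marker_always_removed():
    counts = np.zeros((50, 2), dtype=np.int8)
    counts[:, 1] = np.random.default_rng(1).binomial(2, 0.4, 50)
    gm = GenotypeMatrix(np.array([f"i{k}" for k in range(50)]), counts,
                        np.array(["mono", "poly"]))
    out, _ = filter_markers(gm)
    assert list(out.marker_ids) == ["poly"]


def test_filter_idempotent(small_cohort):
    once, _ = filter_markers(small_cohort.genotypes)
    twice, report = filter_markers(once)
    np.testing.assert_array_equal(once.counts, twice.counts)
    assert report.n_markers_out == once.n_markers


def test_marker_failing_both_counted_in_both_classes_removed_once():
    counts = np.full((100, 2), MISSING, dtype=np.int8)
    counts[:5, 0] = [0, 1, 0, 0, 0]        # call rate 5%, MAF 0.1 -> callrate only
    counts[:5, 1] = 0                      # call rate 5% and MAF 0 -> both
    counts[:, 0][5:] = MISSING
    gm = GenotypeMatrix(np.array([f"i{k}" for k in range(100)]), counts,
                        np.array(["a", "b"]))
    with pytest.raises(EmptyPanelError):
        filter_markers(gm)


def test_empty_panel_raises():
    counts = np.zeros((20, 1), dtype=np.int8)  # monomorphic
    gm = GenotypeMatrix(np.array([f"i{k}" for k in range(20)]), counts, np.array(["m"]))
    with pytest.raises(EmptyPanelError):
        filter_markers(gm)


# -- imputation -------------------------------------------------------------

def test_imputation_degenerate_frequencies():
    counts = np.array([[0, 2]] * 5 + [[MISSING, MISSING]] * 5, dtype=np.int8)
    gm = GenotypeMatrix(np.array([f"i{k}" for k in range(10)]), counts,
                        np.array(["p0", "p1"]))
    out = impute_missing(gm, seed=0)
    assert (out.counts[:, 0] == 0).all()
    assert (out.counts[:, 1] == 2).all()


def test_imputation_preserves_observed_calls(small_cohort):
    filtered, _ = filter_markers(small_cohort.genotypes)
    out = impute_missing(filtered, seed=3)
    obs = ~filtered.missing_mask
    np.testing.assert_array_equal(out.counts[obs], filtered.counts[obs])
    assert not out.missing_mask.any()


def test_imputed_values_follow_binomial_hwe():
    """Moments and genotype-class counts match Binomial(2, 0.4)."""
    n_obs, n_miss = 200, 10_000
    observed = np.concatenate([np.repeat(2, 30), np.repeat(1, 100), np.repeat(0, 70)])
    assert observed.sum() / (2 * n_obs) == 0.4
    counts = np.concatenate([observed, np.full(n_miss, MISSING)]).astype(np.int8)
    gm = GenotypeMatrix(np.array([f"i{k}" for k in range(n_obs + n_miss)]),
                        counts[:, None], np.array(["m"]))
    out = impute_missing(gm, seed=11)
    imputed = out.counts[n_obs:, 0]
    assert abs(imputed.mean() - 0.8) < 4 * np.sqrt(0.48 / n_miss)
    assert abs(imputed.var() - 0.48) < 0.03
    freq = np.bincount(imputed, minlength=3)
    expected = n_miss * np.array([0.36, 0.48, 0.16])
    assert stats.chisquare(freq, expected).pvalue > 1e-3


def test_imputation_rejects_fully_missing_marker():
    counts = np.full((5, 1), MISSING, dtype=np.int8)
    gm = GenotypeMatrix(np.array(list("abcde")), counts, np.array(["m"]))
    with pytest.raises(ValueError, match="call-rate"):
        impute_missing(gm)


def test_imputation_reproducible():
    filtered, _ = filter_markers(_toy_panel())
    a = impute_missing(filtered, seed=5)
    b = impute_missing(filtered, seed=5)
    np.testing.assert_array_equal(a.counts, b.counts)


# -- evenly spaced subsetting ----------------------------------------------

@pytest.mark.parametrize(
    "p,n_target,expected",
    [
        (10, 5, [0, 2, 4, 6, 8]),
        (10, 10, list(range(10))),
        (10, 1, [0]),
        (7, 3, [0, 2, 4]),
    ],
)
def test_evenly_spaced_indices(p, n_target, expected):
    counts = np.tile(np.arange(p, dtype=np.int8) % 3, (4, 1))
    gm = GenotypeMatrix(np.array(list("abcd")), counts,
                        np.array([f"m{k}" for k in range(p)]))
    out = subset_evenly_spaced(gm, n_target)
    assert list(out.marker_ids) == [f"m{k}" for k in expected]


def test_evenly_spaced_rejects_oversized_target(small_cohort):
    with pytest.raises(ValueError):
        subset_evenly_spaced(small_cohort.genotypes, small_cohort.genotypes.n_markers + 1)


def test_evenly_spaced_spacing_within_one_of_uniform(small_cohort):
    out = subset_evenly_spaced(small_cohort.genotypes, 37)
    idx = np.array([list(small_cohort.genotypes.marker_ids).index(m)
                    for m in out.marker_ids])
    gaps = np.diff(idx)
    ideal = small_cohort.genotypes.n_markers / 37
    assert np.all(np.abs(gaps - ideal) <= 1.0)


# -- phenotype adjustment ---------------------------------------------------

def test_adjustment_recovers_simulated_fixed_effects():
    cfg = SimConfig(n_founders=400, n_offspring=600, n_markers=200,
                    sex_effect=10.0, age_effect_per_year=-0.2,
                    missing_rate_range=(0, 0), seed=13)
    cohort = simulate_cohort(cfg)
    adjusted, model = adjust_phenotype(cohort.phenotypes)
    assert abs(model.sex_coefficient - 10.0) < 1.5
    assert abs(model.age_coefficient + 0.2) < 0.05
    resid = adjusted.adjusted_height
    assert abs(resid.sum()) < 1e-6
    # all linear age/sex signal removed
    male = (adjusted.table["sex"] == "M").to_numpy(dtype=float)
    age = adjusted.table["age"].to_numpy()
    for x in (male, age):
        slope = np.cov(resid, x)[0, 1] / np.var(x)
        assert abs(slope) < 1e-8


def test_adjustment_constant_covariates_fall_back_to_mean_centering():
    df = pd.DataFrame(
        {
            "individual_id": list("abcd"),
            "height": [160.0, 170.0, 165.0, 175.0],
            "sex": ["F"] * 4,
            "age": [30.0] * 4,
            "true_genetic_value": np.nan,
            "adjusted_height": np.nan,
        }
    )
    adjusted, model = adjust_phenotype(PhenotypeTable(df))
    np.testing.assert_allclose(
        adjusted.adjusted_height, df["height"] - df["height"].mean()
    )
    assert set(model.dropped_terms) == {"sex", "age"}


def test_adults_only_filter():
    df = pd.DataFrame(
        {
            "individual_id": list("abc"),
            "height": [150.0, 160.0, 170.0],
            "sex": ["F", "M", "F"],
            "age": [10.0, 18.0, 40.0],
            "true_genetic_value": 0.0,
            "adjusted_height": np.nan,
        }
    )
    out = filter_adults(PhenotypeTable(df))
    assert list(out.ids) == ["b", "c"]
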