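"""Fisher-Z correlation analysis and PCA preparation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvp.stats import (
    correlate_measures,
    fisher_z,
    fisher_z_inverse,
    normalize_exercise,
    prepare_pca,
)


def test_fisher_z_known_values():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), rel=1e-12)


@given(r=st.floats(-0.999, 0.999))
@settings(max_examples=50, deadline=None)
def test_fisher_z_odd_and_roundtrip(r):
    assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-14)
    assert fisher_z_inverse(fisher_z(r)) == pytest.approx(r, abs=1e-12)


def test_fisher_z_rejects_unit_correlation():
    with pytest.raises(ValueError):
        fisher_z(1.0)


def _cohort_frame(rng, n=20, n_measures=5, slope=0.0, noise=1.0):
    ex = rng.normal(0, 1, n)
    data = {"mouse": [f"m{i}" for i in range(n)]}
    for j in range(n_measures):
        data[f"meas{j}"] = slope * ex + rng.normal(0, noise, n)
    return pd.DataFrame(data), pd.Series(ex)


def test_correlation_of_constructed_linear_measure(rng):
    measures, ex = _cohort_frame(rng, slope=2.0, noise=0.01)
    summary = correlate_measures(measures, ex)
    for res in summary.results:
        assert res.r > 0.99
        assert res.z > 2.5
        assert res.ci95[0] <= res.r <= res.ci95[1]


def test_null_cohort_mean_z_ci_covers_zero(rng):
    measures, ex = _cohort_frame(rng, n=30, n_measures=22, slope=0.0)
    summary = correlate_measures(measures, ex)
    lo, hi = summary.z_ci95
    assert lo <= 0.0 <= hi


def test_affine_rescaling_of_measure_preserves_r(rng):
    measures, ex = _cohort_frame(rng, slope=1.0, noise=0.5)
    base = correlate_measures(measures, ex)
    scaled = measures.copy()
    scaled["meas0"] = scaled["meas0"] * 13.0 - 7.0
    again = correlate_measures(scaled, ex)
    assert again.results[0].r == pytest.approx(base.results[0].r, abs=1e-12)


def test_duplicate_mouse_rejected(rng):
    measures, ex = _cohort_frame(rng)
    dup = pd.concat([measures, measures.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        correlate_measures(dup, pd.concat([ex, ex.iloc[[0]]],
                                          ignore_index=True))


def test_too_few_pairs_flagged(rng):
    measures, ex = _cohort_frame(rng, n=10)
    measures.loc[3:, "meas0"] = np.nan  # only 3 complete pairs... below 3? 0,1,2 remain
    measures.loc[2, "meas0"] = np.nan   # now 2 pairs -> flagged
    summary = correlate_measures(measures, ex)
    res0 = [r for r in summary.results if r.measure == "meas0"][0]
    assert res0.flagged


def test_normalize_exercise_within_timepoint():
    df = pd.DataFrame({"timepoint": [1, 1, 2, 2],
                       "distance": [0.0, 2.0, 10.0, 30.0]})
    z = normalize_exercise(df)
    np.testing.assert_allclose(z[df.timepoint == 1], [-1.0, 1.0])
    np.testing.assert_allclose(z[df.timepoint == 2], [-1.0, 1.0])


# ---------------------------------------------------------------------------
# PCA


def test_pca_excludes_variables_over_missing_cutoff(rng):
    n = 10
    df = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=list("abcd"))
    df.loc[:2, "d"] = np.nan          # 30% missing -> excluded
    df.loc[0, "c"] = np.nan           # 10% missing -> retained, imputed
    prep = prepare_pca(df)
    assert "d" in prep.excluded_variables
    assert prep.excluded_variables["d"] == pytest.approx(0.3)
    assert set(prep.retained_variables) == {"a", "b", "c"}


def test_pca_eigenvalue_sum_equals_variable_count(rng):
    df = pd.DataFrame(rng.normal(0, 1, (40, 6)),
                      columns=[f"v{i}" for i in range(6)])
    prep = prepare_pca(df)
    assert prep.eigenvalues.sum() == pytest.approx(6.0, abs=1e-9)
    assert np.all(prep.variance_fractions >= 0)
    assert prep.variance_fractions.sum() <= 1.0 + 1e-12


def test_pca_correlated_pair_shares_pc1_contribution(rng):
    """Two perfectly correlated variables + independent noise variables:
    PC1 is the correlated block, its contribution split equally."""
    n = 400
    x = rng.normal(0, 1, n)
    df = pd.DataFrame({
        "a": x, "b": 2.0 * x + 5.0,
        "c": rng.normal(0, 1, n), "d": rng.normal(0, 1, n),
    })
    prep = prepare_pca(df)
    c = prep.contributions["PC1"]
    assert c["a"] == pytest.approx(0.5, abs=0.05)
    assert c["b"] == pytest.approx(0.5, abs=0.05)
    assert c["c"] + c["d"] < 0.1


def test_pca_eigenvalue_rule_is_strict(rng):
    # independent standardized variables at large n: eigenvalues hover
    # around 1; retention uses strictly > 1
    df = pd.DataFrame(rng.normal(0, 1, (2000, 5)),
                      columns=[f"v{i}" for i in range(5)])
    prep = prepare_pca(df)
    for i in prep.retained_pcs:
        assert prep.eigenvalues[i] > 1.0


def test_pca_zero_variance_variable_errors(rng):
    df = pd.DataFrame({"a": rng.normal(0, 1, 10), "b": np.ones(10)})
    with pytest.raises(ValueError, match="zero variance"):
        prepare_pca(df)


def test_pca_mean_imputation_matches_plain_pca_when_complete(rng):
    df = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"))
    prep = prepare_pca(df)
    # oracle: direct eigendecomposition of the correlation matrix
    z = (df - df.mean()) / df.std(ddof=0)
    evals = np.sort(np.linalg.eigvalsh(np.corrcoef(z.T)))[::-1]
    np.testing.assert_allclose(prep.eigenvalues, evals, atol=1e-10)


def test_pca_iterative_imputation_deterministic(rng):
    df = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"))
    df.loc[1, "a"] = np.nan
    p1 = prepare_pca(df, imputation="iterative", seed=3)
    p2 = prepare_pca(df, imputation="iterative", seed=3)
    np.testing.assert_array_equal(p1.eigenvalues, p2.eigenvalues)
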