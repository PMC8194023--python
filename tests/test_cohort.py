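"""Cohort schema, IO, normalization, splitting, filtering, fixture generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lonnrec import (
    Cohort,
    FixtureParams,
    encode_and_normalize,
    filter_positive,
    generate_fixture_cohort,
    read_cohort,
    split_train_test,
    write_cohort,
)
from lonnrec.cohort import fit_normalization
from lonnrec.exceptions import InvalidParameterError, SchemaError


def test_write_read_round_trip(tmp_path, cohort299):
    path = tmp_path / "cohort.csv"
    write_cohort(cohort299, path)
    back = read_cohort(path)
    pd.testing.assert_frame_equal(
        back.df, cohort299.df[back.df.columns], check_dtype=False
    )


def test_read_accepts_variable_aliases(tmp_path):
    path = tmp_path / "alias.csv"
    path.write_text(
        "id,V1,V2,V3,V4,V5,V6,V7,V8,V9,V10,O1,O2,death\n"
        "p1,1,60,250,35,0,260000,1.1,137,0,1,120,1,0\n"
    )
    cohort = read_cohort(path)
    assert list(cohort.df["sex"]) == [1]
    assert cohort.df["ejection_fraction"].iloc[0] == 35
    assert cohort.has_death


def test_read_empty_file_with_header(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(
        "ID,sex,age,creatinine_phosphokinase,ejection_fraction,high_blood_pressure,"
        "platelets,serum_creatinine,serum_sodium,smoking,anemia,time,treatment_key\n"
    )
    assert len(read_cohort(path)) == 0


def test_duplicate_ids_rejected(cohort299):
    df = cohort299.df.copy()
    df.loc[1, "ID"] = df.loc[0, "ID"]
    with pytest.raises(SchemaError, match="duplicated"):
        Cohort(df)


def test_missing_column_named(cohort299):
    df = cohort299.df.drop(columns=["platelets"])
    with pytest.raises(SchemaError, match="platelets"):
        Cohort(df)


def test_non_numeric_cell_reported_with_row(tmp_path, cohort299):
    path = tmp_path / "bad.csv"
    df = cohort299.df.head(5).copy()
    df["age"] = df["age"].astype(object)
    df.loc[3, "age"] = "forty"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="age.*row 3"):
        read_cohort(path)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def test_normalization_edges(cohort299):
    X, Y, spec = encode_and_normalize(cohort299)
    assert X.shape == (299, 10) and Y.shape == (299, 2)
    assert np.all((X >= 0) & (X <= 1)) and np.all((Y >= 0) & (Y <= 1))
    # lower edge -> 0, upper edge -> 1, midpoint -> 0.5
    lo, hi = spec.ranges["age"]
    assert spec.transform_column("age", np.array([lo]))[0] == 0.0
    assert spec.transform_column("age", np.array([hi]))[0] == 1.0
    assert spec.transform_column("age", np.array([(lo + hi) / 2]))[0] == pytest.approx(0.5)


def test_normalization_is_affine_order_preserving(cohort299):
    spec = fit_normalization(cohort299)
    vals = np.sort(cohort299.df["serum_sodium"].to_numpy())
    out = spec.transform_column("serum_sodium", vals)
    assert np.all(np.diff(out) >= 0)


def test_reused_spec_clamps_out_of_range(cohort299):
    _, _, spec = encode_and_normalize(cohort299)
    lo, hi = spec.ranges["age"]
    out = spec.transform_column("age", np.array([lo - 100.0, hi + 100.0]))
    assert out[0] == 0.0 and out[1] == 1.0


def test_constant_column_maps_to_zero(cohort299):
    df = cohort299.df.copy()
    df["serum_sodium"] = 137.0
    X, _, _ = encode_and_normalize(Cohort(df))
    assert np.all(X[:, 7] == 0.0)


# ---------------------------------------------------------------------------
# Split / filter
# ---------------------------------------------------------------------------


def test_split_sizes_and_partition(cohort299):
    train, test = split_train_test(cohort299, 0.8, seed=0)
    assert (len(train), len(test)) == (240, 59)
    ids = set(train.df["ID"]) | set(test.df["ID"])
    assert len(ids) == 299
    assert not set(train.df["ID"]) & set(test.df["ID"])


def test_split_deterministic(cohort299):
    t1, _ = split_train_test(cohort299, 0.8, seed=5)
    t2, _ = split_train_test(cohort299, 0.8, seed=5)
    assert list(t1.df["ID"]) == list(t2.df["ID"])


def test_split_validation(cohort299):
    with pytest.raises(InvalidParameterError):
        split_train_test(cohort299, 1.2, seed=0)
    tiny = Cohort(cohort299.df.head(1).copy())
    with pytest.raises(SchemaError):
        split_train_test(tiny, 0.8, seed=0)


def test_filter_positive_contracts(cohort299):
    df = cohort299.df.copy()
    df["death"] = 0
    df["time"] = 100.0
    all_pos = Cohort(df)
    assert len(filter_positive(all_pos)) == len(all_pos)
    df2 = cohort299.df.copy()
    df2["death"] = 1
    assert len(filter_positive(Cohort(df2))) == 0
    df3 = cohort299.df.drop(columns=["death"])
    with pytest.raises(SchemaError, match="death"):
        filter_positive(Cohort(df3))


def test_filter_positive_retained_fraction_matches_generative_rate():
    params = FixtureParams()
    cohort = generate_fixture_cohort(1000, seed=1, params=params)
    kept = filter_positive(cohort, min_time_days=60.0)
    df = cohort.df
    p_surv = 1.0 - params.death_probability(
        df["ejection_fraction"].to_numpy(),
        df["serum_creatinine"].to_numpy(),
        df["age"].to_numpy(),
    )
    # survivors always have time >= 60 under the default time law
    assert len(kept) / len(cohort) == pytest.approx(float(p_surv.mean()), abs=0.05)
    assert kept.df["death"].sum() == 0
    assert kept.df["time"].mean() > cohort.df["time"].mean()


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------


def test_fixture_empty_and_deterministic():
    assert len(generate_fixture_cohort(0, seed=3)) == 0
    a = generate_fixture_cohort(50, seed=3)
    b = generate_fixture_cohort(50, seed=3)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_fixture_invalid_params_rejected():
    with pytest.raises(InvalidParameterError):
        generate_fixture_cohort(10, seed=0, params=FixtureParams(tk_prob_reduced=1.4))
    with pytest.raises(InvalidParameterError):
        generate_fixture_cohort(-1, seed=0)


def test_treatment_mechanism_rate():
    """P(treatment key = 1 | reduced ejection fraction) is the configured 0.9."""
    cohort = generate_fixture_cohort(5000, seed=42)
    df = cohort.df
    reduced = df["ejection_fraction"] < 40.0
    rate = df.loc[reduced, "treatment_key"].mean()
    assert rate == pytest.approx(0.90, abs=0.02)


def test_fixture_moments_converge():
    """Empirical moments at n=20000 sit within 3 standard errors of the laws."""
    params = FixtureParams()
    cohort = generate_fixture_cohort(20000, seed=7, params=params)
    df = cohort.df
    n = len(df)

    def within(observed, expected, sd):
        assert abs(observed - expected) <= 3 * sd / np.sqrt(n) + 1e-12, (
            observed,
            expected,
        )

    for col, p in (
        ("sex", params.p_sex),
        ("high_blood_pressure", params.p_hbp),
        ("smoking", params.p_smoking),
        ("anemia", params.p_anemia),
    ):
        within(df[col].mean(), p, np.sqrt(p * (1 - p)))

    lo, hi = params.age_range
    a, b = (lo - params.age_mean) / params.age_sd, (hi - params.age_mean) / params.age_sd
    tn = stats.truncnorm(a, b, loc=params.age_mean, scale=params.age_sd)
    within(df["age"].mean(), tn.mean(), tn.std())

    cpk = stats.lognorm(s=params.cpk_log_sd, scale=np.exp(params.cpk_log_mean))
    within(df["creatinine_phosphokinase"].mean(), cpk.mean(), cpk.std())
    creat = stats.lognorm(
        s=params.creatinine_log_sd, scale=np.exp(params.creatinine_log_mean)
    )
    within(df["serum_creatinine"].mean(), creat.mean(), creat.std())

    within(df["platelets"].mean(), params.platelets_mean, params.platelets_sd)

    sodium_mean = params.sodium_intercept + params.sodium_age_slope * (
        tn.mean() - params.age_mean
    )
    sodium_sd = np.sqrt(
        params.sodium_noise_sd**2 + (params.sodium_age_slope * tn.std()) ** 2
    )
    within(df["serum_sodium"].mean(), sodium_mean, sodium_sd)

    ef_mean = (
        params.p_reduced * params.ef_reduced_mean
        + (1 - params.p_reduced) * params.ef_preserved_mean
    )
    ef_var = (
        params.p_reduced * (params.ef_reduced_sd**2 + params.ef_reduced_mean**2)
        + (1 - params.p_reduced)
        * (params.ef_preserved_sd**2 + params.ef_preserved_mean**2)
        - ef_mean**2
    )
    within(df["ejection_fraction"].mean(), ef_mean, np.sqrt(ef_var))

    # outcome mechanisms, conditionally on the drawn covariates
    tk_p = np.where(
        df["ejection_fraction"] < params.ef_threshold,
        params.tk_prob_reduced,
        params.tk_prob_preserved,
    )
    within(df["treatment_key"].mean(), tk_p.mean(), np.sqrt((tk_p * (1 - tk_p)).mean()))
    death_p = params.death_probability(
        df["ejection_fraction"].to_numpy(),
        df["serum_creatinine"].to_numpy(),
        df["age"].to_numpy(),
    )
    within(df["death"].mean(), death_p.mean(), np.sqrt((death_p * (1 - death_p)).mean()))

    t_death = np.mean(params.time_death_range)
    t_surv = np.mean(params.time_survivor_range)
    expected_time = (df["death"] * t_death + (1 - df["death"]) * t_surv).mean()
    time_sd = (params.time_survivor_range[1] - params.time_death_range[0]) / np.sqrt(12)
    within(df["time"].mean(), expected_time, time_sd)
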