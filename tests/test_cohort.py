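import numpy as np
import pandas as pd
import pytest

from akibench.baselines import BaselineMethod
from akibench.cohort import (
    CohortConfig,
    aggregate_features,
    apply_exclusions,
    build_cohort,
    filter_missing_columns,
    impute_chained,
    label_admissions,
    normalize,
)
from akibench.models import SplitConfig
from akibench.synthetic_ehr import SimConfig, generate_population


@pytest.fixture(scope="module")
def labelled(small_bundle):
    return label_admissions(small_bundle, BaselineMethod.M3_mean_180to0_or_mdrd)


class TestExclusions:
    def test_audit_counts_are_consistent(self, small_bundle, labelled):
        ids, audit = apply_exclusions(small_bundle, labelled)
        n_in = audit.iloc[0]["n_remaining"]
        assert n_in - audit["n_excluded"].sum() == len(ids)
        assert audit.iloc[-1]["n_remaining"] == len(ids)

    def test_minors_excluded_first(self, small_bundle, labelled):
        ids, audit = apply_exclusions(small_bundle, labelled)
        demo = small_bundle.admissions.merge(small_bundle.patients, on="patient_id")
        demo = demo.set_index("admission_id")
        assert (demo.loc[ids, "age"] >= 18).all()
        n_minor = int((demo["age"] < 18).sum())
        assert audit.set_index("step").loc["age_lt_min", "n_excluded"] == n_minor

    def test_second_stays_and_rrt_excluded(self, small_bundle, labelled):
        ids, _ = apply_exclusions(small_bundle, labelled)
        demo = small_bundle.admissions.set_index("admission_id").loc[ids]
        assert (demo["stay_number"] == 1).all()
        assert (demo["rrt"] == 0).all()

    def test_no_day1_aki_in_cohort(self, small_bundle, labelled):
        ids, _ = apply_exclusions(small_bundle, labelled)
        lab = labelled.set_index("admission_id").loc[ids]
        assert not lab["day1_flag"].any()

    def test_day1_exclusion_recovers_planted_rate_with_truth_baseline(self):
        """Labelling against the true baseline, the day-1 exclusion count
        matches the planted day-1 trajectory rate (binomial 99% CI)."""
        from akibench.kdigo import detect_aki

        cfg = SimConfig(n_patients=1500, seed=31, aki_day1_rate=0.3, noise_sd=0.0,
                        second_stay_rate=0.0, rrt_rate=0.0,
                        age_range=(20.0, 100.0))
        bundle = generate_population(cfg)
        truth = bundle.truth.set_index("admission_id")
        day1 = 0
        for aid in bundle.admission_ids():
            lab = detect_aki(bundle.creatinine_series(aid), truth.loc[aid, "true_baseline"])
            day1 += lab.flagged and lab.first_detection_day == 1
        n = len(bundle.admissions)
        half = 2.576 * np.sqrt(0.3 * 0.7 / n)
        assert abs(day1 / n - 0.3) <= half


class TestAggregation:
    def test_min_max_of_first24h_events(self, small_bundle):
        ids = small_bundle.admission_ids()[:50]
        feats = aggregate_features(small_bundle, ids)
        ev = small_bundle.icu_events
        hr = ev[(ev.variable == "heart_rate") & (ev.admission_id == ids[0])
                & (ev.offset_h < 24.0)]
        assert feats.loc[ids[0], "heart_rate_min"] == hr["value"].min()
        assert feats.loc[ids[0], "heart_rate_max"] == hr["value"].max()

    def test_one_hot_ethnicity_exactly_one(self, small_bundle):
        ids = small_bundle.admission_ids()[:100]
        feats = aggregate_features(small_bundle, ids)
        onehot = feats[[c for c in feats.columns if c.startswith("ethnicity_")]]
        assert (onehot.sum(axis=1) == 1.0).all()

    def test_urine_output_mean(self, small_bundle):
        ids = small_bundle.admission_ids()[:20]
        feats = aggregate_features(small_bundle, ids)
        uo = small_bundle.urine_output
        mine = uo[(uo.admission_id == ids[3]) & (uo.offset_h < 24.0)]["volume_ml"].mean()
        assert feats.loc[ids[3], "urine_output_mean"] == pytest.approx(mine)

    def test_egfr_feature_from_min_day1_creatinine(self, small_bundle):
        from akibench.renal import ckdepi_egfr

        ids = small_bundle.admission_ids()[:20]
        feats = aggregate_features(small_bundle, ids)
        row = feats.loc[ids[5]]
        sex = "female" if row["sex_female"] else "male"
        if row["age"] >= 18:
            assert row["egfr_ckdepi"] == pytest.approx(
                ckdepi_egfr(row["creatinine_min"], row["age"], sex)
            )


class TestMissingFilter:
    def test_boundary_strictly_greater(self):
        df = pd.DataFrame({
            "keep20": [1.0, 2.0, np.nan, 4.0, 5.0],  # exactly 20%
            "drop68": [np.nan, np.nan, np.nan, 4.0, np.nan],  # 80%
            "full": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        kept, dropped = filter_missing_columns(df, 0.20)
        assert list(kept.columns) == ["keep20", "full"]
        assert dropped.index.tolist() == ["drop68"]
        assert dropped.iloc[0] == pytest.approx(0.8)

    def test_complete_table_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        kept, dropped = filter_missing_columns(df)
        assert kept.equals(df) and dropped.empty

    def test_high_missingness_columns_dropped_in_pipeline(self, noisy_bundle):
        labels = label_admissions(noisy_bundle, BaselineMethod.B3_mean_180to7_or_mdrd)
        ids, _ = apply_exclusions(noisy_bundle, labels)
        feats = aggregate_features(noisy_bundle, ids)
        _, dropped = filter_missing_columns(feats, 0.20)
        names = {c.rsplit("_", 1)[0] for c in dropped.index}
        assert {"albumin", "bilirubin", "globulin", "thrombin"} <= names


class TestImputation:
    def test_complete_table_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0] * 20, "b": [4.0, 5.0, 6.0] * 20})
        out = impute_chained(df, df.index)
        pd.testing.assert_frame_equal(out, df)

    def test_deterministic_and_complete(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        df.loc[rng.random(200) < 0.15, "a"] = np.nan
        train = df.index[:120]
        cfg = CohortConfig(seed=5)
        out1, out2 = impute_chained(df, train, cfg), impute_chained(df, train, cfg)
        pd.testing.assert_frame_equal(out1, out2)
        assert not out1.isna().any().any()

    def test_mcar_mean_recovery(self, rng):
        """MCAR-deleting 10% of a correlated Gaussian column; the imputed
        column mean stays within 3 standard errors of the original."""
        n = 2000
        x = rng.normal(0, 1, n)
        y = 0.8 * x + rng.normal(0, 0.6, n)
        df = pd.DataFrame({"x": x, "y": y})
        pre_mean, se = df["y"].mean(), df["y"].std() / np.sqrt(n)
        df.loc[rng.random(n) < 0.10, "y"] = np.nan
        out = impute_chained(df, df.index, CohortConfig(seed=1))
        assert abs(out["y"].mean() - pre_mean) <= 3 * se

    def test_all_missing_column_raises(self):
        df = pd.DataFrame({"a": [np.nan] * 10, "b": np.arange(10.0)})
        with pytest.raises(ValueError):
            impute_chained(df, df.index)


class TestNormalize:
    def test_train_range_maps_to_unit_interval(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0, 8.0]})
        scaled, _ = normalize(df, pd.Index([0, 1, 2]))
        assert scaled["a"].tolist() == [0.0, 0.5, 1.0, 1.0]  # 8 clipped

    def test_binary_flags_unchanged(self):
        df = pd.DataFrame({"flag": [0.0, 1.0, 0.0, 1.0]})
        scaled, _ = normalize(df, df.index)
        assert scaled["flag"].tolist() == df["flag"].tolist()

    def test_zero_variance_maps_to_zero_with_warning(self):
        df = pd.DataFrame({"c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            scaled, _ = normalize(df, df.index)
        assert (scaled["c"] == 0.0).all()


class TestBuildCohort:
    def test_outcome_prevalence_matches_labeller(self, noisy_bundle):
        ds = build_cohort(
            noisy_bundle, BaselineMethod.B3_mean_180to7_or_mdrd,
            CohortConfig(seed=3), SplitConfig(seed=3),
        )
        lab = ds.labels.set_index("admission_id").loc[ds.y.index]
        assert (ds.y == lab["outcome"]).all()
        assert ds.y.notna().all()

    def test_features_in_unit_interval_and_partitions_disjoint(self, noisy_bundle):
        ds = build_cohort(
            noisy_bundle, BaselineMethod.B1_min_first24h,
            CohortConfig(seed=3), SplitConfig(seed=3),
        )
        assert float(ds.X.min().min()) >= 0.0
        assert float(ds.X.max().max()) <= 1.0
        parts = [set(ds.rows(p)) for p in ("train", "validation", "test")]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert set().union(*parts) == set(ds.X.index)


class TestLeakageGuards:
    def test_scaler_params_invariant_to_test_rows(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        train = df.index[:60]
        from akibench.cohort import fit_minmax

        p1 = fit_minmax(df, train)
        df2 = df.copy()
        df2.iloc[60:] = df2.iloc[60:].sample(frac=1.0, random_state=1).to_numpy()
        df2.iloc[60:, 0] += 100.0  # even altering test rows changes nothing
        p2 = fit_minmax(df2, train)
        pd.testing.assert_frame_equal(p1, p2)

    def test_imputed_train_rows_invariant_to_test_rows(self, rng):
        df = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
        df.loc[rng.random(150) < 0.1, "b"] = np.nan
        train = df.index[:90]
        out1 = impute_chained(df, train, CohortConfig(seed=2))
        df2 = df.copy()
        perm = rng.permutation(np.arange(90, 150))
        df2.iloc[90:] = df.iloc[perm].to_numpy()
        out2 = impute_chained(df2, train, CohortConfig(seed=2))
        pd.testing.assert_frame_equal(out1.iloc[:90], out2.iloc[:90])
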