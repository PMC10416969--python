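import numpy as np
import pandas as pd
import pytest

import cgmcal as c
from cgmcal.synthetic import (
    COHORT_COLUMNS,
    COVARIATES,
    CohortParseError,
    CohortSchemaError,
    CohortValidationError,
    read_summary_csv,
)


def _cfg(**kw):
    defaults = dict(n_patients=2, duration_days=3, seed=7)
    defaults.update(kw)
    return c.CohortConfig(**defaults)


class TestGenerateCohort:
    def test_zero_error_model_gives_perfect_sensor(self):
        cohort = c.generate_cohort(_cfg(error_model=c.ErrorModelSpec.zero()))
        np.testing.assert_array_equal(
            cohort.readings["g_m"].to_numpy(), cohort.readings["g_r"].to_numpy()
        )

    def test_same_seed_is_bit_identical(self, tmp_path):
        a = c.generate_cohort(_cfg())
        b = c.generate_cohort(_cfg())
        pd.testing.assert_frame_equal(a.readings, b.readings)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        c.write_cohort(a.readings, tmp_path / "a.csv")
        c.write_cohort(b.readings, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seeds_differ(self):
        a = c.generate_cohort(_cfg(seed=1))
        b = c.generate_cohort(_cfg(seed=2))
        assert not a.readings["g_r"].equals(b.readings["g_r"])

    def test_cluster_keyed_bias_lands_on_reference_clusters(self):
        em = c.ErrorModelSpec(
            per_cluster_bias=(15.0, 0, 0, 0, 0, -20.0),
            per_cluster_slope=(0.0,) * 6,
            covariate_coefficients=(0.0,) * 7,
            noise_sd=0.0,
            patient_offset_sd=0.0,
        )
        cohort = c.generate_cohort(c.CohortConfig(n_patients=6, duration_days=7, seed=3, error_model=em))
        g_r = cohort.readings["g_r"].to_numpy()
        err = cohort.readings["g_m"].to_numpy() - g_r
        low, high = g_r <= 80, g_r > 250
        assert low.sum() > 0 and high.sum() > 0  # trajectory spans the extremes
        np.testing.assert_allclose(err[low], 15.0, atol=1e-12)
        np.testing.assert_allclose(err[high], -20.0, atol=1e-12)
        mid = ~low & ~high
        np.testing.assert_allclose(err[mid], 0.0, atol=1e-12)

    def test_ground_truth_error_is_recomputable_in_closed_form(self):
        em = c.ErrorModelSpec(noise_sd=0.0, patient_offset_sd=0.0)
        cohort = c.generate_cohort(_cfg(error_model=em))
        df = cohort.readings
        expected = em.systematic_error(df["g_r"].to_numpy(), df[COVARIATES].to_numpy())
        np.testing.assert_allclose(
            df["g_m"].to_numpy() - df["g_r"].to_numpy(), expected, atol=1e-12
        )
        np.testing.assert_allclose(cohort.truth["true_error"].to_numpy(), expected, atol=1e-12)

    def test_truth_decomposition_sums_to_error(self, medium_cohort):
        t = medium_cohort.truth
        total = t["systematic_error"] + t["patient_offset"] + t["noise"]
        recorded = (
            medium_cohort.readings["g_m"] - medium_cohort.readings["g_r"]
        ).to_numpy()
        # equality except where the 1 mg/dL floor clipped the measured value
        close = np.isclose(total.to_numpy(), recorded, atol=1e-9)
        assert close.mean() > 0.99

    @pytest.mark.parametrize(
        "kw,field",
        [
            ({"n_patients": 0}, "n_patients"),
            ({"duration_days": 0}, "duration_days"),
            ({"cgm_interval": 0}, "cgm_interval"),
            ({"references_per_day": 0}, "references_per_day"),
        ],
    )
    def test_invalid_config_names_field(self, kw, field):
        with pytest.raises(CohortValidationError, match=field):
            _cfg(**kw)

    def test_invalid_error_model_rejected(self):
        with pytest.raises(CohortValidationError, match="noise_sd"):
            c.ErrorModelSpec(noise_sd=-1.0)
        with pytest.raises(CohortValidationError, match="per_cluster_bias"):
            c.ErrorModelSpec(per_cluster_bias=(1.0, 2.0))


class TestPairAndMerge:
    @staticmethod
    def _tables():
        ts = lambda s: pd.Timestamp(f"2023-01-01 {s}")
        cgm = pd.DataFrame(
            {
                "patient_id": ["p1"] * 4,
                "timestamp": [ts("10:00"), ts("10:05"), ts("10:20"), ts("11:00")],
                "g_m": [110.0, 112.0, 118.0, 130.0],
            }
        )
        refs = pd.DataFrame(
            {
                "patient_id": ["p1"] * 3,
                "timestamp": [ts("10:02"), ts("10:30"), ts("11:01")],
                "g_r": [100.0, 105.0, 125.0],
            }
        )
        cov = pd.DataFrame(
            {
                "patient_id": ["p1"] * 3,
                "timestamp": [ts("10:00"), ts("10:30"), ts("11:00")],
                **{k: [1.0 + i, 2.0 + i, 3.0 + i] for i, k in enumerate(COVARIATES)},
            }
        )
        cov[["x5", "x6"]] = cov[["x5", "x6"]].abs() + 10.0
        return cgm, refs, cov

    def test_reference_matches_nearest_cgm_within_tolerance(self):
        cgm, refs, cov = self._tables()
        result = c.pair_and_merge(cgm, refs, cov, tolerance=5)
        # 10:02 -> 10:00 reading (nearest), 10:30 dropped (nearest CGM 10:20 is
        # 10 min away), 11:01 -> 11:00
        assert result.n_dropped == 1
        assert list(result.readings["g_m"]) == [110.0, 130.0]
        assert list(result.readings["g_r"]) == [100.0, 125.0]

    def test_all_within_tolerance_pairs_everything(self):
        cgm, refs, cov = self._tables()
        result = c.pair_and_merge(cgm, refs, cov, tolerance=30)
        assert result.n_dropped == 0
        assert len(result.readings) == 3

    def test_missing_columns_reported(self):
        cgm, refs, cov = self._tables()
        with pytest.raises(CohortSchemaError, match="g_r"):
            c.pair_and_merge(cgm, refs.drop(columns="g_r"), cov)

    def test_row_order_invariance(self):
        cgm, refs, cov = self._tables()
        base = c.pair_and_merge(cgm, refs, cov, tolerance=5)
        rng = np.random.default_rng(0)
        shuffled = c.pair_and_merge(
            cgm.sample(frac=1, random_state=1),
            refs.sample(frac=1, random_state=2),
            cov.sample(frac=1, random_state=3),
            tolerance=5,
        )
        pd.testing.assert_frame_equal(base.readings, shuffled.readings)
        assert base.n_dropped == shuffled.n_dropped

    def test_negative_tolerance_rejected(self):
        cgm, refs, cov = self._tables()
        with pytest.raises(CohortValidationError, match="tolerance"):
            c.pair_and_merge(cgm, refs, cov, tolerance=-1)


class TestCohortIO:
    def test_round_trip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        ten = small_cohort.readings.head(10)
        c.write_cohort(ten, path)
        back = c.read_cohort(path)
        pd.testing.assert_frame_equal(back, ten.reset_index(drop=True))

    def test_non_numeric_value_cites_line(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        c.write_cohort(small_cohort.readings.head(5), path)
        lines = path.read_text().splitlines()
        parts = lines[3].split(",")
        parts[2] = "oops"  # g_m on data line 3 => file line 4
        lines[3] = ",".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(CohortParseError, match="line 4") as excinfo:
            c.read_cohort(path)
        assert excinfo.value.line == 4

    def test_header_only_file_is_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(COHORT_COLUMNS) + "\n")
        df = c.read_cohort(path)
        assert len(df) == 0
        assert list(df.columns) == COHORT_COLUMNS

    def test_missing_column_is_schema_error(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        small_cohort.readings.head(3).drop(columns="x5").to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="x5"):
            c.read_cohort(path)

    def test_invalid_values_rejected_on_write(self, small_cohort, tmp_path):
        bad = small_cohort.readings.head(3).copy()
        bad.loc[bad.index[0], "g_r"] = -1.0
        with pytest.raises(CohortValidationError, match="g_r"):
            c.write_cohort(bad, tmp_path / "bad.csv")

    def test_optional_food_quality_column_round_trips(self, small_cohort, tmp_path):
        path = tmp_path / "fq.csv"
        df = small_cohort.readings.head(4).copy()
        df["food_quality"] = [0, 1, 2, 1]
        df2 = df.copy()
        df2["timestamp"] = df2["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df2.to_csv(path, index=False)
        back = c.read_cohort(path)
        assert list(back["food_quality"]) == [0, 1, 2, 1]


def test_summary_csv_reader_maps_wearable_channels(tmp_path):
    path = tmp_path / "Summary.csv"
    pd.DataFrame(
        {
            "Time": ["2023-01-01 10:00:00", "2023-01-01 10:01:00"],
            "HeartRate": [72, 75],
            "BreathingRate": [14, 15],
            "Temp": [33.5, 33.6],
            "Posture": [10, -20],
            "Activity": [0.1, 0.4],
            "PeakAccel": [0.5, 1.2],
            "BatteryVolts": [3.9, 3.9],
        }
    ).to_csv(path, index=False)
    out = read_summary_csv(path)
    assert list(out["x5"]) == [72, 75]
    assert list(out["x6"]) == [14, 15]
    assert list(out["x7"]) == [33.5, 33.6]
    assert list(out["x4"]) == [10, -20]
    assert list(out["x2"]) == [0.1, 0.4]
    assert list(out["x3"]) == [0.5, 1.2]
    assert "timestamp" in out.columns
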