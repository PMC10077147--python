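import math

import numpy as np
import pandas as pd
import pytest

from shockpred import cleaning
from shockpred.cleaning import (
    CohortSpec,
    VariableCluster,
    aggregate_first_recorded,
    clean_matrix,
    convert_unit,
    default_cohort_spec,
    expand_icd9_range,
    missingness_profile,
    normalize_icd9,
    repair_or_drop,
    select_cohort,
)
from shockpred.errors import ConfigError, ParseError
from shockpred.matrix import FeatureMatrix, VariableMeta
from shockpred.synthetic import (
    DEFAULT_CODE_MAP,
    apply_mcar,
    default_missing_rates,
    generate_event_table,
    generate_feature_matrix,
)

from conftest import small_gen_config


def _dx(pairs):
    return pd.DataFrame(
        [(s, c, "diagnosis") for s, c in pairs],
        columns=["subject_id", "icd9_code", "type"],
    )


def _proc(pairs):
    return pd.DataFrame(
        [(s, c, "procedure") for s, c in pairs],
        columns=["subject_id", "icd9_code", "type"],
    )


class TestCohortSelection:
    def test_icd9_range_expansion(self):
        codes = expand_icd9_range("41000", "41092")
        assert len(codes) == 93
        assert codes[0] == "41000" and codes[-1] == "41092"
        assert all(len(c) == 5 for c in codes)

    def test_normalize_rejects_non_numeric(self):
        with pytest.raises(ParseError, match="E119"):
            normalize_icd9("E119")

    def test_shock_plus_procedure_is_patient(self):
        spec = default_cohort_spec("strict")
        groups = select_cohort(_dx([(1, "78551"), (1, "41001")]),
                               _proc([(1, "0066")]), spec)
        assert groups[1] == "patient"

    def test_angina_plus_cath_is_control(self):
        spec = default_cohort_spec("strict")
        groups = select_cohort(_dx([(2, "4139")]), _proc([(2, "8855")]), spec)
        assert groups[2] == "control"

    def test_no_procedure_excluded_strict_included_relaxed(self):
        dx = _dx([(3, "4139")])
        proc = _proc([])
        assert select_cohort(dx, proc, default_cohort_spec("strict"))[3] == "excluded"
        assert select_cohort(dx, proc, default_cohort_spec("relaxed"))[3] == "control"

    def test_shock_code_without_procedure_excluded_strict(self):
        groups = select_cohort(_dx([(4, "78551")]), _proc([]),
                               default_cohort_spec("strict"))
        assert groups[4] == "excluded"

    def test_partition_property(self):
        cfg = small_gen_config(n_controls=50, n_patients=15, seed=1, n_relaxed_extra=5)
        ehr = generate_event_table(cfg)
        groups = select_cohort(ehr.diagnoses, ehr.procedures,
                               default_cohort_spec("strict"))
        # every subject gets exactly one label; groups partition the subjects
        assert groups.index.is_unique
        assert set(groups.unique()) <= {"patient", "control", "excluded"}
        assert len(groups) == len(set(ehr.diagnoses["subject_id"]))

    def test_spec_invariants(self):
        with pytest.raises(ConfigError):
            CohortSpec(patient_only_dx=frozenset({"78551"}),
                       shared_dx=frozenset({"78551"}),
                       required_procedures=frozenset({"0066"}))
        with pytest.raises(ConfigError):
            CohortSpec(patient_only_dx=frozenset({"78551"}),
                       shared_dx=frozenset({"4139"}),
                       required_procedures=frozenset(), mode="strict")


class TestUnitConversion:
    def test_fahrenheit_to_celsius(self):
        assert convert_unit(98.6, "degF", "degC") == pytest.approx(37.0)
        assert convert_unit(32.0, "F", "C") == pytest.approx(0.0)

    def test_identity(self):
        assert convert_unit(5.5, "mmHg", "mmHg") == 5.5

    def test_unregistered_pair_lists_known(self):
        with pytest.raises(ConfigError, match="known:"):
            convert_unit(1.0, "furlong", "m")


class TestRepairOrDrop:
    temp_cluster = VariableCluster(
        target="temperature", codes=("TEMP_C",), unit="degC",
        plausible_range=(30, 43), hard_range=(25, 45),
    )

    def test_decimal_shift_repair(self):
        value, action = repair_or_drop(375.0, self.temp_cluster)
        assert value == pytest.approx(37.5)
        assert action == "repaired"

    def test_implausible_deleted(self):
        value, action = repair_or_drop(5.0, self.temp_cluster)
        assert math.isnan(value)
        assert action == "deleted"

    def test_in_range_unchanged(self):
        assert repair_or_drop(37.0, self.temp_cluster) == (37.0, "kept")

    def test_no_hard_range_total_identity(self):
        cl = VariableCluster(target="x", codes=("X",))
        assert repair_or_drop(1e9, cl) == (1e9, "kept")


class TestAggregateFirstRecorded:
    def _events(self, rows):
        return pd.DataFrame(
            rows, columns=["subject_id", "stay_id", "item_code", "charttime",
                           "value", "unit"],
        )

    sys_cluster = VariableCluster(
        target="systolic_bp", codes=("codeA", "codeB"), unit="mmHg",
    )

    def test_earliest_event_wins(self):
        events = self._events([
            (1, 1, "codeA", "2130-01-01T01:00:00", 120.0, "mmHg"),
            (1, 1, "codeB", "2130-01-01T02:00:00", 118.0, "mmHg"),
        ])
        out = aggregate_first_recorded(events, [self.sys_cluster])
        assert out.df.loc[1, "systolic_bp"] == 120.0

    def test_single_event_identity(self):
        events = self._events([(1, 1, "codeA", "2130-01-01T01:00:00", 99.0, "mmHg")])
        out = aggregate_first_recorded(events, [self.sys_cluster])
        assert out.df.loc[1, "systolic_bp"] == 99.0

    def test_timestamp_tie_breaks_lexicographically(self):
        events = self._events([
            (1, 1, "codeB", "2130-01-01T01:00:00", 111.0, "mmHg"),
            (1, 1, "codeA", "2130-01-01T01:00:00", 222.0, "mmHg"),
        ])
        out = aggregate_first_recorded(events, [self.sys_cluster])
        assert out.df.loc[1, "systolic_bp"] == 222.0  # codeA < codeB

    def test_unit_conversion_applied(self):
        cl = VariableCluster(target="temperature", codes=("TEMP_F",), unit="degC",
                             code_units={"TEMP_F": "degF"})
        events = self._events([(1, 1, "TEMP_F", "2130-01-01T01:00:00", 98.6, "degF")])
        out = aggregate_first_recorded(events, [cl])
        assert out.df.loc[1, "temperature"] == pytest.approx(37.0)

    def test_no_event_means_missing(self):
        events = self._events([(1, 1, "codeA", "2130-01-01T01:00:00", 99.0, "mmHg")])
        out = aggregate_first_recorded(events, [self.sys_cluster], subjects=[1, 2])
        assert np.isnan(float(out.df.loc[2, "systolic_bp"]))

    def test_code_in_two_clusters_rejected(self):
        other = VariableCluster(target="other", codes=("codeA",))
        with pytest.raises(ConfigError, match="codeA"):
            aggregate_first_recorded(self._events([]), [self.sys_cluster, other])

    def test_permutation_invariance(self):
        rows = [
            (1, 1, "codeA", "2130-01-01T03:00:00", 1.0, "mmHg"),
            (1, 1, "codeB", "2130-01-01T01:00:00", 2.0, "mmHg"),
            (2, 2, "codeA", "2130-01-01T02:00:00", 3.0, "mmHg"),
        ]
        a = aggregate_first_recorded(self._events(rows), [self.sys_cluster])
        b = aggregate_first_recorded(self._events(rows[::-1]), [self.sys_cluster])
        pd.testing.assert_frame_equal(a.df, b.df)


class TestRoundTrip:
    def test_clean_of_events_reconstructs_matrix(self):
        # clean(generate_event_table(cfg)) == generate_feature_matrix(cfg)
        cfg = small_gen_config(n_controls=60, n_patients=20, seed=17)
        matrix, labels, _ = generate_feature_matrix(cfg)
        masked = apply_mcar(matrix, default_missing_rates(cfg), seed=cfg.seed)
        ehr = generate_event_table(cfg, matrix=masked, labels=labels)
        code_map = {v.name: DEFAULT_CODE_MAP[v.name] for v in cfg.variables}
        clusters = [
            VariableCluster(target=v.name, codes=tuple(code_map[v.name]),
                            vtype=v.vtype, unit=v.unit, levels=v.levels, role=v.role)
            for v in cfg.variables
        ]
        rebuilt = aggregate_first_recorded(ehr.events, clusters,
                                           subjects=masked.df.index)
        for name in masked.variables:
            a, b = masked.df[name], rebuilt.df[name]
            both_missing = a.isna() & b.isna()
            if masked.meta_for(name).vtype == "continuous":
                equal = np.isclose(a.astype(float), b.astype(float))
            else:
                equal = (a == b)
            assert (both_missing | equal).all(), name


class TestCleanMatrix:
    def _matrix(self, values):
        df = pd.DataFrame({"temperature": values},
                          index=pd.Index(range(len(values)), name="subject_id"))
        return FeatureMatrix(df, [VariableMeta("temperature", "continuous",
                                               unit="degC")])

    clusters = [VariableCluster(target="temperature", codes=("T",), unit="degC",
                                plausible_range=(30, 43), hard_range=(25, 45))]

    def test_repairs_and_deletions_logged(self):
        out, log = clean_matrix(self._matrix([375.0, 5.0, 37.0]), self.clusters)
        assert out.df["temperature"].tolist()[0] == pytest.approx(37.5)
        assert np.isnan(out.df["temperature"].iloc[1])
        assert out.df["temperature"].iloc[2] == 37.0
        assert len(log) == 2
        assert any("repaired" in line for line in log)
        assert any("deleted" in line for line in log)

    def test_idempotent(self):
        once, _ = clean_matrix(self._matrix([375.0, 5.0, 37.0, 44.9]), self.clusters)
        twice, log2 = clean_matrix(once, self.clusters)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert log2 == []


class TestMissingnessProfile:
    def test_simple_count(self):
        df = pd.DataFrame({"a": [1.0] * 9 + [np.nan]},
                          index=pd.Index(range(10), name="subject_id"))
        m = FeatureMatrix(df, [VariableMeta("a", "continuous")])
        per_var, overall = missingness_profile(m)
        assert per_var["a"] == pytest.approx(0.1)
        assert overall == pytest.approx(0.1)

    def test_fully_observed(self, small_cohort):
        _, matrix, _, _ = small_cohort
        per_var, overall = missingness_profile(matrix)
        assert (per_var == 0).all() and overall == 0

    def test_hand_counted_fixture(self):
        # 3 variables x 4 rows, 5 missing -> overall 5/12
        df = pd.DataFrame({
            "a": [1.0, np.nan, 3.0, np.nan],
            "b": [np.nan, 2.0, 3.0, 4.0],
            "c": [1.0, 2.0, np.nan, np.nan],
        }, index=pd.Index(range(4), name="subject_id"))
        m = FeatureMatrix(df, [VariableMeta(c, "continuous") for c in "abc"])
        _, overall = missingness_profile(m)
        assert overall == pytest.approx(5 / 12)

    def test_empty_matrix_rejected(self):
        df = pd.DataFrame({"a": []}, index=pd.Index([], name="subject_id"))
        m = FeatureMatrix(df, [VariableMeta("a", "continuous")])
        with pytest.raises(ConfigError):
            missingness_profile(m)
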