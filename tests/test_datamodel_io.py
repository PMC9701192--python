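"""Domain types, validation, table/report I/O, and experiment assembly."""

import json

import numpy as np
import pytest

from massresponse import (
    Call,
    ConditionSample,
    InferenceConfig,
    MassRecord,
    ParticleClass,
    Role,
    StructureError,
    TestResult,
    ValidationError,
    build_experiment,
    load_config,
    load_measurements,
    read_report,
    save_config,
    save_measurements,
    write_report,
)
from massresponse.io import SchemaError

from conftest import make_experiment_records


class TestMassRecord:
    def test_valid_record(self):
        r = MassRecord(42.5, ParticleClass.INTACT, "c1", Role.TEST, 10.0)
        assert r.mass == 42.5

    @pytest.mark.parametrize("bad_mass", [np.nan, np.inf, -np.inf])
    def test_nonfinite_mass_rejected(self, bad_mass):
        with pytest.raises(ValidationError):
            MassRecord(bad_mass, ParticleClass.DEBRIS, "c", Role.TEST)

    @pytest.mark.parametrize(
        "cls", [ParticleClass.INTACT, ParticleClass.PERMEABLE, ParticleClass.AGGREGATE]
    )
    def test_cell_classes_need_positive_mass(self, cls):
        with pytest.raises(ValidationError):
            MassRecord(-1.0, cls, "c", Role.TEST)

    def test_debris_mass_may_be_nonpositive(self):
        # near-neutral buoyancy debris can read ~0 after noise
        assert MassRecord(-0.2, ParticleClass.DEBRIS, "c", Role.TEST).mass == -0.2

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            MassRecord(5.0, ParticleClass.INTACT, "c", Role.TEST, t_meas=-1.0)


class TestConditionSample:
    def test_masses_canonicalized_sorted(self):
        s = ConditionSample("c", Role.TEST, np.array([3.0, 1.0, 2.0]))
        assert list(s.masses) == [1.0, 2.0, 3.0]
        assert s.n == 3

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValidationError):
            ConditionSample("c", Role.TEST, np.array([1.0, 0.0]))

    def test_subsample_is_sorted_and_seeded(self, rng):
        s = ConditionSample("c", Role.TEST, rng.lognormal(4, 0.3, 100))
        sub = s.subsample(40, np.random.default_rng(3))
        assert sub.n == 40 and np.all(np.diff(sub.masses) >= 0)


class TestBuildExperiment:
    def test_groups_conditions(self, experiment_records):
        exp = build_experiment(experiment_records)
        assert exp.condition_ids == ["DRUG_0", "DRUG_1"]
        assert exp.reference.n == exp.control.n == 50

    def test_missing_control_is_structure_error(self, experiment_records):
        no_ctrl = [r for r in experiment_records if r.role is not Role.CONTROL]
        with pytest.raises(StructureError, match="control"):
            build_experiment(no_ctrl)

    def test_duplicate_reference_is_structure_error(self, experiment_records):
        extra = [MassRecord(30.0, ParticleClass.INTACT, "REF2", Role.REFERENCE)]
        with pytest.raises(StructureError, match="reference"):
            build_experiment(experiment_records + extra)

    def test_permutation_invariance(self, experiment_records, rng):
        a = build_experiment(experiment_records)
        shuffled = list(experiment_records)
        rng.shuffle(shuffled)
        b = build_experiment(shuffled)
        assert np.array_equal(a.reference.masses, b.reference.masses)
        for ta, tb in zip(a.tests, b.tests):
            assert ta.condition_id == tb.condition_id
            assert np.array_equal(ta.masses, tb.masses)

    def test_masses_sorted_ascending(self, experiment_records):
        exp = build_experiment(experiment_records)
        for s in [exp.reference, exp.control, *exp.tests]:
            assert np.all(np.diff(s.masses) >= 0)

    def test_out_of_order_session_warns(self, experiment_records):
        flipped = [
            MassRecord(r.mass, r.particle_class, r.condition_id, r.role,
                       t_meas=(0.0 if r.role is Role.CONTROL else 5000.0))
            for r in experiment_records
        ]
        with pytest.warns(UserWarning, match="sandwich"):
            build_experiment(flipped)


class TestMeasurementTableIO:
    def test_well_formed_table(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "mass_pg,particle_class,condition_id,role\n"
            "10.5,intact,c1,test\n11.5,permeable,c1,test\n9.0,debris,c1,test\n"
        )
        recs = load_measurements(p)
        assert len(recs) == 3
        assert recs[1].particle_class is ParticleClass.PERMEABLE

    def test_invalid_mass_row_rejected_not_fatal(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "mass_pg,particle_class,condition_id,role\n"
            "10.5,intact,c1,test\n-1.0,intact,c1,test\n11.0,intact,c1,test\n"
        )
        assert len(load_measurements(p)) == 2

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("mass_pg,condition_id,role\n10.5,c1,test\n")
        with pytest.raises(SchemaError, match="particle_class"):
            load_measurements(p)

    def test_unknown_class_maps_to_unclassified(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("mass_pg,particle_class,condition_id,role\n10.5,blob,c1,test\n")
        with pytest.warns(UserWarning, match="unclassified"):
            recs = load_measurements(p)
        assert recs[0].particle_class is ParticleClass.UNCLASSIFIED

    def test_missing_role_defaults_to_test(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("mass_pg,particle_class,condition_id,role\n10.5,intact,c1,\n")
        with pytest.warns(UserWarning, match="role"):
            recs = load_measurements(p)
        assert recs[0].role is Role.TEST

    def test_schema_mapping_override(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("m\tk\tcond\twho\n10.5\tintact\tc1\ttest\n")
        recs = load_measurements(
            p, schema={"mass": "m", "particle_class": "k",
                       "condition_id": "cond", "role": "who"})
        assert recs[0].mass == 10.5

    def test_round_trip_preserves_values_exactly(self, tmp_path, rng):
        records = make_experiment_records(n_per=20, seed=3)
        path = save_measurements(records, tmp_path / "rt.csv")
        back = load_measurements(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.mass == b.mass  # full repr precision
            assert a.particle_class is b.particle_class
            assert a.condition_id == b.condition_id and a.role is b.role


class TestConfig:
    def test_defaults_match_protocol(self):
        cfg = InferenceConfig()
        assert (cfg.theta0, cfg.N, cfg.R_test, cfg.r_inner) == (0.03, 2500, 999, 19)
        assert (cfg.R_ci, cfg.ci_level, cfg.drift_limit) == (5000, 0.90, 0.10)

    @pytest.mark.parametrize(
        "kw", [{"theta0": 0.0}, {"theta0": 1.5}, {"alpha": 0.0},
               {"r_inner": 1}, {"ci_level": 1.0}]
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValidationError):
            InferenceConfig(**kw)

    def test_json_round_trip(self, tmp_path):
        cfg = InferenceConfig(theta0=0.05, ci_level=0.95, seed=42)
        path = save_config(cfg, tmp_path / "cfg.json")
        assert load_config(path) == cfg

    def test_unknown_field_rejected(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text(json.dumps({"theta0": 0.03, "bogus": 1}))
        with pytest.raises(ValidationError, match="bogus"):
            load_config(p)


class TestReport:
    @staticmethod
    def _result(cid="DRUG", call=Call.RESPONSE, p=0.001):
        return TestResult(
            condition_id=cid, test_signal=0.12, ctrl_signal=0.02,
            theta_hat=0.10, se_hat=0.005, t_obs=14.0, p_value=p, call=call,
            n_used={"test": 2500, "control": 2500, "reference": 2500},
            seed=7, test_ci=(0.11, 0.13), ctrl_ci=(0.01, 0.03), ci_level=0.9,
        )

    def test_round_trip_equals_in_memory(self, tmp_path):
        results = [self._result("A"), self._result("B", Call.NO_RESPONSE, 0.4)]
        json_path, csv_path = write_report(results, tmp_path,
                                           config=InferenceConfig())
        back, payload = read_report(json_path)
        assert back == results
        assert payload["config"]["R_test"] == 999
        assert csv_path.exists()

    def test_inconclusive_serialized(self, tmp_path):
        json_path, _ = write_report([self._result(call=Call.INCONCLUSIVE)], tmp_path)
        assert json.loads(json_path.read_text())["results"][0]["call"] == "inconclusive"

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_report([], tmp_path)
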