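"""Linear/angular parameter computation and the measurement table."""

import math

import numpy as np
import pandas as pd
import pytest

import cephgrowth as cg
from cephgrowth.cephalometrics import angular_parameter, linear_parameter
from cephgrowth.errors import DataError, DegenerateGeometryError
from cephgrowth.geometry import SubjectSeries
from cephgrowth.landmarks import ANGULAR_NAMES, LANDMARKS, LINEAR_NAMES


class TestLinearParameter:
    def test_three_four_five_triangle(self):
        assert linear_parameter({"nasion": (0, 0), "sella": (3, 4)}, "N-S") == pytest.approx(5.0)

    def test_identical_points_zero(self):
        assert linear_parameter({"nasion": (2, -7), "sella": (2, -7)}, "N-S") == 0.0

    def test_mandibular_length_hand_value(self):
        lm = {"gnathion": (-8.2, -95.1), "condylion": (-60.0, -10.3)}
        expected = math.sqrt(51.8**2 + 84.8**2)  # = 99.36941...
        assert linear_parameter(lm, "Gn-Cd") == pytest.approx(expected, abs=1e-12)
        assert linear_parameter(lm, "Gn-Cd") == pytest.approx(99.369412, abs=1e-6)

    def test_unknown_name_and_missing_landmark(self):
        with pytest.raises(DataError, match="unknown linear parameter"):
            linear_parameter({}, "Q-Z")
        with pytest.raises(DataError, match="missing"):
            linear_parameter({"nasion": (0, 0)}, "N-S")


class TestAngularParameter:
    def test_perpendicular_segments(self):
        lm = {
            "sella": (0.0, 0.0), "nasion": (1.0, 0.0),
            "A_point": (1.0, 1.0),  # N->A = (0, 1), perpendicular to S->N
        }
        assert angular_parameter(lm, "SNA") == pytest.approx(90.0, abs=1e-12)

    def test_parallel_segments_zero(self):
        lm = {"sella": (0, 0), "nasion": (2, 0), "A_point": (5, 0)}
        assert angular_parameter(lm, "SNA") == pytest.approx(0.0, abs=1e-7)

    def test_sna_hand_value(self):
        lm = {"sella": (0.0, 0.0), "nasion": (10.0, 0.0), "A_point": (9.0, -6.0)}
        expected = math.degrees(math.acos(-10.0 / (10.0 * math.sqrt(37.0))))  # 99.4623...
        assert angular_parameter(lm, "SNA") == pytest.approx(expected, abs=1e-12)
        assert angular_parameter(lm, "SNA") == pytest.approx(99.462322, abs=1e-6)

    def test_degenerate_pair_rejected(self):
        lm = {"sella": (1, 1), "nasion": (1, 1), "A_point": (0, 0)}
        with pytest.raises(DegenerateGeometryError, match="zero-length"):
            angular_parameter(lm, "SNA")

    def test_clinical_convexity_is_complement(self):
        rng = np.random.default_rng(0)
        lm = {n: rng.uniform(-50, 50, 2) for n in ("nasion", "A_point", "pogonion")}
        raw = angular_parameter(lm, "Convexity")
        clinical = angular_parameter(lm, "Convexity", clinical_convexity=True)
        assert clinical == pytest.approx(180.0 - raw, abs=1e-12)


def normalized_subject(seed=11, n=4):
    config = cg.SyntheticConfig(n_subjects=n, seed=seed, missing_rate=0.0)
    return [
        cg.normalize_coordinates(s, px_per_mm=config.acquisition.px_per_mm)
        for s in cg.generate_population(config)
    ]


class TestMeasurementTable:
    def test_matches_independent_recomputation_from_truth(self):
        config = cg.SyntheticConfig(
            n_subjects=1, noise_sd=0.0, subject_sd=0.0, missing_rate=0.0,
            acquisition=cg.AcquisitionConfig(rotation_deg=0.0, translation_px=0.0, px_per_mm=1.0),
            seed=0,
        )
        series = cg.generate_population(config)[0]
        normed = cg.normalize_coordinates(series, px_per_mm=1.0)
        table = cg.compute_measurement_table(normed)
        # independent recomputation from raw template arithmetic
        from cephgrowth.synthetic import GROWTH_VECTORS, LANDMARK_TEMPLATE

        for age in (6, 10, 13):
            pts = {
                n: np.array(LANDMARK_TEMPLATE[n]) + age * np.array(GROWTH_VECTORS[n])
                for n in LANDMARKS
            }
            # re-align by hand: sella at origin, nasion on +x
            s, nvec = pts["sella"], pts["nasion"]
            ref = {}
            for name, p in pts.items():
                v = p - s
                w = nvec - s
                th = math.atan2(w[1], w[0])
                rot = np.array([[math.cos(-th), -math.sin(-th)], [math.sin(-th), math.cos(-th)]])
                ref[name] = rot @ v
            got = table[(table.age == age)]
            d_gncd = math.hypot(*(ref["gnathion"] - ref["condylion"]))
            assert got[(got.measurement == "Gn-Cd")]["value"].iloc[0] == pytest.approx(d_gncd, abs=1e-9)
            u = ref["nasion"] - ref["sella"]
            v = ref["A_point"] - ref["nasion"]
            sna = math.degrees(math.acos(u @ v / np.linalg.norm(u) / np.linalg.norm(v)))
            assert got[(got.measurement == "SNA") & (got.kind == "angular")]["value"].iloc[0] == pytest.approx(sna, abs=1e-9)

    def test_shape_and_value_invariants(self):
        table = cg.compute_measurement_table(normalized_subject())
        per_age = table.groupby(["subject_id", "age"]).size().unique()
        assert list(per_age) == [26 * 2 + 13 + 17]
        lin = table[table.kind == "linear"]["value"]
        ang = table[table.kind == "angular"]["value"]
        assert (lin >= 0).all()
        assert ang.between(0, 180).all()
        # N-S equals the x-coordinate of the nasion in the normalized frame
        ns = table[(table.kind == "linear") & (table.measurement == "N-S")]
        nx = table[(table.kind == "coord_x") & (table.measurement == "nasion")]
        merged = ns.merge(nx, on=["subject_id", "age"], suffixes=("_ns", "_nx"))
        np.testing.assert_allclose(merged["value_ns"], merged["value_nx"], atol=1e-9)

    def test_rigid_motion_of_raw_input_leaves_table_unchanged(self):
        config = cg.SyntheticConfig(n_subjects=2, seed=5, missing_rate=0.0)
        population = cg.generate_population(config)
        ppm = config.acquisition.px_per_mm
        base = cg.compute_measurement_table(
            [cg.normalize_coordinates(s, ppm) for s in population]
        )
        th = math.radians(33.0)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        moved = [
            SubjectSeries(
                subject_id=s.subject_id,
                observations={a: v @ rot.T + [77.0, -31.0] for a, v in s.observations.items()},
                frame=s.frame, missing_ages=s.missing_ages,
            )
            for s in population
        ]
        table = cg.compute_measurement_table([cg.normalize_coordinates(s, ppm) for s in moved])
        np.testing.assert_allclose(table["value"], base["value"], atol=1e-9)

    def test_consistent_scale_change_leaves_table_unchanged(self):
        config = cg.SyntheticConfig(n_subjects=2, seed=6, missing_rate=0.0)
        population = cg.generate_population(config)
        ppm = config.acquisition.px_per_mm
        base = cg.compute_measurement_table([cg.normalize_coordinates(s, ppm) for s in population])
        doubled = [
            SubjectSeries(
                subject_id=s.subject_id,
                observations={a: 2.0 * v for a, v in s.observations.items()},
                frame=s.frame, missing_ages=s.missing_ages,
            )
            for s in population
        ]
        table = cg.compute_measurement_table(
            [cg.normalize_coordinates(s, 2.0 * ppm) for s in doubled]
        )
        np.testing.assert_allclose(table["value"], base["value"], atol=1e-9)

    def test_triangle_inequality_on_mandible(self):
        table = cg.compute_measurement_table(normalized_subject(seed=8, n=6))
        wide = table[table.kind == "linear"].pivot_table(
            index=["subject_id", "age"], columns="measurement", values="value"
        )
        assert (wide["Ar-Me"] <= wide["Ar-Go"] + wide["Go-Me"] + 1e-9).all()

    def test_rejects_raw_or_gappy_series(self):
        config = cg.SyntheticConfig(n_subjects=1, seed=2, missing_rate=0.0)
        raw = cg.generate_population(config)[0]
        with pytest.raises(DataError, match="norm_mm"):
            cg.compute_measurement_table(raw)
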