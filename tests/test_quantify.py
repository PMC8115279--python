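import numpy as np
import pandas as pd
import pytest

from mitoqc import quantify as Q
from mitoqc import synthetic
from mitoqc.classifier import MORPHOLOGY_CLASSES
from mitoqc.pixel_seg import BinaryMask


class TestPunctaPerCell:
    def test_empty_mask(self):
        res = Q.count_puncta_per_cell(BinaryMask(np.zeros((32, 32), bool)), 9.7, 5)
        assert res.puncta_count == 0 and res.puncta_per_cell == 0.0

    def test_seven_puncta_two_cells(self):
        m = np.zeros((40, 40), bool)
        for k in range(7):
            y, x = 4 + 10 * (k // 4), 4 + 9 * (k % 4)
            m[y : y + 2, x : x + 2] = True
        res = Q.count_puncta_per_cell(BinaryMask(m), 9.7, 2)
        assert res.puncta_count == 7
        assert res.puncta_per_cell == 3.5

    def test_no_size_filter_on_puncta(self):
        m = np.zeros((16, 16), bool)
        m[3, 3] = True  # single pixel still counts
        assert Q.count_puncta_per_cell(BinaryMask(m), 9.7, 1).puncta_count == 1

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            Q.count_puncta_per_cell(BinaryMask(np.zeros((8, 8), bool)), 9.7, 0)


class TestCountCells:
    def test_scene_nuclei_recovered(self, clean_scene):
        assert Q.count_cells(clean_scene.field) == clean_scene.cell_count

    def test_blank_dapi_gives_zero(self):
        from mitoqc.io_config import FieldImage

        f = FieldImage(channels={"dapi": np.zeros((64, 64))})
        assert Q.count_cells(f) == 0

    def test_explicit_override_wins(self, clean_scene):
        assert Q.count_cells(clean_scene.field, explicit_count=6) == 6

    def test_missing_dapi_without_override_rejected(self):
        from mitoqc.io_config import FieldImage

        f = FieldImage(channels={"gfp": np.zeros((8, 8))})
        with pytest.raises(ValueError, match="dapi"):
            Q.count_cells(f)


class TestPearson:
    def test_perfect_positive_linear(self, rng):
        a = rng.random((32, 32)) * 100
        assert Q.pearson_colocalization(a, 2 * a + 5) == pytest.approx(1.0)

    def test_perfect_negative_linear(self, rng):
        a = rng.random((32, 32)) * 100
        assert Q.pearson_colocalization(a, a.max() - a) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2024)
        a = rng.random((64, 64))
        b = rng.random((64, 64))
        assert abs(Q.pearson_colocalization(a, b)) < 0.05

    def test_zero_variance_signaled(self):
        with pytest.raises(Q.UndefinedStatisticError):
            Q.pearson_colocalization(np.full((8, 8), 3.0), np.random.default_rng(0).random((8, 8)))

    def test_roi_restricts_support(self, rng):
        a = rng.random((16, 16))
        b = a.copy()
        b[:8] = rng.random((8, 16))  # decorrelate outside the roi
        roi = np.zeros((16, 16), bool)
        roi[8:] = True
        assert Q.pearson_colocalization(a, b, roi) == pytest.approx(1.0)


class TestManders:
    def test_identical_channels_full_overlap(self):
        a = np.zeros((20, 20))
        a[5:15, 5:15] = 100.0
        m1, m2, *_ = Q.manders_coefficients(a, a.copy())
        assert m1 == pytest.approx(1.0) and m2 == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[2:8, 2:8] = 50.0
        b[12:18, 12:18] = 50.0
        m1, m2, *_ = Q.manders_coefficients(a, b)
        assert m1 == 0.0 and m2 == 0.0

    def test_half_overlap_gives_half(self):
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[4:12, 4:20] = 10.0  # uniform region
        b[4:12, 12:20] = 10.0  # exactly half of a's support
        m1, _, _, _ = Q.manders_coefficients(a, b, t1=1.0, t2=1.0)
        assert m1 == pytest.approx(0.5, abs=1e-9)

    def test_symmetry_under_channel_swap(self, rng):
        a = (rng.random((32, 32)) > 0.7) * rng.random((32, 32))
        b = (rng.random((32, 32)) > 0.7) * rng.random((32, 32))
        m1, m2, t1, t2 = Q.manders_coefficients(a, b, 0.1, 0.2)
        m2s, m1s, *_ = Q.manders_coefficients(b, a, 0.2, 0.1)
        assert m1 == pytest.approx(m1s) and m2 == pytest.approx(m2s)

    def test_no_signal_signaled(self):
        with pytest.raises(Q.UndefinedStatisticError):
            Q.manders_coefficients(np.zeros((8, 8)), np.ones((8, 8)), t1=1.0, t2=0.5)


class TestSummaries:
    def test_object_fractions(self):
        records = pd.DataFrame(
            {
                "class": ["punctate"] * 4 + ["swollen"] * 6,
                "area": [0.5] * 4 + [2.0] * 6,
            }
        )
        s = Q.summarize_morphology(records)
        assert s.object_fractions["punctate"] == pytest.approx(0.40)
        assert sum(s.object_fractions.values()) == pytest.approx(1.0)
        assert sum(s.area_fractions.values()) == pytest.approx(1.0)

    def test_area_fractions(self):
        records = pd.DataFrame(
            {"class": ["network", "swollen"], "area": [3.0, 1.0]}
        )
        s = Q.summarize_morphology(records)
        assert s.area_fractions["network"] == pytest.approx(0.75)
        assert s.area_fractions["swollen"] == pytest.approx(0.25)

    def test_empty_table_reports_zeros(self):
        s = Q.summarize_morphology(pd.DataFrame(columns=["class", "area"]))
        assert s.total_objects == 0
        assert all(v == 0.0 for v in s.object_fractions.values())


class TestMitophagyFraction:
    def test_half(self):
        out = Q.mitophagy_fraction_by_class({"punctate": 50}, {"punctate": 100})
        assert out["punctate"] == pytest.approx(0.50)

    def test_zero_total_is_undefined_not_zero(self):
        out = Q.mitophagy_fraction_by_class({"network": 0}, {"network": 0})
        assert out["network"] is None

    def test_red_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            Q.mitophagy_fraction_by_class({"swollen": 3}, {"swollen": 2})


class TestPipeline:
    def test_noise_free_scene_recovers_exact_puncta_count(
        self, clean_scene, all_models, default_cfg
    ):
        rec, _ = Q.run_field_pipeline(
            clean_scene.field, all_models, default_cfg, cell_count=clean_scene.cell_count
        )
        assert rec["puncta_count"] == int(clean_scene.table["mitophagy"].sum())
        assert rec["puncta_per_cell"] == rec["puncta_count"] / clean_scene.cell_count

    def test_red_only_objects_are_mostly_punctate(
        self, clean_scene, all_models, default_cfg
    ):
        # mitophagy is programmed to prefer the punctate class; the measured
        # modal class among red-only objects must reflect that
        rec, _ = Q.run_field_pipeline(
            clean_scene.field, all_models, default_cfg, cell_count=clean_scene.cell_count
        )
        fracs = {c: rec[f"red_frac_{c}"] for c in MORPHOLOGY_CLASSES}
        assert max(fracs, key=fracs.get) == "punctate"

    def test_no_mcherry_signal_gives_zero_puncta(self, all_models, default_cfg):
        cfg = synthetic.SceneConfig(
            size_px=384, n_cells=3, n_objects=12, seed=21,
            mitophagy_prob={c: 0.0 for c in MORPHOLOGY_CLASSES},
        ).noise_free()
        scene = synthetic.generate_scene(cfg)
        rec, _ = Q.run_field_pipeline(
            scene.field, all_models, default_cfg, cell_count=scene.cell_count
        )
        assert rec["puncta_count"] == 0
        assert rec["puncta_per_cell"] == 0.0

    def test_rerun_is_bit_identical(self, clean_scene, all_models, default_cfg):
        r1, t1 = Q.run_field_pipeline(
            clean_scene.field, all_models, default_cfg, cell_count=clean_scene.cell_count
        )
        r2, t2 = Q.run_field_pipeline(
            clean_scene.field, all_models, default_cfg, cell_count=clean_scene.cell_count
        )
        assert r1 == r2
        assert t1.equals(t2)

    def test_errors_name_the_stage(self, all_models, default_cfg):
        from mitoqc.io_config import FieldImage

        bad = FieldImage(channels={"gfp": np.zeros((64, 64))})  # no mcherry, no dapi
        with pytest.raises(Exception, match=r"\[stage:"):
            Q.run_field_pipeline(bad, all_models, default_cfg)
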