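"""Phantoms, lesions, temporal progression, notes, labels and manifests."""

import numpy as np
import pytest

from hemofuse.metrics import ssim
from hemofuse.synthetic_data import (
    NOTE_KINDS,
    TABLE2_COUNTS,
    CaseRecord,
    LesionSpec,
    PhantomSpec,
    ProgressionParams,
    assign_labels,
    build_manifest,
    generate_clinical_note,
    generate_phantom,
    lesion_mask,
    make_case,
    phantom_masks,
    progression_masks,
    render_lesion,
    select_model_by_mse,
    sequence_mse,
    simulate_progression,
)
from hemofuse.text_embed import DEFAULT_LEXICON

from conftest import brute_force_disc_area


class TestPhantom:
    def test_zero_noise_tissue_exact(self, quiet_phantom):
        img = generate_phantom(quiet_phantom)
        brain, vent = phantom_masks(quiet_phantom)
        assert np.all(img[brain & ~vent] == 120)
        assert np.all(img[vent] == 60)

    def test_deterministic_for_seed(self, noisy_phantom):
        assert np.array_equal(generate_phantom(noisy_phantom), generate_phantom(noisy_phantom))

    def test_skull_brighter_than_tissue(self, quiet_phantom):
        img = generate_phantom(quiet_phantom)
        assert img.max() == 230

    def test_ventricle_outside_brain_rejected(self):
        with pytest.raises(ValueError, match="ventricle"):
            PhantomSpec(ventricle_ellipses=((5.0, 5.0, 4.0, 4.0),))

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(image_height_px=0)


class TestLesions:
    def test_zero_offset_identity(self, quiet_phantom):
        base = generate_phantom(quiet_phantom)
        lesion = LesionSpec("ICH", (32, 32), 6.0, intensity_offset=0.0)
        assert np.array_equal(render_lesion(base, lesion, quiet_phantom), base)

    def test_ich_disc_area_matches_rasterizer(self, quiet_phantom):
        lesion = LesionSpec("ICH", (32.0, 32.0), 8.0)
        area = int(lesion_mask(lesion, quiet_phantom).sum())
        oracle = brute_force_disc_area((32.0, 32.0), 8.0, (64, 64))
        assert area == oracle
        assert np.pi * 49 <= area <= np.pi * 81

    def test_ivh_outside_ventricles_rejected(self, quiet_phantom):
        base = generate_phantom(quiet_phantom)
        lesion = LesionSpec("IVH", (10.0, 32.0), 3.0)
        with pytest.raises(ValueError, match="ventricle"):
            render_lesion(base, lesion, quiet_phantom)

    @pytest.mark.parametrize("subtype", ["ICH", "SDH", "EDH", "IVH", "SAH"])
    def test_lesion_inside_brain(self, quiet_phantom, subtype):
        center = {"ICH": (32, 32), "IVH": (30, 25)}.get(subtype, (32.0, 52.0))
        mask = lesion_mask(LesionSpec(subtype, center, 4.0), quiet_phantom)
        brain, _ = phantom_masks(quiet_phantom)
        assert mask.any()
        assert np.all(brain[mask])

    @pytest.mark.parametrize("subtype", ["SDH", "EDH"])
    def test_boundary_lesions_touch_inner_skull(self, quiet_phantom, subtype):
        mask = lesion_mask(LesionSpec(subtype, (32.0, 52.0), 4.0), quiet_phantom)
        cr, cc, ar, ac = quiet_phantom.brain_ellipse
        rr, cc_ = np.nonzero(mask)
        e = np.sqrt(((rr - cr) / ar) ** 2 + ((cc_ - cc) / ac) ** 2)
        assert e.max() > 1.0 - 2.0 / min(ar, ac)

    def test_ich_gets_edema_halo(self, quiet_phantom):
        base = generate_phantom(quiet_phantom)
        lesion = LesionSpec("ICH", (32, 32), 5.0, intensity_offset=60.0)
        out = render_lesion(base, lesion, quiet_phantom)
        mask = lesion_mask(lesion, quiet_phantom)
        changed = out != base
        assert changed.sum() > mask.sum()  # halo extends beyond the core


class TestProgression:
    def test_fixed_point_parameters(self, quiet_phantom):
        base = generate_phantom(quiet_phantom)
        lesion = LesionSpec("ICH", (32, 32), 6.0)
        params = ProgressionParams(growth_factor_per_frame=1.0,
                                   shrink_factor_per_frame=1.0,
                                   intensity_decay_per_frame=0.0)
        frames = simulate_progression(base, lesion, params, quiet_phantom)
        assert len(frames) == 5
        for f in frames[1:]:
            assert np.array_equal(f, frames[0])

    def test_area_unimodal_peak_at_frame_two(self, quiet_phantom):
        lesion = LesionSpec("ICH", (32, 32), 6.0)
        params = ProgressionParams(growth_factor_per_frame=1.3,
                                   shrink_factor_per_frame=0.7)
        areas = [int(m.sum()) for m in progression_masks(lesion, params, quiet_phantom)]
        assert areas[0] < areas[1] < areas[2]
        assert areas[2] > areas[3] > areas[4]

    def test_mse_to_frame0_grows_through_peak(self, quiet_phantom):
        base = generate_phantom(quiet_phantom)
        lesion = LesionSpec("ICH", (32, 32), 6.0)
        frames = simulate_progression(base, lesion, ProgressionParams(), quiet_phantom)
        mse = [float(np.mean((f.astype(float) - frames[0].astype(float)) ** 2)) for f in frames]
        assert mse[1] < mse[2]

    def test_ssim_to_final_nondecreasing_in_resorption(self, quiet_phantom):
        base = generate_phantom(quiet_phantom)
        lesion = LesionSpec("ICH", (32, 32), 6.0)
        frames = simulate_progression(base, lesion, ProgressionParams(), quiet_phantom)
        vals = [ssim(frames[t], frames[4]) for t in (2, 3, 4)]
        assert vals[0] <= vals[1] <= vals[2]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ProgressionParams(n_frames=1)
        with pytest.raises(ValueError):
            ProgressionParams(growth_factor_per_frame=0.8)
        with pytest.raises(ValueError):
            ProgressionParams(shrink_factor_per_frame=0.0)


class TestModelSelection:
    def test_sequence_mse_hand_toy(self):
        gen = [np.array([[1, 2], [3, 4]]), np.array([[1, 2], [3, 4]])]
        ref = [np.array([[1, 2], [3, 4]]), np.array([[2, 2], [3, 8]])]
        # frame 1 diffs: 1 and 16 -> total 17 over T*N = 8
        assert sequence_mse(gen, ref) == pytest.approx(17 / 8)

    def test_self_match_selected_with_zero_mse(self, quiet_phantom):
        base = generate_phantom(quiet_phantom)
        lesion = LesionSpec("ICH", (32, 32), 6.0)
        c_star = ProgressionParams(growth_factor_per_frame=1.2,
                                   shrink_factor_per_frame=0.8)
        other = ProgressionParams(growth_factor_per_frame=1.4,
                                  shrink_factor_per_frame=0.6)
        reference = simulate_progression(base, lesion, c_star, quiet_phantom)
        best, table = select_model_by_mse([other, c_star], reference, base, lesion, quiet_phantom)
        assert best is c_star
        assert table["mse"].min() == 0.0
        assert set(table.columns) == {"config", "mse", "ssim", "psnr_db"}

    def test_tie_returns_first_candidate(self, quiet_phantom):
        base = generate_phantom(quiet_phantom)
        lesion = LesionSpec("ICH", (32, 32), 6.0)
        params = ProgressionParams()
        twin = ProgressionParams()
        reference = simulate_progression(base, lesion, params, quiet_phantom)
        best, _ = select_model_by_mse([params, twin], reference, base, lesion, quiet_phantom)
        assert best is params

    def test_empty_candidates_rejected(self, quiet_phantom):
        base = generate_phantom(quiet_phantom)
        with pytest.raises(ValueError):
            select_model_by_mse([], [base], base, LesionSpec("ICH", (32, 32), 5.0), quiet_phantom)


class TestClinicalNotes:
    @pytest.fixture()
    def case(self) -> CaseRecord:
        return make_case("t-ICH-000", "ICH", "train", regime_idx=0, seed=5)

    def test_deterministic(self, case):
        a = generate_clinical_note(case, "consultation", seed=9)
        b = generate_clinical_note(case, "consultation", seed=9)
        assert a == b

    @pytest.mark.parametrize("kind", NOTE_KINDS)
    def test_token_count_in_range(self, case, kind):
        n = len(generate_clinical_note(case, kind, seed=3).split())
        assert 400 <= n <= 900

    def test_unknown_kind_lists_valid(self, case):
        with pytest.raises(ValueError, match="consultation"):
            generate_clinical_note(case, "discharge", seed=0)

    def test_positive_case_uses_positive_lexicon(self, case):
        assert case.prognosis_sentiment == "positive"
        note = case.notes["radiology"].lower()
        assert any(p in note for p in DEFAULT_LEXICON.positive)

    def test_negative_case_uses_negative_lexicon(self):
        case = make_case("t-ICH-001", "ICH", "train", regime_idx=1, seed=5)
        assert case.prognosis_sentiment == "negative"
        note = case.notes["radiology"].lower()
        assert any(p in note for p in DEFAULT_LEXICON.negative)

    def test_note_names_subtype(self, case):
        assert "intracerebral hemorrhage" in case.notes["consultation"].lower()


class TestLabels:
    @pytest.mark.parametrize(
        "subtype, risk",
        [("ICH", "High"), ("SDH", "Moderate"), ("EDH", "Low"),
         ("IVH", "Moderate to High"), ("SAH", "Moderate")],
    )
    def test_risk_map(self, quiet_phantom, subtype, risk):
        center = {"ICH": (32, 32), "IVH": (30, 25)}.get(subtype, (32.0, 52.0))
        lesion = LesionSpec(subtype, center, 4.0)
        _, _, level = assign_labels(lesion, ProgressionParams(), quiet_phantom)
        assert level == risk

    def test_resorbing_course_positive(self, quiet_phantom):
        lesion = LesionSpec("ICH", (32, 32), 6.0)
        params = ProgressionParams(growth_factor_per_frame=1.2,
                                   shrink_factor_per_frame=0.6)
        prognosis, therapeutic, _ = assign_labels(lesion, params, quiet_phantom)
        # final area < initial area under these factors (verified by masks)
        areas = [int(m.sum()) for m in progression_masks(lesion, params, quiet_phantom)]
        assert areas[-1] < areas[0]
        assert prognosis == "positive" and therapeutic == "positive"

    def test_indeterminate_course_uncertain(self, quiet_phantom):
        lesion = LesionSpec("ICH", (32, 32), 6.0)
        params = ProgressionParams(shrink_factor_per_frame=1.0,
                                   intensity_decay_per_frame=0.0)
        prognosis, therapeutic, _ = assign_labels(lesion, params, quiet_phantom)
        assert prognosis == "uncertain" and therapeutic == "uncertain"

    def test_pure_function(self, quiet_phantom):
        lesion = LesionSpec("SDH", (32.0, 52.0), 3.0)
        params = ProgressionParams()
        assert assign_labels(lesion, params, quiet_phantom) == assign_labels(
            lesion, params, quiet_phantom
        )


class TestManifest:
    def test_reference_counts_give_printed_totals(self):
        manifest = build_manifest(TABLE2_COUNTS, frames_per_case=10, seed=0)
        assert manifest.images_total("train") == 3780
        assert manifest.images_total("validation") == 730
        assert manifest.images_total("test") == 750
        assert manifest.images_total() == 5260
        assert manifest.cases_total() == 526

    def test_conservation_invariant(self):
        counts = {"train": {"ICH": 3, "SAH": 2}, "validation": {"EDH": 1}, "test": {"IVH": 1}}
        m = build_manifest(counts, frames_per_case=7, seed=1)
        for split in m.splits:
            assert m.images_total(split) == m.cases_total(split) * 7
        index = m.frame_index()
        assert len(index) == m.images_total()

    def test_empty_manifest(self):
        m = build_manifest({"train": {}}, frames_per_case=10, seed=0)
        assert m.cases_total() == 0 and m.images_total() == 0

    def test_unit_case_ten_frames(self):
        m = build_manifest({"train": {"ICH": 1}}, frames_per_case=10, seed=0)
        assert len(m.frame_index()) == 10
        assert len(m.cases[0].frames) == 5  # stored frames cycled over slots

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            build_manifest({"train": {"ICH": -1}}, seed=0)

    def test_manifest_json_schema(self, tmp_path):
        m = build_manifest({"train": {"ICH": 2}, "validation": {"SDH": 1}, "test": {"EDH": 1}},
                           frames_per_case=10, seed=2)
        schema = m.to_json(tmp_path / "manifest.json")
        assert schema["totals"]["images"] == 40
        assert (tmp_path / "manifest.json").exists()
        assert schema["splits"]["train"]["ICH"] == ["train-ICH-000", "train-ICH-001"]
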