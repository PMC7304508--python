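"""Block design construction and HRF-convolved reference functions."""

import numpy as np
import pytest

from isps.design import (
    DEFAULT_CONDITIONS,
    BlockDesign,
    boxcar_regressor,
    build_default_design,
    build_references,
    convolved_reference,
    default_reference_sets,
    hrf_kernel,
    read_events,
    write_events,
)


class TestDefaultDesign:
    def test_block_structure(self, design):
        assert len(design.blocks) == 16
        for cond in DEFAULT_CONDITIONS:
            assert sum(b[2] == cond for b in design.blocks) == 4
        assert all(b[1] == 16.0 for b in design.blocks)

    def test_gaps_are_jittered_from_allowed_set(self, design):
        gaps = [
            design.blocks[i + 1][0] - (design.blocks[i][0] + design.blocks[i][1])
            for i in range(15)
        ]
        assert set(gaps) == {8.0, 10.0, 12.0}
        assert sorted(gaps).count(8.0) == 5

    def test_total_duration_and_volume_grid(self, design):
        assert design.total_duration_s == 436.0
        assert design.n_acquired_volumes == 218
        assert design.n_analyzed_volumes == 208
        last = design.blocks[-1]
        assert last[0] + last[1] <= design.total_duration_s

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError, match="overlapping|ordered"):
            BlockDesign(("a",), ((0.0, 16.0, "a"), (10.0, 16.0, "a")))
        with pytest.raises(ValueError, match="beyond"):
            BlockDesign(("a",), ((430.0, 16.0, "a"),))
        with pytest.raises(ValueError, match="condition"):
            BlockDesign(("a",), ((0.0, 16.0, "b"),))


class TestBoxcar:
    def test_empty_condition_set_is_zero(self, design):
        assert not boxcar_regressor(design, set()).any()

    def test_single_condition_integral_is_64s(self, design):
        box = boxcar_regressor(design, {"physical_pain"}, upsample_per_tr=10)
        dt = design.tr_s / 10
        assert box.sum() * dt == pytest.approx(64.0)  # 4 blocks x 16 s

    def test_values_are_binary(self, design):
        box = boxcar_regressor(design, {"physical_pain", "affective_pain"})
        assert set(np.unique(box)) <= {0.0, 1.0}

    def test_unknown_label_named_in_error(self, design):
        with pytest.raises(ValueError, match="no_such_condition"):
            boxcar_regressor(design, {"no_such_condition"})


class TestHrfKernel:
    def test_gamma_is_nonnegative_unit_sum(self):
        k = hrf_kernel("gamma_no_undershoot", dt=0.2)
        assert k.min() >= 0
        assert k.sum() == pytest.approx(1.0)

    def test_double_gamma_has_undershoot(self):
        k = hrf_kernel("double_gamma", dt=0.2)
        assert k.min() < 0
        assert np.argmin(k) > np.argmax(k)  # negative lobe after the peak

    def test_unit_sum_preserves_constant_series(self):
        k = hrf_kernel("gamma_no_undershoot", dt=0.2)
        out = np.convolve(np.ones(500), k)
        interior = out[len(k) : 500]
        np.testing.assert_allclose(interior, 1.0, atol=1e-12)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            hrf_kernel("gamma_no_undershoot", dt=0.2, lag_s=-1.0)
        with pytest.raises(ValueError):
            hrf_kernel("gamma_no_undershoot", dt=0.2, width_s=0.0)
        with pytest.raises(ValueError, match="unknown"):
            hrf_kernel("triple_gamma", dt=0.2)


class TestConvolvedReference:
    def test_length_is_analyzed_volume_count(self, design):
        ref = convolved_reference(design, {"physical_pain"})
        assert len(ref.samples) == 208  # 218 acquired - 10 trimmed

    def test_empty_set_gives_zero_reference(self, design):
        ref = convolved_reference(design, set())
        assert not ref.samples.any()

    def test_gamma_reference_nonnegative(self, design):
        ref = convolved_reference(design, {"affective_pain"})
        assert ref.samples.min() >= 0

    def test_impulse_proportional_to_kernel(self):
        # a single very short block approximates a unit impulse
        d = BlockDesign(("a",), ((20.0, 0.2, "a"),), tr_s=2.0,
                        n_acquired_volumes=60, n_trim_volumes=0)
        ref = convolved_reference(d, {"a"}).samples
        kernel = hrf_kernel("gamma_no_undershoot", dt=0.2)
        start = int(20.0 / 0.2)
        expected = np.zeros(600)
        expected[start : start + len(kernel)] = kernel
        np.testing.assert_allclose(ref, expected[::10], atol=1e-12)

    def test_disjoint_union_additivity(self, design):
        a = convolved_reference(design, {"physical_pain"}).samples
        b = convolved_reference(design, {"affective_control"}).samples
        both = convolved_reference(design, {"physical_pain", "affective_control"}).samples
        np.testing.assert_allclose(both, a + b, atol=1e-12)

    def test_onset_shift_by_whole_trs_shifts_samples(self):
        blocks = tuple((o, 16.0, "a") for o in (40.0, 120.0, 200.0))
        d1 = BlockDesign(("a",), blocks, n_acquired_volumes=150, n_trim_volumes=0)
        shifted = tuple((o + 4.0, 16.0, "a") for o in (40.0, 120.0, 200.0))
        d2 = BlockDesign(("a",), shifted, n_acquired_volumes=150, n_trim_volumes=0)
        r1 = convolved_reference(d1, {"a"}).samples
        r2 = convolved_reference(d2, {"a"}).samples
        np.testing.assert_allclose(r2[2:140], r1[:138], atol=1e-12)

    def test_peak_falls_inside_block_plus_lag_window(self, design):
        for cond in DEFAULT_CONDITIONS:
            ref = convolved_reference(design, {cond}, trim=False).samples
            t_peak = np.argmax(ref) * design.tr_s
            windows = [
                (o, o + dur + 32.0) for o, dur, c in design.blocks if c == cond
            ]
            assert any(lo <= t_peak <= hi for lo, hi in windows)


class TestReferenceSets:
    def test_eight_default_sets(self, design):
        sets = default_reference_sets(design)
        assert len(sets) == 8
        assert sets["pain_all"] == {"physical_pain", "affective_pain"}

    def test_build_references_shapes(self, design):
        refs = build_references(design)
        assert all(len(v) == 208 for v in refs.values())


class TestEventsRoundtrip:
    def test_write_read_preserves_design(self, design, tmp_path):
        path = tmp_path / "events.tsv"
        write_events(design, path)
        header = path.read_text().splitlines()[0]
        assert header.split("\t") == ["onset", "duration", "trial_type"]
        loaded = read_events(path, condition_labels=design.condition_labels)
        assert loaded.blocks == design.blocks
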