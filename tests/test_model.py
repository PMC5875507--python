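"""Core forward model: primary response, scatter kernel, segment/beam/
fraction prediction, penumbral rule, serialization."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import wiresignal as ws
from wiresignal.errors import InputDomainError, StructuralError

from conftest import brute_force_segment


def open_pair_segment(wire, separation=100.0, mu=50.0, n=40):
    sep = np.zeros(n)
    sep[wire] = separation
    return ws.Segment(separations=sep, mu=mu)


class TestPrimaryResponse:
    @pytest.mark.parametrize(
        "separation,mu,k,expected",
        [(0.0, 50.0, 1.0, 0.0), (100.0, 50.0, 1.0, 5000.0), (35.0, 2.0, 0.5, 35.0)],
    )
    def test_direct_product(self, separation, mu, k, expected):
        assert ws.primary_response(separation, mu, k) == expected

    def test_linear_in_mu(self):
        assert ws.primary_response(70.0, 20.0, 2.3) == 2 * ws.primary_response(70.0, 10.0, 2.3)

    @pytest.mark.parametrize("bad", [(-1.0, 10.0, 1.0), (10.0, -1.0, 1.0)])
    def test_negative_inputs_rejected(self, bad):
        with pytest.raises(InputDomainError):
            ws.primary_response(*bad)


class TestScatterKernel:
    def test_zero_distance_is_unity(self):
        for lam in (0.5, 1.4034, 3.0):
            assert ws.scatter_kernel(0.0, lam) == 1.0

    def test_one_cm_value(self):
        assert ws.scatter_kernel(1.0, 1.4034) == pytest.approx(np.exp(-1.4034), rel=1e-12)
        assert ws.scatter_kernel(1.0, 1.4034) == pytest.approx(0.2458, abs=5e-5)

    def test_beyond_cutoff_is_zero(self):
        assert ws.scatter_kernel(4.5, 1.4034) == 0.0
        assert ws.scatter_kernel(4.0, 1.4034) > 0.0

    def test_monotone_decreasing_within_cutoff(self):
        d = np.linspace(0, 4, 50)
        vals = ws.scatter_kernel(d, 1.4034)
        assert np.all(np.diff(vals) < 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(InputDomainError):
            ws.scatter_kernel(-0.1, 1.0)


class TestPredictSegment:
    def test_all_closed_gives_zero(self, model):
        seg = ws.Segment(separations=np.zeros(40), mu=100.0)
        assert np.all(ws.predict_segment(seg, model).values == 0)

    def test_single_open_pair_hand_values(self, model):
        sv = ws.predict_segment(open_pair_segment(19), model)
        assert sv.values[19] == pytest.approx(5000.0, rel=1e-12)
        assert sv.values[20] == pytest.approx(5000.0 * np.exp(-1.4034), rel=1e-12)
        assert sv.values[20] == pytest.approx(1228.9, abs=0.2)
        assert sv.values[24] == 0.0  # 5 cm away, beyond the 4 cm cutoff

    def test_length_mismatch_raises(self, model):
        with pytest.raises(StructuralError):
            ws.predict_segment(ws.Segment(separations=np.zeros(30), mu=1.0), model)

    @given(
        separations=arrays(float, 40, elements=st.floats(0.0, 400.0)),
        mu=st.floats(0.1, 100.0),
    )
    def test_matches_brute_force_double_sum(self, separations, mu):
        model = ws.DetectorModel()
        seg = ws.Segment(separations=separations, mu=mu)
        expected = brute_force_segment(seg, model)
        np.testing.assert_allclose(ws.predict_segment(seg, model).values, expected, rtol=1e-9, atol=1e-9)

    @given(separations=arrays(float, 40, elements=st.floats(0.0, 400.0)))
    def test_mirror_symmetry(self, separations):
        model = ws.DetectorModel()
        fwd = ws.predict_segment(ws.Segment(separations=separations, mu=10.0), model).values
        rev = ws.predict_segment(ws.Segment(separations=separations[::-1], mu=10.0), model).values
        np.testing.assert_allclose(fwd, rev[::-1], rtol=1e-12, atol=1e-12)

    def test_single_pair_reduces_to_primary(self, model):
        """With one open pair the value at its own wire is the primary term."""
        sv = ws.predict_segment(open_pair_segment(7, 123.0, 17.0), model)
        assert sv.values[7] == pytest.approx(ws.primary_response(123.0, 17.0, model.k), rel=1e-12)


class TestApplyPenumbra:
    def make_prediction(self, mask_stop, value=1000.0, n=40):
        mask = np.zeros(n, dtype=bool)
        mask[:mask_stop] = True
        predicted = ws.SignalVector(values=np.where(mask, value, 30.0), sigmas=np.zeros(n))
        return predicted, mask

    def test_four_fractions_then_zero(self):
        pen = ws.PenumbraModel(fractions=(0.5, 0.2, 0.1, 0.05), sigmas=(0.1,) * 4)
        predicted, mask = self.make_prediction(7)  # wires 1..7 in-field (1-based)
        out = ws.apply_penumbra(predicted, mask, pen)
        np.testing.assert_allclose(out.values[7:11], [500.0, 200.0, 100.0, 50.0])
        assert np.all(out.values[11:] == 0.0)
        assert np.all(out.values[:7] == 1000.0)

    def test_all_in_field_unchanged(self, pen):
        n = 40
        values = np.linspace(10, 400, n)
        sv = ws.SignalVector(values=values, sigmas=np.zeros(n))
        out = ws.apply_penumbra(sv, np.ones(n, dtype=bool), pen)
        np.testing.assert_array_equal(out.values, values)

    def test_truncated_at_detector_edge(self, pen):
        """Only two wires beyond the field edge: P1, P2 applied, no error."""
        n = 40
        mask = np.zeros(n, dtype=bool)
        mask[: n - 2] = True
        sv = ws.SignalVector(values=np.full(n, 100.0), sigmas=np.zeros(n))
        out = ws.apply_penumbra(sv, mask, pen)
        assert out.values[n - 2] == pytest.approx(pen.fractions[0] * 100.0)
        assert out.values[n - 1] == pytest.approx(pen.fractions[1] * 100.0)

    def test_sigma_assignment(self, pen):
        predicted, mask = self.make_prediction(7)
        out = ws.apply_penumbra(predicted, mask, pen, in_field_sigma=0.01)
        np.testing.assert_allclose(out.sigmas[:7], 10.0)  # 1% of 1000
        assert out.sigmas[7] == pytest.approx(pen.sigmas[0] * out.values[7])

    def test_gap_between_islands_takes_larger_candidate(self, pen):
        n = 40
        mask = np.zeros(n, dtype=bool)
        mask[5:10] = True
        mask[13:18] = True  # 3-wire gap: both edges compete
        values = np.zeros(n)
        values[5:10] = 1000.0
        values[13:18] = 400.0
        sv = ws.SignalVector(values=values, sigmas=np.zeros(n))
        out = ws.apply_penumbra(sv, mask, pen)
        # wire 10: rank 1 from the left island (1000) vs rank 3 from the right (400)
        expected = max(pen.fractions[0] * 1000.0, pen.fractions[2] * 400.0)
        assert out.values[10] == pytest.approx(expected)

    def test_empty_mask_with_signal_raises(self, pen):
        sv = ws.SignalVector(values=np.full(40, 5.0), sigmas=np.zeros(40))
        with pytest.raises(StructuralError):
            ws.apply_penumbra(sv, np.zeros(40, dtype=bool), pen)

    def test_empty_mask_with_zero_signal_ok(self, pen):
        sv = ws.SignalVector(values=np.zeros(40), sigmas=np.zeros(40))
        out = ws.apply_penumbra(sv, np.zeros(40, dtype=bool), pen)
        assert np.all(out.values == 0)


class TestBeamAndFraction:
    def aperture_segment(self, mu=10.0):
        sep = np.zeros(40)
        sep[10:25] = 80.0
        return ws.Segment(separations=sep, mu=mu)

    def test_single_segment_beam_identity(self, model, pen):
        seg = self.aperture_segment()
        beam = ws.Beam(segments=[seg], beam_id="B1")
        raw = ws.predict_segment(seg, model)
        adj = ws.apply_penumbra(raw, ws.in_field_mask(seg, model), pen, model.in_field_sigma)
        np.testing.assert_array_equal(ws.predict_beam(beam, model, pen).values, adj.values)

    def test_two_identical_segments_double(self, model, pen):
        seg = self.aperture_segment()
        one = ws.predict_beam(ws.Beam(segments=[seg], beam_id="b"), model, pen)
        two = ws.predict_beam(ws.Beam(segments=[seg, seg], beam_id="b"), model, pen)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)
        # sigmas add in quadrature, not linearly
        np.testing.assert_allclose(two.sigmas, np.sqrt(2) * one.sigmas, rtol=1e-12)

    def test_fraction_is_sum_of_beams(self, model, pen):
        beams = [
            ws.Beam(segments=[self.aperture_segment(mu)], beam_id=f"B{i}")
            for i, mu in enumerate([5.0, 7.0, 9.0, 11.0, 13.0])
        ]
        plan = ws.Plan(beams=beams, plan_id="p")
        frac = ws.predict_fraction(plan, model, pen)
        total = sum(ws.predict_beam(b, model, pen).values for b in beams)
        np.testing.assert_allclose(frac.values, total, rtol=1e-12)

    def test_fraction_homogeneous_in_mu(self, model, pen):
        config = ws.SimulationConfig(seed=3)
        plan = ws.generate_plan(config, 0)
        scaled = ws.inject_fault(plan, {"mu_scale": 3.0})
        base = ws.predict_fraction(plan, model, pen).values
        np.testing.assert_allclose(ws.predict_fraction(scaled, model, pen).values, 3 * base, rtol=1e-12)

    def test_fraction_homogeneous_in_k(self, pen):
        config = ws.SimulationConfig(seed=3)
        plan = ws.generate_plan(config, 0)
        base = ws.predict_fraction(plan, ws.DetectorModel(k=1.0), pen).values
        twice = ws.predict_fraction(plan, ws.DetectorModel(k=2.0), pen).values
        np.testing.assert_allclose(twice, 2 * base, rtol=1e-12)


class TestInFieldMask:
    def test_closed_threshold(self, model):
        sep = np.zeros(40)
        sep[5] = 0.5  # below 1 mm threshold: closed
        sep[6] = 1.5
        seg = ws.Segment(separations=sep, mu=1.0)
        mask = ws.in_field_mask(seg, model)
        assert not mask[5] and mask[6]

    def test_jaw_restriction(self, model):
        sep = np.full(40, 50.0)
        seg = ws.Segment(separations=sep, mu=1.0, jaw_y=(-50.0, 50.0))
        mask = ws.in_field_mask(seg, model)
        pos = model.wire_positions()
        np.testing.assert_array_equal(mask, (pos >= -50) & (pos <= 50))


class TestSignalSerialization:
    def test_round_trip(self, rng):
        sv = ws.SignalVector(values=rng.uniform(0, 1000, 40), sigmas=rng.uniform(0, 10, 40), level="beam")
        buf = io.StringIO()
        ws.write_signal(sv, buf, plan_id="p1", beam_id="B2")
        buf.seek(0)
        back, meta = ws.read_signal(buf)
        np.testing.assert_array_equal(back.values, sv.values)
        np.testing.assert_array_equal(back.sigmas, sv.sigmas)
        assert back.level == "beam"
        assert meta["plan_id"] == "p1" and meta["beam_id"] == "B2"

    def test_missing_header_rejected(self):
        with pytest.raises(StructuralError):
            ws.read_signal(io.StringIO("1\t2.0\t0.1\n"))


class TestValidation:
    def test_penumbra_must_be_non_increasing(self):
        with pytest.raises(InputDomainError):
            ws.PenumbraModel(fractions=(0.1, 0.5, 0.05, 0.01), sigmas=(0.0,) * 4)

    def test_detector_invariants(self):
        with pytest.raises(InputDomainError):
            ws.DetectorModel(k=-1.0)
        with pytest.raises(InputDomainError):
            ws.DetectorModel(lateral_exponent=0.0)

    def test_negative_separation_rejected(self):
        with pytest.raises(InputDomainError):
            ws.Segment(separations=np.array([-1.0] * 40), mu=1.0)
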