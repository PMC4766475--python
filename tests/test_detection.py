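"""Generalized-angle matching, presence counting, and signatures."""

import numpy as np
import pytest

from hrvlines import (
    EventSpec,
    RRSeries,
    SynthSpec,
    cos_theta,
    delta_field,
    generate,
    make_a2,
    make_b1,
    normalize_global,
    presence,
    scenario_presets,
    signature,
    signature_space_point,
)
from hrvlines.detection import CrossOrderError, PresenceResult


def _field(values, n=5):
    return delta_field(normalize_global(RRSeries(intervals=np.asarray(values))), n)


class TestCosTheta:
    def test_parallel_truncated_b1_window(self):
        a = 0.13
        assert cos_theta(np.array([0, 0, -a, a]), make_b1(5)) == pytest.approx(1.0, abs=1e-12)

    def test_antiparallel_a2(self):
        w = make_a2(5, "+").truncated_unit() * 0.05
        assert cos_theta(w, make_a2(5, "-")) == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_window_inner_product_oracle(self):
        # brute-force inner product: every term of the dot product is zero
        w = np.array([0.1, -0.1, 0.0, 0.0])
        u = make_b1(5).truncated_unit()
        assert float(w @ u) == 0.0
        assert cos_theta(w, make_b1(5)) == pytest.approx(0.0, abs=1e-12)

    def test_quiescent_window_rejected(self):
        with pytest.raises(ValueError, match="quiescent"):
            cos_theta(np.zeros(4), make_b1(5))

    def test_order_mismatch(self):
        with pytest.raises(CrossOrderError):
            cos_theta(np.array([0.1, -0.1, 0.0]), make_b1(5))


class TestPresence:
    def test_single_pair_canonical_presence(self, flat_pair_record):
        rr, _ = flat_pair_record
        res = presence(_field(rr.intervals), make_b1(5))
        assert res.m == 1
        assert res.presence_percent == pytest.approx(100 * 1 * 4 / 100, abs=1e-12)
        assert res.matches[0].cos_theta == pytest.approx(1.0, abs=1e-9)
        # amplitude t recovers the event size along the truncated direction
        assert res.matches[0].amplitude == pytest.approx(0.2 * np.sqrt(2), abs=1e-9)

    def test_constant_series_matches_nothing(self):
        res = presence(_field([0.8] * 50), make_b1(5))
        assert res.m == 0 and res.presence_percent == 0.0

    def test_presence_formula(self):
        # M = 4200, N = 5, m = 42 -> 100*42*4/4195
        res = PresenceResult("B1", 42, 100 * 42 * 4 / 4195, 0.2, 4200, 5)
        assert res.presence_percent == pytest.approx(4.00476758045, abs=1e-9)

    def test_cross_order_error_names_rebuild(self):
        from hrvlines import make_b2

        with pytest.raises(CrossOrderError, match="native order"):
            presence(_field([0.8] * 50, n=5), make_b2(6))

    def test_overlap_suppression_collapses_window_runs(self):
        # a slow A2-like wobble repeated back to back: without suppression
        # neighbouring windows can all match; with it, m counts events
        spec = SynthSpec(
            M=400,
            noise_sd=0.0,
            resp_amplitude=0.0,
            events=tuple(EventSpec("ectopic_pair", i, 0.2, 2) for i in range(30, 360, 40)),
            seed=0,
        )
        rr, log = generate(spec)
        fld = _field(rr.intervals)
        on = presence(fld, make_b1(5), suppress_overlap=True)
        off = presence(fld, make_b1(5), suppress_overlap=False)
        assert on.m == len(log)
        assert off.m >= on.m

    def test_monotone_in_tolerance(self, hf_like_normalized):
        fld = delta_field(hf_like_normalized, 5)
        counts = [
            presence(fld, make_b1(5), cos_tolerance=c).m for c in (0.995, 0.98, 0.9, 0.5)
        ]
        assert counts == sorted(counts)

    def test_amplitude_floor_rejects_small_events(self, flat_pair_record):
        rr, _ = flat_pair_record
        fld = _field(rr.intervals)
        assert presence(fld, make_b1(5), min_amplitude=1.0).m == 0
        assert presence(fld, make_b1(5), min_amplitude=0.1).m == 1


class TestSignature:
    def test_constant_series_all_zero(self):
        sig, _ = signature(RRSeries(intervals=np.full(120, 0.8)))
        assert all(v == 0.0 for v in sig.presences.values())
        assert sig.phi == 0.0

    def test_short_record_names_minimum(self):
        with pytest.raises(ValueError, match="at least 12"):
            signature(RRSeries(intervals=np.full(11, 0.8)))

    def test_hf_like_orders_b1_over_a1(self):
        spec = scenario_presets(seed=5)["hf_like"]
        rr, _ = generate(spec)
        sig, _ = signature(rr)
        assert sig.presences["B1"] > sig.presences["A1+"]

    def test_nsr_like_orders_a1_over_b1(self):
        spec = scenario_presets(seed=5)["nsr_like"]
        rr, _ = generate(spec)
        sig, _ = signature(rr)
        assert sig.presences["A1+"] > sig.presences["B1"]

    def test_presence_scale_invariance(self):
        spec = scenario_presets(seed=9)["hf_like"]
        rr, _ = generate(spec)
        sig1, _ = signature(rr)
        sig2, _ = signature(RRSeries(intervals=1000.0 * rr.intervals))
        for k in sig1.presences:
            assert abs(sig1.presences[k] - sig2.presences[k]) <= 1e-12

    def test_signature_space_point_is_projection(self):
        spec = scenario_presets(seed=2)["nsr_like"]
        rr, _ = generate(spec)
        sig, _ = signature(rr)
        a1p, b1, phi = signature_space_point(sig)
        assert (a1p, b1, phi) == (sig.presences["A1+"], sig.presences["B1"], sig.phi)

    def test_fragments_policy_reports_b2(self):
        spec = scenario_presets(seed=3)["hf_like"]
        rr, _ = generate(spec)
        sig, _ = signature(rr, b2_order_policy="fragments")
        assert "B2" in sig.presences and sig.presences["B2"] >= 0
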