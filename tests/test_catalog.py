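"""Construction of the universal arrhythmic line directions."""

import itertools

import numpy as np
import pytest

from hrvlines import (
    default_catalog,
    make_a1,
    make_a2,
    make_b1,
    make_b2,
    make_b2_family,
    make_b3,
    make_shadow,
)
from hrvlines.catalog import (
    ArrhythmiaLine,
    b2_fragments,
    catalog_from_json,
    catalog_to_json,
    make_b1_split,
)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestA1:
    def test_n5_accelerating_is_descending_ramp(self):
        np.testing.assert_allclose(
            make_a1(5, "+").direction, _unit([2, 1, 0, -1, -2]), atol=1e-12
        )

    def test_minus_is_negation(self):
        for n in (2, 4, 5, 9):
            np.testing.assert_allclose(
                make_a1(n, "-").direction, -make_a1(n, "+").direction, atol=1e-15
            )

    def test_smallest_ramp(self):
        np.testing.assert_allclose(make_a1(2, "+").direction, _unit([1, -1]), atol=1e-12)

    def test_rejects_order_below_two(self):
        with pytest.raises(ValueError):
            make_a1(1, "+")


class TestA2:
    def test_n5_sine_components_and_zero_sum(self):
        d = make_a2(5, "+").direction
        expected = _unit([np.sin(2 * np.pi * k / 5) for k in range(5)])
        np.testing.assert_allclose(d, expected, atol=1e-12)
        assert abs(d.sum()) <= 1e-12

    def test_n4_exact_sines(self):
        np.testing.assert_allclose(make_a2(4, "+").direction, _unit([0, 1, 0, -1]), atol=1e-12)

    def test_negation_and_phase_offset_stay_compensated(self):
        for n in (3, 5, 8):
            np.testing.assert_allclose(
                make_a2(n, "-").direction, -make_a2(n, "+").direction, atol=1e-15
            )
        assert abs(make_a2(5, "+", phase=0.7).direction.sum()) <= 1e-12

    def test_rejects_degenerate_order(self):
        with pytest.raises(ValueError):
            make_a2(2, "+")


class TestB1:
    @pytest.mark.parametrize(
        "n, i, expected",
        [
            (5, 2, [0, 0, -1, 1, 0]),
            (5, 1, [0, -1, 1, 0, 0]),
            (4, 1, [0, -1, 1, 0]),
        ],
    )
    def test_positions(self, n, i, expected):
        line = make_b1(n, i)
        np.testing.assert_allclose(line.direction, _unit(expected), atol=1e-12)
        assert line.compensated and line.terminated

    def test_default_position_is_canonical(self):
        assert make_b1(5).name == "B1"
        np.testing.assert_allclose(make_b1(5).direction, _unit([0, 0, -1, 1, 0]), atol=1e-12)

    def test_position_range(self):
        with pytest.raises(ValueError):
            make_b1(5, 3)  # pair would touch the last component

    def test_split_variant_excluded_from_default(self):
        split = make_b1_split(5)
        np.testing.assert_allclose(split.direction, _unit([1, 0, 0, 0, -1]), atol=1e-12)
        assert "B1_split" not in {l.name for l in default_catalog(5)}


class TestB2Family:
    def test_canonical_order6(self):
        line = make_b2(6)
        np.testing.assert_allclose(line.direction, _unit([4, -1, -1, -1, -1, 0]), atol=1e-12)
        assert line.name == "B2" and line.compensated and line.terminated
        assert line.family_index == 4

    def test_family_members(self):
        np.testing.assert_allclose(
            make_b2_family(2).direction, _unit([2, -1, -1, 0]), atol=1e-12
        )
        for m in range(2, 9):
            line = make_b2_family(m)
            assert line.order == m + 2
            assert abs(line.direction.sum()) <= 1e-12

    def test_fragments_are_order5_sliding_directions(self):
        frags = b2_fragments(4)
        assert [f.name for f in frags] == ["B2_1", "B2_2"]
        assert all(f.order == 5 for f in frags)
        np.testing.assert_allclose(frags[0].direction, _unit([4, -1, -1, -1, -1]), atol=1e-12)
        np.testing.assert_allclose(frags[1].direction, _unit([-1, -1, -1, -1, 4]), atol=1e-12)


class TestB3AndShadows:
    def test_zero_sum_everywhere(self):
        for m, i in itertools.product(range(2, 7), range(1, 3)):
            assert abs(make_b3(m, i).direction.sum()) <= 1e-12
            assert abs(make_shadow(m, i).direction.sum()) <= 1e-12

    def test_distinct_positions_are_non_parallel(self):
        m = 4
        b3s = [make_b3(m, i).direction for i in range(1, m + 1)]
        shadows = [make_shadow(m, i).direction for i in range(1, m + 1)]
        for fam in (b3s, shadows):
            for a, b in itertools.combinations(fam, 2):
                assert abs(a @ b) < 1 - 1e-9

    def test_shadow_not_parallel_to_b3(self):
        for m in (2, 4, 6):
            for i in range(1, m + 1):
                c = make_b3(m, i).direction @ make_shadow(m, i).direction
                assert abs(c) < 1 - 1e-9

    def test_index_validation(self):
        with pytest.raises(ValueError):
            make_b3(4, 0)  # would reproduce B2 itself
        with pytest.raises(ValueError):
            make_shadow(4, 5)


class TestCatalog:
    def test_default_order_and_flags(self):
        lines = default_catalog(5)
        assert [l.name for l in lines] == ["A1+", "A1-", "A2+", "A2-", "B1", "B2"]
        for l in lines:
            assert abs(np.linalg.norm(l.direction) - 1) <= 1e-12
            assert l.compensated
        assert lines[-1].order == 6  # B2 is a cross-order entry

    def test_unit_norm_idempotence(self):
        line = make_a1(5, "+")
        again = ArrhythmiaLine(
            name=line.name,
            order=line.order,
            direction=line.direction,
            compensated=line.compensated,
            terminated=line.terminated,
        )
        np.testing.assert_array_equal(line.direction, again.direction)

    def test_json_round_trip(self, tmp_path):
        lines = default_catalog(5) + [make_b3(4, 2), make_shadow(4, 2)]
        path = tmp_path / "catalog.json"
        catalog_to_json(lines, path)
        back = catalog_from_json(path)
        assert [l.name for l in back] == [l.name for l in lines]
        for a, b in zip(lines, back):
            np.testing.assert_allclose(a.direction, b.direction, atol=1e-15)
            assert (a.compensated, a.terminated, a.order) == (
                b.compensated,
                b.terminated,
                b.order,
            )
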