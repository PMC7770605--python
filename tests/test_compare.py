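"""Validity percentages, rater reliability, cross-species rows, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regionquant import (
    CrossAtlasMapping,
    QuantParams,
    RegionEstimate,
    cell_type_fraction,
    cross_species_table,
    gradient_profile,
    percent_difference,
    rater_reliability,
    validity_table,
)
from regionquant.compare import per_section_density


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ref, test, rounded",
        [
            (2175, 2379, 9),    # parvalbumin neocortex
            (540, 555, 3),      # parvalbumin hippocampal/parahippocampal
            (295, 340, 15),     # parvalbumin striatal/pallidal
            (3400, 3560, 5),    # parvalbumin entorhinal series
            (654, 719, 10),     # calbindin cortical
            (98, 96, -2),       # calbindin hypothalamus
            (63, 91, 44),       # calbindin olfactory
        ],
    )
    def test_printed_count_pairs(self, ref, test, rounded):
        assert percent_difference(ref, test)[1] == rounded

    def test_identity_is_zero(self):
        assert percent_difference(137, 137) == (0.0, 0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0, 5)

    @settings(max_examples=50, deadline=None)
    @given(a=st.integers(1, 10**6), b=st.integers(1, 10**6))
    def test_reciprocal_property(self, a, b):
        p1, _ = percent_difference(a, b)
        p2, _ = percent_difference(b, a)
        assert (p1 >= 0) != (p2 > 0) or (p1 == 0 and p2 == 0)
        assert (1 + p1 / 100) * (1 + p2 / 100) == pytest.approx(1.0)


class TestValidityTable:
    def test_parvalbumin_single_section_rows(self):
        rows = validity_table(
            {"CTX": 2175, "HIP": 540, "STR": 295},
            {"CTX": 2379, "HIP": 555, "STR": 340},
        )
        by = {r.label: r.pct_diff_rounded for r in rows}
        assert by["CTX"] == 9 and by["HIP"] == 3 and by["STR"] == 15
        assert by["ALL"] == percent_difference(2175 + 540 + 295, 2379 + 555 + 340)[1]

    def test_equal_counts_zero(self):
        rows = validity_table({"A": 44}, {"A": 44})
        assert all(r.pct_diff == 0 for r in rows)

    def test_group_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            validity_table({"A": 1}, {"B": 1})

    def test_random_rows_match_formula(self):
        rng = np.random.default_rng(17)
        manual = {f"G{i}": int(rng.integers(1, 1000)) for i in range(6)}
        auto = {g: int(rng.integers(1, 1000)) for g in manual}
        for row in validity_table(manual, auto):
            if row.label == "ALL":
                continue
            assert row.pct_diff == pytest.approx(
                100 * (auto[row.label] - manual[row.label]) / manual[row.label]
            )


class TestRaterReliability:
    def test_identical_tables(self):
        t = {"A": 100, "B": 50}
        res = rater_reliability([t, dict(t), dict(t)])
        assert res.overall_range == (0.0, 0.0)

    def test_constructed_two_rater_range(self):
        res = rater_reliability([{"A": 100, "B": 50}, {"A": 110, "B": 40}])
        assert res.per_rater_group[(1, "A")] == pytest.approx(10.0)
        assert res.per_rater_group[(1, "B")] == pytest.approx(20.0)
        assert res.overall_range == (pytest.approx(10.0), pytest.approx(20.0))

    def test_too_few_tables(self):
        with pytest.raises(ValueError):
            rater_reliability([{"A": 1}])

    def test_five_raters_match_brute_force(self):
        rng = np.random.default_rng(8)
        groups = [f"G{i}" for i in range(4)]
        ref = {g: int(rng.integers(50, 500)) for g in groups}
        tables = [ref] + [
            {g: max(1, int(v * rng.uniform(0.7, 1.3))) for g, v in ref.items()}
            for _ in range(4)
        ]
        res = rater_reliability(tables, reference_index=0)
        brute = [
            abs(100 * (t[g] - ref[g]) / ref[g])
            for t in tables[1:]
            for g in groups
        ]
        assert res.overall_range == (pytest.approx(min(brute)), pytest.approx(max(brute)))


class TestCellTypeFraction:
    @pytest.mark.parametrize("a, b, expected", [(500, 500, 0.5), (0, 7, 0.0)])
    def test_values(self, a, b, expected):
        assert cell_type_fraction(a, b) == expected

    def test_undefined(self):
        with pytest.raises(ValueError):
            cell_type_fraction(0, 0)

    @settings(max_examples=50, deadline=None)
    @given(a=st.integers(0, 10**6), b=st.integers(1, 10**6))
    def test_complement_sums_to_one(self, a, b):
        assert cell_type_fraction(a, b) + cell_type_fraction(b, a) == pytest.approx(1.0)


def _estimate(label, total, volume):
    return RegionEstimate(
        label=label,
        n_raw=total,
        n_corrected=float(total),
        total_estimate=total,
        volume_mm3=volume,
        density_per_mm3=total / volume,
    )


class TestCrossSpecies:
    def _mapping(self):
        return CrossAtlasMapping([("DG", (10,), (20,)), ("PaS", (11,), (21,))])

    def test_printed_density_comparisons(self):
        # unit volumes make pooled densities equal the printed per-mm3 values
        rat = {10: _estimate(10, 231, 1.0), 11: _estimate(11, 1185, 1.0)}
        mouse = {20: _estimate(20, 178, 1.0), 21: _estimate(21, 2614, 1.0)}
        rows = {r.target: r for r in cross_species_table(rat, mouse, self._mapping())}
        # rat DG is ~30% denser than mouse DG
        assert round(100 * (rows["DG"].ratio - 1)) == 30
        # rat PaS is 54.7% lower, inside the printed 46-55% band
        assert rows["PaS"].pct_lower_a_vs_b == pytest.approx(54.67, abs=0.01)
        assert 46 <= rows["PaS"].pct_lower_a_vs_b <= 55

    def test_equal_densities(self):
        a = {10: _estimate(10, 100, 2.0), 11: _estimate(11, 5, 1.0)}
        b = {20: _estimate(20, 50, 1.0), 21: _estimate(21, 5, 1.0)}
        rows = cross_species_table(a, b, self._mapping())
        assert rows[0].ratio == pytest.approx(1.0)
        assert rows[0].pct_lower_a_vs_b == pytest.approx(0.0)

    def test_missing_region_reason_code(self):
        a = {10: _estimate(10, 100, 2.0)}
        b = {20: _estimate(20, 50, 1.0), 21: _estimate(21, 5, 1.0)}
        rows = {r.target: r for r in cross_species_table(a, b, self._mapping())}
        assert rows["PaS"].ratio is None and "missing" in rows["PaS"].status

    def test_volume_rescaling_invariance(self):
        a = {10: _estimate(10, 100, 2.0), 11: _estimate(11, 5, 1.0)}
        b = {20: _estimate(20, 50, 1.0), 21: _estimate(21, 5, 1.0)}
        a2 = {k: _estimate(k, v.total_estimate, v.volume_mm3 * 3) for k, v in a.items()}
        b2 = {k: _estimate(k, v.total_estimate, v.volume_mm3 * 3) for k, v in b.items()}
        r1 = cross_species_table(a, b, self._mapping())
        r2 = cross_species_table(a2, b2, self._mapping())
        for x, y in zip(r1, r2):
            assert x.pct_lower_a_vs_b == pytest.approx(y.pct_lower_a_vs_b)

    def test_pooling_is_volume_weighted(self):
        mapping = CrossAtlasMapping([("X", (1, 2), (3,))])
        a = {1: _estimate(1, 100, 1.0), 2: _estimate(2, 100, 9.0)}
        b = {3: _estimate(3, 20, 1.0)}
        [row] = cross_species_table(a, b, mapping)
        assert row.density_a == pytest.approx(200 / 10.0)  # not mean of 100 and 11.1


class TestGradientProfile:
    def test_strictly_decreasing(self):
        prof = gradient_profile("MEC", [(3, 10), (2, 8), (1, 6), (0, 4)])
        assert prof.spearman_rho == -1.0
        assert prof.classification == "decreasing"

    def test_constant_is_none(self):
        prof = gradient_profile("MEC", [(3, 5), (2, 5), (1, 5), (0, 5)])
        assert prof.spearman_rho == 0.0
        assert prof.classification == "none"

    def test_insufficient_sections(self):
        prof = gradient_profile("MEC", [(1, 2), (0, 3)], min_sections=4)
        assert prof.classification == "insufficient data"
        assert prof.spearman_rho is None

    def test_monotone_transform_invariance(self):
        samples = [(4, 9.0), (3, 3.0), (2, 7.0), (1, 1.0), (0, 5.0)]
        p1 = gradient_profile("X", samples)
        p2 = gradient_profile("X", [(a, d**3 + 2) for a, d in samples])
        assert p1.spearman_rho == pytest.approx(p2.spearman_rho)
        assert p1.classification == p2.classification

    def test_rho_matches_brute_force_ranks(self):
        rng = np.random.default_rng(19)
        densities = np.sort(rng.uniform(1, 10, 8))[::-1]  # decreasing ramp + order
        samples = [(float(7 - i), float(d)) for i, d in enumerate(densities)]
        prof = gradient_profile("X", samples)

        def ranks(v):
            order = np.argsort(v)
            r = np.empty(len(v))
            r[order] = np.arange(1, len(v) + 1)
            return r

        x = np.arange(len(densities), dtype=float)
        rx, ry = ranks(x), ranks(np.array(densities))
        brute = np.corrcoef(rx, ry)[0, 1]
        assert prof.spearman_rho == pytest.approx(brute)
        assert prof.classification == "decreasing"

    def test_per_section_density(self):
        # 1000 px of 10 um pixels, 40 um thick: volume = 1000*1e-4*0.04 mm3
        d = per_section_density(8, 1000, 10.0, 40.0)
        assert d == pytest.approx(8 / (1000 * 1e-4 * 0.04))
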