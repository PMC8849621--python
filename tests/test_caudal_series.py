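import math
import random

import numpy as np
import pytest
from scipy.stats import kendalltau

from morphoclade import caudal_series as cs
from morphoclade.synthetic_data import CaudalSimSpec, simulate_caudal_series

from . import oracles


class TestFacetArea:
    def test_circle(self):
        assert cs.facet_area(2, 2, "ellipse") == pytest.approx(math.pi)

    def test_rectangle(self):
        assert cs.facet_area(3, 4, "rectangle") == pytest.approx(12.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_ellipse_is_pi_over_four_of_rectangle(self, seed):
        rng = random.Random(seed)
        dv, ml = rng.uniform(0.1, 50), rng.uniform(0.1, 50)
        assert cs.facet_area(dv, ml, "ellipse") == pytest.approx(
            math.pi / 4 * cs.facet_area(dv, ml, "rectangle")
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cs.facet_area(0, 1)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            cs.facet_area(1, 1, "trapezoid")


class TestAsi:
    def test_simple_ratio(self):
        assert cs.asi(100.0, 10.0) == pytest.approx(1.0)

    def test_unit_invariance(self):
        # same vertebra in mm and cm
        assert cs.asi(100.0, 10.0) == pytest.approx(cs.asi(1.0, 1.0))

    @pytest.mark.parametrize("seed", range(50))
    def test_unit_invariance_property(self, seed):
        rng = random.Random(seed)
        area, length = rng.uniform(1, 1000), rng.uniform(1, 100)
        k = rng.uniform(0.01, 100)  # unit conversion factor
        assert cs.asi(area * k * k, length * k) == pytest.approx(
            cs.asi(area, length)
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cs.asi(-1.0, 5.0)


def _vert(vid, length, asi_value, anchor=False, diapo=False):
    area = asi_value * length * length
    d = math.sqrt(4 * area / math.pi)
    return cs.VertebraRecord(
        vertebra_id=vid,
        centrum_length=length,
        facet_dv_diameter=d,
        facet_ml_diameter=d,
        has_diapophysis=diapo,
        anchor_flag=anchor,
    )


class TestProfiles:
    def test_anchor_is_hundred(self):
        series = [_vert("a", 50, 1.0, anchor=True), _vert("b", 45, 0.5)]
        prof = cs.asi_profile(series)
        assert prof["a"][1] == pytest.approx(100.0)

    def test_halving_series(self):
        series = [_vert("a", 50, 1.0, anchor=True)] + [
            _vert(f"v{i}", 50, 1.0 / 2**i) for i in range(1, 4)
        ]
        prof = cs.asi_profile(series)
        assert [round(prof[v][1]) for v in ("a", "v1", "v2", "v3")] == [
            100,
            50,
            25,
            12,
        ]

    def test_no_anchor_raises(self):
        with pytest.raises(ValueError, match="anchor"):
            cs.asi_profile([_vert("a", 50, 1.0)])

    def test_length_profile(self):
        series = [
            _vert("a", 50, 1.0, anchor=True),
            _vert("b", 45, 0.9),
            _vert("c", 40, 0.8),
        ]
        prof = cs.length_profile(series)
        assert [prof[v] for v in "abc"] == pytest.approx([100.0, 90.0, 80.0])

    def test_profile_invariant_to_area_model(self):
        series = [_vert("a", 50, 1.0, anchor=True), _vert("b", 45, 0.43)]
        p_ell = cs.asi_profile(series, "ellipse")
        p_rect = cs.asi_profile(series, "rectangle")
        for vid in ("a", "b"):
            assert p_ell[vid][1] == pytest.approx(p_rect[vid][1])

    def test_profile_invariant_to_uniform_scaling(self):
        series = [_vert("a", 50, 1.0, anchor=True), _vert("b", 45, 0.43)]
        scaled = [
            cs.VertebraRecord(
                v.vertebra_id,
                v.centrum_length * 3.0,
                v.facet_dv_diameter * 3.0,
                v.facet_ml_diameter * 3.0,
                has_diapophysis=v.has_diapophysis,
                anchor_flag=v.anchor_flag,
            )
            for v in series
        ]
        p1 = cs.asi_profile(series)
        p2 = cs.asi_profile(scaled)
        for vid in ("a", "b"):
            assert p1[vid][1] == pytest.approx(p2[vid][1])


class TestOrderSeries:
    def test_already_sorted_preserved(self):
        series = [
            _vert("a", 50, 1.0, anchor=True),
            _vert("b", 48, 0.9),
            _vert("c", 46, 0.8),
        ]
        assert cs.order_series(series) == ("a", "b", "c")

    def test_shuffled_recovered(self):
        recs, true_order = simulate_caudal_series(
            CaudalSimSpec(n_vertebrae=12, seed=3)
        )
        assert cs.order_series(recs) == true_order

    def test_permutation_of_input_ids(self):
        recs, _ = simulate_caudal_series(CaudalSimSpec(n_vertebrae=9, seed=4))
        assert sorted(cs.order_series(recs)) == sorted(
            r.vertebra_id for r in recs
        )

    def test_tie_broken_by_length_then_id(self):
        series = [
            _vert("a", 50, 1.0, anchor=True),
            _vert("z", 40, 0.5),
            _vert("b", 45, 0.5),
            _vert("c", 40, 0.5),
        ]
        assert cs.order_series(series) == ("a", "b", "c", "z")

    def test_duplicate_ids_rejected(self):
        series = [_vert("a", 50, 1.0, anchor=True), _vert("a", 45, 0.5)]
        with pytest.raises(ValueError, match="duplicate"):
            cs.order_series(series)

    def test_noisy_recovery_kendall_tau(self):
        """Mean Kendall tau >= 0.9 at 5% multiplicative noise, n=15."""
        taus = []
        for seed in range(100):
            recs, true_order = simulate_caudal_series(
                CaudalSimSpec(n_vertebrae=15, noise_sd=0.05, seed=seed)
            )
            got = cs.order_series(recs)
            true_rank = {v: i for i, v in enumerate(true_order)}
            tau = kendalltau(
                [true_rank[v] for v in got], range(len(got))
            ).statistic
            taus.append(tau)
        assert float(np.mean(taus)) >= 0.9


class TestDiapophysisBounds:
    def test_dilophosaurus(self):
        assert cs.diapophysis_bounds("Dilophosaurus") == 17

    def test_spinosaurus_range(self):
        assert cs.diapophysis_bounds("Spinosaurus") == (16, 19)

    def test_gorgosaurus(self):
        assert cs.diapophysis_bounds("Gorgosaurus") == 12

    def test_others(self):
        assert cs.diapophysis_bounds("Concavenator") == (19, 20)
        assert cs.diapophysis_bounds("Majungasaurus") == 25
        assert cs.diapophysis_bounds("Tyrannosaurus") == 17

    def test_unknown_taxon(self):
        with pytest.raises(KeyError):
            cs.diapophysis_bounds("Allosaurus")


def _template(n=12, decay=0.85, bound=None):
    return cs.TemplateProfile(
        taxon="T",
        positions=tuple(range(1, n + 1)),
        pct_asi=tuple(100.0 * decay**i for i in range(n)),
        last_diapophysis=bound,
    )


class TestAssignPositions:
    def test_exact_match_lands_on_position(self):
        tmpl = _template()
        pct = 100.0 * 0.85**4  # template position 5
        asg = cs.assign_positions([("v", pct)], tmpl)
        assert asg.positions["v"] == 5

    def test_strictly_increasing(self):
        tmpl = _template()
        prof = [("a", 100.0), ("b", 99.0), ("c", 98.5)]
        asg = cs.assign_positions(prof, tmpl)
        pos = [asg.positions[v] for v, _ in prof]
        assert pos == sorted(set(pos))

    def test_diapophysis_constraint_enforced(self):
        tmpl = _template(bound=(3, 3))
        prof = [("a", 100.0), ("b", 40.0)]
        asg = cs.assign_positions(prof, tmpl, {"a": True, "b": True})
        assert asg.positions["b"] <= 3

    def test_infeasible_raises(self):
        tmpl = _template(bound=(2, 2))
        prof = [("a", 100.0), ("b", 90.0), ("c", 80.0)]
        with pytest.raises(ValueError, match="diapophysis"):
            cs.assign_positions(prof, tmpl, {v: True for v in "abc"})

    def test_too_many_vertebrae(self):
        tmpl = _template(n=3)
        prof = [(f"v{i}", 100.0 - i) for i in range(5)]
        with pytest.raises(ValueError):
            cs.assign_positions(prof, tmpl)

    def test_three_vertebrae_brute_force(self):
        tmpl = _template(n=10)
        prof = [("a", 100.0), ("b", 71.0), ("c", 52.0)]
        asg = cs.assign_positions(prof, tmpl)
        slots = tmpl.asi_positions()
        cost, positions = oracles.best_monotone_alignment(
            [p for _, p in prof], slots, [False] * 3, None
        )
        assert tuple(asg.positions[v] for v, _ in prof) == positions

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_oracle(self, seed):
        """Equals exhaustive minimal-|delta| monotone alignment on all
        instances with <= 8 vertebrae and <= 12 template positions."""
        rng = random.Random(seed)
        n_slots = rng.randint(4, 12)
        k = rng.randint(1, min(8, n_slots))
        decay = rng.uniform(0.7, 0.95)
        tmpl = cs.TemplateProfile(
            taxon="T",
            positions=tuple(range(1, n_slots + 1)),
            pct_asi=tuple(100.0 * decay**i for i in range(n_slots)),
            last_diapophysis=(n_slots // 2, n_slots // 2) if rng.random() < 0.5 else None,
        )
        pcts = sorted(
            (rng.uniform(5, 100) for _ in range(k)), reverse=True
        )
        flags = [rng.random() < 0.3 for _ in range(k)]
        prof = [(f"v{i}", p) for i, p in enumerate(pcts)]
        bound = (
            tmpl.last_diapophysis[1] if tmpl.last_diapophysis else None
        )
        exp_cost, exp_pos = oracles.best_monotone_alignment(
            pcts, tmpl.asi_positions(), flags, bound
        )
        flag_map = {f"v{i}": f for i, f in enumerate(flags)}
        if exp_cost is None:
            with pytest.raises(ValueError):
                cs.assign_positions(prof, tmpl, flag_map)
            return
        asg = cs.assign_positions(prof, tmpl, flag_map)
        got_cost = sum(
            abs(p - dict(tmpl.asi_positions())[asg.positions[v]])
            for v, p in prof
        )
        assert got_cost == pytest.approx(exp_cost)
        pos = [asg.positions[v] for v, _ in prof]
        assert pos == sorted(set(pos))
        for v, f in flag_map.items():
            if f and bound is not None:
                assert asg.positions[v] <= bound
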