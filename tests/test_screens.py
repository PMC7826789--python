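import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinoset import (
    AutophagyHit,
    FluxSeries,
    GrowthRecord,
    KinosetError,
    ToxicityRecord,
    autophagy_categorize,
    autophagy_hit_call,
    autophagy_normalize,
    classify_growth_response,
    classify_toxicity,
    compute_gr,
    kinase_toxicity_aggregate,
)
from kinoset.screens import APPEARANCE_STATES, PROLIFERATION_STATES, TOX_TIERS


def rec(x0, x, x_ctrl, line="L1", cmpd="c"):
    return GrowthRecord(cell_line=line, compound=cmpd, x0=x0, x=x, x_ctrl=x_ctrl)


class TestGR:
    def test_vehicle_like_growth_is_one(self):
        assert compute_gr(rec(100, 400, 400)).gr == pytest.approx(1.0)

    def test_stasis_is_zero(self):
        assert compute_gr(rec(100, 100, 400)).gr == pytest.approx(0.0)

    def test_closed_form_midpoint(self):
        # doubling under treatment vs quadrupling in control: 2^(1/2) - 1
        assert compute_gr(rec(100, 200, 400)).gr == pytest.approx(
            2 ** 0.5 - 1, abs=1e-12
        )

    def test_net_loss_is_negative(self):
        assert compute_gr(rec(100, 50, 400)).gr < 0

    def test_nongrowing_control_is_error(self):
        with pytest.raises(KinosetError, match="did not grow"):
            compute_gr(rec(100, 80, 100))

    @given(
        x0=st.floats(10, 1e4), factor=st.floats(0.1, 10),
        growth=st.floats(1.1, 8), treat=st.floats(0.2, 8),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_monotonicity(self, x0, factor, growth, treat):
        g1 = compute_gr(rec(x0, treat * x0, growth * x0)).gr
        g2 = compute_gr(rec(factor * x0, factor * treat * x0,
                            factor * growth * x0)).gr
        assert g1 == pytest.approx(g2, rel=1e-9)
        # strictly increasing in the treated endpoint count
        g_hi = compute_gr(rec(x0, treat * x0 * 1.01, growth * x0)).gr
        assert g_hi > g1


class TestGrowthClassification:
    def test_all_vehicle_like_inactive(self):
        grs = {f"L{i}": 1.0 for i in range(17)}
        assert classify_growth_response(grs) == "inactive"

    def test_uniform_halving_is_broad(self):
        grs = {f"L{i}": 0.5 for i in range(17)}
        assert classify_growth_response(grs) == "broad"

    def test_single_sensitive_line_is_line_dependent(self):
        grs = {f"L{i}": 1.0 for i in range(16)}
        grs["L16"] = 0.2
        assert classify_growth_response(grs) == "line_dependent"

    def test_mild_effect_defaults_to_inactive(self):
        # below the inactive band on some lines but never a 30% decrease
        grs = {"L1": 0.85, "L2": 0.8, "L3": 1.0}
        assert classify_growth_response(grs) == "inactive"

    def test_broad_fraction_boundary(self):
        # 12/16 = 0.75 meets the default "most lines" bar; 11/16 does not
        grs = {f"L{i}": (0.5 if i < 12 else 1.0) for i in range(16)}
        assert classify_growth_response(grs) == "broad"
        grs = {f"L{i}": (0.5 if i < 11 else 1.0) for i in range(16)}
        assert classify_growth_response(grs) == "line_dependent"

    def test_needs_at_least_two_lines(self):
        with pytest.raises(KinosetError):
            classify_growth_response({"L1": 0.5})
        with pytest.raises(KinosetError):
            classify_growth_response({})


class TestToxicity:
    @pytest.mark.parametrize(
        "hf, tier",
        [
            (0.85, "nontoxic"),
            (0.80, "nontoxic"),  # boundary belongs to the healthier side
            (0.79, "reduced"),
            (0.50, "reduced"),
            (0.49, "severe"),
            (1 / 3, "severe"),
            (0.30, "extreme"),  # > 67% decrease in cell count
            (0.0, "extreme"),
            (1.4, "nontoxic"),
        ],
    )
    def test_tier_mapping(self, hf, tier):
        assert classify_toxicity(hf) == tier

    @given(st.floats(min_value=0, max_value=5, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_tiers_partition_halfline(self, hf):
        assert classify_toxicity(hf) in TOX_TIERS

    def test_record_input(self):
        assert classify_toxicity(ToxicityRecord("c", 0.3)) == "extreme"


class TestKinaseToxicityAggregate:
    def test_mean_over_inhibitors(self):
        coverage = {"c1": ["K"], "c2": ["K"]}
        chem = {"c1": "X", "c2": "Y"}
        tox = [ToxicityRecord("c1", 0.2), ToxicityRecord("c2", 0.4)]
        veh = [1.0, 0.98, 1.02, 0.99]
        df = kinase_toxicity_aggregate(coverage, chem, tox, veh)
        assert df.loc[df.kinase == "K", "mean_healthy_fraction"].iloc[0] == (
            pytest.approx(0.3)
        )

    def test_single_chemotype_kinase_excluded(self):
        coverage = {"c1": ["K"], "c2": ["K"]}
        chem = {"c1": "X", "c2": "X"}  # two inhibitors, one chemotype
        tox = [ToxicityRecord("c1", 0.2), ToxicityRecord("c2", 0.4)]
        df = kinase_toxicity_aggregate(coverage, chem, tox, [1.0, 1.0, 0.99])
        assert df.empty

    def test_planted_toxic_kinase_flagged_null_not(self, rng):
        """Simulation with known ground truth: toxic kinase flagged, null not."""
        veh = rng.normal(1.0, 0.03, size=12).clip(min=0)
        coverage, chem, tox = {}, {}, []
        # toxic kinase: 4 inhibitors, healthy fraction ~0.3
        for i in range(4):
            cid = f"tox{i}"
            coverage[cid] = ["TOXK"]
            chem[cid] = f"B{i % 2}"
            for r in range(3):
                tox.append(ToxicityRecord(
                    cid, float(np.clip(rng.normal(0.3, 0.03), 0, None)),
                    replicate=r + 1))
        # null kinase: 4 inhibitors, vehicle-like
        for i in range(4):
            cid = f"nul{i}"
            coverage[cid] = ["NULK"]
            chem[cid] = f"B{i % 2}"
            for r in range(3):
                tox.append(ToxicityRecord(
                    cid, float(np.clip(rng.normal(1.0, 0.03), 0, None)),
                    replicate=r + 1))
        df = kinase_toxicity_aggregate(coverage, chem, tox, veh).set_index("kinase")
        assert bool(df.loc["TOXK", "flagged"])
        assert not bool(df.loc["NULK", "flagged"])

    def test_missing_toxicity_record_is_error(self):
        with pytest.raises(KinosetError, match="no toxicity records"):
            kinase_toxicity_aggregate(
                {"c1": ["K"], "c2": ["K"]}, {"c1": "X", "c2": "Y"},
                [ToxicityRecord("c1", 0.5)], [1.0, 1.0],
            )


def flux(pct, times=None):
    """Build a FluxSeries whose normalized percent-flux equals `pct`."""
    pct = np.asarray(pct, dtype=float)
    n = pct.size
    t = times if times is not None else 2.0 * np.arange(1, n + 1)
    veh = np.ones(n)
    ctl = np.full(n, 0.4)
    ratio = veh + pct / 100.0 * (ctl - veh)
    return FluxSeries("c", t, ratio, veh, ctl)


class TestFluxNormalize:
    def test_vehicle_like_is_zero(self):
        s = flux(np.zeros(8))
        assert autophagy_normalize(s) == pytest.approx(np.zeros(8))

    def test_control_like_is_hundred(self):
        s = flux(np.full(8, 100.0))
        assert autophagy_normalize(s) == pytest.approx(np.full(8, 100.0))

    def test_midpoint_is_fifty(self):
        s = flux(np.full(8, 50.0))
        assert autophagy_normalize(s) == pytest.approx(np.full(8, 50.0))

    def test_degenerate_denominator_names_time(self):
        s = flux(np.zeros(6))
        s.control = s.vehicle.copy()
        with pytest.raises(KinosetError, match="t = 2.0 h"):
            autophagy_normalize(s)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(KinosetError, match="unequal lengths"):
            FluxSeries("c", [1, 2], [0.5, 0.5], [1.0], [0.4, 0.4])


def oracle_hit(pct, threshold=20.0, min_run=5):
    """Brute-force window scan over all windows of length min_run."""
    pct = np.asarray(pct, float)
    for i in range(len(pct) - min_run + 1):
        if np.all(np.abs(pct[i:i + min_run]) > threshold):
            return True
    return False


class TestFluxHitCall:
    def test_five_consecutive_points_is_hit(self):
        pct = np.zeros(12)
        pct[3:8] = 25.0
        hit = autophagy_hit_call(pct)
        assert hit.is_hit and hit.direction == "induced" and hit.run == (3, 5)

    def test_four_points_is_not_a_hit(self):
        pct = np.zeros(12)
        pct[3:7] = 25.0
        assert not autophagy_hit_call(pct).is_hit

    def test_reduced_direction_from_negative_run(self):
        pct = np.zeros(12)
        pct[0:6] = -30.0
        hit = autophagy_hit_call(pct)
        assert hit.direction == "reduced" and hit.run == (0, 6)

    def test_threshold_is_strict(self):
        pct = np.full(8, 20.0)  # exactly at threshold, never above
        assert not autophagy_hit_call(pct).is_hit

    def test_short_series_is_error(self):
        with pytest.raises(KinosetError, match="shorter than min_run"):
            autophagy_hit_call(np.zeros(4), min_run=5)

    def test_matches_window_scan_oracle_on_random_series(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 30))
            pct = rng.normal(0, 18, size=n)
            got = autophagy_hit_call(pct)
            assert got.is_hit == oracle_hit(pct)
            if got.is_hit:
                i, ln = got.run
                assert ln >= 5
                assert np.all(np.abs(pct[i:i + ln]) > 20.0)

    def test_monotone_in_threshold_and_run(self, rng):
        for _ in range(50):
            pct = rng.normal(0, 20, size=20)
            base = autophagy_hit_call(pct, threshold=20, min_run=5).is_hit
            stricter_t = autophagy_hit_call(pct, threshold=30, min_run=5).is_hit
            stricter_r = autophagy_hit_call(pct, threshold=20, min_run=7).is_hit
            if not base:
                assert not stricter_t and not stricter_r


class TestFluxCategories:
    def test_default_category_examples(self):
        hit = AutophagyHit("c", True, direction="induced", run=(0, 5))
        assert autophagy_categorize(hit, "unchanged", "normal") == 1
        hit_r = AutophagyHit("c", True, direction="reduced", run=(0, 5))
        assert autophagy_categorize(hit_r, "reduced", "normal") == 6
        assert autophagy_categorize(hit_r, "reduced", "normal") != 1

    def test_grid_reaches_all_six_categories_exclusively(self):
        seen = {}
        for direction, prolif, appear in itertools.product(
            ("induced", "reduced"), PROLIFERATION_STATES, APPEARANCE_STATES
        ):
            hit = AutophagyHit("c", True, direction=direction, run=(0, 5))
            cat = autophagy_categorize(hit, prolif, appear)
            assert 1 <= cat <= 6
            seen.setdefault(cat, set()).add((direction, prolif, appear))
        assert set(seen) == {1, 2, 3, 4, 5, 6}
        # each input cell maps to exactly one category
        all_inputs = [c for cells in seen.values() for c in cells]
        assert len(all_inputs) == len(set(all_inputs))

    def test_non_hit_cannot_be_categorized(self):
        with pytest.raises(KinosetError, match="non-hit"):
            autophagy_categorize(AutophagyHit("c", False), "unchanged", "normal")
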