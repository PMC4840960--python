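"""Hit-calling cascade: thresholds, nesting, oracle equivalence, confirmation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from myeliscreen import HitCriteria, call_primary_hits, confirm_hits, refine_hits
from myeliscreen.screening import STAGE_RANK, hit_summary
from myeliscreen.synthdata import confirmation_tables, serial_dilution, simulate_dose_response

from conftest import brute_force_stages, random_score_frame


def _row(cid, conc, pct, fm, pct_olig2=150.0, ratio=5.0):
    return {
        "compound_id": cid,
        "concentration": conc,
        "pct_dapt_myelination": pct,
        "fiber_mbp_score": fm,
        "pct_dapt_olig2": pct_olig2,
        "dapi_olig2_ratio": ratio,
        "n_fields_used": 8,
    }


class TestPrimaryCriteria:
    def test_pct_dapt_criterion(self):
        df = pd.DataFrame([_row("A", 5.0, 60.0, 1.0), _row("A", 1.0, 10.0, 1.0)])
        (call,) = call_primary_hits(df)
        assert call.stage == "primary" and call.best_concentration == 5.0
        assert call.criterion_results["pct_dapt@5"]["pass"]

    def test_fiber_mbp_criterion_alone(self):
        """The quotient criterion can fire on its own (OR combination)."""
        df = pd.DataFrame([_row("A", 5.0, 40.0, 1.6)])
        (call,) = call_primary_hits(df)
        assert call.stage == "primary"
        assert call.criterion_results["fiber_mbp@5"]["pass"]
        assert not call.criterion_results["pct_dapt@5"]["pass"]

    def test_both_below_threshold_not_hit(self):
        df = pd.DataFrame([_row("A", 5.0, 49.0, 1.4)])
        (call,) = call_primary_hits(df)
        assert call.stage == "not_hit"

    def test_exact_threshold_ties_fail(self):
        df = pd.DataFrame([_row("A", 5.0, 50.0, 1.5)])
        (call,) = call_primary_hits(df)
        assert call.stage == "not_hit"

    def test_either_concentration_suffices(self):
        df = pd.DataFrame([_row("A", 5.0, 20.0, 1.0), _row("A", 1.0, 70.0, 1.0)])
        (call,) = call_primary_hits(df)
        assert call.stage == "primary" and call.best_concentration == 1.0


class TestRefinement:
    def test_healthy_primary_is_refined_pending_morphology(self):
        df = pd.DataFrame([_row("A", 5.0, 80.0, 1.2, pct_olig2=80.0, ratio=10.0)])
        calls = refine_hits(call_primary_hits(df), df)
        assert calls[0].stage == "flagged_morphology"
        assert calls[0].rank == 2

    def test_antiproliferative_compound_excluded(self):
        """Huge per-OL score with DAPI/Olig2 = 50: the methotrexate signature."""
        df = pd.DataFrame([_row("A", 5.0, 300.0, 2.0, pct_olig2=30.0, ratio=50.0)])
        calls = refine_hits(call_primary_hits(df), df)
        assert calls[0].stage == "primary"
        assert any("anti-proliferative" in r for r in calls[0].reasons)

    def test_olig2_depletion_excluded(self):
        df = pd.DataFrame([_row("A", 5.0, 80.0, 1.2, pct_olig2=20.0, ratio=10.0)])
        calls = refine_hits(call_primary_hits(df), df)
        assert calls[0].stage == "primary"
        assert any("depletion" in r for r in calls[0].reasons)

    def test_operator_review_resolves_morphology_flag(self):
        df = pd.DataFrame(
            [_row("A", 5.0, 80.0, 1.2), _row("B", 5.0, 80.0, 1.2)]
        )
        calls = refine_hits(call_primary_hits(df), df,
                            operator_review={"A": True, "B": False})
        by_id = {c.compound_id: c for c in calls}
        assert by_id["A"].stage == "refined"
        assert by_id["B"].stage == "primary"
        assert any("visual morphology" in r for r in by_id["B"].reasons)


class TestCascadeProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_stages_strictly_nested(self, seed):
        df = random_score_frame(np.random.default_rng(seed), n_compounds=12)
        primary = call_primary_hits(df)
        refined = refine_hits(primary, df)
        counts = hit_summary(refined)
        assert counts["confirmed"] <= counts["refined"] <= counts["primary"] <= counts["n_compounds"]
        for call in refined:
            if call.rank >= 2:
                assert call.criterion_results["olig2_pct_dapt"]["pass"]

    def test_matches_brute_force_oracle_on_random_tables(self):
        """Cascade output equals a naive row-filter oracle on 1000 random tables."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            df = random_score_frame(rng, n_compounds=6)
            calls = refine_hits(call_primary_hits(df), df)
            got = {c.compound_id: min(c.rank, 2) for c in calls}
            expected = {
                cid: {"not_hit": 0, "primary": 1, "refined": 2}[s]
                for cid, s in brute_force_stages(df, HitCriteria()).items()
            }
            assert got == expected

    @given(bump=st.floats(0.0, 100.0))
    def test_raising_pct_threshold_never_adds_hits(self, bump):
        df = random_score_frame(np.random.default_rng(7), n_compounds=10)
        base = {c.compound_id for c in call_primary_hits(df, HitCriteria()) if c.rank >= 1}
        stricter = {
            c.compound_id
            for c in call_primary_hits(df, HitCriteria(pct_dapt_min=50.0 + bump))
            if c.rank >= 1
        }
        assert stricter <= base


class TestConfirmation:
    def _refined_call(self, cid="A"):
        df = pd.DataFrame([_row(cid, 5.0, 80.0, 1.2)])
        return refine_hits(call_primary_hits(df), df, operator_review={cid: True})

    def test_two_clean_curves_confirm(self):
        calls = self._refined_call()
        tables = [
            simulate_dose_response(0, 100, 0.5, 1.0, serial_dilution(10.0, 3.0, 8),
                                   4, 3.0, seed)
            for seed in (1, 2)
        ]
        out = confirm_hits(calls, {"A": tables})
        assert out[0].stage == "confirmed"
        assert out[0].mean_ec50_uM == pytest.approx(0.5, rel=0.25)

    def test_flat_curves_do_not_confirm(self):
        calls = self._refined_call()
        tables = [
            simulate_dose_response(0, 0, 1.0, 1.0, serial_dilution(10.0, 3.0, 8), 4, 5.0, s)
            for s in (3, 4)
        ]
        out = confirm_hits(calls, {"A": tables})
        assert out[0].stage != "confirmed"

    def test_missing_table_recorded(self):
        out = confirm_hits(self._refined_call(), {})
        assert out[0].stage != "confirmed"
        assert any("no dose-response data" in r for r in out[0].reasons)


class TestPlantedScreenRecovery:
    def test_all_planted_hits_confirmed_no_false_positives(self, library_screen):
        """727-compound simulated screen, 10 planted hits: 10/10 confirmed, 0 false."""
        spec, result = library_screen
        table = result.score_table
        calls = refine_hits(call_primary_hits(table), table)
        refined_ids = [c.compound_id for c in calls if c.rank >= 2]
        tables = confirmation_tables(spec, refined_ids, seed=7)
        calls = confirm_hits(calls, tables)
        confirmed = {c.compound_id for c in calls if c.stage == "confirmed"}
        planted = {h.compound_id for h in spec.planted_hits}
        assert confirmed == planted

    def test_confirmed_ec50s_track_planted_potency(self, library_screen):
        spec, result = library_screen
        table = result.score_table
        calls = refine_hits(call_primary_hits(table), table)
        refined_ids = [c.compound_id for c in calls if c.rank >= 2]
        calls = confirm_hits(calls, confirmation_tables(spec, refined_ids, seed=7))
        truth = {h.compound_id: h.ec50_uM for h in spec.planted_hits}
        rels = [
            abs(c.mean_ec50_uM - truth[c.compound_id]) / truth[c.compound_id]
            for c in calls
            if c.stage == "confirmed"
        ]
        assert float(np.median(rels)) <= 0.25
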