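"""Dose metrics: deposition fractions, enhancement arithmetic, ranking."""

import numpy as np
import pandas as pd
import pytest

from nasospray import geometry as geo
from nasospray.dosimetry import (DoseError, RegionalDoseReport,
                                 enhancement_factor, film_region_dose,
                                 initial_DF, relative_change, round_report,
                                 dose_response_sweep, select_optimal)
from nasospray.film import FilmState
from nasospray.spray import DropletSet, DEPOSITED, ESCAPED


def _droplets(n, weight, status):
    ds = DropletSet(position=np.zeros((n, 3)), velocity=np.zeros((n, 3)),
                    diameter=np.full(n, 60e-6), weight=np.full(n, weight))
    ds.status[:] = status
    return ds


class TestInitialDF:
    def test_everything_on_olfactory_gives_hundred(self, flat_patch):
        mesh = geo.unit_cube_mesh(region=geo.Region.OL)
        n, dose = 10, 0.1
        w = dose * 1e-6 / n
        rec = pd.DataFrame({"face_id": range(n), "volume_m3": [w] * n,
                            "region": ["OL"] * n})
        report = initial_DF(rec, _droplets(n, w, DEPOSITED), mesh, dose)
        assert report.df("OL") == pytest.approx(100.0)
        assert sum(v for k, v in report.df_pct.items() if k != "OL") == 0.0

    def test_half_escaped_halves_regional_sum(self, flat_patch):
        n, dose = 10, 0.2
        w = dose * 1e-6 / n
        rec = pd.DataFrame({"face_id": range(5), "volume_m3": [w] * 5,
                            "region": ["VEST"] * 5})
        ds = _droplets(n, w, DEPOSITED)
        ds.status[5:] = ESCAPED
        report = initial_DF(rec, ds, flat_patch, dose)
        assert report.total_deposited_pct() == pytest.approx(50.0)
        assert report.escaped_pct == pytest.approx(50.0)
        total = report.total_deposited_pct() + report.escaped_pct \
            + report.expired_pct
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_empty_records_give_all_zero(self, flat_patch):
        report = initial_DF(pd.DataFrame(), _droplets(3, 1e-9, ESCAPED),
                            flat_patch, 0.1)
        assert all(v == 0.0 for v in report.df_pct.values())


class TestFilmRegionDose:
    def test_single_region_holds_everything(self, flat_patch):
        state = FilmState(h=np.full(flat_patch.n_faces, 1e-4),
                          V=np.zeros((flat_patch.n_faces, 3)))
        vol_ml = state.total_volume(flat_patch) * 1e6
        fr = film_region_dose(state, flat_patch, vol_ml)
        assert fr["VEST"] == pytest.approx(100.0)
        assert sum(fr.values()) == pytest.approx(100.0)

    def test_dry_state_all_zero(self, flat_patch):
        fr = film_region_dose(FilmState.zero(flat_patch), flat_patch, 0.1)
        assert all(v == 0.0 for v in fr.values())

    def test_fractions_stable_under_mesh_refinement(self):
        # same analytic film h(y) evaluated on two mesh resolutions: every
        # region's share of the total moves by under 2 points of dose
        out = []
        for edge in (2.0e-3, 1.2e-3):
            params = geo.NasalGeometryParams(target_edge_length=edge)
            mesh = geo.build_idealized_nasal_passage(params)
            y = mesh.face_centroid[:, 1]
            h = 1e-4 * np.exp(-((y - 0.04) / 0.02) ** 2)
            state = FilmState(h=h, V=np.zeros((mesh.n_faces, 3)))
            vol_ml = state.total_volume(mesh) * 1e6
            out.append(film_region_dose(state, mesh, vol_ml))
        for region in out[0]:
            assert out[0][region] == pytest.approx(out[1][region], abs=2.0)


class TestEnhancementArithmetic:
    def test_published_baseline_fold_change(self):
        # post-migration 1.31% over initial 0.15% ≈ 8.73-fold
        assert round_report(enhancement_factor(1.31, 0.15), "factor") == 8.73

    def test_identity_fold(self):
        assert enhancement_factor(4.2, 4.2) == 1.0

    def test_zero_baseline_flagged_undefined(self):
        assert np.isnan(enhancement_factor(5.0, 0.0))

    def test_negative_baseline_rejected(self):
        with pytest.raises(DoseError):
            enhancement_factor(1.0, -0.1)

    def test_published_vestibule_reduction(self):
        # optimized vs baseline post-migration vestibule: 3.74% -> 0.60%
        assert round_report(relative_change(0.60, 3.74), "change") == -84

    def test_no_change_is_zero_percent(self):
        assert relative_change(7.7, 7.7) == 0.0

    def test_doubling_is_plus_hundred(self):
        assert relative_change(2.0, 1.0) == 100.0

    def test_zero_before_rejected(self):
        with pytest.raises(DoseError):
            relative_change(1.0, 0.0)

    def test_factor_and_change_are_consistent(self):
        # fold f corresponds to (f-1)*100 percent change
        for post, pre in [(6.23, 0.67), (1.31, 0.15), (3.0, 2.0)]:
            f = enhancement_factor(post, pre)
            assert relative_change(post, pre) == pytest.approx((f - 1) * 100)


class TestSweepAndRanking:
    @staticmethod
    def _report(ol, sm, vest):
        df = {r.value: 0.0 for r in geo.Region}
        df.update({"OL": ol, "SM": sm, "VEST": vest})
        return RegionalDoseReport(df_pct=df, escaped_pct=0.0, expired_pct=0.0,
                                  applied_dose_ml=0.1)

    def test_single_dose_sweep_matches_direct_run(self):
        calls = []

        def fake_pipeline(dose):
            calls.append(dose)
            return self._report(1.0, 2.0, 3.0), {r.value: 0.0
                                                 for r in geo.Region}

        table = dose_response_sweep([0.1], fake_pipeline)
        assert calls == [0.1]
        row = table[(table.region == "OL") & (table.phase == "initial")]
        assert row["df_pct"].iloc[0] == 1.0
        assert table.attrs["overflow_onset_ml"] is None

    def test_overflow_onset_detection(self):
        def fake_pipeline(dose):
            film = {r.value: 0.0 for r in geo.Region}
            film["OL"] = 1.0 if dose >= 0.4 else 0.1
            return self._report(0.1, 0.0, 0.0), film

        table = dose_response_sweep([0.1, 0.2, 0.4, 0.8], fake_pipeline)
        assert table.attrs["overflow_onset_ml"] == 0.4

    def test_ranking_prefers_higher_olfactory(self):
        ranked = select_optimal({"a": self._report(1.0, 0, 0),
                                 "b": self._report(2.0, 0, 0)})
        assert ranked[0] == "b"

    def test_ranking_breaks_ol_tie_on_superior_meatus(self):
        ranked = select_optimal({"a": self._report(1.0, 5.0, 0),
                                 "b": self._report(1.0, 2.0, 0)})
        assert ranked[0] == "a"

    def test_ranking_breaks_remaining_tie_on_low_vestibule(self):
        ranked = select_optimal({"a": self._report(1.0, 1.0, 9.0),
                                 "b": self._report(1.0, 1.0, 2.0)})
        assert ranked[0] == "b"

    def test_ranking_independent_of_input_order(self):
        reports = {"a": self._report(1.0, 1.0, 9.0),
                   "b": self._report(1.0, 2.0, 2.0),
                   "c": self._report(3.0, 0.0, 5.0)}
        r1 = select_optimal(reports)
        r2 = select_optimal(dict(reversed(list(reports.items()))))
        assert r1 == r2 == ["c", "b", "a"]

    def test_empty_candidates_rejected(self):
        with pytest.raises(DoseError):
            select_optimal({})
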