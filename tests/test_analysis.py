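"""Cohort tables, indicator correlations, parameter grids, trend summaries."""

import numpy as np
import pandas as pd
import pytest

from rbcredox import (
    GridSpec,
    evaluate_cohort,
    evaluate_subject,
    indicator_correlations,
    trend_summary,
    vmax_km_grid,
)
from rbcredox.analysis import CohortError, grid_to_long_frame
from rbcredox.cli import load_indicator_reference
from rbcredox.network import PatientKinetics

RNG = np.random.default_rng(8)


def two_pass_pearson(x, y):
    """Textbook two-pass Pearson correlation, independent of the package."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def synthetic_table(n=40, recovery=None, initial=None, amount=None, vmax=None, km=None):
    table = pd.DataFrame({
        "label": [f"s{i}" for i in range(n)],
        "vmax": vmax if vmax is not None else RNG.uniform(1, 64, n),
        "km_g6p": km if km is not None else RNG.uniform(7, 152, n),
        "initial_ratio": initial if initial is not None else RNG.uniform(100, 700, n),
        "min_ratio": RNG.uniform(50, 100, n),
        "amount_of_change": amount if amount is not None else RNG.uniform(0, 1, n),
        "recovery_time": recovery if recovery is not None else RNG.uniform(100, 1500, n),
        "error": "",
    })
    return table


class TestPublishedCorrelations:
    """The two printed coefficients recomputed from the packaged table."""

    def test_initial_vs_amount_over_finite_recovery_subjects(self):
        table = load_indicator_reference()
        corr = indicator_correlations(table, "drop", 1800.0)
        assert corr.attrs["n_used"] == 10  # patients 2-10 + control
        assert round(corr.loc["initial_ratio", "amount_of_change"], 2) == 0.99

    def test_recovery_vs_amount_all_subjects_capped(self):
        table = load_indicator_reference()
        corr = indicator_correlations(table, "window_cap", 1800.0)
        assert corr.attrs["n_used"] == 11
        assert round(abs(corr.loc["recovery_time", "amount_of_change"]), 2) == 0.91

    def test_fixture_tampering_detected(self):
        table = load_indicator_reference()
        table.loc[table["label"] == "Patient 5", "amount_of_change"] = 0.02
        corr = indicator_correlations(table, "drop", 1800.0)
        assert round(corr.loc["initial_ratio", "amount_of_change"], 2) != 0.99


class TestIndicatorCorrelations:
    def test_matches_two_pass_oracle_on_random_tables(self):
        for _ in range(10):
            table = synthetic_table()
            corr = indicator_correlations(table, "drop", 1800.0)
            for a, b in [("initial_ratio", "recovery_time"),
                         ("initial_ratio", "amount_of_change"),
                         ("recovery_time", "amount_of_change")]:
                want = two_pass_pearson(table[a], table[b])
                assert corr.loc[a, b] == pytest.approx(want, abs=1e-12)

    def test_exactly_collinear_table(self):
        initial = np.linspace(100, 700, 20)
        table = synthetic_table(20, initial=initial, amount=0.001 * initial)
        corr = indicator_correlations(table, "drop", 1800.0)
        assert corr.loc["initial_ratio", "amount_of_change"] == pytest.approx(1.0)

    def test_zero_variance_flagged_as_nan(self):
        table = synthetic_table(10, amount=np.full(10, 0.25))
        corr = indicator_correlations(table, "drop", 1800.0)
        assert np.isnan(corr.loc["initial_ratio", "amount_of_change"])

    def test_policies_differ_only_on_sentinel_rows(self):
        rec = RNG.uniform(100, 1500, 30)
        rec[[3, 17]] = np.inf
        table = synthetic_table(30, recovery=rec)
        capped = indicator_correlations(table, "window_cap", 1800.0)
        dropped = indicator_correlations(table, "drop", 1800.0)
        assert capped.attrs["n_used"] == 30
        assert dropped.attrs["n_used"] == 28
        # with no sentinel rows, the policies coincide exactly
        finite = synthetic_table(30, recovery=RNG.uniform(100, 1500, 30))
        a = indicator_correlations(finite, "window_cap", 1800.0)
        b = indicator_correlations(finite, "drop", 1800.0)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            indicator_correlations(synthetic_table(2), "drop", 1800.0)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            indicator_correlations(synthetic_table(), "ignore", 1800.0)


class TestEvaluateCohort:
    def test_failures_isolated_per_row(self, model, cfg, monkeypatch, reference_patients):
        import rbcredox.analysis as analysis

        real = analysis.evaluate_subject

        def flaky(kin, model=None, cfg=None):
            if kin.label == "Patient 5":
                raise RuntimeError("synthetic failure")
            return real(kin, model, cfg)

        monkeypatch.setattr(analysis, "evaluate_subject", flaky)
        table = analysis.evaluate_cohort(reference_patients[:6], model, cfg)
        assert len(table) == 6
        failed = table[table["error"] != ""]
        assert list(failed["label"]) == ["Patient 5"]
        assert np.isfinite(table[table["error"] == ""]["initial_ratio"]).all()

    def test_all_failed_raises(self, model, cfg, monkeypatch, reference_patients):
        import rbcredox.analysis as analysis

        monkeypatch.setattr(analysis, "evaluate_subject",
                            lambda *a, **k: (_ for _ in ()).throw(RuntimeError("boom")))
        with pytest.raises(CohortError):
            analysis.evaluate_cohort(reference_patients[:3], model, cfg)

    def test_empty_cohort_rejected(self, model, cfg):
        with pytest.raises(ValueError):
            evaluate_cohort([], model, cfg)


class TestGrid:
    def test_toy_grid_equals_batched_singles(self, model, cfg):
        grid = GridSpec(vmax_values=(4.0, 32.0), km_values=(40.0, 120.0))
        surf = vmax_km_grid(grid, model, cfg)
        assert surf["initial_ratio"].shape == (2, 2)
        for i, vmax in enumerate(grid.vmax_values):
            for j, km in enumerate(grid.km_values):
                kin = PatientKinetics(vmax, km, grid.km_nadp, grid.ki_nadph,
                                      grid.ki_atp, grid.ki_23bpg, label="cell")
                _, _, ind = evaluate_subject(kin, model, cfg)
                assert surf["initial_ratio"][i, j] == pytest.approx(ind.initial_ratio, rel=1e-9)
                assert surf["recovery_time"][i, j] == pytest.approx(ind.recovery_time, rel=1e-9)

    def test_zero_axis_values_floored_and_recorded(self, model, cfg):
        grid = GridSpec(vmax_values=(0.0, 8.0), km_values=(67.0,))
        surf = vmax_km_grid(grid, model, cfg)
        assert (0.0, 67.0) in surf["substituted_cells"]
        assert np.isfinite(surf["initial_ratio"][1, 0])

    def test_long_frame_layout(self, model, cfg):
        grid = GridSpec(vmax_values=(8.0, 32.0), km_values=(40.0,))
        surf = vmax_km_grid(grid, model, cfg)
        long = grid_to_long_frame(surf)
        assert len(long) == 2 * 1 * 3
        assert set(long["indicator"]) == {"initial_ratio", "recovery_time", "amount_of_change"}

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(vmax_values=())
        with pytest.raises(ValueError):
            GridSpec(km_nadp=-1.0)


class TestTrendSummary:
    def test_degenerate_cut_gives_whole_cohort_stratum(self):
        table = synthetic_table(25)
        summary = trend_summary(table, vmax_cut=1e9, km_cut=1e9)
        assert summary.loc[summary["stratum"] == "low_vmax/low_km", "n"].item() == 25
        assert (summary["n"].sum()) == 25

    def test_constructed_vmax_effect_dominates_vmax_cut(self):
        # indicator depends on vmax only: stratifying on vmax must separate
        # medians far more than stratifying on km
        n = 200
        vmax = RNG.uniform(1, 64, n)
        km = RNG.uniform(7, 152, n)
        rec = np.where(vmax < 32.0, 1000.0, 200.0)  # pure f(vmax), aligned with the cut
        table = synthetic_table(n, recovery=rec, vmax=vmax, km=km)
        s = trend_summary(table, vmax_cut=32.0, km_cut=80.0).set_index("stratum")
        med = s["recovery_time_median"]
        across_vmax = abs(med["low_vmax/low_km"] - med["high_vmax/low_km"])
        across_km = abs(med["low_vmax/low_km"] - med["low_vmax/high_km"])
        assert across_vmax == 800.0
        assert across_km == 0.0

    def test_empty_stratum_reported_not_error(self):
        table = synthetic_table(10, vmax=np.full(10, 50.0), km=np.full(10, 100.0))
        summary = trend_summary(table, vmax_cut=32.0, km_cut=80.0)
        empties = summary[summary["n"] == 0]
        assert len(empties) == 3
        assert np.isnan(empties["recovery_time_median"]).all()

    def test_abnormal_recovery_flagged(self):
        rec = np.full(12, 300.0)
        rec[:2] = np.inf
        table = synthetic_table(12, recovery=rec)
        summary = trend_summary(table, vmax_cut=1e9, km_cut=1e9, window=1800.0)
        assert summary["n_abnormal_recovery"].sum() == 2
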