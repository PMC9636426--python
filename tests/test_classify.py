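"""Behaviour classification: LOWESS curve, inflection, quadratic, deviation scores."""

import numpy as np
import pandas as pd
import pytest

from burststage import bursts as bm
from burststage import classify as cl
from burststage import simulate as sim
from burststage.errors import (
    CannotCalibrateError,
    InsufficientDataError,
    NoInflectionError,
    SingularFitError,
)

REGIME_TO_CLASS = {
    "basal": cl.CLASS_BASAL,
    "high_on_high_amp": cl.CLASS_HIGH_ON,
    "low_on_high_amp": cl.CLASS_LOW_ON,
}


def naive_rlowess(x, y, xeval, frac, iters=3):
    """Independent robust LOWESS: local linear, tricube weights, bisquare
    reweighting -- a deliberately slow reference implementation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(2, int(np.ceil(frac * n)))
    delta = np.ones(n)
    for it in range(iters + 1):
        fitted = np.empty(n)
        for i in range(n):
            d = np.abs(x - x[i])
            cutoff = np.sort(d)[k - 1]
            w = np.clip(1 - (d / max(cutoff, 1e-12)) ** 3, 0, 1) ** 3 * delta
            W = w.sum()
            xm = (w * x).sum() / W
            ym = (w * y).sum() / W
            sxx = (w * (x - xm) ** 2).sum()
            slope = 0.0 if sxx <= 1e-12 * max(1.0, xm**2) else (w * (x - xm) * (y - ym)).sum() / sxx
            fitted[i] = ym + slope * (x[i] - xm)
        resid = y - fitted
        s = np.median(np.abs(resid))
        delta = np.clip(1 - (resid / max(6 * s, 1e-12)) ** 2, 0, 1) ** 2
    return np.interp(xeval, x, fitted)


class TestDurationOutputCurve:
    def test_reproduces_exact_linear_relation(self, rng):
        d = np.sort(rng.uniform(0, 60, 80))
        curve = cl.fit_duration_output_curve(d, 2 * d, span=0.3)
        interior = (curve.grid > 5) & (curve.grid < 55)
        assert np.allclose(curve.smoothed_output[interior], 2 * curve.grid[interior], atol=1e-6)

    def test_single_outlier_barely_moves_interior_curve(self, rng):
        d = np.sort(rng.uniform(0, 60, 100))
        y = 100 * d + rng.normal(0, 50, 100)
        base = cl.fit_duration_output_curve(d, y, span=0.4)
        y2 = y.copy()
        y2[50] += 50_000.0  # one extreme outlier
        cont = cl.fit_duration_output_curve(d, y2, span=0.4)
        interior = (base.grid > 10) & (base.grid < 50)
        rel = np.abs(cont.smoothed_output[interior] - base.smoothed_output[interior]) / np.abs(
            base.smoothed_output[interior]
        )
        assert rel.max() < 0.05

    def test_agrees_with_naive_reference_implementation(self, rng):
        d = np.sort(rng.uniform(0, 60, 60))
        y = 50 * d + rng.normal(0, 200, 60)
        curve = cl.fit_duration_output_curve(d, y, span=0.5)
        ref = naive_rlowess(d, y, curve.grid, frac=0.5, iters=3)
        scale = np.abs(ref).max()
        assert np.max(np.abs(curve.smoothed_output - ref)) < 1e-6 * scale

    def test_too_few_cells_rejected(self):
        with pytest.raises(InsufficientDataError):
            cl.fit_duration_output_curve(np.arange(5.0), np.arange(5.0))


class TestFindInflection:
    def make_knee(self, d0=40.0, s1=1.0, s2=4.0):
        grid = np.linspace(0, 60, 121)
        out = np.where(grid <= d0, s1 * grid, s1 * d0 + s2 * (grid - d0))
        return cl.DurationOutputCurve(grid=grid, smoothed_output=out, span=0.3)

    def test_constructed_knee_located_within_grid_step(self):
        curve = self.make_knee(d0=40.0)
        infl, frac = cl.find_inflection(curve, window_min=60.0)
        step = curve.grid[1] - curve.grid[0]
        # light smoothing of the gradient spreads the step over a few points
        assert abs(infl - 40.0) <= 3 * step
        assert np.isclose(frac, infl / 60.0)

    def test_exactly_linear_curve_has_no_inflection(self):
        grid = np.linspace(0, 60, 50)
        curve = cl.DurationOutputCurve(grid=grid, smoothed_output=5 * grid + 3, span=0.3)
        with pytest.raises(NoInflectionError):
            cl.find_inflection(curve)

    def test_too_few_grid_points_rejected(self):
        curve = cl.DurationOutputCurve(grid=np.arange(5.0), smoothed_output=np.arange(5.0))
        with pytest.raises(ValueError):
            cl.find_inflection(curve)


class TestSplitHighLowOn:
    def test_extremes(self):
        assert cl.split_high_low_on([60.0], 50.0)[0] == cl.HIGH_ON
        assert cl.split_high_low_on([0.0], 50.0)[0] == cl.LOW_ON

    def test_tie_goes_low(self):
        assert cl.split_high_low_on([50.0], 50.0)[0] == cl.LOW_ON

    def test_counts_match_brute_force(self, rng):
        d = rng.uniform(0, 60, 500)
        labels = cl.split_high_low_on(d, 33.0)
        assert (labels == cl.HIGH_ON).sum() == int((d > 33.0).sum())


class TestBasalQuadratic:
    def test_exact_square_through_origin(self):
        d = np.linspace(1, 10, 30)
        q = cl.fit_basal_quadratic(d, d**2)
        assert np.allclose(q.coefficients, (1.0, 0.0, 0.0), atol=1e-9)

    def test_line_through_origin_recovered_with_zero_curvature(self):
        d = np.linspace(1, 10, 30)
        q = cl.fit_basal_quadratic(d, 4 * d)
        assert abs(q.coefficients[0]) < 1e-9
        assert np.isclose(q.coefficients[1], 4.0)

    def test_unconstrained_fit_matches_normal_equations_oracle(self, rng):
        d = rng.uniform(0, 50, 40)
        y = rng.normal(2 * d**2 - 3 * d + 7, 5)
        q = cl.fit_basal_quadratic(d, y, through_origin=False)
        X = np.column_stack([d**2, d, np.ones_like(d)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(q.coefficients, beta, rtol=1e-8)

    def test_degenerate_design_rejected(self):
        with pytest.raises(SingularFitError):
            cl.fit_basal_quadratic([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestClassify:
    def test_cell_on_basal_expectation_scores_zero_and_stays_basal(self):
        quad = cl.BasalQuadratic(coefficients=(0.5, 10.0, 0.0), fit_domain=(0, 60))
        d = np.array([10.0, 30.0])
        scores = cl.deviation_scores(d, quad(d), quad)
        assert np.allclose(scores, 0.0)
        table, thr = cl.classify_scores(
            np.array([0.0, 0.0, 500.0]), np.array([cl.LOW_ON] * 3), np.array([10.0, 30.0, 20.0])
        )
        assert table["final_class"].iloc[0] == cl.CLASS_BASAL

    def test_zero_duration_cells_score_zero_and_are_basal(self):
        quad = cl.BasalQuadratic(coefficients=(0.0, 100.0, 0.0), fit_domain=(0, 60))
        scores = cl.deviation_scores(np.array([0.0]), np.array([0.0]), quad)
        assert scores[0] == 0.0

    def test_output_shift_translates_scores_exactly(self, rng):
        d = rng.uniform(1, 60, 50)
        o = rng.uniform(0, 5000, 50)
        quad = cl.BasalQuadratic(coefficients=(1.0, 50.0, 0.0), fit_domain=(0, 60))
        k = 37.0
        a = cl.deviation_scores(d, o, quad)
        b = cl.deviation_scores(d, o + k * d, quad)
        assert np.allclose(b - a, k)

    def test_no_low_on_cells_cannot_calibrate(self):
        with pytest.raises(CannotCalibrateError):
            cl.classify_scores(np.array([1.0]), np.array([cl.HIGH_ON]), np.array([50.0]))

    def test_regime_recovery_on_well_separated_population(self, separated_population):
        cells = separated_population
        summ = bm.summaries_frame([c.trace for c in cells], 350.0)
        res = cl.classify_cells(summ[["cell_id", "on_duration", "output"]], window_min=60.0)
        true = np.array([REGIME_TO_CLASS[c.true_regime] for c in cells])
        assert (res.table["final_class"].to_numpy() == true).mean() >= 0.90

    def test_classification_invariant_to_cell_order(self, separated_population):
        cells = separated_population[:300]
        summ = bm.summaries_frame([c.trace for c in cells], 350.0)
        df = summ[["cell_id", "on_duration", "output"]]
        a = cl.classify_cells(df, window_min=60.0)
        perm = df.sample(frac=1.0, random_state=1)
        b = cl.classify_cells(perm, window_min=60.0)
        merged = a.table.set_index("cell_id")["final_class"]
        merged_b = b.table.set_index("cell_id")["final_class"]
        assert (merged.sort_index() == merged_b.sort_index()).all()
        assert np.isclose(a.amplitude_threshold, b.amplitude_threshold)

    def test_raising_threshold_never_promotes_to_high_amplitude(self, rng):
        scores = rng.normal(0, 50, 200)
        groups = np.where(rng.random(200) < 0.7, cl.LOW_ON, cl.HIGH_ON)
        d = rng.uniform(1, 60, 200)
        table, thr = cl.classify_scores(scores, groups, d)
        high_at_thr = set(np.where(table["amplitude_group"] == cl.HIGH_AMPLITUDE)[0])
        for bump in [10, 100]:
            amp2 = np.where(scores > thr + bump, cl.HIGH_AMPLITUDE, cl.BASAL)
            high2 = set(np.where(amp2 == cl.HIGH_AMPLITUDE)[0])
            assert high2 <= high_at_thr

    def test_basal_only_population_scores_centred_near_zero(self):
        profiles = []
        from dataclasses import replace

        for p in sim.well_separated_profiles():
            profiles.append(replace(p, regime_weights=(1.0, 0.0, 0.0)))
        cells = sim.simulate_population(profiles, n_cells_per_stage=80, seed=4)
        summ = bm.summaries_frame([c.trace for c in cells], 350.0)
        res = cl.classify_cells(summ[["cell_id", "on_duration", "output"]], window_min=60.0)
        low = res.table.loc[res.table["on_group"] == cl.LOW_ON, "deviation_score"]
        assert abs(low.median()) < 0.1 * low.std()


class TestStageProportions:
    def test_all_basal_rows(self):
        stages = np.array(["DS1"] * 4 + ["DS2"] * 3)
        classes = np.array([cl.CLASS_BASAL] * 7)
        out = cl.stage_proportions(stages, classes)
        assert (out[cl.CLASS_BASAL] == 1.0).all()
        assert (out[[cl.CLASS_HIGH_ON, cl.CLASS_LOW_ON]] == 0.0).all().all()

    def test_rows_sum_to_one(self, rng):
        stages = rng.choice(["DS1", "DS2", "DS3"], 300)
        classes = rng.choice(list(cl.CLASS_LABELS), 300)
        out = cl.stage_proportions(stages, classes)
        assert np.allclose(out[list(cl.CLASS_LABELS)].sum(axis=1), 1.0, atol=1e-12)

    def test_empty_stage_flagged_undefined(self):
        out = cl.stage_proportions(np.array(["DS1"]), np.array([cl.CLASS_BASAL]),
                                   stage_labels=["DS1", "DS2"])
        assert bool(out.loc[out["stage"] == "DS2", "undefined"].iloc[0])
        assert np.isnan(out.loc[out["stage"] == "DS2", cl.CLASS_BASAL].iloc[0])

    def test_default_calibration_orders_classes_across_stages(self, large_population):
        cells = large_population
        summ = bm.summaries_frame([c.trace for c in cells], 350.0)
        df = summ[["cell_id", "on_duration", "output"]].copy()
        df["stage"] = [c.stage for c in cells]
        res = cl.classify_cells(df, window_min=60.0)
        prop = cl.stage_proportions(
            res.table["stage"].to_numpy(), res.table["final_class"].to_numpy()
        ).set_index("stage")
        # sporadic high-amplitude bursting enriched at the flanks, continuous
        # high-amplitude bursting at the mid stages, as designed
        flank_low = prop.loc[["DS1", "DS2", "DS5"], cl.CLASS_LOW_ON].mean()
        mid_low = prop.loc[["DS3", "DS4"], cl.CLASS_LOW_ON].mean()
        assert flank_low > mid_low
        mid_high = prop.loc[["DS3", "DS4"], cl.CLASS_HIGH_ON].mean()
        other_high = prop.loc[["DS1", "DS2", "DS5", "DS6"], cl.CLASS_HIGH_ON].mean()
        assert mid_high > other_high


class TestInflectionStability:
    def test_reported_across_spans(self, separated_population):
        cells = separated_population
        summ = bm.summaries_frame([c.trace for c in cells], 350.0)
        out = cl.inflection_stability(summ, spans=(0.2, 0.3, 0.4), window_min=60.0)
        assert list(out["span"]) == [0.2, 0.3, 0.4]
        ok = out.dropna(subset=["inflection_duration"])
        assert len(ok) >= 2
        # every detected knee sits in the near-continuously-active region
        assert (ok["inflection_fraction"] > 0.6).all()
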