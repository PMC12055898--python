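"""Design-of-experiments machinery: designs, ANOVA, surfaces, calibration."""

import numpy as np
import pandas as pd
import pytest

from osteofrac.doe import (
    FactorSpec,
    anova_tss,
    box_behnken,
    calibrate,
    fit_response_surface,
    run_design,
)


def factors(k, half=0.2):
    names = ["Gc_mat", "Gc_cem", "Gc_ost", "E_cem", "E_mat", "E_ost", "extra"]
    bases = [0.35, 0.1, 0.5, 15000.0, 15000.0, 13500.0, 1.0]
    return [FactorSpec(n, b, half) for n, b in zip(names[:k], bases[:k])]


class TestBoxBehnken:
    @pytest.mark.parametrize(
        "k,n_center,rows",
        [(3, 1, 13), (4, 3, 27), (5, 2, 42), (6, 6, 54), (7, 1, 57)],
    )
    def test_row_counts(self, k, n_center, rows):
        assert len(box_behnken(factors(k), n_center)) == rows

    def test_three_factor_rows_have_two_active(self):
        d = box_behnken(factors(3), 1)
        edge = d.coded.iloc[:-1]
        assert ((edge != 0).sum(axis=1) == 2).all()
        assert (d.coded.iloc[-1] == 0).all()

    def test_six_factor_rows_have_three_active(self):
        d = box_behnken(factors(6), 6)
        edge = d.coded.iloc[:-6]
        assert ((edge != 0).sum(axis=1) == 3).all()

    def test_codes_are_three_level(self):
        d = box_behnken(factors(4), 2)
        assert set(np.unique(d.coded.to_numpy())) <= {-1, 0, 1}

    def test_decoding(self):
        d = box_behnken(factors(4, half=0.5), 1)
        dec = d.decoded()
        assert dec["Gc_mat"].max() == pytest.approx(0.35 * 1.5)
        assert dec["Gc_mat"].min() == pytest.approx(0.35 * 0.5)

    def test_unsupported_factor_count(self):
        with pytest.raises(ValueError):
            box_behnken(factors(3)[:2])


class TestRunDesign:
    def test_single_run_table(self):
        d = box_behnken(factors(3), 1)
        d = type(d)(factors=d.factors, coded=d.coded.iloc[:1], run_ids=["r0"])
        out = run_design(d, lambda p: {"y": p["Gc_mat"]})
        assert len(out) == 1 and out.loc[0, "y"] == pytest.approx(0.28)

    def test_failed_runs_flagged_not_dropped(self):
        d = box_behnken(factors(3), 1)

        def evaluate(p):
            if p["Gc_mat"] < 0.35:
                raise RuntimeError("boom")
            return {"y": 1.0}

        out = run_design(d, evaluate)
        assert len(out) == len(d)
        assert out["failed"].sum() > 0

    def test_cache_resumes_identically(self, tmp_path):
        d = box_behnken(factors(3), 1)
        calls = []

        def evaluate(p):
            calls.append(1)
            return {"y": sum(p.values())}

        out1 = run_design(d, evaluate, cache_dir=tmp_path)
        n_calls = len(calls)
        out2 = run_design(d, evaluate, cache_dir=tmp_path)
        assert len(calls) == n_calls  # cached, no re-evaluation
        pd.testing.assert_frame_equal(out1, out2)

    def test_all_failed_raises(self):
        d = box_behnken(factors(3), 1)
        with pytest.raises(RuntimeError):
            run_design(d, lambda p: (_ for _ in ()).throw(RuntimeError()))


class TestAnova:
    def test_pure_signal_assigns_all_variance(self):
        d = box_behnken(factors(6), 6)
        y = 3.0 * d.coded["Gc_mat"].to_numpy() + 1.0
        tab = anova_tss(d, y)
        assert tab.share("Gc_mat") > 0.999
        assert tab.table.loc["Gc_mat", "p"] < 1e-10
        assert tab.table.loc["Gc_mat", "significant"]

    def test_white_noise_spreads_thin(self):
        d = box_behnken(factors(6), 6)
        rng = np.random.default_rng(0)
        shares = []
        pvals = []
        for _ in range(50):
            tab = anova_tss(d, rng.normal(size=len(d)))
            shares.append(tab.table["TSS"].max())
            pvals.extend(tab.table["p"].tolist())
        assert np.mean(shares) < 0.25
        # p-values roughly uniform under the null
        assert 0.3 < np.mean(np.array(pvals) < 0.5) < 0.7

    def test_type_two_equals_type_one_on_orthogonal_design(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        d = box_behnken(factors(6), 6)
        rng = np.random.default_rng(1)
        y = d.coded.to_numpy() @ np.arange(1.0, 7.0) + rng.normal(0, 0.3, len(d))
        data = d.coded.copy()
        data.columns = [f"f_{c}" for c in data.columns]
        data["y"] = y
        model = smf.ols("y ~ " + " + ".join(data.columns[:-1]), data=data).fit()
        a1 = anova_lm(model, typ=1)["sum_sq"].iloc[:-1].to_numpy()
        a2 = anova_lm(model, typ=2)["sum_sq"].iloc[:-1].to_numpy()
        assert np.allclose(a1, a2, rtol=1e-8)

    def test_constant_outcome_flagged_degenerate(self):
        d = box_behnken(factors(6), 6)
        tab = anova_tss(d, np.full(len(d), 2.5))
        assert tab.degenerate
        assert (tab.table["TSS"] == 0.0).all()


class TestResponseSurface:
    def test_exact_linear_function_recovered(self):
        d = box_behnken(factors(4, half=0.5), 3)
        out = run_design(
            d, lambda p: {"y": 2.0 + 3.0 * p["Gc_mat"] - 1.5 * p["Gc_ost"]}
        )
        surf = fit_response_surface(d, out, ["y"], ["Gc_mat", "Gc_ost"])["y"]
        pred = surf.predict({"Gc_mat": 0.4, "Gc_ost": 0.6})
        assert pred == pytest.approx(2.0 + 3.0 * 0.4 - 1.5 * 0.6, rel=1e-10)

    def test_center_prediction_is_intercept(self):
        d = box_behnken(factors(4, half=0.5), 3)
        out = run_design(d, lambda p: {"y": p["Gc_mat"] * 2.0})
        surf = fit_response_surface(d, out, ["y"], ["Gc_mat", "Gc_cem"])["y"]
        centre = {"Gc_mat": 0.35, "Gc_cem": 0.1}
        assert surf.predict(centre) == pytest.approx(
            float(surf.result.params["Intercept"]), rel=1e-12
        )

    def test_confidence_interval_coverage(self):
        # 500 replications of noisy linear data: the 95% CI covers the true
        # slope about 95% of the time
        d = box_behnken(factors(4, half=0.5), 3)
        rng = np.random.default_rng(2024)
        true_slope = 1.7  # on coded units
        hits = 0
        n_rep = 500
        codes = d.coded["Gc_mat"].to_numpy()
        for _ in range(n_rep):
            y = 5.0 + true_slope * codes + rng.normal(0.0, 1.0, len(d))
            out = pd.DataFrame({"y": y, "failed": False})
            surf = fit_response_surface(d, out, ["y"], ["Gc_mat", "Gc_cem"])["y"]
            lo, hi = surf.conf_int().loc["f_Gc_mat"]
            if lo <= true_slope <= hi:
                hits += 1
        assert hits / n_rep == pytest.approx(0.95, abs=0.03)

    def test_unknown_factor_rejected(self):
        d = box_behnken(factors(4), 3)
        out = run_design(d, lambda p: {"y": 1.0})
        with pytest.raises(ValueError):
            fit_response_surface(d, out, ["y"], ["nope"])


class TestCalibration:
    def _surfaces(self):
        d = box_behnken(factors(4, half=0.5), 3)
        out = run_design(
            d,
            lambda p: {
                "peak_force": 10 + 8 * p["Gc_mat"] + 20 * p["Gc_cem"],
                "tortuosity": 1.3 - 2.0 * p["Gc_cem"],
                "J_Ic": 0.2 + 0.5 * p["Gc_mat"],
            },
        )
        return d, fit_response_surface(
            d, out, ["peak_force", "tortuosity", "J_Ic"], ["Gc_mat", "Gc_cem"]
        )

    def test_exact_recovery_at_grid_node(self):
        _, surfaces = self._surfaces()
        truth = {"Gc_mat": 0.425, "Gc_cem": 0.075}
        targets = {
            "peak_force": 10 + 8 * truth["Gc_mat"] + 20 * truth["Gc_cem"],
            "tortuosity": 1.3 - 2.0 * truth["Gc_cem"],
            "J_Ic": 0.2 + 0.5 * truth["Gc_mat"],
        }
        res = calibrate(surfaces, targets, grid_step=0.005)
        assert res.best["Gc_mat"] == pytest.approx(truth["Gc_mat"], abs=1e-12)
        assert res.best["Gc_cem"] == pytest.approx(truth["Gc_cem"], abs=1e-12)
        assert res.cost == pytest.approx(0.0, abs=1e-10)

    def test_cost_invariant_to_outcome_rescaling(self):
        _, surfaces = self._surfaces()
        targets = {"peak_force": 14.0, "tortuosity": 1.1, "J_Ic": 0.38}
        res1 = calibrate(surfaces, targets, grid_step=0.01)
        # rescale one outcome and its target by the same factor: the
        # normalised cost is unchanged
        import copy

        surfaces2 = dict(surfaces)
        scaled = copy.deepcopy(surfaces["peak_force"])
        scaled.result.params[:] = scaled.result.params[:] * 7.0
        surfaces2["peak_force"] = scaled
        targets2 = dict(targets, peak_force=targets["peak_force"] * 7.0)
        res2 = calibrate(surfaces2, targets2, grid_step=0.01)
        assert res2.cost == pytest.approx(res1.cost, rel=1e-9)
        assert res2.best == res1.best

    def test_ties_broken_towards_baseline(self):
        d = box_behnken(factors(4, half=0.5), 3)
        out = run_design(d, lambda p: {"y": 1.0})  # flat surface: all tie
        surf = fit_response_surface(d, out, ["y"], ["Gc_mat", "Gc_cem"])
        res = calibrate(surf, {"y": 1.0}, grid_step=0.01)
        assert res.best["Gc_mat"] == pytest.approx(0.35, abs=0.011)
        assert res.best["Gc_cem"] == pytest.approx(0.1, abs=0.011)

    def test_nonpositive_target_rejected(self):
        _, surfaces = self._surfaces()
        with pytest.raises(ValueError):
            calibrate(surfaces, {"peak_force": 0.0}, grid_step=0.01)
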