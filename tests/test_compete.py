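import numpy as np
import pandas as pd
import pytest

from clsmeta.compete import (
    design_from_frame,
    fit_survival_model,
    relative_lifespan,
    subtract_background,
    survival_confidence_interval,
)
from clsmeta.synthetic import (
    default_competition_design,
    simulate_competition_plate,
    simulate_plate_truth,
)


@pytest.fixture
def design():
    return default_competition_design(n_mutants=6)


def simulate(design, seed, noise_sd):
    truth = simulate_plate_truth(design, seed=seed)
    df = simulate_competition_plate(design, truth, noise_sd=noise_sd, seed=seed + 1)
    return truth, df


class TestRelativeLifespan:
    @pytest.mark.parametrize("s,l", [(0.0, 1.0), (0.2, 1.2), (-0.5, 0.5)])
    def test_formula(self, s, l):
        assert relative_lifespan(s) == l

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            relative_lifespan(float("inf"))


class TestSubtractBackground:
    def test_zero_background_leaves_measurements(self, design):
        truth, df = simulate(design, 3, 0.0)
        df0 = simulate_competition_plate(
            design, truth, noise_sd=0.0, seed=4, background=0.0
        )
        corrected = subtract_background(df0, design, floor=0.0)
        comp = df0["strain"].isin(["WT_RFP", "WT_CFP"]) == False  # noqa: E712
        assert np.allclose(corrected.loc[comp, "rfp"], df0.loc[comp, "rfp"])

    def test_constant_background_removed_exactly(self):
        design = default_competition_design(n_mutants=1)
        rows = []
        for well, strain, rfp, cfp in [
            ("P1-M01", "mut01", 350.0, 250.0),
            ("P1-W01", "WT/WT", 300.0, 300.0),
            ("P1-W02", "WT/WT", 300.0, 300.0),
            ("P1-RRFP", "WT_RFP", 900.0, 100.0),
            ("P1-RCFP", "WT_CFP", 100.0, 900.0),
        ]:
            for day in (1.0, 2.0):
                for hour in (2.0, 4.0):
                    rows.append(
                        dict(plate="P1", well=well, strain=strain,
                             is_wt_wt=strain == "WT/WT", aging_day=day,
                             outgrowth_hour=hour, od=0.5, rfp=rfp, cfp=cfp)
                    )
        df = pd.DataFrame(rows)
        corrected = subtract_background(df, design_from_frame(df))
        mut = corrected[corrected["well"] == "P1-M01"]
        assert np.allclose(mut["rfp"], 250.0)  # 350 - 100 from the CFP-only well
        assert np.allclose(mut["cfp"], 150.0)

    def test_corrected_below_floor_is_clipped(self, design):
        truth, df = simulate(design, 5, 0.0)
        df.loc[df["strain"] == "mut01", "rfp"] = 10.0  # below the 50-unit background
        corrected = subtract_background(df, design)
        assert (corrected.loc[corrected["strain"] == "mut01", "rfp"] == 1.0).all()

    def test_missing_reference_timepoint_falls_back_with_warning(self, design):
        truth, df = simulate(design, 6, 0.0)
        drop = (df["strain"] == "WT_CFP") & (df["aging_day"] == 1.0)
        df = df[~drop]
        with pytest.warns(UserWarning, match="nearest"):
            subtract_background(df, design)


class TestFitSurvivalModel:
    def test_noise_free_recovery(self, design):
        truth, df = simulate(design, 10, 0.0)
        fit = fit_survival_model(subtract_background(df, design), design)
        for e in fit.estimates:
            a, s, g = truth["P1"]["wells"][e.well]
            assert e.A == pytest.approx(a, abs=1e-9)
            assert e.S == pytest.approx(s, abs=1e-9)
            assert e.G == pytest.approx(g, abs=1e-9)
            assert e.L == 1.0 + e.S
        for point, c in truth["P1"]["C"].items():
            assert fit.plate_effects["P1"][point] == pytest.approx(c, abs=1e-9)

    def test_tiny_design_matches_hand_built_normal_equations(self):
        """2 wells (1 mutant, 1 WT/WT), 2 days, 2 hours: closed-form OLS."""
        design = default_competition_design(n_mutants=1)
        rng = np.random.default_rng(0)
        days, times = (1.0, 2.0), (2.0, 4.0)
        truth = simulate_plate_truth(design, seed=2, days=days, times=times)
        df = simulate_competition_plate(
            design, truth, noise_sd=0.05, days=days, times=times, seed=3
        )
        corrected = subtract_background(df, design)
        fit = fit_survival_model(corrected, design, od_min=0.0, od_max=2.0)
        # hand-built design: rows ordered as the fit orders them
        sub = corrected[corrected["strain"].isin(["mut01", "WT/WT"])].copy()
        sub = sub[(sub["od"] >= 0.0) & (sub["od"] <= 2.0)]
        wells = sorted(sub["well"].unique())
        points = sorted(set(zip(sub["aging_day"], sub["outgrowth_hour"])))
        X, y = [], []
        for row in sub.itertuples(index=False):
            y.append(np.log(row.rfp / row.cfp))
            a_cols = [1.0 if row.well == w else 0.0 for w in wells]
            is_mut = row.well.endswith("M01")
            sg = [row.aging_day if is_mut else 0.0, row.outgrowth_hour if is_mut else 0.0]
            k = points.index((row.aging_day, row.outgrowth_hour))
            c_cols = [0.0] * (len(points) - 1)
            if k < len(points) - 1:
                c_cols[k] = 1.0
            else:
                c_cols = [-1.0] * (len(points) - 1)
            X.append(a_cols + sg + c_cols)
        X, y = np.array(X), np.array(y)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        mut = next(e for e in fit.estimates if e.strain == "mut01")
        assert mut.A == pytest.approx(beta[wells.index("P1-M01")], abs=1e-12)
        assert mut.S == pytest.approx(beta[len(wells)], abs=1e-12)
        assert mut.G == pytest.approx(beta[len(wells) + 1], abs=1e-12)

    def test_wt_wt_constrained_to_zero(self, design):
        truth, df = simulate(design, 11, 0.1)
        fit = fit_survival_model(subtract_background(df, design), design)
        for e in fit.estimates:
            if e.is_wt_wt:
                assert e.S == 0.0 and e.G == 0.0 and e.L == 1.0

    def test_invariance_to_constant_signal_rescaling(self, design):
        """Multiplying both channels by a plate-wide constant shifts nothing:
        the log-ratio is unchanged, so all estimates are identical."""
        truth, df = simulate(design, 12, 0.05)
        corrected = subtract_background(df, design)
        scaled = corrected.copy()
        scaled[["rfp", "cfp"]] *= 7.5
        f1 = fit_survival_model(corrected, design)
        f2 = fit_survival_model(scaled, design)
        for e1, e2 in zip(f1.estimates, f2.estimates):
            assert e1.S == pytest.approx(e2.S, abs=1e-12)
            assert e1.G == pytest.approx(e2.G, abs=1e-12)

    def test_constant_rfp_rescaling_absorbed_by_A_and_C(self, design):
        """A constant factor on one channel only shifts every y by a
        constant, absorbed by the intercepts; S and G are untouched."""
        truth, df = simulate(design, 13, 0.05)
        corrected = subtract_background(df, design)
        shifted = corrected.copy()
        shifted["rfp"] *= np.e
        f1 = fit_survival_model(corrected, design)
        f2 = fit_survival_model(shifted, design)
        for e1, e2 in zip(f1.estimates, f2.estimates):
            assert e2.S == pytest.approx(e1.S, abs=1e-10)
            if not e1.is_wt_wt:
                assert e2.A == pytest.approx(e1.A + 1.0, abs=1e-10)

    def test_residual_sd_calibrated(self, design):
        truth, df = simulate(design, 14, 0.2)
        fit = fit_survival_model(subtract_background(df, design), design)
        assert fit.residual_sd["P1"] == pytest.approx(0.2, rel=0.10)

    def test_single_day_rejected(self, design):
        truth = simulate_plate_truth(design, seed=15, days=(1.0,))
        df = simulate_competition_plate(design, truth, days=(1.0,), seed=15)
        with pytest.raises(ValueError, match="aging days"):
            fit_survival_model(subtract_background(df, design), design)

    def test_ci_coverage_near_nominal(self, design):
        """95% CIs for S cover the planted truth at close-to-nominal rate."""
        cover = total = 0
        for rep in range(10):
            truth = simulate_plate_truth(design, seed=300 + rep)
            df = simulate_competition_plate(design, truth, noise_sd=0.1, seed=400 + rep)
            fit = fit_survival_model(subtract_background(df, design), design)
            for e in fit.estimates:
                if e.is_wt_wt:
                    continue
                lo, hi = survival_confidence_interval(e, fit.df_resid[e.plate])
                s_true = truth["P1"]["wells"][e.well][1]
                cover += lo <= s_true <= hi
                total += 1
        assert 0.88 <= cover / total <= 1.0
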