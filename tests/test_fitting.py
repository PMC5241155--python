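"""Tests for model fitting, exclusion rules, kinematics and sensitivity."""

import numpy as np
import pandas as pd
import pytest

from cveukit import (
    CompartmentLabelModel,
    ExclusionPolicy,
    FitScheme,
    ModelParams,
    boundary_sensitivity,
    derive_kinematics,
    exclude_diluted_points,
    fit_front_velocity,
    front_recovery_time,
    pre_shedding_solution,
)


def synthetic_counts(params: ModelParams, times) -> pd.DataFrame:
    sol = pre_shedding_solution(params, times)
    return pd.DataFrame(
        {"time_h": sol.t, "l_crypt_obs": sol.l_crypt, "l_villus_obs": sol.l_villus}
    )


class TestCompartmentFit:
    def test_noiseless_recovery_control_scheme(self):
        """Zero-noise inverse problem: exact recovery of (delta, t1, L_C0)."""
        truth = ModelParams(delta=0.0760, n_crypt=20, l_c0=3.1, l_v0=0.0, t1=12.0)
        counts = synthetic_counts(truth, np.linspace(0, 38, 9))
        res = CompartmentLabelModel(counts, 20, "control", exclusion=None).fit()
        assert res.params.delta == pytest.approx(0.0760, rel=1e-6)
        assert res.params.t1 == pytest.approx(12.0, rel=1e-5)
        assert res.params.l_c0 == pytest.approx(3.1, rel=1e-6)
        assert res.rmse < 1e-8

    def test_noiseless_recovery_arrest_scheme(self):
        """Arrest regime: t0 = t1 fixed, free (delta, L_C0, L_V0)."""
        truth = ModelParams(delta=0.0466, n_crypt=20, l_c0=9.0, l_v0=6.0,
                            t0=25.0, t1=25.0)
        counts = synthetic_counts(truth, np.linspace(25, 57, 8))
        res = CompartmentLabelModel(counts, 20, "arac_late", exclusion=None).fit()
        assert res.params.delta == pytest.approx(0.0466, rel=1e-6)
        assert res.params.l_c0 == pytest.approx(9.0, rel=1e-6)
        assert res.params.l_v0 == pytest.approx(6.0, rel=1e-5)

    def test_recovery_from_simulated_control_duodenum(self, control_duod_sim):
        """Full noise path at the calibrated study conditions: delta within
        15% of the generating rate."""
        from cveukit import compartment_series, profile_from_scores

        profs = [profile_from_scores(m) for m in control_duod_sim.matrices.values()]
        res = CompartmentLabelModel(compartment_series(profs, 20), 20, "control").fit()
        assert res.params.delta == pytest.approx(0.0760, rel=0.15)

    def test_reparameterization_invariance(self):
        """Scaling counts and the boundary by a common factor leaves the
        fitted specific rate unchanged."""
        truth = ModelParams(delta=0.09, n_crypt=20, l_c0=2.5, l_v0=0.0, t1=10.0)
        counts = synthetic_counts(truth, np.linspace(0, 30, 8))
        res1 = CompartmentLabelModel(counts, 20, "control", exclusion=None).fit()
        scaled = counts.copy()
        scaled[["l_crypt_obs", "l_villus_obs"]] *= 3.0
        res2 = CompartmentLabelModel(scaled, 60, "control", exclusion=None).fit()
        assert res2.params.delta == pytest.approx(res1.params.delta, rel=1e-6)

    def test_underdetermined_scheme_rejected(self):
        counts = pd.DataFrame(
            {"time_h": [0, 5, 10], "l_crypt_obs": [2, 3, 4], "l_villus_obs": [0, 0, 1]}
        )
        scheme = FitScheme("custom", fixed={"t0": 0.0}, free=("delta", "t1", "l_c0", "l_v0"))
        CompartmentLabelModel(counts, 20, scheme, exclusion=None)  # 6 points, 4 free: ok
        with pytest.raises(ValueError, match="3 time points"):
            CompartmentLabelModel(counts.iloc[:2], 20, "control", exclusion=None)

    def test_scheme_validation(self):
        with pytest.raises(ValueError, match="both fixed and free"):
            FitScheme("bad", fixed={"delta": 0.1}, free=("delta", "t1"))
        with pytest.raises(ValueError, match="unspecified"):
            FitScheme("bad", fixed={}, free=("delta",))
        with pytest.raises(ValueError, match="unknown scheme"):
            FitScheme.for_regime("contrl")

    def test_summary_lists_estimates(self):
        truth = ModelParams(delta=0.0760, n_crypt=20, l_c0=3.1, l_v0=0.0, t1=12.0)
        counts = synthetic_counts(truth, np.linspace(0, 38, 9))
        res = CompartmentLabelModel(counts, 20, "control", exclusion=None).fit()
        text = res.summary()
        for token in ("delta", "t1", "l_c0", "V_CV", "RMSE"):
            assert token in text


class TestExclusion:
    def test_increasing_series_keeps_everything(self):
        df = pd.DataFrame(
            {"time_h": np.arange(8.0), "l_crypt_obs": np.arange(1, 9.0),
             "l_villus_obs": np.arange(0, 16.0, 2)}
        )
        _, rep = exclude_diluted_points(df)
        assert rep.n_excluded == 0

    def test_crypt_decline_masks_both_compartments(self):
        """Dilution is a property of the sampling time: once crypt counts
        decline, villus points at those times are dropped too."""
        t = np.arange(0, 45, 5.0)
        lc = np.r_[np.linspace(5, 12, 5), [9, 7, 5, 3.5]]
        lv = np.linspace(0, 20, 9)
        df = pd.DataFrame({"time_h": t, "l_crypt_obs": lc, "l_villus_obs": lv})
        _, rep = exclude_diluted_points(df)
        assert len(rep.excluded_crypt_times) > 0
        assert rep.excluded_crypt_times == rep.excluded_villus_times

    def test_villus_plateau_detected(self):
        t = np.arange(0, 50, 5.0)
        lv = np.r_[np.linspace(0, 20, 6), [20.5, 20.2, 20.4, 20.3]]
        lc = np.linspace(5, 12, 10)
        df = pd.DataFrame({"time_h": t, "l_crypt_obs": lc, "l_villus_obs": lv})
        _, rep = exclude_diluted_points(df)
        assert len(rep.excluded_villus_times) >= 3
        assert len(rep.excluded_crypt_times) == 0

    def test_manual_override_removes_exactly_that_list(self):
        df = pd.DataFrame(
            {"time_h": [0.0, 5.0, 10.0, 15.0], "l_crypt_obs": [2, 4, 6, 8],
             "l_villus_obs": [0, 1, 2, 3]}
        )
        policy = ExclusionPolicy(manual_crypt=(5.0,), manual_villus=(10.0, 15.0))
        _, rep = exclude_diluted_points(df, policy)
        assert rep.excluded_crypt_times == (5.0,)
        assert rep.excluded_villus_times == (10.0, 15.0)

    def test_flags_simulated_dilution(self, control_duod_sim):
        """On calibrated simulated data the rule drops the late crypt points
        where detectable counts have fallen below the true label content."""
        from cveukit import compartment_series, profile_from_scores

        profs = [profile_from_scores(m) for m in control_duod_sim.matrices.values()]
        counts = compartment_series(profs, 20)
        _, rep = exclude_diluted_points(counts)
        truth = control_duod_sim.truth
        # true detectable/total divergence is strongest at the final times
        late = truth["detectable_crypt"] < 0.8 * truth["total_crypt"]
        assert set(truth.loc[late, "time_h"]) <= set(rep.excluded_crypt_times)


class TestFrontVelocity:
    def test_two_point_slope(self):
        track = pd.DataFrame({"time_h": [0, 10], "front_position_um": [100, 190]})
        fit = fit_front_velocity(track)
        assert fit.v_lf == pytest.approx(9.0)
        assert fit.intercept_k == pytest.approx(100.0)

    def test_constant_positions(self):
        track = pd.DataFrame({"time_h": [0, 5, 10], "front_position_um": [80, 80, 80]})
        assert fit_front_velocity(track).v_lf == pytest.approx(0.0)

    def test_matches_normal_equations(self):
        """OLS slope cross-checked against the closed form by hand."""
        t = np.array([0.0, 4.0, 9.0])
        y = np.array([50.0, 90.0, 120.0])
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        fit = fit_front_velocity(pd.DataFrame({"time_h": t, "front_position_um": y}))
        assert fit.v_lf == pytest.approx(slope, rel=1e-12)

    def test_noisy_slope_recovery(self):
        """Track at the control-ileum velocity: slope within 3 se of truth."""
        rng = np.random.default_rng(42)
        t = np.linspace(0, 44, 12)
        y = 5.96 * t + 100 + rng.normal(0, 20, t.size)
        fit = fit_front_velocity(pd.DataFrame({"time_h": t, "front_position_um": y}))
        assert abs(fit.v_lf - 5.96) < 3 * fit.se_slope

    def test_single_time_is_error(self):
        with pytest.raises(ValueError):
            fit_front_velocity(
                pd.DataFrame({"time_h": [3, 3], "front_position_um": [1, 2]})
            )


class TestKinematics:
    def test_boundary_velocity_control_ileum(self):
        """delta*N_C reproduces the reported boundary velocity to 3 s.f."""
        p = ModelParams(delta=0.0544, n_crypt=19, l_c0=2.0, l_v0=0.0, t1=15.0)
        kin = derive_kinematics(p, cveu_length_cells=61.5)
        assert round(kin.v_cv, 2) == 1.03

    @pytest.mark.parametrize(
        "delta,n_c,length,total",
        [(0.0760, 20, 99.7, 92.0), (0.0544, 19, 61.5, 95.0), (0.0547, 18, 98.8, 135.0)],
    )
    def test_total_transit_times(self, delta, n_c, length, total):
        """Crypt integral plus villus constant-velocity time reproduces the
        reported crypt-base-to-villus-tip transit totals."""
        p = ModelParams(delta=delta, n_crypt=n_c, l_c0=2.0, l_v0=0.0, t1=15.0)
        kin = derive_kinematics(p, cveu_length_cells=length)
        assert kin.total_transit_h == pytest.approx(total, abs=1.5)
        assert kin.total_transit_h == pytest.approx(
            kin.crypt_transit_h + kin.villus_transit_h
        )

    def test_velocity_profile_and_bounds(self):
        p = ModelParams(delta=0.1, n_crypt=20, l_c0=2.0, l_v0=0.0, t1=10.0)
        kin = derive_kinematics(p, cveu_length_cells=60)
        np.testing.assert_allclose(kin.velocity_at([1, 10, 20]), [0.1, 1.0, 2.0])
        with pytest.raises(ValueError):
            kin.velocity_at(0.5)
        with pytest.raises(ValueError):
            kin.velocity_at(21)

    def test_nonpositive_delta_has_no_transit_time(self):
        p = ModelParams(delta=-0.01, n_crypt=20, l_c0=5.0, l_v0=2.0, t0=15.0, t1=15.0)
        with pytest.raises(ValueError):
            derive_kinematics(p, cveu_length_cells=60)

    def test_phase2_villus_slope_equals_production_on_labeled_content(self):
        """Consistency of the kinematics with the solution: in the transfer
        phase the villus gains delta * L_C* cells/h."""
        p = ModelParams(delta=0.0760, n_crypt=20, l_c0=20.0, l_v0=0.0, t1=0.0)
        sol = pre_shedding_solution(p, [0.0, 10.0])
        slope = (sol.l_villus[1] - sol.l_villus[0]) / 10.0
        kin = derive_kinematics(p, cveu_length_cells=99.7)
        assert slope == pytest.approx(kin.v_cv, rel=1e-12)  # fully labeled crypt


class TestFrontRecovery:
    def test_reported_front_recovery_time(self):
        """Held at 178 um, resumed to 234 um at 6.09 um/h: 9.2 h."""
        assert round(front_recovery_time(178, 234, 6.09), 1) == 9.2

    def test_equal_positions(self):
        assert front_recovery_time(100, 100, 5.0) == 0.0

    def test_simple_arithmetic(self):
        assert front_recovery_time(0, 60.9, 6.09) == pytest.approx(10.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            front_recovery_time(100, 90, 5.0)
        with pytest.raises(ValueError):
            front_recovery_time(0, 10, 0.0)


class TestBoundarySensitivity:
    def test_single_candidate_equals_direct_fit(self):
        truth = ModelParams(delta=0.0760, n_crypt=20, l_c0=3.0, l_v0=0.0, t1=12.0)
        counts = synthetic_counts(truth, np.linspace(0, 38, 9))
        tab = boundary_sensitivity({20: counts}, "control", exclusion=None)
        direct = CompartmentLabelModel(counts, 20, "control", exclusion=None).fit()
        assert tab.loc[0, "delta"] == pytest.approx(direct.params.delta, rel=1e-9)

    def test_noiseless_truth_production_exact(self):
        truth = ModelParams(delta=0.0760, n_crypt=20, l_c0=3.0, l_v0=0.0, t1=12.0)
        counts = synthetic_counts(truth, np.linspace(0, 38, 9))
        tab = boundary_sensitivity({20: counts}, "control", exclusion=None)
        assert tab.loc[0, "production"] == pytest.approx(0.0760 * 20, rel=1e-6)

    def test_failures_do_not_abort_sweep(self):
        truth = ModelParams(delta=0.0760, n_crypt=20, l_c0=3.0, l_v0=0.0, t1=12.0)
        counts = synthetic_counts(truth, np.linspace(0, 38, 9))
        bad = counts.iloc[:2]  # too few points: this boundary must fail alone
        tab = boundary_sensitivity({18: bad, 20: counts}, "control", exclusion=None)
        assert not tab.loc[tab.boundary == 18, "converged"].item()
        assert tab.loc[tab.boundary == 20, "converged"].item()
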