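"""Non-compartmental analysis: lambda-z fitting, AUC rules, parameter
recovery from the simulator, outlier screening and cohort statistics."""

import numpy as np
import pytest

from albupet.nca import (
    NonEstimableError,
    compute_auc,
    drop_flagged,
    fit_lambda_z,
    nca,
    screen_outliers,
    summarize_cohort,
)
from albupet.simulate import PlasmaCurve, TwoCompartmentModel


def curve(times, conc, sid="s1"):
    return PlasmaCurve(sid, np.asarray(times, float), np.asarray(conc, float))


class TestLambdaZ:
    def test_exact_monoexponential_recovered_to_machine_precision(self):
        t = np.array([0.0, 10.0, 50.0, 120.0, 300.0, 700.0])
        lam_true = 0.004
        c = 200.0 * np.exp(-lam_true * t)
        lam, r2, n = fit_lambda_z(curve(t, c))
        assert lam == pytest.approx(lam_true, rel=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_biexponential_terminal_rate_matches_eigenvalue_oracle(self):
        """Sampled over >= 2 terminal half-lives, lambda_z approximates the
        slow eigenvalue of the generating model within 2%."""
        m = TwoCompartmentModel.from_nca_parameters(
            1e6, 9.7, 5434.0, t_half_fast=20.0, t_half_terminal=422.0
        )
        t = np.array([1, 3, 6, 8, 24, 48, 72, 120, 288, 456, 720, 1032], float)
        c = m.concentration(t)
        lam, _, _ = fit_lambda_z(curve(t, c))
        assert lam == pytest.approx(m.eigenvalues[1], rel=0.02)

    def test_two_points_non_estimable(self):
        with pytest.raises(NonEstimableError):
            fit_lambda_z(curve([0, 10, 20], [100, 90, 80]))  # only 2 post-tmax

    def test_rising_curve_non_estimable(self):
        with pytest.raises(NonEstimableError):
            fit_lambda_z(curve([0, 1, 2, 3, 4], [1, 2, 3, 4, 5]))


class TestAuc:
    def test_constant_curve(self):
        auc, aumc = compute_auc(curve([0.0, 10.0], [5.0, 5.0]))
        assert auc == pytest.approx(50.0)
        assert aumc == pytest.approx(5.0 * 10.0**2 / 2.0)

    def test_log_trapezoid_exact_on_exponential_decline(self):
        lam = 0.01
        t = np.array([0.0, 7.0, 31.0, 100.0, 250.0])
        c = 80.0 * np.exp(-lam * t)
        auc, aumc = compute_auc(curve(t, c))
        # analytic integrals over [0, 250]
        T = 250.0
        auc_true = 80.0 / lam * (1 - np.exp(-lam * T))
        aumc_true = 80.0 * (1 / lam**2 - np.exp(-lam * T) * (T / lam + 1 / lam**2))
        assert auc == pytest.approx(auc_true, rel=1e-12)
        assert aumc == pytest.approx(aumc_true, rel=1e-12)

    def test_random_positive_curve_matches_dense_quadrature(self, rng):
        t = np.sort(rng.uniform(0.0, 100.0, 12))
        t[0] = 0.0
        c = rng.uniform(1.0, 50.0, 12)
        auc, _ = compute_auc(curve(t, c))
        # oracle: numeric quadrature of the same interpolation rule on a
        # dense grid (log between decreasing samples, linear otherwise)
        total = 0.0
        for i in range(11):
            tg = np.linspace(t[i], t[i + 1], 4000)
            if c[i] > c[i + 1] > 0:
                k = np.log(c[i] / c[i + 1]) / (t[i + 1] - t[i])
                cg = c[i] * np.exp(-k * (tg - t[i]))
            else:
                cg = np.interp(tg, [t[i], t[i + 1]], [c[i], c[i + 1]])
            total += np.trapezoid(cg, tg)
        assert auc == pytest.approx(total, rel=1e-3)

    def test_negative_concentration_rejected(self):
        c = PlasmaCurve("s", [0.0, 1.0], [1.0, 0.0])
        c.concentrations = np.array([1.0, -1.0])  # bypass curve validation
        with pytest.raises(ValueError):
            compute_auc(c)


class TestNca:
    def test_table_level_consistency_clearance_from_auc(self):
        """CL = dose / AUC reproduces the cohort's printed min/max pairing:
        1 mg with AUC 81,900 -> 12.2 mL/h, with AUC 128,598 -> 7.8 mL/h."""
        assert 1e6 / 81900.0 == pytest.approx(12.2, abs=0.05)
        assert 1e6 / 128598.0 == pytest.approx(7.8, abs=0.05)

    def test_initial_volume_from_cmax(self):
        """dose / Cmax: 1 mg over 390 ng/mL gives ~2.56 L, the plasma volume."""
        assert 1e6 / 390.0 == pytest.approx(2564.0, abs=1.0)

    def test_internal_consistency_identities(self, config):
        from albupet.simulate import simulate_plasma

        res = nca(
            simulate_plasma(config),
            dose=config.dose_mass,
            infusion_duration=config.infusion_duration,
        )
        assert res.clearance * res.auc_0_inf == pytest.approx(config.dose_mass, rel=1e-12)
        assert res.vss == pytest.approx(res.clearance * res.mrt, rel=1e-12)
        assert res.half_life * res.lambda_z == pytest.approx(np.log(2.0), rel=1e-12)
        assert res.auc_0_inf >= res.auc_0_last > 0

    @pytest.mark.parametrize(
        "cl, vss, t_half",
        [(9.7, 5434.0, 422.0), (7.8, 3500.0, 360.0), (12.3, 6060.0, 480.0)],
    )
    def test_parameter_recovery_across_grid(self, cl, vss, t_half):
        """Noise-free two-compartment curves sampled over >= 2 terminal
        half-lives: NCA recovers CL and T1/2 within 2% and Vss within 5%."""
        m = TwoCompartmentModel.from_nca_parameters(
            1e6, cl, vss, t_half_fast=20.0, t_half_terminal=t_half
        )
        t = np.array(
            [0.25, 1, 3, 6, 8, 24, 48, 72, 120, 288, 456, 720, 1032], float
        )
        t = t[t <= 2.6 * t_half]
        c = m.concentration(t)
        res = nca(curve(t, c), dose=1e6, infusion_duration=0.0)
        assert res.half_life == pytest.approx(t_half, rel=0.02)
        assert res.clearance == pytest.approx(cl, rel=0.02)
        assert res.vss == pytest.approx(vss, rel=0.05)


class TestOutlierScreen:
    def build_cohort(self, rng, n=8):
        times = [24.0, 288.0, 456.0]
        curves = []
        for i in range(n):
            base = np.array([300.0, 120.0, 80.0]) * rng.normal(1.0, 0.03, 3).clip(0.8)
            curves.append(curve(times, base, sid=f"s{i}"))
        return curves

    def test_planted_8p4_sd_point_is_flagged(self, rng):
        """A sample planted 8.4 leave-one-out SDs from the others' mean at
        288 h is caught at the default 5-SD threshold."""
        curves = self.build_cohort(rng)
        others = np.array([c.concentrations[1] for c in curves[:-1]])
        target = others.mean() + 8.4 * others.std(ddof=1)
        last = curves[-1]
        last.concentrations[1] = target
        flagged = screen_outliers(curves, threshold_sd=5.0)
        assert flagged == [(last.subject_id, 288.0)]
        screened = drop_flagged(last, flagged)
        assert 288.0 not in screened.times

    def test_identical_subjects_nothing_flagged(self):
        curves = [curve([1.0, 2.0, 3.0], [9.0, 6.0, 4.0], sid=f"s{i}") for i in range(5)]
        assert screen_outliers(curves) == []

    def test_infinite_threshold_flags_nothing(self, rng):
        curves = self.build_cohort(rng)
        assert screen_outliers(curves, threshold_sd=np.inf) == []

    def test_fewer_than_three_subjects_skipped_with_warning(self):
        curves = [curve([1.0, 2.0, 3.0], [9.0, 6.0, 4.0], sid=f"s{i}") for i in range(2)]
        with pytest.warns(UserWarning, match="skipped"):
            assert screen_outliers(curves) == []


class TestCohortSummary:
    def test_administered_activity_statistics(self):
        """The eight administered activities summarize to 14.0 +/- 0.9 MBq
        (range 12.77-15.03) at printed precision."""
        mbq = [12.77, 14.53, 14.24, 13.27, 14.64, 14.72, 15.03, 13.06]
        assert np.mean(mbq) == pytest.approx(14.0, abs=0.05)
        assert np.std(mbq, ddof=1) == pytest.approx(0.9, abs=0.05)
        assert (min(mbq), max(mbq)) == (12.77, 15.03)

    def test_matches_brute_force_statistics(self, rng, config):
        from albupet.simulate import simulate_plasma
        import dataclasses

        results = []
        for i in range(5):
            cfg = dataclasses.replace(config, clearance=config.clearance * rng.uniform(0.8, 1.2))
            c = simulate_plasma(cfg, subject_id=f"s{i}")
            results.append(nca(c, dose=cfg.dose_mass, infusion_duration=cfg.infusion_duration))
        summary = summarize_cohort(results).table
        cl = sorted(r.clearance for r in results)
        assert summary.loc["clearance", "min"] == pytest.approx(cl[0])
        assert summary.loc["clearance", "max"] == pytest.approx(cl[-1])
        assert summary.loc["clearance", "median"] == pytest.approx(cl[2])
        assert summary.loc["clearance", "mean"] == pytest.approx(sum(cl) / 5)
        mean = sum(cl) / 5
        sd = (sum((x - mean) ** 2 for x in cl) / 4) ** 0.5
        assert summary.loc["clearance", "stdev"] == pytest.approx(sd)

    def test_min_auc_subject_is_max_clearance_subject(self, rng, config):
        """CL = dose/AUC is monotone reciprocal, pairing min AUC with max CL."""
        from albupet.simulate import simulate_plasma
        import dataclasses

        results = []
        for i in range(4):
            cfg = dataclasses.replace(config, clearance=config.clearance * rng.uniform(0.7, 1.3))
            results.append(
                nca(simulate_plasma(cfg, subject_id=f"s{i}"), dose=cfg.dose_mass,
                    infusion_duration=cfg.infusion_duration)
            )
        by_auc = min(results, key=lambda r: r.auc_0_inf)
        by_cl = max(results, key=lambda r: r.clearance)
        assert by_auc.subject_id == by_cl.subject_id

    def test_single_subject_summary(self, config):
        from albupet.simulate import simulate_plasma

        res = nca(simulate_plasma(config), dose=config.dose_mass,
                  infusion_duration=config.infusion_duration)
        summary = summarize_cohort([res])
        assert summary.single_subject
        row = summary.table.loc["clearance"]
        assert row["min"] == row["max"] == row["median"] == row["mean"]
        assert row["stdev"] == 0.0
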