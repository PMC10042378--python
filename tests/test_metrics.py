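"""Fall-risk metrics: XCoM, FRI, spatiotemporal stats, joint variability,
divergence curves and Lyapunov slopes, vector assembly, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gaitrisk as gr
from gaitrisk.exceptions import (DegenerateGeometryError, FailedStepError,
                                 InsufficientDataError)
from gaitrisk.metrics import (EmbeddingConfig, METRIC_NAMES, _as_stack,
                              divergence_curve, fri_series, xcom_series)
from gaitrisk.walker import CH, N_CHANNELS, StepTrajectory


def make_traj(T=1.0, L=1.0, **channels):
    """A constant-channel trajectory with supported-step defaults."""
    samples = np.zeros((100, N_CHANNELS))
    samples[:, CH["Fn"]] = 800.0
    samples[:, CH["q8"]] = 1.0
    for name, val in channels.items():
        samples[:, CH[name]] = val
    return StepTrajectory(samples, T=T, L=L, v=L / T)


class TestXCoM:
    def test_constant_sample_substitution(self):
        # x7-xst = 0.10, dx7 = 0.30, l = 0.981 -> 0.10 + 0.30 sqrt(0.1)
        q8 = np.sqrt(0.981 ** 2 - 0.10 ** 2)
        traj = make_traj(q7=0.10, dq7=0.30, q8=q8)
        expected = 0.10 + 0.30 * np.sqrt(0.981 / 9.81)
        assert gr.xcom_step_max(traj) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.19487, abs=5e-6)

    def test_zero_velocity_reduces_to_position(self):
        traj = make_traj(q7=0.0, dq7=0.0)
        traj.samples[:, CH["q7"]] = np.linspace(-0.5, 0.5, 100)
        assert gr.xcom_step_max(traj) == pytest.approx(0.5)

    def test_ramp_matches_per_sample_loop_oracle(self):
        rng = np.random.default_rng(1)
        traj = make_traj()
        traj.samples[:, CH["q7"]] = np.linspace(0, 0.2, 100)
        traj.samples[:, CH["dq7"]] = 0.3 + 0.05 * rng.normal(size=100)
        traj.samples[:, CH["q8"]] = 1.0 + 0.02 * rng.normal(size=100)
        vals = []
        for k in range(100):
            rel_x = traj.samples[k, CH["q7"]] - traj.samples[k, CH["xst"]]
            rel_y = traj.samples[k, CH["q8"]] - traj.samples[k, CH["yst"]]
            ell = np.hypot(rel_x, rel_y)
            vals.append(rel_x + traj.samples[k, CH["dq7"]]
                        * np.sqrt(ell / 9.81))
        assert gr.xcom_step_max(traj) == pytest.approx(max(vals), rel=1e-12)

    def test_degenerate_geometry_rejected(self):
        traj = make_traj(q7=0.0, q8=0.0)
        with pytest.raises(DegenerateGeometryError):
            gr.xcom_step_max(traj)

    def test_translation_invariance(self):
        traj = make_traj(q7=0.1, dq7=0.3)
        base = gr.xcom_step_max(traj)
        traj.samples[:, CH["q7"]] += 5.0
        traj.samples[:, CH["xst"]] += 5.0
        assert gr.xcom_step_max(traj) == pytest.approx(base, rel=1e-12)


class TestFRI:
    def test_pure_ankle_torque(self):
        # Fg = 0, Fa through O, tau_a = 5 N m, Fn = 100 N -> -0.05 m
        traj = make_traj(tau_a=5.0, Ax=0.05, Ay=0.05, Fax=3.0, Fay=3.0)
        traj.samples[:, CH["Fn"]] = 100.0
        assert gr.fri_step_max(traj) == pytest.approx(-0.05, rel=1e-12)

    def test_all_moments_zero(self):
        traj = make_traj()
        assert gr.fri_step_max(traj) == pytest.approx(0.0, abs=1e-15)

    def test_static_equilibrium_matches_center_of_pressure(self):
        # independent oracle: net moment balance about the origin with 3-D
        # cross products
        traj = make_traj(Gx=0.04, Gy=0.03, Fgx=0.0, Fgy=-20.0,
                         Ax=-0.02, Ay=0.08, Fax=30.0, Fay=-500.0,
                         tau_a=12.0, xst=0.1)
        traj.samples[:, CH["Fn"]] = 500.0
        OG = np.array([0.04, 0.03, 0.0])
        OA = np.array([-0.02, 0.08, 0.0])
        Fg = np.array([0.0, -20.0, 0.0])
        Fa = np.array([30.0, -500.0, 0.0])
        cop = (np.cross(OG, Fg)[2] - np.cross(OA, Fa)[2] - 12.0) / 500.0
        assert gr.fri_step_max(traj) == pytest.approx(cop - 0.1, rel=1e-12)

    def test_unsupported_step_rejected(self):
        traj = make_traj()
        traj.samples[0, CH["Fn"]] = -1.0
        with pytest.raises(FailedStepError):
            gr.fri_step_max(traj)

    def test_translation_invariance_with_balanced_vertical_forces(self):
        # shifting all horizontal positions together leaves FRI unchanged
        # when Fg = 0 and Fay = -Fn (the synthesized-walker convention)
        cfg = gr.load_preset("train_05")
        _, traj = gr.simulate_step(cfg, 0.01, 0.005)
        base = gr.fri_step_max(traj)
        for name in ("q7", "xst", "Gx", "Ax"):
            traj.samples[:, CH[name]] += 3.0
        assert gr.fri_step_max(traj) == pytest.approx(base, rel=1e-9)


class TestSpatiotemporal:
    def test_identical_steps(self):
        seq = gr.StepSequence(gr.load_preset("train_05"), np.zeros(5),
                              np.zeros(5))
        stats = gr.spatiotemporal_stats(seq)
        assert stats["step_duration_sd"] == 0.0

    def test_two_value_sample_sd(self):
        trajs = [make_traj(T=0.9), make_traj(T=1.1)]
        stats = gr.spatiotemporal_stats(trajs)
        assert stats["step_duration_mean"] == pytest.approx(1.0)
        # sample SD convention (n-1)
        assert stats["step_duration_sd"] == pytest.approx(
            np.std([0.9, 1.1], ddof=1))

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            gr.spatiotemporal_stats([make_traj()])


class TestJointVariability:
    def test_two_step_closed_form(self):
        # values a +- e at every time point: sample SD = e*sqrt(2)
        eps = np.e
        t1, t2 = make_traj(), make_traj()
        for c in gr.metrics.VARIABILITY_CHANNELS:
            t1.samples[:, CH[c]] = 1.0 - eps
            t2.samples[:, CH[c]] = 1.0 + eps
        jv = gr.joint_variability([t1, t2])
        np.testing.assert_allclose(jv.to_numpy(), np.log(eps * np.sqrt(2)),
                                   rtol=1e-12)

    def test_identical_steps_floored(self):
        jv = gr.joint_variability([make_traj(), make_traj()])
        np.testing.assert_allclose(jv.to_numpy(), np.log(1e-7))

    def test_gaussian_monte_carlo_bias_oracle(self):
        # 200 iid Gaussian steps: E[mean log SD] = ln(sigma) + bias where
        # bias = (psi((n-1)/2) + ln 2 - ln(n-1)) / 2 for sample SDs
        from scipy.special import digamma

        rng = np.random.default_rng(5)
        n = 200
        sigma = 0.03
        trajs = []
        for k in range(n):
            t = make_traj()
            for c in gr.metrics.VARIABILITY_CHANNELS:
                t.samples[:, CH[c]] = 1.0 + rng.normal(0, sigma, size=100)
            trajs.append(t)
        jv = gr.joint_variability(trajs)
        bias = 0.5 * (digamma((n - 1) / 2) + np.log(2) - np.log(n - 1))
        expected = np.log(sigma) + bias
        # SE of the metric ~ sd(ln s)/sqrt(100 time points)
        se = (1 / np.sqrt(2 * (n - 1))) / np.sqrt(100)
        assert np.all(np.abs(jv.to_numpy() - expected) < 4 * se)


class TestDivergenceCurve:
    def test_parallel_trajectories_flat_curve(self):
        # a pure linear ramp: the nearest allowed neighbour of every point
        # runs parallel at constant embedded distance
        # (exclusion+1) * slope * sqrt(dim), so the curve is flat at its log
        cfg = EmbeddingConfig(delay=2, dim=3, exclusion=20, dt=1.0)
        slope = 0.1
        series = slope * np.arange(600.0)
        y = divergence_curve(series, cfg, i_max=50)
        np.testing.assert_allclose(y[:40], np.log(21 * slope * np.sqrt(3)),
                                   rtol=1e-9)

    def test_identical_trajectories_floored(self):
        # a periodic signal with integer sample period: every embedded point
        # has a duplicate one period away (identical up to ~1e-15, below the
        # distance floor), so the whole curve sits at log(d_floor)
        cfg = EmbeddingConfig(delay=2, dim=3, exclusion=20, dt=1.0)
        series = np.sin(2 * np.pi * np.arange(800) / 50)
        y = divergence_curve(series, cfg, i_max=30)
        np.testing.assert_allclose(y[:30], np.log(1e-7), rtol=1e-9)

    def test_matches_naive_reference_implementation(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=500)
        cfg = EmbeddingConfig(delay=3, dim=4, exclusion=20, dt=1.0)
        y = divergence_curve(s, cfg, i_max=40)
        span = (cfg.dim - 1) * cfg.delay
        ne = s.size - span
        X = np.stack([s[t:t + span + 1:cfg.delay] for t in range(ne)])
        pairs = []
        for j in range(ne):
            best, kb = np.inf, -1
            for k in range(ne):
                if abs(k - j) <= cfg.exclusion:
                    continue
                d = np.linalg.norm(X[j] - X[k])
                if d < best:
                    best, kb = d, k
            if kb >= 0:
                pairs.append((j, kb))
        ref = []
        for i in range(41):
            vals = [np.log(max(np.linalg.norm(X[j + i] - X[k + i]),
                               cfg.d_floor))
                    for j, k in pairs if max(j, k) + i < ne]
            ref.append(np.mean(vals))
        np.testing.assert_allclose(y[:41], ref, rtol=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            divergence_curve(np.arange(30.0), EmbeddingConfig())


class TestLyapunovSlopes:
    def test_linear_curve_recovered_exactly(self):
        cfg = EmbeddingConfig()
        i = np.arange(2501)
        lam_s, lam_l = gr.lyapunov_exponents(0.37 * i + 2.0, cfg)
        assert lam_s == pytest.approx(0.37, rel=1e-12)
        assert lam_l == pytest.approx(0.37, rel=1e-12)

    def test_flat_curve_gives_zero(self):
        lam_s, lam_l = gr.lyapunov_exponents(np.full(2500, 1.3),
                                             EmbeddingConfig())
        assert lam_s == pytest.approx(0.0, abs=1e-12)
        assert lam_l == pytest.approx(0.0, abs=1e-12)

    def test_piecewise_linear_curve(self):
        i = np.arange(2500.0)
        curve = np.where(i <= 300, i, 300.0)
        lam_s, lam_l = gr.lyapunov_exponents(curve, EmbeddingConfig())
        assert lam_s == pytest.approx(1.0, rel=1e-12)
        assert lam_l == pytest.approx(0.0, abs=1e-12)

    def test_short_curve_names_deficient_range(self):
        with pytest.raises(InsufficientDataError, match="long"):
            gr.lyapunov_exponents(np.arange(500.0), EmbeddingConfig())


class TestMetricVector:
    def test_always_49_entries(self):
        cfg = gr.load_preset("train_05")
        trials = gr.simulate_brute(cfg, n_steps=10, rng=1)
        vec = gr.metric_vector_from_steps(trials[0], lyapunov=False)
        assert len(vec) == 49
        assert list(vec.values.index) == METRIC_NAMES
        # metric count by family: 2+2+2+2+2 + 12 + 12 + 15
        fam = pd.Series(gr.METRIC_GROUPS)
        assert fam.value_counts()[["lyap_short", "lyap_long"]].tolist() == \
            [12, 12]
        assert (fam == "var_angle").sum() + (fam == "var_velocity").sum() == 15

    def test_few_steps_flags_lyapunov_missing(self):
        cfg = gr.load_preset("train_05")
        trials = gr.simulate_brute(cfg, n_steps=10, rng=1)
        with pytest.warns(UserWarning, match="Lyapunov"):
            vec = gr.metric_vector_from_steps(trials[0])
        assert vec.values.filter(like="lyap").isna().all()
        assert vec.values.filter(like="var").notna().all()

    def test_equals_union_of_individual_operations(self):
        cfg = gr.load_preset("train_07")
        seq = gr.simulate_brute(cfg, n_steps=50, rng=2)[0]
        vec = gr.metric_vector_from_steps(seq)
        samples, T, L, v, g = _as_stack(seq)
        assert vec["xcom_mean"] == pytest.approx(
            xcom_series(samples, g).max(axis=-1).mean())
        assert vec["fri_sd"] == pytest.approx(
            fri_series(samples).max(axis=-1).std(ddof=1))
        for k, val in gr.spatiotemporal_stats(seq).items():
            assert vec[k] == pytest.approx(val)
        jv = gr.joint_variability(seq)
        np.testing.assert_allclose(vec.values[jv.index], jv)
        series = samples[:, :, CH["q1"]].ravel()
        lam_s, lam_l = gr.lyapunov_exponents(divergence_curve(series),
                                             EmbeddingConfig())
        assert vec["lyap_short_q1"] == pytest.approx(lam_s)
        assert vec["lyap_long_q1"] == pytest.approx(lam_l)

    def test_order_invariance_of_step_statistics(self):
        cfg = gr.load_preset("train_07")
        seq = gr.simulate_brute(cfg, n_steps=30, rng=3)[0]
        perm = np.random.default_rng(0).permutation(len(seq))
        shuffled = gr.StepSequence(cfg, seq.x0[perm], seq.s[perm])
        v1 = gr.metric_vector_from_steps(seq, lyapunov=False).values.dropna()
        v2 = gr.metric_vector_from_steps(shuffled,
                                         lyapunov=False).values.dropna()
        np.testing.assert_allclose(v1, v2, rtol=1e-10)


class TestNormalization:
    def test_two_point_example(self):
        # {1, 3}: center 2, sample-SD scale sqrt(2); the normalized values
        # +-1/sqrt(2) have sample SD exactly 1
        df = pd.DataFrame({m: [1.0, 3.0] for m in METRIC_NAMES})
        record = gr.fit_normalization(df)
        z = gr.apply_normalization(record, df)
        np.testing.assert_allclose(
            z.to_numpy(), np.tile([-1.0 / np.sqrt(2), 1.0 / np.sqrt(2)],
                                  (49, 1)).T)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0)

    def test_constant_metric_scale_one_with_warning(self):
        df = pd.DataFrame({m: [1.0, 3.0] for m in METRIC_NAMES})
        df["fri_mean"] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            record = gr.fit_normalization(df)
        assert record.scale["fri_mean"] == 1.0
        z = gr.apply_normalization(record, df)
        np.testing.assert_allclose(z["fri_mean"], 0.0)

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 10_000), st.integers(3, 12))
    def test_fit_then_apply_standardizes(self, seed, nrows):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(10, 3, size=(nrows, 49)),
                          columns=METRIC_NAMES)
        record = gr.fit_normalization(df)
        z = gr.apply_normalization(record, df)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)
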