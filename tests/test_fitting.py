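import numpy as np
import pytest

import vsbright as vb
from vsbright.errors import (
    DegenerateFitError,
    UndefinedMetricError,
    ValidationError,
)


def make_dataset(params: vb.BrightnessModelParams, n=12, seed=0, noise=0.0):
    """Small exact-model dataset with log-spaced Ev and varied S, G."""
    rng = np.random.default_rng(seed)
    ev = np.geomspace(45.0, 2000.0, n)
    s = rng.uniform(0.2, 1.4, n)
    g = rng.uniform(0.3, 1.3, n)
    m = vb.evaluate_m(params, ev, s, g)
    m = 90.0 * m / m.max()
    vsb = np.clip(m + rng.normal(0, noise, n), 0, 100)
    return vb.ExperimentDataset(
        ids=tuple(f"s{i}" for i in range(n)),
        Ev=ev, S=s, G=g,
        vsb_mean=vsb, vsb_sd=np.full(n, noise), n_observers=np.full(n, 28),
    )


TRUTH = vb.get_preset("final_sg").params


class TestMetrics:
    def test_rmse_identical_vectors(self):
        assert vb.rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_rmse_constant_offset(self):
        v = np.arange(5.0)
        assert vb.rmse(v + 2.5, v) == pytest.approx(2.5)

    def test_rmse_hand_value(self):
        # residuals (3, 4): sqrt(25/2)
        assert vb.rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(3.5355339059327378)

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValidationError):
            vb.rmse([1.0], [1.0, 2.0])

    def test_r_squared_perfect_and_mean(self):
        v = np.array([10.0, 30.0, 50.0, 70.0])
        assert vb.r_squared(v, v) == pytest.approx(1.0)
        assert vb.r_squared(np.full(4, v.mean()), v) == pytest.approx(0.0)

    def test_r_squared_can_be_negative(self):
        v = np.array([1.0, 2.0, 3.0])
        assert vb.r_squared(v[::-1], v) < 0

    def test_r_squared_zero_variance_raises(self):
        with pytest.raises(UndefinedMetricError):
            vb.r_squared([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestLinearFit:
    def test_exact_line(self):
        raw = np.array([1.0, 2.0, 3.0])
        a, b = vb.fit_linear_ab(raw, np.array([41.0, 43.0, 45.0]))
        assert (a, b) == (pytest.approx(2.0), pytest.approx(39.0))

    def test_proportional(self):
        raw = np.array([1.0, 2.0, 5.0])
        a, b = vb.fit_linear_ab(raw, 2 * raw)
        assert (a, b) == (pytest.approx(2.0), pytest.approx(0.0, abs=1e-12))

    def test_constant_response(self):
        a, b = vb.fit_linear_ab(np.array([1.0, 2.0, 3.0]), np.full(3, 7.0))
        assert (a, b) == (pytest.approx(0.0, abs=1e-12), pytest.approx(7.0))

    def test_zero_variance_predictor_raises(self):
        with pytest.raises(DegenerateFitError):
            vb.fit_linear_ab(np.full(4, 2.0), np.arange(4.0))

    def test_fit_quality_scaled_model(self):
        v = np.array([10.0, 20.0, 30.0])
        slope, intercept = vb.fit_quality(v / 2, v)
        assert (slope, intercept) == (pytest.approx(2.0), pytest.approx(0.0, abs=1e-9))

    def test_ols_optimality_against_perturbations(self):
        dataset = make_dataset(TRUTH, noise=2.0, seed=3)
        base_rmse, a, b = vb.profiled_objective(TRUTH, dataset)
        raw = vb.evaluate_raw(TRUTH, dataset.Ev, dataset.S, dataset.G)
        rng = np.random.default_rng(4)
        for _ in range(20):
            fa = a * (1 + rng.uniform(-0.1, 0.1))
            fb = b * (1 + rng.uniform(-0.1, 0.1))
            assert vb.rmse(fa * raw + fb, dataset.vsb_mean) >= base_rmse - 1e-12


class TestProfiledObjective:
    def test_zero_at_truth_on_noise_free_data(self):
        dataset = make_dataset(TRUTH)
        err, a, b = vb.profiled_objective(TRUTH, dataset)
        assert err < 1e-9

    def test_unused_g_exponent_is_irrelevant(self):
        p = TRUTH.replace(beta=0.0)
        dataset = make_dataset(p)
        nl1 = (1.0, 0.0, p.gamma, p.delta1, 0.1)
        nl2 = (1.0, 0.0, p.gamma, p.delta1, 0.9)
        assert vb.profiled_objective(nl1, dataset)[0] == pytest.approx(
            vb.profiled_objective(nl2, dataset)[0], abs=1e-12
        )

    def test_profiling_beats_identity_transform(self):
        dataset = make_dataset(TRUTH, noise=4.0, seed=5)
        nl = (1.0, 0.5, 0.3, 0.1, 0.1)
        err, a, b = vb.profiled_objective(nl, dataset)
        params = vb.BrightnessModelParams(*nl, a=1.0, b=0.0)
        raw = vb.evaluate_raw(params, dataset.Ev, dataset.S, dataset.G)
        assert err <= vb.rmse(raw, dataset.vsb_mean)

    def test_weight_scale_degeneracy(self):
        """Profiled RMSE depends on (alpha, beta) only through their ratio."""
        dataset = make_dataset(TRUTH, noise=3.0, seed=6)
        for gamma, d1, d2 in [(0.367, 0.12, 0.12), (0.2629, 0.074, 0.0424)]:
            e1 = vb.profiled_objective((0.5, 0.5, gamma, d1, d2), dataset)[0]
            e2 = vb.profiled_objective((0.92, 0.92, gamma, d1, d2), dataset)[0]
            assert abs(e1 - e2) < 1e-9


class TestGlobalFit:
    def test_recovers_noise_free_data(self):
        dataset = make_dataset(TRUTH, n=20, seed=7)
        res = vb.global_fit(dataset, n_starts=8, seed=0)
        assert res.rmse < 1e-6
        assert vb.rmse(res.predictions(dataset), dataset.vsb_mean) < 1e-6

    def test_deterministic_given_seed(self, noisy_sim):
        r1 = vb.global_fit(noisy_sim.dataset, n_starts=8, seed=3)
        r2 = vb.global_fit(noisy_sim.dataset, n_starts=8, seed=3)
        assert r1 == r2  # bit-identical params and metrics

    def test_fit_quality_is_ideal_after_ab_refit(self, noisy_sim):
        res = vb.global_fit(noisy_sim.dataset, n_starts=8, seed=3)
        assert res.fit_slope == pytest.approx(1.0, abs=1e-9)
        assert abs(res.fit_intercept) < 1e-6

    def test_requires_three_rows(self):
        d = make_dataset(TRUTH, n=12)
        small = vb.ExperimentDataset(
            ids=d.ids[:2], Ev=d.Ev[:2], S=d.S[:2], G=d.G[:2],
            vsb_mean=d.vsb_mean[:2], vsb_sd=d.vsb_sd[:2], n_observers=d.n_observers[:2],
        )
        with pytest.raises(ValidationError):
            vb.global_fit(small)

    def test_beats_coarse_grid_oracle(self, noisy_sim):
        grid = {
            "beta": np.linspace(0.0, 2.0, 4),
            "gamma": np.linspace(0.05, 1.5, 4),
            "delta1": np.linspace(0.0, 1.0, 4),
            "delta2": np.linspace(0.0, 1.0, 4),
        }
        oracle = vb.grid_oracle(noisy_sim.dataset, grid)
        res = vb.global_fit(noisy_sim.dataset, n_starts=16, seed=0)
        assert res.rmse <= oracle.rmse + 1e-12

    def test_degenerate_direction_product_is_stable(self):
        """With tiny compression exponents only (alpha+beta)*a is identified."""
        truth = vb.BrightnessModelParams(1.0, 0.5, 0.2629, 0.01, 0.01, a=8.9974, b=-1.3307)
        sd = vb.simulate(vb.GeneratorConfig(noise_sd=2.0, seed=42), true_params=truth)
        products = []
        for seed in (1, 2, 3):
            r = vb.global_fit(
                sd.dataset,
                free=("beta", "delta1", "delta2"),
                fixed={"alpha": 1.0, "gamma": 0.2629},
                n_starts=12,
                seed=seed,
            )
            products.append((r.params.alpha + r.params.beta) * r.params.a)
        assert max(products) / min(products) < 1.01


class TestGridOracle:
    def test_single_point_at_truth(self):
        dataset = make_dataset(TRUTH)
        grid = {"beta": [TRUTH.beta], "gamma": [TRUTH.gamma],
                "delta1": [TRUTH.delta1], "delta2": [TRUTH.delta2]}
        assert vb.grid_oracle(dataset, grid).rmse < 1e-9

    def test_refinement_never_increases_minimum(self, noisy_sim):
        coarse = {"beta": np.linspace(0, 2, 3), "gamma": np.linspace(0.05, 1.5, 3),
                  "delta1": [0.0, 0.5], "delta2": [0.0, 0.5]}
        fine = {"beta": np.linspace(0, 2, 5), "gamma": np.linspace(0.05, 1.5, 5),
                "delta1": [0.0, 0.25, 0.5], "delta2": [0.0, 0.25, 0.5]}
        # fine grids contain the coarse points
        assert vb.grid_oracle(noisy_sim.dataset, fine).rmse <= vb.grid_oracle(
            noisy_sim.dataset, coarse
        ).rmse + 1e-12

    def test_grid_containing_solution_is_at_least_as_good(self, noisy_sim):
        res = vb.global_fit(noisy_sim.dataset, n_starts=8, seed=1)
        p = res.params
        grid = {"beta": [0.1, p.beta], "gamma": [1.0, p.gamma],
                "delta1": [0.5, p.delta1], "delta2": [0.5, p.delta2]}
        assert vb.grid_oracle(noisy_sim.dataset, grid).rmse <= res.rmse + 1e-12


class TestStagedFit:
    def test_noise_free_final_stage_recovers_truth(self, noisefree_sim):
        ledger = vb.staged_fit(noisefree_sim.dataset, seed=0, n_starts_stage=4, n_starts_global=8)
        assert ledger["step4_global"].rmse < 1e-6
        assert ledger.best.rmse == ledger["step4_global"].rmse

    def test_first_stage_only_refits_scale(self, noisy_sim):
        ledger = vb.staged_fit(noisy_sim.dataset, seed=0, n_starts_stage=2, n_starts_global=2)
        p = ledger["step1_fotios"].params
        fotios = vb.get_preset("fotios_1998").params
        assert (p.alpha, p.beta, p.gamma, p.delta1, p.delta2) == (
            fotios.alpha, fotios.beta, fotios.gamma, fotios.delta1, fotios.delta2
        )
        assert (p.a, p.b) != (fotios.a, fotios.b)

    def test_step_sequence_rmse_non_increasing(self, noisy_sim):
        ledger = vb.staged_fit(noisy_sim.dataset, seed=1)
        step2 = [r.rmse for r in ledger if r.label.startswith("step2")]
        seq = [
            ledger["step1_fotios"].rmse,
            min(step2),
            ledger["step3_delta_refine"].rmse,
            ledger["step4_global"].rmse,
        ]
        assert all(a >= b - 1e-12 for a, b in zip(seq, seq[1:]))
        assert ledger.best.rmse == ledger["step4_global"].rmse

    def test_custom_stage_plan_runs_verbatim(self, noisy_sim):
        plan = [
            ("only_ab", {"alpha": 1.0, "beta": 0.0, "gamma": 1.0, "delta1": 0.24, "delta2": 0.24}, ()),
            ("free_gamma", {"alpha": 1.0, "beta": 0.0, "delta1": 0.0, "delta2": 0.0}, ("gamma",)),
        ]
        ledger = vb.staged_fit(noisy_sim.dataset, stage_plan=plan, seed=0, n_starts_stage=4)
        assert [r.label for r in ledger] == ["only_ab", "free_gamma"]
        assert ledger["only_ab"].free_mask == ()


class TestDatasetIO:
    def test_csv_round_trip(self, tmp_path, noisy_sim):
        path = tmp_path / "d.csv"
        noisy_sim.dataset.to_csv(path)
        back = vb.ExperimentDataset.from_csv(path)
        assert back.ids == noisy_sim.dataset.ids
        assert np.allclose(back.vsb_mean, noisy_sim.dataset.vsb_mean)
        assert np.allclose(back.S, noisy_sim.dataset.S)

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,Ev_lux\nx,100\n")
        with pytest.raises(ValidationError, match="missing columns"):
            vb.ExperimentDataset.from_csv(path)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValidationError):
            vb.ExperimentDataset(
                ids=("a", "b", "c"), Ev=np.array([10.0, -1.0, 5.0]),
                S=np.ones(3), G=np.ones(3), vsb_mean=np.full(3, 50.0),
                vsb_sd=np.zeros(3), n_observers=np.full(3, 28),
            )

    def test_ledger_serialisation(self, tmp_path, noisy_sim):
        ledger = vb.staged_fit(
            noisy_sim.dataset,
            stage_plan=[("only_ab", {"alpha": 1.0, "beta": 0.0, "gamma": 1.0,
                                     "delta1": 0.24, "delta2": 0.24}, ())],
        )
        ledger.to_csv(tmp_path / "ledger.csv")
        text = ledger.to_markdown()
        assert text.startswith("| label |")
        assert "only_ab" in text
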