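"""Multi-start estimation: initialization, recovery, optimizer agreement."""

import copy

import numpy as np
import pytest

from multihill import (
    DoseResponseDataset,
    FitSettings,
    HillPhase,
    MultiphasicModel,
    fit,
    initial_guesses,
    make_configuration,
    objective_f,
    separation_penalty,
    simulate_curve,
)
from multihill.fitters import unpack_parameters

GRID = np.logspace(-2.0, 2.0, 9)


def noiseless(model, grid=GRID, n_rep=3):
    return simulate_curve(model, grid, n_replicates=n_rep, sigma=0.0, seed=0)


class TestInitialGuesses:
    def test_deterministic_under_seed(self):
        ds = noiseless(MultiphasicModel([HillPhase(1.0, 1.0, 0.1)]))
        cfg = make_configuration("BIPHASIC_2I")
        settings = FitSettings(seed=7)
        a = initial_guesses(ds, cfg, settings)
        b = initial_guesses(ds, cfg, settings)
        assert len(a) == settings.n_starts
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_monophasic_starts_inside_tested_range(self):
        ds = noiseless(MultiphasicModel([HillPhase(1.0, 1.0, 0.1)]))
        cfg = make_configuration("HILL_1I")
        for theta in initial_guesses(ds, cfg, FitSettings(seed=3)):
            assert np.log10(GRID.min()) <= theta[0] <= np.log10(GRID.max())

    def test_multiphase_starts_are_ordered(self):
        ds = noiseless(MultiphasicModel([HillPhase(1.0, 1.0, 0.1)]))
        for label in ("BIPHASIC_2I", "BIPHASIC_1S1I", "TRIPHASIC_1S2I"):
            cfg = make_configuration(label)
            for theta in initial_guesses(ds, cfg, FitSettings(seed=5)):
                lecs = theta[0 : 3 * cfg.n_phases : 3]
                assert np.all(np.diff(lecs) > 0)

    def test_too_few_concentrations_rejected(self):
        ds = DoseResponseDataset(np.array([1.0, 10.0]), np.array([[1.0], [0.5]]))
        with pytest.raises(ValueError):
            initial_guesses(ds, make_configuration("HILL_1I"), FitSettings())


class TestSeparationPenalty:
    def test_satisfied_separation_is_free(self):
        m = MultiphasicModel([HillPhase(0.1, 1, 0.5), HillPhase(1.0, 1, 0.1)])
        assert separation_penalty(m, FitSettings(separation_delta=0.5)) == 0.0

    def test_coincident_phases_penalized(self):
        m = MultiphasicModel([HillPhase(1.0, 1, 0.5), HillPhase(1.0, 2, 0.1)])
        assert separation_penalty(m, FitSettings(separation_delta=0.5)) > 0.0

    def test_monophasic_vacuous(self):
        m = MultiphasicModel([HillPhase(1.0, 1, 0.1)])
        assert separation_penalty(m, FitSettings()) == 0.0


class TestFit:
    def test_noiseless_monophasic_recovery(self):
        true = MultiphasicModel([HillPhase(ec50=0.8, h=1.6, e_inf=0.12)])
        ds = noiseless(true, np.logspace(-2, 2, 9))
        res = fit(ds, make_configuration("HILL_1I"), FitSettings(seed=0))
        ph = res.model.phases[0]
        assert ph.ec50 == pytest.approx(0.8, rel=0.01)
        assert ph.h == pytest.approx(1.6, rel=0.01)
        assert ph.e_inf == pytest.approx(0.12, abs=0.005)
        assert res.stats.f_value < 1e-8
        assert res.converged

    def test_noiseless_biphasic_recovery(self):
        true = MultiphasicModel(
            [HillPhase(ec50=0.01, h=2.0, e_inf=0.5), HillPhase(ec50=10.0, h=2.0, e_inf=0.05)]
        )
        ds = noiseless(true, np.logspace(-4, 3, 11))
        res = fit(ds, make_configuration("BIPHASIC_2I"), FitSettings(seed=1))
        ecs = sorted(p.ec50 for p in res.model.phases)
        assert ecs[0] == pytest.approx(0.01, rel=0.05)
        assert ecs[1] == pytest.approx(10.0, rel=0.05)

    def test_three_optimizers_agree_on_noiseless_monophasic(self):
        true = MultiphasicModel([HillPhase(ec50=1.5, h=1.2, e_inf=0.2)])
        ds0 = noiseless(true)
        f_values = {}
        for opt in ("simplex", "simplex_constrained", "trust_region"):
            ds = copy.deepcopy(ds0)
            res = fit(ds, make_configuration("HILL_1I"), FitSettings(optimizer=opt, seed=2))
            f_values[opt] = res.stats.f_value
        spread = max(f_values.values()) - min(f_values.values())
        assert spread < 1e-6

    def test_monotone_improvement_over_starts(self):
        true = MultiphasicModel([HillPhase(ec50=0.5, h=2.0, e_inf=0.1)])
        ds = simulate_curve(true, GRID, 3, 0.05, seed=9)
        cfg = make_configuration("BIPHASIC_2I")
        settings = FitSettings(seed=9)
        res = fit(ds, cfg, settings)
        start_f = [
            objective_f(unpack_parameters(t, cfg, settings), ds, "sd")
            for t in initial_guesses(ds, cfg, settings)
        ]
        assert res.stats.f_value <= min(start_f) + 1e-9

    def test_bitwise_reproducibility(self):
        true = MultiphasicModel([HillPhase(ec50=0.5, h=2.0, e_inf=0.1)])
        results = []
        for _ in range(2):
            ds = simulate_curve(true, GRID, 3, 0.05, seed=4)
            res = fit(ds, make_configuration("HILL_1I"), FitSettings(seed=4))
            results.append(res)
        a, b = results
        assert a.stats.f_value == b.stats.f_value
        assert [(p.ec50, p.h, p.e_inf) for p in a.model.phases] == [
            (p.ec50, p.h, p.e_inf) for p in b.model.phases
        ]

    def test_concentration_scaling_equivariance(self):
        # multiplying all concentrations by 10 shifts log10-EC50 by +1
        true = MultiphasicModel([HillPhase(ec50=0.5, h=2.0, e_inf=0.1)])
        ds1 = simulate_curve(true, GRID, 3, 0.05, seed=5)
        ds2 = DoseResponseDataset(
            ds1.concentrations * 10.0, ds1.effects.copy(), title=ds1.title
        )
        r1 = fit(ds1, make_configuration("HILL_1I"), FitSettings(seed=5))
        r2 = fit(ds2, make_configuration("HILL_1I"), FitSettings(seed=5))
        assert np.log10(r2.model.phases[0].ec50) == pytest.approx(
            np.log10(r1.model.phases[0].ec50) + 1.0, abs=1e-6
        )
        assert r2.model.phases[0].h == pytest.approx(r1.model.phases[0].h, rel=1e-6)
        assert r2.stats.f_value == pytest.approx(r1.stats.f_value, rel=1e-6)

    def test_joint_effect_sigma_scaling_leaves_optimal_f_unchanged(self):
        # scaling observations and their sigmas together is absorbed by
        # the free baseline factor, leaving weighted residuals intact
        true = MultiphasicModel([HillPhase(ec50=0.5, h=2.0, e_inf=0.1)])
        ds1 = simulate_curve(true, GRID, 3, 0.03, seed=6, sigma_known=True)
        lam = 1.2
        ds2 = DoseResponseDataset(
            ds1.concentrations, ds1.effects * lam, sigma=ds1.sigma * lam
        )
        cfg = make_configuration("HILL_1I", baseline_free=True)
        r1 = fit(ds1, cfg, FitSettings(seed=6))
        r2 = fit(ds2, cfg, FitSettings(seed=6))
        assert r2.stats.f_value == pytest.approx(r1.stats.f_value, rel=1e-3, abs=1e-6)
        assert r2.model.baseline_scale == pytest.approx(
            lam * r1.model.baseline_scale, rel=1e-3
        )

    def test_monophasic_recovery_under_noise(self):
        # median relative EC50 error across simulated triplicate curves
        errors = []
        for i in range(50):
            rng = np.random.default_rng(100 + i)
            ec50 = 10 ** rng.uniform(-1, 1)
            true = MultiphasicModel(
                [HillPhase(ec50=ec50, h=rng.uniform(0.8, 3), e_inf=rng.uniform(0, 0.3))]
            )
            ds = simulate_curve(true, GRID, 3, 0.05, seed=200 + i)
            res = fit(ds, make_configuration("HILL_1I"), FitSettings(seed=i, n_starts=4))
            errors.append(abs(res.model.phases[0].ec50 - ec50) / ec50)
        assert np.median(errors) < 0.10
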