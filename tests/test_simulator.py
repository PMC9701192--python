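"""Synthetic population generator: moments, class structure, drug effects,
mixtures, drift, and the noise-versus-cell-count law."""

import numpy as np
import pytest
from scipy.stats import linregress

from massresponse import (
    DriftModel,
    MoaEffect,
    ParticleClass,
    Role,
    SimulationSpec,
    ValidationError,
    apply_moa,
    mass_response,
    mix_populations,
    noise_vs_n_scan,
    sample_masses,
    simulate_experiment,
    simulate_population,
    theta_stat,
)


class TestSimulatePopulation:
    def test_seed_determinism(self, baseline_spec):
        a = simulate_population(baseline_spec, 200, rng=5)
        b = simulate_population(baseline_spec, 200, rng=5)
        assert a == b

    def test_default_weights_all_intact(self, baseline_spec):
        records = simulate_population(baseline_spec, 1000, rng=1)
        assert len(records) == 1000
        assert all(r.particle_class is ParticleClass.INTACT for r in records)

    def test_moment_recovery(self, baseline_spec):
        m = sample_masses(baseline_spec, 100_000, rng=2)
        assert m.mean() == pytest.approx(baseline_spec.mean_mass, rel=0.02)
        assert m.std() / m.mean() == pytest.approx(baseline_spec.cv, rel=0.05)

    def test_class_mean_ordering(self):
        spec = SimulationSpec(class_weights={
            ParticleClass.INTACT: 0.7, ParticleClass.PERMEABLE: 0.1,
            ParticleClass.AGGREGATE: 0.1, ParticleClass.DEBRIS: 0.1,
        })
        records = simulate_population(spec, 20_000, rng=3)
        means = {}
        for cls in (ParticleClass.AGGREGATE, ParticleClass.INTACT,
                    ParticleClass.PERMEABLE, ParticleClass.DEBRIS):
            means[cls] = np.mean([r.mass for r in records
                                  if r.true_class is cls])
        assert (means[ParticleClass.AGGREGATE] > means[ParticleClass.INTACT]
                > means[ParticleClass.PERMEABLE] > means[ParticleClass.DEBRIS])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            SimulationSpec(class_weights={ParticleClass.INTACT: 0.5})
        with pytest.raises(ValidationError):
            SimulationSpec(cv=-0.1)


class TestMoaEffects:
    def test_uniform_shift_recovers_identity(self, baseline_spec):
        records = simulate_population(baseline_spec, 3000, rng=4)
        shifted = apply_moa(records, MoaEffect.uniform_shift(0.10), rng=5)
        x = np.array([r.mass for r in shifted])
        z = np.array([r.mass for r in records])
        assert mass_response(x, z) == pytest.approx(0.10, rel=1e-9)

    def test_membrane_loss_fraction_in_low_mode(self, baseline_spec):
        records = simulate_population(baseline_spec, 5000, rng=6)
        hit = apply_moa(records, MoaEffect.membrane_loss(0.40), rng=7)
        permeable = [r for r in hit if r.particle_class is ParticleClass.PERMEABLE]
        assert len(permeable) == pytest.approx(0.40 * 5000, abs=1)
        intact_masses = [r.mass for r in hit
                         if r.particle_class is ParticleClass.INTACT]
        assert np.mean([r.mass for r in permeable]) < 0.5 * np.mean(intact_masses)

    def test_arrest_mean_directions(self, baseline_spec):
        records = simulate_population(baseline_spec, 4000, rng=8)
        base_mean = np.mean([r.mass for r in records])
        g1 = apply_moa(records, MoaEffect.g1_arrest(), rng=9)
        g2 = apply_moa(records, MoaEffect.g2_arrest(), rng=9)
        assert np.mean([r.mass for r in g1]) < base_mean
        assert np.mean([r.mass for r in g2]) > base_mean

    def test_arrest_consolidates_distribution(self, baseline_spec):
        """Arrest shrinks the CV: the distribution consolidates around the
        arrested-stage mass."""
        records = simulate_population(baseline_spec, 4000, rng=10)
        masses = np.array([r.mass for r in records])
        g1 = np.array([r.mass for r in apply_moa(records,
                                                 MoaEffect.g1_arrest(), rng=11)])
        assert g1.std() / g1.mean() == pytest.approx(
            0.6 * masses.std() / masses.mean(), rel=1e-6)
        assert g1.mean() == pytest.approx(0.75 * masses.mean(), rel=1e-9)


class TestMixtures:
    def test_pure_first_population(self, baseline_spec):
        a = simulate_population(baseline_spec, 300, rng=12,
                                condition_id="a")
        b = simulate_population(baseline_spec, 300, rng=13,
                                condition_id="b")
        mixed = mix_populations([a, b], [1.0, 0.0], n_total=200, rng=14)
        assert len(mixed) == 200
        assert all(r.condition_id == "a" for r in mixed)

    def test_invalid_fractions_rejected(self, baseline_spec):
        pop = simulate_population(baseline_spec, 10, rng=0)
        with pytest.raises(ValidationError):
            mix_populations([pop, pop], [0.6, 0.6])

    def test_response_linear_in_responding_fraction(self, baseline_spec):
        """Mass response grows linearly with the fraction of responding
        cells in the mixture."""
        gen = np.random.default_rng(15)
        base = simulate_population(baseline_spec, 12_000, gen)
        responding = apply_moa(base, MoaEffect.uniform_shift(0.30), gen)
        ref = sample_masses(baseline_spec, 4000, gen)
        fracs = np.arange(0.0, 1.01, 0.25)
        resp = []
        for f in fracs:
            mixed = mix_populations([responding, base], [f, 1 - f],
                                    n_total=4000, rng=gen)
            resp.append(mass_response([r.mass for r in mixed], ref))
        fit = linregress(fracs, resp)
        assert fit.rvalue**2 > 0.99

    def test_combination_additivity(self, baseline_spec):
        """Three subpopulations each sensitive to one drug: the combined
        response approximates the sum of single-drug responses (effects in
        a common direction, so transport contributions do not cancel)."""
        gen = np.random.default_rng(16)
        pops = [simulate_population(baseline_spec, 4000, gen) for _ in range(3)]
        effects = [MoaEffect.uniform_shift(0.12), MoaEffect.g2_arrest(),
                   MoaEffect.anabolic()]
        ref = sample_masses(baseline_spec, 6000, gen)

        def cocktail(applied):
            mix = mix_populations(applied, [1 / 3] * 3, n_total=6000, rng=gen)
            return mass_response([r.mass for r in mix], ref)

        singles = []
        for k in range(3):
            applied = [apply_moa(p, effects[k], gen) if i == k else p
                       for i, p in enumerate(pops)]
            singles.append(cocktail(applied))
        combo = cocktail([apply_moa(p, e, gen) for p, e in zip(pops, effects)])
        assert combo == pytest.approx(sum(singles), rel=0.25)


class TestDriftAndExperiment:
    def test_drift_factor_and_overdraft_error(self):
        d = DriftModel(rate=0.04)
        assert d.factor(3.0) == pytest.approx(0.88)
        with pytest.raises(ValidationError, match="drift"):
            DriftModel(rate=0.5).factor(2.5)

    def test_experiment_structure_and_timing(self, baseline_spec):
        exp = simulate_experiment(
            baseline_spec,
            {"A": MoaEffect.uniform_shift(0.1), "B": None},
            n_per_condition=300, rng=17,
        )
        assert exp.reference.role is Role.REFERENCE
        assert exp.control.role is Role.CONTROL
        assert exp.condition_ids == ["A", "B"]

    def test_null_design_theta_near_zero(self, baseline_spec):
        exp = simulate_experiment(baseline_spec, {"A": None},
                                  n_per_condition=2500, rng=18)
        theta = theta_stat(exp.tests[0].masses, exp.control.masses,
                           exp.reference.masses)
        assert abs(theta) < 0.02

    def test_control_drift_visible_in_ctrl_signal(self, baseline_spec):
        exp = simulate_experiment(
            baseline_spec, {"A": None}, drift=DriftModel(rate=0.04),
            n_per_condition=2500, session_hours=3.0, rng=19,
        )
        ctrl = mass_response(exp.control.masses, exp.reference.masses)
        assert ctrl == pytest.approx(0.12, abs=0.02)


class TestNoiseScan:
    def test_mean_decreases_with_n_at_root_n_rate(self, baseline_spec):
        table = noise_vs_n_scan(baseline_spec, [250, 500, 1000, 2000, 4000],
                                reps=150, rng=20)
        means = table["mean_response"].to_numpy()
        assert np.all(np.diff(means) < 0)
        fit = linregress(np.log(table["n"]), np.log(means))
        assert fit.slope == pytest.approx(-0.5, abs=0.1)

    def test_large_n_approaches_zero(self, baseline_spec):
        table = noise_vs_n_scan(baseline_spec, [50_000], reps=20, rng=21)
        assert table["mean_response"].iloc[0] < 0.005
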