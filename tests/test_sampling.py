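import math

import numpy as np
import pytest

from contactfes._units import KB_KCAL, kj_to_kcal
from contactfes.contact_cv import build_contact_set
from contactfes.errors import ConfigurationError
from contactfes.sampling import (
    BeadSystem,
    EnergyBiasTable,
    EngineParams,
    GaussianWellPotential,
    HarmonicPotential,
    Hill,
    ReplicaState,
    attempt_exchange,
    bias_potential_and_force,
    calibrated_double_well,
    langevin_step,
    make_potential,
    precompute_energy_bias,
    read_hills,
    run_pt_metad,
    tune_ladder,
    write_hills,
)


class TestHillHeight:
    def test_initial_height_is_five_kj_per_mol(self):
        from contactfes.sampling import wt_hill_height
        w0 = kj_to_kcal(5.0)
        assert wt_hill_height(0.0, w0, 10.0, 300.0) == pytest.approx(w0)
        assert w0 == pytest.approx(1.1953, abs=3e-4)

    def test_decays_by_e_at_characteristic_bias(self):
        from contactfes.sampling import wt_hill_height
        v = KB_KCAL * 9.0 * 300.0
        assert wt_hill_height(v, 1.0, 10.0, 300.0) == pytest.approx(1.0 / math.e)

    def test_vanishes_for_large_bias_and_f_near_one(self):
        from contactfes.sampling import wt_hill_height
        assert wt_hill_height(1e4, 1.0, 10.0, 300.0) < 1e-300 or \
            wt_hill_height(1e4, 1.0, 10.0, 300.0) == 0.0
        # f -> 1+ collapses deposition for any positive accumulated bias
        assert wt_hill_height(0.1, 1.0, 1.0 + 1e-9, 300.0) < 1e-100

    def test_invalid_bias_factor(self):
        from contactfes.sampling import wt_hill_height
        with pytest.raises(ConfigurationError):
            wt_hill_height(0.0, 1.0, 1.0, 300.0)


class TestBiasEvaluation:
    def test_empty_hills(self):
        v, dv = bias_potential_and_force([], (0.5, 0.5))
        assert v == 0.0 and np.all(dv == 0.0)

    def test_single_hill_at_center(self):
        h = Hill(0.0, (0.3, 0.7), (0.05, 0.05), 0.8, 10.0)
        v, dv = bias_potential_and_force([h], (0.3, 0.7))
        assert v == pytest.approx(0.8)
        assert np.abs(dv).max() < 1e-12

    def test_matches_naive_full_sum_inside_truncation(self, rng):
        hills = [Hill(2.0 * k, tuple(c), (0.05, 0.07), float(h), 10.0)
                 for k, (c, h) in enumerate(zip(
                     rng.uniform(0.3, 0.7, size=(100, 2)),
                     rng.uniform(0.1, 1.2, size=100)))]
        pt = np.array([0.5, 0.5])
        v, dv = bias_potential_and_force(hills, pt)
        v_naive = sum(h.height * math.exp(
            -((pt[0] - h.center[0]) ** 2 / (2 * h.widths[0] ** 2)
              + (pt[1] - h.center[1]) ** 2 / (2 * h.widths[1] ** 2)))
            for h in hills)
        assert v == pytest.approx(v_naive, abs=1e-6)
        h_step = 1e-7
        for k in range(2):
            p1, p0 = pt.copy(), pt.copy()
            p1[k] += h_step
            p0[k] -= h_step
            fd = (bias_potential_and_force(hills, p1)[0]
                  - bias_potential_and_force(hills, p0)[0]) / (2 * h_step)
            assert dv[k] == pytest.approx(fd, abs=1e-5)


class TestLangevin:
    def _params(self, **kw):
        defaults = dict(temperature_ladder=(300.0,), timestep=0.02,
                        friction=20.0, seed=0)
        defaults.update(kw)
        return EngineParams(**defaults)

    def test_zero_temperature_fixed_point_at_minimum(self):
        params = self._params(temperature_ladder=(1e-12,))
        pot = HarmonicPotential(5.0, (0.2, 0.8))
        state = ReplicaState(np.array([0.2, 0.8]), 0.0, 0)
        out = langevin_step(state, pot, None, params,
                            np.random.default_rng(0))
        assert np.abs(out.coordinates - [0.2, 0.8]).max() < 1e-9

    def test_harmonic_stationary_variance(self):
        """Sample variance matches the discrete-map stationary value
        kBT/k · 1/(1 − kΔt/2γ) within 3 autocorrelation-aware SEs."""
        k_spring, dt, gamma, temp = 5.0, 0.02, 20.0, 300.0
        params = self._params(timestep=dt, friction=gamma,
                              temperature_ladder=(temp,))
        pot = HarmonicPotential(k_spring, (0.0, 0.0))
        state = ReplicaState(np.zeros(2), 0.0, 0)
        rng = np.random.default_rng(42)
        n, burn = 120_000, 5_000
        xs = np.empty(n)
        for i in range(n + burn):
            state = langevin_step(state, pot, None, params, rng)
            if i >= burn:
                xs[i - burn] = state.coordinates[0]
        a = 1.0 - k_spring * dt / gamma
        expected = (KB_KCAL * temp / k_spring) / (1.0 - k_spring * dt
                                                  / (2.0 * gamma))
        tau = -1.0 / math.log(a)
        ess = n / (2.0 * tau)
        se = expected * math.sqrt(2.0 / ess)
        assert abs(xs.var() - expected) < 3.0 * se

    def test_determinism_bitwise(self):
        params = self._params()
        pot = HarmonicPotential(2.0, (0.0, 0.0))

        def run():
            st = ReplicaState(np.array([0.3, -0.1]), 0.0, 0)
            rng = np.random.default_rng(7)
            path = []
            for _ in range(200):
                st = langevin_step(st, pot, None, params, rng)
                path.append(st.coordinates.copy())
            return np.array(path)

        assert np.array_equal(run(), run())

    def test_nonfinite_force_is_diagnosed(self):
        params = self._params()

        class Bad(HarmonicPotential):
            def gradient(self, x):
                return np.array([np.nan, 0.0])

        with pytest.raises(FloatingPointError):
            langevin_step(ReplicaState(np.zeros(2), 0.0, 0), Bad(), None,
                          params, np.random.default_rng(0))


class TestExchange:
    def test_equal_energies_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(attempt_exchange(1.0, 1.0, 300.0, 400.0, rng)
                   for _ in range(100))

    def test_closed_form_value(self):
        # Ti=300 K, Tj=400 K, Ui-Uj = -2 kcal/mol -> p = exp(-0.83871)
        beta_i, beta_j = 1 / (KB_KCAL * 300), 1 / (KB_KCAL * 400)
        p = math.exp((beta_i - beta_j) * (-2.0))
        assert p == pytest.approx(0.4323, abs=2e-4)
        rng = np.random.default_rng(1)
        n = 100_000
        acc = sum(attempt_exchange(-1.0, 1.0, 300.0, 400.0, rng)
                  for _ in range(n)) / n
        assert abs(acc - p) < 3.0 * math.sqrt(p * (1 - p) / n)

    def test_acceptance_on_gaussian_energy_draws(self):
        """Monte-Carlo acceptance over random energy gaps matches the
        averaged Metropolis closed form within 3σ."""
        rng = np.random.default_rng(2)
        draw = np.random.default_rng(3)
        n = 50_000
        beta_i, beta_j = 1 / (KB_KCAL * 300), 1 / (KB_KCAL * 341)
        gaps = draw.normal(0.0, 1.0, size=n)
        acc = np.array([attempt_exchange(g, 0.0, 300.0, 341.0, rng)
                        for g in gaps])
        p_each = np.minimum(1.0, np.exp((beta_i - beta_j) * gaps))
        p_mean = p_each.mean()
        se = math.sqrt(max(p_each.var() / n, p_mean * (1 - p_mean) / n))
        assert abs(acc.mean() - p_mean) < 3.0 * se

    def test_two_level_detailed_balance(self):
        """A two-replica swap chain on fixed configuration energies
        reaches the Boltzmann stationary occupancy."""
        e_lo, e_hi = 0.0, 1.0
        t_i, t_j = 300.0, 400.0
        beta_i, beta_j = 1 / (KB_KCAL * t_i), 1 / (KB_KCAL * t_j)
        rng = np.random.default_rng(4)
        # state: which configuration sits at the cold rung
        cold_has_lo = True
        n, count_lo = 60_000, 0
        for _ in range(n):
            ui, uj = (e_lo, e_hi) if cold_has_lo else (e_hi, e_lo)
            if attempt_exchange(ui, uj, t_i, t_j, rng):
                cold_has_lo = not cold_has_lo
            count_lo += cold_has_lo
        w_lo = math.exp(-beta_i * e_lo - beta_j * e_hi)
        w_hi = math.exp(-beta_i * e_hi - beta_j * e_lo)
        p_expected = w_lo / (w_lo + w_hi)
        p_measured = count_lo / n
        se = math.sqrt(p_expected * (1 - p_expected) / n)
        # swap chain correlates consecutive samples; allow a generous factor
        assert abs(p_measured - p_expected) < 3.0 * se * 3.0


class TestEnergyBias:
    def test_zero_scale_reproduces_unbiased_pt(self):
        pot = make_potential("double_well_2d")
        params = EngineParams(temperature_ladder=(300.0, 330.0, 365.0, 400.0),
                              seed=9)
        tab = precompute_energy_bias(pot, params, n_steps=2000)
        tab0 = EnergyBiasTable(tab.energies, tab.values, scale=0.0)
        r_bias = run_pt_metad(pot, params, 800, deposit_hills=False,
                              energy_bias=tab0)
        r_plain = run_pt_metad(pot, params, 800, deposit_hills=False)
        for a, b in zip(r_bias.replica_paths, r_plain.replica_paths):
            assert np.array_equal(a, b)

    def test_frozen_bias_broadens_energy_histogram(self):
        pot = HarmonicPotential(3.0, (0.5, 0.5))
        params = EngineParams(temperature_ladder=(300.0,), seed=11,
                              timestep=0.02, friction=20.0)
        tab = precompute_energy_bias(pot, params, n_steps=8000,
                                     start=(0.5, 0.5))

        def energy_series(bias):
            res = run_pt_metad(pot, params, 10_000, start=(0.5, 0.5),
                               deposit_hills=False, energy_bias=bias,
                               record_stride=5)
            return np.array([pot.value(p) for p in res.replica_paths[0]])[200:]

        assert energy_series(tab).var() >= energy_series(None).var()

    def test_table_roundtrip_bit_exact(self, tmp_path):
        tab = EnergyBiasTable(np.linspace(0, 3, 7),
                              np.array([0.1, 0.4, 1.1, 0.9, 0.3, 0.05, 0.0]),
                              scale=0.35)
        p = tmp_path / "wte.txt"
        tab.write(p)
        back = EnergyBiasTable.read(p)
        assert np.array_equal(back.energies, tab.energies)
        assert np.array_equal(back.values, tab.values)
        assert back.scale == tab.scale
        back.write(tmp_path / "wte2.txt")
        assert (tmp_path / "wte2.txt").read_text() == p.read_text()


class TestEngine:
    def test_short_run_emits_no_hills(self):
        pot = make_potential("double_well_2d")
        params = EngineParams(temperature_ladder=(300.0,), seed=0,
                              deposition_stride=40)
        res = run_pt_metad(pot, params, 30)
        assert res.hills == []

    def test_hill_heights_nonincreasing_at_a_pinned_point(self):
        """A walker pinned in a stiff well revisits the same CV point, so
        the well-tempered law makes consecutive heights decay."""
        # at T -> 0 the walker sits exactly at the minimum (zero bias force
        # at a hill's own center), so every hill lands on the same point
        pot = HarmonicPotential(400.0, (0.5, 0.5))
        params = EngineParams(temperature_ladder=(1e-12,), seed=1,
                              timestep=0.01, friction=50.0,
                              deposition_stride=10)
        res = run_pt_metad(pot, params, 2000, start=(0.5, 0.5))
        heights = [h.height for h in res.hills]
        assert len(heights) > 10
        assert heights[1] < heights[0]
        assert all(b <= a for a, b in zip(heights, heights[1:]))

    def test_bias_accelerates_barrier_crossing(self):
        """On the calibrated 6 kcal/mol double well the biased walker
        crosses between wells far more often than the unbiased one."""
        pot = calibrated_double_well()
        params = EngineParams(temperature_ladder=(300.0,), seed=3)

        def crossings(deposit):
            res = run_pt_metad(pot, params, 120_000, start=(0.25, 0.5),
                               deposit_hills=deposit, record_stride=40)
            side = np.sign(res.cv_records and
                           np.array([r.cv1 for r in res.cv_records]) - 0.5)
            side = side[side != 0]
            return int(np.sum(side[1:] != side[:-1]))

        biased = crossings(True)
        unbiased = crossings(False)
        assert biased >= 10 * max(unbiased, 1) or (unbiased == 0 and biased >= 4)

    def test_replica_streams_disjoint_from_ladder_size(self):
        pot = make_potential("double_well_2d")
        common = dict(seed=17, deposition_stride=40)
        p2 = EngineParams(temperature_ladder=(300.0, 340.0), **common)
        p5 = EngineParams(temperature_ladder=(300.0, 340.0, 360.0, 380.0,
                                              400.0), **common)
        r2 = run_pt_metad(pot, p2, 500, deposit_hills=False,
                          record_stride=10)
        r5 = run_pt_metad(pot, p5, 500, deposit_hills=False,
                          record_stride=10)
        # exchanges perturb paths; compare with exchanges disabled
        p2 = EngineParams(temperature_ladder=(300.0, 340.0),
                          exchange_stride=10**9, **common)
        p5 = EngineParams(temperature_ladder=(300.0, 340.0, 360.0, 380.0,
                                              400.0),
                          exchange_stride=10**9, **common)
        r2 = run_pt_metad(pot, p2, 500, deposit_hills=False, record_stride=10)
        r5 = run_pt_metad(pot, p5, 500, deposit_hills=False, record_stride=10)
        assert np.array_equal(r2.replica_paths[0], r5.replica_paths[0])

    def test_structure_mode_requires_contact_set(self, two_state):
        sysb = BeadSystem(two_state["ref_in"], stiffness=1.0)
        params = EngineParams(temperature_ladder=(300.0,), seed=0)
        with pytest.raises(ConfigurationError):
            run_pt_metad(sysb, params, 100, mode="structure")

    def test_structure_mode_runs_and_is_deterministic(self, two_state,
                                                      contact_set):
        sysb = BeadSystem(two_state["ref_in"], stiffness=1.0)
        params = EngineParams(temperature_ladder=(300.0, 330.0), seed=5,
                              timestep=0.02, friction=20.0,
                              deposition_stride=25, exchange_stride=10)
        r1 = run_pt_metad(sysb, params, 500, contact_set=contact_set,
                          mode="structure")
        r2 = run_pt_metad(sysb, params, 500, contact_set=contact_set,
                          mode="structure")
        assert len(r1.hills) == 500 // 25
        assert np.array_equal(r1.replica_paths[0], r2.replica_paths[0])
        assert all(0.0 <= r.cv1 <= 1.0 and 0.0 <= r.cv2 <= 1.0
                   for r in r1.cv_records)

    def test_ladder_tuner_reaches_target_band(self, two_state, contact_set):
        """On a many-particle bead system the geometric-ratio tuner lands
        within ±5% of the 30% target rate."""
        sysb = BeadSystem(two_state["ref_in"], stiffness=2.0)
        params = EngineParams(
            temperature_ladder=tuple(300.0 * 1.05**k for k in range(4)),
            seed=2, timestep=0.02, friction=20.0, exchange_stride=10)
        ladder, rate = tune_ladder(sysb, params, target_rate=0.30,
                                   tolerance=0.05, n_steps=1500)
        assert abs(rate - 0.30) <= 0.05
        assert all(b > a for a, b in zip(ladder, ladder[1:]))


def test_hills_file_roundtrip(tmp_path, rng):
    hills = [Hill(2.0 * k, (float(a), float(b)), (0.05, 0.05), float(h), 10.0)
             for k, (a, b, h) in enumerate(rng.uniform(0, 1, size=(20, 3)))]
    p = tmp_path / "HILLS"
    write_hills(hills, p)
    assert p.read_text().splitlines()[0] == \
        "#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf"
    back = read_hills(p)
    for h1, h2 in zip(hills, back):
        assert h1.center == pytest.approx(h2.center, abs=1e-9)
        assert h1.height == pytest.approx(h2.height, abs=1e-9)
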