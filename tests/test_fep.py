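"""Free-energy estimators, the thermodynamic cycle, and substitution rules."""

import math

import numpy as np
import pytest

from bzrmd.fep import (
    BaseSubstitution,
    WorkSamples,
    apply_substitution,
    bar_delta_f,
    binding_ddg,
    kt_to_kcal_per_mol,
    make_lambda_schedule,
    read_sample_table,
    stratified_delta_g,
    write_sample_table,
    zwanzig_delta_f,
)
from bzrmd.synthetic import ToyAlchemySpec, make_toy_binding_system, sample_harmonic_alchemy

ANALYTIC_14 = 0.5 * math.log(4.0)  # harmonic k 1 -> 4 at kT = 1


def harmonic_work(k0, k1, n_f, n_r, seed):
    rng = np.random.default_rng(seed)
    xf = rng.normal(0.0, 1.0 / math.sqrt(k0), n_f)
    xr = rng.normal(0.0, 1.0 / math.sqrt(k1), n_r)
    return 0.5 * (k1 - k0) * xf**2, -0.5 * (k1 - k0) * xr**2


class TestLambdaSchedule:
    def test_two_states(self):
        assert make_lambda_schedule(2).states == (0.0, 1.0)

    def test_three_states(self):
        assert make_lambda_schedule(3).states == (0.0, 0.5, 1.0)

    def test_21_states_gives_19_intermediates(self):
        s = make_lambda_schedule(21)
        assert s.n_states == 21
        assert s.n_intermediates == 19
        assert s.n_steps == 20
        diffs = np.diff(s.states)
        np.testing.assert_allclose(diffs, 0.05, atol=1e-12)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            make_lambda_schedule(1)


class TestBar:
    def test_identical_states_zero(self):
        zeros = np.zeros(100)
        df, err = bar_delta_f(zeros, zeros)
        assert df == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetry_exact(self):
        fwd, rev = harmonic_work(1.0, 2.5, 800, 800, seed=5)
        df_fwd, _ = bar_delta_f(fwd, rev)
        df_rev, _ = bar_delta_f(rev, fwd)
        assert df_fwd == pytest.approx(-df_rev, abs=1e-9)

    def test_harmonic_closed_form_recovered(self):
        fwd, rev = harmonic_work(1.0, 4.0, 10_000, 10_000, seed=12)
        df, err = bar_delta_f(fwd, rev)
        assert df == pytest.approx(ANALYTIC_14, abs=3 * err)

    def test_unequal_sample_counts_unbiased(self):
        # catches a wrong sign on the ln(n_f/n_r) offset in the
        # self-consistency equation
        devs = []
        for seed in range(30):
            fwd, rev = harmonic_work(1.0, 4.0, 8000, 2000, seed=seed)
            df, err = bar_delta_f(fwd, rev)
            devs.append(df - ANALYTIC_14)
        assert abs(np.mean(devs)) < 3 * np.std(devs) / math.sqrt(len(devs))

    def test_reported_uncertainty_tracks_empirical_scatter(self):
        devs, errs = [], []
        for seed in range(40):
            fwd, rev = harmonic_work(1.0, 4.0, 2000, 2000, seed=100 + seed)
            df, err = bar_delta_f(fwd, rev)
            devs.append(df - ANALYTIC_14)
            errs.append(err)
        assert np.mean(errs) == pytest.approx(np.std(devs), rel=0.5)

    def test_non_overlap_raises_with_advice(self):
        fwd = np.full(50, 200.0)
        rev = np.full(50, 200.0)
        with pytest.raises(ValueError, match="more λ states"):
            bar_delta_f(fwd, rev)

    def test_deterministic_given_samples(self):
        fwd, rev = harmonic_work(1.0, 3.0, 500, 500, seed=8)
        assert bar_delta_f(fwd, rev) == bar_delta_f(fwd.copy(), rev.copy())

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            WorkSamples(forward=np.array([]), reverse=np.array([1.0]))


class TestZwanzig:
    def test_zero_differences(self):
        assert zwanzig_delta_f(np.zeros(10)) == pytest.approx(0.0)

    def test_harmonic_closed_form_at_large_n(self):
        rng = np.random.default_rng(77)
        x = rng.normal(0.0, 1.0, 100_000)
        fwd = 0.5 * 3.0 * x**2  # k 1 -> 4
        est = zwanzig_delta_f(fwd)
        assert est == pytest.approx(ANALYTIC_14, abs=0.03)

    def test_one_sided_asymmetry_vs_bar_antisymmetry(self):
        # zwanzig(u) != -zwanzig(-u) in general: one-sided estimators are not
        # direction-symmetric, while BAR is (documented contrast)
        rng = np.random.default_rng(13)
        u = rng.normal(1.0, 2.0, 500)
        assert zwanzig_delta_f(u) != pytest.approx(-zwanzig_delta_f(-u), abs=1e-3)

    def test_bar_beats_zwanzig_in_squared_error(self):
        # minimum-variance property on overlapping equal-n harmonic samples
        bar_sq, zw_sq = [], []
        for seed in range(100):
            fwd, rev = harmonic_work(1.0, 4.0, 400, 400, seed=1000 + seed)
            bar_sq.append((bar_delta_f(fwd, rev)[0] - ANALYTIC_14) ** 2)
            zw_sq.append((zwanzig_delta_f(fwd) - ANALYTIC_14) ** 2)
        assert np.mean(bar_sq) <= np.mean(zw_sq)


class TestStratified:
    def test_identical_state_steps_total_zero(self):
        schedule = make_lambda_schedule(5)
        steps = [WorkSamples(np.zeros(50), np.zeros(50)) for _ in range(4)]
        res = stratified_delta_g(schedule, steps, "bar")
        assert res.delta_g == pytest.approx(0.0, abs=1e-9)

    def test_total_is_sum_of_steps(self):
        steps, _ = sample_harmonic_alchemy(ToyAlchemySpec(seed=4, samples_per_state=2000))
        res = stratified_delta_g(make_lambda_schedule(21), steps, "bar")
        assert res.delta_g == pytest.approx(sum(dg for dg, _ in res.per_step), abs=1e-12)

    def test_harmonic_path_recovers_closed_form(self):
        steps, analytic = sample_harmonic_alchemy(ToyAlchemySpec(seed=6))
        res = stratified_delta_g(make_lambda_schedule(21), steps, "bar")
        assert res.delta_g == pytest.approx(analytic, abs=3 * res.uncertainty)

    def test_schedule_reversal_negates_exactly(self):
        steps, _ = sample_harmonic_alchemy(ToyAlchemySpec(seed=15, samples_per_state=1000))
        schedule = make_lambda_schedule(21)
        fwd = stratified_delta_g(schedule, steps, "bar")
        reversed_steps = [ws.swapped() for ws in reversed(steps)]
        rev = stratified_delta_g(schedule.reversed(), reversed_steps, "bar")
        assert rev.delta_g == pytest.approx(-fwd.delta_g, abs=1e-9)

    def test_state_function_21_vs_41_states(self):
        # ΔG is a state function: refining the λ path does not move the total
        r21 = stratified_delta_g(
            make_lambda_schedule(21),
            sample_harmonic_alchemy(ToyAlchemySpec(seed=2, n_states=21))[0],
            "bar",
        )
        r41 = stratified_delta_g(
            make_lambda_schedule(41),
            sample_harmonic_alchemy(ToyAlchemySpec(seed=2, n_states=41))[0],
            "bar",
        )
        combined = math.hypot(r21.uncertainty, r41.uncertainty)
        assert r21.delta_g == pytest.approx(r41.delta_g, abs=3 * combined)

    def test_missing_step_names_lambda_pair(self):
        schedule = make_lambda_schedule(4)
        with pytest.raises(ValueError, match="missing samples"):
            stratified_delta_g(schedule, {0: WorkSamples(np.zeros(5), np.zeros(5))}, "bar")


class TestBindingDdg:
    def test_cycle_closure_identical_legs(self):
        steps, _ = sample_harmonic_alchemy(ToyAlchemySpec(seed=3, samples_per_state=500))
        res = stratified_delta_g(make_lambda_schedule(21), steps, "bar")
        out = binding_ddg([(res, res)])
        assert out.ddg == pytest.approx(0.0, abs=1e-12)

    def test_toy_binding_recovers_analytic_cycle(self):
        free = ToyAlchemySpec(k0=1.0, k1=1.0, seed=30, samples_per_state=4000)
        complx = ToyAlchemySpec(k0=1.0, k1=4.0, seed=30, samples_per_state=4000)
        reps, analytic = make_toy_binding_system(free, complx, n_replicates=6)
        schedule = make_lambda_schedule(21)
        pairs = [
            (stratified_delta_g(schedule, c, "bar"), stratified_delta_g(schedule, f, "bar"))
            for c, f in reps
        ]
        out = binding_ddg(pairs)
        assert analytic == pytest.approx(ANALYTIC_14)
        se = out.sd / math.sqrt(len(out.replicate_values))
        assert out.mean == pytest.approx(analytic, abs=max(3 * se, 0.02))

    def test_positive_ddg_means_weakened_binding(self):
        # stiffening the complex leg (k 1 -> 4) while the free leg is flat
        # must give a positive ΔΔG: the substitution disfavours the complex
        free = ToyAlchemySpec(k0=1.0, k1=1.0, seed=40, samples_per_state=2000)
        complx = ToyAlchemySpec(k0=1.0, k1=4.0, seed=40, samples_per_state=2000)
        reps, _ = make_toy_binding_system(free, complx, n_replicates=3)
        schedule = make_lambda_schedule(21)
        pairs = [
            (stratified_delta_g(schedule, c, "bar"), stratified_delta_g(schedule, f, "bar"))
            for c, f in reps
        ]
        assert binding_ddg(pairs).mean > 0

    def test_forward_plus_reverse_substitution_closes(self):
        # ΔΔG(fwd) + ΔΔG(rev) = 0 within combined uncertainty on the toy cycle
        schedule = make_lambda_schedule(21)

        def one_direction(k_from, k_to, seed):
            free = ToyAlchemySpec(k0=1.0, k1=1.0, seed=seed, samples_per_state=2000)
            complx = ToyAlchemySpec(k0=k_from, k1=k_to, seed=seed, samples_per_state=2000)
            reps, _ = make_toy_binding_system(free, complx, n_replicates=4)
            pairs = [
                (stratified_delta_g(schedule, c, "bar"), stratified_delta_g(schedule, f, "bar"))
                for c, f in reps
            ]
            return binding_ddg(pairs)

        fwd = one_direction(1.0, 4.0, seed=50)
        rev = one_direction(4.0, 1.0, seed=60)
        n = len(fwd.replicate_values)
        combined = math.hypot(fwd.sd / math.sqrt(n), rev.sd / math.sqrt(n))
        assert fwd.mean + rev.mean == pytest.approx(0.0, abs=max(3 * combined, 0.02))

    def test_six_replicates_reported(self):
        values = [0.1, 0.2, 0.15, 0.12, 0.18, 0.16]
        out = binding_ddg([(v, 0.0) for v in values])
        assert len(out.replicate_values) == 6
        assert out.mean == pytest.approx(np.mean(values))
        assert out.sd == pytest.approx(np.std(values, ddof=1))

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            binding_ddg([])

    def test_kcal_conversion(self):
        assert kt_to_kcal_per_mol(1.0, 300.0) == pytest.approx(0.596, abs=0.001)


class TestSubstitutions:
    def test_c1_to_t1(self):
        rec = apply_substitution(BaseSubstitution("CACGTG", 1, "C", "T"))
        assert rec.altered_motif == "TACGTG"
        assert "G->A" in rec.paired_change

    def test_a2_to_g2(self):
        rec = apply_substitution(BaseSubstitution("CACGTG", 2, "A", "G"))
        assert rec.altered_motif == "CGCGTG"
        assert "T->C" in rec.paired_change

    def test_class_crossing_rejected(self):
        with pytest.raises(ValueError, match="class"):
            apply_substitution(BaseSubstitution("CACGTG", 1, "C", "A"))

    def test_wrong_from_base_rejected(self):
        with pytest.raises(ValueError, match="position"):
            BaseSubstitution("CACGTG", 1, "A", "G")


class TestSampleTable:
    def test_round_trip(self, tmp_path):
        steps, _ = sample_harmonic_alchemy(
            ToyAlchemySpec(seed=1, n_states=4, samples_per_state=20)
        )
        path = tmp_path / "samples.tsv"
        write_sample_table(steps, path)
        back = read_sample_table(path)
        assert len(back) == len(steps)
        for a, b in zip(steps, back):
            np.testing.assert_allclose(a.forward, b.forward, rtol=1e-9)
            np.testing.assert_allclose(a.reverse, b.reverse, rtol=1e-9)

    def test_missing_direction_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("step_index\tdirection\tvalue_kT\n0\tforward\t0.5\n")
        with pytest.raises(ValueError, match="lacks"):
            read_sample_table(path)
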