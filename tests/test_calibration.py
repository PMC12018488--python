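import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pragsub.calibration import (
    c_for_benefit,
    concordance_for_benefit,
    qini_coefficient,
    qini_curve,
)
from pragsub.estimation import CateEstimate
from pragsub.exceptions import DegenerateInputError, UnsupportedInputError
from pragsub.synthesis import oracle_cate, simulate_trial

from conftest import cell_config, null_config, tiny_dataset
from oracles import brute_concordance, brute_qini_coefficient, brute_qini_points


def _estimate_for(ds, tau):
    return CateEstimate.from_arrays(
        subject_id=ds.subject_id.to_numpy(), tau=np.asarray(tau, dtype=float)
    )


class TestQini:
    def test_four_subject_worked_example(self):
        # descending-tau order (A,Y) = (1,1), (0,0), (0,1), (1,0); unit weights
        ds = tiny_dataset(a=[1, 0, 0, 1], y=[1.0, 0.0, 1.0, 0.0])
        est = _estimate_for(ds, [0.4, 0.3, 0.2, 0.1])
        result = qini_curve(est, ds, grid=np.array([0.5, 1.0]))
        np.testing.assert_allclose(
            result.curve.to_numpy(), [[0.0, 0.0], [0.5, 1.0], [1.0, 0.0]]
        )
        assert qini_coefficient(result) == pytest.approx(0.5)

    def test_constant_tau_balanced_rates_gives_zero(self):
        # ids order alternates arms with equal outcome rates at every prefix
        ds = tiny_dataset(a=[1, 0, 1, 0], y=[1.0, 1.0, 0.0, 0.0])
        est = _estimate_for(ds, [0.2, 0.2, 0.2, 0.2])
        result = qini_curve(est, ds, grid=np.array([0.5, 1.0]))
        assert qini_coefficient(result) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(6, 40))
            a = rng.integers(0, 2, n)
            if a.min() == a.max():
                continue
            y = rng.integers(0, 2, n).astype(float)
            tau = rng.normal(size=n).round(2)  # rounded to exercise ties
            ds = tiny_dataset(a=a, y=y)
            w = rng.uniform(0.5, 2.0, n)
            from pragsub.estimation import CensoringWeights
            import pandas as pd

            ids = ds.subject_id.to_numpy()
            weights = CensoringWeights(
                probability=pd.Series(1.0, index=ids),
                weights=pd.Series(w, index=ids),
                truncation_quantile=1.0,
            )
            fractions = np.linspace(0.1, 1.0, 10)
            result = qini_curve(_estimate_for(ds, tau), ds, weights=weights,
                                grid=fractions)
            expected = brute_qini_points(tau, a, y, w, ids, fractions)
            np.testing.assert_allclose(result.curve.to_numpy(), np.asarray(expected))
            assert qini_coefficient(result) == pytest.approx(
                brute_qini_coefficient(expected)
            )

    def test_permuted_tau_centers_at_zero(self):
        ds = simulate_trial(cell_config(2000, seed=50))
        rng = np.random.default_rng(51)
        oracle = oracle_cate(ds)
        coefs = []
        for _ in range(200):
            tau = rng.permutation(oracle.tau)
            coefs.append(qini_coefficient(qini_curve(_estimate_for(ds, tau), ds)))
        se = np.std(coefs) / np.sqrt(len(coefs))
        assert abs(np.mean(coefs)) < 3 * se

    def test_reversed_ranking_flips_sign(self):
        # balanced arms with equal outcome totals per arm: negating tau flips
        # the coefficient's sign (the prefix ratio-adjustment keeps the flip
        # from being an exact negation, so only the sign is asserted)
        rng = np.random.default_rng(7)
        a = np.array([1, 0] * 20)
        y = np.tile([1.0, 1.0, 0.0, 0.0], 10)
        grid = np.arange(1, 41) / 40
        ds = tiny_dataset(a=a, y=y)
        fwd, rev = [], []
        for _ in range(200):
            tau = rng.normal(size=40)
            fwd.append(qini_coefficient(qini_curve(_estimate_for(ds, tau), ds, grid=grid)))
            rev.append(qini_coefficient(qini_curve(_estimate_for(ds, -tau), ds, grid=grid)))
        fwd, rev = np.asarray(fwd), np.asarray(rev)
        assert np.corrcoef(fwd, rev)[0, 1] < -0.8
        se = (fwd + rev).std() / np.sqrt(len(fwd))
        assert abs((fwd + rev).mean()) < 3 * se
        strong = np.abs(fwd) > 0.5
        assert np.mean(np.sign(rev[strong]) == -np.sign(fwd[strong])) > 0.9

    def test_single_arm_rejected(self):
        ds = tiny_dataset(a=[1, 1, 1], y=[1.0, 0.0, 1.0])
        with pytest.raises(UnsupportedInputError):
            qini_curve(_estimate_for(ds, [0.1, 0.2, 0.3]), ds)

    def test_degenerate_curve_rejected(self):
        from pragsub.calibration import QiniResult
        import pandas as pd

        bad = QiniResult(curve=pd.DataFrame({"fraction": [0.0], "uplift": [0.0]}),
                         total_uplift=0.0)
        with pytest.raises(DegenerateInputError):
            qini_coefficient(bad)

    def test_per_subject_scale(self):
        ds = tiny_dataset(a=[1, 0, 0, 1], y=[1.0, 0.0, 1.0, 0.0])
        est = _estimate_for(ds, [0.4, 0.3, 0.2, 0.1])
        counts = qini_coefficient(qini_curve(est, ds, grid=np.array([0.5, 1.0])))
        per = qini_coefficient(
            qini_curve(est, ds, grid=np.array([0.5, 1.0]), scale="per-subject")
        )
        assert per == pytest.approx(counts / 4)


class TestCforBenefit:
    def test_three_pair_worked_examples(self):
        obs = np.array([1, 0, -1])
        assert brute_concordance(obs, np.array([0.3, 0.1, -0.2])) == 1.0
        assert concordance_for_benefit(obs, np.array([0.3, 0.1, -0.2])) == 1.0
        assert concordance_for_benefit(obs, np.array([-0.2, 0.1, 0.3])) == 0.0
        assert concordance_for_benefit(obs, np.array([0.1, 0.1, 0.1])) == 0.5

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = int(rng.integers(3, 30))
            obs = rng.choice([-1, 0, 1], m)
            pred = rng.choice([-0.2, 0.0, 0.1, 0.3], m)
            got = concordance_for_benefit(obs, pred)
            want = brute_concordance(obs, pred)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    @settings(max_examples=150, deadline=None)
    @given(
        obs=st.lists(st.sampled_from([-1, 0, 1]), min_size=2, max_size=25),
        data=st.data(),
    )
    def test_concordance_matches_brute_force_hypothesis(self, obs, data):
        pred = data.draw(
            st.lists(
                st.floats(min_value=-1, max_value=1, allow_nan=False),
                min_size=len(obs), max_size=len(obs),
            )
        )
        got = concordance_for_benefit(np.array(obs), np.array(pred))
        want = brute_concordance(np.array(obs), np.array(pred))
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want)

    def test_pairing_counts_and_ranks(self):
        ds = simulate_trial(cell_config(400, seed=60))
        est = oracle_cate(ds)
        result = c_for_benefit(est, ds, n_boot=0)
        analytic = ds.retained_subset()
        n1 = int((analytic.treatment == 1).sum())
        n0 = int((analytic.treatment == 0).sum())
        assert len(result.pairs) == min(n1, n0)
        # both sides of each pair are sorted descending by tau
        assert (np.diff(result.pairs["predicted"]) <= 1e-12).all()

    def test_degenerate_when_all_observed_equal(self):
        ds = tiny_dataset(a=[1, 0, 1, 0], y=[1.0, 1.0, 1.0, 1.0])
        result = c_for_benefit(_estimate_for(ds, [0.4, 0.3, 0.2, 0.1]), ds, n_boot=0)
        assert result.degenerate
        assert np.isnan(result.statistic)

    def test_invariant_to_monotone_transform(self):
        ds = simulate_trial(cell_config(600, seed=61))
        est = oracle_cate(ds)
        base = c_for_benefit(est, ds, n_boot=0).statistic
        for transform in (lambda t: 2 * t + 1, np.exp, lambda t: t**3):
            warped = _estimate_for(ds.retained_subset(), transform(
                est.aligned_to(ds.retained_subset().subject_id.to_numpy()).tau))
            # rebuild over the full dataset ids
            warped = _estimate_for(ds, transform(est.tau))
            assert c_for_benefit(warped, ds, n_boot=0).statistic == pytest.approx(base)

    def test_bootstrap_ci_brackets_statistic(self):
        ds = simulate_trial(cell_config(800, seed=62))
        result = c_for_benefit(oracle_cate(ds), ds, n_boot=100, seed=3)
        lo, hi = result.ci
        assert lo <= result.statistic <= hi

    def test_bootstrap_seed_determinism(self):
        ds = simulate_trial(cell_config(400, seed=63))
        r1 = c_for_benefit(oracle_cate(ds), ds, n_boot=50, seed=4)
        r2 = c_for_benefit(oracle_cate(ds), ds, n_boot=50, seed=4)
        assert r1.ci == r2.ci


class TestStatisticalBehaviour:
    def test_signal_behaviour_with_oracle_tau(self):
        # planted heterogeneity: better-than-chance in >= 95% of replicates
        wins_q, wins_c, reps = 0, 0, 100
        for seed in range(reps):
            ds = simulate_trial(cell_config(4000, seed=1000 + seed, extra=False))
            est = oracle_cate(ds)
            q = qini_coefficient(qini_curve(est, ds))
            c = c_for_benefit(est, ds, n_boot=0).statistic
            wins_q += q > 0
            wins_c += c > 0.5
        assert wins_q >= 0.95 * reps
        assert wins_c >= 0.95 * reps

    def test_null_noise_tau_centers_on_chance(self):
        rng = np.random.default_rng(5)
        qs, cs = [], []
        for seed in range(200):
            ds = simulate_trial(null_config(500, seed=2000 + seed))
            tau = rng.normal(size=ds.n)
            est = _estimate_for(ds, tau)
            qs.append(qini_coefficient(qini_curve(est, ds)))
            cs.append(c_for_benefit(est, ds, n_boot=0).statistic)
        q_se = np.std(qs) / np.sqrt(len(qs))
        c_se = np.std(cs) / np.sqrt(len(cs))
        assert abs(np.mean(qs)) < 3 * q_se
        assert abs(np.mean(cs) - 0.5) < 3 * c_se

    def test_bootstrap_ci_covers_large_sample_value(self):
        big = simulate_trial(cell_config(40_000, seed=90, extra=False))
        target = c_for_benefit(oracle_cate(big), big, n_boot=0).statistic
        covered = 0
        reps = 50
        for seed in range(reps):
            ds = simulate_trial(cell_config(600, seed=3000 + seed, extra=False))
            result = c_for_benefit(oracle_cate(ds), ds, n_boot=200, seed=seed)
            lo, hi = result.ci
            covered += lo <= target <= hi
        assert covered >= 0.90 * reps
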