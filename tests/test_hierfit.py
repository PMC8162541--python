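"""Hierarchical Wiener model: structure, log-density oracle, sampling
contract, recovery, shrinkage."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from diffstab import ddm, hierfit, synth


def _toy_trials(n_per_person=30, persons=(0, 1), seed=0, params=None):
    rng = np.random.default_rng(seed)
    params = params or ddm.DDMParameters(2.0, 2.0, 0.5, 0.4, 0.7)
    rows = []
    traits = [c.split(":")[0] for c in ddm.CONDITIONS]
    congr = [c.split(":")[1] for c in ddm.CONDITIONS]
    for pid in persons:
        rt, correct = ddm.simulate_trials(params, n_per_person, rng)
        cond = rng.integers(0, 10, n_per_person)
        for j in range(n_per_person):
            rows.append(
                {
                    "participant_id": pid,
                    "time_point": 0,
                    "trait": traits[cond[j]],
                    "congruency": congr[cond[j]],
                    "block_index": int(cond[j]),
                    "trial_index": j,
                    "correct": bool(correct[j]),
                    "rt_s": float(rt[j]),
                }
            )
    return pd.DataFrame(rows)


class TestModelStructure:
    def test_person_parameter_count(self):
        assert hierfit.ModelSpec().n_person_params == 22

    def test_build_collects_persons_and_trials(self):
        trials = _toy_trials(persons=range(10))
        model = hierfit.build_model(trials)
        assert model.n_persons == 10
        # 22 person-level free parameters each
        assert model.spec.n_person_params * model.n_persons == 220

    def test_small_participants_excluded_with_warning(self):
        trials = pd.concat(
            [_toy_trials(n_per_person=30, persons=(0, 1)), _toy_trials(n_per_person=5, persons=(2,))],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="fewer than"):
            model = hierfit.build_model(trials)
        assert model.n_persons == 2
        assert model.excluded_persons == [2]

    def test_all_correct_participant_builds(self):
        trials = _toy_trials(persons=(0, 1), params=ddm.DDMParameters(4.0, 3.0, 0.5, 0.4, 0.7))
        trials["correct"] = True
        model = hierfit.build_model(trials)
        assert model.n_persons == 2

    def test_unknown_condition_label_rejected(self):
        trials = _toy_trials(persons=(0, 1))
        trials.loc[0, "trait"] = "telepathy"
        with pytest.raises(hierfit.FitError):
            hierfit.build_model(trials)

    def test_fewer_than_two_participants_rejected(self):
        with pytest.raises(hierfit.FitError):
            hierfit.build_model(_toy_trials(persons=(0,)))


class TestLogDensity:
    def test_joint_log_density_matches_hand_assembled_sum(self):
        """5-trial toy set: term-by-term oracle for the joint log density."""
        trials = _toy_trials(n_per_person=5, persons=(0, 1), seed=3)
        model = hierfit.build_model(
            trials, spec=hierfit.ModelSpec(min_trials=1)
        )
        rng = np.random.default_rng(4)
        P = np.zeros((2, 22))
        P[:, 0] = [2.1, 1.9]
        P[:, 1] = [2.0, 2.2]
        P[:, 2] = [0.35, 0.30]
        P[:, 3] = [0.60, 0.55]
        P[:, 4:] = 0.01 * rng.standard_normal((2, 18))
        hypers = {
            "mu_nu": 2.0, "sigma_nu": 0.5, "mu_a": 2.0, "sigma_a": 0.5,
            "mu_tau_c": 0.4, "sigma_tau_c": 0.1, "mu_tau_e": 0.6, "sigma_tau_e": 0.1,
            "sigma_eff_nu": 0.1, "sigma_eff_a": 0.05,
            "eff_nu": 0.02 * rng.standard_normal(9),
            "eff_a": 0.01 * rng.standard_normal(9),
        }

        expected = 0.0
        df = trials.sort_values("participant_id", kind="stable")
        for i, (pid, sub) in enumerate(df.groupby("participant_id")):
            dnu = np.append(P[i, 4:13], -P[i, 4:13].sum())
            da = np.append(P[i, 13:22], -P[i, 13:22].sum())
            for row in sub.itertuples():
                c = ddm.CONDITIONS.index(f"{row.trait}:{row.congruency}")
                p = ddm.DDMParameters(
                    P[i, 0] + dnu[c], P[i, 1] + da[c], 0.5, 0.0, 0.0
                )
                tau = P[i, 2] if row.correct else P[i, 3]
                boundary = "upper" if row.correct else "lower"
                expected += float(ddm.wfpt_logdensity(row.rt_s - tau, boundary, p))
            expected += stats.norm.logpdf(P[i, 0], 2.0, 0.5)
            expected += stats.norm.logpdf(P[i, 1], 2.0, 0.5)
            expected += stats.norm.logpdf(P[i, 2], 0.4, 0.1)
            expected += stats.norm.logpdf(P[i, 3], 0.6, 0.1)
            expected += stats.norm.logpdf(P[i, 4:13], hypers["eff_nu"], 0.1).sum()
            expected += stats.norm.logpdf(P[i, 13:22], hypers["eff_a"], 0.05).sum()
        priors = model.priors
        for name in hierfit.HYPER_NAMES:
            expected += priors.logpdf(name, hypers[name])
        for c in range(9):
            expected += priors.logpdf("eff_nu", hypers["eff_nu"][c])
            expected += priors.logpdf("eff_a", hypers["eff_a"][c])

        assert model.log_density(P, hypers) == pytest.approx(expected, rel=1e-9)

    def test_rt_below_ndt_gives_minus_inf(self):
        trials = _toy_trials(n_per_person=5, persons=(0, 1), seed=5)
        model = hierfit.build_model(trials, spec=hierfit.ModelSpec(min_trials=1))
        P = np.zeros((2, 22))
        P[:, :4] = [2.0, 2.0, 10.0, 10.0]  # tau above every RT
        hypers = dict(
            mu_nu=2.0, sigma_nu=0.5, mu_a=2.0, sigma_a=0.5,
            mu_tau_c=0.4, sigma_tau_c=0.1, mu_tau_e=0.6, sigma_tau_e=0.1,
            sigma_eff_nu=0.1, sigma_eff_a=0.05,
            eff_nu=np.zeros(9), eff_a=np.zeros(9),
        )
        assert model.log_density(P, hypers) == -np.inf


class TestSampling:
    def test_retained_draw_count_and_metadata(self, recovery_fit):
        _, _, _, draws = recovery_fit
        assert draws.n_retained == 2000 - 700
        for name in ("mu_nu", "mu_a", "mu_tau_c"):
            assert draws[name].shape == (2, 1300)
        meta = draws.metadata()
        assert meta["n_chains"] == 2 and meta["n_burnin"] == 700

    def test_same_seed_bitwise_identical(self):
        trials = _toy_trials(n_per_person=40, persons=(0, 1, 2), seed=6)
        model = hierfit.build_model(trials)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = hierfit.run_mcmc(model, n_chains=2, n_iter=120, n_burnin=40, seed=11)
            d2 = hierfit.run_mcmc(model, n_chains=2, n_iter=120, n_burnin=40, seed=11)
        for name in d1.draws:
            np.testing.assert_array_equal(d1[name], d2[name])

    def test_burnin_must_be_smaller(self, recovery_fit):
        _, _, model, _ = recovery_fit
        with pytest.raises(hierfit.FitError):
            hierfit.run_mcmc(model, n_iter=100, n_burnin=100)

    def test_known_parameter_set_recovered(self):
        """Persons simulated from one known parameter set: posterior group
        means within 3 posterior SDs of the truth."""
        truth = ddm.DDMParameters(2.0, 2.0, 0.5, 0.40, 0.70)
        trials = _toy_trials(n_per_person=800, persons=(0, 1, 2), seed=12, params=truth)
        model = hierfit.build_model(trials)
        draws = hierfit.run_mcmc(model, n_chains=2, n_iter=1200, n_burnin=400, seed=13)
        for name, true_val in (
            ("mu_nu", truth.drift),
            ("mu_a", truth.boundary_separation),
            ("mu_tau_c", truth.ndt_correct),
        ):
            arr = draws[name].ravel()
            assert abs(arr.mean() - true_val) < 3 * max(arr.std(), 1e-3), name

    def test_person_recovery_correlations(self, recovery_fit):
        traj, _, model, draws = recovery_fit
        med = hierfit.extract_person_medians(draws)
        truth = traj.values[traj.values.wave == 0][["participant_id", "nu", "a", "tau"]]
        m = med.merge(truth, on="participant_id", suffixes=("_est", "_true"))
        for p in ("nu", "a", "tau"):
            r = np.corrcoef(m[f"{p}_est"], m[f"{p}_true"])[0, 1]
            assert r > 0.85, (p, r)

    def test_hierarchical_shrinkage_pulls_small_n_person_toward_group(self):
        """A 30-trial person's estimate lies between their individual MLE and
        the group mean."""
        rng = np.random.default_rng(20)
        rows = []
        # 11 persons at nu=2; one deviant person with few trials at nu=3.2
        for pid in range(11):
            p = ddm.DDMParameters(2.0, 2.0, 0.5, 0.40, 0.70)
            rt, corr = ddm.simulate_trials(p, 300, rng)
            rows.append((pid, rt, corr))
        deviant = ddm.DDMParameters(3.2, 2.0, 0.5, 0.40, 0.70)
        rt, corr = ddm.simulate_trials(deviant, 30, rng)
        rows.append((11, rt, corr))
        frames = []
        for pid, rt, corr in rows:
            frames.append(pd.DataFrame({
                "participant_id": pid, "time_point": 0,
                "trait": "openness", "congruency": "congruent",
                "block_index": 0, "trial_index": np.arange(len(rt)),
                "correct": corr, "rt_s": rt,
            }))
        trials = pd.concat(frames, ignore_index=True)
        model = hierfit.build_model(trials)
        draws = hierfit.run_mcmc(model, n_chains=2, n_iter=900, n_burnin=300, seed=21)
        est = float(np.median(draws.person_param("nu", 11)))
        group = float(draws["mu_nu"].mean())

        # individual MLE of the deviant person's 4 base parameters
        sub = trials[trials.participant_id == 11]
        rt_v = sub["rt_s"].to_numpy()
        c_v = sub["correct"].to_numpy()
        def nll(x):
            nu, a, tp, tm = x
            if a <= 0 or tp < 0 or tm < 0:
                return 1e9
            ll = 0.0
            for r, c in zip(rt_v, c_v):
                t = r - (tp if c else tm)
                if t <= 0:
                    return 1e9
                pp = ddm.DDMParameters(nu, a, 0.5)
                ll += float(ddm.wfpt_logdensity(t, "upper" if c else "lower", pp))
            return -ll
        mle = optimize.minimize(nll, [2.0, 2.0, 0.3, 0.5], method="Nelder-Mead").x
        lo, hi = sorted((group, float(mle[0])))
        assert lo <= est <= hi, (group, est, mle[0])

    def test_zero_trial_person_posterior_matches_hierarchy(self):
        """A person contributing no trials is sampled from the group
        distribution (prior-predictive sanity)."""
        trials = _toy_trials(n_per_person=200, persons=(0, 1, 2, 3), seed=22)
        model = hierfit.build_model(trials)
        # splice in an extra person with an empty trial slice
        model.person_ids.append(99)
        model.offsets = np.append(model.offsets, model.offsets[-1])
        draws = hierfit.run_mcmc(model, n_chains=2, n_iter=1200, n_burnin=400, seed=23)
        nu99 = draws.person_param("nu", 99).ravel()
        mu = draws["mu_nu"].ravel()
        sig = draws["sigma_nu"].ravel()
        assert abs(nu99.mean() - mu.mean()) < 0.3
        assert abs(nu99.std() - np.sqrt((sig**2).mean() + mu.var())) < 0.3


class TestMedians:
    def test_simple_median(self):
        d = hierfit.PosteriorDraws(
            draws={"nu[7]": np.array([[1.0, 2.0, 3.0]]),
                   "a[7]": np.array([[1.0, 1.0, 1.0]]),
                   "tau_c[7]": np.array([[0.4, 0.4, 0.4]])},
            n_chains=1, n_iter=3, n_burnin=0, seed=0, person_ids=[7],
        )
        med = hierfit.extract_person_medians(d)
        assert med.loc[0, "nu"] == 2.0

    def test_missing_person_gets_nan(self, recovery_fit):
        _, _, _, draws = recovery_fit
        med = hierfit.extract_person_medians(draws, person_ids=[*draws.person_ids, 999])
        assert np.isnan(med.set_index("participant_id").loc[999, "nu"])

    def test_no_error_ndt_column_downstream(self, recovery_fit):
        _, _, _, draws = recovery_fit
        med = hierfit.extract_person_medians(draws)
        assert list(med.columns) == ["participant_id", "nu", "a", "tau"]
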