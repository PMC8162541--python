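import warnings

import numpy as np
import pandas as pd
import pytest

from diffstab import hierfit, preprocess, synth


def small_cohort(n_per_block: int = 30, seed: int = 5) -> synth.Trajectories:
    cfg = synth.CohortConfig(
        subgroup_sizes=(4, 4, 2, 1, 1),
        retention=(12, 12, 12, 12),
        trials_per_block=n_per_block,
    )
    return synth.draw_person_trajectories(cohort=cfg, seed=seed)


@pytest.fixture(scope="session")
def recovery_fit():
    """One shared small hierarchical fit: 12 persons x 300 trials at wave 1.

    Used by the fit, diagnostics and PPC tests; returns (trajectories,
    preprocessed trials, model, posterior draws).
    """
    traj = small_cohort()
    trials = synth.generate_trials(traj, seed=6, waves=(0,))
    kept, _, _ = preprocess.preprocess(trials)
    model = hierfit.build_model(kept)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = hierfit.run_mcmc(model, n_chains=2, n_iter=2000, n_burnin=700, seed=7)
    return traj, kept, model, draws


@pytest.fixture()
def medians_table():
    """Deterministic long medians table for the stability analyses."""
    rng = np.random.default_rng(99)
    models = synth.default_parameter_models()
    cfg = synth.CohortConfig(
        subgroup_sizes=(40, 30, 10, 10, 10), retention=(100, 90, 80, 80)
    )
    traj = synth.draw_person_trajectories(models, cfg, seed=rng)
    vals = traj.values.copy()
    med = vals[["participant_id", "subgroup", "wave", "nu", "a", "tau"]].copy()
    med.loc[~vals["observed"].to_numpy(), ["nu", "a", "tau"]] = np.nan
    return med
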