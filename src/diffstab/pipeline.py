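"""End-to-end orchestration: simulate/ingest -> preprocess -> fit per time
point -> convergence gating -> stability analyses -> report.

A run writes into one immutable directory; every stage logs counts and every
numeric decision is a config key with a recorded default, so a rerun with
the same config and seed reproduces all CSVs byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, growth, hierfit, preprocess, stability, synth

STAGES = ("simulate", "preprocess", "fit", "diagnose", "analyze", "report")

#: every numeric design decision, with its default
DEFAULT_CONFIG: dict = {
    "seed": 0,
    # cohort design
    "subgroup_sizes": [113, 109, 26, 63, 58],
    "retention": [369, 358, 327, 327],
    "trials_per_block": 60,
    "correction_constant": 0.3,
    "drift_effect": 0.2,
    "boundary_effect": -0.05,
    "dropout_mode": "car",
    "dropout_weight": 1.0,
    "tau_residual_floor": 1e-4,
    # artifact injection
    "fast_rate": 0.0,
    "slow_rate": 0.0,
    "unrecorded_rate": 0.0,
    # optional external data: path to a trial CSV in the package dialect
    "trials_csv": None,
    # preprocessing
    "rt_low": 0.3,
    "rt_high": 3.0,
    "accuracy_after_rt_filter": False,
    # hierarchical fit
    "n_chains": 4,
    "n_iter": 6000,
    "n_burnin": 1000,
    "min_trials": 20,
    # convergence gate
    "rhat_max": 1.01,
    "ess_min": 400,
    # posterior predictive check
    "ppc_draws": 500,
    "ppc_enabled": False,
    "ppc_min_errors": 11,
    # growth curves
    "growth_enabled": True,
    "growth_chains": 3,
    "growth_iter": 16000,
    "growth_burnin": 4000,
    "growth_slope_var_zero_fraction": 0.03,
    "growth_min_persons": 50,
    # stability
    "hdi_mass": 0.95,
    "small_n_flag": 30,
    "make_plots": False,
}


class PipelineError(RuntimeError):
    pass


def load_config(path=None, **overrides) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update(overrides)
    return cfg


def _cohort(cfg: dict) -> synth.CohortConfig:
    sizes = tuple(int(s) for s in cfg["subgroup_sizes"])
    n_groups = len(sizes)
    ages = tuple("young" if i < max(n_groups - 2, 1) else "old" for i in range(n_groups))
    return synth.CohortConfig(
        subgroup_sizes=sizes,
        subgroup_ages=ages,
        retention=tuple(int(r) for r in cfg["retention"]),
        trials_per_block=int(cfg["trials_per_block"]),
        correction_constant=float(cfg["correction_constant"]),
        drift_effect=float(cfg["drift_effect"]),
        boundary_effect=float(cfg["boundary_effect"]),
        dropout_mode=cfg["dropout_mode"],
        dropout_weight=float(cfg["dropout_weight"]),
    )


def _models(cfg: dict) -> dict:
    models = synth.default_parameter_models()
    floor = float(cfg["tau_residual_floor"])
    tau = models["tau"]
    models["tau"] = synth.LongitudinalParameterModel(
        intercept_mean=tau.intercept_mean, intercept_var=tau.intercept_var,
        slope_mean=tau.slope_mean, slope_var=tau.slope_var,
        intercept_slope_cov=tau.intercept_slope_cov, loadings=tau.loadings,
        residual_vars=tuple(max(e, floor) for e in tau.residual_vars),
    )
    return models


def stage_simulate(cfg: dict, outdir: Path) -> pd.DataFrame:
    if cfg["trials_csv"]:
        trials = synth.read_trials(cfg["trials_csv"])
        synth.write_trials(trials, outdir / "trials.csv")
        return trials
    seed = np.random.SeedSequence([int(cfg["seed"]), 1])
    rng = np.random.default_rng(seed)
    traj = synth.draw_person_trajectories(_models(cfg), _cohort(cfg), seed=rng)
    trials = synth.generate_trials(traj, seed=rng)
    if cfg["fast_rate"] or cfg["slow_rate"] or cfg["unrecorded_rate"]:
        trials, counts = synth.inject_artifacts(
            trials, fast_rate=cfg["fast_rate"], slow_rate=cfg["slow_rate"],
            unrecorded_rate=cfg["unrecorded_rate"], seed=rng,
        )
        (outdir / "artifact_counts.json").write_text(json.dumps(counts, indent=1))
    synth.write_trials(trials, outdir / "trials.csv")
    traj.values.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.6f")
    traj.latents.to_csv(outdir / "ground_truth_latents.csv", index=False, float_format="%.6f")
    return trials


def stage_preprocess(cfg: dict, outdir: Path, trials: pd.DataFrame) -> pd.DataFrame:
    kept, log, by_tp = preprocess.preprocess(
        trials, low=cfg["rt_low"], high=cfg["rt_high"],
        accuracy_after_rt_filter=cfg["accuracy_after_rt_filter"],
    )
    synth.write_trials(kept, outdir / "trials_preprocessed.csv")
    log.to_frame().to_csv(outdir / "exclusion_log.csv", index=False)
    with open(outdir / "low_accuracy.json", "w") as fh:
        json.dump({str(k): v for k, v in by_tp.items()}, fh, indent=1, default=str)
    return kept


def stage_fit(cfg: dict, outdir: Path, kept: pd.DataFrame) -> dict:
    """Fit each time point; returns wave -> PosteriorDraws."""
    fits = {}
    spec = hierfit.ModelSpec(min_trials=int(cfg["min_trials"]))
    waves = sorted(kept["time_point"].unique())
    for w, tp in enumerate(waves):
        sub = kept[kept["time_point"] == tp]
        model = hierfit.build_model(sub, spec=spec)
        draws = hierfit.run_mcmc(
            model, n_chains=int(cfg["n_chains"]), n_iter=int(cfg["n_iter"]),
            n_burnin=int(cfg["n_burnin"]),
            seed=int(np.random.SeedSequence([int(cfg["seed"]), 2, w]).generate_state(1)[0] % 2**31),
        )
        fits[w] = draws
        with open(outdir / f"fit_wave{w}_meta.json", "w") as fh:
            json.dump(draws.metadata(), fh, indent=1)
        rows = []
        for name in hierfit.HYPER_NAMES:
            arr = draws[name]
            for c in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "parameter": name, "chain": c,
                    "iteration": np.arange(arr.shape[1]), "value": arr[c],
                }))
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / f"fit_wave{w}_group_draws.csv", index=False, float_format="%.6f"
        )
    return fits


def stage_diagnose(cfg: dict, outdir: Path, fits: dict, trials: pd.DataFrame) -> pd.DataFrame:
    """Convergence gate + medians; returns long medians table with NaN for
    excluded person-wave vectors."""
    all_ids = sorted(trials["participant_id"].unique())
    rows = []
    for w, draws in sorted(fits.items()):
        persons, diag = diagnostics.apply_exclusion_rules(
            draws, rhat_max=float(cfg["rhat_max"]), ess_min=float(cfg["ess_min"])
        )
        diag.insert(0, "wave", w)
        diag.to_csv(outdir / f"diagnostics_wave{w}.csv", index=False, float_format="%.4f")
        med = hierfit.extract_person_medians(draws, person_ids=all_ids)
        med = med.merge(persons, on="participant_id", how="left")
        med["converged"] = med["converged"].fillna(False).astype(bool)
        med.loc[~med["converged"], ["nu", "a", "tau"]] = np.nan
        med.insert(1, "wave", w)
        rows.append(med)
    medians = pd.concat(rows, ignore_index=True)
    sub_map = trials.drop_duplicates("participant_id").set_index("participant_id")["subgroup"]
    medians["subgroup"] = medians["participant_id"].map(sub_map)
    medians.to_csv(outdir / "person_medians.csv", index=False, float_format="%.6f")
    frac = 1.0 - medians.dropna(subset=["nu"]).shape[0] / max(len(medians), 1)
    (outdir / "exclusion_fraction.json").write_text(
        json.dumps({"person_vector_exclusion_fraction": frac})
    )
    if cfg["ppc_enabled"]:
        for w, draws in sorted(fits.items()):
            tp = sorted(trials["time_point"].unique())[w]
            ppc = diagnostics.posterior_predictive_check(
                draws, trials[trials["time_point"] == tp],
                n_draws=int(cfg["ppc_draws"]),
                seed=int(np.random.SeedSequence([int(cfg["seed"]), 3, w]).generate_state(1)[0] % 2**31),
                min_errors=int(cfg["ppc_min_errors"]),
            )
            ppc.to_csv(outdir / f"ppc_wave{w}.csv", index=False, float_format="%.6f")
    return medians


def stage_analyze(cfg: dict, outdir: Path, medians: pd.DataFrame, fits: dict) -> None:
    # rank-order stability
    for p in stability.PARAMS:
        stability.rank_order_matrix(medians, p, small_n=int(cfg["small_n_flag"])).to_csv(
            outdir / f"rank_order_{p}.csv", index=False, float_format="%.6f"
        )
    # mean-level change on group-level draws
    group_key = {"nu": "mu_nu", "a": "mu_a", "tau": "mu_tau_c"}
    for p, key in group_key.items():
        gd = {w: fits[w][key].ravel() for w in fits}
        stability.mean_level_comparison(gd, mass=float(cfg["hdi_mass"])).to_csv(
            outdir / f"mean_level_{p}.csv", index=False, float_format="%.6f"
        )
    # growth curves
    if cfg["growth_enabled"]:
        spec = growth.GrowthSpec(
            n_chains=int(cfg["growth_chains"]), n_iter=int(cfg["growth_iter"]),
            n_burnin=int(cfg["growth_burnin"]),
            slope_var_zero_fraction=float(cfg["growth_slope_var_zero_fraction"]),
            seed=int(np.random.SeedSequence([int(cfg["seed"]), 4]).generate_state(1)[0] % 2**31),
        )
        for p in stability.PARAMS:
            wide = medians.pivot_table(index="participant_id", columns="wave", values=p)
            for w in range(4):
                if w not in wide.columns:
                    wide[w] = np.nan
            wide = wide[[0, 1, 2, 3]]
            n2 = int((wide.notna().sum(axis=1) >= 2).sum())
            if n2 < int(cfg["growth_min_persons"]):
                continue
            fit = growth.fit_growth_curve(wide, spec)
            est = fit.estimates.copy()
            est.insert(0, "parameter_family", p)
            est["bcfi"] = fit.bcfi
            est["bgammahat"] = fit.bgammahat
            est["converged"] = fit.converged
            est.to_csv(outdir / f"growth_{p}.csv", index=False, float_format="%.6f")
    # profile stability
    z = stability.standardize_profiles(medians)
    stability.q_summary(z).to_csv(outdir / "q_summary.csv", index=False, float_format="%.6f")
    # dropout t-tests (skipped when either group is too small)
    try:
        dropout = stability.dropout_analysis(medians)
    except stability.AnalysisError:
        dropout = pd.DataFrame(
            columns=["parameter", "bf10", "mean_diff", "n_dropout", "n_complete"]
        )
    dropout.to_csv(outdir / "dropout_bf.csv", index=False, float_format="%.6f")
    if cfg["make_plots"]:
        _plots(outdir, medians, z)


def _plots(outdir: Path, medians: pd.DataFrame, z: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for i, j in stability.TIME_PAIRS:
        q = stability.q_profile_correlations(z, i, j)["q"].dropna()
        if len(q) > 1:
            ax.hist(q, bins=np.linspace(-1, 1, 41), histtype="step",
                    density=True, label=f"T{i + 1}-T{j + 1}")
    ax.set_xlabel("q correlation")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.savefig(outdir / "q_density.png", dpi=100)
    plt.close(fig)


def make_report(outdir: Path) -> pd.DataFrame:
    """Assemble descriptives and formatted tables from stage outputs."""
    outdir = Path(outdir)
    med_path = outdir / "person_medians.csv"
    if not med_path.exists():
        raise PipelineError("missing stage output: person_medians.csv (run diagnose first)")
    medians = pd.read_csv(med_path)
    rows = []
    for p in stability.PARAMS:
        for w, sub in medians.groupby("wave"):
            col = sub[p].dropna()
            rows.append((p, w, len(col), col.mean(), col.std(ddof=1), col.min(), col.max()))
    desc = pd.DataFrame(rows, columns=["parameter", "wave", "N", "M", "SD", "min", "max"])
    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    desc.to_csv(report_dir / "descriptives.csv", index=False, float_format="%.6f")

    for p in stability.PARAMS:
        ro_path = outdir / f"rank_order_{p}.csv"
        if ro_path.exists():
            ro = pd.read_csv(ro_path)
            ro["estimate"] = [
                "" if np.isnan(r.rho) else
                f"{r.rho:.2f} [{r.ci_low:.2f}–{r.ci_high:.2f}]"
                for r in ro.itertuples()
            ]
            ro["bf"] = [
                "" if np.isnan(r.bf10) else (">999" if r.bf10 > 999 else f"{r.bf10:.2f}")
                for r in ro.itertuples()
            ]
            ro.to_csv(report_dir / f"correlations_{p}.csv", index=False, float_format="%.6f")
        g_path = outdir / f"growth_{p}.csv"
        if g_path.exists():
            pd.read_csv(g_path).to_csv(
                report_dir / f"growth_{p}.csv", index=False, float_format="%.6f"
            )
    q_path = outdir / "q_summary.csv"
    if q_path.exists():
        pd.read_csv(q_path).to_csv(report_dir / "q_summary.csv", index=False, float_format="%.6f")
    return desc


def run_pipeline(config: dict | str | Path | None = None, outdir=None, seed=None) -> Path:
    """Run all stages in order; any failure halts with the stage name while
    earlier outputs stay on disk."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = dict(DEFAULT_CONFIG, **(config or {}))
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir if outdir is not None else "diffstab_run")
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    _write_manifest(outdir)

    state: dict = {}
    stage = "simulate"
    try:
        state["trials"] = stage_simulate(cfg, outdir)
        stage = "preprocess"
        state["kept"] = stage_preprocess(cfg, outdir, state["trials"])
        stage = "fit"
        state["fits"] = stage_fit(cfg, outdir, state["kept"])
        stage = "diagnose"
        state["medians"] = stage_diagnose(cfg, outdir, state["fits"], state["kept"])
        stage = "analyze"
        stage_analyze(cfg, outdir, state["medians"], state["fits"])
        stage = "report"
        make_report(outdir)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outdir


def _write_manifest(outdir: Path) -> None:
    import arviz
    import numba
    import scipy

    versions = {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "numba": numba.__version__,
        "arviz": arviz.__version__,
    }
    (outdir / "versions.json").write_text(json.dumps(versions, indent=1))
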