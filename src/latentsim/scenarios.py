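"""Seven scripted experiments on interpreting individual differences in
neural coding.

Each scenario composes the behavioral simulator, the model fitter, the
BOLD synthesizer and the first-level GLM to probe one way in which
individual differences in the estimated neural-coding parameter phi can
be real, absent, or spurious:

1. different learning rates, same phi: PE variance differs, phi does not
2. standardizing the PE regressor manufactures phi differences
3. learning-rate and phi differences can co-occur (signal variability)
4. underestimating the event duration inflates phi
5. inverse-temperature differences are harmless for phi
6. unmodeled outcome sensitivity loads onto beta-hat and phi-hat
7. forcing a shared learning rate, or the wrong model family, distorts phi

Every run is reproducible from (config, master seed): all randomness is
drawn from a :class:`numpy.random.SeedSequence` tree rooted at the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .behavioral_fit import ModelSpec, fit_mle, predicted_pe
from .neural_glm import DesignSpec, duration_bias_curve, estimate_phi
from .neural_sim import NeuralConfig, simulate_bold
from .rl_core import RLParams, TaskConfig, pe_variance, simulate_agent

__all__ = [
    "ScenarioConfig",
    "ScenarioSummary",
    "run_scenario",
    "spuriousness_verdict",
    "paired_contrast_flag",
    "scenario1",
    "scenario2",
    "scenario3",
    "scenario4",
    "scenario5",
    "scenario6",
    "scenario7",
]


@dataclass
class ScenarioSummary:
    """Replicate-aggregated result of one scenario experiment."""

    scenario_id: int
    tables: dict
    stats: dict
    flags: dict
    master_seed: int | None = None

    def save(self, out_dir, stem: str | None = None) -> list:
        """Write each table as CSV and stats+flags as JSON; returns paths."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = stem or f"scenario{self.scenario_id}"
        paths = []
        for name, df in self.tables.items():
            p = out / f"{stem}_{name}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        p = out / f"{stem}_summary.json"
        p.write_text(
            json.dumps(
                {
                    "scenario_id": self.scenario_id,
                    "master_seed": self.master_seed,
                    "stats": self.stats,
                    "flags": self.flags,
                },
                indent=2,
                default=float,
            )
        )
        paths.append(p)
        return paths


def spuriousness_verdict(cells: pd.DataFrame, threshold: float = 3.0) -> dict:
    """Flag subject/cell contrasts whose mean phi-hat differ by more
    than ``threshold`` pooled standard errors.

    ``cells`` needs columns ``cell``, ``mean`` and ``se``.  This is an
    internal screening flag, not an inferential test.
    """
    if len(cells) < 2:
        raise ValueError("verdict requires at least two cells")
    flags = {}
    rows = list(cells.itertuples(index=False))
    for i, a in enumerate(rows):
        for b in rows[i + 1 :]:
            pooled = float(np.hypot(a.se, b.se))
            diff = abs(float(a.mean) - float(b.mean))
            flags[f"{a.cell} vs {b.cell}"] = bool(
                pooled > 0 and diff > threshold * pooled
            )
    return flags


def _cells(df: pd.DataFrame, by: str, value: str = "phi_hat") -> pd.DataFrame:
    g = df.groupby(by)[value]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"])
    out = out.rename(columns={by: "cell", "std": "sd", "count": "n"})
    return out[["cell", "mean", "sd", "se", "n"]]


# ---------------------------------------------------------------------------
# scenario experiments


def scenario1(
    n_replicates: int = 50,
    n_trials: int = 100,
    focal_alphas=(0.05, 0.5),
    alpha_grid=None,
    phi: float = 1.0,
    noise_sd: float = 0.1,
    trial_duration: float = 4.0,
    tr: float = 1.0,
    event_duration: float = 0.01,
    verdict_threshold: float = 3.0,
    seed=None,
) -> ScenarioSummary:
    """Learning-rate differences without neural-coding differences.

    Choice-free (pavlovian) learning so both subjects see identical
    outcome sequences; only alpha differs.  Reports the PE-variance
    curve over an alpha grid and shows that phi-hat does not differ
    between the focal subjects even though their PE variances do.
    """
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.05, 1.0, 0.05), 2)
    task = TaskConfig(n_trials=n_trials, mode="pavlovian")
    cfg = NeuralConfig(
        phi=phi,
        tr=tr,
        trial_duration=trial_duration,
        event_duration=event_duration,
        noise_sd=noise_sd,
    )
    design = DesignSpec(assumed_duration=event_duration)
    ss = np.random.SeedSequence(seed)
    curve_rows, focal_rows = [], []
    for rep, rep_ss in enumerate(ss.spawn(n_replicates)):
        outcome_ss, noise_ss = rep_ss.spawn(2)
        noise_children = noise_ss.spawn(len(focal_alphas))
        for a in alpha_grid:
            data = simulate_agent(
                task, RLParams(alpha=float(a), beta=0.0), np.random.default_rng(outcome_ss)
            )
            curve_rows.append(
                {"alpha": float(a), "replicate": rep, "pe_variance": pe_variance(data)}
            )
        for j, a in enumerate(focal_alphas):
            data = simulate_agent(
                task, RLParams(alpha=float(a), beta=0.0), np.random.default_rng(outcome_ss)
            )
            ts = simulate_bold(data.pe, cfg, np.random.default_rng(noise_children[j]))
            res = estimate_phi(ts, data.pe, design, cfg)
            focal_rows.append(
                {
                    "subject": f"alpha={a}",
                    "replicate": rep,
                    "pe_variance": pe_variance(data),
                    "phi_hat": res.phi_hat,
                }
            )
    curve = (
        pd.DataFrame(curve_rows)
        .groupby("alpha", as_index=False)["pe_variance"]
        .agg(mean_pe_variance="mean", sd_pe_variance="std")
    )
    focal = pd.DataFrame(focal_rows)
    cells = _cells(focal, "subject")
    pe_by_subject = focal.groupby("subject")["pe_variance"].mean().to_dict()
    flags = spuriousness_verdict(cells, verdict_threshold)
    stats = {
        "mean_pe_variance_by_subject": pe_by_subject,
        "mean_phi_hat_by_subject": focal.groupby("subject")["phi_hat"].mean().to_dict(),
        "pe_variance_increases_with_alpha": bool(
            pe_by_subject[f"alpha={focal_alphas[1]}"]
            > pe_by_subject[f"alpha={focal_alphas[0]}"]
        ),
    }
    return ScenarioSummary(1, {"curve": curve, "cells": cells, "replicates": focal}, stats, flags)


def scenario2(
    n_replicates: int = 50,
    n_trials: int = 100,
    focal_alphas=(0.05, 0.5),
    phi: float = 1.0,
    noise_sd: float = 0.1,
    trial_duration: float = 4.0,
    tr: float = 1.0,
    event_duration: float = 0.01,
    verdict_threshold: float = 3.0,
    seed=None,
) -> ScenarioSummary:
    """Standardizing the PE regressor manufactures phi differences.

    The same data are analyzed twice, with raw and with
    SD-standardized PE regressors; the standardized phi-hat equals the
    raw one multiplied by the subject's PE SD, exactly.
    """
    task = TaskConfig(n_trials=n_trials, mode="pavlovian")
    cfg = NeuralConfig(
        phi=phi,
        tr=tr,
        trial_duration=trial_duration,
        event_duration=event_duration,
        noise_sd=noise_sd,
    )
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, rep_ss in enumerate(ss.spawn(n_replicates)):
        outcome_ss, noise_ss = rep_ss.spawn(2)
        noise_children = noise_ss.spawn(len(focal_alphas))
        for j, a in enumerate(focal_alphas):
            data = simulate_agent(
                task, RLParams(alpha=float(a), beta=0.0), np.random.default_rng(outcome_ss)
            )
            ts = simulate_bold(data.pe, cfg, np.random.default_rng(noise_children[j]))
            raw = estimate_phi(ts, data.pe, DesignSpec(assumed_duration=event_duration), cfg)
            std = estimate_phi(
                ts,
                data.pe,
                DesignSpec(standardize_pe=True, assumed_duration=event_duration),
                cfg,
            )
            rows.append(
                {
                    "subject": f"alpha={a}",
                    "replicate": rep,
                    "phi_hat_raw": raw.phi_hat,
                    "phi_hat_standardized": std.phi_hat,
                    "pe_sd_used": std.design.pe_sd_used,
                    "ratio": std.phi_hat / raw.phi_hat,
                }
            )
    df = pd.DataFrame(rows)
    raw_cells = _cells(df, "subject", "phi_hat_raw")
    std_cells = _cells(df, "subject", "phi_hat_standardized")
    stats = {
        "max_abs_ratio_minus_sd": float((df["ratio"] - df["pe_sd_used"]).abs().max()),
        "mean_phi_hat_raw_by_subject": df.groupby("subject")["phi_hat_raw"].mean().to_dict(),
        "mean_phi_hat_standardized_by_subject": df.groupby("subject")[
            "phi_hat_standardized"
        ].mean().to_dict(),
    }
    flags = {
        "raw_" + k: v for k, v in spuriousness_verdict(raw_cells, verdict_threshold).items()
    }
    flags.update(
        {
            "standardized_" + k: v
            for k, v in spuriousness_verdict(std_cells, verdict_threshold).items()
        }
    )
    return ScenarioSummary(
        2, {"replicates": df, "raw_cells": raw_cells, "standardized_cells": std_cells}, stats, flags
    )


def scenario3(
    n_replicates: int = 50,
    n_trials: int = 100,
    subjects=((0.05, 2.0), (0.5, 0.5)),
    trial_duration: float = 4.0,
    tr: float = 1.0,
    event_duration: float = 0.01,
    seed=None,
) -> ScenarioSummary:
    """Learning-rate and neural-coding differences can co-occur.

    Subject (alpha=0.05, phi=2) versus (alpha=0.5, phi=0.5): the
    low-learning-rate subject now has the *more* variable neural
    signal, driven by the larger phi.  Variability is quantified as the
    SD of the noiseless convolved signal.
    """
    task = TaskConfig(n_trials=n_trials, mode="pavlovian")
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, rep_ss in enumerate(ss.spawn(n_replicates)):
        for a, phi in subjects:
            cfg = NeuralConfig(
                phi=float(phi),
                tr=tr,
                trial_duration=trial_duration,
                event_duration=event_duration,
                noise_sd=0.0,
            )
            data = simulate_agent(
                task, RLParams(alpha=float(a), beta=0.0), np.random.default_rng(rep_ss)
            )
            ts = simulate_bold(data.pe, cfg, None)
            rows.append(
                {
                    "subject": f"alpha={a},phi={phi}",
                    "alpha": float(a),
                    "phi": float(phi),
                    "replicate": rep,
                    "pe_variance": pe_variance(data),
                    "signal_sd": float(np.std(ts.signal, ddof=1)),
                }
            )
    df = pd.DataFrame(rows)
    means = df.groupby("subject")["signal_sd"].mean()
    low_alpha = f"alpha={subjects[0][0]},phi={subjects[0][1]}"
    high_alpha = f"alpha={subjects[1][0]},phi={subjects[1][1]}"
    stats = {
        "mean_signal_sd_by_subject": means.to_dict(),
        "low_alpha_high_phi_more_variable": bool(means[low_alpha] > means[high_alpha]),
    }
    return ScenarioSummary(3, {"replicates": df}, stats, {})


def scenario4(
    n_replicates: int = 20,
    true_durations=(0.01, 0.05, 0.1, 0.2, 0.25, 0.5, 1.0),
    assumed_duration: float = 0.01,
    n_trials: int = 100,
    alpha: float = 0.1,
    beta: float = 1.0,
    phi: float = 1.0,
    trial_duration: float = 4.0,
    tr: float = 1.0,
    seed=None,
) -> ScenarioSummary:
    """Neglected event duration inflates the neural-coding estimate.

    BOLD series are generated with increasing true event durations but
    analyzed with a stick (0.01 s) regressor; phi-hat grows nearly
    linearly with the size of the misspecification.  Noiseless by
    construction so the ratio checks isolate the convolution effect.
    """
    cfg = NeuralConfig(
        phi=phi,
        tr=tr,
        trial_duration=trial_duration,
        event_duration=assumed_duration,
        noise_sd=0.0,
    )
    task = TaskConfig(n_trials=n_trials, mode="instrumental")
    params = RLParams(alpha=alpha, beta=beta)
    curve = duration_bias_curve(
        true_durations, assumed_duration, cfg, task, params, n_replicates, seed
    )
    means = dict(zip(curve["true_duration"], curve["mean_phi_hat"]))
    ratios = {}
    for d in sorted(means):
        if 2 * d in means and d <= 0.5:
            ratios[f"{2 * d:g}/{d:g}"] = float(means[2 * d] / means[d])
    stats = {
        "monotone_nondecreasing": bool(np.all(np.diff(curve["mean_phi_hat"]) >= 0)),
        "doubling_ratios": ratios,
        "phi_hat_at_assumed_duration": float(means[min(means)]),
        "generative_phi": float(phi),
    }
    return ScenarioSummary(4, {"curve": curve}, stats, {})


def scenario5(
    n_datasets: int = 100,
    n_trials: int = 1000,
    alpha: float = 0.1,
    phi: float = 1.0,
    beta_range=(0.2, 10.0),
    trial_duration: float = 4.0,
    tr: float = 1.0,
    cnr: float = 0.1,
    event_duration: float = 0.01,
    n_restarts: int = 5,
    seed=None,
) -> ScenarioSummary:
    """Inverse temperature neither moves PE variance nor phi-hat.

    One dataset per beta on an evenly spaced sweep; the full latent-input
    pipeline is run: simulate choices, fit the (correct) static model,
    generate BOLD from the true PEs, and estimate phi on the
    model-derived PE regressor.
    """
    betas = np.linspace(beta_range[0], beta_range[1], n_datasets)
    task = TaskConfig(n_trials=n_trials, mode="instrumental")
    cfg = NeuralConfig(
        phi=phi, tr=tr, trial_duration=trial_duration, event_duration=event_duration, cnr=cnr
    )
    spec = ModelSpec("static_rw", free_params=("alpha", "beta"))
    design = DesignSpec(assumed_duration=event_duration)
    ss = np.random.SeedSequence(seed)
    rows = []
    for (beta, d_ss) in zip(betas, ss.spawn(n_datasets)):
        behav_ss, noise_ss, fit_ss = d_ss.spawn(3)
        data = simulate_agent(
            task, RLParams(alpha=alpha, beta=float(beta)), np.random.default_rng(behav_ss)
        )
        fit = fit_mle(data, spec, n_restarts=n_restarts, seed=np.random.default_rng(fit_ss))
        ts = simulate_bold(data.pe, cfg, np.random.default_rng(noise_ss))
        glm = estimate_phi(ts, fit.pe_hat, design, cfg)
        rows.append(
            {
                "beta_true": float(beta),
                "pe_variance": pe_variance(data),
                "alpha_hat": fit.estimates["alpha"],
                "beta_hat": fit.estimates["beta"],
                "phi_hat": glm.phi_hat,
            }
        )
    df = pd.DataFrame(rows)
    rho_pe = spearmanr(df["beta_true"], df["pe_variance"]).statistic
    rho_phi = spearmanr(df["beta_true"], df["phi_hat"]).statistic
    stats = {
        "mean_phi_hat": float(df["phi_hat"].mean()),
        "se_phi_hat": float(df["phi_hat"].std() / np.sqrt(len(df))),
        "spearman_beta_pe_variance": float(rho_pe),
        "spearman_beta_phi_hat": float(rho_phi),
        "median_rel_beta_bias": float(
            ((df["beta_hat"] - df["beta_true"]) / df["beta_true"]).median()
        ),
        "median_alpha_hat": float(df["alpha_hat"].median()),
        "generative": {"alpha": alpha, "phi": phi},
    }
    return ScenarioSummary(5, {"datasets": df}, stats, {})


def scenario6(
    n_datasets: int = 102,
    gammas=None,
    alpha: float = 0.1,
    beta: float = 1.0,
    phi: float = 1.0,
    n_trials: int = 1000,
    trial_duration: float = 4.0,
    tr: float = 1.0,
    cnr: float = 0.1,
    event_duration: float = 0.01,
    n_restarts: int = 5,
    seed=None,
) -> ScenarioSummary:
    """Unmodeled outcome sensitivity creates spurious phi differences.

    Data are generated under a gamma sweep but fitted with gamma fixed
    at 1; the sensitivity loads onto beta-hat (the product beta*gamma
    is what choices identify) and, because the true PEs scale with
    gamma while the fitted ones do not, onto phi-hat.
    """
    if gammas is None:
        gammas = np.geomspace(0.5, 3.0, 6)
    gammas = np.asarray(gammas, dtype=float)
    reps = max(1, n_datasets // gammas.size)
    task = TaskConfig(n_trials=n_trials, mode="instrumental")
    cfg = NeuralConfig(
        phi=phi, tr=tr, trial_duration=trial_duration, event_duration=event_duration, cnr=cnr
    )
    spec = ModelSpec("static_rw", free_params=("alpha", "beta"))
    design = DesignSpec(assumed_duration=event_duration)
    ss = np.random.SeedSequence(seed)
    rows = []
    seeds = iter(ss.spawn(int(reps * gammas.size)))
    for g in gammas:
        for rep in range(reps):
            d_ss = next(seeds)
            behav_ss, noise_ss, fit_ss = d_ss.spawn(3)
            data = simulate_agent(
                task,
                RLParams(alpha=alpha, beta=beta, gamma=float(g)),
                np.random.default_rng(behav_ss),
            )
            fit = fit_mle(data, spec, n_restarts=n_restarts, seed=np.random.default_rng(fit_ss))
            ts = simulate_bold(data.pe, cfg, np.random.default_rng(noise_ss))
            glm = estimate_phi(ts, fit.pe_hat, design, cfg)
            rows.append(
                {
                    "gamma_true": float(g),
                    "replicate": rep,
                    "pe_variance": pe_variance(data),
                    "beta_hat": fit.estimates["beta"],
                    "phi_hat": glm.phi_hat,
                }
            )
    df = pd.DataFrame(rows)
    cells = df.groupby("gamma_true", as_index=False).agg(
        mean_pe_variance=("pe_variance", "mean"),
        mean_beta_hat=("beta_hat", "mean"),
        mean_phi_hat=("phi_hat", "mean"),
        se_phi_hat=("phi_hat", lambda s: s.std() / np.sqrt(len(s))),
    )
    stats = {
        "spearman_gamma_beta_hat": float(
            spearmanr(cells["gamma_true"], cells["mean_beta_hat"]).statistic
        ),
        "spearman_gamma_phi_hat": float(
            spearmanr(cells["gamma_true"], cells["mean_phi_hat"]).statistic
        ),
        "spearman_gamma_pe_variance": float(
            spearmanr(cells["gamma_true"], cells["mean_pe_variance"]).statistic
        ),
        "generative": {"alpha": alpha, "beta": beta, "phi": phi},
    }
    return ScenarioSummary(6, {"datasets": df, "cells": cells}, stats, {})


def paired_contrast_flag(diffs, threshold: float = 3.0) -> bool:
    """Flag a yoked between-subject contrast from per-dataset paired
    differences: |mean| > threshold * SE(mean of the differences).

    For subjects yoked on outcomes and noise draws the paired SE is the
    correct standard error of the contrast; the two-sample pooled SE of
    :func:`spuriousness_verdict` would be badly conservative there.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("paired contrast requires at least two replicates")
    se = diffs.std(ddof=1) / np.sqrt(diffs.size)
    return bool(se > 0 and abs(diffs.mean()) > threshold * se)


def scenario7(
    n_datasets: int = 400,
    n_trials: int = 300,
    trial_duration: float = 4.0,
    tr: float = 1.0,
    cnr: float = 0.1,
    alphas=(0.05, 0.5),
    beta: float = 2.0,
    phi: float = 1.0,
    event_duration: float = 0.01,
    decay_alpha0: float = 0.8,
    decay_rate: float = 0.02,
    n_restarts: int = 5,
    verdict_threshold: float = 3.0,
    seed=None,
) -> ScenarioSummary:
    """Misspecified behavioral models distort the neural-coding estimate.

    Part (a): the scenario-1 pair (choice-free learning, yoked outcome
    sequences, alpha = 0.05 vs 0.5, equal phi) with the scanner-noise
    draws also shared within a dataset.  Using each subject's own
    learning rate for the PE regressor recovers equal phi-hat; assuming
    the high learning rate for both subjects produces a spurious
    phi-hat difference.  Contrasts are flagged with the paired SE
    (the subjects are yoked), while the cells tables report the
    conventional across-dataset SEs.

    Part (b): choice data generated with an exponentially decaying
    learning rate but fitted with the static model; phi-hat is
    underestimated relative to the matched (decay-model) fit on the
    same data and time series.
    """
    task_pav = TaskConfig(n_trials=n_trials, mode="pavlovian")
    task_ins = TaskConfig(n_trials=n_trials, mode="instrumental")
    cfg = NeuralConfig(
        phi=phi, tr=tr, trial_duration=trial_duration, event_duration=event_duration, cnr=cnr
    )
    spec_static = ModelSpec("static_rw", free_params=("alpha", "beta"))
    spec_decay = ModelSpec("decay_rw", free_params=("alpha", "beta", "decay_rate"))
    design = DesignSpec(assumed_duration=event_duration)
    alpha_high = float(max(alphas))
    ss = np.random.SeedSequence(seed)
    rows_a, rows_b = [], []
    for d_idx, d_ss in enumerate(ss.spawn(n_datasets)):
        out_ss, noise_ss, b_ss = d_ss.spawn(3)
        # part a: same high learning rate incorrectly assumed for both
        for a in alphas:
            data = simulate_agent(
                task_pav, RLParams(alpha=float(a), beta=0.0), np.random.default_rng(out_ss)
            )
            ts = simulate_bold(data.pe, cfg, np.random.default_rng(noise_ss))
            phi_ind = estimate_phi(ts, data.pe, design, cfg).phi_hat
            pe_shared = predicted_pe({"alpha": alpha_high}, data)
            phi_sha = estimate_phi(ts, pe_shared, design, cfg).phi_hat
            rows_a.append(
                {
                    "dataset": d_idx,
                    "subject": f"alpha={a}",
                    "alpha_true": float(a),
                    "phi_hat_individual": phi_ind,
                    "phi_hat_shared": phi_sha,
                }
            )
        # part b: decay-generated choices, static versus matched fit
        behav_ss, bnoise_ss, fit1_ss, fit2_ss = b_ss.spawn(4)
        data = simulate_agent(
            task_ins,
            RLParams(alpha=decay_alpha0, beta=beta, decay_rate=decay_rate),
            np.random.default_rng(behav_ss),
        )
        ts = simulate_bold(data.pe, cfg, np.random.default_rng(bnoise_ss))
        fit_static = fit_mle(
            data, spec_static, n_restarts=n_restarts, seed=np.random.default_rng(fit1_ss)
        )
        fit_decay = fit_mle(
            data, spec_decay, n_restarts=n_restarts, seed=np.random.default_rng(fit2_ss)
        )
        rows_b.append(
            {
                "dataset": d_idx,
                "phi_hat_static": estimate_phi(ts, fit_static.pe_hat, design, cfg).phi_hat,
                "phi_hat_decay": estimate_phi(ts, fit_decay.pe_hat, design, cfg).phi_hat,
            }
        )

    df_a = pd.DataFrame(rows_a)
    df_b = pd.DataFrame(rows_b)
    cells_ind = _cells(df_a, "subject", "phi_hat_individual")
    cells_sha = _cells(df_a, "subject", "phi_hat_shared")
    wide = df_a.pivot(index="dataset", columns="subject")
    low, high = f"alpha={alphas[0]}", f"alpha={alphas[1]}"
    diffs_ind = wide[("phi_hat_individual", low)] - wide[("phi_hat_individual", high)]
    diffs_sha = wide[("phi_hat_shared", low)] - wide[("phi_hat_shared", high)]
    flags = {
        f"individual_{low} vs {high}": paired_contrast_flag(diffs_ind, verdict_threshold),
        f"shared_{low} vs {high}": paired_contrast_flag(diffs_sha, verdict_threshold),
    }
    mean_static = float(df_b["phi_hat_static"].mean())
    mean_decay = float(df_b["phi_hat_decay"].mean())
    stats = {
        "mean_phi_hat_individual_by_subject": df_a.groupby("subject")[
            "phi_hat_individual"
        ].mean().to_dict(),
        "mean_phi_hat_shared_by_subject": df_a.groupby("subject")["phi_hat_shared"]
        .mean()
        .to_dict(),
        "paired_diff_individual_mean": float(diffs_ind.mean()),
        "paired_diff_shared_mean": float(diffs_sha.mean()),
        "mean_phi_hat_static_on_decay_data": mean_static,
        "mean_phi_hat_decay_on_decay_data": mean_decay,
        "static_fit_underestimates_phi": bool(mean_static < mean_decay),
        "generative": {
            "alphas": list(alphas),
            "beta": beta,
            "phi": phi,
            "assumed_shared_alpha": alpha_high,
            "decay_alpha0": decay_alpha0,
            "decay_rate": decay_rate,
        },
    }
    return ScenarioSummary(
        7,
        {
            "part_a": df_a,
            "part_a_cells_individual": cells_ind,
            "part_a_cells_shared": cells_sha,
            "part_b": df_b,
        },
        stats,
        flags,
    )


# ---------------------------------------------------------------------------
# dispatch

_SCENARIOS = {
    1: (scenario1, "n_replicates", 50),
    2: (scenario2, "n_replicates", 50),
    3: (scenario3, "n_replicates", 50),
    4: (scenario4, "n_replicates", 20),
    5: (scenario5, "n_datasets", 100),
    6: (scenario6, "n_datasets", 102),
    7: (scenario7, "n_datasets", 400),
}


@dataclass
class ScenarioConfig:
    """Declarative scenario request: id, seed, fast flag and keyword
    overrides forwarded to the scenario function."""

    scenario_id: int
    master_seed: int | None = 0
    fast: bool = False
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario_id not in _SCENARIOS:
            raise ValueError(
                f"unknown scenario_id {self.scenario_id}; valid ids are 1-7"
            )


def run_scenario(config: ScenarioConfig) -> ScenarioSummary:
    """Execute one scenario; ``fast`` runs at 1/10 of the default
    replicate count (minimum 4) unless the count is overridden."""
    fn, count_arg, default_count = _SCENARIOS[config.scenario_id]
    kwargs = dict(config.overrides)
    if config.fast and count_arg not in kwargs:
        kwargs[count_arg] = max(4, default_count // 10)
    summary = fn(seed=config.master_seed, **kwargs)
    summary.master_seed = config.master_seed
    return summary
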