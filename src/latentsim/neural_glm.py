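"""First-level GLM estimation of the neural-coding parameter phi.

Ordinary least squares of the simulated signal on the convolved
(optionally standardized) prediction-error regressor plus an intercept.
The design deliberately exposes the two analysis choices this toolkit
studies as confounds: standardizing the PE regressor by its SD (which
multiplies the estimated phi by that SD) and the event duration assumed
when building the analysis regressor (which, if shorter than the true
duration, inflates phi roughly in proportion to the misspecification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .neural_sim import NeuralConfig, NeuralTimeSeries, build_regressor, simulate_bold
from .rl_core import RLParams, TaskConfig, simulate_agent

__all__ = [
    "DesignSpec",
    "GLMResult",
    "estimate_phi",
    "duration_bias_curve",
]


@dataclass
class DesignSpec:
    """Analysis-side choices for the first-level GLM.

    standardize_pe: divide the trial-level PE amplitudes by their
    sample SD before convolution (the divided-out SD is recorded in
    ``pe_sd_used``).  The SD is taken over the amplitudes, not the
    convolved samples, and no mean-centering is applied unless
    ``center_pe`` is set.  assumed_duration: boxcar length used for the
    analysis regressor, which may differ from the generative one.
    """

    standardize_pe: bool = False
    assumed_duration: float = 0.01
    include_intercept: bool = True
    center_pe: bool = False
    pe_sd_used: float | None = None

    def __post_init__(self) -> None:
        if self.assumed_duration <= 0:
            raise ValueError("assumed_duration must be > 0")


@dataclass
class GLMResult:
    phi_hat: float
    se: float
    residual_sd: float
    design: DesignSpec

    def to_dict(self) -> dict:
        return {
            "phi_hat": float(self.phi_hat),
            "se": float(self.se),
            "residual_sd": float(self.residual_sd),
            "standardize_pe": bool(self.design.standardize_pe),
            "assumed_duration": float(self.design.assumed_duration),
            "pe_sd_used": (
                None if self.design.pe_sd_used is None else float(self.design.pe_sd_used)
            ),
        }


def estimate_phi(
    ts: NeuralTimeSeries,
    pe_hat,
    design: DesignSpec,
    config: NeuralConfig | None = None,
) -> GLMResult:
    """OLS estimate of phi from a time series and a PE regressor.

    ``pe_hat`` is the trial-level PE series entering the analysis (true
    or model-derived); the regressor is built with
    ``design.assumed_duration`` on the config's onset grid and must
    match the series length.
    """
    config = config or ts.config
    amplitudes = np.asarray(pe_hat, dtype=float)
    spec = DesignSpec(
        standardize_pe=design.standardize_pe,
        assumed_duration=design.assumed_duration,
        include_intercept=design.include_intercept,
        center_pe=design.center_pe,
    )
    if spec.center_pe:
        amplitudes = amplitudes - amplitudes.mean()
    if spec.standardize_pe:
        sd = float(np.std(amplitudes, ddof=1))
        if sd == 0:
            raise ValueError("cannot standardize a constant PE series")
        amplitudes = amplitudes / sd
        spec.pe_sd_used = sd

    onsets = np.arange(amplitudes.size) * config.trial_duration
    total_duration = ts.n_scans * config.tr
    x = build_regressor(
        onsets, amplitudes, spec.assumed_duration, config, total_duration=total_duration
    )
    if np.std(x) == 0:
        raise ValueError("degenerate design: PE regressor has zero variance")

    X = sm.add_constant(x) if spec.include_intercept else x[:, None]
    fit = sm.OLS(ts.signal, X).fit()
    k = 1 if spec.include_intercept else 0
    return GLMResult(
        phi_hat=float(fit.params[k]),
        se=float(fit.bse[k]),
        residual_sd=float(np.sqrt(fit.scale)),
        design=spec,
    )


def duration_bias_curve(
    true_durations,
    assumed_duration: float,
    config: NeuralConfig,
    task: TaskConfig,
    params: RLParams,
    n_replicates: int = 20,
    seed=None,
) -> pd.DataFrame:
    """Mean estimated phi per true event duration under a fixed
    assumed analysis duration.

    For each true duration, ``n_replicates`` behavioral datasets are
    simulated, BOLD series generated with that duration, and phi
    estimated with the (typically shorter) ``assumed_duration``.
    Replicate seeds are shared across durations so the curve differs
    only in duration.
    """
    true_durations = list(true_durations)
    if assumed_duration > min(true_durations):
        raise ValueError("assumed_duration must be <= min(true_durations)")
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_replicates)
    design = DesignSpec(assumed_duration=assumed_duration)
    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        behav_seed, noise_seed = rep_seed.spawn(2)
        data = simulate_agent(task, params, np.random.default_rng(behav_seed))
        for dur in true_durations:
            cfg = config.replace(event_duration=float(dur))
            ts = simulate_bold(data.pe, cfg, np.random.default_rng(noise_seed))
            res = estimate_phi(ts, data.pe, design, cfg)
            rows.append(
                {"true_duration": float(dur), "replicate": rep, "phi_hat": res.phi_hat}
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby("true_duration", as_index=False)["phi_hat"]
        .agg(mean_phi_hat="mean", sd_phi_hat="std")
        .sort_values("true_duration", ignore_index=True)
    )
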