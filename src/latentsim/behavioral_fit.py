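"""Maximum-likelihood fitting of reinforcement-learning models to choices.

Supports deliberately misspecified fits (e.g. fixing outcome
sensitivity at 1 when the data were generated with gamma != 1, or
forcing one learning rate across subjects) because the point of the
toolkit is to study what such misspecification does to downstream
neural-coding estimates.

Outcome sensitivity gamma and inverse temperature beta enter the choice
likelihood only through their product, so they are jointly
non-identifiable from choice data; a :class:`ModelSpec` refuses to free
both at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .rl_core import BehavioralData, RLParams

__all__ = [
    "ModelSpec",
    "FitResult",
    "neg_log_likelihood",
    "predicted_pe",
    "fit_mle",
    "fit_shared",
    "PARAM_BOUNDS",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


FAMILY_PARAMS = {
    "static_rw": ("alpha", "beta"),
    "gamma_rw": ("alpha", "beta", "gamma"),
    "decay_rw": ("alpha", "beta", "decay_rate"),
}

PARAM_BOUNDS = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "gamma": (1e-2, 10.0),
    "decay_rate": (0.0, 0.1),
}

_DEFAULT_START = {"alpha": 0.3, "beta": 2.0, "gamma": 1.0, "decay_rate": 0.01}


@dataclass(frozen=True)
class ModelSpec:
    """Which model family to fit and which parameters are free.

    ``fixed_params`` may also carry ``v0`` (default 0.5).  Parameters in
    ``shared_across_subjects`` are forced equal across subjects in
    :func:`fit_shared`.
    """

    family: str = "static_rw"
    free_params: tuple[str, ...] = ("alpha", "beta")
    fixed_params: dict = field(default_factory=dict)
    shared_across_subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILY_PARAMS:
            raise ValueError(f"unknown family {self.family!r}")
        family_params = set(FAMILY_PARAMS[self.family])
        free = set(self.free_params)
        fixed = set(self.fixed_params) - {"v0"}
        if free & fixed:
            raise ValueError("free and fixed parameter sets overlap")
        if free | fixed != family_params:
            raise ValueError(
                f"free+fixed must cover exactly {sorted(family_params)} "
                f"for family {self.family!r}"
            )
        if {"beta", "gamma"} <= free:
            raise ValueError(
                "beta and gamma are non-identifiable from choice data "
                "(they enter the likelihood only as their product); "
                "fix one of them"
            )
        if not set(self.shared_across_subjects) <= free:
            raise ValueError("shared parameters must be free parameters")

    def resolve(self, free_values: dict) -> dict:
        """Full parameter dict (alpha, beta, gamma, decay_rate, v0)."""
        params = {"gamma": 1.0, "decay_rate": 0.0, "v0": 0.5}
        params.update(self.fixed_params)
        params.update(free_values)
        return params


@dataclass
class FitResult:
    estimates: dict
    neg_log_likelihood: float
    converged: bool
    n_restarts_used: int
    pe_hat: np.ndarray
    non_identified: bool = False

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "neg_log_likelihood": float(self.neg_log_likelihood),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
            "non_identified": bool(self.non_identified),
        }


@njit
def _nll_core(choices, outcomes, alpha, beta, gamma, decay_rate, v0):
    va = gamma * v0
    vb = gamma * v0
    nll = 0.0
    for t in range(choices.size):
        dv = beta * (va - vb)
        x = dv if choices[t] == 0 else -dv
        # -log sigmoid(x), stable for large |x|
        if x < -30.0:
            nll += -x
        else:
            nll += math.log1p(math.exp(-x))
        v = va if choices[t] == 0 else vb
        delta = gamma * outcomes[t] - v
        v = v + alpha * math.exp(-decay_rate * t) * delta
        if choices[t] == 0:
            va = v
        else:
            vb = v
    return nll


@njit
def _pe_core(choices, outcomes, alpha, gamma, decay_rate, v0):
    va = gamma * v0
    vb = gamma * v0
    pe = np.empty(choices.size)
    for t in range(choices.size):
        v = va if choices[t] == 0 else vb
        delta = gamma * outcomes[t] - v
        pe[t] = delta
        v = v + alpha * math.exp(-decay_rate * t) * delta
        if choices[t] == 0:
            va = v
        else:
            vb = v
    return pe


def _check_choice_data(data: BehavioralData) -> None:
    if data.mode != "instrumental":
        raise ValueError(
            "choice likelihoods require instrumental data; pavlovian "
            "simulations carry no choice behavior"
        )


def _params_dict(params) -> dict:
    if isinstance(params, RLParams):
        return {
            "alpha": params.alpha,
            "beta": params.beta,
            "gamma": params.gamma,
            "decay_rate": params.decay_rate,
            "v0": params.v0,
        }
    return {"gamma": 1.0, "decay_rate": 0.0, "v0": 0.5, **params}


def neg_log_likelihood(params, data: BehavioralData, spec: ModelSpec | None = None) -> float:
    """-sum_t log Pr(choice_t) with values rebuilt trial by trial.

    ``params`` is an :class:`~latentsim.rl_core.RLParams` or a mapping
    with keys among alpha/beta/gamma/decay_rate/v0; a ``spec`` supplies
    fixed values for missing keys.
    """
    _check_choice_data(data)
    p = spec.resolve(_params_dict(params)) if spec is not None else _params_dict(params)
    return float(
        _nll_core(
            data.choices,
            data.outcomes,
            float(p["alpha"]),
            float(p["beta"]),
            float(p["gamma"]),
            float(p["decay_rate"]),
            float(p["v0"]),
        )
    )


def predicted_pe(params, data: BehavioralData) -> np.ndarray:
    """Trial-wise prediction errors implied by ``params`` for observed
    choices and outcomes."""
    p = _params_dict(params)
    return _pe_core(
        data.choices,
        data.outcomes,
        float(p["alpha"]),
        float(p["gamma"]),
        float(p["decay_rate"]),
        float(p["v0"]),
    )


def _multistart(fun, starts, bounds):
    """Best-of-restarts bounded Nelder-Mead.

    The simplex method is used because the choice likelihood is nearly
    flat in alpha when beta is small, where quasi-Newton methods with
    finite-difference gradients stall on the boundary.
    """
    best = None
    for x0 in starts:
        res = minimize(
            fun,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def _start_points(names, n_restarts, rng):
    points = [np.array([_DEFAULT_START[n] for n in names])]
    for _ in range(max(0, n_restarts - 1)):
        points.append(
            np.array([rng.uniform(*PARAM_BOUNDS[n]) for n in names])
        )
    return points


def fit_mle(
    data: BehavioralData,
    spec: ModelSpec | None = None,
    n_restarts: int = 10,
    seed=None,
) -> FitResult:
    """Best-of-restarts bounded MLE of the free parameters.

    Deterministic given ``seed``.  Data in which every choice is the
    same option leave beta unidentified; the boundary estimate is
    returned with ``non_identified=True`` and ``converged=False``.
    """
    spec = spec or ModelSpec()
    _check_choice_data(data)
    names = list(spec.free_params)
    degenerate = bool(np.all(data.choices == data.choices[0]))

    if not names:
        est = spec.resolve({})
        return FitResult(
            estimates=est,
            neg_log_likelihood=neg_log_likelihood(est, data),
            converged=True,
            n_restarts_used=0,
            pe_hat=predicted_pe(est, data),
        )

    rng = np.random.default_rng(seed)

    def fun(x):
        return neg_log_likelihood(dict(zip(names, x)), data, spec)

    bounds = [PARAM_BOUNDS[n] for n in names]
    best = _multistart(fun, _start_points(names, n_restarts, rng), bounds)
    est = spec.resolve(dict(zip(names, best.x)))
    return FitResult(
        estimates=est,
        neg_log_likelihood=float(best.fun),
        converged=bool(best.success) and not degenerate,
        n_restarts_used=n_restarts,
        pe_hat=predicted_pe(est, data),
        non_identified=degenerate,
    )


def fit_shared(
    datasets: list[BehavioralData],
    spec: ModelSpec,
    n_restarts: int = 10,
    seed=None,
) -> list[FitResult]:
    """Joint MLE with ``spec.shared_across_subjects`` forced equal.

    Returns one :class:`FitResult` per subject; shared estimates are
    identical across results and each result's ``neg_log_likelihood``
    is that subject's own contribution at the joint optimum.
    """
    if not datasets:
        raise ValueError("fit_shared requires at least one dataset")
    for d in datasets:
        _check_choice_data(d)
    shared = list(spec.shared_across_subjects)
    if not shared:
        raise ValueError("spec.shared_across_subjects is empty")
    per_subject = [n for n in spec.free_params if n not in shared]
    n_sub = len(datasets)
    names_flat = shared + [f"{n}" for _ in range(n_sub) for n in per_subject]
    bounds = [PARAM_BOUNDS[n] for n in names_flat]

    def unpack(x):
        shared_vals = dict(zip(shared, x[: len(shared)]))
        out = []
        k = len(shared)
        for _ in range(n_sub):
            vals = dict(shared_vals)
            for n in per_subject:
                vals[n] = x[k]
                k += 1
            out.append(vals)
        return out

    def fun(x):
        return sum(
            neg_log_likelihood(vals, d, spec)
            for vals, d in zip(unpack(x), datasets)
        )

    rng = np.random.default_rng(seed)
    starts = []
    base = [_DEFAULT_START[n] for n in names_flat]
    starts.append(np.array(base))
    for _ in range(max(0, n_restarts - 1)):
        starts.append(np.array([rng.uniform(*b) for b in bounds]))

    best = _multistart(fun, starts, bounds)

    results = []
    for vals, d in zip(unpack(best.x), datasets):
        est = spec.resolve(vals)
        results.append(
            FitResult(
                estimates=est,
                neg_log_likelihood=neg_log_likelihood(est, d),
                converged=bool(best.success),
                n_restarts_used=n_restarts,
                pe_hat=predicted_pe(est, d),
            )
        )
    return results
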