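"""BOLD-like time-series synthesis from a prediction-error series.

The neural model is a scaled parametric modulation: on each trial the
"neural" event has amplitude ``phi * PE_t`` (plus white Gaussian noise
on the sampled scans), realized as a boxcar of a configurable duration
convolved with a double-gamma hemodynamic response function and sampled
at the scanner TR.

Noise can be set either as an explicit standard deviation or as a
contrast-to-noise ratio, defined here as
``CNR = SD(noiseless convolved signal) / noise SD``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HRFSpec",
    "NeuralConfig",
    "NeuralTimeSeries",
    "hrf_kernel",
    "build_regressor",
    "simulate_bold",
]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF in the SPM convention, unit-peak normalized.

    Difference of two gamma densities: a positive lobe peaking around
    ``peak_delay`` seconds and an undershoot around ``undershoot_delay``
    seconds scaled by ``undershoot_ratio``.  ``dt`` is the oversampling
    grid step used for convolution; ``duration`` the kernel support.
    """

    shape: str = "double_gamma"
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    dt: float = 0.01
    duration: float = 32.0

    def __post_init__(self) -> None:
        if self.shape != "double_gamma":
            raise ValueError("only the double_gamma shape is implemented")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.dt > 0.05:
            raise ValueError("dt must be <= 0.05 s for adequate oversampling")


@dataclass(frozen=True)
class NeuralConfig:
    """Everything needed to map a PE series to a BOLD-like series.

    Exactly one of ``noise_sd`` and ``cnr`` must be set (``noise_sd=0``
    is a valid, noiseless, choice).  ``trial_duration`` is the
    inter-onset interval; ``event_duration`` the generative boxcar
    length per event.
    """

    phi: float
    tr: float = 1.0
    trial_duration: float = 4.0
    event_duration: float = 0.01
    noise_sd: float | None = None
    cnr: float | None = None
    hrf: HRFSpec = field(default_factory=HRFSpec)

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi):
            raise ValueError("phi must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.event_duration < self.hrf.dt:
            raise ValueError("event_duration must be >= the hrf dt grid step")
        if (self.noise_sd is None) == (self.cnr is None):
            raise ValueError("set exactly one of noise_sd and cnr")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cnr is not None and self.cnr <= 0:
            raise ValueError("cnr must be > 0")

    def replace(self, **kw) -> "NeuralConfig":
        return replace(self, **kw)


@dataclass
class NeuralTimeSeries:
    """Sampled signal plus the provenance that generated it."""

    times: np.ndarray
    signal: np.ndarray
    config: NeuralConfig
    pe: np.ndarray | None = None
    noise_sd_used: float | None = None

    @property
    def n_scans(self) -> int:
        return int(self.signal.size)


def hrf_kernel(spec: HRFSpec | None = None) -> np.ndarray:
    """Sampled HRF on the ``spec.dt`` grid, zero at t=0, unit peak."""
    spec = spec or HRFSpec()
    t = np.arange(0.0, spec.duration, spec.dt)
    h = gamma_dist.pdf(t, a=spec.peak_delay) - spec.undershoot_ratio * gamma_dist.pdf(
        t, a=spec.undershoot_delay
    )
    return h / h.max()


def _n_scans(total_duration: float, tr: float) -> int:
    return int(ceil(total_duration / tr - 1e-9))


def build_regressor(
    onsets,
    amplitudes,
    durations,
    config: NeuralConfig,
    total_duration: float | None = None,
) -> np.ndarray:
    """Boxcar train (height=amplitude, width=duration) convolved with
    the HRF and sampled at the TR.

    Exactly linear in ``amplitudes``.  ``total_duration`` defaults to
    the last onset plus one trial duration.
    """
    onsets = np.asarray(onsets, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if durations.ndim == 0:
        durations = np.full(onsets.size, float(durations))
    if not (onsets.size == amplitudes.size == durations.size):
        raise ValueError("onsets, amplitudes and durations must have equal length")
    if onsets.size == 0:
        raise ValueError("at least one event is required")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    if np.any(durations < 0):
        raise ValueError("durations must be non-negative")

    dt = config.hrf.dt
    if total_duration is None:
        total_duration = float(onsets[-1]) + config.trial_duration
    n_hi = int(round(total_duration / dt))
    box = np.zeros(n_hi)
    for onset, amp, dur in zip(onsets, amplitudes, durations):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        box[i0 : min(i1, n_hi)] += amp

    conv = fftconvolve(box, hrf_kernel(config.hrf))[:n_hi]
    n_scans = _n_scans(total_duration, config.tr)
    idx = np.minimum(np.round(np.arange(n_scans) * config.tr / dt).astype(int), n_hi - 1)
    return conv[idx]


def resolve_noise_sd(config: NeuralConfig, noiseless: np.ndarray) -> float:
    """Noise SD implied by the config; CNR divides the noiseless
    signal's SD."""
    if config.noise_sd is not None:
        return float(config.noise_sd)
    return float(np.std(noiseless, ddof=1) / config.cnr)


def simulate_bold(pe, config: NeuralConfig, seed=None) -> NeuralTimeSeries:
    """Generate the BOLD-like series ``phi * regressor(PE) + noise``.

    Onsets sit on a regular grid at ``trial_duration`` spacing.  With
    ``cnr`` set, the noise SD is the noiseless signal's SD divided by
    the CNR.  Fully reproducible given ``seed``.
    """
    pe = np.asarray(pe, dtype=float)
    if pe.size == 0:
        raise ValueError("pe series must be non-empty")
    onsets = np.arange(pe.size) * config.trial_duration
    noiseless = config.phi * build_regressor(
        onsets, pe, config.event_duration, config
    )
    sd = resolve_noise_sd(config, noiseless)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signal = noiseless + rng.normal(0.0, sd, noiseless.size) if sd > 0 else noiseless
    times = np.arange(noiseless.size) * config.tr
    return NeuralTimeSeries(
        times=times, signal=signal, config=config, pe=pe, noise_sd_used=sd
    )
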