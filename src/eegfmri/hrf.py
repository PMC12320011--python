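"""Double-gamma hemodynamic response functions with a scalable overshoot delay.

The BOLD signal lags the neural activity it reflects.  To search over that
lag, a family of haemodynamic response functions (HRFs) is built from the
canonical double-gamma shape (overshoot peaking at 6 s, undershoot at 16 s)
by varying the overshoot delay and linearly rescaling the remaining shape
parameters, so that the overall dynamics are preserved while the peak moves.
EEG band-power regressors are convolved with each member of the family
before being correlated with fMRI network time series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "HRFParams",
    "HRFKernel",
    "CANONICAL",
    "scaled_params",
    "hrf_kernel",
    "convolve_feature",
    "delay_family",
]


@dataclass(frozen=True)
class HRFParams:
    """Shape parameters of a double-gamma HRF.

    All temporal parameters are in seconds.  ``peak_undershoot_ratio`` is the
    amplitude ratio between the positive response peak and the post-stimulus
    undershoot (dimensionless).
    """

    overshoot_delay: float = 6.0
    undershoot_delay: float = 16.0
    overshoot_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration: float = 32.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.overshoot_delay < 0:
            raise ValueError("overshoot_delay must be >= 0")
        for name in ("undershoot_delay", "overshoot_dispersion",
                     "undershoot_dispersion", "duration", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.duration < self.overshoot_delay:
            raise ValueError("duration must cover the overshoot delay")


@dataclass(frozen=True)
class HRFKernel:
    """A sampled HRF, normalized to unit peak amplitude."""

    samples: np.ndarray
    dt: float
    params: HRFParams

    @property
    def peak_lag_s(self) -> float:
        """Time of the kernel maximum, in seconds."""
        return float(np.argmax(self.samples) * self.dt)

    @property
    def is_delta(self) -> bool:
        """True for the degenerate zero-delay (identity) kernel."""
        return self.params.overshoot_delay == 0


CANONICAL = HRFParams()


def scaled_params(overshoot_delay: float, canonical: HRFParams = CANONICAL) -> HRFParams:
    """Rescale the canonical shape so the overshoot peaks at ``overshoot_delay``.

    The undershoot delay and both dispersions are multiplied by
    ``overshoot_delay / canonical.overshoot_delay``; the peak:undershoot
    amplitude ratio and the kernel duration are left unchanged, preserving
    the relative dynamics of the response.
    """
    if overshoot_delay < 0:
        raise ValueError("overshoot_delay must be >= 0")
    s = overshoot_delay / canonical.overshoot_delay
    if s == 0:
        # Degenerate: all gamma parameters collapse; represented downstream
        # as an identity (delta) kernel meaning "no hemodynamic lag".
        return replace(canonical, overshoot_delay=0.0)
    return replace(
        canonical,
        overshoot_delay=overshoot_delay,
        undershoot_delay=canonical.undershoot_delay * s,
        overshoot_dispersion=canonical.overshoot_dispersion * s,
        undershoot_dispersion=canonical.undershoot_dispersion * s,
    )


def hrf_kernel(params: HRFParams) -> HRFKernel:
    """Sample the double-gamma HRF on ``[0, duration]`` at spacing ``dt``.

    The kernel is the difference of two gamma densities — one for the
    response peak and one, divided by the peak:undershoot ratio, for the
    undershoot — normalized to unit peak.  A zero overshoot delay yields a
    Kronecker delta (convolution identity).
    """
    n = int(round(params.duration / params.dt)) + 1
    if params.overshoot_delay == 0:
        samples = np.zeros(n)
        samples[0] = 1.0
        return HRFKernel(samples=samples, dt=params.dt, params=params)
    t = np.arange(n) * params.dt
    a1 = params.overshoot_delay / params.overshoot_dispersion
    a2 = params.undershoot_delay / params.undershoot_dispersion
    peak = _gamma_dist.pdf(t, a1, scale=params.overshoot_dispersion)
    under = _gamma_dist.pdf(t, a2, scale=params.undershoot_dispersion)
    h = peak - under / params.peak_undershoot_ratio
    h[0] = 0.0
    peak_val = h.max()
    if peak_val <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return HRFKernel(samples=h / peak_val, dt=params.dt, params=params)


def convolve_feature(ts: np.ndarray, kernel: HRFKernel) -> np.ndarray:
    """Causally convolve time series with an HRF, truncated to input length.

    ``ts`` may be 1-D ``[n_time]`` or N-D with time on the last axis.  The
    past is zero-padded, so the first samples reflect only the kernel onset
    (no acausal leakage); the full length is retained to match whole-series
    correlation downstream.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    if len(kernel.samples) > n:
        raise ValueError(
            f"kernel ({len(kernel.samples)} samples) longer than signal ({n})")
    out = np.apply_along_axis(
        lambda x: np.convolve(x, kernel.samples)[:n], -1, ts)
    return out


def delay_family(delays, canonical: HRFParams = CANONICAL,
                 dt: float | None = None) -> list[HRFKernel]:
    """Build one kernel per overshoot delay, order preserved.

    The default grid used throughout the pipeline is {2, 4, 5, 6, 8, 10} s;
    an extended sweep covers 0-20 s.  Delay 0 is the identity kernel.
    """
    delays = list(delays)
    if not delays:
        raise ValueError("delay grid must be nonempty")
    if any(d < 0 for d in delays):
        raise ValueError("delays must be nonnegative")
    if len(set(delays)) != len(delays):
        raise ValueError("duplicate delays in grid")
    if dt is not None:
        canonical = replace(canonical, dt=dt)
    return [hrf_kernel(scaled_params(d, canonical)) for d in delays]


#: Overshoot-delay grid of the standard analysis (seconds).
DEFAULT_DELAYS = (2.0, 4.0, 5.0, 6.0, 8.0, 10.0)

#: Extended sweep for exploratory delay analyses (seconds).
EXTENDED_DELAYS = tuple(float(d) for d in range(0, 21, 2))
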