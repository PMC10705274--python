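"""Coupled Stuart-Landau (Hopf normal form) whole-brain model.

Each region i follows the supercritical Hopf normal form in Cartesian
coordinates, diffusively coupled through the structural connectome M and
driven by uncorrelated Gaussian noise:

    dx_i = [ (a_i - x_i^2 - y_i^2) x_i - w_i y_i
             + G * sum_j M_ij (x_j - x_i) + F_i(t) cos(w_i t) ] dt
             + beta dW_i^x
    dy_i = [ (a_i - x_i^2 - y_i^2) y_i + w_i x_i
             + G * sum_j M_ij (y_j - y_i) + F_i(t) sin(w_i t) ] dt
             + beta dW_i^y

For a_i > 0 an uncoupled noise-free node settles on a limit cycle of radius
sqrt(a_i) rotating at f_i = w_i / 2pi; for a_i < 0 the origin is a stable
focus and activity is purely noise-driven; at a_i ~ 0 the node sits at the
bifurcation, the default working point.  x_i(t) is the BOLD-like signal.

Note on the printed source equations this model family descends from: the
cubic term is sometimes typeset as (x^2 - y^2) and the rotation with two
minus signs; neither form produces the limit-cycle/fixed-point bifurcation
at radius sqrt(a) and frequency f_i that defines this model, so the standard
Stuart-Landau form above is used.

Integration is Euler-Maruyama: state += drift*dt + beta*sqrt(dt)*N(0,1),
with independent noise streams for x and y.  Stimulation adds a sinusoidal
forcing of amplitude F_i(t) = F0_i + sigma*mu_i(t) at the node's own
frequency; mu_i(t) is redrawn each step and shared between the cos and sin
terms of a node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


import numpy as np
from scipy import signal

from .connectome_core import (
    FunctionalConnectome,
    MesoplastError,
    StructuralConnectome,
)

__all__ = [
    "ModelParameters",
    "StimulusSpec",
    "BOLDRecording",
    "NumericalInstabilityError",
    "integrate",
    "bandpass",
    "simulate_bold",
    "compute_fc",
    "DEFAULT_BAND",
]

#: Band of the empirical resting-state BOLD signals the model emulates.
DEFAULT_BAND = (0.01, 0.1)


class NumericalInstabilityError(MesoplastError):
    """The trajectory left the finite domain (e.g. G too large)."""


@dataclass
class ModelParameters:
    """Parameters of one whole-brain simulation.

    Defaults place every node at the bifurcation (a = 0) oscillating at
    0.05 Hz, noise SD beta = 0.1, 15 min of simulated time at dt = 0.1 s
    with a 60 s transient discarded.
    """

    sc: StructuralConnectome
    G: float = 0.0
    a: float | np.ndarray = 0.0
    f: float | np.ndarray = 0.05  # Hz; angular w_i = 2*pi*f_i
    beta: float = 0.1
    dt: float = 0.1
    duration: float = 900.0
    transient: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.duration > self.transient >= 0):
            raise ValueError("need duration > transient >= 0")
        if self.beta < 0 or self.G < 0:
            raise ValueError("beta and G must be nonnegative")
        n = self.sc.n
        self.a = np.broadcast_to(np.asarray(self.a, float), (n,)).copy()
        self.f = np.broadcast_to(np.asarray(self.f, float), (n,)).copy()

    @property
    def n(self) -> int:
        return self.sc.n

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.f

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class StimulusSpec:
    """Noisy sinusoidal forcing applied to a set of target regions.

    On targets the forcing amplitude is F_i(t) = f0 + sigma*mu_i(t); off
    targets the forcing is identically zero.  Resting state corresponds to
    no stimulus (or f0 = sigma = 0).
    """

    targets: frozenset[int] = field(default_factory=frozenset)
    f0: float = 0.5
    sigma: float = 0.0

    def __post_init__(self) -> None:
        self.targets = frozenset(int(t) for t in self.targets)
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def amplitude_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(n)
        for t in self.targets:
            if not (0 <= t < n):
                raise ValueError(f"stimulus target {t} outside 0..{n - 1}")
            mask[t] = 1.0
        return mask


@dataclass
class BOLDRecording:
    """Simulated BOLD-like signals, samples x regions."""

    signals: np.ndarray
    dt: float
    band: tuple[float, float] | None = None

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_regions(self) -> int:
        return self.signals.shape[1]


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate(
    params: ModelParameters, stimulus: StimulusSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama trajectory of (x, y), including the transient.

    Returns arrays of shape (n_steps, n).  Initial conditions are uniform in
    [-0.1, 0.1]^2 per node, drawn from the seeded stream; the whole
    trajectory is deterministic given the seed.

    Raises
    ------
    NumericalInstabilityError
        naming the step index at which the state became non-finite.
    """
    n = params.n
    n_steps = params.n_steps
    rng = np.random.default_rng(params.seed)
    x = rng.uniform(-0.1, 0.1, size=n)
    y = rng.uniform(-0.1, 0.1, size=n)

    M = params.sc.weights
    row_sum = M.sum(axis=1)
    a = params.a
    w = params.omega
    G = params.G
    dt = params.dt
    sq = np.sqrt(dt)
    beta = params.beta

    if stimulus is not None and stimulus.targets:
        stim_mask = stimulus.amplitude_mask(n)
        f0 = stimulus.f0
        sigma = stimulus.sigma
    else:
        stim_mask = None
        f0 = sigma = 0.0

    xs = np.empty((n_steps, n))
    ys = np.empty((n_steps, n))

    t = 0.0
    check_every = 200
    # divergence surfaces as the instability error, not as numpy warnings
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            r2 = x * x + y * y
            coup_x = G * (M @ x - row_sum * x)
            coup_y = G * (M @ y - row_sum * y)
            dx = (a - r2) * x - w * y + coup_x
            dy = (a - r2) * y + w * x + coup_y
            if stim_mask is not None:
                amp = f0
                if sigma > 0.0:
                    amp = f0 + sigma * rng.standard_normal(n)
                force = stim_mask * amp
                dx = dx + force * np.cos(w * t)
                dy = dy + force * np.sin(w * t)
            x = x + dx * dt
            y = y + dy * dt
            if beta > 0.0:
                noise = rng.standard_normal((2, n))
                x = x + beta * sq * noise[0]
                y = y + beta * sq * noise[1]
            xs[k] = x
            ys[k] = y
            t += dt
            if (k % check_every == 0 or k == n_steps - 1) and not np.isfinite(
                x
            ).all():
                raise NumericalInstabilityError(
                    f"non-finite state at step {k} (t = {k * dt:.1f} s); "
                    f"G = {G} may be too large"
                )
    return xs, ys


def bandpass(
    signals: np.ndarray, low: float, high: float, dt: float
) -> np.ndarray:
    """Zero-phase third-order Bessel band-pass along the time axis.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order
    and removes phase distortion; DC is fully rejected.
    """
    nyq = 0.5 / dt
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = signal.bessel(3, [low, high], btype="bandpass", fs=1.0 / dt, output="sos")
    return signal.sosfiltfilt(sos, signals, axis=0)


def simulate_bold(
    params: ModelParameters,
    stimulus: StimulusSpec | None = None,
    band: tuple[float, float] | None = DEFAULT_BAND,
) -> BOLDRecording:
    """Integrate, discard the transient, and band-pass the x components."""
    xs, _ = integrate(params, stimulus)
    n_drop = int(round(params.transient / params.dt))
    x = xs[n_drop:]
    if band is not None:
        x = bandpass(x, band[0], band[1], params.dt)
        x = x - x.mean(axis=0)  # exact DC removal after the finite-window filter
    return BOLDRecording(signals=x, dt=params.dt, band=band)


def compute_fc(bold: BOLDRecording | np.ndarray) -> FunctionalConnectome:
    """Pairwise Pearson correlations between regional time series.

    Constant regions (reachable at beta = 0, a < 0) are flagged with a
    warning and given correlation 0 to all others rather than NaN.
    """
    sig = bold.signals if isinstance(bold, BOLDRecording) else np.asarray(bold, float)
    if sig.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate")
    sd = sig.std(axis=0)
    constant = sd < 1e-300
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant region(s); correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(sig.T)
    fc = np.nan_to_num(fc, nan=0.0)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return FunctionalConnectome(values=fc, source="simulated")
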