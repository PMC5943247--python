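"""Four-state photophysics model of a photoconvertible fluorophore and
discrete-time simulation of tcPALM acquisitions.

The fluorophore (modelled on Dendra2) occupies one of four states:

1. **pre-converted** — not yet photoactivated; leaves at rate ``k_on``
   (405 nm activation laser),
2. **fluorescent** — the only observable state; blinks into the dark
   state at ``k_dark`` and photobleaches irreversibly at ``k_bleach``
   (561 nm imaging laser),
3. **dark** — reversible blinking state; recovers at ``k_rec``,
4. **bleached** — absorbing.

The discrete-time chain with step ``dt`` uses the transition matrix

    T = [[1 - k_on*dt,  k_on*dt,                      0,           0        ],
         [0,            1 - k_dark*dt - k_bleach*dt,  k_dark*dt,   k_bleach*dt],
         [0,            k_rec*dt,                     1 - k_rec*dt, 0       ],
         [0,            0,                            0,           1        ]]

All molecules start pre-converted. A camera exposure bin (default 60 ms
= 10 steps of 6 ms) records a detection for a molecule if it was
fluorescent at any step within the bin. Within one diffraction-limited
cluster, simultaneously fluorescent molecules merge into a single spot
and contribute a single localization count per bin (``merge=True``);
the non-merged per-bin molecule count is available for diagnostics and
for spatially extended regions where spots do not overlap.

The cumulative whole-trace localization count is fitted with

    N(t) = N0 * (1 - exp(-k_on * t)) + B * t

to estimate the photoactivation rate ``k_on`` (a constant, linear noise
term ``B*t`` absorbs background).

Default rates (1/s): k_on = 1/43, k_dark = 9.61, k_rec = 2.33,
k_bleach = 3.0, with dt = 6 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

PRECONVERTED, FLUORESCENT, DARK, BLEACHED = 1, 2, 3, 4


@dataclass(frozen=True)
class PhotophysicsModel:
    """Kinetic scheme of the 4-state fluorophore; rates in 1/s, dt in s."""

    k_on: float = 1.0 / 43.0
    k_dark: float = 9.61
    k_rec: float = 2.33
    k_bleach: float = 3.0
    dt: float = 0.006

    def __post_init__(self) -> None:
        for name in ("k_on", "k_dark", "k_rec", "k_bleach"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if (self.k_dark + self.k_bleach) * self.dt > 1:
            raise ValueError(
                "dt too large: (k_dark + k_bleach)*dt exceeds 1, "
                "fluorescent-state row would go negative")
        if self.k_on * self.dt > 1:
            raise ValueError("dt too large for k_on: pre-converted row goes negative")
        if self.k_rec * self.dt > 1:
            raise ValueError("dt too large for k_rec: dark row goes negative")

    def transition_matrix(self) -> np.ndarray:
        return build_transition_matrix(self)


#: Dendra2 rates in U2OS at the reference acquisition settings.
DENDRA2 = PhotophysicsModel()


def build_transition_matrix(model: PhotophysicsModel) -> np.ndarray:
    """Row-stochastic 4x4 matrix of the discrete chain; state 4 absorbing."""
    a, d, r, b = (model.k_on * model.dt, model.k_dark * model.dt,
                  model.k_rec * model.dt, model.k_bleach * model.dt)
    T = np.array([
        [1 - a, a, 0.0, 0.0],
        [0.0, 1 - d - b, d, b],
        [0.0, r, 1 - r, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    if (T < 0).any():
        raise ValueError("transition matrix has a negative entry; reduce dt")
    return T


def _step(states: np.ndarray, model: PhotophysicsModel, rng: np.random.Generator) -> None:
    """Advance all molecules by one dt, in place.

    One uniform per molecule, partitioned per the transition-matrix row:
    categorical sampling exactly per T.
    """
    u = rng.random(states.shape)
    pre = states == PRECONVERTED
    fluo = states == FLUORESCENT
    dark = states == DARK
    a = model.k_on * model.dt
    d = model.k_dark * model.dt
    b = model.k_bleach * model.dt
    r = model.k_rec * model.dt
    states[pre & (u < a)] = FLUORESCENT
    to_dark = fluo & (u < d)
    to_bleach = fluo & (u >= d) & (u < d + b)
    states[to_dark] = DARK
    states[to_bleach] = BLEACHED
    states[dark & (u < r)] = FLUORESCENT


def simulate_molecule(model: PhotophysicsModel, n_steps: int, seed) -> np.ndarray:
    """State trajectory of one molecule: length ``n_steps + 1``, starts
    pre-converted, state 4 absorbing."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    states = np.empty(n_steps + 1, dtype=np.int8)
    states[0] = PRECONVERTED
    s = np.array([PRECONVERTED], dtype=np.int8)
    for k in range(1, n_steps + 1):
        _step(s, model, rng)
        states[k] = s[0]
    return states


def occupancy_counts(
    model: PhotophysicsModel, n_molecules: int, n_steps: int, seed
) -> np.ndarray:
    """Ensemble state-occupancy counts, shape (n_steps + 1, 4).

    Row k counts molecules in states 1..4 after k steps; each row sums
    to ``n_molecules``. Useful for checking against the matrix-power
    prediction ``T^k`` applied to the all-pre-converted start.
    """
    rng = np.random.default_rng(seed)
    states = np.full(n_molecules, PRECONVERTED, dtype=np.int8)
    out = np.empty((n_steps + 1, 4), dtype=np.int64)
    for k in range(n_steps + 1):
        if k:
            _step(states, model, rng)
        out[k] = [(states == s).sum() for s in (1, 2, 3, 4)]
    return out


@dataclass
class SimulatedTrace:
    """Per-bin detection counts of a simulated acquisition."""

    counts: np.ndarray          # per camera bin
    bin_s: float
    n_molecules: int
    merged: bool
    window: Optional[Tuple[float, float]] = None
    seed: Optional[int] = None

    @property
    def t(self) -> np.ndarray:
        """Bin end times, s (the cumulative count at t includes the bin)."""
        return (np.arange(len(self.counts)) + 1) * self.bin_s

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.counts)

    def to_time_trace(self):
        from .tcpalm import TimeTrace

        return TimeTrace(counts=self.counts.astype(np.int64), frame_time=self.bin_s)


def simulate_detection_matrix(
    model: PhotophysicsModel, n_molecules: int, n_bins: int,
    steps_per_bin: int, rng: np.random.Generator,
) -> np.ndarray:
    """Boolean (n_bins, n_molecules): molecule fluorescent at any step of bin."""
    states = np.full(n_molecules, PRECONVERTED, dtype=np.int8)
    det = np.zeros((n_bins, n_molecules), dtype=bool)
    for b in range(n_bins):
        seen = np.zeros(n_molecules, dtype=bool)
        for _ in range(steps_per_bin):
            _step(states, model, rng)
            seen |= states == FLUORESCENT
        det[b] = seen
    return det


def simulate_cluster_trace(
    model: PhotophysicsModel,
    n_molecules: int,
    acquisition_s: float,
    bin_s: float = 0.06,
    window: Optional[Tuple[float, float]] = None,
    merge: bool = True,
    seed=0,
) -> SimulatedTrace:
    """Simulate the tcPALM trace of one cluster of ``n_molecules``.

    ``bin_s`` must be an integer multiple of ``model.dt``. With
    ``merge=True`` (single-spot rule) each bin yields 0 or 1 detections;
    otherwise the bin count is the number of molecules fluorescent at
    some step of the bin. A ``window=(t_start, t_end)`` zeroes the
    counts outside it, emulating a transiently assembled cluster.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    ratio = bin_s / model.dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("bin_s must be an integer multiple of model.dt")
    steps_per_bin = int(round(ratio))
    n_bins = int(round(acquisition_s / bin_s))
    if window is not None and not window[0] <= window[1]:
        raise ValueError("window must satisfy t_start <= t_end")
    rng = np.random.default_rng(seed)
    det = simulate_detection_matrix(model, n_molecules, n_bins, steps_per_bin, rng)
    counts = det.any(axis=1).astype(np.int64) if merge else det.sum(axis=1).astype(np.int64)
    if window is not None:
        t = (np.arange(n_bins) + 0.5) * bin_s   # bin centres
        counts = np.where((t >= window[0]) & (t <= window[1]), counts, 0)
    return SimulatedTrace(counts=counts, bin_s=bin_s, n_molecules=n_molecules,
                          merged=merge, window=window, seed=seed)


# ---------------------------------------------------------------------------
# activation-rate fitting
# ---------------------------------------------------------------------------

@dataclass
class ActivationFit:
    k_on: float
    N0: float
    B: float
    residual_norm: float

    @property
    def tau(self) -> float:
        """Activation time constant 1/k_on, s."""
        return 1.0 / self.k_on


def _activation_model(params, t):
    k, n0, b = params
    return n0 * (1.0 - np.exp(-k * t)) + b * t


class ActivationRateModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of a cumulative tcPALM trace to
    ``N(t) = N0 (1 - exp(-k_on t)) + B t``.

    Fitted attributes: ``k_on_``, ``N0_``, ``B_``, ``residual_norm_``.
    By default ``B >= 0`` is enforced: the linear term models a
    nonnegative background rate, and leaving it free lets a negative
    slope trade off against a slower exponential along a flat ridge,
    biasing ``1/k_on`` upward on background-free traces. Set
    ``allow_negative_background=True`` for an unconstrained fit (a
    negative estimate then triggers a warning).
    """

    def __init__(self, xtol: float = 1e-8, max_nfev: int = 10000,
                 allow_negative_background: bool = False):
        self.xtol = xtol
        self.max_nfev = max_nfev
        self.allow_negative_background = allow_negative_background

    def fit(self, t, N):
        t = np.asarray(t, dtype=float).ravel()
        N = np.asarray(N, dtype=float).ravel()
        if len(t) < 100:
            raise ValueError("fit needs a cumulative trace over at least 100 bins")
        if N.max() <= 0:
            raise ValueError("trace carries no signal")
        n0_init = float(N.max())
        # terminal slope estimates the linear background
        tail = max(len(t) // 10, 2)
        b_init = max(float((N[-1] - N[-tail]) / (t[-1] - t[-tail])), 0.0)
        half = np.searchsorted(N, N[-1] / 2)
        t_half = t[min(half, len(t) - 1)]
        k_init = np.log(2.0) / max(t_half, t[1] - t[0])
        if self.allow_negative_background:
            bounds, method = (-np.inf, np.inf), "lm"
        else:
            bounds, method = ([1e-12, 0.0, 0.0], np.inf), "trf"
        res = least_squares(
            lambda p: _activation_model(p, t) - N,
            x0=[max(k_init, 1e-6), n0_init, b_init],
            bounds=bounds,
            xtol=self.xtol, ftol=self.xtol, gtol=self.xtol,
            max_nfev=self.max_nfev, method=method,
        )
        if not res.success:
            raise RuntimeError(
                f"activation-rate fit did not converge: {res.message}; "
                f"final residual norm {np.linalg.norm(res.fun):.3g}, iterate {res.x}")
        k, n0, b = res.x
        if k <= 0:
            raise RuntimeError("activation-rate fit converged to k_on <= 0")
        if b < 0:
            warnings.warn("fitted background slope B is negative", stacklevel=2)
        self.k_on_, self.N0_, self.B_ = float(k), float(n0), float(b)
        self.residual_norm_ = float(np.linalg.norm(res.fun))
        return self

    def predict(self, t):
        return _activation_model((self.k_on_, self.N0_, self.B_), np.asarray(t, float))


def fit_activation_rate(trace, t=None) -> ActivationFit:
    """Fit the activation model to a trace.

    ``trace`` may be a :class:`SimulatedTrace`, a cumulative-count array
    (with ``t`` given), or anything with ``t`` and ``cumulative``.
    """
    if t is None:
        t, N = trace.t, trace.cumulative
    else:
        N = np.asarray(trace, dtype=float)
    m = ActivationRateModel().fit(t, N)
    return ActivationFit(k_on=m.k_on_, N0=m.N0_, B=m.B_,
                         residual_norm=m.residual_norm_)
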