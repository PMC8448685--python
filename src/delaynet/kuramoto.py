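"""Delay-coupled Kuramoto simulation on a delay network.

Each region n is a phase oscillator theta_n obeying

    dtheta_n/dt = omega + k * sum_p C_np sin(theta_p(t - tau_np) - theta_n(t))

with identical natural frequency omega (rad/s), binary coupling matrix C and
per-edge conduction delays tau (s).  Integration is explicit Euler on a
fixed step (delay lookups need a fixed grid); delayed phases are read from a
ring-buffer history, pre-filled for t < 0 by free rotation
theta_n(0) + omega * t.

Synchrony is summarised through the order parameter

    z(t) = (1/N) sum_j exp(i theta_j(t)) = r(t) exp(i Phi(t)),

with *global synchrony* the time-average of r(t) and *metastability* its
standard deviation, both over an analysis window that discards the initial
transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrationError
from .network import DelayNetwork

__all__ = [
    "KuramotoConfig",
    "KuramotoRun",
    "SweepResult",
    "order_parameter",
    "simulate",
    "sweep",
]


def _default_couplings():
    # 0.1 .. 10 inclusive, step 0.1
    return np.round(np.arange(1, 101) * 0.1, 10)


@dataclass
class KuramotoConfig:
    """Simulation protocol.

    ``omega_hz`` is the common natural frequency in Hz (converted to rad/s
    inside the integrator; 40 Hz is the gamma-band default).  ``coupling``
    is the factor k used by :func:`simulate`; ``couplings`` is the sweep
    grid used by :func:`sweep` with ``n_runs`` random-initial-phase
    repetitions per value.  Time is simulated from 0 to ``t_end`` in steps
    of ``dt`` and statistics are taken on samples inside ``window``
    (endpoints included).
    """

    omega_hz: float = 40.0
    coupling: float = 1.0
    couplings: np.ndarray = field(default_factory=_default_couplings)
    n_runs: int = 100
    dt: float = 0.001
    t_end: float = 1.0
    window: tuple = (0.3, 0.7)
    seed: Optional[int] = None
    normalize_coupling: bool = False   # divide the coupling sum by N
    weighted_coupling: bool = False    # use tau-network weights instead of 0/1
    delay_rounding: str = "nearest"    # or "up"
    omega_in_radians: bool = False     # omega_hz already in rad/s

    def validate(self) -> None:
        problems = []
        if self.dt <= 0:
            problems.append("dt must be > 0")
        if self.t_end <= 0:
            problems.append("t_end must be > 0")
        w0, w1 = self.window
        if not (0 <= w0 < w1 <= self.t_end):
            problems.append("window must satisfy 0 <= start < end <= t_end")
        if self.n_runs < 1:
            problems.append("n_runs must be >= 1")
        if self.delay_rounding not in ("nearest", "up"):
            problems.append("delay_rounding must be 'nearest' or 'up'")
        if len(self.couplings) == 0:
            problems.append("couplings grid must be non-empty")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def omega(self) -> float:
        """Natural frequency in rad/s."""
        return self.omega_hz if self.omega_in_radians \
            else 2.0 * np.pi * self.omega_hz


@dataclass
class KuramotoRun:
    """One simulated trajectory plus its window statistics."""

    phases: np.ndarray       # (N, n_steps + 1), radians (unwrapped)
    times: np.ndarray        # (n_steps + 1,), s
    r: np.ndarray            # order-parameter magnitude per sample, [0, 1]
    phi: np.ndarray          # ensemble phase per sample, radians
    synchrony: float         # mean of r over the window
    metastability: float     # SD of r over the window
    coupling: float
    seed: object = None


@dataclass
class SweepResult:
    """Synchrony/metastability statistics across a coupling sweep."""

    couplings: np.ndarray
    synchrony: np.ndarray          # (n_couplings, n_runs)
    metastability: np.ndarray      # (n_couplings, n_runs)
    run_seeds: list                # spawn keys for bit-exact replay

    @property
    def synchrony_mean(self):
        return self.synchrony.mean(axis=1)

    @property
    def synchrony_sd(self):
        return self.synchrony.std(axis=1)

    @property
    def metastability_mean(self):
        return self.metastability.mean(axis=1)

    @property
    def metastability_sd(self):
        return self.metastability.std(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coupling": self.couplings,
            "synchrony_mean": self.synchrony_mean,
            "synchrony_sd": self.synchrony_sd,
            "metastability_mean": self.metastability_mean,
            "metastability_sd": self.metastability_sd,
        })

    def critical_coupling(self, threshold: float = 0.5):
        """First coupling whose mean synchrony exceeds ``threshold``.

        Returns ``(index, coupling)`` or ``(None, None)`` if the sweep never
        crosses the threshold.
        """
        above = np.nonzero(self.synchrony_mean > threshold)[0]
        if above.size == 0:
            return None, None
        i = int(above[0])
        return i, float(self.couplings[i])


def order_parameter(phases):
    """Order parameter of a phase vector: ``(r, phi)`` with r in [0, 1]."""
    phases = np.asarray(phases, dtype=float)
    z = np.exp(1j * phases).mean(axis=-1)
    return np.abs(z), np.angle(z)


def _delay_steps(net: DelayNetwork, config: KuramotoConfig) -> np.ndarray:
    tau = net.tau
    if tau.max() >= config.t_end:
        raise IntegrationError(
            f"max delay {tau.max():.4g} s is not below t_end={config.t_end} s"
        )
    scaled = tau / config.dt
    if config.delay_rounding == "nearest":
        steps = np.rint(scaled)
    else:
        steps = np.ceil(scaled)
    return steps.astype(np.intp)


def simulate(net: DelayNetwork, config: KuramotoConfig,
             run_seed=None, *, coupling: Optional[float] = None,
             init_phases=None, keep_phases: bool = True) -> KuramotoRun:
    """Integrate one run of the delayed Kuramoto model.

    Initial phases are uniform on [0, 2pi) drawn from ``run_seed`` (any
    ``numpy.random`` seed spec) unless ``init_phases`` is given explicitly;
    history for t < 0 is free rotation at the common frequency.  A rounded
    delay of 0 steps reads the current phase.
    """
    config.validate()
    k = config.coupling if coupling is None else float(coupling)
    if k < 0:
        raise ConfigError("coupling must be >= 0")
    n = net.n_rois
    omega = config.omega
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    D = _delay_steps(net, config)
    L = int(D.max()) + 1
    cmat = np.where(net.coupling, net.tau, 0.0) if config.weighted_coupling \
        else net.coupling.astype(float)
    knorm = k / n if config.normalize_coupling else k

    if init_phases is not None:
        theta0 = np.asarray(init_phases, dtype=float).copy()
        if theta0.shape != (n,):
            raise ConfigError(f"init_phases must have shape ({n},)")
    else:
        rng = np.random.default_rng(run_seed)
        theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n)

    hist = np.empty((L, n))
    for s in range(L):        # hist[(-s) % L] holds theta at step -s
        hist[(-s) % L] = theta0 - omega * s * dt
    cols = np.broadcast_to(np.arange(n)[None, :], (n, n))

    phases = np.empty((n, n_steps + 1)) if keep_phases else None
    r = np.empty(n_steps + 1)
    phi = np.empty(n_steps + 1)
    if keep_phases:
        phases[:, 0] = theta0
    r[0], phi[0] = order_parameter(theta0)

    theta = theta0
    for t in range(n_steps):
        delayed = hist[(t - D) % L, cols]
        drive = (cmat * np.sin(delayed - theta[:, None])).sum(axis=1)
        theta = theta + dt * (omega + knorm * drive)
        if not np.all(np.isfinite(theta)):
            raise IntegrationError(f"non-finite phase at step {t + 1}")
        hist[(t + 1) % L] = theta
        if keep_phases:
            phases[:, t + 1] = theta
        r[t + 1], phi[t + 1] = order_parameter(theta)

    r = np.clip(r, 0.0, 1.0)
    times = np.arange(n_steps + 1) * dt
    w0, w1 = config.window
    win = (times >= w0 - 1e-12) & (times <= w1 + 1e-12)
    return KuramotoRun(
        phases=phases, times=times, r=r, phi=phi,
        synchrony=float(r[win].mean()),
        metastability=float(r[win].std()),
        coupling=k, seed=run_seed,
    )


def sweep(net: DelayNetwork, config: KuramotoConfig,
          progress=None) -> SweepResult:
    """Run ``n_runs`` simulations per coupling value and aggregate.

    Per-run seeds derive deterministically from the master seed as
    ``SeedSequence([master, coupling_index, run_index])``, so any single run
    is bit-reproducible in isolation.
    """
    config.validate()
    master = 0 if config.seed is None else int(config.seed)
    couplings = np.asarray(config.couplings, dtype=float)
    nc, nr = couplings.size, config.n_runs
    syn = np.empty((nc, nr))
    met = np.empty((nc, nr))
    seeds = []
    for ci, k in enumerate(couplings):
        row = []
        for ri in range(nr):
            key = (master, ci, ri)
            run = simulate(net, config,
                           run_seed=np.random.SeedSequence(list(key)),
                           coupling=k, keep_phases=False)
            syn[ci, ri] = run.synchrony
            met[ci, ri] = run.metastability
            row.append(key)
        seeds.append(row)
        if progress is not None:
            progress(ci, nc)
    return SweepResult(couplings=couplings, synchrony=syn,
                       metastability=met, run_seeds=seeds)


def replay(net: DelayNetwork, config: KuramotoConfig,
           key: tuple) -> KuramotoRun:
    """Re-run a single sweep member from its ``(master, ci, ri)`` seed key."""
    master, ci, ri = key
    couplings = np.asarray(config.couplings, dtype=float)
    return simulate(net, config,
                    run_seed=np.random.SeedSequence([master, ci, ri]),
                    coupling=float(couplings[ci]), keep_phases=False)
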