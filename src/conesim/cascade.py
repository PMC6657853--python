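"""Photoactivation cascade on a disc face.

A photon isomerizes a cone opsin at a fixed point of one disc.  The active
receptor R* holds a catalytic activity that decreases exponentially with the
number of attached phosphates, nu_j = nu_RT * exp(-k_v (j-1)), and is shut
off by arrestin after a random number of phosphorylations; the state
sequence is a continuous-time Markov chain with phosphorylation rate
lambda_0 and arrestin-binding rate mu_0.  While active, R* produces
activated transducin T* at its (point) location; T* diffuses on the disc
face and converts to activated effector E* by encounter with dark PDE; E*
diffuses and decays at rate k_E.  Neither species leaves the disc
(zero-flux rim).

The default "deterministic" mode mirrors the reference simulations: R*
position fixed, lifetime equal to the CTMC mean absorption time, with stage
durations given by the unconditional expected occupancy of each
phosphorylation state (these sum exactly to the mean lifetime).  Stochastic
sampling of the shutoff sequence and Brownian R* motion are available
behind flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import DiscMesh
from .params import BiochemParams


@dataclass(frozen=True)
class PhotonEvent:
    """One isomerization: height above the base, polar position on the disc."""

    frac_height: float          # z / H in (0, 1)
    rho_frac: float = 0.0       # radial position / local disc radius
    theta: float = 0.0          # rad
    t_activation: float = 0.0   # s

    def __post_init__(self):
        if not (0.0 < self.frac_height < 1.0):
            raise ValueError("frac_height must lie in (0, 1)")
        if not (0.0 <= self.rho_frac <= 1.0):
            raise ValueError("rho_frac must lie in [0, 1]")


def catalytic_activity(j: int, nu_RT: float, k_v: float) -> float:
    """Activity of (j-1)-times phosphorylated opsin: nu_RT * exp(-k_v (j-1))."""
    if j < 1:
        raise ValueError("phosphorylation index j must be >= 1")
    return nu_RT * math.exp(-k_v * (j - 1))


def _chain_rates(lambda0: float, mu0: float, n_step: int,
                 arrestin_any_state: bool):
    """Per-state (phosphorylation, arrest) rates for states j = 0..n_step."""
    lam = [lambda0 if j < n_step else 0.0 for j in range(n_step + 1)]
    if arrestin_any_state:
        mu = [mu0] * (n_step + 1)
    else:
        mu = [0.0] * n_step + [mu0]
    return lam, mu


def state_occupancies(lambda0: float, mu0: float, n_step: int = 1,
                      arrestin_any_state: bool = True) -> np.ndarray:
    """Unconditional expected time spent in each phosphorylation state.

    Occupancy of state j is P(reach j) / (total exit rate of j); the sum over
    states is the mean absorption (shutoff) time.
    """
    if n_step < 0:
        raise ValueError("n_step must be nonnegative")
    lam, mu = _chain_rates(lambda0, mu0, n_step, arrestin_any_state)
    occ = np.empty(n_step + 1)
    reach = 1.0
    for j in range(n_step + 1):
        exit_rate = lam[j] + mu[j]
        if exit_rate <= 0:
            raise ValueError(
                "non-absorbing shutoff chain (state with zero exit rate)")
        occ[j] = reach / exit_rate
        reach *= lam[j] / exit_rate
    return occ


def mean_sojourn_time(lambda0: float, mu0: float, n_step: int = 1,
                      arrestin_any_state: bool = True) -> float:
    """Mean time to arrestin absorption of the phosphorylation chain (s)."""
    return float(state_occupancies(lambda0, mu0, n_step,
                                   arrestin_any_state).sum())


@dataclass(frozen=True)
class ShutoffSchedule:
    """Piecewise-constant catalytic activity of one R* until shutoff.

    ``breakpoints`` has one more entry than ``activities``; stage i is active
    on [breakpoints[i], breakpoints[i+1]) with T*-production rate
    ``activities[i]`` (1/s).  ``tau`` is the total lifetime.
    """

    breakpoints: np.ndarray
    activities: np.ndarray
    mode: str = "deterministic"

    @property
    def tau(self) -> float:
        return float(self.breakpoints[-1])

    def activity_at(self, t):
        """Production rate at time(s) t after activation (vectorized)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        out = np.where((t >= 0) & (idx >= 0) & (idx < len(self.activities)),
                       self.activities[np.clip(idx, 0, len(self.activities) - 1)],
                       0.0)
        return out if out.ndim else float(out)

    def produced_by(self, t: float) -> float:
        """Integral of the activity from 0 to t (total T* molecules made)."""
        edges = np.minimum(self.breakpoints, max(t, 0.0))
        return float(np.sum(self.activities * np.diff(edges)))


def deterministic_schedule(p: BiochemParams) -> ShutoffSchedule:
    """Mean-sojourn-time schedule: stage durations = expected state occupancies."""
    occ = state_occupancies(p.lambda0, p.mu0, p.n_step, p.arrestin_any_state)
    bps = np.concatenate([[0.0], np.cumsum(occ)])
    acts = np.array([catalytic_activity(j + 1, p.nu_RT, p.k_v)
                     for j in range(len(occ))])
    return ShutoffSchedule(breakpoints=bps, activities=acts)


def mean_path_schedule(p: BiochemParams) -> ShutoffSchedule:
    """Deterministic mean-path reduction of the shutoff chain.

    The receptor is quenched exactly at the chain's mean absorption time and
    acquires phosphates at their mean pace (one per 1/lambda0), the
    catalytic activity decaying by exp(-k_v) per phosphate as in the
    multi-phosphorylation shutoff models of the rod literature.  This is the
    default deterministic mode: it reproduces the reference response
    kinetics, whereas freezing the phosphorylation count at n_step holds the
    late-time activity high and retards the response (available as the
    "state_occupancy" mode).
    """
    tau = mean_sojourn_time(p.lambda0, p.mu0, p.n_step, p.arrestin_any_state)
    bps = [0.0]
    acts = []
    j = 0
    while bps[-1] < tau:
        acts.append(catalytic_activity(j + 1, p.nu_RT, p.k_v))
        bps.append(min((j + 1) / p.lambda0, tau))
        j += 1
    return ShutoffSchedule(breakpoints=np.array(bps),
                           activities=np.array(acts))


def default_schedule(p: BiochemParams) -> ShutoffSchedule:
    """Dispatch on the configured deterministic shutoff mode."""
    if p.shutoff_mode == "mean_path":
        return mean_path_schedule(p)
    if p.shutoff_mode == "state_occupancy":
        return deterministic_schedule(p)
    if p.shutoff_mode == "constant":
        return constant_activity_schedule(p)
    raise ValueError(f"unknown shutoff mode {p.shutoff_mode!r}")


def constant_activity_schedule(p: BiochemParams) -> ShutoffSchedule:
    """Single lumped activity nu_1 over the mean lifetime (config alternative)."""
    tau = mean_sojourn_time(p.lambda0, p.mu0, p.n_step, p.arrestin_any_state)
    return ShutoffSchedule(breakpoints=np.array([0.0, tau]),
                           activities=np.array([p.nu_RT]))


def sample_shutoff(p: BiochemParams, rng: np.random.Generator) -> ShutoffSchedule:
    """One stochastic realization of the phosphorylation/arrest sequence."""
    lam, mu = _chain_rates(p.lambda0, p.mu0, p.n_step, p.arrestin_any_state)
    t = 0.0
    bps = [0.0]
    acts = []
    j = 0
    while True:
        exit_rate = lam[j] + mu[j]
        if exit_rate <= 0:
            raise ValueError("non-absorbing shutoff chain")
        t += rng.exponential(1.0 / exit_rate)
        bps.append(t)
        acts.append(catalytic_activity(j + 1, p.nu_RT, p.k_v))
        if rng.random() < mu[j] / exit_rate:
            break
        j += 1
    return ShutoffSchedule(breakpoints=np.array(bps),
                           activities=np.array(acts), mode="stochastic")


# ---------------------------------------------------------------------------
# Surface reaction-diffusion of T* and E*
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    """Nodal surface densities on the activated disc per time level."""

    times: np.ndarray
    T: np.ndarray               # (n_times, m) molecules / um^2
    E: np.ndarray               # (n_times, m)
    lump: np.ndarray            # nodal areas of the scaled disc (um^2)
    source_node: int

    def total_T(self) -> np.ndarray:
        return self.T @ self.lump

    def total_E(self) -> np.ndarray:
        return self.E @ self.lump


def conversion_rate(p: BiochemParams) -> float:
    """Effective T* -> E* rate k_TE*[E] (1/s).

    Calibrated so one fully active R* yields E* at nu_RE with coupling c_TE:
    k_TE*[E] = c_TE * nu_RE, i.e. k_TE* = c_TE * nu_RE / [PDE]_sigma.
    """
    return p.c_TE * p.nu_RE


def simulate_cascade(disc: DiscMesh, radius: float, source_node: int,
                     schedule: ShutoffSchedule, p: BiochemParams,
                     times: np.ndarray,
                     rng: Optional[np.random.Generator] = None,
                     brownian_receptor: bool = False) -> CascadeResult:
    """Implicit-Euler solve of the T*/E* surface system on one disc.

    The Dirac production source is lumped onto the node containing R*
    (point-source load vector of the P1 basis); integrals of the fields are
    mesh-independent even though nodal values near the source are not.
    With ``brownian_receptor`` the source node follows a discretized
    Brownian path with diffusivity D_R (excluded from reference runs).
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("need an increasing time grid")
    m = disc.m
    lam2 = radius * radius
    # lumped mass: keeps the implicit scheme positivity-preserving near the
    # point source, where the consistent-mass scheme oscillates
    M = sp.diags(disc.lump * lam2).tocsc()
    K = disc.K.tocsc()
    kconv = conversion_rate(p)

    T = np.zeros((len(times), m))
    E = np.zeros((len(times), m))
    pos = np.asarray(disc.nodes[source_node], dtype=float) * 1.0

    dts = np.diff(times)
    unique = np.unique(np.round(dts, 15))
    lus = {}
    for dt in unique:
        lus[dt] = (splu((M + dt * (p.D_T * K + kconv * M)).tocsc()),
                   splu((M + dt * (p.D_E * K + p.k_E * M)).tocsc()))

    src = source_node
    for s, dt in enumerate(dts):
        dtr = np.round(dt, 15)
        luT, luE = lus[dtr]
        t_new = times[s + 1]
        if brownian_receptor and rng is not None:
            pos = pos + rng.normal(0.0, math.sqrt(2.0 * p.D_R * dt) / radius, 2)
            rho = np.hypot(*pos)
            if rho > 1.0:       # reflect at the rim
                pos *= (2.0 - rho) / rho
            src = int(np.argmin(np.linalg.norm(disc.nodes - pos, axis=1)))
        # production rate integrated over the step (handles stage boundaries)
        nu_bar = (schedule.produced_by(t_new) - schedule.produced_by(times[s])) / dt
        rhs = M @ T[s] + dt * nu_bar * np.eye(1, m, src).ravel()
        T[s + 1] = luT.solve(rhs)
        E[s + 1] = luE.solve(M @ E[s] + dt * kconv * (M @ T[s + 1]))
    return CascadeResult(times=times, T=T, E=E, lump=disc.lump * lam2,
                         source_node=source_node)


def totals_ode(schedule: ShutoffSchedule, p: BiochemParams,
               times: np.ndarray) -> np.ndarray:
    """Backward-Euler totals (T*_tot, E*_tot) of the lumped cascade ODEs.

    d[T*]/dt = nu(t) - k_TE*[E][T*],  d[E*]/dt = k_TE*[E][T*] - k_E*[E*].
    Identical kinetics to the spatially integrated surface system on the
    same time grid (Galerkin conservation), used directly by the reduced
    models and as the fast-diffusion oracle for the 2D solver.
    """
    times = np.asarray(times, dtype=float)
    kconv = conversion_rate(p)
    out = np.zeros((len(times), 2))
    for s in range(len(times) - 1):
        dt = times[s + 1] - times[s]
        nu_bar = (schedule.produced_by(times[s + 1])
                  - schedule.produced_by(times[s])) / dt
        Tn = (out[s, 0] + dt * nu_bar) / (1.0 + dt * kconv)
        En = (out[s, 1] + dt * kconv * Tn) / (1.0 + dt * p.k_E)
        out[s + 1] = (Tn, En)
    return out
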