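"""Reduced model tiers: longitudinally well-stirred (LWS) and globally
well-stirred (GWS).

LWS collapses the cone onto its axis: cG(z, t), Ca(z, t) obey 1D
reaction-diffusion on (0, H) with zero-flux ends,

    cG_t - D_cG cG_zz = alpha(Ca) - beta_dark cG - (point sinks at z_o),
    Ca_t - D_Ca Ca_zz = (channel/exchanger flux, lumped volumically),

where each activated disc becomes a Dirac sink of strength
k*_hyd E*_tot(t) cG(z_o) and the cascade reduces to the lumped ODE pair for
T*_tot, E*_tot.  The taper enters through the cytosol cross-section
A_c(z) = (nu/(1+nu)) pi lambda(z)^2 weighting the 1D weak form and through
the sliver perimeter density omega0 lambda(z)/cos(gamma) that converts
surface current densities to volumic rates; with these weights the model
integrates to the same dark current as the 3D tiers.  GWS additionally
removes axial diffusion, lumping the outer segment at a point.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.linalg import solve_banded

from . import params as bp
from .cascade import ShutoffSchedule, default_schedule, totals_ode
from .observables import CurrentTrace
from .scenarios import Scenario
from .volumetric import RunResult


def _lws_operators(z: np.ndarray, Ac: np.ndarray):
    """P1 mass/stiffness diagonals with cross-section weights (tridiagonal)."""
    n = len(z)
    h = np.diff(z)
    Am = 0.5 * (Ac[:-1] + Ac[1:])        # element-midpoint cross-section
    # lumped weighted mass
    lump = np.zeros(n)
    lump[:-1] += 0.5 * Am * h
    lump[1:] += 0.5 * Am * h
    # stiffness: K = sum_e (Am/h) (difference form), returned as banded diags
    w = Am / h
    main = np.zeros(n)
    main[:-1] += w
    main[1:] += w
    off = -w
    return lump, main, off


def _banded_solve(main: np.ndarray, off: np.ndarray, rhs: np.ndarray):
    n = len(main)
    ab = np.zeros((3, n))
    ab[0, 1:] = off
    ab[1] = main
    ab[2, :-1] = off
    return solve_banded((1, 1), ab, rhs)


def solve_lws(scenario: Scenario, n_nodes: int = 500,
              schedule: Optional[ShutoffSchedule] = None,
              diffusion_scale: float = 1.0) -> RunResult:
    """Implicit 1D solve of the longitudinal model.

    ``diffusion_scale`` multiplies both diffusivities (used by the
    well-stirred-limit checks); ``n_nodes=1`` is not allowed here - use
    :func:`solve_gws` for the fully lumped tier, to which this solver
    converges as diffusion grows.
    """
    g = scenario.geom
    p = scenario.params
    cfg = scenario.solver
    d = bp.derived_rates(p, g.eps0, g.nu)
    dark = bp.solve_dark_state(p, d)
    dt = cfg.dt
    n_steps = cfg.n_steps
    times = np.arange(n_steps + 1) * dt

    z = np.linspace(0.0, g.H, n_nodes)
    lam = np.asarray(g.lateral_radius(z))
    theta_c = g.nu / (1.0 + g.nu)
    Ac = theta_c * np.pi * lam ** 2
    w_sliver = g.omega0 * lam / g.cos_gamma      # sliver area per unit z
    lump, Kmain, Koff = _lws_operators(z, Ac)
    # trapezoid weights of the sliver-area density for currents/Ca flux
    sw = np.zeros(n_nodes)
    h = np.diff(z)
    sw[:-1] += 0.5 * w_sliver[:-1] * h
    sw[1:] += 0.5 * w_sliver[1:] * h

    sched = schedule or default_schedule(p)
    E_tot = totals_ode(sched, p, times)[:, 1]
    # per-photon point-sink coefficient (times E*_tot(t) * cG(z0)):
    # the "concentrated" reading applies the volumic hydrolysis rate
    # k*_hyd/eta to the disc-averaged E* surface density at the axis point,
    # which overweights the sink by ~1/(eta*pi*lambda^2) relative to the
    # integrated 3D hydrolysis -- the price of collapsing the disc to a
    # point, and the source of this tier's exaggerated response
    sinks = []                                   # (node index, coefficient)
    for ph in scenario.photons:
        node = int(np.argmin(np.abs(z - ph.frac_height * g.H)))
        if cfg.lws_sink_lumping == "concentrated":
            lam0 = float(g.lateral_radius(ph.frac_height * g.H))
            coeff = d.k_hyd_star_volumic / (np.pi * lam0 ** 2)
        elif cfg.lws_sink_lumping == "mass_consistent":
            coeff = p.k_sigma_hyd_star
        else:
            raise ValueError(
                f"unknown lws_sink_lumping {cfg.lws_sink_lumping!r}")
        sinks.append((node, coeff))

    cG = np.full(n_nodes, dark.cG_dark)
    Ca = np.full(n_nodes, dark.Ca_dark)
    jt = np.empty(n_steps + 1)
    cg_hist = np.empty((n_steps + 1, n_nodes))
    ca_hist = np.empty((n_steps + 1, n_nodes))

    def current(cg_vec, ca_vec):
        dens = bp.channel_current_density(np.maximum(cg_vec, 0.0), p,
                                          g.Sigma_cone)
        if p.current_convention == "channel_plus_exchanger":
            dens = dens + bp.exchanger_current_density(
                np.maximum(ca_vec, 0.0), p, g.Sigma_cone)
        return float(sw @ dens)

    jt[0] = current(cG, Ca)
    cg_hist[0], ca_hist[0] = cG, Ca
    Dcg = p.D_cG * diffusion_scale
    Dca = p.D_Ca * diffusion_scale

    beta_eff = d.beta_dark if cfg.enable_reactions else 0.0
    for s in range(n_steps):
        Estar = E_tot[s + 1]
        main_cg = lump + dt * (Dcg * Kmain + beta_eff * lump)
        if cfg.enable_folds:
            for node, coeff in sinks:
                main_cg[node] += dt * coeff * Estar
        off_cg = dt * Dcg * Koff
        main_ca = lump + dt * Dca * Kmain
        off_ca = dt * Dca * Koff

        cg_new, ca_new = cG.copy(), Ca.copy()
        for _ in range(cfg.picard_max):
            alpha = (bp.cyclase_rate(np.maximum(ca_new, 0.0), p)
                     if cfg.enable_reactions else 0.0)
            rhs = lump * cG + dt * lump * alpha
            cg_next = _banded_solve(main_cg, off_cg, rhs)
            rhs_ca = lump * Ca
            if cfg.enable_channels:
                flux = bp.ca_boundary_flux(np.maximum(cg_next, 0.0),
                                           np.maximum(ca_new, 0.0),
                                           p, g.Sigma_cone)
                rhs_ca = rhs_ca + dt * sw * flux
            ca_next = _banded_solve(main_ca, off_ca, rhs_ca)
            err = max(np.max(np.abs(cg_next - cg_new)),
                      np.max(np.abs(ca_next - ca_new))) / max(
                          np.max(np.abs(cg_next)), 1e-30)
            cg_new, ca_new = cg_next, ca_next
            if err < cfg.picard_tol:
                break
        cG, Ca = cg_new, ca_new
        jt[s + 1] = current(cG, Ca)
        cg_hist[s + 1], ca_hist[s + 1] = cG, Ca

    trace = CurrentTrace(times=times, j=jt, j_dark=jt[0])
    return RunResult(model="lws", times=times, trace=trace, sliver_z=z,
                     sliver_theta=np.array([0.5 * g.omega0]),
                     sliver_cg=cg_hist, sliver_ca=ca_hist, dark=dark,
                     fold_E_total=len(sinks) * E_tot)


def solve_gws(scenario: Scenario,
              schedule: Optional[ShutoffSchedule] = None) -> RunResult:
    """Globally well-stirred tier: four-variable implicit ODE integration."""
    g = scenario.geom
    p = scenario.params
    cfg = scenario.solver
    d = bp.derived_rates(p, g.eps0, g.nu)
    dark = bp.solve_dark_state(p, d)
    dt = cfg.dt
    n_steps = cfg.n_steps
    times = np.arange(n_steps + 1) * dt

    theta_c = g.nu / (1.0 + g.nu)
    V_c = theta_c * g.volume
    n_ph = len(scenario.photons)
    sched = schedule or default_schedule(p)
    E_tot = n_ph * totals_ode(sched, p, times)[:, 1]

    cG, Ca = dark.cG_dark, dark.Ca_dark
    jt = np.empty(n_steps + 1)
    cg_hist = np.empty((n_steps + 1, 1))
    ca_hist = np.empty((n_steps + 1, 1))

    def current(cg, ca):
        j = bp.channel_current(max(cg, 0.0), p)
        if p.current_convention == "channel_plus_exchanger":
            j += bp.exchanger_current(max(ca, 0.0), p)
        return j

    jt[0] = current(cG, Ca)
    cg_hist[0], ca_hist[0] = cG, Ca
    for s in range(n_steps):
        khyd = (p.k_sigma_hyd_star * E_tot[s + 1] / V_c
                if cfg.enable_folds else 0.0)
        cg_new, ca_new = cG, Ca
        for _ in range(cfg.picard_max):
            alpha = (bp.cyclase_rate(max(ca_new, 0.0), p)
                     if cfg.enable_reactions else 0.0)
            cg_next = (cG + dt * alpha) / (1.0 + dt * (d.beta_dark + khyd))
            if cfg.enable_channels:
                flux = bp.ca_boundary_flux(max(cg_next, 0.0),
                                           max(ca_new, 0.0), p, g.Sigma_cone)
                ca_next = Ca + dt * g.Sigma_cone * flux / V_c
            else:
                ca_next = Ca
            err = max(abs(cg_next - cg_new), abs(ca_next - ca_new)) / max(
                abs(cg_next), 1e-30)
            cg_new, ca_new = cg_next, ca_next
            if err < cfg.picard_tol:
                break
        cG, Ca = cg_new, ca_new
        jt[s + 1] = current(cG, Ca)
        cg_hist[s + 1], ca_hist[s + 1] = cG, Ca

    trace = CurrentTrace(times=times, j=jt, j_dark=jt[0])
    return RunResult(model="gws", times=times, trace=trace,
                     sliver_z=np.array([0.5 * g.H]),
                     sliver_theta=np.array([0.5 * g.omega0]),
                     sliver_cg=cg_hist, sliver_ca=ca_hist, dark=dark,
                     fold_E_total=E_tot)
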