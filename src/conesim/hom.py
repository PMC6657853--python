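"""The homogenized model tier (HOM).

The homogenized/concentrated-capacity limit of the layered outer segment:
three coupled diffusion processes for each second messenger -- horizontal
diffusion in the cone's cross-sections (vertical interior diffusion is
eliminated by the thin chambers), surface (Laplace-Beltrami) diffusion on
the limiting sliver, and the activated-fold cross-sections -- linked by
trace equality on the closed-margin arc.  The discretization uses one
unknown per physical location, so the trace conditions and the fold-edge
flux terms are satisfied by construction of the conforming Galerkin form;
the chamber microstructure enters only through the capacity weights
nu/(1+nu) (interior) and sigma*eps0 (sliver).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import params as bp
from .cascade import (PhotonEvent, ShutoffSchedule, default_schedule,
                      simulate_cascade)
from .geometry import ConeGeometry, build_hom_mesh
from .scenarios import Scenario
from .volumetric import (FoldSpec, LevelSpec, RunResult, SolverConfig,
                         StackIntegrator, StackModel)


def build_hom_model(scenario: Scenario,
                    schedule: Optional[ShutoffSchedule] = None,
                    rng: Optional[np.random.Generator] = None) -> StackModel:
    """Assemble the homogenized stack model for a scenario."""
    g = scenario.geom
    p = scenario.params
    cfg = scenario.solver
    d = bp.derived_rates(p, g.eps0, g.nu)
    dark = bp.solve_dark_state(p, d)

    mesh = build_hom_mesh(
        g, nr=cfg.nr, na=cfg.na, n_z=cfg.n_z,
        activation_levels=[ph.frac_height * g.H for ph in scenario.photons])

    theta_c = g.nu / (1.0 + g.nu)
    levels = [LevelSpec(z=z, lam=lam, cap=theta_c * w, stiff=theta_c * w,
                        face=theta_c * w)
              for z, lam, w in zip(mesh.z_centers, mesh.lambdas,
                                   mesh.z_weights)]

    model = StackModel(
        name="hom", geom=g, disc=mesh.disc, sliver=mesh.sliver,
        levels=levels, levels_per_block=1, vertical_pairs=[],
        sliver_cap=g.sigma * g.eps0, sdof=mesh.sliver_global_dofs(),
        params=p, derived=d, dark=dark)

    times = np.arange(cfg.n_steps + 1) * cfg.dt
    sched = schedule or default_schedule(p)
    for ph in scenario.photons:
        k = mesh.snap_z(ph.frac_height * g.H)
        src = mesh.disc.node_at(ph.rho_frac, ph.theta)
        casc = simulate_cascade(mesh.disc, float(mesh.lambdas[k]), src,
                                sched, p, times, rng=rng)
        model.folds.append(FoldSpec(block=k, level_in_block=0, cascade=casc))
    return model


def run_hom(scenario: Scenario,
            schedule: Optional[ShutoffSchedule] = None,
            rng: Optional[np.random.Generator] = None) -> RunResult:
    """Full homogenized simulation: cascade, volumic solve, current trace."""
    model = build_hom_model(scenario, schedule=schedule, rng=rng)
    return StackIntegrator(model, scenario.solver).run()
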