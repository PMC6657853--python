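"""Scenario definitions: geometry + parameters + photon events + solver config.

Canonical fixtures follow the reference trials: the single-photon response
(SPR) places one isomerization at the center of the disc four-tenths of the
height above the larger base; the ten-photon response (TPR) places ten
isomerizations at the centers of ten equispaced discs spanning 40% to 58%
of the height.  A "rod biochemistry on cone geometry" variant swaps in
mouse-rod kinetic values while keeping the tapered geometry.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .cascade import PhotonEvent
from .geometry import ConeGeometry
from .params import BiochemParams
from .volumetric import SolverConfig


@dataclass
class Scenario:
    name: str
    geom: ConeGeometry = field(default_factory=ConeGeometry)
    params: BiochemParams = field(default_factory=BiochemParams)
    photons: list = field(default_factory=list)
    solver: SolverConfig = field(default_factory=SolverConfig)

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "geometry": dataclasses.asdict(self.geom),
            "params": self.params.to_dict(),
            "photons": [dataclasses.asdict(ph) for ph in self.photons],
            "solver": dataclasses.asdict(self.solver),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            name=doc.get("name", "scenario"),
            geom=ConeGeometry(**doc.get("geometry", {})),
            params=BiochemParams.from_dict(doc.get("params", {})),
            photons=[PhotonEvent(**ph) for ph in doc.get("photons", [])],
            solver=SolverConfig(**doc.get("solver", {})),
        )

    def replace(self, **kw) -> "Scenario":
        return dataclasses.replace(self, **kw)


def default_params() -> BiochemParams:
    """The packaged default (cone) parameter table."""
    ref = importlib.resources.files("conesim.data") / "default_params.yaml"
    with importlib.resources.as_file(ref) as path:
        return BiochemParams.from_yaml(path)


def spr_scenario(frac_height: float = 0.40, rho_frac: float = 0.0,
                 theta: float = 0.0, **solver_kw) -> Scenario:
    """Single-photon response at the center of one disc (default 40% height)."""
    return Scenario(
        name="spr",
        photons=[PhotonEvent(frac_height=frac_height, rho_frac=rho_frac,
                             theta=theta)],
        solver=SolverConfig(**solver_kw))


def spr_near_tip_scenario(geom: Optional[ConeGeometry] = None,
                          **solver_kw) -> Scenario:
    """SPR with the photon 1 um below the tip, an eighth of the local radius
    inward from the sliver channels' center (the rim point at the mid-angle)."""
    g = geom or ConeGeometry()
    z = g.H - 1.0
    return Scenario(
        name="spr_tip",
        geom=g,
        photons=[PhotonEvent(frac_height=z / g.H, rho_frac=7.0 / 8.0,
                             theta=0.5 * g.omega0)],
        solver=SolverConfig(**solver_kw))


def tpr_scenario(frac_lo: float = 0.40, frac_hi: float = 0.58,
                 n_photons: int = 10, **solver_kw) -> Scenario:
    """Ten-photon response: equispaced disc centers spanning 40-58% of H."""
    fracs = np.linspace(frac_lo, frac_hi, n_photons)
    return Scenario(
        name="tpr",
        photons=[PhotonEvent(frac_height=float(f)) for f in fracs],
        solver=SolverConfig(**solver_kw))


def rod_on_cone_params() -> BiochemParams:
    """Mouse-rod-style kinetics expressed on the cone geometry.

    A synthetic stand-in assembled from the mouse-rod-labelled rows of the
    adopted parameter table (diffusivities, channel affinity, cyclase Hill
    exponent, PDE surface density, phosphorylation decay) with slower
    rod-like cascade shutoff; it is a fixture for morphology-vs-biochemistry
    experiments, not a measured rod parameter set.
    """
    return default_params().replace(
        nu_RT=30.0, nu_RE=30.0, k_E=5.0, mu0=3.5, lambda0=30.0,
        f_Ca=0.12, J_ex_sat=1.1)


def write_fixtures(outdir) -> list:
    """Write the canonical scenario YAMLs (SPR, TPR, rod-on-cone, 20-chamber
    test geometry) into ``outdir``; returns the paths written."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = []
    p = default_params()
    for scen in (spr_scenario(), spr_near_tip_scenario(), tpr_scenario()):
        scen = scen.replace(params=p)
        path = os.path.join(outdir, f"{scen.name}.yaml")
        scen.to_yaml(path)
        paths.append(path)
    rod = tpr_scenario().replace(name="tpr_rod_on_cone",
                                 params=rod_on_cone_params())
    path = os.path.join(outdir, "tpr_rod_on_cone.yaml")
    rod.to_yaml(path)
    paths.append(path)
    test_geo = Scenario(name="test20",
                        geom=ConeGeometry().with_chambers(20),
                        params=p,
                        photons=[PhotonEvent(frac_height=0.5)],
                        solver=SolverConfig(n_z=20, nr=6, na=12))
    path = os.path.join(outdir, "test20.yaml")
    test_geo.to_yaml(path)
    paths.append(path)
    return paths
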