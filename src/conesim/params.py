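"""Biochemical parameters, pointwise flux laws, and the dark steady state.

All quantities live in a fixed internal unit system: lengths in micrometres,
time in seconds, concentrations in micromolar, currents in picoamperes.
Surface densities (PDE, transducin, effector) are molecules per square
micrometre, so a surface hydrolysis rate in um^3/s multiplied by a surface
density (1/um^2) and a concentration (uM) is directly a boundary flux in
uM*um/s -- no Avogadro factor is needed there.  Avogadro's number and
Faraday's constant enter only when converting electrical current densities
(pA/um^2) into calcium molar fluxes.

The dark steady state is not a free parameter: it is the simultaneous root of

    alpha(Ca_dark) = beta_dark * cG_dark          (zero net cGMP production)
    (1/2) f_Ca * J_cG(cG_dark) = J_ex(Ca_dark)    (zero net calcium flux)

and the total circulating dark current j_dark follows from the current
convention (CNG channel current alone by default, optionally channel plus
exchanger).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

#: pA/um^2 divided by (C/mol) converted to uM*um/s:
#: 1 pA = 1e-12 C/s and 1 uM*um = 1e-21 mol/um^2, hence the factor 1e9.
CURRENT_DENSITY_TO_MOLAR_FLUX = 1.0e9


class DarkStateError(RuntimeError):
    """Raised when the dark balance equations admit no physical root."""


@dataclass
class BiochemParams:
    """Biochemical rate constants and channel/exchanger laws.

    Defaults reproduce the adopted cone parameter set (striped-bass geometry
    with mouse-rod kinetics where no cone measurement exists).  ``alpha_min``
    is stored through the high/low suppression ratio of guanylyl cyclase,
    which is what is actually measured.
    """

    alpha_max: float = 1311.0          # uM/s, cyclase rate at low Ca2+
    alpha_suppression_ratio: float = 13.9  # alpha_max / alpha_min
    k_sigma_hyd: float = 5.02e-4       # um^3/s, dark PDE surface hydrolysis
    k_sigma_hyd_star: float = 0.83     # um^3/s, light-activated PDE
    pde_sigma: float = 1000.0          # 1/um^2, dark PDE surface density
    K_cyc: float = 0.1                 # uM, half-max Ca2+ for cyclase
    m_cyc: float = 2.5                 # Hill exponent, cyclase
    K_cG: float = 20.0                 # uM, half-max cGMP for CNG channel
    m_cG: float = 2.0                  # Hill exponent, CNG channel
    K_ex: float = 0.69                 # uM, half-max Ca2+ for exchanger
    J_cG_max: float = 2500.0           # pA, saturated whole-cell CNG current
    J_ex_sat: float = 4.87             # pA, saturated exchanger current
    f_Ca: float = 0.33                 # fraction of CNG current carried by Ca2+
    B_Ca: float = 20.0                 # cytoplasmic Ca2+ buffering power
    B_cG: float = 1.0                  # cytoplasmic cGMP buffering power
    faraday: float = 96500.0           # C/mol
    avogadro: float = 6.02e23          # 1/mol
    D_cG: float = 120.0                # um^2/s
    D_Ca: float = 15.0                 # um^2/s
    D_T: float = 2.2                   # um^2/s, activated transducin (disc)
    D_E: float = 1.2                   # um^2/s, activated PDE (disc)
    D_R: float = 1.5                   # um^2/s, activated opsin (disc)
    nu_RT: float = 125.0               # 1/s, T* production by unphosphorylated R*
    nu_RE: float = 125.0               # 1/s, E* production per fully active R*
    c_TE: float = 1.0                  # G* -> E* coupling coefficient
    k_E: float = 18.5                  # 1/s, E* shutoff
    k_v: float = 0.5                   # catalytic decay per phosphorylation
    lambda0: float = 105.0             # 1/s, CTMC phosphorylation rate
    mu0: float = 12.5                  # 1/s, CTMC arrestin-binding rate
    n_step: int = 1                    # phosphorylation states in the CTMC
    arrestin_any_state: bool = True    # arrestin may bind regardless of phosphates
    shutoff_mode: str = "mean_path"    # deterministic reduction of the chain
    current_convention: str = "channel_only"  # or "channel_plus_exchanger"

    def __post_init__(self) -> None:
        positive = [
            "alpha_max", "alpha_suppression_ratio", "k_sigma_hyd",
            "k_sigma_hyd_star", "pde_sigma", "K_cyc", "K_cG", "K_ex",
            "J_cG_max", "J_ex_sat", "B_Ca", "B_cG", "faraday", "avogadro",
            "D_cG", "D_Ca", "D_T", "D_E", "D_R", "nu_RT", "nu_RE", "k_E",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.f_Ca < 1.0):
            raise ValueError("f_Ca must lie in (0, 1)")
        if self.m_cyc < 1.0 or self.m_cG < 1.0:
            raise ValueError("Hill exponents must be >= 1")
        if self.alpha_suppression_ratio <= 1.0:
            raise ValueError("alpha_min must be below alpha_max")
        if self.current_convention not in ("channel_only", "channel_plus_exchanger"):
            raise ValueError(f"unknown current convention {self.current_convention!r}")
        if self.shutoff_mode not in ("mean_path", "state_occupancy", "constant"):
            raise ValueError(f"unknown shutoff mode {self.shutoff_mode!r}")

    @property
    def alpha_min(self) -> float:
        return self.alpha_max / self.alpha_suppression_ratio

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BiochemParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BiochemParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "BiochemParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DerivedRates:
    """Rates derived from the primary parameter table.

    ``eta`` is the interdiscal half-thickness nu*eps0/2, which converts
    volumic rates to disc-face surface fluxes; ``beta_dark`` is the volumic
    dark hydrolysis rate k_sigma_hyd*[PDE]/eta; ``k_hyd_star_volumic`` is the
    corresponding volumic light-activated rate k*_sigma_hyd/eta used by the
    1D longitudinal reduction.
    """

    eta: float                  # um
    beta_dark: float            # 1/s
    k_hyd_star_volumic: float   # um^2/s


def compute_eta(nu: float, eps0: float) -> float:
    """Volume-to-surface ratio of an interdiscal layer: nu*eps0/2.

    Unit preserving: eps0 in nm gives eta in nm, eps0 in um gives um.
    """
    if nu <= 0 or eps0 <= 0:
        raise ValueError("nu and eps0 must be strictly positive")
    return 0.5 * nu * eps0


def compute_beta_dark(k_sigma_hyd: float, pde_sigma: float, eta: float) -> float:
    """Volumic dark hydrolysis rate, k_sigma_hyd * [PDE] / eta (1/s)."""
    if k_sigma_hyd < 0 or pde_sigma < 0:
        raise ValueError("rates and densities must be nonnegative")
    if eta <= 0:
        raise ValueError("eta must be strictly positive")
    return k_sigma_hyd * pde_sigma / eta


def derived_rates(p: BiochemParams, eps0_um: float, nu: float) -> DerivedRates:
    eta = compute_eta(nu, eps0_um)
    beta = compute_beta_dark(p.k_sigma_hyd, p.pde_sigma, eta)
    return DerivedRates(eta=eta, beta_dark=beta,
                        k_hyd_star_volumic=p.k_sigma_hyd_star / eta)


# ---- pointwise laws ------------------------------------------------------

def cyclase_rate(Ca, p: BiochemParams):
    """Guanylyl-cyclase synthesis rate alpha(Ca) in uM/s (Hill, decreasing)."""
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca < 0):
        raise ValueError("negative calcium concentration")
    a = p.alpha_min + (p.alpha_max - p.alpha_min) / (1.0 + (Ca / p.K_cyc) ** p.m_cyc)
    return a if a.ndim else float(a)


def channel_current(cG, p: BiochemParams):
    """Whole-cell CNG channel current (pA), saturating Hill law in cGMP."""
    cG = np.asarray(cG, dtype=float)
    if np.any(cG < 0):
        raise ValueError("negative cGMP concentration")
    x = cG ** p.m_cG
    j = p.J_cG_max * x / (p.K_cG ** p.m_cG + x)
    return j if j.ndim else float(j)


def exchanger_current(Ca, p: BiochemParams):
    """Whole-cell Na+/Ca2+-K+ exchanger current (pA), Michaelis-Menten."""
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca < 0):
        raise ValueError("negative calcium concentration")
    j = p.J_ex_sat * Ca / (p.K_ex + Ca)
    return j if j.ndim else float(j)


def channel_current_density(cG, p: BiochemParams, sigma_cone: float):
    """CNG current per unit sliver area (pA/um^2), channels uniform on the sliver."""
    return channel_current(cG, p) / sigma_cone


def exchanger_current_density(Ca, p: BiochemParams, sigma_cone: float):
    return exchanger_current(Ca, p) / sigma_cone


def total_current(cG, Ca, p: BiochemParams):
    """Measured circulating current under the configured convention (pA)."""
    j = channel_current(cG, p)
    if p.current_convention == "channel_plus_exchanger":
        j = j + exchanger_current(Ca, p)
    return j


def cg_boundary_flux(cG, Ca, Estar, on_activated_face: bool,
                     p: BiochemParams, d: DerivedRates):
    """Outward-normal cGMP flux on a disc face (uM*um/s).

    eta*alpha(Ca) - eta*beta_dark*cG on every disc face, with the additional
    light-activated hydrolysis -k*_sigma_hyd*[E*]*cG on the activated face.
    All other surfaces carry zero cGMP flux.
    """
    cG = np.asarray(cG, dtype=float)
    if np.any(cG < 0):
        raise ValueError("negative cGMP concentration")
    flux = d.eta * cyclase_rate(Ca, p) - d.eta * d.beta_dark * cG
    if on_activated_face:
        flux = flux - p.k_sigma_hyd_star * np.asarray(Estar, dtype=float) * cG
    return flux if np.ndim(flux) else float(flux)


def ca_boundary_flux(cG, Ca, p: BiochemParams, sigma_cone: float):
    """Outward-normal Ca2+ flux on the sliver exterior (uM*um/s).

    (1/(B_Ca*F)) * (0.5*f_Ca*J_cG(cG) - J_ex(Ca)) with current densities in
    pA/um^2; the 1/2 accounts for calcium's two charges through the channel
    while the exchanger moves one net charge per extruded ion.
    """
    jcg = np.asarray(channel_current_density(cG, p, sigma_cone))
    jex = np.asarray(exchanger_current_density(Ca, p, sigma_cone))
    flux = (CURRENT_DENSITY_TO_MOLAR_FLUX / (p.B_Ca * p.faraday)) * (
        0.5 * p.f_Ca * jcg - jex)
    return flux if flux.ndim else float(flux)


# ---- dark steady state ---------------------------------------------------

@dataclass(frozen=True)
class DarkState:
    cG_dark: float       # uM
    Ca_dark: float       # uM
    j_dark: float        # pA, under the configured current convention
    j_dark_channel_only: float
    j_dark_channel_plus_exchanger: float
    residual_cg: float   # relative residual of the cGMP balance
    residual_ca: float   # relative residual of the Ca2+ balance

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def solve_dark_state(p: BiochemParams, d: DerivedRates,
                     newton_tol: float = 1e-13, max_iter: int = 60) -> DarkState:
    """Solve the two dark mass-balance equations.

    Damped Newton iteration on (cG, Ca) starting from the literature dark
    values; falls back to a monotone bracketing solve on the reduced
    one-variable system g(Ca) = f_Ca*J_cG(alpha(Ca)/beta)/2 - J_ex(Ca),
    which is strictly decreasing, if Newton stalls.
    """
    beta = d.beta_dark

    def residuals(cG, Ca):
        r1 = cyclase_rate(Ca, p) - beta * cG
        r2 = 0.5 * p.f_Ca * channel_current(cG, p) - exchanger_current(Ca, p)
        return r1, r2

    def jac(cG, Ca):
        h = 1e-7
        r1, r2 = residuals(cG, Ca)
        r1c, r2c = residuals(cG + h, Ca)
        r1a, r2a = residuals(cG, Ca + h)
        return np.array([[(r1c - r1) / h, (r1a - r1) / h],
                         [(r2c - r2) / h, (r2a - r2) / h]]), np.array([r1, r2])

    x = np.array([2.0, 0.4])
    ok = False
    for _ in range(max_iter):
        J, r = jac(*x)
        scale = np.array([p.alpha_max, p.J_ex_sat])
        if np.all(np.abs(r) / scale < newton_tol):
            ok = True
            break
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        while lam > 1e-6:
            xn = x + lam * step
            if np.all(xn > 0):
                rn = np.array(residuals(*xn))
                if np.linalg.norm(rn / scale) <= np.linalg.norm(r / scale):
                    break
            lam *= 0.5
        x = x + lam * step
        if not np.all(np.isfinite(x)):
            break

    if not ok:
        from scipy.optimize import brentq

        def g(Ca):
            cG = cyclase_rate(Ca, p) / beta
            return 0.5 * p.f_Ca * channel_current(cG, p) - exchanger_current(Ca, p)

        lo, hi = 1e-9, 1e4
        if g(lo) < 0 or g(hi) > 0:
            raise DarkStateError(
                "no dark steady state in physical range: "
                f"g({lo})={g(lo):.3e}, g({hi})={g(hi):.3e}")
        Ca = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
        x = np.array([cyclase_rate(Ca, p) / beta, Ca])

    cG, Ca = float(x[0]), float(x[1])
    r1, r2 = residuals(cG, Ca)
    j_ch = channel_current(cG, p)
    j_both = j_ch + exchanger_current(Ca, p)
    j = j_ch if p.current_convention == "channel_only" else j_both
    return DarkState(
        cG_dark=cG, Ca_dark=Ca, j_dark=j,
        j_dark_channel_only=j_ch, j_dark_channel_plus_exchanger=j_both,
        residual_cg=abs(r1) / p.alpha_max, residual_ca=abs(r2) / p.J_ex_sat)
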