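"""Tapered cone-outer-segment geometry and structured finite-element meshes.

The outer segment is a right circular truncated cone of tip radius r, base
radius R and height H, carrying n equally spaced membrane discs.  Cytosol
occupies the thin interdiscal chambers (thickness nu*eps0 each) and the
closing sliver, a lateral strip of angular extent omega0 and radial
thickness sigma*eps0 that is the only connection between chambers.

Axial convention: z = 0 at the larger base (radius r_base) and z = H at the
tip, so photon positions quoted as a fraction of height above the base read
off directly; the radius profile lambda(z) is the decreasing affine map.  A
``z_origin="tip"`` flag flips the convention (the physics is invariant).

Two mesh families are produced from one reference triangulation of the unit
disc (polar-structured, mirror-symmetric about the sliver mid-angle):

* :class:`HomMesh` - the homogenized domain: N_z horizontal cross-sections
  (each a scaled copy of the reference disc) plus a 2D surface mesh of the
  limiting sliver whose nodes coincide with cross-section boundary nodes on
  the closed-margin arc (trace equality enforced by shared unknowns).
* :class:`LayeredMesh` - the explicit layered (nonhomogenized) domain:
  n interdiscal chambers, each with two node levels (bottom/top face), and a
  volumic sliver shell meshed as a surface with per-node thickness weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .fem import lumped_mass, p1_matrices

TWO_PI = 2.0 * math.pi


class MeshResolutionError(ValueError):
    """Requested feature cannot be resolved at the given mesh resolution."""


@dataclass(frozen=True)
class ConeGeometry:
    """Truncated-cone outer segment with disc stack and closing sliver."""

    r_tip: float = 1.15        # um
    r_base: float = 3.08       # um
    H: float = 15.0            # um
    omega0: float = math.pi    # rad, angular extent of the closed margin
    n_discs: int = 500
    eps0: float = 0.015        # um, disc thickness
    nu: float = 1.0            # interdiscal-space / disc thickness ratio
    sigma: float = 1.0         # sliver / disc thickness ratio
    z_origin: str = "base"     # "base": z=0 at r_base; "tip": z=0 at r_tip

    def __post_init__(self) -> None:
        if not (0.0 < self.r_tip < self.r_base):
            raise ValueError("require 0 < r_tip < r_base")
        if self.H <= 0:
            raise ValueError("height must be positive")
        if not (0.0 < self.omega0 <= TWO_PI):
            raise ValueError("omega0 must lie in (0, 2*pi]")
        if self.nu <= 0 or self.sigma <= 0 or self.eps0 <= 0:
            raise ValueError("nu, sigma, eps0 must be positive")
        if self.z_origin not in ("base", "tip"):
            raise ValueError("z_origin must be 'base' or 'tip'")

    # -- analytic descriptors ---------------------------------------------
    @property
    def slant_height(self) -> float:
        return math.hypot(self.H, self.r_base - self.r_tip)

    @property
    def cos_gamma(self) -> float:
        """cos of the cone aperture angle gamma."""
        return self.H / self.slant_height

    @property
    def gamma(self) -> float:
        return math.acos(self.cos_gamma)

    @property
    def volume(self) -> float:
        r, R = self.r_tip, self.r_base
        return math.pi / 3.0 * self.H * (R * R + R * r + r * r)

    def lateral_radius(self, z):
        """Affine radius profile lambda(z) under the axial convention."""
        z = np.asarray(z, dtype=float)
        if np.any(z < -1e-12) or np.any(z > self.H + 1e-12):
            raise ValueError("z outside [0, H]")
        if self.z_origin == "base":
            lam = self.r_base + (self.r_tip - self.r_base) * z / self.H
        else:
            lam = self.r_tip + (self.r_base - self.r_tip) * z / self.H
        return lam if lam.ndim else float(lam)

    def sliver_area(self) -> float:
        """Area of the closed-margin strip: (omega0/2)*(r+R)*slant_height."""
        return 0.5 * self.omega0 * (self.r_tip + self.r_base) * self.slant_height

    @property
    def Sigma_cone(self) -> float:
        return self.sliver_area()

    def with_chambers(self, n: int) -> "ConeGeometry":
        """Reduced-chamber geometry: eps scaled so n chambers fill H.

        This keeps the cytosol fraction nu/(1+nu) fixed - the homogenization
        family read backwards - and is how desk-scale layered meshes are run.
        """
        if n < 2:
            raise ValueError("need at least two chambers")
        eps_n = self.H / (n * (1.0 + self.nu))
        if eps_n < 1e-9:
            raise ValueError("chamber thickness below resolvable tolerance")
        return replace(self, n_discs=n, eps0=eps_n)


def cytosol_volume_fraction(g: ConeGeometry, mesh: Optional["LayeredMesh"] = None):
    """Fraction of cone volume available to second-messenger diffusion.

    Analytically nu/(1+nu), independent of eps0 to O(eps0^2).  When a layered
    mesh is supplied the measured ratio (exact frustum volumes of its chamber
    slabs over the cone volume) is returned instead.
    """
    if mesh is None:
        return g.nu / (1.0 + g.nu)
    return mesh.chamber_volume_total() / g.volume


def _frustum_volume(g: ConeGeometry, z0: float, z1: float) -> float:
    l0 = g.lateral_radius(z0)
    l1 = g.lateral_radius(z1)
    return math.pi / 3.0 * (z1 - z0) * (l0 * l0 + l0 * l1 + l1 * l1)


# ---------------------------------------------------------------------------
# Reference cross-section triangulation
# ---------------------------------------------------------------------------

@dataclass
class DiscMesh:
    """Polar-structured P1 triangulation of the unit disc.

    Mirror-symmetric about the sliver mid-angle omega0/2 so that centered
    photon placements produce theta-symmetric fields to machine precision.
    Scaled copies (radius lambda) have stiffness K unchanged (2D scale
    invariance) and mass lambda^2 * M.
    """

    nr: int
    na: int
    omega0: float
    nodes: np.ndarray = field(repr=False)      # (m, 2) unit-disc coordinates
    tris: np.ndarray = field(repr=False)       # (nt, 3)
    theta: np.ndarray = field(repr=False)      # (na,) node angles
    boundary: np.ndarray = field(repr=False)   # (na,) rim node ids by angle index
    sliver_arc: np.ndarray = field(repr=False) # rim node ids with theta in [0, omega0]
    sliver_angle_idx: np.ndarray = field(repr=False)
    mirror: np.ndarray = field(repr=False)     # node id -> mirrored node id
    M: object = field(repr=False, default=None)
    K: object = field(repr=False, default=None)
    lump: np.ndarray = field(repr=False, default=None)

    @property
    def m(self) -> int:
        return len(self.nodes)

    def node_at(self, rho_frac: float, theta: float) -> int:
        """Nearest mesh node to polar position (rho_frac in [0,1], theta)."""
        target = np.array([rho_frac * math.cos(theta), rho_frac * math.sin(theta)])
        return int(np.argmin(np.linalg.norm(self.nodes - target, axis=1)))


def build_disc_mesh(nr: int, na: int, omega0: float = math.pi) -> DiscMesh:
    if nr < 2 or na < 8:
        raise MeshResolutionError("need nr >= 2 and na >= 8")
    n_arc = na * omega0 / TWO_PI
    if abs(n_arc - round(n_arc)) > 1e-9:
        raise MeshResolutionError(
            "na must place nodes exactly at both sliver edges "
            f"(na*omega0/2pi = {n_arc} not integral)")
    n_arc = int(round(n_arc))
    theta = TWO_PI * np.arange(na) / na
    nodes = [np.zeros(2)]
    for j in range(1, nr + 1):
        rho = j / nr
        nodes.append(np.c_[rho * np.cos(theta), rho * np.sin(theta)])
    nodes = np.vstack([nodes[0][None, :], *nodes[1:]])

    def nid(j, i):  # ring j >= 1, angle index i (mod na)
        return 1 + (j - 1) * na + (i % na)

    tris = []
    mid = 0.5 * omega0
    for i in range(na):
        tris.append((0, nid(1, i), nid(1, i + 1)))
    for j in range(1, nr):
        for i in range(na):
            a, b = nid(j, i), nid(j, i + 1)
            c, d = nid(j + 1, i), nid(j + 1, i + 1)
            # mirror-symmetric diagonal choice about the sliver mid-angle
            tc = theta[i] + math.pi / na
            if math.sin(tc - mid) >= 0.0:
                tris.append((a, b, d)); tris.append((a, d, c))
            else:
                tris.append((a, b, c)); tris.append((b, d, c))
    tris = np.array(tris, dtype=np.int64)

    boundary = np.array([nid(nr, i) for i in range(na)])
    arc_idx = np.arange(n_arc + 1)
    sliver_arc = boundary[arc_idx % na]

    i_s = n_arc  # theta -> omega0 - theta maps angle index i -> (i_s - i) mod na
    mirror = np.empty(len(nodes), dtype=np.int64)
    mirror[0] = 0
    for j in range(1, nr + 1):
        for i in range(na):
            mirror[nid(j, i)] = nid(j, (i_s - i) % na)

    M, K, _ = p1_matrices(nodes, tris)
    return DiscMesh(nr=nr, na=na, omega0=omega0, nodes=nodes, tris=tris,
                    theta=theta, boundary=boundary, sliver_arc=sliver_arc,
                    sliver_angle_idx=arc_idx, mirror=mirror,
                    M=M, K=K, lump=lumped_mass(M))


# ---------------------------------------------------------------------------
# Sliver surface mesh
# ---------------------------------------------------------------------------

@dataclass
class SliverMesh:
    """Surface triangulation of the closed margin strip.

    Nodes are indexed by (angle index on the arc, level index) and located at
    (lambda(z) cos theta, lambda(z) sin theta, z); the Laplace-Beltrami
    operator is the P1 stiffness matrix of the embedded triangulation.
    """

    theta: np.ndarray          # (ns,) angles in [0, omega0]
    z_levels: np.ndarray       # (L,)
    nodes: np.ndarray = field(repr=False)   # (ns*L, 3)
    tris: np.ndarray = field(repr=False)
    M: object = field(repr=False, default=None)
    K: object = field(repr=False, default=None)
    lump: np.ndarray = field(repr=False, default=None)

    @property
    def ns(self) -> int:
        return len(self.theta)

    def node_index(self, i_theta, level):
        return np.asarray(level) * self.ns + np.asarray(i_theta)

    def area(self) -> float:
        return float(self.lump.sum())


def build_sliver_mesh(g: ConeGeometry, theta: np.ndarray,
                      z_levels: np.ndarray) -> SliverMesh:
    theta = np.asarray(theta, dtype=float)
    z_levels = np.asarray(z_levels, dtype=float)
    ns, L = len(theta), len(z_levels)
    lam = np.asarray(g.lateral_radius(z_levels))
    tt, zz = np.meshgrid(theta, z_levels)          # (L, ns)
    ll = np.repeat(lam[:, None], ns, axis=1)
    nodes = np.c_[(ll * np.cos(tt)).ravel(), (ll * np.sin(tt)).ravel(),
                  zz.ravel()]

    mid = 0.5 * g.omega0
    tris = []
    for l in range(L - 1):
        for i in range(ns - 1):
            a = l * ns + i
            b = a + 1
            c = a + ns
            d = c + 1
            tc = 0.5 * (theta[i] + theta[i + 1])
            if math.sin(tc - mid) >= 0.0:
                tris.append((a, b, d)); tris.append((a, d, c))
            else:
                tris.append((a, b, c)); tris.append((b, d, c))
    tris = np.array(tris, dtype=np.int64)
    M, K, _ = p1_matrices(nodes, tris)
    return SliverMesh(theta=theta, z_levels=z_levels, nodes=nodes, tris=tris,
                      M=M, K=K, lump=lumped_mass(M))


# ---------------------------------------------------------------------------
# Homogenized mesh
# ---------------------------------------------------------------------------

@dataclass
class HomMesh:
    """Discretization of the homogenized domain: slice stack + limiting sliver.

    Global unknown layout: slice k occupies dofs [k*m, (k+1)*m); the sliver
    has no separate unknowns - its (i_theta, k) node IS the slice-k rim node
    on the closed-margin arc, which enforces trace equality exactly.
    """

    geom: ConeGeometry
    disc: DiscMesh
    z_centers: np.ndarray           # vertex-centered slice levels, 0..H
    dz: float
    z_weights: np.ndarray           # per-slice thickness (dz, halved at ends)
    lambdas: np.ndarray
    sliver: SliverMesh
    activation_slices: np.ndarray   # slice indices hosting activated folds

    @property
    def n_slices(self) -> int:
        return len(self.z_centers)

    @property
    def n_dofs(self) -> int:
        return self.n_slices * self.disc.m

    def sliver_global_dofs(self) -> np.ndarray:
        """Global dof of sliver node (i, k), flattened in sliver node order."""
        m = self.disc.m
        out = np.empty(self.n_slices * self.sliver.ns, dtype=np.int64)
        for k in range(self.n_slices):
            out[k * self.sliver.ns:(k + 1) * self.sliver.ns] = (
                k * m + self.disc.sliver_arc)
        return out

    def snap_z(self, z: float) -> int:
        return int(np.argmin(np.abs(self.z_centers - z)))


def build_hom_mesh(g: ConeGeometry, nr: int = 10, na: int = 20,
                   n_z: int = 500,
                   activation_levels: Sequence[float] = ()) -> HomMesh:
    """Mesh the homogenized cone with n_z horizontal cross-sections.

    ``activation_levels`` are z positions in (0, H); each is snapped to the
    nearest cross-section, which then hosts the activated-fold reaction.
    """
    disc = build_disc_mesh(nr, na, g.omega0)
    if n_z < 2:
        raise MeshResolutionError("need n_z >= 2")
    dz = g.H / (n_z - 1)
    z_centers = np.linspace(0.0, g.H, n_z)
    z_weights = np.full(n_z, dz)
    z_weights[0] = z_weights[-1] = 0.5 * dz
    lambdas = np.asarray(g.lateral_radius(z_centers))
    theta = disc.theta[disc.sliver_angle_idx % disc.na].copy()
    theta[-1] = g.omega0  # exact arc endpoint (wraps to angle 0 when full circle)
    sliver = build_sliver_mesh(g, theta, z_centers)

    act = []
    for z in activation_levels:
        if not (0.0 < z < g.H):
            raise MeshResolutionError(f"activation level z={z} outside (0, H)")
        act.append(int(np.argmin(np.abs(z_centers - z))))
    return HomMesh(geom=g, disc=disc, z_centers=z_centers, dz=dz,
                   z_weights=z_weights, lambdas=lambdas, sliver=sliver,
                   activation_slices=np.array(sorted(set(act)), dtype=np.int64))


# ---------------------------------------------------------------------------
# Layered (nonhomogenized) mesh
# ---------------------------------------------------------------------------

@dataclass
class LayeredMesh:
    """Explicit layered domain: n chambers (two node levels each) + sliver shell.

    Chamber c spans [z_bot_c, z_top_c] with thickness nu*eps; the discs
    between chambers have thickness eps and carry no unknowns (they are the
    excised lipid volume).  The volumic sliver shell of radial thickness
    sigma*eps is radially lumped onto the lateral surface and meshed as a
    SliverMesh over all 2n levels; chamber rim nodes on the closed-margin
    arc are identified with sliver nodes, so chambers communicate only
    through the sliver.
    """

    geom: ConeGeometry          # geometry with eps scaled for this n
    disc: DiscMesh
    n_chambers: int
    eps: float
    levels_z: np.ndarray        # (2n,) chamber face z
    lambdas: np.ndarray         # (2n,)
    sliver: SliverMesh          # over all 2n levels
    disc_face_levels: np.ndarray  # all levels carry dark PDE/cyclase flux

    @property
    def n_levels(self) -> int:
        return len(self.levels_z)

    @property
    def n_dofs(self) -> int:
        return self.n_levels * self.disc.m

    def chamber_levels(self, c: int):
        return 2 * c, 2 * c + 1

    def chamber_volume_total(self) -> float:
        v = 0.0
        for c in range(self.n_chambers):
            b, t = self.chamber_levels(c)
            v += _frustum_volume(self.geom, self.levels_z[b], self.levels_z[t])
        return v

    def sliver_global_dofs(self) -> np.ndarray:
        m = self.disc.m
        out = np.empty(self.n_levels * self.sliver.ns, dtype=np.int64)
        for l in range(self.n_levels):
            out[l * self.sliver.ns:(l + 1) * self.sliver.ns] = (
                l * m + self.disc.sliver_arc)
        return out

    def snap_to_disc_face(self, z: float):
        """Nearest activated face: returns (chamber, level_index, z_face).

        Photon events land on a disc face; the face chosen is the chamber
        face closest to the requested height.
        """
        idx = int(np.argmin(np.abs(self.levels_z - z)))
        return idx // 2, idx, float(self.levels_z[idx])


def build_nhom_mesh(g: ConeGeometry, n_chambers: int,
                    nr: int = 6, na: int = 12) -> LayeredMesh:
    """Layered mesh at n chambers, eps rescaled so the stack fills H."""
    if n_chambers < 2:
        raise MeshResolutionError("need n_chambers >= 2")
    gg = g.with_chambers(n_chambers)
    disc = build_disc_mesh(nr, na, gg.omega0)
    period = (1.0 + gg.nu) * gg.eps0
    z = []
    for c in range(n_chambers):
        z0 = c * period + 0.5 * gg.eps0
        z.append(z0)
        z.append(z0 + gg.nu * gg.eps0)
    levels_z = np.array(z)
    lambdas = np.asarray(gg.lateral_radius(levels_z))
    theta = disc.theta[disc.sliver_angle_idx % disc.na].copy()
    theta[-1] = gg.omega0
    sliver = build_sliver_mesh(gg, theta, levels_z)
    return LayeredMesh(geom=gg, disc=disc, n_chambers=n_chambers,
                       eps=gg.eps0, levels_z=levels_z, lambdas=lambdas,
                       sliver=sliver,
                       disc_face_levels=np.arange(2 * n_chambers))


# ---------------------------------------------------------------------------
# Connectivity and export
# ---------------------------------------------------------------------------

def element_graph_components(mesh, include_sliver: bool = True) -> int:
    """Number of connected components of the element-induced node graph.

    For a LayeredMesh without its sliver elements this equals n_chambers:
    the chambers communicate only through the closed margin.
    """
    import networkx as nx

    G = nx.Graph()
    m = mesh.disc.m
    if isinstance(mesh, LayeredMesh):
        levels = range(mesh.n_levels)
        for l in levels:
            off = l * m
            for tri in mesh.disc.tris:
                G.add_edge(off + tri[0], off + tri[1])
                G.add_edge(off + tri[1], off + tri[2])
        for c in range(mesh.n_chambers):
            b, t = mesh.chamber_levels(c)
            for i in range(m):
                G.add_edge(b * m + i, t * m + i)
    else:
        for k in range(mesh.n_slices):
            off = k * m
            for tri in mesh.disc.tris:
                G.add_edge(off + tri[0], off + tri[1])
                G.add_edge(off + tri[1], off + tri[2])
    if include_sliver:
        sdof = mesh.sliver_global_dofs()
        for tri in mesh.sliver.tris:
            G.add_edge(sdof[tri[0]], sdof[tri[1]])
            G.add_edge(sdof[tri[1]], sdof[tri[2]])
    return nx.number_connected_components(G)


def write_vtk_surface(path, nodes: np.ndarray, tris: np.ndarray,
                      point_data: Optional[dict] = None) -> None:
    """Legacy-ASCII VTK writer for surface triangulations (visualization)."""
    nodes = np.asarray(nodes, dtype=float)
    if nodes.shape[1] == 2:
        nodes = np.c_[nodes, np.zeros(len(nodes))]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nconesim surface\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for p in nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("\n".join(["5"] * len(tris)) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, vals in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in np.asarray(vals)) + "\n")
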