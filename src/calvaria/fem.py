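"""Small-strain linear-elastic FE on multi-region tetrahedral meshes.

Linear (constant-strain) tetrahedra, isotropic materials per region role,
sparse direct solves.  The unit system is mm–N–MPa: coordinates mm, Young's
moduli MPa, forces N, displacements mm, strains dimensionless.

The load scheme mirrors external calvarial loading experiments: a point
force split equally over a disc of surface nodes, applied dorsoventrally;
an anterior node set constrained in the load direction (incisor-against-
tube contact) and a posterior-ventral node set fixed in all degrees of
freedom (basioccipital).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import TetMesh

#: Voigt order xx, yy, zz, xy, yz, zx (engineering shear strains)
_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0)]


@dataclass
class MaterialSet:
    """Per-role Young's moduli (MPa) and a single Poisson's ratio.

    Roles without an explicit entry fall back: ``constraint`` patches get
    bone, ``cover`` gets suture, ``endocast`` gets brain.
    """

    young: dict[str, float] = field(
        default_factory=lambda: {"bone": 3500.0, "suture": 0.03, "brain": 3e-6}
    )
    poisson: float = 0.3

    _FALLBACK = {"constraint": "bone", "cover": "suture", "endocast": "brain"}

    def __post_init__(self) -> None:
        if not (0 <= self.poisson < 0.5):
            raise ValueError("need 0 <= poisson < 0.5")
        for k, v in self.young.items():
            if v <= 0:
                raise ValueError(f"young[{k}] must be > 0")

    def young_for_role(self, role: str) -> float:
        if role in self.young:
            return self.young[role]
        alias = self._FALLBACK.get(role)
        if alias in self.young:
            return self.young[alias]
        raise KeyError(f"no Young's modulus for role {role!r}")

    @classmethod
    def adjusted(cls, bone: float = 20.0) -> "MaterialSet":
        """The calibrated set: brain 3 Pa, suture 30 kPa, bone in MPa."""
        return cls({"bone": bone, "suture": 0.03, "brain": 3e-6}, 0.3)


@dataclass
class LoadCase:
    """Point load on a disc of surface nodes plus two fixations.

    ``load_point`` mm; ``force`` N total, split equally over the disc
    nodes; ``direction`` a unit vector (default dorsoventral, i.e. −y).
    ``anterior_mode`` — 'direction' fixes only the load-direction component
    of the anterior constraint patch, 'all' clamps it.
    """

    load_point: np.ndarray
    disc_diameter: float = 1.0
    force: float = 0.1
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    anterior_mode: str = "direction"

    def __post_init__(self) -> None:
        self.load_point = np.asarray(self.load_point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError("direction must be a unit vector")
        if self.force <= 0:
            raise ValueError("force must be > 0")


def elasticity_matrix(young: float, poisson: float) -> np.ndarray:
    e, nu = young, poisson
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def shape_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-tet constant shape-function gradients (m, 4, 3) and volumes."""
    x = mesh.nodes[mesh.tets]
    d = x[:, 1:] - x[:, :1]                      # (m, 3, 3) edge matrix
    vol = np.linalg.det(d) / 6.0
    if (vol <= 0).any():
        bad = int(np.argmax(vol <= 0))
        raise ValueError(f"inverted element {bad} (volume {vol[bad]:.3e})")
    dinv = np.linalg.inv(d)                      # columns ↔ ∇N1..3
    g = np.empty((mesh.n_tets, 4, 3))
    g[:, 1:, :] = np.swapaxes(dinv, 1, 2)
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vol


def _b_matrices(g: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, (m, 6, 12), Voigt engineering shear."""
    m = g.shape[0]
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = g[:, a, 0], g[:, a, 1], g[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


def _scatter(mesh: TetMesh, ke: np.ndarray) -> sp.csr_matrix:
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    )
    return K.tocsr()


def element_stiffness(nodes4: np.ndarray, young: float, poisson: float) -> np.ndarray:
    """12×12 stiffness of a single linear tetrahedron (for oracles/tests)."""
    mesh = TetMesh(np.asarray(nodes4, float), np.arange(4)[None, :], np.array([1]))
    g, vol = shape_gradients(mesh)
    B = _b_matrices(g)[0]
    D = elasticity_matrix(young, poisson)
    return vol[0] * B.T @ D @ B


@dataclass
class FESystem:
    """Assembled stiffness plus boundary-condition bookkeeping."""

    mesh: TetMesh
    K: sp.csr_matrix
    f: np.ndarray
    fixed: np.ndarray          # (3n,) bool
    fixed_values: np.ndarray   # (3n,)
    load_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def fix_dofs(self, node_ids, components=(0, 1, 2), values=0.0) -> None:
        vals = np.broadcast_to(
            np.asarray(values, dtype=float),
            (np.asarray(node_ids).size, len(components)),
        )
        for j, c in enumerate(components):
            d = 3 * np.asarray(node_ids) + c
            self.fixed[d] = True
            self.fixed_values[d] = vals[:, j]

    def add_forces(self, node_ids, vectors) -> None:
        vecs = np.broadcast_to(np.asarray(vectors, float), (np.asarray(node_ids).size, 3))
        for c in range(3):
            np.add.at(self.f, 3 * np.asarray(node_ids) + c, vecs[:, c])


def region_stiffnesses(mesh: TetMesh, poisson: float) -> dict[int, sp.csr_matrix]:
    """Unit-modulus stiffness per region label; K(E) = Σ E_label · K_label.

    Exact because the isotropic stiffness is linear in E at fixed ν —
    this is what makes modulus sweeps cheap (one assembly, many solves).
    """
    g, vol = shape_gradients(mesh)
    B = _b_matrices(g)
    D1 = elasticity_matrix(1.0, poisson)
    ke = np.einsum("mji,jk,mkl->mil", B, D1, B) * vol[:, None, None]
    out = {}
    for lab in np.unique(mesh.region):
        sel = mesh.region == lab
        sub = TetMesh(mesh.nodes, mesh.tets[sel], mesh.region[sel])
        out[int(lab)] = _scatter(sub, ke[sel])
    return out


def combine_stiffness(
    parts: dict[int, sp.csr_matrix], mesh: TetMesh, mats: MaterialSet
) -> sp.csr_matrix:
    K = None
    for lab, Kl in parts.items():
        e = mats.young_for_role(mesh.label_roles.get(lab, "bone"))
        K = e * Kl if K is None else K + e * Kl
    return K.tocsr()


def assemble(mesh: TetMesh, mats: MaterialSet) -> FESystem:
    """Assemble the global stiffness for a multi-region mesh."""
    g, vol = shape_gradients(mesh)
    B = _b_matrices(g)
    young = np.array(
        [mats.young_for_role(mesh.label_roles.get(int(l), "bone")) for l in mesh.region]
    )
    D1 = elasticity_matrix(1.0, mats.poisson)
    ke = np.einsum("mji,jk,mkl->mil", B, D1, B) * (vol * young)[:, None, None]
    K = _scatter(mesh, ke)
    n = 3 * mesh.n_nodes
    return FESystem(mesh, K, np.zeros(n), np.zeros(n, bool), np.zeros(n))


def system_from_stiffness(mesh: TetMesh, K: sp.csr_matrix) -> FESystem:
    n = 3 * mesh.n_nodes
    return FESystem(mesh, K, np.zeros(n), np.zeros(n, bool), np.zeros(n))


def apply_load_case(system: FESystem, lc: LoadCase) -> FESystem:
    """Select the load disc and the constraint node sets of a skull mesh.

    The disc is the set of surface nodes of structural (bone/constraint)
    regions within ``disc_diameter/2`` of the surface projection of the
    load point; the total force is split equally across its nodes.
    """
    mesh = system.mesh
    bone = [l for l, r in mesh.label_roles.items() if r == "bone"]
    constraint = [l for l, r in mesh.label_roles.items() if r == "constraint"]
    surf = mesh.surface_nodes(labels=bone + constraint)
    if constraint:  # never load the clamped patches
        surf = np.setdiff1d(surf, mesh.region_nodes(constraint))
    pos = mesh.nodes[surf]
    d = np.linalg.norm(pos - lc.load_point, axis=1)
    if d.min() > lc.disc_diameter:
        raise ValueError(
            f"empty load disc; nearest surface node is {d.min():.3f} mm from "
            "the load point"
        )
    proj = pos[np.argmin(d)]
    disc = surf[np.linalg.norm(pos - proj, axis=1) <= lc.disc_diameter / 2.0]
    if disc.size == 0:
        raise ValueError(
            f"empty load disc; nearest surface node is {d.min():.3f} mm away"
        )
    system.load_nodes = disc
    system.add_forces(disc, lc.direction * (lc.force / disc.size))

    anterior = [l for l, r in mesh.label_roles.items() if r == "constraint"]
    if len(anterior) >= 2:
        ant, post = anterior[0], anterior[-1]
        ant_nodes = mesh.region_nodes([ant])
        post_nodes = mesh.region_nodes([post])
        if lc.anterior_mode == "direction":
            comp = int(np.argmax(np.abs(lc.direction)))
            system.fix_dofs(ant_nodes, components=(comp,))
        else:
            system.fix_dofs(ant_nodes)
        system.fix_dofs(post_nodes)
    elif len(anterior) == 1:
        system.fix_dofs(mesh.region_nodes(anterior))
    overlap = np.intersect1d(system.load_nodes, np.where(system.fixed.reshape(-1, 3).any(axis=1))[0])
    if overlap.size:
        raise ValueError("load disc overlaps a fixed node set")
    return system


@dataclass
class FEResult:
    """Displacements, per-element strain tensors and scalar measures."""

    mesh: TetMesh
    u: np.ndarray                # (n, 3) mm
    strain: np.ndarray           # (m, 3, 3)
    von_mises: np.ndarray        # (m,)
    e1: np.ndarray
    e3: np.ndarray
    residual: float

    def reaction_forces(self, K: sp.csr_matrix, f: np.ndarray, fixed: np.ndarray):
        r = K @ self.u.ravel() - f
        out = np.zeros_like(r)
        out[fixed] = r[fixed]
        return out.reshape(-1, 3)


def strain_measures(tensors: np.ndarray):
    """von Mises equivalent strain and 1st/3rd principal strains.

    ε_vm = √(⅔ · ε_dev : ε_dev); principal strains are the ordered
    eigenvalues of the symmetric tensor.
    """
    t = np.asarray(tensors, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    if not np.allclose(t, np.swapaxes(t, 1, 2), atol=1e-10):
        raise ValueError("strain tensors must be symmetric")
    tr = np.trace(t, axis1=1, axis2=2)
    dev = t - tr[:, None, None] / 3.0 * np.eye(3)
    vm = np.sqrt(2.0 / 3.0 * np.einsum("mij,mij->m", dev, dev))
    ev = np.linalg.eigvalsh(t)
    e1, e3 = ev[:, 2], ev[:, 0]
    if single:
        return float(vm[0]), float(e1[0]), float(e3[0])
    return vm, e1, e3


def displacement_strains(mesh: TetMesh, u: np.ndarray, measure: str = "small"):
    """Per-element strain tensors of a nodal displacement field.

    ``small``: ε = (H + Hᵀ)/2 of the displacement gradient H — the nominal
    measure (a uniform stretch Δ/w reads exactly Δ/w, at any magnitude).
    ``green``: Green–Lagrange E = (H + Hᵀ + HᵀH)/2.
    """
    g, _ = shape_gradients(mesh)
    ue = u[mesh.tets]                        # (m, 4, 3)
    H = np.einsum("maj,mak->mjk", ue, g)     # H[j,k] = du_j/dx_k
    eps = 0.5 * (H + np.swapaxes(H, 1, 2))
    if measure == "green":
        eps = eps + 0.5 * np.einsum("mij,mik->mjk", H, H)
    elif measure != "small":
        raise ValueError(f"unknown strain measure {measure!r}")
    return eps


def solve(system: FESystem, measure: str = "small") -> FEResult:
    """Direct sparse solve with Dirichlet elimination."""
    K, f = system.K, system.f
    fixed, uc = system.fixed, system.fixed_values
    free = ~fixed
    if not free.any():
        u = uc.copy()
    else:
        Kff = K[free][:, free]
        rhs = f[free] - K[free][:, fixed] @ uc[fixed]
        uf = spla.spsolve(Kff.tocsc(), rhs)
        u = uc.copy()
        u[free] = uf
        denom = max(np.linalg.norm(rhs), 1e-30)
        res = np.linalg.norm(Kff @ uf - rhs) / denom
        if not np.isfinite(res) or res > 1e-6:
            raise RuntimeError(
                f"singular or ill-conditioned system (residual {res:.2e}); "
                "check that every component is constrained"
            )
    eps = displacement_strains(system.mesh, u.reshape(-1, 3), measure)
    vm, e1, e3 = strain_measures(eps)
    rel = 0.0
    if free.any():
        rel = float(res)
    return FEResult(system.mesh, u.reshape(-1, 3), eps, vm, e1, e3, rel)


def suture_average(
    result: FEResult, region_index: np.ndarray, index: int
) -> dict[str, float]:
    """Tet-volume-weighted mean strain measures over one suture region.

    ``region_index`` is a per-tet integer id (e.g. from
    :func:`calvaria.morphology.segment_sutures` mapped onto elements).
    """
    sel = region_index == index
    if not sel.any():
        raise ValueError(f"empty region {index}")
    w = result.mesh.volumes()[sel]
    w = w / w.sum()
    return {
        "von_mises": float(result.von_mises[sel] @ w),
        "e1": float(result.e1[sel] @ w),
        "e3": float(result.e3[sel] @ w),
    }


def face_traction_loads(system: FESystem, faces: np.ndarray, traction) -> None:
    """Consistent nodal loads for a uniform traction (N/mm² = MPa) on
    boundary triangles: each node gets traction · area/3."""
    v = system.mesh.nodes
    a = v[faces[:, 1]] - v[faces[:, 0]]
    b = v[faces[:, 2]] - v[faces[:, 0]]
    area = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
    t = np.asarray(traction, dtype=float)
    for k in range(3):
        system.add_forces(faces[:, k], t[None, :] * (area[:, None] / 3.0))
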