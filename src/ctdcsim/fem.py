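"""First-order tetrahedral finite-element solver for the quasistatic
current-flow problem.

The injected tDCS current obeys the continuity equation div(sigma grad Phi) = 0
inside the head (the quasistatic approximation of Maxwell's equations in a
purely resistive volume conductor), with a Neumann boundary: the normal
current density equals the applied density under each electrode patch and
vanishes elsewhere on the scalp.  Electrodes are modeled as pure Neumann
patches on the outer surface with area-proportional current density — no
contact-impedance layer and no sponge volume; a deliberate simplification
that preserves the interior field distribution the rest of the pipeline
consumes.

The weak form gives the standard symmetric positive-semidefinite stiffness
system K phi = f with a constant nullspace; compatibility requires the
electrode currents to sum to zero.  Two solution paths are provided:

* ``direct`` — sparse LU of the Lagrange-augmented system [[K, c],[c^T, 0]]
  (c = 1/n), which pins the mean potential without pinning any node.  The
  factorization is cached, so repeated solves against new load vectors (the
  lead-field assembly loop) cost one triangular solve each, and linearity
  closures (superposition, reciprocity) hold to machine precision.
* ``cg`` — deflated conjugate gradients with Jacobi preconditioning,
  relative tolerance 1e-8 by default, for meshes too large to factorize.

After either path the potential is shifted to zero mean over the
scalp-surface nodes (the reported gauge); gauge shifts are free.

Units: mesh coordinates mm, currents mA, conductivity S/m; potentials are in
volts and electric fields in V/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import ElectrodeSpec, HeadMesh

__all__ = [
    "TissueModel",
    "Montage",
    "PotentialSolution",
    "FemSystem",
    "assemble_system",
    "solve_potential",
    "element_field",
    "make_montage_preset",
    "MONTAGE_PRESETS",
]

_MM = 1e-3
_MA = 1e-3
_CURRENT_BALANCE_TOL = 1e-12  # mA


@dataclass(frozen=True)
class TissueModel:
    """Isotropic conductivity per tissue label (S/m)."""

    conductivity: dict[int, float]

    def __post_init__(self) -> None:
        for label, s in self.conductivity.items():
            if s <= 0:
                raise ValueError(f"tissue label {label}: conductivity must be > 0")

    @classmethod
    def from_shells(cls, shells) -> "TissueModel":
        ordered = sorted(shells, key=lambda s: s.outer_radius)
        return cls({i + 1: s.conductivity for i, s in enumerate(ordered)})

    def for_mesh(self, mesh: HeadMesh) -> np.ndarray:
        """Per-element sigma; raises naming any uncovered label."""
        labels = np.unique(mesh.element_label)
        missing = [int(l) for l in labels if int(l) not in self.conductivity]
        if missing:
            raise ValueError(f"no conductivity for mesh labels {missing}")
        lut = np.zeros(int(labels.max()) + 1)
        for label, s in self.conductivity.items():
            if label <= labels.max():
                lut[label] = s
        return lut[mesh.element_label]


@dataclass
class Montage:
    """Electrodes with their injected currents (mA, anode positive)."""

    electrodes: list[tuple[ElectrodeSpec, float]]
    name: str = "custom"

    def __post_init__(self) -> None:
        total = sum(c for _, c in self.electrodes)
        if abs(total) > _CURRENT_BALANCE_TOL:
            raise ValueError(
                f"montage {self.name!r}: currents must sum to 0 "
                f"(Neumann compatibility), got {total:g} mA"
            )

    @property
    def total_current_ma(self) -> float:
        return sum(abs(c) for _, c in self.electrodes) / 2.0

    def scaled(self, factor: float) -> "Montage":
        return Montage(
            electrodes=[(e, c * factor) for e, c in self.electrodes],
            name=f"{self.name}*{factor:g}",
        )

    def swapped(self) -> "Montage":
        return Montage(
            electrodes=[(e, -c) for e, c in self.electrodes],
            name=f"{self.name}(swapped)",
        )


@dataclass
class PotentialSolution:
    """Node potentials and element fields for one montage."""

    mesh: HeadMesh
    node_potentials: np.ndarray  # (n_nodes,) V, zero mean over scalp nodes
    element_field: np.ndarray  # (n_elem, 3) V/m
    montage: Montage
    diagnostics: dict = field(default_factory=dict)

    @property
    def element_enorm(self) -> np.ndarray:
        return np.linalg.norm(self.element_field, axis=1)


# ---------------------------------------------------------------------------
# assembly


def _shape_gradients(mesh: HeadMesh) -> tuple[np.ndarray, np.ndarray]:
    """Gradients (in 1/m) of the four linear shape functions per element and
    element volumes (m^3)."""
    p = mesh.nodes[mesh.elements] * _MM  # (m, 4, 3)
    e = p[:, 1:] - p[:, :1]  # (m, 3, 3) edge matrix rows p_i - p_0
    det = np.linalg.det(e)
    vol = det / 6.0
    if np.any(vol <= 0):
        raise ValueError("assembly requires positively oriented elements")
    inv = np.linalg.inv(e)  # (m, 3, 3); columns are grad(lambda_1..3)
    g123 = np.transpose(inv, (0, 2, 1))  # (m, 3(fn), 3(xyz))
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (m, 4, 3)
    return grads, vol


def assemble_system(mesh: HeadMesh, tissues: TissueModel) -> sp.csr_matrix:
    """Stiffness operator K (symmetric PSD, constant nullspace).

    K_ij = sum_e sigma_e V_e grad(N_i) . grad(N_j).
    """
    sigma = tissues.for_mesh(mesh)
    grads, vol = _shape_gradients(mesh)
    coef = (sigma * vol)[:, None, None]
    klocal = coef * np.einsum("eid,ejd->eij", grads, grads)  # (m, 4, 4)
    rows = np.repeat(mesh.elements, 4, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 4)).ravel()
    K = sp.coo_matrix(
        (klocal.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return K


def local_stiffness(points: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """4x4 element stiffness for a single tetrahedron given its 4 vertices
    (mm).  Exposed for verification against hand assembly."""
    mesh = HeadMesh(
        nodes=np.asarray(points, dtype=float),
        elements=np.array([[0, 1, 2, 3]]),
        element_label=np.array([1]),
    )
    grads, vol = _shape_gradients(mesh)
    return sigma * vol[0] * grads[0] @ grads[0].T


# ---------------------------------------------------------------------------
# boundary handling


def boundary_faces(mesh: HeadMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surface triangles (faces owned by exactly one tetra): node triples,
    areas (mm^2), centroids (mm)."""
    tets = mesh.elements
    faces = np.vstack(
        [
            tets[:, [0, 1, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 3]],
            tets[:, [1, 2, 3]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    surf = faces[first[counts == 1]]
    p = mesh.nodes[surf]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    centroids = p.mean(axis=1)
    return surf, areas, centroids


def _electrode_faces(
    centroids: np.ndarray, electrode: ElectrodeSpec, scalp_radius: float
) -> np.ndarray:
    """Indices of surface faces under an electrode's equal-area geodesic
    disc; falls back to the single nearest face when the disc is below the
    surface mesh resolution."""
    center = np.asarray(electrode.center, dtype=float)
    cnorm = np.linalg.norm(center)
    if cnorm == 0 or abs(cnorm - scalp_radius) / scalp_radius > 0.2:
        raise ValueError(
            f"electrode {electrode.id!r} center (radius {cnorm:.1f} mm) is not "
            f"on the scalp surface (radius {scalp_radius:.1f} mm)"
        )
    cdir = center / cnorm
    fdir = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    ang = np.arccos(np.clip(fdir @ cdir, -1.0, 1.0))
    ang_radius = electrode.equivalent_disc_radius_mm / scalp_radius
    idx = np.nonzero(ang <= ang_radius)[0]
    if idx.size == 0:
        idx = np.array([int(np.argmin(ang))])
    return idx


def neumann_load(mesh: HeadMesh, montage: Montage) -> np.ndarray:
    """Nodal load vector (A): each electrode's current spread over its
    surface faces proportionally to face area, each face's share split
    equally among its three nodes (exact for linear shape functions under a
    facet-constant density)."""
    surf, areas, centroids = boundary_faces(mesh)
    R = mesh.outer_radius
    f = np.zeros(mesh.n_nodes)
    for electrode, current_ma in montage.electrodes:
        if current_ma == 0:
            continue
        fidx = _electrode_faces(centroids, electrode, R)
        w = areas[fidx] / areas[fidx].sum()
        face_current = current_ma * _MA * w
        np.add.at(f, surf[fidx].ravel(), np.repeat(face_current / 3.0, 3))
    return f


# ---------------------------------------------------------------------------
# solving


class FemSystem:
    """Assembled operator for one (mesh, tissue) pair with a cached
    factorization, reused across the many load vectors of a lead-field
    assembly."""

    #: meshes above this node count fall back to CG under method="auto"
    DIRECT_NODE_LIMIT = 200_000

    def __init__(self, mesh: HeadMesh, tissues: TissueModel):
        self.mesh = mesh
        self.tissues = tissues
        self.K = assemble_system(mesh, tissues)
        self._grads, self._vol = _shape_gradients(mesh)
        surf, _, _ = boundary_faces(mesh)
        self.scalp_nodes = np.unique(surf)
        self._lu = None

    # -- solvers ------------------------------------------------------------

    def _solve_direct(self, f: np.ndarray) -> np.ndarray:
        n = self.K.shape[0]
        if self._lu is None:
            c = sp.csc_matrix(np.full((n, 1), 1.0 / n))
            aug = sp.bmat([[self.K, c], [c.T, None]], format="csc")
            self._lu = spla.splu(aug)
        sol = self._lu.solve(np.concatenate([f, [0.0]]))
        return sol[:n]

    def _solve_cg(self, f: np.ndarray, tol: float, maxiter: int) -> tuple[np.ndarray, int]:
        d = self.K.diagonal()
        minv = 1.0 / np.where(d > 0, d, 1.0)

        def project(v):
            return v - v.mean()

        A = spla.LinearOperator(self.K.shape, matvec=lambda v: project(self.K @ project(v)))
        M = spla.LinearOperator(self.K.shape, matvec=lambda v: project(minv * v))
        it = {"n": 0}

        def cb(_):
            it["n"] += 1

        phi, info = spla.cg(A, project(f), rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
        if info > 0:
            raise RuntimeError(
                f"CG did not converge within {maxiter} iterations "
                f"(residual info={info}, iterations={it['n']})"
            )
        return project(phi), it["n"]

    def solve(
        self,
        montage: Montage,
        method: str = "auto",
        tol: float = 1e-8,
        maxiter: int = 10_000,
    ) -> PotentialSolution:
        f = neumann_load(self.mesh, montage)
        if method == "auto":
            method = "direct" if self.mesh.n_nodes <= self.DIRECT_NODE_LIMIT else "cg"
        if method == "direct":
            phi = self._solve_direct(f)
            iters = 0
        elif method == "cg":
            phi, iters = self._solve_cg(f, tol, maxiter)
        else:
            raise ValueError(f"unknown solver method {method!r}")

        # gauge: zero mean over scalp-surface nodes
        phi = phi - phi[self.scalp_nodes].mean()
        fnorm = np.linalg.norm(f)
        resid = float(np.linalg.norm(self.K @ phi - f) / fnorm) if fnorm > 0 else 0.0
        E = self.element_field(phi)
        return PotentialSolution(
            mesh=self.mesh,
            node_potentials=phi,
            element_field=E,
            montage=montage,
            diagnostics={"method": method, "relative_residual": resid, "iterations": iters},
        )

    def element_field(self, phi: np.ndarray) -> np.ndarray:
        """E = -grad(Phi), constant per first-order element, V/m."""
        return -np.einsum("ei,eid->ed", phi[self.mesh.elements], self._grads)


def solve_potential(
    mesh: HeadMesh,
    tissues: TissueModel,
    montage: Montage,
    method: str = "auto",
    tol: float = 1e-8,
    maxiter: int = 10_000,
) -> PotentialSolution:
    """One-shot convenience wrapper around :class:`FemSystem`."""
    return FemSystem(mesh, tissues).solve(montage, method=method, tol=tol, maxiter=maxiter)


def element_field(solution: PotentialSolution) -> np.ndarray:
    """Per-element E (V/m) of a solved potential (already stored; recomputed
    here from the node potentials for API completeness)."""
    grads, _ = _shape_gradients(solution.mesh)
    return -np.einsum(
        "ei,eid->ed", solution.node_potentials[solution.mesh.elements], grads
    )


# ---------------------------------------------------------------------------
# montage presets

MONTAGE_PRESETS = ("celnik", "manto", "hd4x1")


def _sph(radius: float, polar_deg: float, azim_deg: float) -> tuple[float, float, float]:
    th, ph = math.radians(polar_deg), math.radians(azim_deg)
    return (
        radius * math.sin(th) * math.cos(ph),
        radius * math.sin(th) * math.sin(ph),
        radius * math.cos(th),
    )


def make_montage_preset(name: str, scalp_radius: float = 92.0) -> Montage:
    """Published two-electrode and 4x1 high-definition ctDCS montages mapped
    onto the spherical phantom.

    Landmark analogues (polar angle from vertex, azimuth with +y anterior,
    +x right; posterior = 270 deg): the inion sits posterior slightly below
    the equator.  The cerebellar anode is 1 cm below and 3 cm lateral
    (rightward) of the inion.

    * ``celnik`` — 5x5 cm anode over the right cerebellum, 5x5 cm cathode on
      the right buccinator (cheek), 2 mA.
    * ``manto`` — same anode, 5x5 cm cathode on the contralateral
      supraorbital area, 2 mA.
    * ``hd4x1`` — 3.14 cm^2 anode in the midline 10% below the
      occipital-pole landmark, four 3.14 cm^2 cathodes (occipital/parietal
      ring) at -0.25 mA each, 1 mA total anodal.

    5x5 cm square patches are realized as equal-area geodesic discs
    (radius ~2.82 cm) on the sphere; a true rectangle on a sphere is
    ill-defined and the equal-area disc preserves the injected current
    density.
    """
    R = scalp_radius
    inion_polar = 105.0
    lat_deg = math.degrees(0.03 / (R * _MM) / math.sin(math.radians(inion_polar)))
    down_deg = math.degrees(0.01 / (R * _MM))
    anode_center = _sph(R, inion_polar + down_deg, 270.0 + lat_deg)

    if name in ("celnik", "manto"):
        pad = ("rect", (5.0, 5.0))
        anode = ElectrodeSpec("cb_anode", anode_center, *pad)
        if name == "celnik":
            cathode = ElectrodeSpec("buccinator", _sph(R, 110.0, 40.0), *pad)
        else:
            cathode = ElectrodeSpec("supraorbital", _sph(R, 95.0, 75.0), *pad)
        return Montage([(anode, 2.0), (cathode, -2.0)], name=name)
    if name == "hd4x1":
        disc = ("disc", (1.0,))  # radius 1 cm -> area 3.14 cm^2
        anode = ElectrodeSpec("hd_anode", _sph(R, 108.0, 270.0), *disc)
        cathodes = [
            ElectrodeSpec("Oz", _sph(R, 90.0, 270.0), *disc),
            ElectrodeSpec("O2", _sph(R, 90.0, 288.0), *disc),
            ElectrodeSpec("P8", _sph(R, 90.0, 324.0), *disc),
            ElectrodeSpec("PO8", _sph(R, 85.0, 300.0), *disc),
        ]
        return Montage(
            [(anode, 1.0)] + [(c, -0.25) for c in cathodes], name=name
        )
    raise ValueError(f"unknown montage preset {name!r}; choose from {MONTAGE_PRESETS}")
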