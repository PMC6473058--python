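"""Synthetic head phantoms: nested-sphere tetrahedral meshes, a wedge
parcellation emulating a cerebellar lobule atlas, and scalp electrode catalogs.

Real pipelines segment a subject MRI into scalp/skull/CSF/gray/white
compartments and mesh them.  The phantom replaces that stage with a
concentric multi-shell sphere so that every downstream stage (FEM solve,
region extraction, lead-field assembly, montage optimization) is testable
without imaging data.  Shell radii are arbitrary but anatomically ordered;
conductivities default to the standard isotropic literature values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

__all__ = [
    "ShellSpec",
    "HeadMesh",
    "ParcellationVolume",
    "ElectrodeSpec",
    "ElectrodeCatalog",
    "DEFAULT_SHELLS",
    "build_shell_phantom",
    "build_parcellation",
    "candidate_layout",
    "check_mesh",
]


@dataclass(frozen=True)
class ShellSpec:
    """One concentric tissue shell: everything inside ``outer_radius`` not
    claimed by a deeper shell belongs to this tissue."""

    name: str
    outer_radius: float  # mm
    conductivity: float  # S/m

    def __post_init__(self) -> None:
        if self.outer_radius <= 0:
            raise ValueError(f"shell {self.name!r}: outer_radius must be > 0")
        if self.conductivity <= 0:
            raise ValueError(f"shell {self.name!r}: conductivity must be > 0")


#: Default five-compartment phantom.  Conductivities (S/m) are the standard
#: isotropic values used in tDCS volume-conductor modeling; radii are
#: arbitrary but anatomically ordered (scalp outermost, white innermost).
DEFAULT_SHELLS: tuple[ShellSpec, ...] = (
    ShellSpec("scalp", 92.0, 0.465),
    ShellSpec("skull", 86.0, 0.010),
    ShellSpec("csf", 81.0, 1.654),
    ShellSpec("gray", 79.0, 0.276),
    ShellSpec("white", 67.0, 0.126),
)


@dataclass
class HeadMesh:
    """Labeled tetrahedral volume conductor.

    Coordinates are millimetres in RAS axes (X mediolateral toward the
    right, Y posteroanterior toward the front, Z inferosuperior toward the
    vertex), origin at the sphere center.
    """

    nodes: np.ndarray  # (n_nodes, 3) float, mm
    elements: np.ndarray  # (n_elem, 4) int node indices
    element_label: np.ndarray  # (n_elem,) int tissue id
    label_names: dict[int, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.elements.shape[0])

    def element_volumes(self) -> np.ndarray:
        """Signed tetra volumes in mm^3 (positive after orientation fix)."""
        p = self.nodes[self.elements]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    @property
    def outer_radius(self) -> float:
        return float(np.linalg.norm(self.nodes, axis=1).max())


@dataclass
class ParcellationVolume:
    """Integer label volume on a regular voxel grid (voxel -> mm affine).

    ``lobule_ids`` enumerate the cerebellar lobule labels (28 by default);
    ``brain_mask_id`` marks the pooled non-cerebellar brain.  Background is 0.
    """

    affine: np.ndarray  # (4, 4)
    labels: np.ndarray  # (nx, ny, nz) int
    lobule_ids: tuple[int, ...]
    brain_mask_id: int
    names: dict[int, str] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        """World-space (mm) centers of all voxels, shape (n_voxels, 3)."""
        nx, ny, nz = self.labels.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
        return (ijk @ self.affine.T)[:, :3]

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass(frozen=True)
class ElectrodeSpec:
    """A scalp electrode: disc (dims = (radius_cm,)) or rect (dims = (w_cm, h_cm))."""

    id: str
    center: tuple[float, float, float]  # mm, on the scalp surface
    shape: str = "disc"
    dims: tuple[float, ...] = (0.5,)  # cm
    role: str = "stim"

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "rect"):
            raise ValueError(f"electrode {self.id!r}: unknown shape {self.shape!r}")
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"electrode {self.id!r}: dims must be > 0")
        if self.shape == "disc" and len(self.dims) != 1:
            raise ValueError(f"electrode {self.id!r}: disc takes one dim (radius cm)")
        if self.shape == "rect" and len(self.dims) != 2:
            raise ValueError(f"electrode {self.id!r}: rect takes (w, h) in cm")

    @property
    def area_cm2(self) -> float:
        if self.shape == "disc":
            return math.pi * self.dims[0] ** 2
        return self.dims[0] * self.dims[1]

    @property
    def equivalent_disc_radius_mm(self) -> float:
        """Radius (mm) of the equal-area geodesic disc realizing this electrode
        on a spherical scalp (a true rectangle on a sphere is ill-defined)."""
        return math.sqrt(self.area_cm2 / math.pi) * 10.0


@dataclass
class ElectrodeCatalog:
    """Candidate electrode positions plus the designated reference."""

    electrodes: list[ElectrodeSpec]
    reference_id: str
    min_separation_deg: float

    def __iter__(self):
        return iter(self.electrodes)

    def __len__(self) -> int:
        return len(self.electrodes)

    def get(self, electrode_id: str) -> ElectrodeSpec:
        for e in self.electrodes:
            if e.id == electrode_id:
                return e
        raise KeyError(f"unknown electrode id {electrode_id!r}")

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.electrodes]


# ---------------------------------------------------------------------------
# mesh construction


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _validate_shells(shells: list[ShellSpec]) -> list[ShellSpec]:
    if len(shells) < 1:
        raise ValueError("at least one shell is required")
    ordered = sorted(shells, key=lambda s: -s.outer_radius)
    radii = [s.outer_radius for s in ordered]
    if len(set(radii)) != len(radii):
        raise ValueError("shell radii must be strictly decreasing (duplicates found)")
    if list(radii) != [s.outer_radius for s in shells]:
        raise ValueError("shells must be listed with strictly decreasing radii")
    return list(shells)


def build_shell_phantom(
    shells: list[ShellSpec] | tuple[ShellSpec, ...] = DEFAULT_SHELLS,
    resolution: float = 8.0,
    seed: int = 0,
) -> HeadMesh:
    """Build a watertight nested-shell tetrahedral sphere mesh.

    Nodes are placed on concentric layers (every shell interface plus
    intermediate layers at ~``resolution`` mm radial spacing, each layer a
    golden-angle point set at ~``resolution`` mm tangential spacing) and
    tetrahedralized with a Delaunay triangulation; each element is labeled by
    the innermost shell containing its centroid.

    Labels count from the innermost shell: with the default five shells,
    white=1, gray=2, csf=3, skull=4, scalp=5.
    """
    shells = _validate_shells(list(shells))
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    radii_desc = [s.outer_radius for s in shells]
    boundaries = [0.0] + sorted(radii_desc)
    thicknesses = np.diff(boundaries)
    thinnest = float(thicknesses.min())
    if resolution > 4.0 * thinnest:
        raise ValueError(
            f"resolution {resolution:g} mm too coarse to resolve the thinnest "
            f"shell ({thinnest:g} mm thick); use resolution <= {4.0 * thinnest:g} mm"
        )

    rng = np.random.default_rng(seed)
    layer_radii: list[float] = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        nsub = max(1, int(math.ceil((b - a) / resolution)))
        layer_radii.extend(a + (b - a) * (k + 1) / nsub for k in range(nsub))

    points = [np.zeros((1, 3))]
    for r in layer_radii:
        n = max(6, int(round(4.0 * math.pi * r * r / resolution**2)))
        pts = _fibonacci_sphere(n)
        # random rotation per layer decorrelates layers and avoids Delaunay
        # degeneracies from radially aligned points
        q = rng.normal(size=(3, 3))
        qmat, _ = np.linalg.qr(q)
        if np.linalg.det(qmat) < 0:
            qmat[:, 0] *= -1
        points.append(r * (pts @ qmat.T))
    nodes = np.vstack(points)

    tri = Delaunay(nodes)
    elems = tri.simplices.astype(np.int64)

    # orientation fix: make all signed volumes positive
    p = nodes[elems]
    vol6 = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    )
    flip = vol6 < 0
    elems[flip, 1], elems[flip, 2] = elems[flip, 2].copy(), elems[flip, 1].copy()
    vol = np.abs(vol6) / 6.0
    keep = vol > 1e-9 * resolution**3
    elems = elems[keep]

    centroids = nodes[elems].mean(axis=1)
    rc = np.linalg.norm(centroids, axis=1)
    # innermost shell whose outer radius contains the centroid
    radii_asc = np.array(sorted(radii_desc))  # innermost first
    label = np.searchsorted(radii_asc, rc, side="left") + 1
    label = np.minimum(label, len(shells))

    names = {
        i + 1: s.name for i, s in enumerate(sorted(shells, key=lambda s: s.outer_radius))
    }
    mesh = HeadMesh(nodes=nodes, elements=elems, element_label=label, label_names=names)
    check_mesh(mesh)
    return mesh


def check_mesh(mesh: HeadMesh) -> None:
    """Quality gate: positive volumes, every label populated, one connected
    component.  Raises ValueError on failure."""
    vol = mesh.element_volumes()
    if not np.all(vol > 0):
        raise ValueError("mesh quality gate: non-positive tetra volumes present")
    if mesh.label_names:
        present = set(np.unique(mesh.element_label))
        missing = set(mesh.label_names) - present
        if missing:
            raise ValueError(f"mesh quality gate: empty tissue labels {sorted(missing)}")
    # connectivity via shared nodes
    m = mesh.n_elements
    rows = np.repeat(np.arange(m), 4)
    cols = mesh.elements.ravel()
    inc = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(m, mesh.n_nodes))
    adj = inc @ inc.T
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError(f"mesh quality gate: {ncomp} connected components (expected 1)")


# ---------------------------------------------------------------------------
# parcellation

# Cerebellar lobule naming scheme: 10 lobules per hemisphere + 8 vermis
# regions = 28.  Bands are ordered from the cap axis outward; the cap axis
# points posterior-inferior, so the axis-adjacent bands are the most inferior
# lobules (X, IX, VIII...), mirroring real topology.
_HEMI_BANDS = ("X", "IX", "VIIIb", "VIIIa", "VIIb", "Crus_II", "Crus_I", "VI", "V", "I_IV")
_VERMIS_BANDS = (
    "Vermis_X",
    "Vermis_IX",
    "Vermis_VIIIb",
    "Vermis_VIIIa",
    "Vermis_VIIb",
    "Vermis_CrusII",
    "Vermis_CrusI",
    "Vermis_VI",
)

BRAIN_MASK_ID = 100


def _brain_radius(mesh: HeadMesh) -> float:
    """Outer radius of the 'brain' (gray+white) compartment of a shell phantom.

    Labels count from the innermost shell, so brain = labels {1, 2} when the
    mesh has >= 4 shells (white + gray), else the innermost label only.
    """
    labels = np.unique(mesh.element_label)
    brain_labels = labels[:2] if labels.size >= 4 else labels[:1]
    sel = np.isin(mesh.element_label, brain_labels)
    node_ids = np.unique(mesh.elements[sel])
    return float(np.linalg.norm(mesh.nodes[node_ids], axis=1).max())


def build_parcellation(
    mesh: HeadMesh,
    n_lobules: int = 28,
    voxel_size: float = 1.0,
    cap_angle_deg: float = 50.0,
    inner_radius_frac: float = 0.55,
    vermis_frac: float = 0.35,
    seed: int = 0,
) -> ParcellationVolume:
    """Wedge-parcellated pseudo-cerebellum plus a non-cerebellar brain mask.

    The pseudo-cerebellum is a spherical-cap sector centered on the
    posterior-inferior direction (0, -1, -1)/sqrt(2), spanning radii
    [inner_radius_frac, 1] x brain radius and polar angles up to
    ``cap_angle_deg`` from the cap axis.  With ``n_lobules=28`` it is split
    into 10 polar bands per hemisphere plus 8 vermis bands; the vermis is the
    midline strip occupying the central ``vermis_frac`` of each band's
    mediolateral extent (|x| <= vermis_frac/2 * r sin(gamma)), so every polar
    band keeps left and right hemisphere portions.  Other counts use a
    generic bands-by-hemisphere tiling.  The rest of the gray/white
    compartment is the pooled non-cerebellar brain mask.  Deterministic given
    the grid and n_lobules (``seed`` is accepted for interface symmetry).
    """
    if n_lobules < 2:
        raise ValueError("n_lobules must be >= 2")
    del seed  # construction is deterministic

    rb = _brain_radius(mesh)
    half = rb + voxel_size
    n_side = int(math.ceil(2 * half / voxel_size))
    # voxel centers at affine @ (i,j,k,1); center the grid on the origin
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -voxel_size * (n_side - 1) / 2.0

    shape = (n_side, n_side, n_side)
    idx = np.arange(n_side) * voxel_size + affine[0, 3]
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    inside_brain = r <= rb

    axis = np.array([0.0, -1.0, -1.0]) / math.sqrt(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosg = (X * axis[0] + Y * axis[1] + Z * axis[2]) / np.where(r > 0, r, np.inf)
    gamma = np.degrees(np.arccos(np.clip(cosg, -1.0, 1.0)))

    in_cap = inside_brain & (r >= inner_radius_frac * rb) & (gamma <= cap_angle_deg)

    labels = np.zeros(shape, dtype=np.int16)
    labels[inside_brain] = BRAIN_MASK_ID

    names: dict[int, str] = {BRAIN_MASK_ID: "non_cerebellar_brain"}
    if n_lobules == 28:
        n_hemi, n_vermis = len(_HEMI_BANDS), len(_VERMIS_BANDS)
        with np.errstate(invalid="ignore"):
            lateral_extent = r * np.sin(np.radians(gamma))
        is_vermis = in_cap & (np.abs(X) <= 0.5 * vermis_frac * lateral_extent)
        is_hemi = in_cap & ~is_vermis
        band_h = np.minimum(
            (gamma / cap_angle_deg * n_hemi).astype(np.int32), n_hemi - 1
        )
        band_v = np.minimum(
            (gamma / cap_angle_deg * n_vermis).astype(np.int32), n_vermis - 1
        )
        left = X < 0
        labels[is_hemi & left] = 1 + band_h[is_hemi & left]
        labels[is_hemi & ~left] = 11 + band_h[is_hemi & ~left]
        labels[is_vermis] = 21 + band_v[is_vermis]
        for b, nm in enumerate(_HEMI_BANDS):
            names[1 + b] = f"Left_{nm}"
            names[11 + b] = f"Right_{nm}"
        for b, nm in enumerate(_VERMIS_BANDS):
            names[21 + b] = nm
        lobule_ids = tuple(range(1, 29))
    else:
        n_bands = n_lobules // 2
        odd = n_lobules % 2 == 1
        band = np.minimum(
            (gamma / cap_angle_deg * n_bands).astype(np.int32), max(n_bands - 1, 0)
        )
        left = X < 0
        labels[in_cap & left] = 1 + band[in_cap & left]
        labels[in_cap & ~left] = 1 + n_bands + band[in_cap & ~left]
        if odd:
            # final odd label: outermost band, both hemispheres pooled
            outer = in_cap & (band == n_bands - 1)
            labels[outer] = n_lobules
        lobule_ids = tuple(range(1, n_lobules + 1))
        names.update({i: f"lobule_{i}" for i in lobule_ids})

    parc = ParcellationVolume(
        affine=affine,
        labels=labels,
        lobule_ids=lobule_ids,
        brain_mask_id=BRAIN_MASK_ID,
        names=names,
    )
    counts = np.bincount(labels.ravel(), minlength=max(lobule_ids) + 1)
    empty = [names[i] for i in lobule_ids if counts[i] == 0]
    if empty:
        raise ValueError(
            f"parcellation produced empty lobules {empty}; refine the voxel grid "
            f"or enlarge the cap"
        )
    return parc


# ---------------------------------------------------------------------------
# electrode layout


def candidate_layout(
    scheme: str = "quasi-uniform",
    n: int = 8,
    reference_id: str = "Cz",
    scalp_radius: float = 92.0,
    disc_radius_cm: float = 0.5,
    min_separation_deg: float | None = None,
    ring_polar_deg: float = 110.0,
    exclusion_z_frac: float = -0.6,
) -> ElectrodeCatalog:
    """Candidate scalp electrode positions including a vertex reference.

    ``quasi-uniform`` spreads n-1 electrodes over the scalp (golden-angle
    spiral, excluding the lower cap below ``exclusion_z_frac`` x radius where
    no electrode can be placed) plus the vertex reference.  ``ring`` places
    n-1 electrodes on a circle of constant polar angle.  The achieved minimum
    pairwise angular separation is reported on the catalog; if
    ``min_separation_deg`` is given and cannot be met, the layout is rejected.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    R = scalp_radius

    if scheme == "quasi-uniform":
        # grow the full-sphere point set until the allowed band (below the
        # vertex slot, above the neck line) holds exactly n-1 points, so the
        # catalog covers the band uniformly rather than favoring the vertex
        zmax = math.cos(math.radians(10.0))  # keep clear of the reference

        def _band(n_gen: int) -> np.ndarray:
            pts = _fibonacci_sphere(n_gen)
            return pts[(pts[:, 2] > exclusion_z_frac) & (pts[:, 2] < zmax)]

        n_gen = n - 1
        while len(_band(n_gen)) < n - 1:
            n_gen += 1
        while len(_band(n_gen)) > n - 1:
            n_gen -= 1
        pts = _band(n_gen)
        if len(pts) < n - 1:  # counts are not monotone in n_gen; step back up
            n_gen += 1
            pts = _band(n_gen)[: n - 1]
        centers = R * pts
    elif scheme == "ring":
        th = math.radians(ring_polar_deg)
        phis = 2 * math.pi * np.arange(n - 1) / (n - 1)
        centers = R * np.column_stack(
            [math.sin(th) * np.cos(phis), math.sin(th) * np.sin(phis),
             np.full(n - 1, math.cos(th))]
        )
    else:
        raise ValueError(f"unknown layout scheme {scheme!r}")

    electrodes = [
        ElectrodeSpec(
            id=reference_id,
            center=(0.0, 0.0, R),
            shape="disc",
            dims=(disc_radius_cm,),
            role="reference",
        )
    ]
    electrodes += [
        ElectrodeSpec(
            id=f"E{i+1:02d}",
            center=tuple(np.round(c, 6)),
            shape="disc",
            dims=(disc_radius_cm,),
        )
        for i, c in enumerate(centers)
    ]

    units = np.array([e.center for e in electrodes]) / R
    dots = np.clip(units @ units.T, -1.0, 1.0)
    np.fill_diagonal(dots, -1.0)
    min_sep = float(np.degrees(np.arccos(dots.max())))
    if min_separation_deg is not None and min_sep < min_separation_deg:
        raise ValueError(
            f"cannot pack {n} electrodes at >= {min_separation_deg:g} deg "
            f"separation (achieved {min_sep:.2f} deg)"
        )
    return ElectrodeCatalog(
        electrodes=electrodes, reference_id=reference_id, min_separation_deg=min_sep
    )
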