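"""Voxelization of element-wise fields and atlas-region field statistics.

The FEM solution carries one constant E vector per tetrahedron.  To compare
against (and average within) a voxel parcellation, the field is rasterized:
each voxel takes the field of the element containing its center — exact for
first-order elements, no interpolation — and voxels whose center lies in no
element are masked invalid (distinguishable from a zero field).  Region means
are plain unweighted voxel averages; the field-strength summary Enorm is the
mean of per-voxel magnitudes, not the magnitude of the mean vector, so
mean(Enorm) >= ||mean(E)|| holds per region by Jensen's inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fem import PotentialSolution
from .phantom import HeadMesh, ParcellationVolume

__all__ = [
    "FieldVolume",
    "VoxelSampler",
    "rasterize_field",
    "lobule_means",
    "current_density",
    "LOBULE_TABLE_COLUMNS",
]

LOBULE_TABLE_COLUMNS = ("region", "n_voxels", "Ex", "Ey", "Ez", "Enorm")


@dataclass
class FieldVolume:
    """Per-voxel electric-field components (V/m) with a validity mask."""

    affine: np.ndarray  # (4, 4)
    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray
    mask: np.ndarray  # bool, True where the voxel center lay inside the mesh
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.ex.shape)  # type: ignore[return-value]

    @property
    def enorm(self) -> np.ndarray:
        return np.sqrt(self.ex**2 + self.ey**2 + self.ez**2)

    def components(self) -> dict[str, np.ndarray]:
        return {"Ex": self.ex, "Ey": self.ey, "Ez": self.ez, "Enorm": self.enorm}


class VoxelSampler:
    """Cached voxel-center -> containing-element map for one (mesh, grid).

    Rasterizing a new solution on the same mesh and grid is then a pure
    gather, which is what makes the lead-field loop (many solves, one grid)
    cheap.  Containment is found by testing barycentric coordinates against
    the nearest candidate elements (by centroid) with an escalating candidate
    count; centers matching no element are marked outside (-1).
    """

    def __init__(self, mesh: HeadMesh, affine: np.ndarray, shape: tuple[int, int, int]):
        self.mesh = mesh
        self.affine = np.asarray(affine, dtype=float)
        self.shape = tuple(shape)
        self.element_index = self._build()
        if not np.any(self.element_index >= 0):
            raise ValueError("voxel grid does not overlap the mesh")

    def _voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        ijk = np.column_stack(
            [ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)]
        )
        return (ijk @ self.affine.T)[:, :3]

    def _build(self) -> np.ndarray:
        mesh = self.mesh
        centers = self._voxel_centers()
        # cheap prefilter: only test points within the mesh bounding sphere
        rmax = mesh.outer_radius + 1e-9
        candidates = np.linalg.norm(centers, axis=1) <= rmax
        pts = centers[candidates]

        p = mesh.nodes[mesh.elements]
        p0 = p[:, 0]
        T = p[:, 1:] - p[:, :1]  # (m, 3, 3)
        Tinv = np.linalg.inv(np.transpose(T, (0, 2, 1)))  # maps (x - p0) -> lambda_123

        tree = cKDTree(mesh.element_centroids())
        idx_local = np.full(len(pts), -1, dtype=np.int64)
        unresolved = np.arange(len(pts))
        tol = 1e-9
        for k in (8, 32, 96):
            if unresolved.size == 0:
                break
            k_eff = min(k, mesh.n_elements)
            _, cand = tree.query(pts[unresolved], k=k_eff)
            cand = np.asarray(cand).reshape(unresolved.size, k_eff)
            found = np.full(unresolved.size, -1, dtype=np.int64)
            remaining = np.arange(unresolved.size)
            for j in range(k_eff):
                if remaining.size == 0:
                    break
                e = cand[remaining, j]
                d = pts[unresolved[remaining]] - p0[e]
                lam = np.einsum("mij,mj->mi", Tinv[e], d)
                ok = (
                    (lam >= -tol).all(axis=1)
                    & (lam.sum(axis=1) <= 1.0 + tol)
                )
                found[remaining[ok]] = e[ok]
                remaining = remaining[~ok]
            hit = found >= 0
            idx_local[unresolved[hit]] = found[hit]
            unresolved = unresolved[~hit]

        element_index = np.full(len(centers), -1, dtype=np.int64)
        element_index[candidates] = idx_local
        return element_index.reshape(self.shape)

    def sample(self, element_values: np.ndarray) -> np.ndarray:
        """Gather per-element values onto the grid; invalid voxels get 0 and
        must be read through the mask."""
        out = np.zeros(self.shape + element_values.shape[1:], dtype=float)
        valid = self.element_index >= 0
        out[valid] = element_values[self.element_index[valid]]
        return out

    @property
    def valid_mask(self) -> np.ndarray:
        return self.element_index >= 0


def rasterize_field(
    solution: PotentialSolution,
    affine: np.ndarray,
    shape: tuple[int, int, int],
    sampler: VoxelSampler | None = None,
) -> FieldVolume:
    """Rasterize a solved field onto a voxel grid (default grids are 1 mm
    isotropic).  Pass a prebuilt :class:`VoxelSampler` to reuse the
    voxel-element map across solutions."""
    if sampler is None:
        sampler = VoxelSampler(solution.mesh, affine, shape)
    else:
        if sampler.mesh is not solution.mesh or not np.allclose(sampler.affine, affine):
            raise ValueError("sampler was built for a different mesh or grid")
    E = sampler.sample(solution.element_field)
    return FieldVolume(
        affine=np.asarray(affine, dtype=float),
        ex=E[..., 0],
        ey=E[..., 1],
        ez=E[..., 2],
        mask=sampler.valid_mask.copy(),
        meta={"montage": solution.montage.name},
    )


def lobule_means(fieldvol: FieldVolume, parc: ParcellationVolume) -> pd.DataFrame:
    """Region-wise unweighted voxel means of Ex, Ey, Ez and Enorm.

    Returns one row per lobule plus a final pooled non-cerebellar-brain row
    (29 rows for the default 28-lobule parcellation), with fixed column order
    (region, n_voxels, Ex, Ey, Ez, Enorm) and the region id as index.
    """
    if fieldvol.shape != parc.shape or not np.allclose(fieldvol.affine, parc.affine):
        raise ValueError(
            "field and parcellation grids differ: "
            f"field affine=\n{fieldvol.affine}\nparcellation affine=\n{parc.affine}"
        )
    labels = parc.labels
    valid = fieldvol.mask
    enorm = fieldvol.enorm
    rows = []
    region_ids = list(parc.lobule_ids) + [parc.brain_mask_id]
    for rid in region_ids:
        sel = (labels == rid) & valid
        n = int(sel.sum())
        name = parc.names.get(rid, f"region_{rid}")
        if n == 0:
            raise ValueError(f"region {name!r} (id {rid}) has no valid voxels")
        rows.append(
            {
                "region": name,
                "n_voxels": n,
                "Ex": float(fieldvol.ex[sel].mean()),
                "Ey": float(fieldvol.ey[sel].mean()),
                "Ez": float(fieldvol.ez[sel].mean()),
                "Enorm": float(enorm[sel].mean()),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(region_ids, name="region_id"), columns=list(LOBULE_TABLE_COLUMNS))


def current_density(current_ma: float, area_cm2: float, ndigits: int | None = None) -> float:
    """Electrode-skin interface current density in mA/cm^2.

    E.g. a 2 mA pad of 25 cm^2 carries 0.08 mA/cm^2 while a 1 mA
    high-definition disc of 3.14 cm^2 carries 0.32 mA/cm^2 (2-decimal
    convention via ``ndigits=2``).
    """
    if area_cm2 <= 0:
        raise ValueError("electrode area must be > 0")
    j = current_ma / area_cm2
    return round(j, ndigits) if ndigits is not None else j
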