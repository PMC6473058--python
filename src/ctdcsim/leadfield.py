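"""Lead-field ("transfer") matrix: electrode currents -> region-averaged
electric fields.

In an Ohmic volume conductor the mapping from injected electrode currents to
the electric field anywhere in the head is linear, b = LF . s.  The matrix is
assembled column by column from unit bipolar simulations: anode n at +1 mA
against a common reference (vertex) cathode at -1 mA, region-averaged per
direction, giving one 29-region x N-electrode matrix per field direction
(X, Y, Z), in (V/m)/mA.  Any zero-sum current vector's field then follows by
superposition without further FEM solves, which is what makes montage
optimization over many candidate electrodes tractable.

The reference electrode has no column: its contribution is implied by the
zero-sum constraint.  Predictions are therefore invariant to which catalog
electrode served as the reference.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .fem import FemSystem, Montage, TissueModel
from .phantom import ElectrodeCatalog, HeadMesh, ParcellationVolume
from .roi import VoxelSampler, lobule_means, rasterize_field

__all__ = ["LeadField", "CurrentVector", "assemble_leadfield", "predict_fields"]

DIRECTIONS = ("X", "Y", "Z")


@dataclass
class CurrentVector:
    """Electrode currents in mA (anode positive), summing to zero."""

    currents: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.currents.values())
        if abs(total) > 1e-9:
            raise ValueError(f"currents must sum to 0 mA (got {total:g})")

    def as_array(self, ids: list[str], allow_missing_reference: str | None = None) -> np.ndarray:
        """Currents ordered by ``ids``; electrodes absent from the vector get
        0.  Unknown ids in the vector are rejected."""
        known = set(ids)
        if allow_missing_reference is not None:
            known.add(allow_missing_reference)
        unknown = set(self.currents) - known
        if unknown:
            raise ValueError(f"unknown electrode ids {sorted(unknown)}")
        return np.array([self.currents.get(i, 0.0) for i in ids])

    @property
    def total_abs_ma(self) -> float:
        return sum(abs(c) for c in self.currents.values())


@dataclass
class LeadField:
    """Per-direction region x electrode matrices, (V/m)/mA."""

    matrices: dict[str, np.ndarray]  # "X"|"Y"|"Z" -> (n_regions, n_electrodes)
    electrode_ids: list[str]  # column order; reference excluded
    reference_id: str
    region_ids: list[int]
    region_names: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def stacked(self, directions=DIRECTIONS) -> np.ndarray:
        """Rows of the chosen directions stacked for joint optimization."""
        return np.vstack([self.matrices[d] for d in directions])

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.attrs["format"] = "ctdcsim-leadfield-1"
            h5.attrs["reference_id"] = self.reference_id
            h5.attrs["provenance"] = json.dumps(self.provenance)
            for d in DIRECTIONS:
                h5.create_dataset(f"LF_{d}", data=self.matrices[d])
            h5.create_dataset("region_ids", data=np.asarray(self.region_ids))
            str_dt = h5py.string_dtype("utf-8")
            h5.create_dataset("region_names", data=self.region_names, dtype=str_dt)
            h5.create_dataset("electrode_ids", data=self.electrode_ids, dtype=str_dt)

    @classmethod
    def load(cls, path) -> "LeadField":
        with h5py.File(path, "r") as h5:
            if h5.attrs.get("format") != "ctdcsim-leadfield-1":
                raise ValueError(f"{path}: not a ctdcsim lead-field container")
            return cls(
                matrices={d: h5[f"LF_{d}"][()] for d in DIRECTIONS},
                electrode_ids=[s.decode() if isinstance(s, bytes) else s for s in h5["electrode_ids"][()]],
                reference_id=str(h5.attrs["reference_id"]),
                region_ids=[int(i) for i in h5["region_ids"][()]],
                region_names=[s.decode() if isinstance(s, bytes) else s for s in h5["region_names"][()]],
                provenance=json.loads(h5.attrs["provenance"]),
            )

    def to_tsv(self, path_prefix) -> list[str]:
        """One TSV per direction (regions x electrodes)."""
        paths = []
        for d in DIRECTIONS:
            df = pd.DataFrame(
                self.matrices[d], index=self.region_names, columns=self.electrode_ids
            )
            p = f"{path_prefix}_{d}.tsv"
            df.to_csv(p, sep="\t", index_label="region")
            paths.append(p)
        return paths


def _mesh_hash(mesh: HeadMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.nodes).tobytes())
    h.update(np.ascontiguousarray(mesh.elements).tobytes())
    h.update(np.ascontiguousarray(mesh.element_label).tobytes())
    return h.hexdigest()[:16]


def assemble_leadfield(
    mesh: HeadMesh,
    tissues: TissueModel,
    catalog: ElectrodeCatalog,
    reference_id: str,
    parc: ParcellationVolume,
    unit_current_ma: float = 1.0,
    solver_method: str = "auto",
    system: FemSystem | None = None,
    sampler: VoxelSampler | None = None,
) -> LeadField:
    """One FEM solve per non-reference electrode (+1 mA against the reference
    at -1 mA), region-averaged on the parcellation grid.

    The stiffness factorization and the voxel-element map are built once and
    reused across all solves; pass them in to reuse across calls too.
    Column order is deterministic (catalog order).
    """
    reference = catalog.get(reference_id)
    if system is None:
        system = FemSystem(mesh, tissues)
    if sampler is None:
        sampler = VoxelSampler(mesh, parc.affine, parc.shape)

    electrode_ids = [e.id for e in catalog if e.id != reference_id]
    region_ids: list[int] | None = None
    region_names: list[str] | None = None
    mats = {d: np.zeros((0, 0)) for d in DIRECTIONS}
    for col, eid in enumerate(electrode_ids):
        try:
            montage = Montage(
                electrodes=[(catalog.get(eid), unit_current_ma), (reference, -unit_current_ma)],
                name=f"bipolar:{eid}-{reference_id}",
            )
            sol = system.solve(montage, method=solver_method)
            fv = rasterize_field(sol, parc.affine, parc.shape, sampler=sampler)
            table = lobule_means(fv, parc)
        except Exception as exc:  # noqa: BLE001 - re-raise with electrode context
            raise RuntimeError(f"lead-field solve failed for electrode {eid!r}: {exc}") from exc
        if region_ids is None:
            region_ids = [int(i) for i in table.index]
            region_names = list(table["region"])
            for d in DIRECTIONS:
                mats[d] = np.zeros((len(region_ids), len(electrode_ids)))
        for d, colname in zip(DIRECTIONS, ("Ex", "Ey", "Ez")):
            mats[d][:, col] = table[colname].to_numpy() / unit_current_ma

    assert region_ids is not None and region_names is not None
    provenance = {
        "mesh_hash": _mesh_hash(mesh),
        "tissues": {str(k): v for k, v in tissues.conductivity.items()},
        "unit_current_ma": unit_current_ma,
        "grid_shape": list(parc.shape),
        "voxel_size_mm": float(abs(parc.affine[0, 0])),
        "n_electrodes": len(electrode_ids),
    }
    return LeadField(
        matrices=mats,
        electrode_ids=electrode_ids,
        reference_id=reference_id,
        region_ids=region_ids,
        region_names=region_names,
        provenance=provenance,
    )


def predict_fields(lf: LeadField, x: CurrentVector | dict[str, float]) -> pd.DataFrame:
    """Superposition prediction b_hat = LF_d . x for each direction.

    ``x`` must sum to zero; the reference electrode's current is implied and
    carries no column.  Returns a region x (X, Y, Z) DataFrame in V/m.
    """
    if not isinstance(x, CurrentVector):
        x = CurrentVector(dict(x))
    xv = x.as_array(lf.electrode_ids, allow_missing_reference=lf.reference_id)
    data = {d: lf.matrices[d] @ xv for d in DIRECTIONS}
    return pd.DataFrame(data, index=pd.Index(lf.region_ids, name="region_id"))
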