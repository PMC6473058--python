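"""File-format adapters: Gmsh .msh (ASCII v2.2), NIfTI-1 volumes, and TSV
electrode catalogs.

The msh dialect is the minimal one the pipeline needs: $Nodes, $Elements with
tetrahedra (element type 4, physical tag = tissue label) and optional
$ElementData blocks (Ex/Ey/Ez/Enorm) for post-processing in Gmsh.  Any other
element type is rejected by name rather than silently skipped.  Node
coordinates round-trip at full double precision; connectivity and labels
exactly.

NIfTI volumes go through nibabel: integer label volumes round-trip bit-exact;
float field volumes are stored at 32-bit (relative storage error ~1e-7,
documented contract 1e-6).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import (
    ElectrodeCatalog,
    ElectrodeSpec,
    HeadMesh,
    ParcellationVolume,
)
from .roi import FieldVolume

__all__ = [
    "write_msh",
    "read_msh",
    "write_parcellation_nifti",
    "read_parcellation_nifti",
    "write_field_nifti",
    "read_field_nifti",
    "write_catalog_tsv",
    "read_catalog_tsv",
]

_ELEMENT_TYPE_NAMES = {
    1: "line",
    2: "triangle",
    3: "quadrangle",
    4: "tetrahedron",
    5: "hexahedron",
    6: "prism",
    7: "pyramid",
    15: "point",
}


# ---------------------------------------------------------------------------
# Gmsh msh


def write_msh(
    path, mesh: HeadMesh, element_data: dict[str, np.ndarray] | None = None
) -> None:
    """ASCII v2.2 writer; one scalar $ElementData block per entry of
    ``element_data`` (values per element, e.g. Ex/Ey/Ez/Enorm)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} {z:.17g}")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(mesh.n_elements))
    for i, (tet, label) in enumerate(zip(mesh.elements, mesh.element_label), start=1):
        n = " ".join(str(v + 1) for v in tet)
        lines.append(f"{i} 4 2 {int(label)} {int(label)} {n}")
    lines.append("$EndElements")
    if element_data:
        for name, values in element_data.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (mesh.n_elements,):
                raise ValueError(
                    f"element data {name!r}: expected {mesh.n_elements} scalars"
                )
            lines += [
                "$ElementData",
                "1",
                f'"{name}"',
                "1",
                "0.0",
                "3",
                "0",
                "1",
                str(mesh.n_elements),
            ]
            lines += [f"{i} {v:.9g}" for i, v in enumerate(values, start=1)]
            lines.append("$EndElementData")
    Path(path).write_text("\n".join(lines) + "\n")


def read_msh(path) -> tuple[HeadMesh, dict[str, np.ndarray]]:
    """Read an ASCII v2.2 mesh; returns (mesh, element_data).  Rejects any
    element type other than tetrahedra, naming the offending type."""
    text = Path(path).read_text().splitlines()
    i = 0

    def expect(tag: str) -> None:
        nonlocal i
        if text[i].strip() != tag:
            raise ValueError(f"{path}: expected {tag!r} at line {i + 1}, got {text[i]!r}")
        i += 1

    expect("$MeshFormat")
    version = text[i].split()[0]
    if not version.startswith("2."):
        raise ValueError(f"{path}: unsupported msh version {version} (need ASCII 2.2)")
    i += 1
    expect("$EndMeshFormat")

    expect("$Nodes")
    n_nodes = int(text[i]); i += 1
    nodes = np.empty((n_nodes, 3))
    id_map: dict[int, int] = {}
    for k in range(n_nodes):
        parts = text[i].split(); i += 1
        id_map[int(parts[0])] = k
        nodes[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
    expect("$EndNodes")

    expect("$Elements")
    n_elem = int(text[i]); i += 1
    elems, labels = [], []
    for _ in range(n_elem):
        parts = text[i].split(); i += 1
        etype = int(parts[1])
        if etype != 4:
            name = _ELEMENT_TYPE_NAMES.get(etype, f"type {etype}")
            raise ValueError(
                f"{path}: unsupported element type {etype} ({name}); "
                f"only tetrahedra are supported"
            )
        ntags = int(parts[2])
        labels.append(int(parts[3]) if ntags >= 1 else 1)
        conn = parts[3 + ntags : 7 + ntags]
        elems.append([id_map[int(c)] for c in conn])
    expect("$EndElements")

    data: dict[str, np.ndarray] = {}
    while i < len(text):
        if text[i].strip() != "$ElementData":
            i += 1
            continue
        i += 1
        n_str = int(text[i]); i += 1
        name = text[i].strip().strip('"'); i += int(n_str)
        n_real = int(text[i]); i += 1
        i += int(n_real)
        n_int = int(text[i]); i += 1
        ints = [int(text[i + k]) for k in range(n_int)]
        i += n_int
        n_vals = ints[2] if len(ints) >= 3 else ints[-1]
        vals = np.empty(n_vals)
        order = np.empty(n_vals, dtype=int)
        for k in range(n_vals):
            p = text[i].split(); i += 1
            order[k] = int(p[0]) - 1
            vals[k] = float(p[1])
        out = np.empty(n_vals)
        out[order] = vals
        data[name] = out
        if text[i].strip() != "$EndElementData":
            raise ValueError(f"{path}: malformed $ElementData block {name!r}")
        i += 1

    mesh = HeadMesh(
        nodes=nodes,
        elements=np.asarray(elems, dtype=np.int64),
        element_label=np.asarray(labels, dtype=np.int64),
    )
    return mesh, data


# ---------------------------------------------------------------------------
# NIfTI


def write_parcellation_nifti(path, parc: ParcellationVolume) -> None:
    """Integer label volume (int16) plus a JSON sidecar with label names and
    region roles (bit-exact label round trip)."""
    img = nib.Nifti1Image(parc.labels.astype(np.int16), parc.affine)
    nib.save(img, str(path))
    sidecar = {
        "lobule_ids": list(parc.lobule_ids),
        "brain_mask_id": parc.brain_mask_id,
        "names": {str(k): v for k, v in parc.names.items()},
    }
    Path(_sidecar_path(path)).write_text(json.dumps(sidecar, indent=1))


def read_parcellation_nifti(path) -> ParcellationVolume:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    sidecar_path = Path(_sidecar_path(path))
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        lobule_ids = tuple(int(i) for i in sc["lobule_ids"])
        brain_mask_id = int(sc["brain_mask_id"])
        names = {int(k): v for k, v in sc["names"].items()}
    else:
        present = sorted(int(v) for v in np.unique(labels) if v != 0)
        brain_mask_id = present[-1]
        lobule_ids = tuple(v for v in present if v != brain_mask_id)
        names = {v: f"region_{v}" for v in present}
    return ParcellationVolume(
        affine=np.asarray(img.affine),
        labels=labels,
        lobule_ids=lobule_ids,
        brain_mask_id=brain_mask_id,
        names=names,
    )


def _sidecar_path(path) -> str:
    s = str(path)
    for suffix in (".nii.gz", ".nii"):
        if s.endswith(suffix):
            return s[: -len(suffix)] + "_labels.json"
    return s + "_labels.json"


def write_field_nifti(path, fieldvol: FieldVolume) -> None:
    """4D float32 volume: components Ex, Ey, Ez, and the validity mask as a
    fourth (0/1) component.  Fields round-trip to ~1e-7 relative (32-bit
    storage; documented tolerance 1e-6)."""
    stack = np.stack(
        [fieldvol.ex, fieldvol.ey, fieldvol.ez, fieldvol.mask.astype(float)], axis=-1
    ).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, fieldvol.affine), str(path))


def read_field_nifti(path) -> FieldVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 4:
        raise ValueError(f"{path}: expected a 4D field volume with 4 components")
    return FieldVolume(
        affine=np.asarray(img.affine),
        ex=data[..., 0],
        ey=data[..., 1],
        ez=data[..., 2],
        mask=data[..., 3] > 0.5,
    )


# ---------------------------------------------------------------------------
# electrode catalogs


def write_catalog_tsv(path, catalog: ElectrodeCatalog) -> None:
    rows = [
        {
            "id": e.id,
            "x": e.center[0],
            "y": e.center[1],
            "z": e.center[2],
            "shape": e.shape,
            "dims": "x".join(f"{d:g}" for d in e.dims),
            "role": e.role,
        }
        for e in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> ElectrodeCatalog:
    df = pd.read_csv(path, sep="\t")
    electrodes = [
        ElectrodeSpec(
            id=str(r["id"]),
            center=(float(r["x"]), float(r["y"]), float(r["z"])),
            shape=str(r["shape"]),
            dims=tuple(float(v) for v in str(r["dims"]).split("x")),
            role=str(r["role"]),
        )
        for _, r in df.iterrows()
    ]
    refs = [e.id for e in electrodes if e.role == "reference"]
    reference_id = refs[0] if refs else electrodes[0].id
    units = np.array([e.center for e in electrodes])
    units /= np.linalg.norm(units, axis=1, keepdims=True)
    dots = np.clip(units @ units.T, -1, 1)
    np.fill_diagonal(dots, -1)
    min_sep = float(np.degrees(np.arccos(dots.max()))) if len(electrodes) > 1 else 180.0
    return ElectrodeCatalog(
        electrodes=electrodes, reference_id=reference_id, min_separation_deg=min_sep
    )
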