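"""Solve the published two-pad and 4x1 high-definition cerebellar montages on
the synthetic five-shell head and print per-lobule field summaries.

Builds the phantom head model, solves the quasistatic current-flow problem
for each montage preset, rasterizes the element fields on the parcellation
grid, and prints the strongest lobule per montage plus the electrode-skin
current densities.  Field strengths are volume-averaged V/m per lobule; the
current density (mA/cm^2) is what safety guidelines bound at the skin.
"""

import numpy as np

import ctdcsim as c
from ctdcsim.fem import FemSystem, TissueModel, make_montage_preset
from ctdcsim.roi import VoxelSampler, current_density, lobule_means, rasterize_field

mesh = c.build_shell_phantom(c.DEFAULT_SHELLS, resolution=8.0, seed=1)
tissues = TissueModel.from_shells(c.DEFAULT_SHELLS)
parc = c.build_parcellation(mesh, voxel_size=2.0)
system = FemSystem(mesh, tissues)
sampler = VoxelSampler(mesh, parc.affine, parc.shape)

for preset in ("celnik", "manto", "hd4x1"):
    montage = make_montage_preset(preset, scalp_radius=mesh.outer_radius)
    solution = system.solve(montage)
    field = rasterize_field(solution, parc.affine, parc.shape, sampler=sampler)
    table = lobule_means(field, parc)

    lobules = table.iloc[:28]
    top = lobules.sort_values("Enorm", ascending=False).head(3)
    anode, anode_ma = next((e, cur) for e, cur in montage.electrodes if cur > 0)
    j = current_density(anode_ma, anode.area_cm2, ndigits=2)
    print(f"\n{preset}: anode {anode_ma:g} mA over {anode.area_cm2:.2f} cm^2 "
          f"-> {j:.2f} mA/cm^2 at the skin")
    for _, row in top.iterrows():
        print(f"  {row['region']:15s} Enorm {row['Enorm']:.3f} V/m "
              f"(Ex {row['Ex']:+.3f}, Ey {row['Ey']:+.3f}, Ez {row['Ez']:+.3f})")
    print(f"  non-cerebellar brain mean Enorm: "
          f"{table.loc[parc.brain_mask_id, 'Enorm']:.3f} V/m")
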