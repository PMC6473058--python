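# ctdcsim

Volume-conductor electric-field modeling and multi-electrode montage
optimization for cerebellar transcranial direct-current stimulation (ctDCS).

Targeting the cerebellum with scalp currents is hard: the structure is deep,
heavily folded, and split into functionally distinct lobules, so a montage
that works for one lobule set (say, the lower-limb lobules VIIb–IX) spills
into others.  This package implements the computational chain a stimulation
modeler needs to reason about that problem quantitatively, end to end and
without imaging data:

1. **Phantom head models** (`ctdcsim.phantom`) — concentric multi-shell
   sphere meshes (scalp/skull/CSF/gray/white, standard isotropic
   conductivities), a 28-lobule wedge parcellation emulating a cerebellar
   atlas in the posterior-inferior octant, and quasi-uniform scalp electrode
   catalogs with a vertex reference.
2. **Analytic oracle** (`ctdcsim.oracle`) — Legendre-series potential for
   point-current injection on concentric shells, the independent check for
   the solver.
3. **FEM solver** (`ctdcsim.fem`) — first-order tetrahedral finite elements
   for the quasistatic current-flow equation ∇·(σ∇Φ) = 0 with Neumann
   current injection at electrode patches; E = −∇Φ per element.  Includes
   the published two-pad ("Celnik", "Manto") and 4×1 high-definition
   montages as presets.
4. **Region statistics** (`ctdcsim.roi`) — rasterization of element fields
   onto 1 mm voxel grids and volume-averaged Ex/Ey/Ez/Enorm per lobule plus
   the pooled non-cerebellar brain (29 regions).
5. **Lead field** (`ctdcsim.leadfield`) — the transfer matrix **b** = LF·**s**
   from electrode currents to region-averaged fields, assembled column by
   column from unit bipolar solves against a common vertex cathode; field
   prediction for arbitrary zero-sum current vectors by superposition.
6. **Montage optimizer** (`ctdcsim.optimize`) — the convex current-steering
   program arg min‖LF·x − b‖² subject to Σx = 0 and Σ|x| ≤ 4 mA (so total
   anodal current ≤ 2 mA), i.e. weighted constrained least squares over the
   candidate electrodes.
7. **Statistics** (`ctdcsim.stats`) — N-way fixed-effects ANOVA of
   voxel-level field values with classical eta-squared effect sizes and
   Bonferroni-corrected post-hoc mean comparisons.
8. **I/O and CLI** (`ctdcsim.fileio`, `ctdcsim.cli`) — Gmsh ASCII v2.2
   meshes with element-data blocks, NIfTI-1 label/field volumes, TSV tables,
   an HDF5 lead-field container, strict YAML run configs, and a `ctdcsim`
   command with `phantom | simulate | extract | leadfield | optimize |
   verify | stats` subcommands.

## Worked example

`examples/02_optimize_montage.py` steers the field toward the right
posterior-inferior lobules (VIIb, VIIIa, VIIIb, IX — the set associated with
ankle function) over a 48-electrode candidate catalog:

```text
residual ||LF.x - b||: 0.0690 (target 0.05 V/m on 4 lobules)
net current -1.70e-16 mA, total |current| 4.000 mA (cap 4), anodal 2.000 mA (<= 2)
active electrodes (|x| > 1% of cap):
  E05   +0.077 mA
  E13   +0.170 mA
  ...
peak predicted field strength: Right_VIIIa (inside the target set)
```

The optimizer spends the full 4 mA budget (2 mA anodal / 2 mA cathodal,
exactly balanced), distributes it over many small-current electrodes rather
than one pad, and the peak predicted field strength lands inside the target
lobule set.  `examples/01_simulate_published_montages.py` solves the three
published montage presets and prints per-lobule field tables along with the
electrode-skin current densities (0.08 mA/cm² for the 25 cm² pads at 2 mA,
0.32 mA/cm² for the 3.14 cm² high-definition disc at 1 mA);
`examples/03_anova_effects.py` runs the ANOVA layer over those simulations.

The same workflow is available from the shell:

```bash
ctdcsim phantom --out-mesh head.msh --out-parc parc.nii.gz --out-catalog cat.tsv
ctdcsim simulate --mesh head.msh --preset celnik --out sol.msh
ctdcsim extract --solution sol.msh --parc parc.nii.gz --out lobules.tsv
ctdcsim leadfield --mesh head.msh --parc parc.nii.gz --catalog cat.tsv --out lf.h5
ctdcsim optimize --lf lf.h5 --out montage.tsv
ctdcsim verify --lf lf.h5 --mesh head.msh --parc parc.nii.gz \
    --catalog cat.tsv --montage montage.tsv --out verify.json
```

## Scope notes

The package models isotropic conductivities on synthetic spherical phantoms.
MRI segmentation, atlas registration to individual anatomy, and cortical
folding are out of scope: real-head workflows exist in dedicated pipelines,
and this package's phantom stages stand in for them so that every downstream
method (solver, lead field, optimizer, statistics) is fully testable.  See
`docs/methods.md` for the model details, numerical choices, and limitations.
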