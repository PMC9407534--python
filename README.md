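# gelshell

Phase-field fracture of thin hydrogel shells of arbitrary curvature, on
triangle surface meshes.

The model combines:

* a **membrane finite-element solver** (constant-strain triangles with a
  plane-stress through-thickness stretch, optional discrete-hinge bending)
  for hyperelastic shells at large deformation;
* a **tension/compression split neo-Hookean hydrogel**
  `W = [(1-K) p^2 + K] W+ + W-` where only the tensile part `W+`
  (stretches > 1, J > 1) is degraded by the damage field `p`
  (`p = 1` intact, `p = 0` broken);
* a **one-term Ogden model** for soft-tissue substrate regions;
* a **vertex-based damage equation on the mesh graph**, discretized with
  cotangent edge weights and barycentric vertex areas:
  `(4 l (1-K) W+/Gc + 1) p_i + 4 l^2 (1/a_i) sum_j w_ij (p_i - p_j) = 1`,
  with irreversibility through a per-element history field;
* a **staggered quasi-static driver** alternating energy minimization over
  displacements with the linear damage solve, plus reaction-force and
  energy bookkeeping per load step.

All quantities are nondimensional.

## Command line

```bash
# bundled desk-scale scenarios:
#   sent, sphere-compression, sphere-shear, fiber-strip, cap-patch
gelshell demo sent --gc 0.002 --out out_sent

# run from a YAML config
gelshell run config.yaml --out results

# write a generated mesh to OFF (+ node-set sidecar JSON)
gelshell generate-mesh fiber-strip -p length=4 -p width=1 \
    -p thickness=0.1 -p n_fibers=4 -p target_h=0.06 --out strip.off

# schema check (lists every problem at once)
gelshell validate-config config.yaml
```

A run writes `record.csv` (per step: load factor, reaction force, energy
split, min p, staggered iteration count), a VTU time series with a `.pvd`
index (point data: `p`, `displacement`; cell data: `effective_stress`,
`W_plus`, `region`), and the fully resolved `config.yaml` so any run can
be reproduced exactly from its output directory.

Example config (see `gelshell.config.demo_config` for complete ones):

```yaml
schema_version: 1
mesh:
  generator: notched_plate
  params: {length: 1.0, width: 1.0, notch_length: 0.3, target_h: 0.03}
materials:
  - {region: default, type: hydrogel, mu: 1.0, chi: 2.17, k_res: 1.0e-4}
phase_field: {ell: 0.05, gc: 2.0e-3}
schedule:
  driven: {set: top, direction: [0, 1, 0], magnitudes: {max: 0.3, steps: 30}}
  fixed: [{set: bottom, components: [0, 1, 2]}]
```

## Package layout

| module | contents |
| --- | --- |
| `gelshell.mesh` | `TriMesh` data model, validation, OFF/OBJ readers |
| `gelshell.vtu` | VTU writer and `.pvd` series index |
| `gelshell.graph` | cotangent weights, vertex areas, graph Laplacian |
| `gelshell.generators` | notched plate, perforated sphere patch, fiber strip, cap-with-patch, icosphere |
| `gelshell.constitutive` | split neo-Hookean and Ogden energies/stresses |
| `gelshell.shell` | membrane kinematics, plane-stress closure, force assembly, hinge bending |
| `gelshell.phasefield` | damage system assembly/solve, history field |
| `gelshell.solver` | staggered stepping, schedules, records |
| `gelshell.run` | config-driven orchestration |
| `gelshell.config`, `gelshell.cli` | schema, demos, command line |
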