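# vcfem

Forward modeling of extracellular potentials in volume conductors at
EEG/ECoG/micro-electrode-array scale: tetrahedral Lagrangian FEM with
resistive, capacitive and dispersive media, electrode–electrolyte interface
boundary conditions (constant-phase-angle pseudocapacitance and charge
transfer), floating recording electrodes, FEM–Fourier transient stimulation,
and an analytical multilayer-sphere series for validation.

## Modules

| module | contents |
| --- | --- |
| `vcfem.meshkit` | `TetMesh` data model, layered-sphere and slab-in-bath fixture generators, red/bisection refinement, submesh extraction, Gmsh MSH 2.2 ASCII I/O, legacy VTK export, quasi-uniform sphere sampling |
| `vcfem.dielectrics` | four-term Cole-Cole dispersion, packaged tissue constants (grey/white matter, CSF, cortical bone, dry skin, saline), complex admittivity `y = sigma + j w eps0 eps_r`, anisotropic conductivity tensors, YAML/JSON overrides |
| `vcfem.interface_models` | CPA pseudocapacitance `K (jw)^-beta`, charge-transfer resistance `RT/(nF j0)`, parallel networks, per-area surface admittance `g + jb`, lumped electrode impedance, cone lateral area |
| `vcfem.fem_core` | P1/P2 stiffness assembly (scalar or tensor admittivity), complex coupled-block formulation, Robin interface terms, floating electrodes via Lagrange multipliers, point monopole/dipole sources, CG/GMRES solves with a zero-mean reference, field evaluation |
| `vcfem.analytic_reference` | concentric-sphere dipole potential (Legendre series with complex admittivities), axial monopole-pair series, relative-difference (RD) metric, FEM-vs-analytic depth/orientation sweeps |
| `vcfem.fourier_pipeline` | waveform synthesis (square/alpha/sine), one-sided FFT decomposition, coefficient pruning, per-frequency FEM solves with capacitive/dispersive material and RC/CPA interface modes, inverse-FFT probe reconstruction |
| `vcfem.cli_app` | `vcfem` command-line entry point with YAML configs |

## CLI

All commands take `--config <yaml>`, `--seed <int>`, `--out <dir>` and are
deterministic for a fixed seed.

```sh
vcfem generate-mesh   --config cfg.yaml --seed 1 --out run/   # MSH 2.2 ASCII
vcfem solve           --config cfg.yaml --seed 1 --out run/   # probes.csv + VTK
vcfem validate-sphere --config cfg.yaml --seed 1 --out run/   # rd.csv (+plot)
vcfem simulate-pulse  --config cfg.yaml --seed 1 --out run/   # waveforms.csv
```

A minimal config for a four-layer head-model validation sweep:

```yaml
mesh:
  kind: sphere
  sphere:
    radii: [0.079, 0.080, 0.085, 0.090]     # brain, CSF, skull, scalp (m)
    edge_length: [0.009, 0.0035, 0.006, 0.007]
    refine_region: {center: [0, 0, 0.0765], radius: 0.012, min_inradius: 3.5e-4}
materials:
  1: {tissue: grey}
  2: {tissue: csf}
  3: {tissue: skull}
  4: {tissue: scalp}
frequency: 1.0e+7
validate_sphere: {depths_mm: [1, 2, 3, 4, 5], orientations: [radial, tangential, 45deg]}
```

See `tests/test_cli_app.py` for slab/pulse configs.

## Notes

- Units are SI throughout (meters, seconds, S/m); configs use meters even
  where the literature quotes cm/um.
- The complex-admittivity problem is assembled in the coupled real-block
  form `[[A_r, -A_j], [A_j, A_r]]`; solves use the equivalent complex
  operator (same residuals, half the memory) and `FemSystem.to_block_operator`
  exposes the doubled real system for verification.
- Pure-Neumann problems are solved in the constants-orthogonal complement
  and reported with a volume-weighted zero-mean reference.
- Robin interfaces and floating electrodes are implemented for P1 elements;
  P2 is available for source/volume validation runs.
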