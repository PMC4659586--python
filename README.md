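# ptmetad

Conformational free-energy analysis with well-tempered parallel-tempering
metadynamics, on analytic model systems with exact ground truth.

Protein kinases switch between active and inactive conformations — the flip
of the conserved DFG motif and the opening of the activation loop — and the
free-energy balance between these states controls, among other things, how
well type II inhibitors such as imatinib can bind.  Mapping such landscapes
requires enhanced sampling: metadynamics biases along a few collective
variables (CVs), parallel tempering over a replica ladder, reconstruction of
the free-energy surface (FES) from the bias, and decomposition of basin free
energies into enthalpy and entropy from their temperature dependence.

`ptmetad` implements that entire analysis chain as a tested library for
people who develop, teach or validate these methods.  Instead of
microsecond-scale solvated-protein simulations it ships analytic model
systems — double wells, entropy pairs with prescribed dH/dS, a periodic
three-dihedral flip, a two-channel (un-)binding topology, and
Gaussian-fluctuation pseudo-proteins — whose basin free energies are known
exactly by quadrature, so every estimator in the pipeline can be checked
against a known answer.

## What is implemented

* **Model systems** (`ptmetad.potentials`) with quadrature oracles in
  `ground_truth`.
* **Sampling** (`ptmetad.sampling`): BAOAB Langevin dynamics and parallel
  tempering with Metropolis swaps
  `(b_i-b_j)(U_i-U_j) + b_i[V_i(s_i)-V_i(s_j)] + b_j[V_j(s_j)-V_j(s_i)]`.
* **Collective variables** (`ptmetad.cvs`): COM distances, the dihedral
  similarity `f = sum_i (1+cos(t_i - t_i^ref))/2` (n at the reference
  conformation, 0 at the antipodal one), and path CVs
  `s = sum i e^(-l D_i) / sum e^(-l D_i)`, `z = -(1/l) ln sum e^(-l D_i)`
  with a Kabsch-superposition MSD metric.
* **Well-tempered metadynamics** (`ptmetad.hills`, `ptmetad.metad`): hill
  heights `w = w0 exp(-V/(k_B (gamma-1) T))`, per-replica hill logs,
  optional well-tempered ensemble (a grown-then-frozen metadynamics bias on
  the potential energy).
* **FES reconstruction** (`ptmetad.fes`): bias integration
  `F = -(gamma/(gamma-1)) V` and time-independent reweighting with
  `w(t) = exp(beta [V(s(t),t) - c(t)])`, reprojection onto arbitrary target
  CVs, basin dG, convergence diagnostics.
* **Thermodynamics** (`ptmetad.thermo`): `dG(T) = dH - T dS` by linear
  regression over the replica ladder, with range-robustness refits.
* **Flexibility** (`ptmetad.flexibility`): windowed RMSF (non-overlapping
  windows, iterative superposition on the window mean) and PCA with
  cross-trajectory projection and explored-area summaries.
* **I/O and CLI** (`ptmetad.io`, `ptmetad.cli`): PLUMED-dialect HILLS and
  COLVAR files (exact round trips), plain-text FES tables, strict YAML
  configs, PDB/DCD export via mdtraj, and a `ptmetad` command with
  `simulate`, `metad`, `ptmetad`, `fes`, `reweight`, `basins`, `thermo`,
  `rmsf`, `pca` and `demo` subcommands.

See `docs/methods.md` for the models, estimators, defaults and limitations.

## Worked example

The end-to-end demo samples the entropy-pair system (two basins, minima
offset 2 kcal/mol, curvature ratio 4, hence an analytic
TdS(305 K) = -(k_B 305/2) ln 4 = -0.42 kcal/mol) with five-replica
parallel-tempering metadynamics at 305-400 K, reconstructs each replica's
FES with both estimators, and fits dG(T):

```sh
ptmetad demo --seed 7 --outdir demo_run
```

prints (about 2.5 minutes on one CPU; abridged):

```json
{
  "system": "entropy_pair (width_ratio 4, delta_e 2 kcal/mol)",
  "delta_g_kcal_mol": {
    "305": 2.3294, "326": 2.4381, "349": 2.5781, "373": 2.4460, "400": 2.5220
  },
  "fit": {
    "delta_h_kcal_mol": 1.8987,
    "t_delta_s_305K_kcal_mol": -0.4907,
    "r_squared": 0.41047
  },
  "analytic_harmonic": {
    "delta_h_kcal_mol": 2.0,
    "t_delta_s_305K_kcal_mol": -0.4201
  },
  "exchange_acceptance": { "0-1": 0.91, "1-2": 0.9, "2-3": 0.9175, "3-4": 0.9113 }
}
```

`delta_g_kcal_mol` are the per-replica basin free-energy differences
(narrow minus wide basin) at each ladder temperature: dG grows with T
because the narrow basin loses entropy.  The linear fit returns the
enthalpic offset (`delta_h`, designed value 2.0, recovered here to
0.10 kcal/mol) and the entropic part at 305 K (`t_delta_s`, analytic
-0.42, recovered to 0.07); the modest R^2 is expected — dG changes by only
~0.2 kcal/mol across this temperature window, comparable to the per-replica
sampling noise, which is exactly why the decomposition leans on the
time-averaged per-replica estimator.  `demo_run/` also contains
the per-replica HILLS files, both FES tables per temperature, and a
`delta_g_vs_T.csv` with the exact quadrature values alongside the sampled
ones.  Repeating the command with the same seed reproduces every numeric
output byte for byte.

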