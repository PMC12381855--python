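# chdamp

**Charge-damped electrostatic embedding (CH-d): preparation and calibration
toolkit for QM/MM interaction-energy analysis.**

`chdamp` is for computational (bio)chemists who evaluate enzyme active-site
electrostatics with a simple electrostatic-embedding scheme: the reacting
moiety (the *reaction kernel*, RK) is treated quantum mechanically while the
surrounding residues enter the calculation only as fixed MM point charges.
That scheme is cheap and engine-agnostic, but it suffers from *electron
spill-out* — with no Pauli repulsion in the embedding, point charges close
to the kernel overpolarize its electron density and short-range interaction
energies are overestimated.

The remedy implemented here attenuates each point charge by a sigmoidal
function of its distance r to the nearest kernel atom:

```
d(r) = 1 / (1 + exp((r − d_c)/d_w)),   d_c = r0/2,   d_w = d_c / ln 100,
q′   = q · (1 − d(r))
```

so a single parameter — the damping range `r0` (Å) — controls the whole
ramp: charges at contact are suppressed to 1/101 of their value, a charge at
`r0/2` is halved, and charges beyond `r0` keep ≥ 100/101 of their value.
The toolkit then *calibrates* `r0` and a post-hoc scaling factor `λ`
(`E_QM ≈ λ·E_CH`) statistically against reference interaction energies:
Pearson r, RMSE and Σ_avg E (per-snapshot energy sums averaged over
snapshots) are computed per damping range, the r0 maximizing Pearson r is
selected, and λ comes from per-snapshot zero-intercept regressions.

What the package provides:

* the damping math and its application to charge sets (`chdamp.damping`);
* structure/charge I/O (PDB, PQR, XYZ + charge table, lossless CSV),
  Gaussian-dialect embedding inputs with trailing point-charge blocks, and
  engine energy parsing (`chdamp.io`);
* kernel carving: environment selection within a cutoff, hydrogen capping of
  severed bonds, residue→point-charge conversion (`chdamp.carving`);
* Coulomb energies and the QM/CH interaction-energy assembly
  (`chdamp.electrostatics`);
* the calibration statistics and the Q_RK-keyed recommendation scheme
  (`chdamp.calibration`);
* a surrogate reference engine and synthetic benchmark generators so the
  whole workflow runs and is testable without a QM engine
  (`chdamp.synthetic`);
* a CLI orchestrating the end-to-end template (`chdamp.cli`).

The toolkit never runs a QM engine itself: it prepares inputs and consumes
engine totals (Gaussian-style logs or CSV energy tables).

## Worked example

Generate a synthetic enzyme-like benchmark (neutral 10-atom kernel, 5
reactant + 5 transition-state snapshots, 40 residues each), run the full
calibration loop with the built-in surrogate engine, and read the report:

```
chdamp synth    -w run --seed 1
chdamp carve    -w run
chdamp prepare  -w run
chdamp engine   -w run
chdamp collate  -w run
chdamp calibrate -w run
```

The last command prints (abridged):

```
state R  (n = 200 pairs)
  Σ_avg E (QM reference):     -52.97 kcal/mol
    r0 [Å]    Σ_avg E      r      RMSE     λ       STD(λ)
      0.00     -57.25   0.9934   0.460   0.962    0.031
      2.00     -57.18   0.9935   0.455   0.963    0.030
      2.50     -56.71   0.9942   0.424   0.971    0.027
      3.00     -55.08   0.9955   0.361   0.995    0.019 *
  selected r0 = 3 Å (max Pearson r); min-RMSE r0 = 3 Å; λ = 0.995
```

Reading it: with plain point-charge embedding (r0 = 0) the summed
interaction energy is overestimated (−57.25 vs the −52.97 kcal/mol
reference) because close, favorably-oriented residues interact too
strongly.  Damping with r0 = 3 Å raises the Pearson correlation
(0.9934 → 0.9955), cuts the RMSE by ~20 % (0.460 → 0.361 kcal/mol) and
moves the energy sum toward the reference; the fitted λ then corrects the
remaining offset.  Repeating the experiment with a charged kernel
(`--q-rk -2`) selects a shorter damping range (2.0 Å): monopole-dominated
interactions are already accurate at long range and aggressive damping only
removes real electrostatics — which is exactly the advisory scheme the
report echoes (neutral kernels: r0 2.5–3.0 Å, λ 1.1–1.3; charged kernels:
r0 ≤ 2.0 Å, λ = 1.0).

For a real system, replace `synth`/`engine` with your own snapshots
(`snapshots/{replica}_{R|TS}.csv` or PQR), a `kernel_selection.txt` of
0-based atom indices, optionally `severed_bonds.txt`, and an `energies.csv`
produced by your QM engine from the inputs `prepare` writes.

Library use mirrors the CLI:

```python
from chdamp import DampingScheme, apply_damping, scan_r0
from chdamp.synthetic import generate_snapshot_set, SurrogateParams

ds = generate_snapshot_set(params=SurrogateParams(seed=1))
result = scan_r0(ds.records, state="R")
print(result.optimal.r0, result.optimal.lam)   # 3.0 0.995...
```

## Documentation

`docs/methods.md` describes the model, the assembly conventions, the
statistics, the surrogate benchmark and its limitations, and every
numerical choice (tolerances, tie-breaks, precision contracts).
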