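# coacervate

Tools for quantifying liquid–liquid phase separation of an oppositely
charged protein/RNA pair (tau + polyU) under cellular conditions, along two
complementary modeling tracks:

- an **analytic lattice track** — Flory–Huggins free energy with a
  Voorn–Overbeek Debye–Hückel electrostatic term — that turns measured
  cloud points into an effective interaction parameter `chi(T)` and a
  thermodynamic decomposition of the driving forces, and
- a **field-theoretic simulation track** — complex-Langevin sampling of
  the exact auxiliary-field representation of discrete charged Gaussian
  chains — that resolves sequence charge patterns and predicts coexistence
  without a mean-field closure.

Modules:

| module | contents |
|---|---|
| `coacervate.sequences` | residue charge model, tau constructs, polyU, FASTA I/O |
| `coacervate.cloudpoint` | turbidity-curve sigmoid fits, cloud-point extraction |
| `coacervate.fhvo` | FH–VO free energy, bitangent binodals, `chi(T)` fitting |
| `coacervate.thermo` | Bjerrum length, `v(T)`/`chi(T)` maps, dH/TdS decomposition |
| `coacervate.fts` | field-theoretic model, complex-Langevin driver, coexistence |
| `coacervate.synthetic_data` | reproducible synthetic turbidity / grids / sequences |
| `coacervate.models` | statsmodels-style Model/Results wrappers for the two fits |
| `coacervate.cli` | `coacervate` command-line entry point |

See `docs/methods.md` for conventions, derivations and numerical choices.

## Worked example

### 1. Cloud points from turbidity curves

Generate two noisy heating-branch turbidity curves and fit them with the
statsmodels-style model object:

```python
from coacervate.synthetic_data import SyntheticSpec, gen_turbidity
from coacervate.models import TurbiditySigmoidModel

spec = SyntheticSpec(truth=[(300.0, 2.0), (303.0, 2.0)], noise_sd=0.01,
                     decay=0.9, seed=7)
curves = gen_turbidity(spec)
res = TurbiditySigmoidModel(curves).fit()
print(res.summary())
```

```
Cloud-point sigmoid fits
==============================================================
label       branch       T_cp (K)     +/-   k (1/K)     +/-
cycle1      heating       300.000   0.020     1.774   0.056
cycle2      heating       302.989   0.017     1.833   0.051
==============================================================
```

### 2. Phase diagram → chi(T) → thermodynamic decomposition

Generate a 12-condition cloud-point grid from a known LCST interaction law,
then recover the law and decompose the driving forces:

```python
from coacervate.synthetic_data import SyntheticSpec, gen_cloudpoint_grid
from coacervate.fhvo import ChiLaw
from coacervate.models import PhaseDiagramModel

spec = SyntheticSpec(truth=ChiLaw(A=1.8, B=-390.0), tau_uM=(10, 25, 50, 100),
                     nacl_mM=(30, 60, 120), noise_sd=0.3, seed=11)
grid = gen_cloudpoint_grid(spec)
fit = PhaseDiagramModel.from_dataframe(grid).fit()
print(fit.summary())
```

```
FH-VO phase-diagram fit: chi(T) = A + B/T
==========================================================
  observations          12
  A (entropic)          +1.7800
  B (enthalpic, K)      -384.13
  R-squared (chi~1/T)   0.9991
  character             LCST-like (B < 0)
==========================================================
  tau_uM  nacl_mM    T_cp_K       chi
    10.0     30.0    299.09    0.4960
    10.0     60.0    303.22    0.5124
    10.0    120.0    308.00    0.5325
    25.0     30.0    293.60    0.4722
    ...
==========================================================
```

Cloud points fall with protein concentration and rise with added salt; the
negative `B` marks heat-induced demixing. The decomposition at 300 K in the
dense phase (water fraction 0.722):

```python
dec = fit.decompose(T=300.0, phi_w=0.722)
print(f"dH_ex = {dec.dH_ex:.2f} kJ/mol, T dS_noncomb = {dec.TdS_noncomb:.2f} kJ/mol")
```

```
dH_ex = 2.31 kJ/mol, T dS_noncomb = 3.21 kJ/mol
```

(truth-law values 2.3 and 3.24): condensation is opposed by a small excess
enthalpy and driven by a larger noncombinatoric entropy gain per monomer.

### 3. Field-theoretic simulation

Build a charge-balanced tau/polyU model and sample the osmotic pressure by
complex Langevin (a desk-scale N = 20 run; production settings in
`docs/methods.md`):

```python
from coacervate.sequences import load_tau, make_polyU, ChargedSequence
from coacervate.fts import build_model, run_cl, neutral_fractions

tau = load_tau("tau187")
print(f"{tau.name}: N = {tau.N}, net charge = {tau.q_net:+d}")
print("fractions:", neutral_fractions([tau, make_polyU(tau.N)]))

zc = tuple(1 if i % 2 == 0 else 0 for i in range(20))
pc = ChargedSequence("".join("K" if z else "G" for z in zc), zc, "pc")
m = build_model([pc, make_polyU(20)], B=0.294, E=4.92, C=0.015,
                L=16.0, M=16, dt=0.01, seed=3)
traj = run_cl(m, steps=800, seed=3, sample_every=10, pressure_every=2)
print("Pi R0^3 = %.5f +/- %.5f" % traj.mean_se("Pi_re"))
```

```
tau187: N = 187, net charge = +9
charge-matched chain fractions: tau 0.954, polyU 0.046
CL pressure: Pi R0^3 = 0.00451 +/- 0.00256
```

`find_coexistence` turns a density scan of `(C, mu, Pi)` samples into
binodal densities; `save_state`/`load_state` checkpoint trajectories to
HDF5.

### Command line

```sh
coacervate thermo decompose --source fhvo
coacervate simdata grid --noise 0.3 --seed 11 --out grid.csv
coacervate fhvo fit-chi grid.csv
coacervate fhvo binodal --chi-a 1.8 --chi-b -390 --axis nacl --fixed 50
coacervate fts run --length 20 --charge 10 --E 100 --C 0.015 --steps 2000
```

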