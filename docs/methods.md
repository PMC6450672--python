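# Methods

This note records the modeling conventions, derivations and numerical
choices behind the package, in enough detail to reproduce every computed
quantity. Symbols: `T` temperature (K), `phi_i` volume fraction of species
`i`, `N_i` degree of polymerization, `sigma_i` average charge per monomer,
`chi` the Flory interaction parameter, `l_B` the Bjerrum length, `b` the
statistical segment length (4 A throughout), `R` the gas constant, `k_B`
Boltzmann's constant.

## 1. Charge model (`coacervate.sequences`)

Both analysis tracks share one integer charge assignment at neutral pH:
aspartate and glutamate carry -1, lysine and arginine +1, all other
residues — including histidine and the chain termini — are neutral. PolyU
RNA is a fully charged polyanion, one negative charge per nucleotide
(monomer mass 306 Da; chain lengths from molar mass are floored).
Phosphoserine carries -2.

A Henderson–Hasselbalch estimate with fractional side-chain and terminal
charges is provided for comparison with commonly quoted per-molecule
charges, but it never enters the models. The bundled tau constructs are the
N-terminally truncated 187-residue 4R fragment (with the C291S
substitution), the same fragment with its 20-residue expression tag, and a
114-residue sub-fragment. Integer counting gives net charges +9 (187-mer)
and +10 (207-mer); either reproduces the composition rule of §4.

Charge matching: at a 1:1 charge ratio the nucleotide concentration equals
`q_tau [tau]`, so the matched RNA mass concentration is
`[tau](uM) x q_tau x 306 x 1e-3` ug/mL.

## 2. Cloud points from turbidity (`coacervate.cloudpoint`)

Heating-branch absorbance traces (500 nm) are min–max normalized per curve
— which removes slow amplitude decay across thermal cycles by construction
— and fitted by unweighted least squares with the logistic sigmoid

    turbidity(T) = 1 / (1 + exp(-k (T - T_cp))),

so the fitted curve crosses 1/2 at `T_cp` exactly. Initial guesses: `T_cp`
from the first 0.5-crossing by linear interpolation, `k = 4/(T90 - T10)`.
Cooling branches are fitted but kept separate (nucleation hysteresis). A
non-positive optimal `k` is reported in the forward parameterization with
an `inverted` flag.

Known bias: min–max normalization of noisy data compresses the amplitude
(the observed extrema exceed [0, 1]), which biases `k` low by roughly
`4 x noise x k`; `T_cp` is unaffected. Similarly, a transition whose tails
are not resolved inside the temperature window biases `T_cp` slightly
toward the window center.

## 3. FH-VO lattice model (`coacervate.fhvo`)

The five-species mixture (tau, RNA, Na+, Cl-, water) has mixing free energy
per lattice site

    f = sum_i (phi_i/N_i) ln phi_i - alpha [sum_i sigma_i phi_i]^{3/2}
        + sum_{i<j} chi_ij phi_i phi_j,

with Debye–Hückel strength `alpha(T) = (2/3) sqrt(pi) (l_B/l_w)^{3/2}`,
lattice length `l_w = (1e-3/(c_w N_A))^{1/3} = 0.3103 nm` from the molarity
of water `c_w = 55.56 M`, and `l_B = e^2/(4 pi eps_0 eps_r k_B T)` with
`eps_r = 80` taken temperature-independent. At 300 K, `l_B = 0.696 nm` and
`alpha = 3.97`. A single adjustable `chi` acts on the polymer–water pairs.

Composition rules. With the 207-site tau construct of charge +11 and
charge-matched RNA, `[tau]` in uM maps to volume fractions as
`phi_tau = [tau] N_tau / c_w`, `phi_RNA = [tau] q_tau / c_w`, and
`phi_salt = ([NaCl] + 20 mM buffer)/c_w` split equally between the ions.
The polymer is one effective component with fixed internal split
tau:RNA = `N_tau : q_tau`, so at fixed salt and temperature `f` is a
function of the total polymer fraction `phi` alone.

Binodal construction. Coexisting compositions `(phi_1, phi_2)` solve the
common-tangent (bitangent) system `f'(phi_1) = f'(phi_2)` and
`f(phi_1) - phi_1 f'(phi_1) = f(phi_2) - phi_2 f'(phi_2)`. The production
path is a damped Newton iteration in `(ln phi_1, ln phi_2)` with the
analytic Jacobian, seeded from the spinodal interval (sign changes of
`f''` on a log grid). An independent oracle — lower convex envelope on a
dense log grid followed by tangent iteration — cross-checks every result
(agreement within 1e-6 in `phi` is asserted in tests, together with the
closed-form neutral-FH critical point `chi_c = (1 + 1/sqrt(N))^2 / 2`,
`phi_c = 1/(1 + sqrt(N))`).

chi fitting. For each measured cloud point the dilute composition is
pinned at the experimental `phi_1*`; the equal-intercept condition is then
*linear* in `chi`, reducing the fit to a one-dimensional root search in
`phi_2` (solved by bracketing + Brent), after which the full bitangent is
recomputed as verification. The `(T_cp, chi)` points are regressed as
`chi(T) = A + B/T` by linear least squares in `1/T`. Heat-induced demixing
(LCST) corresponds to `B < 0`. Cloud-point prediction inverts the
construction: solve `chi_required(T) = chi_law(T)` for `T`.

## 4. Field-theoretic simulation (`coacervate.fts`)

Particle model: discrete Gaussian chains with per-monomer integer charges,
contact excluded volume `v`, Coulomb interactions of strength `l_B`, and
unit-normalized Gaussian smearing `Gamma` of every monomer and ion
(spectral form `exp(-k^2 b^2/12)`). All lengths are in units of
`R0 = b/sqrt(6)` (so the ideal-chain gyration radius is `R0 N^{1/2}`), and
the state is set by `B = v/R0^3`, `E = 4 pi l_B/R0`, and the monomer
density `C = rho R0^3`. Salt in mM converts to a dimensionless ion density
via `N_A R0^3` (120 mM -> 3.1e-4). Chain fractions follow from global
charge neutrality; for a polycation of net charge `q` with equal-length
fully charged RNA this gives `phi_tau = N/(N + q)` — 0.954 for either tau
construct. Residual polymer charge is absorbed by counter-ions; if that is
impossible the model is rejected.

Exact field transform: two complex auxiliary fields, `w` (excluded volume)
and `phi` (electrostatics), with Hamiltonian

    H = 1/(2B) int w^2 + 1/(2E) int |grad phi|^2 - sum_l n_l ln Q_l,

the sum running over chain types and the two point-ion species. A monomer
of charge `z` sees `psi_z = i Gamma*w + i z Gamma*phi`; the imaginary
electrostatic coupling is forced by the sign of the Coulomb interaction
(like charges must repel after the Gaussian integration). Single-chain
partition functions come from the Chapman–Kolmogorov recursion
`q_{j+1} = exp(-psi_{z_{j+1}}) x (bond kernel * q_j)` with
`q_0 = exp(-psi_{z_0})` and `Q = (1/V) int q_{N-1}`; the bond kernel is
the normalized Gaussian `(3/2 pi b^2)^{3/2} exp(-3 r^2/2 b^2)` applied
spectrally (`exp(-k^2)` in R0 units). Zero fields give `Q = 1` exactly;
a uniform field `c` gives `Q = exp(-N c)`.

Operators. Chemical potential: `mu_l = ln(C phi_l / N_l) - ln Q_l`.
Density: `rho_j = (n_l / V Q_l) q_j qdag_j exp(+psi_j)` summed over
monomers, with the backward propagator streamed; its spatial mean equals
`C` plus ion densities as an operator identity. Pressure: derived from
`Pi = d(ln Z)/dV` by rescaling positions at fixed fields —

    Pi = (chain + ion number density) - (1/V) (1/2B) int w^2
         - (1/3V) (1/2E) int |grad phi|^2 + sum_l (n_l/V) d ln Q_l/d ln V,

the last term evaluated by a central finite difference of `ln Q` on
kernels with `k^2` scaled by `exp(-+2 eps/3)` (`eps = 1e-5`). At the
homogeneous saddle this reproduces the mean-field `Pi = C/N + B C^2/2`
exactly. Under fluctuating sampling a Gaussian-reference counterterm
`M^3/(2V) + (M^3 - 1)/(6V)` must be added (the Hubbard–Stratonovich
identity divides out normalized Gaussian measures whose widths are
volume-dependent); it exactly cancels the equipartition part of the
quadratic operator terms and is applied automatically inside `run_cl`.

Complex Langevin sampling. Exponential time differencing with the linear
coefficients from the Gaussian part of H (`a_w = lambda/B`,
`a_phi(k) = lambda k^2/E`), real Gaussian noise with the *exact* discrete
Ornstein–Uhlenbeck variance `lambda (1 - exp(-2 a dt))/(a dV)` (the naive
`2 lambda dt/dV` leaves an `O(a dt)` bias in the field variance, which
visibly shifts the pressure), applied spectrally for the k-dependent `phi`
relaxation. The `phi` zero mode is gauge-fixed to zero. `dt = 0.01` and
`lambda_w = lambda_phi = 1` by default. Trajectories are bitwise
reproducible from one integer seed (counter-based Philox generator).
Observables are recorded along the trajectory; means use block averaging
(10 blocks) after an automatic equilibration cutoff (marginal-standard-
error rule on Re H, at least 20% discarded). Divergent trajectories abort
with the step index and are restarted from a perturbed substream; if most
attempts diverge a smaller `dt` is suggested. Note that the sampled `mu`
exceeds the mean-field value by the physical one-loop self-energy
`~ (B N/2)(Gamma*Gamma)(0)`; pressure is the cleaner mean-field check.

Phase coexistence. Samples `(C, mu, Pi)` along a density scan are
classified by the van-der-Waals loop of `mu(C)`: the dilute branch ends at
the first local maximum, the concentrated branch starts at the last local
minimum. Each stable branch's `Pi(mu)` is interpolated and the crossing
`mu*` gives the coexisting densities `(rho_I, rho_II)` by inverse
interpolation. A monotone `mu(C)` (single phase) or non-overlapping
branches (unsampled gap) return no coexistence rather than a fabricated
point.

## 5. Temperature maps and decomposition (`coacervate.thermo`)

The lattice track sees temperature through `chi(T) = eps_s + eps_H/T`; the
field track through `l_B ~ 1/T` and an empirical excluded volume
`v(T) = -v0 (1 - theta/T)` (LCST form: the solvent turns poor above
`theta`). The two are linked by the second-virial relation
`v = b^3 (1 - 2 chi)`, so `(v0, theta)` implies
`eps_s = (1 + v0)/2`, `eps_H = -v0 theta/2`.

From the noncombinatoric free energy `Delta G_mix = R T n chi phi_w`, the
*phase separation* quantities (negated mixing quantities) per mole of
monomer are

    Delta H^ex = -R phi_w eps_H,
    T Delta S^noncomb = +R T phi_w eps_s,

evaluated at `T = 300 K` and a representative dense-phase water fraction
`phi_w = 0.722`. With the default parameterizations:

| source | eps_s | eps_H (K) | Delta H^ex | T Delta S^noncomb |
|---|---|---|---|---|
| field-theory map (v0 = 0.25 b^3, theta = 309 K) | 0.625 | -38.625 | 0.23 | 1.1 |
| lattice-model law (chi = 1.8 - 390/T) | 1.8 | -390 | 2.3 | 3.24 |

(kJ/mol monomer; both positive `Delta H^ex` and larger `T Delta S^noncomb`
mean entropy-driven, enthalpically opposed association on top of the
electrostatic driving force.)

Precision note: with CODATA constants, `l_B/b` is 1.741 at 300 K and 1.782
at 293 K; the conventionally quoted 1.75 and 1.79 are roundings one unit
high in the last digit. Tests assert the computed values within 0.02 b and
the nanometer value (0.70 nm at 300 K) exactly at two decimals.

## 6. Synthetic data (`coacervate.synthetic_data`)

Turbidity: logistic sigmoids plus homoscedastic Gaussian noise on the
normalized signal, with an optional per-cycle amplitude factor in (0, 1]
mimicking RNA degradation across thermal cycles. Cloud-point grids: exact
dilute-branch cloud points from a chosen LCST `chi(T)` through the full
FH-VO forward model, plus Gaussian noise on `T_cp`; compositions that are
single-phase at every temperature in range are marked missing (NaN), never
fabricated. Sequences: random chains with exact net charge and a
`blockiness` parameter in [0, 1] interpolating between a random shuffle
and fully segregated charge blocks at identical composition. All
generators are bitwise reproducible from their seed.

## 7. Numerical defaults

- Lattice: log-spaced `phi` grids down to 1e-12 (the dilute branch is
  steep in `ln phi`); Newton tolerances 1e-12; hull oracle on 2000-point
  grids with 60 tangent iterations.
- FTS: pseudo-spectral operations on a periodic mesh, defaults
  `L = 34 R0`, `M = 32`, scaled down to `M = 16` and truncated chains for
  desk-scale tests.
- Fits: `scipy.optimize.curve_fit` (sigmoids), `numpy.linalg.lstsq`
  (chi law), Brent bracketing for scalar roots.
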